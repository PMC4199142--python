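"""AFM height-image morphometry of beaded microfibrils.

Fibrillin microfibrils imaged by atomic force microscopy appear as
"beads on a string": chains of roughly radially symmetric height bumps
with a characteristic bead-to-bead repeat (periodicity) near 56 nm.
This module turns a raw AFM height raster into per-chain morphometry:

1. per-scanline baseline compensation (``flatten_scanlines``),
2. masking of large surface-contamination artifacts (``mask_artifacts``),
3. a second compensation pass that ignores masked pixels,
4. bead detection with sub-pixel centroid refinement (``detect_beads``),
5. greedy linking of beads into chains (``link_chains``),
6. periodicity / length measurement (``measure``).

``analyze_image`` chains the steps with a single parameter set.
All physical coordinates are nanometres; ``x`` is the column axis and
``y`` the row axis, origin at the top-left pixel centre.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = [
    "HeightImage",
    "BeadChain",
    "MorphometryParams",
    "MorphometryResult",
    "flatten_scanlines",
    "mask_artifacts",
    "invert_contrast",
    "detect_beads",
    "link_chains",
    "measure",
    "analyze_image",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class HeightImage:
    """A 2-D height raster with a physical pixel scale.

    Parameters
    ----------
    values
        Height raster (arbitrary height units), row-major, origin top-left.
    pixel_scale
        Physical size of one pixel in nanometres.
    mask
        Optional boolean raster of *excluded* pixels (True = excluded),
        same shape as ``values``.
    """

    values: np.ndarray
    pixel_scale: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("height raster must be a non-empty 2-D array")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive (nm per pixel)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- I/O ---------------------------------------------------------------- #

    def to_text(self, path: str | Path) -> None:
        """Write the raster as a whitespace-delimited text matrix.

        The pixel scale goes in a ``# pixel_scale_nm`` header comment.
        """
        np.savetxt(path, self.values, header=f"pixel_scale_nm {self.pixel_scale}")

    @classmethod
    def from_text(cls, path: str | Path, pixel_scale: float | None = None) -> "HeightImage":
        path = Path(path)
        if pixel_scale is None:
            with open(path) as fh:
                first = fh.readline()
            if "pixel_scale_nm" in first:
                pixel_scale = float(first.split()[-1])
            else:
                raise ValueError("pixel_scale not given and no header comment found")
        return cls(np.loadtxt(path), pixel_scale)

    def to_tiff(self, path: str | Path) -> None:
        """Write a 16-bit grayscale TIFF plus a JSON sidecar.

        Heights are linearly rescaled into the uint16 range; the affine
        (offset, factor) and the pixel scale go in ``<path>.json`` so the
        float raster round-trips.
        """
        import tifffile

        lo = float(self.values.min())
        hi = float(self.values.max())
        factor = (hi - lo) / 65535.0 if hi > lo else 1.0
        scaled = np.round((self.values - lo) / factor).astype(np.uint16)
        tifffile.imwrite(str(path), scaled)
        meta = {"pixel_scale_nm": self.pixel_scale, "offset": lo, "factor": factor}
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_scale: float | None = None) -> "HeightImage":
        import tifffile

        raw = tifffile.imread(str(path)).astype(float)
        sidecar = Path(str(path) + ".json")
        offset, factor = 0.0, 1.0
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            offset = meta.get("offset", 0.0)
            factor = meta.get("factor", 1.0)
            pixel_scale = pixel_scale or meta.get("pixel_scale_nm")
        if pixel_scale is None:
            raise ValueError("pixel_scale not given and no sidecar found")
        return cls(raw * factor + offset, float(pixel_scale))


@dataclass
class BeadChain:
    """Ordered bead centroids of one microfibril.

    ``repeats`` are the Euclidean distances (nm) between consecutive
    centroids; a reportable chain has at least two beads.
    """

    chain_id: int
    x_nm: np.ndarray
    y_nm: np.ndarray

    def __post_init__(self) -> None:
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if self.x_nm.shape != self.y_nm.shape or self.x_nm.ndim != 1:
            raise ValueError("x_nm and y_nm must be 1-D arrays of equal length")

    @property
    def bead_count(self) -> int:
        return self.x_nm.size

    @property
    def repeats(self) -> np.ndarray:
        return np.hypot(np.diff(self.x_nm), np.diff(self.y_nm))


@dataclass
class MorphometryResult:
    """Pooled morphometry of one image: per-chain lengths and periodicities."""

    chains: list[BeadChain]
    pixel_scale: float
    provenance: dict = field(default_factory=dict)

    @property
    def bead_counts(self) -> np.ndarray:
        return np.array([c.bead_count for c in self.chains], dtype=int)

    @property
    def periodicities(self) -> np.ndarray:
        """All bead-to-bead distances pooled across chains (nm)."""
        if not self.chains:
            return np.empty(0)
        return np.concatenate([c.repeats for c in self.chains])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chains:
            for i, (x, y) in enumerate(zip(c.x_nm, c.y_nm)):
                rows.append((c.chain_id, i, x, y))
        return pd.DataFrame(rows, columns=["chain_id", "bead_idx", "x_nm", "y_nm"])


# --------------------------------------------------------------------------- #
# scanline compensation
# --------------------------------------------------------------------------- #

def _robust_sigma(values: np.ndarray) -> float:
    """1.4826 * median absolute deviation — Gaussian-consistent scale."""
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def flatten_scanlines(img: HeightImage, order: int = 1) -> HeightImage:
    """Subtract a per-row baseline ("line-by-line compensation").

    Scanning-probe images carry row-wise offsets and tilts from the
    raster scan.  ``order=0`` removes the per-row median; ``order=1``
    fits a robust straight line per row (pixels within 3 robust sigma of
    the row median, so beads do not drag the baseline) and removes it.
    Masked pixels are excluded from the baseline estimate.  Output rows
    have median ~0.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    v = img.values
    if v.shape[1] < order + 1:
        raise ValueError(f"rows have {v.shape[1]} pixels; need more than {order}")
    excluded = img.mask if img.mask is not None else np.zeros(v.shape, bool)
    vv = np.where(excluded, np.nan, v)
    # rows with every pixel masked fall back to the raw row
    all_nan = np.all(np.isnan(vv), axis=1)
    vv[all_nan] = v[all_nan]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(vv, axis=1, keepdims=True)
        if order == 0:
            baseline = np.broadcast_to(row_med, v.shape)
        else:
            mad = np.nanmedian(np.abs(vv - row_med), axis=1, keepdims=True)
            tol = 3 * 1.4826 * mad
            inlier = np.abs(vv - row_med) <= np.maximum(tol, 1e-12)
            inlier &= ~np.isnan(vv)
            # weighted least squares per row, closed form
            x = np.arange(v.shape[1], dtype=float)[None, :]
            w = inlier.astype(float)
            y = np.where(inlier, v, 0.0)
            sw = w.sum(axis=1)
            sw = np.where(sw < 2, np.nan, sw)
            sx = (w * x).sum(axis=1)
            sy = y.sum(axis=1)
            sxx = (w * x * x).sum(axis=1)
            sxy = (w * x * y).sum(axis=1)
            denom = sw * sxx - sx * sx
            slope = np.where(np.abs(denom) > 1e-12, (sw * sxy - sx * sy) / denom, 0.0)
            icept = (sy - slope * sx) / sw
            slope = np.nan_to_num(slope)
            icept = np.nan_to_num(icept, nan=0.0)
            baseline = icept[:, None] + slope[:, None] * x
        out = v - baseline
        # pin the row medians (of unmasked pixels) to zero exactly
        resid_med = np.nanmedian(np.where(excluded, np.nan, out), axis=1, keepdims=True)
        resid_med = np.nan_to_num(resid_med)
    out = out - resid_med
    return HeightImage(out, img.pixel_scale, img.mask)


# --------------------------------------------------------------------------- #
# artifact masking
# --------------------------------------------------------------------------- #

def mask_artifacts(
    img: HeightImage,
    z_threshold: float = 4.0,
    min_blob_area: int = 200,
    dilation: int = 2,
) -> np.ndarray:
    """Flag large high blobs (surface contamination) for exclusion.

    A pixel blob is an artifact when its height exceeds
    ``median + z_threshold * robust sigma`` *and* its connected area
    exceeds ``min_blob_area`` pixels — i.e. it is far larger than a
    bead.  The returned boolean mask (True = excluded) is dilated by
    ``dilation`` pixels to cover blob skirts.
    """
    if not z_threshold > 0:
        raise ValueError("z_threshold must be positive")
    v = img.values
    med = float(np.median(v))
    sig = _robust_sigma(v)
    # a zero-spread (saturated/constant) image is entirely unusable
    high = v > med + z_threshold * sig if sig > 0 else v >= med
    labels, n = ndimage.label(high)
    if n == 0:
        return np.zeros(v.shape, bool)
    areas = ndimage.sum_labels(np.ones_like(v), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas > min_blob_area) + 1
    mask = np.isin(labels, keep)
    if dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilation)
    return mask


def invert_contrast(img: HeightImage) -> HeightImage:
    """Negate heights about the image median (dark beads on light ground).

    Positions of extrema are unchanged; applying it twice restores the
    original raster.
    """
    med = float(np.median(img.values))
    return HeightImage(2.0 * med - img.values, img.pixel_scale, img.mask)


# --------------------------------------------------------------------------- #
# bead detection
# --------------------------------------------------------------------------- #

def detect_beads(
    img: HeightImage,
    mask: np.ndarray | None = None,
    smoothing_sigma: float = 5.0,
    min_prominence: float | None = None,
    min_separation: float = 30.0,
    polarity: str = "max",
) -> pd.DataFrame:
    """Detect bead centroids as qualifying local maxima.

    The raster is Gaussian-smoothed (``smoothing_sigma`` in nm), and
    3x3-neighbourhood local maxima outside the mask whose height above
    the smoothed-image median is at least ``min_prominence`` are kept.
    Peaks closer than ``min_separation`` (nm) are suppressed greedily in
    order of decreasing height (ties broken row-major).  Each kept peak
    is refined to a sub-pixel centroid by the intensity-weighted centre
    of mass of the positive part of its 5x5 neighbourhood.

    ``min_prominence=None`` uses 5 robust sigma of the smoothed raster
    (with a floor of 2% of the peak height for noise-free rasters).
    Maxima within two smoothing sigma of the frame edge are ignored.
    ``polarity="min"`` detects beads as height minima (inverted display).

    Returns a DataFrame with columns ``x_nm, y_nm, row, col, height``
    sorted by descending peak height.
    """
    if polarity not in ("max", "min"):
        raise ValueError("polarity must be 'max' or 'min'")
    scale = img.pixel_scale
    if min_separation < 2 * scale:
        raise ValueError("min_separation must be at least two pixels")
    if smoothing_sigma < scale:
        warnings.warn(
            "smoothing_sigma below one pixel; clamping to one pixel", stacklevel=2
        )
        smoothing_sigma = scale

    excluded = np.zeros(img.shape, bool)
    if img.mask is not None:
        excluded |= img.mask
    if mask is not None:
        excluded |= np.asarray(mask, bool)

    work = img.values if polarity == "max" else 2.0 * np.median(img.values) - img.values
    med = float(np.median(work[~excluded])) if not excluded.all() else float(np.median(work))
    filled = np.where(excluded, med, work)
    smooth = ndimage.gaussian_filter(filled, sigma=smoothing_sigma / scale)
    height = smooth - float(np.median(smooth))
    if min_prominence is None:
        # noise floor plus a 2%-of-peak floor for noise-free rasters
        min_prominence = max(5.0 * _robust_sigma(height), 0.02 * height.max())
        if min_prominence <= 0:
            return pd.DataFrame(columns=["x_nm", "y_nm", "row", "col", "height"])

    is_peak = (height == ndimage.maximum_filter(height, size=3)) & ~excluded
    is_peak &= height >= min_prominence
    # smoothing at the frame edge averages fewer independent pixels, so
    # border maxima are unreliable; exclude a 2-sigma rim
    border = int(np.ceil(2 * smoothing_sigma / scale))
    if border > 0:
        is_peak[:border, :] = False
        is_peak[-border:, :] = False
        is_peak[:, :border] = False
        is_peak[:, -border:] = False
    rows, cols = np.nonzero(is_peak)
    if rows.size == 0:
        return pd.DataFrame(columns=["x_nm", "y_nm", "row", "col", "height"])

    h = height[rows, cols]
    order = np.lexsort((cols, rows, -h))  # height desc, then row-major
    rows, cols, h = rows[order], cols[order], h[order]

    sep_px = min_separation / scale
    kept: list[int] = []
    kept_rc = np.empty((0, 2))
    for i in range(rows.size):
        rc = np.array([rows[i], cols[i]], float)
        if kept and np.min(np.hypot(*(kept_rc - rc).T)) < sep_px:
            continue
        kept.append(i)
        kept_rc = np.vstack([kept_rc, rc])

    out = []
    nr, nc = img.shape
    for i in kept:
        r, c = int(rows[i]), int(cols[i])
        r0, r1 = max(r - 2, 0), min(r + 3, nr)
        c0, c1 = max(c - 2, 0), min(c + 3, nc)
        win = np.clip(height[r0:r1, c0:c1], 0.0, None)
        win = np.where(excluded[r0:r1, c0:c1], 0.0, win)
        total = win.sum()
        if total <= 0:
            rr, cc = float(r), float(c)
        else:
            gr, gc = np.mgrid[r0:r1, c0:c1]
            rr = float((win * gr).sum() / total)
            cc = float((win * gc).sum() / total)
        out.append((cc * scale, rr * scale, rr, cc, float(h[i])))
    return pd.DataFrame(out, columns=["x_nm", "y_nm", "row", "col", "height"])


# --------------------------------------------------------------------------- #
# chain linking
# --------------------------------------------------------------------------- #

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _turn_ok(p_prev, p_mid, p_new, max_turn_deg: float) -> bool:
    u = p_mid - p_prev
    v = p_new - p_mid
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) <= max_turn_deg + 1e-9


def link_chains(
    beads: pd.DataFrame,
    max_link: float = 125.0,
    max_turn: float = 60.0,
) -> list[BeadChain]:
    """Greedily link bead centroids into chains (paths).

    Candidate links are bead pairs within ``max_link`` nm, admitted in
    order of increasing distance (ties broken by smaller bead index).  A
    link is accepted only if neither bead already has two links, it does
    not close a cycle, and the turn angle it makes with any existing
    link at either endpoint is at most ``max_turn`` degrees.  Beads left
    unlinked are discarded; each chain is returned ordered end-to-end.
    """
    if not max_link > 0:
        raise ValueError("max_link must be positive")
    pts = beads[["x_nm", "y_nm"]].to_numpy(float)
    n = len(pts)
    if n < 2:
        return []
    tree = cKDTree(pts)
    pairs = sorted(tree.query_pairs(max_link))
    dists = [float(np.linalg.norm(pts[i] - pts[j])) for i, j in pairs]
    order = sorted(range(len(pairs)), key=lambda k: (dists[k], pairs[k]))

    neigh: list[list[int]] = [[] for _ in range(n)]
    uf = _UnionFind(n)
    for k in order:
        i, j = pairs[k]
        if len(neigh[i]) >= 2 or len(neigh[j]) >= 2:
            continue
        if uf.find(i) == uf.find(j):
            continue  # would close a cycle
        ok = all(_turn_ok(pts[a], pts[i], pts[j], max_turn) for a in neigh[i])
        ok = ok and all(_turn_ok(pts[a], pts[j], pts[i], max_turn) for a in neigh[j])
        if not ok:
            continue
        neigh[i].append(j)
        neigh[j].append(i)
        uf.union(i, j)

    chains: list[BeadChain] = []
    visited = np.zeros(n, bool)
    endpoints = sorted(i for i in range(n) if len(neigh[i]) == 1)
    cid = 0
    for start in endpoints:
        if visited[start]:
            continue
        path = [start]
        visited[start] = True
        cur, prev = start, -1
        while True:
            nxt = [b for b in neigh[cur] if b != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited[cur] = True
            path.append(cur)
        chains.append(BeadChain(cid, pts[path, 0], pts[path, 1]))
        cid += 1
    return chains


# --------------------------------------------------------------------------- #
# measurement
# --------------------------------------------------------------------------- #

def measure(
    chains: list[BeadChain],
    pixel_scale: float,
    provenance: dict | None = None,
) -> MorphometryResult:
    """Pool periodicities (nm) and lengths (beads per chain).

    Periodicity is the Euclidean distance between consecutive centroids;
    length is the bead count (the repeat count is one less).  Chains
    with fewer than two beads are excluded and logged.
    """
    kept = []
    for c in chains:
        if c.bead_count < 2:
            log.info("chain %d has %d bead(s); excluded", c.chain_id, c.bead_count)
            continue
        kept.append(c)
    return MorphometryResult(kept, pixel_scale, provenance or {})


# --------------------------------------------------------------------------- #
# end-to-end pipeline
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class MorphometryParams:
    """Parameter set for ``analyze_image``.

    Defaults assume beads of ~10 nm radius with repeats of 30-120 nm:
    smoothing at half the bead radius, a minimum peak separation below
    the smallest plausible repeat, and a link ceiling just above the
    largest plausible repeat.
    """

    flatten_order: int = 1
    z_threshold: float = 4.0
    min_blob_area: int = 200
    smoothing_sigma: float = 5.0
    min_prominence: float | None = None
    min_separation: float = 30.0
    max_link: float = 125.0
    max_turn: float = 60.0
    polarity: str = "max"


def analyze_image(
    img: HeightImage,
    params: MorphometryParams = MorphometryParams(),
) -> MorphometryResult:
    """Run the full morphometry pipeline on one height image.

    Flatten, identify artifacts, re-apply the compensation with artifact
    pixels excluded from the baseline, detect beads, link them into
    chains and measure periodicity and length.
    """
    flat = flatten_scanlines(img, params.flatten_order)
    art = mask_artifacts(flat, params.z_threshold, params.min_blob_area)
    flat2 = flatten_scanlines(
        HeightImage(img.values, img.pixel_scale, art), params.flatten_order
    )
    beads = detect_beads(
        flat2,
        smoothing_sigma=params.smoothing_sigma,
        min_prominence=params.min_prominence,
        min_separation=params.min_separation,
        polarity=params.polarity,
    )
    chains = link_chains(beads, params.max_link, params.max_turn)
    return measure(chains, img.pixel_scale, {"n_beads_detected": len(beads)})
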