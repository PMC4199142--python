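"""Synthetic-data generation with ground truth.

Every downstream stage is validated against data this module fabricates:

* periodicity samples drawn from truncated Lorentzian (Cauchy) mixtures
  emulating a healthy population (single peak at 56 nm), a damaged one
  (two resting-periodicity populations at 51 and 73 nm) and combed
  (tensioned) states with mass shifted above 60 nm;
* chain-length samples from a moment-matched log-normal (lengths in
  beads per microfibril; right-skew is required to reconcile an SD of
  19 with a mean of 18);
* AFM-like height images of beaded chains laid along smooth
  low-curvature random paths, with scanline offsets, pixel noise and
  blob artifacts, plus a bead-level ground-truth table;
* layered tissue sections (straight bands or an annulus) with known
  lamellar geometry, stain coverage, regional fluorescence means and
  regional wave-speed fields.

Fixed seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .afm import HeightImage
from .stats import PeriodicitySample
from .tissue import TissueImage

__all__ = [
    "LorentzianComponent",
    "DistributionPreset",
    "ChainRenderConfig",
    "TissueSectionConfig",
    "GroundTruth",
    "CONTROL_PERIODICITY",
    "DIABETIC_PERIODICITY",
    "COMBED_CONTROL_PERIODICITY",
    "COMBED_DIABETIC_PERIODICITY",
    "CONTROL_LENGTH",
    "DIABETIC_LENGTH",
    "PRESETS",
    "sample_periodicities",
    "sample_chain_lengths",
    "render_chain_image",
    "render_tissue_section",
]


# --------------------------------------------------------------------------- #
# presets
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class LorentzianComponent:
    centre: float       # nm
    half_width: float   # gamma, nm
    weight: float       # mixture fraction


@dataclass(frozen=True)
class DistributionPreset:
    """A truncated Lorentzian mixture describing bead-repeat distances."""

    components: tuple[LorentzianComponent, ...]
    truncation: tuple[float, float] = (30.0, 120.0)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("preset needs at least one component")
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1 (got {w})")
        lo, hi = self.truncation
        if not lo < hi:
            raise ValueError("truncation bounds must be ordered")
        for c in self.components:
            if not lo <= c.centre <= hi:
                raise ValueError(f"centre {c.centre} outside truncation bounds")
            if not c.half_width >= 0:
                raise ValueError("half_width must be non-negative")


CONTROL_PERIODICITY = DistributionPreset(
    (LorentzianComponent(56.0, 3.0, 1.0),), label="control"
)
DIABETIC_PERIODICITY = DistributionPreset(
    (LorentzianComponent(51.0, 3.0, 0.7), LorentzianComponent(73.0, 3.0, 0.3)),
    label="diabetic",
)
# tensioned (molecularly combed) states: mass shifted above 60 nm
COMBED_CONTROL_PERIODICITY = DistributionPreset(
    (LorentzianComponent(58.0, 5.0, 1.0),), label="combed_control"
)
COMBED_DIABETIC_PERIODICITY = DistributionPreset(
    (LorentzianComponent(60.0, 6.0, 1.0),), label="combed_diabetic"
)

# chain-length presets: (mean, SD) in beads per microfibril
CONTROL_LENGTH = (21.0, 13.0)
DIABETIC_LENGTH = (18.0, 19.0)

PRESETS = {
    "control": CONTROL_PERIODICITY,
    "diabetic": DIABETIC_PERIODICITY,
    "combed": COMBED_CONTROL_PERIODICITY,
    "combed_control": COMBED_CONTROL_PERIODICITY,
    "combed_diabetic": COMBED_DIABETIC_PERIODICITY,
}


# --------------------------------------------------------------------------- #
# configuration / truth containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ChainRenderConfig:
    """Rendering parameters for synthetic AFM fields.

    Height units are arbitrary; lateral units are nm.  ``bead_radius``
    must stay below half the smallest bead spacing so neighbouring beads
    remain resolvable.
    """

    pixel_scale: float = 4.0              # nm per pixel
    image_size: tuple[int, int] = (1024, 1024)  # rows, cols
    bead_amplitude: float = 10.0
    bead_radius: float = 10.0             # nm; rendered bump sigma = radius/2
    noise_sd: float = 1.0
    scanline_offset_sd: float = 2.0
    artifact_density: int = 0             # blobs per image
    clearance: float = 200.0              # nm between distinct chains
    max_placement_retries: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")
        if min(self.image_size) <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("bead_amplitude", "bead_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def validate_against(self, preset: DistributionPreset) -> None:
        if self.bead_radius >= preset.truncation[0] / 2:
            raise ValueError(
                "bead_radius must be below half the minimum bead spacing"
            )


@dataclass
class GroundTruth:
    """What the generator actually drew.

    ``beads``: one row per bead (chain_id, bead_idx, x_nm, y_nm);
    ``chain_periodicities``: consecutive bead distances per chain;
    ``chain_lengths``: bead count per chain; ``artifacts``: blob table
    (x_nm, y_nm, radius_nm); ``tissue``: section-level truth dict.
    """

    beads: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chain_id", "bead_idx", "x_nm", "y_nm"]
        )
    )
    chain_periodicities: dict[int, np.ndarray] = field(default_factory=dict)
    chain_lengths: dict[int, int] = field(default_factory=dict)
    artifacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x_nm", "y_nm", "radius_nm"])
    )
    tissue: dict = field(default_factory=dict)

    @property
    def mean_periodicity(self) -> float:
        if not self.chain_periodicities:
            return np.nan
        return float(np.concatenate(list(self.chain_periodicities.values())).mean())

    @property
    def mean_length(self) -> float:
        if not self.chain_lengths:
            return np.nan
        return float(np.mean(list(self.chain_lengths.values())))


# --------------------------------------------------------------------------- #
# sampling
# --------------------------------------------------------------------------- #

def sample_periodicities(
    preset: DistributionPreset,
    n: int,
    seed: int,
    return_components: bool = False,
):
    """Draw ``n`` bead-repeat distances from a truncated Lorentzian mixture.

    Component membership is drawn from the preset weights and the value
    from the component's Cauchy law; draws outside the truncation bounds
    are rejected and redrawn (so the realized component frequencies are
    the truncation-renormalized weights).  With ``return_components``
    the accepted component indices are returned alongside.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    lo, hi = preset.truncation
    weights = np.array([c.weight for c in preset.components])
    centres = np.array([c.centre for c in preset.components])
    gammas = np.array([c.half_width for c in preset.components])

    out = np.empty(n)
    comp_out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(weights), size=m, p=weights)
        vals = centres[comp] + gammas[comp] * np.tan(np.pi * (rng.random(m) - 0.5))
        ok = (vals >= lo) & (vals <= hi)
        k = int(ok.sum())
        out[filled:filled + k] = vals[ok]
        comp_out[filled:filled + k] = comp[ok]
        filled += k
    sample = PeriodicitySample(out, group=preset.label)
    return (sample, comp_out) if return_components else sample


def sample_chain_lengths(
    mean: float,
    sd: float,
    n: int,
    seed: int,
    stratified: bool = False,
) -> np.ndarray:
    """Integer bead counts from a moment-matched log-normal, >= 2 beads.

    The log-normal is matched to the requested (mean, SD), drawn,
    rounded to the nearest integer, and draws that would round below 2
    are rejected and redrawn.  ``sd=0`` degenerates to a constant.

    ``stratified=True`` draws one value per equal-probability quantile
    stratum (Latin-hypercube over the truncated law, order shuffled).
    The marginal distribution is unchanged but the sample mean has far
    lower variance — the right design when the sample feeds a recovery
    benchmark and length-sampling noise would otherwise swamp the
    quantity under test.
    """
    if mean < 2:
        raise ValueError("mean chain length must be at least 2 beads")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n, int(round(mean)), dtype=int)
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    if stratified:
        from scipy.stats import norm

        p0 = norm.cdf((np.log(1.5) - mu) / sigma)  # mass rounding below 2
        u = p0 + (1.0 - p0) * (np.arange(n) + rng.random(n)) / n
        vals = np.round(np.exp(mu + sigma * norm.ppf(u))).astype(int)
        # the top stratum is unbounded; represent it by its conditional
        # mean so one extreme tail draw cannot dominate the sample mean
        z_top = norm.ppf(p0 + (1.0 - p0) * (n - 1) / n)
        tail_mean = (np.exp(mu + sigma2 / 2.0)
                     * norm.cdf(sigma - z_top) / norm.sf(z_top))
        vals[-1] = int(round(tail_mean))
        vals = np.maximum(vals, 2)
        rng.shuffle(vals)
        return vals
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        vals = np.round(rng.lognormal(mu, sigma, n - filled)).astype(int)
        vals = vals[vals >= 2]
        out[filled:filled + len(vals)] = vals
        filled += len(vals)
    return out


# --------------------------------------------------------------------------- #
# chain image rendering
# --------------------------------------------------------------------------- #

class PlacementError(RuntimeError):
    """A chain could not be placed without overlap within the retry budget."""


def _grow_chain(
    rng: np.random.Generator,
    spacings: np.ndarray,
    box: tuple[float, float, float, float],
    other_beads: np.ndarray,
    clearance: float,
    self_clearance: float = 140.0,
    turn_sd_deg: float = 12.0,
    max_turn_deg: float = 50.0,
) -> np.ndarray | None:
    """Grow one smooth low-curvature bead path inside ``box`` (nm).

    Each step turns by a small random angle; when the nominal heading
    would leave the box or violate clearances, nearby headings (still
    within the curvature bound) are tried before giving up.  The
    self-clearance (ignoring the four most recent beads) is kept above
    the downstream link ceiling so a chain never runs close enough to
    itself to be mis-linked.
    """
    x0, y0, x1, y1 = box
    tree = cKDTree(other_beads) if len(other_beads) else None
    start = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
    if tree is not None and tree.query(start)[0] < clearance:
        return None
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    offsets = np.radians([0, 10, -10, 20, -20, 30, -30, 40, -40, 50, -50])
    for d in spacings:
        turn0 = np.clip(rng.normal(0.0, np.radians(turn_sd_deg)),
                        -np.radians(max_turn_deg), np.radians(max_turn_deg))
        placed = False
        for off in offsets:
            turn = np.clip(turn0 + off, -np.radians(max_turn_deg),
                           np.radians(max_turn_deg))
            h = heading + turn
            q = pts[-1] + d * np.array([np.cos(h), np.sin(h)])
            if not (x0 <= q[0] <= x1 and y0 <= q[1] <= y1):
                continue
            if tree is not None and tree.query(q)[0] < clearance:
                continue
            if len(pts) > 4:
                own = np.array(pts[:-4])
                if np.min(np.hypot(*(own - q).T)) < self_clearance:
                    continue
            pts.append(q)
            heading = h
            placed = True
            break
        if not placed:
            return None
    return np.array(pts)


def render_chain_image(
    preset: DistributionPreset,
    lengths,
    config: ChainRenderConfig,
) -> tuple[HeightImage, GroundTruth]:
    """Render beaded chains into an AFM-like height raster with truth.

    ``lengths`` is a sequence of bead counts, one per chain.  For each
    chain, bead spacings are drawn from ``preset`` and the beads are laid
    along a smooth random path (bounded turn per step, so arc-length and
    Euclidean spacing coincide at the bead scale).  Beads are rendered as
    radially symmetric Gaussian bumps; per-row scanline offsets, white
    pixel noise and optional large blob artifacts are added.  Offset and
    noise fields are drawn from the RNG even at zero amplitude, so the
    same seed yields the same realization apart from those terms.

    Raises :class:`PlacementError` when a chain cannot be placed within
    the retry budget.
    """
    config.validate_against(preset)
    lengths = [int(v) for v in np.atleast_1d(lengths)]
    rng = np.random.default_rng(config.rng_seed)
    nrow, ncol = config.image_size
    scale = config.pixel_scale
    margin = 4 * config.bead_radius
    box = (margin, margin, ncol * scale - margin, nrow * scale - margin)
    if box[2] <= box[0] or box[3] <= box[1]:
        raise ValueError("image too small for the configured bead radius")

    truth = GroundTruth()
    placed_beads: list[np.ndarray] = []
    rows = []
    for cid, n_beads in enumerate(lengths):
        if n_beads < 1:
            raise ValueError("chain length must be at least 1 bead")
        other = (np.concatenate(placed_beads) if placed_beads
                 else np.empty((0, 2)))
        pts = None
        for _ in range(config.max_placement_retries):
            if n_beads > 1:
                spacings = sample_periodicities(
                    preset, n_beads - 1, int(rng.integers(2**31))
                ).values
            else:
                spacings = np.empty(0)
            pts = _grow_chain(rng, spacings, box, other, config.clearance)
            if pts is not None:
                break
        if pts is None:
            raise PlacementError(
                f"chain {cid} ({n_beads} beads) could not be placed in a "
                f"{ncol * scale:.0f}x{nrow * scale:.0f} nm field after "
                f"{config.max_placement_retries} retries"
            )
        placed_beads.append(pts)
        for i, (px, py) in enumerate(pts):
            rows.append((cid, i, px, py))
        truth.chain_lengths[cid] = n_beads
        truth.chain_periodicities[cid] = np.hypot(*np.diff(pts, axis=0).T)
    truth.beads = pd.DataFrame(rows, columns=["chain_id", "bead_idx", "x_nm", "y_nm"])

    canvas = np.zeros((nrow, ncol))
    sigma_px = (config.bead_radius / 2.0) / scale
    half = int(np.ceil(4 * sigma_px))
    for _, _, px, py in rows:
        c, r = px / scale, py / scale
        r0, r1 = max(int(r) - half, 0), min(int(r) + half + 1, nrow)
        c0, c1 = max(int(c) - half, 0), min(int(c) + half + 1, ncol)
        gr, gc = np.mgrid[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] += config.bead_amplitude * np.exp(
            -((gr - r) ** 2 + (gc - c) ** 2) / (2 * sigma_px**2)
        )

    # blob artifacts: super-Gaussian bumps far larger than a bead
    art_rows = []
    all_beads = np.concatenate(placed_beads) if placed_beads else np.empty((0, 2))
    btree = cKDTree(all_beads) if len(all_beads) else None
    for _ in range(config.artifact_density):
        radius = rng.uniform(3.0, 6.0) * config.bead_radius
        amp = rng.uniform(2.0, 4.0) * config.bead_amplitude
        for _ in range(200):
            pos = np.array([rng.uniform(box[0], box[2]), rng.uniform(box[1], box[3])])
            if btree is None or btree.query(pos)[0] > radius + 3 * config.bead_radius:
                break
        else:
            continue
        c, r = pos[0] / scale, pos[1] / scale
        rad_px = radius / scale
        half_a = int(np.ceil(1.5 * rad_px))
        r0, r1 = max(int(r) - half_a, 0), min(int(r) + half_a + 1, nrow)
        c0, c1 = max(int(c) - half_a, 0), min(int(c) + half_a + 1, ncol)
        gr, gc = np.mgrid[r0:r1, c0:c1]
        rr = ((gr - r) ** 2 + (gc - c) ** 2) / rad_px**2
        canvas[r0:r1, c0:c1] += amp * np.exp(-(rr**2))
        art_rows.append((pos[0], pos[1], radius))
    truth.artifacts = pd.DataFrame(art_rows, columns=["x_nm", "y_nm", "radius_nm"])

    # same RNG consumption regardless of amplitudes: comparable seeds
    canvas += config.scanline_offset_sd * rng.standard_normal((nrow, 1))
    canvas += config.noise_sd * rng.standard_normal((nrow, ncol))
    return HeightImage(canvas, scale), truth


def render_chain_batches(
    preset: DistributionPreset,
    lengths,
    config: ChainRenderConfig,
    chains_per_image: int = 5,
):
    """Render many chains across several fields of view.

    Splits ``lengths`` into groups of ``chains_per_image`` (longest
    chains first, so crowded fields hold the short ones) and yields one
    ``(HeightImage, GroundTruth)`` pair per field; per-field RNG seeds
    derive from ``config.rng_seed``.
    """
    lengths = sorted((int(v) for v in np.atleast_1d(lengths)), reverse=True)
    for b in range(0, len(lengths), chains_per_image):
        cfg = replace(config, rng_seed=(config.rng_seed + 7919 * (b + 1)) % 2**31)
        yield render_chain_image(preset, lengths[b:b + chains_per_image], cfg)


# --------------------------------------------------------------------------- #
# tissue section rendering
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class TissueSectionConfig:
    """Geometry and signal levels of a synthetic aortic section.

    The medial wall alternates ``n_lamellae`` thin elastic lamellae with
    thicker inter-lamellar (smooth-muscle) spaces; defaults give a
    7-lamella wall 90 um thick.  Wave speeds are in m/s; the
    inter-lamellar speed can be a mixture (list of (mean, sd, weight))
    to emulate a bimodal region.
    """

    geometry: str = "bands"               # "bands" | "annulus"
    image_size: tuple[int, int] = (512, 512)
    pixel_scale: float = 1.0              # um per pixel
    n_lamellae: int = 7
    lamellar_um: float = 3.0
    interlamellar_um: float = 11.5
    lamellar_intensity: float = 40.6      # fluorescence A.U.
    interlamellar_intensity: float = 51.6
    intensity_noise_sd: float = 2.0
    lamellar_speed: tuple[float, float] = (1883.0, 15.0)       # mean, sd m/s
    interlamellar_speed: tuple = ((1850.0, 15.0, 1.0),)        # (mean, sd, w), ...
    void_fraction: float = 0.0            # fraction of tissue carved into voids
    tissue_level: float = 100.0
    annulus_inner_um: float | None = None  # default: centred ring

    @property
    def wall_thickness_um(self) -> float:
        return (self.n_lamellae * self.lamellar_um
                + (self.n_lamellae - 1) * self.interlamellar_um)


def _layer_label(depth_um: np.ndarray, cfg: TissueSectionConfig) -> np.ndarray:
    """0 outside the wall, 1 lamellar, 2 inter-lamellar, by depth."""
    period = cfg.lamellar_um + cfg.interlamellar_um
    label = np.zeros(depth_um.shape, dtype=int)
    inside = (depth_um >= 0) & (depth_um < cfg.wall_thickness_um)
    phase = np.mod(depth_um, period)
    lam = phase < cfg.lamellar_um
    label[inside & lam] = 1
    label[inside & ~lam] = 2
    return label


def render_tissue_section(
    config: TissueSectionConfig = TissueSectionConfig(),
    stain_fraction: float = 31.0,
    seed: int = 0,
) -> tuple[TissueImage, GroundTruth]:
    """Render a layered synthetic section with known truth.

    Channels produced: ``tissue`` (flat counterstain over the wall),
    ``stain`` (binary-valued stain covering exactly the requested
    percentage of tissue pixels, spatially correlated), ``fitc``
    (fluorescence with the configured regional means plus noise) and
    ``wave_speed`` (per-region draws in m/s).  The truth dict records
    the realized stain fraction, wall thickness, regional means and the
    lamellar / inter-lamellar masks.
    """
    if not 0.0 <= stain_fraction <= 100.0:
        raise ValueError("stain_fraction must be in [0, 100]")
    rng = np.random.default_rng(seed)
    nrow, ncol = config.image_size
    scale = config.pixel_scale
    thick = config.wall_thickness_um

    yy, xx = np.mgrid[0:nrow, 0:ncol]
    if config.geometry == "bands":
        top = (nrow * scale - thick) / 2.0
        depth = yy * scale - top
    elif config.geometry == "annulus":
        cy, cx = (nrow - 1) / 2.0, (ncol - 1) / 2.0
        r_um = np.hypot(yy - cy, xx - cx) * scale
        inner = config.annulus_inner_um
        if inner is None:
            inner = max(min(nrow, ncol) * scale / 2.0 - thick - 10 * scale, scale)
        if inner + thick > min(nrow, ncol) * scale / 2.0:
            raise ValueError("annulus does not fit in the image")
        depth = r_um - inner
    else:
        raise ValueError("geometry must be 'bands' or 'annulus'")

    label = _layer_label(depth, config)
    wall = label > 0
    void = np.zeros((nrow, ncol), bool)
    if config.void_fraction > 0:
        blob = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), 4.0)
        cut = np.quantile(blob[wall], 1.0 - config.void_fraction)
        void = wall & (blob > cut)
    tissue_mask = wall & ~void
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise ValueError("no tissue pixels at this geometry/resolution")

    k = int(round(stain_fraction / 100.0 * n_tissue))
    realized = 100.0 * k / n_tissue
    if abs(realized - stain_fraction) > 0.5:
        raise ValueError(
            f"stain fraction {stain_fraction}% unreachable at this resolution "
            f"(nearest {realized:.2f}%)"
        )
    # spatially correlated coverage: threshold a smooth field at the
    # exact pixel count
    field_ = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), 3.0)
    field_ += 1e-9 * rng.standard_normal((nrow, ncol))  # break ties
    stain = np.zeros((nrow, ncol))
    if k > 0:
        vals = field_[tissue_mask]
        cut = np.partition(vals, -k)[-k]
        sel = tissue_mask & (field_ >= cut)
        # exact count despite any residual ties
        extra = int(sel.sum()) - k
        if extra > 0:
            idx = np.flatnonzero(sel.ravel() & (field_.ravel() == cut))[:extra]
            sel.ravel()[idx] = False
        stain[sel] = 200.0

    lam_mask = (label == 1) & ~void
    inter_mask = (label == 2) & ~void

    fitc = np.zeros((nrow, ncol))
    fitc[lam_mask] = config.lamellar_intensity
    fitc[inter_mask] = config.interlamellar_intensity
    fitc += config.intensity_noise_sd * rng.standard_normal((nrow, ncol))
    fitc = np.clip(fitc, 0.0, None)

    speed = np.zeros((nrow, ncol))
    mu, sd = config.lamellar_speed
    speed[lam_mask] = mu + sd * rng.standard_normal(int(lam_mask.sum()))
    modes = np.array([m[:2] for m in config.interlamellar_speed])
    wts = np.array([m[2] for m in config.interlamellar_speed])
    wts = wts / wts.sum()
    pick = rng.choice(len(wts), size=int(inter_mask.sum()), p=wts)
    speed[inter_mask] = (modes[pick, 0]
                         + modes[pick, 1] * rng.standard_normal(pick.size))

    tissue_chan = np.where(tissue_mask, config.tissue_level, 0.0)
    img = TissueImage(
        {"tissue": tissue_chan, "stain": stain, "fitc": fitc, "wave_speed": speed},
        scale,
        void_mask=void,
    )
    truth = GroundTruth(tissue={
        "stain_fraction_pct": realized,
        "requested_stain_fraction_pct": stain_fraction,
        "wall_thickness_um": thick,
        "lamellar_intensity": config.lamellar_intensity,
        "interlamellar_intensity": config.interlamellar_intensity,
        "lamellar_speed": config.lamellar_speed,
        "interlamellar_speed": config.interlamellar_speed,
        "lamellar_mask": lam_mask,
        "interlamellar_mask": inter_mask,
        "medial_mask": tissue_mask,
        "geometry": config.geometry,
    })
    return img, truth
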