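"""Tissue-section quantification for the aortic wall.

Covers the section-scale readouts: stain area fractions (collagen /
elastin as a percentage of tissue area), cubic-spline straightening of
the curved wall, medial thickness profiles, regional gelatinase
(fluorescence) intensity per unit area, and acoustic statistics — the
plane-wave relation between longitudinal wave speed and Young's modulus

    v_L = sqrt(C11 / rho),   C11 = E (1 - nu) / ((1 + nu)(1 - 2 nu)),

plus per-region wave-speed summaries with a modality call.  Rasters are
plain 2-D arrays grouped in a :class:`TissueImage` with a micrometre
pixel scale; region membership is by boolean mask (a pixel belongs to a
region iff its centre does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from skimage.filters import threshold_otsu

from .stats import PeriodicitySample, select_modality

log = logging.getLogger(__name__)

__all__ = [
    "TissueImage",
    "RegionSpec",
    "AcousticMaterial",
    "area_fraction",
    "straighten_wall",
    "medial_thickness",
    "regional_gelatinase",
    "zymo_strips",
    "wave_speed_from_modulus",
    "modulus_from_wave_speed",
    "region_wave_speed_stats",
]


@dataclass
class TissueImage:
    """Named 2-D channels with a shared micrometre pixel scale.

    Typical channels: ``tissue`` (counterstain used to delimit tissue),
    ``stain`` (collagen or elastin signal), ``fitc`` (gelatinase
    fluorescence), ``dapi``, ``wave_speed`` (m/s map).  ``void_mask``
    marks holes/glass to exclude from tissue area.
    """

    channels: dict[str, np.ndarray]
    pixel_scale: float  # micrometres per pixel
    void_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive (um per pixel)")
        self.channels = {k: np.asarray(v, float) for k, v in self.channels.items()}
        if self.void_mask is not None:
            self.void_mask = np.asarray(self.void_mask, bool)
            if self.void_mask.shape != self.shape:
                raise ValueError("void_mask shape must match the channels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class RegionSpec:
    """One labelled pixel region (e.g. a lamella or a zymography strip)."""

    region_id: int
    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError(f"region {self.region_id} ({self.label}) is empty")


@dataclass
class AcousticMaterial:
    """Isotropic elastic symbol set: E (Pa), rho (kg/m^3), nu, C11 (Pa),
    longitudinal wave speed v_L (m/s), tied by C11 = rho * v_L**2."""

    E: float
    rho: float
    nu: float
    C11: float = field(init=False)
    v_L: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("E must be positive")
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
        self.v_L = float(wave_speed_from_modulus(self.E, self.rho, self.nu))
        self.C11 = float(self.rho * self.v_L**2)


# --------------------------------------------------------------------------- #
# thresholding / area fractions
# --------------------------------------------------------------------------- #

def _threshold_mask(values: np.ndarray, domain: np.ndarray, policy) -> np.ndarray:
    """Boolean mask of pixels above a threshold computed on ``domain``."""
    if isinstance(policy, str) and policy.startswith("fixed:"):
        policy = ("fixed", float(policy.split(":", 1)[1]))
    if policy == "otsu":
        sel = values[domain] if domain is not None else values.ravel()
        if np.ptp(sel) == 0:  # constant channel: on iff positive
            return (values > 0) if sel.flat[0] > 0 else np.zeros(values.shape, bool)
        t = threshold_otsu(sel)
    elif isinstance(policy, tuple) and policy[0] == "fixed":
        t = float(policy[1])
    else:
        raise ValueError("policy must be 'otsu', 'fixed:t' or ('fixed', t)")
    return values > t


def area_fraction(
    img: TissueImage,
    signal_channel: str,
    tissue_channel: str,
    policy="otsu",
    tissue_policy="otsu",
) -> float:
    """Stain coverage as a percentage of tissue area.

    The tissue mask comes from thresholding ``tissue_channel`` (voids
    excluded); the signal mask from thresholding ``signal_channel`` with
    ``policy`` (``'otsu'`` or ``'fixed:t'``).  Returns
    ``100 * |signal AND tissue| / |tissue|``.
    """
    tissue = _threshold_mask(img[tissue_channel], None, tissue_policy)
    if img.void_mask is not None:
        tissue &= ~img.void_mask
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    sig = _threshold_mask(img[signal_channel], tissue, policy)
    return 100.0 * float((sig & tissue).sum()) / float(tissue.sum())


# --------------------------------------------------------------------------- #
# wall straightening and medial thickness
# --------------------------------------------------------------------------- #

def straighten_wall(
    img: TissueImage,
    centerline: np.ndarray,
    half_width_px: int,
    closed: bool | None = None,
) -> TissueImage:
    """Resample the image into arc-length x normal-offset coordinates.

    ``centerline`` is an (N, 2) array of (x=col, y=row) control points in
    pixels (N >= 4) tracing the mid-wall; a cubic spline through them is
    sampled at one-pixel arc-length steps, and the image is re-gridded by
    bilinear interpolation along the local normals out to
    ``+/- half_width_px``.  The output has the same pixel scale, rows =
    normal offsets (row ``half_width_px`` is the centerline), columns =
    arc length.  If the first and last control point coincide (or
    ``closed=True``) the spline is periodic.

    Raises if the normals self-intersect, i.e. the local curvature
    radius falls below ``half_width_px``.
    """
    pts = np.asarray(centerline, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("centerline needs at least 4 (x, y) control points")
    shape = img.shape
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > shape[1] - 1 or pts[:, 1].max() > shape[0] - 1):
        raise ValueError("centerline control points must lie within the image")
    if closed is None:
        closed = bool(np.allclose(pts[0], pts[-1]))
    if closed and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]

    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, per=int(closed), k=3)
    # dense pass to build the arc-length table
    u_dense = np.linspace(0, 1, 20 * len(pts) + 1)
    xd, yd = interpolate.splev(u_dense, tck)
    seg = np.hypot(np.diff(xd), np.diff(yd))
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]
    if closed:  # even steps that tile the closed contour
        n_cols = max(int(round(total)), 2)
        s_targets = total * np.arange(n_cols) / n_cols
    else:  # exact one-pixel steps
        s_targets = np.arange(0.0, total + 1e-9, 1.0)
    u = np.interp(s_targets, s_dense, u_dense)

    x, y = interpolate.splev(u, tck)
    dx, dy = interpolate.splev(u, tck, der=1)
    ddx, ddy = interpolate.splev(u, tck, der=2)
    speed = np.hypot(dx, dy)
    tx, ty = dx / speed, dy / speed
    nx, ny = -ty, tx  # left normal
    kappa = np.abs(dx * ddy - dy * ddx) / speed**3
    bad = kappa * half_width_px >= 1.0
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"normals self-intersect: curvature radius {1/kappa[i]:.1f} px "
            f"< half width {half_width_px} px at arc position {s_targets[i]:.1f} px"
        )

    offsets = np.arange(-half_width_px, half_width_px + 1, dtype=float)
    sample_x = x[None, :] + offsets[:, None] * nx[None, :]
    sample_y = y[None, :] + offsets[:, None] * ny[None, :]
    coords = np.stack([sample_y, sample_x])  # (row, col) order

    out_channels = {
        name: ndimage.map_coordinates(chan, coords, order=1, mode="constant", cval=0.0)
        for name, chan in img.channels.items()
    }
    void = None
    if img.void_mask is not None:
        void = ndimage.map_coordinates(
            img.void_mask.astype(float), coords, order=0, mode="constant", cval=1.0
        ) > 0.5
    return TissueImage(out_channels, img.pixel_scale, void)


def medial_thickness(
    straightened: TissueImage,
    medial_mask: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Medial thickness profile of a straightened wall.

    For each column (arc-length position) the medial tissue pixels are
    counted perpendicular to the intima and converted to micrometres;
    void pixels must already be absent from ``medial_mask`` ("only
    pixels which contained tissue").  Columns with no medial pixels are
    excluded and logged.  Returns the per-column profile (um) and a
    summary dict with mean, sd, min, max and the column count.
    """
    mask = np.asarray(medial_mask, bool)
    if mask.shape != straightened.shape:
        raise ValueError("mask shape must match the straightened image")
    if not mask.any():
        raise ValueError("medial mask is empty")
    counts = mask.sum(axis=0).astype(float)
    empty = counts == 0
    if empty.any():
        log.info("%d column(s) with no medial pixels excluded", int(empty.sum()))
    profile = counts[~empty] * straightened.pixel_scale
    summary = {
        "mean_um": float(profile.mean()),
        "sd_um": float(profile.std(ddof=1)) if profile.size > 1 else np.nan,
        "min_um": float(profile.min()),
        "max_um": float(profile.max()),
        "n_columns": int(profile.size),
    }
    return profile, summary


# --------------------------------------------------------------------------- #
# regional gelatinase intensity
# --------------------------------------------------------------------------- #

def regional_gelatinase(
    img: TissueImage,
    regions: list[RegionSpec],
    background: float | np.ndarray,
    channel: str = "fitc",
) -> pd.DataFrame:
    """Background-subtracted mean fluorescence intensity per um^2.

    ``background`` is either a scalar or a boolean mask of a
    user-designated off-tissue area whose median defines the background
    level.  The background is subtracted from the fluorescence channel,
    negatives are clipped to zero, and each region's mean pixel
    intensity is divided by the pixel area (``pixel_scale**2`` um^2).
    """
    fitc = img[channel]
    if isinstance(background, np.ndarray):
        bgmask = np.asarray(background, bool)
        if bgmask.shape != img.shape:
            raise ValueError("background mask shape must match the image")
        if not bgmask.any():
            raise ValueError("background mask is empty")
        bg = float(np.median(fitc[bgmask]))
    else:
        bg = float(background)
    corrected = np.clip(fitc - bg, 0.0, None)
    px_area = img.pixel_scale**2
    rows = []
    for reg in regions:
        if reg.mask.shape != img.shape:
            raise ValueError(f"region {reg.region_id} lies outside the image grid")
        vals = corrected[reg.mask]
        rows.append(
            (reg.region_id, reg.label, float(vals.mean()) / px_area,
             int(vals.size), bg)
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "label", "intensity_per_um2", "n_pixels", "background"],
    )


def zymo_strips(
    medial_mask: np.ndarray,
    strip_width_px: int = 100,
) -> list[RegionSpec]:
    """Cut a straightened medial mask into consecutive strips.

    Strips run perpendicular to the intima (full medial depth), each
    ``strip_width_px`` columns wide along the arc-length axis; a final
    partial strip is kept if it contains tissue.
    """
    mask = np.asarray(medial_mask, bool)
    regions = []
    rid = 0
    for c0 in range(0, mask.shape[1], strip_width_px):
        sub = np.zeros_like(mask)
        sub[:, c0:c0 + strip_width_px] = mask[:, c0:c0 + strip_width_px]
        if sub.any():
            regions.append(RegionSpec(rid, "zymo_strip", sub))
            rid += 1
    return regions


# --------------------------------------------------------------------------- #
# acoustic conversion and per-region wave-speed statistics
# --------------------------------------------------------------------------- #

def _check_nu(nu) -> None:
    nu = np.asarray(nu, float)
    if np.any(nu >= 0.5) or np.any(nu <= -1.0):
        raise ValueError("Poisson's ratio must lie in (-1, 0.5)")


def wave_speed_from_modulus(E, rho, nu):
    """Longitudinal wave speed v_L = sqrt(C11/rho) from Young's modulus.

    C11 = E (1 - nu) / ((1 + nu)(1 - 2 nu)); at nu = 0 this reduces to
    sqrt(E/rho).  Units: E in Pa, rho in kg/m^3, result in m/s.
    """
    E = np.asarray(E, float)
    rho = np.asarray(rho, float)
    _check_nu(nu)
    if np.any(E <= 0) or np.any(rho <= 0):
        raise ValueError("E and rho must be positive")
    c11 = E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))
    out = np.sqrt(c11 / rho)
    return float(out) if out.ndim == 0 else out


def modulus_from_wave_speed(v_L, rho, nu):
    """Algebraic inverse: E = rho * v_L^2 (1+nu)(1-2nu)/(1-nu)."""
    v_L = np.asarray(v_L, float)
    rho = np.asarray(rho, float)
    _check_nu(nu)
    if np.any(v_L <= 0) or np.any(rho <= 0):
        raise ValueError("v_L and rho must be positive")
    out = rho * v_L**2 * (1.0 + nu) * (1.0 - 2.0 * nu) / (1.0 - nu)
    return float(out) if out.ndim == 0 else out


def region_wave_speed_stats(
    speed_map: np.ndarray,
    regions: list[RegionSpec],
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Per-region wave-speed samples: mean +/- SEM and a modality call.

    Each region's pixel values are summarized (mean, SD, SEM, n) and, when
    the sample is large and non-degenerate enough for a histogram fit,
    its distribution is classified as unimodal (1) or bimodal (2) with
    ``bin_width`` m/s bins.  A constant region is unimodal by definition;
    a region below 50 pixels gets no call (None).
    """
    speed_map = np.asarray(speed_map, float)
    rows = []
    for reg in regions:
        if reg.mask.shape != speed_map.shape:
            raise ValueError(f"region {reg.region_id} lies outside the map")
        vals = speed_map[reg.mask]
        if vals.size == 0:
            raise ValueError(f"region {reg.region_id} is empty")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        sem = sd / np.sqrt(vals.size) if vals.size > 1 else np.nan
        if vals.size < 50:
            modality = None
        elif np.ptp(vals) == 0:
            modality = 1
        else:
            modality = select_modality(
                PeriodicitySample(vals, group=reg.label), bin_width
            )
        rows.append(
            (reg.region_id, reg.label, float(vals.mean()), sd, sem,
             int(vals.size), modality)
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "label", "mean", "sd", "sem", "n", "modality"],
    )
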