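"""Synthetic study data: DWI phantoms, H&E-like images and ROI cohorts.

Three generators make every pipeline stage testable without any download:

* :func:`simulate_dwi_phantom` — multi-b prostate-like DWI with region-wise
  kurtosis-model parameters, Rician magnitude noise (per-channel Gaussian
  noise of variance sigma²/averages, modeling multi-average acquisition)
  and a companion noise-only volume acquired "without excitation".
* :func:`simulate_histology_image` — an RGB image composed of three tissue
  classes (cellularity: blue-purple, hue 0.7; fibromuscular stroma: eosin
  pink; luminal space: near-white) laid out as seeded smooth blobs, with
  exact per-class pixel counts in ``exact_count`` mode.
* :func:`simulate_cohort` — a 20-patient study-shaped ROI table.  Tissue
  compositions are scaled-Beta draws matched to the published group medians
  and ranges (fibromuscular stroma by subtraction, resampled into its
  range); DKI medians follow linear links

      D_app = a0 + a1*luminal - a2*cellularity + eps   (10^-3 mm²/s)
      K_app = b0 + b1*cellularity - b2*fsm + eps

  with coefficients calibrated once (scripts/calibrate_cohort.py) so group
  medians and the signs/magnitudes of the significant rank correlations
  match the study tables.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dki_core import BValueScheme, DKIParams, dki_signal
from .dki_fitting import DWISeries, FitStatus, ParameterMaps
from .histo_segmentation import TissueFractions
from .roi_stats import CohortTable, ROIRecord

__all__ = [
    "Region",
    "DWIPhantomSpec",
    "HistologyPhantomSpec",
    "CohortSimSpec",
    "DEFAULT_CLASS_COLORS",
    "simulate_dwi_phantom",
    "simulate_histology_image",
    "simulate_cohort",
]


# --------------------------------------------------------------------------
# DWI phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """Geometric tissue region: an axis-aligned box or an ellipsoid."""

    kind: str  # "box" | "ellipsoid"
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    params: DKIParams

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        if self.kind not in ("box", "ellipsoid"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        if self.kind == "box":
            inside = np.ones(shape, dtype=bool)
            for g, c, r in zip(grids, self.center, self.radii):
                inside &= np.abs(g - c) <= r
            return inside
        acc = np.zeros(shape)
        for g, c, r in zip(grids, self.center, self.radii):
            acc += ((g - c) / max(r, 1e-12)) ** 2
        return acc <= 1.0


@dataclass(frozen=True)
class DWIPhantomSpec:
    """Specification of a multi-b DWI phantom with Rician noise."""

    shape: tuple[int, int, int] = (24, 24, 2)
    regions: tuple[Region, ...] = ()
    scheme: BValueScheme = field(default_factory=BValueScheme)
    sigma: float = 0.0  # per-channel noise before averaging (signal units)
    averages: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.averages < 1:
            raise ValueError("averages must be >= 1")

    @property
    def sigma_eff(self) -> float:
        """Per-channel noise after ``averages`` signal averages."""
        return self.sigma / np.sqrt(self.averages)


def simulate_dwi_phantom(
    spec: DWIPhantomSpec,
) -> tuple[DWISeries, ParameterMaps, np.ndarray]:
    """Simulate (DWI series, ground-truth maps, noise-only 4D volume).

    Region voxels carry the noise-free kurtosis-model signal; background
    voxels carry S = 0.  Rician magnitude noise is applied as
    |(S + e1) + i*e2| with e ~ N(0, sigma_eff²) per channel.  The noise-only
    volume repeats the acquisition with S = 0 everywhere.
    """
    shape = tuple(spec.shape)
    masks = [r.mask(shape) for r in spec.regions]
    overlap = np.zeros(shape, dtype=int)
    for m in masks:
        overlap += m
    if np.any(overlap > 1):
        raise ValueError("phantom regions overlap")

    b = spec.scheme.as_array
    clean = np.zeros(shape + (len(b),))
    s0_map = np.full(shape, np.nan)
    d_map = np.full(shape, np.nan)
    k_map = np.full(shape, np.nan)
    status = np.full(shape, int(FitStatus.SKIPPED), dtype=np.int8)
    for region, mask in zip(spec.regions, masks):
        clean[mask] = dki_signal(b, region.params)
        s0_map[mask] = region.params.s0
        d_map[mask] = region.params.d_app
        k_map[mask] = region.params.k_app
        status[mask] = int(FitStatus.OK)
    truth = ParameterMaps(
        s0_map=s0_map,
        d_app_map=d_map,
        k_app_map=k_map,
        status_map=status,
        rss_map=np.zeros(shape),
    )

    rng = np.random.default_rng(spec.seed)
    if spec.sigma == 0.0:
        data = clean.copy()
        noise_only = np.zeros_like(clean)
    else:
        s_eff = spec.sigma_eff
        e1 = rng.normal(0.0, s_eff, size=clean.shape)
        e2 = rng.normal(0.0, s_eff, size=clean.shape)
        data = np.hypot(clean + e1, e2)
        f1 = rng.normal(0.0, s_eff, size=clean.shape)
        f2 = rng.normal(0.0, s_eff, size=clean.shape)
        noise_only = np.hypot(f1, f2)
    series = DWISeries(data=data, scheme=spec.scheme)
    return series, truth, noise_only


# --------------------------------------------------------------------------
# Histology phantom
# --------------------------------------------------------------------------

# Class colors in HSV: cellularity sits at the default hue window center
# (0.70, hematoxylin blue-purple), stroma is eosin pink (hue 0.95, outside
# the window), luminal space is unstained near-white.
DEFAULT_CLASS_COLORS: dict[str, tuple[float, float, float]] = {
    "cellularity": colorsys.hsv_to_rgb(0.70, 0.65, 0.62),
    "fsm": colorsys.hsv_to_rgb(0.95, 0.45, 0.88),
    "luminal": colorsys.hsv_to_rgb(0.0, 0.0, 0.97),
}

_CLASS_ORDER = ("cellularity", "fsm", "luminal")


@dataclass(frozen=True)
class HistologyPhantomSpec:
    """Specification of an H&E-like phantom with programmed composition."""

    shape: tuple[int, int] = (100, 100)
    target_fractions: TissueFractions = field(
        default_factory=lambda: TissueFractions(0.39, 0.50, 0.11)
    )
    mode: str = "exact_count"  # "exact_count" | "textured"
    class_colors: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COLORS))
    blob_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exact_count", "textured"):
            raise ValueError("mode must be exact_count|textured")
        if self.blob_scale <= 0:
            raise ValueError("blob_scale must be > 0")
        if set(self.class_colors) != set(_CLASS_ORDER):
            raise ValueError(f"class_colors must have keys {_CLASS_ORDER}")


def _largest_remainder_counts(fractions: TissueFractions, n: int) -> np.ndarray:
    """Apportion n pixels to the three classes by largest remainder."""
    quotas = np.array(fractions.as_tuple()) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def simulate_histology_image(
    spec: HistologyPhantomSpec,
) -> tuple[np.ndarray, list, TissueFractions]:
    """Simulate (uint8 RGB image, ROI polygon, realized fractions).

    Class labels are assigned by thresholding a seeded smooth random field
    at the exact per-class pixel counts (largest-remainder apportionment of
    the target fractions), so spatially coherent blobs with exactly the
    programmed composition result.  ``textured`` mode adds per-pixel HSV
    jitter on top of the clean class colors.  The returned polygon covers
    the full image, so every pixel center falls inside the ROI.
    """
    h, w = spec.shape
    n = h * w
    counts = _largest_remainder_counts(spec.target_fractions, n)
    if np.any(counts < 0):
        raise ValueError("target fractions infeasible for image size")

    rng = np.random.default_rng(spec.seed)
    fld = gaussian_filter(rng.normal(size=(h, w)), sigma=spec.blob_scale)
    order = np.argsort(fld.ravel(), kind="stable")
    labels = np.empty(n, dtype=np.uint8)
    stop0 = counts[0]
    stop1 = counts[0] + counts[1]
    labels[order[:stop0]] = 0  # cellularity
    labels[order[stop0:stop1]] = 1  # fsm
    labels[order[stop1:]] = 2  # luminal
    labels = labels.reshape(h, w)

    palette = np.array(
        [spec.class_colors[name] for name in _CLASS_ORDER], dtype=float
    )
    rgb = palette[labels]
    if spec.mode == "textured":
        import skimage.color

        hsv = skimage.color.rgb2hsv(rgb)
        hsv[..., 0] = (hsv[..., 0] + rng.normal(0.0, 0.015, size=(h, w))) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + rng.normal(0.0, 0.04, size=(h, w)), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] + rng.normal(0.0, 0.03, size=(h, w)), 0, 1)
        rgb = skimage.color.hsv2rgb(hsv)
    image = np.round(rgb * 255.0).astype(np.uint8)

    realized = TissueFractions(
        cellularity=counts[0] / n, fsm=counts[1] / n, luminal=counts[2] / n
    )
    polygon = [[0.0, 0.0], [float(w), 0.0], [float(w), float(h)], [0.0, float(h)]]
    return image, polygon, realized


# --------------------------------------------------------------------------
# Cohort simulator
# --------------------------------------------------------------------------

# Composition models: (low, high, median) of the scaled-Beta support per
# component, from the published group medians and ranges; the stromal
# fraction is 1 - cellularity - luminal, resampled into its printed range.
NORMAL_COMPOSITION = {
    "cellularity": (0.10, 0.40, 0.24),
    "luminal": (0.11, 0.33, 0.20),
    "fsm_range": (0.45, 0.65),
}
TUMOR_LOW_COMPOSITION = {
    "cellularity": (0.35, 0.47, 0.38),
    "luminal": (0.06, 0.15, 0.09),
    "fsm_range": (0.45, 0.55),
}
TUMOR_HIGH_COMPOSITION = {
    "cellularity": (0.32, 0.61, 0.44),
    "luminal": (0.06, 0.21, 0.09),
    "fsm_range": (0.32, 0.51),
}

#: Linear composition->DKI link, calibrated by scripts/calibrate_cohort.py.
#: D_app in 10^-3 mm²/s: a0 + a1*luminal - a2*cellularity
#: K_app unitless:       b0 + b1*cellularity - b2*fsm
DEFAULT_DKI_LINK = {
    "alpha": (1.806, 3.0, 1.4),
    "beta": (1.59, 0.5, 2.0),
    "sigma_d": 0.10,
    "sigma_k": 0.12,
}

#: Gleason-score distribution of the 20-patient study population.
DEFAULT_GS_DISTRIBUTION = {"3+3": 0.15, "3+4": 0.45, "4+3": 0.30, "8+": 0.10}
_GS_LOW = ("3+3", "3+4")

#: P(1..4 tumor ROIs); mean ~1.95, matching "1-4 (mean 2)".
DEFAULT_ROIS_PER_PATIENT = (0.35, 0.40, 0.20, 0.05)

BETA_CONCENTRATION = 16.0


@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a study-shaped ROI cohort."""

    n_patients: int = 20
    rois_per_patient: tuple[float, ...] = DEFAULT_ROIS_PER_PATIENT
    gs_distribution: dict = field(default_factory=lambda: dict(DEFAULT_GS_DISTRIBUTION))
    dki_link: dict = field(default_factory=lambda: dict(DEFAULT_DKI_LINK))
    roi_area_range: tuple[float, float] = (3.1, 365.4)
    beta_concentration: float = BETA_CONCENTRATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.gs_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("gs_distribution probabilities must sum to 1")
        if abs(sum(self.rois_per_patient) - 1.0) > 1e-9:
            raise ValueError("rois_per_patient probabilities must sum to 1")


def _scaled_beta(rng, lo: float, hi: float, median: float, nu: float) -> float:
    """Draw from lo + (hi-lo)*Beta(a, nu-a) with a chosen so the Beta median
    lands on (median-lo)/(hi-lo) (Kerman's median approximation)."""
    m = (median - lo) / (hi - lo)
    a = m * (nu - 2.0 / 3.0) + 1.0 / 3.0
    return lo + (hi - lo) * rng.beta(a, nu - a)


def _draw_composition(rng, model: dict, nu: float) -> TissueFractions:
    lo_f, hi_f = model["fsm_range"]
    cell = lum = fsm = None
    for _ in range(500):
        cell = _scaled_beta(rng, *model["cellularity"], nu)
        lum = _scaled_beta(rng, *model["luminal"], nu)
        fsm = 1.0 - cell - lum
        if lo_f <= fsm <= hi_f:
            break
    return TissueFractions(cellularity=cell, fsm=fsm, luminal=lum)


def _dki_from_composition(rng, frac: TissueFractions, link: dict):
    a0, a1, a2 = link["alpha"]
    b0, b1, b2 = link["beta"]
    d = a0 + a1 * frac.luminal - a2 * frac.cellularity
    d += rng.normal(0.0, link["sigma_d"])
    k = b0 + b1 * frac.cellularity - b2 * frac.fsm
    k += rng.normal(0.0, link["sigma_k"])
    d = float(np.clip(d, 0.05, 4.0))  # 10^-3 mm²/s, within model bounds
    k = float(np.clip(k, 0.01, 3.0))
    return d, k


def simulate_cohort(spec: CohortSimSpec) -> CohortTable:
    """Simulate a cohort of tumor ROIs with matched normal ROIs.

    Each patient draws a Gleason score (grouped low = <=3+4 vs high =
    >=4+3), 1-4 tumor ROIs and as many matched normal ROIs.  Compositions
    come from the group-conditional models; DKI medians from the linear
    links; ROI areas are log-uniform over the study's observed range.
    """
    rng = np.random.default_rng(spec.seed)
    gs_names = list(spec.gs_distribution)
    gs_probs = np.array([spec.gs_distribution[g] for g in gs_names])
    nu = spec.beta_concentration
    lo_a, hi_a = spec.roi_area_range

    records = []
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        gs = gs_names[rng.choice(len(gs_names), p=gs_probs)]
        group = "low" if gs in _GS_LOW else "high"
        tumor_model = (
            TUMOR_LOW_COMPOSITION if group == "low" else TUMOR_HIGH_COMPOSITION
        )
        n_rois = int(rng.choice(4, p=np.asarray(spec.rois_per_patient))) + 1
        for r in range(1, n_rois + 1):
            for tissue, model in (("tumor", tumor_model), ("normal", NORMAL_COMPOSITION)):
                frac = _draw_composition(rng, model, nu)
                d, k = _dki_from_composition(rng, frac, spec.dki_link)
                area = float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
                records.append(
                    ROIRecord(
                        patient_id=pid,
                        roi_id=f"{pid}-{tissue[0].upper()}{r}",
                        tissue=tissue,
                        gs_group=group if tissue == "tumor" else "none",
                        median_d_app=d,
                        median_k_app=k,
                        fractions=frac,
                        area_mm2=area,
                    )
                )
    return CohortTable(records=records)
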