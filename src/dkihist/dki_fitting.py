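"""Voxelwise noise-compensated fitting of the kurtosis model.

Each voxel's magnitude signals across b-values are fitted to the
noise-biased model

    S_n(b) = sqrt( (S0*exp(-b*D + b**2*D**2*K/6))**2 + n**2 )

by bounded non-linear least squares with the trust-region reflective
algorithm.  With ``n = 0`` this reduces to ordinary least squares on the
noise-free model.  Starting values come from an exact linearization:
``log S`` is a quadratic in ``b`` for noiseless data, so a linear
least-squares fit of ``log S = c0 + c1*b + c2*b**2`` yields
``s0 = exp(c0)``, ``d = -c1``, ``k = 6*c2/d**2``.

Fits are voxel-independent (no spatial regularization) and deterministic:
identical inputs produce bit-identical maps regardless of traversal order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .dki_core import (
    D_APP_MAX,
    K_APP_MAX,
    BValueScheme,
    DKIParams,
    NoiseEstimate,
    max_valid_bvalue,
)

__all__ = [
    "DWISeries",
    "FitConfig",
    "FitStatus",
    "ParameterMaps",
    "initialize_params",
    "fit_voxel",
    "fit_volume",
]

_S0_LOWER = 1e-12
_FALLBACK_D = 1.5e-3
_FALLBACK_K = 0.8


class FitStatus(enum.IntEnum):
    """Per-voxel fit diagnostic code."""

    OK = 0
    SKIPPED = 1
    NON_CONVERGED = 2
    AT_BOUND = 3
    BEYOND_BSTAR = 4


@dataclass(frozen=True)
class DWISeries:
    """4D multi-b diffusion-weighted magnitude volume.

    ``data`` is indexed (x, y, z, b-index) and aligned with ``scheme``;
    ``voxel_dims`` are mm per axis (in-plane pixel, in-plane pixel, slice
    spacing).
    """

    data: np.ndarray
    scheme: BValueScheme
    voxel_dims: tuple[float, float, float] = (1.25, 1.25, 5.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {data.shape}")
        if data.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension ({data.shape[3]}) must match number of "
                f"b-values ({len(self.scheme)})"
            )
        if np.any(data[np.isfinite(data)] < 0):
            raise ValueError("magnitude intensities must be >= 0")
        object.__setattr__(self, "data", data)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class FitConfig:
    """Bounds, convergence settings and noise model for the voxelwise fit.

    ``s0_bounds=None`` defers the upper S0 bound to 10x the maximum observed
    signal.  ``mask_threshold`` skips voxels whose lowest-b signal does not
    exceed ``mask_threshold * n``; with no noise estimate only exact zeros
    are skipped.
    """

    s0_bounds: tuple[float, float] | None = None
    d_bounds: tuple[float, float] = (1e-5, D_APP_MAX)
    k_bounds: tuple[float, float] = (0.0, K_APP_MAX)
    max_iterations: int = 200
    tolerance: float = 1e-8
    mask_threshold: float = 3.0
    noise: NoiseEstimate | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        for lo, hi in filter(None, (self.s0_bounds, self.d_bounds, self.k_bounds)):
            if not lo < hi:
                raise ValueError("bounds must satisfy lower < upper")

    @property
    def n(self) -> float:
        return self.noise.n if self.noise is not None else 0.0


@dataclass
class ParameterMaps:
    """Voxelwise fit output: parameter maps plus diagnostics.

    Non-ok voxels carry NaN in the parameter maps; ``status_map`` holds
    :class:`FitStatus` codes and ``rss_map`` the residual sum of squares of
    every attempted fit.
    """

    s0_map: np.ndarray
    d_app_map: np.ndarray
    k_app_map: np.ndarray
    status_map: np.ndarray
    rss_map: np.ndarray

    def __post_init__(self) -> None:
        shape = self.s0_map.shape
        for name in ("d_app_map", "k_app_map", "status_map", "rss_map"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape differs from s0_map shape {shape}")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.s0_map.shape

    def status_counts(self) -> dict[str, int]:
        return {
            status.name.lower(): int(np.sum(self.status_map == status))
            for status in FitStatus
        }


def _resolve_bounds(config: FitConfig, signals: np.ndarray):
    if config.s0_bounds is not None:
        s0_lo, s0_hi = config.s0_bounds
    else:
        s0_lo = _S0_LOWER
        s0_hi = 10.0 * max(float(np.max(signals)), _S0_LOWER)
    lb = np.array([s0_lo, config.d_bounds[0], config.k_bounds[0]])
    ub = np.array([s0_hi, config.d_bounds[1], config.k_bounds[1]])
    return lb, ub


def _clip_interior(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    # trust-region reflective needs a feasible start; nudge strictly inside
    span = ub - lb
    return np.clip(x, lb + 1e-12 * span, ub - 1e-12 * span)


def initialize_params(
    signals,
    scheme: BValueScheme,
    config: FitConfig | None = None,
) -> DKIParams:
    """Starting values from the exact log-quadratic linearization.

    Falls back to fixed prostate-typical defaults (d = 1.5e-3 mm²/s,
    k = 0.8, s0 = max signal) when any signal is non-positive, where the
    log transform is undefined.
    """
    config = config or FitConfig()
    signals = np.asarray(signals, dtype=float)
    lb, ub = _resolve_bounds(config, np.maximum(signals, _S0_LOWER))
    if np.any(signals <= 0) or not np.all(np.isfinite(signals)):
        x0 = np.array(
            [max(float(np.max(signals)), _S0_LOWER), _FALLBACK_D, _FALLBACK_K]
        )
    else:
        b = scheme.as_array
        c2, c1, c0 = np.polyfit(b, np.log(signals), 2)
        d = -c1
        s0 = float(np.exp(c0))
        k = 6.0 * c2 / (d * d) if d > 1e-12 else 0.0
        x0 = np.array([s0, d, k])
    x0 = _clip_interior(x0, lb, ub)
    return DKIParams(s0=float(x0[0]), d_app=float(x0[1]), k_app=float(x0[2]))


def fit_voxel(
    signals,
    scheme: BValueScheme,
    config: FitConfig | None = None,
) -> tuple[DKIParams, FitStatus, float]:
    """Fit one voxel's signals; return (params, status, residual sum of squares).

    Minimizes sum_b (signal_b - sqrt(model(b)**2 + n**2))**2 over bounded
    (s0, d_app, k_app) with the trust-region reflective algorithm, starting
    from :func:`initialize_params`.  Status records non-convergence, active
    box bounds, and fitted parameters whose turnover b* falls below the
    acquired b_max (in that order of precedence).
    """
    config = config or FitConfig()
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (len(scheme),):
        raise ValueError(
            f"expected {len(scheme)} signals, got shape {signals.shape}"
        )
    n = config.n
    b = scheme.as_array
    lb, ub = _resolve_bounds(config, signals)
    start = initialize_params(signals, scheme, config)
    x0 = _clip_interior(
        np.array([start.s0, start.d_app, start.k_app]), lb, ub
    )

    def residuals(x):
        model = x[0] * np.exp(-b * x[1] + b * b * x[1] * x[1] * x[2] / 6.0)
        return np.sqrt(model * model + n * n) - signals

    result = least_squares(
        residuals,
        x0,
        bounds=(lb, ub),
        method="trf",
        xtol=config.tolerance,
        ftol=config.tolerance,
        gtol=config.tolerance,
        max_nfev=config.max_iterations,
        x_scale=np.array([max(float(np.max(signals)), 1.0), 1e-3, 1.0]),
    )
    params = DKIParams(
        s0=float(result.x[0]), d_app=float(result.x[1]), k_app=float(result.x[2])
    )
    rss = 2.0 * float(result.cost)

    if result.status == 0:
        status = FitStatus.NON_CONVERGED
    elif np.any(result.active_mask != 0):
        status = FitStatus.AT_BOUND
    elif scheme.b_max > max_valid_bvalue(params):
        status = FitStatus.BEYOND_BSTAR
    else:
        status = FitStatus.OK
    return params, status, rss


def fit_volume(series: DWISeries, config: FitConfig | None = None) -> ParameterMaps:
    """Apply :func:`fit_voxel` independently to every foreground voxel.

    A voxel is fitted when its lowest-b signal exceeds
    ``mask_threshold * n`` (strictly greater, so an all-zero background is
    always skipped) and all its signals are finite.  Output is independent
    of traversal order; skipped and non-ok voxels carry NaN in the
    parameter maps.
    """
    config = config or FitConfig()
    shape = series.spatial_shape
    data = series.data
    if config.s0_bounds is None:
        # one volume-wide S0 bound keeps per-voxel fits mutually consistent
        config = replace(
            config, s0_bounds=(_S0_LOWER, 10.0 * max(float(data.max()), _S0_LOWER))
        )
    threshold = config.mask_threshold * config.n

    s0_map = np.full(shape, np.nan)
    d_map = np.full(shape, np.nan)
    k_map = np.full(shape, np.nan)
    status_map = np.full(shape, int(FitStatus.SKIPPED), dtype=np.int8)
    rss_map = np.full(shape, np.nan)

    for idx in np.ndindex(shape):
        sig = data[idx]
        if not np.all(np.isfinite(sig)) or sig[0] <= threshold:
            continue
        params, status, rss = fit_voxel(sig, series.scheme, config)
        status_map[idx] = int(status)
        rss_map[idx] = rss
        if status == FitStatus.OK:
            s0_map[idx] = params.s0
            d_map[idx] = params.d_app
            k_map[idx] = params.k_app
    return ParameterMaps(
        s0_map=s0_map,
        d_app_map=d_map,
        k_app_map=k_map,
        status_map=status_map,
        rss_map=rss_map,
    )
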