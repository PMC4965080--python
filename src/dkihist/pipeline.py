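"""End-to-end simulated study: cohort -> images -> fits/segmentation -> stats.

For every simulated ROI the pipeline synthesizes the measurements the study
made on real data:

1. a small DWI phantom carrying the ROI's true (S0, D_app, K_app) with
   Rician noise plus a matched noise-only volume; the noise level is
   re-estimated from the noise volume and the phantom is fitted with noise
   compensation; the ROI-median fitted D_app/K_app become the measured DKI
   values;
2. an H&E-like image with the ROI's true composition; positive-pixel
   segmentation recovers the measured fractions.

The measured cohort table then runs through the full comparison grid
(rank-sum tests and Spearman correlations).  Everything derives from one
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dki_core import BValueScheme, DKIParams, estimate_noise_level
from .dki_fitting import FitConfig, FitStatus, fit_volume
from .histo_segmentation import (
    SegmentationSettings,
    classify_pixels,
    compute_tissue_fractions,
    rasterize_roi,
)
from .io import write_cohort_csv
from .roi_stats import (
    CohortTable,
    ROIRecord,
    format_report,
    roi_median,
    run_study_analyses,
)
from .synthetic_data import (
    CohortSimSpec,
    DWIPhantomSpec,
    HistologyPhantomSpec,
    Region,
    simulate_cohort,
    simulate_dwi_phantom,
    simulate_histology_image,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("dkihist")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the simulated end-to-end study."""

    n_patients: int = 20
    seed: int = 0
    s0: float = 100.0
    snr: float = 50.0  # S0 / sigma_eff of the phantom acquisition
    averages: int = 8
    phantom_shape: tuple[int, int, int] = (12, 12, 1)
    noise_window: int = 11  # Wiener window for the small phantom planes
    noise_convention: str = "rayleigh_rms"
    histology_shape: tuple[int, int] = (80, 80)
    histology_mode: str = "exact_count"
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        seg = cfg.pop("segmentation", None)
        kwargs = {}
        for name in (
            "n_patients",
            "seed",
            "s0",
            "snr",
            "averages",
            "noise_window",
            "noise_convention",
            "histology_mode",
        ):
            if name in cfg:
                kwargs[name] = cfg[name]
        for name in ("phantom_shape", "histology_shape"):
            if name in cfg:
                kwargs[name] = tuple(cfg[name])
        if seg is not None:
            kwargs["segmentation"] = SegmentationSettings(**seg)
        return cls(**kwargs)


def _measure_roi_dki(record: ROIRecord, config: PipelineConfig, seed: int):
    """Fit a noisy single-region phantom built from the ROI's true values;
    return (median D_app in 10^-3 mm²/s, median K_app) or None if every
    voxel failed."""
    shape = config.phantom_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    radii = (shape[0] * 0.38, shape[1] * 0.38, max(shape[2] * 0.45, 0.55))
    params = DKIParams(
        s0=config.s0,
        d_app=record.median_d_app * 1e-3,
        k_app=record.median_k_app,
    )
    region = Region(kind="ellipsoid", center=center, radii=radii, params=params)
    sigma = config.s0 / config.snr * np.sqrt(config.averages)
    spec = DWIPhantomSpec(
        shape=shape,
        regions=(region,),
        sigma=sigma,
        averages=config.averages,
        seed=seed,
    )
    series, truth, noise_volume = simulate_dwi_phantom(spec)
    window = min(config.noise_window, min(shape[:2]))
    window -= 1 - window % 2  # keep odd
    noise = estimate_noise_level(
        noise_volume, window=window, convention=config.noise_convention
    )
    maps = fit_volume(series, FitConfig(noise=noise))
    roi_mask = truth.status_map == int(FitStatus.OK)
    try:
        d = roi_median(maps.d_app_map, roi_mask) * 1e3
        k = roi_median(maps.k_app_map, roi_mask)
    except ValueError:
        return None
    return d, k


def _measure_roi_fractions(record: ROIRecord, config: PipelineConfig, seed: int):
    spec = HistologyPhantomSpec(
        shape=config.histology_shape,
        target_fractions=record.fractions,
        mode=config.histology_mode,
        seed=seed,
    )
    image, polygon, _ = simulate_histology_image(spec)
    mask = rasterize_roi(polygon, image.shape[:2])
    classes = classify_pixels(image, mask, config.segmentation)
    return compute_tissue_fractions(classes)


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run simulate -> fit -> segment -> summarize -> analyze.

    Returns a dict with the truth and measured cohort tables (DataFrames),
    the 22-row analysis results, the text report, and per-stage metadata;
    optionally writes everything under ``out_dir``.
    """
    config = config or PipelineConfig()
    truth = simulate_cohort_truth(config)
    rng = np.random.default_rng(config.seed + 1)  # measurement-stage stream

    measured_records = []
    dropped = 0
    for record in truth.records:
        dki_seed = int(rng.integers(2**31))
        histo_seed = int(rng.integers(2**31))
        dki = _measure_roi_dki(record, config, dki_seed)
        if dki is None:
            dropped += 1
            logger.warning("ROI %s: no valid fitted voxels; dropped", record.roi_id)
            continue
        fractions = _measure_roi_fractions(record, config, histo_seed)
        measured_records.append(
            ROIRecord(
                patient_id=record.patient_id,
                roi_id=record.roi_id,
                tissue=record.tissue,
                gs_group=record.gs_group,
                median_d_app=dki[0],
                median_k_app=dki[1],
                fractions=fractions,
                area_mm2=record.area_mm2,
            )
        )
    measured = CohortTable(records=measured_records)
    results = run_study_analyses(measured)
    report = format_report(results)

    out = {
        "truth_table": truth.to_dataframe(),
        "measured_table": measured.to_dataframe(),
        "results": results,
        "report": report,
        "n_rois_dropped": dropped,
        "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(out["truth_table"], out_dir / "cohort_truth.csv")
        write_cohort_csv(out["measured_table"], out_dir / "cohort_measured.csv")
        results.to_csv(out_dir / "analysis_results.csv", index=False)
        (out_dir / "report.txt").write_text(report)
        (out_dir / "run.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "n_patients": config.n_patients,
                    "snr": config.snr,
                    "n_rois": len(measured_records),
                    "n_rois_dropped": dropped,
                    "noise_convention": config.noise_convention,
                },
                indent=2,
            )
        )
    return out


def simulate_cohort_truth(config: PipelineConfig) -> CohortTable:
    return simulate_cohort(CohortSimSpec(n_patients=config.n_patients, seed=config.seed))
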