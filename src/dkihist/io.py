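"""File formats: NIfTI volumes, FSL-style b-value text, ROI JSON, CSV, YAML.

All volumes are written as NIfTI-1 with a diagonal RAS+ affine built from
the voxel dimensions; parameter maps inherit the input affine.  The
diffusivity map is written in 10^-3 mm²/s, the reporting unit of the study
tables.  CSV files are UTF-8, comma-separated with a header row.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .dki_core import BValueScheme
from .dki_fitting import DWISeries, FitConfig, ParameterMaps

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_volume",
    "write_volume",
    "read_bvals",
    "write_bvals",
    "write_parameter_maps",
    "read_parameter_maps",
    "write_label_map",
    "read_roi_polygons",
    "write_roi_polygons",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_yaml_config",
]

logger = logging.getLogger("dkihist")

D_APP_REPORT_SCALE = 1e3  # mm²/s -> 10^-3 mm²/s


def _affine(voxel_dims) -> np.ndarray:
    aff = np.diag(list(voxel_dims) + [1.0])
    return aff


def read_bvals(path) -> list[float]:
    """Read a whitespace-separated FSL-style .bval text file."""
    text = Path(path).read_text()
    vals = [float(tok) for tok in text.split()]
    if not vals:
        raise ValueError(f"no b-values found in {path}")
    if any(v < 0 for v in vals):
        raise ValueError("b-values must be non-negative")
    return vals


def write_bvals(values, path) -> None:
    Path(path).write_text(" ".join(f"{v:g}" for v in values) + "\n")


def read_volume(path):
    """Read a NIfTI volume; returns (float array, voxel_dims)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def write_volume(data, path, voxel_dims=(1.25, 1.25, 5.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_dims))
    img.header.set_zooms(tuple(voxel_dims) + (1.0,) * (len(data.shape) - 3))
    nib.save(img, str(path))


def read_dwi(volume_path, bval_path) -> DWISeries:
    """Read a 4D DWI volume plus its b-value file into a validated series.

    Unsorted b-values are reordered (volumes reordered consistently) with a
    warning; a count mismatch or negative b raises.
    """
    data, voxel_dims = read_volume(volume_path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    bvals = read_bvals(bval_path)
    if len(bvals) != data.shape[3]:
        raise ValueError(
            f"b-value count ({len(bvals)}) does not match 4th dimension "
            f"({data.shape[3]})"
        )
    order = np.argsort(np.asarray(bvals), kind="stable")
    if not np.array_equal(order, np.arange(len(bvals))):
        warnings.warn("b-values were unsorted; volumes reordered to match")
        logger.warning("b-values were unsorted; volumes reordered to match")
        data = data[..., order]
        bvals = [bvals[i] for i in order]
    return DWISeries(data=data, scheme=BValueScheme(tuple(bvals)), voxel_dims=voxel_dims)


def write_dwi(series: DWISeries, volume_path, bval_path) -> None:
    write_volume(series.data, volume_path, series.voxel_dims)
    write_bvals(series.scheme.values, bval_path)


def write_parameter_maps(
    maps: ParameterMaps,
    out_dir,
    voxel_dims=(1.25, 1.25, 5.0),
    config: FitConfig | None = None,
) -> dict:
    """Write s0/d_app/k_app/status/rss NIfTI maps plus a JSON fit report.

    The d_app map is scaled to 10^-3 mm²/s.  Returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(maps.s0_map, out_dir / "s0.nii.gz", voxel_dims)
    write_volume(
        maps.d_app_map * D_APP_REPORT_SCALE, out_dir / "d_app.nii.gz", voxel_dims
    )
    write_volume(maps.k_app_map, out_dir / "k_app.nii.gz", voxel_dims)
    write_volume(maps.status_map.astype(float), out_dir / "status.nii.gz", voxel_dims)
    write_volume(maps.rss_map, out_dir / "rss.nii.gz", voxel_dims)
    report = {
        "status_counts": maps.status_counts(),
        "d_app_units": "1e-3 mm^2/s",
        "config": None
        if config is None
        else {
            "d_bounds": list(config.d_bounds),
            "k_bounds": list(config.k_bounds),
            "max_iterations": config.max_iterations,
            "tolerance": config.tolerance,
            "mask_threshold": config.mask_threshold,
            "noise_n": config.n,
            "noise_convention": None
            if config.noise is None
            else config.noise.convention,
        },
    }
    (out_dir / "fit_report.json").write_text(json.dumps(report, indent=2))
    return report


def read_parameter_maps(out_dir) -> ParameterMaps:
    """Read maps written by :func:`write_parameter_maps` (d_app rescaled
    back to mm²/s)."""
    out_dir = Path(out_dir)
    s0, _ = read_volume(out_dir / "s0.nii.gz")
    d, _ = read_volume(out_dir / "d_app.nii.gz")
    k, _ = read_volume(out_dir / "k_app.nii.gz")
    status, _ = read_volume(out_dir / "status.nii.gz")
    rss, _ = read_volume(out_dir / "rss.nii.gz")
    return ParameterMaps(
        s0_map=s0,
        d_app_map=d / D_APP_REPORT_SCALE,
        k_app_map=k,
        status_map=status.astype(np.int8),
        rss_map=rss,
    )


def write_label_map(labels: np.ndarray, path) -> None:
    """Write a segmentation label map as a single-channel 8-bit image
    (0=luminal background, 1=positive, 2=negative, 255=outside ROI)."""
    iio.imwrite(str(path), np.asarray(labels, dtype=np.uint8))


def read_roi_polygons(path) -> list[dict]:
    """Read ROI polygons: a JSON list of {"label": str, "vertices": [[x,y],...]}."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    for entry in data:
        if "vertices" not in entry:
            raise ValueError("each ROI entry needs a 'vertices' key")
    return data


def write_roi_polygons(rois: list[dict], path) -> None:
    Path(path).write_text(json.dumps(rois, indent=2))


def read_cohort_csv(path) -> pd.DataFrame:
    from .roi_stats import COHORT_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_yaml_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError("config YAML must contain a mapping")
    return cfg
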