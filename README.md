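# dkihist

Noise-compensated diffusional kurtosis imaging (DKI) parameter mapping,
positive-pixel histology tissue-composition quantification, and the
rank-based statistics linking the two — with synthetic-data generators so
the entire analysis is runnable and testable without any imaging data.

## The scientific problem

Prostate cancer alters tissue microstructure: tumors are more cellular,
have less fibromuscular stroma and less glandular luminal space than normal
peripheral-zone tissue, and these shifts intensify with Gleason grade.
Diffusion-weighted MRI probes the same microstructure non-invasively. The
kurtosis representation of the direction-averaged signal decay is

```
S(b) = S0 · exp(−b·D_app + (1/6)·b²·D_app²·K_app)
```

with diffusion weighting `b` (s/mm², here 150/600/1050/1500), apparent
diffusivity `D_app` (mm²/s) and apparent kurtosis `K_app` (unitless, a
measure of non-Gaussian diffusion and hence tissue heterogeneity). Magnitude
MRI carries Rician noise, which floors the signal at high `b`; with noise
parameter `n` estimated from a noise-only acquisition, each voxel is fitted
to the biased model

```
S_n(b) = sqrt(S(b)² + n²)
```

by bounded trust-region non-linear least squares, yielding `D_app`/`K_app`
maps. On the histology side, H&E-stained sections are partitioned by a
hue-window rule (hue 0.7, window 0.35 on the [0,1) hue circle) into
cellularity (positive), fibromuscular stromal matrix (negative) and luminal
space (unstained), and fractional areas are pixel-count ratios over each
region of interest (ROI). ROI-level medians and fractions are then compared
with Wilcoxon rank-sum tests (tumor vs normal, high- vs low-grade) and
Spearman rank correlations (composition vs DKI medians, per tissue
stratum).

The package is aimed at researchers in quantitative MRI / radiology–
pathology correlation who want a reproducible, tested reference
implementation of this analysis chain.

## Worked example

Simulate an aggressive-tumor phantom (`D_app = 1.08×10⁻³ mm²/s`,
`K_app = 1.28`, S0/σ = 50), estimate the noise level from the matching
noise-only volume, and fit with noise compensation:

```python
import math
from dkihist import (BValueScheme, DKIParams, FitConfig, FitStatus,
                     estimate_noise_level, fit_volume, roi_median)
from dkihist.synthetic_data import DWIPhantomSpec, Region, simulate_dwi_phantom

region = Region(kind="box", center=(11.5, 11.5, 0.5), radii=(9.5, 9.5, 0.5),
                params=DKIParams(s0=100.0, d_app=1.08e-3, k_app=1.28))
spec = DWIPhantomSpec(shape=(24, 24, 2), regions=(region,),
                      sigma=2.0 * math.sqrt(8), averages=8, seed=1)
series, truth, noise_volume = simulate_dwi_phantom(spec)

noise = estimate_noise_level(noise_volume, window=21)
print(f"noise parameter n = {noise.n:.3f} ({noise.convention})")

maps = fit_volume(series, FitConfig(noise=noise))
print("status counts:", maps.status_counts())

roi = truth.status_map == int(FitStatus.OK)
print(f"ROI median D_app = {roi_median(maps.d_app_map, roi) * 1e3:.3f}")
print(f"ROI median K_app = {roi_median(maps.k_app_map, roi):.3f}")
```

Output:

```
noise parameter n = 2.804 (rayleigh_rms)
status counts: {'ok': 784, 'skipped': 352, 'non_converged': 0, 'at_bound': 2, 'beyond_bstar': 14}
ROI median D_app = 1.075
ROI median K_app = 1.253
```

`n ≈ 2.8` is √2 × the effective channel noise (σ_eff = 2), the value that
makes the bias model the exact root second moment of Rician data; the ROI
medians land within 0.5% (D_app, in 10⁻³ mm²/s) and 2% (K_app) of the
programmed truth. Background voxels fall below the 3·n mask threshold and
are skipped; a handful of noisy voxels end at a box bound or imply a model
turnover b\* = 3/(D_app·K_app) below the top acquired b-value and are
flagged rather than silently kept.

The same stages are scriptable from the shell (`dkihist --help`):
`simulate-dwi`, `simulate-histology`, `simulate-cohort`, `fit`, `segment`,
`summarize`, `analyze`, and `pipeline`, which runs a full 20-patient
simulated study (cohort → per-ROI phantoms and histology images → fitting
and segmentation → the 22-row statistics grid) from one seed.

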