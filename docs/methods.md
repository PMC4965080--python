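# Methods

## Signal model and noise compensation

The kurtosis representation of the direction-averaged diffusion signal,

    S(b) = S0 · exp(−b·D_app + (1/6)·b²·D_app²·K_app),

is a second-order cumulant expansion: it is accurate for moderate `b` and
turns unphysically upward at b\* = 3/(D_app·K_app). The default b-value
scheme (150, 600, 1050, 1500 s/mm²) deliberately starts above b = 100 to
avoid pseudoperfusion contamination and tops out below b\* for typical
prostate parameters (b\* ≈ 2600 s/mm² at the tumor medians). Fits whose
parameters imply b\* below the top acquired b-value are flagged
(`beyond_bstar`), not rejected: the flag marks voxels where the model left
its monotone regime, a diagnostic the user should treat as suspect.

Magnitude reconstruction of complex Gaussian data makes the measured signal
Rician. We compensate at the level of the first/second moment: the fit
target is `S_n = sqrt(S² + n²)`, which is exactly the root second moment of
a Rician variate when `n = √2·σ` (per-channel noise σ). The noise parameter
comes from a noise-only acquisition: each 2D plane is smoothed with a
pixelwise adaptive Wiener (local linear minimum-mean-square, "Lee") filter,

    out = μ + max(0, v − ν²)/max(v, ν²) · (x − μ),

with window-local mean μ and variance v (default window 25 px, reflection
padding) and noise power ν² set to the mean local variance; the global mean
m of the smoothed image is then converted to `n`. Two conversions are
provided. `rayleigh_rms` (default): `n = 2m/√π = √2·σ`, self-consistent
with the bias model above because the mean of a Rayleigh background is
`σ·√(π/2)`. `paper_literal`: `n = m·π/2` ("mean divided by 2/π"), a
convention found in the applied literature; dividing a Rayleigh mean by 2/π
yields neither σ nor √2·σ, so it is offered for comparability only and
every estimate records its convention. Single-coil Rician statistics are
assumed throughout; non-central-chi noise from multi-coil reconstruction is
out of scope.

## Voxelwise fitting

Each voxel minimizes Σ_b (y_b − sqrt(model(b)² + n²))² over (S0, D_app,
K_app) with the trust-region reflective algorithm and box bounds
S0 ∈ (0, 10·max signal], D_app ∈ [10⁻⁵, 4×10⁻³] mm²/s, K_app ∈ [0, 3] —
generous around the physiological range, and capping the degenerate
k → ∞ ridge. Starting values use the exact linearization log S = c0 + c1·b
+ c2·b² (noiseless data make this exact; d = −c1, k = 6·c2/d²), clipped
into bounds, with fixed fallbacks (d = 1.5×10⁻³, k = 0.8) when a signal is
non-positive. Convergence tolerances are 10⁻⁸ on relative step, cost and
gradient with at most 200 function evaluations — at four data points this
is cheap and delivers ≤10⁻⁶ relative recovery on noiseless data, which the
tests assert. Parameters are internally scaled (x_scale ≈ [S0, 10⁻³, 1])
so the trust region treats the three axes comparably.

Per-voxel status is one of ok / skipped / non_converged / at_bound /
beyond_bstar (first match in that precedence); non-ok voxels carry NaN in
the parameter maps and are excluded from ROI medians, with the residual sum
of squares retained for every attempted fit. Volume fitting masks out
voxels whose lowest-b signal does not exceed 3·n (background); fits are
voxel-independent with no spatial regularization, so maps are bit-identical
across runs and traversal orders. With no noise estimate the objective
reduces to ordinary least squares on the noise-free model.

At the study's operating point (S0/σ ≈ 50) the noise floor is a small
perturbation and the free kurtosis term absorbs most of it, so the
uncompensated bias appears mainly in K_app and only secondarily in D_app;
the tests check both a deterministic expectation-level comparison and a
fixed-seed Monte-Carlo one.

## Histology segmentation

RGB pixels inside an ROI are converted by the standard hexcone HSV
transform (hue normalized to [0, 1)) and partitioned: background/luminal if
saturation < 0.05 or value ≥ 0.94 (unstained, near-white); otherwise
positive/cellularity if the circular hue distance
min(|h−c|, 1−|h−c|) to the window center (default 0.7, blue-purple
hematoxylin) is at most half the window width (default 0.35); otherwise
negative/stroma (eosin pink). The three labels partition the ROI exactly,
so the fractional areas sum to 1 and luminal space is the complement of the
two stained classes. The vendor-style weak/medium/strong positivity tiers
are collapsed into one positive class — only the binary split enters the
fractions — and per-slide manual retuning is represented as per-image
settings overrides, not an auto-tuner. The saturation/brightness thresholds
are this package's declared defaults, not a reconstruction of any vendor's
internal rule.

ROI polygons use 0-based pixel coordinates; a pixel belongs to the ROI iff
its center (col+0.5, row+0.5) lies strictly inside the polygon (even-odd
rule for the simple polygons we accept). Centers exactly on an edge count
as outside; with integer-vertex polygons and half-integer centers this
arises only on 45° edges and is deterministic.

## Statistics

The unit of analysis is the ROI, not the patient; matched tumor/normal
regions are compared with the *unpaired* Wilcoxon rank-sum test and
within-patient clustering is not modeled, replicating the original
univariate design (the report header carries this caveat). Aggregation to
one ROI per patient, if wanted, is a one-line groupby on the cohort table
before calling the analysis.

Rank-sum: midranks over the pooled sample; for n1+n2 ≤ 20 the two-sided p
is computed by exact enumeration of all C(n1+n2, n1) assignments of the
pooled midranks — a conditional permutation test that is equally valid with
ties (enumeration with midranks is the standard conditional-on-ties exact
test, and it makes identical groups return p = 1 exactly). Larger samples
use the normal approximation with tie-corrected variance and a continuity
correction. Spearman: Pearson correlation of midranks with a two-sided p
from t = ρ·√((n−2)/(1−ρ²)) on n−2 df; |ρ| = 1 reports p = 0. No
multiple-testing correction is applied, matching the original analysis; the
text report flags p < 0.05.

The full grid is fixed at 22 rows: 5 tumor-vs-normal tests (three
fractions, two DKI medians), 5 Gleason-group tests (≥4+3 vs ≤3+4, tumors
only), and 12 Spearman cells (3 fractions × 2 DKI medians × 2 tissue
strata).

## Synthetic data

*DWI phantoms* place box/ellipsoid regions of constant (S0, D_app, K_app)
in a zero background, apply Rician noise as |(S+ε₁) + i·ε₂| with per-channel
ε ~ N(0, σ²/averages) (default 8 averages, modeling a multi-average
acquisition; σ_eff = σ/√averages), and emit an identically-acquired
noise-only volume. They emulate the SNR regime and noise statistics of the
acquisition, not anatomy, partial volume, EPI distortion or motion — so
parameter-recovery results speak to estimator behavior under Rician noise,
not to co-registration or segmentation error on real data.

*Histology phantoms* apportion the image's pixels to the three classes by
largest-remainder rounding of the target fractions (exact composition by
construction), arrange them as blobs by thresholding a seeded
Gaussian-smoothed noise field (blob scale 6 px), and paint clean class
colors chosen well inside/outside the default hue window; `textured` mode
adds small per-pixel HSV jitter. They validate counting and the
classification rule, not stain variability or scanner white balance.

*Cohorts* follow the study's shape: 20 patients by default, Gleason
distribution (3+3 / 3+4 / 4+3 / ≥8) = (0.15, 0.45, 0.30, 0.10) grouped as
low = ≤3+4 vs high = ≥4+3, 1–4 tumor ROIs per patient (probabilities
0.35/0.40/0.20/0.05, mean ≈ 2) each with a matched normal ROI, ROI areas
log-uniform on 3.1–365.4 mm². Cellularity and luminal fractions are scaled
Beta draws (concentration 16, support equal to the published group ranges,
shape chosen so the Beta median hits the published group median via the
(a−1/3)/(a+b−2/3) approximation); stroma is 1 − cell − luminal, resampled
until it falls in its published range. DKI medians follow linear links

    D_app = 1.806 + 3.0·luminal − 1.4·cellularity + N(0, 0.10)   [10⁻³ mm²/s]
    K_app = 1.59 + 0.5·cellularity − 2.0·fsm + N(0, 0.12)

clipped to (0.05, 4.0) and (0.01, 3.0). The coefficients solve the group
medians exactly at the published compositions; the noise scales set the
within-group spread so the significant correlation magnitudes land in the
0.45–0.65 band. `scripts/calibrate_cohort.py` reruns this check. The
generator claims to match published medians, ranges and correlation signs —
not the unknown real joint distribution, and not within-patient
correlation (ROIs are drawn independently given the patient's grade group).

## End-to-end pipeline

`pipeline` measures every simulated ROI the way the study measured real
ones: a 12×12×1 single-region phantom at S0 = 100, S0/σ_eff = 50 (8
averages) is fitted with the noise level re-estimated from its noise-only
companion (Wiener window clamped to the plane size), and ROI medians of the
fitted maps become the measured DKI values; an 80×80 exact-count histology
image of the ROI's true composition is segmented for the measured
fractions. These problem sizes keep a full 20-patient study (~80 ROIs,
~8000 voxel fits) around ten seconds while leaving enough voxels per ROI
for stable medians. ROIs whose fits all fail (possible only at extreme
noise) are dropped with a logged warning rather than imputed. The measured
table then runs through the 22-row grid; with the default calibration the
direction and significance of every published significant effect is
reproduced, which the acceptance-level test asserts.

## Known limitations

- Single-coil Rician noise only; the second-moment bias target `sqrt(S²+n²)`
  is not the exact Rician mean, leaving a small residual bias at very low SNR.
- The cumulant model is used strictly below b\*; no constrained fitting ties
  b\* to the scheme, only flagging.
- Segmentation operates on clean or mildly jittered synthetic colors; real
  H&E stain variation, pixel-size conversion to mm², and histology→MRI
  co-registration are out of scope.
- The statistics treat ROIs as independent; p-values on the simulated
  cohort inherit that assumption just as the original design did.
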