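"""One-off calibration check of the cohort simulator defaults.

Simulates a large cohort (2000 patients) from the default spec and prints
group medians of composition and DKI parameters plus the Spearman
correlation grid, for comparison with the published group medians and the
signs/magnitudes of the significant correlations.  Used once to fix the
link coefficients and noise scales that ship as the module defaults; it is
a diagnostic, not part of the pipeline.

Run:  python scripts/calibrate_cohort.py [--n-patients 2000] [--seed 0]
"""

from __future__ import annotations

import argparse

import numpy as np

from dkihist.roi_stats import spearman_correlation
from dkihist.synthetic_data import CohortSimSpec, simulate_cohort

TARGET_MEDIANS = {
    # (tissue or GS group) -> (cellularity, fsm, luminal, D_app, K_app)
    "normal": (0.24, 0.55, 0.20, 2.07, 0.59),
    "tumor": (0.39, 0.50, 0.09, 1.53, 0.75),
    "gs_low": (0.38, 0.52, 0.09, 1.74, 0.72),
    "gs_high": (0.44, 0.45, 0.09, 1.41, 0.87),
}
TARGET_RHO = {
    ("normal", "median_d_app", "cellularity"): -0.487,
    ("normal", "median_d_app", "luminal"): 0.648,
    ("tumor", "median_k_app", "cellularity"): 0.499,
    ("tumor", "median_k_app", "fsm"): -0.445,
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-patients", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    df = simulate_cohort(
        CohortSimSpec(n_patients=args.n_patients, seed=args.seed)
    ).to_dataframe()
    groups = {
        "normal": df[df.tissue == "normal"],
        "tumor": df[df.tissue == "tumor"],
        "gs_low": df[df.gs_group == "low"],
        "gs_high": df[df.gs_group == "high"],
    }
    cols = ("cellularity", "fsm", "luminal", "median_d_app", "median_k_app")
    print(f"{'group':<8} " + " ".join(f"{c:>14}" for c in cols))
    for name, g in groups.items():
        med = [g[c].median() for c in cols]
        tgt = TARGET_MEDIANS[name]
        print(
            f"{name:<8} "
            + " ".join(f"{m:7.3f}/{t:<6.3f}" for m, t in zip(med, tgt))
            + f"   (n={len(g)})  [simulated/target]"
        )
    print()
    for (stratum, dki, frac), target in TARGET_RHO.items():
        g = groups[stratum]
        res = spearman_correlation(g[dki].to_numpy(), g[frac].to_numpy())
        print(
            f"rho({dki}, {frac} | {stratum}) = {res.statistic:+.3f}"
            f"   target {target:+.3f}"
        )


if __name__ == "__main__":
    main()
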