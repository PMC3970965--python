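#!/usr/bin/env python
"""Calibration and power of the synonymous-site depletion statistic.

Part 1 (type-I behaviour): 200 neutral CDS pairs at the default study
divergence; pools all 25-codon sliding windows and reports the fraction
with depletion p < 0.05 alongside the mean window expectation, making the
conservatism of the discrete Poisson lower tail visible.

Part 2 (power/localization): 50 pairs with a 50-codon window in which
synonymous substitution is fully suppressed (multiplier 0) at pairwise
synonymous divergence p-hat ~ 0.3; reports how often the minimum-p window
falls within +/-13 and +/-25 codons of the planted center, and the median
minimum ratio/p inside the planted window.

Writes results/syncon_calibration.tsv and results/syncon_power.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dicistro import syncon
from dicistro import synthetic_data as sd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def neutral_calibration(n_rep: int = 200, seed0: int = 10_000) -> pd.DataFrame:
    rows = []
    for i in range(n_rep):
        pair = sd.evolve_pair(sd.EvolvedPairSpec(seed=seed0 + i))
        prof = syncon.profile_alignment(pair.alignment, 25, 1)
        pvals = np.array([w.p_value for w in prof.windows])
        exps = np.array([w.exp for w in prof.windows])
        rows.append(
            {
                "replicate": i,
                "n_windows": len(pvals),
                "frac_p_lt_05": float((pvals < 0.05).mean()),
                "mean_exp_w": float(exps.mean()),
                "p_hat": prof.p_hat,
            }
        )
    return pd.DataFrame(rows)


def planted_power(n_rep: int = 50, seed0: int = 20_000) -> pd.DataFrame:
    center = 300.5
    rows = []
    for i in range(n_rep):
        spec = sd.EvolvedPairSpec(
            n_codons=600, syn_rate=0.20, nonsyn_rate=0.03,
            conserved_window=(276, 325, 0.0), seed=seed0 + i,
        )
        prof = syncon.profile_alignment(sd.evolve_pair(spec).alignment, 25, 1)
        best = min(prof.windows, key=lambda w: w.p_value)
        inside = [w for w in prof.windows if w.start >= 276 and w.end <= 325]
        rows.append(
            {
                "replicate": i,
                "p_hat": prof.p_hat,
                "minp_center": best.center,
                "deviation": best.center - center,
                "min_ratio_inside": min(w.ratio for w in inside),
                "min_p_inside": min(w.p_value for w in inside),
            }
        )
    return pd.DataFrame(rows)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    cal = neutral_calibration()
    cal.to_csv(RESULTS / "syncon_calibration.tsv", sep="\t", index=False)
    pooled = cal["frac_p_lt_05"] * cal["n_windows"]
    frac = pooled.sum() / cal["n_windows"].sum()
    print(f"neutral calibration over {len(cal)} pairs "
          f"({int(cal['n_windows'].sum())} windows):")
    print(f"  pooled fraction of windows with p<0.05 = {frac:.4f}")
    print(f"  mean window expectation exp_w = {cal['mean_exp_w'].mean():.2f}, "
          f"mean p_hat = {cal['p_hat'].mean():.3f}")
    print("  (the discrete Poisson lower tail is conservative at these "
          "window means: achieved level sits well below the nominal 0.05)")

    pw = planted_power()
    pw.to_csv(RESULTS / "syncon_power.tsv", sep="\t", index=False)
    within13 = (pw["deviation"].abs() <= 13).mean()
    within25 = (pw["deviation"].abs() <= 25).mean()
    print(f"\nplanted 50-codon multiplier-0 window over {len(pw)} pairs "
          f"(mean p_hat = {pw['p_hat'].mean():.3f}):")
    print(f"  min-p window within +/-13 codons of center: {within13:.2f}")
    print(f"  min-p window within +/-25 codons of center: {within25:.2f}")
    print(f"  median min ratio inside window: {pw['min_ratio_inside'].median():.3f}; "
          f"median min p inside: {pw['min_p_inside'].median():.2e}")


if __name__ == "__main__":
    main()
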