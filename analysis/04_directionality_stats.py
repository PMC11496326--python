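#!/usr/bin/env python
"""Directional asymmetry statistics for functional and evoked connectivity.

Three analyses:

1. Single-recording contact-pair tests: for each metric (GC/DTF/PDC) and
   band, region pairs are pooled from the matrices written by script 02
   and tested with the two-level ANOVA plus the element-wise asymmetry
   t-test. With a single synthetic patient these serve as a worked
   example; their contact-pair observations share one fitted model, so
   the cohort analysis below is the calibrated test.
2. Cohort ANOVA: four independently drawn patients (300 s each), pooling
   one value per patient and direction — the region pair acting as a
   between-subject factor.
3. Evoked (CCEP) ANOVA over the z table from script 03.

Writes results/directionality_single.csv, _cohort.csv, _ccep.csv and a
plain-text summary of favored directions with significance stars.
"""

from pathlib import Path

import pandas as pd

from mtlnet.pipeline import cohort_directionality
from mtlnet.stats import (
    anova_direction,
    asymmetry_differences,
    pool_ccep_pairs,
    pool_region_pairs,
    ttest_zero_mean,
)

ROOT = Path(__file__).resolve().parents[1]
BANDS = ("delta", "theta", "alpha", "beta", "low_gamma")
METRICS = ("gc", "dtf", "pdc")


def single_recording_tests():
    rows = []
    for metric in METRICS:
        for band in BANDS:
            path = ROOT / "results" / f"connectivity_{metric}_{band}.csv"
            df = pd.read_csv(path, index_col=0)
            labels = list(df.index)
            region_of = {l: l[:-1] for l in labels}
            groups = pool_region_pairs(df.values, labels, region_of,
                                       metric=metric.upper(), band=band)
            diffs = asymmetry_differences(df.values, labels, region_of)
            n_comp = len(groups) * len(BANDS)
            for g in groups:
                r = anova_direction(g, n_comparisons=n_comp)
                t = ttest_zero_mean(diffs[g.pair], pair=g.pair, band=band,
                                    metric=metric.upper())
                rows.append({
                    "metric": metric.upper(), "band": band,
                    "pair": f"{g.pair[0]}-{g.pair[1]}",
                    "direction": r.favored, "F": r.F, "df2": r.df2,
                    "p_raw": r.p, "p_corrected": r.p_corrected,
                    "stars": r.stars, "t_asym": t.t, "p_asym": t.p,
                })
    return pd.DataFrame(rows)


def main():
    outdir = ROOT / "results"
    single = single_recording_tests()
    single.to_csv(outdir / "directionality_single.csv", index=False)

    cohort = cohort_directionality(n_patients=4, duration=300.0, seed=1,
                                   bands=("beta", "low_gamma"))
    cohort.to_csv(outdir / "directionality_cohort.csv", index=False)

    ccep = pd.read_csv(outdir / "ccep_responses.csv")
    groups = pool_ccep_pairs(ccep)
    rows = []
    for g in groups:
        r = anova_direction(g, n_comparisons=len(groups))
        rows.append({
            "pair": f"{g.pair[0]}-{g.pair[1]}", "direction": r.favored,
            "n_fwd": r.n_fwd, "n_rev": r.n_rev, "F": r.F, "df2": r.df2,
            "p_raw": r.p, "p_corrected": r.p_corrected, "stars": r.stars,
        })
    ccep_tab = pd.DataFrame(rows)
    ccep_tab.to_csv(outdir / "directionality_ccep.csv", index=False)

    lines = ["favored directions (cohort GC, Bonferroni-corrected):"]
    for _, r in cohort.iterrows():
        lines.append(f"  {r['pair']:8s} {r['band']:10s} {r['direction']:10s}"
                     f" F={r['F']:8.2f}  p_corr={r['p_corrected']:.2e} "
                     f"{r['stars']}")
    lines.append("evoked network (CCEP z-scores):")
    for _, r in ccep_tab.iterrows():
        lines.append(f"  {r['pair']:8s} {r['direction']:10s}"
                     f" F={r['F']:8.2f}  p_corr={r['p_corrected']:.2e} "
                     f"{r['stars']}")
    summary = "\n".join(lines)
    (outdir / "directionality_summary.txt").write_text(summary + "\n")
    print(summary)


if __name__ == "__main__":
    main()
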