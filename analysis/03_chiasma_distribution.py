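"""Chiasma-count distribution analysis.

Reads results/data/chiasma_*.csv and, per scenario: summary statistics
(mean, range, percent of cells within 6-8 chiasmata, univalent
frequency), the Poisson expectation for the same 6-8 window at the
sample mean, and the Poisson goodness-of-fit in both the conventional
12-bin form and the pooled-bin form. Ends with the rank-sum comparison
of the two scenarios. Writes results/chiasma_stats.csv.
"""

import pathlib

import pandas as pd

from tetracross.chiasma import (
    poisson_gof,
    poisson_range_proportion,
    rank_test_counts,
    summarize,
)
from tetracross.io import read_chiasma_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    samples = {}
    for name in ("wildtype_like", "mutant_like"):
        sample = read_chiasma_table(ROOT / "data" / f"chiasma_{name}.csv")[name]
        samples[name] = sample
        s = summarize(sample)
        expected_pct = 100.0 * poisson_range_proportion(s["mean"], 6, 8)
        gof_pooled = poisson_gof(sample, mode="pooled")
        gof_conv = poisson_gof(sample, mode="conventional")
        print(f"{name}: mean {s['mean']:.2f}, range {s['range']}, "
              f"{s['percent_in_range']:.0f}% of cells with 6-8 chiasmata "
              f"(Poisson expectation {expected_pct:.1f}%)")
        if "univalent_frequency_percent" in s:
            print(f"  univalent frequency {s['univalent_frequency_percent']:.1f}%")
        print(f"  Poisson GOF pooled: chi2 = {gof_pooled.chi2:.1f}, df = {gof_pooled.df}, "
              f"P = {gof_pooled.p:.3g}; 12-bin: chi2 = {gof_conv.chi2:.1f}, "
              f"df = {gof_conv.df}, P = {gof_conv.p:.3g}")
        rows.append(dict(scenario=name, mean=s["mean"], lo=s["range"][0], hi=s["range"][1],
                         pct_6_8=s["percent_in_range"], poisson_pct_6_8=expected_pct,
                         univalent_pct=s.get("univalent_frequency_percent", 0.0),
                         chi2_pooled=gof_pooled.chi2, df_pooled=gof_pooled.df, p_pooled=gof_pooled.p,
                         chi2_12bin=gof_conv.chi2, df_12bin=gof_conv.df, p_12bin=gof_conv.p))

    cmp = rank_test_counts(samples["wildtype_like"].counts, samples["mutant_like"].counts)
    print(f"rank-sum wild-type-like vs mutant-like: U = {cmp['statistic']:.0f}, P = {cmp['p']:.3g}")
    pd.DataFrame(rows).to_csv(ROOT / "chiasma_stats.csv", index=False)
    print(f"wrote {ROOT / 'chiasma_stats.csv'}")


if __name__ == "__main__":
    main()
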