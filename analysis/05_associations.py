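#!/usr/bin/env python
"""Association statistics over the packaged cell-line summary table.

Recomputes the headline statistics: OLS of invasiveness and IC50 on mean
stiffness, group comparisons by distribution pattern, median
dichotomization cutoffs, the pattern-by-morphology chi-squared, and a
housekeeping-normalized differential-expression run on a synthetic
expression table with planted fold changes. Writes
results/associations.json and results/diffexpr.csv.
"""

import json
import sys
from pathlib import Path

from cellmech.simgen import gen_expression_table
from cellmech.stats_assoc import (
    chi2_categorical,
    compare_groups,
    dichotomize,
    diff_expression,
    linreg,
    load_table1,
    normalize_expression,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> int:
    OUT.mkdir(exist_ok=True)
    t1 = load_table1()
    results = {}

    r_inv = linreg(t1.mean_E_kPa, t1.invasiveness_score)
    r_ic = linreg(t1.mean_E_kPa, t1.ic50_uM)
    results["invasiveness_vs_stiffness"] = {
        "r_squared": round(r_inv.r_squared, 2), "p": round(r_inv.p_value, 2)
    }
    results["ic50_vs_stiffness"] = {
        "r_squared": round(r_ic.r_squared, 2), "p": round(r_ic.p_value, 2)
    }
    print(f"invasiveness ~ mean E: R2 {r_inv.r_squared:.2f}, p {r_inv.p_value:.2f}")
    print(f"IC50 ~ mean E:        R2 {r_ic.r_squared:.2f}, p {r_ic.p_value:.2f}")

    inv = compare_groups(t1.invasiveness_score, t1.pattern)
    cv = compare_groups(t1.cv_percent, t1.pattern)
    results["invasiveness_by_pattern"] = {
        k: round(v) for k, v in inv.group_means.items()
    }
    results["cv_by_pattern"] = {k: round(v) for k, v in cv.group_means.items()}
    print(
        f"invasiveness by pattern: bimodal {inv.group_means['Bimodal']:.0f} vs "
        f"unimodal {inv.group_means['Gaussian']:.0f} (p {inv.p_value:.2f}, {inv.method})"
    )
    print(
        f"CV% by pattern: bimodal {cv.group_means['Bimodal']:.0f} vs "
        f"unimodal {cv.group_means['Gaussian']:.0f} (p {cv.p_value:.3f}, {cv.method})"
    )

    _, ic50_cut = dichotomize(t1.ic50_uM)
    _, cv_cut = dichotomize(t1.cv_percent)
    results["median_cutoffs"] = {"ic50_uM": round(ic50_cut), "cv_percent": round(cv_cut)}
    print(f"median cutoffs: IC50 {ic50_cut:.1f} µM, CV% {cv_cut:.1f}")

    table = (
        t1.assign(morph=t1.morph_class, pat=t1.pattern)
        .groupby(["morph", "pat"])
        .size()
        .unstack(fill_value=0)
    )
    chi = chi2_categorical(table.to_numpy())
    results["pattern_by_morphology_chi2"] = {
        "statistic": round(chi.statistic, 3), "p": round(chi.p_value, 2)
    }
    print(f"pattern x morphology: chi2 {chi.statistic:.2f}, p {chi.p_value:.2f}")

    expr, groups = gen_expression_table(
        200, {"GENE0005": 4.0, "GENE0010": 0.25}, n_reps=6, seed=SEED
    )
    de = diff_expression(normalize_expression(expr), groups)
    de.to_csv(OUT / "diffexpr.csv", index=False)
    hits = de[de.significant & (de.log2fc.abs() > 1)]
    print(
        f"differential expression: {len(hits)} genes with |log2FC|>1 at p<0.05 "
        f"out of {len(de)} ({', '.join(hits.gene)})"
    )
    results["diffexpr_strong_hits"] = sorted(hits.gene)

    (OUT / "associations.json").write_text(json.dumps(results, indent=1))
    print(f"wrote {OUT / 'associations.json'} and {OUT / 'diffexpr.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
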