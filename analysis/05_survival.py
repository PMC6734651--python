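"""Survival battery on the two synthetic cohorts.

Per cohort: Kaplan-Meier 5-year DFS per marker group, log-rank test,
multivariate Cox model, stage I-II subset analysis, and the marker x
chemotherapy 2x2 factorial interaction. Writes cox_*.tsv and
survival_summary.tsv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from boolmark import (
    chemo_interaction,
    cox_fit,
    encode_clinical_covariates,
    five_year_rate,
    logrank_test,
    read_clinical_table,
    stage_subset_analysis,
)

ROOT = Path(__file__).resolve().parents[1]


def analyse(name: str, clin: pd.DataFrame, out_dir: Path, rows: list[dict]) -> None:
    low = clin["marker_low"].astype(int) == 1
    groups = pd.Series(["low" if x else "high" for x in low], index=clin.index)
    times = clin["dfs_months"].astype(float).to_numpy()
    events = clin["dfs_event"].astype(int).to_numpy()

    r_low = five_year_rate(times[low.to_numpy()], events[low.to_numpy()])
    r_high = five_year_rate(times[~low.to_numpy()], events[~low.to_numpy()])
    chi2, p = logrank_test(times, events, groups.to_numpy())
    print(f"[{name}] 5-year DFS: marker-low {r_low:.1%} vs marker-high {r_high:.1%} "
          f"(log-rank p = {p:.2e})")

    cov = encode_clinical_covariates(clin, clin["marker_low"].astype(float))
    model = pd.concat([clin[["dfs_months", "dfs_event"]], cov], axis=1)
    covariates = ["marker_low", "age60", "sex_male", "stage_ordinal", "chemo_yes"]
    table, _ = cox_fit(model, "dfs_months", "dfs_event", covariates)
    table.to_csv(out_dir / f"cox_{name}_dfs.tsv", sep="\t")
    hr = table.loc["marker_low"]
    print(f"[{name}] multivariate Cox marker-low HR = {hr['hr']:.3f} "
          f"({hr['ci_low']:.3f}-{hr['ci_high']:.3f}), p = {hr['p_value']:.3g}")

    early = stage_subset_analysis(clin, groups, {"I", "II"})
    print(f"[{name}] stage I-II subset (n = {early['n']}): 5-year DFS "
          f"low {early['five_year_rates'].get('low', float('nan')):.1%} vs "
          f"high {early['five_year_rates'].get('high', float('nan')):.1%}, "
          f"log-rank p = {early['logrank_p']:.2e}")

    inter_df = model[model["chemo_yes"].notna()]
    inter = chemo_interaction(inter_df, "dfs_months", "dfs_event", "marker_low", "chemo_yes")
    print(f"[{name}] marker x chemo interaction: multiplicative p = "
          f"{inter.multiplicative_p:.3f}; RERI = {inter.reri:.2f} "
          f"(95% CI {inter.reri_ci[0]:.2f} to {inter.reri_ci[1]:.2f})")

    rows.append({
        "cohort": name, "n": len(clin),
        "five_year_dfs_low": r_low, "five_year_dfs_high": r_high,
        "logrank_p": p, "cox_marker_hr": hr["hr"],
        "cox_marker_ci_low": hr["ci_low"], "cox_marker_ci_high": hr["ci_high"],
        "cox_marker_p": hr["p_value"],
        "early_stage_logrank_p": early["logrank_p"],
        "interaction_multiplicative_p": inter.multiplicative_p,
        "interaction_reri": inter.reri,
    })


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    rows: list[dict] = []
    for name, fname in [("discovery", "clinical_discovery.tsv"),
                        ("validation", "clinical_validation.tsv")]:
        clin = read_clinical_table(args.study / fname)
        analyse(name, clin, args.out, rows)

    # disease-specific survival exists only in the validation cohort
    clin_v = read_clinical_table(args.study / "clinical_validation.tsv")
    if "dss_months" in clin_v.columns and clin_v["dss_months"].notna().any():
        cov = encode_clinical_covariates(clin_v, clin_v["marker_low"].astype(float))
        model = pd.concat([clin_v[["dss_months", "dss_event"]], cov], axis=1)
        table, _ = cox_fit(model, "dss_months", "dss_event",
                           ["marker_low", "age60", "sex_male", "stage_ordinal"])
        table.to_csv(args.out / "cox_validation_dss.tsv", sep="\t")
        hr = table.loc["marker_low"]
        print(f"[validation] DSS Cox marker-low HR = {hr['hr']:.3f} "
              f"({hr['ci_low']:.3f}-{hr['ci_high']:.3f}), p = {hr['p_value']:.3g}")

    pd.DataFrame(rows).to_csv(args.out / "survival_summary.tsv", sep="\t", index=False)
    print(f"wrote {args.out / 'survival_summary.tsv'} and cox_*.tsv")


if __name__ == "__main__":
    main()
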