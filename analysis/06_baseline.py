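"""Baseline characteristics tables for both cohorts, dichotomized by marker.

Runs the clinical test battery (chi-square / Fisher, pooled t, Mann-Whitney)
per variable and writes baseline_discovery.tsv / baseline_validation.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from boolmark import baseline_table, read_clinical_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    for name, fname in [("discovery", "clinical_discovery.tsv"),
                        ("validation", "clinical_validation.tsv")]:
        clin = read_clinical_table(args.study / fname)
        grouping = pd.Series(
            ["low" if x == 1 else "high" for x in clin["marker_low"].astype(int)],
            index=clin.index,
        )
        table = baseline_table(clin, grouping)
        table.to_csv(args.out / f"baseline_{name}.tsv", sep="\t")
        print(f"[{name}] baseline comparison ({(grouping == 'low').sum()} low vs "
              f"{(grouping == 'high').sum()} high):")
        with pd.option_context("display.width", 120):
            print(table[["test", "p_value", "note"]].to_string())
        print()
    print(f"wrote baseline tables to {args.out}")


if __name__ == "__main__":
    main()
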