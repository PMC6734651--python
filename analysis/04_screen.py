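"""Reduce the implication hit list to candidate biomarkers.

Applies the support filter (>= 40% of CRC arrays) and the differential-
expression filter (> 2-fold, p < 0.001 vs both normal mucosa and IBD), then
writes candidates.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from boolmark import (
    differential_expression,
    read_annotations,
    read_expression_matrix,
    screen_candidates,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    matrix = read_expression_matrix(args.study / "matrix.tsv")
    ann = read_annotations(args.study / "annotations.tsv")
    res = pd.read_csv(args.out / "implications.tsv", sep="\t")

    crc = ann.index[ann["tissue_class"] == "CRC"].tolist()
    normal = ann.index[ann["tissue_class"] == "normal"].tolist()
    ibd = ann.index[ann["tissue_class"] == "IBD"].tolist()
    de_normal = differential_expression(matrix, crc, normal)
    de_ibd = differential_expression(matrix, crc, ibd)

    out = screen_candidates(res, de_normal, de_ibd)
    out.to_csv(args.out / "candidates.tsv", sep="\t")

    candidates = out[out["candidate"]]
    print(f"screened {len(out)} genes: {int(out['implication_pass'].sum())} passed the "
          f"implication filter, {int(out['support_pass'].sum())} the support filter")
    print(f"  candidates passing all filters: {len(candidates)}")
    for gene, row in candidates.iterrows():
        print(f"  {gene}: S = {row['statistic']:.2f}, "
              f"fold vs normal = {row['fc_vs_normal']:.2f} (p = {row['p_vs_normal']:.2e}), "
              f"fold vs IBD = {row['fc_vs_ibd']:.2f} (p = {row['p_vs_ibd']:.2e})")
    print(f"wrote {args.out / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
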