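"""Genome-wide search for genes whose low expression implies high VIM.

Reads results/calls.tsv and results/study/annotations.tsv; tests every gene X
for "X-low implies VIM-high" over the CRC arrays, estimates the permutation
FDR of the threshold configuration, and writes implications.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from boolmark import estimate_fdr, read_annotations, search_partners
from boolmark.stepminer import letters_to_calls

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--target", default="VIM")
    parser.add_argument("--n-perm", type=int, default=100)
    args = parser.parse_args()

    letters = pd.read_csv(args.out / "calls.tsv", sep="\t", index_col=0, dtype=str,
                          keep_default_na=False)
    calls = letters_to_calls(letters)
    ann = read_annotations(args.study / "annotations.tsv")
    crc = ann.index[ann["tissue_class"] == "CRC"].tolist()

    res = search_partners(calls, args.target, relation="low=>high", population=crc)
    fdr = estimate_fdr(calls, args.target, relation="low=>high", population=crc,
                       n_perm=args.n_perm, seed=args.seed)
    res["fdr"] = fdr["fdr"]
    res.to_csv(args.out / "implications.tsv", sep="\t", index=False)

    passing = res[res["passes"]]
    print(f"tested {len(res)} genes against {args.target} over {len(crc)} CRC arrays")
    print(f"  passing (S > 3, err < 0.1): {len(passing)}")
    if len(passing):
        top = passing.iloc[0]
        print(f"  top hit: {top['gene_x']} (S = {top['statistic']:.2f}, "
              f"err = {top['error_rate']:.3f}, support = {top['support_fraction']:.2f})")
    print(f"  permutation FDR of the configuration: {fdr['fdr']:.4f} "
          f"({fdr['n_perm']} permutations)")
    print(f"wrote {args.out / 'implications.tsv'}")


if __name__ == "__main__":
    main()
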