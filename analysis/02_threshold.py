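"""Fit a step-function threshold per gene and call every sample low/high.

Reads results/study/matrix.tsv; writes thresholds.tsv and calls.tsv under
results/.
"""

import argparse
from pathlib import Path

from boolmark import read_expression_matrix, threshold_all_genes
from boolmark.stepminer import calls_to_letters, fits_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--margin", type=float, default=0.5,
                        help="intermediate-zone half width in log2 units")
    args = parser.parse_args()

    matrix = read_expression_matrix(args.study / "matrix.tsv")
    fits, calls = threshold_all_genes(matrix, margin=args.margin)
    fits_to_frame(fits).to_csv(args.out / "thresholds.tsv", sep="\t")
    letters = calls_to_letters(calls)
    letters.index.name = "gene_id"
    letters.to_csv(args.out / "calls.tsv", sep="\t")

    n_deg = sum(f.degenerate for f in fits.values())
    print(f"fitted {len(fits)} genes ({n_deg} degenerate); margin = {args.margin} log2 units")
    for gene in ("PPM1H", "VIM"):
        if gene in fits:
            f = fits[gene]
            print(f"  {gene}: threshold {f.threshold:.2f} "
                  f"(segment means {f.left_mean:.2f} / {f.right_mean:.2f})")
    print(f"wrote {args.out / 'thresholds.tsv'} and {args.out / 'calls.tsv'}")


if __name__ == "__main__":
    main()
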