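"""Step-function thresholding of per-gene expression (StepMiner-style).

Each gene's expression values are sorted ascending and a one-step function is
fitted: every breakpoint ``i`` (1..n-1 samples on the left) defines a fit with
left mean muL and right mean muR, and the breakpoint minimizing the residual
sum of squares is kept. The high/low threshold is the midpoint (muL + muR)/2.
Samples are then called LOW / HIGH with an optional intermediate margin ``m``
(in log2 units) around the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("boolmark")

# integer call codes used throughout; NA in TSV output
LOW, INTERMEDIATE, HIGH, MISSING = 0, 1, 2, -1
CALL_LETTERS = {LOW: "L", INTERMEDIATE: "I", HIGH: "H", MISSING: "NA"}

MIN_FIT_N = 4


@dataclass(frozen=True)
class StepFit:
    """One-step fit of a gene's sorted expression values."""

    gene_id: str
    breakpoint_index: int  # number of samples in the left (low) segment, 1-based
    left_mean: float
    right_mean: float
    threshold: float
    sse_step: float
    sse_flat: float  # total sum of squares about the grand mean
    f_stat: float
    degenerate: bool  # True iff right_mean == left_mean (constant input)


def fit_step_threshold(values: np.ndarray, gene_id: str = "") -> StepFit:
    """Fit the one-step function minimizing SSE over all breakpoints.

    ``values`` must be >= 4 finite reals (the caller removes missing values).
    Ties in SSE are broken toward the smallest breakpoint index, so the fit is
    deterministic and permutation-invariant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("fit_step_threshold expects a 1-d vector")
    if not np.isfinite(x).all():
        raise ValueError("fit_step_threshold requires finite values only")
    n = x.size
    if n < MIN_FIT_N:
        raise ValueError(f"need at least {MIN_FIT_N} values, got {n}")

    s = np.sort(x)
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    total, total_sq = csum[-1], csq[-1]
    grand = total / n
    sse_flat = float(total_sq - n * grand * grand)

    i = np.arange(1, n)  # left-segment sizes
    left_sum = csum[:-1]
    left_sq = csq[:-1]
    right_sum = total - left_sum
    right_sq = total_sq - left_sq
    sse = (left_sq - left_sum**2 / i) + (right_sq - right_sum**2 / (n - i))
    best = int(np.argmin(sse))  # argmin returns the first minimum: smallest i*
    i_star = best + 1
    mu_l = float(left_sum[best] / i_star)
    mu_r = float(right_sum[best] / (n - i_star))
    sse_step = float(max(sse[best], 0.0))
    degenerate = mu_r - mu_l == 0.0
    denom = sse_step / (n - 2)
    if denom > 0:
        f_stat = float((sse_flat - sse_step) / denom)
    else:
        f_stat = float("inf") if sse_flat > 0 else 0.0
    return StepFit(
        gene_id=gene_id,
        breakpoint_index=i_star,
        left_mean=mu_l,
        right_mean=mu_r,
        threshold=(mu_l + mu_r) / 2.0,
        sse_step=sse_step,
        sse_flat=sse_flat,
        f_stat=f_stat,
        degenerate=degenerate,
    )


def classify_samples(values: np.ndarray, fit: StepFit, margin: float) -> np.ndarray:
    """Call each sample LOW / INTERMEDIATE / HIGH / MISSING against ``fit``.

    LOW iff value < t - m, HIGH iff value > t + m, INTERMEDIATE within the
    closed band |value - t| <= m; NaN values are MISSING. A degenerate fit
    (flat gene) yields INTERMEDIATE for every non-missing sample.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    x = np.asarray(values, dtype=float)
    calls = np.full(x.shape, INTERMEDIATE, dtype=np.int8)
    miss = np.isnan(x)
    if not fit.degenerate:
        t = fit.threshold
        calls[x < t - margin] = LOW
        calls[x > t + margin] = HIGH
    calls[miss] = MISSING
    return calls


def threshold_all_genes(
    matrix: ExpressionMatrix, margin: float = 0.5
) -> tuple[dict[str, StepFit], pd.DataFrame]:
    """Fit every gene with >= 4 non-missing values and call all samples.

    Returns (fits keyed by gene id, int8 call DataFrame genes x samples).
    Genes with too few values are skipped and logged.
    """
    fits: dict[str, StepFit] = {}
    rows: list[np.ndarray] = []
    kept: list[str] = []
    skipped = 0
    vals = matrix.values
    arr = vals.to_numpy(dtype=float)
    for k, gene in enumerate(vals.index):
        row = arr[k]
        finite = row[~np.isnan(row)]
        if finite.size < MIN_FIT_N:
            skipped += 1
            continue
        fit = fit_step_threshold(finite, gene_id=gene)
        fits[gene] = fit
        rows.append(classify_samples(row, fit, margin))
        kept.append(gene)
    if skipped:
        logger.info(
            "threshold_all_genes: skipped %d gene(s) with < %d non-missing values",
            skipped,
            MIN_FIT_N,
        )
    calls = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(vals.columns)), dtype=np.int8),
        index=kept,
        columns=vals.columns,
        dtype=np.int8,
    )
    return fits, calls


def fits_to_frame(fits: dict[str, StepFit]) -> pd.DataFrame:
    """Tabulate fits for the thresholds TSV."""
    return pd.DataFrame(
        {
            "gene_id": list(fits),
            "threshold": [f.threshold for f in fits.values()],
            "left_mean": [f.left_mean for f in fits.values()],
            "right_mean": [f.right_mean for f in fits.values()],
            "f_stat": [f.f_stat for f in fits.values()],
            "degenerate": [f.degenerate for f in fits.values()],
        }
    ).set_index("gene_id")


def calls_to_letters(calls: pd.DataFrame) -> pd.DataFrame:
    """Map int8 call codes to the L/I/H/NA letters used in the calls TSV."""
    return calls.replace(CALL_LETTERS)


def letters_to_calls(letters: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`calls_to_letters`."""
    inverse = {v: k for k, v in CALL_LETTERS.items()}
    return letters.apply(lambda col: col.map(inverse)).astype(np.int8)
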