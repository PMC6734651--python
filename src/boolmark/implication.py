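"""Boolean-implication statistics between binarized gene pairs.

An implication such as "X-low implies Y-high" holds when the contradicting
quadrant of the 2x2 low/high contingency table (here X-low & Y-low) is
statistically sparse relative to independence. With sparse-quadrant count
``o``, its independence expectation ``e = (row margin)(column margin)/n``, the
statistic is

    S = (e - o) / sqrt(e)

(the deficit in Poisson-scale units) and the error rate is the average
conditional leak into the sparse quadrant,

    err = 1/2 * (o / row_margin + o / col_margin).

A pair passes when S > s_min and err < err_max (BooleanNet-style defaults
s_min = 3, err_max = 0.1). The genome-wide search tests every gene X against a
fixed target Y; the FDR of a threshold configuration is estimated by
within-gene permutation of the calls, which destroys pairwise association
while preserving each gene's call composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stepminer import HIGH, LOW

logger = logging.getLogger("boolmark")

RELATIONS = ("low=>high", "low=>low", "high=>low", "high=>high")

# sparse (contradicting) quadrant per relation, as (X call, Y call)
_SPARSE_QUADRANT = {
    "low=>high": (LOW, LOW),
    "low=>low": (LOW, HIGH),
    "high=>low": (HIGH, HIGH),
    "high=>high": (HIGH, LOW),
}

DEFAULT_S_MIN = 3.0
DEFAULT_ERR_MAX = 0.1
DEFAULT_MIN_N = 20


@dataclass(frozen=True)
class QuadrantCounts:
    """2x2 low/high contingency counts (X call, Y call); intermediates and
    missing samples are excluded."""

    n_ll: int
    n_lh: int
    n_hl: int
    n_hh: int

    @property
    def n(self) -> int:
        return self.n_ll + self.n_lh + self.n_hl + self.n_hh


@dataclass(frozen=True)
class ImplicationStat:
    relation: str
    sparse_count: int
    expected: float
    statistic: float
    error_rate: float
    passes: bool
    evaluable: bool = True


def quadrant_counts(calls_x: np.ndarray, calls_y: np.ndarray) -> QuadrantCounts:
    """Count the low/high quadrants; a sample contributes iff both calls are
    LOW or HIGH."""
    x = np.asarray(calls_x)
    y = np.asarray(calls_y)
    if x.shape != y.shape:
        raise ValueError("call vectors must cover the same sample universe")
    xl, xh = x == LOW, x == HIGH
    yl, yh = y == LOW, y == HIGH
    return QuadrantCounts(
        n_ll=int(np.sum(xl & yl)),
        n_lh=int(np.sum(xl & yh)),
        n_hl=int(np.sum(xh & yl)),
        n_hh=int(np.sum(xh & yh)),
    )


def _margins(counts: QuadrantCounts, quadrant: tuple[int, int]) -> tuple[int, int, int]:
    """(sparse count o, X-side margin, Y-side margin) for a sparse quadrant."""
    table = {
        (LOW, LOW): counts.n_ll,
        (LOW, HIGH): counts.n_lh,
        (HIGH, LOW): counts.n_hl,
        (HIGH, HIGH): counts.n_hh,
    }
    o = table[quadrant]
    x_margin = counts.n_ll + counts.n_lh if quadrant[0] == LOW else counts.n_hl + counts.n_hh
    y_margin = counts.n_ll + counts.n_hl if quadrant[1] == LOW else counts.n_lh + counts.n_hh
    return o, x_margin, y_margin


def implication_statistic(
    counts: QuadrantCounts,
    relation: str = "low=>high",
    s_min: float = DEFAULT_S_MIN,
    err_max: float = DEFAULT_ERR_MAX,
) -> ImplicationStat:
    """Sparse-quadrant statistic, error rate and pass flag for one pair.

    A zero margin for the tested quadrant makes the statistic not evaluable
    (never a pass).
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; choose from {RELATIONS}")
    o, x_margin, y_margin = _margins(counts, _SPARSE_QUADRANT[relation])
    n = counts.n
    if n == 0 or x_margin == 0 or y_margin == 0:
        logger.debug("implication_statistic: zero margin, not evaluable")
        return ImplicationStat(relation, o, float("nan"), float("nan"), float("nan"),
                               passes=False, evaluable=False)
    e = x_margin * y_margin / n
    s = (e - o) / math.sqrt(e)
    err = 0.5 * (o / x_margin + o / y_margin)
    return ImplicationStat(
        relation=relation,
        sparse_count=o,
        expected=e,
        statistic=s,
        error_rate=err,
        passes=bool(s > s_min and err < err_max),
    )


def derived_relation_flags(
    counts: QuadrantCounts,
    s_min: float = DEFAULT_S_MIN,
    err_max: float = DEFAULT_ERR_MAX,
) -> dict[str, bool]:
    """Equivalence/opposite flags as conjunctions of two implications.

    equivalent: X-low => Y-low AND X-high => Y-high both hold;
    opposite:   X-low => Y-high AND X-high => Y-low both hold.
    These are reported for audit only — the search tests single implications.
    """
    stat = {r: implication_statistic(counts, r, s_min, err_max) for r in RELATIONS}
    return {
        "equivalent": stat["low=>low"].passes and stat["high=>high"].passes,
        "opposite": stat["low=>high"].passes and stat["high=>low"].passes,
    }


def _batch_stats(
    calls: np.ndarray,
    target: np.ndarray,
    relation: str,
    s_min: float,
    err_max: float,
    min_n: int,
) -> dict[str, np.ndarray]:
    """Vectorized quadrant counts + statistics for many X genes vs one target Y.

    ``calls``: int8 (genes x samples); ``target``: int8 (samples,).
    """
    xl = calls == LOW
    xh = calls == HIGH
    tl = (target == LOW).astype(np.int64)
    th = (target == HIGH).astype(np.int64)
    n_ll = xl @ tl
    n_lh = xl @ th
    n_hl = xh @ tl
    n_hh = xh @ th
    n = n_ll + n_lh + n_hl + n_hh

    qx, qy = _SPARSE_QUADRANT[relation]
    o = {(LOW, LOW): n_ll, (LOW, HIGH): n_lh, (HIGH, LOW): n_hl, (HIGH, HIGH): n_hh}[(qx, qy)]
    x_margin = n_ll + n_lh if qx == LOW else n_hl + n_hh
    y_margin = n_ll + n_hl if qy == LOW else n_lh + n_hh

    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(n > 0, x_margin * y_margin / np.maximum(n, 1), np.nan)
        s = (e - o) / np.sqrt(e)
        err = 0.5 * (o / x_margin + o / y_margin)
    evaluable = (n > 0) & (x_margin > 0) & (y_margin > 0)
    s = np.where(evaluable, s, np.nan)
    err = np.where(evaluable, err, np.nan)
    passes = evaluable & (n >= min_n) & (s > s_min) & (err < err_max)
    return {
        "n_ll": n_ll, "n_lh": n_lh, "n_hl": n_hl, "n_hh": n_hh, "n": n,
        "sparse_count": o, "expected": e, "statistic": s, "error_rate": err,
        "evaluable": evaluable, "passes": passes,
    }


def search_partners(
    calls: pd.DataFrame,
    target_gene: str,
    relation: str = "low=>high",
    population: list[str] | None = None,
    s_min: float = DEFAULT_S_MIN,
    err_max: float = DEFAULT_ERR_MAX,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Test every gene X != target for ``X relation target`` in a population.

    ``calls`` is the int8 call matrix (genes x samples). ``population``
    restricts the sample universe (e.g. CRC arrays only); support_fraction is
    the fraction of that population contributing low/high calls for both
    genes. Genes with n < min_n are reported but can never pass. Results are
    sorted by the statistic, descending.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; choose from {RELATIONS}")
    if target_gene not in calls.index:
        raise ValueError(f"target gene {target_gene!r} absent from call matrix")
    sub = calls[population] if population is not None else calls
    target = sub.loc[target_gene].to_numpy(dtype=np.int8)
    others = sub.drop(index=target_gene)
    stats = _batch_stats(others.to_numpy(dtype=np.int8), target, relation, s_min, err_max, min_n)
    n_pop = sub.shape[1]
    out = pd.DataFrame(
        {
            "gene_x": others.index,
            "relation": relation,
            **{k: stats[k] for k in ("n_ll", "n_lh", "n_hl", "n_hh", "n")},
            "statistic": stats["statistic"],
            "error_rate": stats["error_rate"],
            "support_fraction": stats["n"] / n_pop if n_pop else np.nan,
            "evaluable": stats["evaluable"],
            "passes": stats["passes"],
        }
    )
    return out.sort_values("statistic", ascending=False, kind="mergesort").reset_index(drop=True)


def estimate_fdr(
    calls: pd.DataFrame,
    target_gene: str,
    relation: str = "low=>high",
    population: list[str] | None = None,
    s_min: float = DEFAULT_S_MIN,
    err_max: float = DEFAULT_ERR_MAX,
    min_n: int = DEFAULT_MIN_N,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation FDR for one threshold configuration of the partner search.

    Every permutation independently shuffles each non-target gene's calls
    across samples and recounts passing pairs; FDR = (mean null passing count)
    / (observed passing count), reported as 1.0 when nothing passes observed
    and capped at 1. Bit-reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = search_partners(calls, target_gene, relation, population, s_min, err_max, min_n)
    n_observed = int(observed["passes"].sum())

    sub = calls[population] if population is not None else calls
    target = sub.loc[target_gene].to_numpy(dtype=np.int8)
    others = sub.drop(index=target_gene).to_numpy(dtype=np.int8)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        shuffled = rng.permuted(others, axis=1)
        stats = _batch_stats(shuffled, target, relation, s_min, err_max, min_n)
        null_counts[p] = int(stats["passes"].sum())
    mean_null = float(null_counts.mean())
    fdr = 1.0 if n_observed == 0 else min(1.0, mean_null / n_observed)
    return {
        "fdr": fdr,
        "observed_passing": n_observed,
        "mean_null_passing": mean_null,
        "n_perm": n_perm,
    }
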