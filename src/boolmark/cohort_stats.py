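"""Baseline-table statistics for marker-dichotomized patient cohorts.

The battery mirrors the convention of clinical baseline ("Table 1") reporting:
Pearson chi-square (no continuity correction) or Fisher's exact test for
nominal variables, the pooled-variance Student t-test for continuous
summaries, and a tie-corrected asymptotic Mann-Whitney U test for ordinal
variables (stage, grade). Missing values are excluded from every test. The
summary-statistic t-test takes (mean, sd, n) per group so published tables
can be re-tested without patient-level data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("boolmark")

FISHER_EXPECTED_MIN = 5.0  # any expected cell below this switches chi2 -> Fisher

STAGE_ORDER = ("I", "II", "III")
GRADE_ORDER = ("well", "moderate", "poor")


@dataclass(frozen=True)
class SummaryStats:
    """Per-group mean / sd / n for a summary-level t-test."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be an integer >= 2")


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    chi2 = n (ad - bc)^2 / (r1 r2 c1 c2); two-sided p from chi2(1). A zero
    margin is an error directing the caller to Fisher's exact test.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: use fisher_exact_2x2")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables (fixed margins) no more probable than the observed one."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def expected_counts_2x2(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def nominal_test_2x2(table: np.ndarray) -> tuple[str, float]:
    """Dispatch chi-square vs Fisher: Fisher whenever any expected count < 5."""
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return "fisher", fisher_exact_2x2(t)
    if (expected_counts_2x2(t) < FISHER_EXPECTED_MIN).any():
        return "fisher", fisher_exact_2x2(t)
    _, p = pearson_chi2_2x2(t)
    return "chi2", p


def student_t_from_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from per-group (mean, sd, n).

    df = n_a + n_b - 2. Zero pooled variance with equal means gives (0, df, 1);
    with unequal means it is an error.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0.0:
        if a.mean == b.mean:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float(t), df, float(2.0 * sps.t.sf(abs(t), df))


def mann_whitney_ordinal(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[float, float, float]:
    """Mann-Whitney U on ordinal category counts via midranks.

    Normal approximation with tie-corrected variance
    Var = n_a n_b / 12 * [(n + 1) - sum(t^3 - t) / (n (n - 1))],
    no continuity correction; two-sided p. Returns (U for group a, z, p).
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    if ca.shape != cb.shape or ca.ndim != 1 or ca.size < 2:
        raise ValueError("need matching per-category counts over >= 2 ordered categories")
    if (ca < 0).any() or (cb < 0).any():
        raise ValueError("counts must be non-negative")
    n_a, n_b = ca.sum(), cb.sum()
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    ties = ca + cb
    n = n_a + n_b
    cum = np.concatenate([[0.0], np.cumsum(ties)])
    midrank = cum[:-1] + (ties + 1) / 2.0
    rank_sum_a = float((ca * midrank).sum())
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - ((ties**3 - ties).sum()) / (n * (n - 1)))
    if var <= 0:  # every observation in one category
        return float(u_a), 0.0, 1.0
    z = (u_a - n_a * n_b / 2.0) / np.sqrt(var)
    return float(u_a), float(z), float(2.0 * sps.norm.sf(abs(z)))


def _ordinal_counts(series: pd.Series, order: tuple[str, ...]) -> np.ndarray:
    return np.array([(series == level).sum() for level in order], dtype=float)


def baseline_table(clinical: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Compare baseline variables between two marker groups.

    ``grouping`` maps patient id -> group label (exactly two labels, e.g.
    low/high). Dispatch per variable type: nominal -> chi-square (Fisher if
    any expected count < 5), continuous -> pooled t, ordinal (stage, grade)
    -> Mann-Whitney. Rows with missing/unknown values are excluded per test;
    chemo's explicit "missing" category is shown but excluded from its test.
    Returns one row per variable with the test used and the p-value.
    """
    groups = grouping.dropna()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"grouping must have exactly two labels, got {labels}")
    df = clinical.loc[clinical.index.intersection(groups.index)].copy()
    df["_group"] = groups.loc[df.index]
    g_lo = df[df["_group"] == labels[0]]
    g_hi = df[df["_group"] == labels[1]]

    rows: list[dict] = []

    def add(variable: str, test: str, p: float | None, note: str = "", detail: str = "") -> None:
        rows.append({"variable": variable, "test": test, "p_value": p,
                     "note": note, "detail": detail})

    # continuous: age (+ optional serum markers)
    for var in ("age", "cea", "ca199"):
        if var not in df.columns:
            continue
        a = pd.to_numeric(g_lo[var], errors="coerce").dropna()
        b = pd.to_numeric(g_hi[var], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            add(var, "t", None, note="skipped: fewer than 2 observations in a group")
            continue
        sa = SummaryStats(a.mean(), a.std(ddof=1), len(a))
        sb = SummaryStats(b.mean(), b.std(ddof=1), len(b))
        try:
            _, _, p = student_t_from_summary(sa, sb)
        except ValueError:
            add(var, "t", None, note="skipped: degenerate variance")
            continue
        add(var, "t", p,
            detail=f"{sa.mean:.2f} ({sa.sd:.2f}) vs {sb.mean:.2f} ({sb.sd:.2f})")

    # nominal 2-level variables
    nominal_specs = {
        "sex": ("F", "M"),
        "location": ("colon", "rectum"),
        "chemo": ("yes", "no"),
    }
    for var, levels in nominal_specs.items():
        if var not in df.columns:
            continue
        counts = np.array(
            [[(g[var] == lv).sum() for lv in levels] for g in (g_lo, g_hi)], dtype=float
        )
        n_missing = int(len(df) - counts.sum())
        observed_levels = (counts.sum(axis=0) > 0).sum()
        if observed_levels < 2 or (counts.sum(axis=1) == 0).any():
            add(var, "chi2", None, note="skipped: single observed category")
            continue
        test, p = nominal_test_2x2(counts)
        note = f"{n_missing} missing excluded" if n_missing else ""
        add(var, test, p, note=note, detail=str(counts.astype(int).tolist()))

    # ordinal variables
    for var, order in (("stage", STAGE_ORDER), ("grade", GRADE_ORDER)):
        if var not in df.columns:
            continue
        ca = _ordinal_counts(g_lo[var], order)
        cb = _ordinal_counts(g_hi[var], order)
        if ca.sum() == 0 or cb.sum() == 0 or (ca + cb > 0).sum() < 2:
            add(var, "mann-whitney", None, note="skipped: insufficient ordinal data")
            continue
        _, _, p = mann_whitney_ordinal(ca, cb)
        add(var, "mann-whitney", p, detail=f"{ca.astype(int).tolist()} vs {cb.astype(int).tolist()}")

    out = pd.DataFrame(rows).set_index("variable")
    skipped = out["p_value"].isna().sum()
    if skipped:
        logger.info("baseline_table: %d variable(s) skipped", skipped)
    return out
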