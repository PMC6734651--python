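"""Candidate-reduction filters after the genome-wide implication search.

Two filters reduce the implication hit list to candidate biomarkers:

1. support — drop pairs identified from less than a minimum fraction
   (default 40%) of the population's arrays;
2. differential expression — keep genes changed by more than ``fc_min``-fold
   (default 2) at p < ``p_max`` (default 0.001, Welch two-sample t on log2
   values) versus BOTH normal mucosa and IBD tissue.

Both fold-change and p cutoffs are strict inequalities. No multiple-testing
correction is applied inside the DE filter; FDR control lives in the
implication stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

logger = logging.getLogger("boolmark")

DEFAULT_MIN_SUPPORT = 0.40
DEFAULT_FC_MIN = 2.0
DEFAULT_P_MAX = 0.001
MIN_DE_N = 3


def support_filter(results: pd.DataFrame, min_fraction: float = DEFAULT_MIN_SUPPORT) -> pd.DataFrame:
    """Retain implication results with support_fraction >= min_fraction."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    keep = results["support_fraction"] >= min_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info("support_filter: removed %d result(s) below support %.2f", removed, min_fraction)
    return results.loc[keep].reset_index(drop=True)


def differential_expression(
    matrix: ExpressionMatrix, samples_a: list[str], samples_b: list[str]
) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups on log2 values.

    Genes with fewer than 3 non-missing values in either group are skipped
    (logged). Returns gene_id, group means, signed log2 fold change (a - b),
    fold_change = 2^|log2_fc| and the two-sided p-value.
    """
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("both sample groups must be non-empty")
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    ok = (n_a >= MIN_DE_N) & (n_b >= MIN_DE_N)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("differential_expression: skipped %d gene(s) with < %d values in a group",
                    skipped, MIN_DE_N)
    t, p = sps.ttest_ind(a[ok], b[ok], axis=1, equal_var=False, nan_policy="omit")
    mean_a = np.nanmean(a[ok], axis=1)
    mean_b = np.nanmean(b[ok], axis=1)
    log2_fc = mean_a - mean_b
    return pd.DataFrame(
        {
            "gene_id": np.asarray(matrix.gene_ids)[ok],
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_fc": log2_fc,
            "fold_change": 2.0 ** np.abs(log2_fc),
            "t_stat": t,
            "p_value": p,
        }
    ).set_index("gene_id")


def screen_candidates(
    results: pd.DataFrame,
    de_normal: pd.DataFrame,
    de_ibd: pd.DataFrame,
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> pd.DataFrame:
    """Combine the support and differential-expression filters.

    A gene is a candidate iff its implication result passes, its support
    fraction is >= min_support, and it shows fold change strictly greater
    than fc_min with p strictly below p_max versus BOTH normal and IBD
    tissue. Genes absent from a DE table are excluded as not evaluable
    (logged). Every per-filter flag is kept for audit.
    """
    rec = results.set_index("gene_x") if "gene_x" in results.columns else results
    in_both = rec.index.isin(de_normal.index) & rec.index.isin(de_ibd.index)
    dropped = int((~in_both).sum())
    if dropped:
        logger.info("screen_candidates: %d gene(s) absent from a DE table, excluded", dropped)
    rec = rec.loc[in_both]
    dn = de_normal.loc[rec.index]
    di = de_ibd.loc[rec.index]
    out = pd.DataFrame(index=rec.index)
    out["statistic"] = rec["statistic"]
    out["support_fraction"] = rec["support_fraction"]
    out["implication_pass"] = rec["passes"].astype(bool)
    out["support_pass"] = rec["support_fraction"] >= min_support
    out["fc_vs_normal"] = dn["fold_change"]
    out["p_vs_normal"] = dn["p_value"]
    out["de_normal_pass"] = (dn["fold_change"] > fc_min) & (dn["p_value"] < p_max)
    out["fc_vs_ibd"] = di["fold_change"]
    out["p_vs_ibd"] = di["p_value"]
    out["de_ibd_pass"] = (di["fold_change"] > fc_min) & (di["p_value"] < p_max)
    out["candidate"] = (
        out["implication_pass"] & out["support_pass"] & out["de_normal_pass"] & out["de_ibd_pass"]
    )
    out.index.name = "gene_id"
    return out.sort_values("statistic", ascending=False, kind="mergesort")
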