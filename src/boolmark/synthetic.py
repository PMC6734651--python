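"""Seeded synthetic studies with the structure the analysis assumes.

The generator emulates, at reduced scale, a colorectal expression-array
compendium (CRC, polyp, IBD and normal-mucosa samples) plus two survival
cohorts, together with the ground truth needed for recovery tests:

* bimodal marker genes drawn from a two-Gaussian mixture (default modes 5 and
  9 log2 units, sigma 0.5, i.e. 4-sigma separation);
* one planted implication pair — the partner's mixture component is sampled
  conditionally on the marker's, with leak ``epsilon`` into the low-low
  quadrant, so marginals stay bimodal;
* a marker-low CRC subgroup of configurable prevalence (default 22.6%),
  enriched for MSI and BRAF-mutant labels by a configurable odds multiplier;
* differentially expressed genes shifted between CRC and normal/IBD tissue;
* proportional-hazards survival: exponential event times with group-, stage-
  and age-dependent log-hazards, and independent uniform censoring whose
  window is solved numerically to hit a target censoring fraction.

Everything is a pure function of (config, seed). Each gene and each patient
draws from a sub-stream derived from the master seed and its own index, so
enlarging the study does not perturb existing entities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, write_clinical_table, write_expression_matrix

logger = logging.getLogger("boolmark")


@dataclass
class StudyConfig:
    """Parameters of a synthetic study; defaults give the standard conditions."""

    # compendium composition (≈1/5 scale of 2480/98/451/396 CRC/polyp/IBD/normal)
    n_crc: int = 500
    n_polyp: int = 20
    n_ibd: int = 90
    n_normal: int = 80

    # gene panel
    n_genes: int = 500
    n_bimodal: int = 50        # independent bimodal background genes
    n_de: int = 10             # unimodal genes shifted vs normal/IBD (besides the marker)
    mode_low: float = 5.0
    mode_high: float = 9.0
    sigma: float = 0.5         # mixture-component sd (log2 units)
    sigma_background: float = 1.0
    bimodal_mixing: float = 0.3

    # planted implication: marker-low implies target(VIM)-high
    marker_gene: str = "PPM1H"
    target_gene: str = "VIM"
    plant_implication: bool = True
    epsilon: float = 0.02      # P(target low | marker low): the sparse-quadrant leak
    pi_low: float = 0.226      # marker-low fraction among CRC samples
    target_high_given_marker_high: float = 0.45
    de_shift: float = 1.5      # log2 shift of normal/IBD over CRC for DE genes

    # molecular-feature labels
    msi_rate: float = 0.15
    braf_rate: float = 0.10
    kras_rate: float = 0.40
    tp53_rate: float = 0.50
    enrichment_odds: float = 4.0  # odds multiplier for MSI/BRAF in marker-low CRC

    # survival cohorts
    n_discovery: int = 889
    n_validation: int = 691
    pi_low_validation: float = 0.331
    baseline_hazard: float = -math.log(0.75) / 60.0  # per month; S(60)=0.75 ref group
    beta_discovery: float = math.log(1.37)
    beta_validation: float = math.log(4.05)
    beta_stage: float = math.log(2.266)  # per stage increase
    beta_age: float = math.log(1.181)    # age >= 60
    dss_hazard_scale: float = 0.4
    beta_dss: float = math.log(2.608)
    dss_censoring_rate: float = 0.88  # disease-specific deaths are rarer than relapses
    censoring_rate: float = 0.70  # ~30% event rate, matching 5-year DFS near 75%
    horizon_months: float = 120.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_low < 1.0 or not 0.0 < self.pi_low_validation < 1.0:
            raise ValueError("marker-low fractions must lie in (0, 1)")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.sigma <= 0 or self.sigma_background <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")
        n_special = 2 + self.n_bimodal + self.n_de
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for 2 planted + "
                f"{self.n_bimodal} bimodal + {self.n_de} DE genes"
            )


@dataclass
class TruthBundle:
    """Planted parameters of a synthetic study, for recovery tests."""

    marker_gene: str
    target_gene: str
    planted_pair: tuple[str, str] | None
    epsilon: float
    pi_low: float
    bimodal_thresholds: dict[str, float]   # gene -> true mixture midpoint
    de_genes: list[str]
    marker_low_samples: list[str]          # CRC samples drawn in the low mode
    beta_discovery: float
    beta_validation: float
    censoring_rate: float


@dataclass
class StudyBundle:
    expression: ExpressionMatrix
    annotations: pd.DataFrame
    clinical_discovery: pd.DataFrame
    clinical_validation: pd.DataFrame
    truth: TruthBundle


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def generate_expression(
    config: StudyConfig, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthBundle]:
    """Generate the array compendium, its annotation table and the truth."""
    c = config
    sample_ids = (
        [f"CRC{i:04d}" for i in range(c.n_crc)]
        + [f"POL{i:04d}" for i in range(c.n_polyp)]
        + [f"IBD{i:04d}" for i in range(c.n_ibd)]
        + [f"NOR{i:04d}" for i in range(c.n_normal)]
    )
    tissue = np.array(
        ["CRC"] * c.n_crc + ["polyp"] * c.n_polyp + ["IBD"] * c.n_ibd + ["normal"] * c.n_normal
    )
    n_samples = len(sample_ids)
    is_crc = tissue == "CRC"
    is_shifted = (tissue == "normal") | (tissue == "IBD")

    # stream 0: CRC mixture memberships shared between marker and target
    memb_rng = _rng(seed, 0)
    marker_low = memb_rng.random(c.n_crc) < c.pi_low
    if c.plant_implication:
        target_high = np.where(
            marker_low,
            memb_rng.random(c.n_crc) >= c.epsilon,                      # leak into low-low
            memb_rng.random(c.n_crc) < c.target_high_given_marker_high,
        )
    else:
        target_high = memb_rng.random(c.n_crc) < 0.5
    target_high_noncrc = memb_rng.random(n_samples - c.n_crc) < 0.5

    gene_ids: list[str] = [c.marker_gene, c.target_gene]
    gene_ids += [f"BIM{i:04d}" for i in range(c.n_bimodal)]
    de_genes = [f"DEG{i:04d}" for i in range(c.n_de)]
    gene_ids += de_genes
    gene_ids += [f"BG{i:05d}" for i in range(c.n_genes - len(gene_ids))]

    mid = (c.mode_low + c.mode_high) / 2.0
    values = np.empty((c.n_genes, n_samples), dtype=float)
    bimodal_thresholds: dict[str, float] = {c.marker_gene: mid, c.target_gene: mid}

    for g, gene in enumerate(gene_ids):
        rng = _rng(seed, 1, g)
        noise = rng.normal(0.0, c.sigma, n_samples)
        if gene == c.marker_gene:
            means = np.full(n_samples, c.mode_high)
            means[is_crc] = np.where(marker_low, c.mode_low, c.mode_high)
            means[is_shifted] = c.mode_high + c.de_shift  # marker lost in tumours
            values[g] = means + noise
        elif gene == c.target_gene:
            high = np.concatenate([target_high, target_high_noncrc])
            values[g] = np.where(high, c.mode_high, c.mode_low) + noise
        elif gene.startswith("BIM"):
            high = rng.random(n_samples) >= c.bimodal_mixing
            values[g] = np.where(high, c.mode_high, c.mode_low) + noise
            bimodal_thresholds[gene] = mid
        elif gene.startswith("DEG"):
            base = rng.uniform(6.0, 8.0)
            means = np.full(n_samples, base)
            means[is_shifted] = base + c.de_shift
            means[tissue == "polyp"] = base + c.de_shift / 2.0
            values[g] = means + rng.normal(0.0, c.sigma, n_samples)
        else:
            base = rng.uniform(6.0, 8.0)
            values[g] = base + rng.normal(0.0, c.sigma_background, n_samples)

    # stream 3: molecular-feature labels (CRC only; enrichment in marker-low)
    lab_rng = _rng(seed, 3)

    def _enriched(base_rate: float) -> np.ndarray:
        odds = base_rate / (1.0 - base_rate)
        p_low = odds * c.enrichment_odds / (1.0 + odds * c.enrichment_odds)
        p = np.where(marker_low, p_low, base_rate)
        return lab_rng.random(c.n_crc) < p

    msi = _enriched(c.msi_rate)
    braf = _enriched(c.braf_rate)
    kras = lab_rng.random(c.n_crc) < c.kras_rate
    tp53 = lab_rng.random(c.n_crc) < c.tp53_rate

    annotations = pd.DataFrame(
        {
            "tissue_class": tissue,
            "msi": "unknown",
            "kras": "unknown",
            "braf": "unknown",
            "tp53": "unknown",
            "cohort_id": "synthetic",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    annotations.loc[is_crc, "msi"] = np.where(msi, "MSI", "MSS")
    annotations.loc[is_crc, "braf"] = np.where(braf, "mutant", "wildtype")
    annotations.loc[is_crc, "kras"] = np.where(kras, "mutant", "wildtype")
    annotations.loc[is_crc, "tp53"] = np.where(tp53, "mutant", "wildtype")

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        annotations=annotations,
    )
    truth = TruthBundle(
        marker_gene=c.marker_gene,
        target_gene=c.target_gene,
        planted_pair=(c.marker_gene, c.target_gene) if c.plant_implication else None,
        epsilon=c.epsilon,
        pi_low=c.pi_low,
        bimodal_thresholds=bimodal_thresholds,
        de_genes=[c.marker_gene] + de_genes,
        marker_low_samples=[s for s, low in zip(sample_ids[: c.n_crc], marker_low) if low],
        beta_discovery=c.beta_discovery,
        beta_validation=c.beta_validation,
        censoring_rate=c.censoring_rate,
    )
    return matrix, annotations, truth


def _censoring_window(hazards: np.ndarray, target_rate: float, horizon: float) -> float:
    """Solve the Uniform(0, tau) censoring window hitting the target fraction.

    With C ~ U(0, tau) and T ~ Exp(h), P(censored) = mean_i (1-exp(-h_i tau))
    / (h_i tau), which decreases from 1 (tau -> 0) toward 0. The accrual
    horizon caps tau; a target below the horizon's minimum is unreachable.
    """

    def frac(tau: float) -> float:
        x = hazards * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    if target_rate <= 0.0:
        return math.inf
    at_horizon = frac(horizon)
    if target_rate < at_horizon:
        raise ValueError(
            f"target censoring rate {target_rate:.3f} unreachable within "
            f"horizon {horizon} months (minimum {at_horizon:.3f})"
        )
    if target_rate >= frac(1e-9):
        return 1e-9
    return float(brentq(lambda tau: frac(tau) - target_rate, 1e-9, horizon, xtol=1e-10))


def generate_clinical(
    config: StudyConfig,
    true_low: pd.Series,
    seed: int,
    beta: float | None = None,
    include_dss: bool = False,
) -> pd.DataFrame:
    """Generate a survival cohort for given per-patient true marker groups.

    Event times are exponential with hazard h0 * exp(beta*1[low] +
    beta_stage*(stage-2) + beta_age*1[age>=60]); censoring is independent
    Uniform(0, tau) with tau solved for the target censoring fraction.
    """
    c = config
    if beta is None:
        beta = c.beta_discovery
    patients = list(true_low.index)
    n = len(patients)
    low = true_low.to_numpy(dtype=bool)

    cov_rng = _rng(seed, 10)
    stage = cov_rng.choice(np.array(["I", "II", "III"]), size=n, p=[0.09, 0.54, 0.37])
    age = np.clip(cov_rng.normal(67.0, 13.0, n), 20.0, 95.0)
    sex = np.where(cov_rng.random(n) < 0.54, "M", "F")
    chemo = cov_rng.choice(np.array(["yes", "no", "missing"]), size=n, p=[0.33, 0.50, 0.17])
    location = np.where(cov_rng.random(n) < 0.52, "colon", "rectum")
    grade = cov_rng.choice(np.array(["well", "moderate", "poor"]), size=n, p=[0.02, 0.70, 0.28])
    cea = np.exp(cov_rng.normal(math.log(3.5), 1.0, n))
    ca199 = np.exp(cov_rng.normal(math.log(12.0), 1.2, n))

    stage_code = pd.Series(stage).map({"I": 1, "II": 2, "III": 3}).to_numpy()
    log_hr = beta * low + c.beta_stage * (stage_code - 2) + c.beta_age * (age >= 60)
    hazard = c.baseline_hazard * np.exp(log_hr)

    # per-patient event-time sub-streams
    t_event = np.array(
        [_rng(seed, 11, i).exponential(1.0 / hazard[i]) for i in range(n)]
    )
    cens_rng = _rng(seed, 12)
    tau = _censoring_window(hazard, c.censoring_rate, c.horizon_months)
    t_cens = np.full(n, np.inf) if math.isinf(tau) else cens_rng.uniform(0.0, tau, n)
    dfs_months = np.minimum(t_event, t_cens)
    dfs_event = (t_event <= t_cens).astype(int)
    dfs_months = np.maximum(dfs_months, 1e-3)  # strictly positive

    table = pd.DataFrame(
        {
            "dfs_months": dfs_months,
            "dfs_event": dfs_event,
            "stage": stage,
            "age": age,
            "sex": sex,
            "location": location,
            "grade": grade,
            "chemo": chemo,
            "cea": cea,
            "ca199": ca199,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    if include_dss:
        h_dss = c.baseline_hazard * c.dss_hazard_scale * np.exp(c.beta_dss * low)
        t_dss = np.array(
            [_rng(seed, 13, i).exponential(1.0 / h_dss[i]) for i in range(n)]
        )
        tau_d = _censoring_window(h_dss, c.dss_censoring_rate, c.horizon_months * 2)
        c_dss = np.full(n, np.inf) if math.isinf(tau_d) else cens_rng.uniform(0.0, tau_d, n)
        table["dss_months"] = np.maximum(np.minimum(t_dss, c_dss), 1e-3)
        table["dss_event"] = (t_dss <= c_dss).astype(int)
    return table


def generate_study(config: StudyConfig, seed: int, out_dir: str | Path | None = None) -> StudyBundle:
    """Full synthetic study: compendium + discovery and validation cohorts.

    The two cohorts share the planted truth (the same marker and effect
    structure) but have independent noise. If ``out_dir`` is given, the
    expression matrix, annotations, both clinical tables and a truth JSON are
    written as TSV/JSON.
    """
    c = config
    matrix, annotations, truth = generate_expression(c, seed)

    grp_rng = _rng(seed, 20)
    disc_low = pd.Series(
        grp_rng.random(c.n_discovery) < c.pi_low,
        index=[f"DISC{i:04d}" for i in range(c.n_discovery)],
    )
    val_low = pd.Series(
        grp_rng.random(c.n_validation) < c.pi_low_validation,
        index=[f"VAL{i:04d}" for i in range(c.n_validation)],
    )
    clinical_discovery = generate_clinical(c, disc_low, seed + 1, beta=c.beta_discovery)
    clinical_validation = generate_clinical(
        c, val_low, seed + 2, beta=c.beta_validation, include_dss=True
    )
    clinical_discovery["marker_low"] = disc_low.astype(int)
    clinical_validation["marker_low"] = val_low.astype(int)

    bundle = StudyBundle(matrix, annotations, clinical_discovery, clinical_validation, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(matrix, out / "matrix.tsv")
        ann = annotations.copy()
        ann.index.name = "sample_id"
        ann.to_csv(out / "annotations.tsv", sep="\t")
        write_clinical_table(clinical_discovery, out / "clinical_discovery.tsv")
        write_clinical_table(clinical_validation, out / "clinical_validation.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(dataclasses.asdict(truth), fh, indent=2, default=str)
        logger.info("generate_study: wrote study files to %s", out)
    return bundle
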