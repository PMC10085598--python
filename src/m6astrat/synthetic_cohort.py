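"""Synthetic tumor cohorts with the statistical structure the pipeline assumes.

The generator emulates the shape of a bulk-expression tumor cohort of a few
hundred patients: a small panel of regulator genes carrying a planted
k-cluster mean structure, a block of prognostic genes loading on a latent
per-sample score ``z``, an immune gene block shifted in one cluster, pure
noise background genes, right-censored exponential survival whose log-hazard
is linear in ``z``, negative-binomial mutation counts whose log-mean is
affine in ``z``, and gene-level copy-number calls.  Every downstream stage
therefore has ground truth: cluster labels, the latent score, per-gene
prognostic flags, and the planted score-TMB rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from m6astrat.io_core import (
    ClinicalTable, CopyNumberTable, ExpressionMatrix, GeneSetCollection,
    MutationTable, RegulatorPanel, DEFAULT_REGULATOR_PANEL, UNKNOWN,
    CLINICAL_COLUMNS,
)

CLUSTER_NAMES = "ABCDEFGHIJ"

#: Variant-class sampling probabilities (silent counts toward TMB but is
#: excluded from non-silent mutation frequencies).
DEFAULT_MUT_CLASSES = {"missense": 0.55, "silent": 0.25, "nonsense": 0.10, "splice_site": 0.10}


class ConfigError(ValueError):
    """Raised for infeasible simulation settings."""


@dataclass
class SimulationConfig:
    """Study-condition knobs for :func:`simulate_cohort`.

    Defaults emulate a TCGA-scale stomach-adenocarcinoma cohort: ~400
    patients, 3 molecular subtypes, ~55% censoring, a moderate latent
    prognostic effect, and a score-TMB rank correlation of 0.35.
    """

    n_samples: int = 400
    n_background_genes: int = 1800
    n_prognostic_genes: int = 200
    n_immune_genes: int = 50
    k_true: int = 3
    #: regulator-gene mean shift between clusters, in noise-SD units
    cluster_sep: float = 4.0
    #: separation of latent-score means between adjacent clusters (SD units);
    #: makes prognostic genes simultaneously cluster-DE
    score_cluster_sep: float = 0.8
    #: |loading| of each prognostic gene on the latent score z
    prognostic_effect: float = 0.7
    #: optional cluster-specific mean pattern on prognostic genes (SD units);
    #: 0 leaves their subtype signal to flow through z alone
    prognostic_cluster_sep: float = 0.0
    #: fraction of prognostic genes loading positively on z; the imbalance
    #: anchors the sign of the PCA score (a perfectly sign-balanced
    #: signature has an arbitrary score orientation)
    prognostic_pos_fraction: float = 0.65
    #: mean shift of immune-block genes in the first cluster
    immune_shift: float = 1.0
    #: log hazard ratio per unit of the latent score
    beta_score: float = 0.8
    #: baseline hazard (1/months); default gives ~20-month median at z=0
    baseline_hazard: float = 0.0347
    censor_rate: float = 0.55
    #: target Spearman correlation between the latent score and TMB
    tmb_link: float = 0.35
    #: negative-binomial mean mutation count at z=0
    baseline_mut_rate: float = 30.0
    #: negative-binomial size (inverse-dispersion) parameter
    nb_dispersion: float = 4.0
    cnv_gain_range: tuple[float, float] = (0.02, 0.30)
    cnv_loss_range: tuple[float, float] = (0.02, 0.30)
    mut_classes: dict = field(default_factory=lambda: dict(DEFAULT_MUT_CLASSES))
    panel: RegulatorPanel = field(default_factory=lambda: DEFAULT_REGULATOR_PANEL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3 * self.k_true:
            raise ConfigError("n_samples must be at least 3 * k_true")
        if self.cluster_sep < 0:
            raise ConfigError("cluster_sep must be non-negative")
        if not (0 <= self.censor_rate < 1):
            raise ConfigError("censor_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    copynumber: CopyNumberTable
    truth_samples: pd.DataFrame   # sample_id, cluster, latent_score, tmb
    truth_genes: pd.DataFrame     # gene, prognostic, cluster_de, immune, true_beta
    config: SimulationConfig

    def immune_gene_sets(self) -> GeneSetCollection:
        """Gene sets over the planted immune and stromal-like blocks."""
        imm = list(self.truth_genes.loc[self.truth_genes["immune"], "gene"])
        half = max(1, len(imm) // 2)
        return GeneSetCollection(
            {"IMMUNE_INFILTRATE": imm,
             "IMMUNE_SIG_A": imm[:half],
             "IMMUNE_SIG_B": imm[half:] or imm[:1]},
            {"IMMUNE_INFILTRATE": "planted immune block",
             "IMMUNE_SIG_A": "first half of immune block",
             "IMMUNE_SIG_B": "second half of immune block"},
        )


def _cluster_assignments(n: int, k: int) -> np.ndarray:
    """Balanced block assignment: sizes differ by at most 1."""
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    return np.repeat(np.arange(k), sizes)


def _regulator_means(rng: np.random.Generator, n_genes: int, k: int,
                     sep: float) -> np.ndarray:
    """Per-gene, per-cluster mean shifts in {-1, 0, +1} * sep.

    Resampled per gene until the clusters are not all identical, so that
    every regulator carries some subtype signal whenever sep > 0.
    """
    means = np.zeros((n_genes, k))
    if sep == 0:
        return means
    for g in range(n_genes):
        while True:
            pattern = rng.integers(-1, 2, size=k)
            if len(set(pattern.tolist())) > 1:
                break
        means[g] = sep * pattern
    return means


def _calibrate_tmb_slope(target_rho: float, sd_z: float, baseline: float,
                         dispersion: float) -> float:
    """Slope b of log E[count] = log(baseline) + b*z realizing a target
    Spearman(z, count), found by deterministic Monte-Carlo root finding."""
    if target_rho == 0:
        return 0.0
    rng = np.random.default_rng(123456789)
    z = rng.normal(0.0, sd_z, size=20000)
    noise = rng.uniform(size=z.size)  # shared uniforms keep the curve smooth

    def realized(b: float) -> float:
        mu = baseline * np.exp(b * z)
        p = dispersion / (dispersion + mu)
        counts = stats.nbinom.ppf(noise, dispersion, p)
        return stats.spearmanr(z, counts).statistic

    lo, hi = 0.0, 0.05
    while realized(hi) < abs(target_rho):
        hi *= 2
        if hi > 50:
            raise ConfigError("tmb_link not attainable with these settings")
    b = optimize.brentq(lambda b: realized(b) - abs(target_rho), lo, hi, xtol=1e-4)
    return float(np.sign(target_rho) * b)


def _censoring_rate_param(lam_subject: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate achieving the target expected censored
    fraction, P(C < T) averaged over subjects."""
    if censor_rate == 0:
        return 0.0

    def frac(lc: float) -> float:
        return float(np.mean(lc / (lam_subject + lc)))

    hi = float(lam_subject.max())
    while frac(hi) < censor_rate:
        hi *= 2
    return float(optimize.brentq(lambda lc: frac(lc) - censor_rate, 1e-12, hi))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully ground-truthed cohort under ``config``.

    Reproducible: the same config (including seed) yields an identical
    cohort.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_samples, cfg.k_true
    sample_ids = [f"S{i:04d}" for i in range(n)]
    clusters = _cluster_assignments(n, k)
    cluster_labels = [CLUSTER_NAMES[c] for c in clusters]

    # latent per-sample prognostic score: cluster-shifted standard normal
    z_means = cfg.score_cluster_sep * (np.arange(k) - (k - 1) / 2.0)
    z = z_means[clusters] + rng.normal(size=n)

    # --- expression blocks -------------------------------------------------
    panel_genes = cfg.panel.genes
    reg_means = _regulator_means(rng, len(panel_genes), k, cfg.cluster_sep)
    reg_expr = reg_means[:, clusters] + rng.normal(size=(len(panel_genes), n))

    prog_genes = [f"PRG{i:04d}" for i in range(cfg.n_prognostic_genes)]
    loadings = cfg.prognostic_effect * rng.choice(
        [1.0, -1.0], size=cfg.n_prognostic_genes,
        p=[cfg.prognostic_pos_fraction, 1.0 - cfg.prognostic_pos_fraction])
    prog_expr = loadings[:, None] * z[None, :] + rng.normal(size=(cfg.n_prognostic_genes, n))
    if cfg.prognostic_cluster_sep > 0:
        prog_means = _regulator_means(rng, cfg.n_prognostic_genes, k,
                                      cfg.prognostic_cluster_sep)
        prog_expr += prog_means[:, clusters]

    imm_genes = [f"IMM{i:04d}" for i in range(cfg.n_immune_genes)]
    imm_shift = np.where(clusters == 0, cfg.immune_shift, 0.0)
    imm_expr = imm_shift[None, :] + rng.normal(size=(cfg.n_immune_genes, n))

    # PD-L1-like marker tracks the latent score
    marker_expr = 0.5 * z[None, :] + rng.normal(size=(1, n))

    bg_genes = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    bg_expr = rng.normal(size=(cfg.n_background_genes, n))

    genes = panel_genes + prog_genes + imm_genes + ["CD274"] + bg_genes
    values = np.vstack([reg_expr, prog_expr, imm_expr, marker_expr, bg_expr])
    # shift to a log-expression-like positive scale
    expr = ExpressionMatrix(pd.DataFrame(values + 8.0, index=pd.Index(genes, name="gene"),
                                         columns=sample_ids))

    # --- survival ----------------------------------------------------------
    lam = cfg.baseline_hazard * np.exp(cfg.beta_score * z)
    t_event = rng.exponential(1.0 / lam)
    lam_c = _censoring_rate_param(lam, cfg.censor_rate)
    if lam_c > 0:
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    os_time = np.maximum(os_time, 1e-3)

    age = np.clip(np.round(rng.normal(65, 10, size=n)), 30, 90).astype(int)
    gender = np.where(rng.uniform(size=n) < 0.65, "male", "female")
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.05, 0.2, 0.45, 0.3])
    n_stage = rng.choice(["N0", "N1", "N2", "N3"], size=n, p=[0.3, 0.27, 0.22, 0.21])
    m_stage = rng.choice(["M0", "M1"], size=n, p=[0.93, 0.07])
    tnm = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.14, 0.32, 0.43, 0.11])
    grade = rng.choice(["G1", "G2", "G3"], size=n, p=[0.03, 0.37, 0.60])
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids, "os_time": os_time, "os_event": os_event,
        "age": age, "gender": gender, "t_stage": t_stage, "n_stage": n_stage,
        "m_stage": m_stage, "tnm_stage": tnm, "grade": grade,
    })[CLINICAL_COLUMNS])

    # --- mutations ---------------------------------------------------------
    slope = _calibrate_tmb_slope(cfg.tmb_link, float(np.std(z)),
                                 cfg.baseline_mut_rate, cfg.nb_dispersion)
    mu = cfg.baseline_mut_rate * np.exp(slope * z)
    p_nb = cfg.nb_dispersion / (cfg.nb_dispersion + mu)
    counts = rng.negative_binomial(cfg.nb_dispersion, p_nb)

    mut_pool = panel_genes + prog_genes[:50] + bg_genes[:200]
    class_names = list(cfg.mut_classes)
    class_p = np.array([cfg.mut_classes[c] for c in class_names], dtype=float)
    class_p = class_p / class_p.sum()
    rec_samples: list[str] = []
    rec_genes: list[str] = []
    rec_classes: list[str] = []
    for sid, c in zip(sample_ids, counts):
        if c == 0:
            continue
        rec_samples.extend([sid] * int(c))
        rec_genes.extend(rng.choice(mut_pool, size=int(c)).tolist())
        rec_classes.extend(rng.choice(class_names, size=int(c), p=class_p).tolist())
    mutations = MutationTable(pd.DataFrame({
        "sample_id": rec_samples, "gene": rec_genes, "variant_classification": rec_classes,
    }))

    # --- copy number (regulator panel) -------------------------------------
    gain_f = rng.uniform(*cfg.cnv_gain_range, size=len(panel_genes))
    loss_f = rng.uniform(*cfg.cnv_loss_range, size=len(panel_genes))
    cn_rows = []
    for g, gf, lf in zip(panel_genes, gain_f, loss_f):
        u = rng.uniform(size=n)
        state = np.zeros(n, dtype=int)
        state[u < gf] = rng.choice([1, 2], size=int((u < gf).sum()))
        mask_loss = (u >= gf) & (u < gf + lf)
        state[mask_loss] = rng.choice([-1, -2], size=int(mask_loss.sum()))
        cn_rows.append(pd.DataFrame({"gene": g, "sample_id": sample_ids, "cn_state": state}))
    copynumber = CopyNumberTable(pd.concat(cn_rows, ignore_index=True))

    truth_samples = pd.DataFrame({
        "sample_id": sample_ids, "cluster": cluster_labels,
        "latent_score": z, "tmb": counts.astype(int),
    })
    truth_genes = pd.DataFrame({
        "gene": genes,
        "prognostic": [g in set(prog_genes) for g in genes],
        "cluster_de": [(g in set(panel_genes) and cfg.cluster_sep > 0)
                       or (g in set(prog_genes) and cfg.score_cluster_sep > 0)
                       or (g in set(imm_genes) and cfg.immune_shift != 0)
                       or (g == "CD274" and cfg.score_cluster_sep > 0)
                       for g in genes],
        "immune": [g in set(imm_genes) for g in genes],
        "true_beta": np.concatenate([
            np.zeros(len(panel_genes)),          # hazard link only via cluster
            loadings * cfg.beta_score,
            np.zeros(cfg.n_immune_genes),
            [0.5 * cfg.beta_score],              # CD274 marker
            np.zeros(cfg.n_background_genes),
        ]),
    })
    return SyntheticCohort(expr, clinical, mutations, copynumber,
                           truth_samples, truth_genes, cfg)


def truth_report(cohort: SyntheticCohort) -> dict:
    """Planted-truth summary: k, cluster sizes, true beta, realized censor
    fraction, realized latent-score/TMB rank correlation."""
    ts = cohort.truth_samples
    sizes = ts["cluster"].value_counts().sort_index()
    events = cohort.clinical.data["os_event"]
    rho = stats.spearmanr(ts["latent_score"], ts["tmb"]).statistic
    return {
        "k_true": cohort.config.k_true,
        "cluster_sizes": {str(c): int(v) for c, v in sizes.items()},
        "beta_score": cohort.config.beta_score,
        "realized_censor_fraction": float(1.0 - events.mean()),
        "realized_score_tmb_spearman": float(rho),
        "n_samples": int(len(ts)),
        "n_genes": int(cohort.expression.shape[0]),
    }
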