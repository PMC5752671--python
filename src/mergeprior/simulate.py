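"""Synthetic screens with known ground truth.

The generator emulates the structure the marker-potential model assumes: a
genes x 5 driver-feature matrix in which a chosen weight vector truly
determines each gene's marker potential; an expression matrix with
correlated gene blocks (planted hubs) plus per-class co-expression modules
formed by each class's marker genes; and drug AUC generated as a noisy
linear function of the drug's marker genes' expression, with drugs in a
mechanism class sharing their markers.

Marker modules are what make marker potential learnable at screen scale:
a drug's response has bounded variance, so dozens of *independent* marker
genes could only ever reach correlations of order 1/sqrt(k).  Letting a
class's markers share a latent expression factor — biologically, a pathway
module — gives every true pair a correlation whose Fisher z has variance
close to the configured ``true_omega2`` inflation, while each gene's
marginal marker probability still follows the marker-potential logit
exactly.

The default scale mirrors a small AML screen: p = 1000 genes, q = 53
drugs, n = 30 discovery samples, with 14-sample (attenuation 0.8) and
12-sample (attenuation 0.4) validation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .features import assemble_features
from .matrixio import DrugClassAnnotation, DrugResponseMatrix, ExpressionMatrix

DEFAULT_TRUE_V = np.array([0.3, 0.8, 0.35, 0.15, -0.35])
DEFAULT_TRUE_V = DEFAULT_TRUE_V / np.linalg.norm(DEFAULT_TRUE_V)


@dataclass
class TruthConfig:
    """Parameters of the generative law.

    ``true_v`` is the driver-feature weight vector (unit norm); the
    per-gene marker-potential logit is ``true_lambda0 + true_lam * (D @
    true_v)``.  ``signal_share`` is the fraction of each drug's response
    variance carried by its marker genes; ``marker_module_rho`` the
    variance share of the class module factor in each marker's expression;
    ``block_rho`` the within-block share around each planted hub.
    ``true_omega2`` is the nominal variance inflation of true-pair
    z-scores the defaults aim at.
    """

    true_v: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_V.copy())
    true_lambda0: float = float(special.logit(0.02))
    true_lam: float = 2.0
    true_omega2: float = 4.0
    signal_share: float = 0.55
    marker_module_rho: float = 0.5
    shared_axis_rho: float = 0.25  # variance share of the common
    # drug-sensitivity axis inside each class module (screens show a
    # moderate general-sensitivity factor across drugs)
    # batch confounding: a dataset-specific factor loads on a random gene
    # subset and on every drug's response, creating significant but
    # irreproducible associations — the failure mode prior-guided
    # prioritisation protects against.  The confounded subset is redrawn
    # per data set (a new batch), so these associations never replicate.
    confound_share: float = 0.35
    confound_gene_fraction: float = 0.1
    confound_gene_rho: float = 0.55
    n_classes: int = 12
    multiclass_fraction: float = 0.3
    hub_spacing: int = 50  # one planted hub per this many genes
    block_size: int = 10
    block_rho: float = 0.5
    heavy_tailed_noise: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth produced by :func:`generate_dataset`.

    ``loadings`` (p x n_factors) and ``idio_sd`` define the expression
    law ``x = loadings @ f + idio_sd * e`` with standard-normal factors
    ``f`` and noise ``e``; factor order is hub blocks then class modules.
    """

    config: TruthConfig
    seed: int
    gene_ids: list[str]
    drug_ids: list[str]
    true_v: np.ndarray
    true_lambda0: float
    true_lam: float
    true_omega2: float
    logits: np.ndarray  # per-gene marker-potential logit
    pi: np.ndarray
    marker_indicator: np.ndarray  # p x q bool
    effect_sizes: np.ndarray  # p x q signed coefficients
    noise_sd: np.ndarray  # per-drug response noise sd
    response_sd: np.ndarray  # per-drug total response sd (at attenuation 1)
    planted_hubs: list[str]
    blocks: list[np.ndarray]  # gene indices per hub block (hub first)
    class_map: DrugClassAnnotation
    primary_class: list[str]
    loadings: np.ndarray  # p x (n_blocks + n_classes)
    idio_sd: np.ndarray  # per-gene idiosyncratic sd

    @property
    def n_true_pairs(self) -> int:
        return int(self.marker_indicator.sum())

    def response_scale(self, attenuation: float = 1.0) -> np.ndarray:
        """Per-drug response sd when effects are scaled by ``attenuation``."""
        beta = self.effect_sizes * attenuation
        sig = np.einsum("fp,pq->fq", self.loadings.T, beta)
        var = (sig**2).sum(axis=0) + ((self.idio_sd[:, None] * beta) ** 2).sum(
            axis=0
        )
        return np.sqrt(var + self.noise_sd**2)


def _draw_expression(truth: SyntheticTruth, n: int, rng, prefix: str):
    """Expression plus this data set's batch factor.

    A fresh random gene subset loads on a fresh batch factor ``b`` (the
    subset and factor model a batch/platform effect, so they never carry
    over between data sets).  Returns ``(X, b)``; the response draw reuses
    ``b`` to confound the same batch into the drug response.
    """
    p, n_fac = truth.loadings.shape
    cfg = truth.config
    f = rng.standard_normal((n_fac, n))
    e = rng.standard_normal((p, n))
    X = truth.loadings @ f + truth.idio_sd[:, None] * e
    b = rng.standard_normal(n)
    n_conf = int(round(cfg.confound_gene_fraction * p))
    if n_conf > 0 and cfg.confound_gene_rho > 0:
        conf_genes = rng.choice(p, size=n_conf, replace=False)
        rho_c = cfg.confound_gene_rho
        X[conf_genes] = (
            np.sqrt(1.0 - rho_c) * X[conf_genes] + np.sqrt(rho_c) * b
        )
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    return ExpressionMatrix(truth.gene_ids, sample_ids, X), b


def _draw_response(
    truth: SyntheticTruth,
    X: ExpressionMatrix,
    batch: np.ndarray,
    rng,
    attenuation: float = 1.0,
) -> DrugResponseMatrix:
    beta = truth.effect_sizes * attenuation
    cfg = truth.config
    n = len(X.sample_ids)
    q = len(truth.drug_ids)
    if cfg.heavy_tailed_noise:
        eps = rng.standard_t(df=3, size=(q, n)) / np.sqrt(3.0)
    else:
        eps = rng.standard_normal((q, n))
    conf_sign = rng.choice([-1.0, 1.0], size=q)
    conf_coef = conf_sign * np.sqrt(cfg.confound_share)
    raw = (
        beta.T @ X.values
        + conf_coef[:, None] * batch[None, :]
        + truth.noise_sd[:, None] * eps
    )
    sd = np.sqrt(truth.response_scale(attenuation) ** 2 + cfg.confound_share)
    sd = np.where(sd > 1e-12, sd, 1.0)
    auc = stats.norm.cdf(raw / sd[:, None])
    return DrugResponseMatrix(truth.drug_ids, X.sample_ids, auc)


def generate_dataset(
    p: int = 1000,
    q: int = 53,
    n: int = 30,
    config: TruthConfig | None = None,
    seed: int = 0,
):
    """Generate one synthetic screen with known truth.

    Returns ``(X, Y, features, classes, truth)``: expression (p x n), drug
    AUC (q x n), the genes x 5 driver-feature matrix, the drug-class
    annotation, and the :class:`SyntheticTruth` record.
    """
    if p < 20 or q < 2 or n < 8:
        raise ValueError("need p >= 20, q >= 2, n >= 8")
    config = config or TruthConfig()
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i + 1:04d}" for i in range(p)]
    drug_ids = [f"d{j + 1:03d}" for j in range(q)]

    # planted hub blocks ------------------------------------------------
    n_hubs = max(1, p // config.hub_spacing)
    if n_hubs * config.block_size > p:
        raise ValueError("more planted block members than genes")
    perm = rng.permutation(p)
    blocks = [
        perm[i * config.block_size : (i + 1) * config.block_size]
        for i in range(n_hubs)
    ]
    hubs = [int(b[0]) for b in blocks]

    # driver features ----------------------------------------------------
    mutated = rng.random(p) < 0.15
    mutation = np.where(mutated, rng.beta(1.5, 8.0, size=p), 0.0)
    # overdispersed neighbour counts, consistent with the planted hubs
    hubness = rng.negative_binomial(2, 0.5, size=p).astype(float)  # mean 2
    for b in blocks:
        hubness[b[0]] += config.block_size - 1 + rng.poisson(3)
        hubness[b[1:]] += 1
    regulator = (rng.random(p) < 0.15).astype(float)
    cnv = rng.standard_normal(p)
    methylation = rng.standard_normal(p)
    features = assemble_features(
        mutation, hubness, regulator, cnv, methylation, gene_ids=gene_ids
    )

    # marker potential ---------------------------------------------------
    m_true = features.standardized_values @ config.true_v
    logits = config.true_lambda0 + config.true_lam * m_true
    pi = special.expit(logits)

    # drug classes: random primary class per drug, optional second label --
    n_classes = min(config.n_classes, q)
    labels = [f"c{c + 1:02d}" for c in range(n_classes)]
    primary_idx = np.concatenate(
        [np.arange(n_classes), rng.integers(0, n_classes, size=q - n_classes)]
    )
    rng.shuffle(primary_idx)
    primary_idx = primary_idx.astype(int)
    primary = [labels[c] for c in primary_idx]
    class_map = {}
    for j, d in enumerate(drug_ids):
        cls = {primary[j]}
        if rng.random() < config.multiclass_fraction and n_classes > 1:
            extra = labels[int(rng.integers(0, n_classes))]
            if extra != primary[j]:
                cls.add(extra)
        class_map[d] = frozenset(cls)

    # class-shared markers: gene i marks class c with probability pi_i ----
    class_marker = rng.random((p, n_classes)) < pi[:, None]
    # one association direction per gene, consistent across classes
    gene_sign = rng.choice([-1.0, 1.0], size=p)

    # expression law: hub-block factors + class marker modules.  Each class
    # module f_c = sqrt(kappa) * g + sqrt(1-kappa) * h_c shares a common
    # sensitivity axis g, so genes marking many classes stay strongly
    # correlated with each class's drugs instead of diluting their variance
    # over orthogonal factors.  Factor order: blocks, g, h_c.
    kappa = config.shared_axis_rho
    n_fac = n_hubs + 1 + n_classes
    loadings = np.zeros((p, n_fac))
    block_share = np.zeros(p)
    for bi, b in enumerate(blocks):
        loadings[b, bi] = np.sqrt(config.block_rho)
        block_share[b] = config.block_rho
    M = class_marker.sum(axis=1)  # classes marked per gene
    marker_share = np.minimum(
        config.marker_module_rho * M, np.maximum(0.9 - block_share, 0.0)
    )
    # per-class module coefficient: variance l^2 (kappa M^2 + (1-kappa) M)
    denom = kappa * M.astype(float) ** 2 + (1.0 - kappa) * M
    with np.errstate(divide="ignore", invalid="ignore"):
        l_gene = np.sqrt(np.where(M > 0, marker_share / np.maximum(denom, 1e-12), 0.0))
    loadings[:, n_hubs] = gene_sign * l_gene * np.sqrt(kappa) * M
    loadings[:, n_hubs + 1 :] = (
        (gene_sign * l_gene * np.sqrt(1.0 - kappa))[:, None] * class_marker
    )
    idio_var = 1.0 - (loadings**2).sum(axis=1)
    idio_sd = np.sqrt(np.maximum(idio_var, 1e-6))

    # response coefficients: equal magnitude on each marker, signed by the
    # gene's association direction so class markers pull together
    marker = class_marker[:, primary_idx]
    raw_w = np.where(marker, gene_sign[:, None], 0.0)

    sig = np.einsum("pf,pq->fq", loadings, raw_w)
    sig_var = (sig**2).sum(axis=0) + ((idio_sd[:, None] * raw_w) ** 2).sum(axis=0)
    scale = np.where(
        sig_var > 0,
        np.sqrt(config.signal_share / np.maximum(sig_var, 1e-300)),
        0.0,
    )
    beta = raw_w * scale[None, :]
    resid = max(1.0 - config.signal_share - config.confound_share, 0.05)
    noise_sd = np.full(q, float(np.sqrt(resid)))
    # drugs without any marker: their signal share goes to noise instead
    noise_sd[sig_var == 0] = float(
        np.sqrt(max(1.0 - config.confound_share, 0.05))
    )

    truth = SyntheticTruth(
        config=config,
        seed=seed,
        gene_ids=gene_ids,
        drug_ids=drug_ids,
        true_v=np.asarray(config.true_v, dtype=float),
        true_lambda0=config.true_lambda0,
        true_lam=config.true_lam,
        true_omega2=config.true_omega2,
        logits=logits,
        pi=pi,
        marker_indicator=marker,
        effect_sizes=beta,
        noise_sd=noise_sd,
        response_sd=np.ones(q),
        planted_hubs=[gene_ids[i] for i in hubs],
        blocks=blocks,
        class_map=DrugClassAnnotation(class_map),
        primary_class=primary,
        loadings=loadings,
        idio_sd=idio_sd,
    )
    truth.response_sd = truth.response_scale(1.0)

    X, batch = _draw_expression(truth, n, rng, prefix="P")
    Y = _draw_response(truth, X, batch, rng)
    return X, Y, features, truth.class_map, truth


def generate_validation_replicate(
    truth: SyntheticTruth, n_val: int, attenuation: float = 1.0, seed: int = 1
):
    """New samples from the same law with effects scaled by ``attenuation``.

    ``attenuation=1`` is a faithful replicate, ``0`` a pure null (the
    response carries no marker signal).  Sample IDs are prefixed ``V``.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X, batch = _draw_expression(truth, n_val, rng, prefix="V")
    Y = _draw_response(truth, X, batch, rng, attenuation=attenuation)
    return X, Y


def generate_raw_screen(
    n_drugs: int = 3, n_samples: int = 2, n_conc: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Minimal long-format viability screen from 4PL ground truth.

    Concentrations span 1e-10..1e-5 M; duplicate wells with small Gaussian
    noise.  Intended for exercising the dose-response pipeline.
    """
    rng = np.random.default_rng(seed)
    conc = np.logspace(-10, -5, n_conc)
    rows = []
    for di in range(n_drugs):
        for si in range(n_samples):
            ec50 = 10 ** rng.uniform(-9, -6)
            hill = rng.uniform(0.5, 2.0)
            bottom = rng.uniform(0.0, 0.3)
            viab = bottom + (1.0 - bottom) / (1.0 + (conc / ec50) ** hill)
            for rep in (1, 2):
                noisy = np.clip(viab + rng.normal(0, 0.02, size=n_conc), 0, 1.5)
                for c, v in zip(conc, noisy):
                    rows.append(
                        {
                            "drug_id": f"d{di + 1:02d}",
                            "sample_id": f"P{si + 1:03d}",
                            "concentration_M": c,
                            "replicate": rep,
                            "viability_fraction": v,
                        }
                    )
    return pd.DataFrame(rows)


def truth_to_json(truth: SyntheticTruth) -> dict:
    """JSON-serialisable summary of the planted truth (no large matrices)."""
    return {
        "seed": truth.seed,
        "true_v": truth.true_v.tolist(),
        "true_lambda0": truth.true_lambda0,
        "true_lam": truth.true_lam,
        "true_omega2": truth.true_omega2,
        "signal_share": truth.config.signal_share,
        "n_true_pairs": truth.n_true_pairs,
        "planted_hubs": truth.planted_hubs,
        "n_classes": len(truth.class_map.class_labels),
    }
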