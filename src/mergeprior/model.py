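"""Marker-potential model: a two-groups z-score mixture with a
covariate-dependent prior over genes.

Each gene-drug pair contributes a Fisher z-score ``z_ij``.  Pairs split into
a null group (z ~ N(0, 1)) and a true-association group with inflated
variance (z ~ N(0, 1 + omega2); direction is kept in the association table,
only magnitude enters the mixture).  The chance that gene i's pairs are true
associations is driven by the gene's marker potential:

    logit(pi_i) = lambda0 + lam * m_i,       m_i = sum_k v_k d_ik

where d_ik are the gene's five standardised driver features (mutation,
hubness, regulator, cnv, methylation).  Fitting jointly learns the feature
weights v, the baseline log-odds lambda0, the impact lam >= 0 of the score
on the prior, and the variance inflation omega2 — so the learned score m_i
explains the observed associations as well as the features allow.

Inference is EM.  The E-step computes per-pair responsibilities; the M-step
solves a responsibility-weighted logistic regression of genes' mean
responsibilities on the driver features (Newton with step halving, so the
expected complete-data objective never decreases) and updates omega2 in
closed form from responsibility-weighted second moments.  The (v, lam)
scale indeterminacy is resolved by reporting v with unit Euclidean norm and
folding the magnitude into lam (hence lam >= 0 automatically).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .association import AssociationTable, SignificantPairSet, bh_select
from .features import FEATURE_NAMES, DriverFeatureMatrix

logger = logging.getLogger("mergeprior")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(z, var):
    return -0.5 * z**2 / var - 0.5 * np.log(var) - _LOG_SQRT_2PI


@dataclass
class MergeScores:
    """Per-gene marker-potential scores and their dense ranking."""

    gene_ids: list[str]
    m: np.ndarray
    rank: np.ndarray  # 1 = highest score; ties broken by gene_id

    def top(self, N: int) -> list[str]:
        order = np.argsort(self.rank)
        return [self.gene_ids[i] for i in order[:N]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "merge_score": self.m, "rank": self.rank}
        )


@dataclass
class PrioritizedResult:
    """Top-N genes by score plus their FDR-significant drug associations."""

    N: int
    prioritized_genes: list[str]
    selected_pairs: SignificantPairSet


class MergeModel:
    """Joint model of driver features and observed gene-drug associations.

    Parameters
    ----------
    assoc : AssociationTable
        Pairwise statistics from :func:`mergeprior.association.pairwise_association`.
        Only the z-scores enter the likelihood.
    features : DriverFeatureMatrix
        Standardised genes x 5 driver features, same gene universe as
        ``assoc`` (reindexed automatically when orders differ).
    """

    def __init__(self, assoc: AssociationTable, features: DriverFeatureMatrix):
        if set(assoc.gene_ids) - set(features.gene_ids):
            raise ValueError("association table contains genes absent from features")
        self.assoc = assoc
        self.features = features.reindex(assoc.gene_ids)
        self.z = np.asarray(assoc.z, dtype=float)
        self._mask = np.isfinite(self.z)
        n_bad = int((~self._mask).sum())
        if n_bad:
            logger.info("fit excludes %d non-finite z entr%s", n_bad,
                        "y" if n_bad == 1 else "ies")

    @classmethod
    def from_dataframes(
        cls, assoc: AssociationTable, features: pd.DataFrame
    ) -> "MergeModel":
        """Build from a gene-indexed DataFrame with the 5 feature columns."""
        fm = DriverFeatureMatrix(
            list(features.index.astype(str)),
            features[list(FEATURE_NAMES)].to_numpy(),
        )
        return cls(assoc, fm)

    # ------------------------------------------------------------------
    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-6,
        seed: int | None = None,
    ) -> "MergeResults":
        """Run EM to convergence and return a :class:`MergeResults`.

        ``tol`` is the relative change in marginal log-likelihood below
        which iteration stops.  ``seed`` is accepted for interface
        stability; the default initialisation is deterministic.
        """
        D = self.features.standardized_values
        z = self.z
        mask = self._mask
        p, q = z.shape
        qi = mask.sum(axis=1).astype(float)  # pairs per gene

        identifiable = len(self.features.constant_features) < len(FEATURE_NAMES)
        # working parameters: eta_i = lambda0 + D @ b with b = lam * v
        lambda0 = float(special.logit(0.01))
        b = np.zeros(D.shape[1])
        omega2 = 4.0
        # reflect the conventional lam=0.1, v=0 start: b = lam * v = 0

        loglik_trace: list[float] = []
        prev = -np.inf
        gamma = np.zeros_like(z)
        converged = False

        for it in range(max_iter):
            eta = lambda0 + D @ b
            pi = special.expit(eta)
            # E-step -----------------------------------------------------
            log_null = _norm_logpdf(z, 1.0)
            log_alt = _norm_logpdf(z, 1.0 + omega2)
            with np.errstate(divide="ignore"):
                log_pi = np.log(pi)[:, None]
                log_1mpi = np.log1p(-pi)[:, None]
            a = log_pi + log_alt
            bmat = log_1mpi + log_null
            mx = np.maximum(a, bmat)
            denom = mx + np.log(np.exp(a - mx) + np.exp(bmat - mx))
            gamma = np.where(mask, np.exp(a - denom), 0.0)

            loglik = float(denom[mask].sum())
            loglik_trace.append(loglik)
            if loglik + 1e-8 < prev:
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev:.8f} -> {loglik:.8f}"
                )
            if prev > -np.inf and abs(loglik - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
            prev = loglik

            # M-step: logistic part --------------------------------------
            gbar = np.where(qi > 0, gamma.sum(axis=1) / np.maximum(qi, 1.0), 0.0)
            lambda0, b = _weighted_logistic(
                D if identifiable else np.zeros_like(D), gbar, qi, lambda0, b
            )
            # M-step: variance inflation ---------------------------------
            wsum = gamma[mask].sum()
            if wsum > 1e-10:
                sigma1 = (gamma[mask] * z[mask] ** 2).sum() / wsum
                omega2 = max(sigma1 - 1.0, 1e-6)

        lam = float(np.linalg.norm(b))
        v = b / lam if lam > 0 else np.zeros_like(b)

        cov = _logistic_covariance(D, lambda0, b, qi)
        return MergeResults(
            model=self,
            v=v,
            lam=lam,
            lambda0=lambda0,
            omega2=float(omega2),
            responsibilities=np.where(mask, gamma, np.nan),
            loglik_trace=np.asarray(loglik_trace),
            converged=converged,
            n_iter=len(loglik_trace),
            feature_weights_identifiable=identifiable,
            _coef_cov=cov,
        )


def _weighted_logistic(D, target, weight, intercept, coef, max_newton=50):
    """Maximise sum_i weight_i * [t_i log pi_i + (1-t_i) log(1-pi_i)].

    Newton iterations with step halving on the objective, so the returned
    parameters never have a lower objective than the incoming ones.  A tiny
    ridge keeps the Hessian invertible when features are collinear.
    """
    X = np.column_stack([np.ones(D.shape[0]), D])
    beta = np.concatenate([[intercept], coef])
    w = weight
    ridge = 1e-8

    def objective(bv):
        eta = X @ bv
        # w * [t*eta - log(1 + exp(eta))]
        return float(np.sum(w * (target * eta - np.logaddexp(0.0, eta))))

    obj = objective(beta)
    for _ in range(max_newton):
        pi = special.expit(X @ beta)
        grad = X.T @ (w * (target - pi))
        W = w * pi * (1.0 - pi)
        H = (X * W[:, None]).T @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            break
        if not np.all(np.isfinite(step)):
            break
        # step halving keeps the M-step monotone
        t_step = 1.0
        new = objective(beta + t_step * step)
        while new < obj - 1e-12 and t_step > 1e-6:
            t_step *= 0.5
            new = objective(beta + t_step * step)
        if new < obj - 1e-12:
            break
        improved = new - obj
        beta = beta + t_step * step
        obj = new
        if improved < 1e-10 * (abs(obj) + 1.0):
            break
    return float(beta[0]), beta[1:]


def _logistic_covariance(D, intercept, coef, weight):
    """Inverse observed information of the logistic stage (approximate SEs).

    Conditional on the final responsibilities; it understates the full EM
    uncertainty but ranks the precision of the feature weights sensibly.
    """
    X = np.column_stack([np.ones(D.shape[0]), D])
    pi = special.expit(X @ np.concatenate([[intercept], coef]))
    W = weight * pi * (1.0 - pi)
    H = (X * W[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full((X.shape[1], X.shape[1]), np.nan)


@dataclass
class MergeResults:
    """Fitted marker-potential model.

    Attributes
    ----------
    v : ndarray (5,)
        Driver-feature weights, unit Euclidean norm (all zeros when the
        features carry no information).
    lam : float
        Impact (>= 0) of the score on the prior log-odds.
    lambda0 : float
        Baseline log-odds that a pair is a true association.
    omega2 : float
        Variance inflation of true-association z-scores.
    responsibilities : ndarray (p, q)
        Posterior probability each pair is a true association.
    """

    model: MergeModel
    v: np.ndarray
    lam: float
    lambda0: float
    omega2: float
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    feature_weights_identifiable: bool = True
    _coef_cov: np.ndarray | None = field(default=None, repr=False)

    # -- parameter table -------------------------------------------------
    @property
    def feature_weights(self) -> pd.Series:
        return pd.Series(self.v, index=list(FEATURE_NAMES), name="weight")

    def bse(self) -> pd.Series:
        """Approximate standard errors of (lambda0, lam*v_k)."""
        if self._coef_cov is None:
            raise ValueError("covariance unavailable")
        se = np.sqrt(np.diag(self._coef_cov))
        return pd.Series(
            se, index=["lambda0"] + [f"impact_{f}" for f in FEATURE_NAMES]
        )

    def scores(self) -> MergeScores:
        """Per-gene scores ``m = D_std @ v`` with deterministic ranking."""
        D = self.model.features.standardized_values
        m = D @ self.v
        gene_ids = self.model.features.gene_ids
        order = np.lexsort((np.asarray(gene_ids), -m))
        rank = np.empty(len(m), dtype=int)
        rank[order] = np.arange(1, len(m) + 1)
        return MergeScores(list(gene_ids), m, rank)

    def prioritize(
        self, N: int = 500, q: float = 0.1, assoc: AssociationTable | None = None
    ) -> PrioritizedResult:
        """Top-N genes by score, keeping their genome-wide-BH significant pairs.

        BH runs over all p x q pairs first (genome-wide), then the surviving
        pairs are intersected with the prioritised gene subset.
        """
        assoc = assoc if assoc is not None else self.model.assoc
        scores = self.scores()
        p = len(scores.gene_ids)
        if N > p:
            logger.warning("prioritize: N=%d exceeds %d genes; clipped", N, p)
            N = p
        if N < 1:
            raise ValueError("N must be >= 1")
        top = set(scores.top(N))
        genome_wide = bh_select(assoc, q=q)
        selected = SignificantPairSet(
            pairs={pr for pr in genome_wide.pairs if pr[0] in top},
            q_threshold=q,
            method=genome_wide.method,
            q_values=genome_wide.q_values,
        )
        return PrioritizedResult(N, scores.top(N), selected)

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured)."""
        from statsmodels.iolib.table import SimpleTable

        info = [
            ("genes", len(self.model.assoc.gene_ids)),
            ("drugs", len(self.model.assoc.drug_ids)),
            ("EM iterations", self.n_iter),
            ("converged", self.converged),
            ("log-likelihood", f"{self.loglik_trace[-1]:.3f}"),
            ("baseline log-odds lambda0", f"{self.lambda0:.4f}"),
            ("impact lam", f"{self.lam:.4f}"),
            ("variance inflation omega2", f"{self.omega2:.4f}"),
        ]
        head = SimpleTable(
            [[k, str(val)] for k, val in info],
            headers=["", ""],
            title="Marker-potential two-groups mixture",
        )
        se = None
        if self._coef_cov is not None:
            se = np.sqrt(np.diag(self._coef_cov))[1:] / max(self.lam, 1e-12)
        rows = []
        for k, name in enumerate(FEATURE_NAMES):
            row = [name, f"{self.v[k]:+.4f}"]
            row.append(f"{se[k]:.4f}" if se is not None else "")
            rows.append(row)
        wtab = SimpleTable(
            rows,
            headers=["driver feature", "weight v_k", "approx. SE"],
            title="Feature weights (unit norm)",
        )
        return str(head) + "\n" + str(wtab)

    # -- persistence ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "format": "mergeprior-model",
            "version": 1,
            "feature_names": list(FEATURE_NAMES),
            "v": self.v.tolist(),
            "lam": self.lam,
            "lambda0": self.lambda0,
            "omega2": self.omega2,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "feature_weights_identifiable": self.feature_weights_identifiable,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def fit_merge(
    assoc: AssociationTable,
    features: DriverFeatureMatrix,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> MergeResults:
    """Convenience wrapper: build a :class:`MergeModel` and fit it."""
    return MergeModel(assoc, features).fit(max_iter=max_iter, tol=tol, seed=seed)


def merge_scores(results: MergeResults) -> MergeScores:
    """Scores from a fitted model (see :meth:`MergeResults.scores`)."""
    return results.scores()


def rank_pairs_by_method(
    method: str,
    X,
    Y,
    features: DriverFeatureMatrix | None = None,
    results: MergeResults | None = None,
    assoc: AssociationTable | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """A deterministic total order on gene-drug pairs for one method.

    merge
        Genes in descending score order; within a gene its drugs in
        ascending association p-value (so a budget of q_drugs * N pairs
        covers the top N genes on average).
    pearson / spearman
        All pairs in ascending p-value.
    elasticnet
        Per-drug elastic net (mixing 0.5, penalty path by 5-fold CV, fixed
        seed) on standardised expression; pairs in descending |coefficient|,
        zero-coefficient pairs appended in lexicographic order.
    """
    from .association import pairwise_association

    if method in ("pearson", "spearman"):
        if assoc is None or (method == "spearman") != assoc.rank_based:
            assoc = pairwise_association(X, Y, rank_based=method == "spearman")
        frame = assoc.to_frame().dropna(subset=["p"])
        frame = frame.sort_values(["p", "gene_id", "drug_id"], kind="mergesort")
        return list(zip(frame["gene_id"], frame["drug_id"]))

    if method == "merge":
        if results is None:
            if features is None:
                raise ValueError("merge ranking needs a fitted model or features")
            if assoc is None:
                assoc = pairwise_association(X, Y)
            results = fit_merge(assoc, features, seed=seed)
        assoc = assoc if assoc is not None else results.model.assoc
        scores = results.scores()
        order = np.argsort(scores.rank)
        gene_index = {g: i for i, g in enumerate(assoc.gene_ids)}
        out = []
        drug_ids = np.asarray(assoc.drug_ids)
        for gi in order:
            gene = scores.gene_ids[gi]
            row = assoc.pval[gene_index[gene]]
            jorder = np.lexsort((drug_ids, row))
            out.extend((gene, assoc.drug_ids[j]) for j in jorder)
        return out

    if method == "elasticnet":
        return _elasticnet_ranking(X, Y, seed)

    raise ValueError(f"unknown ranking method {method!r}")


def _elasticnet_ranking(X, Y, seed: int) -> list[tuple[str, str]]:
    from sklearn.linear_model import ElasticNetCV
    from sklearn.model_selection import KFold

    from .matrixio import assert_aligned

    assert_aligned(X, Y)
    Xt = X.values.T
    Xt = (Xt - Xt.mean(axis=0)) / np.where(Xt.std(axis=0) > 1e-12, Xt.std(axis=0), 1.0)
    rows = []
    for j, drug in enumerate(Y.drug_ids):
        y = Y.values[j]
        cv = KFold(n_splits=5, shuffle=True, random_state=seed)
        enet = ElasticNetCV(l1_ratio=0.5, cv=cv, alphas=40, max_iter=5000)
        enet.fit(Xt, y)
        for g, c in zip(X.gene_ids, enet.coef_):
            rows.append((g, drug, abs(float(c))))
    frame = pd.DataFrame(rows, columns=["gene_id", "drug_id", "abscoef"])
    frame = frame.sort_values(
        ["abscoef", "gene_id", "drug_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return list(zip(frame["gene_id"], frame["drug_id"]))
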