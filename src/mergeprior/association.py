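"""Univariate gene-drug association statistics and FDR selection.

Every gene-drug pair gets a correlation between the gene's expression and
the drug's AUC across samples, the matching t statistic and two-sided
p-value, and a Fisher z-score ``atanh(r) * sqrt(n - 3)`` that is
approximately N(0, 1) under the null — the quantity the marker-potential
mixture model operates on.  Sign convention: negative r (high expression,
low AUC) marks a sensitivity association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrixio import DrugResponseMatrix, ExpressionMatrix, assert_aligned

_TINY = np.finfo(float).tiny


@dataclass
class AssociationTable:
    """Pairwise gene-drug association statistics.

    Matrices are genes x drugs.  Pairs whose correlation is undefined
    (zero-variance gene or drug) hold NaN throughout.
    """

    gene_ids: list[str]
    drug_ids: list[str]
    r: np.ndarray
    t: np.ndarray
    pval: np.ndarray
    z: np.ndarray
    n_used: np.ndarray
    rank_based: bool = False

    @property
    def shape(self):
        return self.r.shape

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene_id, drug_id, r, t, p, z, n_used."""
        p, q = self.shape
        gi, di = np.meshgrid(range(p), range(q), indexing="ij")
        return pd.DataFrame(
            {
                "gene_id": np.asarray(self.gene_ids)[gi.ravel()],
                "drug_id": np.asarray(self.drug_ids)[di.ravel()],
                "r": self.r.ravel(),
                "t": self.t.ravel(),
                "p": self.pval.ravel(),
                "z": self.z.ravel(),
                "n_used": self.n_used.ravel(),
            }
        )

    def restrict_genes(self, gene_ids) -> "AssociationTable":
        idx = pd.Index(self.gene_ids).get_indexer(list(gene_ids))
        if (idx < 0).any():
            raise KeyError("gene(s) missing from association table")
        return AssociationTable(
            [str(g) for g in gene_ids],
            self.drug_ids,
            self.r[idx],
            self.t[idx],
            self.pval[idx],
            self.z[idx],
            self.n_used[idx],
            self.rank_based,
        )


@dataclass
class SignificantPairSet:
    """Gene-drug pairs passing BH selection at level ``q_threshold``."""

    pairs: set = field(default_factory=set)
    q_threshold: float = 0.1
    method: str = "genome-wide BH"
    q_values: dict = field(default_factory=dict)

    def __contains__(self, pair):
        return pair in self.pairs

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each row of M on covariate columns C (with intercept)."""
    n = M.shape[1]
    design = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(design)
    return M - (M @ Q) @ Q.T


def _rankdata_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, M)


def pairwise_association(
    X: ExpressionMatrix,
    Y: DrugResponseMatrix,
    covariates: pd.DataFrame | None = None,
    rank_based: bool = False,
) -> AssociationTable:
    """All-pairs correlation of expression rows against drug AUC rows.

    Without covariates: Pearson (or Spearman when ``rank_based``)
    correlation, ``t = r * sqrt((n-2) / (1-r^2))`` and a two-sided p-value
    from the t distribution with n-2 df.  With covariates: partial
    correlation after residualising both sides on the covariates
    (equivalent to the p-value of the gene coefficient in a linear model of
    AUC on expression plus covariates), with n-2-c df.
    """
    assert_aligned(X, Y)
    n = len(X.sample_ids)
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")

    Xv, Yv = X.values, Y.values
    if rank_based:
        Xv, Yv = _rankdata_rows(Xv), _rankdata_rows(Yv)

    df_loss = 0
    if covariates is not None:
        C = covariates.loc[X.sample_ids].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), C])) < C.shape[1] + 1:
            # constant / collinear covariates carry no information
            keep = [
                j
                for j in range(C.shape[1])
                if np.ptp(C[:, j]) > 1e-12
            ]
            C = C[:, keep]
        if C.shape[1] > 0:
            Xv = _residualize(Xv, C)
            Yv = _residualize(Yv, C)
            df_loss = C.shape[1]

    x_sd = Xv.std(axis=1)
    y_sd = Yv.std(axis=1)
    bad_x = x_sd < 1e-12
    bad_y = y_sd < 1e-12
    Xs = np.zeros_like(Xv)
    Ys = np.zeros_like(Yv)
    Xs[~bad_x] = (Xv[~bad_x] - Xv[~bad_x].mean(axis=1, keepdims=True)) / x_sd[
        ~bad_x, None
    ]
    Ys[~bad_y] = (Yv[~bad_y] - Yv[~bad_y].mean(axis=1, keepdims=True)) / y_sd[
        ~bad_y, None
    ]

    r = (Xs @ Ys.T) / n
    r = np.clip(r, -1.0, 1.0)
    r[bad_x, :] = np.nan
    r[:, bad_y] = np.nan

    dof = n - 2 - df_loss
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    # perfect correlation: report the smallest positive value, not 0
    pval = np.where(np.isinf(t), _TINY, pval)
    pval = np.where(np.isnan(r), np.nan, np.maximum(pval, _TINY))

    z = fisher_z(r, n - df_loss)
    n_used = np.full(r.shape, n, dtype=int)
    return AssociationTable(
        list(X.gene_ids), list(Y.drug_ids), r, t, pval, z, n_used, rank_based
    )


def fisher_z(r, n):
    """Fisher-transformed correlation: ``atanh(r) * sqrt(n - 3)``.

    Approximately standard normal under independence.  |r| = 1 is clipped
    to 1 - 1e-12 with a warning so the transform stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.isscalar(n) and n <= 3:
        raise ValueError("fisher z needs n > 3")
    with np.errstate(invalid="ignore"):
        hit = np.abs(r) >= 1.0  # NaN compares False, as intended
    if np.any(hit):
        warnings.warn("|r| = 1 clipped to 1 - 1e-12 in fisher_z")
    r = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    out = np.arctanh(r) * np.sqrt(np.asarray(n, dtype=float) - 3.0)
    return out if out.ndim else float(out)


def bh_select(
    pvals, labels=None, q: float = 0.1, per_drug: bool = False
) -> SignificantPairSet:
    """Benjamini-Hochberg step-up selection over gene-drug pairs.

    ``pvals`` is either an :class:`AssociationTable` (all p x q pairs are
    corrected jointly, i.e. genome-wide) or a flat sequence with matching
    ``labels``.  ``per_drug=True`` corrects each drug's gene family
    separately instead of jointly.
    """
    if isinstance(pvals, AssociationTable):
        table = pvals
        if per_drug:
            out = SignificantPairSet(q_threshold=q, method="per-drug BH")
            for j, drug in enumerate(table.drug_ids):
                col = table.pval[:, j]
                sub = bh_select(
                    col[~np.isnan(col)],
                    [
                        (g, drug)
                        for g, pv in zip(table.gene_ids, col)
                        if not np.isnan(pv)
                    ],
                    q=q,
                )
                out.pairs |= sub.pairs
                out.q_values.update(sub.q_values)
            return out
        flat = table.pval.ravel()
        p_idx, d_idx = np.meshgrid(
            range(len(table.gene_ids)), range(len(table.drug_ids)), indexing="ij"
        )
        labels = [
            (table.gene_ids[i], table.drug_ids[j])
            for i, j in zip(p_idx.ravel(), d_idx.ravel())
        ]
        keep = ~np.isnan(flat)
        flat = flat[keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
        pvals = flat

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return SignificantPairSet(q_threshold=q)
    if labels is None:
        labels = list(range(pvals.size))
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    pairs = {lab for lab, rej in zip(labels, reject) if rej}
    qmap = {lab: float(qv) for lab, qv in zip(labels, qvals)}
    return SignificantPairSet(pairs=pairs, q_threshold=q, q_values=qmap)
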