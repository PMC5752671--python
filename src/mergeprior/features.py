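"""Per-gene driver features: mutation, expression hubness, regulator status,
copy number, methylation.

The five features are the covariates of the marker-potential prior.  Four are
consumed as precomputed per-gene vectors; expression hubness is estimated
here as a gene's neighbour count in a co-expression network inferred from an
expression compendium (hub genes concentrate regulatory influence and are
enriched for disease drivers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import Lasso

from .matrixio import ExpressionMatrix

logger = logging.getLogger("mergeprior")

FEATURE_NAMES = ("mutation", "hubness", "regulator", "cnv", "methylation")


@dataclass
class GeneNetwork:
    """Undirected co-expression network over genes."""

    gene_ids: list[str]
    adjacency: sparse.csr_matrix  # symmetric binary, no self-edges

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def validate(self) -> None:
        a = self.adjacency
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().sum() != 0:
            raise ValueError("adjacency must have no self-edges")


class DriverFeatureMatrix:
    """Genes x 5 driver features, raw and column-standardised.

    Standardisation is per feature (z-score with population variance); a
    constant raw column is mapped to all zeros and flagged, since its weight
    would be unidentifiable.
    """

    feature_names = FEATURE_NAMES

    def __init__(self, gene_ids, raw_values):
        raw = np.asarray(raw_values, dtype=float)
        if raw.shape != (len(gene_ids), len(FEATURE_NAMES)):
            raise ValueError(
                f"expected shape ({len(gene_ids)}, {len(FEATURE_NAMES)}), "
                f"got {raw.shape}"
            )
        self.gene_ids = [str(g) for g in gene_ids]
        self.raw_values = raw
        self.standardized_values, self.constant_features = _standardize(raw)

    @property
    def shape(self):
        return self.raw_values.shape

    def to_frame(self, standardized: bool = True) -> pd.DataFrame:
        vals = self.standardized_values if standardized else self.raw_values
        return pd.DataFrame(vals, index=self.gene_ids, columns=FEATURE_NAMES)

    def reindex(self, gene_ids) -> "DriverFeatureMatrix":
        """Restrict/reorder to ``gene_ids`` (all must be present)."""
        idx = pd.Index(self.gene_ids).get_indexer(list(gene_ids))
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes missing from feature matrix: {missing[:10]}")
        return DriverFeatureMatrix(list(gene_ids), self.raw_values[idx])


def _standardize(raw: np.ndarray) -> tuple[np.ndarray, list[str]]:
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)  # population variance: ddof=0
    constant = sd < 1e-12
    out = np.zeros_like(raw)
    nz = ~constant
    out[:, nz] = (raw[:, nz] - mean[nz]) / sd[nz]
    flagged = [FEATURE_NAMES[k] for k in np.flatnonzero(constant)]
    for name in flagged:
        warnings.warn(
            f"driver feature {name!r} is constant; standardised column set "
            "to zeros (its weight is unidentifiable)"
        )
    return out, flagged


def standardize_features(values: np.ndarray) -> np.ndarray:
    """Column z-scores (population variance); constant columns -> zeros."""
    return _standardize(np.asarray(values, dtype=float))[0]


def infer_hubness(
    expression_panel: ExpressionMatrix,
    method: str = "lasso-neighborhood",
    target_mean_degree: float = 5.0,
) -> GeneNetwork:
    """Infer a co-expression network and return it (degrees = hubness).

    lasso-neighborhood
        Per-gene sparse regression on all other genes; an edge i-j is kept
        if either regression selects the other gene (OR rule).  A single
        penalty shared across genes is chosen by bisection so the mean
        degree matches ``target_mean_degree``.
    correlation-threshold
        |Pearson r| above the quantile that yields the target mean degree.

    Genes with constant expression get degree 0 and are excluded from the
    regressions.
    """
    X = expression_panel.values
    p, n = X.shape
    if n < 20:
        warnings.warn(
            f"hubness estimated from only {n} samples; neighbour counts "
            "will be noisy"
        )
    sd = X.std(axis=1)
    constant = sd < 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-expression gene(s) excluded "
            "from network inference (degree 0)"
        )
    Z = np.zeros_like(X)
    ok = ~constant
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]

    if method == "correlation-threshold":
        adj = _correlation_network(Z, ok, target_mean_degree)
    elif method == "lasso-neighborhood":
        adj = _lasso_network(Z, ok, target_mean_degree)
    else:
        raise ValueError(f"unknown network method {method!r}")

    net = GeneNetwork(expression_panel.gene_ids, sparse.csr_matrix(adj))
    net.validate()
    logger.info(
        "infer_hubness(%s): mean degree %.2f (target %.2f)",
        method,
        net.degree.mean(),
        target_mean_degree,
    )
    return net


def _correlation_network(Z, ok, target_mean_degree):
    p, n = Z.shape
    R = (Z @ Z.T) / n
    np.fill_diagonal(R, 0.0)
    R[~ok, :] = 0.0
    R[:, ~ok] = 0.0
    absr = np.abs(R[np.triu_indices(p, k=1)])
    # mean degree d over p nodes needs p*d/2 undirected edges
    n_edges = int(round(p * target_mean_degree / 2))
    n_edges = min(n_edges, absr.size)
    if n_edges == 0:
        return sparse.csr_matrix((p, p))
    thresh = np.partition(absr, absr.size - n_edges)[absr.size - n_edges]
    adj = (np.abs(R) >= max(thresh, 1e-12)).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def _lasso_neighbors(Z, ok, alpha):
    """Directed selection matrix: S[i, j] = 1 if gene j selected for gene i."""
    p, n = Z.shape
    sel = np.zeros((p, p), dtype=np.int8)
    idx = np.flatnonzero(ok)
    for i in idx:
        mask = ok.copy()
        mask[i] = False
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            continue
        model = Lasso(alpha=alpha, max_iter=2000, tol=1e-3)
        model.fit(Z[cols].T, Z[i])
        sel[i, cols[np.abs(model.coef_) > 1e-10]] = 1
    return sel


def _lasso_network(Z, ok, target_mean_degree, max_bisect: int = 12):
    p, n = Z.shape
    lo, hi = 1e-4, 1.5  # alpha >= max|corr| selects nothing for z-scored data

    def mean_degree(alpha):
        sel = _lasso_neighbors(Z, ok, alpha)
        adj = ((sel + sel.T) > 0).astype(np.int8)  # OR rule
        return adj, adj.sum() / p

    adj, d = mean_degree(hi)
    if d >= target_mean_degree:
        return adj
    adj_lo, d_lo = mean_degree(lo)
    if d_lo <= target_mean_degree:
        return adj_lo
    best = adj_lo
    for _ in range(max_bisect):
        mid = np.sqrt(lo * hi)
        adj, d = mean_degree(mid)
        if abs(d - target_mean_degree) <= 0.25:
            return adj
        if d > target_mean_degree:
            lo = mid
        else:
            hi = mid
        best = adj
    return best


def assemble_features(
    mutation, hubness, regulator, cnv, methylation, gene_ids=None
) -> DriverFeatureMatrix:
    """Assemble the five per-gene vectors into a :class:`DriverFeatureMatrix`.

    Inputs may be pandas Series (indexed by gene) or arrays aligned with
    ``gene_ids``.  A gene missing from a Series is imputed with that
    feature's minimum observed value and flagged.
    """
    vectors = [mutation, hubness, regulator, cnv, methylation]
    if gene_ids is None:
        series = [v for v in vectors if isinstance(v, pd.Series)]
        if not series:
            raise ValueError("gene_ids required when inputs are plain arrays")
        gene_ids = list(series[0].index.astype(str))
    gene_ids = [str(g) for g in gene_ids]

    cols = []
    for name, vec in zip(FEATURE_NAMES, vectors):
        if isinstance(vec, pd.Series):
            vec = vec.copy()
            vec.index = vec.index.astype(str)
            aligned = vec.reindex(gene_ids)
            n_missing = int(aligned.isna().sum())
            if n_missing:
                fill = float(vec.min())
                warnings.warn(
                    f"{n_missing} gene(s) missing feature {name!r}; imputed "
                    f"with the feature minimum {fill:g}"
                )
                aligned = aligned.fillna(fill)
            cols.append(aligned.to_numpy(dtype=float))
        else:
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (len(gene_ids),):
                raise ValueError(
                    f"feature {name!r} has length {arr.size}, expected "
                    f"{len(gene_ids)}"
                )
            cols.append(arr)
    return DriverFeatureMatrix(gene_ids, np.column_stack(cols))


def read_features(path) -> DriverFeatureMatrix:
    """Read a gene_id + 5 named-column driver feature table (TSV/CSV)."""
    from .matrixio import _sniff_delimiter

    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    df = df[list(FEATURE_NAMES)]
    return DriverFeatureMatrix(list(df.index.astype(str)), df.to_numpy())


def write_features(features: DriverFeatureMatrix, path, sep: str = "\t") -> None:
    df = features.to_frame(standardized=False)
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, float_format="%.10g")
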