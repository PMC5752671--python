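"""Evaluation statistics for prioritised gene-drug associations.

Covers: replication ("consistency") of discovery-significant pairs in a
left-out data set; drug-class specificity (DCS) of each gene's associated
drugs with a label-permutation null; enrichment of drug mechanism classes in
a response-pattern dendrogram; class-specific marker tables conserved across
data sets; and drug-response prediction scored by Spearman correlation with
a signed-rank comparison between methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .association import AssociationTable, SignificantPairSet, bh_select
from .matrixio import DrugClassAnnotation, DrugResponseMatrix, ExpressionMatrix
from .model import MergeResults, MergeScores

logger = logging.getLogger("mergeprior")


# ---------------------------------------------------------------------------
# consistency of associations in left-out data
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyCurve:
    """Replication rate of top-ranked significant pairs vs subset size N."""

    N_grid: np.ndarray
    rate: np.ndarray  # NaN where no significant pairs fall in the budget
    total: np.ndarray
    replicated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.N_grid,
                "total_significant": self.total,
                "replicated": self.replicated,
                "rate": self.rate,
            }
        )


def consistency_rate(
    ranking: list[tuple[str, str]],
    discovery_assoc: AssociationTable,
    validation_assoc: AssociationTable,
    N_grid,
    q: float = 0.1,
    replication_alpha: float = 0.05,
) -> ConsistencyCurve:
    """Fraction of budgeted discovery-significant pairs replicating in
    validation data.

    For each N the budget is the first ``n_drugs * N`` pairs of ``ranking``
    (N genes per drug on average).  Budgeted pairs that are significant in
    the discovery data (genome-wide BH at ``q``) count as replicated when
    the validation p-value is below ``replication_alpha`` with the same
    association sign.  Pairs absent from the validation gene universe are
    excluded from both counts.
    """
    shared_genes = set(discovery_assoc.gene_ids) & set(validation_assoc.gene_ids)
    if not shared_genes:
        raise ValueError("no shared genes between discovery and validation")

    sig = bh_select(discovery_assoc, q=q).pairs

    d_gene = {g: i for i, g in enumerate(discovery_assoc.gene_ids)}
    d_drug = {d: j for j, d in enumerate(discovery_assoc.drug_ids)}
    v_gene = {g: i for i, g in enumerate(validation_assoc.gene_ids)}
    v_drug = {d: j for j, d in enumerate(validation_assoc.drug_ids)}

    def replicates(pair) -> bool:
        g, d = pair
        vp = validation_assoc.pval[v_gene[g], v_drug[d]]
        vr = validation_assoc.r[v_gene[g], v_drug[d]]
        dr = discovery_assoc.r[d_gene[g], d_drug[d]]
        return (
            np.isfinite(vp)
            and vp < replication_alpha
            and np.sign(vr) == np.sign(dr)
        )

    usable = [
        pr
        for pr in ranking
        if pr[0] in v_gene and pr[1] in v_drug and pr[0] in d_gene
    ]
    n_drugs = len(discovery_assoc.drug_ids)

    N_grid = np.asarray(list(N_grid), dtype=int)
    totals, reps, rates = [], [], []
    for N in N_grid:
        budget = usable[: n_drugs * int(N)]
        chosen = [pr for pr in budget if pr in sig]
        total = len(chosen)
        rep = sum(replicates(pr) for pr in chosen)
        totals.append(total)
        reps.append(rep)
        rates.append(rep / total if total > 0 else np.nan)
    return ConsistencyCurve(
        N_grid, np.asarray(rates), np.asarray(totals), np.asarray(reps)
    )


# ---------------------------------------------------------------------------
# drug-class specificity
# ---------------------------------------------------------------------------


@dataclass
class DCSResult:
    """Per-gene drug-class specificity with permutation significance.

    ``empirical_p`` uses add-one smoothing, ``(1 + #{perm >= obs})/(B+1)``:
    conservative (super-uniform) under the null, never zero.  Because the
    DCS statistic is discrete, ties with permuted values make it strictly
    conservative; ``empirical_p_randomized`` breaks ties uniformly at
    random (a PIT), making it exactly uniform under exchangeability — the
    quantity to plot in a QQ calibration check.
    """

    gene_id: str
    associated_drugs: frozenset
    dcs: float
    empirical_p: float = float("nan")
    empirical_p_randomized: float = float("nan")


def _class_membership(
    classes: DrugClassAnnotation, universe: list[str]
) -> tuple[list[str], np.ndarray]:
    """Boolean classes x drugs membership over an ordered drug universe."""
    labels = sorted(
        {c for d in universe if d in classes for c in classes[d]}
    )
    member = np.zeros((len(labels), len(universe)), dtype=bool)
    for ci, label in enumerate(labels):
        in_class = classes.drugs_in_class(label)
        member[ci] = [d in in_class for d in universe]
    return labels, member


def _min_fisher_p(assoc_matrix: np.ndarray, member: np.ndarray) -> np.ndarray:
    """One-sided Fisher p, minimised over classes, for each gene.

    ``assoc_matrix``: genes x drugs boolean.  ``member``: classes x drugs
    boolean.  With fixed margins the one-sided Fisher exact p-value is the
    hypergeometric survival function, which vectorises.
    """
    M = member.shape[1]
    K = member.sum(axis=1)  # class sizes
    n_assoc = assoc_matrix.sum(axis=1)  # genes' associated-set sizes
    overlap = assoc_matrix.astype(int) @ member.T.astype(int)  # genes x classes
    p = stats.hypergeom.sf(overlap - 1, M, K[None, :], n_assoc[:, None])
    return np.minimum(p.min(axis=1), 1.0)


def dcs_score(
    associated_drugs,
    classes: DrugClassAnnotation,
    universe,
) -> float:
    """Drug-class specificity of one gene's associated drug set.

    One-sided Fisher's exact p for the 2x2 table (associated vs not x
    in-class vs not) per class — multi-class drugs count in each of their
    classes — and ``-log10`` of the minimum over classes.  Genes associated
    with every drug (or none of a class structure) score 0.
    """
    universe = sorted(universe)
    associated = set(associated_drugs)
    if not associated:
        raise ValueError("associated drug set must be non-empty")
    if not associated <= set(universe):
        raise ValueError("associated drugs must lie inside the universe")
    _, member = _class_membership(classes, universe)
    if member.size == 0:
        return 0.0
    assoc_row = np.array([[d in associated for d in universe]])
    p = _min_fisher_p(assoc_row, member)[0]
    return float(-np.log10(p))


def dcs_permutation_test(
    gene_assoc_sets: dict[str, set],
    classes: DrugClassAnnotation,
    universe,
    B: int = 1000,
    seed: int = 0,
) -> tuple[list[DCSResult], float]:
    """Permutation test of drug-class specificity across genes.

    Shuffles the drugs' class assignments (each drug keeps its number of
    classes; the assignment sets are permuted across drugs), recomputes
    every gene's DCS per permutation, and reports per-gene empirical
    p-values with add-one smoothing plus a global p comparing the mean
    observed DCS to the permuted means.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    universe = sorted(universe)
    n_drugs = len(universe)
    genes = sorted(gene_assoc_sets)
    assoc_matrix = np.array(
        [[d in gene_assoc_sets[g] for d in universe] for g in genes]
    )
    if (assoc_matrix.sum(axis=1) == 0).any():
        raise ValueError("every gene must have at least one associated drug")

    _, member = _class_membership(classes, universe)
    obs_dcs = -np.log10(_min_fisher_p(assoc_matrix, member))

    rng = np.random.default_rng(seed)
    greater = np.zeros(len(genes))
    ties = np.zeros(len(genes))
    perm_means = np.empty(B)
    for bi in range(B):
        perm = rng.permutation(n_drugs)
        perm_dcs = -np.log10(_min_fisher_p(assoc_matrix, member[:, perm]))
        greater += perm_dcs > obs_dcs + 1e-12
        ties += np.abs(perm_dcs - obs_dcs) <= 1e-12
        perm_means[bi] = perm_dcs.mean()

    emp_p = (1.0 + greater + ties) / (B + 1.0)
    u = rng.random(len(genes))
    emp_p_rand = (greater + u * (1.0 + ties)) / (B + 1.0)
    global_p = float(
        (1.0 + np.sum(perm_means >= obs_dcs.mean() - 1e-12)) / (B + 1.0)
    )
    results = [
        DCSResult(g, frozenset(gene_assoc_sets[g]), float(o), float(e),
                  float(er))
        for g, o, e, er in zip(genes, obs_dcs, emp_p, emp_p_rand)
    ]
    return results, global_p


# ---------------------------------------------------------------------------
# dendrogram class enrichment
# ---------------------------------------------------------------------------


def cluster_class_enrichment(
    Y: DrugResponseMatrix,
    classes: DrugClassAnnotation,
    enrichment_alpha: float = 0.06,
    return_details: bool = False,
):
    """Count mechanism classes enriched in some branch of an AUC dendrogram.

    Drug AUC rows are standardised, clustered (average linkage, Euclidean),
    and every internal node's leaf set of size 2..q-1 is tested for
    enrichment of each multi-drug class by one-sided Fisher's exact test at
    ``enrichment_alpha``.
    """
    drugs = Y.drug_ids
    q = len(drugs)
    if q < 2:
        raise ValueError("need at least 2 drugs to cluster")
    vals = Y.values.astype(float).copy()
    sd = vals.std(axis=1)
    const = sd < 1e-12
    if const.any():
        warnings.warn(
            f"{int(const.sum())} drug(s) with constant AUC left unstandardised"
        )
    vals[~const] = (
        vals[~const] - vals[~const].mean(axis=1, keepdims=True)
    ) / sd[~const, None]

    link = hierarchy.linkage(vals, method="average", metric="euclidean")
    root, nodes = hierarchy.to_tree(link, rd=True)
    leaf_sets = []
    for node in nodes:
        if node.is_leaf():
            continue
        leaves = node.pre_order(lambda lf: lf.id)
        if 2 <= len(leaves) <= q - 1:
            leaf_sets.append(frozenset(drugs[i] for i in leaves))

    labels = [c for c in classes.class_labels if len(classes.drugs_in_class(c)) > 1]
    enriched = {}
    for label in labels:
        in_class = classes.drugs_in_class(label) & set(drugs)
        if len(in_class) < 2:
            continue
        best = (1.0, None)
        for leaves in leaf_sets:
            a = len(leaves & in_class)
            b = len(leaves) - a
            c = len(in_class) - a
            d = q - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            if p < best[0]:
                best = (p, leaves)
        if best[0] <= enrichment_alpha:
            enriched[label] = best
    count = len(enriched)
    logger.info(
        "cluster_class_enrichment: %d/%d multi-drug classes enriched",
        count,
        len(labels),
    )
    if return_details:
        return count, enriched
    return count


# ---------------------------------------------------------------------------
# class-specific marker tables
# ---------------------------------------------------------------------------


def class_specific_markers(
    scores: MergeScores,
    patient_pairs: SignificantPairSet,
    cellline_pairs: SignificantPairSet,
    classes: DrugClassAnnotation,
    universe,
    alpha: float = 0.05,
    top_per_class: int | None = 3,
) -> pd.DataFrame:
    """Top-scoring genes specific to a drug class and conserved elsewhere.

    For each class: genes whose patient-data associated drugs are enriched
    in the class (one-sided Fisher p < ``alpha``) and that keep at least one
    association to a drug of the class in the second (cell-line) data set;
    ranked by marker-potential score, ``top_per_class`` retained.
    """
    universe = sorted(universe)
    gene_assoc: dict[str, set] = {}
    for g, d in patient_pairs:
        gene_assoc.setdefault(g, set()).add(d)
    cell_assoc: dict[str, set] = {}
    for g, d in cellline_pairs:
        cell_assoc.setdefault(g, set()).add(d)

    score_map = dict(zip(scores.gene_ids, scores.m))
    labels, member = _class_membership(classes, universe)
    rows = []
    for label, row in zip(labels, member):
        in_class = {d for d, m in zip(universe, row) if m}
        for gene, assoc in gene_assoc.items():
            assoc_u = assoc & set(universe)
            if not assoc_u:
                continue
            a = len(assoc_u & in_class)
            table = [
                [a, len(assoc_u) - a],
                [len(in_class) - a, len(universe) - len(assoc_u) - len(in_class) + a],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            if p >= alpha:
                continue
            conserved = sorted(cell_assoc.get(gene, set()) & in_class)
            if not conserved:
                continue
            rows.append(
                {
                    "class": label,
                    "gene_id": gene,
                    "merge_score": score_map.get(gene, np.nan),
                    "class_p": p,
                    "conserved_drugs": ";".join(conserved),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["class", "gene_id", "merge_score", "class_p", "conserved_drugs"]
    )
    if frame.empty:
        return frame
    frame = frame.sort_values(
        ["class", "merge_score", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    if top_per_class is not None:
        frame = frame.groupby("class", group_keys=False).head(top_per_class)
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# drug-response prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictionReport:
    """Per-drug Spearman correlation of predicted vs observed response."""

    method: str
    per_drug_rho: pd.Series

    @property
    def mean_rho(self) -> float:
        return float(self.per_drug_rho.mean())


def predict_response(
    train_X: ExpressionMatrix,
    train_Y: DrugResponseMatrix,
    test_X: ExpressionMatrix,
    results: MergeResults | None = None,
    method: str = "merge",
    genes_per_drug: int | None = 10,
    assoc_alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Predict test-sample drug response (drugs x test samples).

    merge
        Per drug: among genes with train-data association p < ``assoc_alpha``
        take the ``genes_per_drug`` highest-scoring genes (falling back to
        the smallest train p-values when none pass), then ridge regression
        with the penalty chosen by efficient leave-one-out on the train set.
        ``genes_per_drug=None`` uses all genes (plain ridge).
    elasticnet
        Per-drug elastic net (mixing 0.5, 5-fold CV).
    multitask
        Multi-task elastic net over all drugs jointly (shared support).
    """
    from sklearn.linear_model import ElasticNetCV, MultiTaskElasticNetCV, RidgeCV
    from sklearn.model_selection import KFold

    from .association import pairwise_association
    from .matrixio import assert_aligned

    assert_aligned(train_X, train_Y)
    shared = sorted(set(train_X.gene_ids) & set(test_X.gene_ids))
    if not shared:
        raise ValueError("train and test share no genes")
    trX = train_X.subset_rows(shared)
    teX = test_X.subset_rows(shared)
    if len(train_X.sample_ids) < 5:
        raise ValueError("need at least 5 training samples")

    Xtr = trX.values.T  # samples x genes
    Xte = teX.values.T
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd

    alphas = np.logspace(-3, 3, 25)
    preds = np.zeros((len(train_Y.drug_ids), Xte.shape[0]))

    if method == "multitask":
        cv = KFold(n_splits=5, shuffle=True, random_state=seed)
        mt = MultiTaskElasticNetCV(l1_ratio=0.5, cv=cv, alphas=30, max_iter=5000)
        mt.fit(Xtr, train_Y.values.T)
        preds = mt.predict(Xte).T
        return pd.DataFrame(preds, index=train_Y.drug_ids, columns=teX.sample_ids)

    score_map = None
    assoc = None
    if method == "merge":
        if results is None:
            raise ValueError("merge prediction needs fitted results")
        sc = results.scores()
        score_map = dict(zip(sc.gene_ids, sc.m))
        assoc = pairwise_association(trX, train_Y)

    for j, drug in enumerate(train_Y.drug_ids):
        y = train_Y.values[j]
        if np.ptp(y) < 1e-12:
            preds[j] = y.mean()
            logger.warning("constant train response for %s; predicting mean", drug)
            continue
        if method == "merge":
            pcol = assoc.pval[:, j]
            candidates = [
                (shared[i], pcol[i])
                for i in range(len(shared))
                if np.isfinite(pcol[i])
            ]
            passing = [g for g, pv in candidates if pv < assoc_alpha]
            if genes_per_drug is None:
                chosen = shared
            elif passing:
                chosen = sorted(
                    passing,
                    key=lambda g: (-score_map.get(g, -np.inf), g),
                )[:genes_per_drug]
            else:  # fallback: best train p-values
                chosen = [
                    g
                    for g, _ in sorted(candidates, key=lambda t: (t[1], t[0]))[
                        :genes_per_drug
                    ]
                ]
            cols = [shared.index(g) for g in chosen]
            model = RidgeCV(alphas=alphas)
            model.fit(Xtr[:, cols], y)
            preds[j] = model.predict(Xte[:, cols])
        elif method == "elasticnet":
            cv = KFold(n_splits=5, shuffle=True, random_state=seed)
            enet = ElasticNetCV(l1_ratio=0.5, cv=cv, alphas=30, max_iter=5000)
            enet.fit(Xtr, y)
            preds[j] = enet.predict(Xte)
        else:
            raise ValueError(f"unknown prediction method {method!r}")
    return pd.DataFrame(preds, index=train_Y.drug_ids, columns=teX.sample_ids)


def score_predictions(
    predicted: pd.DataFrame, actual: DrugResponseMatrix, method: str = ""
) -> PredictionReport:
    """Per-drug Spearman rho between predicted and observed response."""
    rhos = {}
    act = actual.to_frame()
    for drug in predicted.index:
        if drug not in act.index:
            continue
        y = act.loc[drug, predicted.columns].to_numpy(dtype=float)
        yhat = predicted.loc[drug].to_numpy(dtype=float)
        if np.ptp(y) < 1e-12 or np.ptp(yhat) < 1e-12:
            rhos[drug] = np.nan
            continue
        rho, _ = stats.spearmanr(yhat, y)
        rhos[drug] = float(rho)
    return PredictionReport(method, pd.Series(rhos, name="spearman_rho"))


def compare_methods(report_a: PredictionReport, report_b: PredictionReport) -> float:
    """One-sided Wilcoxon signed-rank p for "method a beats method b".

    Computed over the drugs present in both reports; zero differences are
    dropped (p = 1 when every difference is zero).
    """
    common = report_a.per_drug_rho.index.intersection(report_b.per_drug_rho.index)
    a = report_a.per_drug_rho.loc[common].to_numpy(dtype=float)
    b = report_b.per_drug_rho.loc[common].to_numpy(dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 6:
        raise ValueError("need at least 6 drugs with finite scores")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    _, p = stats.wilcoxon(diff, alternative="greater", zero_method="wilcox")
    return float(p)


def split_half_evaluation(
    X: ExpressionMatrix,
    Y: DrugResponseMatrix,
    batches: tuple[list[str], list[str]],
    predict_fn,
) -> PredictionReport:
    """Train on one sample batch, test on the other, both directions.

    ``predict_fn(train_X, train_Y, test_X)`` returns a drugs x test-samples
    DataFrame.  Per-drug Spearman rho is averaged across the two directions.
    """
    rho_frames = []
    for train_ids, test_ids in (batches, batches[::-1]):
        trX, trY = X.subset_samples(train_ids), Y.subset_samples(train_ids)
        teX, teY = X.subset_samples(test_ids), Y.subset_samples(test_ids)
        pred = predict_fn(trX, trY, teX)
        rho_frames.append(score_predictions(pred, teY).per_drug_rho)
    mean_rho = pd.concat(rho_frames, axis=1).mean(axis=1)
    return PredictionReport("split-half", mean_rho)


def loocv_evaluation(
    X: ExpressionMatrix, Y: DrugResponseMatrix, predict_fn
) -> PredictionReport:
    """Leave-one-out predictions across samples, scored per drug."""
    samples = X.sample_ids
    cols = {}
    for s in samples:
        rest = [t for t in samples if t != s]
        pred = predict_fn(
            X.subset_samples(rest), Y.subset_samples(rest), X.subset_samples([s])
        )
        cols[s] = pred[s]
    pred_all = pd.DataFrame(cols)
    return score_predictions(pred_all, Y, method="loocv")
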