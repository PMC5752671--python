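import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import mergeprior as mp
from mergeprior.evaluation import score_predictions


# ---------------------------------------------------------------------------
# consistency rate
# ---------------------------------------------------------------------------


def test_self_replication_rate_is_one(synthetic_screen):
    X, Y, D, classes, truth = synthetic_screen
    assoc = mp.pairwise_association(X, Y)
    ranking = mp.rank_pairs_by_method("pearson", X, Y, assoc=assoc)
    curve = mp.consistency_rate(ranking, assoc, assoc, N_grid=[1, 5, 20])
    nonzero = curve.total > 0
    assert np.all(curve.rate[nonzero] == 1.0)
    assert np.all(np.diff(curve.total) >= 0)


def test_hand_enumerated_toy_rate():
    # 2 genes x 2 drugs; all four pairs discovery-significant, two replicate
    genes, drugs = ["g1", "g2"], ["d1", "d2"]
    pv = np.full((2, 2), 1e-6)
    r = np.ones((2, 2))
    disc = mp.AssociationTable(genes, drugs, r, r, pv, r, np.full((2, 2), 10))
    val_p = np.array([[0.01, 0.5], [0.01, 0.8]])
    val_r = np.ones((2, 2))
    val = mp.AssociationTable(genes, drugs, val_r, val_r, val_p, val_r,
                              np.full((2, 2), 10))
    ranking = [("g1", "d1"), ("g1", "d2"), ("g2", "d1"), ("g2", "d2")]
    curve = mp.consistency_rate(ranking, disc, val, N_grid=[2], q=0.5)
    assert curve.total[0] == 4
    assert curve.replicated[0] == 2
    assert curve.rate[0] == pytest.approx(0.5)


def test_opposite_sign_does_not_replicate():
    genes, drugs = ["g1"], ["d1"]
    pv = np.array([[1e-6]])
    disc = mp.AssociationTable(genes, drugs, np.array([[0.9]]), pv, pv, pv,
                               np.array([[10]]))
    val = mp.AssociationTable(genes, drugs, np.array([[-0.9]]), pv,
                              np.array([[0.001]]), pv, np.array([[10]]))
    curve = mp.consistency_rate([("g1", "d1")], disc, val, N_grid=[1])
    assert curve.rate[0] == 0.0


def test_attenuation_lowers_consistency():
    """Weaker validation signal must not raise the consistency curve."""
    rates = {0.4: [], 1.0: []}
    for seed in range(3):
        X, Y, D, classes, truth = mp.generate_dataset(p=200, q=10, n=30,
                                                      seed=40 + seed)
        assoc = mp.pairwise_association(X, Y)
        ranking = mp.rank_pairs_by_method("pearson", X, Y, assoc=assoc)
        for att in rates:
            Xv, Yv = mp.generate_validation_replicate(
                truth, n_val=200, attenuation=att, seed=90 + seed
            )
            val = mp.pairwise_association(Xv, Yv)
            curve = mp.consistency_rate(ranking, assoc, val, N_grid=[20])
            rates[att].append(curve.rate[0])
    assert np.nanmean(rates[1.0]) >= np.nanmean(rates[0.4])


# ---------------------------------------------------------------------------
# drug-class specificity
# ---------------------------------------------------------------------------


def _toy_classes():
    mapping = {f"d{i}": frozenset({"kinase" if i < 4 else "alkyl"})
               for i in range(10)}
    return mp.DrugClassAnnotation(mapping)


def test_dcs_exact_class_match():
    classes = _toy_classes()
    universe = [f"d{i}" for i in range(10)]
    dcs = mp.dcs_score({"d0", "d1", "d2", "d3"}, classes, universe)
    # P(all 4 associated drugs land in the 4-drug class) = 1 / C(10,4)
    from math import comb

    assert dcs == pytest.approx(-np.log10(1 / comb(10, 4)))


def test_dcs_no_specificity_when_associated_with_everything():
    classes = _toy_classes()
    universe = [f"d{i}" for i in range(10)]
    assert mp.dcs_score(set(universe), classes, universe) == pytest.approx(0.0)


def test_dcs_single_drug_single_class():
    mapping = {f"d{i}": frozenset({f"c{i}"}) for i in range(10)}
    classes = mp.DrugClassAnnotation(mapping)
    universe = [f"d{i}" for i in range(10)]
    dcs = mp.dcs_score({"d3"}, classes, universe)
    assert dcs == pytest.approx(-np.log10(1 / 10))


def test_dcs_matches_fisher_exact_enumeration():
    """Vectorised hypergeometric path vs scipy's Fisher test, small universes."""
    rng = np.random.default_rng(2)
    universe = [f"d{i}" for i in range(12)]
    mapping = {
        d: frozenset({f"c{rng.integers(0, 3)}"}) for d in universe
    }
    mapping["d0"] = frozenset({"c0", "c1"})  # one multi-class drug
    classes = mp.DrugClassAnnotation(mapping)
    for _ in range(20):
        k = int(rng.integers(1, 6))
        assoc = set(rng.choice(universe, size=k, replace=False))
        expected = 1.0
        for label in classes.class_labels:
            in_class = classes.drugs_in_class(label)
            a = len(assoc & in_class)
            table = [
                [a, len(assoc) - a],
                [len(in_class) - a, 12 - len(assoc) - len(in_class) + a],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            expected = min(expected, p)
        assert mp.dcs_score(assoc, classes, universe) == pytest.approx(
            -np.log10(expected), abs=1e-10
        )


def test_dcs_permutation_intact_class_hits_resolution_floor():
    classes = _toy_classes()
    universe = [f"d{i}" for i in range(10)]
    gene_sets = {"g_specific": {"d0", "d1", "d2", "d3"}}
    results, _ = mp.dcs_permutation_test(gene_sets, classes, universe,
                                         B=200, seed=1)
    # only permutations recreating the exact class split can tie the observed
    assert results[0].empirical_p < 0.05


def test_dcs_permutation_seed_contract():
    classes = _toy_classes()
    universe = [f"d{i}" for i in range(10)]
    gene_sets = {"g1": {"d0", "d5"}, "g2": {"d2", "d3", "d8"}}
    a = mp.dcs_permutation_test(gene_sets, classes, universe, B=150, seed=9)
    b = mp.dcs_permutation_test(gene_sets, classes, universe, B=150, seed=9)
    c = mp.dcs_permutation_test(gene_sets, classes, universe, B=150, seed=10)
    assert [r.empirical_p for r in a[0]] == [r.empirical_p for r in b[0]]
    assert a[1] == b[1]
    assert a[1] != c[1] or [r.empirical_p for r in a[0]] != [
        r.empirical_p for r in c[0]
    ]


# ---------------------------------------------------------------------------
# dendrogram class enrichment
# ---------------------------------------------------------------------------


def test_two_block_structure_both_classes_enriched():
    rng = np.random.default_rng(3)
    base1, base2 = rng.standard_normal((2, 20))
    rows = [base1 + 0.01 * rng.standard_normal(20) for _ in range(3)]
    rows += [base2 + 0.01 * rng.standard_normal(20) for _ in range(3)]
    Y = mp.DrugResponseMatrix(
        [f"d{i}" for i in range(6)], [f"s{j}" for j in range(20)], np.vstack(rows)
    )
    classes = mp.DrugClassAnnotation(
        {f"d{i}": frozenset({"A" if i < 3 else "B"}) for i in range(6)}
    )
    assert mp.cluster_class_enrichment(Y, classes) == 2


def test_enrichment_count_matches_manual_enumeration():
    from scipy.cluster import hierarchy

    rng = np.random.default_rng(6)
    vals = rng.standard_normal((6, 15))
    Y = mp.DrugResponseMatrix([f"d{i}" for i in range(6)],
                              [f"s{j}" for j in range(15)], vals)
    classes = mp.DrugClassAnnotation(
        {f"d{i}": frozenset({"A" if i % 2 else "B"}) for i in range(6)}
    )
    count, details = mp.cluster_class_enrichment(Y, classes, return_details=True)

    # manual enumeration over every internal node of the same dendrogram
    std = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    link = hierarchy.linkage(std, method="average", metric="euclidean")
    _, nodes = hierarchy.to_tree(link, rd=True)
    leafsets = [
        frozenset(f"d{i}" for i in nd.pre_order(lambda lf: lf.id))
        for nd in nodes
        if not nd.is_leaf() and 2 <= nd.get_count() <= 5
    ]
    manual = 0
    for label in ("A", "B"):
        in_class = classes.drugs_in_class(label)
        ps = []
        for ls in leafsets:
            a = len(ls & in_class)
            tab = [[a, len(ls) - a],
                   [len(in_class) - a, 6 - len(ls) - len(in_class) + a]]
            ps.append(stats.fisher_exact(tab, alternative="greater")[1])
        manual += int(min(ps) <= 0.06)
    assert count == manual


def test_shuffled_labels_degrade_enrichment(synthetic_screen):
    X, Y, D, classes, truth = synthetic_screen
    observed = mp.cluster_class_enrichment(Y, classes)
    rng = np.random.default_rng(0)
    drug_ids = list(classes.drug_ids)
    shuffled_counts = []
    for _ in range(10):
        perm = rng.permutation(len(drug_ids))
        shuffled = mp.DrugClassAnnotation(
            {drug_ids[i]: classes[drug_ids[perm[i]]] for i in range(len(drug_ids))}
        )
        shuffled_counts.append(mp.cluster_class_enrichment(Y, shuffled))
    assert observed >= np.mean(shuffled_counts)


# ---------------------------------------------------------------------------
# class-specific markers
# ---------------------------------------------------------------------------


def test_empty_cellline_pairs_vacuous_conservation(synthetic_screen):
    X, Y, D, classes, truth = synthetic_screen
    assoc = mp.pairwise_association(X, Y)
    res = mp.fit_merge(assoc, D)
    patient = mp.bh_select(assoc, q=0.2)
    empty = mp.SignificantPairSet()
    table = mp.class_specific_markers(
        res.scores(), patient, empty, classes, Y.drug_ids
    )
    assert table.empty


def test_planted_class_markers_recovered():
    """Markers planted for one class should be returned for that class.

    Classes need >1 drug for Fisher specificity to be attainable, so the
    screen uses 4 classes over 16 drugs.
    """
    cfg = mp.TruthConfig(n_classes=4, multiclass_fraction=0.0)
    X, Y, D, classes, truth = mp.generate_dataset(p=200, q=16, n=40,
                                                  config=cfg, seed=13)
    assoc = mp.pairwise_association(X, Y)
    res = mp.fit_merge(assoc, D)
    patient = mp.bh_select(assoc, q=0.1)
    Xv, Yv = mp.generate_validation_replicate(truth, n_val=40, attenuation=1.0,
                                              seed=14)
    cell = mp.bh_select(mp.pairwise_association(Xv, Yv), q=0.1)
    table = mp.class_specific_markers(
        res.scores(), patient, cell, classes, Y.drug_ids, top_per_class=3
    )
    assert not table.empty
    # every reported gene is truly a marker of a drug in its class
    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    didx = {d: j for j, d in enumerate(truth.drug_ids)}
    tp = 0
    for _, row in table.iterrows():
        drugs = row["conserved_drugs"].split(";")
        tp += any(truth.marker_indicator[gidx[row["gene_id"]], didx[d]]
                  for d in drugs)
    assert tp / len(table) > 0.8


def test_filter_relaxation_returns_all_conserved(synthetic_screen):
    X, Y, D, classes, truth = synthetic_screen
    assoc = mp.pairwise_association(X, Y)
    res = mp.fit_merge(assoc, D)
    patient = mp.bh_select(assoc, q=0.2)
    strict = mp.class_specific_markers(
        res.scores(), patient, patient, classes, Y.drug_ids, top_per_class=1
    )
    relaxed = mp.class_specific_markers(
        res.scores(), patient, patient, classes, Y.drug_ids,
        alpha=1.0, top_per_class=None,
    )
    assert len(relaxed) >= len(strict)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def test_noiseless_interpolation_gives_perfect_rank_correlation():
    rng = np.random.default_rng(21)
    n, p = 20, 30
    Xv = rng.standard_normal((p, n))
    X = mp.ExpressionMatrix([f"g{i}" for i in range(p)],
                            [f"s{j}" for j in range(n)], Xv)
    y = 0.8 * Xv[0] - 0.5 * Xv[1]
    Y = mp.DrugResponseMatrix(["d1"], X.sample_ids, [y])
    pred = mp.predict_response(X, Y, X, method="elasticnet", seed=0)
    rep = score_predictions(pred, Y, "enet")
    assert rep.per_drug_rho["d1"] == pytest.approx(1.0)


def test_full_gene_merge_prediction_reduces_to_plain_ridge(fitted_results,
                                                           synthetic_screen):
    from sklearn.linear_model import RidgeCV

    X, Y, D, classes, truth = synthetic_screen
    _, results = fitted_results
    pred = mp.predict_response(X, Y, X, results=results, method="merge",
                               genes_per_drug=None)
    Xs = X.values.T
    Xs = (Xs - Xs.mean(axis=0)) / np.where(Xs.std(axis=0) > 1e-12,
                                           Xs.std(axis=0), 1.0)
    ridge = RidgeCV(alphas=np.logspace(-3, 3, 25))
    ridge.fit(Xs, Y.values[0])
    np.testing.assert_allclose(pred.iloc[0].to_numpy(), ridge.predict(Xs),
                               atol=1e-8)


def test_constant_drug_response_reported_missing():
    rng = np.random.default_rng(2)
    X = mp.ExpressionMatrix(["g1", "g2"], [f"s{j}" for j in range(8)],
                            rng.standard_normal((2, 8)))
    Y = mp.DrugResponseMatrix(["d"], X.sample_ids, [np.full(8, 0.5)])
    pred = mp.predict_response(X, Y, X, method="elasticnet")
    np.testing.assert_allclose(pred.loc["d"], 0.5)
    rep = score_predictions(pred, Y)
    assert np.isnan(rep.per_drug_rho["d"])


def test_compare_methods_exact_signed_rank():
    drugs = [f"d{i}" for i in range(8)]
    a = mp.PredictionReport("a", pd.Series(np.linspace(0.5, 0.9, 8), index=drugs))
    b = mp.PredictionReport("b", pd.Series(np.linspace(0.1, 0.45, 8), index=drugs))
    p_ab = mp.compare_methods(a, b)
    assert p_ab == pytest.approx(1 / 2**8)
    # reversal maps to the complementary tail (which includes the atom at W=0)
    p_ba = mp.compare_methods(b, a)
    assert p_ba == pytest.approx(1.0)
    assert mp.compare_methods(a, a) == 1.0


def test_planted_signal_beats_shuffled_predictor():
    """A prior-guided predictor must beat a response-shuffled one."""
    X, Y, D, classes, truth = mp.generate_dataset(p=300, q=20, n=40, seed=21)
    assoc = mp.pairwise_association(X, Y)
    results = mp.fit_merge(assoc, D)
    Xt, Yt = mp.generate_validation_replicate(truth, n_val=30, attenuation=1.0,
                                              seed=22)
    pred = mp.predict_response(X, Y, Xt, results=results, method="merge")
    real = score_predictions(pred, Yt, "merge")

    rng = np.random.default_rng(23)
    Y_shuf = mp.DrugResponseMatrix(
        Y.drug_ids, Y.sample_ids, Y.values[:, rng.permutation(Y.shape[1])]
    )
    assoc_s = mp.pairwise_association(X, Y_shuf)
    res_s = mp.fit_merge(assoc_s, D)
    pred_s = mp.predict_response(X, Y_shuf, Xt, results=res_s, method="merge")
    shuf = score_predictions(pred_s, Yt, "shuffled")
    assert mp.compare_methods(real, shuf) < 0.05


def test_split_half_and_loocv_harnesses():
    X, Y, D, classes, truth = mp.generate_dataset(p=60, q=4, n=16, seed=31)
    assoc = mp.pairwise_association(X, Y)
    results = mp.fit_merge(assoc, D)

    def predict_fn(trX, trY, teX):
        a = mp.pairwise_association(trX, trY)
        r = mp.fit_merge(a, D)
        return mp.predict_response(trX, trY, teX, results=r, method="merge",
                                   genes_per_drug=5)

    batches = (X.sample_ids[:8], X.sample_ids[8:])
    rep = mp.split_half_evaluation(X, Y, batches, predict_fn)
    assert len(rep.per_drug_rho) == 4
    assert np.all(np.abs(rep.per_drug_rho.dropna()) <= 1.0)

    small = X.sample_ids[:8]
    rep2 = mp.loocv_evaluation(X.subset_samples(small), Y.subset_samples(small),
                               predict_fn)
    assert len(rep2.per_drug_rho) == 4
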