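import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mergeprior as mp


def _naive_association(X, Y):
    """O(p*q*n) loop oracle for Pearson r, t and p."""
    p, q = len(X.gene_ids), len(Y.drug_ids)
    n = len(X.sample_ids)
    r = np.zeros((p, q))
    t = np.zeros((p, q))
    pv = np.zeros((p, q))
    for i in range(p):
        for j in range(q):
            ri, pi = stats.pearsonr(X.values[i], Y.values[j])
            r[i, j] = ri
            t[i, j] = ri * np.sqrt((n - 2) / (1 - ri**2))
            pv[i, j] = pi
    return r, t, pv


def test_matches_naive_loop_oracle():
    rng = np.random.default_rng(10)
    X = mp.ExpressionMatrix(
        [f"g{i}" for i in range(20)], [f"s{j}" for j in range(10)],
        rng.standard_normal((20, 10)),
    )
    Y = mp.DrugResponseMatrix(
        [f"d{j}" for j in range(5)], X.sample_ids, rng.random((5, 10))
    )
    table = mp.pairwise_association(X, Y)
    r0, t0, p0 = _naive_association(X, Y)
    np.testing.assert_allclose(table.r, r0, atol=1e-10)
    np.testing.assert_allclose(table.t, t0, atol=1e-10)
    np.testing.assert_allclose(table.pval, p0, atol=1e-10)


def test_toy_vectors_match_formula():
    X = mp.ExpressionMatrix(["g"], list("abcde"), [[1, 2, 3, 4, 5]])
    Y = mp.DrugResponseMatrix(["d"], list("abcde"), [[2, 1, 4, 3, 5]])
    table = mp.pairwise_association(X, Y)
    r = np.corrcoef([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])[0, 1]
    t = r * np.sqrt(3 / (1 - r**2))
    assert table.r[0, 0] == pytest.approx(r, abs=1e-12)
    assert table.t[0, 0] == pytest.approx(t, abs=1e-12)
    assert table.pval[0, 0] == pytest.approx(2 * stats.t.sf(abs(t), 3), abs=1e-12)


def test_perfect_association_reports_tiny_p():
    x = np.arange(8.0)
    X = mp.ExpressionMatrix(["g"], [f"s{i}" for i in range(8)], [x])
    Y = mp.DrugResponseMatrix(["d"], X.sample_ids, [x])
    with pytest.warns(UserWarning):
        table = mp.pairwise_association(X, Y)
    assert table.r[0, 0] == pytest.approx(1.0)
    assert 0 < table.pval[0, 0] <= np.finfo(float).tiny


def test_null_pvalues_uniform():
    rng = np.random.default_rng(7)
    X = mp.ExpressionMatrix(
        [f"g{i}" for i in range(100)], [f"s{j}" for j in range(30)],
        rng.standard_normal((100, 30)),
    )
    Y = mp.DrugResponseMatrix(
        [f"d{j}" for j in range(10)], X.sample_ids, rng.standard_normal((10, 30))
    )
    table = mp.pairwise_association(X, Y)
    stat, p = stats.kstest(table.pval.ravel(), "uniform")
    assert p > 0.01


def test_spearman_equals_rank_pearson():
    rng = np.random.default_rng(12)
    X = mp.ExpressionMatrix(["g"], [f"s{i}" for i in range(12)],
                            rng.standard_normal((1, 12)))
    Y = mp.DrugResponseMatrix(["d"], X.sample_ids, rng.random((1, 12)))
    table = mp.pairwise_association(X, Y, rank_based=True)
    rho, pv = stats.spearmanr(X.values[0], Y.values[0])
    assert table.r[0, 0] == pytest.approx(rho, abs=1e-12)


def test_zero_variance_rows_marked_missing():
    X = mp.ExpressionMatrix(["flat", "g"], list("abcd"),
                            [[1, 1, 1, 1], [1, 2, 3, 4]])
    Y = mp.DrugResponseMatrix(["d"], list("abcd"), [[0.1, 0.4, 0.2, 0.9]])
    table = mp.pairwise_association(X, Y)
    assert np.isnan(table.r[0, 0]) and np.isnan(table.pval[0, 0])
    assert np.isfinite(table.r[1, 0])


def test_constant_covariate_leaves_p_unchanged():
    rng = np.random.default_rng(3)
    X = mp.ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"s{j}" for j in range(12)],
        rng.standard_normal((5, 12)),
    )
    Y = mp.DrugResponseMatrix(["d"], X.sample_ids, rng.random((1, 12)))
    plain = mp.pairwise_association(X, Y)
    cov = pd.DataFrame({"c": np.ones(12)}, index=X.sample_ids)
    adj = mp.pairwise_association(X, Y, covariates=cov)
    np.testing.assert_allclose(adj.pval, plain.pval, atol=1e-9)


def test_real_covariate_matches_ols_gene_coefficient():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    n = 20
    c = rng.standard_normal(n)
    x = 0.5 * c + rng.standard_normal(n)
    y = 0.7 * x + 0.4 * c + rng.standard_normal(n)
    X = mp.ExpressionMatrix(["g"], [f"s{i}" for i in range(n)], [x])
    Y = mp.DrugResponseMatrix(["d"], X.sample_ids, [y])
    cov = pd.DataFrame({"c": c}, index=X.sample_ids)
    table = mp.pairwise_association(X, Y, covariates=cov)
    ols = sm.OLS(y, sm.add_constant(np.column_stack([x, c]))).fit()
    assert table.pval[0, 0] == pytest.approx(ols.pvalues[1], abs=1e-9)


def test_fisher_z_closed_form_and_symmetry():
    assert mp.fisher_z(0.0, 30) == 0.0
    assert mp.fisher_z(0.5, 30) == pytest.approx(np.arctanh(0.5) * np.sqrt(27))
    r = 0.37
    assert mp.fisher_z(-r, 25) == pytest.approx(-mp.fisher_z(r, 25))
    with pytest.warns(UserWarning):
        z = mp.fisher_z(1.0, 30)
    assert np.isfinite(z)


def _bh_oracle(pvals, q):
    """Exhaustive step-up enumeration."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= q * k / m:
            k_max = k
    return set(order[:k_max])


def test_bh_select_matches_exhaustive_oracle():
    pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.9])
    sel = mp.bh_select(pvals, labels=list(range(5)), q=0.1)
    assert sel.pairs == _bh_oracle(pvals, 0.1)


def test_bh_edge_cases():
    assert len(mp.bh_select(np.ones(4), q=0.1)) == 0
    assert mp.bh_select(np.array([0.05]), labels=["only"], q=0.1).pairs == {"only"}
    assert len(mp.bh_select(np.array([]), q=0.1)) == 0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    pv=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
    q1=st.floats(0.01, 0.5),
    q2=st.floats(0.01, 0.5),
)
def test_bh_monotone_in_q_and_order_invariant(pv, q1, q2):
    pv = np.asarray(pv)
    lo, hi = min(q1, q2), max(q1, q2)
    sel_lo = mp.bh_select(pv, labels=list(range(len(pv))), q=lo).pairs
    sel_hi = mp.bh_select(pv, labels=list(range(len(pv))), q=hi).pairs
    assert sel_lo <= sel_hi
    perm = np.random.default_rng(0).permutation(len(pv))
    sel_perm = mp.bh_select(pv[perm], labels=list(perm), q=hi).pairs
    assert sel_perm == sel_hi


def test_bh_select_on_association_table(toy_pair_data):
    X, Y = toy_pair_data
    table = mp.pairwise_association(X, Y)
    sel = mp.bh_select(table, q=0.1)
    oracle_idx = _bh_oracle(table.pval.ravel(), 0.1)
    labels = [
        (g, d) for g in X.gene_ids for d in Y.drug_ids
    ]
    assert sel.pairs == {labels[i] for i in oracle_idx}
    assert ("g0", "dA") in sel.pairs
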