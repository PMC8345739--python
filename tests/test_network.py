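"""Spearman matrix, paired volume comparison, significance network, and the
neighborhood regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mmqinet import network
from mmqinet.network import MetricTable


def _table(**cols) -> MetricTable:
    return MetricTable(pd.DataFrame(cols))


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------

def test_monotone_pair_has_rho_one():
    x = np.arange(10.0)
    t = _table(ADC=x, D=np.exp(x))
    rho, p, labels = network.spearman_matrix(t)
    assert rho.loc["ADC", "D"] == pytest.approx(1.0)
    assert p.loc["ADC", "D"] < 1e-10
    assert labels.loc["ADC", "D"] == "strong"


def test_published_significance_calibration():
    """rho = 0.48 at n = 27 gives two-sided p ~ 0.011 under the t
    approximation (prints as 0.01)."""
    rho = 0.48
    t_stat = rho * np.sqrt((27 - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(t_stat, 25)
    got = network._p_from_rho(np.array(rho), 27)
    assert float(got) == pytest.approx(p, rel=1e-12)
    assert round(float(got), 2) == 0.01
    assert abs(float(got) - 0.011) < 5e-4


def test_exact_permutation_p_matches_enumeration():
    """Package exact p at n = 6 vs an independent brute-force enumeration of
    all 720 orderings."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    rho, p_exact = network.spearman_pvalue(x, y, method="exact")
    # oracle: enumerate permutations, Spearman via scipy on raw data
    obs = abs(stats.spearmanr(x, y).statistic)
    count = sum(
        abs(stats.spearmanr(x, np.asarray(perm)).statistic) >= obs - 1e-12
        for perm in itertools.permutations(y)
    )
    assert p_exact == pytest.approx(count / 720.0, abs=1e-12)
    assert rho == pytest.approx(stats.spearmanr(x, y).statistic, rel=1e-12)


def test_constant_column_flagged_and_excluded():
    t = _table(ADC=np.arange(8.0), D=np.arange(8.0) ** 2, f=np.full(8, 0.2))
    rho, p, labels = network.spearman_matrix(t)
    assert np.isnan(rho.loc["ADC", "f"]) and np.isnan(p.loc["ADC", "f"])
    assert labels.loc["ADC", "f"] == "undefined"
    g = network.build_significance_network(rho, p, ("ADC", "D", "f"), 0.05)
    assert not any("f" in e for e in g.edges)
    assert "f" in g.nodes


def test_pairwise_complete_handling():
    x = np.arange(12.0)
    y = 2 * x
    y[3] = np.nan
    t = _table(ADC=x, D=y)
    rho, p, _ = network.spearman_matrix(t)
    assert rho.loc["ADC", "D"] == pytest.approx(1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rho_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    r0, p0 = network.spearman_pvalue(x, y)
    r1, p1 = network.spearman_pvalue(np.exp(x), 2 * y - 7)
    assert r1 == pytest.approx(r0, abs=1e-12)
    assert p1 == pytest.approx(p0, abs=1e-12)


def test_strength_bands():
    assert network.strength_label(0.29) == "weak"
    assert network.strength_label(-0.3) == "moderate"
    assert network.strength_label(0.5) == "strong"


# --------------------------------------------------------------------------
# paired volume comparison
# --------------------------------------------------------------------------

def test_wilcoxon_identical_volumes():
    v = np.arange(1.0, 11.0)
    stat, p, flag = network.compare_volumes(v, v)
    assert p == 1.0 and flag == "all_zero_differences"


def test_wilcoxon_large_shift_rejects():
    rng = np.random.default_rng(1)
    v1 = 10 + rng.normal(scale=0.5, size=27)
    stat, p, flag = network.compare_volumes(v1, v1 + 5.0)
    assert p < 0.01 and flag == "ok"


def test_wilcoxon_exact_small_sample():
    """n = 8 exact signed-rank distribution: compare against enumeration of
    all 2^8 sign assignments."""
    rng = np.random.default_rng(3)
    v1 = rng.normal(size=8)
    v2 = v1 + rng.normal(size=8) * 0.8 + 0.5
    stat, p, _ = network.compare_volumes(v1, v2)
    d = v1 - v2
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist, dtype=float)
    w_obs = min(w_plus, n * (n + 1) / 2 - w_plus)
    p_exact = np.mean(np.minimum(dist, n * (n + 1) / 2 - dist) <= w_obs + 1e-12)
    assert p == pytest.approx(p_exact, abs=1e-12)


# --------------------------------------------------------------------------
# significance network
# --------------------------------------------------------------------------

def test_network_alpha_zero_has_no_edges():
    rho, _, n = network.load_published_spearman()
    assert network.published_network(alpha=1e-300).number_of_edges() == 0


def test_network_complete_when_everything_significant():
    m = 5
    names = list(network.METRIC_NAMES[:m])
    rho = pd.DataFrame(np.full((m, m), 0.9), index=names, columns=names)
    p = pd.DataFrame(np.full((m, m), 1e-6), index=names, columns=names)
    g = network.build_significance_network(rho, p, tuple(names), 0.05)
    assert g.number_of_edges() == m * (m - 1) // 2


def test_network_empty_include_raises():
    rho, _, _ = network.load_published_spearman()
    with pytest.raises(ValueError):
        network.build_significance_network(rho, rho, (), 0.05)


def test_published_fixture_degrees():
    """The packaged published matrix yields degree(Ktrans)=7 and
    degree(K1)=6 over the 16 network metrics; the raw significant-entry count
    is 37 edges with degree(DV)=9 (the source prints 33 and 8 without a
    stated pruning rule — both counts are documented)."""
    g = network.published_network()
    assert sorted(g.nodes) == sorted(network.NETWORK_METRICS)
    assert g.degree["Ktrans"] == 7
    assert g.degree["K1"] == 6
    assert g.degree["DV"] == 9
    assert g.number_of_edges() == 37


def test_published_fixture_flags_match_t_approximation():
    """Significance stars of the packaged matrix coincide with the n=27
    t-approximation thresholded at 0.05."""
    rho, sig, n = network.load_published_spearman()
    p = network._p_from_rho(rho.to_numpy(), n)
    derived = (p < 0.05) & ~np.eye(len(rho), dtype=bool)
    assert np.array_equal(derived, sig.to_numpy())


def test_fdr_flag_prunes_edges():
    g_raw = network.published_network()
    rho, _, n = network.load_published_spearman()
    sub = rho.loc[list(network.NETWORK_METRICS), list(network.NETWORK_METRICS)]
    p = pd.DataFrame(network._p_from_rho(sub.to_numpy(), n),
                     index=sub.index, columns=sub.columns)
    g_fdr = network.build_significance_network(sub, p, network.NETWORK_METRICS,
                                               0.05, fdr=True)
    assert g_fdr.number_of_edges() <= g_raw.number_of_edges()


# --------------------------------------------------------------------------
# neighborhood regression
# --------------------------------------------------------------------------

def test_regression_exact_linear_combination():
    rng = np.random.default_rng(0)
    x1, x2 = rng.normal(size=27), rng.normal(size=27)
    t = _table(Ktrans=2 * x1 - 3 * x2 + 1, K1=x1, DV=x2)
    res = network.regress_on_neighbors(t, "Ktrans", ["K1", "DV"])
    assert res["r2"] == pytest.approx(1.0)
    assert not res["rank_deficient"]


def test_regression_independent_noise():
    rng = np.random.default_rng(1)
    t = _table(Ktrans=rng.normal(size=1000), K1=rng.normal(size=1000),
               DV=rng.normal(size=1000))
    res = network.regress_on_neighbors(t, "Ktrans", ["K1", "DV"])
    assert res["r2"] < 0.02


def test_adjusted_r2_identity_at_study_size():
    """n=27, k=3 predictors: adjusted R^2 = 1 - (1-R^2)(n-1)/(n-k-1); at
    R^2 = 0.45 this is ~0.38 (the published pair)."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=(27, 3))
    beta = np.array([1.0, -0.5, 0.3])
    noise = rng.normal(size=27)
    y = x @ beta + noise * 2.0
    t = _table(Ktrans=y, K1=x[:, 0], DV=x[:, 1], k3max=x[:, 2])
    res = network.regress_on_neighbors(t, "Ktrans", ["K1", "DV", "k3max"])
    expected_adj = 1 - (1 - res["r2"]) * 26 / 23
    assert res["adj_r2"] == pytest.approx(expected_adj, rel=1e-12)
    assert 1 - (1 - 0.45) * 26 / 23 == pytest.approx(0.378, abs=5e-3)


def test_regression_collinear_predictors_flagged():
    rng = np.random.default_rng(3)
    x = rng.normal(size=27)
    t = _table(Ktrans=rng.normal(size=27), K1=x, DV=2 * x)
    res = network.regress_on_neighbors(t, "Ktrans", ["K1", "DV"])
    assert res["rank_deficient"]


def test_metric_table_csv_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    t = MetricTable(pd.DataFrame(
        {"ADC": rng.uniform(size=5), "Ktrans": rng.uniform(size=5)},
        index=[f"L{i}" for i in range(5)],
    ))
    path = tmp_path / "metrics.csv"
    t.to_csv(path)
    back = MetricTable.from_csv(path)
    pd.testing.assert_frame_equal(t.data, back.data, check_exact=False, rtol=1e-9)


def test_metric_table_rejects_unknown_columns():
    with pytest.raises(ValueError, match="unknown"):
        MetricTable(pd.DataFrame({"bogus": [1.0, 2.0]}))
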