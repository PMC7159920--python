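"""GRM construction, PCs, inverse-normal transform, REML and Haseman-Elston."""

import numpy as np
import pytest
from scipy import stats

import popdynh2 as p
from popdynh2.io import read_gcta_grm, read_grm_text, write_gcta_grm, write_grm_text


# ------------------------------------------------------------------ GRM
def test_grm_duplicate_individuals():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(30, 500)).astype(float)
    d[1] = d[0]
    g = p.compute_grm(d)
    assert abs(g.values[0, 1] - g.values[0, 0]) < 1e-6


def test_grm_unrelateds_moments():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 5000), size=(500, 5000))
    g = p.compute_grm(d)
    assert abs(np.mean(np.diag(g.values)) - 1.0) < 0.02
    off = g.values[np.triu_indices(500, k=1)]
    assert abs(off.mean()) < 0.01


def test_grm_full_sibs_half_related(sib_cohort):
    c = sib_cohort
    kids = np.flatnonzero(c.generation_mask(1))
    g = p.compute_grm(c.dosages[kids])
    # consecutive children of the same couple are full sibs
    sib_vals = [g.values[i, i + 1] for i in range(0, len(kids) - 1, 2)]
    assert abs(np.mean(sib_vals) - 0.5) < 0.05


def test_grm_monomorphic_error():
    with pytest.raises(p.DataError):
        p.compute_grm(np.full((10, 5), 2.0))


def test_grm_asymmetric_rejected():
    vals = np.eye(3)
    vals[0, 1] = 0.5
    with pytest.raises(p.DataError):
        p.GRMatrix(ids=["a", "b", "c"], values=vals, n_snps_per_pair=np.ones((3, 3)))


# ------------------------------------------------------------------ PCs
def test_pcs_separate_subpopulations(strat_cohort):
    c = strat_cohort
    g = p.compute_grm(c.dosages)
    pc1 = p.compute_pcs(g, 2)[:, 0]
    lab = c.individuals["subpop"].to_numpy()
    assert abs(np.corrcoef(pc1, lab)[0, 1]) > 0.9


def test_pcs_no_structure_flat_spectrum():
    # many more variants than individuals: without structure no eigenvalue
    # should dominate the bulk
    rng = np.random.default_rng(2)
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 4000), size=(300, 4000))
    g = p.compute_grm(d)
    lam = np.linalg.eigvalsh(g.values)
    assert lam[-1] / lam[:-1].mean() < 3.0


def test_pcs_rank_one_recovery():
    v = np.array([3.0, -1.0, 2.0, 0.5])
    G = np.outer(v, v) + np.eye(4) * 1e-9
    g = p.GRMatrix(ids=list("abcd"), values=G, n_snps_per_pair=np.ones((4, 4), dtype=int))
    s = p.compute_pcs(g, 1)[:, 0]
    s_unit = s / np.linalg.norm(s)
    v_unit = v / np.linalg.norm(v)
    assert np.allclose(np.abs(s_unit), np.abs(v_unit), atol=1e-6)
    # sign convention: largest-magnitude loading positive
    assert s_unit[np.argmax(np.abs(s_unit))] > 0


def test_pcs_argument_errors(founder_grm):
    _, g = founder_grm
    with pytest.raises(p.DataError):
        p.compute_pcs(g, 0)
    with pytest.raises(p.DataError):
        p.compute_pcs(g, len(g.ids))


# ------------------------------------------------------------------ INT
def test_int_blom_hand_values():
    # ranks (2, 1, 3), quantiles of (rank - 3/8) / (3 + 1/4)
    out = p.inverse_normal_transform([5.0, 1.0, 9.0])
    expected = stats.norm.ppf((np.array([2, 1, 3]) - 0.375) / 3.25)
    assert np.allclose(out, expected)
    assert np.allclose(out, [0.0, -0.86942, 0.86942], atol=1e-4)


def test_int_preserves_order_and_missing():
    x = np.array([3.0, np.nan, -1.0, 7.0, 2.0])
    out = p.inverse_normal_transform(x)
    assert np.isnan(out[1])
    ok = ~np.isnan(x)
    assert np.array_equal(np.argsort(x[ok]), np.argsort(out[ok]))
    assert abs(np.nanmean(out)) < 1e-6


def test_int_ties_share_rank():
    out = p.inverse_normal_transform([1.0, 1.0, 5.0])
    assert out[0] == out[1]


def test_int_constant_error():
    with pytest.raises(p.DataError):
        p.inverse_normal_transform([2.0, 2.0, 2.0])


# ------------------------------------------------------------------ REML
def test_reml_null_trait(founder_grm):
    rows, g = founder_grm
    rng = np.random.default_rng(21)
    y = rng.standard_normal(len(rows))
    fit = p.reml_univariate(y, None, g)
    assert fit.h2 <= 2 * fit.se_h2 + 1e-9


def test_reml_recovers_h2(null_cohort, founder_grm):
    rows, g = founder_grm
    y = null_cohort.phenos["trait_a"].to_numpy()[rows]
    fit = p.reml_univariate(y, None, g)
    assert fit.converged
    assert abs(fit.h2 - 0.6) < 2 * fit.se_h2


def test_reml_identity_grm_not_identifiable():
    g = p.GRMatrix(ids=[f"i{i}" for i in range(50)], values=np.eye(50),
                   n_snps_per_pair=np.ones((50, 50), dtype=int))
    with pytest.raises(p.NonIdentifiableError):
        p.reml_univariate(np.random.default_rng(0).standard_normal(50), None, g)


def test_reml_scale_invariance(null_cohort, founder_grm):
    rows, g = founder_grm
    y = null_cohort.phenos["trait_a"].to_numpy()[rows]
    f1 = p.reml_univariate(y, None, g)
    f2 = p.reml_univariate(3.0 * y, None, g)
    assert abs(f1.h2 - f2.h2) < 1e-6
    assert abs(f2.sigma2_g / f1.sigma2_g - 9.0) < 1e-3


def test_reml_likelihood_ascent(null_cohort, founder_grm):
    rows, g = founder_grm
    y = null_cohort.phenos["trait_a"].to_numpy()[rows]
    trace = p.reml_univariate(y, None, g).loglik_trace
    assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))


def test_reml_singular_covariates(null_cohort, founder_grm):
    rows, g = founder_grm
    y = null_cohort.phenos["trait_a"].to_numpy()[rows]
    X = np.ones((len(rows), 2))  # duplicates the implicit intercept
    with pytest.raises(p.DataError):
        p.reml_univariate(y, X, g)


def test_reml_bivariate_self_correlation(null_cohort, founder_grm):
    rows, g = founder_grm
    y = null_cohort.phenos["trait_a"].to_numpy()[rows]
    noise = 1e-4 * np.random.default_rng(3).standard_normal(len(y))
    fit = p.reml_bivariate(y, y + noise, None, g)
    assert abs(fit.rg - 1.0) < 1e-3
    assert abs(fit.r_p - 1.0) < 1e-3


def test_reml_bivariate_decomposition():
    # rg_true = 0, residuals correlated 0.5, h2 = 0.5 both: r_p ~ 0.25, rg ~ 0
    cfg = p.SimConfig(n_founder_couples=500, n_snps=800, n_causal=400, h2_target=0.5,
                      h2_target_B=0.5, rg_true=0.0, env_corr=0.5, seed=22)
    c = p.simulate_scenario(cfg)
    g = p.compute_grm(c.dosages)
    fit = p.reml_bivariate(
        c.phenos["trait_a"].to_numpy(), c.phenos["trait_b"].to_numpy(), None, g
    )
    assert abs(fit.rg) < 2 * fit.se_rg
    assert abs(fit.r_p - 0.25) < 0.08


# ------------------------------------------------------------------ HE
def test_he_agrees_with_reml(null_cohort, founder_grm):
    rows, g = founder_grm
    y = null_cohort.phenos["trait_a"].to_numpy()[rows]
    reml = p.reml_univariate(y, None, g)
    he, se_he = p.he_regression(y, g)
    assert abs(he - reml.h2) < 3 * np.hypot(se_he, reml.se_h2)


def test_he_permuted_phenotype_null(null_cohort, founder_grm):
    rows, g = founder_grm
    y = np.random.default_rng(23).permutation(
        null_cohort.phenos["trait_a"].to_numpy()[rows]
    )
    he, se = p.he_regression(y, g)
    assert abs(he) < 2 * se


def test_he_two_block_toy_closed_form():
    # 25 pairs of relatedness a = 0.5, unrelated across pairs; the slope of
    # products on off-diagonals equals cov(prod, a) / var(a), computed here
    # directly from the same pair data as the hand/moment oracle.
    rng = np.random.default_rng(24)
    n = 50
    a = 0.5
    G = np.eye(n)
    for i in range(0, n, 2):
        G[i, i + 1] = G[i + 1, i] = a
    L = np.linalg.cholesky(0.6 * G + 0.4 * np.eye(n))
    y = L @ rng.standard_normal(n)
    he, _ = p.he_regression(y, p.GRMatrix(
        ids=[str(i) for i in range(n)], values=G,
        n_snps_per_pair=np.ones((n, n), dtype=int)))
    z = (y - y.mean()) / y.std()
    iu, ju = np.triu_indices(n, k=1)
    av = G[iu, ju]
    prod = z[iu] * z[ju]
    slope_oracle = np.cov(av, prod)[0, 1] / np.var(av, ddof=1)
    assert abs(he - slope_oracle) < 1e-8


def test_he_cross_trait(null_cohort, founder_grm):
    rows, g = founder_grm
    yA = null_cohort.phenos["trait_a"].to_numpy()[rows]
    yB = null_cohort.phenos["trait_b"].to_numpy()[rows]
    cov_he, se = p.he_regression_cross(yA, yB, g)
    assert np.isfinite(cov_he) and se > 0


def test_he_small_sample_refused(founder_grm):
    _, g = founder_grm
    with pytest.raises(p.DataError):
        p.he_regression(np.ones(10), g.subset(np.arange(10)))


# ------------------------------------------------------------------ pruning / IO
def test_prune_related(sib_cohort):
    kids = np.flatnonzero(sib_cohort.generation_mask(1))
    g = p.compute_grm(sib_cohort.dosages[kids])
    keep = p.prune_related(g, threshold=0.1)
    sub = g.subset(keep)
    off = sub.values[np.triu_indices(len(keep), k=1)]
    assert np.all(np.abs(off) <= 0.1)
    assert len(keep) < len(kids)


def test_grm_io_roundtrip(tmp_path, founder_grm):
    _, g = founder_grm
    idx = np.arange(40)
    small = g.subset(idx)
    write_gcta_grm(small, tmp_path / "test")
    back = read_gcta_grm(tmp_path / "test")
    assert back.ids == small.ids
    assert np.allclose(back.values, small.values, atol=1e-6)
    write_grm_text(small, tmp_path / "test.grm.gz")
    back2 = read_grm_text(tmp_path / "test.grm.gz", small.ids)
    assert np.allclose(back2.values, small.values, atol=1e-5)
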