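"""Reverse-regression fit, joint test, BIC subset machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleioscan import (
    PhenotypeTable,
    SingularFitError,
    all_subsets,
    analyse_snp,
    bic,
    fit_reverse,
    joint_test,
    select_best,
    sidak,
)
from pleioscan.genio import DosageVector
from pleioscan.regression import GENOME_WIDE_P

from conftest import compound_symmetry


def _table(Y, kinds=None):
    n, J = Y.shape
    return PhenotypeTable(
        individual_ids=[f"i{i}" for i in range(n)],
        phenotype_names=[f"p{j}" for j in range(J)],
        values=np.asarray(Y, float),
        column_kinds=kinds or ["continuous"] * J,
    )


def _dose(values):
    return DosageVector(np.asarray(values, float), "G", "A")


def _random_instance(rng, n=None, J=None):
    n = n or int(rng.integers(20, 200))
    J = J or int(rng.integers(1, 6))
    Y = rng.standard_normal((n, J))
    g = np.clip(rng.normal(0.8, 0.5, size=n), 0.0, 2.0)
    return _dose(g), _table(Y)


def _ols_oracle(g, X):
    """Independent normal-equations fit via pseudo-inverse and ML variance."""
    coef = np.linalg.pinv(X) @ g
    resid = g - X @ coef
    rss = resid @ resid
    n = g.shape[0]
    sigma2 = rss / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    vcov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, vcov, loglik, rss


# ---------------------------------------------------------------------------
# fit_reverse
# ---------------------------------------------------------------------------

def test_null_model_is_intercept_only(rng):
    d, t = _random_instance(rng, n=80, J=3)
    fit = fit_reverse(d, t, ())
    assert fit.alpha == pytest.approx(d.values.mean())
    sigma2 = np.var(d.values)  # ML variance
    expect = -0.5 * 80 * (math.log(2 * math.pi * sigma2) + 1.0)
    assert fit.loglik == pytest.approx(expect, rel=1e-12)
    assert fit.k_params == 2


def test_orthogonal_phenotype_has_zero_coefficient(rng):
    n = 100
    g = rng.normal(1.0, 0.4, size=n)
    y = rng.standard_normal(n)
    y -= y.mean()
    gc = g - g.mean()
    y -= (y @ gc) / (gc @ gc) * gc  # orthogonal to centred dosage
    fit = fit_reverse(_dose(np.clip(g, 0, 2) * 0 + g), _table(y[:, None]), (0,))
    assert abs(fit.beta[0]) < 1e-10


def test_fit_matches_independent_oracle(rng):
    """beta, vcov, loglik agree with pinv normal equations to 1e-8."""
    for _ in range(30):
        d, t = _random_instance(rng)
        subset = tuple(range(t.n_phenotypes))
        fit = fit_reverse(d, t, subset)
        X = np.column_stack([np.ones(d.n), t.values])
        coef, vcov, loglik, _ = _ols_oracle(d.values, X)
        np.testing.assert_allclose(fit.beta, coef[1:], atol=1e-8)
        np.testing.assert_allclose(fit.vcov, vcov[1:, 1:], atol=1e-8)
        assert fit.loglik == pytest.approx(loglik, abs=1e-8)


def test_fit_matches_statsmodels(rng):
    """Cross-check against a second, library-based least-squares route."""
    sm = pytest.importorskip("statsmodels.api")
    d, t = _random_instance(rng, n=150, J=4)
    fit = fit_reverse(d, t, (0, 1, 2, 3))
    X = sm.add_constant(t.values)
    res = sm.OLS(d.values, X).fit()
    np.testing.assert_allclose(fit.beta, res.params[1:], atol=1e-9)
    assert fit.loglik == pytest.approx(res.llf, abs=1e-8)
    # statsmodels scales by n-k; rescale to the ML variance used here
    np.testing.assert_allclose(
        fit.vcov,
        np.asarray(res.cov_params())[1:, 1:] * res.df_resid / res.nobs,
        atol=1e-9,
    )


def test_complete_cases_shared_across_subsets(rng):
    d, t = _random_instance(rng, n=60, J=3)
    t.values[5, 2] = np.nan  # missing in phenotype 3 only
    f0 = fit_reverse(d, t, (0,))
    f_all = fit_reverse(d, t, (0, 1, 2))
    assert f0.n_used == f_all.n_used == 59


def test_collinear_design_raises(rng):
    n = 50
    y = rng.standard_normal(n)
    Y = np.column_stack([y, 2 * y])
    with pytest.raises(SingularFitError):
        fit_reverse(_dose(rng.normal(1, 0.3, n)), _table(Y), (0, 1))


def test_constant_dosage_raises(rng):
    with pytest.raises(SingularFitError):
        fit_reverse(_dose(np.ones(30)), _table(rng.standard_normal((30, 1))), (0,))


def test_discrete_phenotype_expands_to_indicators(rng):
    n = 120
    levels = rng.integers(0, 3, size=n).astype(float)
    g = rng.normal(1, 0.4, n) + 0.3 * (levels == 2)
    fit = fit_reverse(_dose(g), _table(levels[:, None], kinds=["discrete"]), (0,))
    assert fit.beta.shape == (2,)  # 3 levels -> 2 indicator columns
    assert fit.k_params == 4  # intercept + 2 indicators + sigma^2


# ---------------------------------------------------------------------------
# joint test
# ---------------------------------------------------------------------------

def test_joint_test_no_signal_is_p_one():
    class F:
        loglik = -12.5
        n_used = 50

    chi2, p = joint_test(F, -12.5, 3)
    assert chi2 == 0.0 and p == 1.0


def test_joint_test_equals_rss_ratio_identity(rng):
    d, t = _random_instance(rng, n=90, J=2)
    null = fit_reverse(d, t, ())
    full = fit_reverse(d, t, (0, 1))
    chi2, _ = joint_test(full, null.loglik, 2, null.n_used)
    assert chi2 == pytest.approx(90 * math.log(null.rss / full.rss), rel=1e-10)


def test_strong_signal_is_genome_wide_significant(assoc_study):
    causal = int(np.argmax(assoc_study.truth.causal))
    r = analyse_snp(assoc_study.records[causal], assoc_study.phenotypes)
    assert r.p_value < GENOME_WIDE_P
    nulls = [
        analyse_snp(rec, assoc_study.phenotypes).p_value
        for i, rec in enumerate(assoc_study.records)
        if i != causal
    ]
    assert all(p > GENOME_WIDE_P for p in nulls)


def test_joint_p_invariant_to_affine_phenotype_transform(rng):
    """Any invertible affine map of the predictors leaves the LRT unchanged."""
    d, t = _random_instance(rng, n=120, J=3)
    r1 = analyse_snp_from(d, t)
    A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
    t2 = _table(t.values @ A.T + rng.standard_normal(3))
    r2 = analyse_snp_from(d, t2)
    assert r1 == pytest.approx(r2, rel=1e-9)


def analyse_snp_from(d, t):
    null = fit_reverse(d, t, ())
    full = fit_reverse(d, t, tuple(range(t.n_phenotypes)))
    return joint_test(full, null.loglik, t.n_phenotypes)[0]


def test_nesting_logliks_non_decreasing(rng):
    d, t = _random_instance(rng, n=70, J=3)
    lls = {s: fit_reverse(d, t, s).loglik for s in
           itertools.chain.from_iterable(
               itertools.combinations(range(3), r) for r in range(4))}
    for s, ll in lls.items():
        for bigger in lls:
            if set(s) <= set(bigger):
                assert lls[bigger] >= ll - 1e-9


# ---------------------------------------------------------------------------
# BIC and subset selection
# ---------------------------------------------------------------------------

def test_bic_definition_null_model(rng):
    d, t = _random_instance(rng, n=100, J=2)
    fit = fit_reverse(d, t, ())
    assert bic(fit) == pytest.approx(-2 * fit.loglik + 2 * math.log(100))


def test_bic_null_phenotype_costs_log_n(rng):
    """Adding a no-effect phenotype raises BIC by ~log(n) on average."""
    diffs = []
    for seed in range(40):
        r = np.random.default_rng(seed)
        n = 3000
        g = r.binomial(2, 0.3, n).astype(float)
        t = _table(r.standard_normal((n, 1)))
        d = _dose(g)
        diffs.append(bic(fit_reverse(d, t, (0,))) - bic(fit_reverse(d, t, ())))
    # E[diff] = log(n) - E[chi2_1] = log(n) - 1
    assert np.mean(diffs) == pytest.approx(math.log(3000) - 1.0, abs=1.0)


def test_all_subsets_matches_exhaustive_oracle(rng):
    d, t = _random_instance(rng, n=80, J=3)
    got = all_subsets(d, t)
    assert len(got) == 8
    X0 = np.column_stack([np.ones(d.n), t.values])
    for subset in got:
        X = X0[:, [0] + [j + 1 for j in subset]]
        _, _, loglik, _ = _ols_oracle(d.values, X)
        expect = -2 * loglik + (len(subset) + 2) * math.log(d.n)
        assert got[subset] == pytest.approx(expect, abs=1e-8)


def test_all_subsets_guard():
    d = _dose(np.zeros(3))
    t = _table(np.zeros((3, 21)))
    with pytest.raises(Exception, match="J <= 20"):
        all_subsets(d, t)


def test_select_best_tie_rules():
    assert select_best({(): 10.0, (0,): -5.0}) == (0,)
    assert select_best({(): 1.0, (0,): 1.0, (1,): 1.0, (0, 1): 1.0}) == ()
    assert select_best({(1,): 0.0, (0,): 0.0}) == (0,)


@pytest.mark.parametrize(
    "p,m,expected",
    [(0.0, 5, 0.0), (0.25, 1, 0.25), (0.01, 4, 0.03940399)],
)
def test_sidak_closed_form(p, m, expected):
    assert sidak(p, m) == pytest.approx(expected, rel=1e-9)


@given(
    st.floats(0.0, 1.0),
    st.floats(0.0, 1.0),
    st.integers(1, 20),
)
@settings(deadline=None, derandomize=True)
def test_sidak_monotone(p1, p2, m):
    lo, hi = sorted((p1, p2))
    assert sidak(lo, m) <= sidak(hi, m) + 1e-15
    assert sidak(lo, m) <= sidak(lo, m + 1) + 1e-15


# ---------------------------------------------------------------------------
# Allele flip
# ---------------------------------------------------------------------------

def test_allele_flip_negates_beta_keeps_test(assoc_study):
    causal = int(np.argmax(assoc_study.truth.causal))
    rec = assoc_study.records[causal]
    rb = analyse_snp(rec, assoc_study.phenotypes, effect_allele="B")
    ra = analyse_snp(rec, assoc_study.phenotypes, effect_allele="A")
    np.testing.assert_allclose(ra.full_fit.beta, -rb.full_fit.beta, atol=1e-10)
    assert ra.chi2 == pytest.approx(rb.chi2, abs=1e-10)
    assert ra.p_value == pytest.approx(rb.p_value, abs=1e-10)
    assert ra.eaf == pytest.approx(1.0 - rb.eaf, abs=1e-12)
    # intercept shifts: G_A = 2 - G_B implies alpha_A = 2 - alpha_B
    assert ra.full_fit.alpha == pytest.approx(2.0 - rb.full_fit.alpha, abs=1e-10)


def test_subset_recovery_on_causal_snp(assoc_study):
    causal = int(np.argmax(assoc_study.truth.causal))
    r = analyse_snp(assoc_study.records[causal], assoc_study.phenotypes, with_subsets=True)
    assert select_best(r.subset_bics) == (0,)
    assert r.delta_bics[()] == 0.0
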