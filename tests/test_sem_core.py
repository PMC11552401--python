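"""Unit and property tests for the covariance-structure SEM engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fusionaudit as fa
from fusionaudit import Fixed, Free, SemModelSpec
from fusionaudit.sem_core import CompiledModel, SemInputError, SemSpecError

from conftest import ONE_FACTOR_TRUTH, one_factor_spec, path_toy_spec, saturated_spec


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------


def test_implied_identity_measurement_returns_theta():
    """With identity loadings, zero Psi and Theta = S0 the model returns S0."""
    s0 = np.array([[2.0, 0.3], [0.3, 1.5]])
    spec = SemModelSpec(
        observed_names=("x", "y"), latent_names=("tx", "ty"),
        loadings=(("x", "tx", Fixed(1.0)), ("y", "ty", Fixed(1.0))),
        psi=(("tx", "tx", Fixed(0.0)), ("ty", "ty", Fixed(0.0))),
        theta=(("x", "x", Fixed(2.0)), ("y", "y", Fixed(1.5)),
               ("x", "y", Fixed(0.3))))
    got = fa.implied_covariance(spec, {})
    assert np.allclose(got, s0)


def test_implied_one_factor_two_indicators():
    """Unit loadings, factor variance 1, error variances 0.5 each."""
    spec = SemModelSpec(
        observed_names=("y1", "y2"), latent_names=("L",),
        loadings=(("y1", "L", Fixed(1.0)), ("y2", "L", Fixed(1.0))),
        psi=(("L", "L", Fixed(1.0)),),
        theta=(("y1", "y1", Fixed(0.5)), ("y2", "y2", Fixed(0.5))))
    assert np.allclose(fa.implied_covariance(spec, {}),
                       [[1.5, 1.0], [1.0, 1.5]])


def test_implied_composite_variance_of_uncorrelated_parts():
    """An exact unit-weight composite of two uncorrelated unit-variance true
    scores has variance 2."""
    spec = SemModelSpec(
        observed_names=("t1", "t2"), latent_names=("ts_t1", "ts_t2", "S"),
        loadings=(("t1", "ts_t1", Fixed(1.0)), ("t2", "ts_t2", Fixed(1.0))),
        paths=(("ts_t1", "S", Fixed(1.0)), ("ts_t2", "S", Fixed(1.0))),
        psi=(("ts_t1", "ts_t1", Fixed(1.0)), ("ts_t2", "ts_t2", Fixed(1.0)),
             ("S", "S", Fixed(0.0))))
    cm = CompiledModel(spec)
    _, bet, psi, _ = cm.matrices(np.zeros(0))
    C = np.linalg.inv(np.eye(3) - bet)
    V = C @ psi @ C.T
    assert V[cm.lat_index["S"], cm.lat_index["S"]] == pytest.approx(2.0)


def test_implied_missing_value_raises():
    spec = SemModelSpec(observed_names=("x",), latent_names=("tx",),
                        loadings=(("x", "tx", Fixed(1.0)),),
                        psi=(("tx", "tx", Free("v")),))
    with pytest.raises(SemInputError):
        fa.implied_covariance(spec, {})


# ---------------------------------------------------------------------------
# ML discrepancy
# ---------------------------------------------------------------------------


def test_ml_discrepancy_examples(compact, compact_sigma):
    s = np.array([[2.0, 0.5], [0.5, 1.0]])
    assert fa.ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)
    val = fa.ml_discrepancy(np.eye(2), np.diag([2.0, 2.0]))
    assert val == pytest.approx(math.log(4) + 1 - 2, abs=1e-12)
    # at the exact population covariance of a generating model, F = 0
    assert fa.ml_discrepancy(compact_sigma, compact_sigma) == pytest.approx(0.0, abs=1e-12)


def test_ml_discrepancy_input_errors():
    with pytest.raises(SemInputError):
        fa.ml_discrepancy(np.eye(2), np.eye(3))
    with pytest.raises(Exception):
        fa.ml_discrepancy(np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(-1.5, 1.5), min_size=18, max_size=18),
       st.lists(st.floats(-1.5, 1.5), min_size=18, max_size=18))
def test_ml_discrepancy_nonnegative_property(a_flat, b_flat):
    """F(S, Sigma) >= 0 for PD pairs, with equality iff Sigma = S."""
    A = np.array(a_flat).reshape(3, 6)
    B = np.array(b_flat).reshape(3, 6)
    S = A @ A.T / 6 + 0.5 * np.eye(3)
    Sigma = B @ B.T / 6 + 0.5 * np.eye(3)
    assert fa.ml_discrepancy(S, Sigma) >= -1e-12
    assert fa.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_saturated_model_chi_square_exactly_zero(rng):
    A = rng.normal(size=(4, 8))
    S = A @ A.T / 8 + 0.5 * np.eye(4)
    spec = saturated_spec(("a", "b", "c", "d"))
    assert spec.df == 0
    fit = fa.fit_ml(spec, S, 200)
    assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
    assert fit.p_value == 1.0
    # free moments recover the sample moments themselves
    assert fit.estimates["v_a"] == pytest.approx(S[0, 0], abs=1e-7)
    assert fit.estimates["c_a_b"] == pytest.approx(S[0, 1], abs=1e-7)


def test_fit_recovers_generating_parameters_at_population(compact, compact_sigma):
    """Population-covariance oracle: F_min ~ 0 and exact parameter recovery."""
    fit = fa.fit_ml(compact.generating_spec, compact_sigma, 3600)
    assert fit.converged and fit.admissible
    assert fit.f_min < 1e-10
    for name, truth in compact.true_values.items():
        assert fit.estimates[name] == pytest.approx(truth, abs=1e-5)


def test_degrees_of_freedom_hand_counts():
    """df = p(p+1)/2 - #free on hand-counted toy specs."""
    assert one_factor_spec().df == 10 - 8
    assert saturated_spec(("a", "b", "c")).df == 0
    assert path_toy_spec().df == 10 - 10


def test_duplicate_free_parameter_rejected():
    with pytest.raises(SemSpecError):
        SemModelSpec(observed_names=("x", "y"), latent_names=("tx", "ty"),
                     loadings=(("x", "tx", Fixed(1.0)), ("y", "ty", Fixed(1.0))),
                     psi=(("tx", "tx", Free("v")), ("ty", "ty", Free("v"))))


def test_cyclic_structure_rejected():
    with pytest.raises(SemSpecError):
        SemModelSpec(observed_names=("x",), latent_names=("a", "b"),
                     loadings=(("x", "a", Fixed(1.0)),),
                     paths=(("a", "b", Fixed(0.5)), ("b", "a", Fixed(0.5))))


def test_nonpd_sample_covariance_rejected():
    spec = saturated_spec(("a", "b"))
    with pytest.raises(SemInputError):
        fa.fit_ml(spec, np.array([[1.0, 2.0], [2.0, 1.0]]), 100)


def test_freeing_a_parameter_never_increases_f_min(compact, compact_sigma):
    """Nesting monotonicity on a perturbed sample covariance."""
    S = fa.sample_cov(compact_sigma, 400, 7)
    study = compact.study
    nested = fa.fit_ml(fa.build_fusion(study, ()), S, 400)
    fuller = fa.fit_ml(fa.build_fusion(study, (("a1", "d1"),)), S, 400)
    assert fuller.f_min <= nested.f_min + 1e-9


# ---------------------------------------------------------------------------
# chi-square statistics
# ---------------------------------------------------------------------------


def test_chi_square_stat_scaling_and_limits():
    chi2, df, p = fa.chi_square_stat(0.002, 3616, 11)
    assert chi2 == pytest.approx((3616 - 1) * 0.002)
    chi2, df, p = fa.chi_square_stat(0.0, 1000, 5)
    assert chi2 == 0.0 and p == 1.0
    chi2_n, _, _ = fa.chi_square_stat(0.002, 3616, 11, scale="n")
    assert chi2_n == pytest.approx(3616 * 0.002)
    with pytest.raises(SemInputError):
        fa.chi_square_stat(-0.1, 100, 5)


def test_chisq_pvalue_reproduces_published_tail_probabilities():
    """Right-tail probabilities to 2 dp from the printed (chi2, df) pairs."""
    assert round(fa.chisq_pvalue(7.23, 11), 2) == 0.78
    assert round(fa.chisq_pvalue(23.60, 28), 2) == 0.70
    assert fa.chisq_pvalue(0.0, 7) == 1.0
    assert fa.chisq_pvalue(192.25, 35) < 1e-4


def test_chisq_pvalue_matches_numerical_integration():
    """Agreement with direct quadrature of the chi-square density to 1e-8."""
    from scipy.integrate import quad
    from scipy.special import gammaln

    def density(t, k):
        return math.exp((k / 2 - 1) * math.log(t) - t / 2
                        - (k / 2) * math.log(2) - gammaln(k / 2))

    for x in (0.5, 3.0, 7.23, 20.0):
        for k in (1, 4, 11, 28):
            val, _ = quad(density, x, np.inf, args=(k,), limit=200)
            assert fa.chisq_pvalue(x, k) == pytest.approx(val, abs=1e-8)


def test_chisq_pvalue_monotone_in_x():
    xs = np.linspace(0, 30, 40)
    ps = [fa.chisq_pvalue(x, 9) for x in xs]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
    with pytest.raises(SemInputError):
        fa.chisq_pvalue(1.0, 0)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------


def _fd_hessian(cm, x, S, h=1e-5):
    q = len(x)
    H = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            acc = 0.0
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                xx = x.copy()
                xx[i] += si * h
                xx[j] += sj * h
                acc += si * sj * cm.gradient(xx, S)[0]
            H[i, j] = acc / (4 * h * h)
    return H


def test_standard_errors_match_numerical_hessian():
    """SEs from the expected information agree with a brute-force
    finite-difference Hessian of the discrepancy within 5%."""
    spec = one_factor_spec()
    pop = fa.implied_covariance(spec, ONE_FACTOR_TRUTH)
    n = 500
    fit = fa.fit_ml(spec, pop, n)
    se, _ = fa.standard_errors(fit)
    cm = CompiledModel(spec)
    cm.set_logdet_s(pop)
    x = np.array([fit.estimates[k] for k in cm.free_names])
    acov = 2.0 / (n - 1) * np.linalg.inv(_fd_hessian(cm, x, pop))
    for i, k in enumerate(cm.free_names):
        assert se[k] == pytest.approx(math.sqrt(acov[i, i]), rel=0.05)


def test_standard_errors_shrink_with_sample_size():
    spec = one_factor_spec()
    pop = fa.implied_covariance(spec, ONE_FACTOR_TRUTH)
    se_small, _ = fa.standard_errors(fa.fit_ml(spec, pop, 400))
    se_big, _ = fa.standard_errors(fa.fit_ml(spec, pop, 4000))
    for k in se_small:
        assert se_big[k] < se_small[k]


def test_fixed_parameters_absent_from_standard_errors():
    spec = one_factor_spec()
    pop = fa.implied_covariance(spec, ONE_FACTOR_TRUTH)
    se, bands = fa.standard_errors(fa.fit_ml(spec, pop, 500))
    assert set(se) == set(ONE_FACTOR_TRUTH)  # only the free parameters
    assert set(bands) == set(se)


# ---------------------------------------------------------------------------
# standardization and total effects
# ---------------------------------------------------------------------------


def test_standardization_identity_for_unit_variances():
    """With all latent variances 1, standardized equals unstandardized, and an
    exogenous covariance of 0.20 is the correlation 0.20."""
    spec = SemModelSpec(
        observed_names=("x", "y"), latent_names=("tx", "ty"),
        loadings=(("x", "tx", Fixed(1.0)), ("y", "ty", Fixed(1.0))),
        psi=(("tx", "tx", Fixed(1.0)), ("ty", "ty", Fixed(1.0)),
             ("tx", "ty", Fixed(0.20))))
    fit = fa.fit_ml(spec, fa.implied_covariance(spec, {}), 100)
    assert fit.standardized[("tx", "ty")] == pytest.approx(0.20, abs=1e-10)


def test_standardization_preserves_sign(compact, compact_sigma):
    fit = fa.fit_ml(compact.generating_spec, compact_sigma, 3600)
    for c, e, stt in fit.spec.paths:
        if isinstance(stt, Free):
            raw = fit.estimates[stt.name]
            if abs(raw) > 1e-12:
                assert np.sign(fit.standardized[(c, e)]) == np.sign(raw)


def test_total_effects_chain_product():
    """x -> y (0.5), y -> z (0.4): total x -> z is 0.20; no paths, no effects."""
    spec = SemModelSpec(
        observed_names=("x", "y", "z"), latent_names=("tx", "ty", "tz"),
        loadings=(("x", "tx", Fixed(1.0)), ("y", "ty", Fixed(1.0)),
                  ("z", "tz", Fixed(1.0))),
        paths=(("tx", "ty", Fixed(0.5)), ("ty", "tz", Fixed(0.4))),
        psi=(("tx", "tx", Fixed(1.0)),
             ("ty", "ty", Fixed(1.0 - 0.25)), ("tz", "tz", Fixed(1.0 - 0.16))))
    fit = fa.fit_ml(spec, fa.implied_covariance(spec, {}), 100)
    tot = fa.total_effects(fit)
    assert tot.loc["tx", "tz"] == pytest.approx(0.2, abs=1e-10)
    assert tot.loc["tx", "ty"] == pytest.approx(0.5, abs=1e-10)
    assert tot.loc["tz", "tx"] == 0.0


def test_total_effects_match_path_enumeration_oracle():
    """Sum over enumerated directed paths of products of standardized
    coefficients equals the matrix total (I - B_std)^-1 - I."""
    import networkx as nx

    spec = path_toy_spec()
    truth = {"b11": 0.4, "b21": -0.3, "b12": 0.2, "b22": 0.25, "byy": 0.5,
             "v1": 1.0, "v2": 1.3, "c12": 0.3, "d1": 0.8, "d2": 0.9}
    fit = fa.fit_ml(spec, fa.implied_covariance(spec, truth), 500)
    tot = fa.total_effects(fit)
    g = nx.DiGraph()
    for c, e, _ in spec.paths:
        g.add_edge(c, e, w=fit.standardized[(c, e)])
    for src in g.nodes:
        for dst in g.nodes:
            if src == dst:
                continue
            acc = 0.0
            for path in nx.all_simple_paths(g, src, dst):
                prod = 1.0
                for a, b in zip(path, path[1:]):
                    prod *= g[a][b]["w"]
                acc += prod
            assert tot.loc[src, dst] == pytest.approx(acc, abs=1e-9)
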