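"""Core model: response function, likelihood, priors, nesting, transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from birt import (
    ModelSpec,
    ParameterState,
    PriorConfig,
    ResponseData,
    log_likelihood,
    log_posterior,
    log_prior,
    logistic,
    reduce_model,
    success_probability,
)
from birt.model import (
    corr_chol_from_unconstrained,
    lkj_chol_logpdf,
    natural_to_unconstrained,
    unconstrained_from_corr_chol,
    unconstrained_to_natural,
)


# ---------------------------------------------------------------------------
# logistic and response function


@pytest.mark.parametrize(
    "x, expected",
    [
        (0.0, 0.5),
        (2.0, 0.8807970779778823),
        (math.inf, 1.0),
        (-math.inf, 0.0),
        (800.0, 1.0),
        (-800.0, 0.0),
    ],
)
def test_logistic_values(x, expected):
    assert logistic(x) == pytest.approx(expected, abs=1e-15)


def test_logistic_symmetry_identity():
    assert logistic(1.7) + logistic(-1.7) == pytest.approx(1.0, abs=1e-15)


def test_logistic_rejects_non_numeric():
    with pytest.raises((TypeError, ValueError)):
        logistic("not a number")


def test_success_probability_values():
    assert success_probability(0, 1, 0, 0, 0) == pytest.approx(0.5)
    # lower asymptote equals the guessing probability for an 8-choice item
    assert success_probability(3.0, 1.0, 0.125, 0.0, -math.inf) == pytest.approx(0.125)
    assert success_probability(1, 2, 0.2, 0.1, 0.5) == pytest.approx(
        0.2 + 0.7 * logistic(2.0), abs=1e-15
    )


def test_success_probability_rejects_invalid_asymptotes():
    with pytest.raises(ValueError):
        success_probability(0, 1, 0.7, 0.5, 0)


@settings(derandomize=True, max_examples=100)
@given(
    beta=st.floats(-5, 5),
    logalpha=st.floats(-2, 2),
    gamma=st.floats(0, 0.45),
    psi=st.floats(0, 0.45),
    theta=st.floats(-6, 6),
)
def test_success_probability_bounds_and_monotonicity(beta, logalpha, gamma, psi, theta):
    alpha = math.exp(logalpha)
    p = success_probability(beta, alpha, gamma, psi, theta)
    assert gamma <= p <= 1 - psi
    # strictly increasing in theta and in beta
    eps = 1e-4
    assert success_probability(beta, alpha, gamma, psi, theta + eps) > p
    assert success_probability(beta + eps, alpha, gamma, psi, theta) > p


# ---------------------------------------------------------------------------
# likelihood: brute-force oracle


def _brute_force_loglik(data, state):
    """Independent summation oracle over raw Bernoulli terms."""
    total = 0.0
    pointwise = []
    for person, item, y in zip(data.person, data.item, data.y):
        p = state.gamma[item] + (1 - state.gamma[item] - state.psi[item]) / (
            1.0 + math.exp(-(state.beta[item] + state.alpha[item] * state.theta[person]))
        )
        ll = math.log(p) if y == 1 else math.log(1.0 - p)
        pointwise.append(ll)
        total += ll
    return total, np.array(pointwise)


def _toy_state_3x3():
    return ParameterState(
        beta=np.array([-0.5, 0.3, 1.1]),
        alpha=np.array([0.8, 1.4, 1.0]),
        gamma=np.array([0.1, 0.0, 0.2]),
        psi=np.array([0.05, 0.0, 0.0]),
        theta=np.array([-1.2, 0.1, 0.9]),
        sigma_theta=1.3,
    )


def _toy_data_3x3():
    person, item = np.divmod(np.arange(9), 3)
    y = np.array([1, 0, 0, 1, 1, 0, 1, 1, 1], dtype=np.int8)
    return ResponseData(person=person, item=item, y=y, n_persons=3, n_items=3)


def test_log_likelihood_simple_values():
    data = ResponseData(person=np.array([0]), item=np.array([0]), y=np.array([1]),
                        n_persons=1, n_items=1)
    state = ParameterState(beta=[0.0], alpha=[1.0], gamma=[0.0], psi=[0.0], theta=[0.0])
    res = log_likelihood(data, state)
    assert res.total == pytest.approx(math.log(0.5), abs=1e-15)


def test_impossible_observation_gives_neg_inf_without_raising():
    data = ResponseData(person=np.array([0]), item=np.array([0]), y=np.array([0]),
                        n_persons=1, n_items=1)
    # gamma = 1 forces p = 1, so observing y = 0 is impossible
    state = ParameterState(beta=[0.0], alpha=[1.0], gamma=[1.0], psi=[0.0], theta=[0.0])
    res = log_likelihood(data, state)
    assert res.total == -math.inf


def test_nan_state_rejected():
    data = _toy_data_3x3()
    state = _toy_state_3x3()
    state.beta[1] = math.nan
    with pytest.raises(ValueError):
        log_likelihood(data, state)


def test_log_likelihood_matches_brute_force_oracle():
    data, state = _toy_data_3x3(), _toy_state_3x3()
    expected_total, expected_pw = _brute_force_loglik(data, state)
    res = log_likelihood(data, state)
    assert res.total == pytest.approx(expected_total, abs=1e-12)
    np.testing.assert_allclose(res.pointwise, expected_pw, atol=1e-12)
    assert res.total == np.sum(res.pointwise)  # exact, same accumulation


# ---------------------------------------------------------------------------
# priors


def test_log_prior_non_hierarchical_item_at_prior_mean():
    spec = ModelSpec("1PL", hierarchical=False, sigma_theta_fixed=1.0)
    scale = spec.priors.scale["beta"]
    state = ParameterState(
        beta=[spec.priors.loc["beta"]], alpha=[1.0], gamma=[0.0], psi=[0.0],
        theta=[0.0], sigma_theta=1.0,
    )
    expected = math.log(1.0 / (scale * math.sqrt(2 * math.pi)))  # item term
    expected += norm.logpdf(0.0)  # person term
    assert log_prior(state, spec) == pytest.approx(expected, abs=1e-12)


def test_log_prior_person_block_standard_normal():
    J = 7
    spec = ModelSpec("1PL", hierarchical=False, sigma_theta_fixed=1.0)
    base = ParameterState(beta=[0.4], alpha=[1.0], gamma=[0.0], psi=[0.0],
                          theta=np.zeros(1), sigma_theta=1.0)
    many = ParameterState(beta=[0.4], alpha=[1.0], gamma=[0.0], psi=[0.0],
                          theta=np.zeros(J), sigma_theta=1.0)
    diff = log_prior(many, spec) - log_prior(base, spec)
    assert diff == pytest.approx((J - 1) * (-0.9189385332046727), abs=1e-12)


def test_hierarchical_identity_correlation_factorizes():
    spec = ModelSpec("2PL", hierarchical=True, sigma_theta_fixed=1.0)
    rng = np.random.default_rng(0)
    I = 5
    eta = rng.normal(size=(I, 2))
    b_bar = np.array([0.2, -0.1])
    sigma = np.array([0.8, 0.5])
    state = ParameterState(
        beta=eta[:, 0], alpha=np.exp(eta[:, 1]), gamma=np.zeros(I), psi=np.zeros(I),
        theta=np.array([0.3]), sigma_theta=1.0,
        b_bar=b_bar, sigma=sigma, omega_chol=np.eye(2),
    )
    total = log_prior(state, spec)
    # independent-priors value assembled from univariate normal densities
    expected = float(norm.logpdf(0.3))
    for k, (loc, scl) in enumerate([(0.0, 3.0), (0.0, 1.0)]):
        expected += float(np.sum(norm.logpdf(eta[:, k], b_bar[k], sigma[k])))
        expected += float(norm.logpdf(b_bar[k], loc, scl))
    for s in sigma:
        expected += math.log(2.0) + float(norm.logpdf(s, 0.0, 1.0))
    assert total == pytest.approx(expected, abs=1e-10)


def test_invalid_sigma_rejected():
    spec = ModelSpec("1PL", hierarchical=False)
    state = ParameterState(beta=[0.0], alpha=[1.0], gamma=[0.0], psi=[0.0],
                           theta=[0.0], sigma_theta=-1.0)
    with pytest.raises(ValueError):
        log_prior(state, spec)


# ---------------------------------------------------------------------------
# posterior


def test_flat_prior_posterior_equals_likelihood():
    data, state = _toy_data_3x3(), _toy_state_3x3()
    spec = ModelSpec("4PL", hierarchical=False, priors=PriorConfig.flat_prior())
    assert log_posterior(data, state, spec) == pytest.approx(
        log_likelihood(data, state).total, abs=1e-12
    )


def test_posterior_decomposition_identity():
    data, state = _toy_data_3x3(), _toy_state_3x3()
    spec = ModelSpec("4PL", hierarchical=False)
    lp = log_posterior(data, state, spec)
    assert lp - log_likelihood(data, state).total == pytest.approx(
        log_prior(state, spec), abs=1e-12
    )


def test_posterior_matches_termwise_oracle_2x2():
    person, item = np.divmod(np.arange(4), 2)
    data = ResponseData(person=person, item=item, y=np.array([1, 0, 0, 1]),
                        n_persons=2, n_items=2)
    state = ParameterState(beta=[0.2, -0.4], alpha=[1.0, 1.5], gamma=[0.1, 0.15],
                           psi=[0.0, 0.0], theta=[0.5, -0.3], sigma_theta=1.0)
    spec = ModelSpec("3PL", hierarchical=False, sigma_theta_fixed=1.0)
    from scipy.special import logit
    ll, _ = _brute_force_loglik(data, state)
    prior = float(norm.logpdf(0.5) + norm.logpdf(-0.3))
    prior += float(np.sum(norm.logpdf(state.beta, 0.0, 3.0)))
    prior += float(np.sum(norm.logpdf(np.log(state.alpha), 0.0, 1.0)))
    prior += float(np.sum(norm.logpdf(logit(state.gamma), -2.0, 1.0)))
    assert log_posterior(data, state, spec) == pytest.approx(ll + prior, abs=1e-10)


# ---------------------------------------------------------------------------
# nesting / reduction


def test_nesting_identities_exact():
    rng = np.random.default_rng(7)
    data = _toy_data_3x3()
    full = ParameterState(
        beta=rng.normal(size=3), alpha=np.exp(rng.normal(size=3) * 0.3),
        gamma=rng.uniform(0.05, 0.3, 3), psi=rng.uniform(0.01, 0.2, 3),
        theta=rng.normal(size=3),
    )
    # 4PL with psi=0 == 3PL; additionally gamma=0 == 2PL; additionally alpha=1 == 1PL
    s3 = reduce_model(full, "3PL")
    s2 = reduce_model(full, "2PL")
    s1 = reduce_model(full, "1PL")
    manual3 = ParameterState(beta=full.beta, alpha=full.alpha, gamma=full.gamma,
                             psi=np.zeros(3), theta=full.theta)
    np.testing.assert_array_equal(
        log_likelihood(data, s3).pointwise, log_likelihood(data, manual3).pointwise
    )
    manual2 = ParameterState(beta=full.beta, alpha=full.alpha, gamma=np.zeros(3),
                             psi=np.zeros(3), theta=full.theta)
    assert log_likelihood(data, s2).total == log_likelihood(data, manual2).total
    manual1 = ParameterState(beta=full.beta, alpha=np.ones(3), gamma=np.zeros(3),
                             psi=np.zeros(3), theta=full.theta)
    np.testing.assert_allclose(
        log_likelihood(data, s1).pointwise, log_likelihood(data, manual1).pointwise,
        atol=1e-12,
    )


# ---------------------------------------------------------------------------
# transforms


@settings(derandomize=True, max_examples=80)
@given(x=st.floats(-8, 8))
def test_transforms_round_trip(x):
    for cls in ("beta", "logalpha", "logitgamma", "logitpsi"):
        nat = unconstrained_to_natural(cls, np.array([x]))
        back = natural_to_unconstrained(cls, nat)
        assert abs(back[0] - x) < 1e-10


def test_corr_chol_round_trip():
    rng = np.random.default_rng(5)
    for dim in (2, 3, 4):
        u = rng.normal(size=dim * (dim - 1) // 2)
        L, _ = corr_chol_from_unconstrained(u, dim)
        omega = L @ L.T
        np.testing.assert_allclose(np.diag(omega), 1.0, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(omega) > -1e-12)
        np.testing.assert_allclose(unconstrained_from_corr_chol(L), u, atol=1e-9)


def test_lkj_uniform_pushforward_dim2():
    # for dim 2 and shape 1 the implied density of the single correlation is
    # uniform: density x Jacobian of r = tanh(u) must be constant in u
    for u in np.linspace(-2.5, 2.5, 11):
        L, jac = corr_chol_from_unconstrained(np.array([u]), 2)
        r = L[1, 0]
        log_density_r = lkj_chol_logpdf(L, 1.0) + jac - math.log1p(-r * r)
        assert log_density_r == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# spec / data containers


def test_model_spec_yaml_round_trip():
    spec = ModelSpec("3PL", hierarchical=False, gamma_fixed=0.125,
                     sigma_theta_fixed=1.0)
    again = ModelSpec.from_yaml(spec.to_yaml())
    assert again == spec


def test_model_spec_free_classes_reduction_chain():
    assert ModelSpec("1PL").free_classes == ("beta",)
    assert ModelSpec("2PL").free_classes == ("beta", "logalpha")
    assert ModelSpec("3PL").free_classes == ("beta", "logalpha", "logitgamma")
    assert ModelSpec("3PL", gamma_fixed=0.125).free_classes == ("beta", "logalpha")
    assert ModelSpec("4PL").free_classes == (
        "beta", "logalpha", "logitgamma", "logitpsi",
    )
    fixed = ModelSpec("2PL").fixed_natural(3)
    assert np.all(fixed["gamma"] == 0) and np.all(fixed["psi"] == 0)


def test_response_data_validation():
    with pytest.raises(ValueError):  # duplicate pair
        ResponseData(person=np.array([0, 0]), item=np.array([0, 0]),
                     y=np.array([1, 0]), n_persons=1, n_items=1)
    with pytest.raises(ValueError):  # non-binary
        ResponseData(person=np.array([0]), item=np.array([0]), y=np.array([2]),
                     n_persons=1, n_items=1)
    with pytest.raises(ValueError):  # non-dense person index
        ResponseData(person=np.array([0, 0]), item=np.array([0, 1]),
                     y=np.array([1, 0]), n_persons=2, n_items=2)
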