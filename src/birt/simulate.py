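"""Synthetic binary IRT data with known ground truth.

The generator mirrors the statistical structure the analysis assumes:
item parameters drawn on their unconstrained scales from a correlated
multivariate normal around configurable class means, abilities drawn from
``normal(0, sigma_theta)``, and responses drawn cell-wise from the 4PL
response probability.  A fixed 499-person x 12-item 3PL fixture with
increasing item difficulty and modest guessing emulates the shape of a
hard progressive-matrices short form and anchors the end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from .model import (
    MODEL_CLASSES,
    ModelSpec,
    ParameterState,
    ResponseData,
    state_from_eta,
    success_probability,
)

__all__ = [
    "GeneratorConfig",
    "draw_parameters",
    "simulate_responses",
    "simulate_dataset",
    "spm_ls_like_fixture",
    "marginal_correct_rates",
]


def _default_means() -> dict[str, float]:
    # median slope exp(0.4) ~ 1.5: a well-discriminating ability test;
    # median guessing logistic(-2.2) ~ 0.10; lapses rare
    return {"beta": 0.0, "logalpha": 0.4, "logitgamma": -2.2, "logitpsi": -4.0}


def _default_sds() -> dict[str, float]:
    return {"beta": 1.0, "logalpha": 0.3, "logitgamma": 0.3, "logitpsi": 0.3}


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration for one synthetic dataset.

    ``means``/``sds`` parameterize the item hyperdistribution per
    unconstrained class; ``omega`` is the between-class correlation matrix
    over the classes free in ``model_class`` (identity when omitted).
    """

    n_persons: int
    n_items: int
    model_class: str = "2PL"
    sigma_theta: float = 1.0
    means: Mapping[str, float] = field(default_factory=_default_means)
    sds: Mapping[str, float] = field(default_factory=_default_sds)
    omega: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_items < 1:
            raise ValueError("n_persons and n_items must be >= 1")
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
        if not self.sigma_theta > 0:
            raise ValueError("sigma_theta must be strictly positive")
        if self.omega is not None:
            om = np.asarray(self.omega, dtype=float)
            C = len(self.spec.free_classes)
            if om.shape != (C, C):
                raise ValueError("omega misaligned with the model's free classes")
            if not np.allclose(om, om.T) or not np.allclose(np.diag(om), 1.0):
                raise ValueError("omega must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(om).min() < -1e-10:
                raise ValueError("omega must be positive semi-definite")

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(model_class=self.model_class, hierarchical=True)


def draw_parameters(config: GeneratorConfig, rng: np.random.Generator | None = None) -> ParameterState:
    """Draw one ground-truth parameter state from the configured hyperpriors."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    spec = config.spec
    classes = spec.free_classes
    C = len(classes)
    means = np.array([config.means[c] for c in classes])
    sds = np.array([config.sds[c] for c in classes])
    omega = np.eye(C) if config.omega is None else np.asarray(config.omega, dtype=float)
    # allow semi-definite omega (e.g. perfectly correlated classes)
    w, V = np.linalg.eigh(omega)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((config.n_items, C))
    eta = means + (z @ L.T) * sds
    theta = config.sigma_theta * rng.standard_normal(config.n_persons)
    L_chol = np.linalg.cholesky(omega + 1e-12 * np.eye(C)) if C else np.empty((0, 0))
    return state_from_eta(
        eta, spec, theta, config.sigma_theta, b_bar=means, sigma=sds, omega_chol=L_chol
    )


def simulate_responses(
    state: ParameterState, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> ResponseData:
    """Draw one complete persons x items Bernoulli response matrix."""
    if state.n_items != config.n_items or state.n_persons != config.n_persons:
        raise ValueError("state dimensions do not match the generator config")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    p = success_probability(
        state.beta[None, :],
        state.alpha[None, :],
        state.gamma[None, :],
        state.psi[None, :],
        state.theta[:, None],
    )
    Y = (rng.random((config.n_persons, config.n_items)) < p).astype(np.int8)
    return ResponseData.from_matrix(Y)


def simulate_dataset(config: GeneratorConfig) -> tuple[ResponseData, ParameterState]:
    """Parameters plus responses from a single seeded stream."""
    rng = np.random.default_rng(config.seed)
    state = draw_parameters(config, rng)
    data = simulate_responses(state, config, rng)
    return data, state


def spm_ls_like_fixture(seed: int = 0) -> tuple[ResponseData, ParameterState, GeneratorConfig]:
    """A 499 x 12 3PL dataset shaped like a hard matrix-reasoning short form.

    Truth (recorded here as the fixture's metadata): easiness declining
    linearly from +1.5 to -3.0 across the 12 items, so the hardest items sit
    near the guessing floor for most of the ability range (the defining
    feature of a hardest-block short form); slopes log-normal around
    log-alpha 0.25 (sd 0.25), guessing around 0.10 (logit -2.2, sd 0.3), no
    lapses, abilities standard normal.  Responses are Bernoulli draws under
    the 4PL response function.
    """
    rng = np.random.default_rng(seed)
    J, I = 499, 12
    beta = np.linspace(1.5, -3.0, I)
    alpha = np.exp(0.25 + 0.25 * rng.standard_normal(I))
    gamma = expit(-2.2 + 0.3 * rng.standard_normal(I))
    psi = np.zeros(I)
    theta = rng.standard_normal(J)
    state = ParameterState(beta=beta, alpha=alpha, gamma=gamma, psi=psi, theta=theta, sigma_theta=1.0)
    config = GeneratorConfig(n_persons=J, n_items=I, model_class="3PL", seed=seed)
    p = success_probability(
        beta[None, :], alpha[None, :], gamma[None, :], psi[None, :], theta[:, None]
    )
    Y = (rng.random((J, I)) < p).astype(np.int8)
    return ResponseData.from_matrix(Y), state, config


def marginal_correct_rates(state: ParameterState, n_quad: int = 61) -> np.ndarray:
    """Item-wise P(correct) with ability integrated out by Gauss-Hermite."""
    x, w = hermgauss(n_quad)
    theta_q = np.sqrt(2.0) * state.sigma_theta * x
    wq = w / np.sqrt(np.pi)
    p = success_probability(
        state.beta[:, None],
        state.alpha[:, None],
        state.gamma[:, None],
        state.psi[:, None],
        theta_q[None, :],
    )
    return p @ wq
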