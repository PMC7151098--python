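"""Core probability model for binary item response data.

This module houses the four-parameter logistic (4PL) response function and
its nested reductions (3PL, 2PL, 1PL/Rasch), the Bernoulli log-likelihood,
weakly-informative priors under both non-hierarchical and hierarchical
(correlated item-parameter) regimes, and the joint unnormalized
log-posterior shared by every estimation route.

Model
-----
For person ``j`` with ability ``theta_j`` and item ``i`` with easiness
``beta_i``, slope ``alpha_i > 0``, guessing probability ``gamma_i`` and
lapse probability ``psi_i``, a correct response has probability

    P(y_ji = 1) = gamma_i + (1 - gamma_i - psi_i) * logistic(beta_i + alpha_i * theta_j)

The 3PL fixes ``psi = 0``, the 2PL additionally ``gamma = 0`` and the 1PL
additionally ``alpha = 1``.  Item parameters live on unconstrained scales
(``beta``, ``log alpha``, ``logit gamma``, ``logit psi``) where normal
priors apply; abilities follow ``theta_j ~ normal(0, sigma_theta)`` with no
overall person intercept (the item locations absorb it).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.linalg import solve_triangular
from scipy.special import expit, logit as _logit

__all__ = [
    "MODEL_CLASSES",
    "PARAM_CLASSES",
    "ResponseData",
    "PriorConfig",
    "ModelSpec",
    "ParameterState",
    "logistic",
    "success_probability",
    "response_logprob",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "reduce_model",
    "natural_to_unconstrained",
    "unconstrained_to_natural",
    "corr_chol_from_unconstrained",
    "unconstrained_from_corr_chol",
    "lkj_chol_logpdf",
]

MODEL_CLASSES = ("1PL", "2PL", "3PL", "4PL")
PARAM_CLASSES = ("beta", "logalpha", "logitgamma", "logitpsi")

_LOG_2PI = math.log(2.0 * math.pi)
_LOG_HALFNORM = 0.5 * math.log(2.0 / math.pi)


# ---------------------------------------------------------------------------
# response data


@dataclass(frozen=True)
class ResponseData:
    """Long-format binary responses with dense person/item indices.

    One record per observation: ``person[n]`` in ``[0, n_persons)``,
    ``item[n]`` in ``[0, n_items)`` and ``y[n]`` in ``{0, 1}``.  Every
    (person, item) pair occurs at most once and every index value at least
    once.
    """

    person: np.ndarray
    item: np.ndarray
    y: np.ndarray
    n_persons: int
    n_items: int

    def __post_init__(self) -> None:
        person = np.ascontiguousarray(self.person, dtype=np.int64)
        item = np.ascontiguousarray(self.item, dtype=np.int64)
        y = np.ascontiguousarray(self.y, dtype=np.int8)
        object.__setattr__(self, "person", person)
        object.__setattr__(self, "item", item)
        object.__setattr__(self, "y", y)
        if not (person.shape == item.shape == y.shape) or person.ndim != 1:
            raise ValueError("person, item and y must be 1-D arrays of equal length")
        if person.size == 0:
            raise ValueError("response data must contain at least one observation")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be exactly 0 or 1")
        if person.min() < 0 or person.max() >= self.n_persons:
            raise ValueError("person index out of range")
        if item.min() < 0 or item.max() >= self.n_items:
            raise ValueError("item index out of range")
        code = person * self.n_items + item
        if np.unique(code).size != code.size:
            raise ValueError("duplicate (person, item) observations")
        if np.unique(person).size != self.n_persons:
            raise ValueError("person indices are not dense in [0, n_persons)")
        if np.unique(item).size != self.n_items:
            raise ValueError("item indices are not dense in [0, n_items)")

    @property
    def n_obs(self) -> int:
        return int(self.person.size)

    @classmethod
    def from_matrix(cls, responses: np.ndarray) -> "ResponseData":
        """Build from a complete persons x items 0/1 matrix."""
        Y = np.asarray(responses)
        J, I = Y.shape
        person, item = np.divmod(np.arange(J * I), I)
        return cls(person=person, item=item, y=Y.reshape(-1), n_persons=J, n_items=I)

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (persons x items response matrix, observed mask)."""
        Y = np.zeros((self.n_persons, self.n_items), dtype=np.int8)
        mask = np.zeros((self.n_persons, self.n_items), dtype=bool)
        Y[self.person, self.item] = self.y
        mask[self.person, self.item] = True
        return Y, mask

    @property
    def complete(self) -> bool:
        return self.n_obs == self.n_persons * self.n_items


# ---------------------------------------------------------------------------
# model specification


def _default_locs() -> dict[str, float]:
    # Weakly-informative class-wise prior locations: guessing centered near
    # logistic(-2) ~ 0.12 (close to the 1/8 uniform-choice value for an
    # 8-alternative item) and lapses a-priori rare.
    return {"beta": 0.0, "logalpha": 0.0, "logitgamma": -2.0, "logitpsi": -4.0}


def _default_scales() -> dict[str, float]:
    return {"beta": 3.0, "logalpha": 1.0, "logitgamma": 1.0, "logitpsi": 1.0}


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the weakly-informative priors.

    ``loc``/``scale`` give the normal prior per unconstrained item-parameter
    class.  Under the non-hierarchical regime they apply to each item's
    parameter directly; under the hierarchical regime they apply to the
    overall (mean) parameter ``b_bar`` of the class, with half-normal(0,
    ``sigma_scale``) priors on the between-item standard deviations, an LKJ
    prior (shape ``lkj_eta``) on the item-parameter correlation matrix, and
    half-normal(0, ``sigma_theta_scale``) on the ability scale.
    ``flat=True`` removes every prior term (used for definitional checks and
    the maximum-likelihood route).
    """

    loc: Mapping[str, float] = field(default_factory=_default_locs)
    scale: Mapping[str, float] = field(default_factory=_default_scales)
    sigma_scale: float = 1.0
    sigma_theta_scale: float = 1.0
    lkj_eta: float = 1.0
    flat: bool = False

    def __post_init__(self) -> None:
        for c in PARAM_CLASSES:
            if c not in self.loc or c not in self.scale:
                raise ValueError(f"prior loc/scale missing for class {c!r}")
            if not self.scale[c] > 0:
                raise ValueError("prior scales must be strictly positive")
        if not (self.sigma_scale > 0 and self.sigma_theta_scale > 0):
            raise ValueError("prior scales must be strictly positive")
        if not self.lkj_eta > 0:
            raise ValueError("lkj_eta must be strictly positive")

    @classmethod
    def flat_prior(cls) -> "PriorConfig":
        return cls(flat=True)

    def to_dict(self) -> dict:
        return {
            "loc": dict(self.loc),
            "scale": dict(self.scale),
            "sigma_scale": self.sigma_scale,
            "sigma_theta_scale": self.sigma_theta_scale,
            "lkj_eta": self.lkj_eta,
            "flat": self.flat,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorConfig":
        return cls(**{k: dict(v) if isinstance(v, Mapping) else v for k, v in d.items()})


@dataclass(frozen=True)
class ModelSpec:
    """Which model of the 1PL-4PL family to fit, and under which priors."""

    model_class: str
    hierarchical: bool = True
    gamma_fixed: float | None = None
    sigma_theta_fixed: float | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
        if self.gamma_fixed is not None:
            if self.model_class in ("1PL", "2PL"):
                raise ValueError("gamma_fixed only applies to 3PL/4PL models")
            if not (0.0 <= self.gamma_fixed <= 1.0):
                raise ValueError("gamma_fixed must lie in [0, 1]")
        if self.sigma_theta_fixed is not None and not self.sigma_theta_fixed > 0:
            raise ValueError("sigma_theta_fixed must be strictly positive")

    @property
    def free_classes(self) -> tuple[str, ...]:
        classes = ["beta"]
        if self.model_class in ("2PL", "3PL", "4PL"):
            classes.append("logalpha")
        if self.model_class in ("3PL", "4PL") and self.gamma_fixed is None:
            classes.append("logitgamma")
        if self.model_class == "4PL":
            classes.append("logitpsi")
        return tuple(classes)

    @property
    def n_free_classes(self) -> int:
        return len(self.free_classes)

    def fixed_natural(self, n_items: int) -> dict[str, np.ndarray]:
        """Natural-scale values of the item-parameter classes fixed by the spec."""
        out: dict[str, np.ndarray] = {}
        if self.model_class == "1PL":
            out["alpha"] = np.ones(n_items)
        if self.model_class in ("1PL", "2PL"):
            out["gamma"] = np.zeros(n_items)
        elif self.gamma_fixed is not None:
            out["gamma"] = np.full(n_items, float(self.gamma_fixed))
        if self.model_class != "4PL":
            out["psi"] = np.zeros(n_items)
        return out

    # -- plain-text round-trippable serialization ---------------------------

    def to_dict(self) -> dict:
        return {
            "model_class": self.model_class,
            "hierarchical": self.hierarchical,
            "gamma_fixed": self.gamma_fixed,
            "sigma_theta_fixed": self.sigma_theta_fixed,
            "priors": self.priors.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        if "priors" in d and d["priors"] is not None:
            d["priors"] = PriorConfig.from_dict(d["priors"])
        else:
            d.pop("priors", None)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


# ---------------------------------------------------------------------------
# parameter state


@dataclass
class ParameterState:
    """One full set of item and person parameters on the natural scale.

    The hierarchical block (``b_bar``, ``sigma``, ``omega_chol``) is aligned
    with ``spec.free_classes`` and present only under the hierarchical prior
    regime; the item deviations are recoverable as ``eta - b_bar``.
    """

    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    sigma_theta: float = 1.0
    b_bar: np.ndarray | None = None
    sigma: np.ndarray | None = None
    omega_chol: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "gamma", "psi", "theta"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        I = self.beta.size
        if not (self.alpha.size == self.gamma.size == self.psi.size == I):
            raise ValueError("item parameter arrays must share one length")

    @property
    def n_items(self) -> int:
        return int(self.beta.size)

    @property
    def n_persons(self) -> int:
        return int(self.theta.size)

    def validate(self) -> None:
        arrays = (self.beta, self.alpha, self.gamma, self.psi, self.theta)
        if any(np.isnan(a).any() for a in arrays):
            raise ValueError("NaN in parameter state")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be strictly positive")
        if np.any((self.gamma < 0) | (self.gamma > 1) | (self.psi < 0) | (self.psi > 1)):
            raise ValueError("gamma and psi must lie in [0, 1]")
        if np.any(self.gamma + self.psi > 1.0 + 1e-12):
            raise ValueError("gamma + psi must not exceed 1")
        if not self.sigma_theta > 0:
            raise ValueError("sigma_theta must be strictly positive")

    def eta_matrix(self, classes: Sequence[str]) -> np.ndarray:
        """Unconstrained item parameters, one column per requested class."""
        cols = [natural_to_unconstrained(c, self._natural_of(c)) for c in classes]
        return np.column_stack(cols) if cols else np.empty((self.n_items, 0))

    def _natural_of(self, cls_name: str) -> np.ndarray:
        return {
            "beta": self.beta,
            "logalpha": self.alpha,
            "logitgamma": self.gamma,
            "logitpsi": self.psi,
        }[cls_name]


def natural_to_unconstrained(cls_name: str, value: np.ndarray) -> np.ndarray:
    """Map a natural-scale item-parameter class onto the real line."""
    value = np.asarray(value, dtype=float)
    if cls_name == "beta":
        return value.copy()
    if cls_name == "logalpha":
        return np.log(value)
    if cls_name in ("logitgamma", "logitpsi"):
        return _logit(value)
    raise ValueError(f"unknown parameter class {cls_name!r}")


def unconstrained_to_natural(cls_name: str, eta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`natural_to_unconstrained`."""
    eta = np.asarray(eta, dtype=float)
    if cls_name == "beta":
        return eta.copy()
    if cls_name == "logalpha":
        return np.exp(eta)
    if cls_name in ("logitgamma", "logitpsi"):
        return expit(eta)
    raise ValueError(f"unknown parameter class {cls_name!r}")


def state_from_eta(
    eta: np.ndarray,
    spec: ModelSpec,
    theta: np.ndarray,
    sigma_theta: float,
    b_bar: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    omega_chol: np.ndarray | None = None,
) -> ParameterState:
    """Assemble a natural-scale state from free unconstrained item columns."""
    classes = spec.free_classes
    n_items = eta.shape[0]
    nat = {k: v for k, v in spec.fixed_natural(n_items).items()}
    name_of = {"beta": "beta", "logalpha": "alpha", "logitgamma": "gamma", "logitpsi": "psi"}
    for k, c in enumerate(classes):
        nat[name_of[c]] = unconstrained_to_natural(c, eta[:, k])
    return ParameterState(
        beta=nat["beta"],
        alpha=nat["alpha"],
        gamma=nat["gamma"],
        psi=nat["psi"],
        theta=np.asarray(theta, dtype=float),
        sigma_theta=float(sigma_theta),
        b_bar=None if b_bar is None else np.asarray(b_bar, dtype=float),
        sigma=None if sigma is None else np.asarray(sigma, dtype=float),
        omega_chol=None if omega_chol is None else np.asarray(omega_chol, dtype=float),
    )


# ---------------------------------------------------------------------------
# response function


def logistic(x):
    """Numerically stable standard logistic function 1 / (1 + exp(-x))."""
    arr = np.asarray(x)
    if arr.dtype.kind not in "fiub":
        raise TypeError("logistic expects numeric input")
    out = expit(arr.astype(float, copy=False))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out

def success_probability(beta, alpha, gamma, psi, theta):
    """4PL probability of a correct response (broadcasting elementwise).

    ``gamma + (1 - gamma - psi) * logistic(beta + alpha * theta)``; lies in
    ``[gamma, 1 - psi]`` and is strictly increasing in ``theta`` for
    ``alpha > 0`` and ``gamma + psi < 1``.
    """
    beta, alpha, gamma, psi, theta = map(np.asarray, (beta, alpha, gamma, psi, theta))
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    if np.any(gamma + psi > 1.0 + 1e-12):
        raise ValueError("gamma + psi must not exceed 1")
    p = gamma + (1.0 - gamma - psi) * expit(beta + alpha * theta)
    return float(p) if p.ndim == 0 else p


def response_logprob(beta, alpha, gamma, psi, theta):
    """Stable ``(log P(y=1), log P(y=0))`` under the 4PL, elementwise.

    Works in the log domain throughout: with ``x = beta + alpha * theta``,
    ``log P(y=1) = logaddexp(log gamma, log(1-gamma-psi) + log logistic(x))``
    and symmetrically for ``log P(y=0)`` with ``psi`` and ``-x``.  This
    avoids forming ``p`` and logging it, which underflows for extreme
    abilities when ``gamma`` or ``psi`` is zero.
    """
    x = np.asarray(beta) + np.asarray(alpha) * np.asarray(theta)
    log_sig = -np.logaddexp(0.0, -x)      # log logistic(x)
    log_sig_neg = log_sig - x             # log logistic(-x) = log logistic(x) - x
    gamma = np.asarray(gamma, dtype=float)
    psi = np.asarray(psi, dtype=float)
    with np.errstate(divide="ignore"):
        log_gamma = np.log(gamma)
        log_psi = np.log(psi)
        log_mid = np.log1p(-(gamma + psi))
    lp1 = np.logaddexp(log_gamma, log_mid + log_sig)
    lp0 = np.logaddexp(log_psi, log_mid + log_sig_neg)
    return lp1, lp0


# ---------------------------------------------------------------------------
# likelihood / prior / posterior


@dataclass(frozen=True)
class LogLikResult:
    total: float
    pointwise: np.ndarray


def log_likelihood(data: ResponseData, state: ParameterState) -> LogLikResult:
    """Bernoulli log-likelihood: total and the pointwise vector (length N).

    The total is the plain left-to-right sum of the pointwise vector.
    Observations that are impossible under the state (p exactly 0 or 1 on
    the wrong side) contribute ``-inf`` without raising.
    """
    state.validate()
    if state.n_items < data.n_items or state.n_persons < data.n_persons:
        raise ValueError("state dimensions do not cover the data")
    lp1, lp0 = response_logprob(
        state.beta[data.item],
        state.alpha[data.item],
        state.gamma[data.item],
        state.psi[data.item],
        state.theta[data.person],
    )
    pointwise = np.where(data.y == 1, lp1, lp0)
    return LogLikResult(total=float(np.sum(pointwise)), pointwise=pointwise)


def _normal_lp(x, loc, scale):
    """Normal log-density; identically zero when scale is infinite (flat)."""
    x = np.asarray(x, dtype=float)
    scale = np.asarray(scale, dtype=float)
    z = np.where(np.isinf(scale), 0.0, (x - loc) / np.where(np.isinf(scale), 1.0, scale))
    out = np.where(
        np.isinf(scale), 0.0, -0.5 * _LOG_2PI - np.log(scale) - 0.5 * z * z
    )
    return out if out.ndim else float(out)


def _halfnormal_lp(x: float, scale: float) -> float:
    """Half-normal log-density on x > 0; zero when scale is infinite."""
    if x <= 0:
        raise ValueError("half-normal variate must be strictly positive")
    if np.isinf(scale):
        return 0.0
    return _LOG_HALFNORM - math.log(scale) - 0.5 * (x / scale) ** 2


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior density of a state under the spec's regime.

    All normalizing constants of the component densities are included, so
    optimization and sampling target literally the same function.  Under
    ``spec.priors.flat`` every term vanishes.
    """
    state.validate()
    priors = spec.priors
    if priors.flat:
        return 0.0
    classes = spec.free_classes
    eta = state.eta_matrix(classes)
    total = 0.0
    # person block
    total += float(np.sum(_normal_lp(state.theta, 0.0, state.sigma_theta)))
    if spec.sigma_theta_fixed is None:
        total += _halfnormal_lp(state.sigma_theta, priors.sigma_theta_scale)
    locs = np.array([priors.loc[c] for c in classes])
    scales = np.array([priors.scale[c] for c in classes])
    if not spec.hierarchical:
        for k in range(len(classes)):
            total += float(np.sum(_normal_lp(eta[:, k], locs[k], scales[k])))
        return total
    # hierarchical block
    if state.b_bar is None or state.sigma is None:
        raise ValueError("hierarchical prior requires b_bar and sigma in the state")
    C = len(classes)
    if state.b_bar.size != C or state.sigma.size != C:
        raise ValueError("hierarchical block misaligned with the free classes")
    if np.any(state.sigma <= 0):
        raise ValueError("hierarchical sigma must be strictly positive")
    L_omega = np.eye(C) if state.omega_chol is None else state.omega_chol
    if L_omega.shape != (C, C):
        raise ValueError("omega_chol misaligned with the free classes")
    btilde = eta - state.b_bar
    L_cov = state.sigma[:, None] * L_omega
    q = solve_triangular(L_cov, btilde.T, lower=True)
    total += float(
        -0.5 * np.sum(q * q)
        - state.n_items * (np.sum(np.log(np.diag(L_cov))) + 0.5 * C * _LOG_2PI)
    )
    total += float(np.sum(_normal_lp(state.b_bar, locs, scales)))
    for s in state.sigma:
        total += _halfnormal_lp(float(s), priors.sigma_scale)
    if C >= 2:
        total += lkj_chol_logpdf(L_omega, priors.lkj_eta)
    return total


def log_posterior(data: ResponseData, state: ParameterState, spec: ModelSpec) -> float:
    """Unnormalized log posterior: log-likelihood plus log prior."""
    return log_likelihood(data, state).total + log_prior(state, spec)


def reduce_model(state: ParameterState, target_class: str) -> ParameterState:
    """Project a state onto a simpler nested model class.

    Fixes ``psi = 0`` below the 4PL, additionally ``gamma = 0`` below the
    3PL and ``alpha = 1`` for the 1PL; the hierarchical block is dropped
    because its class alignment no longer applies.
    """
    if target_class not in MODEL_CLASSES:
        raise ValueError(f"target_class must be one of {MODEL_CLASSES}")
    new = replace(state, b_bar=None, sigma=None, omega_chol=None)
    new.psi = np.zeros_like(state.psi)
    if target_class in ("1PL", "2PL"):
        new.gamma = np.zeros_like(state.gamma)
    else:
        new.gamma = state.gamma.copy()
    new.alpha = np.ones_like(state.alpha) if target_class == "1PL" else state.alpha.copy()
    return new


# ---------------------------------------------------------------------------
# correlation matrices (unconstrained Cholesky parameterization + LKJ prior)


def corr_chol_from_unconstrained(u: np.ndarray, dim: int) -> tuple[np.ndarray, float]:
    """Map a free vector of length dim*(dim-1)/2 to a correlation Cholesky.

    Row-wise stick-breaking through canonical partial correlations
    ``tanh(u)``; also returns the log-Jacobian of the map, needed when
    sampling the correlation matrix on the unconstrained scale.
    """
    u = np.asarray(u, dtype=float)
    if u.size != dim * (dim - 1) // 2:
        raise ValueError("wrong number of unconstrained correlation parameters")
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    log_jac = 0.0
    idx = 0
    for i in range(1, dim):
        row_sq = 0.0
        for j in range(i):
            cpc = math.tanh(u[idx])
            idx += 1
            mult = math.sqrt(max(1.0 - row_sq, 0.0))
            L[i, j] = cpc * mult
            log_jac += math.log1p(-cpc * cpc) + 0.5 * math.log(max(1.0 - row_sq, 1e-300))
            row_sq += L[i, j] ** 2
        L[i, i] = math.sqrt(max(1.0 - row_sq, 0.0))
    return L, log_jac


def unconstrained_from_corr_chol(L: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_chol_from_unconstrained` (free vector)."""
    L = np.asarray(L, dtype=float)
    dim = L.shape[0]
    u = []
    for i in range(1, dim):
        row_sq = 0.0
        for j in range(i):
            mult = math.sqrt(max(1.0 - row_sq, 1e-300))
            cpc = L[i, j] / mult
            u.append(math.atanh(np.clip(cpc, -1 + 1e-15, 1 - 1e-15)))
            row_sq += L[i, j] ** 2
    return np.asarray(u)


def lkj_chol_logpdf(L: np.ndarray, eta: float) -> float:
    """LKJ log density over correlation Cholesky factors (unnormalized).

    ``sum_k (dim - k - 1 + 2*(eta - 1)) * log L_kk`` over rows ``k >= 1``
    (zero-based); ``eta = 1`` is uniform over valid correlation matrices.
    The eta-dependent normalizing constant is omitted (fixed across states).
    """
    L = np.asarray(L, dtype=float)
    dim = L.shape[0]
    diag = np.diag(L)[1:]
    coeff = dim - np.arange(1, dim) - 1.0 + 2.0 * (eta - 1.0)
    with np.errstate(divide="ignore"):
        return float(np.sum(coeff * np.log(diag)))
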