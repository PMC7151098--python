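"""Fitting routines: MCMC sampling, MAP/ML estimation via EM, diagnostics.

Four estimation routes share one probability model (:mod:`birt.model`):

* ``mcmc_sample`` with a hierarchical spec (MCMC-H) samples the full
  posterior including item hyperparameters and their correlation matrix,
  using the non-centered parameterization of the item deviations.
* ``mcmc_sample`` with a non-hierarchical spec (MCMC-NH) samples item
  parameters under fixed weakly-informative normal priors.
* ``map_fit`` maximizes the ability-marginalized penalized log-likelihood
  (expectation-maximization with fixed-point Gauss-Hermite quadrature).
* ``ml_fit`` is the same EM with all item-parameter priors removed; the
  ability distribution ``normal(0, sigma_theta)`` is retained, following
  the standard marginal maximum-likelihood convention.

The MCMC kernel is adaptive Metropolis-within-Gibbs: persons are updated
jointly in one vectorized step (they are conditionally independent given
the items), item rows likewise, and hyperparameters with scalar
random-walk steps.  Proposal scales adapt only during warmup, so the
post-warmup chain is a fixed Markov kernel with the correct invariant
distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import solve_triangular
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logit as _logit

from .model import (
    ModelSpec,
    ParameterState,
    ResponseData,
    _halfnormal_lp,
    _normal_lp,
    corr_chol_from_unconstrained,
    lkj_chol_logpdf,
    response_logprob,
    unconstrained_to_natural,
)

__all__ = [
    "PosteriorDraws",
    "PointEstimate",
    "mcmc_sample",
    "map_fit",
    "ml_fit",
    "compute_rhat",
    "compute_ess",
    "mcse_mean",
]

_NAT_OF = {"beta": "beta", "logalpha": "alpha", "logitgamma": "gamma", "logitpsi": "psi"}


# ---------------------------------------------------------------------------
# posterior draws container


@dataclass
class PosteriorDraws:
    """Natural-scale posterior draws, shaped (chain, draw, ...)."""

    spec: ModelSpec
    n_persons: int
    n_items: int
    params: dict[str, np.ndarray]
    seed: int | None = None
    n_warmup: int = 0
    converged: bool = True
    max_rhat: float = math.nan
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape[:2] for v in self.params.values()}
        if len(shapes) != 1:
            raise ValueError("all parameter arrays must share (chain, draw) shape")
        (nc, nd) = shapes.pop()
        if nc < 2:
            raise ValueError("at least two chains are required")
        self._nc, self._nd = nc, nd

    @property
    def n_chains(self) -> int:
        return self._nc

    @property
    def n_draws(self) -> int:
        return self._nd

    @property
    def n_total(self) -> int:
        return self._nc * self._nd

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened: (chain*draw, ...)."""
        arr = self.params[name]
        return arr.reshape((self.n_total,) + arr.shape[2:])

    def state_at(self, s: int) -> ParameterState:
        """Natural-scale ParameterState of flattened draw ``s``."""
        g = lambda name: self.stacked(name)[s]
        return ParameterState(
            beta=g("beta"), alpha=g("alpha"), gamma=g("gamma"), psi=g("psi"),
            theta=g("theta"), sigma_theta=float(self.stacked("sigma_theta")[s]),
        )

    def theta_mean(self) -> np.ndarray:
        return self.stacked("theta").mean(axis=0)

    def _scalar_views(self) -> dict[str, np.ndarray]:
        """Expand stored arrays into named scalar chains (chain, draw)."""
        out: dict[str, np.ndarray] = {}
        classes = self.spec.free_classes
        for c in classes:
            nat = _NAT_OF[c]
            for i in range(self.n_items):
                out[f"{nat}[{i}]"] = self.params[nat][:, :, i]
        for j in range(self.n_persons):
            out[f"theta[{j}]"] = self.params["theta"][:, :, j]
        if self.spec.sigma_theta_fixed is None:
            out["sigma_theta"] = self.params["sigma_theta"]
        if self.spec.hierarchical:
            for k, c in enumerate(classes):
                out[f"b_bar[{c}]"] = self.params["b_bar"][:, :, k]
                out[f"sigma[{c}]"] = self.params["sigma"][:, :, k]
            C = len(classes)
            for a in range(C):
                for b in range(a + 1, C):
                    out[f"omega[{a},{b}]"] = self.params["omega"][:, :, a, b]
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central 95% interval, R-hat and bulk ESS."""
        views = self._scalar_views()
        rhat = compute_rhat(self)
        ess = compute_ess(self)
        rows = []
        for name, arr in views.items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": rhat.get(name, math.nan),
                    "ess_bulk": ess.get(name, math.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- tidy persistence ---------------------------------------------------

    def to_tidy(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        views = self._scalar_views()
        nc, nd = self.n_chains, self.n_draws
        chain = np.repeat(np.arange(nc), nd)
        iteration = np.tile(np.arange(nd), nc)
        frames = [
            pd.DataFrame(
                {"chain": chain, "iteration": iteration, "parameter": name,
                 "value": arr.reshape(-1)}
            )
            for name, arr in views.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_tidy().to_csv(directory / "draws.csv", index=False)
        meta = {
            "spec": self.spec.to_dict(),
            "n_persons": self.n_persons,
            "n_items": self.n_items,
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "n_warmup": self.n_warmup,
            "seed": self.seed,
            "converged": bool(self.converged),
            "max_rhat": float(self.max_rhat),
        }
        (directory / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "meta.yaml").read_text())
        spec = ModelSpec.from_dict(meta["spec"])
        tidy = pd.read_csv(directory / "draws.csv")
        nc, nd = meta["n_chains"], meta["n_draws"]
        I, J = meta["n_items"], meta["n_persons"]
        classes = spec.free_classes
        C = len(classes)
        wide = tidy.pivot_table(
            index=["chain", "iteration"], columns="parameter", values="value", sort=False
        )
        def grab(name):
            return wide[name].to_numpy().reshape(nc, nd)
        params: dict[str, np.ndarray] = {}
        fixed = spec.fixed_natural(I)
        for c in ("beta", "logalpha", "logitgamma", "logitpsi"):
            nat = _NAT_OF[c]
            if c in classes:
                params[nat] = np.stack([grab(f"{nat}[{i}]") for i in range(I)], axis=-1)
            else:
                params[nat] = np.broadcast_to(fixed[nat], (nc, nd, I)).copy()
        params["theta"] = np.stack([grab(f"theta[{j}]") for j in range(J)], axis=-1)
        if spec.sigma_theta_fixed is None:
            params["sigma_theta"] = grab("sigma_theta")
        else:
            params["sigma_theta"] = np.full((nc, nd), float(spec.sigma_theta_fixed))
        if spec.hierarchical:
            params["b_bar"] = np.stack([grab(f"b_bar[{c}]") for c in classes], axis=-1)
            params["sigma"] = np.stack([grab(f"sigma[{c}]") for c in classes], axis=-1)
            omega = np.broadcast_to(np.eye(C), (nc, nd, C, C)).copy()
            for a in range(C):
                for b in range(a + 1, C):
                    omega[:, :, a, b] = omega[:, :, b, a] = grab(f"omega[{a},{b}]")
            params["omega"] = omega
        return cls(
            spec=spec, n_persons=J, n_items=I, params=params, seed=meta["seed"],
            n_warmup=meta["n_warmup"], converged=meta["converged"],
            max_rhat=meta["max_rhat"],
        )


# ---------------------------------------------------------------------------
# convergence diagnostics (delegated to arviz, with degenerate-chain guards)


def _guard_chains(x: np.ndarray) -> float | None:
    """Handle degenerate chain sets before delegating to the estimator."""
    if x.ndim != 2:
        raise ValueError("expected an array shaped (chain, draw)")
    if x.shape[0] < 2:
        raise ValueError("at least two chains are required")
    within = x.var(axis=1)
    if np.all(within == 0.0):
        if np.all(x == x.flat[0]):
            warnings.warn("constant chains: R-hat undefined", RuntimeWarning)
            return math.nan
        return math.inf
    return None


def _rhat_array(x: np.ndarray) -> float:
    guard = _guard_chains(np.asarray(x, dtype=float))
    if guard is not None:
        return guard
    return float(az.rhat(np.asarray(x, dtype=float)))


def _ess_array(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    guard = _guard_chains(x)
    if guard is not None:
        return 0.0 if math.isinf(guard) else math.nan
    # cap at the total draw count: correlated chains cannot carry more
    # information than independent ones
    return float(min(az.ess(x), x.size))


def _diag_dataset(draws: "PosteriorDraws") -> dict[str, np.ndarray]:
    """Stored free-parameter arrays keyed for one batched arviz call."""
    post: dict[str, np.ndarray] = {}
    classes = draws.spec.free_classes
    for c in classes:
        post[_NAT_OF[c]] = draws.params[_NAT_OF[c]]
    post["theta"] = draws.params["theta"]
    if draws.spec.sigma_theta_fixed is None:
        post["sigma_theta"] = draws.params["sigma_theta"]
    if draws.spec.hierarchical and "b_bar" in draws.params:
        post["b_bar"] = draws.params["b_bar"]
        post["sigma"] = draws.params["sigma"]
        C = len(classes)
        pairs = [(a, b) for a in range(C) for b in range(a + 1, C)]
        if pairs:
            post["omega_offdiag"] = np.stack(
                [draws.params["omega"][:, :, a, b] for a, b in pairs], axis=-1
            )
    return post


def _expand_diag(draws: "PosteriorDraws", ds) -> pd.Series:
    classes = draws.spec.free_classes
    out: dict[str, float] = {}
    for var in ds.data_vars:
        vals = np.atleast_1d(ds[var].values)
        if var in ("b_bar", "sigma"):
            for k, c in enumerate(classes):
                out[f"{var}[{c}]"] = float(vals[k])
        elif var == "omega_offdiag":
            C = len(classes)
            pairs = [(a, b) for a in range(C) for b in range(a + 1, C)]
            for k, (a, b) in enumerate(pairs):
                out[f"omega[{a},{b}]"] = float(vals[k])
        elif vals.size == 1:
            out[var] = float(vals[0])
        else:
            for i, v in enumerate(vals):
                out[f"{var}[{i}]"] = float(v)
    return pd.Series(out)


def _apply_diag(draws: "PosteriorDraws | np.ndarray", fn) -> "pd.Series | float":
    if isinstance(draws, np.ndarray):
        return fn(draws)
    post = _diag_dataset(draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fn is _rhat_array:
            ds = az.rhat(az.from_dict(posterior=post))
        else:
            ds = az.ess(az.from_dict(posterior=post))
    series = _expand_diag(draws, ds)
    if fn is _ess_array:
        series = series.clip(upper=draws.n_total)
    return series


def compute_rhat(draws: "PosteriorDraws | np.ndarray"):
    """Rank-normalized split R-hat, per parameter (or for one 2-D array).

    Constant chains at one shared value give NaN with a warning (the
    estimator is undefined there); constant chains at different values give
    ``+inf`` (zero within-chain variance).
    """
    return _apply_diag(draws, _rhat_array)


def compute_ess(draws: "PosteriorDraws | np.ndarray"):
    """Bulk effective sample size, per parameter (or for one 2-D array)."""
    return _apply_diag(draws, _ess_array)


def mcse_mean(x: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean of one parameter."""
    x = np.asarray(x, dtype=float)
    ess = _ess_array(x)
    if not ess > 0:
        return math.inf
    return float(x.std(ddof=1) / math.sqrt(ess))


# ---------------------------------------------------------------------------
# MCMC


def _slice_step(logf, x0: float, width: float, rng: np.random.Generator,
                max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out and shrinkage)."""
    y0 = logf(x0)
    if not math.isfinite(y0):
        return x0
    y = y0 + math.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    j = int(max_steps * rng.random())
    k = max_steps - 1 - j
    while j > 0 and y < logf(lo):
        lo -= width
        j -= 1
    while k > 0 and y < logf(hi):
        hi += width
        k -= 1
    for _ in range(100):
        x1 = lo + (hi - lo) * rng.random()
        if y < logf(x1):
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def mcmc_sample(
    data: ResponseData,
    spec: ModelSpec,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int | None = None,
    fixed_item_params: ParameterState | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of the spec'd model.

    ``fixed_item_params`` conditions on known item parameters (only
    abilities, and the ability scale if free, are sampled) — used for
    oracle checks against deterministic quadrature.

    Raises on empty data or fewer than two chains; convergence failure
    (any split R-hat above 1.05) is flagged on the result and warned
    about, never silently ignored.
    """
    if data.n_obs == 0 or data.n_persons == 0 or data.n_items == 0:
        raise ValueError("cannot sample from empty response data")
    if n_chains < 2:
        raise ValueError("at least two chains are required")
    if n_draws < 4 or n_warmup < 0:
        raise ValueError("need n_draws >= 4 and n_warmup >= 0")
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(n_chains)
    stores = [
        _run_chain(data, spec, n_warmup, n_draws, np.random.default_rng(s), fixed_item_params)
        for s in chain_seeds
    ]
    params = {
        name: np.stack([st[name] for st in stores], axis=0) for name in stores[0]
    }
    draws = PosteriorDraws(
        spec=spec,
        n_persons=data.n_persons,
        n_items=data.n_items,
        params=params,
        seed=seed,
        n_warmup=n_warmup,
        meta={"n_chains": n_chains, "fixed_items": fixed_item_params is not None},
    )
    rhat = compute_rhat(draws)
    finite = rhat.dropna()
    draws.max_rhat = float(finite.max()) if len(finite) else math.nan
    draws.converged = bool(np.all(finite <= 1.05)) if len(finite) else True
    if not draws.converged:
        warnings.warn(
            f"MCMC convergence flagged: max split R-hat {draws.max_rhat:.3f} > 1.05",
            RuntimeWarning,
        )
    return draws


def _run_chain(
    data: ResponseData,
    spec: ModelSpec,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    fixed_item_params: ParameterState | None,
) -> dict[str, np.ndarray]:
    y1 = data.y == 1
    pi, ii = data.person, data.item
    J, I, N = data.n_persons, data.n_items, data.n_obs
    classes = spec.free_classes
    C = len(classes)
    priors = spec.priors
    locs = np.array([priors.loc[c] for c in classes])
    scales = np.array([priors.scale[c] for c in classes])
    fixed_nat = spec.fixed_natural(I)
    hier = spec.hierarchical and fixed_item_params is None
    sample_items = fixed_item_params is None
    est_sigma_theta = spec.sigma_theta_fixed is None
    n_corr = C * (C - 1) // 2 if hier else 0

    # --- initial values -------------------------------------------------
    rate = np.clip(np.bincount(pi, weights=data.y.astype(float), minlength=J)
                   / np.bincount(pi, minlength=J), 0.02, 0.98)
    theta = 0.5 * (rate - rate.mean()) / max(rate.std(), 1e-3) + 0.1 * rng.standard_normal(J)
    log_st = math.log(float(spec.sigma_theta_fixed)) if not est_sigma_theta else \
        0.1 * rng.standard_normal()
    item_rate = np.clip(np.bincount(ii, weights=data.y.astype(float), minlength=I)
                        / np.bincount(ii, minlength=I), 0.02, 0.98)
    overall = _logit(np.clip(data.y.mean(), 0.02, 0.98))

    def nat_from_eta(eta: np.ndarray):
        nat = dict(fixed_nat)
        for k, c in enumerate(classes):
            nat[_NAT_OF[c]] = unconstrained_to_natural(c, eta[:, k])
        return nat["beta"], nat["alpha"], nat["gamma"], nat["psi"]

    if hier:
        b_bar = locs.copy()
        b_bar[0] = overall
        b_bar += 0.05 * rng.standard_normal(C)
        log_sigma = math.log(0.5) + 0.05 * rng.standard_normal(C)
        u = 0.05 * rng.standard_normal(n_corr)
        L_om, log_jac = corr_chol_from_unconstrained(u, C)
        z = 0.1 * rng.standard_normal((I, C))
        z[:, 0] = (_logit(item_rate) - overall) / 0.5
        eta = b_bar + (z @ L_om.T) * np.exp(log_sigma)
    elif sample_items:
        eta = np.tile(locs, (I, 1)).astype(float)
        eta[:, 0] = _logit(item_rate)
        eta += 0.05 * rng.standard_normal((I, C))
    else:
        eta = np.column_stack(
            [fixed_item_params.eta_matrix([c])[:, 0] for c in classes]
        )
    beta_c, alpha_c, gamma_c, psi_c = nat_from_eta(eta)

    def obs_ll(beta, alpha, gamma, psi, th):
        # specialized per-observation Bernoulli log-likelihood: asymptote
        # terms are assembled on the item level (I values) and gathered
        x = beta[ii] + alpha[ii] * th[pi]
        log_sig = -np.logaddexp(0.0, -x)
        log_sig_neg = log_sig - x
        has_g = gamma.any()
        has_p = psi.any()
        if not has_g and not has_p:
            return np.where(y1, log_sig, log_sig_neg)
        with np.errstate(divide="ignore"):
            lmid = np.log1p(-(gamma + psi))
            lp1 = np.logaddexp(np.log(gamma)[ii], lmid[ii] + log_sig) if has_g \
                else lmid[ii] + log_sig
            lp0 = np.logaddexp(np.log(psi)[ii], lmid[ii] + log_sig_neg) if has_p \
                else lmid[ii] + log_sig_neg
        return np.where(y1, lp1, lp0)

    # --- adaptive proposal scales ---------------------------------------
    s_theta = np.full(J, 0.8)
    s_item = np.full((I, C), 0.3)
    s_row = np.full(I, 0.6)
    row_mean = np.zeros((I, C))
    row_M2 = np.zeros((I, C, C))
    row_chol = np.broadcast_to(np.eye(C) * 0.3, (I, C, C)).copy()
    n_row = 0
    s_bbar = np.full(C, 0.1)
    s_logst = 0.2
    s_scale_move = 0.2
    s_shift_move = 0.2

    store: dict[str, np.ndarray] = {
        "beta": np.empty((n_draws, I)),
        "alpha": np.empty((n_draws, I)),
        "gamma": np.empty((n_draws, I)),
        "psi": np.empty((n_draws, I)),
        "theta": np.empty((n_draws, J)),
        "sigma_theta": np.empty(n_draws),
    }
    if hier:
        store["b_bar"] = np.empty((n_draws, C))
        store["sigma"] = np.empty((n_draws, C))
        store["omega"] = np.empty((n_draws, C, C))

    total = n_warmup + n_draws
    for t in range(total):
        adapting = t < n_warmup
        lr = (t + 1.0) ** -0.55 if adapting else 0.0
        st = math.exp(log_st)

        # persons: conditionally independent joint vectorized MH
        ll_cur = obs_ll(beta_c, alpha_c, gamma_c, psi_c, theta)
        per_cur = np.bincount(pi, weights=ll_cur, minlength=J)
        prop = theta + s_theta * rng.standard_normal(J)
        ll_prop = obs_ll(beta_c, alpha_c, gamma_c, psi_c, prop)
        per_prop = np.bincount(pi, weights=ll_prop, minlength=J)
        logr = per_prop - per_cur + 0.5 * (theta**2 - prop**2) / st**2
        acc = np.log(rng.random(J)) < logr
        theta = np.where(acc, prop, theta)
        if adapting:
            s_theta *= np.exp(lr * (acc - 0.44))

        # items: conditionally independent row-wise MH, one parameter class
        # at a time so each class keeps its own adaptive step size
        cur_ll_total = None
        if sample_items:
            it_cur = np.bincount(
                ii, weights=obs_ll(beta_c, alpha_c, gamma_c, psi_c, theta), minlength=I
            )
            for k in range(C):
                if hier:
                    zp = z.copy()
                    zp[:, k] += s_item[:, k] * rng.standard_normal(I)
                    eta_p = b_bar + (zp @ L_om.T) * np.exp(log_sigma)
                    prior_diff = 0.5 * (z[:, k] ** 2 - zp[:, k] ** 2)
                else:
                    eta_p = eta.copy()
                    eta_p[:, k] += s_item[:, k] * rng.standard_normal(I)
                    prior_diff = _normal_lp(eta_p[:, k], locs[k], scales[k]) - _normal_lp(
                        eta[:, k], locs[k], scales[k]
                    )
                b_p, a_p, g_p, p_p = nat_from_eta(eta_p)
                it_prop = np.bincount(
                    ii, weights=obs_ll(b_p, a_p, g_p, p_p, theta), minlength=I
                )
                acc = np.log(rng.random(I)) < it_prop - it_cur + prior_diff
                if hier:
                    z[acc, k] = zp[acc, k]
                    eta = b_bar + (z @ L_om.T) * np.exp(log_sigma)
                else:
                    eta[acc, k] = eta_p[acc, k]
                beta_c, alpha_c, gamma_c, psi_c = nat_from_eta(eta)
                it_cur = np.where(acc, it_prop, it_cur)
                if adapting:
                    s_item[:, k] *= np.exp(lr * (acc - 0.44))
            if C >= 2:
                # one joint row proposal on top of the class-wise sweeps,
                # preconditioned by the per-item covariance accumulated over
                # warmup, to follow correlated within-item directions (e.g.
                # the easiness-guessing ridge of hard items)
                x_row = z if hier else eta
                if adapting:
                    n_row += 1
                    d1 = x_row - row_mean
                    row_mean += d1 / n_row
                    row_M2 += np.einsum("ic,id->icd", d1, x_row - row_mean)
                    if n_row > 100 and t % 25 == 0:
                        cov = row_M2 / (n_row - 1) + 1e-8 * np.eye(C)
                        row_chol = np.linalg.cholesky(cov)
                step = np.einsum("icd,id->ic", row_chol, rng.standard_normal((I, C)))
                if hier:
                    zp = z + s_row[:, None] * step
                    eta_p = b_bar + (zp @ L_om.T) * np.exp(log_sigma)
                    prior_diff = 0.5 * (np.sum(z**2, axis=1) - np.sum(zp**2, axis=1))
                else:
                    eta_p = eta + s_row[:, None] * step
                    prior_diff = np.sum(
                        _normal_lp(eta_p, locs, scales) - _normal_lp(eta, locs, scales),
                        axis=1,
                    )
                b_p, a_p, g_p, p_p = nat_from_eta(eta_p)
                it_prop = np.bincount(
                    ii, weights=obs_ll(b_p, a_p, g_p, p_p, theta), minlength=I
                )
                acc = np.log(rng.random(I)) < it_prop - it_cur + prior_diff
                if hier:
                    z = np.where(acc[:, None], zp, z)
                    eta = b_bar + (z @ L_om.T) * np.exp(log_sigma)
                else:
                    eta = np.where(acc[:, None], eta_p, eta)
                beta_c, alpha_c, gamma_c, psi_c = nat_from_eta(eta)
                it_cur = np.where(acc, it_prop, it_cur)
                if adapting:
                    s_row *= np.exp(lr * (acc - 0.30))
            cur_ll_total = float(np.sum(it_cur))

        # hyperparameters: the means move by random-walk MH; the scales move
        # by slice sampling in both the non-centered (likelihood-coupled)
        # and centered (prior-coupled) coordinate systems.  Interweaving the
        # two parameterizations is what lets the scales cross their funnels;
        # a couple of repetitions per sweep cuts their autocorrelation.
        for _rep in range(1 if hier and sample_items else 0):
            cur_ll = cur_ll_total
            bt = (z @ L_om.T) * np.exp(log_sigma)
            for k in range(C):
                cand = b_bar.copy()
                cand[k] += s_bbar[k] * rng.standard_normal()
                eta_p = cand + bt
                b_p, a_p, g_p, p_p = nat_from_eta(eta_p)
                ll_p = float(np.sum(obs_ll(b_p, a_p, g_p, p_p, theta)))
                logr = (
                    ll_p - cur_ll
                    + float(_normal_lp(cand[k], locs[k], scales[k]))
                    - float(_normal_lp(b_bar[k], locs[k], scales[k]))
                )
                ok = math.log(rng.random()) < logr
                if ok:
                    b_bar, cur_ll = cand, ll_p
                    eta = eta_p
                    beta_c, alpha_c, gamma_c, psi_c = b_p, a_p, g_p, p_p
                if adapting:
                    s_bbar[k] *= math.exp(lr * (ok - 0.44))
            # non-centered scale updates by slice sampling: the conditional
            # of a hyper scale given the standardized deviations is explored
            # fully each sweep, which together with the centered slice below
            # (interweaving) is what lets the scale cross its funnel
            w_mat = z @ L_om.T
            for k in range(C):
                def logf_nc(ls, k=k):
                    sig_try = np.exp(log_sigma)
                    sig_try[k] = math.exp(ls)
                    b_t, a_t, g_t, p_t = nat_from_eta(b_bar + w_mat * sig_try)
                    return (
                        float(np.sum(obs_ll(b_t, a_t, g_t, p_t, theta)))
                        + _halfnormal_lp(math.exp(ls), priors.sigma_scale)
                        + ls
                    )
                log_sigma[k] = _slice_step(logf_nc, log_sigma[k], 0.5, rng)
            eta = b_bar + w_mat * np.exp(log_sigma)
            beta_c, alpha_c, gamma_c, psi_c = nat_from_eta(eta)
            cur_ll = float(np.sum(obs_ll(beta_c, alpha_c, gamma_c, psi_c, theta)))
            if n_corr:
                # correlation matrix, one partial-correlation coordinate at a
                # time, in centered coordinates: the item deviations (hence
                # the likelihood) stay fixed while the standardized z adjust,
                # so the conditional is cheap and slice sampling explores it
                # fully each sweep
                w_fix = z @ L_om.T
                for m in range(n_corr):
                    def logf_u(uv, m=m):
                        u_t = u.copy()
                        u_t[m] = uv
                        L_t, jac_t = corr_chol_from_unconstrained(u_t, C)
                        z_t = solve_triangular(L_t, w_fix.T, lower=True)
                        return (
                            -0.5 * float(np.sum(z_t * z_t))
                            - I * float(np.sum(np.log(np.diag(L_t))))
                            + lkj_chol_logpdf(L_t, priors.lkj_eta)
                            + jac_t
                        )
                    u[m] = _slice_step(logf_u, float(u[m]), 1.0, rng)
                L_om, log_jac = corr_chol_from_unconstrained(u, C)
                z = solve_triangular(L_om, w_fix.T, lower=True).T

            # centered-coordinate updates: with the item predictors (hence
            # the likelihood) held fixed, the hyper means and scales have
            # cheap exact conditionals, sampled by univariate slice steps
            bt_c = eta - b_bar

            def mvn_term(sig_vec):
                L_cov = sig_vec[:, None] * L_om
                q = solve_triangular(L_cov, bt_c.T, lower=True)
                return -0.5 * float(np.sum(q * q)) - I * float(
                    np.sum(np.log(np.diag(L_cov)))
                )

            for k in range(C):
                def logf_c(ls, k=k):
                    sig_try = np.exp(log_sigma)
                    sig_try[k] = math.exp(ls)
                    return (
                        mvn_term(sig_try)
                        + _halfnormal_lp(math.exp(ls), priors.sigma_scale)
                        + ls
                    )
                log_sigma[k] = _slice_step(logf_c, log_sigma[k], 1.0, rng)
            sig = np.exp(log_sigma)
            for k in range(C):
                def logf_b(b, k=k):
                    b_try = b_bar.copy()
                    b_try[k] = b
                    q = solve_triangular(
                        sig[:, None] * L_om, (eta - b_try).T, lower=True
                    )
                    return -0.5 * float(np.sum(q * q)) + float(
                        _normal_lp(b, locs[k], scales[k])
                    )
                b_bar[k] = _slice_step(logf_b, b_bar[k], 0.5, rng)
            z = solve_triangular(L_om, ((eta - b_bar) / sig).T, lower=True).T
            # the centered block leaves every item predictor unchanged
            cur_ll_total = cur_ll

        # ridge moves: likelihood-invariant reparameterization proposals that
        # travel along the scale and location trade-offs the priors only
        # weakly pin down (theta scale vs slopes, theta location vs easiness)
        if sample_items and est_sigma_theta and "logalpha" in classes:
            ka = classes.index("logalpha")
            eps = s_scale_move * rng.standard_normal()
            st = math.exp(log_st)
            st_p = math.exp(log_st + eps)
            # theta -> e^eps * theta, sigma_theta -> e^eps * sigma_theta,
            # log-slopes shift by -eps; the Jacobian e^{J*eps} cancels the
            # theta-prior normalization change exactly
            logr = (
                _halfnormal_lp(st_p, priors.sigma_theta_scale)
                - _halfnormal_lp(st, priors.sigma_theta_scale)
                + eps
            )
            if hier:
                logr += float(
                    _normal_lp(b_bar[ka] - eps, locs[ka], scales[ka])
                    - _normal_lp(b_bar[ka], locs[ka], scales[ka])
                )
            else:
                logr += float(np.sum(
                    _normal_lp(eta[:, ka] - eps, locs[ka], scales[ka])
                    - _normal_lp(eta[:, ka], locs[ka], scales[ka])
                ))
            ok = math.log(rng.random()) < logr
            if ok:
                theta = theta * math.exp(eps)
                log_st = log_st + eps
                if hier:
                    b_bar[ka] -= eps
                    eta = b_bar + (z @ L_om.T) * np.exp(log_sigma)
                else:
                    eta[:, ka] -= eps
                beta_c, alpha_c, gamma_c, psi_c = nat_from_eta(eta)
            if adapting:
                s_scale_move *= math.exp(lr * (ok - 0.44))
        if sample_items:
            # theta -> theta + delta, item easiness absorbs -alpha*delta
            # (class 'beta' is first, so its non-centered column is z[:, 0])
            delta = s_shift_move * rng.standard_normal()
            st = math.exp(log_st)
            theta_p = theta + delta
            logr = float(np.sum(
                _normal_lp(theta_p, 0.0, st) - _normal_lp(theta, 0.0, st)
            ))
            if hier:
                sig0 = float(np.exp(log_sigma[0]))
                z0_p = z[:, 0] - alpha_c * delta / sig0
                logr += 0.5 * float(np.sum(z[:, 0] ** 2 - z0_p**2))
            else:
                eb_p = eta[:, 0] - alpha_c * delta
                logr += float(np.sum(
                    _normal_lp(eb_p, locs[0], scales[0])
                    - _normal_lp(eta[:, 0], locs[0], scales[0])
                ))
            ok = math.log(rng.random()) < logr
            if ok:
                theta = theta_p
                if hier:
                    z[:, 0] = z0_p
                    eta = b_bar + (z @ L_om.T) * np.exp(log_sigma)
                else:
                    eta[:, 0] = eb_p
                beta_c, alpha_c, gamma_c, psi_c = nat_from_eta(eta)
            if adapting:
                s_shift_move *= math.exp(lr * (ok - 0.44))

        # ability scale (prior-only block: the likelihood does not involve it)
        if est_sigma_theta:
            cand = log_st + s_logst * rng.standard_normal()
            st_p = math.exp(cand)
            logr = (
                float(np.sum(_normal_lp(theta, 0.0, st_p) - _normal_lp(theta, 0.0, st)))
                + _halfnormal_lp(st_p, priors.sigma_theta_scale) + cand
                - _halfnormal_lp(st, priors.sigma_theta_scale) - log_st
            )
            ok = math.log(rng.random()) < logr
            if ok:
                log_st = cand
            if adapting:
                s_logst *= math.exp(lr * (ok - 0.44))

        if not adapting:
            d = t - n_warmup
            store["beta"][d] = beta_c
            store["alpha"][d] = alpha_c
            store["gamma"][d] = gamma_c
            store["psi"][d] = psi_c
            store["theta"][d] = theta
            store["sigma_theta"][d] = math.exp(log_st)
            if hier:
                store["b_bar"][d] = b_bar
                store["sigma"][d] = np.exp(log_sigma)
                store["omega"][d] = L_om @ L_om.T
    return store


# ---------------------------------------------------------------------------
# MAP / ML via EM with Gauss-Hermite quadrature


@dataclass
class PointEstimate:
    """Natural-scale point estimates with flags and approximate SEs.

    ``se`` maps parameter names to natural-scale standard errors;
    ``se_available`` is False when the observed-information matrix is
    singular or indefinite (the SEs are then None, mirroring the failure
    mode of unregularized maximum likelihood on overparameterized
    instances).  ``boundary`` flags items whose guessing/lapse estimate sits
    at the edge of the parameter space, where ML theory does not hold.
    """

    spec: ModelSpec
    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    sigma_theta: float
    theta_eap: np.ndarray
    theta_sd: np.ndarray
    se: dict[str, np.ndarray | None]
    se_available: bool
    converged: bool
    n_iter: int
    boundary: np.ndarray
    objective: float
    objective_trace: np.ndarray
    method: str = "MAP"

    def state(self) -> ParameterState:
        return ParameterState(
            beta=self.beta, alpha=self.alpha, gamma=self.gamma, psi=self.psi,
            theta=self.theta_eap, sigma_theta=self.sigma_theta,
        )

    def summary(self) -> pd.DataFrame:
        classes = self.spec.free_classes
        rows = []
        for c in classes:
            nat = _NAT_OF[c]
            vals = getattr(self, nat)
            ses = self.se.get(nat)
            for i in range(vals.size):
                rows.append(
                    {"parameter": f"{nat}[{i}]", "estimate": vals[i],
                     "se": math.nan if ses is None else ses[i],
                     "boundary": bool(self.boundary[i]) and nat in ("gamma", "psi")}
                )
        rows.append({"parameter": "sigma_theta", "estimate": self.sigma_theta,
                     "se": math.nan if self.se.get("sigma_theta") is None
                     else float(self.se["sigma_theta"]), "boundary": False})
        return pd.DataFrame(rows).set_index("parameter")


_ETA_BOUND = 15.0


def _em_fit(
    data: ResponseData,
    spec: ModelSpec,
    item_prior: bool,
    n_quad: int,
    tol: float,
    max_iter: int,
    compute_se: bool,
    method: str,
) -> PointEstimate:
    if n_quad < 11:
        raise ValueError("need at least 11 quadrature points")
    J, I = data.n_persons, data.n_items
    Y, mask = data.to_matrix()
    Yf = Y.astype(float) * mask
    Mf = mask.astype(float)
    classes = spec.free_classes
    C = len(classes)
    priors = spec.priors
    locs = np.array([priors.loc[c] for c in classes])
    scales = np.array([priors.scale[c] for c in classes])
    fixed_nat = spec.fixed_natural(I)

    x_gh, w_gh = hermgauss(n_quad)
    t_nodes = np.sqrt(2.0) * x_gh                # ability grid in sd units
    lw = np.log(w_gh / np.sqrt(np.pi))

    if spec.sigma_theta_fixed is not None:
        est_st, sigma_theta = False, float(spec.sigma_theta_fixed)
    elif spec.model_class == "1PL":
        est_st, sigma_theta = True, 1.0
    else:
        # scale identified through the slopes; fix the latent sd (the
        # conventional marginal-ML identification)
        est_st, sigma_theta = False, 1.0

    item_rate = np.clip(Yf.sum(axis=0) / Mf.sum(axis=0), 0.02, 0.98)
    eta = np.tile(locs, (I, 1)).astype(float)
    eta[:, 0] = _logit(item_rate)

    def nat_of(eta_mat):
        nat = dict(fixed_nat)
        for k, c in enumerate(classes):
            nat[_NAT_OF[c]] = unconstrained_to_natural(c, eta_mat[:, k])
        return nat

    def item_logprobs(eta_mat, st):
        nat = nat_of(eta_mat)
        theta_q = st * t_nodes
        return response_logprob(
            nat["beta"][:, None], nat["alpha"][:, None],
            nat["gamma"][:, None], nat["psi"][:, None], theta_q[None, :],
        )

    def prior_terms(eta_mat, st):
        total = 0.0
        if item_prior:
            for k in range(C):
                total += float(np.sum(_normal_lp(eta_mat[:, k], locs[k], scales[k])))
            if est_st:
                total += _halfnormal_lp(st, priors.sigma_theta_scale)
        return total

    def person_node_ll(eta_mat, st):
        lp1, lp0 = item_logprobs(eta_mat, st)   # (I, Q)
        return Yf @ lp1 + (Mf - Yf) @ lp0       # (J, Q)

    def objective_parts(eta_mat, st):
        Ljq = person_node_ll(eta_mat, st) + lw
        m = Ljq.max(axis=1, keepdims=True)
        marg = m[:, 0] + np.log(np.sum(np.exp(Ljq - m), axis=1))
        return float(marg.sum()) + prior_terms(eta_mat, st), Ljq, marg

    trace = []
    converged = False
    obj, Ljq, marg = objective_parts(eta, sigma_theta)
    for it in range(1, max_iter + 1):
        trace.append(obj)
        # E-step
        r = np.exp(Ljq - marg[:, None])                      # (J, Q)
        n1 = Yf.T @ r                                        # (I, Q)
        n0 = (Mf - Yf).T @ r
        # M-step: items (conditionally independent given responsibilities)
        theta_q = sigma_theta * t_nodes
        for i in range(I):
            def neg_q(e_i, i=i):
                nat = dict(fixed_nat)
                nat_i = {k: v[i] for k, v in nat.items()}
                for k, c in enumerate(classes):
                    nat_i[_NAT_OF[c]] = unconstrained_to_natural(c, np.atleast_1d(e_i[k]))[0]
                lp1, lp0 = response_logprob(
                    nat_i["beta"], nat_i["alpha"], nat_i["gamma"], nat_i["psi"], theta_q
                )
                val = float(n1[i] @ lp1 + n0[i] @ lp0)
                if item_prior:
                    val += float(np.sum(_normal_lp(e_i, locs, scales)))
                return -val
            x0 = eta[i].copy()
            f0 = neg_q(x0)
            res = minimize(
                neg_q, x0, method="L-BFGS-B",
                bounds=[(-_ETA_BOUND, _ETA_BOUND)] * C,
            )
            if res.fun <= f0:
                eta[i] = res.x
        # M-step: latent scale (one-dimensional, grid moves with it)
        if est_st:
            def neg_q_st(log_s):
                s = math.exp(log_s)
                lp1, lp0 = item_logprobs(eta, s)
                val = float(np.sum(n1 * lp1) + np.sum(n0 * lp0))
                if item_prior:
                    val += _halfnormal_lp(s, priors.sigma_theta_scale)
                return -val
            res = minimize_scalar(neg_q_st, bounds=(math.log(0.05), math.log(10.0)),
                                  method="bounded")
            if res.fun <= neg_q_st(math.log(sigma_theta)):
                sigma_theta = math.exp(res.x)
        new_obj, Ljq, marg = objective_parts(eta, sigma_theta)
        if abs(new_obj - obj) < tol * (abs(new_obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    trace.append(obj)

    # EAP ability scores under the fitted items
    r = np.exp(Ljq - marg[:, None])
    theta_q = sigma_theta * t_nodes
    theta_eap = r @ theta_q
    theta_sd = np.sqrt(np.clip(r @ theta_q**2 - theta_eap**2, 0.0, None))

    nat = nat_of(eta)
    boundary = np.zeros(I, dtype=bool)
    for k, c in enumerate(classes):
        if c in ("logitgamma", "logitpsi"):
            v = nat[_NAT_OF[c]]
            boundary |= (v < 1e-3) | (v > 1 - 1e-3)
        boundary |= np.abs(eta[:, k]) >= _ETA_BOUND - 0.01

    se: dict[str, np.ndarray | None] = {_NAT_OF[c]: None for c in classes}
    se["sigma_theta"] = None
    se_available = False
    if compute_se:
        se, se_available = _observed_info_se(
            eta, sigma_theta, est_st, classes, nat, objective_parts
        )
    return PointEstimate(
        spec=spec,
        beta=nat["beta"], alpha=nat["alpha"], gamma=nat["gamma"], psi=nat["psi"],
        sigma_theta=sigma_theta, theta_eap=theta_eap, theta_sd=theta_sd,
        se=se, se_available=se_available, converged=converged, n_iter=len(trace) - 1,
        boundary=boundary, objective=obj, objective_trace=np.asarray(trace),
        method=method,
    )


def _observed_info_se(eta, sigma_theta, est_st, classes, nat, objective_parts):
    """Delta-method natural-scale SEs from a central-difference Hessian."""
    I, C = eta.shape
    x0 = eta.reshape(-1)
    if est_st:
        x0 = np.append(x0, math.log(sigma_theta))
    D = x0.size

    def f(x):
        e = x[: I * C].reshape(I, C)
        st = math.exp(x[I * C]) if est_st else sigma_theta
        return objective_parts(e, st)[0]

    h = 1e-4 * (1.0 + np.abs(x0))
    H = np.empty((D, D))
    f0 = f(x0)
    fp = np.empty(D)
    fm = np.empty(D)
    for a in range(D):
        xa = x0.copy(); xa[a] += h[a]; fp[a] = f(xa)
        xa = x0.copy(); xa[a] -= h[a]; fm[a] = f(xa)
        H[a, a] = (fp[a] - 2.0 * f0 + fm[a]) / h[a] ** 2
    for a in range(D):
        for b in range(a + 1, D):
            xa = x0.copy(); xa[a] += h[a]; xa[b] += h[b]; fpp = f(xa)
            xa = x0.copy(); xa[a] -= h[a]; xa[b] -= h[b]; fmm = f(xa)
            H[a, b] = H[b, a] = (
                fpp - fp[a] - fp[b] + 2.0 * f0 - fm[a] - fm[b] + fmm
            ) / (2.0 * h[a] * h[b])
    se: dict[str, np.ndarray | None] = {_NAT_OF[c]: None for c in classes}
    se["sigma_theta"] = None
    try:
        info = -H
        np.linalg.cholesky(info)  # positive-definiteness check
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError
        se_eta = np.sqrt(diag[: I * C]).reshape(I, C)
    except np.linalg.LinAlgError:
        return se, False
    for k, c in enumerate(classes):
        if c == "beta":
            se[_NAT_OF[c]] = se_eta[:, k]
        elif c == "logalpha":
            se[_NAT_OF[c]] = se_eta[:, k] * nat["alpha"]
        elif c == "logitgamma":
            se[_NAT_OF[c]] = se_eta[:, k] * nat["gamma"] * (1 - nat["gamma"])
        else:
            se[_NAT_OF[c]] = se_eta[:, k] * nat["psi"] * (1 - nat["psi"])
    if est_st:
        se["sigma_theta"] = np.asarray(math.sqrt(diag[-1]) * sigma_theta)
    return se, True


def map_fit(
    data: ResponseData,
    spec: ModelSpec,
    n_quad: int = 21,
    tol: float = 1e-5,
    max_iter: int = 500,
    compute_se: bool = True,
) -> PointEstimate:
    """Maximum a-posteriori fit: EM over the ability-marginalized posterior.

    Item parameters carry the spec's class-wise normal priors (applied
    non-hierarchically, as in optimization-based fitting of these models);
    abilities are integrated out on a fixed-point Gauss-Hermite grid that
    rescales with the provisional ability sd.  Person scores are
    expected-a-posteriori values under the fitted items.
    """
    return _em_fit(data, spec, item_prior=not spec.priors.flat, n_quad=n_quad,
                   tol=tol, max_iter=max_iter, compute_se=compute_se, method="MAP")


def ml_fit(
    data: ResponseData,
    spec: ModelSpec,
    n_quad: int = 21,
    tol: float = 1e-5,
    max_iter: int = 500,
    compute_se: bool = True,
) -> PointEstimate:
    """Marginal maximum-likelihood fit (EM, no item-parameter priors).

    The ability distribution ``normal(0, sigma_theta)`` is retained; its sd
    is estimated for the 1PL and fixed at 1 otherwise (the scale is then
    carried by the slopes).  Approximate SEs come from the observed
    information matrix and are flagged unavailable when it is singular.
    """
    return _em_fit(data, spec, item_prior=False, n_quad=n_quad, tol=tol,
                   max_iter=max_iter, compute_se=compute_se, method="ML")
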