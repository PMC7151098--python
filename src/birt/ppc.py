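"""Posterior-predictive item and person fit checks.

Three steps: (1) the fit statistic ``T(y, p)`` — the summed Bernoulli
log-likelihood over a unit's observations — is evaluated on the observed
responses at each posterior draw; (2) the same statistic is evaluated on
responses replicated from the model at that draw, ``T(y_rep, p)``; (3)
the per-draw difference ``D = T(y_rep, p) - T(y, p)`` is summarized per
item or per person.  If most of the posterior mass of ``D`` lies above
zero, the model predicts its own replicated data better than the observed
responses, indicating misfit for that unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import PosteriorDraws
from .model import ResponseData, response_logprob

__all__ = [
    "FitStatResult",
    "posterior_predict",
    "fit_statistic",
    "fit_summary_table",
    "person_fit_report",
]


@dataclass(frozen=True)
class FitStatResult:
    """Posterior of the log-likelihood difference D for one unit."""

    unit_kind: str
    unit_index: int
    d_draws: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.d_draws.mean())

    @property
    def interval(self) -> tuple[float, float]:
        return (
            float(np.quantile(self.d_draws, 0.025)),
            float(np.quantile(self.d_draws, 0.975)),
        )

    @property
    def p_above_zero(self) -> float:
        return float(np.mean(self.d_draws > 0))


def _prob_matrix(draws: PosteriorDraws, data: ResponseData, chunk: int = 200):
    """Yield (lo, hi, lp1, lp0) chunks of per-draw observation log-probs."""
    beta = draws.stacked("beta")
    alpha = draws.stacked("alpha")
    gamma = draws.stacked("gamma")
    psi = draws.stacked("psi")
    theta = draws.stacked("theta")
    ii, pi = data.item, data.person
    for lo in range(0, draws.n_total, chunk):
        hi = min(lo + chunk, draws.n_total)
        lp1, lp0 = response_logprob(
            beta[lo:hi][:, ii], alpha[lo:hi][:, ii],
            gamma[lo:hi][:, ii], psi[lo:hi][:, ii], theta[lo:hi][:, pi],
        )
        yield lo, hi, lp1, lp0


def posterior_predict(
    draws: PosteriorDraws, data: ResponseData, seed: int | None = None
) -> np.ndarray:
    """Replicate responses: ``y_rep[s, n] ~ Bernoulli(p_n(draw s))``.

    Deterministic under ``seed``; shaped (total draws, observations).
    """
    if draws.n_items != data.n_items or draws.n_persons != data.n_persons:
        raise ValueError("draws and data dimensions do not match")
    rng = np.random.default_rng(seed)
    y_rep = np.empty((draws.n_total, data.n_obs), dtype=np.int8)
    for lo, hi, lp1, _ in _prob_matrix(draws, data):
        p = np.exp(lp1)
        y_rep[lo:hi] = rng.random(p.shape) < p
    return y_rep


def fit_statistic(
    draws: PosteriorDraws,
    data: ResponseData,
    y_rep: np.ndarray,
    unit_kind: str = "item",
) -> list[FitStatResult]:
    """Per-unit posterior of ``D = T(y_rep, p) - T(y, p)``.

    ``T`` is the summed pointwise Bernoulli log-likelihood over the unit's
    observations, so item-level D values add up (over items, per draw) to
    the whole-data statistic.
    """
    if unit_kind not in ("item", "person"):
        raise ValueError("unit_kind must be 'item' or 'person'")
    if y_rep.shape != (draws.n_total, data.n_obs):
        raise ValueError("y_rep misaligned with draws and data")
    idx = data.item if unit_kind == "item" else data.person
    n_units = data.n_items if unit_kind == "item" else data.n_persons
    if np.bincount(idx, minlength=n_units).min() == 0:
        raise ValueError(f"some {unit_kind} has zero observations")
    onehot = np.zeros((data.n_obs, n_units))
    onehot[np.arange(data.n_obs), idx] = 1.0
    y1 = data.y == 1
    D = np.empty((draws.n_total, n_units))
    for lo, hi, lp1, lp0 in _prob_matrix(draws, data):
        ll_obs = np.where(y1[None, :], lp1, lp0)
        ll_rep = np.where(y_rep[lo:hi] == 1, lp1, lp0)
        D[lo:hi] = (ll_rep - ll_obs) @ onehot
    return [FitStatResult(unit_kind=unit_kind, unit_index=u, d_draws=D[:, u])
            for u in range(n_units)]


def fit_summary_table(results: list[FitStatResult]) -> pd.DataFrame:
    """Per-unit summary: mean D, central 95% interval, P(D > 0)."""
    rows = []
    for r in results:
        lo, hi = r.interval
        rows.append(
            {"unit": r.unit_index, "kind": r.unit_kind, "mean_d": r.mean,
             "q2.5": lo, "q97.5": hi, "p_above_zero": r.p_above_zero}
        )
    return pd.DataFrame(rows).set_index("unit")


def person_fit_report(
    draws_by_model: Mapping[str, PosteriorDraws],
    data: ResponseData,
    person_index: int,
    seed: int | None = None,
) -> dict[str, FitStatResult]:
    """Cross-model fit posterior for one person.

    Each model replicates with the same seed offset so the comparison is
    not confounded by the replication stream.
    """
    if not (0 <= person_index < data.n_persons):
        raise KeyError(f"unknown person index {person_index}")
    out: dict[str, FitStatResult] = {}
    for name, draws in draws_by_model.items():
        y_rep = posterior_predict(draws, data, seed=seed)
        res = fit_statistic(draws, data, y_rep, unit_kind="person")
        out[name] = res[person_index]
    return out


def plot_fit_densities(results: list[FitStatResult], path=None):
    """Optional density-strip export of per-unit D posteriors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    ncol = min(4, n)
    nrow = math.ceil(n / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    for ax, r in zip(axes.reshape(-1), results):
        ax.hist(r.d_draws, bins=40, density=True, color="steelblue", alpha=0.8)
        ax.axvline(0.0, color="black", lw=1)
        ax.set_title(f"{r.unit_kind} {r.unit_index} (P>0: {r.p_above_zero:.2f})", fontsize=8)
    for ax in axes.reshape(-1)[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
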