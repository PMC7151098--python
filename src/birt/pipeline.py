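"""End-to-end analysis pipeline: ingest, fit the model ladder, compare, check.

The ladder is fitted bottom-up (1PL towards 4PL): simpler models are
cheaper and their failures are easier to localize, and the comparison
then quantifies how much predictive fit each added item-parameter class
buys.  Every artifact written by :func:`run_ladder` is stamped with the
seed and a hash of the resolved configuration, and the report bundle
embeds the configuration needed to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import map_fit, mcmc_sample, ml_fit
from .loo import comparison_table, pointwise_loglik, psis_loo
from .model import ModelSpec, ResponseData
from .ppc import fit_statistic, fit_summary_table, posterior_predict
from .simulate import spm_ls_like_fixture

__all__ = [
    "load_long",
    "wide_to_long",
    "PipelineConfig",
    "run_ladder",
]

logger = logging.getLogger("birt.pipeline")


# ---------------------------------------------------------------------------
# ingest


def load_long(path) -> tuple[ResponseData, list, list]:
    """Read long-format CSV (person, item, response) into dense indices.

    Identifier mapping is stable sorted-order assignment; the original
    labels are returned alongside the data.  Duplicate (person, item) rows
    and non-binary codes are hard errors reported with row numbers.
    """
    df = pd.read_csv(path)
    required = {"person", "item", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"long-format input needs columns {sorted(required)}")
    bad = df.index[~df["response"].isin([0, 1])].tolist()
    if bad:
        raise ValueError(f"non-binary response codes at rows {bad[:10]}")
    dup = df.duplicated(subset=["person", "item"], keep=False)
    if dup.any():
        raise ValueError(f"duplicate person x item rows at {df.index[dup].tolist()[:10]}")
    persons = sorted(df["person"].unique().tolist())
    items = sorted(df["item"].unique().tolist())
    pmap = {p: k for k, p in enumerate(persons)}
    imap = {i: k for k, i in enumerate(items)}
    data = ResponseData(
        person=df["person"].map(pmap).to_numpy(),
        item=df["item"].map(imap).to_numpy(),
        y=df["response"].to_numpy(),
        n_persons=len(persons),
        n_items=len(items),
    )
    return data, persons, items


def wide_to_long(table: pd.DataFrame, answer_key: Mapping) -> tuple[ResponseData, list, list]:
    """Dichotomize a wide raw-choice table against an answer key.

    One row per person, one column per item; a response is correct (1)
    exactly when the raw choice equals the keyed alternative.  Missing
    cells are omitted with a logged count; non-integer codes are hard
    errors with row numbers.
    """
    items = [c for c in table.columns if c in answer_key]
    if not items:
        raise ValueError("no table column matches the answer key")
    long = table[items].reset_index(drop=True).melt(
        ignore_index=False, var_name="item", value_name="choice"
    ).reset_index(names="person")
    n_missing = int(long["choice"].isna().sum())
    if n_missing:
        logger.warning("omitting %d missing responses", n_missing)
    long = long.dropna(subset=["choice"])
    nonint = long["choice"] != long["choice"].astype(int)
    if nonint.any():
        raise ValueError(
            f"non-integer raw choices at rows {long.index[nonint].tolist()[:10]}"
        )
    persons = sorted(long["person"].unique().tolist())
    pmap = {p: k for k, p in enumerate(persons)}
    imap = {i: k for k, i in enumerate(items)}
    key = long["item"].map(dict(answer_key))
    data = ResponseData(
        person=long["person"].map(pmap).to_numpy(),
        item=long["item"].map(imap).to_numpy(),
        y=(long["choice"].astype(int) == key).to_numpy().astype(np.int8),
        n_persons=len(persons),
        n_items=len(items),
    )
    return data, persons, items


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings of one ladder run (serialized with every bundle)."""

    input_path: str | None = None
    input_format: str = "long"
    answer_key: Mapping | None = None
    models: Sequence[str] = ("1PL", "2PL", "3PL", "4PL")
    hierarchical: bool = True
    estimators: Sequence[str] = ("mcmc",)
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    out_dir: str = "ladder_report"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model is required")
        if not self.estimators:
            raise ValueError("at least one estimator is required")
        for e in self.estimators:
            if e not in ("mcmc", "map", "ml"):
                raise ValueError(f"unknown estimator {e!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["estimators"] = list(self.estimators)
        d["answer_key"] = None if self.answer_key is None else dict(self.answer_key)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["models"] = tuple(d.get("models", ("1PL", "2PL", "3PL", "4PL")))
        d["estimators"] = tuple(d.get("estimators", ("mcmc",)))
        return cls(**d)

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# ladder


def _load_input(config: PipelineConfig) -> ResponseData:
    if config.input_path is None:
        logger.info("no input path: using the built-in synthetic fixture")
        data, _, _ = spm_ls_like_fixture(seed=config.seed)
        return data
    if config.input_format == "long":
        data, _, _ = load_long(config.input_path)
        return data
    if config.input_format == "wide":
        if config.answer_key is None:
            raise ValueError("wide input requires an answer key")
        table = pd.read_csv(config.input_path)
        data, _, _ = wide_to_long(table, config.answer_key)
        return data
    raise ValueError(f"unknown input format {config.input_format!r}")


def run_ladder(config: PipelineConfig, data: ResponseData | None = None) -> dict:
    """Fit the configured model ladder and write the report bundle.

    Per model: parameter summaries and convergence flags; across MCMC
    models: the LOO comparison table and item-level predictive fit
    summaries; across all fits: person-score correlations and 95%
    interval-width tables.  A model that fails to converge is recorded
    and the ladder continues.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_ladder_inner(config, data, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_ladder_inner(config: PipelineConfig, data: ResponseData | None, out: Path) -> dict:
    if data is None:
        data = _load_input(config)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    loo_results = {}
    scores: dict[str, np.ndarray] = {}
    widths: dict[str, np.ndarray] = {}
    convergence: dict[str, bool] = {}
    tables: dict[str, pd.DataFrame] = {}
    draws_by_model = {}
    for k, model in enumerate(config.models):
        spec = ModelSpec(model_class=model, hierarchical=config.hierarchical)
        for estimator in config.estimators:
            label = f"{model}_{estimator}"
            logger.info("fitting %s", label)
            try:
                if estimator == "mcmc":
                    draws = mcmc_sample(
                        data, spec, n_chains=config.n_chains,
                        n_warmup=config.n_warmup, n_draws=config.n_draws,
                        seed=config.seed + 1000 * k,
                    )
                    convergence[label] = bool(draws.converged)
                    tables[f"summary_{label}"] = draws.summary()
                    draws_by_model[model] = draws
                    loo_results[model] = psis_loo(pointwise_loglik(draws, data))
                    th = draws.stacked("theta")
                    scores[label] = th.mean(axis=0)
                    widths[label] = np.quantile(th, 0.975, axis=0) - np.quantile(th, 0.025, axis=0)
                else:
                    fit = map_fit(data, spec) if estimator == "map" else ml_fit(data, spec)
                    convergence[label] = bool(fit.converged)
                    tables[f"summary_{label}"] = fit.summary()
                    scores[label] = fit.theta_eap
                    widths[label] = 2.0 * 1.959964 * fit.theta_sd
            except Exception as exc:  # noqa: BLE001 - ladder must survive one failure
                logger.error("fit %s failed: %s", label, exc)
                convergence[label] = False
    if loo_results:
        tables["comparison"] = comparison_table(loo_results)
    # predictive fit checks per MCMC model, shared replication seed offset
    for model, draws in draws_by_model.items():
        y_rep = posterior_predict(draws, data, seed=config.seed + 77)
        tables[f"ppc_items_{model}"] = fit_summary_table(
            fit_statistic(draws, data, y_rep, unit_kind="item")
        )
    if scores:
        score_df = pd.DataFrame(scores)
        tables["person_scores"] = score_df
        tables["person_score_correlations"] = score_df.corr()
        tables["interval_widths"] = pd.DataFrame(widths)
    digest = hashlib.sha256()
    for name in sorted(tables):
        csv_text = tables[name].to_csv(float_format="%.10g")
        (out / f"{name}.csv").write_text(csv_text)
        digest.update(name.encode())
        digest.update(csv_text.encode())
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "tables_hash": digest.hexdigest(),
        "n_persons": data.n_persons,
        "n_items": data.n_items,
        "n_obs": data.n_obs,
        "convergence": convergence,
        "tables": sorted(tables),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    report["_tables"] = tables
    report["_loo"] = loo_results
    return report
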