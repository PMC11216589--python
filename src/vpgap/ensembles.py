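"""Ensemble encoding models built by aggregating stored per-stimulus predictions.

A within-model ensemble combines, per site, the predictions of the k layers
of one network with the highest in-distribution scores for that site; a
cross-model ensemble combines the top k layers within each of the top k
networks (networks ranked by their layer-neuron population in-distribution
score).  Members are aggregated per stimulus with the mean or the median of
the raw predicted responses and the aggregate is rescored exactly like a
single encoding model.  Selection uses in-distribution scores only, so
out-of-distribution ensemble scores remain honest generalization numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .predictivity import (
    PredictivityTable,
    _pearson_columns,
    population_score,
    select_layer_neuron,
)
from .synthetic import ID_DOMAIN, OOD_DOMAIN

__all__ = ["EnsembleSpec", "build_ensemble", "aggregate_and_score", "ensemble_population_score"]

Member = tuple[str, str]  # (model, layer)


@dataclass(frozen=True)
class EnsembleSpec:
    scope: str = "within_model"  # "within_model" | "cross_model"
    k_layers: int = 5
    k_models: int = 5
    aggregator: str = "mean"  # "mean" | "median"

    def __post_init__(self) -> None:
        if self.scope not in ("within_model", "cross_model"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.aggregator not in ("mean", "median"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.k_layers < 1 or self.k_models < 1:
            raise ValueError("k_layers and k_models must be >= 1")


def _top_layers_for_site(
    mean_id: pd.DataFrame, model: str, site: str, k: int
) -> list[Member]:
    col = mean_id.loc[model][site].dropna()
    if len(col) < k:
        warnings.warn(
            f"model {model!r} has only {len(col)} scored layers for site {site!r}; "
            f"using all of them",
            stacklevel=3,
        )
        k = len(col)
    # stable sort keeps declared layer order among ties -> earliest layer wins
    top = col.sort_values(ascending=False, kind="stable").index[:k]
    return [(model, layer) for layer in top]


def build_ensemble(
    table: PredictivityTable,
    spec: EnsembleSpec,
    model: str | None = None,
) -> dict[str, list[Member]]:
    """Per-site member lists selected by in-distribution score only."""
    mean_id = table.mean_scores(ID_DOMAIN)
    sites = [s for s in table.site_ids if s in mean_id.columns]
    if spec.scope == "within_model":
        if model is None:
            models = table.models
            if len(models) != 1:
                raise ValueError("within_model ensemble needs a single model")
            model = models[0]
        return {
            site: _top_layers_for_site(mean_id, model, site, spec.k_layers)
            for site in sites
        }
    # cross_model: rank models by layer-neuron population ID score
    ranking = {
        m: population_score(table, select_layer_neuron(table, m), ID_DOMAIN)
        for m in table.models
    }
    ranked = sorted(
        table.models, key=lambda m: (-ranking[m], table.models.index(m))
    )
    if len(ranked) < spec.k_models:
        warnings.warn(
            f"only {len(ranked)} models available for a top-{spec.k_models} "
            "cross-model ensemble; using all of them",
            stacklevel=2,
        )
    chosen = ranked[: spec.k_models]
    return {
        site: [
            member
            for m in chosen
            for member in _top_layers_for_site(mean_id, m, site, spec.k_layers)
        ]
        for site in sites
    }


def aggregate_and_score(
    table: PredictivityTable,
    members_per_site: dict[str, list[Member]],
    measurements: dict[str, np.ndarray],
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Score per-site ensembles in both domains, per cross-validation repetition.

    ``measurements`` maps domain -> (stimuli x sites) trial-averaged
    responses aligned with ``table.stimulus_ids`` / ``table.site_ids``.
    Aggregation reuses the stored per-repetition fold predictions, so
    ensemble error bars follow the same convention as single-model scores.
    """
    agg_fn = {"mean": np.mean, "median": np.median}[aggregator]
    site_index = {s: i for i, s in enumerate(table.site_ids)}
    rows = []
    for domain in (ID_DOMAIN, OOD_DOMAIN):
        Y = np.asarray(measurements[domain], dtype=float)
        if Y.shape[0] != len(table.stimulus_ids[domain]):
            raise ValueError(f"measurement rows misaligned with {domain} stimulus ids")
        for site, members in members_per_site.items():
            j = site_index[site]
            arrays = []
            n_reps = None
            for member in members:
                key = (*member, domain)
                if key not in table.predictions:
                    raise ValueError(f"no stored predictions for {key}")
                arr = table.predictions[key][:, :, j]
                n_reps = arr.shape[0] if n_reps is None else n_reps
                arrays.append(arr)
            stacked = np.stack(arrays, axis=0)  # members x reps x stimuli
            combined = agg_fn(stacked, axis=0)  # reps x stimuli
            for r in range(combined.shape[0]):
                score = _pearson_columns(combined[r][:, None], Y[:, j][:, None])[0]
                rows.append(("ensemble", site, r, domain, score))
    return pd.DataFrame(
        rows, columns=["model", "site", "repetition", "domain", "score"]
    )


def ensemble_population_score(ensemble_scores: pd.DataFrame, domain: str) -> float:
    """Median across sites per repetition, mean across repetitions."""
    df = ensemble_scores[ensemble_scores["domain"] == domain]
    if df.empty:
        raise ValueError(f"no ensemble scores for domain {domain!r}")
    per_rep = df.groupby("repetition")["score"].median()
    return float(per_rep.mean())
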