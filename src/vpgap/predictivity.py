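"""Cross-validated PLS encoding models, layer mappings and the generalization gap.

For each candidate feature layer, a partial-least-squares regression from
(projected) unit activations to trial-averaged site responses is fitted
under k-fold cross-validation on the training domain.  Each site's score in
the training domain is the Pearson correlation between held-out predictions
(pooled across folds) and measurements; the score in the other domain is
the correlation between fold-averaged predictions on *all* other-domain
stimuli and their measurements.  The whole procedure is repeated with
independent fold assignments and summarized as median across sites, then
mean across repetitions.

Two layer-to-area mapping assumptions are supported:

* layer-area — one layer for the whole population, the one with the best
  population in-distribution score;
* layer-neuron — each site gets its own best in-distribution layer.

Both select on in-distribution scores only, so out-of-distribution results
remain genuine generalization measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from .synthetic import ID_DOMAIN, OOD_DOMAIN, ActivationSet

__all__ = [
    "CVConfig",
    "PredictivityTable",
    "MappingAssignment",
    "GapResult",
    "fit_score_layer",
    "select_layer_area",
    "select_layer_neuron",
    "population_score",
    "generalization_gap",
    "site_class_summary",
    "best_layer_offset",
]

SCORE_COLUMNS = ["model", "layer", "site", "repetition", "domain", "score"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for one scoring run.

    Defaults: 10 folds, 25 PLS components, 5 repetitions, fitting on the
    in-distribution domain.  ``pool_folds=False`` switches the
    training-domain score from pooled held-out correlation to the average
    of per-fold correlations.  ``per_site=True`` refits one single-response
    PLS per site instead of one multi-response model per fold.
    """

    n_folds: int = 10
    n_components: int = 25
    n_repetitions: int = 5
    train_domain: str = ID_DOMAIN
    seed: int = 0
    pool_folds: bool = True
    per_site: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.train_domain not in (ID_DOMAIN, OOD_DOMAIN):
            raise ValueError("train_domain must be 'ID' or 'OOD'")

    @property
    def eval_domain(self) -> str:
        return OOD_DOMAIN if self.train_domain == ID_DOMAIN else ID_DOMAIN


@dataclass
class PredictivityTable:
    """Per (model, layer, site, repetition, domain) correlation scores.

    Per-stimulus predictions are retained per (model, layer, domain) as a
    (repetitions, stimuli, sites) array so that ensemble and
    prediction-consistency analyses can reuse exactly the cross-validated
    predictions that produced the scores.
    """

    scores: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SCORE_COLUMNS)
    )
    predictions: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    stimulus_ids: dict[str, np.ndarray] = field(default_factory=dict)
    site_ids: list[str] = field(default_factory=list)
    layer_order: dict[str, list[str]] = field(default_factory=dict)

    def extend(self, other: "PredictivityTable") -> None:
        if self.scores.empty:
            self.scores = other.scores.copy()
        else:
            self.scores = pd.concat([self.scores, other.scores], ignore_index=True)
        self.predictions.update(other.predictions)
        for dom, ids in other.stimulus_ids.items():
            self.stimulus_ids.setdefault(dom, ids)
        for site in other.site_ids:
            if site not in self.site_ids:
                self.site_ids.append(site)
        for model, layers in other.layer_order.items():
            known = self.layer_order.setdefault(model, [])
            for layer in layers:
                if layer not in known:
                    known.append(layer)

    @property
    def models(self) -> list[str]:
        return list(self.layer_order)

    def mean_scores(self, domain: str, model: str | None = None) -> pd.DataFrame:
        """Repetition-averaged scores as a (model, layer) x site frame."""
        df = self.scores[self.scores["domain"] == domain]
        if model is not None:
            df = df[df["model"] == model]
        if df.empty:
            raise ValueError(f"no scores for domain {domain!r}" + (f", model {model!r}" if model else ""))
        wide = df.groupby(["model", "layer", "site"], sort=False)["score"].mean().unstack("site")
        return wide.reindex(columns=[s for s in self.site_ids if s in wide.columns])

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PredictivityTable":
        scores = pd.read_csv(path, sep="\t")
        table = cls(scores=scores)
        for model in scores["model"].unique():
            table.layer_order[model] = list(
                scores.loc[scores["model"] == model, "layer"].unique()
            )
        table.site_ids = list(scores["site"].unique())
        return table


def _pearson_columns(pred: np.ndarray, meas: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation; NaN where either column is constant."""
    p = pred - pred.mean(axis=0)
    m = meas - meas.mean(axis=0)
    sp = np.sqrt((p**2).sum(axis=0))
    sm = np.sqrt((m**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (p * m).sum(axis=0) / (sp * sm)
    r[(sp < 1e-14) | (sm < 1e-14)] = np.nan
    return r


def _fit_predict_pls(
    X_tr: np.ndarray,
    Y_tr: np.ndarray,
    X_eval: list[np.ndarray],
    n_components: int,
    per_site: bool,
) -> list[np.ndarray]:
    m = min(n_components, X_tr.shape[0] - 1, X_tr.shape[1])
    if m < n_components:
        warnings.warn(
            f"reducing PLS components from {n_components} to training rank {m}",
            stacklevel=3,
        )
    # The NIPALS inner iteration is run essentially to its numerical fixed
    # point so that scores do not depend on convergence conventions.
    def _make():
        return PLSRegression(n_components=m, scale=False, tol=1e-24, max_iter=5000)

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        if per_site:
            outs = [np.empty((X.shape[0], Y_tr.shape[1])) for X in X_eval]
            for j in range(Y_tr.shape[1]):
                pls = _make().fit(X_tr, Y_tr[:, j])
                for out, X in zip(outs, X_eval):
                    out[:, j] = pls.predict(X).ravel()
            return outs
        pls = _make().fit(X_tr, Y_tr)
        return [pls.predict(X) for X in X_eval]


def fit_score_layer(
    X_train: ActivationSet,
    X_other: ActivationSet,
    Y_train: np.ndarray,
    Y_other: np.ndarray,
    site_ids: list[str],
    cv: CVConfig,
    model_name: str = "model",
) -> PredictivityTable:
    """Cross-validated PLS scoring of one layer for one session.

    ``X_train``/``Y_train`` are the activations and trial-averaged responses
    of the training domain (stimulus-aligned rows); ``X_other``/``Y_other``
    the evaluation domain.  Returns a table holding per-site scores for both
    domains and every repetition, plus the per-stimulus predictions.
    """
    Y_train = np.asarray(Y_train, dtype=float)
    Y_other = np.asarray(Y_other, dtype=float)
    n_train, n_sites = Y_train.shape
    if X_train.X.shape[0] != n_train or X_other.X.shape[0] != Y_other.shape[0]:
        raise ValueError("activation and response stimulus counts differ")
    if Y_other.shape[1] != n_sites or len(site_ids) != n_sites:
        raise ValueError("site axes misaligned")
    if n_train < cv.n_folds:
        raise ValueError(
            f"{n_train} training stimuli cannot be split into {cv.n_folds} folds"
        )

    layer = X_train.layer
    other_domain = cv.eval_domain
    rows: list[tuple] = []
    preds_train_all = np.empty((cv.n_repetitions, n_train, n_sites))
    preds_other_all = np.empty((cv.n_repetitions, Y_other.shape[0], n_sites))

    for r in range(cv.n_repetitions):
        rng = np.random.default_rng(cv.seed + r)
        folds = np.array_split(rng.permutation(n_train), cv.n_folds)
        preds_train = np.empty((n_train, n_sites))
        preds_other = np.zeros((Y_other.shape[0], n_sites))
        fold_scores = np.zeros((cv.n_folds, n_sites)) if not cv.pool_folds else None
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n_train), test_idx)
            p_test, p_other = _fit_predict_pls(
                X_train.X[train_idx],
                Y_train[train_idx],
                [X_train.X[test_idx], X_other.X],
                cv.n_components,
                cv.per_site,
            )
            preds_train[test_idx] = p_test
            preds_other += p_other
            if fold_scores is not None:
                fold_scores[f] = _pearson_columns(p_test, Y_train[test_idx])
        preds_other /= cv.n_folds

        if cv.pool_folds:
            r_train = _pearson_columns(preds_train, Y_train)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r_train = np.nanmean(fold_scores, axis=0)
        r_other = _pearson_columns(preds_other, Y_other)
        if np.any(np.isnan(r_train)) or np.any(np.isnan(r_other)):
            warnings.warn(
                f"undefined correlation for some sites in layer {layer}; "
                "recorded as missing",
                stacklevel=2,
            )
        for j, site in enumerate(site_ids):
            rows.append((model_name, layer, site, r, cv.train_domain, r_train[j]))
            rows.append((model_name, layer, site, r, other_domain, r_other[j]))
        preds_train_all[r] = preds_train
        preds_other_all[r] = preds_other

    table = PredictivityTable(
        scores=pd.DataFrame(rows, columns=SCORE_COLUMNS),
        predictions={
            (model_name, layer, cv.train_domain): preds_train_all,
            (model_name, layer, other_domain): preds_other_all,
        },
        stimulus_ids={
            cv.train_domain: np.asarray(X_train.stimulus_ids),
            other_domain: np.asarray(X_other.stimulus_ids),
        },
        site_ids=list(site_ids),
        layer_order={model_name: [layer]},
    )
    return table


@dataclass
class MappingAssignment:
    """A layer-to-site assignment plus the ID selection scores that produced it."""

    scheme: str  # "layer_area" | "layer_neuron"
    model: str
    site_layers: dict[str, str]
    selection_scores: pd.Series  # per-site repetition-averaged ID score of the chosen layer


def _single_model(table: PredictivityTable, model: str | None) -> str:
    models = table.models
    if model is None:
        if len(models) != 1:
            raise ValueError(f"table holds {models}; specify which model to map")
        return models[0]
    if model not in models:
        raise ValueError(f"model {model!r} not in table")
    return model


def select_layer_area(
    table: PredictivityTable, model: str | None = None
) -> MappingAssignment:
    """One layer for the whole population: per repetition, take the median ID
    score across sites; average those medians across repetitions; pick the
    argmax layer (earliest layer on ties)."""
    model = _single_model(table, model)
    df = table.scores.query("model == @model and domain == @ID_DOMAIN")
    if df.empty:
        raise ValueError("no ID scores to select from")
    per_layer = (
        df.groupby(["layer", "repetition"], sort=False)["score"]
        .median()
        .groupby("layer", sort=False)
        .mean()
        .reindex(table.layer_order[model])
        .dropna()
    )
    best = per_layer.idxmax()  # first occurrence wins ties, i.e. earliest layer
    mean_id = table.mean_scores(ID_DOMAIN, model).droplevel("model")
    sel = mean_id.loc[best]
    return MappingAssignment(
        scheme="layer_area",
        model=model,
        site_layers={site: best for site in sel.index},
        selection_scores=sel,
    )


def select_layer_neuron(
    table: PredictivityTable, model: str | None = None
) -> MappingAssignment:
    """Per-site best layer by repetition-averaged ID score (earliest on ties)."""
    model = _single_model(table, model)
    mean_id = table.mean_scores(ID_DOMAIN, model).droplevel("model")
    mean_id = mean_id.reindex(table.layer_order[model])
    site_layers = {}
    selection = {}
    for site in mean_id.columns:
        col = mean_id[site].dropna()
        if col.empty:
            continue
        best = col.idxmax()
        site_layers[site] = best
        selection[site] = col.loc[best]
    if not site_layers:
        raise ValueError("no valid ID scores to select from")
    return MappingAssignment(
        scheme="layer_neuron",
        model=model,
        site_layers=site_layers,
        selection_scores=pd.Series(selection),
    )


def _assigned_scores(
    table: PredictivityTable, assignment: MappingAssignment, domain: str
) -> pd.DataFrame:
    """Site x repetition matrix of scores at each site's assigned layer."""
    model = assignment.model
    df = table.scores.query("model == @model and domain == @domain")
    if df.empty:
        raise ValueError(f"no scores for domain {domain!r}")
    pivot = df.set_index(["layer", "site", "repetition"])["score"].sort_index()
    out = {}
    for site, layer in assignment.site_layers.items():
        out[site] = pivot.loc[(layer, site)]
    return pd.DataFrame(out).T  # sites x repetitions


def population_score(
    table: PredictivityTable, assignment: MappingAssignment, domain: str
) -> float:
    """Median across sites per repetition, then mean across repetitions."""
    mat = _assigned_scores(table, assignment, domain)
    per_rep = mat.median(axis=0, skipna=True)
    if per_rep.isna().all():
        raise ValueError("no valid site scores")
    return float(per_rep.mean())


@dataclass
class GapResult:
    """In- vs out-of-distribution population predictivity and their gap.

    ``c_gap`` is the difference of the two population scores; ``c_gap_sitewise``
    applies the median at the level of per-site score differences (median of
    differences rather than difference of medians) — the two usually agree
    closely but are not identical.
    """

    c_nat: float
    c_syn: float
    c_gap: float
    c_gap_sitewise: float
    per_site_gaps: pd.Series

    def __post_init__(self) -> None:
        assert abs(self.c_gap - (self.c_nat - self.c_syn)) < 1e-12


def generalization_gap(
    table: PredictivityTable, assignment: MappingAssignment
) -> GapResult:
    id_mat = _assigned_scores(table, assignment, ID_DOMAIN)
    ood_mat = _assigned_scores(table, assignment, OOD_DOMAIN)
    if ood_mat.isna().all(axis=None):
        raise ValueError("missing OOD scores")
    diffs = id_mat - ood_mat  # sites x repetitions
    c_gap_sitewise = float(diffs.median(axis=0, skipna=True).mean())
    c_nat = population_score(table, assignment, ID_DOMAIN)
    c_syn = population_score(table, assignment, OOD_DOMAIN)
    return GapResult(
        c_nat=c_nat,
        c_syn=c_syn,
        c_gap=c_nat - c_syn,
        c_gap_sitewise=c_gap_sitewise,
        per_site_gaps=diffs.median(axis=1, skipna=True),
    )


def site_class_summary(
    table: PredictivityTable,
    assignment: MappingAssignment,
    high: float = 0.6,
    low: float = 0.4,
) -> dict[str, dict[str, float]]:
    """Fraction of sites predicted well (> high) and poorly (< low) per domain."""
    if not (-1 < low <= high < 1):
        raise ValueError("thresholds must satisfy -1 < low <= high < 1")
    out = {}
    for domain in (ID_DOMAIN, OOD_DOMAIN):
        mean_site = _assigned_scores(table, assignment, domain).mean(axis=1)
        valid = mean_site.dropna()
        out[domain] = {
            "above_high": float((valid > high).mean()) if len(valid) else float("nan"),
            "below_low": float((valid < low).mean()) if len(valid) else float("nan"),
        }
    return out


def best_layer_offset(
    table: PredictivityTable, model: str | None = None
) -> tuple[pd.Series, float]:
    """Per site: (1-based index of best ID layer) - (index of best OOD layer).

    Negative mean offset means sites generalize out-of-distribution best
    from *deeper* layers than the ones that predict them best in
    distribution.
    """
    model = _single_model(table, model)
    order = table.layer_order[model]
    if len(order) < 2:
        warnings.warn("single layer: all offsets are zero", stacklevel=2)
    index_of = {layer: i + 1 for i, layer in enumerate(order)}
    offsets = {}
    for domain in (ID_DOMAIN, OOD_DOMAIN):
        mean = table.mean_scores(domain, model).droplevel("model").reindex(order)
        best = {
            site: index_of[mean[site].dropna().idxmax()]
            for site in mean.columns
            if mean[site].notna().any()
        }
        offsets[domain] = best
    sites = [s for s in offsets[ID_DOMAIN] if s in offsets[OOD_DOMAIN]]
    series = pd.Series(
        {s: offsets[ID_DOMAIN][s] - offsets[OOD_DOMAIN][s] for s in sites}, dtype=float
    )
    return series, float(series.mean())
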