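"""End-to-end orchestration: simulate, reduce, score, map, and summarize.

``run_pipeline`` wires the stages together on synthetic data with known
ground truth: generate stimuli and sessions, estimate measurement
reliability and drop unreliable sites, fit the reference PCA basis per
layer, score every candidate layer of every candidate model with
cross-validated PLS, apply both layer-mapping assumptions, compute the
cross-domain generalization gap, and build ensemble predictors.  A
persisted configuration re-executes to identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import consistency as cons
from . import ensembles as ens
from . import features, io, predictivity, synthetic
from .predictivity import CVConfig, PredictivityTable
from .synthetic import ID_DOMAIN, OOD_DOMAIN, DomainShift, TruthConfig

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "score_model",
    "metric_rank_correlation",
]

logger = logging.getLogger("vpgap")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run.

    Default sizes are desk-scale: 160 in-distribution + 80
    out-of-distribution stimuli, 300 reference stimuli, 40 sites read out
    from a 4-layer ReLU hierarchy, scored with 10-fold / 25-component /
    5-repetition cross-validated PLS.
    """

    seed: int = 0
    n_id: int = 160
    n_ood: int = 80
    n_reference: int = 300
    d_z: int = 8
    units_per_layer: list[int] = field(default_factory=lambda: [50, 50, 50, 50])
    nonlinearity: str = "relu"
    n_models: int = 1
    n_sites: int = 40
    rep_range: tuple[int, int] = (31, 51)
    shift_offset: float | list[float] = 0.0
    shift_cov_scale: float = 1.0
    weight_sparsity: float = 0.5
    noise_sd: float = 1.0
    baseline: float = 5.0
    ood_readout_perturbation: float = 0.0
    ood_layer_override: str | None = None
    ood_override_mix: float = 1.0
    true_layers: list[str] | None = None
    n_folds: int = 10
    n_components: int = 25
    n_repetitions: int = 5
    train_domain: str = ID_DOMAIN
    pca_components: int | None = None
    no_pca: bool = False
    consistency_splits: int = 100
    consistency_threshold: float = 0.7
    ensemble_k_layers: int = 3
    ensemble_k_models: int = 2
    mapping: str = "layer_neuron"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rep_range"] = list(self.rep_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rep_range" in d:
            d["rep_range"] = tuple(d["rep_range"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    table: PredictivityTable
    ground_truth: synthetic.SyntheticGroundTruth
    consistency: pd.DataFrame  # per-site internal consistency
    retained_sites: list[str]
    assignments: dict[str, predictivity.MappingAssignment]
    gaps: dict[str, predictivity.GapResult]
    site_classes: dict[str, dict[str, dict[str, float]]]
    layer_offsets: tuple[pd.Series, float]
    ensemble_scores: pd.DataFrame
    summary: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.ground_truth.to_json(out / "ground_truth.json")
        self.table.to_tsv(out / "scores.tsv")
        self.consistency.to_csv(out / "consistency.tsv", sep="\t", index=False)
        if not self.ensemble_scores.empty:
            self.ensemble_scores.to_csv(out / "ensemble_scores.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)


def _simulate(config: RunConfig):
    shift = DomainShift(
        offset=np.asarray(config.shift_offset, dtype=float)
        if isinstance(config.shift_offset, list)
        else float(config.shift_offset),
        cov_scale=config.shift_cov_scale,
    )
    stimuli = synthetic.generate_stimuli(
        config.n_id, config.n_ood, config.d_z, shift, seed=config.seed
    )
    # reference stimuli emulate a third, ID-like image set distinct from the
    # experimental stimuli
    reference = synthetic.generate_stimuli(
        config.n_reference, 2, config.d_z, DomainShift(), seed=config.seed + 1
    ).subset(ID_DOMAIN)
    hierarchies = [
        synthetic.generate_hierarchy(
            config.d_z, config.units_per_layer, config.nonlinearity, seed=config.seed + 10 + m
        )
        for m in range(config.n_models)
    ]
    truth = TruthConfig(
        true_layers=config.true_layers,
        weight_sparsity=config.weight_sparsity,
        noise_sd=config.noise_sd,
        baseline=config.baseline,
        ood_readout_perturbation=config.ood_readout_perturbation,
        ood_layer_override=config.ood_layer_override,
        ood_override_mix=config.ood_override_mix,
    )
    sessions, gt = synthetic.generate_sessions(
        hierarchies[0],
        stimuli,
        config.n_sites,
        truth,
        rep_range=config.rep_range,
        seed=config.seed + 2,
    )
    return stimuli, reference, hierarchies, sessions, gt


def score_model(
    hierarchy: synthetic.FeatureHierarchy,
    stimuli: synthetic.StimulusSet,
    reference: synthetic.StimulusSet,
    Y: dict[str, np.ndarray],
    site_ids: list[str],
    cv: CVConfig,
    model_name: str = "model0",
    no_pca: bool = False,
    pca_components: int | None = None,
) -> PredictivityTable:
    """Score every layer of one candidate model against one session.

    ``Y`` maps domain -> trial-averaged (stimuli x sites) responses aligned
    with the domain subsets of ``stimuli``.  Layers are reduced in the
    reference PCA basis unless ``no_pca``.
    """
    acts = synthetic.compute_activations(hierarchy, stimuli)
    ref_acts = synthetic.compute_activations(hierarchy, reference)
    table = PredictivityTable()
    train_dom, eval_dom = cv.train_domain, cv.eval_domain
    for layer in hierarchy.layer_names:
        if no_pca:
            Xl = acts[layer]
        else:
            basis = features.fit_reference_basis(ref_acts[layer], k=pca_components)
            Xl = features.project(acts[layer], basis)
        table.extend(
            predictivity.fit_score_layer(
                Xl.subset(train_dom),
                Xl.subset(eval_dom),
                Y[train_dom],
                Y[eval_dom],
                site_ids,
                cv,
                model_name=model_name,
            )
        )
    return table


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    logger.info("run %s (seed=%d)", config.config_hash(), config.seed)
    try:
        stimuli, reference, hierarchies, sessions, gt = _simulate(config)
    except Exception as e:  # pragma: no cover - defensive stage tagging
        raise RuntimeError(f"[simulate] {e}") from e

    # --- measurement reliability and site filtering -------------------------
    try:
        cons_rows = []
        id_sess = sessions[ID_DOMAIN]
        for site in id_sess.site_ids:
            res = cons.internal_consistency(
                id_sess.site_matrix(site),
                n_splits=config.consistency_splits,
                seed=_site_seed(config.seed + 3, site),
                site_id=site,
            )
            cons_rows.append((site, res.corrected, res.unreliable))
        cons_df = pd.DataFrame(
            cons_rows, columns=["site", "internal_consistency", "unreliable"]
        )
        results = [
            cons.InternalConsistencyResult(s, np.empty(0), c, config.consistency_splits, u)
            for s, c, u in cons_rows
        ]
        retained = cons.filter_sites(results, threshold=config.consistency_threshold)
        if not retained:
            raise ValueError("no site passes the internal-consistency threshold")
    except Exception as e:
        raise RuntimeError(f"[consistency] {e}") from e

    site_idx = [id_sess.site_ids.index(s) for s in retained]
    Y = {d: sessions[d].trial_mean()[:, site_idx] for d in (ID_DOMAIN, OOD_DOMAIN)}

    # --- basis fitting and scoring ------------------------------------------
    try:
        cv = CVConfig(
            n_folds=config.n_folds,
            n_components=config.n_components,
            n_repetitions=config.n_repetitions,
            train_domain=config.train_domain,
            seed=config.seed + 500,
        )
        table = PredictivityTable()
        for m, hier in enumerate(hierarchies):
            table.extend(
                score_model(
                    hier,
                    stimuli,
                    reference,
                    Y,
                    retained,
                    cv,
                    model_name=f"model{m}",
                    no_pca=config.no_pca,
                    pca_components=config.pca_components,
                )
            )
    except Exception as e:
        raise RuntimeError(f"[score] {e}") from e

    # --- mapping, gap, diagnostics ------------------------------------------
    try:
        primary = "model0"
        assignments = {
            "layer_area": predictivity.select_layer_area(table, primary),
            "layer_neuron": predictivity.select_layer_neuron(table, primary),
        }
        gaps = {k: predictivity.generalization_gap(table, a) for k, a in assignments.items()}
        site_classes = {
            k: predictivity.site_class_summary(table, a) for k, a in assignments.items()
        }
        offsets = predictivity.best_layer_offset(table, primary)
    except Exception as e:
        raise RuntimeError(f"[map] {e}") from e

    # --- ensembles -----------------------------------------------------------
    try:
        ens_rows = []
        for aggregator in ("mean", "median"):
            spec = ens.EnsembleSpec(
                scope="within_model",
                k_layers=config.ensemble_k_layers,
                aggregator=aggregator,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                members = ens.build_ensemble(table, spec, model=primary)
                scored = ens.aggregate_and_score(table, members, Y, aggregator)
            scored.insert(0, "scope", "within_model")
            scored.insert(1, "aggregator", aggregator)
            ens_rows.append(scored)
            if config.n_models > 1:
                spec = ens.EnsembleSpec(
                    scope="cross_model",
                    k_layers=config.ensemble_k_layers,
                    k_models=config.ensemble_k_models,
                    aggregator=aggregator,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    members = ens.build_ensemble(table, spec)
                    scored = ens.aggregate_and_score(table, members, Y, aggregator)
                scored.insert(0, "scope", "cross_model")
                scored.insert(1, "aggregator", aggregator)
                ens_rows.append(scored)
        ensemble_scores = pd.concat(ens_rows, ignore_index=True)
    except Exception as e:
        raise RuntimeError(f"[ensemble] {e}") from e

    chosen = assignments[config.mapping]
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sites_total": config.n_sites,
        "n_sites_retained": len(retained),
        "median_internal_consistency": float(cons_df["internal_consistency"].median()),
        "mapping": config.mapping,
        "population_score": {
            k: {
                ID_DOMAIN: predictivity.population_score(table, a, ID_DOMAIN),
                OOD_DOMAIN: predictivity.population_score(table, a, OOD_DOMAIN),
            }
            for k, a in assignments.items()
        },
        "gap": {
            k: {
                "c_nat": g.c_nat,
                "c_syn": g.c_syn,
                "c_gap": g.c_gap,
                "c_gap_sitewise": g.c_gap_sitewise,
            }
            for k, g in gaps.items()
        },
        "site_classes": site_classes,
        "mean_best_layer_offset": offsets[1],
        "ensemble_population_score": {
            f"{scope}/{agg}": {
                d: ens.ensemble_population_score(
                    ensemble_scores[
                        (ensemble_scores["scope"] == scope)
                        & (ensemble_scores["aggregator"] == agg)
                    ],
                    d,
                )
                for d in (ID_DOMAIN, OOD_DOMAIN)
            }
            for scope in ensemble_scores["scope"].unique()
            for agg in ("mean", "median")
        },
        "chosen_mapping_gap": gaps[config.mapping].c_gap,
        "chosen_assignment": {s: l for s, l in chosen.site_layers.items()},
    }

    result = PipelineResult(
        config=config,
        table=table,
        ground_truth=gt,
        consistency=cons_df,
        retained_sites=retained,
        assignments=assignments,
        gaps=gaps,
        site_classes=site_classes,
        layer_offsets=offsets,
        ensemble_scores=ensemble_scores,
        summary=summary,
    )
    if out_dir is not None:
        result.write(out_dir)
        io.write_sessions(Path(out_dir) / "responses.h5", sessions)
    return result


def _site_seed(base: int, site_id: str) -> int:
    """Per-site split seed independent of processing order."""
    h = hashlib.sha256(f"{base}:{site_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def metric_rank_correlation(
    metrics: pd.DataFrame, metric_name: str, domain: str
) -> tuple[float, float]:
    """Spearman rank correlation between an external per-model metric and
    per-model predictivity scores in one domain.

    ``metrics`` must carry one row per model with columns ``metric_name``
    and ``predictivity_<domain>``.  Returns (rho, two-sided p-value).
    """
    score_col = f"predictivity_{domain}"
    for col in (metric_name, score_col):
        if col not in metrics.columns:
            raise ValueError(f"column {col!r} missing from metric table")
    df = metrics[[metric_name, score_col]].dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 models with both values")
    if df[metric_name].std() < 1e-14:
        warnings.warn("constant metric: rank correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(df[metric_name], df[score_col])
    return float(res.statistic), float(res.pvalue)
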