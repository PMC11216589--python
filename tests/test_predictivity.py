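"""Cross-validated PLS scoring, layer mappings, gap statistic, and invariances."""

import numpy as np
import pandas as pd
import pytest

from _reference import reference_scores
from vpgap.predictivity import (
    CVConfig,
    PredictivityTable,
    SCORE_COLUMNS,
    best_layer_offset,
    fit_score_layer,
    generalization_gap,
    population_score,
    select_layer_area,
    select_layer_neuron,
    site_class_summary,
)
from vpgap.synthetic import ActivationSet


def _acts(X, domain, layer="L"):
    n = X.shape[0]
    pre = "i" if domain == "ID" else "o"
    return ActivationSet(layer, [f"{pre}{k}" for k in range(n)], [domain] * n, X)


def make_table(scores_by_layer, n_reps=1, model="m0", jitter=None):
    """Fixture table from {layer: {site: mean score}} for both domains.

    ``scores_by_layer`` may map to a scalar (same score in both domains) or
    a (id_score, ood_score) pair.  ``jitter`` adds per-repetition noise.
    """
    rng = np.random.default_rng(0)
    rows = []
    layers = list(scores_by_layer)
    sites = list(next(iter(scores_by_layer.values())))
    for layer in layers:
        for site in sites:
            val = scores_by_layer[layer][site]
            id_s, ood_s = (val, val) if np.isscalar(val) else val
            for r in range(n_reps):
                eps = rng.normal(0, jitter) if jitter else 0.0
                rows.append((model, layer, site, r, "ID", id_s + eps))
                rows.append((model, layer, site, r, "OOD", ood_s + eps))
    table = PredictivityTable(scores=pd.DataFrame(rows, columns=SCORE_COLUMNS))
    table.site_ids = sites
    table.layer_order = {model: layers}
    return table


class TestFitScoreLayer:
    def test_realizable_target_scores_near_one(self, rng):
        # responses exactly equal one predictor unit, noise-free
        X = rng.standard_normal((100, 8))
        Xo = rng.standard_normal((30, 8))
        Y, Yo = X[:, [2]], Xo[:, [2]]
        cv = CVConfig(n_folds=10, n_components=8, n_repetitions=1, seed=0)
        tab = fit_score_layer(_acts(X, "ID"), _acts(Xo, "OOD"), Y, Yo, ["s0"], cv)
        assert tab.scores.query("domain == 'ID'")["score"].iloc[0] >= 0.999

    def test_independent_responses_score_near_zero(self, rng):
        # Monte-Carlo null: responses permuted across stimuli.  Pooled
        # cross-validated correlation carries a small negative bias (each
        # fold's predictions depend on the other folds' targets through the
        # training means), so the null is centered near, not exactly at, 0.
        means = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 6))
            y = X @ r.standard_normal((6, 1))
            y = y[r.permutation(200)]
            cv = CVConfig(n_folds=5, n_components=5, n_repetitions=1, seed=seed)
            tab = fit_score_layer(
                _acts(X, "ID"), _acts(X[:10], "OOD"), y, y[:10], ["s0"], cv
            )
            means.append(tab.scores.query("domain == 'ID'")["score"].iloc[0])
        assert abs(np.mean(means)) < 0.1

    def test_matches_independent_reference_pipeline(self, rng):
        X = rng.standard_normal((40, 6))
        Xo = rng.standard_normal((20, 6))
        B = rng.standard_normal((6, 3))
        Y = X @ B + 0.5 * rng.standard_normal((40, 3))
        Yo = Xo @ B + 0.5 * rng.standard_normal((20, 3))
        cv = CVConfig(n_folds=5, n_components=4, n_repetitions=3, seed=11)
        tab = fit_score_layer(
            _acts(X, "ID"), _acts(Xo, "OOD"), Y, Yo, ["s0", "s1", "s2"], cv
        )
        ref_id, ref_ood = reference_scores(X, Xo, Y, Yo, 5, 4, 3, 11)
        got_id = tab.scores.query("domain=='ID'").pivot(
            index="repetition", columns="site", values="score"
        ).values
        got_ood = tab.scores.query("domain=='OOD'").pivot(
            index="repetition", columns="site", values="score"
        ).values
        assert np.abs(got_id - ref_id).max() < 1e-8
        assert np.abs(got_ood - ref_ood).max() < 1e-8

    def test_same_seed_reproduces_bitwise(self, rng):
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 2))
        cv = CVConfig(n_folds=5, n_components=3, n_repetitions=2, seed=5)
        args = (_acts(X, "ID"), _acts(X[:8], "OOD"), Y, Y[:8], ["a", "b"])
        t1 = fit_score_layer(*args, cv)
        t2 = fit_score_layer(*args, cv)
        assert t1.scores["score"].equals(t2.scores["score"])
        k = ("model", "L", "ID")
        assert np.array_equal(t1.predictions[k], t2.predictions[k])

    def test_component_count_reduced_to_rank_with_warning(self, rng):
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 1))
        cv = CVConfig(n_folds=4, n_components=10, n_repetitions=1, seed=1)
        with pytest.warns(UserWarning, match="reducing PLS components"):
            fit_score_layer(_acts(X, "ID"), _acts(X[:5], "OOD"), Y, Y[:5], ["s"], cv)

    def test_zero_variance_site_recorded_as_missing(self, rng):
        X = rng.standard_normal((30, 5))
        Y = np.column_stack([X @ rng.standard_normal(5), np.full(30, 2.0)])
        cv = CVConfig(n_folds=5, n_components=3, n_repetitions=1, seed=2)
        with pytest.warns(UserWarning, match="undefined correlation"):
            tab = fit_score_layer(
                _acts(X, "ID"), _acts(X[:6], "OOD"), Y, Y[:6], ["ok", "flat"], cv
            )
        df = tab.scores.set_index(["site", "domain"])["score"]
        assert np.isnan(df.loc[("flat", "ID")].item())
        assert np.isfinite(df.loc[("ok", "ID")].item())

    def test_shared_affine_rescaling_leaves_scores_unchanged(self, rng):
        X = rng.standard_normal((40, 6))
        Y = X @ rng.standard_normal((6, 3)) + 0.3 * rng.standard_normal((40, 3))
        cv = CVConfig(n_folds=5, n_components=4, n_repetitions=1, seed=3)
        base = fit_score_layer(_acts(X, "ID"), _acts(X[:8], "OOD"), Y, Y[:8], list("abc"), cv)
        scaled = fit_score_layer(
            _acts(X, "ID"), _acts(X[:8], "OOD"), 3.7 * Y + 11.0, 3.7 * Y[:8] + 11.0,
            list("abc"), cv,
        )
        assert np.allclose(base.scores["score"], scaled.scores["score"], atol=1e-10)

    def test_per_site_mode_invariant_to_single_site_rescaling(self, rng):
        X = rng.standard_normal((40, 6))
        Y = X @ rng.standard_normal((6, 3)) + 0.3 * rng.standard_normal((40, 3))
        cv = CVConfig(n_folds=5, n_components=4, n_repetitions=1, seed=3, per_site=True)
        Y2 = Y.copy()
        Y2[:, 1] = 5.0 * Y2[:, 1] - 2.0
        base = fit_score_layer(_acts(X, "ID"), _acts(X[:8], "OOD"), Y, Y[:8], list("abc"), cv)
        mod = fit_score_layer(
            _acts(X, "ID"), _acts(X[:8], "OOD"), Y2, np.column_stack(
                [Y[:8, 0], 5.0 * Y[:8, 1] - 2.0, Y[:8, 2]]
            ), list("abc"), cv,
        )
        assert np.allclose(base.scores["score"], mod.scores["score"], atol=1e-10)

    def test_orthonormal_rotation_of_predictors_leaves_scores_unchanged(self, rng):
        X = rng.standard_normal((40, 6))
        Y = X @ rng.standard_normal((6, 2)) + 0.3 * rng.standard_normal((40, 2))
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        cv = CVConfig(n_folds=5, n_components=4, n_repetitions=1, seed=4)
        base = fit_score_layer(_acts(X, "ID"), _acts(X[:8], "OOD"), Y, Y[:8], ["a", "b"], cv)
        rot = fit_score_layer(
            _acts(X @ Q, "ID"), _acts(X[:8] @ Q, "OOD"), Y, Y[:8], ["a", "b"], cv
        )
        assert np.allclose(base.scores["score"], rot.scores["score"], atol=1e-8)


class TestLayerMappings:
    def test_single_layer_maps_to_itself(self):
        t = make_table({"L1": {"a": 0.5, "b": 0.7}})
        assert set(select_layer_area(t).site_layers.values()) == {"L1"}

    def test_layer_area_matches_brute_force_median_argmax(self, rng):
        layers = ["L1", "L2", "L3"]
        sites = [f"s{i}" for i in range(7)]
        vals = {l: {s: rng.uniform(0, 1) for s in sites} for l in layers}
        t = make_table(vals, n_reps=3, jitter=0.05)
        id_scores = t.scores[t.scores["domain"] == "ID"]
        layer_means = {}
        for l in layers:
            per_rep = []
            for r in range(3):
                sub = id_scores[(id_scores["layer"] == l) & (id_scores["repetition"] == r)]
                per_rep.append(np.median(sub["score"].to_numpy()))
            layer_means[l] = np.mean(per_rep)
        best = max(layers, key=layer_means.get)
        assert set(select_layer_area(t).site_layers.values()) == {best}

    def test_layer_area_tie_prefers_earlier_layer(self):
        t = make_table({"L1": {"a": 0.6, "b": 0.6}, "L2": {"a": 0.6, "b": 0.6}})
        assert set(select_layer_area(t).site_layers.values()) == {"L1"}

    def test_layer_neuron_picks_per_site_argmax(self):
        t = make_table(
            {"L1": {"A": 0.9, "B": 0.2}, "L2": {"A": 0.5, "B": 0.5}, "L3": {"A": 0.1, "B": 0.8}}
        )
        assert select_layer_neuron(t).site_layers == {"A": "L1", "B": "L3"}

    def test_mappings_agree_when_one_layer_dominates(self):
        t = make_table({"L1": {"a": 0.3, "b": 0.4}, "L2": {"a": 0.8, "b": 0.9}})
        assert select_layer_area(t).site_layers == select_layer_neuron(t).site_layers

    def test_layer_neuron_selection_median_dominates_layer_area(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            layers = ["L1", "L2", "L3", "L4"]
            sites = [f"s{i}" for i in range(9)]
            t = make_table(
                {l: {s: r.uniform(-0.2, 1) for s in sites} for l in layers},
                n_reps=2,
                jitter=0.1,
            )
            ln = select_layer_neuron(t).selection_scores.median()
            la = select_layer_area(t).selection_scores.median()
            assert ln >= la


class TestPopulationAndGap:
    def test_single_site_single_repetition_passthrough(self):
        t = make_table({"L1": {"a": (0.8, 0.5)}})
        a = select_layer_area(t)
        assert population_score(t, a, "ID") == pytest.approx(0.8)
        g = generalization_gap(t, a)
        assert g.c_gap == pytest.approx(0.3)
        assert g.c_gap_sitewise == pytest.approx(0.3)

    def test_identical_domain_scores_give_zero_gap(self):
        t = make_table({"L1": {s: 0.6 for s in "abcd"}})
        g = generalization_gap(t, select_layer_area(t))
        assert g.c_gap == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_median_then_mean(self, rng):
        sites = [f"s{i}" for i in range(5)]
        id_s = rng.uniform(0, 1, (5, 3))
        ood_s = rng.uniform(0, 1, (5, 3))
        rows = []
        for i, s in enumerate(sites):
            for r in range(3):
                rows.append(("m0", "L1", s, r, "ID", id_s[i, r]))
                rows.append(("m0", "L1", s, r, "OOD", ood_s[i, r]))
        t = PredictivityTable(scores=pd.DataFrame(rows, columns=SCORE_COLUMNS))
        t.site_ids = sites
        t.layer_order = {"m0": ["L1"]}
        a = select_layer_area(t)
        assert population_score(t, a, "ID") == pytest.approx(
            np.mean(np.median(id_s, axis=0))
        )
        g = generalization_gap(t, a)
        assert g.c_gap_sitewise == pytest.approx(
            np.mean(np.median(id_s - ood_s, axis=0))
        )
        assert g.c_gap == pytest.approx(
            np.mean(np.median(id_s, axis=0)) - np.mean(np.median(ood_s, axis=0))
        )

    def test_constant_scores_return_constant(self):
        t = make_table({"L1": {s: 0.42 for s in "abc"}}, n_reps=2)
        assert population_score(t, select_layer_area(t), "ID") == pytest.approx(0.42)


class TestSiteClassSummary:
    def test_all_high(self):
        t = make_table({"L1": {s: 0.9 for s in "abc"}})
        out = site_class_summary(t, select_layer_area(t))
        assert out["ID"] == {"above_high": 1.0, "below_low": 0.0}

    def test_direct_count(self):
        t = make_table({"L1": {"a": 0.7, "b": 0.5, "c": 0.3}})
        out = site_class_summary(t, select_layer_area(t))
        assert out["ID"]["above_high"] == pytest.approx(1 / 3)
        assert out["ID"]["below_low"] == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_fixture(self, rng):
        sites = [f"s{i}" for i in range(20)]
        vals = {s: rng.uniform(-0.2, 1.0) for s in sites}
        t = make_table({"L1": vals})
        out = site_class_summary(t, select_layer_area(t))
        arr = np.array(list(vals.values()))
        assert out["ID"]["above_high"] == pytest.approx((arr > 0.6).mean())
        assert out["ID"]["below_low"] == pytest.approx((arr < 0.4).mean())


class TestBestLayerOffset:
    def test_direct_definition(self):
        t = make_table(
            {
                "L1": {"a": (0.1, 0.2)},
                "L2": {"a": (0.9, 0.3)},
                "L3": {"a": (0.2, 0.4)},
                "L4": {"a": (0.3, 0.9)},
            }
        )
        offsets, mean = best_layer_offset(t)
        assert offsets["a"] == -2  # best ID layer 2, best OOD layer 4
        assert mean == -2

    def test_identical_profiles_give_zero_offsets(self, rng):
        sites = list("abcd")
        t = make_table(
            {l: {s: rng.uniform(0, 1) for s in sites} for l in ["L1", "L2", "L3"]}
        )
        offsets, mean = best_layer_offset(t)
        assert (offsets == 0).all() and mean == 0

    def test_matches_brute_force_argmax_on_random_fixture(self, rng):
        layers = [f"L{i}" for i in range(1, 6)]
        sites = [f"s{i}" for i in range(25)]
        vals = {
            l: {s: (rng.uniform(0, 1), rng.uniform(0, 1)) for s in sites}
            for l in layers
        }
        t = make_table(vals)
        offsets, mean = best_layer_offset(t)
        for s in sites:
            id_best = int(np.argmax([vals[l][s][0] for l in layers])) + 1
            ood_best = int(np.argmax([vals[l][s][1] for l in layers])) + 1
            assert offsets[s] == id_best - ood_best
        assert mean == pytest.approx(offsets.mean())

    def test_single_layer_warns_and_returns_zeros(self):
        t = make_table({"L1": {"a": 0.5}})
        with pytest.warns(UserWarning, match="single layer"):
            offsets, mean = best_layer_offset(t)
        assert mean == 0


def test_table_tsv_roundtrip(tmp_path, scored_world):
    path = tmp_path / "scores.tsv"
    scored_world.to_tsv(path)
    back = PredictivityTable.from_tsv(path)
    a = scored_world.scores.sort_values(SCORE_COLUMNS[:5]).reset_index(drop=True)
    b = back.scores.sort_values(SCORE_COLUMNS[:5]).reset_index(drop=True)
    assert np.allclose(a["score"], b["score"], equal_nan=True)
    assert back.layer_order == scored_world.layer_order
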