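"""Expression/variation filters and membership-based regulator calls."""

import numpy as np
import pandas as pd
import pytest

import splicedyn.synthetic_data as sd
from conftest import make_sample_map
from splicedyn.core_io import ExprTable
from splicedyn.regulator_inference import (
    filter_expressed_variable,
    host_gene_concordance,
    infer_regulators,
)
from splicedyn.temporal_clustering import ClusterModel, fuzzy_cmeans, scale_profiles


def _expr(rows: dict[str, list[float]], unit="cpm") -> ExprTable:
    n = len(next(iter(rows.values())))
    samples = make_sample_map([f"c{i}" for i in range(n)], n_reps=1)
    vals = pd.DataFrame(rows, dtype=float).T
    vals.columns = samples.sample_ids
    return ExprTable(vals, samples, unit, is_subset=True)


def _model_from_specs(specs=None) -> tuple[ClusterModel, list]:
    specs = specs or sd.default_trajectory_specs()
    centroids = sd.cluster_centroid_profiles(specs)
    k = len(specs)
    model = ClusterModel(k=k, m=1.25, centroids=centroids,
                         memberships=np.full((1, k), 1.0 / k),
                         iterations=0, objective=0.0)
    return model, specs


class TestFilter:
    def test_expression_passes_but_cv_decides(self):
        e = _expr({"g": [6, 6, 6, 6, 0, 0]})
        out = filter_expressed_variable(e)
        # expressed in 4 >= ceil(6/3)=2 samples, CV = sd/mean = 0.775 >= 0.2
        assert list(out.values.index) == ["g"]

    def test_constant_gene_dropped_by_cv(self):
        e = _expr({"g": [10.0] * 6})
        assert len(filter_expressed_variable(e).values) == 0

    def test_expression_boundary_is_inclusive(self):
        # cpm >= 5 in exactly ceil(6/3) = 2 samples: kept
        e = _expr({"g": [5, 5, 1, 1, 1, 1]})
        assert list(filter_expressed_variable(e).values.index) == ["g"]
        # one sample fewer: dropped
        e2 = _expr({"g": [5, 1, 1, 1, 1, 1]})
        assert len(filter_expressed_variable(e2).values) == 0

    def test_counts_unit_rejected(self):
        e = _expr({"g": [1, 2, 3]}, unit="counts")
        with pytest.raises(ValueError, match="cpm"):
            filter_expressed_variable(e)


class TestInferRegulators:
    def test_noiseless_planted_regulator_yields_single_call(self):
        model, specs = _model_from_specs()
        expr, _ = sd.simulate_rbp_expression(specs, 1, 0, 0, noise_sd=0.0,
                                             seed=0)
        scaled, _ = scale_profiles(
            filter_expressed_variable(expr).values)
        calls = infer_regulators(scaled, model)
        by_rbp = {}
        for c in calls:
            by_rbp.setdefault(c.rbp_id, []).append(c)
        for rbp, cs in by_rbp.items():
            assert len(cs) == 1
            assert cs[0].polarity == "positive"
            cluster = rbp.removeprefix("pos_").rsplit("_", 1)[0]
            assert specs[cs[0].cluster_id].cluster_id == cluster

    def test_planted_negative_regulator_has_negative_polarity(self):
        model, specs = _model_from_specs()
        expr, _ = sd.simulate_rbp_expression(specs, 0, 1, 0, noise_sd=0.0,
                                             seed=0)
        scaled, _ = scale_profiles(filter_expressed_variable(expr).values)
        calls = infer_regulators(scaled, model)
        assert calls and all(c.polarity == "negative" for c in calls)

    def test_polarity_antisymmetry(self, rng):
        model, specs = _model_from_specs()
        x = rng.normal(0, 1, (40, model.centroids.shape[1]))
        scaled, _ = scale_profiles(x)
        fwd = infer_regulators(scaled, model)
        rev = infer_regulators(-scaled, model)
        flip = {"positive": "negative", "negative": "positive"}
        fwd_set = {(c.rbp_id, c.cluster_id, c.polarity) for c in fwd}
        rev_set = {(c.rbp_id, c.cluster_id, flip[c.polarity]) for c in rev}
        assert fwd_set == rev_set

    def test_threshold_monotonicity(self, rng):
        model, _ = _model_from_specs()
        scaled, _ = scale_profiles(rng.normal(0, 1, (60, 12)))
        loose = infer_regulators(scaled, model, membership_min=0.2)
        strict = infer_regulators(scaled, model, membership_min=0.4)
        loose_set = {(c.rbp_id, c.cluster_id, c.polarity) for c in loose}
        strict_set = {(c.rbp_id, c.cluster_id, c.polarity) for c in strict}
        assert strict_set <= loose_set

    def test_unscaled_input_detected(self):
        model, _ = _model_from_specs()
        raw = pd.DataFrame(np.full((3, 12), 50.0))
        with pytest.raises(ValueError, match="scaled"):
            infer_regulators(raw, model)

    def test_recovery_with_noise(self):
        """Planted regulators recovered with precision/recall >= 0.8."""
        specs = sd.default_trajectory_specs()
        x, _ = sd.simulate_scaled_trajectories(100, specs, noise_sd=0.3,
                                               seed=20)
        scaled, _ = scale_profiles(x)
        model = fuzzy_cmeans(scaled, k=6, m=1.25, seed=21, n_restarts=10)
        mapping = sd.match_centroids(model.centroids, specs)
        expr, truth = sd.simulate_rbp_expression(specs, 5, 5, 200,
                                                 noise_sd=0.3, seed=22)
        sc, _ = scale_profiles(filter_expressed_variable(expr).values)
        calls = infer_regulators(sc, model)
        pred = {(c.rbp_id, mapping[c.cluster_id], c.polarity) for c in calls}
        want = {(r, row["cluster_id"], row["role"])
                for r, row in truth.rbps.iterrows()
                if row["role"] in ("positive", "negative")}
        tp = len(pred & want)
        assert tp / len(pred) >= 0.8
        assert tp / len(want) >= 0.8


class TestHostGeneConcordance:
    def test_constant_hosts_are_never_concordant(self):
        model, _ = _model_from_specs()
        e = _expr({"g0": [50.0] * 12, "g1": [50.0] * 12})
        frac = host_gene_concordance(
            e, model, {"ev0": "g0", "ev1": "g1"},
            {"ev0": 0, "ev1": 0})
        assert frac.loc[0, "concordant"] == 0
        assert frac.loc[0, "contrasting"] == 0
        assert frac.loc[0, "neither"] == 1.0

    def test_centroid_host_is_concordant(self):
        model, specs = _model_from_specs()
        vals = 100 + 20 * sd.cluster_centroid_profiles(specs)[0]
        e = _expr({"g0": list(vals)})
        frac = host_gene_concordance(e, model, {"ev0": "g0"}, {"ev0": 0})
        assert frac.loc[0, "concordant"] == 1.0

    def test_planted_mixture_fractions_recovered(self, rng):
        """10% concordant / 10% contrasting / 80% independent hosts."""
        model, specs = _model_from_specs()
        centroid = sd.cluster_centroid_profiles(specs)[2]
        n = 400
        rows, mapping, clusters = {}, {}, {}
        for i in range(n):
            if i < 40:
                prof = centroid + rng.normal(0, 0.2, 12)
            elif i < 80:
                prof = -centroid + rng.normal(0, 0.2, 12)
            else:
                prof = rng.normal(0, 1, 12)
            rows[f"g{i}"] = list(100 + 20 * prof)
            mapping[f"ev{i}"] = f"g{i}"
            clusters[f"ev{i}"] = 2
        frac = host_gene_concordance(_expr(rows), model, mapping, clusters)
        assert frac.loc[2, "concordant"] == pytest.approx(0.10, abs=0.03)
        assert frac.loc[2, "contrasting"] == pytest.approx(0.10, abs=0.03)

    def test_fractions_sum_to_one(self, rng):
        model, _ = _model_from_specs()
        rows = {f"g{i}": list(rng.uniform(10, 100, 12)) for i in range(20)}
        mapping = {f"ev{i}": f"g{i}" for i in range(20)}
        clusters = {f"ev{i}": i % 3 for i in range(20)}
        frac = host_gene_concordance(_expr(rows), model, mapping, clusters)
        total = frac[["concordant", "contrasting", "neither"]].sum(axis=1)
        assert np.allclose(total, 1.0)
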