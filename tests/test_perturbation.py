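"""ΔΔPSI dependency classification, control sets, overlap statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splicedyn.synthetic_data as sd
from conftest import fisher_exact_oracle, make_psi_table, make_sample_map
from splicedyn.core_io import PauTable, SpliceEvent
from splicedyn.perturbation import (
    PerturbationDesign,
    as_apa_overlap,
    classify_apa_dependency,
    classify_dependency,
    delta_delta,
    overlap_stats,
    psi_distribution_shift_test,
    select_control_exons,
)


def _design(n_arms=1):
    arms = tuple(f"t{i}" for i in range(n_arms))
    return PerturbationDesign("base", "ctrl", arms)


class TestDeltaDelta:
    def test_hand_arithmetic(self):
        t = make_psi_table({"base": [[40.0, 40.0]], "ctrl": [[60.0, 60.0]],
                            "t0": [[45.0, 45.0]]})
        dd = delta_delta(t, _design())
        assert dd["t0"].iloc[0] == pytest.approx(-15.0)

    def test_treatment_equal_control_gives_zero(self):
        t = make_psi_table({"base": [[40.0, 40.0]], "ctrl": [[60.0, 62.0]],
                            "t0": [[60.0, 62.0]]})
        assert delta_delta(t, _design())["t0"].iloc[0] == pytest.approx(0.0)

    def test_baseline_cancels(self, rng):
        """ΔΔ is algebraically independent of the baseline values."""
        common = {"ctrl": rng.uniform(0, 100, (20, 2)),
                  "t0": rng.uniform(0, 100, (20, 2))}
        t1 = make_psi_table({"base": rng.uniform(0, 100, (20, 2)), **common})
        t2 = make_psi_table({"base": rng.uniform(0, 100, (20, 2)), **common})
        a = delta_delta(t1, _design())["t0"]
        b = delta_delta(t2, _design())["t0"]
        assert np.allclose(a, b)

    def test_missing_design_condition_rejected(self):
        t = make_psi_table({"base": [[40.0, 40.0]], "ctrl": [[60.0, 60.0]]})
        with pytest.raises(ValueError, match="t0"):
            delta_delta(t, _design())


class TestClassifyDependency:
    def _two_arm_table(self, arm_vals: list[tuple[float, float]],
                       base=30.0, ctrl=60.0):
        n = len(arm_vals)
        return make_psi_table({
            "base": [[base, base]] * n,
            "ctrl": [[ctrl, ctrl]] * n,
            "t0": [[ctrl + v[0]] * 2 for v in arm_vals],
            "t1": [[ctrl + v[1]] * 2 for v in arm_vals],
        })

    def test_both_arms_passing_is_dependent(self):
        t = self._two_arm_table([(-20.0, -18.0)])
        ds = classify_dependency(t, _design(2))
        assert set(ds.dependent) == {"ev0"}

    def test_discordant_arms_is_unclassified(self):
        t = self._two_arm_table([(-20.0, -4.0)])
        ds = classify_dependency(t, _design(2))
        assert "ev0" in ds.unclassified

    def test_changing_event_with_tiny_ddpsi_is_independent(self):
        t = self._two_arm_table([(0.5, -1.0)])  # base->ctrl shift = 30
        ds = classify_dependency(t, _design(2))
        assert "ev0" in ds.independent

    def test_sets_are_disjoint_and_cover_events(self, rng):
        t, design, _ = sd.simulate_perturbation(30, 30, 30, seed=1)
        ds = classify_dependency(t, design)
        dep = set(ds.dependent)
        assert not dep & ds.independent
        assert not dep & ds.unclassified
        assert dep | ds.independent | ds.unclassified == set(t.event_ids)

    def test_replicate_relabeling_invariance(self):
        t, design, _ = sd.simulate_perturbation(20, 20, 20, seed=2)
        ds1 = classify_dependency(t, design)
        # swap the two replicate columns of every condition
        cols = []
        for cond in t.samples.conditions:
            s = t.samples.samples_of(cond)
            cols.extend(s[::-1])
        from splicedyn.core_io import PsiTable
        t2 = PsiTable.build(
            t.events, t.samples,
            t.psi[cols].set_axis(t.samples.sample_ids, axis=1),
            t.reads[cols].set_axis(t.samples.sample_ids, axis=1))
        ds2 = classify_dependency(t2, design)
        assert set(ds1.dependent) == set(ds2.dependent)
        assert ds1.independent == ds2.independent

    def test_noiseless_truth_recovered_exactly(self):
        t, design, truth = sd.simulate_perturbation(25, 25, 25,
                                                    rep_noise_sd=0.0, seed=3)
        ds = classify_dependency(t, design)
        st = truth.perturbation["status"]
        assert set(ds.dependent) == set(st[st == "dependent"].index)
        assert ds.independent == set(st[st == "independent"].index)


class TestOverlapStats:
    def test_identical_sets_fully_concordant(self):
        from splicedyn.perturbation import DependencySet
        a = DependencySet({"e1": 12.0, "e2": -15.0}, set(), set())
        b = DependencySet({"e1": 20.0, "e2": -3.0}, set(), set())
        out = overlap_stats(a, b)
        assert out["n_shared"] == 2
        assert out["jaccard"] == 1.0
        assert out["direction_concordance"] == 1.0

    def test_disjoint_sets(self):
        from splicedyn.perturbation import DependencySet
        a = DependencySet({"e1": 12.0}, set(), set())
        b = DependencySet({"e2": 12.0}, set(), set())
        out = overlap_stats(a, b)
        assert out["n_shared"] == 0 and out["jaccard"] == 0.0

    def test_zero_ddpsi_excluded_from_concordance(self):
        from splicedyn.perturbation import DependencySet
        a = DependencySet({"e1": 0.0, "e2": 5.0}, set(), set())
        b = DependencySet({"e1": 3.0, "e2": 5.0}, set(), set())
        out = overlap_stats(a, b)
        assert out["n_zero_excluded"] == 1
        assert out["direction_concordance"] == 1.0

    def test_random_overlap_matches_hypergeometric(self, rng):
        universe = [f"e{i}" for i in range(4000)]
        from splicedyn.perturbation import DependencySet
        shared = []
        for _ in range(60):
            sa = set(rng.choice(universe, 300, replace=False))
            sb = set(rng.choice(universe, 350, replace=False))
            a = DependencySet({e: 1.0 for e in sa}, set(), set())
            b = DependencySet({e: 1.0 for e in sb}, set(), set())
            shared.append(overlap_stats(a, b)["n_shared"])
        expected = 300 * 350 / 4000  # hypergeometric mean
        assert np.mean(shared) == pytest.approx(expected, rel=0.1)


class TestControlExons:
    def test_candidate_rules(self):
        t = make_psi_table({
            "a": [[50.0, 50.0], [95.0, 95.0], [50.0, 50.0]],
            "b": [[50.5, 50.5], [95.0, 95.0], [70.0, 70.0]],
        })
        out = select_control_exons(t, ["a", "b"], set(), size=1, seed=0)
        assert out == {"ev0"}  # ev1 extreme PSI, ev2 changes by 20

    def test_exclusions_and_determinism(self):
        t = make_psi_table({"a": [[50.0, 50.0]] * 50,
                            "b": [[50.5, 50.5]] * 50})
        s1 = select_control_exons(t, ["a", "b"], {"ev0"}, size=10, seed=7)
        s2 = select_control_exons(t, ["a", "b"], {"ev0"}, size=10, seed=7)
        assert s1 == s2 and "ev0" not in s1 and len(s1) == 10

    def test_short_candidate_list_returned_with_warning(self):
        t = make_psi_table({"a": [[50.0, 50.0]] * 3,
                            "b": [[50.5, 50.5]] * 3})
        with pytest.warns(UserWarning, match="candidates"):
            out = select_control_exons(t, ["a", "b"], set(), size=10, seed=0)
        assert len(out) == 3


class TestPsiDistributionShift:
    def test_symmetric_table_gives_or_one(self):
        psi = {"a": [[50.0, 50.0]] * 10 + [[90.0, 90.0]] * 10,
               "b": [[50.0, 50.0]] * 10 + [[90.0, 90.0]] * 10}
        t = make_psi_table(psi)
        out = psi_distribution_shift_test(t, set(t.event_ids), "a", "b")
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_p_matches_enumeration_oracle(self):
        psi = {"a": [[50.0, 50.0]] * 20 + [[90.0, 90.0]] * 5,
               "b": [[50.0, 50.0]] * 5 + [[90.0, 90.0]] * 20}
        # construct a table where the same events flip between conditions
        t = make_psi_table(psi)
        out = psi_distribution_shift_test(t, set(t.event_ids), "a", "b")
        table = [list(out["counts"]["a"]), list(out["counts"]["b"])]
        assert out["p"] == pytest.approx(fisher_exact_oracle(table),
                                         abs=1e-12)

    def test_empty_event_set_rejected(self):
        t = make_psi_table({"a": [[50.0, 50.0]], "b": [[50.0, 50.0]]})
        with pytest.raises(ValueError):
            psi_distribution_shift_test(t, set(), "a", "b")


class TestApa:
    def _pau_table(self, tpm_low_sites=(), shift_genes=("gA",)):
        conds = ["base", "ctrl", "t0", "t1"]
        samples = make_sample_map(conds, n_reps=3)
        genes = ["gA", "gA", "gB", "gB"]
        n = len(genes)
        sites = pd.DataFrame({
            "gene_id": genes, "chrom": ["chr1"] * n,
            "start": np.arange(n) * 1000, "end": np.arange(n) * 1000 + 300,
            "strand": ["+"] * n,
        }, index=pd.Index([f"s{i}" for i in range(n)], name="polyA_site_id"))
        pau = pd.DataFrame(50.0, index=sites.index,
                           columns=samples.sample_ids)
        # in shifted genes the first site gains 13 PAU in both arms
        first_site = {"gA": "s0", "gB": "s2"}
        second_site = {"gA": "s1", "gB": "s3"}
        for gene in shift_genes:
            for arm in ("t0", "t1"):
                for s in samples.samples_of(arm):
                    pau.loc[first_site[gene], s] = 63.0
                    pau.loc[second_site[gene], s] = 37.0
        tpm = pd.DataFrame(10.0, index=sites.index,
                           columns=samples.sample_ids)
        for site in tpm_low_sites:
            tpm.loc[site] = [10.0] * 9 + [1.0] * 3  # only 9 of 12 pass
        return PauTable(sites, samples, pau, tpm)

    def test_shifted_sites_called_dependent(self):
        p = self._pau_table()
        dep_sites, dep_genes = classify_apa_dependency(p, _design(2))
        assert set(dep_sites) == {"s0", "s1"} and dep_genes == {"gA"}

    def test_gene_left_with_single_expressed_site_filtered(self):
        # gB shifts too, but its second site fails the tpm filter, so
        # the gene drops below the two-site minimum
        p = self._pau_table(tpm_low_sites=("s3",), shift_genes=("gA", "gB"))
        dep_sites, dep_genes = classify_apa_dependency(p, _design(2))
        assert "s2" not in dep_sites and dep_genes == {"gA"}

    def test_expression_boundary_ten_of_twelve(self):
        p = self._pau_table(tpm_low_sites=("s0",))
        dep_sites, _ = classify_apa_dependency(p, _design(2))
        assert "s0" not in dep_sites


class TestAsApaOverlap:
    def _events(self, spans):
        return [SpliceEvent(f"e{i}", f"g{i}", "CEx", "chr1", s, t,
                            s + 1, s + 2, "+")
                for i, (s, t) in enumerate(spans)]

    def _sites(self, ivs):
        return pd.DataFrame({
            "gene_id": [f"ag{i}" for i in range(len(ivs))],
            "chrom": ["chr1"] * len(ivs),
            "start": [a for a, _ in ivs], "end": [b for _, b in ivs],
            "strand": ["+"] * len(ivs),
        }, index=pd.Index([f"s{i}" for i in range(len(ivs))],
                          name="polyA_site_id"))

    def test_shared_base_is_overlap(self):
        pairs, _ = as_apa_overlap(self._events([(100, 500)]),
                                  self._sites([(400, 600)]))
        assert pairs == [("e0", "s0")]

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        pairs, _ = as_apa_overlap(self._events([(100, 200)]),
                                  self._sites([(200, 300)]))
        assert pairs == []

    def test_matches_all_pairs_oracle(self, rng):
        spans = [(int(a), int(a) + int(l)) for a, l in
                 zip(rng.integers(0, 10_000, 80), rng.integers(1, 800, 80))]
        ivs = [(int(a), int(a) + int(l)) for a, l in
               zip(rng.integers(0, 10_000, 60), rng.integers(1, 500, 60))]
        events = self._events(spans)
        sites = self._sites(ivs)
        pairs, _ = as_apa_overlap(events, sites)
        oracle = {(e.event_id, s)
                  for e in events for s, row in sites.iterrows()
                  if max(e.span_start, row["start"]) < min(e.span_end,
                                                           row["end"])}
        assert set(pairs) == oracle
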