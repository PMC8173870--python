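"""Sequence features, splice-site scoring, rank tests and RNA maps."""

import numpy as np
import pytest

import splicedyn.synthetic_data as sd
from conftest import mannwhitney_u_oracle
from splicedyn.seq_features import (
    FeatureVector,
    compare_features,
    compute_features,
    gc_content,
    motif_match_starts,
    rna_map,
    score_splice_site,
    train_splice_site_model,
    window_coverage,
)


class TestFeatures:
    def test_gc_content_examples(self):
        assert gc_content("GGCC") == 1.0
        assert gc_content("ATAT") == 0.0
        assert gc_content("ACGT") == 0.5

    def test_lengths_from_sequences(self):
        seqs = {"e1": {"exon": "A" * 84, "intron_up": "C" * 300,
                       "intron_down": "G" * 500}}
        (f,) = compute_features(seqs)
        assert f.exon_length == 84
        assert f.up_intron_length == 300
        assert f.down_intron_length == 500
        assert np.isnan(f.score_5ss)  # no model supplied

    def test_gc_of_random_sequence_near_half(self, rng):
        loci = sd.simulate_loci(200, 0, "TTTTT", p_plant=0.0, seed=1)
        feats = compute_features(loci.feature_windows())
        gcs = [f.gc_exon for f in feats]
        se = np.sqrt(0.25 / (200 * 90))  # ~90 nt per exon
        assert np.mean(gcs) == pytest.approx(0.5, abs=5 * se + 0.01)


class TestSpliceSiteModel:
    def test_consensus_scores_highest_among_training_set(self, rng):
        consensus = "CAGGTAAGT"
        seqs = [consensus]
        for _ in range(30):
            s = list(consensus)
            pos = rng.integers(0, 9)
            s[pos] = "ACGT"[rng.integers(0, 4)]
            seqs.append("".join(s))
        model = train_splice_site_model(seqs, pseudocount=0.5)
        scores = [score_splice_site(s, model) for s in seqs]
        assert np.argmax(scores) == 0

    def test_uniform_pwm_scores_zero_everywhere(self):
        seqs = ["ACGT"[i % 4] * 4 for i in range(4)]
        # each position sees each base once -> freq 0.25 everywhere
        seqs = ["AAAA", "CCCC", "GGGG", "TTTT"]
        model = train_splice_site_model(seqs)
        for s in ("ACGT", "TTTT", "GCGC"):
            assert score_splice_site(s, model) == pytest.approx(0.0)

    def test_non_acgt_gives_missing_score(self):
        model = train_splice_site_model(["AAAA", "CCCC", "GGGG", "TTTT"])
        assert np.isnan(score_splice_site("ACNT", model))

    def test_background_expectation_closed_form(self, rng):
        """Mean score of background-drawn sequences matches
        Σ_pos Σ_b bg(b)·log-odds(pos, b) computed in closed form."""
        train = ["".join(rng.choice(list("ACGT"), 6,
                                    p=[0.4, 0.1, 0.1, 0.4]))
                 for _ in range(500)]
        model = train_splice_site_model(train, pseudocount=1.0)
        expected = (0.25 * model.log_odds).sum()
        draws = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(3000)]
        scores = [score_splice_site(s, model) for s in draws]
        se = np.std(scores) / np.sqrt(len(scores))
        assert np.mean(scores) == pytest.approx(expected, abs=4 * se)

    def test_length_mismatch_rejected(self):
        model = train_splice_site_model(["AAAA"])
        with pytest.raises(ValueError, match="length"):
            score_splice_site("AAAAA", model)


class TestCompareFeatures:
    def _fv(self, eid, **kw):
        base = dict(exon_length=80, up_intron_length=500,
                    down_intron_length=500, gc_exon=0.5, gc_up_intron=0.4,
                    gc_down_intron=0.4, score_5ss=5.0, score_3ss=5.0)
        base.update(kw)
        return FeatureVector(eid, **base)

    def test_identical_groups_not_significant(self):
        g = [self._fv(f"a{i}", exon_length=70 + i) for i in range(8)]
        out = compare_features(g, g)
        assert (out["p"].dropna() > 0.9).all()

    def test_large_shift_is_significant(self, rng):
        g = [self._fv(f"a{i}", exon_length=float(50 + rng.integers(0, 5)))
             for i in range(15)]
        c = [self._fv(f"b{i}", exon_length=float(500 + rng.integers(0, 5)))
             for i in range(15)]
        out = compare_features(g, c)
        assert out.loc["exon_length", "p"] < 0.001

    def test_u_statistic_matches_pair_enumeration(self, rng):
        xs = list(rng.uniform(0, 10, 5))
        ys = list(rng.uniform(0, 10, 5))
        g = [self._fv(f"a{i}", exon_length=x) for i, x in enumerate(xs)]
        c = [self._fv(f"b{i}", exon_length=y) for i, y in enumerate(ys)]
        out = compare_features(g, c)
        assert out.loc["exon_length", "U"] == mannwhitney_u_oracle(xs, ys)

    def test_groups_below_three_rejected(self):
        g = [self._fv("a0"), self._fv("a1")]
        with pytest.raises(ValueError):
            compare_features(g, g)


class TestMotifScan:
    def test_overlapping_matches_reported(self):
        hits = motif_match_starts("TTTTTT", "TTTTT")
        assert hits.tolist() == [True, True]

    def test_iupac_degenerate_positions(self):
        hits = motif_match_starts("ACGTAG", "RYGT")  # R=A/G, Y=C/T
        assert hits.tolist() == [True, False, False]

    def test_matches_naive_substring_oracle(self, rng):
        iupac_sets = {"A": "A", "C": "C", "G": "G", "T": "T",
                      "R": "AG", "Y": "CT", "N": "ACGT", "W": "AT"}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 80))
            motif = "".join(rng.choice(list("ACGTRYNW"), 5))
            hits = motif_match_starts(seq, motif)
            naive = [all(seq[i + j] in iupac_sets[m]
                         for j, m in enumerate(motif))
                     for i in range(len(seq) - len(motif) + 1)]
            assert hits.tolist() == naive


class TestWindowCoverage:
    def test_match_covers_centered_window(self):
        seq = "A" * 20 + "TTTTT" + "A" * 20
        cov = window_coverage([seq], "TTTTT", window=31, length=45)
        covered = np.flatnonzero(cov[0])
        # match occupies 20..24; centers j with j-15 <= 20, 24 <= j+15
        assert covered.min() == 9 and covered.max() == 35

    def test_motif_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            window_coverage(["A" * 40], "T" * 33, window=31, length=40)


class TestRnaMap:
    def test_identical_groups_have_no_significant_segment(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(40)]
        groups = {"regulated": {"intron_down": seqs},
                  "control": {"intron_down": list(seqs)}}
        m = rna_map(groups, "TTTT", n_perm=200, seed=0)
        assert m.significant_segments["intron_down"] == []

    def test_planted_window_recovered(self):
        loci = sd.simulate_loci(150, 150, "TTTTT", p_plant=1.0, seed=2)
        m = rna_map(loci.map_input(), "TTTTT", n_perm=300, seed=3)
        segs = m.segments_as_positions("intron_down")
        assert any(a <= -80 and b >= -120 for a, b in segs)

    def test_coverage_invariant_to_sequence_order(self, rng):
        loci = sd.simulate_loci(30, 30, "TTTTT", p_plant=0.8, seed=4)
        groups = loci.map_input()
        m1 = rna_map(groups, "TTTTT", n_perm=50, seed=5)
        shuffled = {g: {r: list(reversed(s)) for r, s in by.items()}
                    for g, by in groups.items()}
        m2 = rna_map(shuffled, "TTTTT", n_perm=50, seed=5)
        for r in m1.regions:
            assert np.allclose(m1.coverage["regulated"][r],
                               m2.coverage["regulated"][r])

    def test_pvalues_respect_add_one_floor(self):
        loci = sd.simulate_loci(40, 40, "TTTTT", p_plant=1.0, seed=6)
        m = rna_map(loci.map_input(), "TTTTT", n_perm=100, seed=7)
        for r in m.regions:
            assert (m.pvals[r] >= 1.0 / 101).all()

    def test_short_sequences_skipped_with_warning(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(10)]
        groups = {"regulated": {"intron_down": seqs + ["ACGT"]},
                  "control": {"intron_down": seqs}}
        with pytest.warns(UserWarning, match="shorter"):
            m = rna_map(groups, "TTTT", n_perm=20, seed=8)
        assert m.n_skipped["regulated/intron_down"] == 1
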