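"""End-to-end recovery experiments on planted synthetic data.

Each function simulates a dataset with known ground truth using
:mod:`splicedyn.synthetic_data`, runs the corresponding caller, and
returns recovery metrics. These are the study's internal benchmarks:
they quantify how reliably each step of the pipeline reconstructs a
planted signal under the simulated conditions (two replicates, Poisson
coverage, Gaussian replicate jitter — see the generator module).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

import splicedyn.synthetic_data as sd
from splicedyn.orf_impact import predict_impact
from splicedyn.perturbation import classify_dependency
from splicedyn.psi_diff import diff_union
from splicedyn.regulator_inference import (
    filter_expressed_variable,
    infer_regulators,
)
from splicedyn.seq_features import rna_map
from splicedyn.temporal_clustering import fuzzy_cmeans, scale_profiles


def _sub(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0]
               % (2 ** 31))


def diff_caller_recovery(n_regulated_per_cluster: int = 50,
                         n_unregulated: int = 500,
                         seed: int = 0) -> dict[str, float]:
    """Sensitivity/specificity of the pairwise ΔPSI caller on a
    simulated time course with planted regulated trajectories."""
    t, truth = sd.simulate_timecourse(
        n_regulated_per_cluster, n_unregulated=n_unregulated,
        coverage_mean=200, noise_sd_psi=1.0, seed=_sub(seed, 1))
    union, _ = diff_union(t, t.samples.conditions)
    regulated = set(
        truth.events.index[truth.events["cluster_id"] != "unregulated"])
    null = set(truth.events.index) - regulated
    return {
        "sensitivity": len(union & regulated) / len(regulated),
        "false_call_rate": len(union & null) / len(null),
        "n_events": len(truth.events),
    }


def clustering_recovery(n_per_cluster: int = 300, noise_sd: float = 0.3,
                        m: float = 1.25, seed: int = 0,
                        n_restarts: int = 10) -> dict[str, float]:
    """Adjusted Rand index of fuzzy c-means hard labels vs planted
    clusters at the given scaled-space noise level."""
    specs = sd.default_trajectory_specs()
    x, labels = sd.simulate_scaled_trajectories(
        n_per_cluster, specs, noise_sd=noise_sd, seed=_sub(seed, 2))
    scaled, _ = scale_profiles(x)
    model = fuzzy_cmeans(scaled, k=len(specs), m=m, seed=_sub(seed, 3),
                         n_restarts=n_restarts)
    ari = adjusted_rand_score(labels.loc[scaled.index],
                              model.hard_assignments())
    return {"ari": float(ari), "n_events": int(len(scaled)),
            "membership_row_sum_error": float(
                np.abs(model.memberships.sum(axis=1) - 1.0).max())}


def regulator_recovery(n_pos: int = 10, n_neg: int = 10, n_null: int = 500,
                       noise_sd: float = 0.3, seed: int = 0,
                       ) -> dict[str, float]:
    """Precision/recall of membership-based regulator calls against
    planted positive/negative regulators among null RBPs."""
    specs = sd.default_trajectory_specs()
    x, _ = sd.simulate_scaled_trajectories(300, specs, noise_sd=noise_sd,
                                           seed=_sub(seed, 4))
    scaled, _ = scale_profiles(x)
    model = fuzzy_cmeans(scaled, k=len(specs), m=1.25, seed=_sub(seed, 5),
                         n_restarts=10)
    mapping = sd.match_centroids(model.centroids, specs)
    expr, truth = sd.simulate_rbp_expression(
        specs, n_pos, n_neg, n_null, noise_sd=noise_sd, seed=_sub(seed, 6))
    sc, _ = scale_profiles(filter_expressed_variable(expr).values)
    calls = infer_regulators(sc, model)
    pred = {(c.rbp_id, mapping[c.cluster_id], c.polarity) for c in calls}
    want = {(r, row["cluster_id"], row["role"])
            for r, row in truth.rbps.iterrows()
            if row["role"] in ("positive", "negative")}
    tp = len(pred & want)
    return {
        "precision": tp / len(pred) if pred else 0.0,
        "recall": tp / len(want),
        "n_calls": len(pred),
        "n_planted": len(want),
    }


def dependency_calibration(n_events: int = 1000, rep_noise_sd: float = 2.0,
                           effect_ddpsi: float = 20.0, seed: int = 0,
                           ) -> dict[str, float]:
    """Null dependent-call rate (planted effect 0) and sensitivity at
    the planted effect size, two-shRNA design."""
    # null events shift during reprogramming but carry zero ΔΔ effect
    t0, d0, _ = sd.simulate_perturbation(
        0, n_events, 0, effect_ddpsi=0.0, rep_noise_sd=rep_noise_sd,
        seed=_sub(seed, 7))
    null_rate = len(classify_dependency(t0, d0).dependent) / n_events

    t1, d1, _ = sd.simulate_perturbation(
        n_events // 2, 0, 0, effect_ddpsi=effect_ddpsi,
        rep_noise_sd=rep_noise_sd, seed=_sub(seed, 8))
    sens = len(classify_dependency(t1, d1).dependent) / (n_events // 2)
    return {"null_dependent_rate": null_rate, "sensitivity": sens,
            "n_events": n_events}


def rna_map_recovery(n_regulated: int = 300, n_control: int = 300,
                     motif: str = "TTTTT", p_plant: float = 0.8,
                     n_perm: int = 1000, seed: int = 0,
                     window_lo: int = -120, window_hi: int = -80,
                     ) -> dict[str, float]:
    """Does a significant RNA-map segment overlap the planted
    downstream-intron window?"""
    loci = sd.simulate_loci(n_regulated, n_control, motif,
                            p_plant=p_plant, seed=_sub(seed, 9))
    m = rna_map(loci.map_input(), motif, n_perm=n_perm, seed=_sub(seed, 10))
    segs = m.segments_as_positions("intron_down")
    hit = any(a <= window_hi and b >= window_lo for a, b in segs)
    return {
        "planted_window_recovered": float(hit),
        "n_significant_positions": int(
            sum((m.pvals[r] <= m.alpha).sum() for r in m.regions)),
        "n_loci": n_regulated + n_control,
    }


def rna_map_null_calibration(n_replicates: int = 30, n_loci: int = 150,
                             motif: str = "TTTT", n_perm: int = 300,
                             seed: int = 0, spacing: int = 31,
                             ) -> dict[str, float]:
    """Empirical per-position type-I error of the map's permutation test.

    Runs independent null datasets (no planting) and pools randomized
    p-values at positions spaced one window apart, where positions are
    independent and the binomial reference applies.
    """
    hits = total = 0
    for i in range(n_replicates):
        loci = sd.simulate_loci(n_loci, n_loci, motif, p_plant=0.0,
                                seed=_sub(seed, 100 + i))
        m = rna_map(loci.map_input(), motif, n_perm=n_perm,
                    seed=_sub(seed, 200 + i), randomized_p=True)
        for r in m.regions:
            ps = m.pvals[r][::spacing]
            hits += int((ps <= 0.05).sum())
            total += len(ps)
    return {"sig_fraction": hits / total, "n_positions": total,
            "nominal": 0.05}


def orf_classifier_accuracy() -> dict[str, float]:
    """Fraction of constructed ORF-impact cases classified exactly."""
    cases, genome = sd.simulate_orf_cases()
    correct = 0
    for case in cases:
        call = predict_impact(case.exon, case.transcript,
                              genome[case.transcript.chrom],
                              event_id=case.event_id)
        correct += (call.category == case.expected_category
                    and call.reason == case.expected_reason)
    return {"accuracy": correct / len(cases), "n_cases": len(cases)}


def pseudotime_recovery(seed: int = 0) -> dict[str, float]:
    """Stage-group ARI and pseudotime/generative-time rank agreement on
    the two-dataset stage-structured expression simulation."""
    from splicedyn.core_io import ExprTable
    from splicedyn.expression_pseudotime import pca_group_pseudotime

    expr, meta = sd.simulate_stage_expression(seed=_sub(seed, 11))
    scaled, _ = scale_profiles(expr.values)
    scaled_t = ExprTable(scaled, expr.samples, "scaled")
    res = pca_group_pseudotime(scaled_t, k=4, start_anchor="Bcells_r1",
                               seed=_sub(seed, 12))
    ari = adjusted_rand_score(meta["stage"], res.groups)
    rhos = []
    for _, grp in meta.groupby("dataset"):
        pt = res.pseudotime.loc[grp.index]
        rhos.append(pt.rank().corr(grp["progress"].rank()))
    return {"stage_ari": float(ari), "min_rank_corr": float(min(rhos)),
            "n_samples": len(meta)}
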