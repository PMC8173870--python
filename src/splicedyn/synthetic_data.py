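"""Synthetic reprogramming data with planted ground truth.

Generators emulate the statistical structure of a two-dataset
reprogramming study: a bulk RNA-seq time course (two replicates across
6–8 stages) whose cassette exons follow logistic inclusion
trajectories grouped into clusters, RBP expression profiles correlated
or anti-correlated with those cluster centroids, a day-0 → day-12
perturbation design with a control arm and one or more shRNA arms, and
toy loci carrying a planted RNA-binding motif inside a chosen window.
Every generator is deterministic under a fixed seed and records the
planted truth, so downstream callers can be scored for recovery.

The default time grid mirrors a B-cell reprogramming design:
{Bα, day2, day4, day6, day8, iPS} → pseudotime {0, 1, 2, 3, 4, 5}.

Observed PSI combines binomial read sampling (reads per event drawn
Poisson around the target coverage) with additive replicate jitter on
the PSI scale, clipped to [0, 100]; the clipping is a slight bias at
extreme PSI values. Coverage is Poisson rather than negative binomial:
PSI sampling noise, not count overdispersion, is the quantity under
test here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from splicedyn.core_io import (
    ExprTable,
    PsiTable,
    SampleMap,
    SpliceEvent,
    write_fasta,
)
from splicedyn.perturbation import PerturbationDesign

DEFAULT_TIMEPOINTS = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
DEFAULT_CONDITIONS = ["Balpha", "day2", "day4", "day6", "day8", "iPS"]


@dataclass(frozen=True)
class TrajectorySpec:
    """Logistic PSI trajectory of one planted cluster."""

    cluster_id: str
    shift_time: float
    direction: str  # up | down
    baseline_psi: float
    final_psi: float
    steepness: float = 2.5

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        delta = self.final_psi - self.baseline_psi
        if abs(delta) < 10:
            raise ValueError(
                f"{self.cluster_id}: planted shift |{delta}| < 10 PSI")
        if (delta > 0) != (self.direction == "up"):
            raise ValueError(f"{self.cluster_id}: direction/shift mismatch")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def psi_at(self, t: float | np.ndarray) -> np.ndarray:
        """True PSI along the logistic curve, in [0, 100]."""
        span = self.final_psi - self.baseline_psi
        return self.baseline_psi + span / (
            1.0 + np.exp(-self.steepness * (np.asarray(t, float)
                                            - self.shift_time)))


def default_trajectory_specs() -> list[TrajectorySpec]:
    """Six cluster shapes: pulse, early up/down, middle up/down, late up.

    Shift times and steepness are varied so that no two scaled
    centroids coincide or are exact negations of each other — sharp
    early switches versus gradual declines, mirroring the distinct
    kinetic classes seen in reprogramming time courses. (A pair of
    mirror-image centroids would make the positive/negative regulator
    distinction between the two clusters undefined.)
    """
    return [
        TrajectorySpec("pulse_up", 0.6, "up", 20, 80, steepness=10.0),
        TrajectorySpec("gradual_up", 0.6, "up", 15, 75, steepness=1.6),
        TrajectorySpec("early_down", 1.4, "down", 80, 20, steepness=7.5),
        TrajectorySpec("middle_up", 2.0, "up", 25, 85, steepness=6.5),
        TrajectorySpec("middle_down", 3.2, "down", 85, 25, steepness=5.0),
        TrajectorySpec("late_up", 4.3, "up", 20, 80, steepness=6.0),
    ]


@dataclass
class TruthTable:
    """Planted labels per entity; one frame per generator kind."""

    events: pd.DataFrame | None = None        # event_id -> cluster_id
    rbps: pd.DataFrame | None = None          # rbp_id -> role, cluster_id
    perturbation: pd.DataFrame | None = None  # event_id -> status
    loci: pd.DataFrame | None = None          # locus_id -> group, plant info


def _make_sample_map(conditions: list[str], n_reps: int,
                     dataset: str) -> SampleMap:
    rows = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            rows.append({"sample_id": f"{cond}_r{rep}", "condition": cond,
                         "replicate": rep, "dataset": dataset})
    return SampleMap(pd.DataFrame(rows).set_index("sample_id"))


def _toy_events(event_ids: list[str], exon_len: int = 90,
                chrom: str = "chr1") -> list[SpliceEvent]:
    """Placeholder cassette-exon coordinates, one locus per 10 kb."""
    events = []
    for i, eid in enumerate(event_ids):
        span_s = 10_000 * (i + 1)
        exon_s = span_s + 2_000
        events.append(SpliceEvent(
            event_id=eid, gene_id=f"gene_{i}", event_type="CEx",
            chrom=chrom, span_start=span_s, span_end=span_s + 5_000,
            exon_start=exon_s, exon_end=exon_s + exon_len, strand="+"))
    return events


def _observe_psi(true_psi: np.ndarray, coverage_mean: float,
                 noise_sd_psi: float, rng: np.random.Generator,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Binomial sampling at Poisson coverage plus PSI-scale jitter."""
    shape = true_psi.shape
    if math.isinf(coverage_mean):
        reads = np.full(shape, 10_000, dtype=int)
        obs = true_psi.copy()
    else:
        reads = rng.poisson(coverage_mean, size=shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs = np.where(
                reads > 0,
                100.0 * rng.binomial(reads, np.clip(true_psi, 0, 100) / 100.0)
                / np.maximum(reads, 1),
                np.nan)
    if noise_sd_psi > 0:
        obs = obs + rng.normal(0.0, noise_sd_psi, size=shape)
    return np.clip(obs, 0.0, 100.0), reads


def simulate_timecourse(n_per_cluster: int,
                        specs: list[TrajectorySpec] | None = None,
                        n_unregulated: int = 0,
                        timepoints: list[float] | None = None,
                        n_reps: int = 2,
                        coverage_mean: float = 200.0,
                        noise_sd_psi: float = 1.0,
                        seed: int = 0,
                        conditions: list[str] | None = None,
                        dataset: str = "Bcell",
                        min_reads: int = 10,
                        ) -> tuple[PsiTable, TruthTable]:
    """Simulate a PSI time course with planted trajectory clusters.

    Each regulated event follows its cluster's logistic curve; the
    observation model is binomial read sampling at Poisson coverage
    plus Gaussian replicate jitter. Unregulated events hold a constant
    PSI drawn uniformly in [10, 90]. Requires ≥ 3 time points
    (fewer leaves trajectory clustering undefined).
    """
    specs = default_trajectory_specs() if specs is None else specs
    if not specs:
        raise ValueError("specs must be non-empty")
    timepoints = DEFAULT_TIMEPOINTS if timepoints is None else timepoints
    if len(timepoints) < 3:
        raise ValueError("need at least 3 timepoints")
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    conditions = (DEFAULT_CONDITIONS[: len(timepoints)]
                  if conditions is None else conditions)
    if len(conditions) != len(timepoints):
        raise ValueError("conditions and timepoints differ in length")

    rng = np.random.default_rng(seed)
    samples = _make_sample_map(conditions, n_reps, dataset)
    t_per_sample = np.repeat(timepoints, n_reps)

    event_ids: list[str] = []
    truth_rows = []
    true_rows = []
    for spec in specs:
        curve = spec.psi_at(t_per_sample)
        for j in range(n_per_cluster):
            eid = f"{spec.cluster_id}_{j}"
            event_ids.append(eid)
            truth_rows.append({"event_id": eid, "cluster_id": spec.cluster_id})
            true_rows.append(curve)
    for j in range(n_unregulated):
        eid = f"unreg_{j}"
        event_ids.append(eid)
        truth_rows.append({"event_id": eid, "cluster_id": "unregulated"})
        true_rows.append(np.full(len(t_per_sample),
                                 rng.uniform(10.0, 90.0)))

    true_psi = np.array(true_rows)
    obs, reads = _observe_psi(true_psi, coverage_mean, noise_sd_psi, rng)
    idx = pd.Index(event_ids, name="event_id")
    psi = pd.DataFrame(obs, index=idx, columns=samples.sample_ids)
    reads_df = pd.DataFrame(reads, index=idx, columns=samples.sample_ids)
    table = PsiTable.build(_toy_events(event_ids), samples, psi, reads_df,
                           min_reads=min_reads)
    truth = TruthTable(events=pd.DataFrame(truth_rows).set_index("event_id"))
    return table, truth


def simulate_scaled_trajectories(n_per_cluster: int,
                                 specs: list[TrajectorySpec] | None = None,
                                 noise_sd: float = 0.3,
                                 seed: int = 0,
                                 timepoints: list[float] | None = None,
                                 n_reps: int = 2,
                                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Scaled-space trajectories: cluster centroid + Gaussian noise.

    The direct scaled-space counterpart of :func:`simulate_timecourse`,
    used to probe the clustering machinery at a controlled noise level
    (``noise_sd`` in scaled units) without the read-sampling layer.
    Returns the profile matrix and the true cluster label per row.
    """
    specs = default_trajectory_specs() if specs is None else specs
    rng = np.random.default_rng(seed)
    centroids = cluster_centroid_profiles(specs, timepoints, n_reps)
    rows, ids, labels = [], [], []
    for ci, spec in enumerate(specs):
        for j in range(n_per_cluster):
            rows.append(centroids[ci]
                        + rng.normal(0.0, noise_sd, centroids.shape[1]))
            ids.append(f"{spec.cluster_id}_{j}")
            labels.append(spec.cluster_id)
    x = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="event_id"))
    return x, pd.Series(labels, index=x.index, name="cluster_id")


# ---------------------------------------------------------------------------
# RBP expression
# ---------------------------------------------------------------------------

def cluster_centroid_profiles(specs: list[TrajectorySpec],
                              timepoints: list[float] | None = None,
                              n_reps: int = 2) -> np.ndarray:
    """Scaled per-sample centroid trajectory of each planted cluster."""
    timepoints = DEFAULT_TIMEPOINTS if timepoints is None else timepoints
    t = np.repeat(timepoints, n_reps)
    curves = np.array([spec.psi_at(t) for spec in specs])
    mean = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, ddof=1, keepdims=True)
    return (curves - mean) / sd


def match_centroids(model_centroids: np.ndarray,
                    specs: list[TrajectorySpec],
                    timepoints: list[float] | None = None,
                    n_reps: int = 2) -> dict[int, str]:
    """Map fitted centroid indices to the planted cluster they recover.

    Fuzzy c-means labels are arbitrary; each fitted centroid is
    assigned the planted cluster whose scaled centroid is nearest in
    Euclidean distance (sign kept: negated matches do not count).
    """
    planted = cluster_centroid_profiles(specs, timepoints, n_reps)
    out = {}
    for i, c in enumerate(model_centroids):
        d = ((planted - c) ** 2).sum(axis=1)
        out[i] = specs[int(d.argmin())].cluster_id
    return out


def simulate_rbp_expression(cluster_model_truth: list[TrajectorySpec],
                            n_pos_per_cluster: int,
                            n_neg_per_cluster: int,
                            n_null: int,
                            noise_sd: float = 0.3,
                            seed: int = 0,
                            timepoints: list[float] | None = None,
                            n_reps: int = 2,
                            dataset: str = "Bcell",
                            conditions: list[str] | None = None,
                            base_cpm: float = 100.0,
                            amplitude_cpm: float = 25.0,
                            n_low_expressed: int = 0,
                            n_low_variance: int = 0,
                            ) -> tuple[ExprTable, TruthTable]:
    """Simulate RBP cpm profiles tied to planted AS cluster centroids.

    Positive regulators track the scaled centroid of their cluster plus
    Gaussian noise (sd ``noise_sd`` in scaled units), negative
    regulators track the negated centroid, nulls are independent noise.
    Profiles are mapped to the cpm scale affinely
    (base + amplitude·z), so scaling them back recovers the planted
    shape exactly, and the defaults put every planted RBP past the
    cpm ≥ 5 / CV ≥ 0.2 filters. Optional extra genes are constructed
    to fail the expression or the variation filter, and a padding gene
    absorbs the remainder so that cpm columns sum to one million.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    timepoints = DEFAULT_TIMEPOINTS if timepoints is None else timepoints
    conditions = (DEFAULT_CONDITIONS[: len(timepoints)]
                  if conditions is None else conditions)
    rng = np.random.default_rng(seed)
    samples = _make_sample_map(conditions, n_reps, dataset)
    n_samples = len(samples.sample_ids)
    centroids = cluster_centroid_profiles(cluster_model_truth, timepoints,
                                          n_reps)

    rows, ids, truth_rows = [], [], []

    def add(rbp_id: str, profile_z: np.ndarray, role: str,
            cluster: str) -> None:
        ids.append(rbp_id)
        rows.append(base_cpm + amplitude_cpm * profile_z)
        truth_rows.append({"rbp_id": rbp_id, "role": role,
                           "cluster_id": cluster})

    for ci, spec in enumerate(cluster_model_truth):
        for j in range(n_pos_per_cluster):
            z = centroids[ci] + rng.normal(0, noise_sd, n_samples)
            add(f"pos_{spec.cluster_id}_{j}", z, "positive", spec.cluster_id)
        for j in range(n_neg_per_cluster):
            z = -centroids[ci] + rng.normal(0, noise_sd, n_samples)
            add(f"neg_{spec.cluster_id}_{j}", z, "negative", spec.cluster_id)
    for j in range(n_null):
        add(f"null_{j}", rng.normal(0, 1.0, n_samples), "null", "")
    for j in range(n_low_expressed):
        ids.append(f"lowexpr_{j}")
        rows.append(np.full(n_samples, 1.0))  # cpm 1 everywhere
        truth_rows.append({"rbp_id": f"lowexpr_{j}",
                           "role": "filtered_low_expression", "cluster_id": ""})
    for j in range(n_low_variance):
        ids.append(f"lowvar_{j}")
        rows.append(np.full(n_samples, 10.0 * base_cpm))  # CV = 0
        truth_rows.append({"rbp_id": f"lowvar_{j}",
                           "role": "filtered_low_variance", "cluster_id": ""})

    values = np.clip(np.array(rows), 0.1, None)
    padding = 1e6 - values.sum(axis=0)
    if (padding <= 0).any():
        raise ValueError("cpm budget exhausted; lower base_cpm or gene count")
    values = np.vstack([values, padding])
    ids.append("_padding")
    truth_rows.append({"rbp_id": "_padding", "role": "padding",
                       "cluster_id": ""})
    table = ExprTable(
        pd.DataFrame(values, index=pd.Index(ids, name="gene_id"),
                     columns=samples.sample_ids),
        samples, "cpm")
    truth = TruthTable(rbps=pd.DataFrame(truth_rows).set_index("rbp_id"))
    return table, truth


# ---------------------------------------------------------------------------
# perturbation design
# ---------------------------------------------------------------------------

def simulate_perturbation(n_dependent: int, n_independent: int,
                          n_unchanged: int,
                          base_shift: float = 30.0,
                          effect_ddpsi: float = 20.0,
                          n_shrna: int = 2,
                          rep_noise_sd: float = 2.0,
                          seed: int = 0,
                          n_reps: int = 2,
                          factor: str = "FAC",
                          min_reads: int = 10,
                          ) -> tuple[PsiTable, PerturbationDesign, TruthTable]:
    """Simulate a day0 → day12 knockdown experiment.

    Independent events shift by ``base_shift`` PSI in the control and
    every shRNA arm; dependent events shift by ``base_shift`` in the
    control but ``base_shift − effect_ddpsi`` in every arm (so their
    arm-level ΔΔPSI is −effect_ddpsi); unchanged events are static.
    Replicate noise is Gaussian on the PSI scale. Read support is held
    high so quality never censors the classification under test.
    """
    if n_shrna < 1:
        raise ValueError("need at least one shRNA arm")
    rng = np.random.default_rng(seed)
    baseline = "NI_day0"
    control = "shSCR_day12"
    arms = [f"sh{factor}{i+1}_day12" for i in range(n_shrna)]
    samples = _make_sample_map([baseline, control, *arms], n_reps, "MEF")
    design = PerturbationDesign(baseline, control, tuple(arms),
                                label=factor)

    statuses = (["dependent"] * n_dependent
                + ["independent"] * n_independent
                + ["unchanged"] * n_unchanged)
    event_ids = [f"{s}_{i}" for i, s in enumerate(statuses)]
    base_psi = rng.uniform(20.0, 50.0, len(statuses))

    true_by_cond = {baseline: base_psi}
    shift = np.array([0.0 if s == "unchanged" else base_shift
                      for s in statuses])
    true_by_cond[control] = base_psi + shift
    arm_shift = np.array(
        [0.0 if s == "unchanged"
         else base_shift - (effect_ddpsi if s == "dependent" else 0.0)
         for s in statuses])
    for arm in arms:
        true_by_cond[arm] = base_psi + arm_shift

    cols, data = [], []
    for cond in [baseline, control, *arms]:
        for rep in range(1, n_reps + 1):
            cols.append(f"{cond}_r{rep}")
            noise = (rng.normal(0, rep_noise_sd, len(statuses))
                     if rep_noise_sd > 0 else 0.0)
            data.append(np.clip(true_by_cond[cond] + noise, 0.0, 100.0))
    idx = pd.Index(event_ids, name="event_id")
    psi = pd.DataFrame(np.column_stack(data), index=idx, columns=cols)
    psi = psi[samples.sample_ids]
    reads = pd.DataFrame(100, index=idx, columns=samples.sample_ids)
    table = PsiTable.build(_toy_events(event_ids), samples, psi, reads,
                           min_reads=min_reads)
    truth = TruthTable(perturbation=pd.DataFrame(
        {"event_id": event_ids, "status": statuses}).set_index("event_id"))
    return table, design, truth


# ---------------------------------------------------------------------------
# toy loci with planted motifs
# ---------------------------------------------------------------------------

REGION_LENGTHS = {"intron_up": 150, "exon_start": 50,
                  "exon_end": 50, "intron_down": 150}


@dataclass
class LociSet:
    """Toy loci: full sequences plus the four RNA-map windows."""

    full: dict[str, dict[str, str]]     # locus -> {exon, intron_up, intron_down}
    regions: dict[str, dict[str, str]]  # region -> locus -> window sequence
    groups: dict[str, str]              # locus -> regulated | control
    truth: TruthTable = field(default=None)  # type: ignore[assignment]

    def map_input(self) -> dict[str, dict[str, list[str]]]:
        """Sequences grouped for :func:`splicedyn.seq_features.rna_map`."""
        out: dict[str, dict[str, list[str]]] = {}
        for region, by_locus in self.regions.items():
            for locus, seq in by_locus.items():
                grp = self.groups[locus]
                out.setdefault(grp, {}).setdefault(region, []).append(seq)
        return out

    def feature_windows(self) -> dict[str, dict[str, str]]:
        """Per-locus windows for :func:`compute_features` (incl. ss5/ss3)."""
        out = {}
        for locus, w in self.full.items():
            exon, up, down = w["exon"], w["intron_up"], w["intron_down"]
            out[locus] = {
                "exon": exon, "intron_up": up, "intron_down": down,
                "ss5": exon[-3:] + down[:6],
                "ss3": up[-20:] + exon[:3],
            }
        return out

    def write_fastas(self, out_dir: str) -> list[str]:
        import os

        paths = []
        for region, by_locus in self.regions.items():
            path = os.path.join(out_dir, f"{region}.fa")
            write_fasta(by_locus, path)
            paths.append(path)
        return paths


def _random_seq(rng: np.random.Generator, length: int,
                gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, length, p=p)])


def _motif_instance(rng: np.random.Generator, motif: str) -> str:
    from splicedyn.seq_features import IUPAC

    return "".join(
        rng.choice(list(IUPAC[ch]))
        for ch in motif.upper().replace("U", "T"))


def simulate_loci(n_regulated: int, n_control: int, motif: str,
                  planted_window: tuple[str, int, int] = ("intron_down", -120, -80),
                  exon_len_range: tuple[int, int] = (60, 120),
                  intron_len_range: tuple[int, int] = (300, 1000),
                  gc_shift: float = 0.0,
                  seed: int = 0,
                  p_plant: float = 0.8,
                  ) -> LociSet:
    """Generate toy exon loci, planting the motif in regulated ones.

    ``planted_window`` is (region, start, end) in the region's position
    labels (intronic windows count −150..−1 toward the downstream
    3' splice site, exonic windows 1..50 / −50..−1). Each regulated
    locus carries, with probability ``p_plant``, one motif instance at
    a uniform position such that the match lies fully inside the
    window; control loci carry only the background motif frequency.
    ``gc_shift`` raises exon GC over intron GC (both default 0.5).
    """
    from splicedyn.seq_features import DEFAULT_REGION_POSITIONS

    region_name, w_start, w_end = planted_window
    if region_name not in REGION_LENGTHS:
        raise ValueError(f"unknown region {region_name!r}")
    labels = list(DEFAULT_REGION_POSITIONS[region_name])
    if w_start not in labels or w_end not in labels:
        raise ValueError("planted window outside region bounds")
    w_lo, w_hi = labels.index(w_start), labels.index(w_end)
    if w_hi - w_lo + 1 < len(motif):
        raise ValueError("planted window shorter than the motif")

    rng = np.random.default_rng(seed)
    full: dict[str, dict[str, str]] = {}
    regions: dict[str, dict[str, str]] = {r: {} for r in REGION_LENGTHS}
    groups: dict[str, str] = {}
    truth_rows = []

    def windows_of(exon: str, up: str, down: str) -> dict[str, str]:
        return {"intron_up": up[-150:], "exon_start": exon[:50],
                "exon_end": exon[-50:], "intron_down": down[-150:]}

    names = ([f"reg_{i}" for i in range(n_regulated)]
             + [f"ctrl_{i}" for i in range(n_control)])
    for name in names:
        regulated = name.startswith("reg_")
        exon_len = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        up_len = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        down_len = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        exon = _random_seq(rng, exon_len, 0.5 + gc_shift)
        up = _random_seq(rng, up_len)
        down = _random_seq(rng, down_len)
        win = windows_of(exon, up, down)

        planted_at: int | None = None
        if regulated and rng.random() < p_plant:
            start = int(rng.integers(w_lo, w_hi - len(motif) + 2))
            seq = win[region_name]
            instance = _motif_instance(rng, motif)
            win[region_name] = (seq[:start] + instance
                                + seq[start + len(motif):])
            planted_at = labels[start]
            # write the window back into the full sequence
            if region_name == "intron_down":
                down = down[:-150] + win[region_name]
            elif region_name == "intron_up":
                up = up[:-150] + win[region_name]
            elif region_name == "exon_start":
                exon = win[region_name] + exon[50:]
            else:
                exon = exon[:-50] + win[region_name]

        full[name] = {"exon": exon, "intron_up": up, "intron_down": down}
        for r, s in win.items():
            regions[r][name] = s
        groups[name] = "regulated" if regulated else "control"
        truth_rows.append({"locus_id": name, "group": groups[name],
                           "motif_planted": planted_at is not None,
                           "plant_region": region_name if planted_at is not None else "",
                           "plant_position": planted_at})

    truth = TruthTable(loci=pd.DataFrame(truth_rows).set_index("locus_id"))
    return LociSet(full, regions, groups, truth)


# ---------------------------------------------------------------------------
# constructed ORF-impact cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfCase:
    """One constructed exon/transcript pair with its expected impact."""

    event_id: str
    exon: tuple[int, int]
    transcript: "object"  # TranscriptModel
    expected_category: str
    expected_reason: str


def _codon_filler(n: int) -> str:
    """Stop-free filler in every forward frame (GCA/GCT repeats)."""
    s = "GCTGCA" * (n // 6 + 1)
    return s[:n]


def simulate_orf_cases() -> tuple[list[OrfCase], dict[str, str]]:
    """Constructed transcripts covering every ORF-impact category.

    Builds a small synthetic genome and one locus per case: frameshift
    in either direction, an NMD-triggering premature stop, premature
    stops escaping NMD with mild and with severe (> 300 aa)
    truncation, an ORF-preserving exon, 5'/3'-UTR and non-coding
    locations, minus-strand mirrors, and an unmatchable exon. The
    expected category/reason labels follow from the construction.
    """
    from splicedyn.core_io import TranscriptModel

    cases: list[OrfCase] = []
    genome: dict[str, str] = {}

    def new_chrom(name: str, length: int = 6000) -> list[str]:
        return list(_codon_filler(length))

    def place(chrom: list[str], s: int, seq: str) -> None:
        chrom[s:s + len(seq)] = list(seq)

    # layout shared by most plus-strand cases:
    # e1 [100,250), alt [300,300+L), e3 [500,650), e4 [700,820)
    e1, e3, e4 = (100, 250), (500, 650), (700, 820)

    def tm(name, exons, cs, ce, strand="+", chrom_name=None):
        return TranscriptModel(name, name, chrom_name or name, strand,
                               exons if strand == "+" else exons[::-1],
                               cs, ce)

    # 1. 85-nt exon annotated-included: skipping frameshifts
    c = new_chrom("fs_excl")
    genome["fs_excl"] = "".join(c)
    cases.append(OrfCase(
        "fs_excl", (300, 385),
        tm("fs_excl", [e1, (300, 385), e3, e4], 130, 759),
        "disrupt_on_exclusion", "frameshift"))

    # 2. 85-nt intronic exon: inclusion frameshifts
    genome["fs_incl"] = "".join(new_chrom("fs_incl"))
    cases.append(OrfCase(
        "fs_incl", (300, 385),
        tm("fs_incl", [e1, e3, e4], 130, 760),
        "disrupt_on_inclusion", "frameshift"))

    # 3. 84-nt intronic exon carrying an in-frame stop far upstream of
    #    the last junction: NMD-triggering PTC on inclusion
    c = new_chrom("ptc_nmd")
    place(c, 330, "TAA")
    place(c, 757, "TAA")  # annotated stop
    genome["ptc_nmd"] = "".join(c)
    cases.append(OrfCase(
        "ptc_nmd", (300, 384),
        tm("ptc_nmd", [e1, e3, e4], 130, 760),
        "disrupt_on_inclusion", "ptc_nmd"))

    # 4. 84-nt exon with a stop 12 nt before its own 3' end, inserted
    #    into the LAST intron: the PTC lands < 50 nt upstream of the
    #    final junction (escapes NMD) and the protein is not shortened
    #    by more than the 300-aa rule — preserving.
    c = new_chrom("ptc_mild")
    place(c, 300 + 72, "TAA")
    place(c, 548, "TAA")  # annotated stop
    genome["ptc_mild"] = "".join(c)
    cases.append(OrfCase(
        "ptc_mild", (300, 384),
        tm("ptc_mild", [(100, 250), (500, 560)], 130, 551),
        "orf_preserving", "none"))

    # 5. same geometry but the final exon carries > 1 kb of CDS:
    #    the non-NMD PTC now truncates > 300 aa — disrupting.
    c = new_chrom("ptc_trunc")
    place(c, 300 + 72, "TAA")
    place(c, 1529, "TAA")  # annotated stop
    genome["ptc_trunc"] = "".join(c)
    cases.append(OrfCase(
        "ptc_trunc", (300, 384),
        tm("ptc_trunc", [(100, 250), (500, 1540)], 130, 1532),
        "disrupt_on_inclusion", "truncation_gt300"))

    # 6. clean 84-nt exon: both isoforms translate through — preserving
    c = new_chrom("preserve")
    place(c, 757, "TAA")  # annotated stop
    genome["preserve"] = "".join(c)
    cases.append(OrfCase(
        "preserve", (300, 384),
        tm("preserve", [e1, (300, 384), e3, e4], 130, 760),
        "orf_preserving", "none"))

    # 7. exon upstream of the CDS start (+ strand): 5' UTR
    genome["utr5_plus"] = "".join(new_chrom("utr5_plus"))
    cases.append(OrfCase(
        "utr5_plus", (20, 60),
        tm("utr5_plus", [(20, 60), e1, e3, e4], 130, 760),
        "utr5", "none"))

    # 8. exon downstream of the CDS end (+ strand): 3' UTR
    genome["utr3_plus"] = "".join(new_chrom("utr3_plus"))
    cases.append(OrfCase(
        "utr3_plus", (900, 950),
        tm("utr3_plus", [e1, e3, e4, (900, 950)], 130, 760),
        "utr3", "none"))

    # 9. non-coding host transcript
    genome["ncrna"] = "".join(new_chrom("ncrna"))
    cases.append(OrfCase(
        "ncrna", (300, 384),
        tm("ncrna", [e1, (300, 384), e3], None, None),
        "ncRNA", "none"))

    # 10. minus-strand mirror of case 1: skipping frameshifts
    c = new_chrom("fs_excl_minus")
    genome["fs_excl_minus"] = "".join(c)
    cases.append(OrfCase(
        "fs_excl_minus", (300, 385),
        tm("fs_excl_minus", [e1, (300, 385), e3, e4], 131, 760,
           strand="-"),
        "disrupt_on_exclusion", "frameshift"))

    # 11. minus-strand 5' UTR: exon genomically right of the CDS end
    genome["utr5_minus"] = "".join(new_chrom("utr5_minus"))
    cases.append(OrfCase(
        "utr5_minus", (900, 950),
        tm("utr5_minus", [e1, e3, e4, (900, 950)], 130, 760, strand="-"),
        "utr5", "none"))

    # 12. minus-strand 3' UTR: exon genomically left of the CDS start
    genome["utr3_minus"] = "".join(new_chrom("utr3_minus"))
    cases.append(OrfCase(
        "utr3_minus", (20, 60),
        tm("utr3_minus", [(20, 60), e1, e3, e4], 130, 760, strand="-"),
        "utr3", "none"))

    # 13. exon overlapping but not matching any annotated structure
    genome["nomatch"] = "".join(new_chrom("nomatch"))
    cases.append(OrfCase(
        "nomatch", (240, 330),
        tm("nomatch", [e1, e3, e4], 130, 760),
        "uncertain", "none"))

    return cases, genome


# ---------------------------------------------------------------------------
# two-dataset stage-structured expression (for PCA / pseudotime)
# ---------------------------------------------------------------------------

STAGE_ORDER = ["start", "early", "late", "pluripotent"]

DEFAULT_STAGE_DESIGN = {
    "Bcell": [("Bcells", "start"), ("Balpha", "start"), ("day2", "early"),
              ("day4", "early"), ("day6", "late"), ("day8", "late"),
              ("iPS", "pluripotent"), ("ES", "pluripotent")],
    "MEF": [("MEF", "start"), ("Mday3", "early"), ("Mday5", "early"),
            ("Mday7", "late"), ("Mday10", "late"), ("MiPS", "pluripotent"),
            ("MES", "pluripotent")],
}

_STAGE_PROGRESS = {"start": 0.05, "early": 0.35, "late": 0.65,
                   "pluripotent": 0.95}


def simulate_stage_expression(n_genes: int = 400, noise_sd: float = 3.0,
                              seed: int = 0, n_reps: int = 2,
                              design: dict[str, list[tuple[str, str]]] | None = None,
                              ) -> tuple[ExprTable, pd.DataFrame]:
    """Two-dataset expression table with four planted stage groups.

    Samples carry a latent reprogramming progress (four well-separated
    stage blobs shared between datasets, with small per-timepoint
    offsets); each gene loads linearly on the progress axis, so PCA
    recovers the generative order on its first component. Returns the
    table (arbitrary positive expression units, ``tpm``) and a truth
    frame with per-sample dataset, stage and generative progress.
    """
    design = DEFAULT_STAGE_DESIGN if design is None else design
    rng = np.random.default_rng(seed)
    rows = []
    for dataset, stages in design.items():
        for ti, (cond, stage) in enumerate(stages):
            progress = _STAGE_PROGRESS[stage] + 0.02 * (ti % 2)
            for rep in range(1, n_reps + 1):
                rows.append({"sample_id": f"{cond}_r{rep}",
                             "condition": cond, "replicate": rep,
                             "dataset": dataset, "stage": stage,
                             "time_index": ti, "progress": progress})
    meta = pd.DataFrame(rows).set_index("sample_id")
    samples = SampleMap(meta[["condition", "replicate", "dataset"]])

    progress = meta["progress"].to_numpy()
    loadings = rng.uniform(10.0, 30.0, n_genes) * rng.choice([-1, 1], n_genes)
    signal = loadings[:, None] * (2.0 * progress[None, :] - 1.0)
    values = 100.0 + signal + rng.normal(0.0, noise_sd,
                                         (n_genes, len(progress)))
    values = np.clip(values, 0.1, None)
    table = ExprTable(
        pd.DataFrame(values,
                     index=pd.Index([f"g{i}" for i in range(n_genes)],
                                    name="gene_id"),
                     columns=meta.index),
        samples, "tpm")
    return table, meta
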