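"""Factor-dependency classification from perturbation endpoints.

A perturbation experiment compares a reprogramming endpoint under a
control arm (scrambled shRNA or empty vector) with one or more
treatment arms (two shRNAs per factor, or an overexpression
construct), each against a shared day-0 baseline. The second
difference

    ΔΔPSI_j = (ΔPSI treat_j − baseline) − (ΔPSI control − baseline)
            = mean PSI(treat_j) − mean PSI(control)

isolates the perturbation effect. Events are *dependent* on the factor
when |ΔΔPSI| ≥ 10 in every treatment arm (and on the arm average),
*independent* when they change during reprogramming at all but with
|ΔΔPSI| < 2, and unclassified otherwise. The same logic applies to
poly-A-site usage (ΔΔPAU) for alternative polyadenylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from splicedyn.config import DEFAULTS
from splicedyn.core_io import QUAL_OK, PauTable, PsiTable, SpliceEvent
from splicedyn.psi_diff import call_diff


@dataclass(frozen=True)
class PerturbationDesign:
    """Conditions entering a ΔΔ computation for one factor."""

    baseline: str
    control_end: str
    treatment_ends: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.treatment_ends:
            raise ValueError("treatment_ends must be non-empty")

    def validate(self, t: PsiTable | PauTable) -> None:
        known = set(t.samples.table["condition"])
        for cond in (self.baseline, self.control_end, *self.treatment_ends):
            if cond not in known:
                raise ValueError(f"design condition {cond!r} not in sample map")


@dataclass
class DependencySet:
    """Disjoint dependent / independent / unclassified event sets."""

    dependent: dict[str, float]      # event_id -> arm-average ΔΔPSI
    independent: set[str]
    unclassified: set[str]
    label: str = ""
    per_arm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        dep = set(self.dependent)
        if dep & self.independent or dep & self.unclassified \
                or self.independent & self.unclassified:
            raise ValueError("dependency sets are not disjoint")


def _cond_means(t: PsiTable, cond: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-event mean PSI for a condition and an all-cells-OK mask."""
    sids = t.samples.samples_of(cond)
    vals = t.psi[sids].to_numpy(float)
    ok = (t.quality[sids].to_numpy() == QUAL_OK).all(axis=1)
    return vals.mean(axis=1), ok


def delta_delta(t: PsiTable, d: PerturbationDesign) -> pd.DataFrame:
    """Per-event ΔΔPSI for every treatment arm plus the arm average.

    Baseline cancels algebraically (ΔΔ = mean_treat − mean_control) but
    its cells still gate evaluability: an event is evaluable only when
    every contributing cell in baseline, control and all arms is OK.
    Non-evaluable events carry NaN.
    """
    d.validate(t)
    _, ok_base = _cond_means(t, d.baseline)
    mean_ctrl, ok_ctrl = _cond_means(t, d.control_end)
    ok = ok_base & ok_ctrl
    out = pd.DataFrame(index=pd.Index(t.event_ids, name="event_id"))
    arm_vals = []
    for arm in d.treatment_ends:
        mean_arm, ok_arm = _cond_means(t, arm)
        ok &= ok_arm
        arm_vals.append(mean_arm - mean_ctrl)
    for arm, vals in zip(d.treatment_ends, arm_vals):
        out[arm] = np.where(ok, vals, np.nan)
    out["arm_average"] = np.where(ok, np.mean(arm_vals, axis=0), np.nan)
    return out


def classify_dependency(t: PsiTable, d: PerturbationDesign,
                        ddpsi_min: float = DEFAULTS["ddpsi_min"],
                        ddpsi_indep_max: float = DEFAULTS["ddpsi_indep_max"],
                        base_change_min: float = DEFAULTS["base_change_min"],
                        range_min: float = DEFAULTS["range_min"],
                        require_all_treatments: bool = True,
                        base_change_any_arm: bool = True,
                        ) -> DependencySet:
    """Split events into factor-dependent / -independent / unclassified.

    Dependent: |ΔΔ| ≥ ddpsi_min in every treatment arm (or any arm when
    ``require_all_treatments`` is off) *and* on the arm average — for a
    single-arm design the two coincide. Independent: the event passes
    the differential-splicing rule (|ΔPSI| ≥ base_change_min, replicate
    range ≥ range_min) baseline→endpoint in the control or any
    treatment arm (control only when ``base_change_any_arm`` is off),
    and max |ΔΔ| over arms < ddpsi_indep_max. Events not evaluable in
    all arms are unclassified.
    """
    dd = delta_delta(t, d)
    arms = list(d.treatment_ends)
    arm_abs = dd[arms].abs()
    evaluable = ~dd["arm_average"].isna()

    if require_all_treatments:
        dep_arms = (arm_abs >= ddpsi_min).all(axis=1)
    else:
        dep_arms = (arm_abs >= ddpsi_min).any(axis=1)
    dep_mask = evaluable & dep_arms & (dd["arm_average"].abs() >= ddpsi_min)

    # base change during reprogramming, per arm (incl. control)
    base_conds = [d.control_end] + (arms if base_change_any_arm else [])
    changing = pd.Series(False, index=dd.index)
    for cond in base_conds:
        calls = call_diff(t, d.baseline, cond, dpsi_min=base_change_min,
                          range_min=range_min)
        passed = pd.Series({c.event_id: c.passed for c in calls})
        changing |= passed.reindex(dd.index, fill_value=False)
    indep_mask = (evaluable & ~dep_mask & changing
                  & (arm_abs.max(axis=1) < ddpsi_indep_max))

    dependent = {eid: float(dd.loc[eid, "arm_average"])
                 for eid in dd.index[dep_mask]}
    independent = set(dd.index[indep_mask])
    unclassified = set(dd.index) - set(dependent) - independent
    return DependencySet(dependent, independent, unclassified,
                         label=d.label, per_arm=dd)


def overlap_stats(a: DependencySet, b: DependencySet) -> dict:
    """Overlap between two factors' dependent sets.

    Returns counts, Jaccard index and the fraction of shared dependent
    events whose ΔΔ values agree in sign (events with ΔΔ exactly 0 in
    either factor are excluded from the concordance denominator and
    counted separately).
    """
    sa, sb = set(a.dependent), set(b.dependent)
    shared = sa & sb
    signable = [e for e in shared
                if a.dependent[e] != 0 and b.dependent[e] != 0]
    concordant = sum(
        1 for e in signable
        if np.sign(a.dependent[e]) == np.sign(b.dependent[e]))
    union = sa | sb
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "n_shared": len(shared),
        "jaccard": len(shared) / len(union) if union else 0.0,
        "direction_concordance":
            concordant / len(signable) if signable else float("nan"),
        "n_zero_excluded": len(shared) - len(signable),
    }


def select_control_exons(t: PsiTable, conditions: list[str],
                         exclude: set[str], size: int, seed: int,
                         psi_low: float = 10.0, psi_high: float = 90.0,
                         dpsi_max: float = 2.0) -> set[str]:
    """Random alternative-but-non-changing control set (AS_NC).

    Candidates keep an intermediate mean PSI (10 < PSI < 90, strict) in
    every condition and shift by at most ``dpsi_max`` between any pair
    of conditions; excluded ids (e.g. the dependent/independent sets
    under study) are removed before sampling. When fewer candidates
    than ``size`` remain, all are returned with a warning.
    """
    import warnings

    means, oks = zip(*(_cond_means(t, c) for c in conditions))
    mean_mat = np.column_stack(means)
    ok = np.column_stack(oks).all(axis=1)
    intermediate = ((mean_mat > psi_low) & (mean_mat < psi_high)).all(axis=1)
    stable = (mean_mat.max(axis=1) - mean_mat.min(axis=1)) <= dpsi_max
    cand = [eid for eid, keep in zip(t.event_ids, ok & intermediate & stable)
            if keep and eid not in exclude]
    if len(cand) <= size:
        if len(cand) < size:
            warnings.warn(
                f"only {len(cand)} control candidates for requested {size}")
        return set(cand)
    rng = np.random.default_rng(seed)
    return set(rng.choice(cand, size=size, replace=False))


def psi_distribution_shift_test(t: PsiTable, event_set: set[str],
                                cond_a: str, cond_b: str,
                                lo: float = 25.0, hi: float = 75.0) -> dict:
    """Fisher test on intermediate vs extreme PSI between two conditions.

    For each condition, events in ``event_set`` are counted as
    *intermediate* (lo < PSI < hi, on the replicate-mean PSI) or
    *extreme* (PSI ≤ lo or ≥ hi); the resulting 2×2 table is tested
    with a two-sided Fisher exact test.
    """
    if not event_set:
        raise ValueError("empty event set")
    idx = [eid for eid in t.event_ids if eid in event_set]
    table = []
    for cond in (cond_a, cond_b):
        mean, ok = _cond_means(t, cond)
        sel = pd.Series(mean, index=t.event_ids).loc[idx]
        okv = pd.Series(ok, index=t.event_ids).loc[idx]
        vals = sel[okv].to_numpy(float)
        inter = int(((vals > lo) & (vals < hi)).sum())
        table.append([inter, len(vals) - inter])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "counts": {cond_a: tuple(table[0]), cond_b: tuple(table[1])},
        "odds_ratio": float(odds),
        "p": float(p),
    }


def classify_apa_dependency(p: PauTable, d: PerturbationDesign,
                            tpm_min: float = DEFAULTS["tpm_min"],
                            min_samples: int = DEFAULTS["apa_min_samples"],
                            min_sites: int = DEFAULTS["apa_min_sites"],
                            ddpau_min: float = DEFAULTS["ddpau_min"],
                            ) -> tuple[dict[str, float], set[str]]:
    """Factor-dependent poly-A sites (and their host genes) by ΔΔPAU.

    Sites are first filtered for transcript expression (tpm ≥ tpm_min
    in ≥ min_samples samples) and gene-level site count (≥ min_sites
    after filtering); a site is dependent when |ΔΔPAU| ≥ ddpau_min in
    every treatment arm. No independent class is defined for APA.
    """
    d.validate(p)
    expressed = (p.tpm.to_numpy(float) >= tpm_min).sum(axis=1) >= min_samples
    keep = pd.Series(expressed, index=p.sites.index)
    gene_sizes = p.sites.loc[keep, "gene_id"].value_counts()
    good_genes = set(gene_sizes.index[gene_sizes >= min_sites])
    keep &= p.sites["gene_id"].isin(good_genes)

    def cond_mean(cond: str) -> pd.Series:
        sids = p.samples.samples_of(cond)
        return p.pau[sids].mean(axis=1)

    ctrl = cond_mean(d.control_end)
    dd_arms = pd.DataFrame(
        {arm: cond_mean(arm) - ctrl for arm in d.treatment_ends})
    dep_mask = keep & (dd_arms.abs() >= ddpau_min).all(axis=1)
    dep_sites = {sid: float(dd_arms.loc[sid].mean())
                 for sid in p.sites.index[dep_mask]}
    dep_genes = set(p.sites.loc[list(dep_sites), "gene_id"])
    return dep_sites, dep_genes


def as_apa_overlap(events: list[SpliceEvent], apa_sites: pd.DataFrame,
                   ) -> tuple[list[tuple[str, str]], dict]:
    """Interval overlaps between AS event spans and APA last exons.

    Overlap requires ≥ 1 shared base between the event's largest
    junction and the site's last-exon interval on the same chromosome
    (half-open intervals; adjacent intervals do not overlap; strand is
    ignored). Returns the overlapping (event, site) pairs and a
    gene-level summary.
    """
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for sid, row in apa_sites.iterrows():
        by_chrom.setdefault(str(row["chrom"]), []).append(
            (int(row["start"]), int(row["end"]), str(sid), str(row["gene_id"])))
    for ivs in by_chrom.values():
        ivs.sort()
    pairs: list[tuple[str, str]] = []
    as_genes: set[str] = set()
    for e in events:
        for s0, s1, sid, gid in by_chrom.get(e.chrom, []):
            if s0 >= e.span_end:
                break
            if s1 > e.span_start:  # max(starts) < min(ends)
                pairs.append((e.event_id, sid))
                as_genes.add(e.gene_id)
    apa_genes = set(apa_sites["gene_id"].astype(str))
    event_genes = {e.gene_id for e in events}
    summary = {
        "n_pairs": len(pairs),
        "genes_as": len(event_genes),
        "genes_apa": len(apa_genes),
        "genes_both_overlapping": len(
            as_genes & {g for _, s in pairs
                        for g in [str(apa_sites.loc[s, "gene_id"])]}),
        "genes_shared": len(event_genes & apa_genes),
    }
    return pairs, summary
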