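"""Sequence features of exon groups and permutation-tested RNA motif maps.

Features compared between exon sets: exon and flanking-intron lengths,
GC content of exon and introns, and splice-site strength. Splice sites
are scored with a position-weight log-odds model trained from a
supplied set of constitutive sites against a background composition
(externally trained maximum-entropy-style score tables can be used in
its place by constructing the model from their frequencies). Group
differences use the two-sided Mann–Whitney rank-sum test.

RNA maps give, per position around the regulated exons (first/last
50 nt of the exon, first/last 150 nt of the flanking introns), the
fraction of sequences carrying a motif match within a centered sliding
window (default 31 nt), compared between a regulated and a control
set; significance per position comes from a label-permutation null.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from splicedyn.config import DEFAULTS

_BASES = "ACGT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# canonical window composition of the splice-site scoring inputs
SS5_EXON_NT, SS5_INTRON_NT = 3, 6     # 9-nt 5'ss window
SS3_INTRON_NT, SS3_EXON_NT = 20, 3    # 23-nt 3'ss window


# ---------------------------------------------------------------------------
# splice-site scoring
# ---------------------------------------------------------------------------

@dataclass
class SpliceSiteModel:
    """Per-position log2-odds of base frequencies vs background."""

    log_odds: np.ndarray  # (length, 4) over ACGT

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


def train_splice_site_model(site_seqs: list[str],
                            background: dict[str, float] | None = None,
                            pseudocount: float = 0.0) -> SpliceSiteModel:
    """Train a first-order PWM from aligned constitutive-site sequences.

    ``background`` defaults to uniform base frequencies; passing the
    genome-wide composition sharpens the odds. A pseudocount may be
    added per (position, base) cell to avoid −inf at unseen bases.
    """
    if not site_seqs:
        raise ValueError("no training sequences")
    length = len(site_seqs[0])
    if any(len(s) != length for s in site_seqs):
        raise ValueError("training sequences have unequal lengths")
    counts = np.full((length, 4), pseudocount, float)
    for s in site_seqs:
        for i, b in enumerate(s.upper()):
            j = _BASES.find(b)
            if j < 0:
                raise ValueError(f"non-ACGT base {b!r} in training sequence")
            counts[i, j] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    bg = np.array([0.25] * 4 if background is None
                  else [background[b] for b in _BASES])
    with np.errstate(divide="ignore"):
        lo = np.log2(freq / bg)
    return SpliceSiteModel(lo)


def score_splice_site(seq: str, model: SpliceSiteModel) -> float:
    """Log-odds score of one site; NaN for non-ACGT characters."""
    seq = seq.upper()
    if len(seq) != model.length:
        raise ValueError(
            f"sequence length {len(seq)} != model length {model.length}")
    score = 0.0
    for i, b in enumerate(seq):
        j = _BASES.find(b)
        if j < 0:
            return float("nan")
        score += model.log_odds[i, j]
    return float(score)


# ---------------------------------------------------------------------------
# per-event features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    event_id: str
    exon_length: float
    up_intron_length: float
    down_intron_length: float
    gc_exon: float
    gc_up_intron: float
    gc_down_intron: float
    score_5ss: float
    score_3ss: float


FEATURE_NAMES = [f.name for f in
                 FeatureVector.__dataclass_fields__.values()][1:]


def gc_content(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def compute_features(sequences: dict[str, dict[str, str]],
                     ss5_model: SpliceSiteModel | None = None,
                     ss3_model: SpliceSiteModel | None = None,
                     ) -> list[FeatureVector]:
    """One feature vector per event from its sequence windows.

    ``sequences`` maps event_id → {exon, intron_up, intron_down, ss5,
    ss3}; any absent window (terminal exon, unscored site) yields NaN
    for the features that need it.
    """
    out = []
    for eid, win in sequences.items():
        exon = win.get("exon", "")
        up = win.get("intron_up", "")
        down = win.get("intron_down", "")
        s5 = (score_splice_site(win["ss5"], ss5_model)
              if ss5_model is not None and "ss5" in win else float("nan"))
        s3 = (score_splice_site(win["ss3"], ss3_model)
              if ss3_model is not None and "ss3" in win else float("nan"))
        out.append(FeatureVector(
            event_id=eid,
            exon_length=float(len(exon)) if exon else float("nan"),
            up_intron_length=float(len(up)) if up else float("nan"),
            down_intron_length=float(len(down)) if down else float("nan"),
            gc_exon=gc_content(exon),
            gc_up_intron=gc_content(up),
            gc_down_intron=gc_content(down),
            score_5ss=s5,
            score_3ss=s3,
        ))
    return out


def features_frame(features: list[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in features]).set_index("event_id")


def compare_features(group: list[FeatureVector],
                     control: list[FeatureVector]) -> pd.DataFrame:
    """Per-feature medians and two-sided Mann–Whitney U vs the control set.

    Missing values are dropped per feature. Requires ≥ 3 usable values
    on each side for a test; features with fewer get NaN statistics.
    """
    if len(group) < 3 or len(control) < 3:
        raise ValueError("both groups need at least 3 members")
    g = features_frame(group)
    c = features_frame(control)
    rows = []
    for feat in FEATURE_NAMES:
        gv = g[feat].dropna().to_numpy(float)
        cv = c[feat].dropna().to_numpy(float)
        if len(gv) >= 3 and len(cv) >= 3:
            u, p = stats.mannwhitneyu(gv, cv, alternative="two-sided")
        else:
            u, p = float("nan"), float("nan")
        rows.append({"feature": feat,
                     "median_group": float(np.median(gv)) if len(gv) else np.nan,
                     "median_control": float(np.median(cv)) if len(cv) else np.nan,
                     "U": float(u), "p": float(p)})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# motif scanning and RNA maps
# ---------------------------------------------------------------------------

def motif_regex(motif: str) -> re.Pattern:
    pattern = "".join(
        f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch]
        for ch in motif.upper().replace("U", "T"))
    return re.compile(f"(?=({pattern}))")


def motif_match_starts(seq: str, motif: str) -> np.ndarray:
    """Boolean array over positions: does a motif match start here?

    Overlapping matches are all reported; length is
    len(seq) − len(motif) + 1 (empty for sequences shorter than the
    motif).
    """
    m = len(motif)
    n = len(seq) - m + 1
    hits = np.zeros(max(0, n), bool)
    for match in motif_regex(motif).finditer(seq.upper()):
        hits[match.start()] = True
    return hits


def window_coverage(seqs: list[str], motif: str, window: int,
                    length: int) -> np.ndarray:
    """Per-sequence, per-position binary coverage matrix.

    Position j of a sequence is covered when at least one motif match
    lies entirely inside the window of ``window`` nt centered on j
    (clipped at the region boundaries).
    """
    m = len(motif)
    if m > window:
        raise ValueError("motif longer than the sliding window")
    half = window // 2
    cov = np.zeros((len(seqs), length), bool)
    for i, seq in enumerate(seqs):
        starts = motif_match_starts(seq, motif)
        if not starts.any():
            continue
        where = np.flatnonzero(starts)
        for s in where:
            # match occupies s..s+m-1; covers centers j with
            # j-half <= s and s+m-1 <= j+half
            lo = max(0, s + m - 1 - half)
            hi = min(length - 1, s + half)
            if lo <= hi:
                cov[i, lo:hi + 1] = True
    return cov


@dataclass
class RnaMap:
    """Positional motif-coverage map for one set of regions."""

    regions: list[str]
    positions: dict[str, np.ndarray]            # region -> position labels
    coverage: dict[str, dict[str, np.ndarray]]  # group -> region -> fraction
    pvals: dict[str, np.ndarray]                # region -> per-position p
    significant_segments: dict[str, list[tuple[int, int]]]  # index intervals
    alpha: float
    n_perm: int
    n_skipped: dict[str, int] = field(default_factory=dict)

    def segments_as_positions(self, region: str) -> list[tuple[int, int]]:
        lab = self.positions[region]
        return [(int(lab[a]), int(lab[b - 1]))
                for a, b in self.significant_segments[region]]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


# default position labelling of the four map regions: exonic positions
# count 1..50 from each exon boundary; intronic positions −150..−1
# upstream of a 3'ss. The downstream-intron window sits at the intron's
# 3' end (upstream of the distal 3' splice site).
DEFAULT_REGION_POSITIONS = {
    "intron_up": np.arange(-150, 0),
    "exon_start": np.arange(1, 51),
    "exon_end": np.arange(-50, 0),
    "intron_down": np.arange(-150, 0),
}


def rna_map(seqs_by_group: dict[str, dict[str, list[str]]], motif: str,
            window: int = DEFAULTS["map_window"],
            n_perm: int = DEFAULTS["map_n_perm"],
            alpha: float = DEFAULTS["map_alpha"],
            seed: int = 0,
            region_positions: dict[str, np.ndarray] | None = None,
            test_groups: tuple[str, str] = ("regulated", "control"),
            randomized_p: bool = False,
            ) -> RnaMap:
    """Build a positional motif map with a permutation null per region.

    ``seqs_by_group`` maps group → region → sequences; the groups named
    in ``test_groups`` (regulated vs control) enter the permutation
    test, any further groups (e.g. independent) are profiled only.
    Per position the statistic is |coverage(regulated) −
    coverage(control)|; the null redistributes sequences between the
    two groups, and the empirical p uses the add-one estimator, so
    p ≥ 1/(n_perm+1) and ties count against significance (slightly
    conservative, the safe default for reporting). With
    ``randomized_p`` the tie mass is broken uniformly at random, which
    makes the p-value exactly uniform under the exchangeable null —
    the construction to use when auditing calibration. Significant
    segments are maximal runs of positions with p ≤ alpha. Sequences
    shorter than the region length are skipped and counted.
    """
    positions = dict(region_positions or DEFAULT_REGION_POSITIONS)
    reg_name, ctrl_name = test_groups
    regions = [r for r in positions if r in seqs_by_group[reg_name]]
    rng = np.random.default_rng(seed)
    coverage: dict[str, dict[str, np.ndarray]] = {g: {} for g in seqs_by_group}
    pvals: dict[str, np.ndarray] = {}
    segments: dict[str, list[tuple[int, int]]] = {}
    skipped: dict[str, int] = {}

    for region in regions:
        length = len(positions[region])
        mats: dict[str, np.ndarray] = {}
        for group, by_region in seqs_by_group.items():
            seqs = [s for s in by_region.get(region, []) if len(s) >= length]
            n_short = len(by_region.get(region, [])) - len(seqs)
            if n_short:
                skipped[f"{group}/{region}"] = n_short
                warnings.warn(
                    f"{n_short} sequences shorter than region {region!r} skipped")
            seqs = [s[:length] for s in seqs]
            mats[group] = window_coverage(seqs, motif, window, length)
            coverage[group][region] = mats[group].mean(axis=0) \
                if len(seqs) else np.zeros(length)

        pool = np.vstack([mats[reg_name], mats[ctrl_name]]).astype(float)
        n_reg = mats[reg_name].shape[0]
        obs = np.abs(pool[:n_reg].mean(axis=0) - pool[n_reg:].mean(axis=0))
        greater = np.zeros(length)
        ties = np.zeros(length)
        for _ in range(n_perm):
            perm = rng.permutation(pool.shape[0])
            stat = np.abs(pool[perm[:n_reg]].mean(axis=0)
                          - pool[perm[n_reg:]].mean(axis=0))
            greater += stat > obs + 1e-12
            ties += np.abs(stat - obs) <= 1e-12
        if randomized_p:
            u = rng.uniform(size=length)
            p = (greater + u * (ties + 1.0)) / (n_perm + 1.0)
        else:
            p = (1.0 + greater + ties) / (n_perm + 1.0)
        pvals[region] = p
        segments[region] = _runs(p <= alpha)

    return RnaMap(regions, {r: positions[r] for r in regions}, coverage,
                  pvals, segments, alpha, n_perm, skipped)
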