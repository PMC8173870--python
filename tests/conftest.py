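"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (brute-force enumeration,
hand-written codon table, O(n²)/O(n³) loops) and share no code with
the package paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from splicedyn.core_io import (
    PsiTable,
    QUAL_OK,
    SampleMap,
    SpliceEvent,
)


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def make_sample_map(conditions: list[str], n_reps: int = 2,
                    dataset: str = "D") -> SampleMap:
    rows = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            rows.append({"sample_id": f"{cond}_r{rep}", "condition": cond,
                         "replicate": rep, "dataset": dataset})
    return SampleMap(pd.DataFrame(rows).set_index("sample_id"))


def make_events(event_ids: list[str]) -> list[SpliceEvent]:
    return [
        SpliceEvent(eid, f"g{i}", "CEx", "chr1", 1000 * (i + 1),
                    1000 * (i + 1) + 500, 1000 * (i + 1) + 100,
                    1000 * (i + 1) + 190, "+")
        for i, eid in enumerate(event_ids)
    ]


def make_psi_table(psi_by_cond: dict[str, np.ndarray],
                   reads: int = 100) -> PsiTable:
    """Build a PsiTable from per-condition (events × reps) PSI arrays."""
    conds = list(psi_by_cond)
    n_reps = np.asarray(psi_by_cond[conds[0]]).shape[1]
    samples = make_sample_map(conds, n_reps)
    mat = np.hstack([np.asarray(psi_by_cond[c], float) for c in conds])
    event_ids = [f"ev{i}" for i in range(mat.shape[0])]
    idx = pd.Index(event_ids, name="event_id")
    psi = pd.DataFrame(mat, index=idx, columns=samples.sample_ids)
    reads_df = pd.DataFrame(reads, index=idx, columns=samples.sample_ids)
    return PsiTable.build(make_events(event_ids), samples, psi, reads_df)


def random_psi_table(rng: np.random.Generator, n_events: int,
                     conditions: list[str], n_reps: int = 2) -> PsiTable:
    psi_by_cond = {
        c: np.round(rng.uniform(0, 100, (n_events, n_reps)), 2)
        for c in conditions
    }
    return make_psi_table(psi_by_cond)


# ---------------------------------------------------------------------------
# brute-force differential-splicing oracle
# ---------------------------------------------------------------------------

def brute_force_diff_union(t: PsiTable, conditions: list[str],
                           dpsi_min: float = 10.0,
                           range_min: float = 5.0) -> set[str]:
    """Plain-python enumeration of the ΔPSI ≥ 10 / range ≥ 5 rule."""
    union = set()
    for ca, cb in combinations(conditions, 2):
        sa = t.samples.samples_of(ca)
        sb = t.samples.samples_of(cb)
        for eid in t.event_ids:
            va = [t.psi.loc[eid, s] for s in sa]
            vb = [t.psi.loc[eid, s] for s in sb]
            quals = [t.quality.loc[eid, s] for s in sa + sb]
            if any(q != QUAL_OK for q in quals):
                continue
            dpsi = sum(vb) / len(vb) - sum(va) / len(va)
            if abs(dpsi) < dpsi_min:
                continue
            sign = 1.0 if dpsi >= 0 else -1.0
            gaps = [sign * (b - a) for a in va for b in vb]
            if min(gaps) >= range_min:
                union.add(eid)
    return union


# ---------------------------------------------------------------------------
# exact statistics oracles
# ---------------------------------------------------------------------------

def _ln_factorial(n: int) -> float:
    out = 0.0
    for i in range(2, n + 1):
        out += np.log(i)
    return out


def _ln_choose(n: int, k: int) -> float:
    return _ln_factorial(n) - _ln_factorial(k) - _ln_factorial(n - k)


def fisher_exact_oracle(table: list[list[int]]) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return float(np.exp(_ln_choose(r1, x) + _ln_choose(r2, c1 - x)
                            - _ln_choose(n, c1)))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def mannwhitney_u_oracle(x: list[float], y: list[float]) -> float:
    """U statistic by exhaustive pair comparison (0.5 per tie)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mannwhitney_p_oracle(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = mannwhitney_u_oracle(x, y)
    mu = n_x * len(y) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_x):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mannwhitney_u_oracle(gx, gy)
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def ward_linkage_oracle(points: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive O(n³) Ward agglomeration: merge order + heights.

    Uses the Lance–Williams Ward distance between clusters; returns at
    each step the two merged clusters (as frozensets of leaf indices)
    and the merge height (same convention as scipy linkage).
    """
    clusters: dict[frozenset, np.ndarray] = {
        frozenset([i]): points[i:i + 1] for i in range(len(points))}
    merges = []
    while len(clusters) > 1:
        best = None
        for ka, kb in combinations(clusters, 2):
            pa, pb = clusters[ka], clusters[kb]
            na, nb = len(pa), len(pb)
            d2 = ((pa.mean(0) - pb.mean(0)) ** 2).sum()
            ward = np.sqrt(2.0 * na * nb / (na + nb) * d2)
            if best is None or ward < best[0]:
                best = (ward, ka, kb)
        h, ka, kb = best
        merges.append((ka, kb, h))
        merged = np.vstack([clusters.pop(ka), clusters.pop(kb)])
        clusters[ka | kb] = merged
    return merges


# ---------------------------------------------------------------------------
# independent translation (codon-table) oracle
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def oracle_translate(seq: str) -> str:
    aa = []
    for i in range(0, len(seq) - 2, 3):
        aa.append(_CODON_TABLE[seq[i:i + 3]])
    return "".join(aa)


def six_frame_translations(seq: str) -> list[str]:
    rc = seq.translate(_COMPLEMENT)[::-1]
    return [oracle_translate(s[f:]) for s in (seq, rc) for f in range(3)]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
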