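"""Threshold-based differential-splicing calls between condition pairs.

An event is differentially spliced between two conditions when the
difference of mean PSI reaches ``dpsi_min`` (default 10) and, in
addition, every cross-condition replicate pair differs by at least
``range_min`` (default 5) in the direction of the mean change. The
range criterion guards against calls driven by a single outlying
replicate. Both thresholds are inclusive (≥).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from splicedyn.config import DEFAULTS
from splicedyn.core_io import QUAL_OK, PsiTable


@dataclass(frozen=True)
class DiffCall:
    """Outcome of one pairwise comparison for one event.

    ``dpsi`` is mean(condition_b) − mean(condition_a);
    ``min_pairwise_gap`` is the smallest cross-condition replicate
    difference taken in the direction of ``dpsi``. ``evaluable`` is
    False when a contributing cell is missing or low quality, in which
    case ``passed`` is False and the statistics are NaN.
    """

    event_id: str
    condition_a: str
    condition_b: str
    dpsi: float
    min_pairwise_gap: float
    passed: bool
    evaluable: bool = True


def psi_from_counts(inclusion_reads: int, skipping_reads: int,
                    min_reads: int = DEFAULTS["min_reads"],
                    ) -> tuple[float, str]:
    """PSI from junction read counts: 100·inc/(inc+skip).

    Returns ``(psi, quality)``; PSI is NaN with quality NA when no reads
    support either junction, and quality is VLOW below the read floor.
    """
    if inclusion_reads < 0 or skipping_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = inclusion_reads + skipping_reads
    if total == 0:
        return float("nan"), "NA"
    psi = 100.0 * inclusion_reads / total
    return psi, ("VLOW" if total < min_reads else "OK")


def call_diff(t: PsiTable, cond_a: str, cond_b: str,
              dpsi_min: float = DEFAULTS["dpsi_min"],
              range_min: float = DEFAULTS["range_min"],
              require_quality: bool = True,
              sign_consistent: bool = DEFAULTS["sign_consistent_range"],
              ) -> list[DiffCall]:
    """Call differential splicing for every event between two conditions.

    With ``sign_consistent`` (default) the replicate-range criterion is
    the minimal cross-condition gap in the direction of the mean
    change; otherwise the minimal absolute gap is used.
    """
    sa = t.samples.samples_of(cond_a)
    sb = t.samples.samples_of(cond_b)
    psi_a = t.psi[sa].to_numpy(float)
    psi_b = t.psi[sb].to_numpy(float)
    if require_quality:
        ok = ((t.quality[sa].to_numpy() == QUAL_OK).all(axis=1)
              & (t.quality[sb].to_numpy() == QUAL_OK).all(axis=1))
    else:
        ok = (~np.isnan(psi_a)).all(axis=1) & (~np.isnan(psi_b)).all(axis=1)

    dpsi = psi_b.mean(axis=1) - psi_a.mean(axis=1)
    # all cross-condition replicate differences, shape (events, |a|·|b|)
    gaps = (psi_b[:, None, :] - psi_a[:, :, None]).reshape(len(dpsi), -1)
    if sign_consistent:
        sign = np.where(dpsi >= 0, 1.0, -1.0)
        min_gap = (gaps * sign[:, None]).min(axis=1)
    else:
        min_gap = np.abs(gaps).min(axis=1)

    calls = []
    for i, eid in enumerate(t.event_ids):
        if not ok[i]:
            calls.append(DiffCall(eid, cond_a, cond_b, float("nan"),
                                  float("nan"), False, evaluable=False))
            continue
        passed = bool(abs(dpsi[i]) >= dpsi_min and min_gap[i] >= range_min)
        calls.append(DiffCall(eid, cond_a, cond_b, float(dpsi[i]),
                              float(min_gap[i]), passed))
    return calls


def diff_union(t: PsiTable, conditions: list[str],
               dpsi_min: float = DEFAULTS["dpsi_min"],
               range_min: float = DEFAULTS["range_min"],
               require_quality: bool = True,
               sign_consistent: bool = DEFAULTS["sign_consistent_range"],
               ) -> tuple[set[str], dict[str, list[DiffCall]]]:
    """Events differentially spliced in at least one pairwise comparison.

    Returns the union set and, per event, the list of passing pairwise
    calls. An event not evaluable in one pair can still enter the union
    through another pair.
    """
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    union: set[str] = set()
    fired: dict[str, list[DiffCall]] = {}
    for ca, cb in combinations(conditions, 2):
        for call in call_diff(t, ca, cb, dpsi_min, range_min,
                              require_quality, sign_consistent):
            if call.passed:
                union.add(call.event_id)
                fired.setdefault(call.event_id, []).append(call)
    return union, fired
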