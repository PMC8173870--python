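"""Membership-based inference of RBP splicing regulators.

Candidate RNA-binding proteins are first filtered for detectable
expression (cpm ≥ 5 in at least a third of samples) and minimal
temporal variation (coefficient of variation ≥ 0.2). Each surviving
RBP's scaled expression trajectory is then scored against every AS
cluster centroid and its negative: a membership of at least 0.3 to a
centroid nominates the RBP as a putative positive regulator of that
cluster, and to the negated centroid as a putative negative regulator.
The same machinery scores the expression trajectories of the genes
hosting the clustered exons (concordant / contrasting / neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from splicedyn.config import DEFAULTS
from splicedyn.core_io import ExprTable
from splicedyn.temporal_clustering import ClusterModel, membership_to, scale_profiles


@dataclass(frozen=True)
class RegulatorCall:
    """One (RBP, cluster, polarity) nomination with its membership."""

    rbp_id: str
    cluster_id: int
    polarity: str  # positive | negative
    membership: float


def filter_expressed_variable(e: ExprTable,
                              cpm_min: float = DEFAULTS["cpm_min"],
                              frac_samples: float = DEFAULTS["frac_samples"],
                              cv_min: float = DEFAULTS["cv_min"],
                              ) -> ExprTable:
    """Keep genes expressed (cpm ≥ cpm_min in ≥ ceil(frac·n) samples)
    and variable (CV = sd/mean ≥ cv_min, computed over all samples).

    Both boundaries are inclusive. Input must be cpm (or tpm, treated
    the same way); counts should be converted first.
    """
    if e.unit not in ("cpm", "tpm"):
        raise ValueError(f"expected a cpm/tpm table, got unit {e.unit!r}")
    n = e.values.shape[1]
    if n == 0:
        raise ValueError("expression table has no samples")
    need = ceil(frac_samples * n)
    v = e.values.to_numpy(float)
    expressed = (v >= cpm_min).sum(axis=1) >= need
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = expressed & (cv >= cv_min)
    return ExprTable(e.values.loc[keep], e.samples, e.unit, is_subset=True)


def _check_scaled(values: pd.DataFrame) -> None:
    v = values.to_numpy(float)
    if not np.allclose(v.mean(axis=1), 0.0, atol=1e-6):
        raise ValueError("profiles are not scaled (row means differ from 0); "
                         "run scale_profiles first")


def infer_regulators(rbp_expr: ExprTable | pd.DataFrame, model: ClusterModel,
                     membership_min: float = DEFAULTS["membership_min"],
                     scoring_m: float = 2.0) -> list[RegulatorCall]:
    """Nominate positive/negative regulators of each AS cluster.

    ``rbp_expr`` must already be filtered and scaled (rows mean 0).
    An RBP may be called for several clusters; each call records the
    membership that produced it. The comparison is inclusive
    (membership ≥ membership_min).

    ``scoring_m`` is the fuzzifier for the membership computation —
    the classical c-means value of 2, independent of the (crisper)
    fuzzifier used to fit the clusters. A soft fuzzifier is what makes
    the absolute 0.3 cutoff discriminative: with it an uncorrelated
    profile spreads its membership near-uniformly over the 2k
    prototypes, while a profile tracking one centroid still
    concentrates well above the cutoff.
    """
    values = rbp_expr.values if isinstance(rbp_expr, ExprTable) else rbp_expr
    _check_scaled(values)
    u = membership_to(values, model, include_negatives=True, m=scoring_m)
    calls: list[RegulatorCall] = []
    for rbp_id, row in u.iterrows():
        for c in range(model.k):
            if row[f"pos_{c}"] >= membership_min:
                calls.append(RegulatorCall(str(rbp_id), c, "positive",
                                           float(row[f"pos_{c}"])))
            if row[f"neg_{c}"] >= membership_min:
                calls.append(RegulatorCall(str(rbp_id), c, "negative",
                                           float(row[f"neg_{c}"])))
    return calls


def host_gene_concordance(host_expr: ExprTable, model: ClusterModel,
                          event_to_gene: dict[str, str],
                          event_clusters: dict[str, int],
                          membership_min: float = DEFAULTS["membership_min"],
                          scoring_m: float = 2.0) -> pd.DataFrame:
    """Fraction of host genes whose expression follows each AS cluster.

    For every clustered event the expression trajectory of its host
    gene is scored against the event's cluster centroid and its
    negative: membership ≥ threshold to the centroid counts the gene
    as *concordant*, to the negative as *contrasting*, anything else
    (including genes absent from ``host_expr`` or with flat profiles)
    as *neither*. Returns one row per cluster with the three fractions
    (summing to 1) and the event count.
    """
    scaled, dropped = _scaled_or_empty(host_expr)
    u = (membership_to(scaled, model, include_negatives=True, m=scoring_m)
         if len(scaled) else pd.DataFrame())
    rows = []
    for cluster in sorted(set(event_clusters.values())):
        events = [ev for ev, c in event_clusters.items() if c == cluster]
        n_conc = n_contr = n_neither = 0
        for ev in events:
            gene = event_to_gene.get(ev)
            if gene is None or gene not in u.index:
                n_neither += 1
                continue
            if u.loc[gene, f"pos_{cluster}"] >= membership_min:
                n_conc += 1
            elif u.loc[gene, f"neg_{cluster}"] >= membership_min:
                n_contr += 1
            else:
                n_neither += 1
        n = max(1, len(events))
        rows.append({"cluster": cluster, "n_events": len(events),
                     "concordant": n_conc / n, "contrasting": n_contr / n,
                     "neither": n_neither / n})
    return pd.DataFrame(rows).set_index("cluster")


def _scaled_or_empty(host_expr: ExprTable) -> tuple[pd.DataFrame, list[str]]:
    try:
        return scale_profiles(host_expr.values)
    except ValueError:
        # all-constant table: no gene can be concordant or contrasting
        return pd.DataFrame(columns=host_expr.values.columns), \
            [str(i) for i in host_expr.values.index]
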