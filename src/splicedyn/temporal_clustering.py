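"""Fuzzy c-means clustering of scaled inclusion trajectories.

Trajectories (PSI or cpm across time points) are z-scaled per row and
clustered with the classical fuzzy c-means (FCM) algorithm in Euclidean
space. Each item then carries a normalized *membership* toward every
cluster centroid — and, for regulator inference, toward every negated
centroid, so anti-correlated profiles score as negative regulators.

The fuzzifier m controls how soft the partition is; for time-course
data values near 1.1–1.5 keep clusters crisp while still yielding
informative memberships, and the default is 1.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model in scaled-trajectory space."""

    k: int
    m: float
    centroids: np.ndarray          # (k, n_timepoints)
    memberships: np.ndarray        # (n_items, k), rows sum to 1
    iterations: int
    objective: float
    converged: bool = True
    objective_trace: list[float] = field(default_factory=list)
    item_ids: list[str] | None = None

    def hard_assignments(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)


def scale_profiles(x: pd.DataFrame | np.ndarray,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Z-scale each row to mean 0, sd 1 (sample sd, ddof=1).

    Rows with zero variance carry no trajectory information and are
    dropped; their ids are returned alongside the scaled matrix.
    Raises if every row is constant.
    """
    df = pd.DataFrame(x)
    if df.shape[1] < 3:
        raise ValueError("need at least 3 columns to scale a trajectory")
    v = df.to_numpy(float)
    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all rows are constant; nothing to scale")
    dropped = [str(i) for i in df.index[~keep]]
    kept = v[keep]
    scaled = (kept - kept.mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(scaled, index=df.index[keep], columns=df.columns), dropped


def _fcm_memberships(x: np.ndarray, centroids: np.ndarray, m: float,
                     ) -> np.ndarray:
    """u_ic = 1 / Σ_j (d_ic / d_ij)^(2/(m−1)); items at a centroid get 1."""
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = np.zeros((x.shape[0], centroids.shape[0]))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        p = d2[rest] ** (1.0 / (m - 1.0))
        u[rest] = (1.0 / p) / (1.0 / p).sum(axis=1, keepdims=True)
    return u


def _fcm_once(x: np.ndarray, k: int, m: float, tol: float, max_iter: int,
              rng: np.random.Generator) -> ClusterModel:
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = _fcm_memberships(x, centroids, m)
        um = u ** m
        new = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - new[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((um * d2).sum()))
        shift = np.sqrt(((new - centroids) ** 2).sum(axis=1)).max()
        centroids = new
        if shift < tol:
            converged = True
            break
    u = _fcm_memberships(x, centroids, m)
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    obj = float(((u ** m) * d2).sum())
    return ClusterModel(k, m, centroids, u, it, obj, converged, trace)


def fuzzy_cmeans(x_scaled: pd.DataFrame | np.ndarray, k: int,
                 m: float = 1.25, tol: float = 1e-6, max_iter: int = 500,
                 n_restarts: int = 5, seed: int = 0) -> ClusterModel:
    """Fit fuzzy c-means with several seeded restarts; best objective wins.

    Restarts use distinct sub-seeds derived from ``seed``; ties in the
    objective are broken toward the earlier restart, so the result is
    deterministic. A run that does not converge within ``max_iter``
    is returned with ``converged=False`` rather than raising.
    """
    df = pd.DataFrame(x_scaled)
    x = df.to_numpy(float)
    if k >= x.shape[0]:
        raise ValueError(f"k={k} must be smaller than n_items={x.shape[0]}")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    best: ClusterModel | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        model = _fcm_once(x, k, m, tol, max_iter, rng)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    best.item_ids = [str(i) for i in df.index]
    return best


def min_centroid_distance(model: ClusterModel) -> float:
    """Smallest pairwise Euclidean distance between centroids (Dmin)."""
    c = model.centroids
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(model.k, 1)
    return float(d[iu].min())


def mean_within_distance(model: ClusterModel, x_scaled) -> float:
    """Mean distance of items to their hard-assigned centroid."""
    x = pd.DataFrame(x_scaled).to_numpy(float)
    hard = model.hard_assignments()
    d = np.sqrt(((x - model.centroids[hard]) ** 2).sum(axis=1))
    return float(d.mean())


def select_k(x_scaled, k_range: list[int], m: float = 1.25, seed: int = 0,
             criterion: str = "dmin", drop_frac: float = 0.1,
             n_restarts: int = 5) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters from a diagnostics curve.

    With the default ``dmin`` criterion the minimum inter-centroid
    distance is computed for each k; once real structure is exhausted,
    extra centroids start splitting existing clusters and Dmin
    collapses. The selected k is the largest one before the curve drops
    below ``drop_frac`` of its value at the smallest k. The full curve
    is returned for inspection. ``criterion='within'`` exposes the mean
    distance to the hard-assigned centroid instead (elbow by the same
    relative-drop rule on its decrease).
    """
    if not k_range:
        raise ValueError("empty k_range")
    ks = sorted(k_range)
    rows = []
    for k in ks:
        model = fuzzy_cmeans(x_scaled, k, m=m, seed=seed,
                             n_restarts=n_restarts)
        rows.append({
            "k": k,
            "dmin": min_centroid_distance(model) if k >= 2 else np.nan,
            "within": mean_within_distance(model, x_scaled),
        })
    curve = pd.DataFrame(rows).set_index("k")
    if len(ks) == 1:
        return ks[0], curve
    stat = curve[criterion if criterion in ("dmin", "within") else "dmin"]
    ref = stat.iloc[0]
    selected = ks[0]
    for k in ks:
        if stat.loc[k] >= drop_frac * ref:
            selected = k
        else:
            break
    return selected, curve


def membership_to(profiles_scaled, model: ClusterModel,
                  include_negatives: bool = True,
                  m: float | None = None) -> pd.DataFrame:
    """Membership of arbitrary scaled profiles to the model's centroids.

    With ``include_negatives`` the membership formula runs against the
    augmented prototype set {v_1..v_k, −v_1..−v_k} so that correlated
    and anti-correlated profiles receive comparable, jointly normalized
    scores. Columns are ``pos_<c>`` and ``neg_<c>``; rows sum to 1.

    ``m`` overrides the fuzzifier used for scoring (default: the
    model's own). Scoring external profiles usually wants a softer
    fuzzifier than the one the clustering was fit with: at crisp m the
    membership of *any* profile — including pure noise — concentrates
    on its nearest prototype, and an absolute membership threshold
    loses its meaning.
    """
    df = pd.DataFrame(profiles_scaled)
    x = df.to_numpy(float)
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError("profile length does not match centroid length")
    protos = model.centroids
    cols = [f"pos_{c}" for c in range(model.k)]
    if include_negatives:
        protos = np.vstack([protos, -protos])
        cols = cols + [f"neg_{c}" for c in range(model.k)]
    u = _fcm_memberships(x, protos, model.m if m is None else m)
    return pd.DataFrame(u, index=df.index, columns=cols)
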