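"""Expression normalization, sample correlation, PCA grouping, pseudotime.

cpm is plain counts-per-million (no between-library scaling factors).
The most variable features are those above an empirical
coefficient-of-variation quantile (3rd quartile by default). Samples
from the two reprogramming systems are projected jointly by PCA on
scaled profiles; k-means (k = 4) on the leading components separates
{starting cells, early, late, pluripotent} stages, and the projection
onto the first component — sign-oriented so a designated starting
sample is minimal — serves as a reprogramming pseudotime. Heatmap
ordering uses Ward/Euclidean hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from splicedyn.core_io import ExprTable


def cpm(counts: ExprTable) -> ExprTable:
    """Counts per million: value · 1e6 / column sum."""
    if counts.unit != "counts":
        raise ValueError(f"expected counts, got {counts.unit!r}")
    sums = counts.values.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero-count samples: {bad}")
    vals = counts.values * 1e6 / sums
    return ExprTable(vals, counts.samples, "cpm")


def variable_features(e: ExprTable, cv_quantile: float = 0.75,
                      ) -> tuple[ExprTable, float]:
    """Features whose CV reaches the empirical ``cv_quantile`` of CVs.

    The realized CV threshold is returned; the comparison is inclusive,
    so ties at the threshold are kept.
    """
    if e.values.shape[0] < 4:
        raise ValueError("need at least 4 features")
    v = e.values.to_numpy(float)
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    threshold = float(np.quantile(cv, cv_quantile))
    keep = cv >= threshold
    return ExprTable(e.values.loc[keep], e.samples, e.unit,
                     is_subset=True), threshold


def correlation_matrix(x: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between columns."""
    return x.corr(method="pearson")


@dataclass
class PseudotimeResult:
    coords: pd.DataFrame          # samples × components
    groups: pd.Series             # k-means labels per sample
    pseudotime: pd.Series
    variance_explained: np.ndarray
    dataset_ranks: pd.Series      # pseudotime rank within each dataset


def pca_group_pseudotime(scaled: ExprTable, k: int = 4,
                         start_anchor: str | None = None, seed: int = 0,
                         n_components_kmeans: int = 2,
                         n_init: int = 50) -> PseudotimeResult:
    """PCA on samples, k-means grouping, PC1-projection pseudotime.

    Samples are points in feature space; k-means runs on the first
    ``n_components_kmeans`` components with ``n_init`` seeded restarts.
    Pseudotime is the PC1 coordinate with the sign chosen so that the
    anchor sample (the designated starting cell state) is minimal
    within its dataset.
    """
    features = scaled.values.to_numpy(float).T  # samples × features
    n_samples = features.shape[0]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds n_samples={n_samples}")
    sample_ids = scaled.values.columns
    if start_anchor is None:
        start_anchor = sample_ids[0]
    if start_anchor not in sample_ids:
        raise ValueError(f"anchor {start_anchor!r} not among samples")

    n_comp = min(n_samples, features.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    coords = pca.fit_transform(features)

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords[:, :n_components_kmeans])

    pc1 = coords[:, 0].copy()
    anchor_idx = list(sample_ids).index(start_anchor)
    anchor_ds = scaled.samples.table.loc[start_anchor, "dataset"]
    ds_mask = (scaled.samples.table["dataset"] == anchor_ds).to_numpy()
    if pc1[anchor_idx] > pc1[ds_mask].min():
        pc1 = -pc1
        coords[:, 0] = -coords[:, 0]

    pt = pd.Series(pc1, index=sample_ids, name="pseudotime")
    ranks = pt.groupby(scaled.samples.table["dataset"]).rank() \
        .reindex(sample_ids)
    return PseudotimeResult(
        coords=pd.DataFrame(coords, index=sample_ids,
                            columns=[f"PC{i+1}" for i in range(n_comp)]),
        groups=pd.Series(labels, index=sample_ids, name="group"),
        pseudotime=pt,
        variance_explained=pca.explained_variance_ratio_,
        dataset_ranks=ranks,
    )


def ward_cluster(x: pd.DataFrame | np.ndarray,
                 ) -> tuple[np.ndarray, list[int]]:
    """Ward/Euclidean agglomerative clustering of rows.

    Returns the scipy linkage matrix and the dendrogram leaf order
    (used to order heatmap rows). Deterministic given input order.
    """
    v = pd.DataFrame(x).to_numpy(float)
    link = hierarchy.linkage(v, method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return link, [int(i) for i in leaves]
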