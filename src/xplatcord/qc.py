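"""Sample-level QC: PCA with advisory outlier flags, and the
dose-dependency heatmap matrix with complete-linkage column clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InputError, SampleDesign


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components


def pca_scores(matrix: ExpressionMatrix, k: int = 2) -> PcaResult:
    """Gene-centered SVD of a log2-scale matrix; top-``k`` sample scores.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores deterministic.
    """
    if matrix.kind == "counts":
        raise InputError("PCA expects a log2-scale matrix, not raw counts")
    n_samples = len(matrix.sample_ids)
    if n_samples < 3:
        raise InputError("PCA needs at least 3 samples")
    if k >= n_samples:
        raise InputError(f"k={k} must be smaller than the number of samples ({n_samples})")
    X = matrix.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)  # center each gene
    # samples as observations: SVD of the samples x genes matrix
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    evr = S[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(Vt[:k].T, index=matrix.feature_ids, columns=comp_names),
    )


def flag_outliers(
    pca: PcaResult, design: SampleDesign, mad_factor: float = 5.0
) -> pd.Series:
    """Advisory outlier flags in PCA score space.

    A sample is flagged when its distance to its condition centroid
    exceeds median + ``mad_factor`` x MAD of all within-condition
    distances. Scale-invariant; removal is left to the user.
    """
    for cond in design.conditions:
        design.require_replicates(cond, 2)
    dists = pd.Series(0.0, index=pca.scores.index)
    for cond in design.conditions:
        ids = design.samples(cond)
        pts = pca.scores.loc[ids].to_numpy()
        centroid = pts.mean(axis=0)
        dists[ids] = np.linalg.norm(pts - centroid, axis=1)
    med = float(dists.median())
    mad = float((dists - med).abs().median())
    threshold = med + mad_factor * mad
    return dists > threshold


# ---------------------------------------------------------------------------
# complete-linkage clustering (naive agglomeration, lexicographic ties)


def complete_linkage(
    dist: pd.DataFrame,
) -> tuple[list, list]:
    """Agglomerative complete-linkage clustering of labelled items.

    Returns ``(merges, leaf_order)`` where each merge is
    ``(cluster_a_labels, cluster_b_labels, height)``. Ties in merge
    distance are broken by the lexicographically smallest pair of cluster
    labels, so the dendrogram is reproducible.
    """
    labels = list(dist.index)
    clusters: dict[tuple, list] = {(lab,): [lab] for lab in labels}
    merges = []

    def cluster_dist(ca, cb):
        return max(dist.loc[x, y] for x in clusters[ca] for y in clusters[cb])

    order: dict[tuple, list] = {(lab,): [lab] for lab in labels}
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                d = cluster_dist(ka, kb)
                cand = (d, min(ka[0], kb[0]), max(ka[0], kb[0]), ka, kb)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        d, _, _, ka, kb = best
        first, second = (ka, kb) if ka[0] < kb[0] else (kb, ka)
        merged_key = tuple(sorted(ka + kb))
        merges.append((sorted(clusters[ka]), sorted(clusters[kb]), float(d)))
        new_order = order[first] + order[second]
        members = clusters.pop(ka) + clusters.pop(kb)
        del order[first], order[second]
        clusters[merged_key] = members
        order[merged_key] = new_order
    leaf_order = next(iter(order.values()))
    return merges, leaf_order


def dose_heatmap(
    log2fc_tables: dict[tuple, pd.Series]
) -> tuple[pd.DataFrame, list, list]:
    """Genes x (platform, dose) log2FC matrix with clustered column order.

    ``log2fc_tables`` maps (platform, dose) to a per-gene log2FC Series;
    all Series must share one gene index. Columns are clustered by
    Euclidean distance with complete linkage; ties break on column label.
    Returns (matrix, column_order, merges).
    """
    if not log2fc_tables:
        raise InputError("no log2FC tables supplied")
    keys = list(log2fc_tables)
    index = log2fc_tables[keys[0]].index
    for key in keys[1:]:
        if not log2fc_tables[key].index.equals(index):
            raise InputError(f"gene set mismatch for column {key}")
    matrix = pd.DataFrame(
        {f"{plat}_{dose}": s for (plat, dose), s in log2fc_tables.items()}
    )
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float).T
    diff = X[:, None, :] - X[None, :, :]
    dist = pd.DataFrame(np.sqrt((diff**2).sum(axis=2)), index=cols, columns=cols)
    merges, order = complete_linkage(dist)
    return matrix, order, merges
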