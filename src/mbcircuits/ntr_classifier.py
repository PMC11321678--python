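"""Cohort-level tumor subgrouping from neurotransmitter-receptor expression.

The classifier z-scores each NTR gene across samples, runs K-means over a
range of cluster numbers with silhouette analysis choosing k (ties toward
smaller k for parsimony), nominates one marker gene per cluster by one-way
ANOVA (the BH-significant gene with the highest within-cluster mean), and
predicts new samples by nearest trained centroid (Euclidean on the stored
z-scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortMatrix",
    "ClusterResult",
    "normalize_cohort",
    "cluster_cohort",
    "anova_marker_genes",
    "predict_subgroup",
]


@dataclass
class CohortMatrix:
    """samples x NTR genes, z-scored per gene; normalization params stored."""

    X: pd.DataFrame
    gene_means: pd.Series
    gene_sds: pd.Series
    dropped_genes: list


@dataclass
class ClusterResult:
    labels: pd.Series
    chosen_k: int
    silhouettes: dict  # k -> mean silhouette
    centroids: pd.DataFrame  # clusters x genes (z scale)
    seed: int
    k_fixed: int | None = None


def normalize_cohort(expression: pd.DataFrame, ntr_gene_list) -> CohortMatrix:
    """Restrict to the NTR genes and z-score each across samples.

    Genes missing from the expression table or with zero variance are
    dropped with a warning.
    """
    if expression.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    wanted = list(ntr_gene_list)
    missing = [g for g in wanted if g not in expression.columns]
    if missing:
        warnings.warn(f"{len(missing)} NTR gene(s) missing from expression; dropped", stacklevel=2)
    present = [g for g in wanted if g in expression.columns]
    sub = expression[present]
    sds = sub.std(axis=0, ddof=0)
    flat = list(sds.index[sds == 0])
    if flat:
        warnings.warn(f"{len(flat)} zero-variance gene(s) dropped: {flat[:5]}...", stacklevel=2)
    keep = [g for g in present if g not in set(flat)]
    sub = sub[keep]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    return CohortMatrix(
        X=(sub - mu) / sd, gene_means=mu, gene_sds=sd, dropped_genes=missing + flat
    )


def cluster_cohort(
    cohort: CohortMatrix,
    k_range=range(2, 9),
    k_fixed: int | None = None,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterResult:
    """K-means with silhouette-guided choice of k.

    Mean silhouette (Euclidean) is computed for every k in ``k_range``;
    chosen k is its argmax (ties toward smaller k) unless ``k_fixed``
    overrides.  Deterministic for a fixed seed.
    """
    X = cohort.X.to_numpy()
    n = X.shape[0]
    ks = sorted(set(k_range))
    if k_fixed is not None:
        if k_fixed < 2:
            raise ValueError("k_fixed must be >= 2 (silhouette undefined at 1)")
        if k_fixed > n:
            raise ValueError("k_fixed exceeds sample count")
        ks = sorted(set(ks) | {k_fixed})
    if not ks or max(ks) >= n:
        raise ValueError("max(k_range) must be < n_samples")
    if min(ks) < 2:
        raise ValueError("k must be >= 2")
    sil = {}
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        sil[k] = float(silhouette_score(X, lab, metric="euclidean"))
        fits[k] = (lab, km.cluster_centers_)
    if k_fixed is not None:
        chosen = k_fixed
    else:
        best = max(sil.values())
        chosen = min(k for k, v in sil.items() if v == best)
    lab, cent = fits[chosen]
    return ClusterResult(
        labels=pd.Series(lab, index=cohort.X.index, name="cluster"),
        chosen_k=chosen,
        silhouettes=sil,
        centroids=pd.DataFrame(cent, columns=cohort.X.columns),
        seed=seed,
        k_fixed=k_fixed,
    )


def anova_marker_genes(
    cohort: CohortMatrix,
    labels: pd.Series,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across clusters per gene; nominate per-cluster markers.

    Returns a long (cluster, gene) table with F, p, BH q, within/outside
    means, and ``is_nominated`` flagging, per cluster, the q < q_cut gene
    with the highest within-cluster mean.
    """
    X = cohort.X
    labels = labels.reindex(X.index)
    clusters = sorted(labels.unique())
    for cl in clusters:
        if (labels == cl).sum() < 3:
            raise ValueError(f"cluster {cl!r} has < 3 samples")
    groups_by_cluster = {cl: X[labels == cl] for cl in clusters}
    F, p = stats.f_oneway(*[g.to_numpy() for g in groups_by_cluster.values()], axis=0)
    q = multipletests(p, method="fdr_bh")[1]
    rows = []
    for cl in clusters:
        mean_in = groups_by_cluster[cl].mean(axis=0)
        mean_out = X[labels != cl].mean(axis=0)
        sig = pd.Series(q < q_cut, index=X.columns)
        nominated = mean_in[sig].idxmax() if sig.any() else None
        for j, gene in enumerate(X.columns):
            rows.append(
                (
                    cl,
                    gene,
                    float(F[j]),
                    float(p[j]),
                    float(q[j]),
                    float(mean_in[gene]),
                    float(mean_out[gene]),
                    gene == nominated,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "gene", "F", "p", "q", "mean_in", "mean_out", "is_nominated"],
    )


def predict_subgroup(
    expression_new: pd.DataFrame,
    cohort: CohortMatrix,
    result: ClusterResult,
) -> pd.DataFrame:
    """Nearest-centroid assignment of new samples (Euclidean, z scale).

    New samples must share at least half of the trained genes; prediction
    uses the shared genes only, z-scored with the stored training
    parameters.
    """
    genes = [g for g in cohort.X.columns if g in expression_new.columns]
    if len(genes) == 0:
        raise ValueError("no shared genes between new samples and trained model")
    if len(genes) < 0.5 * len(cohort.X.columns):
        raise ValueError(
            f"only {len(genes)}/{len(cohort.X.columns)} trained genes present; need >= 50%"
        )
    Z = (expression_new[genes] - cohort.gene_means[genes]) / cohort.gene_sds[genes]
    C = result.centroids[genes].to_numpy()
    D = np.linalg.norm(Z.to_numpy()[:, None, :] - C[None, :, :], axis=2)
    lab = D.argmin(axis=1)
    return pd.DataFrame(
        {"cluster": lab, "distance": D[np.arange(len(lab)), lab]},
        index=expression_new.index,
    )
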