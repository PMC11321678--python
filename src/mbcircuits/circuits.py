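"""Marker features, co-accessibility, positive TF regulators, and the
TF -> target / TF -> NTR regulatory network.

A *positive TF regulator* is a TF whose own gene activity score tracks its
motif's accessibility deviation across cell clusters (Pearson r > 0.5,
BH-adjusted p < 0.01, and a motif delta -- max minus min cluster-mean
z-score -- in the top quartile): evidence that the factor actively opens its
binding sites.  Candidate targets of a positive TF are genes whose promoter
(+/-5 kb of the TSS) or distal co-accessible cCREs contain the TF's motif
AND whose gene score passes the exhaustive gene x motif correlation screen.
Restricting targets to neurotransmitter-receptor (NTR) genes yields the
TF -> NTR circuit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motif_activity import MotifPeakMatrix

__all__ = [
    "marker_features",
    "co_accessibility",
    "assemble_ccans",
    "identify_positive_regulators",
    "correlation_screen",
    "screen_pair_count",
    "build_tf_target_network",
    "extract_ntr_circuit",
    "interval_overlap_fraction",
    "annotate_clusters_by_signature",
    "printed_percent",
]


# ---------------------------------------------------------------------------
# marker features
# ---------------------------------------------------------------------------


def marker_features(
    matrix,
    feature_ids,
    cluster_labels,
    fdr_cut: float = 0.01,
    lfc_cut: float = 0.5,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Cluster-vs-rest rank-sum markers.

    For each cluster and feature: two-sided Wilcoxon rank-sum of the
    cluster's cells against all other cells, log2 fold change of means with
    pseudocount 1, BH correction within cluster.  Clusters with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    X = np.asarray(matrix.todense() if hasattr(matrix, "todense") else matrix, dtype=float)
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    frames = []
    for cl in clusters:
        inside = labels == cl
        if inside.sum() < min_cells:
            warnings.warn(f"cluster {cl!r} has < {min_cells} cells; skipped", stacklevel=2)
            continue
        a, b = X[inside], X[~inside]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        lfc = np.log2((a.mean(axis=0) + 1) / (b.mean(axis=0) + 1))
        q = multipletests(res.pvalue, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "feature": list(feature_ids),
                    "cluster": cl,
                    "log2fc": lfc,
                    "p": res.pvalue,
                    "fdr": q,
                    "is_marker": (q <= fdr_cut) & (lfc >= lfc_cut),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# co-accessibility and CCANs
# ---------------------------------------------------------------------------


def co_accessibility(
    peak_matrix,
    embedding: np.ndarray,
    max_dist: int = 250_000,
    cor_cut: float = 0.5,
    k_agg: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Cis peak-pair links by aggregate correlation.

    Cells are pooled into ~n/k_agg pseudo-bulk groups by k-means on the
    embedding (each cell assigned once); Pearson correlation is computed
    between depth-normalized log1p aggregate profiles of same-chromosome
    peak pairs whose midpoints lie within ``max_dist``; pairs with
    correlation >= ``cor_cut`` become links (peak_a < peak_b canonical).
    """
    from sklearn.cluster import KMeans

    if max_dist <= 0:
        raise ValueError(f"max_dist must be positive, got {max_dist}")
    X = peak_matrix.X
    n_cells = X.shape[0]
    if n_cells < k_agg:
        raise ValueError("need at least k_agg cells")
    n_groups = max(2, n_cells // k_agg)
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    grp = km.fit_predict(np.asarray(embedding))
    agg = np.zeros((n_groups, X.shape[1]))
    Xd = np.asarray(X.todense(), dtype=float)
    for g in range(n_groups):
        agg[g] = Xd[grp == g].sum(axis=0)
    depth = agg.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    prof = np.log1p(agg / depth * 1e4)
    peaks = peak_matrix.peaks.reset_index(drop=True)
    mid = ((peaks.start + peaks.end) // 2).to_numpy()
    links = []
    sd = prof.std(axis=0)
    mu = prof.mean(axis=0)
    for chrom in peaks.chrom.unique():
        idx = np.flatnonzero((peaks.chrom == chrom).to_numpy() & (sd > 0))
        if len(idx) < 2:
            continue
        Z = (prof[:, idx] - mu[idx]) / sd[idx]
        R = (Z.T @ Z) / n_groups
        m = mid[idx]
        for a in range(len(idx)):
            b_hi = np.searchsorted(m, m[a] + max_dist, side="right")
            for b in range(a + 1, b_hi):
                if R[a, b] >= cor_cut:
                    links.append(
                        (int(idx[a]), int(idx[b]), float(R[a, b]), int(m[b] - m[a]))
                    )
    return pd.DataFrame(links, columns=["peak_a", "peak_b", "correlation", "distance"])


def assemble_ccans(
    links: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = (-2_000, 2_000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Connected components of the link graph and their gene assignments.

    Returns (ccans, gene_links).  A gene joins a component when one of the
    component's peaks overlaps the gene's promoter (TSS + promoter_window,
    half-open); the component's other members become the gene's distal
    cCREs.
    """
    peaks = peaks.reset_index(drop=True)
    G = nx.Graph()
    G.add_edges_from(zip(links.peak_a, links.peak_b))
    comp_rows, link_rows = [], []
    for cid, comp in enumerate(sorted(nx.connected_components(G), key=sorted)):
        members = sorted(comp)
        comp_rows.append((cid, members, len(members)))
        for row in genes.itertuples():
            p0, p1 = row.tss + promoter_window[0], row.tss + promoter_window[1]
            prom = [
                m
                for m in members
                if peaks.chrom.iloc[m] == row.chrom
                and peaks.start.iloc[m] < p1
                and peaks.end.iloc[m] > p0
            ]
            if prom:
                distal = [m for m in members if m not in prom]
                link_rows.append((row.gene_id, cid, prom, distal))
    ccans = pd.DataFrame(comp_rows, columns=["ccan", "peaks", "n_peaks"])
    gene_links = pd.DataFrame(
        link_rows, columns=["gene_id", "ccan", "promoter_peaks", "distal_peaks"]
    )
    return ccans, gene_links


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------


def _cluster_means(
    frame: pd.DataFrame, labels: np.ndarray, min_cluster_cells: int = 1
) -> pd.DataFrame:
    """Mean of each column within each cluster label (rows = clusters).

    Clusters with fewer than ``min_cluster_cells`` cells are excluded: a
    mean over a handful of cells is single-cell noise, and such clusters act
    as high-leverage points in cluster-level correlations.
    """
    lab = pd.Series(labels, index=frame.index)
    means = frame.groupby(lab).mean()
    sizes = lab.value_counts()
    keep = sizes.index[sizes >= min_cluster_cells]
    return means.loc[sorted(keep)]


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for Pearson r with n observations (t distribution)."""
    r = np.clip(r, -0.9999999, 0.9999999)
    if n <= 2:
        return np.ones_like(r)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def identify_positive_regulators(
    gene_scores: pd.DataFrame,
    deviations_z: pd.DataFrame,
    cluster_labels,
    tf_motif_map: dict,
    r_cut: float = 0.5,
    padj_cut: float = 0.01,
    delta_quantile: float = 0.75,
    per_cell: bool = False,
    min_cluster_cells: int = 5,
) -> pd.DataFrame:
    """Positive-regulator table: one row per TF gene with a mapped motif.

    r is the Pearson correlation of the TF's cluster-mean gene score with
    its motif's cluster-mean deviation z (or single-cell vectors when
    ``per_cell``); positive requires r > r_cut (strict), BH-adjusted p <
    padj_cut, and motif delta (max - min cluster-mean z) at or above the
    ``delta_quantile`` quantile over all tested TFs.
    """
    labels = np.asarray(cluster_labels)
    if len(np.unique(labels)) < 3:
        raise ValueError("need >= 3 clusters")
    gs = (
        gene_scores
        if per_cell
        else _cluster_means(gene_scores, labels, min_cluster_cells)
    )
    zc_full = _cluster_means(deviations_z.T, labels, min_cluster_cells)
    zs = deviations_z.T if per_cell else zc_full
    rows = []
    for tf, motif in tf_motif_map.items():
        if tf not in gs.columns or motif not in zs.columns:
            continue
        x = gs[tf].to_numpy()
        y = zs[motif].to_numpy()
        delta = float(zc_full[motif].max() - zc_full[motif].min())
        if np.std(x) == 0 or np.std(y) == 0 or not np.all(np.isfinite(y)):
            rows.append((tf, motif, np.nan, np.nan, delta, "constant-or-nonfinite"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((tf, motif, r, p, delta, ""))
    out = pd.DataFrame(rows, columns=["tf", "motif_id", "r", "p", "delta", "reason"])
    out["padj"] = np.nan
    ok = out.p.notna()
    if ok.any():
        out.loc[ok, "padj"] = multipletests(out.p[ok], method="fdr_bh")[1]
    delta_cut = float(out.delta.quantile(delta_quantile)) if len(out) else np.inf
    out["positive"] = (
        (out.r > r_cut) & (out.padj < padj_cut) & (out.delta >= delta_cut)
    ).fillna(False)
    out.loc[out.positive, "reason"] = ""
    return out


def screen_pair_count(n_genes: int, n_motifs: int) -> int:
    """Number of (gene, motif) pairs the exhaustive screen enumerates."""
    return int(n_genes) * int(n_motifs)


def correlation_screen(
    gene_scores: pd.DataFrame,
    deviations_z: pd.DataFrame,
    cluster_labels,
    r_cut: float = 0.5,
    padj_cut: float = 0.01,
    min_cluster_cells: int = 5,
) -> pd.DataFrame:
    """Exhaustive gene x motif correlation screen over cluster means.

    Enumerates every (gene, motif) pair -- n_genes * n_motifs rows -- with
    Pearson r over cluster means, two-sided p, global BH adjustment, and a
    kept flag (r > r_cut and padj < padj_cut).  Constant vectors yield NaN
    statistics and are never kept.
    """
    labels = np.asarray(cluster_labels)
    gm = _cluster_means(gene_scores, labels, min_cluster_cells)  # clusters x genes
    zm = _cluster_means(deviations_z.T, labels, min_cluster_cells)  # clusters x motifs
    k = gm.shape[0]
    G = gm.to_numpy()
    Z = zm.to_numpy()
    gsd = G.std(axis=0)
    zsd = Z.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Gz = (G - G.mean(axis=0)) / gsd
        Zz = (Z - Z.mean(axis=0)) / zsd
        R = (Gz.T @ Zz) / k
    genes = list(gm.columns)
    motifs = list(zm.columns)
    r = R.ravel()
    p = np.where(np.isfinite(r), _pearson_p(np.nan_to_num(r), k), np.nan)
    out = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, len(motifs)),
            "motif_id": np.tile(motifs, len(genes)),
            "r": r,
            "p": p,
        }
    )
    out["padj"] = np.nan
    ok = out.p.notna()
    if ok.any():
        out.loc[ok, "padj"] = multipletests(out.p[ok], method="fdr_bh")[1]
    out["kept"] = ((out.r > r_cut) & (out.padj < padj_cut)).fillna(False)
    return out


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def build_tf_target_network(
    regulators: pd.DataFrame,
    screen: pd.DataFrame,
    motif_peak_matrix: MotifPeakMatrix,
    genes: pd.DataFrame,
    gene_links: pd.DataFrame | None = None,
    promoter_flank: int = 5_000,
) -> nx.DiGraph:
    """Directed TF -> target edges with motif-location + correlation evidence.

    Edge TF -> G exists iff TF is a positive regulator AND (a peak within
    TSS(G) +/- promoter_flank carries the TF's motif, or a distal cCRE of G
    carries it) AND the (G, TF-motif) pair passed the correlation screen.
    Every edge stores its evidence labels.
    """
    peaks = motif_peak_matrix.peaks.reset_index(drop=True)
    M = motif_peak_matrix.M
    midx = {m: i for i, m in enumerate(motif_peak_matrix.motif_ids)}
    kept_pairs = {
        (row.gene_id, row.motif_id) for row in screen[screen.kept].itertuples()
    }
    distal_of: dict[str, set] = {}
    if gene_links is not None:
        for row in gene_links.itertuples():
            distal_of.setdefault(row.gene_id, set()).update(row.distal_peaks)
    G = nx.DiGraph()
    pos_regs = regulators[regulators.positive]
    for reg in pos_regs.itertuples():
        if reg.motif_id not in midx:
            warnings.warn(f"TF {reg.tf} has no motif sites; no edges", stacklevel=2)
            continue
        motif_row = M[midx[reg.motif_id]].toarray().ravel() > 0
        for g in genes.itertuples():
            evidence = []
            p0, p1 = g.tss - promoter_flank, g.tss + promoter_flank
            prom_peaks = peaks[
                (peaks.chrom == g.chrom) & (peaks.start < p1) & (peaks.end > p0)
            ]
            if motif_row[prom_peaks.index.to_numpy()].any():
                evidence.append("promoter-motif")
            dis = distal_of.get(g.gene_id, ())
            if any(motif_row[d] for d in dis):
                evidence.append("distal-motif-linked")
            if not evidence:
                continue
            if (g.gene_id, reg.motif_id) not in kept_pairs:
                continue
            evidence.append("correlation")
            G.add_edge(reg.tf, g.gene_id, evidence=tuple(evidence), motif=reg.motif_id)
    return G


def extract_ntr_circuit(graph: nx.DiGraph, ntr_gene_ids) -> nx.DiGraph:
    """Subgraph of edges targeting NTR genes; TFs without NTR targets drop."""
    ntr = set(ntr_gene_ids)
    H = nx.DiGraph()
    for u, v, data in graph.edges(data=True):
        if v in ntr:
            H.add_edge(u, v, **data)
    return H


# ---------------------------------------------------------------------------
# small arithmetic utilities used in reported summaries
# ---------------------------------------------------------------------------


def interval_overlap_fraction(
    query_peaks: pd.DataFrame, reference_intervals: pd.DataFrame
) -> tuple[int, float]:
    """(count, fraction) of query peaks sharing >= 1 bp with any reference
    interval (sorted half-open intervals)."""
    if len(query_peaks) == 0:
        raise ValueError("empty query: overlap fraction undefined")
    n = 0
    for chrom in query_peaks.chrom.unique():
        q = query_peaks[query_peaks.chrom == chrom]
        r = reference_intervals[reference_intervals.chrom == chrom]
        if len(r) == 0:
            continue
        rs = r.start.to_numpy()
        re_ = r.end.to_numpy()
        order = np.argsort(rs)
        rs, re_ = rs[order], re_[order]
        run_max_end = np.maximum.accumulate(re_)
        for row in q.itertuples():
            j = np.searchsorted(rs, row.end, side="left")
            if j > 0 and run_max_end[j - 1] > row.start:
                n += 1
    return n, n / len(query_peaks)


def printed_percent(
    numerator: int, denominator: int, decimals: int, mode: str = "round"
) -> float:
    """Percentage formatted as publications print it.

    mode="round" is half-up rounding at ``decimals``; mode="truncate" floors
    (e.g. 130616/341426 -> 38.25 at two decimals truncated, though it rounds
    to 38.26).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    scale = 10**decimals
    if mode == "truncate":
        return math.floor(pct * scale) / scale
    if mode == "round":
        return math.floor(pct * scale + 0.5) / scale
    raise ValueError(f"unknown mode {mode!r}")


def annotate_clusters_by_signature(
    gene_scores: pd.DataFrame,
    cluster_labels,
    signature_sets: dict,
) -> pd.DataFrame:
    """Assign each cluster the signature with highest mean z-scored score.

    Ties are broken alphabetically with ``tie=True``; clusters with no
    signature gene present get "unassigned".
    """
    labels = np.asarray(cluster_labels)
    sd = gene_scores.std(axis=0).replace(0, np.nan)
    z = (gene_scores - gene_scores.mean(axis=0)) / sd
    rows = []
    for cl in np.unique(labels):
        sub = z[labels == cl]
        scores = {}
        for name, gene_set in signature_sets.items():
            present = [g for g in gene_set if g in z.columns and sd[g] > 0]
            if len(present) < 2:
                continue
            scores[name] = float(sub[present].mean(axis=1).mean())
        if not scores:
            rows.append((cl, "unassigned", np.nan, False))
            continue
        best = max(scores.values())
        winners = sorted(k for k, v in scores.items() if np.isclose(v, best))
        rows.append((cl, winners[0], best, len(winners) > 1))
    return pd.DataFrame(rows, columns=["cluster", "label", "score", "tie"])
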