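"""Tile/peak count matrices, gene activity scores, and LSI clustering.

The tile matrix counts Tn5 insertions (both fragment endpoints) in fixed
500-bp genomic bins; its grand total is exactly twice the summed fragment
counts of the kept cells.  Gene activity scores aggregate tile insertions in
a 100-kb window either side of the TSS with an exponential distance weight
exp(-d / 5 kb) relative to the gene body (weight 1 inside the body) and a
gene-size multiplier: 1/length rescaled linearly onto [1, 5] so that scores
are comparable across genomes.  LSI clustering (TF-IDF, truncated SVD,
k-means) is deliberately single-pass plumbing used to group cells before
cluster-level statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD

from .synthetic_data import GenomeSpec

__all__ = [
    "TileMatrix",
    "PeakMatrix",
    "GeneScoreMatrix",
    "build_tile_matrix",
    "build_peak_matrix",
    "compute_gene_scores",
    "lsi_cluster",
    "merge_intervals",
    "peak_gc",
]


@dataclass
class TileMatrix:
    """cells x tiles insertion counts over genome-wide fixed bins."""

    X: sp.csr_matrix
    barcodes: list
    genome: GenomeSpec

    def tile_interval(self, j: int):
        codes, starts, ends = self.genome.tile_table()
        name = self.genome.chrom_names[codes[j]]
        return (name, int(starts[j]), int(ends[j]))


@dataclass
class PeakMatrix:
    X: sp.csr_matrix
    barcodes: list
    peaks: pd.DataFrame  # chrom, start, end (merged, sorted)


@dataclass
class GeneScoreMatrix:
    X: np.ndarray  # cells x genes, dense
    barcodes: list
    genes: pd.DataFrame
    size_multiplier: np.ndarray  # m_g per gene, in size_scale
    cell_depth: np.ndarray | None = None  # total insertions per cell

    def frame(self, depth_normalize: bool = False, target: float = 1e4) -> pd.DataFrame:
        """Scores as cells x genes frame.

        ``depth_normalize`` rescales each cell by target/total-insertions,
        removing sequencing-depth variation before cross-cluster
        comparisons (raw scores scale with depth; motif deviations do not).
        """
        X = self.X
        if depth_normalize:
            if self.cell_depth is None:
                raise ValueError("cell_depth not recorded; cannot depth-normalize")
            d = np.maximum(self.cell_depth, 1.0)
            X = X * (target / d)[:, None]
        return pd.DataFrame(X, index=self.barcodes, columns=list(self.genes.gene_id))


def _insertion_arrays(fragments: pd.DataFrame, kept: list):
    """(chrom str array, positions, cell index, weight) of both endpoints."""
    keep_set = pd.Index(kept)
    bar = fragments.barcode.astype(str)
    mask = bar.isin(keep_set).to_numpy()
    f = fragments[mask]
    cell = keep_set.get_indexer(bar[mask])
    chrom = f.chrom.astype(str).to_numpy()
    w = f["count"].to_numpy()
    return (
        np.concatenate([chrom, chrom]),
        np.concatenate([f.start.to_numpy(), f.end.to_numpy() - 1]),
        np.concatenate([cell, cell]),
        np.concatenate([w, w]),
    )


def build_tile_matrix(
    fragments: pd.DataFrame,
    genome: GenomeSpec,
    kept_barcodes,
    tile_size: int | None = None,
) -> TileMatrix:
    """Count both insertions of every fragment into fixed genome-wide bins."""
    kept = list(kept_barcodes)
    if not kept:
        raise ValueError("kept_barcodes must be nonempty")
    if tile_size is not None and tile_size != genome.tile_size:
        genome = GenomeSpec(
            chromosomes=genome.chromosomes,
            tile_size=tile_size,
            gc_track={
                c: _retile_gc(genome, c, tile_size) for c in genome.chrom_names
            },
            blacklist=genome.blacklist,
        )
    chrom, pos, cell, w = _insertion_arrays(fragments, kept)
    offsets = genome.tile_offsets
    off = np.array([offsets[c] for c in chrom], dtype=np.int64)
    tile = off + pos // genome.tile_size
    X = sp.coo_matrix(
        (w.astype(np.int64), (cell, tile)),
        shape=(len(kept), genome.total_tiles),
    ).tocsr()
    return TileMatrix(X=X, barcodes=kept, genome=genome)


def _retile_gc(genome: GenomeSpec, chrom: str, tile_size: int) -> np.ndarray:
    # nearest-tile resampling of the GC track onto a different bin width
    old = np.asarray(genome.gc_track[chrom])
    n_new = -(-genome.lengths[chrom] // tile_size)
    centers = (np.arange(n_new) * tile_size + tile_size / 2) // genome.tile_size
    return old[np.clip(centers.astype(int), 0, len(old) - 1)]


def merge_intervals(intervals: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Sort and merge overlapping half-open intervals; returns (merged, n_merged)."""
    iv = intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    n_merged = 0
    for row in iv.itertuples():
        if rows and rows[-1][0] == row.chrom and row.start < rows[-1][2]:
            rows[-1][2] = max(rows[-1][2], row.end)
            n_merged += 1
        else:
            rows.append([row.chrom, row.start, row.end])
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]), n_merged


def build_peak_matrix(
    fragments: pd.DataFrame,
    peaks: pd.DataFrame,
    kept_barcodes,
) -> PeakMatrix:
    """cells x peaks insertion counts (half-open interval membership).

    Overlapping peaks are merged with a warning reporting how many were
    collapsed.
    """
    kept = list(kept_barcodes)
    if not kept:
        raise ValueError("kept_barcodes must be nonempty")
    merged, n_merged = merge_intervals(peaks[["chrom", "start", "end"]])
    if n_merged:
        warnings.warn(f"merged {n_merged} overlapping peak(s)", stacklevel=2)
    merged = merged.reset_index(drop=True)
    n_peaks = len(merged)
    chrom, pos, cell, w = _insertion_arrays(fragments, kept)
    rows_cell, rows_peak, rows_w = [], [], []
    for c in merged.chrom.unique():
        sub = merged[merged.chrom == c]
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        base = sub.index.to_numpy()
        m = chrom == c
        p = pos[m]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, len(ends) - 1)])
        rows_cell.append(cell[m][ok])
        rows_peak.append(base[j[ok]])
        rows_w.append(w[m][ok])
    if rows_cell:
        X = sp.coo_matrix(
            (
                np.concatenate(rows_w).astype(np.int64),
                (np.concatenate(rows_cell), np.concatenate(rows_peak)),
            ),
            shape=(len(kept), n_peaks),
        ).tocsr()
    else:
        X = sp.csr_matrix((len(kept), n_peaks), dtype=np.int64)
    return PeakMatrix(X=X, barcodes=kept, peaks=merged)


def peak_gc(peaks: pd.DataFrame, genome: GenomeSpec) -> np.ndarray:
    """GC fraction per peak from the genome's tile-level GC track."""
    out = np.empty(len(peaks))
    ts = genome.tile_size
    for i, row in enumerate(peaks.itertuples()):
        gc = np.asarray(genome.gc_track[row.chrom])
        lo, hi = row.start // ts, (row.end - 1) // ts + 1
        out[i] = gc[lo:hi].mean()
    return out


def compute_gene_scores(
    tile_matrix: TileMatrix,
    genes: pd.DataFrame,
    window_bp: int = 100_000,
    decay_bp: int = 5_000,
    size_scale: tuple[float, float] = (1.0, 5.0),
) -> GeneScoreMatrix:
    """Distance-weighted, size-corrected accessibility score per gene.

    score(g, c) = m_g * sum over tiles t whose center lies within
    ``window_bp`` of the TSS of  exp(-d(t, g)/decay_bp) * x(t, c), with
    d the bp distance from the tile center to the nearest gene-body
    coordinate (0 inside the body) and m_g = 1/gene-length rescaled linearly
    onto ``size_scale`` over all genes.  Windows are clipped at chromosome
    ends only.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if decay_bp <= 0:
        raise ValueError(f"decay_bp must be positive, got {decay_bp}")
    genome = tile_matrix.genome
    for row in genes.itertuples():
        if not (0 <= row.tss < genome.lengths[row.chrom]):
            raise ValueError(f"TSS of {row.gene_id} outside {row.chrom}")
    codes, starts, ends = genome.tile_table()
    centers = (starts + ends) / 2.0

    lengths = (genes.end - genes.start).to_numpy().astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene length must be positive")
    inv = 1.0 / lengths
    lo, hi = size_scale
    if np.ptp(inv) == 0:
        m_g = np.full(len(genes), (lo + hi) / 2.0)
    else:
        m_g = lo + (hi - lo) * (inv - inv.min()) / np.ptp(inv)

    rows, cols, vals = [], [], []
    offsets = genome.tile_offsets
    ts = genome.tile_size
    for gi, row in enumerate(genes.itertuples()):
        off = offsets[row.chrom]
        n = genome.n_tiles(row.chrom)
        lo_t = max(0, (row.tss - window_bp) // ts)
        hi_t = min(n - 1, (row.tss + window_bp) // ts)
        t = np.arange(lo_t, hi_t + 1)
        c = centers[off + t]
        in_window = (c >= row.tss - window_bp) & (c <= row.tss + window_bp)
        t = t[in_window]
        c = c[in_window]
        d = np.maximum(0.0, np.maximum(row.start - c, c - (row.end - 1)))
        wgt = m_g[gi] * np.exp(-d / decay_bp)
        rows.append(np.full(len(t), gi))
        cols.append(off + t)
        vals.append(wgt)
    W = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(genes), genome.total_tiles),
    ).tocsr()
    X = np.asarray((tile_matrix.X @ W.T).todense())
    return GeneScoreMatrix(
        X=X, barcodes=tile_matrix.barcodes, genes=genes.reset_index(drop=True),
        size_multiplier=m_g,
        cell_depth=np.asarray(tile_matrix.X.sum(axis=1)).ravel().astype(float),
    )


def lsi_cluster(
    tile_matrix: TileMatrix,
    n_dims: int = 30,
    n_clusters: int = 8,
    seed: int = 0,
    n_features: int = 25_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass LSI (TF-IDF + truncated SVD) followed by k-means.

    Returns (labels in 0..n_clusters-1, cells x n_dims embedding);
    deterministic for a fixed seed.  The ``n_features`` most accessible tiles
    are used as LSI features.
    """
    X = tile_matrix.X
    n_cells = X.shape[0]
    if n_cells < n_clusters:
        raise ValueError("need at least n_clusters cells")
    if n_dims >= min(n_cells, X.shape[1]):
        raise ValueError("n_dims must be < min(n_cells, n_tiles)")
    totals = np.asarray(X.sum(axis=0)).ravel()
    order = np.argsort(totals)[::-1]
    feats = np.sort(order[: min(n_features, (totals > 0).sum())])
    Xf = X[:, feats].astype(float)
    depth = np.asarray(Xf.sum(axis=1)).ravel()
    depth[depth == 0] = 1.0
    tf = sp.diags(1.0 / depth) @ Xf
    df = np.asarray((Xf > 0).sum(axis=0)).ravel().astype(float)
    idf = np.log1p(n_cells / np.maximum(df, 1.0))
    mat = tf @ sp.diags(idf)
    mat.data = np.log1p(mat.data * 1e4)
    svd = TruncatedSVD(n_components=n_dims, random_state=seed)
    emb = svd.fit_transform(mat)
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    emb = emb / norms[:, None]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    return labels, emb
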