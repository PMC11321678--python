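"""Motif-in-peak annotation, marker-peak motif enrichment, and per-cell
motif accessibility deviations.

Deviations follow the background-matched framework used throughout
single-cell chromatin work: for motif m and cell c, the expected insertion
count in motif-bearing peaks is f_m * T_c (f_m the motif peak set's share of
all insertions, T_c the cell total), the raw deviation is
(observed - expected) / expected, and the z-score standardizes the raw
deviation against ``n_background`` deviations of matched background peak
sets, where each motif peak is replaced by a peak sampled from its nearest
neighbors in standardized (GC, log1p mean accessibility) space.  Counts are
used as-is (not binarized), which makes the per-motif conservation
sum_c (observed - expected) = 0 exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .matrices import PeakMatrix

__all__ = [
    "MotifPeakMatrix",
    "DeviationMatrix",
    "annotate_motif_peaks",
    "motif_enrichment_in_markers",
    "compute_deviations",
]


@dataclass
class MotifPeakMatrix:
    """motifs x peaks binary membership (1 iff >= 1 bp overlap)."""

    M: sp.csr_matrix
    motif_ids: list
    peaks: pd.DataFrame
    sites: pd.DataFrame  # retained for promoter lookups


@dataclass
class DeviationMatrix:
    raw: pd.DataFrame  # motifs x cells
    z: pd.DataFrame
    dropped_motifs: list
    n_background: int
    seed: int


def annotate_motif_peaks(
    peaks: pd.DataFrame,
    motif_sites: pd.DataFrame,
    motif_catalog: list | None = None,
) -> MotifPeakMatrix:
    """Binary motifs x peaks matrix: entry 1 iff a motif site interval shares
    at least one bp with the peak (half-open intervals; abutment is not
    overlap)."""
    motif_ids = (
        list(motif_catalog)
        if motif_catalog is not None
        else sorted(motif_sites.motif_id.unique())
    )
    unknown = set(motif_sites.motif_id) - set(motif_ids)
    if unknown:
        raise ValueError(f"motif id(s) absent from catalog: {sorted(unknown)}")
    mi = {m: i for i, m in enumerate(motif_ids)}
    peaks = peaks.reset_index(drop=True)
    rows, cols = [], []
    for chrom in peaks.chrom.unique():
        psub = peaks[peaks.chrom == chrom]
        starts = psub.start.to_numpy()
        ends = psub.end.to_numpy()
        base = psub.index.to_numpy()
        ssub = motif_sites[motif_sites.chrom == chrom]
        for site in ssub.itertuples():
            # peaks sorted & non-overlapping: overlap iff start < site.end
            # and end > site.start
            j0 = np.searchsorted(ends, site.start, side="right")
            j1 = np.searchsorted(starts, site.end, side="left")
            for j in range(j0, j1):
                rows.append(mi[site.motif_id])
                cols.append(base[j])
    M = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(motif_ids), len(peaks)),
    ).tocsr()
    M.data = np.minimum(M.data, 1).astype(np.int8)
    return MotifPeakMatrix(M=M, motif_ids=motif_ids, peaks=peaks, sites=motif_sites)


def motif_enrichment_in_markers(
    motif_peak_matrix: MotifPeakMatrix,
    marker_peaks,
    all_peaks=None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each motif in marker peaks.

    ``marker_peaks`` are positional peak indices (a subset of all peaks).
    Returns odds ratio, hypergeometric p and BH-adjusted q per motif.
    """
    n_peaks = motif_peak_matrix.M.shape[1]
    all_idx = np.arange(n_peaks) if all_peaks is None else np.asarray(list(all_peaks))
    marker_idx = np.asarray(list(marker_peaks))
    if len(marker_idx) == 0:
        return pd.DataFrame(
            columns=["motif_id", "n_marker_with", "n_marker", "odds_ratio", "p", "q"]
        )
    if not set(marker_idx).issubset(set(all_idx)):
        raise ValueError("marker_peaks must be a subset of all_peaks")
    M = motif_peak_matrix.M
    has = np.asarray(M[:, all_idx].sum(axis=1)).ravel()  # K per motif
    k = np.asarray(M[:, marker_idx].sum(axis=1)).ravel()
    Ntot = len(all_idx)
    n = len(marker_idx)
    rows = []
    for i, motif in enumerate(motif_peak_matrix.motif_ids):
        K = int(has[i])
        ki = int(k[i])
        p = float(hypergeom.sf(ki - 1, Ntot, K, n))
        a, b = ki, n - ki
        c, d = K - ki, (Ntot - n) - (K - ki)
        p_in = a / n
        p_out = c / (Ntot - n) if Ntot > n else p_in
        if p_in == p_out:  # equal proportions (e.g. motif in every peak)
            odds = 1.0
        elif b * c > 0:
            odds = (a * d) / (b * c)
        else:
            odds = np.inf if a * d > 0 else 0.0
        rows.append((motif, ki, n, odds, p))
    out = pd.DataFrame(rows, columns=["motif_id", "n_marker_with", "n_marker", "odds_ratio", "p"])
    out["q"] = multipletests(out.p, method="fdr_bh")[1] if len(out) else []
    return out


def _set_deviation(idx_counts: sp.csr_matrix, Xt: sp.csr_matrix, totals, grand, T):
    """Raw deviation rows for peak-multiset selections.

    idx_counts: selections x peaks (integer multiplicities); Xt: peaks x
    cells counts; totals: per-peak totals; T: per-cell totals.
    Returns (raw, expected_share f).
    """
    obs = np.asarray((idx_counts @ Xt).todense(), dtype=float)
    f = (idx_counts @ totals) / grand
    expected = np.outer(f, T)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (obs - expected) / expected
    return raw, f


def compute_deviations(
    peak_matrix: PeakMatrix,
    motif_peak_matrix: MotifPeakMatrix,
    peak_gc: np.ndarray,
    n_background: int = 50,
    seed: int = 0,
    n_neighbors: int = 100,
) -> DeviationMatrix:
    """Per-cell motif deviations and background-normalized z-scores.

    Background sets are drawn by replacing every motif peak with one of its
    ``n_neighbors`` nearest peaks in standardized (GC, log1p mean
    accessibility) space (Euclidean, self excluded); ``n_background``
    replicate sets give the normalization mean/sd.  Motifs with zero expected
    counts are dropped with a warning.  Deterministic for a fixed seed.
    """
    X = peak_matrix.X  # cells x peaks
    Xt = X.T.tocsr().astype(np.int64)
    n_cells, n_peaks = X.shape
    T = np.asarray(X.sum(axis=1)).ravel().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    grand = totals.sum()
    M = motif_peak_matrix.M.astype(np.int64)

    raw, f = _set_deviation(M, Xt, totals, grand, T)
    keep = f > 0
    dropped = [m for m, k in zip(motif_peak_matrix.motif_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} motif(s) with zero expected counts: {dropped}",
            stacklevel=2,
        )
    motif_ids = [m for m, k in zip(motif_peak_matrix.motif_ids, keep) if k]
    M = M[keep]
    raw = raw[keep]

    # matched background peaks in (GC, log1p mean accessibility) space
    feats = np.column_stack([np.asarray(peak_gc, dtype=float), np.log1p(totals / n_cells)])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - mu) / sd
    k_nn = min(n_neighbors + 1, n_peaks)
    nn = NearestNeighbors(n_neighbors=k_nn).fit(feats)
    nbr = nn.kneighbors(feats, return_distance=False)
    # drop self wherever present; keep n_neighbors columns
    cleaned = np.empty((n_peaks, k_nn - 1), dtype=np.int64)
    for p in range(n_peaks):
        row = nbr[p][nbr[p] != p][: k_nn - 1]
        if len(row) < k_nn - 1:  # self absent from neighbors
            row = nbr[p][: k_nn - 1]
        cleaned[p] = row

    rng = np.random.default_rng(seed)
    bg_mean = np.zeros_like(raw)
    bg_m2 = np.zeros_like(raw)
    for b in range(n_background):
        choice = cleaned[np.arange(n_peaks), rng.integers(0, cleaned.shape[1], n_peaks)]
        P = sp.coo_matrix(
            (np.ones(n_peaks), (np.arange(n_peaks), choice)),
            shape=(n_peaks, n_peaks),
        ).tocsr()
        raw_b, _ = _set_deviation(M @ P, Xt, totals, grand, T)
        delta = raw_b - bg_mean
        bg_mean += delta / (b + 1)
        bg_m2 += delta * (raw_b - bg_mean)
    bg_sd = np.sqrt(bg_m2 / max(n_background - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - bg_mean) / bg_sd
    cells = peak_matrix.barcodes
    return DeviationMatrix(
        raw=pd.DataFrame(raw, index=motif_ids, columns=cells),
        z=pd.DataFrame(z, index=motif_ids, columns=cells),
        dropped_motifs=dropped,
        n_background=n_background,
        seed=seed,
    )
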