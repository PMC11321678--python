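"""Single-cell copy-number inference from windowed insertion counts.

The genome is tiled into 10-Mb windows shifted by 2 Mb.  Windows dominated by
blacklist intervals or with GC content in the low tail (where composition
bias produces false-positive signals) are dropped.  For each cell and window
the raw log2 fold change compares the window's insertion count with the mean
count over its k=100 GC-nearest windows (self excluded), which cancels most
composition-driven coverage bias; subtracting the per-window mean over
diploid reference cells (the immune-like population) removes what remains.
A window is a candidate amplification when the corrected value exceeds the
threshold (+1 by default) and a candidate deletion below the symmetric
negative threshold; per-cell calls shorter than ``min_consecutive`` adjacent
windows are smoothed to neutral, and clone-level consensus calls ask what
fraction of a clone's cells support the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import GenomeSpec

__all__ = [
    "CnvWindowSet",
    "CnvMatrix",
    "make_cnv_windows",
    "count_window_reads",
    "gc_matched_log2fc",
    "reference_correct_and_call",
    "consensus_calls",
    "window_truth_labels",
    "call_metrics",
]

WIDTH_DEFAULT = 10_000_000
STEP_DEFAULT = 2_000_000


@dataclass
class CnvWindowSet:
    """Sliding windows with GC and blacklist annotation.

    ``windows`` has one row per enumerated window (chrom, start, end, gc,
    blacklist_frac, kept) in genomic order; trailing windows shorter than
    width/2 were already dropped at enumeration.
    """

    windows: pd.DataFrame
    width: int
    step: int

    @property
    def kept(self) -> pd.DataFrame:
        return self.windows[self.windows.kept].reset_index(drop=True)


@dataclass
class CnvMatrix:
    """cells x kept-windows log2 ratios and discrete calls (-1/0/+1)."""

    raw: pd.DataFrame
    corrected: pd.DataFrame
    calls: pd.DataFrame
    windows: CnvWindowSet
    threshold: float


def _overlap_lengths(starts, ends, iv_starts, iv_ends) -> np.ndarray:
    """Total bp of each [start, end) covered by the (possibly overlapping
    after merge) sorted intervals."""
    out = np.zeros(len(starts))
    for s0, e0 in zip(iv_starts, iv_ends):
        out += np.clip(np.minimum(ends, e0) - np.maximum(starts, s0), 0, None)
    return out


def make_cnv_windows(
    genome: GenomeSpec,
    width: int = WIDTH_DEFAULT,
    step: int = STEP_DEFAULT,
    blacklist: pd.DataFrame | None = None,
    min_gc: float | None = None,
    max_blacklist_frac: float = 0.5,
    min_gc_quantile: float = 0.05,
) -> CnvWindowSet:
    """Enumerate sliding windows and flag which survive the filters.

    Trailing windows are truncated at the chromosome end and kept only if at
    least width/2 long (shorter windows would distort the un-normalized
    GC-matched comparison).  ``min_gc`` defaults to the ``min_gc_quantile``
    quantile of window GC, dropping the composition-bias-prone low-GC tail.
    """
    if not (width >= step > 0):
        raise ValueError(f"need width >= step > 0, got width={width} step={step}")
    if blacklist is None:
        blacklist = genome.blacklist
    rows = []
    for chrom, length in genome.chromosomes:
        if length < width // 2:
            raise ValueError(f"chromosome {chrom} shorter than half a window")
        gc = np.asarray(genome.gc_track[chrom])
        ts = genome.tile_size
        for start in range(0, length, step):
            end = min(start + width, length)
            if end - start < width / 2:
                continue
            lo, hi = start // ts, (end - 1) // ts + 1
            # length-weighted tile GC over the window
            t_start = np.arange(lo, hi) * ts
            t_end = np.minimum(t_start + ts, length)
            w_bp = np.minimum(t_end, end) - np.maximum(t_start, start)
            gwin = float(np.average(gc[lo:hi], weights=w_bp))
            bl = blacklist[blacklist.chrom == chrom]
            bl_bp = _overlap_lengths(
                np.array([start]), np.array([end]),
                bl.start.to_numpy(), bl.end.to_numpy(),
            )[0]
            rows.append((chrom, start, end, gwin, bl_bp / (end - start)))
    win = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "blacklist_frac"])
    if min_gc is None:
        min_gc = float(np.quantile(win.gc, min_gc_quantile))
    win["kept"] = (win.blacklist_frac <= max_blacklist_frac) & (win.gc >= min_gc)
    return CnvWindowSet(windows=win, width=width, step=step)


def count_window_reads(
    fragments: pd.DataFrame,
    window_set: CnvWindowSet,
    cells,
) -> pd.DataFrame:
    """cells x kept-windows insertion counts (overlapping windows each count
    shared insertions; the window grid is not a partition)."""
    kept = window_set.kept
    cells = list(cells)
    idx = pd.Index(cells)
    width, step = window_set.width, window_set.step
    counts = np.zeros((len(cells), len(kept)), dtype=np.int64)
    bar = fragments.barcode.astype(str)
    mask = bar.isin(idx).to_numpy()
    f = fragments[mask]
    cell = idx.get_indexer(bar[mask])
    chrom = f.chrom.astype(str).to_numpy()
    pos = np.concatenate([f.start.to_numpy(), f.end.to_numpy() - 1])
    cell2 = np.concatenate([cell, cell])
    chrom2 = np.concatenate([chrom, chrom])
    w2 = np.concatenate([f["count"].to_numpy()] * 2)
    n_shift = width // step + (1 if width % step else 0)
    for c in kept.chrom.unique():
        sub = kept[kept.chrom == c]
        # kept window starts are multiples of step: start//step -> column
        col_lut = np.full(int(sub.start.max()) // step + 1, -1, dtype=np.int64)
        col_lut[sub.start.to_numpy() // step] = sub.index.to_numpy()
        m = chrom2 == c
        p = pos[m]
        ci = cell2[m]
        wt = w2[m]
        j_hi = p // step  # largest candidate window start index
        for s in range(n_shift):
            j = j_hi - s
            ok = (j >= 0) & (j < len(col_lut)) & (p < (j * step) + width)
            if not ok.any():
                continue
            cols = col_lut[j[ok]]
            sel = cols >= 0
            np.add.at(counts, (ci[ok][sel], cols[sel]), wt[ok][sel])
    return pd.DataFrame(counts, index=cells, columns=kept.index)


def gc_matched_log2fc(
    counts: pd.DataFrame,
    window_set: CnvWindowSet,
    k: int = 100,
    pseudocount: float = 1.0,
    background: str = "median",
) -> pd.DataFrame:
    """Raw log2 fold change of each window vs its k GC-nearest windows.

    The background of window w is summarized from the same cell's counts
    over the k kept windows, excluding w itself, with GC content closest to
    w's (ties broken by genomic order).  With k a large share of all
    windows, the background set unavoidably contains copy-altered windows in
    aneuploid cells; their contribution biases a plain average and pulls the
    expected log2 ratio of true events toward zero, so the default summary
    is the contamination-robust *median*; ``background="mean"`` restores
    plain averaging.
    """
    if background not in ("median", "mean"):
        raise ValueError(f"background must be 'median' or 'mean', got {background!r}")
    kept = window_set.kept
    n_win = len(kept)
    if n_win < k + 1:
        raise ValueError(
            f"only {n_win} kept windows but k={k}; lower k (need >= k+1 windows)"
        )
    gc = kept.gc.to_numpy()
    C = counts.to_numpy(dtype=float)
    bg = np.empty_like(C)
    summarize = np.median if background == "median" else np.mean
    for w in range(n_win):
        d = np.abs(gc - gc[w])
        d[w] = np.inf
        order = np.lexsort((np.arange(n_win), d))
        nbr = order[:k]
        bg[:, w] = summarize(C[:, nbr], axis=1)
    raw = np.log2((C + pseudocount) / (bg + pseudocount))
    return pd.DataFrame(raw, index=counts.index, columns=counts.columns)


def _smooth_calls(calls_row: np.ndarray, chrom_codes: np.ndarray, min_consecutive: int):
    if min_consecutive <= 1:
        return calls_row
    out = calls_row.copy()
    n = len(out)
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and out[j + 1] == out[i]
            and chrom_codes[j + 1] == chrom_codes[i]
        ):
            j += 1
        if out[i] != 0 and (j - i + 1) < min_consecutive:
            out[i : j + 1] = 0
        i = j + 1
    return out


def reference_correct_and_call(
    raw: pd.DataFrame,
    reference_cells,
    window_set: CnvWindowSet,
    threshold: float = 1.0,
    min_consecutive: int = 2,
) -> CnvMatrix:
    """Subtract the per-window reference mean and call gains/losses.

    corrected(c, w) = raw(c, w) - mean over reference cells of raw(., w).
    Per cell: call = +1 (gain) iff corrected > threshold, -1 (loss) iff
    corrected < -threshold; runs of identical non-neutral calls shorter than
    ``min_consecutive`` adjacent same-chromosome windows are reset to neutral
    (set min_consecutive=1 for the unsmoothed literal rule).
    """
    reference_cells = [c for c in reference_cells if c in raw.index]
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    ref_mean = raw.loc[reference_cells].mean(axis=0)
    corrected = raw - ref_mean
    calls = np.zeros(corrected.shape, dtype=np.int8)
    calls[corrected.to_numpy() > threshold] = 1
    calls[corrected.to_numpy() < -threshold] = -1
    kept = window_set.kept
    chrom_codes = kept.chrom.astype("category").cat.codes.to_numpy()
    for i in range(calls.shape[0]):
        calls[i] = _smooth_calls(calls[i], chrom_codes, min_consecutive)
    calls = pd.DataFrame(calls, index=raw.index, columns=raw.columns)
    return CnvMatrix(
        raw=raw, corrected=corrected, calls=calls, windows=window_set,
        threshold=threshold,
    )


def consensus_calls(
    cnv: CnvMatrix,
    groups: pd.Series,
    min_cell_frac: float = 0.10,
) -> pd.DataFrame:
    """Clone-level call per window: the majority non-neutral per-cell call,
    provided at least ``min_cell_frac`` of the clone's cells carry it.

    Single-cell window counts put a clean single-copy change right at the
    log2 threshold, so individual cells support a true event only a minority
    of the time while neutral windows essentially never miscall; the
    consensus fraction separates the two regimes.
    """
    out = {}
    for g in groups.unique():
        cells = groups.index[groups == g]
        sub = cnv.calls.loc[cnv.calls.index.intersection(cells)]
        frac_gain = (sub == 1).mean(axis=0)
        frac_loss = (sub == -1).mean(axis=0)
        call = np.zeros(sub.shape[1], dtype=np.int8)
        call[(frac_gain >= min_cell_frac) & (frac_gain > frac_loss)] = 1
        call[(frac_loss >= min_cell_frac) & (frac_loss > frac_gain)] = -1
        out[g] = call
    return pd.DataFrame(out, index=cnv.calls.columns).T


def window_truth_labels(
    window_set: CnvWindowSet, segments, baseline: int = 2
) -> pd.Series:
    """Per kept window: +1/-1 if fully inside a gain/loss segment, 0 if
    disjoint from all segments, NaN if partially overlapping (ambiguous:
    such windows have intermediate expected ratios and are excluded from
    scoring)."""
    kept = window_set.kept
    lab = np.zeros(len(kept))
    for i, row in enumerate(kept.itertuples()):
        for chrom, s, e, cn in segments:
            if row.chrom != chrom:
                continue
            if s <= row.start and row.end <= e:
                lab[i] = 1 if cn > baseline else (-1 if cn < baseline else 0)
            elif row.start < e and s < row.end:
                lab[i] = np.nan
    return pd.Series(lab, index=kept.index)


def call_metrics(
    consensus: pd.DataFrame,
    window_set: CnvWindowSet,
    cnv_segments_by_group: dict,
) -> dict:
    """Pooled window-level precision/recall of consensus calls vs truth.

    Only unambiguous windows count: fully inside a segment (expected event)
    or disjoint from every segment (expected neutral).
    """
    tp = fp = fn = 0
    for g, segs in cnv_segments_by_group.items():
        truth = window_truth_labels(window_set, segs)
        pred = consensus.loc[g]
        ok = ~truth.isna()
        t = truth[ok].to_numpy()
        p = pred[ok.to_numpy()].to_numpy()
        tp += int(((t != 0) & (p == t)).sum())
        fn += int(((t != 0) & (p != t)).sum())
        fp += int(((t == 0) & (p != 0)).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
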