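"""Fragment-file parsing and per-cell quality control.

Cells are kept when they have at least ``min_fragments`` unique nuclear
fragments and a TSS enrichment score of at least ``min_tss`` (both thresholds
inclusive), after which at most ``top_n_by_tss`` cells per sample are retained
ranked by TSS enrichment.  TSS enrichment is computed on the aggregate
meta-profile over all TSSs: the per-bp insertion rate in the +/-50 bp center
window divided by the per-bp rate in the two distal 1,901-2,000 bp flanks plus
a pseudocount (the pseudocount is added to the summed-profile per-bp flank
rate, not to a per-TSS rate, so deep cells are not penalized).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .synthetic_data import GenomeSpec

__all__ = ["FragmentParseError", "read_fragments", "compute_cell_qc", "filter_cells"]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


class FragmentParseError(ValueError):
    """A fragments-file record failed validation; carries the 1-based line."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


def _locate_line(path, bad_df_index: int) -> int:
    """Map a data-row index back to a 1-based file line (comments skipped)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    data_row = -1
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            data_row += 1
            if data_row == bad_df_index:
                return lineno
    return -1


def read_fragments(path, genome: GenomeSpec) -> pd.DataFrame:
    """Read and validate a 5-column fragments TSV (optionally gzipped).

    Records are validated against genome bounds (0 <= start < end <= length,
    known chromosome, integer coordinates, count >= 1); the returned frame
    preserves file order.  Validation failures raise
    :class:`FragmentParseError` naming the offending line.
    """
    # comment handling is line-leading only: '#' also occurs inside
    # sample#barcode identifiers, so pandas' comment= cannot be used
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "barcode": str},
    )
    df = df[~df.chrom.str.startswith("#")].reset_index(drop=True)

    def fail(idx, msg):
        raise FragmentParseError(_locate_line(path, int(idx)), msg)

    for col in ("start", "end", "count"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | (num != np.floor(num.astype(float)))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            fail(i, f"non-integer {col} value {df[col].iloc[i]!r}")
        df[col] = num.astype(np.int64)

    lengths = genome.lengths
    known = df.chrom.isin(lengths)
    if not known.all():
        i = int(np.flatnonzero(~known.to_numpy())[0])
        fail(i, f"unknown chromosome {df.chrom.iloc[i]!r}")
    if (df.start < 0).any():
        fail(np.flatnonzero((df.start < 0).to_numpy())[0], "negative start")
    bad = df.start >= df.end
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        fail(i, f"start {df.start.iloc[i]} >= end {df.end.iloc[i]}")
    maxlen = df.chrom.map(lengths).to_numpy()
    bad = df.end.to_numpy() > maxlen
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        fail(i, f"end {df.end.iloc[i]} beyond chromosome length {maxlen[i]}")
    if (df["count"] < 1).any():
        fail(np.flatnonzero((df["count"] < 1).to_numpy())[0], "count < 1")
    return df


def _insertions(fragments: pd.DataFrame):
    """Insertion positions (start and end-1 of each fragment) with cell codes.

    Each record contributes its two insertions weighted by the record's
    ``count``.  Returns (chrom codes, positions, cell codes, weights,
    barcode categories, chrom categories).
    """
    bar = fragments.barcode
    if not isinstance(bar.dtype, pd.CategoricalDtype):
        bar = bar.astype("category")
    chrom = fragments.chrom
    if not isinstance(chrom.dtype, pd.CategoricalDtype):
        chrom = chrom.astype("category")
    cell = bar.cat.codes.to_numpy()
    ccode = chrom.cat.codes.to_numpy()
    w = fragments["count"].to_numpy()
    pos = np.concatenate([fragments.start.to_numpy(), fragments.end.to_numpy() - 1])
    return (
        np.concatenate([ccode, ccode]),
        pos,
        np.concatenate([cell, cell]),
        np.concatenate([w, w]),
        list(bar.cat.categories),
        list(chrom.cat.categories),
    )


def compute_cell_qc(
    fragments: pd.DataFrame,
    tss_positions: pd.DataFrame,
    center_halfwidth: int = 50,
    flank_range: tuple[int, int] = (1_901, 2_000),
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-cell QC table: barcode, n_unique_fragments, tss_enrichment.

    ``tss_positions`` needs columns chrom and tss (or pos).  Every fragment
    contributes two insertions (start and end-1).  A TSS whose windows
    overlap another's double-counts insertions, matching the aggregate
    meta-profile convention.
    """
    if len(tss_positions) < 1:
        raise ValueError("at least one TSS must be provided")
    tss_positions = tss_positions.rename(columns={"pos": "tss"})
    if len(fragments) == 0:
        return pd.DataFrame(
            columns=["barcode", "n_unique_fragments", "tss_enrichment", "passed"]
        )
    ccode, pos, cell, w, barcodes, chrom_cats = _insertions(fragments)
    n_cells = len(barcodes)
    center = np.zeros(n_cells)
    flank = np.zeros(n_cells)
    f_lo, f_hi = flank_range
    for ci, chrom in enumerate(chrom_cats):
        centers = np.sort(
            tss_positions.loc[tss_positions.chrom == chrom, "tss"].to_numpy()
        )
        if len(centers) == 0:
            continue
        m = ccode == ci
        p, c, wt = pos[m], cell[m], w[m]
        # pairs (insertion, TSS) with |pos - tss| <= halfwidth
        n_c = np.searchsorted(centers, p + center_halfwidth, side="right") - (
            np.searchsorted(centers, p - center_halfwidth, side="left")
        )
        # flank pairs: tss in [pos+f_lo, pos+f_hi] or [pos-f_hi, pos-f_lo]
        n_f = (
            np.searchsorted(centers, p + f_hi, side="right")
            - np.searchsorted(centers, p + f_lo, side="left")
            + np.searchsorted(centers, p - f_lo, side="right")
            - np.searchsorted(centers, p - f_hi, side="left")
        )
        np.add.at(center, c, n_c * wt)
        np.add.at(flank, c, n_f * wt)
    center_bp = 2 * center_halfwidth + 1
    flank_bp = 2 * (f_hi - f_lo + 1)
    enrichment = (center / center_bp) / (flank / flank_bp + pseudocount)
    n_frag = np.zeros(n_cells, dtype=np.int64)
    codes = (
        fragments.barcode.cat.codes.to_numpy()
        if isinstance(fragments.barcode.dtype, pd.CategoricalDtype)
        else fragments.barcode.astype("category").cat.codes.to_numpy()
    )
    np.add.at(n_frag, codes, 1)
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "n_unique_fragments": n_frag,
            "tss_enrichment": enrichment,
        }
    )


def filter_cells(
    qc_table: pd.DataFrame,
    min_fragments: int = 1_000,
    min_tss: float = 4.0,
    top_n_by_tss: int = 12_000,
    sample_of: dict | None = None,
    exclude_barcodes: Iterable[str] | None = None,
) -> list[str]:
    """Kept barcodes: both thresholds inclusive, then per-sample top-N by TSS.

    Ties in the top-N ranking are broken by barcode lexical order.
    ``sample_of`` optionally maps barcode -> sample id (default: one sample);
    ``exclude_barcodes`` is a hook for an external doublet exclusion list.
    """
    if min_fragments < 0 or min_tss < 0 or top_n_by_tss < 0:
        raise ValueError("thresholds must be >= 0")
    qc = qc_table
    mask = (qc.n_unique_fragments >= min_fragments) & (qc.tss_enrichment >= min_tss)
    if exclude_barcodes is not None:
        mask &= ~qc.barcode.isin(set(exclude_barcodes))
    kept = qc[mask].copy()
    kept["sample"] = (
        kept.barcode.map(sample_of) if sample_of is not None else "sample"
    )
    out: list[str] = []
    for _, grp in kept.groupby("sample", sort=True):
        grp = grp.sort_values(
            ["tss_enrichment", "barcode"], ascending=[False, True], kind="mergesort"
        )
        out.extend(grp.barcode.head(top_n_by_tss))
    return sorted(out)
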