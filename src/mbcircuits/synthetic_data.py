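"""Synthetic scATAC-seq data and cohort expression with planted ground truth.

Every downstream stage of the package (QC, tile/gene-score matrices, CNV
inference, motif deviations, regulatory circuits, cohort classification) is
exercised on data produced here, because the patient data the analyses were
designed for are not publicly deposited.  The generator therefore emulates the
*data model* of a multi-sample tumor scATAC-seq experiment:

* a small genome split into fixed-width tiles, each carrying a GC fraction
  produced by a smoothed random walk (so GC-matched neighborhoods are
  nontrivial) plus a blacklist of unmappable-like intervals;
* per-cell Tn5 fragments whose two endpoints are insertion sites, sampled from
  a per-group tile rate law

      rate(tile) = base(tile) * exp(gc_bias * (gc - 0.5))
                   * (copy_number / 2) * program_multiplier

  with a negative-binomial fragment count per cell and a fraction of
  insertions concentrated in +/-50 bp of gene TSSs (so TSS enrichment is a
  meaningful QC statistic);
* clonal arm-scale copy-number segments on tumor groups, with at least one
  diploid CNV-free "reference" group standing in for tumor-infiltrating
  immune cells;
* TF programs: a motif, its TF gene, target genes, and a peak set whose
  accessibility is jointly elevated in the program's group, driving the
  covariation between motif-bearing peaks and target-gene accessibility that
  the circuit-detection stages look for;
* a bulk expression cohort of samples x neurotransmitter-receptor (NTR) genes
  with block-structured subgroup programs, two of which share part of their
  program (the Group3/Group4 analogue).

All randomness flows through a single integer seed; a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "GenomeSpec",
    "TfProgram",
    "TruthSet",
    "generate_genome",
    "place_genes",
    "tile_sampling_rates",
    "simulate_fragments",
    "simulate_cohort",
    "write_fragments",
    "regulatory_scenario",
    "cnv_scenario",
    "RegulatoryScenario",
    "CnvScenario",
]

TILE_SIZE_DEFAULT = 500


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """A toy genome: chromosome sizes, per-tile GC track, blacklist.

    ``chromosomes`` is an ordered tuple of ``(name, length_bp)``;
    ``gc_track[chrom]`` holds one GC fraction in [0, 1] per ``tile_size`` tile
    (``ceil(length / tile_size)`` tiles per chromosome); ``blacklist`` is a
    0-based half-open interval table (chrom, start, end).
    """

    chromosomes: tuple
    tile_size: int
    gc_track: Mapping[str, np.ndarray]
    blacklist: pd.DataFrame

    def __post_init__(self):
        for name, length in self.chromosomes:
            n = self.n_tiles(name)
            gc = np.asarray(self.gc_track[name])
            if gc.shape != (n,):
                raise ValueError(
                    f"gc_track for {name} has {gc.shape[0]} tiles, expected {n}"
                )
            if not np.all(np.isfinite(gc)) or gc.min() < 0 or gc.max() > 1:
                raise ValueError(f"gc_track for {name} must be finite in [0, 1]")
        for row in self.blacklist.itertuples():
            L = self.lengths[row.chrom]
            if not (0 <= row.start < row.end <= L):
                raise ValueError(
                    f"blacklist interval {row.chrom}:{row.start}-{row.end} "
                    f"outside chromosome bounds (length {L})"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_tiles(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.tile_size)

    @property
    def tile_offsets(self) -> dict[str, int]:
        off, cum = {}, 0
        for name, _ in self.chromosomes:
            off[name] = cum
            cum += self.n_tiles(name)
        return off

    @property
    def total_tiles(self) -> int:
        return sum(self.n_tiles(c) for c in self.chrom_names)

    def tile_table(self):
        """Global tile arrays: (chrom_code, start, end) per tile, genome order."""
        codes, starts, ends = [], [], []
        for ci, (name, length) in enumerate(self.chromosomes):
            n = self.n_tiles(name)
            s = np.arange(n, dtype=np.int64) * self.tile_size
            e = np.minimum(s + self.tile_size, length)
            codes.append(np.full(n, ci, dtype=np.int32))
            starts.append(s)
            ends.append(e)
        return (
            np.concatenate(codes),
            np.concatenate(starts),
            np.concatenate(ends),
        )

    def gc_concat(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.gc_track[c]) for c in self.chrom_names])

    def tile_index(self, chrom: str, pos) -> np.ndarray:
        """Global tile index of genomic position(s) on ``chrom``."""
        return self.tile_offsets[chrom] + np.asarray(pos) // self.tile_size


def generate_genome(
    n_chrom: int = 3,
    chrom_length_bp: int = 60_000_000,
    tile_size: int = TILE_SIZE_DEFAULT,
    gc_smoothness: int = 200,
    seed: int = 0,
    blacklist_per_chrom: int = 3,
    blacklist_width: int = 20_000,
) -> GenomeSpec:
    """Deterministically generate a :class:`GenomeSpec`.

    The GC track is a Gaussian random walk smoothed with a boxcar of
    ``gc_smoothness`` tiles, rescaled to mean 0.5 / sd 0.08 and clipped to
    [0.25, 0.75]; ``gc_smoothness`` at or above the tile count yields a
    constant track.
    """
    if n_chrom < 1:
        raise ValueError(f"n_chrom must be >= 1, got {n_chrom}")
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    if chrom_length_bp < 20 * tile_size:
        raise ValueError(
            f"chrom_length_bp must be >= 20 * tile_size ({20 * tile_size}), "
            f"got {chrom_length_bp}"
        )
    if gc_smoothness <= 0:
        raise ValueError(f"gc_smoothness must be positive, got {gc_smoothness}")
    rng = np.random.default_rng(seed)
    chromosomes, gc_track = [], {}
    bl_rows = []
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        chromosomes.append((name, int(chrom_length_bp)))
        n = -(-chrom_length_bp // tile_size)
        if gc_smoothness >= n:
            gc = np.full(n, 0.5)
        else:
            walk = np.cumsum(rng.normal(size=n))
            sm = uniform_filter1d(walk, size=int(gc_smoothness), mode="nearest")
            sd = sm.std()
            if sd == 0:
                gc = np.full(n, 0.5)
            else:
                gc = np.clip(0.5 + 0.08 * (sm - sm.mean()) / sd, 0.25, 0.75)
        gc_track[name] = gc
        if blacklist_per_chrom > 0 and chrom_length_bp > 2 * blacklist_width:
            starts = np.sort(
                rng.integers(0, chrom_length_bp - blacklist_width, blacklist_per_chrom)
            )
            for s in starts:
                bl_rows.append((name, int(s), int(s + blacklist_width)))
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])
    return GenomeSpec(
        chromosomes=tuple(chromosomes),
        tile_size=tile_size,
        gc_track=gc_track,
        blacklist=blacklist,
    )


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------


def place_genes(
    genome: GenomeSpec,
    n_genes: int,
    seed: int = 0,
    min_len: int = 2_000,
    max_len: int = 20_000,
    margin: int = 1_000_000,
) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping genes round-robin across chromosomes.

    Returns a gene-model table with columns gene_id, chrom, strand, start,
    end, tss, is_ntr, is_tf, motif_id.  The TSS coincides with the body start
    (+ strand) or body end - 1 (- strand).  Role flags default to False/None
    and are assigned by scenario builders.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    per_chrom = [n_genes // len(chroms)] * len(chroms)
    for i in range(n_genes % len(chroms)):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        L = genome.lengths[chrom]
        usable = L - 2 * margin
        if usable <= 0 or n_here == 0:
            continue
        spacing = usable / max(n_here, 1)
        for j in range(n_here):
            center = margin + (j + 0.5) * spacing
            center += rng.uniform(-0.2, 0.2) * spacing
            length = int(rng.integers(min_len, max_len + 1))
            start = int(max(margin, center - length / 2))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            rows.append((f"G{gid:04d}", chrom, strand, start, end, tss))
            gid += 1
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss"]
    )
    genes["is_ntr"] = False
    genes["is_tf"] = False
    genes["motif_id"] = None
    return genes


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TfProgram:
    """A planted accessibility program.

    When ``motif_id``/``tf_gene`` are set this is a TF regulon: the motif's
    sites live in ``peaks`` and the group's cells have ``effect``-fold
    elevated sampling rates on those peaks and on the tf/target gene bodies.
    With ``motif_id=None`` it is a plain group-identity accessibility profile
    (used e.g. for the immune-like reference population).
    """

    motif_id: str | None
    tf_gene: str | None
    targets: tuple
    peaks: tuple
    effect: float


@dataclass
class TruthSet:
    """Planted ground truth for parameter-recovery tests."""

    cells: pd.DataFrame  # barcode, group, is_reference
    cnv_segments: dict  # group -> tuple of (chrom, start, end, copy_number)
    tf_programs: dict  # group -> tuple of TfProgram
    seed: int

    def reference_barcodes(self) -> list[str]:
        return list(self.cells.loc[self.cells.is_reference, "barcode"])

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "cells": self.cells.to_dict(orient="list"),
            "cnv_segments": {
                g: [list(s) for s in segs] for g, segs in self.cnv_segments.items()
            },
            "tf_programs": {
                g: [dataclasses.asdict(p) for p in progs]
                for g, progs in self.tf_programs.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=lambda o: list(o) if isinstance(o, tuple) else o)


def _peak_tiles(genome: GenomeSpec, peaks: pd.DataFrame, idx=None) -> np.ndarray:
    """Global tile indices covered by the selected peaks (unique, sorted)."""
    if idx is not None:
        peaks = peaks.iloc[list(idx)]
    out = []
    ts = genome.tile_size
    for row in peaks.itertuples():
        off = genome.tile_offsets[row.chrom]
        out.append(np.arange(off + row.start // ts, off + (row.end - 1) // ts + 1))
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(out))


def _gene_body_tiles(genome: GenomeSpec, genes: pd.DataFrame, gene_ids) -> np.ndarray:
    sub = genes[genes.gene_id.isin(list(gene_ids))]
    out = []
    ts = genome.tile_size
    for row in sub.itertuples():
        off = genome.tile_offsets[row.chrom]
        out.append(np.arange(off + row.start // ts, off + (row.end - 1) // ts + 1))
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(out))


def tile_sampling_rates(
    genome: GenomeSpec,
    genes: pd.DataFrame,
    groups_spec: Mapping[str, Mapping],
    cnv_segments: Mapping[str, Sequence] | None = None,
    tf_programs: Mapping[str, Sequence[TfProgram]] | None = None,
    gc_bias_strength: float = 0.0,
    peaks: pd.DataFrame | None = None,
    peak_weight: float = 50.0,
) -> dict[str, np.ndarray]:
    """Per-group expected per-tile sampling rates (unnormalized).

    This is the generator's own rate law; Monte-Carlo tests compare realized
    counts against it.  Reference groups carry no copy-number term.
    """
    cnv_segments = cnv_segments or {}
    tf_programs = tf_programs or {}
    codes, starts, ends = genome.tile_table()
    gc = genome.gc_concat()
    base = np.ones(genome.total_tiles)
    if peaks is not None and len(peaks):
        tiles = _peak_tiles(genome, peaks)
        base[tiles] += peak_weight
    bias = np.exp(gc_bias_strength * (gc - 0.5))
    rates = {}
    for group, spec in groups_spec.items():
        is_ref = bool(spec.get("reference", False))
        rate = base * bias
        segs = cnv_segments.get(group, ())
        if is_ref and len(segs):
            raise ValueError(f"reference group {group!r} may not carry CNV segments")
        for chrom, s, e, cn in segs:
            if chrom not in genome.lengths:
                raise ValueError(f"CNV segment on unknown chromosome {chrom!r}")
            if not (0 <= s < e <= genome.lengths[chrom]):
                raise ValueError(
                    f"CNV segment {chrom}:{s}-{e} outside genome bounds"
                )
            off = genome.tile_offsets[chrom]
            lo = off + s // genome.tile_size
            hi = off + (e - 1) // genome.tile_size + 1
            rate[lo:hi] = rate[lo:hi] * (cn / 2.0)
        for prog in tf_programs.get(group, ()):
            tiles = [
                t
                for t in (
                    _peak_tiles(genome, peaks, prog.peaks)
                    if peaks is not None and len(prog.peaks)
                    else np.empty(0, dtype=np.int64),
                    _gene_body_tiles(
                        genome,
                        genes,
                        [g for g in ((prog.tf_gene,) if prog.tf_gene else ()) ]
                        + list(prog.targets),
                    )
                    if len(genes)
                    else np.empty(0, dtype=np.int64),
                )
            ]
            tiles = np.unique(np.concatenate(tiles)) if tiles else np.empty(0, int)
            if len(tiles):
                rate[tiles] = rate[tiles] * prog.effect
        rates[group] = rate
    return rates


def simulate_fragments(
    genome: GenomeSpec,
    genes: pd.DataFrame,
    groups_spec: Mapping[str, Mapping],
    n_cells_per_group: int | Mapping[str, int],
    depth_mean: float = 8_000,
    cnv_segments: Mapping[str, Sequence] | None = None,
    tf_programs: Mapping[str, Sequence[TfProgram]] | None = None,
    gc_bias_strength: float = 0.0,
    seed: int = 0,
    peaks: pd.DataFrame | None = None,
    peak_weight: float = 50.0,
    tss_fraction: float = 0.10,
    depth_dispersion: float = 8.0,
    fragment_len_shape: float = 2.0,
    fragment_len_scale: float = 80.0,
    fragment_len_min: int = 30,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate a fragments table (chrom, start, end, barcode, count) + truth.

    Fragment endpoints are the two Tn5 insertion positions (``start`` and
    ``end - 1``), following the 10x fragments-file convention with the +4/-5
    shift pre-applied.  The first insertion is drawn from the group's tile
    rate law (with a ``tss_fraction`` mixture component landing within
    +/-50 bp of a TSS, gene chosen proportional to its promoter-tile rate);
    the second insertion sits one sampled fragment length downstream, clipped
    at the chromosome end.  Output is sorted by (chrom, start, end).
    """
    if depth_mean <= 0:
        raise ValueError(f"depth_mean must be positive, got {depth_mean}")
    ref_groups = [g for g, s in groups_spec.items() if s.get("reference", False)]
    if not ref_groups:
        raise ValueError("groups_spec must include at least one reference group")
    rates = tile_sampling_rates(
        genome,
        genes,
        groups_spec,
        cnv_segments=cnv_segments,
        tf_programs=tf_programs,
        gc_bias_strength=gc_bias_strength,
        peaks=peaks,
        peak_weight=peak_weight,
    )
    rng = np.random.default_rng(seed)
    codes, tile_starts, tile_ends = genome.tile_table()
    tile_len = tile_ends - tile_starts
    chrom_len_by_code = np.array([L for _, L in genome.chromosomes], dtype=np.int64)
    use_tss = len(genes) > 0 and tss_fraction > 0

    all_chrom, all_start, all_end, all_cell = [], [], [], []
    cell_rows = []
    cell_counter = 0
    for group, spec in groups_spec.items():
        n_cells = (
            n_cells_per_group[group]
            if isinstance(n_cells_per_group, Mapping)
            else int(n_cells_per_group)
        )
        is_ref = bool(spec.get("reference", False))
        p = rates[group] / rates[group].sum()
        cum = np.cumsum(p)
        cum[-1] = 1.0
        r = depth_dispersion
        nfr = rng.negative_binomial(r, r / (r + depth_mean), n_cells)
        nfr = np.maximum(nfr, 1)
        if use_tss:
            n_tss = rng.binomial(nfr, tss_fraction)
        else:
            n_tss = np.zeros(n_cells, dtype=np.int64)
        n_bg = nfr - n_tss

        # background insertions from the tile rate law
        tot_bg = int(n_bg.sum())
        tiles = np.searchsorted(cum, rng.random(tot_bg), side="right")
        pos_bg = tile_starts[tiles] + rng.integers(0, tile_len[tiles])
        code_bg = codes[tiles]
        cell_bg = np.repeat(np.arange(n_cells), n_bg)

        # TSS-concentrated insertions
        if use_tss:
            tss_tile = np.array(
                [genome.tile_index(c, t) for c, t in zip(genes.chrom, genes.tss)]
            )
            gw = p[tss_tile]
            gw = gw / gw.sum()
            gcum = np.cumsum(gw)
            gcum[-1] = 1.0
            tot_tss = int(n_tss.sum())
            gi = np.searchsorted(gcum, rng.random(tot_tss), side="right")
            tss_arr = genes.tss.to_numpy()[gi]
            chrom_codes_genes = np.array(
                [genome.chrom_names.index(c) for c in genes.chrom]
            )[gi]
            pos_tss = tss_arr + rng.integers(-50, 51, tot_tss)
            pos_tss = np.clip(pos_tss, 0, chrom_len_by_code[chrom_codes_genes] - 1)
            cell_tss = np.repeat(np.arange(n_cells), n_tss)
            pos = np.concatenate([pos_bg, pos_tss])
            code = np.concatenate([code_bg, chrom_codes_genes])
            cell = np.concatenate([cell_bg, cell_tss])
        else:
            pos, code, cell = pos_bg, code_bg, cell_bg

        lengths = (
            rng.gamma(fragment_len_shape, fragment_len_scale, len(pos))
            + fragment_len_min
        ).astype(np.int64)
        ins2 = np.minimum(pos + lengths, chrom_len_by_code[code] - 1)
        all_chrom.append(code)
        all_start.append(pos.astype(np.int64))
        all_end.append((ins2 + 1).astype(np.int64))
        all_cell.append(cell + cell_counter)
        for j in range(n_cells):
            cell_rows.append((f"{group}#{j:04d}", group, is_ref))
        cell_counter += n_cells

    code = np.concatenate(all_chrom)
    start = np.concatenate(all_start)
    end = np.concatenate(all_end)
    cell = np.concatenate(all_cell)
    order = np.lexsort((end, start, code))
    cells_df = pd.DataFrame(cell_rows, columns=["barcode", "group", "is_reference"])
    barcodes = cells_df.barcode.to_numpy()
    chrom_names = np.array(genome.chrom_names)
    fragments = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(code[order], categories=list(chrom_names)),
            "start": start[order],
            "end": end[order],
            "barcode": pd.Categorical.from_codes(cell[order], categories=list(barcodes)),
            "count": np.ones(len(order), dtype=np.int32),
        }
    )
    truth = TruthSet(
        cells=cells_df,
        cnv_segments={g: tuple(map(tuple, s)) for g, s in (cnv_segments or {}).items()},
        tf_programs={g: tuple(p) for g, p in (tf_programs or {}).items()},
        seed=seed,
    )
    return fragments, truth


def write_fragments(fragments: pd.DataFrame, path) -> None:
    """Write a 5-column fragments TSV (optionally .gz by extension)."""
    fragments.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _cohort_blocks(n_genes: int, k_groups: int) -> tuple[list, list]:
    """Disjoint marker blocks per group plus a block shared by the last two.

    The last two groups (the Group3/Group4 analogue) get smaller private
    blocks and share one joint block, so that forcing k-1 clusters merges
    exactly that pair.  Returns (private_blocks, shared_block) as index lists.
    """
    b_share = max(2, round(0.128 * n_genes))
    b_small = b_share
    if k_groups > 2:
        b_big = max(2, round(0.213 * n_genes))
        need = (k_groups - 2) * b_big + 2 * b_small + b_share
        if need > n_genes:
            b_big = max(1, (n_genes - 2 * b_small - b_share) // (k_groups - 2))
    else:
        b_big = 0
    sizes = [b_big] * (k_groups - 2) + [b_small, b_small]
    cursor = 0
    private = []
    for s in sizes:
        private.append(list(range(cursor, cursor + s)))
        cursor += s
    shared = list(range(cursor, cursor + b_share))
    cursor += b_share
    if cursor > n_genes:
        raise ValueError(
            f"n_ntr_genes={n_genes} too small for k_groups={k_groups} marker blocks"
        )
    return private, shared


@dataclass
class CohortTruth:
    labels: pd.Series
    marker_blocks: dict  # group -> list of gene names
    shared_block: list  # gene names elevated in the last two groups
    shared_pair: tuple  # the two program-sharing group names


def simulate_cohort(
    n_samples: int = 763,
    n_ntr_genes: int = 94,
    k_groups: int = 4,
    effect_size: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    group_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a bulk cohort (samples x NTR genes) with planted subgroups.

    Each group elevates its private marker block by ``effect_size`` over
    N(0, noise_sd) noise; the last two groups additionally share one elevated
    block, so their mutual distance is smaller than any other pair's and a
    forced (k-1)-clustering merges exactly them.
    """
    if k_groups < 2:
        raise ValueError(f"k_groups must be >= 2, got {k_groups}")
    if n_ntr_genes < k_groups:
        raise ValueError("n_ntr_genes must be >= k_groups")
    if effect_size < 0:
        raise ValueError(f"effect_size must be >= 0, got {effect_size}")
    if group_names is None:
        group_names = (
            ["WNT", "SHH", "Group3", "Group4"]
            if k_groups == 4
            else [f"G{i + 1}" for i in range(k_groups)]
        )
    rng = np.random.default_rng(seed)
    gene_names = [f"NTR{i + 1:03d}" for i in range(n_ntr_genes)]
    sample_names = [f"S{i + 1:04d}" for i in range(n_samples)]
    private, shared = _cohort_blocks(n_ntr_genes, k_groups)
    assign = rng.permuted(np.arange(n_samples) % k_groups)
    X = rng.normal(0.0, noise_sd, (n_samples, n_ntr_genes))
    for g in range(k_groups):
        rows = assign == g
        X[np.ix_(rows, private[g])] += effect_size
        if g >= k_groups - 2:
            X[np.ix_(rows, shared)] += effect_size
    expr = pd.DataFrame(X, index=sample_names, columns=gene_names)
    labels = pd.Series(
        [group_names[a] for a in assign], index=sample_names, name="group"
    )
    truth = CohortTruth(
        labels=labels,
        marker_blocks={
            group_names[g]: [gene_names[i] for i in private[g]] for g in range(k_groups)
        },
        shared_block=[gene_names[i] for i in shared],
        shared_pair=(group_names[-2], group_names[-1]),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# scenario builders (the study conditions of the synthetic analyses)
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryScenario:
    genome: GenomeSpec
    genes: pd.DataFrame
    peaks: pd.DataFrame
    motif_sites: pd.DataFrame
    groups_spec: dict
    tf_programs: dict
    fragments: pd.DataFrame
    truth: TruthSet
    planted_tfs: dict  # group -> tf gene_id
    planted_edges: set  # {(tf_gene, target_gene)} over NTR targets


def _random_peak(rng, genome, chrom, lo, hi, width=500):
    s = int(rng.integers(lo, hi - width))
    return (chrom, s, s + width)


def regulatory_scenario(
    seed: int = 0,
    n_reference: int = 200,
    n_per_tumor_group: int = 100,
    depth_mean: float = 8_000,
    n_chrom: int = 2,
    chrom_length_bp: int = 30_000_000,
    n_genes: int = 160,
    n_decoy_tfs: int = 40,
    n_ntr_per_group: int = 2,
    n_extra_targets: int = 3,
    n_background_peaks: int = 800,
    program_distal_per_target: int = 4,
    effect: float = 2.0,
    profile_peaks_per_group: int = 40,
    background_sites_per_motif: int = 30,
    peak_weight: float = 50.0,
) -> RegulatoryScenario:
    """The default regulatory study: 4 tumor groups + an immune-like reference.

    Plants one TF program per tumor group (motif sites in the promoter peaks
    of its 5 targets -- 2 NTR genes + 3 others -- and in per-target distal
    peaks), 40 decoy TFs whose motifs sit only in random distal peaks, and a
    group-identity accessibility profile per group so clustering has broad
    subgroup-specific peaks to work with (as tumor subgroups do).
    """
    rng = np.random.default_rng(seed)
    genome = generate_genome(
        n_chrom=n_chrom, chrom_length_bp=chrom_length_bp, seed=seed
    )
    genes = place_genes(genome, n_genes, seed=seed + 1)
    groups = ["WNT", "SHH", "Group3", "Group4"]
    n_planted = len(groups)

    # role assignment over a seeded shuffle so roles spread across the genome
    order = rng.permutation(n_genes)
    tf_planted_idx = order[:n_planted]
    decoy_tf_idx = order[n_planted : n_planted + n_decoy_tfs]
    ntr_idx = order[
        n_planted + n_decoy_tfs : n_planted + n_decoy_tfs + n_ntr_per_group * n_planted
    ]
    extra_idx = order[
        n_planted
        + n_decoy_tfs
        + n_ntr_per_group * n_planted : n_planted
        + n_decoy_tfs
        + n_ntr_per_group * n_planted
        + n_extra_targets * n_planted
    ]
    genes.loc[genes.index[np.concatenate([tf_planted_idx, decoy_tf_idx])], "is_tf"] = True
    genes.loc[genes.index[ntr_idx], "is_ntr"] = True
    for i in np.concatenate([tf_planted_idx, decoy_tf_idx]):
        genes.loc[genes.index[i], "motif_id"] = "M_" + genes.iloc[i].gene_id

    # peaks: one promoter peak per gene, then program distal, then background
    tss_arr = genes.tss.to_numpy()
    tss_by_chrom = {
        c: np.sort(genes.loc[genes.chrom == c, "tss"].to_numpy())
        for c in genome.chrom_names
    }

    def near_tss(chrom, s, e, flank=5_001):
        t = tss_by_chrom[chrom]
        i = np.searchsorted(t, s - flank)
        j = np.searchsorted(t, e + flank)
        return j > i

    peak_rows = []  # (chrom, start, end, key)
    for row in genes.itertuples():
        peak_rows.append((row.chrom, row.tss - 250, row.tss + 250, f"prom:{row.gene_id}"))

    def overlaps_existing(chrom, s, e):
        for c, s0, e0, _ in peak_rows:
            if c == chrom and s < e0 and s0 < e:
                return True
        return False

    target_map = {}  # group -> list of target gene_ids
    distal_keys = {}  # group -> list of peak keys of program distal peaks
    ntr_list = list(genes.iloc[ntr_idx].gene_id)
    extra_list = list(genes.iloc[extra_idx].gene_id)
    for gi, group in enumerate(groups):
        targets = (
            ntr_list[gi * n_ntr_per_group : (gi + 1) * n_ntr_per_group]
            + extra_list[gi * n_extra_targets : (gi + 1) * n_extra_targets]
        )
        target_map[group] = targets
        distal_keys[group] = []
        for t in targets:
            g = genes[genes.gene_id == t].iloc[0]
            for d in range(program_distal_per_target):
                for _ in range(50):  # rejection sampling
                    off = int(rng.integers(20_000, 150_000)) * (
                        1 if rng.random() < 0.5 else -1
                    )
                    s = int(g.tss + off)
                    e = s + 500
                    if s < 0 or e > genome.lengths[g.chrom]:
                        continue
                    if near_tss(g.chrom, s, e) or overlaps_existing(g.chrom, s, e):
                        continue
                    key = f"distal:{group}:{t}:{d}"
                    peak_rows.append((g.chrom, s, e, key))
                    distal_keys[group].append(key)
                    break

    bg_keys = []
    n_bg_placed = 0
    while n_bg_placed < n_background_peaks:
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        c, s, e = _random_peak(rng, genome, chrom, 100_000, genome.lengths[chrom] - 100_000)
        if near_tss(c, s, e):
            continue
        key = f"bg:{n_bg_placed}"
        peak_rows.append((c, s, e, key))
        bg_keys.append(key)
        n_bg_placed += 1
    # background peaks may rarely overlap each other or distal peaks; drop dups
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "key"])
    peaks = peaks.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    keep = np.ones(len(peaks), dtype=bool)
    last_end = {}
    for i, row in enumerate(peaks.itertuples()):
        if row.chrom in last_end and row.start < last_end[row.chrom]:
            if row.key.startswith("bg:"):
                keep[i] = False
                continue
        last_end[row.chrom] = max(last_end.get(row.chrom, 0), row.end)
    peaks = peaks[keep].reset_index(drop=True)
    key_to_idx = {k: i for i, k in enumerate(peaks.key)}
    bg_keys = [k for k in bg_keys if k in key_to_idx]

    # motif sites.  The background-peak pool is partitioned: the first slice
    # feeds group-identity profiles, the rest hosts motif background sites --
    # otherwise decoy motifs would inherit group structure from profile peaks
    # and stop being exchangeable nulls.
    site_rows = []

    def add_site(motif, peak_key):
        p = peaks.iloc[key_to_idx[peak_key]]
        s = int(rng.integers(p.start, p.end - 10))
        site_rows.append((p.chrom, s, s + 10, motif))

    bg_perm = rng.permutation(len(bg_keys))
    n_profile_pool = profile_peaks_per_group * 5
    profile_pool = [bg_keys[j] for j in bg_perm[:n_profile_pool]]
    site_pool = [bg_keys[j] for j in bg_perm[n_profile_pool:]]
    cursor = 0
    tf_programs: dict[str, list[TfProgram]] = {g: [] for g in groups}
    planted_tfs = {}
    planted_edges = set()
    for gi, group in enumerate(groups):
        tf_gene = genes.iloc[tf_planted_idx[gi]].gene_id
        motif = "M_" + tf_gene
        planted_tfs[group] = tf_gene
        prog_keys = [f"prom:{t}" for t in target_map[group]] + distal_keys[group]
        for k in prog_keys:
            add_site(motif, k)
        for _ in range(background_sites_per_motif):
            add_site(motif, site_pool[cursor % len(site_pool)])
            cursor += 1
        tf_programs[group].append(
            TfProgram(
                motif_id=motif,
                tf_gene=tf_gene,
                targets=tuple(target_map[group]),
                peaks=tuple(key_to_idx[k] for k in prog_keys),
                effect=effect,
            )
        )
        for t in target_map[group]:
            if genes.loc[genes.gene_id == t, "is_ntr"].iloc[0]:
                planted_edges.add((tf_gene, t))
    for i in decoy_tf_idx:
        motif = "M_" + genes.iloc[i].gene_id
        for _ in range(background_sites_per_motif):
            add_site(motif, site_pool[cursor % len(site_pool)])
            cursor += 1

    # group identity profiles (broad subgroup-specific accessibility)
    groups_spec = {"Reference": {"reference": True}}
    for g in groups:
        groups_spec[g] = {}
    all_profile_groups = ["Reference"] + groups
    tf_programs["Reference"] = []
    for pi, g in enumerate(all_profile_groups):
        prof = [
            key_to_idx[profile_pool[pi * profile_peaks_per_group + j]]
            for j in range(profile_peaks_per_group)
        ]
        tf_programs[g].append(
            TfProgram(motif_id=None, tf_gene=None, targets=(), peaks=tuple(prof), effect=effect)
        )

    motif_sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "motif_id"])
    motif_sites = motif_sites.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    n_cells = {"Reference": n_reference}
    for g in groups:
        n_cells[g] = n_per_tumor_group
    fragments, truth = simulate_fragments(
        genome,
        genes,
        groups_spec,
        n_cells,
        depth_mean=depth_mean,
        tf_programs=tf_programs,
        gc_bias_strength=0.5,
        seed=seed + 2,
        peaks=peaks,
        peak_weight=peak_weight,
    )
    return RegulatoryScenario(
        genome=genome,
        genes=genes,
        peaks=peaks[["chrom", "start", "end", "key"]],
        motif_sites=motif_sites,
        groups_spec=groups_spec,
        tf_programs={g: tuple(v) for g, v in tf_programs.items()},
        fragments=fragments,
        truth=truth,
        planted_tfs=planted_tfs,
        planted_edges=planted_edges,
    )


@dataclass
class CnvScenario:
    genome: GenomeSpec
    fragments: pd.DataFrame
    truth: TruthSet
    groups_spec: dict
    cnv_segments: dict


def cnv_scenario(
    seed: int = 0,
    n_reference: int = 200,
    n_per_clone: int = 100,
    n_clones: int = 4,
    depth_mean: float = 8_000,
    n_chrom: int = 6,
    chrom_length_bp: int = 60_000_000,
    gain_cn: int = 4,
    loss_cn: int = 1,
    segment_bp: int = 12_000_000,
    gc_bias_strength: float = 1.0,
) -> CnvScenario:
    """The default CNV study: 4 tumor clones + diploid reference, 600 cells.

    Each clone carries one copy-``gain_cn`` and one copy-``loss_cn`` segment
    of ``segment_bp`` (spanning >= 2 full 10 Mb windows) on clone-specific
    chromosomes, over a GC-biased coverage background.
    """
    genome = generate_genome(
        n_chrom=n_chrom, chrom_length_bp=chrom_length_bp, seed=seed
    )
    genes = place_genes(genome, 0, seed=seed)
    groups_spec: dict = {"Reference": {"reference": True}}
    n_cells = {"Reference": n_reference}
    cnv_segments = {}
    for i in range(n_clones):
        name = f"Clone{i + 1}"
        groups_spec[name] = {}
        n_cells[name] = n_per_clone
        gain_chrom = genome.chrom_names[i % n_chrom]
        loss_chrom = genome.chrom_names[(i + n_chrom // 2) % n_chrom]
        cnv_segments[name] = (
            (gain_chrom, 10_000_000, 10_000_000 + segment_bp, gain_cn),
            (loss_chrom, 36_000_000, 36_000_000 + segment_bp, loss_cn),
        )
    fragments, truth = simulate_fragments(
        genome,
        genes,
        groups_spec,
        n_cells,
        depth_mean=depth_mean,
        cnv_segments=cnv_segments,
        gc_bias_strength=gc_bias_strength,
        seed=seed + 2,
        tss_fraction=0.0,
    )
    return CnvScenario(
        genome=genome,
        fragments=fragments,
        truth=truth,
        groups_spec=groups_spec,
        cnv_segments=cnv_segments,
    )
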