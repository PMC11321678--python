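"""Shared fixtures.

The two heavy session fixtures run the full synthetic studies once each --
the regulatory study (QC through deviations, clustering and gene scores) and
the CNV study (windowed counts through consensus calls) -- so every test
interrogating planted truth reuses the same computed state.
"""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from mbcircuits import cnv, matrices, motif_activity, qc
from mbcircuits.synthetic_data import (
    cnv_scenario,
    generate_genome,
    regulatory_scenario,
    simulate_cohort,
)

SEED = 11


@pytest.fixture(scope="session")
def reg():
    """The regulatory study, computed end to end on planted synthetic data."""
    sc = regulatory_scenario(seed=SEED)
    qc_table = qc.compute_cell_qc(sc.fragments, sc.genes[["chrom", "tss"]])
    kept = qc.filter_cells(qc_table)
    tile = matrices.build_tile_matrix(sc.fragments, sc.genome, kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        peak = matrices.build_peak_matrix(sc.fragments, sc.peaks, kept)
    gscores = matrices.compute_gene_scores(tile, sc.genes)
    labels, embedding = matrices.lsi_cluster(tile, n_clusters=24, seed=SEED)
    mpm = motif_activity.annotate_motif_peaks(peak.peaks, sc.motif_sites)
    gc = matrices.peak_gc(peak.peaks, sc.genome)
    deviations = motif_activity.compute_deviations(peak, mpm, gc, seed=SEED)
    groups = sc.truth.cells.set_index("barcode").group.loc[kept]
    return SimpleNamespace(
        scenario=sc,
        qc_table=qc_table,
        kept=kept,
        tile=tile,
        peak=peak,
        gscores=gscores,
        labels=labels,
        embedding=embedding,
        mpm=mpm,
        peak_gc=gc,
        deviations=deviations,
        groups=groups,
    )


@pytest.fixture(scope="session")
def cnv_run():
    """The CNV study: 600 cells, planted copy-4 and copy-1 clone segments."""
    sc = cnv_scenario(seed=SEED)
    windows = cnv.make_cnv_windows(sc.genome)
    cells = list(sc.truth.cells.barcode)
    counts = cnv.count_window_reads(sc.fragments, windows, cells)
    raw = cnv.gc_matched_log2fc(counts, windows, k=100)
    mat = cnv.reference_correct_and_call(raw, sc.truth.reference_barcodes(), windows)
    groups = pd.Series(
        sc.truth.cells.group.values, index=sc.truth.cells.barcode
    )
    consensus = cnv.consensus_calls(mat, groups)
    return SimpleNamespace(
        scenario=sc,
        windows=windows,
        counts=counts,
        raw=raw,
        mat=mat,
        groups=groups,
        consensus=consensus,
    )


@pytest.fixture(scope="session")
def cohort_run():
    expr, truth = simulate_cohort(seed=SEED)
    return SimpleNamespace(expr=expr, truth=truth)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(n_chrom=1, chrom_length_bp=200_000, seed=0)


def frame_from_records(records):
    """Build a fragments frame from (chrom, start, end, barcode, count)."""
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "barcode", "count"]
    )


@pytest.fixture()
def make_fragments():
    return frame_from_records
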