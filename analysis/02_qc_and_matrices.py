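"""Cell QC, tile/peak matrices, gene activity scores, LSI clustering.

Reads the fragments written by 01_simulate_data.py, keeps cells with >= 1000
unique fragments and TSS enrichment >= 4 (top 12,000 by enrichment per
sample), and writes per-cell QC, cluster labels, the LSI embedding, gene
activity scores and the peak count matrix under results/.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio

from mbcircuits import matrices, qc
from mbcircuits.synthetic_data import regulatory_scenario


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-clusters", type=int, default=24)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # the genome object is re-derived from the recorded seed
    sc = regulatory_scenario(seed=args.seed)
    fragments = qc.read_fragments(args.datadir / "fragments.tsv", sc.genome)
    genes = pd.read_csv(args.datadir / "genes.tsv", sep="\t")
    peaks = pd.read_csv(
        args.datadir / "peaks.bed",
        sep="\t",
        names=["chrom", "start", "end", "key"],
    )

    qc_table = qc.compute_cell_qc(fragments, genes[["chrom", "tss"]])
    kept = qc.filter_cells(qc_table)
    qc_table["passed"] = qc_table.barcode.isin(set(kept))
    qc_table.to_csv(args.outdir / "cell_qc.tsv", sep="\t", index=False)

    tile = matrices.build_tile_matrix(fragments, sc.genome, kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        peak = matrices.build_peak_matrix(fragments, peaks, kept)
    gscores = matrices.compute_gene_scores(tile, genes)
    labels, embedding = matrices.lsi_cluster(
        tile, n_clusters=args.n_clusters, seed=args.seed
    )

    gscores.frame().to_csv(args.outdir / "gene_scores.tsv", sep="\t")
    gscores.frame(depth_normalize=True).to_csv(
        args.outdir / "gene_scores_norm.tsv", sep="\t"
    )
    pd.DataFrame({"barcode": kept, "cluster": labels}).to_csv(
        args.outdir / "clusters.tsv", sep="\t", index=False
    )
    np.save(args.outdir / "embedding.npy", embedding)
    sio.mmwrite(args.outdir / "peak_matrix.mtx", peak.X)
    peak.peaks.to_csv(args.outdir / "peak_matrix_peaks.tsv", sep="\t", index=False)
    pd.Series(kept, name="barcode").to_csv(
        args.outdir / "peak_matrix_barcodes.tsv", sep="\t", index=False
    )
    print(
        f"kept {len(kept)}/{len(qc_table)} cells "
        f"(median TSS enrichment {qc_table.tss_enrichment.median():.1f}); "
        f"tile matrix {tile.X.shape}, {args.n_clusters} LSI clusters"
    )


if __name__ == "__main__":
    main()
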