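"""Motif annotation, per-cell deviations, and marker-peak motif enrichment.

Loads the peak matrix written by 02_qc_and_matrices.py, annotates motif
sites onto peaks, computes chromVAR-style deviations and z-scores against 50
GC/accessibility-matched background sets, reports how well each planted
motif separates its subgroup, and runs the hypergeometric motif enrichment
on each cluster's marker peaks.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from mbcircuits import circuits, matrices, motif_activity
from mbcircuits.matrices import PeakMatrix
from mbcircuits.synthetic_data import regulatory_scenario


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--resdir", type=Path, default=Path("results"))
    ap.add_argument("--n-background", type=int, default=50)
    args = ap.parse_args()

    sc = regulatory_scenario(seed=args.seed)  # genome + planted truth
    X = sp.csr_matrix(sio.mmread(args.resdir / "peak_matrix.mtx"))
    peaks = pd.read_csv(args.resdir / "peak_matrix_peaks.tsv", sep="\t")
    barcodes = list(
        pd.read_csv(args.resdir / "peak_matrix_barcodes.tsv", sep="\t").barcode
    )
    pm = PeakMatrix(X=X, barcodes=barcodes, peaks=peaks)
    sites = pd.read_csv(
        args.datadir / "motif_sites.bed",
        sep="\t",
        names=["chrom", "start", "end", "motif_id"],
    )
    mpm = motif_activity.annotate_motif_peaks(peaks, sites)
    gc = matrices.peak_gc(peaks, sc.genome)
    dev = motif_activity.compute_deviations(
        pm, mpm, gc, n_background=args.n_background, seed=args.seed
    )
    dev.raw.to_csv(args.resdir / "deviations.tsv", sep="\t")
    dev.z.to_csv(args.resdir / "deviations_z.tsv", sep="\t")

    groups = sc.truth.cells.set_index("barcode").group.reindex(barcodes)
    seps = {}
    for group, tf in sc.planted_tfs.items():
        z = dev.z.loc["M_" + tf]
        zin, zout = z[(groups == group).values], z[(groups != group).values]
        seps[group] = (zin.mean() - zout.mean()) / zout.std()
    print(
        "planted motif separation (sd units): "
        + ", ".join(f"{g}={s:.1f}" for g, s in seps.items())
    )

    # motif enrichment in each cluster's marker peaks
    clusters = pd.read_csv(args.resdir / "clusters.tsv", sep="\t")
    labels = clusters.set_index("barcode").cluster.reindex(barcodes).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        markers = circuits.marker_features(
            X, list(range(X.shape[1])), labels, fdr_cut=0.05, lfc_cut=0.25
        )
    rows = []
    for cl, sub in markers[markers.is_marker].groupby("cluster"):
        enr = motif_activity.motif_enrichment_in_markers(mpm, list(sub.feature))
        enr["cluster"] = cl
        rows.append(enr)
    if rows:
        pd.concat(rows).to_csv(
            args.resdir / "motif_enrichment.tsv", sep="\t", index=False
        )
        n_sig = sum((r.q < 0.05).sum() for r in rows)
        print(f"marker-peak enrichment: {n_sig} significant motif-cluster pairs")


if __name__ == "__main__":
    main()
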