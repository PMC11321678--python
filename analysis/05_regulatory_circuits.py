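"""Positive TF regulators, co-accessibility, and the TF -> NTR network.

Combines depth-normalized gene activity scores with motif deviation
z-scores over LSI clusters to nominate positive TF regulators (r > 0.5,
BH padj < 0.01, top-quartile motif delta), runs the exhaustive gene x motif
correlation screen, links distal cCREs to genes through co-accessibility
components, assembles the motif-evidence-gated TF -> target network, and
scores the NTR restriction of that network against the planted circuit.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from mbcircuits import circuits
from mbcircuits.matrices import PeakMatrix
from mbcircuits.motif_activity import annotate_motif_peaks
from mbcircuits.synthetic_data import regulatory_scenario


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--resdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    sc = regulatory_scenario(seed=args.seed)
    genes = pd.read_csv(args.datadir / "genes.tsv", sep="\t")
    gf = pd.read_csv(args.resdir / "gene_scores_norm.tsv", sep="\t", index_col=0)
    dev_z = pd.read_csv(args.resdir / "deviations_z.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(args.resdir / "clusters.tsv", sep="\t")
    labels = clusters.set_index("barcode").cluster.reindex(gf.index).to_numpy()
    emb = np.load(args.resdir / "embedding.npy")
    X = sp.csr_matrix(sio.mmread(args.resdir / "peak_matrix.mtx"))
    peaks = pd.read_csv(args.resdir / "peak_matrix_peaks.tsv", sep="\t")
    pm = PeakMatrix(X=X, barcodes=list(gf.index), peaks=peaks)
    sites = pd.read_csv(
        args.datadir / "motif_sites.bed",
        sep="\t",
        names=["chrom", "start", "end", "motif_id"],
    )
    mpm = annotate_motif_peaks(peaks, sites)

    tf_map = {r.gene_id: r.motif_id for r in genes[genes.is_tf].itertuples()}
    regulators = circuits.identify_positive_regulators(gf, dev_z, labels, tf_map)
    screen = circuits.correlation_screen(gf, dev_z, labels)
    links = circuits.co_accessibility(pm, emb, seed=args.seed)
    ccans, gene_links = circuits.assemble_ccans(links, peaks, genes)
    graph = circuits.build_tf_target_network(
        regulators, screen, mpm, genes, gene_links
    )
    ntr_graph = circuits.extract_ntr_circuit(graph, genes.loc[genes.is_ntr, "gene_id"])

    regulators.to_csv(args.resdir / "regulators.tsv", sep="\t", index=False)
    links.to_csv(args.resdir / "coaccess_links.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [(u, v, ";".join(d["evidence"])) for u, v, d in ntr_graph.edges(data=True)],
        columns=["tf", "target", "evidence"],
    )
    edges.to_csv(args.resdir / "ntr_network.tsv", sep="\t", index=False)

    planted = set(sc.planted_tfs.values())
    positive = set(regulators[regulators.positive].tf)
    got = set(ntr_graph.edges())
    tp = len(got & sc.planted_edges)
    summary = {
        "positive_tf_recovered": len(positive & planted),
        "decoy_tf_false_positives": len(positive - planted),
        "n_coaccess_links": len(links),
        "n_ccans": len(ccans),
        "n_gene_links": len(gene_links),
        "ntr_edge_recall": tp / len(sc.planted_edges),
        "ntr_edge_precision": tp / len(got) if got else 0.0,
    }
    with open(args.resdir / "circuit_metrics.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(
        f"positive TFs {summary['positive_tf_recovered']}/4 planted, "
        f"{summary['decoy_tf_false_positives']} decoy false positives; "
        f"{len(links)} co-accessibility links in {len(ccans)} CCANs; "
        f"TF->NTR edges recall={summary['ntr_edge_recall']:.2f} "
        f"precision={summary['ntr_edge_precision']:.2f}"
    )


if __name__ == "__main__":
    main()
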