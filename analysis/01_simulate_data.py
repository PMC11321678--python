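"""Simulate the regulatory study's raw data with planted ground truth.

Writes a 10x-style fragments file, peak/motif-site/gene annotations and the
truth record under results/data/.  Five cell populations are planted: an
immune-like diploid reference and four tumor subgroups, each with its own
broad accessibility profile and one TF program (motif sites in the promoter
and distal peaks of 5 target genes, 2 of them neurotransmitter receptors).
"""

import argparse
import json
from pathlib import Path

from mbcircuits.synthetic_data import regulatory_scenario, write_fragments


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sc = regulatory_scenario(seed=args.seed)
    write_fragments(sc.fragments, args.outdir / "fragments.tsv")
    sc.peaks.to_csv(args.outdir / "peaks.bed", sep="\t", header=False, index=False)
    sc.motif_sites.to_csv(
        args.outdir / "motif_sites.bed", sep="\t", header=False, index=False
    )
    sc.genes.to_csv(args.outdir / "genes.tsv", sep="\t", index=False)
    sc.truth.to_json(args.outdir / "truth.json")
    with open(args.outdir / "planted.json", "w") as fh:
        json.dump(
            {
                "seed": args.seed,
                "planted_tfs": sc.planted_tfs,
                "planted_ntr_edges": sorted(sc.planted_edges),
            },
            fh,
            indent=1,
        )
    n_cells = len(sc.truth.cells)
    print(
        f"simulated {len(sc.fragments):,} fragments for {n_cells} cells "
        f"({int(sc.truth.cells.is_reference.sum())} reference), "
        f"{len(sc.peaks)} peaks, {sc.motif_sites.motif_id.nunique()} motifs -> {args.outdir}"
    )


if __name__ == "__main__":
    main()
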