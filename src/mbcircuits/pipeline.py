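"""End-to-end orchestration: configuration, stage ordering, provenance.

``run_pipeline`` executes the synthetic regulatory study end to end —
simulate -> qc -> matrices -> {cnv, motifs} -> circuits -> classify — writing
each stage's tables under the run directory and a manifest recording seeds,
shapes and output checksums.  Every stochastic stage receives a sub-seed
derived deterministically from the global seed and the stage name, so reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuits, cnv, matrices, motif_activity, ntr_classifier, qc
from .synthetic_data import regulatory_scenario, simulate_cohort, write_fragments

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]

STAGES = ["simulate", "qc", "matrices", "cnv", "motifs", "circuits", "classify"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # stage parameters (defaults follow the printed values where they exist)
    n_reference: int = 200
    n_per_tumor_group: int = 100
    depth_mean: float = 8_000
    min_fragments: int = 1_000
    min_tss: float = 4.0
    top_n_by_tss: int = 12_000
    tile_size: int = 500
    gene_window_bp: int = 100_000
    gene_decay_bp: int = 5_000
    n_lsi_dims: int = 30
    n_clusters: int = 24
    cnv_width: int = 10_000_000
    cnv_step: int = 2_000_000
    cnv_k: int = 12  # scaled to the small default genome (needs >= k+1 windows)
    cnv_threshold: float = 1.0
    n_background: int = 50
    coaccess_max_dist: int = 250_000
    coaccess_cor_cut: float = 0.5
    promoter_flank: int = 5_000
    r_cut: float = 0.5
    padj_cut: float = 0.01
    delta_quantile: float = 0.75
    cohort_n_samples: int = 763
    cohort_n_genes: int = 94
    cohort_k_groups: int = 4
    cohort_effect: float = 5.0
    cohort_noise_sd: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw):
    df.to_csv(path, sep="\t", **kw)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run enabled stages in dependency order; returns the manifest dict.

    Stage outputs land in ``config.outdir``; a stage whose upstream output
    is missing raises an error naming the stage to run first.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": asdict(config)}
    enabled = {s: config.stages.get(s, True) for s in STAGES}
    state: dict = {}

    def record(stage, files, **info):
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "outputs": {f.name: _sha256(f) for f in files},
            **info,
        }

    def need(stage, key):
        if key not in state:
            raise RuntimeError(
                f"stage {stage!r} needs output of a disabled/unrun stage; "
                f"run the upstream stage first"
            )
        return state[key]

    if enabled["simulate"]:
        sc = regulatory_scenario(
            seed=stage_seed(config.seed, "simulate"),
            n_reference=config.n_reference,
            n_per_tumor_group=config.n_per_tumor_group,
            depth_mean=config.depth_mean,
        )
        state["scenario"] = sc
        frag_path = out / "fragments.tsv"
        write_fragments(sc.fragments, frag_path)
        peaks_path = _write(sc.peaks, out / "peaks.bed", index=False, header=False)
        genes_path = _write(sc.genes, out / "genes.tsv", index=False)
        sites_path = _write(sc.motif_sites, out / "motif_sites.bed", index=False, header=False)
        sc.truth.to_json(out / "truth.json")
        record(
            "simulate",
            [frag_path, peaks_path, genes_path, sites_path, out / "truth.json"],
            n_cells=len(sc.truth.cells),
            n_fragments=len(sc.fragments),
        )

    if enabled["qc"]:
        sc = need("qc", "scenario")
        tss = sc.genes[["chrom", "tss"]]
        qc_table = qc.compute_cell_qc(sc.fragments, tss)
        kept = qc.filter_cells(
            qc_table,
            min_fragments=config.min_fragments,
            min_tss=config.min_tss,
            top_n_by_tss=config.top_n_by_tss,
        )
        qc_table["passed"] = qc_table.barcode.isin(set(kept))
        state["kept"] = kept
        p = _write(qc_table, out / "cell_qc.tsv", index=False)
        record("qc", [p], n_cells_in=len(qc_table), n_cells_kept=len(kept))

    if enabled["matrices"]:
        sc = need("matrices", "scenario")
        kept = need("matrices", "kept")
        tm = matrices.build_tile_matrix(sc.fragments, sc.genome, kept)
        pm = matrices.build_peak_matrix(sc.fragments, sc.peaks, kept)
        gs = matrices.compute_gene_scores(
            tm, sc.genes, window_bp=config.gene_window_bp, decay_bp=config.gene_decay_bp
        )
        labels, emb = matrices.lsi_cluster(
            tm,
            n_dims=config.n_lsi_dims,
            n_clusters=config.n_clusters,
            seed=stage_seed(config.seed, "matrices"),
        )
        state.update(tile=tm, peak=pm, gscores=gs, labels=labels, embedding=emb)
        gs_path = _write(gs.frame(), out / "gene_scores.tsv")
        lab_path = _write(
            pd.DataFrame({"barcode": kept, "cluster": labels}),
            out / "clusters.tsv",
            index=False,
        )
        record(
            "matrices",
            [gs_path, lab_path],
            tile_shape=list(tm.X.shape),
            peak_shape=list(pm.X.shape),
        )

    if enabled["cnv"]:
        sc = need("cnv", "scenario")
        kept = need("cnv", "kept")
        ws = cnv.make_cnv_windows(sc.genome, width=config.cnv_width, step=config.cnv_step)
        counts = cnv.count_window_reads(sc.fragments, ws, kept)
        raw = cnv.gc_matched_log2fc(counts, ws, k=config.cnv_k)
        ref = [b for b in sc.truth.reference_barcodes() if b in raw.index]
        mat = cnv.reference_correct_and_call(raw, ref, ws, threshold=config.cnv_threshold)
        p = _write(mat.corrected, out / "cnv_matrix.tsv")
        w = _write(ws.kept, out / "cnv_windows.bed", index=False, header=False)
        record("cnv", [p, w], n_windows=int(ws.kept.shape[0]))

    if enabled["motifs"]:
        sc = need("motifs", "scenario")
        pm = need("motifs", "peak")
        mpm = motif_activity.annotate_motif_peaks(pm.peaks, sc.motif_sites)
        gc = matrices.peak_gc(pm.peaks, sc.genome)
        dev = motif_activity.compute_deviations(
            pm,
            mpm,
            gc,
            n_background=config.n_background,
            seed=stage_seed(config.seed, "motifs"),
        )
        state.update(mpm=mpm, deviations=dev)
        p1 = _write(dev.raw, out / "deviations.tsv")
        p2 = _write(dev.z, out / "deviations_z.tsv")
        record("motifs", [p1, p2], n_motifs=dev.z.shape[0])

    if enabled["circuits"]:
        sc = need("circuits", "scenario")
        gs = need("circuits", "gscores")
        dev = need("circuits", "deviations")
        mpm = need("circuits", "mpm")
        pm = need("circuits", "peak")
        labels = need("circuits", "labels")
        emb = need("circuits", "embedding")
        links = circuits.co_accessibility(
            pm,
            emb,
            max_dist=config.coaccess_max_dist,
            cor_cut=config.coaccess_cor_cut,
            seed=stage_seed(config.seed, "circuits"),
        )
        _, gene_links = circuits.assemble_ccans(links, pm.peaks, sc.genes)
        tf_map = {
            row.gene_id: row.motif_id
            for row in sc.genes[sc.genes.is_tf].itertuples()
        }
        regs = circuits.identify_positive_regulators(
            gs.frame(depth_normalize=True),
            dev.z,
            labels,
            tf_map,
            r_cut=config.r_cut,
            padj_cut=config.padj_cut,
            delta_quantile=config.delta_quantile,
        )
        screen = circuits.correlation_screen(
            gs.frame(depth_normalize=True), dev.z, labels, r_cut=config.r_cut, padj_cut=config.padj_cut
        )
        graph = circuits.build_tf_target_network(
            regs, screen, mpm, sc.genes, gene_links, promoter_flank=config.promoter_flank
        )
        ntr_graph = circuits.extract_ntr_circuit(
            graph, sc.genes.loc[sc.genes.is_ntr, "gene_id"]
        )
        edges = pd.DataFrame(
            [
                (u, v, ";".join(d["evidence"]))
                for u, v, d in ntr_graph.edges(data=True)
            ],
            columns=["tf", "target", "evidence"],
        )
        p1 = _write(regs, out / "regulators.tsv", index=False)
        p2 = _write(edges, out / "ntr_network.tsv", index=False)
        p3 = _write(links, out / "links.bedpe", index=False, header=False)
        record(
            "circuits",
            [p1, p2, p3],
            n_positive=int(regs.positive.sum()),
            n_ntr_edges=len(edges),
        )

    if enabled["classify"]:
        expr, truth = simulate_cohort(
            n_samples=config.cohort_n_samples,
            n_ntr_genes=config.cohort_n_genes,
            k_groups=config.cohort_k_groups,
            effect_size=config.cohort_effect,
            noise_sd=config.cohort_noise_sd,
            seed=stage_seed(config.seed, "classify"),
        )
        cohort = ntr_classifier.normalize_cohort(expr, list(expr.columns))
        res = ntr_classifier.cluster_cohort(
            cohort, seed=stage_seed(config.seed, "classify")
        )
        markers = ntr_classifier.anova_marker_genes(cohort, res.labels)
        p1 = _write(res.labels.to_frame(), out / "cohort_labels.tsv")
        p2 = _write(
            pd.DataFrame(
                sorted(res.silhouettes.items()), columns=["k", "mean_silhouette"]
            ),
            out / "silhouette.tsv",
            index=False,
        )
        p3 = _write(markers[markers.is_nominated], out / "cohort_markers.tsv", index=False)
        p4 = _write(res.centroids, out / "centroids.tsv")
        record("classify", [p1, p2, p3, p4], chosen_k=res.chosen_k)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
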