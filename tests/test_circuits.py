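"""Markers, co-accessibility, regulators, the screen, and the network."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mbcircuits import circuits
from mbcircuits.matrices import PeakMatrix
from mbcircuits.motif_activity import annotate_motif_peaks


class TestMarkerFeatures:
    def test_planted_exclusive_feature_is_a_marker(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2, (60, 5)).astype(float)
        labels = np.repeat([0, 1], 30)
        X[labels == 1, 2] += 20  # feature 2 exclusive to cluster 1
        out = circuits.marker_features(X, [f"f{i}" for i in range(5)], labels)
        hit = out[(out.cluster == 1) & (out.feature == "f2")]
        assert hit.is_marker.all()
        assert not out[(out.cluster == 0) & out.is_marker].feature.eq("f2").any()

    def test_identical_distributions_yield_no_markers(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3, (80, 40)).astype(float)
        labels = np.repeat([0, 1], 40)
        out = circuits.marker_features(X, [f"f{i}" for i in range(40)], labels)
        assert out.is_marker.sum() == 0

    def test_infinite_lfc_cut_empties_the_marker_set(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2, (40, 6)).astype(float)
        X[:20, 0] += 30
        labels = np.repeat([0, 1], 20)
        out = circuits.marker_features(
            X, list("abcdef"), labels, lfc_cut=np.inf
        )
        assert out.is_marker.sum() == 0

    def test_tiny_cluster_skipped_with_warning(self):
        X = np.ones((10, 3))
        labels = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            out = circuits.marker_features(X, list("abc"), labels)
        assert set(out.cluster) == {0}


def correlated_peak_matrix(seed=0):
    """30 pseudo-cells, two planted co-accessible peak groups on chr1."""
    rng = np.random.default_rng(seed)
    n = 200
    act1 = rng.gamma(2, 1, n)
    act2 = rng.gamma(2, 1, n)
    base = rng.gamma(2, 1, (n, 6))
    X = np.column_stack(
        [
            rng.poisson(act1 * 20),  # p0 chr1
            rng.poisson(act1 * 25),  # p1 chr1 (near p0)
            rng.poisson(act2 * 20),  # p2 chr1 far from p0/p1
            rng.poisson(act2 * 25),  # p3 chr2: same program, other chrom
            rng.poisson(base[:, 0] * 10),  # p4 chr1 independent
        ]
    )
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr1"],
            "start": [10_000, 60_000, 900_000, 60_000, 100_000],
            "end": [10_500, 60_500, 900_500, 60_500, 100_500],
        }
    )
    order = peaks.sort_values(["chrom", "start"]).index
    pm = PeakMatrix(
        X=sp.csr_matrix(X[:, order]),
        barcodes=[f"c{i}" for i in range(n)],
        peaks=peaks.loc[order].reset_index(drop=True),
    )
    emb = np.column_stack([act1, act2])
    return pm, emb


class TestCoAccessibility:
    def test_same_program_nearby_peaks_are_linked(self):
        pm, emb = correlated_peak_matrix()
        links = circuits.co_accessibility(pm, emb, seed=0)
        # peaks at 10k and 60k on chr1 share a driver and are within 250 kb
        pair = {
            int(pm.peaks[(pm.peaks.chrom == "chr1") & (pm.peaks.start == s)].index[0])
            for s in (10_000, 60_000)
        }
        assert any({a, b} == pair for a, b in zip(links.peak_a, links.peak_b))

    def test_cross_chromosome_pairs_never_link(self):
        pm, emb = correlated_peak_matrix()
        links = circuits.co_accessibility(pm, emb, seed=0)
        for a, b in zip(links.peak_a, links.peak_b):
            assert pm.peaks.chrom.iloc[a] == pm.peaks.chrom.iloc[b]

    def test_impossible_cutoff_gives_no_links(self):
        pm, emb = correlated_peak_matrix()
        links = circuits.co_accessibility(pm, emb, cor_cut=1.01, seed=0)
        assert links.empty

    def test_distance_limit_respected(self):
        pm, emb = correlated_peak_matrix()
        links = circuits.co_accessibility(pm, emb, max_dist=250_000, seed=0)
        assert (links.distance <= 250_000).all()
        with pytest.raises(ValueError, match="max_dist"):
            circuits.co_accessibility(pm, emb, max_dist=0, seed=0)


class TestAssembleCcans:
    def genes_df(self, rows):
        df = pd.DataFrame(
            rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss"]
        )
        df["is_ntr"] = False
        return df

    def test_promoter_component_links_gene_to_distal_ccres(self):
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [10_000, 30_000, 50_000, 70_000, 90_000, 300_000],
                "end": [10_500, 30_500, 50_500, 70_500, 90_500, 300_500],
            }
        )
        links = pd.DataFrame(
            {"peak_a": [0, 0, 1, 2], "peak_b": [1, 2, 3, 4], "correlation": 0.9,
             "distance": 1},
        )
        genes = self.genes_df([("G", "chr1", "+", 10_200, 20_000, 10_200)])
        ccans, gene_links = circuits.assemble_ccans(links, peaks, genes)
        assert len(ccans) == 1
        row = gene_links.iloc[0]
        assert row.gene_id == "G"
        assert sorted(row.distal_peaks) == [1, 2, 3, 4]

    def test_component_without_promoter_links_no_gene(self):
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": [500_000, 520_000], "end": [500_500, 520_500]}
        )
        links = pd.DataFrame(
            {"peak_a": [0], "peak_b": [1], "correlation": 0.9, "distance": 1}
        )
        genes = self.genes_df([("G", "chr1", "+", 10_200, 20_000, 10_200)])
        _, gene_links = circuits.assemble_ccans(links, peaks, genes)
        assert gene_links.empty


def planted_cluster_vectors(seed=0, n_clusters=10):
    """Cluster-mean-like gene scores / deviations with one planted TF."""
    rng = np.random.default_rng(seed)
    cells_per = 10
    n = n_clusters * cells_per
    labels = np.repeat(np.arange(n_clusters), cells_per)
    active = labels < 3  # the planted TF's clusters
    gs = pd.DataFrame(
        {
            "TF1": 10 + 5 * active + rng.normal(0, 0.5, n),
            "TF2": 10 + rng.normal(0, 0.5, n),
            "GENE": 10 + 5 * active + rng.normal(0, 0.5, n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    z = pd.DataFrame(
        {
            "M1": 4 * active + rng.normal(0, 0.3, n),
            "M2": rng.normal(0, 0.3, n),
        },
        index=gs.index,
    ).T
    return gs, z, labels


class TestIdentifyPositiveRegulators:
    def test_planted_regulator_found_and_decoy_rejected(self):
        gs, z, labels = planted_cluster_vectors()
        out = circuits.identify_positive_regulators(
            gs, z, labels, {"TF1": "M1", "TF2": "M2"}, delta_quantile=0.5
        )
        assert out.set_index("tf").positive["TF1"]
        assert not out.set_index("tf").positive["TF2"]

    def test_correlation_at_exactly_the_cutoff_is_not_positive(self):
        gs, z, labels = planted_cluster_vectors()
        out = circuits.identify_positive_regulators(
            gs, z, labels, {"TF1": "M1"}, delta_quantile=0.0
        )
        r = out.r.iloc[0]
        strict = circuits.identify_positive_regulators(
            gs, z, labels, {"TF1": "M1"}, r_cut=r, delta_quantile=0.0
        )
        assert not strict.positive.iloc[0]  # r > r_cut is strict

    def test_anticorrelated_pair_is_not_positive(self):
        gs, z, labels = planted_cluster_vectors()
        gs["TF1"] = 20 - gs["TF1"]
        out = circuits.identify_positive_regulators(
            gs, z, labels, {"TF1": "M1"}, delta_quantile=0.0
        )
        assert not out.positive.iloc[0]
        assert out.r.iloc[0] < -0.5

    def test_constant_vector_flagged_not_positive(self):
        gs, z, labels = planted_cluster_vectors()
        gs["TF1"] = 7.0
        out = circuits.identify_positive_regulators(
            gs, z, labels, {"TF1": "M1"}, delta_quantile=0.0
        )
        assert not out.positive.iloc[0]
        assert "constant" in out.reason.iloc[0]

    def test_requires_three_clusters(self):
        gs, z, _ = planted_cluster_vectors()
        labels = np.repeat([0, 1], 50)
        with pytest.raises(ValueError, match="clusters"):
            circuits.identify_positive_regulators(gs, z, labels, {"TF1": "M1"})


class TestCorrelationScreen:
    def test_pair_count_is_the_product(self):
        gs, z, labels = planted_cluster_vectors()
        out = circuits.correlation_screen(gs, z, labels)
        assert len(out) == 3 * 2
        assert circuits.screen_pair_count(3, 4) == 12

    def test_planted_pair_kept(self):
        gs, z, labels = planted_cluster_vectors()
        out = circuits.correlation_screen(gs, z, labels).set_index(
            ["gene_id", "motif_id"]
        )
        assert out.loc[("GENE", "M1")].kept
        assert not out.loc[("GENE", "M2")].kept

    def test_null_data_keeps_almost_nothing(self):
        rng = np.random.default_rng(3)
        n = 300
        labels = np.repeat(np.arange(15), 20)
        gs = pd.DataFrame(
            rng.normal(0, 1, (n, 100)),
            index=[f"c{i}" for i in range(n)],
            columns=[f"g{j}" for j in range(100)],
        )
        z = pd.DataFrame(
            rng.normal(0, 1, (20, n)),
            index=[f"m{j}" for j in range(20)],
            columns=gs.index,
        )
        out = circuits.correlation_screen(gs, z, labels)
        assert out.kept.mean() <= 0.01

    def test_tightening_cutoffs_is_monotone(self):
        gs, z, labels = planted_cluster_vectors()
        loose = circuits.correlation_screen(gs, z, labels, r_cut=0.3, padj_cut=0.05)
        tight = circuits.correlation_screen(gs, z, labels, r_cut=0.6, padj_cut=0.001)
        assert set(map(tuple, tight[tight.kept][["gene_id", "motif_id"]].values)) <= set(
            map(tuple, loose[loose.kept][["gene_id", "motif_id"]].values)
        )


class TestNetwork:
    def build_inputs(self):
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [99_800, 150_000, 200_000],
                "end": [100_300, 150_500, 200_500],
            }
        )
        sites = pd.DataFrame(
            [("chr1", 99_900, 99_910, "M1"), ("chr1", 150_100, 150_110, "M1")],
            columns=["chrom", "start", "end", "motif_id"],
        )
        mpm = annotate_motif_peaks(peaks, sites)
        genes = pd.DataFrame(
            [
                ("TF1", "chr1", "+", 500_000, 510_000, 500_000, False, True, "M1"),
                ("NTR1", "chr1", "+", 100_000, 110_000, 100_000, True, False, None),
                ("OTHER", "chr1", "+", 300_000, 310_000, 300_000, False, False, None),
            ],
            columns=[
                "gene_id", "chrom", "strand", "start", "end", "tss",
                "is_ntr", "is_tf", "motif_id",
            ],
        )
        regulators = pd.DataFrame(
            {
                "tf": ["TF1"],
                "motif_id": ["M1"],
                "r": [0.9],
                "p": [1e-6],
                "padj": [1e-5],
                "delta": [5.0],
                "positive": [True],
                "reason": [""],
            }
        )
        screen = pd.DataFrame(
            {
                "gene_id": ["NTR1", "OTHER"],
                "motif_id": ["M1", "M1"],
                "r": [0.9, 0.9],
                "p": [1e-6, 1e-6],
                "padj": [1e-5, 1e-5],
                "kept": [True, True],
            }
        )
        return regulators, screen, mpm, genes

    def test_edge_requires_motif_location_and_screen(self):
        regulators, screen, mpm, genes = self.build_inputs()
        g = circuits.build_tf_target_network(regulators, screen, mpm, genes)
        # NTR1 has a motif-bearing peak in its promoter window; OTHER does not
        assert ("TF1", "NTR1") in g.edges
        assert ("TF1", "OTHER") not in g.edges
        assert "promoter-motif" in g.edges["TF1", "NTR1"]["evidence"]
        assert "correlation" in g.edges["TF1", "NTR1"]["evidence"]

    def test_failed_screen_blocks_the_edge(self):
        regulators, screen, mpm, genes = self.build_inputs()
        screen.loc[screen.gene_id == "NTR1", "kept"] = False
        g = circuits.build_tf_target_network(regulators, screen, mpm, genes)
        assert ("TF1", "NTR1") not in g.edges

    def test_distal_ccre_evidence(self):
        regulators, screen, mpm, genes = self.build_inputs()
        gene_links = pd.DataFrame(
            {
                "gene_id": ["OTHER"],
                "ccan": [0],
                "promoter_peaks": [[2]],
                "distal_peaks": [[1]],  # peak 1 carries M1
            }
        )
        g = circuits.build_tf_target_network(
            regulators, screen, mpm, genes, gene_links
        )
        assert ("TF1", "OTHER") in g.edges
        assert "distal-motif-linked" in g.edges["TF1", "OTHER"]["evidence"]

    def test_no_positive_regulators_gives_empty_graph(self):
        regulators, screen, mpm, genes = self.build_inputs()
        regulators["positive"] = False
        g = circuits.build_tf_target_network(regulators, screen, mpm, genes)
        assert g.number_of_edges() == 0

    def test_extract_ntr_circuit_filters_targets(self):
        import networkx as nx

        g = nx.DiGraph()
        for t in ["N1", "N2", "X1", "X2", "X3"]:
            g.add_edge("TF", t, evidence=("promoter-motif", "correlation"))
        sub = circuits.extract_ntr_circuit(g, ["N1", "N2"])
        assert set(sub.edges) == {("TF", "N1"), ("TF", "N2")}
        assert circuits.extract_ntr_circuit(g, []).number_of_edges() == 0


class TestOverlapAndPercent:
    def test_identical_sets_fully_overlap(self):
        q = pd.DataFrame({"chrom": "chr1", "start": [10, 100], "end": [20, 200]})
        n, frac = circuits.interval_overlap_fraction(q, q)
        assert (n, frac) == (2, 1.0)

    def test_disjoint_sets_do_not_overlap(self):
        q = pd.DataFrame({"chrom": "chr1", "start": [10], "end": [20]})
        r = pd.DataFrame({"chrom": "chr1", "start": [20], "end": [30]})
        assert circuits.interval_overlap_fraction(q, r) == (0, 0.0)

    def test_empty_query_rejected(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        r = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10]})
        with pytest.raises(ValueError, match="empty"):
            circuits.interval_overlap_fraction(empty, r)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(6)
        q = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 300),
                "start": rng.integers(0, 100_000, 300),
            }
        )
        q["end"] = q.start + rng.integers(1, 500, 300)
        r = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 200),
                "start": rng.integers(0, 100_000, 200),
            }
        )
        r["end"] = r.start + rng.integers(1, 500, 200)
        n, frac = circuits.interval_overlap_fraction(q, r)
        brute = 0
        for a in q.itertuples():
            if any(
                a.chrom == b.chrom and a.start < b.end and b.start < a.end
                for b in r.itertuples()
            ):
                brute += 1
        assert n == brute and frac == brute / len(q)

    def test_printed_percent_modes(self):
        assert circuits.printed_percent(1, 3, 2, "truncate") == 33.33
        assert circuits.printed_percent(2, 3, 2, "round") == 66.67
        assert circuits.printed_percent(2, 3, 2, "truncate") == 66.66
        with pytest.raises(ValueError):
            circuits.printed_percent(1, 0, 2)


class TestSignatureAnnotation:
    def test_planted_signature_wins_and_ties_flag(self):
        rng = np.random.default_rng(7)
        n = 60
        labels = np.repeat([0, 1], 30)
        gs = pd.DataFrame(
            {
                "a1": rng.normal(0, 1, n) + 5 * (labels == 0),
                "a2": rng.normal(0, 1, n) + 5 * (labels == 0),
                "b1": rng.normal(0, 1, n) + 5 * (labels == 1),
                "b2": rng.normal(0, 1, n) + 5 * (labels == 1),
            },
            index=[f"c{i}" for i in range(n)],
        )
        out = circuits.annotate_clusters_by_signature(
            gs, labels, {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        )
        assert list(out.label) == ["A", "B"]
        assert not out.tie.any()

    def test_all_zero_scores_unassigned(self):
        gs = pd.DataFrame(
            np.zeros((10, 3)), columns=["a1", "a2", "a3"],
            index=[f"c{i}" for i in range(10)],
        )
        out = circuits.annotate_clusters_by_signature(
            gs, np.zeros(10, dtype=int), {"A": ["a1", "a2"]}
        )
        assert list(out.label) == ["unassigned"]

    def test_single_signature_assigned_everywhere(self):
        rng = np.random.default_rng(8)
        gs = pd.DataFrame(
            rng.normal(0, 1, (20, 2)), columns=["a1", "a2"],
            index=[f"c{i}" for i in range(20)],
        )
        labels = np.repeat([0, 1], 10)
        out = circuits.annotate_clusters_by_signature(gs, labels, {"A": ["a1", "a2"]})
        assert list(out.label) == ["A", "A"]
        assert not out.tie.any()
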