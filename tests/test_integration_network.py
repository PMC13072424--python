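"""Enhancer-target assignment, DEG integration, coverage and the
co-expression network."""

import numpy as np
import pandas as pd
import pytest

from ovisepi import integration_network as inet
from ovisepi.genomic_io import (GeneAnnotation, GenomicInterval,
                                InvalidParameterError, Loop,
                                gene_from_interval)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return gene_from_interval(gene_id,
                              GenomicInterval(chrom, start, end, strand))


class TestProximalTargets:
    def test_promoter_overlap_wins(self):
        genes = [gene("gA", 10_000, 15_000), gene("gB", 10_500, 12_000)]
        # enhancer inside gA's promoter window (TSS-2000..+500) and gB's body
        out = inet.proximal_targets([iv(8_500, 9_000)], genes)
        assert out[0].gene_id == "gA"
        assert out[0].category == "promoter"

    def test_gene_body_second_priority(self):
        genes = [gene("gA", 10_000, 30_000)]
        out = inet.proximal_targets([iv(20_000, 21_000)], genes)
        assert out[0].gene_id == "gA"
        assert out[0].category == "gene_body"

    def test_nearest_tss_within_window(self):
        genes = [gene("gA", 100_000, 105_000), gene("gB", 160_000, 165_000)]
        out = inet.proximal_targets([iv(120_000, 121_000)], genes)
        assert out[0].gene_id == "gA"
        assert out[0].category == "intergenic"

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        genes = [gene("gB", 200_000, 205_000), gene("gA", 100_000, 105_000)]
        # enhancer midpoint chosen so both TSS distances are equal:
        # gA TSS 100000, gB TSS 200000; enhancer [149001, 151000)
        enh = iv(149_001, 151_000)
        d_a = 149_001 - 100_000
        d_b = 200_000 - 150_999
        assert d_a == d_b
        out = inet.proximal_targets([enh], genes)
        assert out[0].gene_id == "gA"

    def test_no_gene_in_window_unassigned(self):
        genes = [gene("gA", 500_000, 505_000)]
        out = inet.proximal_targets([iv(0, 1000)], genes)
        assert out[0].gene_id == ""

    def test_matches_nearest_tss_brute_force(self, rng):
        genes = [gene(f"g{i:03d}", int(p), int(p) + 2_000,
                      strand="+" if rng.random() < 0.5 else "-")
                 for i, p in enumerate(np.sort(
                     rng.choice(np.arange(0, 2_000_000, 25_000), 40,
                                replace=False)))]
        enhancers = [iv(int(s), int(s) + 1_000)
                     for s in rng.integers(0, 2_000_000, 60)]
        out = inet.proximal_targets(enhancers, genes)
        for enh, a in zip(enhancers, out):
            if a.category != "intergenic" or not a.gene_id:
                continue
            dists = {}
            for g in genes:
                d = inet._point_distance(enh, g.tss)
                dists.setdefault(d, []).append(g.gene_id)
            best = min(dists)
            assert a.gene_id == sorted(dists[best])[0]
            assert a.distance == best


class TestLoopTargets:
    def test_enhancer_anchor_a_tss_anchor_b(self):
        genes = [gene("gA", 500_000, 505_000)]
        loop = Loop(iv(100_000, 110_000), iv(498_000, 502_000))
        out = inet.loop_targets([iv(104_000, 106_000)], [loop], genes)
        assert len(out) == 1
        assert out[0].gene_id == "gA" and out[0].mode == "loop"

    def test_reverse_orientation_also_found(self):
        genes = [gene("gA", 100_000, 105_000)]
        loop = Loop(iv(98_000, 102_000), iv(500_000, 510_000))
        out = inet.loop_targets([iv(504_000, 506_000)], [loop], genes)
        assert len(out) == 1 and out[0].gene_id == "gA"

    def test_enhancer_in_no_anchor_yields_nothing(self):
        genes = [gene("gA", 500_000, 505_000)]
        loop = Loop(iv(100_000, 110_000), iv(498_000, 502_000))
        assert inet.loop_targets([iv(200_000, 201_000)], [loop], genes) == []

    def test_enhancer_spanning_both_anchors_excluded(self):
        genes = [gene("gA", 100_500, 105_000)]
        loop = Loop(iv(100_000, 101_000), iv(102_000, 103_000))
        out = inet.loop_targets([iv(100_500, 102_500)], [loop], genes)
        assert out == []

    def test_multiple_targets_per_enhancer(self):
        genes = [gene("gA", 500_000, 505_000), gene("gB", 501_000, 506_000)]
        loop = Loop(iv(100_000, 110_000), iv(498_000, 503_000))
        out = inet.loop_targets([iv(104_000, 106_000)], [loop], genes)
        assert {a.gene_id for a in out} == {"gA", "gB"}


class TestIntegrateWithDegs:
    def make_deg(self, up, other=()):
        rows = [{"gene_id": g, "status": "SH_up"} for g in up]
        rows += [{"gene_id": g, "status": "not_DE"} for g in other]
        return pd.DataFrame(rows).set_index("gene_id")

    def assign(self, genes, mode):
        return [inet.TargetAssignment(iv(0, 100), g, mode, 0) for g in genes]

    def test_coverage_with_printed_counts(self):
        up = [f"g{i:03d}" for i in range(145)]
        assignments = (self.assign(up[:15], "proximal")
                       + self.assign(up[10:25], "loop"))
        out = inet.integrate_with_degs(assignments, self.make_deg(up))
        assert out["n_union"] == 25
        assert out["n_considered"] == 145
        assert out["coverage_pct"] == 17.24

    def test_disjoint_sets_zero_coverage(self):
        out = inet.integrate_with_degs(self.assign(["x"], "proximal"),
                                       self.make_deg(["a", "b"]))
        assert out["coverage_pct"] == 0.0

    def test_duplicate_assignments_do_not_inflate(self):
        up = ["a", "b", "c", "d"]
        dup = self.assign(["a", "a", "a"], "proximal") \
            + self.assign(["a"], "loop")
        out = inet.integrate_with_degs(dup, self.make_deg(up))
        assert out["n_union"] == 1
        assert out["coverage_pct"] == 25.0

    def test_union_matches_set_oracle(self, rng):
        up = [f"g{i}" for i in range(50)]
        prox = list(rng.choice(up, 20, replace=False))
        loop = list(rng.choice(up, 15, replace=False))
        out = inet.integrate_with_degs(
            self.assign(prox, "proximal") + self.assign(loop, "loop"),
            self.make_deg(up))
        assert set(out["union_genes"]) == set(prox) | set(loop)

    def test_referential_integrity(self):
        # assignments to genes absent from the DEG table never appear
        out = inet.integrate_with_degs(
            self.assign(["a", "zzz"], "proximal"), self.make_deg(["a", "b"]))
        assert out["union_genes"] == ["a"]

    def test_loc_exclusion_changes_denominator(self):
        up = ["LOC1", "LOC2", "a", "b", "c"]
        out = inet.integrate_with_degs(self.assign(["a"], "proximal"),
                                       self.make_deg(up), drop_loc=True)
        assert out["n_considered"] == 3
        assert out["coverage_pct"] == 33.33

    def test_empty_deg_table_rejected(self):
        with pytest.raises(InvalidParameterError):
            inet.integrate_with_degs([], pd.DataFrame(columns=["status"]))


class TestCoexpressionNetwork:
    def test_identical_profiles_edge_retained(self):
        x = np.array([1, 5, 2, 8, 3, 9], dtype=float)
        tpm = pd.DataFrame({"a": x, "b": x, "c": x[::-1]}).T
        tpm.columns = [f"s{i}" for i in range(6)]
        G, hubs = inet.coexpression_network(tpm)
        assert G.has_edge("a", "b")
        assert G["a"]["b"]["r"] == pytest.approx(1.0)

    def test_r_0805_at_n6_not_retained(self):
        # construct profiles with sample correlation exactly 0.805:
        # below the n=6 critical r (~0.811) at alpha 0.05, so no edge
        x = np.array([-5, -3, -1, 1, 3, 5], dtype=float)
        z = np.array([1, -1, 0, 0, -1, 1], dtype=float)  # orthogonal to x
        r = 0.805
        y = r * x / x.std() + np.sqrt(1 - r ** 2) * z / z.std()
        tpm = pd.DataFrame({"a": x, "b": y, "c": x}).T
        tpm.columns = [f"s{i}" for i in range(6)]
        G, _ = inet.coexpression_network(tpm, log_transform=False)
        obs_r = np.corrcoef(x, y)[0, 1]
        assert obs_r == pytest.approx(0.805, abs=1e-12)
        assert not G.has_edge("a", "b")
        assert G.has_edge("a", "c")

    def test_hubs_match_brute_force_max_degree(self, rng):
        n = 10
        base = rng.random(8)
        rows = {}
        for i in range(n):
            # genes 0-4 share a profile (clique); 5-9 are noise
            rows[f"g{i}"] = (base + rng.normal(0, 0.01, 8) if i < 5
                             else rng.random(8))
        tpm = pd.DataFrame(rows).T
        tpm.columns = [f"s{i}" for i in range(8)]
        G, hubs = inet.coexpression_network(tpm, top_k_hubs=3)
        degrees = {g: G.degree[g] for g in G.nodes}
        brute = sorted(degrees, key=lambda g: (-degrees[g], g))[:3]
        assert hubs == brute

    def test_degree_sum_is_twice_edges(self, rng):
        tpm = pd.DataFrame(rng.random((6, 8)),
                           index=[f"g{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(8)])
        G, _ = inet.coexpression_network(tpm, r_min=0.0, alpha=1.0)
        assert sum(dict(G.degree).values()) == 2 * G.number_of_edges()

    def test_constant_gene_excluded_with_warning(self):
        tpm = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [2, 4, 6, 8.0],
                            "c": [5, 5, 5, 5.0]}).T
        tpm.columns = [f"s{i}" for i in range(4)]
        G, _ = inet.coexpression_network(tpm)
        assert "c" not in G.nodes
        assert G.graph["excluded_constant"] == ["c"]

    def test_too_few_genes_rejected(self):
        tpm = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [1, 2, 3, 4.0]}).T
        tpm.columns = [f"s{i}" for i in range(4)]
        with pytest.raises(InvalidParameterError):
            inet.coexpression_network(tpm)


class TestLoopExpressionCorrelation:
    def test_planted_links_positive_and_proximal_stronger(
            self, dataset, truth, de_result, consensus_set):
        from ovisepi.bsr_enhancers import classify_bsr
        lists, _ = classify_bsr(consensus_set)
        sh_enh = lists["SH_specific"]
        prox = inet.proximal_targets(sh_enh, dataset.genes)
        loops = inet.loop_targets(sh_enh, dataset.loops, dataset.genes)
        track = dataset.breed_signal("SH", "H3K27ac")
        sh_tpm = dataset.tpm[[c for c in dataset.tpm.columns
                              if c.startswith("SH")]].mean(axis=1)
        c_prox = inet.assignment_signal_expression(prox, track, sh_tpm,
                                                   mode="proximal")
        c_loop = inet.assignment_signal_expression(loops, track, sh_tpm,
                                                   mode="loop")
        assert c_prox["r"] > 0 and c_prox["p"] < 0.05
        assert c_loop["r"] > 0 and c_loop["p"] < 0.05
        assert c_prox["r"] > c_loop["r"]

    def test_permuted_gene_labels_null(self, dataset, truth, rng):
        links = [l for l in truth.planted_links if l.mode == "loop"]
        track = dataset.breed_signal("SH", "H3K27ac")
        sh_tpm = dataset.tpm[[c for c in dataset.tpm.columns
                              if c.startswith("SH")]].mean(axis=1)
        perm = rng.permutation([l.gene_id for l in links])
        shuffled = [inet.TargetAssignment(l.enhancer, g, "loop", None)
                    for l, g in zip(links, perm)]
        out = inet.assignment_signal_expression(shuffled, track, sh_tpm)
        assert abs(out["r"]) < 0.7  # centred on 0, broad seed-level bound

    def test_single_pair_missing(self, dataset):
        track = dataset.breed_signal("SH", "H3K27ac")
        tpmv = pd.Series({"g": 5.0})
        out = inet.assignment_signal_expression(
            [inet.TargetAssignment(iv(0, 1000), "g", "loop", None)],
            track, tpmv)
        assert np.isnan(out["r"])
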