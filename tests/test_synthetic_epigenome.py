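"""The generator's statistical guarantees: determinism, Markov structure,
emission fidelity, NB count properties, link planting and feasibility
errors."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from ovisepi import expression as ex
from ovisepi.chromatin_states import PROTOTYPE_EMISSIONS, STATE_NAMES
from ovisepi.genomic_io import InvalidParameterError, MARKS
from ovisepi.synthetic_epigenome import (DEFAULT_METHYLATION_MEANS,
                                         SimulationConfig, plant_bsr_links,
                                         simulate)
from conftest import small_config

ENH = STATE_NAMES.index("EnhA")
K27AC = MARKS.index("H3K27ac")


def dataset_fingerprint(ds):
    h = hashlib.sha256()
    for sample in sorted(ds.marks):
        for chrom in ds.marks[sample].chroms:
            h.update(ds.marks[sample].matrices[chrom].tobytes())
    h.update(ds.counts.to_csv().encode())
    h.update(ds.tpm.round(9).to_csv().encode())
    h.update(ds.methylation.round(9).to_csv().encode())
    h.update(ds.phenotypes.round(9).to_csv().encode())
    for key in sorted(ds.signals):
        for chrom in sorted(ds.signals[key].values):
            h.update(np.round(ds.signals[key].values[chrom], 9).tobytes())
    for lp in ds.loops:
        h.update(repr(lp).encode())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = small_config(seed=21)
        d1, t1 = simulate(cfg)
        d2, t2 = simulate(small_config(seed=21))
        assert dataset_fingerprint(d1) == dataset_fingerprint(d2)
        assert t1.planted_deg.equals(t2.planted_deg)
        assert t1.planted_links == t2.planted_links

    def test_different_seed_differs(self):
        d1, _ = simulate(small_config(seed=21))
        d2, _ = simulate(small_config(seed=22))
        assert dataset_fingerprint(d1) != dataset_fingerprint(d2)


class TestStateTrack:
    def test_self_transition_within_tolerance(self, truth):
        """Empirical self-transition of the realised chain within +/-0.01 of
        the configured 0.96 at the default genome size."""
        same, total = 0, 0
        for chrom, states in truth.state_tracks["HU"].items():
            same += int((states[1:] == states[:-1]).sum())
            total += len(states) - 1
        assert abs(same / total - 0.96) < 0.01

    def test_per_state_mark_frequency_matches_emissions(self, dataset, truth):
        """Observed mark frequency per state deviates < 0.05 from the
        emission matrix at the default genome size."""
        freq = np.zeros((15, 5))
        counts = np.zeros(15)
        mat = dataset.marks["HU1"]
        for chrom in mat.chroms:
            states = truth.state_tracks["HU"][chrom]
            for k in range(15):
                mask = states == k
                if mask.any():
                    freq[k] += mat.matrices[chrom][mask].sum(axis=0)
                    counts[k] += mask.sum()
        observed = freq / counts[:, None]
        assert np.abs(observed - PROTOTYPE_EMISSIONS).max() < 0.05

    def test_planted_sh_enhancers_have_marks_in_sh_not_hu(self, dataset,
                                                          truth):
        """Planted SH enhancers show the EnhA pattern in both SH replicates
        and no H3K27ac signal in either HU replicate (by construction)."""
        bs = dataset.config.bin_size
        for enh, breed in truth.planted_bsr:
            if breed != "SH":
                continue
            a, b = enh.start // bs, enh.end // bs
            for rep in ("SH1", "SH2"):
                block = dataset.marks[rep].matrices[enh.chrom][a:b]
                assert block[:, K27AC].all()
            for rep in ("HU1", "HU2"):
                block = dataset.marks[rep].matrices[enh.chrom][a:b]
                assert not block[:, K27AC].any()

    def test_planted_tracks_carry_enh_and_qui(self, truth):
        for enh, breed in truth.planted_bsr:
            other = "HU" if breed == "SH" else "SH"
            bs = 200
            a, b = enh.start // bs, enh.end // bs
            assert (truth.state_tracks[breed][enh.chrom][a:b] == ENH).all()
            assert (truth.state_tracks[other][enh.chrom][a:b]
                    == STATE_NAMES.index("Qui")).all()


class TestCounts:
    def test_nb_variance_exceeds_mean(self, dataset):
        norm = dataset.counts.to_numpy(dtype=float)
        mu = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        strong = mu > 100
        assert (var[strong] > mu[strong]).mean() > 0.8

    def test_null_config_false_positives_near_alpha(self):
        """With no planted effect, the DEG caller at alpha=0.05 flags about
        alpha * n_genes false positives."""
        cfg = SimulationConfig(seed=31, n_chroms=1, chrom_length=2_000_000,
                               n_genes=100, n_planted_deg=0, n_bsr_sh=0,
                               n_bsr_hu=0, n_loops=0,
                               generate_sequence=False,
                               reads_per_library=1000)
        rates = []
        for seed in (31, 32, 33, 34, 35):
            import dataclasses
            ds, _ = simulate(dataclasses.replace(cfg, seed=seed))
            de = ex.differential_expression(ds.counts, ds.sample_breeds,
                                            tpm_matrix=ds.tpm)
            p = de.table["p_value"].dropna()
            rates.append((p < 0.05).mean())
        assert 0.02 <= np.mean(rates) <= 0.08

    def test_planted_direction_consistent_with_linked_enhancer(self, truth):
        sh_up = set(truth.planted_deg.loc[
            truth.planted_deg["direction"] == "SH_up", "gene_id"])
        for (enh, breed), link in zip(truth.planted_bsr,
                                      truth.planted_links):
            assert (link.gene_id in sh_up) == (breed == "SH")


class TestLinkPlanting:
    def test_deterministic_distal_count(self, truth, dataset):
        n_sh = dataset.config.n_bsr_sh
        sh_links = [l for l in truth.planted_links
                    if l.gene_id in set(
                        truth.planted_deg.loc[
                            truth.planted_deg.direction == "SH_up",
                            "gene_id"])]
        n_loop = sum(1 for l in sh_links if l.mode == "loop")
        assert n_loop == round(dataset.config.frac_distal_links * n_sh)

    @pytest.mark.parametrize("frac,expected_loop", [(0.0, 0), (1.0, 6)])
    def test_frac_distal_extremes(self, frac, expected_loop):
        cfg = small_config(frac_distal_links=frac)
        _, truth = simulate(cfg)
        sh_up = set(truth.planted_deg.loc[
            truth.planted_deg.direction == "SH_up", "gene_id"])
        sh_links = [l for l in truth.planted_links if l.gene_id in sh_up]
        assert sum(1 for l in sh_links if l.mode == "loop") == expected_loop

    def test_frac_distal_zero_all_recoverable_proximally(self):
        from ovisepi import integration_network as inet
        ds, truth = simulate(small_config(frac_distal_links=0.0))
        sh_up = set(truth.planted_deg.loc[
            truth.planted_deg.direction == "SH_up", "gene_id"])
        sh_links = [l for l in truth.planted_links if l.gene_id in sh_up]
        out = inet.proximal_targets([l.enhancer for l in sh_links], ds.genes)
        assert all(a.gene_id == l.gene_id for a, l in zip(out, sh_links))

    def test_frac_distal_one_proximal_recovers_none(self):
        from ovisepi import integration_network as inet
        ds, truth = simulate(small_config(frac_distal_links=1.0))
        sh_up = set(truth.planted_deg.loc[
            truth.planted_deg.direction == "SH_up", "gene_id"])
        sh_links = [l for l in truth.planted_links if l.gene_id in sh_up]
        out = inet.proximal_targets([l.enhancer for l in sh_links], ds.genes)
        assert all(a.gene_id == "" for a in out)

    def test_infeasible_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate(small_config(n_bsr_sh=50, n_planted_deg=10))


class TestMethylationAndPhenotypes:
    def test_methylation_fractions_in_unit_interval(self, dataset):
        assert dataset.methylation["frac"].between(0, 1).all()

    def test_state_means_ordering(self, dataset, truth):
        """TssA territory is the least methylated; Repr/Qui the most."""
        bs = dataset.config.bin_size
        by_state = {}
        for chrom, sub in dataset.methylation.groupby("chrom"):
            states = truth.state_tracks["HU"][chrom][
                sub["pos"].to_numpy() // bs]
            for k in (0, 13, 14):
                by_state.setdefault(k, []).extend(
                    sub["frac"].to_numpy()[states == k])
        tssa = np.mean(by_state[0])
        repr_qui = min(np.mean(by_state[13]), np.mean(by_state[14]))
        assert tssa < 0.12
        assert repr_qui > 0.7

    def test_phenotypes_track_driver_genes(self, dataset, truth):
        expr = np.log2(dataset.tpm.loc[truth.phenotype_genes] + 1).mean(axis=0)
        for trait in dataset.phenotypes.columns:
            r = np.corrcoef(expr, dataset.phenotypes[trait])[0, 1]
            assert r > 0.5

    def test_written_dataset_manifest_complete(self, tmp_path):
        ds, _ = simulate(small_config())
        manifest = ds.write(tmp_path)
        for _, row in manifest.iterrows():
            assert (tmp_path / row["file"]).exists()
        roles = set(manifest["role"])
        assert {"gene_annotation", "rna_counts", "rna_tpm", "loops",
                "methylation", "phenotypes", "peaks",
                "binarized_marks"} <= roles
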