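"""End-to-end pipeline orchestration, run manifest and summary report.

Stage order: simulate -> qc -> diffexpr -> segment -> bsr -> integrate.
Every stage's outputs are plain-text files under the run directory; the run
manifest (JSON) records the configuration snapshot, seed, per-stage output
checksums and timings. The report aggregates the headline numbers of each
stage and is byte-identical across reruns with the same seed and
configuration (timings live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsr_enhancers as bsr
from . import chromatin_states as cs
from . import expression as ex
from . import integration_network as inet
from . import qc_metrics as qc
from .genomic_io import GenomicInterval, InvalidParameterError, write_bed
from .synthetic_epigenome import (SimulationConfig, SyntheticDataset,
                                  SyntheticTruth, simulate)

log = logging.getLogger("ovisepi")


class ConfigError(ValueError):
    """Invalid or unreadable pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


_PIPELINE_FIELDS = {
    "hmm_max_iter": 100,
    "hmm_tol": 1e-3,
    "hmm_seed": 0,
    "decode_method": "posterior",
    "lfc_threshold": 1.0,
    "alpha": 0.05,
    "tpm_threshold": 1.0,
    "proximal_window": 100_000,
    "r_min": 0.8,
    "n_permutations": 200,
    "deg_flank": 2_000,
    "drop_loc": False,
    "write_signals": False,
    "min_overlap_bp": 1,
}


@dataclass
class PipelineConfig:
    """Simulation design plus every analysis threshold, as one flat namespace."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-3
    hmm_seed: int = 0
    decode_method: str = "posterior"
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    tpm_threshold: float = 1.0
    proximal_window: int = 100_000
    r_min: float = 0.8
    n_permutations: int = 200
    deg_flank: int = 2_000
    drop_loc: bool = False
    write_signals: bool = False
    min_overlap_bp: int = 1

    def flat(self) -> dict:
        d = {f.name: getattr(self.sim, f.name)
             for f in dataclasses.fields(SimulationConfig)}
        d["emission"] = np.asarray(d["emission"]).tolist()
        d["methylation_state_means"] = np.asarray(
            d["methylation_state_means"]).tolist()
        for k in _PIPELINE_FIELDS:
            d[k] = getattr(self, k)
        return d

    @classmethod
    def from_flat(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping or {})
        sim_names = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_kwargs, pipe_kwargs = {}, {}
        for key, value in mapping.items():
            if key in sim_names:
                sim_kwargs[key] = value
            elif key in _PIPELINE_FIELDS:
                pipe_kwargs[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        try:
            sim = SimulationConfig(**sim_kwargs)
        except (InvalidParameterError, TypeError) as exc:
            raise ConfigError(str(exc))
        return cls(sim=sim, **pipe_kwargs)


def load_config(path) -> PipelineConfig:
    """Load a flat key-value YAML configuration file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a flat key: value mapping")
    return PipelineConfig.from_flat(data)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[Path], seconds: float):
        self.stages.append({
            "stage": name,
            "seconds": round(seconds, 3),
            "outputs": [{"path": str(p), "sha256": _sha256(p)}
                        for p in outputs],
        })

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "stages": self.stages}, fh, indent=1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_truth(truth: SyntheticTruth, outdir, bin_size: int) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for breed, tracks in truth.state_tracks.items():
        p = outdir / f"truth_states_{breed}.bed"
        seg = cs.Segmentation(bin_size, tracks, list(cs.STATE_NAMES))
        seg.to_bed(p)
        paths.append(p)
    p = outdir / "truth_bsr.bed"
    write_bed(p, [iv for iv, _ in truth.planted_bsr],
              names=[breed for _, breed in truth.planted_bsr])
    paths.append(p)
    p = outdir / "truth_deg.tsv"
    truth.planted_deg.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "truth_links.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\tmode\tstrength\n")
        for link in truth.planted_links:
            e = link.enhancer
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{link.gene_id}"
                     f"\t{link.mode}\t{link.strength:.6g}\n")
    paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def union_mark_matrix(dataset: SyntheticDataset, breed: str
                      ) -> cs.BinnedMarkMatrix:
    """Replicate-union binarization for one breed (mark present in any rep)."""
    reps = [m for s, m in dataset.marks.items() if s.startswith(breed)]
    matrices = {c: np.maximum.reduce([m.matrices[c] for m in reps])
                for c in dataset.chrom_lengths}
    return cs.BinnedMarkMatrix(breed, dataset.config.bin_size, matrices)


def qc_stage(dataset: SyntheticDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for (sample, mark), positions in sorted(dataset.read_positions.items()):
        metrics = qc.complexity_metrics(positions)
        metrics.frip = qc.frip(positions, dataset.peaks[(sample, mark)])
        rows.append({
            "library": f"{sample}_{mark}", "sample": sample, "assay": mark,
            "nrf": metrics.nrf, "pbc1": metrics.pbc1,
            "pbc2": (np.inf if metrics.pbc2_undefined else metrics.pbc2),
            "frip": metrics.frip,
            "passes_encode": metrics.passes_encode(),
        })
    qc_table = pd.DataFrame(rows).set_index("library")
    tracks = {f"{breed}_{mark}": dataset.breed_signal(breed, mark)
              for breed in ("HU", "SH") for mark in
              ("ATAC", "H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3")}
    corr = qc.binned_correlation(tracks, bin_size=500)
    return qc_table, corr


def segmentation_stage(dataset: SyntheticDataset, config: PipelineConfig):
    """Fit one pooled model on all four replicates, then decode each
    replicate (for BSR scoring) and each breed's replicate-union matrix
    (for per-breed state summaries)."""
    hmm = cs.BernoulliHMM(n_states=dataset.config.n_states,
                          seed=config.hmm_seed,
                          max_iter=config.hmm_max_iter, tol=config.hmm_tol)
    model = hmm.fit(list(dataset.marks.values()))
    rep_segs = {s: cs.decode(model, m, config.decode_method)
                for s, m in dataset.marks.items()}
    breed_segs = {b: cs.decode(model, union_mark_matrix(dataset, b),
                               config.decode_method) for b in ("HU", "SH")}
    return model, rep_segs, breed_segs


def bsr_stage(dataset: SyntheticDataset, rep_segs: dict,
              config: PipelineConfig):
    enha = {s: seg.state_intervals("EnhA") for s, seg in rep_segs.items()}
    consensus = bsr.build_consensus(enha, min_overlap_bp=config.min_overlap_bp)
    class_lists, counts = bsr.classify_bsr(consensus)
    tracks = {b: dataset.breed_signal(b, "H3K27ac") for b in ("HU", "SH")}
    profiles = {}
    for cls in ("HU_specific", "SH_specific"):
        if class_lists[cls]:
            curves, _ = bsr.bsr_signal_profile(class_lists[cls], tracks)
            profiles[cls] = curves
    motifs = None
    if dataset.genome is not None and class_lists["SH_specific"]:
        fg = class_lists["SH_specific"]
        bg = bsr.shuffle_background(fg, dataset.chrom_lengths,
                                    seed=dataset.config.seed)
        motifs = bsr.known_motif_enrichment(
            fg, bg, dataset.genome, bsr.builtin_motif_library())
    return consensus, class_lists, counts, profiles, motifs


def integration_stage(dataset: SyntheticDataset, class_lists: dict,
                      de_result: ex.DifferentialExpressionResult,
                      config: PipelineConfig):
    sh_enh = class_lists["SH_specific"]
    prox = inet.proximal_targets(sh_enh, dataset.genes,
                                 window=config.proximal_window)
    loops = inet.loop_targets(sh_enh, dataset.loops, dataset.genes)
    assignments = prox + loops
    integration = inet.integrate_with_degs(
        assignments, de_result.table, up_status="SH_up",
        drop_loc=config.drop_loc)
    sh_track = dataset.breed_signal("SH", "H3K27ac")
    sh_tpm = dataset.tpm[[s for s in dataset.tpm.columns
                          if s.startswith("SH")]].mean(axis=1)
    corr_prox = inet.assignment_signal_expression(
        prox, sh_track, sh_tpm, mode="proximal")
    corr_loop = inet.assignment_signal_expression(
        loops, sh_track, sh_tpm, mode="loop")
    candidates = integration["union_genes"]
    network, hubs = None, []
    if len(candidates) >= 3:
        network, hubs = inet.coexpression_network(
            dataset.tpm.loc[candidates], r_min=config.r_min,
            alpha=config.alpha)
    return assignments, integration, corr_prox, corr_loop, network, hubs


def run_pipeline(config: PipelineConfig, outdir,
                 seed: int | None = None) -> tuple[dict, RunManifest]:
    """Run every stage on a fresh simulation; returns (report, manifest)."""
    if seed is not None:
        config = dataclasses.replace(
            config, sim=dataclasses.replace(config.sim, seed=seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.flat(), seed=config.sim.seed)
    report: dict = {"seed": config.sim.seed}

    def run_stage(name, fn):
        log.info("[%s] starting", name)
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:
            log.error("[%s] failed: %s", name, exc)
            raise StageError(name, exc)
        manifest.add_stage(name, outputs, time.perf_counter() - t0)
        log.info("[%s] done (%.1fs)", name, time.perf_counter() - t0)

    state: dict = {}

    def stage_simulate():
        dataset, truth = simulate(config.sim)
        state["dataset"], state["truth"] = dataset, truth
        written = dataset.write(outdir / "data")
        if not config.write_signals:
            for _, row in written.iterrows():
                if row["role"] in ("signal", "read_positions",
                                   "binarized_marks"):
                    (outdir / "data" / row["file"]).unlink()
        paths = write_truth(truth, outdir / "truth", config.sim.bin_size)
        return [outdir / "data" / "manifest.tsv"] + paths

    def stage_qc():
        qc_table, corr = qc_stage(state["dataset"])
        state["qc_table"] = qc_table
        p1 = outdir / "qc_libraries.tsv"
        qc_table.to_csv(p1, sep="\t")
        p2 = outdir / "qc_correlation.tsv"
        corr.to_csv(p2, sep="\t")
        report["qc"] = {
            "n_libraries": int(len(qc_table)),
            "all_pass_encode": bool(qc_table["passes_encode"].all()),
            "min_frip": float(qc_table["frip"].min()),
        }
        return [p1, p2]

    def stage_diffexpr():
        ds = state["dataset"]
        de = ex.differential_expression(
            ds.counts, ds.sample_breeds, tpm_matrix=ds.tpm,
            lfc_threshold=config.lfc_threshold, alpha=config.alpha,
            tpm_threshold=config.tpm_threshold)
        state["de"] = de
        p = outdir / "deg_table.tsv"
        de.table.to_csv(p, sep="\t", index_label="gene_id")
        counts = de.status_counts()
        expressed = int((de.table["status"] != "not_expressed").sum())
        report["expression"] = {
            "n_genes": int(len(de.table)),
            "n_expressed": expressed,
            "SH_up": int(counts.get("SH_up", 0)),
            "HU_up": int(counts.get("HU_up", 0)),
            "n_deg": int(counts.get("SH_up", 0) + counts.get("HU_up", 0)),
        }
        pheno = ds.phenotypes
        hu = pheno.loc[[s for s in pheno.index if s.startswith("HU")]]
        sh = pheno.loc[[s for s in pheno.index if s.startswith("SH")]]
        report["phenotypes"] = {
            trait: {"p": ex.phenotype_test(hu[trait], sh[trait])[1]}
            for trait in pheno.columns}
        return [p]

    def stage_segment():
        ds = state["dataset"]
        model, rep_segs, breed_segs = segmentation_stage(ds, config)
        state.update(model=model, rep_segs=rep_segs, breed_segs=breed_segs)
        paths = []
        p = outdir / "model_emissions.tsv"
        pd.DataFrame(model.emission, index=model.labels,
                     columns=list(cs.MARKS)).to_csv(p, sep="\t",
                                                    index_label="state")
        paths.append(p)
        p = outdir / "model_transitions.tsv"
        pd.DataFrame(model.transition, index=model.labels,
                     columns=model.labels).to_csv(p, sep="\t",
                                                  index_label="state")
        paths.append(p)
        summaries = {}
        for breed, seg in breed_segs.items():
            p = outdir / f"segmentation_{breed}.bed"
            seg.to_bed(p)
            paths.append(p)
            summaries[breed] = cs.state_summary(seg)
        p = outdir / "state_summary.tsv"
        rows = []
        for breed, summ in summaries.items():
            for lab in cs.STATE_NAMES:
                rows.append({"breed": breed, "state": lab, **summ[lab]})
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths.append(p)
        report["states"] = {
            "n_states": model.n_states,
            "labels": sorted(model.labels),
            "converged": bool(model.converged),
            "n_iterations": model.n_iter,
        }
        for breed, summ in summaries.items():
            report["states"][f"functional_fraction_{breed}"] = round(
                summ["functional_fraction"], 4)
            report["states"][f"n_segments_{breed}"] = int(
                sum(summ[lab]["n_segments"] for lab in cs.STATE_NAMES))
        meth = cs.methylation_by_state(breed_segs["HU"],
                                       state["dataset"].methylation)
        report["methylation_by_state"] = {
            k: (None if np.isnan(v) else round(v, 4))
            for k, v in meth.items()}
        p = outdir / "methylation_by_state.tsv"
        pd.Series(meth, name="mean_methylation").to_csv(
            p, sep="\t", index_label="state")
        paths.append(p)
        # enrichment of states in SH-up DEG territory
        de = state["de"]
        sh_up = de.genes_with_status("SH_up")
        if sh_up:
            regions = []
            for g in ds.genes:
                if g.gene_id in sh_up:
                    iv = g.interval
                    regions.append(GenomicInterval(
                        iv.chrom, max(iv.start - config.deg_flank, 0),
                        iv.end + config.deg_flank))
            enr = cs.deg_state_enrichment(
                breed_segs["SH"], regions, n_perm=config.n_permutations,
                seed=config.sim.seed)
            report["deg_state_enrichment"] = {
                k: {"fold": round(v["fold"], 3), "p": round(v["p"], 4)}
                for k, v in enr.items()}
            p = outdir / "deg_state_enrichment.tsv"
            pd.DataFrame(enr).T.to_csv(p, sep="\t", index_label="state")
            paths.append(p)
        return paths

    def stage_bsr():
        ds = state["dataset"]
        consensus, class_lists, counts, profiles, motifs = bsr_stage(
            ds, state["rep_segs"], config)
        state["class_lists"] = class_lists
        paths = []
        p = outdir / "consensus_enhancers.bed"
        write_bed(p, consensus.intervals, names=consensus.classes)
        paths.append(p)
        for cls in ("HU_specific", "SH_specific", "shared"):
            p = outdir / f"bsr_{cls}.bed"
            write_bed(p, class_lists[cls])
            paths.append(p)
        report["bsr"] = {**counts, "n_consensus": len(consensus)}
        if motifs:
            p = outdir / "motif_enrichment.tsv"
            pd.DataFrame([dataclasses.asdict(m) for m in motifs]).to_csv(
                p, sep="\t", index=False)
            paths.append(p)
            report["bsr"]["top_motif"] = min(
                motifs, key=lambda m: m.p_value).motif_id
        return paths

    def stage_integrate():
        ds = state["dataset"]
        (assignments, integration, corr_prox, corr_loop,
         network, hubs) = integration_stage(
            ds, state["class_lists"], state["de"], config)
        paths = []
        p = outdir / "target_assignments.tsv"
        rows = [{"chrom": a.enhancer.chrom, "start": a.enhancer.start,
                 "end": a.enhancer.end, "gene_id": a.gene_id,
                 "mode": a.mode, "distance": a.distance,
                 "category": a.category} for a in assignments]
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths.append(p)
        p = outdir / "coverage.json"
        with open(p, "w") as fh:
            json.dump(integration, fh, indent=1, sort_keys=True)
        paths.append(p)
        report["integration"] = {
            "n_proximal_genes": integration["n_proximal"],
            "n_loop_genes": integration["n_loop"],
            "n_union": integration["n_union"],
            "n_considered": integration["n_considered"],
            "coverage_pct": integration["coverage_pct"],
            "proximal_r": (None if np.isnan(corr_prox["r"])
                           else round(corr_prox["r"], 4)),
            "loop_r": (None if np.isnan(corr_loop["r"])
                       else round(corr_loop["r"], 4)),
        }
        if network is not None:
            p = outdir / "network_edges.tsv"
            inet.network_edge_table(network).to_csv(p, sep="\t", index=False)
            paths.append(p)
            report["network"] = {
                "n_nodes": network.number_of_nodes(),
                "n_edges": network.number_of_edges(),
                "hubs": hubs,
            }
        return paths

    for name, fn in [("simulate", stage_simulate), ("qc", stage_qc),
                     ("diffexpr", stage_diffexpr), ("segment", stage_segment),
                     ("bsr", stage_bsr), ("integrate", stage_integrate)]:
        run_stage(name, fn)

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    text_path = outdir / "report.txt"
    with open(text_path, "w") as fh:
        fh.write(render_text_report(report))
    manifest.add_stage("report", [report_path, text_path], 0.0)
    manifest.write(outdir / "run_manifest.json")
    return report, manifest


def render_text_report(report: dict) -> str:
    lines = [f"ovisepi pipeline report (seed {report['seed']})", ""]
    if "qc" in report:
        q = report["qc"]
        lines.append(f"QC: {q['n_libraries']} libraries, "
                     f"all ENCODE-pass={q['all_pass_encode']}, "
                     f"min FRiP={q['min_frip']:.3f}")
    if "expression" in report:
        e = report["expression"]
        lines.append(f"Expression: {e['n_expressed']}/{e['n_genes']} expressed; "
                     f"DEGs {e['n_deg']} (SH_up {e['SH_up']}, HU_up {e['HU_up']})")
    if "states" in report:
        s = report["states"]
        lines.append(f"Chromatin states: {s['n_states']} states, "
                     f"converged={s['converged']} in {s['n_iterations']} iter")
    if "bsr" in report:
        b = report["bsr"]
        lines.append(f"BSR: SH-specific {b['SH_specific']}, "
                     f"HU-specific {b['HU_specific']}, shared {b['shared']}, "
                     f"other {b['other']} of {b['n_consensus']} consensus regions")
    if "integration" in report:
        i = report["integration"]
        lines.append(f"Integration: union {i['n_union']}/{i['n_considered']} "
                     f"SH-up genes covered = {i['coverage_pct']}% "
                     f"(proximal r={i['proximal_r']}, loop r={i['loop_r']})")
    if "network" in report:
        n = report["network"]
        lines.append(f"Network: {n['n_nodes']} nodes, {n['n_edges']} edges, "
                     f"hubs: {', '.join(n['hubs'])}")
    return "\n".join(lines) + "\n"
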