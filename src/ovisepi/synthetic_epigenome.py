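"""Synthetic two-breed epigenome with planted ground truth.

The generator emulates a two-breed comparative muscle epigenome design:
purebred HU and crossbred SH sheep, RNA-seq with three biological
replicates per breed, and five binarized chromatin marks (ATAC, H3K4me3,
H3K27ac, H3K4me1, H3K27me3) with two replicates per breed. Ground truth is
planted at every level so downstream stages can be scored:

* a 15-state Markov state track per breed (shared background realisation,
  so untouched regions are breed-concordant);
* breed-specific active enhancers: EnhA-state runs written into one breed's
  track and forced to quiescent in the other, with a short quiescent guard
  band on both sides in both breeds so that neighbouring background
  enhancers cannot fuse with them during consensus merging;
* negative-binomial expression counts with planted up-regulated genes
  (symmetric half-fold-change applied to each breed);
* enhancer->gene causal links, proximal (enhancer 2-4 kb upstream of the
  target TSS) or loop-mediated (enhancer in a gene desert, joined to the
  target TSS by a chromatin loop). Each link carries a strength u; the
  enhancer's H3K27ac intensity scales with u and the target's baseline
  expression scales with u**beta, with beta larger for proximal links than
  for loop links so that proximal signal-expression coupling is the
  stronger of the two, mirroring the qualitative ordering reported for
  real enhancer-promoter regulation;
* a CpG methylation track drawn Beta-distributed around per-state means
  (low at active promoters, high at repressed/quiescent chromatin);
* phenotypes (body weights, eye-muscle area) generated as linear functions
  of three chosen planted genes' expression plus Gaussian noise.

Genome layout: each chromosome devotes its first ``gene_zone_fraction`` to
genes placed one per fixed-width cell (with jittered position), and the
remainder to a gene desert that hosts loop-linked enhancers and loop
anchors; the desert guarantees that loop-only links cannot be recovered by
proximal assignment. Marks are simulated directly at bin resolution (no
reads); "peaks" are maximal runs of positive bins. Read positions for the
QC metrics are sampled from the continuous signal with a configurable
duplication rate.

One master seed drives everything through named, order-independent
substreams, so identical configurations give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin_states import (PROTOTYPE_EMISSIONS, STATE_NAMES,
                               BinnedMarkMatrix)
from .expression import tpm as compute_tpm
from .genomic_io import (MARKS, GeneAnnotation, GenomicInterval,
                         InvalidParameterError, Loop, PeakSet, SignalTrack,
                         gene_from_interval, write_bed, write_bedgraph,
                         write_bedpe, write_fasta, write_gff3_genes,
                         write_tsv_matrix)

ENH_STATE = STATE_NAMES.index("EnhA")
QUI_STATE = STATE_NAMES.index("Qui")
K27AC = MARKS.index("H3K27ac")

#: Per-state mean CpG methylation fraction (order follows STATE_NAMES):
#: lowest at active promoters, intermediate at transcribed/enhancer states,
#: highest at repressed and quiescent chromatin.
DEFAULT_METHYLATION_MEANS = np.array([
    0.05, 0.15, 0.20, 0.50, 0.55, 0.50, 0.30, 0.35,
    0.40, 0.40, 0.50, 0.25, 0.40, 0.80, 0.85,
])

_SUBSTREAMS = ("layout", "links", "states", "marks", "signal", "rna",
               "meth", "pheno", "loops", "sequence", "reads")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic epigenome."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 200
    n_genes: int = 400
    n_states: int = 15
    self_transition: float = 0.96
    emission: np.ndarray | None = None          # default: prototype table
    n_bsr_sh: int = 40
    n_bsr_hu: int = 15
    bsr_width: int = 2000
    n_planted_deg: int = 60                     # up-regulated per breed
    deg_log2fc: float = 2.5
    nb_dispersion: float = 0.1
    mean_depth: float = 500.0
    n_loops: int = 50
    frac_distal_links: float = 0.5
    methylation_state_means: np.ndarray | None = None
    rna_replicates: int = 3
    mark_replicates: int = 2
    gene_zone_fraction: float = 0.8
    loc_gene_fraction: float = 0.15
    reads_per_library: int = 20_000
    duplicate_rate: float = 0.08
    generate_sequence: bool = True
    signal_gamma_shape: float = 4.0
    signal_baseline: float = 0.1
    linked_expression_sigma: float = 0.35
    baseline_expression_sigma: float = 0.8
    proximal_coupling: float = 2.0
    loop_coupling: float = 1.0
    motif_plant_prob: float = 0.7

    def __post_init__(self):
        if self.emission is None:
            if self.n_states != len(STATE_NAMES):
                raise InvalidParameterError(
                    "a custom emission matrix is required when "
                    f"n_states != {len(STATE_NAMES)}")
            self.emission = PROTOTYPE_EMISSIONS.copy()
        self.emission = np.asarray(self.emission, dtype=float)
        if self.emission.shape != (self.n_states, len(MARKS)):
            raise InvalidParameterError(
                f"emission must be {self.n_states}x{len(MARKS)}")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise InvalidParameterError("emission entries must lie in [0, 1]")
        if not 0 < self.self_transition < 1:
            raise InvalidParameterError("self_transition must be in (0, 1)")
        if not 0 <= self.frac_distal_links <= 1:
            raise InvalidParameterError("frac_distal_links must be in [0, 1]")
        if self.methylation_state_means is None:
            if self.n_states == len(DEFAULT_METHYLATION_MEANS):
                self.methylation_state_means = DEFAULT_METHYLATION_MEANS.copy()
            else:
                raise InvalidParameterError(
                    "methylation_state_means required for custom n_states")
        self.methylation_state_means = np.asarray(
            self.methylation_state_means, dtype=float)
        if self.bsr_width % self.bin_size:
            raise InvalidParameterError("bsr_width must be a bin multiple")
        if self.chrom_length % self.bin_size:
            raise InvalidParameterError("chrom_length must be a bin multiple")

    def transition_matrix(self) -> np.ndarray:
        K = self.n_states
        A = np.full((K, K), (1 - self.self_transition) / (K - 1))
        np.fill_diagonal(A, self.self_transition)
        return A

    def rna_samples(self) -> list[str]:
        return [f"{b}_{r + 1}" for b in ("HU", "SH")
                for r in range(self.rna_replicates)]

    def mark_samples(self) -> list[str]:
        return [f"{b}{r + 1}" for b in ("HU", "SH")
                for r in range(self.mark_replicates)]


@dataclass(frozen=True)
class PlantedLink:
    enhancer: GenomicInterval
    gene_id: str
    mode: str        # "proximal" | "loop"
    strength: float  # u, the coupling multiplier


@dataclass
class SyntheticTruth:
    """Everything planted: the answer key for recovery tests."""

    state_tracks: dict[str, dict[str, np.ndarray]]   # breed -> chrom -> states
    planted_bsr: list[tuple[GenomicInterval, str]]   # (interval, breed)
    planted_deg: pd.DataFrame                        # gene_id, direction, log2fc
    planted_links: list[PlantedLink]
    methylation_state_means: np.ndarray
    phenotype_genes: list[str]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    chrom_lengths: dict[str, int]
    genes: list[GeneAnnotation]
    marks: dict[str, BinnedMarkMatrix]                  # sample -> matrix
    signals: dict[tuple[str, str], SignalTrack]         # (sample, mark)
    peaks: dict[tuple[str, str], PeakSet]
    counts: pd.DataFrame
    tpm: pd.DataFrame
    sample_breeds: pd.Series
    loops: list[Loop]
    methylation: pd.DataFrame
    phenotypes: pd.DataFrame
    genome: dict[str, str] | None
    read_positions: dict[tuple[str, str], list[tuple[str, int]]]

    def breed_signal(self, breed: str, mark: str) -> SignalTrack:
        """Replicate-averaged signal track for one breed and mark."""
        reps = [s for (s, m) in self.signals
                if m == mark and s.startswith(breed)]
        values = {}
        for chrom in self.chrom_lengths:
            values[chrom] = np.mean(
                [self.signals[(s, mark)].values[chrom] for s in sorted(reps)],
                axis=0)
        return SignalTrack(self.config.bin_size, values)

    def gene_by_id(self, gene_id: str) -> GeneAnnotation:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def write(self, outdir) -> pd.DataFrame:
        """Write every component as plain-text files plus a manifest TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []

        def emit(name, role, sample=""):
            rows.append({"file": name, "role": role, "sample": sample})
            return outdir / name

        with open(emit("chrom_sizes.tsv", "chrom_sizes"), "w") as fh:
            for c, l in self.chrom_lengths.items():
                fh.write(f"{c}\t{l}\n")
        write_gff3_genes(emit("genes.gff3", "gene_annotation"), self.genes)
        write_tsv_matrix(emit("counts.tsv", "rna_counts"), self.counts,
                         index_label="gene_id")
        write_tsv_matrix(emit("tpm.tsv", "rna_tpm"), self.tpm,
                         index_label="gene_id")
        self.sample_breeds.rename("breed").to_csv(
            emit("samples.tsv", "rna_samples"), sep="\t",
            index_label="sample")
        self.phenotypes.to_csv(emit("phenotypes.tsv", "phenotypes"),
                               sep="\t", index_label="sample")
        write_bedpe(emit("loops.bedpe", "loops"), self.loops)
        self.methylation.to_csv(emit("methylation.tsv", "methylation"),
                                sep="\t", index=False)
        if self.genome is not None:
            write_fasta(emit("genome.fa", "genome_sequence"), self.genome)
        for sample, mat in self.marks.items():
            path = emit(f"binarized_{sample}.tsv", "binarized_marks", sample)
            _write_mark_matrix(path, mat)
        for (sample, mark), ps in self.peaks.items():
            write_bed(emit(f"peaks_{sample}_{mark}.bed", "peaks",
                           f"{sample}:{mark}"), ps.intervals)
        for (sample, mark), tr in self.signals.items():
            write_bedgraph(emit(f"signal_{sample}_{mark}.bedgraph", "signal",
                                f"{sample}:{mark}"), tr)
        for (sample, mark), pos in self.read_positions.items():
            with open(emit(f"reads_{sample}_{mark}.tsv", "read_positions",
                           f"{sample}:{mark}"), "w") as fh:
                for chrom, p in pos:
                    fh.write(f"{chrom}\t{p}\n")
        manifest = pd.DataFrame(rows)
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        return manifest


def _write_mark_matrix(path, mat: BinnedMarkMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\t" + "\t".join(MARKS) + "\n")
        for chrom in mat.chroms:
            m = mat.matrices[chrom]
            for i in range(m.shape[0]):
                fh.write(f"{chrom}\t{i * mat.bin_size}\t"
                         + "\t".join(str(int(v)) for v in m[i]) + "\n")


def read_mark_matrix(path, sample_id: str, bin_size: int) -> BinnedMarkMatrix:
    df = pd.read_csv(path, sep="\t")
    matrices = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("bin_start")
        matrices[chrom] = sub[list(MARKS)].to_numpy(dtype=np.uint8)
    return BinnedMarkMatrix(sample_id, bin_size, matrices)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)}


def _simulate_state_track(n_bins: int, K: int, self_p: float,
                          rng: np.random.Generator) -> np.ndarray:
    """A Markov-chain realisation with uniform off-diagonal transitions,
    generated run-length-wise (run lengths are geometric)."""
    expected_runs = int(n_bins * (1 - self_p)) + 10
    states = []
    lengths = []
    covered = 0
    s = int(rng.integers(K))
    while covered < n_bins:
        m = max(expected_runs, 16)
        ln = rng.geometric(1 - self_p, size=m)
        jumps = rng.integers(0, K - 1, size=m)
        for li, ji in zip(ln, jumps):
            states.append(s)
            lengths.append(li)
            covered += li
            s = (s + 1 + ji) % K
            if covered >= n_bins:
                break
    track = np.repeat(np.array(states, dtype=np.int16),
                      np.array(lengths)).astype(np.int16)
    return track[:n_bins]


def _place_genes(config: SimulationConfig, rng) -> list[GeneAnnotation]:
    genes = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    n_loc = int(round(config.loc_gene_fraction * config.n_genes))
    loc_flags = np.zeros(config.n_genes, dtype=bool)
    loc_flags[rng.choice(config.n_genes, size=n_loc, replace=False)] = True
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        zone = int(config.gene_zone_fraction * config.chrom_length)
        n = per_chrom[ci]
        cell = zone // n
        # 6 kb margins on both sides leave room for an upstream enhancer
        # (<= 4 kb offset + 2 kb width) without leaving the cell
        max_len = min(5_000, cell - 12_500)
        if max_len < 2_000:
            raise InvalidParameterError(
                "gene zone too crowded: need >= 14.5 kb per gene "
                f"(got {cell} bp); reduce n_genes or grow chrom_length")
        for j in range(n):
            length = int(rng.integers(2_000, max_len + 1))
            lo = 6_000
            hi = cell - length - 6_000
            start = j * cell + int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if loc_flags[gi]:
                gene_id = f"LOC{105000 + gi}"
            else:
                gene_id = f"GENE{gi + 1:04d}"
            genes.append(gene_from_interval(
                gene_id, GenomicInterval(chrom, start, start + length, strand)))
            gi += 1
    return genes


def _desert_slots(config: SimulationConfig) -> dict[str, list[int]]:
    """Disjoint 8-kb slots inside each chromosome's gene desert, all at
    least 100 kb from the last gene so proximal assignment cannot reach.
    Each slot hosts at most one enhancer or loop anchor (<= 6 kb extent)."""
    slots = {}
    zone = int(config.gene_zone_fraction * config.chrom_length)
    lo = zone + 110_000
    hi = config.chrom_length - 10_000
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        slots[chrom] = list(range(lo, hi, 8_000))
    return slots


def plant_bsr_links(genes: list[GeneAnnotation], deg_table: pd.DataFrame,
                    config: SimulationConfig, rng) -> list[PlantedLink]:
    """Plan enhancer->gene causal links for the planted enhancers.

    Every SH-specific enhancer is linked to exactly one planted SH-up gene;
    a deterministic ``round(frac_distal_links * n_bsr_sh)`` of them are
    loop-mediated (enhancer in the gene desert), the rest proximal
    (enhancer 2-4 kb upstream of the target TSS). HU-specific enhancers are
    all linked proximally to planted HU-up genes.
    """
    by_gene = {g.gene_id: g for g in genes}
    sh_up = list(deg_table.loc[deg_table["direction"] == "SH_up", "gene_id"])
    hu_up = list(deg_table.loc[deg_table["direction"] == "HU_up", "gene_id"])
    if config.n_bsr_sh > len(sh_up) or config.n_bsr_hu > len(hu_up):
        raise InvalidParameterError(
            "more planted enhancers than planted up-regulated genes "
            f"(SH {config.n_bsr_sh}/{len(sh_up)}, "
            f"HU {config.n_bsr_hu}/{len(hu_up)})")
    sh_targets = list(rng.choice(sh_up, size=config.n_bsr_sh, replace=False))
    hu_targets = list(rng.choice(hu_up, size=config.n_bsr_hu, replace=False))
    n_distal = int(round(config.frac_distal_links * config.n_bsr_sh))
    slots = _desert_slots(config)
    used_slots: dict[str, int] = {c: 0 for c in slots}
    links = []
    w = config.bsr_width
    bs = config.bin_size

    def proximal_interval(gene: GeneAnnotation) -> GenomicInterval:
        d = int(rng.integers(2_000, 4_001))
        if gene.interval.strand != "-":
            end = (gene.tss - d) // bs * bs
            return GenomicInterval(gene.chrom, end - w, end)
        start = -(-(gene.tss + 1 + d) // bs) * bs
        return GenomicInterval(gene.chrom, start, start + w)

    for i, gid in enumerate(sh_targets):
        gene = by_gene[gid]
        if i < n_distal:
            chrom = gene.chrom
            if used_slots[chrom] >= len(slots[chrom]):
                raise InvalidParameterError(
                    f"gene desert on {chrom} cannot host more enhancers")
            base = slots[chrom][used_slots[chrom]]
            used_slots[chrom] += 1
            start = base // bs * bs
            enh = GenomicInterval(chrom, start, start + w)
            mode = "loop"
        else:
            enh = proximal_interval(gene)
            mode = "proximal"
        u = float(2.0 ** rng.uniform(-1, 1))
        links.append(PlantedLink(enh, gid, mode, u))
    for gid in hu_targets:
        gene = by_gene[gid]
        u = float(2.0 ** rng.uniform(-1, 1))
        links.append(PlantedLink(proximal_interval(gene), gid, "proximal", u))
    return links


def simulate_counts(gene_means: np.ndarray, log2fc: np.ndarray,
                    samples: list[str], breeds: list[str],
                    dispersion: float, rng,
                    depth_range: tuple[float, float] = (0.8, 1.2)
                    ) -> pd.DataFrame:
    """Negative-binomial count matrix with a symmetric breed fold change.

    SH samples draw from mean * 2**(log2fc/2), HU samples from
    mean * 2**(-log2fc/2); per-sample depth factors are uniform in
    ``depth_range``. With dispersion ~ 0 the draws fall back to Poisson.
    """
    n_genes = len(gene_means)
    depth = rng.uniform(*depth_range, size=len(samples))
    cols = {}
    for s, sample in enumerate(samples):
        sign = 0.5 if breeds[s] == "SH" else -0.5
        mu = gene_means * (2.0 ** (sign * log2fc)) * depth[s]
        if dispersion > 1e-6:
            n = 1.0 / dispersion
            p = n / (n + mu)
            cols[sample] = rng.negative_binomial(n, p)
        else:
            cols[sample] = rng.poisson(mu)
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])


def simulate(config: SimulationConfig
             ) -> tuple[SyntheticDataset, SyntheticTruth]:
    """Generate the full two-breed dataset bundle and its answer key."""
    rngs = _rngs(config.seed)
    chrom_lengths = {f"chr{i + 1}": config.chrom_length
                     for i in range(config.n_chroms)}
    n_bins = config.chrom_length // config.bin_size
    bs = config.bin_size

    # --- genes and planted differential expression -------------------------
    genes = _place_genes(config, rngs["layout"])
    gene_ids = [g.gene_id for g in genes]
    if 2 * config.n_planted_deg > len(genes):
        raise InvalidParameterError("too many planted DEGs for n_genes")
    order = rngs["layout"].permutation(len(genes))
    sh_ids = [gene_ids[i] for i in order[:config.n_planted_deg]]
    hu_ids = [gene_ids[i]
              for i in order[config.n_planted_deg:2 * config.n_planted_deg]]
    deg_table = pd.DataFrame(
        {"gene_id": sh_ids + hu_ids,
         "direction": ["SH_up"] * len(sh_ids) + ["HU_up"] * len(hu_ids),
         "true_log2fc": ([config.deg_log2fc] * len(sh_ids)
                         + [-config.deg_log2fc] * len(hu_ids))})

    # --- enhancer->gene links ----------------------------------------------
    if config.n_bsr_sh or config.n_bsr_hu:
        links = plant_bsr_links(genes, deg_table, config, rngs["links"])
    else:
        links = []
    sh_links = [l for l in links if l.gene_id in set(sh_ids)]
    hu_links = [l for l in links if l.gene_id in set(hu_ids)]
    planted_bsr = ([(l.enhancer, "SH") for l in sh_links]
                   + [(l.enhancer, "HU") for l in hu_links])

    # --- state tracks -------------------------------------------------------
    guard = 3  # bins forced quiescent around each planted enhancer, both breeds
    tracks = {"HU": {}, "SH": {}}
    for chrom in chrom_lengths:
        base = _simulate_state_track(n_bins, config.n_states,
                                     config.self_transition, rngs["states"])
        tracks["HU"][chrom] = base.copy()
        tracks["SH"][chrom] = base.copy()
    for enh, breed in planted_bsr:
        a, b = enh.start // bs, enh.end // bs
        other = "HU" if breed == "SH" else "SH"
        for br in ("HU", "SH"):
            tracks[br][enh.chrom][max(a - guard, 0):b + guard] = QUI_STATE
        tracks[breed][enh.chrom][a:b] = ENH_STATE

    # --- binarized marks and peaks ------------------------------------------
    marks: dict[str, BinnedMarkMatrix] = {}
    peaks: dict[tuple[str, str], PeakSet] = {}
    rng_m = rngs["marks"]
    for breed in ("HU", "SH"):
        for rep in range(config.mark_replicates):
            sample = f"{breed}{rep + 1}"
            mats = {}
            for chrom in chrom_lengths:
                probs = config.emission[tracks[breed][chrom]]
                mats[chrom] = (rng_m.random(probs.shape) < probs
                               ).astype(np.uint8)
            mat = BinnedMarkMatrix(sample, bs, mats)
            marks[sample] = mat
            for mi, mark in enumerate(MARKS):
                ivs = []
                for chrom in chrom_lengths:
                    col = mat.matrices[chrom][:, mi]
                    change = np.flatnonzero(np.diff(col)) + 1
                    bounds = np.concatenate([[0], change, [len(col)]])
                    for s, e in zip(bounds[:-1], bounds[1:]):
                        if col[s]:
                            ivs.append(GenomicInterval(chrom, int(s) * bs,
                                                       int(e) * bs))
                peaks[(sample, mark)] = PeakSet(mark, sample, ivs)

    # --- continuous signal ---------------------------------------------------
    strength = {br: {c: np.ones(n_bins) for c in chrom_lengths}
                for br in ("HU", "SH")}
    for link, breed in [(l, "SH") for l in sh_links] + \
                       [(l, "HU") for l in hu_links]:
        a, b = link.enhancer.start // bs, link.enhancer.end // bs
        strength[breed][link.enhancer.chrom][a:b] = link.strength
    signals: dict[tuple[str, str], SignalTrack] = {}
    rng_s = rngs["signal"]
    shape = config.signal_gamma_shape
    for breed in ("HU", "SH"):
        for rep in range(config.mark_replicates):
            sample = f"{breed}{rep + 1}"
            for mi, mark in enumerate(MARKS):
                values = {}
                for chrom in chrom_lengths:
                    inten = (config.signal_baseline
                             + config.emission[tracks[breed][chrom], mi])
                    if mi == K27AC:
                        inten = inten * strength[breed][chrom]
                    noise = rng_s.gamma(shape, 1.0 / shape, size=n_bins)
                    values[chrom] = inten * noise
                signals[(sample, mark)] = SignalTrack(bs, values)

    # --- RNA counts and TPM ---------------------------------------------------
    rng_r = rngs["rna"]
    sig_b = config.baseline_expression_sigma
    sig_l = config.linked_expression_sigma
    base_noise = rng_r.lognormal(-sig_b ** 2 / 2, sig_b, size=len(genes))
    link_noise = rng_r.lognormal(-sig_l ** 2 / 2, sig_l, size=len(genes))
    gene_means = config.mean_depth * base_noise
    fc = np.zeros(len(genes))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for _, row in deg_table.iterrows():
        fc[idx[row["gene_id"]]] = row["true_log2fc"]
    for link in links:
        i = idx[link.gene_id]
        beta = (config.proximal_coupling if link.mode == "proximal"
                else config.loop_coupling)
        gene_means[i] = (config.mean_depth * (link.strength ** beta)
                         * link_noise[i])
    samples = config.rna_samples()
    breeds = [s.split("_")[0] for s in samples]
    counts = simulate_counts(gene_means, fc, samples, breeds,
                             config.nb_dispersion, rng_r)
    counts.index = gene_ids
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    tpm = compute_tpm(counts, lengths)
    sample_breeds = pd.Series(breeds, index=samples, name="breed")

    # --- methylation -----------------------------------------------------------
    rng_me = rngs["meth"]
    kappa = 20.0
    meth_rows = []
    means = np.clip(config.methylation_state_means, 0.02, 0.98)
    for chrom in chrom_lengths:
        n_cpg = config.chrom_length // 150
        pos = np.sort(rng_me.choice(config.chrom_length, size=n_cpg,
                                    replace=False))
        m = means[tracks["HU"][chrom][pos // bs]]
        frac = rng_me.beta(kappa * m, kappa * (1 - m))
        meth_rows.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "frac": frac}))
    methylation = pd.concat(meth_rows, ignore_index=True)

    # --- phenotypes -------------------------------------------------------------
    rng_p = rngs["pheno"]
    driver_pool = [g for g in sh_ids if not g.startswith("LOC")]
    drivers = sorted(driver_pool)[:3] if len(driver_pool) >= 3 else []
    pheno = {}
    if drivers:
        expr = np.log2(tpm.loc[drivers] + 1).mean(axis=0)
        z = ((expr - expr.mean()) / expr.std()).to_numpy()
    else:
        z = np.zeros(len(samples))
    for trait, (mean, slope, sd) in {
            "body_weight_100d": (28.0, 2.0, 0.6),
            "body_weight_120d": (35.0, 2.5, 0.7),
            "eye_muscle_area": (14.0, 1.8, 0.5)}.items():
        pheno[trait] = mean + slope * z + rng_p.normal(0, sd, len(samples))
    phenotypes = pd.DataFrame(pheno, index=samples)

    # --- loops -------------------------------------------------------------------
    rng_l = rngs["loops"]
    loops = []
    for link in sh_links:
        if link.mode != "loop":
            continue
        gene = next(g for g in genes if g.gene_id == link.gene_id)
        a = GenomicInterval(gene.chrom, max(gene.tss - 2_000, 0),
                            gene.tss + 2_000)
        b = GenomicInterval(link.enhancer.chrom, link.enhancer.start - 1_000,
                            link.enhancer.end + 1_000)
        first, second = (a, b) if a.start <= b.start else (b, a)
        loops.append(Loop(first, second))
    slots = _desert_slots(config)
    used = {c: sum(1 for l in sh_links if l.mode == "loop"
                   and l.enhancer.chrom == c) for c in slots}
    extra = config.n_loops - len(loops)
    chroms = sorted(chrom_lengths)
    ci = 0
    while extra > 0:
        chrom = chroms[ci % len(chroms)]
        free = slots[chrom][used[chrom]:]
        if len(free) < 2:
            ci += 1
            if all(len(slots[c][used[c]:]) < 2 for c in chroms):
                break
            continue
        a_base, b_base = free[0], free[1]
        used[chrom] += 2
        ja = int(rng_l.integers(0, 2_000))
        jb = int(rng_l.integers(0, 2_000))
        loops.append(Loop(GenomicInterval(chrom, a_base + ja, a_base + ja + 4_000),
                          GenomicInterval(chrom, b_base + jb, b_base + jb + 4_000)))
        extra -= 1
        ci += 1

    # --- genome sequence with planted motif instances -----------------------------
    genome = None
    if config.generate_sequence:
        rng_q = rngs["sequence"]
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        genome = {}
        arrays = {}
        for chrom in chrom_lengths:
            arrays[chrom] = alphabet[rng_q.integers(
                0, 4, size=config.chrom_length)].copy()
        motif = np.frombuffer(b"CTAAAAATAG", dtype=np.uint8)
        for link in sh_links:
            if rng_q.random() < config.motif_plant_prob:
                mid = (link.enhancer.start + link.enhancer.end) // 2
                arrays[link.enhancer.chrom][mid:mid + len(motif)] = motif
        for chrom, arr in arrays.items():
            genome[chrom] = arr.tobytes().decode("ascii")

    # --- read positions for the QC metrics -----------------------------------------
    rng_rd = rngs["reads"]
    read_positions: dict[tuple[str, str], list[tuple[str, int]]] = {}
    chrom_list = sorted(chrom_lengths)
    for (sample, mark), track in signals.items():
        weights = np.concatenate([track.values[c] for c in chrom_list])
        weights = weights / weights.sum()
        draws = rng_rd.choice(len(weights), size=config.reads_per_library,
                              p=weights)
        offsets = rng_rd.integers(0, bs, size=config.reads_per_library)
        pos_bp = draws * bs + offsets
        n_dup = int(config.duplicate_rate * config.reads_per_library)
        if n_dup:
            src = rng_rd.integers(0, config.reads_per_library, size=n_dup)
            dst = rng_rd.choice(config.reads_per_library, size=n_dup,
                                replace=False)
            pos_bp[dst] = pos_bp[src]
            draws[dst] = draws[src]
        out = []
        for bin_idx, p in zip(draws, pos_bp):
            ci = bin_idx // n_bins
            out.append((chrom_list[ci], int(p - ci * n_bins * bs)))
        read_positions[(sample, mark)] = out

    truth = SyntheticTruth(
        state_tracks=tracks,
        planted_bsr=planted_bsr,
        planted_deg=deg_table,
        planted_links=links,
        methylation_state_means=config.methylation_state_means.copy(),
        phenotype_genes=drivers,
    )
    dataset = SyntheticDataset(
        config=config, chrom_lengths=chrom_lengths, genes=genes, marks=marks,
        signals=signals, peaks=peaks, counts=counts, tpm=tpm,
        sample_breeds=sample_breeds, loops=loops, methylation=methylation,
        phenotypes=phenotypes, genome=genome, read_positions=read_positions)
    return dataset, truth
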