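# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `ovisepi`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and interval algebra

All coordinates are 0-based half-open internally (BED convention); GFF3 is
converted at the I/O boundary. Interval merging unions regions that overlap
or lie within a configurable `gap` (default 0, so book-ended intervals
merge, matching common merge-tool behaviour). Strand is carried but ignored
by the algebra; it matters only for TSS derivation and profile orientation.
Chromosome names are never normalised — a `chr1`/`1` mismatch should fail
loudly rather than silently drop intervals.

## Chromatin-state model

A K-state HMM over 200-bp bins with product-of-independent-Bernoulli
emissions for the five marks in fixed order (ATAC, H3K4me3, H3K27ac,
H3K4me1, H3K27me3). The 200-bp bin is the customary resolution for this
model family; it is configurable.

*Fitting.* Baum–Welch EM with Rabiner-scaled forward/backward recursions
(numba-compiled). The 5-bit mark pattern of each bin is collapsed to one of
32 observation codes, so the E-step accumulates sufficient statistics per
code and the emission update is exact. Emission probabilities are clipped
to [1e-6, 1 − 1e-6] in the M-step and wherever logs are taken; transition
rows and the initial distribution are floored at tiny positive values and
renormalised. The clip perturbs the likelihood by a negligible amount; the
code still asserts per-iteration monotonicity of the log-likelihood to a
relative 1e-6 and raises if it is violated. EM stops at |ΔLL| < `tol`
(default 1e-4; the pipeline uses 1e-3, which on the default synthetic
genome converges in ~20 iterations) or `max_iter`.

*Initialisation and labeling.* With the default 15 states the emission
matrix starts from a fixed prototype table encoding the semantics of the
standard state names (active promoter = ATAC+K4me3+K27ac; "Het" variants
lack ATAC; "Wk" variants are attenuated; EnhA = ATAC+K27ac+K4me1 without
K4me3; TssBiv = K4me3+K27me3; Repr = K27me3 only; Qui = nothing), perturbed
by seed-controlled uniform(±0.05) noise. This stabilises state identity
across seeds while leaving EM free to fit. After fitting, labels are
assigned by minimum-cost bijective matching (Hungarian algorithm,
Euclidean distance on emission rows) to the same prototype table, so
labeling is permutation-equivariant and works for models fitted from any
initialisation. The prototype values are a semantic reconstruction of the
conventional emission patterns, not measurements.

*Decoding.* Posterior-maximum per bin (forward–backward marginals) by
default, matching the behaviour of the standard segmentation tools;
Viterbi is available. One model is fitted jointly on all four mark samples
(both breeds pooled); each replicate is then decoded separately for
enhancer scoring, and each breed's replicate-union binarization (mark
present in either replicate) is decoded for the per-breed state summaries.

*Binarization.* Peak mode sets a bin on ≥ 1 bp peak overlap. Signal mode
applies a Poisson tail test per bin against the genome-wide mean rate
(p < 1e-4, values rounded to counts) — the classic binarization heuristic.

## Per-state summaries

Genome fractions, segment counts and mean lengths come from run-length
encoding of the decoded track; the "functional" fraction excludes the
quiescent state. Methylation per state is the unweighted mean of CpG
fractions falling in each state's territory (states without CpGs are
missing, never zero). TSS enrichment divides state frequency at each
offset bin by the genome-wide state frequency. Enrichment of states in DEG
territory is fold = (state share inside the gene-body ± 2 kb union) /
(genome-wide share); its empirical p comes from length- and
chromosome-matched uniform random placements (default 1,000 in the API,
200 in the pipeline run), with the +1/(n+1) small-sample correction. The
observed territory is a union, while permuted placements may overlap each
other; at the region densities involved the bias is far below Monte-Carlo
error.

## Differential expression

A deliberately minimal NB pipeline, re-implemented rather than delegated
(bit-identity with any external package is not claimed; correctness is
established by null calibration, planted-truth recovery and agreement with
an independent NB likelihood-ratio oracle in the test suite):

1. size factors by median-of-ratios over genes positive in every sample;
2. per-gene dispersion α by method of moments on normalised counts,
   pooled within groups, floored at 1e-8;
3. Wald statistic on Δlog2 of group means (pseudocount 0.5), delta-method
   standard error with Var(X) = μ + αμ², referred to **t(n₁+n₂−2)**. With
   2–3 replicates the plug-in dispersion is noisy and a normal reference is
   visibly anti-conservative; the t reference restores nominal type-I
   error (checked at 2,000 null genes in the suite).

Thresholds: |log2FC| > 1 ("fold change > 2"), nominal p < 0.05 (no
multiple-testing correction by default, as is customary when nominal
p-values are the stated criterion; Benjamini–Hochberg is available behind
a flag), and "expressed" = breed-mean TPM > 1 in at least one breed (the
per-sample and overall-mean readings of that filter are possible; the
breed-mean reading is the default and the threshold is configurable).
Genes with zero counts everywhere are `not_expressed` and never tested.
Swapping breed labels negates every log2FC and swaps up-calls exactly.

Phenotypes use the two-sided Wilcoxon rank-sum test: exact distribution
for both n ≤ 10 without ties, normal approximation with midrank tie
correction otherwise; all-equal data returns p = 1. Note that at n = 3 vs
3 the smallest achievable two-sided exact p is 0.1. Trait–gene association
uses Spearman correlation with 0.05/0.01 star notation.

## Breed-specific enhancers

Consensus = union-merge of the four replicates' EnhA segments. Scoring
uses ≥ 1 bp overlap by default (`min_overlap_bp`, `min_overlap_frac`
configurable) — the minimum-overlap convention of the interval tools this
mirrors. "Shared" strictly requires presence in all four replicates,
consistent with the strict two-replicate BSR definition; a relaxed mode
(≥ 1 replicate per breed) is behind a flag. Classification is symmetric
under breed-label swap by construction.

Signal profiles rescale each region to 20 interior bins plus ±3-kb flanks.
Motif analysis is a known-motif scan: PWMs (built-in myogenic trio
MEF2/E-box/AP-1, or a user library in a simple text format) are scored
log-odds against a uniform 0-order background on both strands; a region is
a hit at ≥ 80% of the motif's maximum achievable score; enrichment over a
within-chromosome shuffled background (seeded, foreground-avoiding) is a
2×2 Fisher exact test. De-novo discovery is out of scope.

## Enhancer→gene integration and the network

Proximal priority: promoter window (TSS −2000..+500, strand-oriented) →
gene body → nearest TSS within 100 kb (window configurable; both values
are common practice rather than measured constants), ties to the smaller
gene id. Loop targets: enhancer overlapping one anchor ≥ 1 bp paired with
every gene whose TSS lies in the partner anchor; an enhancer overlapping
both anchors of a loop gains nothing from it. The TSS (not the gene body)
must sit in the anchor — the stricter and less ambiguous reading.

Coverage = 100 × |union of proximal and loop target genes ∩ up-regulated
DEGs| / |considered up-regulated genes|, rounded to two decimals, with set
semantics. Gene ids beginning "LOC" (uncharacterised loci) are always
reported separately and excluded from the considered set only when
`drop_loc` is set; both denominators appear in the coverage report.

The co-expression network computes all-pairs Pearson r on log2(TPM+1)
(raw-TPM mode available), retains edges with r > 0.8 **and** two-sided
p < 0.05 (at n = 6 the p-filter is the binding one: the critical r is
≈ 0.811, so r = 0.805 is rejected), and ranks hubs by degree (top 3 by
default). Constant profiles are excluded and recorded on the graph.

## The synthetic epigenome

The generator emulates the two-breed muscle study design: per breed, 2
replicates of 5 binarized marks and 3 RNA replicates; defaults are 2
chromosomes × 5 Mb at 200-bp bins, 400 genes, 15 states with
self-transition 0.96 and the prototype table as the generating emissions,
40 SH- and 15 HU-specific planted enhancers (2 kb each), 60 planted
up-regulated genes per breed at log2FC 2.5, NB dispersion 0.1 at mean
depth 500, 50 loops, half of the SH enhancer links loop-mediated,
Beta-distributed methylation around per-state means (lowest at TssA,
highest at Repr/Qui), and phenotypes that are linear in three planted
genes' expression plus Gaussian noise. No effect-size distribution for
real breed differences is available to fit, so these are stated, fixed
study conditions, not estimates.

Design points worth knowing:

* **Layout.** Each chromosome gives its first 80% to genes (one per
  fixed-width cell, jittered) and the rest to a gene desert beginning
  110 kb after the last cell. Loop-linked enhancers and loop anchors live
  only in the desert, which guarantees loop-only links are invisible to
  proximal assignment and that decorative loops cannot create accidental
  enhancer–TSS pairs. Proximal enhancers sit 2–4 kb upstream of their
  target TSS, inside the target's cell.
* **Planting.** A planted enhancer writes an EnhA run into the owning
  breed's state track and forces quiescent in the other breed, with a
  3-bin quiescent guard band in both breeds so neighbouring background
  enhancers cannot fuse with it during consensus merging. Background
  chromatin is one shared Markov realisation per chromosome, so untouched
  regions are breed-concordant and false breed-specific calls come only
  from replicate sampling noise.
* **Coupling.** Each link carries a strength u (log2-uniform in ±1). The
  enhancer's H3K27ac intensity scales with u and the target's baseline
  expression with u^β, β = 2 for proximal and 1 for loop links, with
  smaller residual expression noise for linked genes. This encodes the
  qualitative expectation that distal (loop) regulation couples more
  weakly than proximal regulation, so the recovered correlation ordering
  has a known sign. Fold changes themselves are constant (±2.5/2 applied
  symmetrically to each breed), independent of u.
* **Signal and reads.** Continuous tracks are (0.1 + emission) × Gamma
  (shape 4, mean 1) — heavy-tailed, RPKM-like. "Peaks" are maximal runs of
  positive binarized bins (read-level peak calling is out of scope, so the
  generator produces peak-level truth directly). QC read positions are
  sampled from the signal with an 8% duplication rate, giving realistic
  NRF/PBC values; reads are single coordinates, as no alignment records
  exist anywhere in the package.
* **Sequence.** An i.i.d. uniform ACGT genome with a MEF2-like consensus
  planted in 70% of SH-specific enhancers, so known-motif enrichment has a
  planted positive.
* **Randomness.** One master seed spawns named substreams (layout, links,
  states, marks, signal, rna, meth, pheno, loops, sequence, reads) via
  `numpy.random.SeedSequence`, so identical configurations are
  bit-identical and adding draws to one stage never perturbs another.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: mappability and GC artefacts, fragment-size
structure, covariance between marks beyond state identity, realistic gene
length/expression distributions, isoforms, inter-individual variability
beyond NB dispersion, population structure of the breeds, and realistic
state-segment length distributions (the uniform off-diagonal transition
gives every non-self state the same expected run length). Recovery rates
measured here are upper bounds for real-data performance.

## Problem sizes and runtimes

The default conditions (50,000 genome bins, 4 mark samples, 400 genes)
were chosen so the complete pipeline finishes in seconds on one CPU and
the full test suite in well under a minute after numba compilation;
calibration checks use 2,000-gene simulations and the smaller
property-test configurations use a 1-Mb single chromosome. These sizes are
the package's own validation conditions; nothing prevents running the same
code at larger genomes.

## Known limitations

* The Wald/t small-sample correction is a pragmatic calibration device,
  not an exact likelihood treatment; borderline genes can differ from a
  full GLM analysis (the suite bounds this disagreement at 5%).
* `deg_state_enrichment` permutes placements independently per segment;
  territory overlaps in the null are ignored.
* `interval_set_jaccard` is O(n·m) over merged intervals — fine for
  enhancer-scale sets, not for genome-wide state sets.
* The HMM assumes conditionally independent marks given the state; real
  co-binding structure beyond state identity is not modelled.
* Headline counts from real sheep data (e.g. genome-wide state counts or
  BSR totals) are properties of that data and are deliberately not
  reproduction targets of the synthetic conditions.
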