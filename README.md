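# ovisepi

Epigenomic analysis toolkit for two-breed comparative designs in livestock,
modelled on the study layout used for crossbred (Suffolk × Hu, "SH") versus
purebred Hu ("HU") sheep muscle: chromatin-state segmentation of five
epigenetic marks, breed-specific active-enhancer (BSR EnhA) calling,
differential-expression filtering, enhancer→gene assignment (proximal and
chromatin-loop mediated) and a co-expression hub network — exercised
end-to-end on a synthetic epigenome generator with planted ground truth, so
every stage can be validated without any sequencing data.

It is written for computational biologists who want a transparent,
dependency-light re-implementation of this analysis style (the heavy
originals are ChromHMM-class segmenters, DESeq2-class testers and
bedtools-style interval plumbing) together with a simulator that knows the
right answers.

## The models at the core

**Chromatin states.** Five binarized marks (ATAC, H3K4me3, H3K27ac,
H3K4me1, H3K27me3) on 200-bp bins are segmented with a K = 15 hidden Markov
model whose emissions are products of independent Bernoullis: given state
k, mark m is present with probability e_km. Parameters (π, A, E) are fitted
by Baum–Welch EM in a scaled forward–backward implementation; bins are
decoded to their posterior-maximum state (Viterbi optional). States are
named by minimum-cost matching of fitted emission rows to a fixed prototype
table covering the standard vocabulary TssA … Qui (promoters, transcribed
flanks, the enhancer family, bivalent TSS, Polycomb-repressed, quiescent).

**Breed-specific enhancers.** EnhA segments from the four mark replicates
(HU1, HU2, SH1, SH2) are union-merged into a consensus set; each region is
scored 1 per replicate on ≥ 1 bp overlap. Score pattern (1,1,0,0) is
HU-specific, (0,0,1,1) SH-specific, all ones shared, anything else "other".

**Differential expression.** A minimal negative-binomial Wald pipeline:
median-of-ratios size factors, per-gene method-of-moments dispersion, Wald
statistic on log2 fold change referred to t(n₁+n₂−2). Calls use
|log2FC| > 1, nominal p < 0.05, and breed-mean TPM > 1.

**Integration.** SH-specific enhancers are assigned target genes by a
promoter → gene-body → nearest-TSS (≤ 100 kb) priority rule and through
chromatin-loop anchors (enhancer in one anchor, gene TSS in the partner).
The coverage statistic is the percentage of up-regulated genes reachable by
either route; candidate genes are wired into a Pearson co-expression
network (edges r > 0.8, p < 0.05; hubs = top-degree nodes).

## Worked example

```bash
ovisepi all -o run1 --seed 1
```

runs simulate → qc → diffexpr → segment → bsr → integrate on the default
design (two 5-Mb chromosomes, 400 genes, 2 mark replicates and 3 RNA
replicates per breed, 40 SH- and 15 HU-specific planted enhancers each
causally linked to a planted up-regulated gene, half of the SH links only
through a chromatin loop) and prints:

```
ovisepi pipeline report (seed 1)

QC: 20 libraries, all ENCODE-pass=True, min FRiP=0.684
Expression: 400/400 expressed; DEGs 119 (SH_up 60, HU_up 59)
Chromatin states: 15 states, converged=True in 21 iter
BSR: SH-specific 40, HU-specific 16, shared 125, other 12 of 193 consensus regions
Integration: union 40/60 SH-up genes covered = 66.67% (proximal r=0.8788, loop r=0.6932)
Network: 40 nodes, 759 edges, hubs: GENE0033, GENE0045, GENE0046
```

Reading this: all 20 simulated mark libraries pass the ENCODE complexity
thresholds (NRF > 0.7, PBC1 > 0.9, PBC2 > 3) with FRiP ≥ 0.68; the DEG
caller recovers essentially all 120 planted up-regulated genes (60 per
breed) with no excess; the segmentation recovers the full 15-state
vocabulary; BSR classification finds the 40 planted SH-specific enhancers
exactly and 16 HU-specific (15 planted plus one background fluctuation);
40 of the 60 SH-up genes are reachable from SH-specific enhancers (the 40
planted links), and the proximal signal–expression correlation exceeds the
loop-mediated one, as expected when distal coupling is weaker. Full tables
(DEG table, segmentation BEDs, state summaries, methylation-by-state,
consensus enhancers, target assignments, network edges) are written under
`run1/`, with a checksum manifest in `run1/run_manifest.json`.

Individual stages are also exposed (`ovisepi simulate|qc|diffexpr|segment|
bsr|integrate`), each a thin wrapper over the library API in
`ovisepi.genomic_io`, `ovisepi.synthetic_epigenome`, `ovisepi.qc_metrics`,
`ovisepi.expression`, `ovisepi.chromatin_states`, `ovisepi.bsr_enhancers`,
`ovisepi.integration_network` and `ovisepi.pipeline`.

## Scope

Read-level processing (trimming, alignment, deduplication, peak calling
from reads), de-novo motif discovery, GO/KEGG enrichment and Hi-C loop
calling are out of scope: peaks, loops and methylation arrive as standard
interval/track files (BED, BEDPE, bedGraph, GFF3, TSV), and motif analysis
is a transparent known-motif PWM scan with Fisher enrichment. See
`docs/methods.md` for the model details, generator assumptions and known
limitations.
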