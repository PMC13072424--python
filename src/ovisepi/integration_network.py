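"""Enhancer-to-gene assignment, DEG integration and the co-expression network.

Proximal assignment follows a priority rule: an enhancer overlapping a
promoter window (TSS -2000..+500, strand-oriented) is assigned to that
gene; failing that, overlap with a gene body assigns the gene; failing
that, the nearest TSS within a configurable window (default 100 kb) is
used, ties broken toward the lexicographically smaller gene id. Loop
assignment pairs an enhancer overlapping one anchor (>= 1 bp) with any
gene whose TSS lies in the partner anchor; an enhancer overlapping both
anchors of one loop yields nothing from that loop (self-loops excluded).

The coverage statistic is the percentage of the considered up-regulated
genes reachable from breed-specific enhancers through either route, with
set semantics (duplicate assignments do not inflate it).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .chromatin_states import (enhancer_expression_correlation,
                               mean_signal_over_intervals)
from .genomic_io import (GeneAnnotation, GenomicInterval,
                         InvalidParameterError, Loop, SignalTrack)

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class TargetAssignment:
    enhancer: GenomicInterval
    gene_id: str
    mode: str                 # "proximal" | "loop"
    distance: int | None      # bp for proximal assignments
    category: str | None = None   # promoter | gene_body | intergenic
    loop_index: int | None = None


def _promoter_window(gene: GeneAnnotation) -> GenomicInterval:
    if gene.interval.strand != "-":
        start, end = gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
    else:
        start, end = gene.tss - PROMOTER_DOWNSTREAM + 1, gene.tss + PROMOTER_UPSTREAM + 1
    return GenomicInterval(gene.chrom, max(start, 0), end)


def _point_distance(iv: GenomicInterval, pos: int) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def proximal_targets(enhancers: list[GenomicInterval],
                     annotation: list[GeneAnnotation],
                     window: int = 100_000) -> list[TargetAssignment]:
    """Assign each enhancer its proximal target gene by the priority rule.

    Enhancers with no gene within ``window`` yield an unassigned record
    (gene_id ""), keeping the enhancer accounted for in reports.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: g.tss)
    out = []
    for enh in enhancers:
        genes = by_chrom.get(enh.chrom, [])
        chosen, category, dist = None, None, None
        # priority 1: promoter window overlap
        prom_hits = [g for g in genes
                     if enh.intersection_length(_promoter_window(g)) >= 1]
        if prom_hits:
            chosen = min(prom_hits, key=lambda g: g.gene_id)
            category, dist = "promoter", _point_distance(enh, chosen.tss)
        else:
            body_hits = [g for g in genes
                         if enh.intersection_length(g.interval) >= 1]
            if body_hits:
                chosen = min(body_hits, key=lambda g: g.gene_id)
                category, dist = "gene_body", _point_distance(enh, chosen.tss)
            else:
                best = None
                for g in genes:
                    d = _point_distance(enh, g.tss)
                    if d <= window and (best is None or d < best[0]
                                        or (d == best[0]
                                            and g.gene_id < best[1].gene_id)):
                        best = (d, g)
                if best is not None:
                    dist, chosen = best
                    category = "intergenic"
        if chosen is None:
            out.append(TargetAssignment(enh, "", "proximal", None,
                                        "intergenic"))
        else:
            out.append(TargetAssignment(enh, chosen.gene_id, "proximal",
                                        dist, category))
    return out


def loop_targets(enhancers: list[GenomicInterval], loops: list[Loop],
                 annotation: list[GeneAnnotation]) -> list[TargetAssignment]:
    """Loop-mediated assignments: enhancer in one anchor, gene TSS in the
    partner anchor. An enhancer may gain multiple loop targets; a loop whose
    both anchors overlap the same enhancer contributes nothing."""
    out = []
    for li, loop in enumerate(loops):
        for enh in enhancers:
            in_a = enh.intersection_length(loop.anchor_a) >= 1
            in_b = enh.intersection_length(loop.anchor_b) >= 1
            if in_a and in_b:
                continue  # self-loop: enhancer spans both anchors
            if not (in_a or in_b):
                continue
            partner = loop.anchor_b if in_a else loop.anchor_a
            for g in annotation:
                if (g.chrom == partner.chrom
                        and partner.start <= g.tss < partner.end):
                    out.append(TargetAssignment(enh, g.gene_id, "loop",
                                                None, None, li))
    return out


def integrate_with_degs(assignments: list[TargetAssignment],
                        deg_table: pd.DataFrame,
                        up_status: str = "SH_up",
                        drop_loc: bool = False) -> dict:
    """Intersect enhancer target genes with up-regulated DEGs.

    ``deg_table`` must be indexed by gene id with a ``status`` column.
    Returns the proximal-overlap, loop-overlap and union gene sets plus the
    coverage statistic, reported against both the full up-regulated
    denominator and the non-LOC denominator (gene ids beginning "LOC" are
    flagged; they are excluded from the considered set when ``drop_loc``).
    """
    if len(deg_table) == 0:
        raise InvalidParameterError("empty DEG table")
    up_genes = set(deg_table.index[deg_table["status"] == up_status])
    if not up_genes:
        raise InvalidParameterError(f"no genes with status {up_status!r}")
    non_loc_up = {g for g in up_genes if not g.startswith("LOC")}
    proximal = {a.gene_id for a in assignments
                if a.mode == "proximal" and a.gene_id} & up_genes
    loop = {a.gene_id for a in assignments
            if a.mode == "loop" and a.gene_id} & up_genes
    union = proximal | loop
    considered = non_loc_up if drop_loc else up_genes
    union_considered = union & considered
    coverage = coverage_statistic(len(union_considered), len(considered))
    non_loc_cov = (coverage_statistic(len(union & non_loc_up), len(non_loc_up))
                   if non_loc_up else float("nan"))
    return {
        "proximal_genes": sorted(proximal),
        "loop_genes": sorted(loop),
        "union_genes": sorted(union),
        "n_proximal": len(proximal),
        "n_loop": len(loop),
        "n_union": len(union_considered),
        "n_considered": len(considered),
        "coverage_pct": coverage,
        "n_up_total": len(up_genes),
        "n_up_non_loc": len(non_loc_up),
        "coverage_pct_non_loc": non_loc_cov,
    }


def coverage_statistic(n_union: int, n_considered: int) -> float:
    """100 * covered / considered, rounded to 2 decimals."""
    if n_considered <= 0:
        raise InvalidParameterError("denominator must be positive")
    return round(100.0 * n_union / n_considered, 2)


def assignment_signal_expression(assignments: list[TargetAssignment],
                                 signal: SignalTrack,
                                 tpm: pd.Series,
                                 mode: str | None = None) -> dict:
    """Correlate per-assignment enhancer signal with target expression.

    Signal is the mean track value over each assignment's enhancer;
    expression is the target gene's TPM. Restricting ``mode`` to "loop"
    gives the loop-pair correlation. Fewer than 4 usable pairs
    yields NaNs.
    """
    xs, ys = [], []
    for a in assignments:
        if mode is not None and a.mode != mode:
            continue
        if not a.gene_id or a.gene_id not in tpm.index:
            continue
        xs.append(mean_signal_over_intervals(signal, [a.enhancer]))
        ys.append(float(tpm.loc[a.gene_id]))
    return enhancer_expression_correlation(xs, ys)


def coexpression_network(tpm_rows: pd.DataFrame, r_min: float = 0.8,
                         alpha: float = 0.05, log_transform: bool = True,
                         top_k_hubs: int = 3):
    """All-pairs Pearson co-expression network over candidate genes.

    Edges require r > r_min and two-sided p < alpha on log2(TPM+1)
    profiles (raw TPM with ``log_transform=False``). Returns
    (networkx.Graph, hubs) where hubs are the ``top_k_hubs`` genes by
    degree (degree then gene id as tie-break). Constant-profile genes are
    excluded with a warning attribute on the graph.
    """
    if tpm_rows.shape[0] < 3:
        raise InvalidParameterError("need >= 3 genes")
    if tpm_rows.shape[1] < 4:
        raise InvalidParameterError("need >= 4 samples")
    data = tpm_rows.to_numpy(dtype=float)
    if log_transform:
        data = np.log2(data + 1)
    keep = np.ptp(data, axis=1) > 0
    excluded = list(tpm_rows.index[~keep])
    genes = list(tpm_rows.index[keep])
    data = data[keep]
    G = nx.Graph()
    G.add_nodes_from(genes)
    G.graph["excluded_constant"] = excluded
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r, p = stats.pearsonr(data[i], data[j])
            if r > r_min and p < alpha:
                G.add_edge(genes[i], genes[j], r=float(r), p=float(p))
    hubs = sorted(G.nodes, key=lambda g: (-G.degree[g], g))[:top_k_hubs]
    return G, hubs


def network_edge_table(G: nx.Graph) -> pd.DataFrame:
    rows = [{"gene_a": a, "gene_b": b, "r": d["r"], "p": d["p"]}
            for a, b, d in G.edges(data=True)]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])
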