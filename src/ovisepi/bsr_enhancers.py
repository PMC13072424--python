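"""Breed-specific regulatory element (BSR) identification over EnhA segments.

A consensus set of non-redundant strong-active-enhancer (EnhA) regions is
built by union-merging the EnhA segments decoded from each of the four mark
replicates (HU1, HU2, SH1, SH2). Each consensus region is scored 1 against
a replicate iff that replicate's EnhA segments overlap it (>= 1 bp by
default), giving a binary score vector per region. Classification is
strict: a region is HU-specific iff its scores are (1,1,0,0), SH-specific
iff (0,0,1,1), shared iff present in all four replicates; every other
pattern is "other". A relaxed mode treats presence in at least one
replicate of each breed as shared.

Motif analysis is a transparent known-motif scan: position weight matrices
are scored log-odds against a 0-order background, a region is a hit when
its best window (either strand) reaches a fraction of the PWM's maximum
achievable score, and enrichment of foreground vs background regions is a
2x2 Fisher exact test. Backgrounds default to foreground intervals
shuffled within chromosomes avoiding the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_io import (GenomicInterval, InvalidParameterError,
                         GenomicValidationError, SignalTrack,
                         merge_intervals)

REPLICATE_ORDER = ("HU1", "HU2", "SH1", "SH2")
CLASSES = ("HU_specific", "SH_specific", "shared", "other")


@dataclass
class ConsensusEnhancerSet:
    """Non-redundant EnhA regions with per-replicate scores and classes."""

    intervals: list[GenomicInterval]
    scores: np.ndarray               # regions x 4, {0,1}, REPLICATE_ORDER
    classes: list[str]

    def __len__(self):
        return len(self.intervals)

    def class_intervals(self, cls: str) -> list[GenomicInterval]:
        return [iv for iv, c in zip(self.intervals, self.classes) if c == cls]

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for c in self.classes:
            out[c] += 1
        return out


def _overlap_flags(regions: list[GenomicInterval],
                   segments: list[GenomicInterval],
                   min_bp: int, min_frac: float) -> np.ndarray:
    """Per region, 1 iff any segment overlaps it by >= min_bp (and >=
    min_frac of the region length). Both inputs sorted per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda iv: iv.start)
    flags = np.zeros(len(regions), dtype=np.uint8)
    for i, region in enumerate(regions):
        segs = by_chrom.get(region.chrom, [])
        starts = [s.start for s in segs]
        lo = np.searchsorted(starts, region.start)
        # step back while previous segments may still reach into the region
        j = lo - 1
        need = max(min_bp, int(np.ceil(min_frac * region.length)))
        hit = False
        while j >= 0 and segs[j].end > region.start:
            if region.intersection_length(segs[j]) >= need:
                hit = True
                break
            j -= 1
        j = lo
        while not hit and j < len(segs) and segs[j].start < region.end:
            if region.intersection_length(segs[j]) >= need:
                hit = True
            j += 1
        flags[i] = 1 if hit else 0
    return flags


def _classify_pattern(hu1, hu2, sh1, sh2, relaxed_shared: bool) -> str:
    hu = (hu1, hu2)
    sh = (sh1, sh2)
    if hu == (1, 1) and sh == (0, 0):
        return "HU_specific"
    if hu == (0, 0) and sh == (1, 1):
        return "SH_specific"
    if relaxed_shared:
        if max(hu) and max(sh):
            return "shared"
    elif hu == (1, 1) and sh == (1, 1):
        return "shared"
    return "other"


def build_consensus(enha_by_replicate: dict[str, list[GenomicInterval]],
                    min_overlap_bp: int = 1,
                    min_overlap_frac: float = 0.0,
                    relaxed_shared: bool = False) -> ConsensusEnhancerSet:
    """Build, score and classify the consensus EnhA set.

    ``enha_by_replicate`` must carry the four replicates HU1, HU2, SH1, SH2
    (EnhA segment lists from each replicate's decoded segmentation).
    """
    missing = [r for r in REPLICATE_ORDER if r not in enha_by_replicate]
    if missing:
        raise InvalidParameterError(f"missing replicate lists: {missing}")
    if min_overlap_bp < 1:
        raise InvalidParameterError("min_overlap_bp must be >= 1")
    pooled = [iv for r in REPLICATE_ORDER for iv in enha_by_replicate[r]]
    consensus = merge_intervals(pooled)
    scores = np.zeros((len(consensus), 4), dtype=np.uint8)
    for ri, rep in enumerate(REPLICATE_ORDER):
        scores[:, ri] = _overlap_flags(consensus, enha_by_replicate[rep],
                                       min_overlap_bp, min_overlap_frac)
    classes = [_classify_pattern(*row, relaxed_shared) for row in scores]
    return ConsensusEnhancerSet(consensus, scores, classes)


def classify_bsr(consensus: ConsensusEnhancerSet
                 ) -> tuple[dict[str, list[GenomicInterval]], dict[str, int]]:
    """Partition the consensus set by class; returns (interval lists, counts)."""
    lists = {c: consensus.class_intervals(c) for c in CLASSES}
    return lists, consensus.class_counts()


def interval_set_jaccard(a: list[GenomicInterval],
                         b: list[GenomicInterval]) -> float:
    """Base-pair Jaccard index between two interval sets (after merging)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    inter = 0
    for iv in am:
        for jv in bm:
            inter += iv.intersection_length(jv)
    union = (sum(iv.length for iv in am) + sum(iv.length for iv in bm)
             - inter)
    return inter / union if union else float("nan")


def bsr_signal_profile(regions: list[GenomicInterval],
                       tracks: dict[str, SignalTrack],
                       flank: int = 3000, n_body_bins: int = 20):
    """Average H3K27ac signal across regions scaled to a common length.

    Each region is resampled to ``n_body_bins`` interior bins plus its
    flank bins on either side; tracks are keyed by breed. Returns
    ``(curves, heat)`` where curves maps breed -> mean profile vector and
    heat maps breed -> (regions x profile) matrix.
    """
    curves, heats = {}, {}
    for breed, track in tracks.items():
        bs = track.bin_size
        if flank % bs:
            raise InvalidParameterError("flank must be a multiple of bin_size")
        fl = flank // bs
        rows = []
        for iv in regions:
            arr = track.values.get(iv.chrom)
            if arr is None:
                continue
            a, b = iv.start // bs, max(-(-iv.end // bs), iv.start // bs + 1)
            body = arr[max(a, 0):min(b, len(arr))]
            if len(body) == 0:
                continue
            # resample the body to a fixed number of bins
            src = np.linspace(0, len(body), n_body_bins + 1)
            resampled = np.array([
                body[int(src[i]):max(int(src[i + 1]), int(src[i]) + 1)].mean()
                for i in range(n_body_bins)])
            left = np.full(fl, np.nan)
            right = np.full(fl, np.nan)
            li = np.arange(a - fl, a)
            ri = np.arange(b, b + fl)
            ok = (li >= 0) & (li < len(arr))
            left[ok] = arr[li[ok]]
            ok = (ri >= 0) & (ri < len(arr))
            right[ok] = arr[ri[ok]]
            rows.append(np.concatenate([left, resampled, right]))
        heat = np.array(rows) if rows else np.empty((0, 2 * fl + n_body_bins))
        heats[breed] = heat
        with np.errstate(invalid="ignore"):
            curves[breed] = (np.nanmean(heat, axis=0) if len(heat)
                             else np.full(2 * fl + n_body_bins, np.nan))
    return curves, heats


# ---------------------------------------------------------------------------
# known-motif enrichment
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PWM:
    """A position weight matrix of base probabilities, 4 rows (ACGT) x L."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise InvalidParameterError("PWM matrix must be 4 x L")
        sums = self.matrix.sum(axis=0)
        if (sums <= 0).any():
            raise InvalidParameterError("PWM columns must have positive sums")
        self.matrix = self.matrix / sums

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = (np.full(4, 0.25) if background is None
              else np.asarray(background, dtype=float))
        return np.log2(np.clip(self.matrix, 1e-6, None) / bg[:, None])

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=0).sum())


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    foreground_hits: int
    foreground_total: int
    background_hits: int
    background_total: int
    odds_ratio: float
    p_value: float


def pwm_from_consensus(motif_id: str, consensus: str,
                       match_prob: float = 0.85) -> PWM:
    """A PWM putting ``match_prob`` on the consensus base at each position."""
    L = len(consensus)
    m = np.full((4, L), (1 - match_prob) / 3)
    for i, base in enumerate(consensus.upper()):
        m[_BASE_INDEX[base], i] = match_prob
    return PWM(motif_id, m)


def builtin_motif_library() -> list[PWM]:
    """A small library of myogenesis-relevant consensus motifs."""
    return [
        pwm_from_consensus("MEF2", "CTAAAAATAG"),
        pwm_from_consensus("MYOD_Ebox", "CAGCTG"),
        pwm_from_consensus("AP1", "TGACTCA"),
    ]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def pwm_scan_max(pwm: PWM, seq: str, both_strands: bool = True) -> float:
    """Best log-odds window score of a PWM over a sequence (both strands)."""
    lo = pwm.log_odds()
    best = -np.inf
    for s in ([seq, seq[::-1].translate(_COMPLEMENT)] if both_strands
              else [seq]):
        enc = _encode(s)
        L = pwm.length
        if len(enc) < L:
            continue
        # column-gather score for every window
        scores = np.zeros(len(enc) - L + 1)
        valid = np.ones(len(enc) - L + 1, dtype=bool)
        for j in range(L):
            col = enc[j:len(enc) - L + 1 + j]
            bad = col < 0
            valid &= ~bad
            scores += np.where(bad, 0.0, lo[np.clip(col, 0, 3), j])
        if valid.any():
            best = max(best, float(scores[valid].max()))
    return best


def shuffle_background(foreground: list[GenomicInterval],
                       chrom_lengths: dict[str, int], seed: int = 0,
                       max_tries: int = 200) -> list[GenomicInterval]:
    """Length- and chromosome-matched background intervals placed uniformly
    at random while avoiding the foreground."""
    rng = np.random.default_rng(seed)
    merged = merge_intervals(foreground)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in foreground:
        L = chrom_lengths[iv.chrom]
        placed = None
        for _ in range(max_tries):
            start = int(rng.integers(0, max(L - iv.length, 1)))
            cand = GenomicInterval(iv.chrom, start, start + iv.length)
            if all(cand.intersection_length(f) == 0
                   for f in by_chrom.get(iv.chrom, [])):
                placed = cand
                break
        if placed is None:
            raise InvalidParameterError(
                f"could not place background interval on {iv.chrom}")
        out.append(placed)
    return out


def known_motif_enrichment(foreground: list[GenomicInterval],
                           background: list[GenomicInterval],
                           genome: dict[str, str],
                           motifs: list[PWM],
                           score_fraction: float = 0.8
                           ) -> list[MotifEnrichmentResult]:
    """Fisher-exact enrichment of known motifs in foreground vs background.

    A region is a hit for a motif when its best window log-odds score (on
    either strand) reaches ``score_fraction`` of that motif's maximum
    achievable score.
    """
    def seqs(intervals):
        out = []
        for iv in intervals:
            if iv.chrom not in genome:
                raise GenomicValidationError(f"no sequence for {iv.chrom}")
            if iv.end > len(genome[iv.chrom]):
                raise GenomicValidationError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} outside sequence")
            out.append(genome[iv.chrom][iv.start:iv.end])
        return out

    fg_seqs, bg_seqs = seqs(foreground), seqs(background)
    results = []
    for pwm in motifs:
        threshold = score_fraction * pwm.max_score()
        fg_hits = sum(pwm_scan_max(pwm, s) >= threshold for s in fg_seqs)
        bg_hits = sum(pwm_scan_max(pwm, s) >= threshold for s in bg_seqs)
        table = [[fg_hits, len(fg_seqs) - fg_hits],
                 [bg_hits, len(bg_seqs) - bg_hits]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(MotifEnrichmentResult(
            pwm.motif_id, fg_hits, len(fg_seqs), bg_hits, len(bg_seqs),
            float(odds), float(p)))
    return results


def read_pwm_library(path) -> list[PWM]:
    """Read PWMs from a simple text format::

        >MOTIF_ID
        a1 a2 ... aL
        c1 c2 ... cL
        g1 g2 ... gL
        t1 t2 ... tL
    """
    motifs = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    motifs.append(PWM(name, np.array(rows)))
                name, rows = line[1:].split()[0], []
            else:
                rows.append([float(x) for x in line.split()])
    if name is not None:
        motifs.append(PWM(name, np.array(rows)))
    return motifs


def write_pwm_library(path, motifs: list[PWM]) -> None:
    with open(path, "w") as fh:
        for pwm in motifs:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write(" ".join(format(v, ".6g") for v in row) + "\n")
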