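"""Library-quality and cross-assay consistency metrics.

"Read positions" throughout are single genomic coordinates (read 5' ends);
no alignment records exist in this package's scope. PBC2 with no position
seen exactly twice is reported as +inf with a flag, following the ENCODE
reporting convention, rather than raising.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import InvalidParameterError, PeakSet, SignalTrack


@dataclass
class LibraryQC:
    """ENCODE-style complexity metrics and fraction of reads in peaks."""

    nrf: float
    pbc1: float
    pbc2: float
    pbc2_undefined: bool = False
    frip: float | None = None

    def passes_encode(self) -> bool:
        """The customary thresholds: NRF > 0.7, PBC1 > 0.9, PBC2 > 3."""
        pbc2_ok = self.pbc2_undefined or self.pbc2 > 3
        return self.nrf > 0.7 and self.pbc1 > 0.9 and pbc2_ok


def complexity_metrics(read_positions) -> LibraryQC:
    """NRF/PBC1/PBC2 from a list of (chrom, pos) read coordinates.

    NRF = distinct positions / total reads;
    PBC1 = positions seen exactly once / distinct positions;
    PBC2 = positions seen once / positions seen twice (+inf when none seen
    twice, flagged).
    """
    positions = list(read_positions)
    if not positions:
        raise InvalidParameterError("empty read-position list")
    counts = Counter(positions)
    total = len(positions)
    distinct = len(counts)
    ones = sum(1 for v in counts.values() if v == 1)
    twos = sum(1 for v in counts.values() if v == 2)
    undefined = twos == 0
    return LibraryQC(
        nrf=distinct / total,
        pbc1=ones / distinct,
        pbc2=float("inf") if undefined else ones / twos,
        pbc2_undefined=undefined,
    )


def frip(read_positions, peaks: PeakSet) -> float:
    """Fraction of read positions falling inside any peak (half-open)."""
    positions = list(read_positions)
    if not positions:
        return 0.0
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in peaks.intervals:
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
    # merge-sorted arrays; peaks may overlap, so collapse first
    merged = {}
    for chrom in starts:
        s = np.asarray(starts[chrom])
        e = np.asarray(ends[chrom])
        order = np.argsort(s)
        s, e = s[order], e[order]
        keep_s, keep_e = [], []
        for a, b in zip(s, e):
            if keep_e and a <= keep_e[-1]:
                keep_e[-1] = max(keep_e[-1], b)
            else:
                keep_s.append(a)
                keep_e.append(b)
        merged[chrom] = (np.asarray(keep_s), np.asarray(keep_e))
    inside = 0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, pos in by_chrom.items():
        if chrom not in merged:
            continue
        s, e = merged[chrom]
        p = np.asarray(pos)
        idx = np.searchsorted(s, p, side="right") - 1
        ok = idx >= 0
        inside += int((p[ok] < e[idx[ok]]).sum())
    return inside / len(positions)


def rebin_track(track: SignalTrack, bin_size: int) -> SignalTrack:
    """Re-bin a track by summing, allocating source bins to target bins in
    proportion to base-pair overlap (handles non-divisible bin sizes)."""
    if bin_size <= 0:
        raise InvalidParameterError("bin_size must be positive")
    if bin_size == track.bin_size:
        return track
    out = {}
    for chrom, arr in track.values.items():
        length = len(arr) * track.bin_size
        n_new = -(-length // bin_size)
        new = np.zeros(n_new)
        src_starts = np.arange(len(arr)) * track.bin_size
        src_ends = src_starts + track.bin_size
        first = src_starts // bin_size
        last = (src_ends - 1) // bin_size
        same = first == last
        np.add.at(new, first[same], arr[same])
        for i in np.flatnonzero(~same):
            a, b = src_starts[i], src_ends[i]
            for j in range(first[i], last[i] + 1):
                lo = max(a, j * bin_size)
                hi = min(b, (j + 1) * bin_size)
                new[j] += arr[i] * (hi - lo) / track.bin_size
        out[chrom] = new
    return SignalTrack(bin_size=bin_size, values=out)


def binned_correlation(tracks: dict[str, SignalTrack],
                       bin_size: int = 500) -> pd.DataFrame:
    """Pearson correlation matrix of tracks over fixed genomic bins.

    Tracks are re-binned to ``bin_size`` by (proportional) summing. The
    matrix is symmetric with unit diagonal; a zero-variance track yields
    NaN against every other track rather than 0.
    """
    if len(tracks) < 2:
        raise InvalidParameterError("need at least two tracks")
    names = list(tracks)
    vectors = []
    for name in names:
        t = rebin_track(tracks[name], bin_size)
        vectors.append(t.concatenated())
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise InvalidParameterError("tracks span different genomes")
    data = np.vstack(vectors)
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=names, columns=names)


def meta_profile(signal: SignalTrack, anchors, flank: int) -> np.ndarray:
    """Average signal in bins around anchor positions.

    ``anchors`` holds (chrom, pos, strand) tuples; minus-strand windows are
    reversed so that the profile is in the 5'->3' orientation of the anchor.
    Windows running off a chromosome end are truncated, and each offset is
    averaged over the anchors that actually cover it. Returns a vector of
    length 2*flank/bin_size + 1.
    """
    if flank % signal.bin_size:
        raise InvalidParameterError("flank must be a multiple of bin_size")
    w = flank // signal.bin_size
    n_off = 2 * w + 1
    sums = np.zeros(n_off)
    cover = np.zeros(n_off)
    for chrom, pos, strand in anchors:
        if chrom not in signal.values:
            continue
        arr = signal.values[chrom]
        center = pos // signal.bin_size
        offs = np.arange(-w, w + 1)
        idx = center + (offs if strand != "-" else -offs)
        ok = (idx >= 0) & (idx < len(arr))
        sums[ok] += arr[idx[ok]]
        cover[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cover > 0, sums / cover, np.nan)
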