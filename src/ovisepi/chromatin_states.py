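"""Chromatin-state segmentation and per-state summaries.

The segmentation model is a K-state hidden Markov model whose emissions are
products of independent Bernoulli variables, one per epigenetic mark
(ATAC, H3K4me3, H3K27ac, H3K4me1, H3K27me3), fitted by Baum-Welch EM on
binarized 200-bp bins. States are then given the standard functional
vocabulary (TssA ... Qui) by minimum-cost matching of the fitted emission
rows against a fixed 15-row prototype table.

The prototype table encodes the semantics of the state names: "Het" states
lack ATAC accessibility, "Wk" states have attenuated marks, the bivalent
promoter state carries both H3K4me3 and H3K27me3, and the quiescent state
carries nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from . import _hmm_kernels as _k
from .genomic_io import (MARKS, GenomicInterval, InvalidParameterError,
                         GenomicValidationError, PeakSet, SignalTrack,
                         merge_intervals)

N_MARKS = len(MARKS)
N_CODES = 2 ** N_MARKS
_CODE_WEIGHTS = (2 ** np.arange(N_MARKS)).astype(np.int64)

STATE_NAMES = (
    "TssA", "TssAWk", "TssAHet", "TxFlnk", "TxFlnkHet", "TxFlnkWk",
    "EnhA", "EnhAHet", "EnhAMe", "EnhAWk", "EnhPois", "ATAC_Is",
    "TssBiv", "Repr", "Qui",
)

# Prototype emission rows (ATAC, H3K4me3, H3K27ac, H3K4me1, H3K27me3)
# used for state labeling and EM initialisation.
PROTOTYPE_EMISSIONS = np.array([
    [1.0, 1.0, 1.0, 0.5, 0.0],   # TssA
    [0.5, 0.5, 0.5, 0.5, 0.0],   # TssAWk
    [0.0, 1.0, 1.0, 0.5, 0.0],   # TssAHet
    [1.0, 0.5, 0.5, 1.0, 0.0],   # TxFlnk
    [0.0, 0.5, 0.5, 1.0, 0.0],   # TxFlnkHet
    [0.5, 0.5, 0.0, 0.5, 0.0],   # TxFlnkWk
    [1.0, 0.0, 1.0, 1.0, 0.0],   # EnhA
    [0.0, 0.0, 1.0, 1.0, 0.0],   # EnhAHet
    [1.0, 0.0, 0.5, 0.5, 0.0],   # EnhAMe
    [0.5, 0.0, 0.5, 1.0, 0.0],   # EnhAWk
    [0.0, 0.0, 0.0, 1.0, 1.0],   # EnhPois
    [1.0, 0.0, 0.0, 0.0, 0.0],   # ATAC_Is
    [0.5, 1.0, 0.0, 0.0, 1.0],   # TssBiv
    [0.0, 0.0, 0.0, 0.0, 1.0],   # Repr
    [0.0, 0.0, 0.0, 0.0, 0.0],   # Qui
])

_EPS = 1e-6


# ---------------------------------------------------------------------------
# binned data
# ---------------------------------------------------------------------------

@dataclass
class BinnedMarkMatrix:
    """Per-bin binary presence of the five marks for one sample."""

    sample_id: str
    bin_size: int
    matrices: dict[str, np.ndarray]  # chrom -> (n_bins, 5) uint8

    def __post_init__(self):
        for chrom, m in self.matrices.items():
            m = np.ascontiguousarray(m, dtype=np.uint8)
            if m.ndim != 2 or m.shape[1] != N_MARKS:
                raise GenomicValidationError(
                    f"{chrom}: expected (bins, {N_MARKS}) matrix, got {m.shape}")
            if m.max(initial=0) > 1:
                raise GenomicValidationError(f"{chrom}: entries must be 0/1")
            self.matrices[chrom] = m

    @property
    def chroms(self) -> list[str]:
        return sorted(self.matrices)

    def codes(self) -> dict[str, np.ndarray]:
        """5-bit observation code per bin (ATAC is the least significant bit)."""
        return {c: (self.matrices[c].astype(np.int64) @ _CODE_WEIGHTS)
                for c in self.matrices}


def binarize_peaks(peaks: PeakSet, bin_size: int,
                   chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Binary per-bin vector: 1 iff the bin is overlapped >= 1 bp by a peak."""
    out = {c: np.zeros(-(-length // bin_size), dtype=np.uint8)
           for c, length in chrom_lengths.items()}
    for iv in peaks.intervals:
        if iv.chrom not in out:
            continue
        first = iv.start // bin_size
        last = -(-iv.end // bin_size)
        out[iv.chrom][first:last] = 1
    return out


def binarize_signal(track: SignalTrack, p_threshold: float = 1e-4
                    ) -> dict[str, np.ndarray]:
    """Binary per-bin vector from a continuous track via a Poisson tail test.

    A bin is set iff P(X >= x) < p_threshold for X ~ Poisson(lambda) with
    lambda the genome-wide mean bin value; bin values are rounded to counts.
    """
    lam = float(np.mean(track.concatenated()))
    out = {}
    for chrom, arr in track.values.items():
        if len(arr) == 0 or lam == 0:
            out[chrom] = np.zeros(len(arr), dtype=np.uint8)
            continue
        k = np.round(arr).astype(np.int64)
        pvals = stats.poisson.sf(k - 1, lam)  # P(X >= k)
        out[chrom] = (pvals < p_threshold).astype(np.uint8)
    if all(v.sum() == 0 for v in out.values()):
        warnings.warn("binarize_signal produced an all-zero matrix")
    return out


def assemble_mark_matrix(sample_id: str, bin_size: int,
                         per_mark: dict[str, dict[str, np.ndarray]]
                         ) -> BinnedMarkMatrix:
    """Stack per-mark binary vectors (keyed by assay) into one sample matrix."""
    missing = [m for m in MARKS if m not in per_mark]
    if missing:
        raise InvalidParameterError(f"missing marks: {missing}")
    chroms = sorted(per_mark[MARKS[0]])
    matrices = {c: np.stack([per_mark[m][c] for m in MARKS], axis=1)
                for c in chroms}
    return BinnedMarkMatrix(sample_id, bin_size, matrices)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ChromatinStateModel:
    """A fitted multivariate-Bernoulli HMM with functional state labels."""

    initial: np.ndarray          # (K,)
    transition: np.ndarray       # (K, K)
    emission: np.ndarray         # (K, 5) Bernoulli success probabilities
    labels: list[str] | None = None
    loglik_history: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def n_states(self) -> int:
        return len(self.initial)

    def validate(self):
        if not np.allclose(self.transition.sum(axis=1), 1, atol=1e-8):
            raise GenomicValidationError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1, atol=1e-8):
            raise GenomicValidationError("initial probabilities must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise GenomicValidationError("emission entries must lie in [0, 1]")


def emission_code_table(emission: np.ndarray) -> np.ndarray:
    """(K, 32) likelihood of each 5-bit observation code under each state."""
    E = np.clip(emission, _EPS, 1 - _EPS)
    codes = np.arange(N_CODES)
    bits = ((codes[:, None] >> np.arange(N_MARKS)) & 1).astype(float)  # (32, 5)
    logB = bits @ np.log(E).T + (1 - bits) @ np.log1p(-E).T            # (32, K)
    return np.exp(logB).T.copy()


def _as_code_sequences(data) -> list[np.ndarray]:
    seqs = []
    for item in data:
        if isinstance(item, BinnedMarkMatrix):
            for chrom in item.chroms:
                seqs.append(item.codes()[chrom])
        else:
            arr = np.asarray(item)
            if arr.ndim == 2:
                if arr.shape[1] != N_MARKS:
                    raise InvalidParameterError(
                        f"expected {N_MARKS} mark columns, got {arr.shape[1]}")
                seqs.append(arr.astype(np.int64) @ _CODE_WEIGHTS)
            else:
                seqs.append(arr.astype(np.int64))
    if not seqs:
        raise InvalidParameterError("no input sequences")
    return seqs


class BernoulliHMM:
    """Multivariate Bernoulli-emission HMM fitted by Baum-Welch EM.

    Parameters
    ----------
    n_states : number of hidden states (default 15).
    seed : controls the EM initialisation jitter; fitting is deterministic
        given the seed and input order.
    max_iter, tol : EM stops when |delta log-likelihood| < tol or after
        max_iter iterations.
    init_emission : optional (K, 5) starting emission matrix. With the
        default 15 states the prototype table is used, perturbed by
        uniform(+/-0.05) noise so that state identity is stable while EM
        remains free to move the parameters.
    """

    def __init__(self, n_states: int = 15, seed: int = 0, max_iter: int = 200,
                 tol: float = 1e-4, init_emission: np.ndarray | None = None):
        if n_states < 1:
            raise InvalidParameterError("n_states must be >= 1")
        self.n_states = n_states
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.init_emission = init_emission

    def _initial_params(self):
        K = self.n_states
        rng = np.random.default_rng(self.seed)
        if self.init_emission is not None:
            E = np.asarray(self.init_emission, dtype=float).copy()
        elif K == len(STATE_NAMES):
            E = PROTOTYPE_EMISSIONS + rng.uniform(-0.05, 0.05,
                                                  PROTOTYPE_EMISSIONS.shape)
        else:
            E = rng.uniform(0.2, 0.8, size=(K, N_MARKS))
        E = np.clip(E, 0.02, 0.98)
        pi = np.full(K, 1.0 / K)
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
        A /= A.sum(axis=1, keepdims=True)
        return pi, A, E

    def fit(self, data, label: bool = True) -> ChromatinStateModel:
        """Fit on a list of BinnedMarkMatrix (or raw (T, 5) binary arrays)."""
        seqs = _as_code_sequences(data)
        total_bins = sum(len(s) for s in seqs)
        pi, A, E = self._initial_params()
        if all((np.asarray(s) == 0).all() for s in seqs):
            warnings.warn("all-zero input data; model is degenerate")
        history: list[float] = []
        converged = False
        n_iter = 0
        for it in range(self.max_iter):
            B = emission_code_table(E)
            ll = 0.0
            pi_acc = np.zeros(self.n_states)
            xi_acc = np.zeros((self.n_states, self.n_states))
            cg_acc = np.zeros((self.n_states, N_CODES))
            gs_acc = np.zeros(self.n_states)
            for codes in seqs:
                sll, g0, xi, cg, gs = _k.em_accumulate(
                    codes, pi, A, B, N_CODES)
                ll += sll
                pi_acc += g0
                xi_acc += xi
                cg_acc += cg
                gs_acc += gs
            if history and ll < history[-1] - 1e-6 * (1 + abs(history[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{history[-1]:.6f} -> {ll:.6f}")
            history.append(ll)
            n_iter = it + 1
            if len(history) > 1 and abs(history[-1] - history[-2]) < self.tol:
                converged = True
                break
            # M-step
            pi = pi_acc / pi_acc.sum()
            if self.n_states > 1:
                row = xi_acc.sum(axis=1, keepdims=True)
                A = np.where(row > 0, xi_acc / np.maximum(row, 1e-300), A)
                A = np.clip(A, 1e-12, None)
                A /= A.sum(axis=1, keepdims=True)
            bits = ((np.arange(N_CODES)[:, None] >> np.arange(N_MARKS)) & 1
                    ).astype(float)
            with np.errstate(invalid="ignore"):
                E = (cg_acc @ bits) / np.maximum(gs_acc[:, None], 1e-300)
            E = np.clip(E, _EPS, 1 - _EPS)
            pi = np.clip(pi, 1e-12, None)
            pi /= pi.sum()
        model = ChromatinStateModel(
            initial=pi, transition=A, emission=E,
            loglik_history=history, converged=converged, n_iter=n_iter)
        model.validate()
        if label and self.n_states == len(STATE_NAMES):
            model = label_states(model)
        self.model_ = model
        self._total_bins = total_bins
        return model


def loglikelihood(model: ChromatinStateModel, data, direction: str = "forward"
                  ) -> float:
    """Total data log-likelihood via the forward or the backward recursion."""
    B = emission_code_table(model.emission)
    total = 0.0
    for codes in _as_code_sequences(data):
        if direction == "forward":
            _, _, ll = _k.forward_scaled(codes, model.initial,
                                         model.transition, B)
        elif direction == "backward":
            ll = _k.backward_loglik(codes, model.initial, model.transition, B)
        else:
            raise InvalidParameterError(f"unknown direction {direction!r}")
        total += ll
    return total


def posterior_marginals(model: ChromatinStateModel, codes: np.ndarray
                        ) -> tuple[np.ndarray, float]:
    """Forward-backward posterior state probabilities for one sequence."""
    B = emission_code_table(model.emission)
    return _k.posterior(np.asarray(codes, dtype=np.int64),
                        model.initial, model.transition, B)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    """Per-bin decoded states, run-length encodable into state segments."""

    bin_size: int
    states: dict[str, np.ndarray]   # chrom -> int array of state indices
    labels: list[str]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.states)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def segments(self) -> list[tuple[str, int, int, int]]:
        """(chrom, start_bp, end_bp, state_index) runs tiling each chromosome."""
        out = []
        for chrom in self.chroms:
            s = self.states[chrom]
            if len(s) == 0:
                continue
            change = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(s)]])
            for a, b in zip(starts, ends):
                out.append((chrom, int(a) * self.bin_size,
                            int(b) * self.bin_size, int(s[a])))
        return out

    def state_intervals(self, state: int | str) -> list[GenomicInterval]:
        """Merged genomic intervals occupied by one state."""
        if isinstance(state, str):
            state = self.labels.index(state)
        ivs = [GenomicInterval(c, s, e) for c, s, e, st in self.segments()
               if st == state]
        return merge_intervals(ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, st in self.segments():
                fh.write(f"{chrom}\t{start}\t{end}\t{self.labels[st]}\n")

    def genome_bins(self) -> int:
        return sum(len(v) for v in self.states.values())


def decode(model: ChromatinStateModel, sample: BinnedMarkMatrix,
           method: str = "posterior") -> Segmentation:
    """Decode one sample's bins into states.

    ``posterior`` (default) assigns each bin its posterior-maximum state
    from the forward-backward marginals; ``viterbi`` returns the single most
    probable path.
    """
    if model.emission.shape[1] != N_MARKS:
        raise InvalidParameterError("model/data mark-count mismatch")
    labels = model.labels or [f"S{i + 1}" for i in range(model.n_states)]
    B = emission_code_table(model.emission)
    states = {}
    for chrom, codes in sample.codes().items():
        if method == "posterior":
            gamma, _ = _k.posterior(codes, model.initial, model.transition, B)
            states[chrom] = np.argmax(gamma, axis=1).astype(np.int16)
        elif method == "viterbi":
            states[chrom] = _k.viterbi(codes, model.initial,
                                       model.transition, B).astype(np.int16)
        else:
            raise InvalidParameterError(f"unknown decode method {method!r}")
    return Segmentation(sample.bin_size, states, list(labels))


def label_states(model: ChromatinStateModel) -> ChromatinStateModel:
    """Assign functional labels by minimum-cost bijective matching of the
    fitted emission rows to the prototype table (Euclidean distance)."""
    K = model.n_states
    if K != len(STATE_NAMES):
        raise InvalidParameterError(
            f"labeling requires {len(STATE_NAMES)} states, got {K}")
    d = np.linalg.norm(model.emission[:, None, :]
                       - PROTOTYPE_EMISSIONS[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    labels = [""] * K
    for r, c in zip(rows, cols):
        labels[r] = STATE_NAMES[c]
    model.labels = labels
    return model


# ---------------------------------------------------------------------------
# per-state summaries
# ---------------------------------------------------------------------------

def state_summary(seg: Segmentation, functional_exclude: tuple[str, ...] = ("Qui",)):
    """Segment counts, mean lengths and genome fraction per labeled state.

    Returns a dict keyed by label with ``n_segments``, ``mean_length_bp``
    and ``genome_fraction``, plus the aggregate ``functional_fraction``
    (all states except the quiescent background).
    """
    segs = seg.segments()
    genome_bp = seg.genome_bins() * seg.bin_size
    per = {lab: {"n_segments": 0, "total_bp": 0} for lab in seg.labels}
    for chrom, start, end, st in segs:
        d = per[seg.labels[st]]
        d["n_segments"] += 1
        d["total_bp"] += end - start
    out = {}
    for lab, d in per.items():
        out[lab] = {
            "n_segments": d["n_segments"],
            "mean_length_bp": (d["total_bp"] / d["n_segments"]
                               if d["n_segments"] else float("nan")),
            "genome_fraction": d["total_bp"] / genome_bp if genome_bp else 0.0,
        }
    out["functional_fraction"] = sum(
        v["genome_fraction"] for lab, v in out.items()
        if lab not in functional_exclude and isinstance(v, dict))
    return out


def methylation_by_state(seg: Segmentation, methylation) -> dict[str, float]:
    """Mean CpG methylation fraction over each state's territory.

    ``methylation`` is a DataFrame with columns chrom, pos, frac. The mean is
    unweighted over CpGs; states whose territory contains no CpG are NaN.
    """
    fracs = np.asarray(methylation["frac"], dtype=float)
    if ((fracs < 0) | (fracs > 1)).any():
        raise GenomicValidationError("methylation fractions must lie in [0, 1]")
    sums = np.zeros(seg.n_states)
    counts = np.zeros(seg.n_states, dtype=np.int64)
    for chrom, sub in methylation.groupby("chrom", sort=False):
        if chrom not in seg.states:
            continue
        states = seg.states[chrom]
        idx = np.asarray(sub["pos"], dtype=np.int64) // seg.bin_size
        ok = (idx >= 0) & (idx < len(states))
        st = states[idx[ok]]
        np.add.at(sums, st, np.asarray(sub["frac"], dtype=float)[ok])
        np.add.at(counts, st, 1)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return {lab: (float(means[i]) if counts[i] else float("nan"))
            for i, lab in enumerate(seg.labels)}


def tss_state_enrichment(seg: Segmentation, tss_list, flank: int = 2000
                         ) -> np.ndarray:
    """Positional state enrichment around TSS anchors.

    ``tss_list`` holds (chrom, pos, strand) tuples. Returns a
    (n_states, 2*flank/bin + 1) array of frequency-at-offset divided by
    genome-wide state frequency; 1 means no enrichment. Minus-strand anchors
    are orientation-flipped.
    """
    if flank % seg.bin_size:
        raise InvalidParameterError("flank must be a multiple of bin_size")
    w = flank // seg.bin_size
    n_off = 2 * w + 1
    counts = np.zeros((seg.n_states, n_off))
    totals = np.zeros(n_off)
    for chrom, pos, strand in tss_list:
        if chrom not in seg.states:
            continue
        states = seg.states[chrom]
        center = pos // seg.bin_size
        offs = np.arange(-w, w + 1)
        idx = center + (offs if strand != "-" else -offs)
        ok = (idx >= 0) & (idx < len(states))
        cols = np.arange(n_off)[ok]
        counts[states[idx[ok]], cols] += 1
        totals[cols] += 1
    genome = np.concatenate([seg.states[c] for c in seg.chroms])
    gfreq = np.bincount(genome, minlength=seg.n_states) / len(genome)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = counts / totals
        enr = freq / gfreq[:, None]
    return enr


def _state_prefix_sums(seg: Segmentation) -> dict[str, np.ndarray]:
    """Per chromosome, (K, n_bins+1) prefix sums of state indicators."""
    out = {}
    for chrom in seg.chroms:
        s = seg.states[chrom]
        ind = (s[None, :] == np.arange(seg.n_states)[:, None])
        out[chrom] = np.concatenate(
            [np.zeros((seg.n_states, 1), dtype=np.int64),
             np.cumsum(ind, axis=1, dtype=np.int64)], axis=1)
    return out


def deg_state_enrichment(seg: Segmentation, regions, n_perm: int = 1000,
                         seed: int = 0):
    """Enrichment fold of each state inside a set of genomic regions, with an
    empirical p from length- and chromosome-matched random placements.

    fold = (state bp inside the regions / region bp)
           / (state bp genome-wide / genome bp).

    The observed territory is the union of the regions; null placements keep
    each region's length and chromosome and draw its start uniformly.
    Returns {label: {"fold": f, "p": p}}.
    """
    if not regions:
        raise InvalidParameterError("empty region set")
    rng = np.random.default_rng(seed)
    K = seg.n_states
    prefix = _state_prefix_sums(seg)
    nbins = {c: len(seg.states[c]) for c in seg.chroms}
    genome_bins = sum(nbins.values())
    gcounts = np.array([prefix[c][:, -1] for c in seg.chroms]).sum(axis=0)
    gfreq = gcounts / genome_bins

    # observed: union mask
    masks = {c: np.zeros(nbins[c], dtype=bool) for c in seg.chroms}
    spans = []
    for iv in regions:
        if iv.chrom not in masks:
            continue
        a = iv.start // seg.bin_size
        b = min(-(-iv.end // seg.bin_size), nbins[iv.chrom])
        masks[iv.chrom][a:b] = True
        spans.append((iv.chrom, b - a))
    terr_bins = sum(int(m.sum()) for m in masks.values())
    if terr_bins == 0:
        raise InvalidParameterError("regions cover no bins of the segmentation")
    obs_counts = np.zeros(K, dtype=np.int64)
    for c in seg.chroms:
        if masks[c].any():
            obs_counts += np.bincount(seg.states[c][masks[c]], minlength=K)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_fold = (obs_counts / terr_bins) / gfreq

    # null: random placement per span via prefix sums
    perm_counts = np.zeros((n_perm, K), dtype=np.int64)
    total_span = sum(w for _, w in spans)
    for chrom, w in spans:
        hi = max(nbins[chrom] - w, 1)
        starts = rng.integers(0, hi, size=n_perm)
        pc = prefix[chrom]
        perm_counts += (pc[:, starts + w] - pc[:, starts]).T
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_fold = (perm_counts / total_span) / gfreq[None, :]
    p = (1 + (perm_fold >= obs_fold[None, :]).sum(axis=0)) / (n_perm + 1)
    return {lab: {"fold": float(obs_fold[i]), "p": float(p[i])}
            for i, lab in enumerate(seg.labels)}


def mean_signal_over_intervals(track: SignalTrack, intervals) -> float:
    """Mean track value over the bins covered by a set of intervals."""
    total, n = 0.0, 0
    for iv in intervals:
        if iv.chrom not in track.values:
            continue
        arr = track.values[iv.chrom]
        a = iv.start // track.bin_size
        b = min(-(-iv.end // track.bin_size), len(arr))
        if b > a:
            total += float(arr[a:b].sum())
            n += b - a
    return total / n if n else float("nan")


def enhancer_expression_correlation(signal_values, expression_values,
                                    log_transform: bool = True):
    """Pearson correlation (with least-squares line) between per-gene
    enhancer signal and expression, both log2(x+1)-transformed by default.

    Returns a dict with r, p, slope, intercept and n; all-NaN when either
    vector is constant or fewer than 4 pairs are available.
    """
    x = np.asarray(signal_values, dtype=float)
    y = np.asarray(expression_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if log_transform:
        x = np.log2(x + 1)
        y = np.log2(y + 1)
    if len(x) < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "slope": float("nan"),
                "intercept": float("nan"), "n": int(len(x))}
    res = stats.linregress(x, y)
    return {"r": float(res.rvalue), "p": float(res.pvalue),
            "slope": float(res.slope), "intercept": float(res.intercept),
            "n": int(len(x))}
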