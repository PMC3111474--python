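"""PSSM motif scanning and the conditional sequence likelihood P(S | Z).

The promoter sequence of a target gene (Z=1) is modeled as emitted from a
two-state (background / motif) hidden layer; for a non-target (Z=0) the
hidden layer stays in the background state.  The HMM is approximated by a
motif scan: a segment is called a motif when its log likelihood-ratio score
against the background reaches a threshold.  The scan's sufficient
statistics are N_b (background bases), N_m (called motifs) and log R (sum of
the called motifs' scores), from which

    log P(S | Z=1) - log P(S | Z=0) = N_b log(1-q) + N_m log(q) + log R

where q is the marginal probability that a hidden position-state is "motif".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from typing import Sequence

import numpy as np

__all__ = [
    "PSSM",
    "SequenceModelParams",
    "MotifHit",
    "MotifScanSummary",
    "build_pssm",
    "score_segment",
    "scan_window",
    "seq_loglik",
    "seq_loglik_difference",
    "select_best_window",
    "binding_affinity",
    "interspecies_affinity_difference",
    "pool_scans",
    "encode",
    "revcomp",
]

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (N -> 4)."""
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTN base {exc.args[0]!r} in sequence") from exc


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class PSSM:
    """Position-specific probability matrix with genomic background.

    ``probs`` is (width, 4) over A, C, G, T; each row sums to 1 and is
    strictly positive (after pseudocount).  ``background`` is the genome-wide
    base composition p_b.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if probs.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive (use a pseudocount)")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9) or np.any(bg <= 0):
            raise ValueError("background must be a positive length-4 distribution")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 5) log(probs/background); the N column scores 0."""
        lo = np.log(self.probs / self.background)
        return np.hstack([lo, np.zeros((self.width, 1))])

    @property
    def max_score(self) -> float:
        """Best achievable segment score (consensus against background)."""
        return float(np.log(self.probs / self.background).max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def permuted(self, row_perm: Sequence[int], col_perm: Sequence[int]) -> "PSSM":
        """Shuffle motif positions (rows) and base identities (columns)."""
        row_perm = np.asarray(row_perm)
        col_perm = np.asarray(col_perm)
        if sorted(row_perm.tolist()) != list(range(self.width)):
            raise ValueError("row_perm must permute 0..width-1")
        if sorted(col_perm.tolist()) != [0, 1, 2, 3]:
            raise ValueError("col_perm must permute 0..3")
        return replace(self, probs=self.probs[row_perm][:, col_perm])


@dataclass(frozen=True)
class SequenceModelParams:
    """q: marginal motif probability of a hidden position-state; threshold:
    minimum per-segment log likelihood-ratio for calling a motif, as a
    fraction of the PSSM's maximum score if ``threshold_is_relative``."""

    q: float = 0.005
    threshold: float = 0.6
    threshold_is_relative: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def call_threshold(self, pssm: PSSM) -> float:
        if self.threshold_is_relative:
            return self.threshold * pssm.max_score
        return self.threshold


@dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based, on the forward strand
    end: int    # half-open
    strand: str  # '+' or '-'
    score: float


@dataclass(frozen=True)
class MotifScanSummary:
    """Sufficient statistics of one scanned window.

    ``n_background`` (N_b) + ``n_motifs`` (N_m) * motif width partitions the
    window; ``log_r`` is the summed log likelihood-ratio score of the called
    motifs (log of R); ``background_loglik`` is sum(log p_b) over the
    window's bases (N bases contribute 0), i.e. log P(S | Z=0).
    """

    seq_id: str
    start: int
    end: int
    n_background: int
    n_motifs: int
    log_r: float
    background_loglik: float
    width: int
    hits: tuple[MotifHit, ...] = field(default_factory=tuple)

    @property
    def window_length(self) -> int:
        return self.end - self.start


def build_pssm(
    matrix,
    pseudocount: float = 0.0,
    background: Sequence[float] = UNIFORM_BG,
    name: str = "motif",
) -> PSSM:
    """Normalize a count or probability matrix (rows = positions, cols = A,C,G,T).

    ``pseudocount`` is added to every cell before normalization; a zero cell
    without a pseudocount is an error.  Probability input passes through
    unchanged up to renormalization.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("matrix must have 4 columns (A, C, G, T)")
    if np.any(mat < 0):
        raise ValueError("matrix entries must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mat = mat + pseudocount
    if np.any(mat <= 0):
        raise ValueError("zero entries require a positive pseudocount")
    probs = mat / mat.sum(axis=1, keepdims=True)
    return PSSM(probs=probs, background=np.asarray(background, float), pseudocount=pseudocount, name=name)


def score_segment(segment: str, pssm: PSSM) -> float:
    """Log likelihood-ratio of one segment: sum_k log(probs[k][b_k]/p_b(b_k))."""
    codes = encode(segment)
    if codes.size != pssm.width:
        raise ValueError(f"segment length {codes.size} != motif width {pssm.width}")
    return float(pssm.log_odds[np.arange(pssm.width), codes].sum())


def _strand_scores(codes: np.ndarray, pssm: PSSM) -> np.ndarray:
    """Scores of every forward-strand offset for one encoded strand."""
    w = pssm.width
    if codes.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return pssm.log_odds[np.arange(w), windows].sum(axis=1)


def scan_window(
    window_sequence: str,
    pssm: PSSM,
    params: SequenceModelParams,
    seq_id: str = "window",
    offset: int = 0,
) -> MotifScanSummary:
    """Scan both strands; call non-overlapping hits greedily by descending score.

    Overlap is judged on forward-strand base intervals regardless of strand,
    so N_b + N_m * width exactly partitions the window.  Windows shorter than
    the motif yield N_m = 0.
    """
    if not window_sequence:
        raise ValueError("window must be nonempty")
    codes = encode(window_sequence)
    length = codes.size
    w = pssm.width
    bg_ll = float(np.concatenate([np.log(pssm.background), [0.0]])[codes].sum())
    threshold = params.call_threshold(pssm)

    candidates: list[MotifHit] = []
    fwd = _strand_scores(codes, pssm)
    for pos in np.flatnonzero(fwd >= threshold):
        candidates.append(MotifHit(int(pos), int(pos) + w, "+", float(fwd[pos])))
    rc_codes = encode(revcomp(window_sequence))
    rev = _strand_scores(rc_codes, pssm)
    for pos in np.flatnonzero(rev >= threshold):
        start = length - int(pos) - w
        candidates.append(MotifHit(start, start + w, "-", float(rev[pos])))

    # greedy non-overlapping selection, ties broken by leftmost then strand
    candidates.sort(key=lambda h: (-h.score, h.start, h.strand))
    taken: list[MotifHit] = []
    occupied = np.zeros(length, dtype=bool)
    for hit in candidates:
        if not occupied[hit.start : hit.end].any():
            occupied[hit.start : hit.end] = True
            taken.append(hit)
    taken.sort(key=lambda h: h.start)

    n_m = len(taken)
    return MotifScanSummary(
        seq_id=seq_id,
        start=offset,
        end=offset + length,
        n_background=length - n_m * w,
        n_motifs=n_m,
        log_r=float(sum(h.score for h in taken)),
        background_loglik=bg_ll,
        width=w,
        hits=tuple(
            MotifHit(h.start + offset, h.end + offset, h.strand, h.score) for h in taken
        ),
    )


def seq_loglik_difference(scan: MotifScanSummary, params: SequenceModelParams) -> float:
    """log P(S | Z=1) - log P(S | Z=0) from the scan's sufficient statistics."""
    return (
        scan.n_background * log(1.0 - params.q)
        + scan.n_motifs * log(params.q)
        + scan.log_r
    )


def seq_loglik(
    scan: MotifScanSummary,
    z: int,
    params: SequenceModelParams,
    pssm: PSSM | None = None,
    window_sequence: str | None = None,
) -> float:
    """Conditional log-probability of the window sequence given state ``z``.

    For z=0 every base is background: sum of log p_b.  For z=1 the background
    term is augmented by N_b log(1-q) + N_m log(q) + log R.  If
    ``window_sequence`` is given it is checked against the scan.
    """
    if z not in (0, 1):
        raise ValueError("z must be 0 or 1")
    if window_sequence is not None:
        if len(window_sequence) != scan.window_length:
            raise ValueError("window_sequence does not match the scan's window")
        if pssm is not None:
            codes = encode(window_sequence)
            bg = float(np.concatenate([np.log(pssm.background), [0.0]])[codes].sum())
            if not np.isclose(bg, scan.background_loglik):
                raise ValueError("window_sequence inconsistent with scan background")
    if z == 0:
        return scan.background_loglik
    return scan.background_loglik + seq_loglik_difference(scan, params)


def _window_starts(length: int, window_size: int, step: int) -> list[int]:
    starts = list(range(0, length - window_size + 1, step))
    last = length - window_size
    if starts[-1] != last:
        starts.append(last)  # flush window keeps the grid end-anchored
    return starts


def select_best_window(
    long_sequence: str,
    pssm: PSSM,
    params: SequenceModelParams,
    window_size: int = 500,
    step: int = 250,
    seq_id: str = "region",
) -> MotifScanSummary:
    """Scan every sliding window and keep the most target-like one.

    The representative window maximizes the z=1 vs z=0 log-likelihood
    difference; ties go to the first window by coordinate.  A sequence
    shorter than ``window_size`` is scanned whole.
    """
    if window_size < pssm.width:
        raise ValueError("window_size must be at least the motif width")
    if step < 1:
        raise ValueError("step must be >= 1")
    length = len(long_sequence)
    if length < window_size:
        import warnings

        warnings.warn(
            f"sequence {seq_id!r} shorter than window_size; scanning it whole",
            stacklevel=2,
        )
        return scan_window(long_sequence, pssm, params, seq_id=seq_id)
    best: MotifScanSummary | None = None
    best_diff = -np.inf
    for start in _window_starts(length, window_size, step):
        scan = scan_window(
            long_sequence[start : start + window_size], pssm, params, seq_id=seq_id, offset=start
        )
        diff = seq_loglik_difference(scan, params)
        if diff > best_diff:
            best, best_diff = scan, diff
    assert best is not None
    return best


def binding_affinity(
    long_sequence: str,
    pssm: PSSM,
    params: SequenceModelParams,
    window_size: int = 500,
    step: int = 250,
) -> float:
    """Affinity of a regulatory region: the best window's z=1 vs z=0 difference."""
    scan = select_best_window(long_sequence, pssm, params, window_size, step)
    return seq_loglik_difference(scan, params)


def interspecies_affinity_difference(affinities: Sequence[float]) -> float:
    """Mean absolute pairwise difference of per-species affinities."""
    a = np.asarray(affinities, float)
    if a.size < 2:
        raise ValueError("need at least two species")
    diffs = [abs(a[i] - a[j]) for i in range(a.size) for j in range(i + 1, a.size)]
    return float(np.mean(diffs))


def pool_scans(scans: Sequence[MotifScanSummary]) -> MotifScanSummary:
    """Pool scans of the same window by several PSSMs (multi-TF aggregate).

    N_m and log R add; N_b is recomputed as window length minus the pooled
    motif footprint.  All scans must cover the same window.
    """
    if not scans:
        raise ValueError("no scans to pool")
    first = scans[0]
    if any((s.seq_id, s.start, s.end) != (first.seq_id, first.start, first.end) for s in scans):
        raise ValueError("scans cover different windows")
    n_m = sum(s.n_motifs for s in scans)
    footprint = sum(s.n_motifs * s.width for s in scans)
    return MotifScanSummary(
        seq_id=first.seq_id,
        start=first.start,
        end=first.end,
        n_background=first.window_length - footprint,
        n_motifs=n_m,
        log_r=float(sum(s.log_r for s in scans)),
        background_loglik=first.background_loglik,
        width=first.width,
        hits=tuple(h for s in scans for h in s.hits),
    )
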