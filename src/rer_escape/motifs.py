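"""PWM motif scanning with exact p-values and conservation filtering.

A position probability matrix is converted to a log2-odds matrix against a
background composition, sites on both strands are scored by a sliding window,
and each site score gets an exact p-value from the discrete distribution of
scores under the background model, computed by position-wise convolution on a
discretized score lattice (the FIMO approach).  Sites are then annotated with
the mean per-base conservation over their span and retained when it exceeds a
strict threshold (default 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .regions import GenomicInterval
from .tracks import CoverageTrack

__all__ = [
    "PWMRecord",
    "MotifHit",
    "pwm_log_odds",
    "ScoreDistribution",
    "scan_sequence",
    "conservation_filter",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_THRESHOLD_P",
    "DEFAULT_CONSERVATION_THRESHOLD",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_P = 1e-4
DEFAULT_CONSERVATION_THRESHOLD = 0.70
DEFAULT_GRID = 1000


@dataclass
class PWMRecord:
    """A position probability matrix over A,C,G,T with a background.

    Each row of ``probs`` sums to 1 (tolerance 1e-9); the background sums
    to 1.  The matrix is the carrier for scanning and for the exact p-value
    computation.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: probs must be width x 4")
        if np.any(self.probs < 0):
            raise ValueError(f"motif {self.motif_id}: negative probability")
        rowsums = self.probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError(f"motif {self.motif_id}: row does not sum to 1")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError(f"motif {self.motif_id}: background does not sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWMRecord":
        return PWMRecord(
            self.motif_id, self.probs[::-1, ::-1].copy(), self.background.copy()
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in np.argmax(self.probs, axis=1))


@dataclass
class MotifHit:
    """One scored motif occurrence within a region's sequence.

    ``offset`` is 0-based on the region's forward strand for both strand
    orientations; ``score`` is the log2-odds of the matching orientation.
    ``mean_conservation``/``retained`` are filled by :func:`conservation_filter`.
    """

    region_id: str
    motif_id: str
    offset: int
    strand: str
    width: int
    score: float
    p_value: float
    mean_conservation: Optional[float] = None
    retained: Optional[bool] = None


def pwm_log_odds(pwm: PWMRecord, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Log2-odds matrix: log2(((p + c*b) / (1 + c)) / b) per cell.

    With pseudocount 0, a zero probability maps to -inf (the letter can never
    match); the exact p-value machinery requires finite entries and therefore
    a positive pseudocount for such matrices.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    adjusted = (pwm.probs + pseudocount * pwm.background) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(adjusted / pwm.background)


class ScoreDistribution:
    """Exact distribution of window scores under the background model.

    Scores are discretized onto an integer lattice with step
    ``max(column range) / grid`` and the pmf of the lattice score of a random
    background window is built by convolving one column at a time.  Observed
    windows are scored on the same lattice, so DP tail probabilities agree
    exactly with exhaustive enumeration of all 4^w words.
    """

    def __init__(self, log_odds: np.ndarray, background: np.ndarray, grid: int = DEFAULT_GRID):
        if grid < 100:
            raise ValueError("grid must be >= 100")
        lo = np.asarray(log_odds, dtype=float)
        if not np.all(np.isfinite(lo)):
            raise ValueError(
                "zero probability with zero pseudocount: log-odds must be finite "
                "for the exact score distribution"
            )
        bg = np.asarray(background, dtype=float)
        w = lo.shape[0]
        col_min = lo.min(axis=1)
        col_range = lo.max(axis=1) - col_min
        h = float(col_range.max()) / grid
        if h == 0.0:
            h = 1.0  # degenerate: every entry identical; all lattice scores are 0
        self.step = h
        self.offset = float(col_min.sum())
        # integer lattice entries per (position, letter)
        self.int_matrix = np.rint((lo - col_min[:, None]) / h).astype(np.int64)
        pmf = np.zeros(int(self.int_matrix.max(axis=1).sum()) + 1)
        pmf[0] = 1.0
        filled = 0
        for pos in range(w):
            new = np.zeros_like(pmf)
            top = filled + int(self.int_matrix[pos].max())
            for j in range(4):
                shift = int(self.int_matrix[pos, j])
                new[shift : filled + shift + 1] += bg[j] * pmf[: filled + 1]
            pmf = new
            filled = top
        self.pmf = pmf
        # survival function on the lattice: sf[s] = P(lattice score >= s)
        self.sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        self.sf = np.minimum(self.sf, 1.0)

    def pvalue_int(self, s: int) -> float:
        """P(lattice score >= s) for an integer lattice score."""
        if s <= 0:
            return 1.0
        if s >= len(self.sf):
            return 0.0
        return float(self.sf[s])

    def tail_prob(self, score: float) -> float:
        """P(score >= given log2-odds score), via the lattice."""
        s = int(np.rint((score - self.offset) / self.step))
        return self.pvalue_int(max(s, 0))


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A,C,G,T to 0..3; any other letter (N, lowercase handled upstream) to -1."""
    codes = np.full(len(sequence), -1, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    for c, i in _CODE.items():
        codes[arr == ord(c)] = i
    return codes


def _window_scores(codes: np.ndarray, int_matrix: np.ndarray, log_odds: np.ndarray):
    """Lattice and float scores of every window; invalid (N-containing) -> masked."""
    w = int_matrix.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0), np.zeros(0, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    lattice = np.zeros(n_win, dtype=np.int64)
    floats = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for pos in range(w):
        seg = safe[pos : pos + n_win]
        lattice += int_matrix[pos, seg]
        floats += log_odds[pos, seg]
        valid &= codes[pos : pos + n_win] >= 0
    return lattice, floats, valid


def scan_sequence(
    region_id: str,
    sequence: str,
    pwm: PWMRecord,
    threshold_p: float = DEFAULT_THRESHOLD_P,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    grid: int = DEFAULT_GRID,
) -> list[MotifHit]:
    """Scan both strands of a sequence, reporting hits with p <= threshold_p.

    Windows containing any non-ACGT letter are skipped.  A sequence shorter
    than the motif yields an empty result.  Hits are sorted by offset, then
    strand; overlapping hits are allowed.
    """
    w = pwm.width
    if len(sequence) < w:
        return []
    codes = encode_sequence(sequence)
    lo_fwd = pwm_log_odds(pwm, pseudocount)
    dist = ScoreDistribution(lo_fwd, pwm.background, grid)
    rc = pwm.reverse_complement()
    lo_rev = pwm_log_odds(rc, pseudocount)
    # The rc matrix is the fwd matrix flipped in both axes, so its lattice
    # entries reuse the same step/offset; a window matching the motif on the
    # minus strand scores the rc matrix on the forward sequence.
    int_rev = dist.int_matrix[::-1, ::-1]

    hits: list[MotifHit] = []
    for strand, im, lom in (("+", dist.int_matrix, lo_fwd), ("-", int_rev, lo_rev)):
        lattice, floats, valid = _window_scores(codes, im, lom)
        for i in np.nonzero(valid)[0]:
            p = dist.pvalue_int(int(lattice[i]))
            if p <= threshold_p:
                hits.append(
                    MotifHit(
                        region_id=region_id,
                        motif_id=pwm.motif_id,
                        offset=int(i),
                        strand=strand,
                        width=w,
                        score=float(floats[i]),
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def conservation_filter(
    hits: Sequence[MotifHit],
    conservation: CoverageTrack,
    region_coords: Mapping[str, GenomicInterval],
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    summary: str = "mean",
) -> list[MotifHit]:
    """Annotate hits with per-site conservation and flag retained ones.

    The site span is mapped to genomic coordinates through ``region_coords``;
    uncovered bases score 0.  ``summary`` is the per-site aggregate ("mean" or
    "min"); a site is retained iff its summary is strictly greater than
    ``threshold``.
    """
    if summary not in ("mean", "min"):
        raise ValueError(f"summary must be 'mean' or 'min', got {summary!r}")
    out: list[MotifHit] = []
    for hit in hits:
        region = region_coords[hit.region_id]
        start = region.start + hit.offset
        end = start + hit.width
        if summary == "mean":
            value = conservation.mean_over(region.chrom, start, end)
        else:
            value = float(conservation.per_base(region.chrom, start, end).min())
        out.append(replace(hit, mean_conservation=value, retained=value > threshold))
    return out
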