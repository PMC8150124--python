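"""Step-function coverage tracks (bedGraph semantics).

A :class:`CoverageTrack` stores, per chromosome, a sorted list of
non-overlapping ``(start, end, value)`` steps.  Positions outside any step
have value 0 — the bedGraph convention for unreported bases.  Tracks carry
H3K4me3 / H3K4me1 signal intensities and per-base conservation scores.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CoverageTrack"]


class CoverageTrack:
    def __init__(self, steps: dict[str, list[tuple[int, int, float]]] | None = None):
        # per chrom: parallel arrays of step starts, ends, values
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        if steps:
            for chrom, triples in steps.items():
                self._set_chrom(chrom, triples)

    def _set_chrom(self, chrom: str, triples: list[tuple[int, int, float]]) -> None:
        triples = sorted(triples)
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        values = np.array([t[2] for t in triples], dtype=float)
        if np.any(starts >= ends):
            bad = int(np.argmax(starts >= ends))
            raise ValueError(f"empty step on {chrom}: ({starts[bad]}, {ends[bad]})")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            bad = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValueError(
                f"overlapping steps on {chrom} near position {int(starts[bad + 1])}"
            )
        self._starts[chrom] = starts
        self._ends[chrom] = ends
        self._values[chrom] = values

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def steps(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._starts:
            return []
        return [
            (int(s), int(e), float(v))
            for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._values[chrom])
        ]

    def iter_steps(self):
        for chrom in self.chroms:
            for triple in self.steps(chrom):
                yield (chrom, *triple)

    def value_at(self, chrom: str, pos: int) -> float:
        """Point query; 0 outside every step."""
        if chrom not in self._starts:
            return 0.0
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end); uncovered bases add 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._starts:
            return 0.0
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end), uncovered bases counted as 0."""
        return self.sum_over(chrom, start, end) / (end - start)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end) (test oracle / small spans)."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._starts:
            return out
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start : min(e, end) - start] = v
        return out
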