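"""Independent brute-force oracles used to cross-check the production paths.

Everything here is deliberately naive (dense bitmaps, exhaustive
enumeration, textbook formulas) and never shares code with the package.
"""

import itertools

import numpy as np


def coverage_bitmap(intervals, chrom_lengths: dict) -> dict:
    """Dense boolean coverage per chromosome."""
    bitmaps = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for iv in intervals:
        bitmaps[iv.chrom][iv.start : iv.end] = True
    return bitmaps


def bitmap_intersection_fragments(stage_interval_lists, chrom_lengths: dict):
    """Per-base AND of all stages, returned as (chrom, start, end) runs."""
    common = {c: np.ones(n, dtype=bool) for c, n in chrom_lengths.items()}
    for intervals in stage_interval_lists:
        bm = coverage_bitmap(intervals, chrom_lengths)
        for c in common:
            common[c] &= bm[c]
    frags = []
    for c in sorted(common):
        arr = common[c]
        padded = np.concatenate([[False], arr, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        frags.extend((c, int(s), int(e)) for s, e in zip(starts, ends))
    return frags


_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_scan(sequence: str, log_odds: np.ndarray, int_matrix: np.ndarray, sf, threshold_p):
    """Sliding-window rescan using python loops; N windows skipped.

    Returns (offset, strand, lattice_score) triples with p <= threshold.
    """
    w = log_odds.shape[0]
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand in "+-":
        for i in range(len(sequence) - w + 1):
            window = sequence[i : i + w]
            if any(ch not in code for ch in window):
                continue
            if strand == "-":
                window = revcomp(window)
            s = sum(int_matrix[k, code[ch]] for k, ch in enumerate(window))
            if sf(s) <= threshold_p:
                hits.append((i, strand, s))
    return hits


def exhaustive_score_tail(int_matrix: np.ndarray, background: np.ndarray):
    """Exact tail P(lattice score >= s) by enumerating all 4^w words."""
    w = int_matrix.shape[0]
    scores = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(int_matrix[k, c] for k, c in enumerate(word)))
        p = float(np.prod([background[c] for c in word]))
        scores[s] = scores.get(s, 0.0) + p
    smax = max(scores)
    tail = {}
    acc = 0.0
    for s in range(smax, -1, -1):
        acc += scores.get(s, 0.0)
        tail[s] = acc
    return tail


def pooled_t(a, b):
    """Textbook pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def pearson_chi2(table):
    """Direct sum of (O - E)^2 / E with margins-based expectations."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
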