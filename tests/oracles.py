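"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by direct enumeration: every candidate
alignment of every window is materialised explicitly (index arithmetic per
alignment), instead of the cumulative-sum / banded-DP search the package
uses.  They are slow but simple, and share no search code with the
implementation.
"""

from __future__ import annotations

import numpy as np

from apexmir.targets import normalize, pair_penalty, position_weight


def _penalties(mir: str, tx: str) -> np.ndarray:
    return np.array(
        [[pair_penalty(m, t) for t in tx] for m in mir], dtype=float
    )


def enumerate_candidates(
    mirna: str, transcript: str, max_score: float
) -> list[tuple[float, int, int, str]]:
    """Every window/alignment with <= 1 bulge scoring within ``max_score``.

    Returns ``(score, start0, length, ops)`` tuples.  Each alignment class
    (bulge-free, one bulged target nt after miRNA position g, one bulged
    miRNA nt at position b) is scored by explicitly gathering the penalty of
    every paired position.
    """
    mir, tx = normalize(mirna), normalize(transcript)
    n, T = len(mir), len(tx)
    if T < n:
        return []
    P = _penalties(mir, tx)
    w = np.array([position_weight(p) for p in range(1, n + 1)])
    out: list[tuple[float, int, int, str]] = []

    def add(offsets: list[tuple[int, int]], bulge_pen: float, L: int, ops: str) -> None:
        if T < L:
            return
        starts = np.arange(T - L + 1)
        total = np.full(len(starts), bulge_pen)
        for p, off in offsets:  # p: 1-based miRNA position paired at start + off
            total += w[p - 1] * P[p - 1, starts + off]
        for s in np.nonzero(total <= max_score + 1e-9)[0]:
            out.append((float(total[s]), int(s), L, ops))

    # bulge-free: miRNA position p pairs transcript start + (n - p)
    add([(p, n - p) for p in range(1, n + 1)], 0.0, n, "M" * n)
    # bulged target nucleotide between miRNA positions g and g+1
    for g in range(1, n):
        offsets = [(p, n + 1 - p) for p in range(1, g + 1)]
        offsets += [(p, n - p) for p in range(g + 1, n + 1)]
        add(offsets, position_weight(g + 1), n + 1, "M" * g + "B" + "M" * (n - g))
    # bulged miRNA nucleotide at position b (internal)
    for b in range(2, n):
        offsets = [(p, n - 1 - p) for p in range(1, b)]
        offsets += [(p, n - p) for p in range(b + 1, n + 1)]
        add(offsets, position_weight(b), n - 1, "M" * (b - 1) + "b" + "M" * (n - b))
    return out


def oracle_scan(
    mirna: str, transcript: str, max_score: float = 5.0
) -> list[tuple[float, int, int, str]]:
    """Reference site set: enumeration plus an independent greedy resolution.

    Same deterministic rule as the package contract: overlap groups resolve
    to the lowest score, ties to the smallest start, then shortest site.
    Returned as ``(score, start1, end1, ops)``.
    """
    cands = enumerate_candidates(mirna, transcript, max_score)
    cands.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    chosen: list[tuple[float, int, int, str]] = []
    taken: list[tuple[int, int]] = []
    for score, s, L, ops in cands:
        lo, hi = s, s + L - 1
        if any(not (hi < a or lo > b) for a, b in taken):
            continue
        taken.append((lo, hi))
        chosen.append((score, s + 1, s + L, ops))
    chosen.sort(key=lambda c: (c[0], c[1]))
    return chosen


def oracle_window_mean(
    counts_by_rep: dict[str, list[int]], center: int, width: int
) -> float:
    """Brute-force window sum (clipped), averaged across replicates."""
    half = (width - 1) // 2
    sums = []
    for vec in counts_by_rep.values():
        total = 0
        for pos in range(center - half, center + half + 1):
            if 1 <= pos <= len(vec):
                total += vec[pos - 1]
        sums.append(total)
    return float(np.mean(sums))
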