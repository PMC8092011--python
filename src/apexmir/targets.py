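"""Plant-style miRNA target-site scoring and transcript scanning.

The scoring scheme is the penalty system used for plant miRNA target
prediction: each duplex position contributes

* 0.0 for a Watson-Crick match,
* 0.5 for a G:U wobble,
* 1.0 for a mismatch or a bulged (unpaired) nucleotide,

and every penalty is doubled when it falls at miRNA positions 2-13 counted
from the miRNA 5' end (the seed plus the region around the AGO cleavage
site).  A perfect complement scores 0; sites are usually accepted up to a
maximum penalty of 5.

Conventions
-----------
* Sequences are normalised internally to the DNA alphabet (U -> T);
  alignments may be rendered with U for RNA input.
* The duplex is antiparallel: miRNA position 1 (5') pairs the 3'-most
  nucleotide of the target site.
* Alignment paths are strings over ``M`` (paired position), ``B``
  (bulged target nucleotide) and ``b`` (bulged miRNA nucleotide), written
  in miRNA 5'->3' order.
* The guide-directed cleavage position is the transcript nucleotide paired
  with miRNA position 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MATCH, WOBBLE, MISMATCH = 0.0, 0.5, 1.0
CRITICAL_REGION = (2, 13)  # miRNA positions with doubled penalties
CLEAVAGE_MIRNA_POSITION = 10

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PairingError(ValueError):
    """Alignment path inconsistent with the sequences it claims to align."""


class CleavageAmbiguousError(ValueError):
    """miRNA position 10 is bulged out; no cleavage position can be assigned."""


def normalize(seq: str) -> str:
    """Uppercase and collapse the RNA alphabet onto DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(normalize(seq)))


def pair_penalty(mirna_nt: str, target_nt: str) -> float:
    """Penalty class for one duplex pair (symmetric in its arguments)."""
    a, b = normalize(mirna_nt), normalize(target_nt)
    if _COMPLEMENT.get(a) == b:
        return MATCH
    if (a, b) in (("G", "T"), ("T", "G")):
        return WOBBLE
    return MISMATCH


def position_weight(pos: int, exempt_position_one: bool = False) -> float:
    """Penalty multiplier for a miRNA position (1-based from the 5' end)."""
    if exempt_position_one and pos == 1:
        return 0.0
    lo, hi = CRITICAL_REGION
    return 2.0 if lo <= pos <= hi else 1.0


def _weights(n: int, exempt_position_one: bool) -> np.ndarray:
    return np.array(
        [position_weight(i, exempt_position_one) for i in range(1, n + 1)], dtype=float
    )


# ---------------------------------------------------------------------------
# duplex scoring along an explicit alignment path
# ---------------------------------------------------------------------------


def score_duplex(
    mirna: str,
    site: str,
    pairing: str | Iterable[str],
    weights: Sequence[float] | None = None,
    exempt_position_one: bool = False,
) -> float:
    """Penalty score of a miRNA/target-site duplex along an alignment path.

    Parameters
    ----------
    mirna, site:
        Both 5'->3'.  The duplex is antiparallel, so the path consumes the
        site from its 3' end.
    pairing:
        Ops in miRNA 5'->3' order: ``M`` paired, ``B`` bulged target
        nucleotide, ``b`` bulged miRNA nucleotide.
    weights:
        Optional per-miRNA-position multipliers (index 0 = position 1)
        overriding the default doubling at positions 2-13.  A bulged target
        nucleotide takes the weight of the next miRNA position 3' of the gap.
    """
    mir = normalize(mirna)
    tgt = normalize(site)
    ops = "".join(pairing)
    n_m = sum(1 for op in ops if op in "Mb")
    n_t = sum(1 for op in ops if op in "MB")
    if set(ops) - set("MBb"):
        raise PairingError(f"unknown alignment op in {ops!r}")
    if n_m != len(mir):
        raise PairingError(f"path consumes {n_m} miRNA nt, sequence has {len(mir)}")
    if n_t != len(tgt):
        raise PairingError(f"path consumes {n_t} site nt, sequence has {len(tgt)}")

    if weights is None:
        w = _weights(len(mir), exempt_position_one)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(mir):
            raise PairingError("weights length must equal miRNA length")

    def weight_at(pos: int) -> float:  # clamp for a terminal target bulge
        return float(w[min(pos, len(mir)) - 1])

    score = 0.0
    i = 0  # miRNA nt consumed
    t = len(tgt)  # next site index (1-based, consumed 3'->5')
    for op in ops:
        if op == "M":
            i += 1
            score += weight_at(i) * pair_penalty(mir[i - 1], tgt[t - 1])
            t -= 1
        elif op == "b":
            i += 1
            score += weight_at(i) * 1.0
        else:  # "B"
            score += weight_at(i + 1) * 1.0
            t -= 1
    return score


# ---------------------------------------------------------------------------
# target sites
# ---------------------------------------------------------------------------


@dataclass
class TargetSite:
    """A scored miRNA binding site in transcript coordinates (1-based, inclusive)."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    score: float
    ops: str
    mirna_seq: str
    site_seq: str
    cleavage_pos: int | None = None
    cleavage_ambiguous: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.cleavage_pos is None and not self.cleavage_ambiguous:
            try:
                self.cleavage_pos = predict_cleavage_position(self)
            except CleavageAmbiguousError:
                self.cleavage_ambiguous = True

    def render(self, rna: bool = False) -> str:
        """Three-line alignment: target 5'->3' on top, miRNA 3'->5' below."""
        cols: list[tuple[str, str, str]] = []
        mir = normalize(self.mirna_seq)
        tgt = normalize(self.site_seq)
        i, t = 0, len(tgt)
        for op in self.ops:
            if op == "M":
                i += 1
                pen = pair_penalty(mir[i - 1], tgt[t - 1])
                sym = "|" if pen == MATCH else ("o" if pen == WOBBLE else " ")
                cols.append((tgt[t - 1], sym, mir[i - 1]))
                t -= 1
            elif op == "b":
                i += 1
                cols.append(("-", " ", mir[i - 1]))
            else:
                cols.append((tgt[t - 1], " ", "-"))
                t -= 1
        cols.reverse()  # display left-to-right = target 5'->3'
        top = "".join(c[0] for c in cols)
        mid = "".join(c[1] for c in cols)
        bot = "".join(c[2] for c in cols)
        if rna:
            top, bot = top.replace("T", "U"), bot.replace("T", "U")
        return (
            f"5' {top} 3' {self.transcript_id}:{self.site_start}-{self.site_end}\n"
            f"   {mid}\n"
            f"3' {bot} 5' {self.mirna_id} (score {self.score:g})"
        )

    def compact_alignment(self) -> str:
        """Single-token alignment rendering for TSV output."""
        lines = self.render().splitlines()
        top = lines[0].split()[1]
        mid = lines[1][3 : 3 + len(top)].replace(" ", ".")
        bot = lines[2].split()[1]
        return f"{top}/{mid}/{bot}"


def predict_cleavage_position(site: TargetSite) -> int:
    """Transcript coordinate paired with miRNA position 10, read off the path.

    With bulges, the pairing partner is found by walking the alignment, not
    by arithmetic offset.  A site whose miRNA position 10 lies in a bulge has
    no defined cleavage position and raises :class:`CleavageAmbiguousError`.
    """
    i = 0
    t = site.site_end
    for op in site.ops:
        if op == "M":
            i += 1
            if i == CLEAVAGE_MIRNA_POSITION:
                return t
            t -= 1
        elif op == "b":
            i += 1
            if i == CLEAVAGE_MIRNA_POSITION:
                raise CleavageAmbiguousError(
                    f"miRNA position {CLEAVAGE_MIRNA_POSITION} bulged out for "
                    f"{site.mirna_id} at {site.transcript_id}:{site.site_start}"
                )
        else:
            t -= 1
    raise PairingError("alignment path shorter than the miRNA")


# ---------------------------------------------------------------------------
# transcript scanning
# ---------------------------------------------------------------------------


def _penalty_matrix(mir: str, tx: str, w: np.ndarray) -> np.ndarray:
    """P[i, t] = weighted penalty of miRNA position i+1 against transcript nt t."""
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    pen = np.ones((5, 5))  # anything unknown is a mismatch
    for a, ia in codes.items():
        for b, ib in codes.items():
            pen[ia, ib] = pair_penalty(a, b)
    m_idx = np.array([codes.get(c, 4) for c in mir])
    t_idx = np.array([codes.get(c, 4) for c in tx])
    return w[:, None] * pen[m_idx[:, None], t_idx[None, :]]


def _candidates_fast(
    mir: str, tx: str, w: np.ndarray, max_score: float
) -> list[tuple[float, int, int, str]]:
    """All windows with <= 1 bulge scoring within ``max_score``.

    Returns tuples ``(score, start0, length, ops)``; computed with shifted
    cumulative sums of the per-position penalty matrix.
    """
    n, T = len(mir), len(tx)
    P = _penalty_matrix(mir, tx, w)
    eps = 1e-9
    out: list[tuple[float, int, int, str]] = []

    # bulge-free frame: A[i, s] = P[i, s + n - 1 - i], s in [0, T - n]
    n_s = T - n + 1
    A = np.empty((n, n_s))
    for i in range(n):
        A[i] = P[i, n - 1 - i : n - 1 - i + n_s]
    cumA = np.cumsum(A, axis=0)
    score0 = cumA[-1]
    for s in np.nonzero(score0 <= max_score + eps)[0]:
        out.append((float(score0[s]), int(s), n, "M" * n))

    # one bulged target nucleotide between miRNA positions g and g+1
    if T >= n + 1:
        for g in range(1, n):
            bulge_w = float(w[g])  # weight of miRNA position g+1
            sc = cumA[g - 1][1:] + bulge_w + (score0 - cumA[g - 1])[: n_s - 1]
            for s in np.nonzero(sc <= max_score + eps)[0]:
                out.append((float(sc[s]), int(s), n + 1, "M" * g + "B" + "M" * (n - g)))

    # one bulged miRNA nucleotide at position b (internal only)
    if n >= 3 and T >= n - 1:
        n_s2 = T - n + 2
        B = np.empty((n - 1, n_s2))
        for i in range(n - 1):
            B[i] = P[i, n - 2 - i : n - 2 - i + n_s2]
        cumB = np.cumsum(B, axis=0)
        A2 = np.zeros((n, n_s2))
        for i in range(1, n):
            A2[i] = P[i, n - 1 - i : n - 1 - i + n_s2]
        sufA2 = np.cumsum(A2[::-1], axis=0)[::-1]
        for b in range(2, n):
            sc = cumB[b - 2] + float(w[b - 1]) + sufA2[b]
            for s in np.nonzero(sc <= max_score + eps)[0]:
                out.append((float(sc[s]), int(s), n - 1, "M" * (b - 1) + "b" + "M" * (n - b)))
    return out


def _candidates_dp(
    mir: str, tx: str, w: np.ndarray, max_score: float, max_bulges: int
) -> list[tuple[float, int, int, str]]:
    """Per-window alignment DP for configurations allowing > 1 bulge (slow path)."""
    n, T = len(mir), len(tx)
    eps = 1e-9
    out: list[tuple[float, int, int, str]] = []
    for length in range(max(1, n - max_bulges), n + max_bulges + 1):
        for s in range(0, T - length + 1):
            window = tx[s : s + length]
            res = _dp_align(mir, window, w, max_bulges)
            if res is not None and res[0] <= max_score + eps:
                out.append((res[0], s, length, res[1]))
    return out


def _dp_align(
    mir: str, site: str, w: np.ndarray, max_bulges: int
) -> tuple[float, str] | None:
    """Best-score global alignment of a miRNA against one site window.

    The site is consumed 3'->5' (antiparallel).  State: (miRNA consumed i,
    site consumed j, bulges used).  Returns (score, ops) or None if the
    window cannot be aligned within the bulge budget.
    """
    n, L = len(mir), len(site)
    if abs(L - n) > max_bulges:
        return None
    INF = float("inf")
    best: dict[tuple[int, int, int], tuple[float, str]] = {(0, 0, 0): (0.0, "")}
    for i in range(n + 1):
        for j in range(L + 1):
            for g in range(max_bulges + 1):
                cur = best.get((i, j, g))
                if cur is None:
                    continue
                sc, ops = cur
                if i < n and j < L:  # paired position
                    pen = w[i] * pair_penalty(mir[i], site[L - 1 - j])
                    _dp_relax(best, (i + 1, j + 1, g), (sc + pen, ops + "M"))
                if i < n and g < max_bulges:  # miRNA bulge
                    _dp_relax(best, (i + 1, j, g + 1), (sc + w[i] * 1.0, ops + "b"))
                if j < L and g < max_bulges:  # target bulge
                    bw = float(w[min(i, n - 1)])
                    _dp_relax(best, (i, j + 1, g + 1), (sc + bw * 1.0, ops + "B"))
    final = [best[(n, L, g)] for g in range(max_bulges + 1) if (n, L, g) in best]
    if not final:
        return None
    return min(final, key=lambda t: (t[0], t[1]))


def _dp_relax(best: dict, key: tuple, value: tuple[float, str]) -> None:
    cur = best.get(key)
    if cur is None or (value[0], value[1]) < (cur[0], cur[1]):
        best[key] = value


def select_nonoverlapping(
    candidates: list[tuple[float, int, int, str]],
) -> list[tuple[float, int, int, str]]:
    """Greedy resolution of overlapping candidate windows.

    Sorted by (score, start, length, ops); a candidate is kept when it does
    not overlap an already-kept site, so within any overlap group the lowest
    score wins and remaining ties go to the smallest start.
    """
    kept: list[tuple[float, int, int, str]] = []
    intervals: list[tuple[int, int]] = []
    for cand in sorted(candidates, key=lambda c: (c[0], c[1], c[2], c[3])):
        s, L = cand[1], cand[2]
        lo, hi = s, s + L - 1
        if any(lo <= b and a <= hi for a, b in intervals):
            continue
        kept.append(cand)
        intervals.append((lo, hi))
    return kept


def scan_transcript(
    mirna: str,
    transcript: str,
    max_score: float = 5.0,
    max_bulges: int = 1,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
    exempt_position_one: bool = False,
) -> list[TargetSite]:
    """Locate every binding site for one miRNA scoring within ``max_score``.

    Overlapping candidate windows are resolved to the best-scoring one (ties
    to the smallest start); results are sorted by (score, start).  A
    transcript shorter than the miRNA yields an empty list.
    """
    mir = normalize(mirna)
    tx = normalize(transcript)
    n = len(mir)
    if len(tx) < n or n == 0:
        return []
    w = _weights(n, exempt_position_one)
    if max_bulges <= 1:
        cands = _candidates_fast(mir, tx, w, max_score)
        if max_bulges == 0:
            cands = [c for c in cands if len(c[3]) == n and "b" not in c[3]]
    else:
        cands = _candidates_dp(mir, tx, w, max_score, max_bulges)
    sites = []
    for _arr_score, s, length, ops in select_nonoverlapping(cands):
        site_seq = tx[s : s + length]
        score = score_duplex(mir, site_seq, ops, exempt_position_one=exempt_position_one)
        sites.append(
            TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                site_start=s + 1,
                site_end=s + length,
                score=score,
                ops=ops,
                mirna_seq=mir,
                site_seq=site_seq,
            )
        )
    sites.sort(key=lambda st: (st.score, st.site_start))
    return sites


def scan_many(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_score: float = 5.0,
    max_bulges: int = 1,
    exempt_position_one: bool = False,
) -> list[TargetSite]:
    """Scan every miRNA against every transcript."""
    sites: list[TargetSite] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            sites.extend(
                scan_transcript(
                    mseq,
                    tseq,
                    max_score=max_score,
                    max_bulges=max_bulges,
                    mirna_id=mid,
                    transcript_id=tid,
                    exempt_position_one=exempt_position_one,
                )
            )
    sites.sort(key=lambda st: (st.mirna_id, st.transcript_id, st.score, st.site_start))
    return sites
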