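import numpy as np
import pytest

from apexmir.targets import (
    CleavageAmbiguousError,
    PairingError,
    TargetSite,
    _candidates_dp,
    _weights,
    normalize,
    pair_penalty,
    predict_cleavage_position,
    revcomp,
    scan_transcript,
    score_duplex,
    select_nonoverlapping,
)

from oracles import oracle_scan

MIR = "ACGTACGTACGTACGTACGTA"  # 21 nt


def perfect_site(mir: str) -> str:
    return revcomp(mir)


def mutate_site(mir: str, spec: list[tuple[int, str]]) -> tuple[str, str]:
    """Independent site construction: substitutions on the perfect complement,
    insertions for target bulges.  Returns (site, ops)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    wob = {"G": "T", "T": "G"}
    n = len(mir)
    chars = list(perfect_site(mir))  # index n - p holds the partner of miRNA pos p
    ops = ["M"] * n
    for pos, kind in sorted(spec, reverse=True):
        if kind == "mismatch":
            m = mir[pos - 1]
            bad = [c for c in "ACGT" if c != comp[m] and c != wob.get(m)]
            chars[n - pos] = bad[0]
        elif kind == "wobble":
            chars[n - pos] = wob[mir[pos - 1]]
        elif kind == "bulge":  # extra transcript nt between miRNA pos and pos+1
            chars.insert(n - pos, "A")
            ops.insert(pos, "B")
        else:
            raise AssertionError(kind)
    return "".join(chars), "".join(ops)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        assert score_duplex(MIR, perfect_site(MIR), "M" * 21) == 0.0

    @pytest.mark.parametrize(
        "spec, expected",
        [
            ([(14, "wobble")], 0.5),           # outside the doubled region
            ([(5, "mismatch")], 2.0),          # doubled at positions 2-13
            ([(3, "wobble")], 1.0),            # doubled wobble
            ([(20, "mismatch")], 1.0),
            ([(1, "mismatch")], 1.0),          # position 1 penalised by default
            ([(14, "bulge")], 1.0),            # bulge weight of position 15
            ([(5, "bulge")], 2.0),             # bulge inside the doubled region
            ([(5, "mismatch"), (14, "wobble"), (20, "mismatch")], 3.5),
        ],
    )
    def test_hand_applied_penalties(self, spec, expected):
        mir = "ACGTTGCAACGTTGCAACGTT"
        site, ops = mutate_site(mir, spec)
        assert score_duplex(mir, site, ops) == pytest.approx(expected)

    def test_position_one_exemption_flag(self):
        mir = "ACGTTGCAACGTTGCAACGTT"
        site, ops = mutate_site(mir, [(1, "mismatch")])
        assert score_duplex(mir, site, ops, exempt_position_one=True) == 0.0

    def test_inconsistent_path_rejected(self):
        with pytest.raises(PairingError):
            score_duplex(MIR, perfect_site(MIR), "M" * 20)
        with pytest.raises(PairingError):
            score_duplex(MIR, perfect_site(MIR), "M" * 20 + "B")

    def test_pair_penalty_symmetric(self):
        for a in "ACGT":
            for b in "ACGT":
                assert pair_penalty(a, b) == pair_penalty(b, a)

    def test_strand_perspective_symmetry_uniform_weights(self):
        """With flat positional weights the duplex scores identically from
        either strand's perspective (path reversed, bulge roles swapped)."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(8, 22))
            mir = "".join(rng.choice(list("ACGT"), n))
            spec = []
            if rng.random() < 0.5:
                spec.append((int(rng.integers(1, n)), "bulge"))
            if rng.random() < 0.7:
                spec.append((int(rng.integers(1, n + 1)), "mismatch"))
            try:
                site, ops = mutate_site(mir, spec)
            except (KeyError, IndexError):
                continue
            ones_m = [1.0] * n
            ones_s = [1.0] * len(site)
            fwd = score_duplex(mir, site, ops, weights=ones_m)
            swapped_ops = ops[::-1].translate(str.maketrans("Bb", "bB"))
            rev = score_duplex(site, mir, swapped_ops, weights=ones_s)
            assert fwd == pytest.approx(rev)


class TestPredictCleavage:
    def test_bulge_free_arithmetic(self):
        site = TargetSite("m", "t", 101, 121, 0.0, "M" * 21, MIR, perfect_site(MIR))
        assert predict_cleavage_position(site) == 112

    def test_transcript_bulge_shifts_partner_by_one(self):
        # bulge between miRNA positions 5 and 6 lies 3' of the position-10
        # partner on the transcript, shifting it one nucleotide 5'
        site_seq, ops = mutate_site(MIR, [(5, "bulge")])
        site = TargetSite("m", "t", 100, 100 + len(site_seq) - 1, 2.0, ops, MIR, site_seq)
        end = site.site_end
        # independent path walk
        i, t = 0, end
        expected = None
        for op in ops:
            if op == "M":
                i += 1
                if i == 10:
                    expected = t
                    break
                t -= 1
            elif op == "B":
                t -= 1
        assert expected == end - 10  # one further than the bulge-free end - 9
        assert predict_cleavage_position(site) == expected

    def test_bulge_after_position_ten_does_not_shift(self):
        site_seq, ops = mutate_site(MIR, [(14, "bulge")])
        site = TargetSite("m", "t", 50, 50 + len(site_seq) - 1, 1.0, ops, MIR, site_seq)
        assert predict_cleavage_position(site) == site.site_end - 9

    def test_mirna_bulge_at_ten_is_ambiguous(self):
        ops = "M" * 9 + "b" + "M" * 11
        site_seq = perfect_site(MIR)[1:]  # one transcript nt fewer
        site = TargetSite("m", "t", 10, 10 + len(site_seq) - 1, 2.0, ops, MIR, site_seq)
        assert site.cleavage_ambiguous and site.cleavage_pos is None
        with pytest.raises(CleavageAmbiguousError):
            predict_cleavage_position(site)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestScanTranscript:
    def test_planted_perfect_site_found_exactly(self):
        rng = np.random.default_rng(0)
        mir = random_seq(rng, 21)
        tx = random_seq(rng, 80) + perfect_site(mir) + random_seq(rng, 80)
        sites = scan_transcript(mir, tx, max_score=0.0)
        assert len(sites) == 1
        s = sites[0]
        assert (s.site_start, s.site_end, s.score) == (81, 101, 0.0)
        assert s.cleavage_pos == 101 - 9

    def test_site_above_threshold_absent(self):
        rng = np.random.default_rng(1)
        mir = "ACGTTGCAACGTTGCAACGTT"
        site, ops = mutate_site(
            mir, [(5, "mismatch"), (6, "mismatch"), (20, "mismatch"), (14, "wobble")]
        )
        assert score_duplex(mir, site, ops) == 5.5
        tx = random_seq(rng, 60) + site + random_seq(rng, 60)
        coords5 = {(s.site_start, s.site_end) for s in scan_transcript(mir, tx, 5.0)}
        assert (61, 60 + len(site)) not in coords5
        found = scan_transcript(mir, tx, 5.5)
        assert any(
            s.site_start == 61 and s.score == pytest.approx(5.5) for s in found
        )

    def test_shorter_transcript_returns_empty(self):
        assert scan_transcript(MIR, "ACGT") == []

    def test_max_score_zero_equals_naive_string_search(self):
        rng = np.random.default_rng(2)
        mir = random_seq(rng, 21)
        target = perfect_site(mir)
        tx = (
            random_seq(rng, 40) + target + random_seq(rng, 40)
            + target + random_seq(rng, 30)
        )
        naive = {
            (i + 1, i + 21)
            for i in range(len(tx) - 20)
            if tx[i : i + 21] == target
        }
        scanned = {(s.site_start, s.site_end) for s in scan_transcript(mir, tx, 0.0)}
        assert scanned == naive and len(naive) == 2

    def test_monotone_in_max_score(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mir = random_seq(rng, 21)
            tx = random_seq(rng, 300)
            lo = {(s.site_start, s.site_end) for s in scan_transcript(mir, tx, 6.0)}
            hi = {(s.site_start, s.site_end) for s in scan_transcript(mir, tx, 9.0)}
            assert lo <= hi

    def test_agrees_with_enumeration_oracle_small(self):
        rng = np.random.default_rng(4)
        for _ in range(6):
            mir = random_seq(rng, 21)
            tx = random_seq(rng, 120)
            got = [
                (s.score, s.site_start, s.site_end, s.ops)
                for s in scan_transcript(mir, tx, 7.0)
            ]
            assert got == oracle_scan(mir, tx, 7.0)

    def test_fast_path_matches_dp_search(self):
        """The cumulative-sum search and the banded alignment DP must select
        identical site sets for the single-bulge budget."""
        rng = np.random.default_rng(6)
        for _ in range(3):
            mir = random_seq(rng, 12)
            tx = random_seq(rng, 60)
            fast = [
                (s.score, s.site_start, s.site_end)
                for s in scan_transcript(mir, tx, 8.0, max_bulges=1)
            ]
            w = _weights(len(mir), False)
            dp = select_nonoverlapping(_candidates_dp(mir, tx, w, 8.0, 1))
            dp_sites = sorted(
                (round(sc, 6), s + 1, s + L) for sc, s, L, _ in dp
            )
            assert sorted((round(a, 6), b, c) for a, b, c in fast) == dp_sites

    def test_scores_are_half_integer(self):
        rng = np.random.default_rng(7)
        mir = random_seq(rng, 21)
        tx = random_seq(rng, 400)
        for s in scan_transcript(mir, tx, 10.0):
            assert (2 * s.score) == int(2 * s.score) and s.score >= 0

    def test_rna_input_equivalent_to_dna(self):
        mir_rna = MIR.replace("T", "U")
        tx = perfect_site(MIR).replace("T", "U")
        sites = scan_transcript(mir_rna, tx, 0.0)
        assert len(sites) == 1 and sites[0].score == 0.0

    def test_overlap_tie_resolution_keeps_lowest_score_then_smallest_start(self):
        cands = [(1.0, 10, 21, "M" * 21), (0.5, 15, 21, "M" * 21), (0.5, 40, 21, "M" * 21)]
        kept = select_nonoverlapping(cands)
        assert [(c[0], c[1]) for c in kept] == [(0.5, 15), (0.5, 40)]


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=6, max_size=24), st.data())
def test_score_duplex_nonnegative_half_integer_property(mir, data):
    """Any single-mutation duplex scores a nonnegative half-integer, and
    adding a mutation never lowers the score."""
    kind = data.draw(st.sampled_from(["mismatch", "bulge", None]))
    spec = []
    if kind == "bulge":
        spec = [(data.draw(st.integers(1, len(mir) - 1)), "bulge")]
    elif kind == "mismatch":
        spec = [(data.draw(st.integers(1, len(mir))), "mismatch")]
    site, ops = mutate_site(mir, spec)
    score = score_duplex(mir, site, ops)
    assert score >= 0.0
    assert 2 * score == int(2 * score)
    if spec:
        base, base_ops = mutate_site(mir, [])
        assert score >= score_duplex(mir, base, base_ops)
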