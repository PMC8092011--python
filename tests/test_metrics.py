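import numpy as np
import pandas as pd
import pytest

from apexmir.expression import MirnaFamily
from apexmir.io import APEX_DOMAINS, ExpressionAtlas
from apexmir.metrics import (
    metric_correlations,
    mirna_target_ratio,
    precursor_domain,
    processing_efficiency_ratio,
    records_to_frame,
    relative_pare,
)
from apexmir.pare import CleavageCall
from apexmir.targets import TargetSite, revcomp

MIR = "ACGTACGTACGTACGTACGTA"


def atlas(rows: dict[str, list[float]]) -> ExpressionAtlas:
    return ExpressionAtlas(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(APEX_DOMAINS))
    )


def flat_row(value: float, **overrides: float) -> list[float]:
    row = {d: value for d in APEX_DOMAINS}
    row.update(overrides)
    return [row[d] for d in APEX_DOMAINS]


FAMILY = MirnaFamily("famA", {"famA_iso0": MIR}, {"pA0": "famA_iso0", "pA1": "famA_iso0"})


def make_call(transcript_id: str, w_s: float, score: float = 0.0, start: int = 41) -> CleavageCall:
    site = TargetSite(
        "famA_iso0", transcript_id, start, start + 20, score, "M" * 21, MIR, revcomp(MIR)
    )
    return CleavageCall(site=site, w_s=w_s, w_l=w_s, ratio=1.0, passed=True)


class TestPrecursorDomain:
    def test_single_expressed_domain(self):
        prec = atlas({"pA0": flat_row(0.0, vasculature=9.0), "pA1": flat_row(0.0)})
        assert precursor_domain(prec, FAMILY) == "vasculature"

    def test_tie_breaks_to_atlas_order(self, caplog):
        prec = atlas({"pA0": flat_row(0.0, meristem=5.0, P2=5.0), "pA1": flat_row(0.0)})
        with caplog.at_level("WARNING"):
            assert precursor_domain(prec, FAMILY) == "meristem"
        assert any("tie" in rec.message for rec in caplog.records)

    def test_override_wins(self):
        prec = atlas({"pA0": flat_row(1.0, meristem=50.0), "pA1": flat_row(0.0)})
        assert precursor_domain(prec, FAMILY, {"famA": "abaxial"}) == "abaxial"

    def test_no_expressed_precursor_errors(self):
        prec = atlas({"pA0": flat_row(0.0), "pA1": flat_row(0.0)})
        with pytest.raises(ValueError, match="expressed"):
            precursor_domain(prec, FAMILY)

    def test_matches_argmax_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(0, 10, (2, 12))
            prec = ExpressionAtlas(
                pd.DataFrame(vals, index=["pA0", "pA1"], columns=list(APEX_DOMAINS))
            )
            brute = list(APEX_DOMAINS)[int(np.argmax(vals.sum(axis=0)))]
            assert precursor_domain(prec, FAMILY) == brute


PREC = atlas({"pA0": flat_row(1.0, vasculature=10.0), "pA1": flat_row(0.5, vasculature=4.0)})
FAMS = {"famA": FAMILY}


class TestRelativePare:
    def test_unique_mapping_schemes_identical(self):
        tgt = atlas({"t1": flat_row(2.0, vasculature=4.0)})
        calls = [make_call("t1", w_s=8.0)]
        for scheme in ("independent", "abundance-weighted"):
            (rec,) = relative_pare(calls, tgt, PREC, FAMS, scheme=scheme)
            assert rec.w_s == 8.0
            assert rec.relative_pare == pytest.approx(8.0 / 4.0)

    def _shared_calls_and_transcripts(self):
        # identical sequence context around both cleavage positions -> one signature
        seq = "A" * 40 + revcomp(MIR) + "A" * 40
        transcripts = {"t1": seq, "t2": seq}
        return [make_call("t1", w_s=8.0), make_call("t2", w_s=8.0)], transcripts

    def test_abundance_weighted_split_three_to_one(self):
        calls, transcripts = self._shared_calls_and_transcripts()
        tgt = atlas({"t1": flat_row(1.0, vasculature=3.0), "t2": flat_row(1.0, vasculature=1.0)})
        recs = relative_pare(
            calls, tgt, PREC, FAMS, scheme="abundance-weighted", transcripts=transcripts
        )
        assigned = {r.target_id: r.w_s for r in recs}
        assert assigned == pytest.approx({"t1": 6.0, "t2": 2.0})
        indep = relative_pare(
            calls, tgt, PREC, FAMS, scheme="independent", transcripts=transcripts
        )
        assert {r.target_id: r.w_s for r in indep} == {"t1": 8.0, "t2": 8.0}

    def test_weighted_assignment_conserves_signature_ws(self):
        calls, transcripts = self._shared_calls_and_transcripts()
        tgt = atlas({"t1": flat_row(1.0, vasculature=3.0), "t2": flat_row(1.0, vasculature=1.0)})
        recs = relative_pare(
            calls, tgt, PREC, FAMS, scheme="abundance-weighted", transcripts=transcripts
        )
        assert sum(r.w_s for r in recs) == pytest.approx(8.0, abs=1e-9)

    def test_low_expression_targets_excluded(self):
        tgt = atlas({"t1": flat_row(0.2)})  # below 1 RPM everywhere
        assert relative_pare([make_call("t1", 8.0)], tgt, PREC, FAMS) == []

    def test_zero_domain_expression_flagged_undefined(self):
        tgt = atlas({"t1": flat_row(2.0, vasculature=0.0)})
        (rec,) = relative_pare([make_call("t1", 8.0)], tgt, PREC, FAMS)
        assert not rec.defined

    def test_scaling_equivariance(self):
        tgt = atlas({"t1": flat_row(2.0, vasculature=4.0)})
        (base,) = relative_pare([make_call("t1", 8.0)], tgt, PREC, FAMS)
        (scaled_pare,) = relative_pare([make_call("t1", 24.0)], tgt, PREC, FAMS)
        assert scaled_pare.relative_pare == pytest.approx(3 * base.relative_pare)
        tgt3 = atlas({"t1": flat_row(6.0, vasculature=12.0)})
        (scaled_expr,) = relative_pare([make_call("t1", 8.0)], tgt3, PREC, FAMS)
        assert scaled_expr.relative_pare == pytest.approx(base.relative_pare / 3)


class TestMirnaTargetRatio:
    def test_per_target_ratio(self):
        # precursor sum in vasculature = 14
        tgt = atlas({"t1": flat_row(1.0, vasculature=7.0)})
        (rec,) = mirna_target_ratio(PREC, tgt, FAMILY, ["t1"])
        assert rec.ratio == pytest.approx(2.0)

    def test_combined_ratio(self):
        tgt = atlas(
            {"t1": flat_row(1.0, vasculature=7.0), "t2": flat_row(1.0, vasculature=21.0)}
        )
        (rec,) = mirna_target_ratio(PREC, tgt, FAMILY, ["t1", "t2"], mode="combined")
        assert rec.ratio == pytest.approx(14.0 / 28.0)

    def test_zero_denominator_flagged(self):
        tgt = atlas({"t1": flat_row(1.0, vasculature=0.0)})
        (rec,) = mirna_target_ratio(PREC, tgt, FAMILY, ["t1"])
        assert rec.ratio is None

    def test_combined_is_harmonic_combination_of_per_target(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            exprs = rng.uniform(1, 20, 4)
            rows = {f"t{i}": flat_row(1.0, vasculature=float(e)) for i, e in enumerate(exprs)}
            tgt = atlas(rows)
            per = mirna_target_ratio(PREC, tgt, FAMILY, list(rows))
            (comb,) = mirna_target_ratio(PREC, tgt, FAMILY, list(rows), mode="combined")
            assert comb.ratio == pytest.approx(1.0 / sum(1.0 / r.ratio for r in per))


class TestMetricCorrelations:
    def test_linear_relation_gives_r_one(self):
        df = pd.DataFrame({"relative_pare": [1.0, 2.0, 3.0, 4.0], "score": [2.0, 4.0, 6.0, 8.0]})
        out = metric_correlations(df, covariate_cols=["score"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r_hand = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        df = pd.DataFrame({"relative_pare": y, "score": x})
        out = metric_correlations(df, covariate_cols=["score"])
        assert out.loc[0, "r"] == pytest.approx(r_hand)

    def test_undefined_records_dropped(self):
        df = pd.DataFrame(
            {"relative_pare": [1.0, np.nan, 3.0, 4.0], "score": [1.0, 2.0, 3.0, 4.0]}
        )
        out = metric_correlations(df, covariate_cols=["score"])
        assert out.loc[0, "n"] == 3

    def test_too_few_points_errors(self):
        df = pd.DataFrame({"relative_pare": [1.0, 2.0], "score": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 3"):
            metric_correlations(df, covariate_cols=["score"])

    def test_independent_covariate_stays_below_null_quantile(self):
        """Permuting a covariate destroys correlation: |r| should stay under
        the analytic 95% null quantile in ~95% of seeds."""
        n = 20
        crit = 1.96 / np.sqrt(n - 3)  # Fisher-z approximation
        crit = float(np.tanh(crit))
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            metric = rng.uniform(0, 1, n)
            cov = rng.permutation(metric)
            df = pd.DataFrame({"relative_pare": metric, "score": cov})
            r = metric_correlations(df, covariate_cols=["score"]).loc[0, "r"]
            if abs(r) < crit:
                hits += 1
        assert hits >= 180


class TestProcessingEfficiency:
    def _atlases(self, mut_rows, wt_rows):
        return atlas(mut_rows), atlas(wt_rows)

    def test_identical_atlases_all_equal(self):
        rows = {"p1": flat_row(5.0), "p2": flat_row(2.0)}
        mut, wt = self._atlases(rows, rows)
        table = processing_efficiency_ratio(mut, wt, "CZ", "P3")
        assert (table["classification"] == "equal").all()
        assert np.allclose(table[["ratio_a", "ratio_b"]], 1.0)

    def test_doubling_only_in_tissue_b_classifies_above(self):
        wt_rows = {"p1": flat_row(4.0)}
        mut_rows = {"p1": flat_row(4.0, P3=8.5)}
        mut, wt = self._atlases(mut_rows, wt_rows)
        table = processing_efficiency_ratio(mut, wt, "CZ", "P3", pseudocount=0.5)
        assert table.loc[0, "classification"] == "above"
        assert table.loc[0, "ratio_b"] == pytest.approx(9.0 / 4.5)
        assert table.loc[0, "ratio_a"] == pytest.approx(1.0)

    def test_missing_precursor_named(self):
        mut = atlas({"p1": flat_row(1.0), "p2": flat_row(1.0)})
        wt = atlas({"p1": flat_row(1.0)})
        with pytest.raises(KeyError, match="p2"):
            processing_efficiency_ratio(mut, wt, "CZ", "P3")

    def test_counts_match_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(2)
        genes = [f"p{i}" for i in range(30)]
        mut_vals = rng.uniform(0.0, 20.0, (30, 12))
        wt_vals = rng.uniform(0.0, 20.0, (30, 12))
        mut = ExpressionAtlas(pd.DataFrame(mut_vals, index=genes, columns=list(APEX_DOMAINS)))
        wt = ExpressionAtlas(pd.DataFrame(wt_vals, index=genes, columns=list(APEX_DOMAINS)))
        table = processing_efficiency_ratio(mut, wt, "CZ", "P3", pseudocount=0.5)
        ia, ib = list(APEX_DOMAINS).index("CZ"), list(APEX_DOMAINS).index("P3")
        above = below = 0
        for i in range(30):
            if max(mut_vals[i, ia], wt_vals[i, ia], mut_vals[i, ib], wt_vals[i, ib]) < 1.0:
                continue
            ra = (mut_vals[i, ia] + 0.5) / (wt_vals[i, ia] + 0.5)
            rb = (mut_vals[i, ib] + 0.5) / (wt_vals[i, ib] + 0.5)
            if rb > ra:
                above += 1
            elif rb < ra:
                below += 1
        counts = table["classification"].value_counts()
        assert counts.get("above", 0) == above
        assert counts.get("below", 0) == below

    def test_records_to_frame_shapes(self):
        tgt = atlas({"t1": flat_row(2.0, vasculature=4.0)})
        recs = relative_pare([make_call("t1", 8.0)], tgt, PREC, FAMS)
        df = records_to_frame(recs)
        assert list(df["target"]) == ["t1"]
        assert df.loc[0, "relative_pare"] == pytest.approx(2.0)
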