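"""Cleavage-efficacy metrics built on validated PARE calls and the atlas.

* ``relative_pare`` -- the relative frequency of PARE signatures: the W_s
  value of a validated cleavage signature over the target's mRNA level in
  the miRNA precursor domain.  Signatures shared by several targets (caused
  by target sequence conservation) are handled two ways: assigned to each
  target independently, or distributed according to the targets' relative
  transcript abundance in the precursor domain.
* ``mirna_target_ratio`` -- summed precursor expression over target
  expression in the precursor domain, per target or combined over all
  targets of a family.
* ``metric_correlations`` -- Pearson correlations of the relative PARE
  frequency against complementarity score, miRNA level, or the
  miRNA-to-target ratio.
* ``processing_efficiency_ratio`` -- per-precursor mutant/wild-type
  expression ratios in two tissues (the dcl1-2 processing-efficiency
  comparison) and their classification relative to the equal-ratio line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import NONOVERLAPPING_DOMAINS, ExpressionAtlas
from .expression import MirnaFamily
from .pare import CleavageCall

logger = logging.getLogger(__name__)

SCHEMES = ("independent", "abundance-weighted")


@dataclass
class RelativePareRecord:
    target_id: str
    family: str
    mirna_id: str
    w_s: float
    target_expr: float
    relative_pare: float | None  # None when the denominator is 0 (flagged undefined)
    scheme: str
    score: float
    signature_group: str

    @property
    def defined(self) -> bool:
        return self.relative_pare is not None


@dataclass
class MirnaTargetRatio:
    family: str
    target_id: str  # or "combined"
    precursor_sum: float
    target_expr: float
    ratio: float | None  # None (flagged) when target_expr == 0


def precursor_domain(
    atlas: ExpressionAtlas,
    family: MirnaFamily,
    override: Mapping[str, str] | None = None,
) -> str:
    """The domain where a family's precursors are most expressed.

    Resolved as the argmax of summed precursor expression across domains;
    ties break to the first domain in atlas order (with a warning).  An
    explicit family -> domain mapping overrides the rule.
    """
    if override and family.name in override:
        dom = override[family.name]
        if dom not in atlas.domains:
            raise KeyError(f"override domain {dom!r} not in atlas")
        return dom
    precs = [p for p in family.all_precursors if p in atlas.data.index]
    if not precs:
        raise ValueError(f"family {family.name!r} has no precursors in the atlas")
    totals = atlas.data.loc[precs].sum(axis=0)
    if float(totals.max()) <= 0:
        raise ValueError(f"family {family.name!r} has no expressed precursor")
    best = totals.to_numpy(dtype=float)
    winners = np.nonzero(best == best.max())[0]
    if len(winners) > 1:
        logger.warning(
            "precursor domain tie for family %s between %s; keeping %s",
            family.name,
            [atlas.domains[i] for i in winners],
            atlas.domains[winners[0]],
        )
    return atlas.domains[int(winners[0])]


def _family_of(mirna_id: str, families: Mapping[str, MirnaFamily]) -> MirnaFamily:
    for fam in families.values():
        if mirna_id in fam.mature_isoforms:
            return fam
    raise KeyError(f"miRNA {mirna_id!r} not in any family")


def signature_groups(
    calls: Sequence[CleavageCall],
    families: Mapping[str, MirnaFamily],
    transcripts: Mapping[str, str] | None = None,
    context: int = 15,
) -> list[str]:
    """Group label per call; calls in one group share one PARE signature.

    Two calls share a signature when they come from the same miRNA family
    and their transcripts carry an identical sequence context of
    ``2 * context + 1`` nt around the cleavage position (the situation
    created by target sequence conservation).  Without transcript sequences
    every call is its own group.
    """
    labels: list[str] = []
    seen: dict[tuple[str, str], str] = {}
    for idx, call in enumerate(calls):
        site = call.site
        fam = _family_of(site.mirna_id, families).name
        if transcripts is None or site.transcript_id not in transcripts:
            labels.append(f"sig{idx}")
            continue
        seq = transcripts[site.transcript_id]
        lo = max(0, site.cleavage_pos - 1 - context)
        hi = min(len(seq), site.cleavage_pos + context)
        key = (fam, seq[lo:hi].upper().replace("U", "T"))
        if key not in seen:
            seen[key] = f"sig{len(seen)}"
        labels.append(seen[key])
    return labels


def relative_pare(
    calls: Sequence[CleavageCall],
    target_atlas: ExpressionAtlas,
    precursor_atlas: ExpressionAtlas,
    families: Mapping[str, MirnaFamily],
    scheme: str = "independent",
    transcripts: Mapping[str, str] | None = None,
    domain_override: Mapping[str, str] | None = None,
    min_rpm: float = 1.0,
    passed_only: bool = True,
) -> list[RelativePareRecord]:
    """Relative PARE frequency per validated target site.

    ``scheme="independent"``: every target of a shared signature receives
    the full observed W_s.  ``scheme="abundance-weighted"``: a signature
    shared by k targets is split proportionally to their expression in the
    miRNA precursor domain.  Targets below ``min_rpm`` in every tissue are
    excluded; a zero denominator flags the record undefined.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    use = [c for c in calls if c.passed] if passed_only else list(calls)
    groups = signature_groups(use, families, transcripts)

    # drop targets failing the global expression filter
    kept: list[tuple[CleavageCall, str]] = []
    for call, grp in zip(use, groups):
        tid = call.site.transcript_id
        if tid not in target_atlas.data.index:
            raise KeyError(f"target {tid!r} absent from target atlas")
        if float(target_atlas.data.loc[tid].max()) < min_rpm:
            continue
        kept.append((call, grp))

    by_group: dict[str, list[CleavageCall]] = {}
    for call, grp in kept:
        by_group.setdefault(grp, []).append(call)

    records: list[RelativePareRecord] = []
    for call, grp in kept:
        site = call.site
        fam = _family_of(site.mirna_id, families)
        dom = precursor_domain(precursor_atlas, fam, domain_override)
        expr = float(target_atlas.data.loc[site.transcript_id, dom])
        members = by_group[grp]
        group_ws = float(np.mean([m.w_s for m in members]))
        if scheme == "independent" or len(members) == 1:
            assigned = group_ws
        else:
            weights = np.array(
                [float(target_atlas.data.loc[m.site.transcript_id, dom]) for m in members]
            )
            total = weights.sum()
            if total > 0:
                share = expr / total
            else:
                share = 1.0 / len(members)
            assigned = group_ws * share
        rel = assigned / expr if expr > 0 else None
        records.append(
            RelativePareRecord(
                target_id=site.transcript_id,
                family=fam.name,
                mirna_id=site.mirna_id,
                w_s=assigned,
                target_expr=expr,
                relative_pare=rel,
                scheme=scheme,
                score=site.score,
                signature_group=grp,
            )
        )
    n_undef = sum(not r.defined for r in records)
    if n_undef:
        logger.info("relative PARE: %d records flagged undefined (zero expression)", n_undef)
    return records


def mirna_target_ratio(
    precursor_atlas: ExpressionAtlas,
    target_atlas: ExpressionAtlas,
    family: MirnaFamily,
    targets: Sequence[str],
    mode: str = "per-target",
    domain_override: Mapping[str, str] | None = None,
) -> list[MirnaTargetRatio]:
    """miRNA-to-target expression ratio in the family's precursor domain."""
    if mode not in ("per-target", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    dom = precursor_domain(precursor_atlas, family, domain_override)
    precs = [p for p in family.all_precursors if p in precursor_atlas.data.index]
    prec_sum = float(precursor_atlas.data.loc[precs, dom].sum())
    out: list[MirnaTargetRatio] = []
    if mode == "per-target":
        for tid in targets:
            expr = float(target_atlas.data.loc[tid, dom])
            ratio = prec_sum / expr if expr > 0 else None
            out.append(MirnaTargetRatio(family.name, tid, prec_sum, expr, ratio))
    else:
        expr = float(target_atlas.data.loc[list(targets), dom].sum())
        ratio = prec_sum / expr if expr > 0 else None
        out.append(MirnaTargetRatio(family.name, "combined", prec_sum, expr, ratio))
    return out


def records_to_frame(records: Sequence[RelativePareRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [r.target_id for r in records],
            "family": [r.family for r in records],
            "mirna": [r.mirna_id for r in records],
            "w_s": [r.w_s for r in records],
            "target_expr": [r.target_expr for r in records],
            "relative_pare": [r.relative_pare if r.defined else np.nan for r in records],
            "scheme": [r.scheme for r in records],
            "score": [r.score for r in records],
            "signature_group": [r.signature_group for r in records],
        }
    )


def metric_correlations(
    table: pd.DataFrame,
    metric_col: str = "relative_pare",
    covariate_cols: Sequence[str] = ("score", "mirna_level", "mirna_target_ratio"),
) -> pd.DataFrame:
    """Pearson r and p of the metric against each covariate column.

    Rows with an undefined metric or covariate are dropped per covariate
    (and counted in the log); fewer than 3 remaining points is an error.
    """
    rows = []
    for cov in covariate_cols:
        if cov not in table.columns:
            raise KeyError(f"covariate column {cov!r} missing")
        sub = table[[metric_col, cov]].dropna()
        dropped = len(table) - len(sub)
        if dropped:
            logger.info("correlation vs %s: dropped %d undefined records", cov, dropped)
        if len(sub) < 3:
            raise ValueError(f"need >= 3 defined records for covariate {cov!r}, have {len(sub)}")
        r, p = pearsonr(sub[metric_col], sub[cov])
        rows.append({"covariate": cov, "r": float(r), "pvalue": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def processing_efficiency_ratio(
    expr_mut: ExpressionAtlas,
    expr_wt: ExpressionAtlas,
    tissue_a: str,
    tissue_b: str,
    pseudocount: float = 0.5,
    min_rpm: float = 1.0,
    rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Mutant/wild-type expression ratios per precursor in two tissues.

    For each precursor, ``ratio_a = (mut + pc) / (wt + pc)`` in tissue_a and
    likewise in tissue_b; the classification says whether the precursor lies
    above the equal-ratio line (``ratio_b > ratio_a``: stronger mutant effect
    in tissue_b, i.e. higher processing efficacy there in the wild type),
    on it, or below.  Only precursors reaching ``min_rpm`` in at least one of
    the four measurements are reported.
    """
    for dom in (tissue_a, tissue_b):
        for atlas, label in ((expr_mut, "mutant"), (expr_wt, "wild-type")):
            if dom not in atlas.domains:
                raise KeyError(f"tissue {dom!r} absent from {label} atlas")
    missing = [g for g in expr_mut.genes if g not in expr_wt.data.index]
    if missing:
        raise KeyError(f"precursor {missing[0]!r} missing from the wild-type atlas")
    rows = []
    for gene in expr_mut.genes:
        vals = [
            float(expr_mut.data.loc[gene, tissue_a]),
            float(expr_wt.data.loc[gene, tissue_a]),
            float(expr_mut.data.loc[gene, tissue_b]),
            float(expr_wt.data.loc[gene, tissue_b]),
        ]
        if max(vals) < min_rpm:
            continue
        r_a = (vals[0] + pseudocount) / (vals[1] + pseudocount)
        r_b = (vals[2] + pseudocount) / (vals[3] + pseudocount)
        if math.isclose(r_a, r_b, rel_tol=rel_tol):
            cls = "equal"
        elif r_b > r_a:
            cls = "above"
        else:
            cls = "below"
        rows.append(
            {
                "precursor": gene,
                "ratio_a": r_a,
                "ratio_b": r_b,
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)
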