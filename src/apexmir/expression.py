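"""Expression-atlas computations.

Covers the atlas-level operations of the analysis: per-gene min-max
normalisation (``y(i) = [x(i) - min(x)] / [max(x) - min(x)]``) used for
heatmap clustering, the >= 1 RPM expressed-precursor filter, family-level
precursor sums over a domain subset, the precursor-vs-mature Spearman
correlation with outlier flagging, and deterministic hierarchical
clustering of atlas rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, spearmanr

from .io import NONOVERLAPPING_DOMAINS, ExpressionAtlas, SmallRnaTable

logger = logging.getLogger(__name__)


@dataclass
class MirnaFamily:
    """A miRNA family: mature isoforms and the precursor genes producing them."""

    name: str
    mature_isoforms: dict[str, str]  # isoform id -> mature sequence
    precursors: dict[str, str] = field(default_factory=dict)  # precursor id -> isoform id

    def __post_init__(self) -> None:
        for prec, iso in self.precursors.items():
            if iso not in self.mature_isoforms:
                raise ValueError(
                    f"precursor {prec!r} maps to unknown isoform {iso!r} "
                    f"in family {self.name!r}"
                )

    def precursors_of(self, isoform: str) -> list[str]:
        return [p for p, iso in self.precursors.items() if iso == isoform]

    @property
    def all_precursors(self) -> list[str]:
        return list(self.precursors)


def families_from_table(df: pd.DataFrame, mature_seqs: Mapping[str, str]) -> dict[str, MirnaFamily]:
    """Build families from a membership table (columns family/isoform/precursor)."""
    fams: dict[str, MirnaFamily] = {}
    for fam_name, sub in df.groupby("family", sort=True):
        isoforms = {iso: mature_seqs.get(iso, "") for iso in sub["isoform"].unique()}
        precursors = dict(zip(sub["precursor"], sub["isoform"]))
        fams[fam_name] = MirnaFamily(fam_name, isoforms, precursors)
    return fams


# ---------------------------------------------------------------------------
# normalisation and filtering
# ---------------------------------------------------------------------------


def minmax_normalize(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Rescale each gene row to [0, 1]; a constant row maps to all zeros."""
    values = atlas.values
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ExpressionAtlas(pd.DataFrame(norm, index=atlas.genes, columns=atlas.domains))


def expressed_precursors(atlas: ExpressionAtlas, min_rpm: float = 1.0) -> list[str]:
    """Genes reaching ``min_rpm`` (inclusive) in at least one domain."""
    mask = atlas.values.max(axis=1) >= min_rpm
    return [g for g, m in zip(atlas.genes, mask) if m]


def family_precursor_sum(
    atlas: ExpressionAtlas,
    family: MirnaFamily,
    isoform: str,
    domains: Sequence[str] = NONOVERLAPPING_DOMAINS,
) -> tuple[pd.Series, float]:
    """Summed precursor expression for one mature isoform over a domain subset.

    Returns the per-domain sum and the grand total across the listed domains.
    """
    precs = family.precursors_of(isoform)
    if not precs:
        raise ValueError(f"isoform {isoform!r} has no precursors in family {family.name!r}")
    missing = [d for d in domains if d not in atlas.domains]
    if missing:
        raise KeyError(f"domains absent from atlas: {missing}")
    sub = atlas.data.loc[precs, list(domains)]
    per_domain = sub.sum(axis=0)
    return per_domain, float(per_domain.sum())


# ---------------------------------------------------------------------------
# precursor vs mature correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n: int
    table: pd.DataFrame  # per-isoform log values, ranks, residuals, outlier flag
    outliers: list[str]


def precursor_mature_correlation(
    precursor_totals: Mapping[str, float],
    mature: SmallRnaTable,
    min_raw: int = 10,
    pseudocount: float = 1.0,
    outlier_mads: float = 2.0,
) -> CorrelationResult:
    """Spearman correlation of log precursor totals vs log mature miRNA RPM.

    Isoforms enter the analysis when detected (raw read count >= ``min_raw``);
    both axes are log10(x + pseudocount) transformed (rank-based, so the base
    and pseudocount matter only for zero handling).  Residuals from the
    least-squares fit of log mature level on log precursor total identify
    isoforms with higher or lower mature accumulation than their precursor
    expression predicts; an isoform is flagged when its absolute residual
    exceeds ``outlier_mads`` median absolute deviations.  (Residuals on the
    ranks themselves are too coarse to separate even strong fold changes;
    the log-scale fit is robust to the flagged outliers through the MAD
    threshold.)
    """
    detected = [
        iso
        for iso in precursor_totals
        if iso in mature.data.index and mature.raw[iso] >= min_raw
    ]
    if len(detected) < 3:
        raise ValueError(
            f"need >= 3 isoforms detected at raw >= {min_raw}, have {len(detected)}"
        )
    x = np.log10(np.array([precursor_totals[i] for i in detected]) + pseudocount)
    y = np.log10(mature.rpm[detected].to_numpy(dtype=float) + pseudocount)
    r, p = spearmanr(x, y)

    rx, ry = rankdata(x), rankdata(y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    scale = mad if mad > 0 else float(np.std(resid)) or 1.0
    flagged = np.abs(resid) > outlier_mads * scale

    table = pd.DataFrame(
        {
            "log_precursor": x,
            "log_mature": y,
            "rank_precursor": rx,
            "rank_mature": ry,
            "residual": resid,
            "outlier": flagged,
        },
        index=pd.Index(detected, name="isoform"),
    )
    outliers = [iso for iso, f in zip(detected, flagged) if f]
    logger.info(
        "precursor-mature correlation: r=%.3f p=%.3g over %d isoforms, %d outliers",
        r,
        p,
        len(detected),
        len(outliers),
    )
    return CorrelationResult(float(r), float(p), len(detected), table, outliers)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    row_order: list[str]


def cluster_rows(
    atlas: ExpressionAtlas, method: str = "complete", metric: str = "euclidean"
) -> ClusterResult:
    """Deterministic agglomerative clustering of atlas rows.

    Euclidean distance with complete linkage by default; the emitted row
    order is the dendrogram leaf order, which for fixed input order and
    distances is deterministic.
    """
    if len(atlas.genes) < 2:
        raise ValueError("clustering needs at least 2 rows")
    dist = pdist(atlas.values, metric=metric)
    Z = linkage(dist, method=method)
    order = leaves_list(Z)
    return ClusterResult(Z, [atlas.genes[i] for i in order])
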