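"""End-to-end analysis: scan -> PARE validation -> efficacy metrics.

The pipeline wires the stages together under one YAML-configurable run:

1. predict binding sites for every miRNA against every transcript;
2. validate predicted cleavage positions against the PARE library with the
   dual-window filter;
3. compute relative PARE frequencies for validated targets;
4. compute per-target and combined miRNA-to-target ratios;
5. correlate the relative PARE frequency with complementarity score,
   miRNA level and miRNA-to-target ratio.

Every run writes its resolved configuration next to the outputs, and for
fixed inputs the outputs are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression, io, metrics, pare, targets

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and stage parameters of one pipeline run."""

    # inputs
    mirnas: str = ""
    transcripts: str = ""
    precursor_atlas: str = ""
    target_atlas: str = ""
    pare_tags: str = ""
    families: str = ""
    mature: str | None = None
    outdir: str = "results"
    # stage parameters (study defaults)
    max_score: float = 5.0
    max_bulges: int = 1
    exempt_position_one: bool = False
    w_small: int = 5
    w_large: int = 31
    min_ratio: float = 0.75
    min_ws: float = 4.0
    window_stat: str = "sum"
    normalized_pare: bool = False
    min_rpm: float = 1.0
    min_raw: int = 10
    scheme: str = "independent"
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    sites: list
    calls: list
    relative_pare_table: pd.DataFrame
    ratio_table: pd.DataFrame
    correlation_table: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all result tables to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")

    _stage("read inputs")
    mirna_seqs = io.read_fasta(config.mirnas)
    transcripts = io.read_fasta(config.transcripts)
    prec_atlas = io.read_expression_tsv(config.precursor_atlas)
    tgt_atlas = io.read_expression_tsv(config.target_atlas)
    lengths = {tid: len(seq) for tid, seq in transcripts.items()}
    library = io.read_pare_bed(config.pare_tags, lengths)
    fam_table = io.read_family_tsv(config.families)
    families = expression.families_from_table(fam_table, mirna_seqs)

    _stage("scan transcripts")
    sites = targets.scan_many(
        mirna_seqs,
        transcripts,
        max_score=config.max_score,
        max_bulges=config.max_bulges,
        exempt_position_one=config.exempt_position_one,
    )
    logger.info("sites predicted: %d", len(sites))
    usable = [s for s in sites if not s.cleavage_ambiguous]
    if len(usable) < len(sites):
        logger.info("cleavage-ambiguous sites excluded: %d", len(sites) - len(usable))

    _stage("PARE validation")
    calls = pare.validate_sites(
        usable,
        library,
        w_small=config.w_small,
        w_large=config.w_large,
        min_ratio=config.min_ratio,
        min_ws=config.min_ws,
        window_stat=config.window_stat,
        normalized=config.normalized_pare,
    )
    targets_with_sites = {s.transcript_id for s in usable}
    targets_validated = {c.site.transcript_id for c in calls if c.passed}
    logger.info(
        "targets with predicted sites: %d; validated: %d; without degradome products: %d",
        len(targets_with_sites),
        len(targets_validated),
        len(targets_with_sites - targets_validated),
    )

    _stage("relative PARE")
    records = metrics.relative_pare(
        calls,
        tgt_atlas,
        prec_atlas,
        families,
        scheme=config.scheme,
        transcripts=transcripts,
        min_rpm=config.min_rpm,
    )
    rel_table = metrics.records_to_frame(records)

    _stage("miRNA-to-target ratios")
    ratio_rows = []
    for fam_name in sorted(families):
        fam = families[fam_name]
        fam_targets = sorted(
            {
                r.target_id
                for r in records
                if r.family == fam_name and r.target_id in tgt_atlas.data.index
            }
        )
        if not fam_targets:
            continue
        for mode in ("per-target", "combined"):
            for rec in metrics.mirna_target_ratio(
                prec_atlas, tgt_atlas, fam, fam_targets, mode=mode
            ):
                ratio_rows.append(
                    {
                        "family": rec.family,
                        "target": rec.target_id,
                        "precursor_sum": rec.precursor_sum,
                        "target_expr": rec.target_expr,
                        "ratio": rec.ratio if rec.ratio is not None else float("nan"),
                        "mode": mode,
                    }
                )
    ratio_table = pd.DataFrame(
        ratio_rows,
        columns=["family", "target", "precursor_sum", "target_expr", "ratio", "mode"],
    )

    _stage("correlations")
    per_target_ratio = {
        (row["family"], row["target"]): row["ratio"]
        for _, row in ratio_table.iterrows()
        if row["mode"] == "per-target"
    }
    mirna_level = {}
    for fam_name, fam in families.items():
        precs = [p for p in fam.all_precursors if p in prec_atlas.data.index]
        mirna_level[fam_name] = float(
            prec_atlas.data.loc[precs, list(io.NONOVERLAPPING_DOMAINS)].sum().sum()
        )
    corr_input = rel_table.copy()
    corr_input["mirna_level"] = corr_input["family"].map(mirna_level)
    corr_input["mirna_target_ratio"] = [
        per_target_ratio.get((row["family"], row["target"]), float("nan"))
        for _, row in corr_input.iterrows()
    ]
    try:
        corr_table = metrics.metric_correlations(corr_input)
    except ValueError as err:
        logger.warning("correlation stage skipped: %s", err)
        corr_table = pd.DataFrame(columns=["covariate", "r", "pvalue", "n"])

    _stage("write outputs")
    outputs = {
        "sites": outdir / "sites.tsv",
        "calls": outdir / "calls.tsv",
        "relative_pare": outdir / "relative_pare.tsv",
        "ratios": outdir / "ratios.tsv",
        "correlations": outdir / "correlations.tsv",
    }
    io.write_sites_tsv(sites, outputs["sites"])
    io.write_calls_tsv(calls, outputs["calls"])
    rel_table.to_csv(outputs["relative_pare"], sep="\t", index=False, float_format="%.10g")
    ratio_table.to_csv(outputs["ratios"], sep="\t", index=False, float_format="%.10g")
    corr_table.to_csv(outputs["correlations"], sep="\t", index=False, float_format="%.10g")
    return RunResult(sites, calls, rel_table, ratio_table, corr_table, outputs)
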