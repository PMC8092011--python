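"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* multi-member miRNA families whose precursors follow one of three
  domain-expression archetypes (meristem, primordia, vasculature), with
  log-normal per-domain dispersion;
* mature miRNA abundance coupled to summed precursor expression through
  multiplicative log-normal noise, with a configurable fraction of outlier
  isoforms shifted by a fixed fold;
* target transcripts carrying complementary sites with controlled
  mismatch/wobble/bulge structure (and hand-computable penalty scores);
* replicated PARE libraries with a homogeneous Poisson degradation
  background plus a tag peak at each truly cleaved site; decoy sites
  receive background only;
* shared PARE signatures, created by copying a site's sequence context
  into a second target of the same family (mimicking target sequence
  conservation), whose peak tags map to every member locus.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import MirnaFamily
from .io import (
    APEX_DOMAINS,
    NONOVERLAPPING_DOMAINS,
    ExpressionAtlas,
    PareLibrary,
    SmallRnaTable,
    write_expression_tsv,
    write_family_tsv,
    write_fasta,
    write_pare_bed,
    write_smallrna_tsv,
)
from .targets import TargetSite, normalize, position_weight, revcomp

ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}

# domain weight archetypes (unnormalised); drawn from the three major
# expression clusters of the shoot apex: meristem, leaf primordia, vasculature
ARCHETYPES: dict[str, dict[str, float]] = {
    "meristem": {
        "meristem": 10.0, "CZ": 7.0, "L1": 5.0, "L2": 5.0, "P0": 3.0,
        "P1": 1.0, "P2": 0.5, "P3": 0.5, "internode": 0.5,
        "vasculature": 0.5, "adaxial": 0.5, "abaxial": 0.5,
    },
    "primordia": {
        "meristem": 0.5, "CZ": 0.3, "L1": 1.0, "L2": 1.0, "P0": 5.0,
        "P1": 8.0, "P2": 8.0, "P3": 6.0, "internode": 1.0,
        "vasculature": 0.5, "adaxial": 4.0, "abaxial": 4.0,
    },
    "vasculature": {
        "meristem": 0.5, "CZ": 0.3, "L1": 0.3, "L2": 0.3, "P0": 0.3,
        "P1": 0.5, "P2": 0.5, "P3": 1.0, "internode": 5.0,
        "vasculature": 12.0, "adaxial": 0.5, "abaxial": 0.5,
    },
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the shipped conditions."""

    seed: int = 0
    # family structure
    n_families: int = 20
    isoforms_per_family: int = 2
    precursors_per_family: int = 4
    n_targets_per_family: int = 3
    mirna_length: int = 21
    transcript_length: int = 300
    # expression atlas
    expression_mu: float = 2.0      # mean log10 RPM of isoform precursor totals
    expression_sigma: float = 0.45  # sd of log10 totals across isoforms
    profile_dispersion: float = 0.2  # per-domain log10 jitter of precursor rows
    target_mu: float = 2.0
    target_sigma: float = 0.45
    target_anticorrelation: float = 0.5  # vasculature damping of vascular-family targets
    # mature miRNA coupling
    coupling_sigma: float = 0.18    # sd (log10) of mature-vs-precursor noise
    outlier_fraction: float = 0.1
    outlier_fold: float = 8.0
    library_depth: int = 1_000_000  # so RPM == raw count
    # binding sites
    max_site_mutations: int = 2
    site_mutation_spec: dict[str, list[tuple[int, str]]] | None = None  # site id -> spec
    # PARE
    background_rate: float = 0.02   # Poisson tags per nucleotide per replicate
    peak_height_scale: float = 30.0  # mean peak tags per replicate at unit strength
    peak_clip: tuple[float, float] = (0.5, 2.0)
    replicates: int = 2
    decoy_fraction: float = 0.5
    sharing_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "expression_sigma", "profile_dispersion", "coupling_sigma",
            "background_rate", "peak_height_scale", "outlier_fold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("outlier_fraction", "decoy_fraction", "sharing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stage, reproducible under the seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def analytic_rank_correlation(self) -> float:
        """Closed-form Spearman correlation of the precursor-mature coupling.

        log10 precursor totals are Normal(mu, sigma_x) and log10 mature
        abundance adds independent Normal(0, sigma_c) noise, so the pair is
        bivariate normal with Pearson rho = sigma_x / hypot(sigma_x, sigma_c)
        and Spearman rho_s = (6 / pi) * arcsin(rho / 2).
        """
        rho = self.expression_sigma / float(
            np.hypot(self.expression_sigma, self.coupling_sigma)
        )
        return float(6.0 / np.pi * np.arcsin(rho / 2.0))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

_STREAM_FAMILIES = 1
_STREAM_ATLAS = 2
_STREAM_TRANSCRIPTOME = 3
_STREAM_PARE = 4


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def simulate_families(config: SimConfig) -> list[MirnaFamily]:
    """Deterministic family structure: isoforms are single-nucleotide variants."""
    rng = config.rng(_STREAM_FAMILIES)
    families: list[MirnaFamily] = []
    for f in range(config.n_families):
        name = f"fam{f:02d}"
        base = _random_seq(rng, config.mirna_length)
        isoforms: dict[str, str] = {}
        for i in range(config.isoforms_per_family):
            seq = base
            if i > 0:  # mature-sequence polymorphism within the family
                pos = int(rng.integers(0, config.mirna_length))
                alt = [c for c in ALPHABET if c != seq[pos]]
                seq = seq[:pos] + str(rng.choice(alt)) + seq[pos + 1 :]
            isoforms[f"{name}_iso{i}"] = seq
        precursors = {
            f"{name}_p{k}": f"{name}_iso{k % config.isoforms_per_family}"
            for k in range(config.precursors_per_family)
        }
        families.append(MirnaFamily(name, isoforms, precursors))
    return families


def family_archetype(family_index: int) -> str:
    names = list(ARCHETYPES)
    return names[family_index % len(names)]


# ---------------------------------------------------------------------------
# expression atlas + mature miRNAs
# ---------------------------------------------------------------------------


@dataclass
class AtlasSim:
    precursor_atlas: ExpressionAtlas
    target_atlas: ExpressionAtlas
    mature: SmallRnaTable
    families: list[MirnaFamily]
    isoform_totals: dict[str, float]  # 6-domain precursor sums, pre-noise
    outliers: list[str]
    archetypes: dict[str, str]


def simulate_atlas(config: SimConfig, families: Sequence[MirnaFamily] | None = None) -> AtlasSim:
    """Precursor and target expression atlases plus a coupled mature table.

    Each isoform's summed precursor expression over the six non-overlapping
    domains is exactly ``10**Normal(mu, sigma)``; mature abundance multiplies
    that total by log-normal coupling noise, with outlier isoforms further
    multiplied or divided by the outlier fold (alternating).
    """
    if families is None:
        families = simulate_families(config)
    rng = config.rng(_STREAM_ATLAS)
    domains = list(APEX_DOMAINS)
    nonov = list(NONOVERLAPPING_DOMAINS)
    arch_of: dict[str, str] = {}

    prec_rows: dict[str, np.ndarray] = {}
    isoform_totals: dict[str, float] = {}
    for f_idx, fam in enumerate(families):
        arch = family_archetype(f_idx)
        arch_of[fam.name] = arch
        weights = np.array([ARCHETYPES[arch][d] for d in domains])
        for iso in fam.mature_isoforms:
            total = 10.0 ** rng.normal(config.expression_mu, config.expression_sigma)
            precs = fam.precursors_of(iso)
            shares = rng.dirichlet(np.ones(len(precs)) * 2.0) if precs else []
            rows = {}
            for prec, share in zip(precs, shares):
                jitter = 10.0 ** rng.normal(0.0, config.profile_dispersion, len(domains))
                rows[prec] = weights * jitter * share
            # rescale so the isoform's 6-domain precursor sum equals `total`
            idx = [domains.index(d) for d in nonov]
            current = sum(row[idx].sum() for row in rows.values())
            scale = total / current if current > 0 else 0.0
            for prec, row in rows.items():
                prec_rows[prec] = row * scale
            isoform_totals[iso] = total

    prec_atlas = ExpressionAtlas(
        pd.DataFrame.from_dict(prec_rows, orient="index", columns=domains)
    )

    # mature miRNA abundance: coupled to the precursor total, with outliers
    isoforms = list(isoform_totals)
    n_out = int(np.floor(config.outlier_fraction * len(isoforms)))
    out_idx = sorted(rng.choice(len(isoforms), size=n_out, replace=False).tolist())
    outliers = [isoforms[i] for i in out_idx]
    raw: dict[str, int] = {}
    for k, iso in enumerate(isoforms):
        value = isoform_totals[iso] * 10.0 ** rng.normal(0.0, config.coupling_sigma)
        if iso in outliers:
            fold = config.outlier_fold
            value = value * fold if outliers.index(iso) % 2 == 0 else value / fold
        # tag counts quantize RPM at 1e6 / library_depth resolution
        raw[iso] = int(round(value * config.library_depth / 1e6))
    mature = SmallRnaTable.from_raw(raw, library_total=config.library_depth)

    # targets: archetype-shaped, damped in the vasculature for vascular families
    tgt_rows: dict[str, np.ndarray] = {}
    vas_idx = domains.index("vasculature")
    for f_idx, fam in enumerate(families):
        arch = arch_of[fam.name]
        weights = np.array([ARCHETYPES[arch][d] for d in domains], dtype=float)
        if arch == "vasculature":
            weights = weights.copy()
            weights[vas_idx] *= 1.0 - config.target_anticorrelation
        for j in range(config.n_targets_per_family):
            total = 10.0 ** rng.normal(config.target_mu, config.target_sigma)
            jitter = 10.0 ** rng.normal(0.0, config.profile_dispersion, len(domains))
            row = weights * jitter
            tgt_rows[f"{fam.name}_t{j}"] = row * total / row.sum()
    tgt_atlas = ExpressionAtlas(
        pd.DataFrame.from_dict(tgt_rows, orient="index", columns=domains)
    )
    return AtlasSim(prec_atlas, tgt_atlas, mature, list(families), isoform_totals,
                    outliers, arch_of)


# ---------------------------------------------------------------------------
# transcriptome with planted sites
# ---------------------------------------------------------------------------


@dataclass
class TranscriptomeSim:
    families: list[MirnaFamily]
    mirnas: dict[str, str]       # isoform id -> mature sequence
    transcripts: dict[str, str]  # target id -> sequence
    truth: pd.DataFrame          # one row per planted site


def _draw_mutation_spec(
    rng: np.random.Generator, mirna: str, config: SimConfig
) -> list[tuple[int, str]]:
    """Random per-site mutation spec keeping the planted score within 5."""
    n = len(mirna)
    for _attempt in range(50):
        n_mut = int(rng.integers(0, config.max_site_mutations + 1))
        spec: list[tuple[int, str]] = []
        used: set[int] = set()
        score = 0.0
        ok = True
        for _ in range(n_mut):
            kind = str(rng.choice(["mismatch", "wobble", "bulge"], p=[0.5, 0.35, 0.15]))
            if kind == "bulge":
                pos = int(rng.integers(1, n))  # gap between pos and pos+1
                penalty = position_weight(pos + 1)
            else:
                pos = int(rng.integers(1, n + 1))
                if kind == "wobble" and mirna[pos - 1] not in _WOBBLE_PARTNER:
                    ok = False
                    break
                penalty = position_weight(pos) * (0.5 if kind == "wobble" else 1.0)
            if pos in used:
                ok = False
                break
            used.add(pos)
            score += penalty
            spec.append((pos, kind))
        if ok and score <= 5.0:
            return sorted(spec)
    return []


def _build_site(mirna: str, spec: list[tuple[int, str]]) -> tuple[str, str, float]:
    """Realise a binding site from a mutation spec.

    Returns (site sequence 5'->3', alignment ops, truth score).  The score is
    computed additively from the spec (each mutation contributes its penalty
    times the positional weight), independent of the scoring module.
    """
    n = len(mirna)
    mir = normalize(mirna)
    muts = dict(spec)
    for pos, kind in spec:
        if kind == "bulge":
            if not 1 <= pos <= n - 1:
                raise ValueError(f"bulge gap position {pos} outside 1..{n - 1}")
        elif not 1 <= pos <= n:
            raise ValueError(f"mutation position {pos} outside 1..{n}")
    ops_parts: list[str] = []
    site_rev: list[str] = []  # built 3'->5'
    score = 0.0
    # bulged-nucleotide identity: seeded from sequence content, not hash()
    rng_local = np.random.default_rng(sum(ord(c) * (k + 1) for k, c in enumerate(mir)))
    for pos in range(1, n + 1):
        kind = muts.get(pos)
        m_nt = mir[pos - 1]
        if kind == "mismatch":
            options = [c for c in ALPHABET if c != _COMP[m_nt] and c != _WOBBLE_PARTNER.get(m_nt)]
            site_rev.append(options[0])
            score += position_weight(pos) * 1.0
        elif kind == "wobble":
            site_rev.append(_WOBBLE_PARTNER[m_nt])
            score += position_weight(pos) * 0.5
        else:
            site_rev.append(_COMP[m_nt])
        ops_parts.append("M")
        if kind == "bulge":
            # extra transcript nucleotide between miRNA positions pos and pos+1
            site_rev.append(str(rng_local.choice(list(ALPHABET))))
            ops_parts.append("B")
            score += position_weight(pos + 1) * 1.0
    ops = "".join(ops_parts)
    site = "".join(reversed(site_rev))
    return site, ops, score


def _truth_cleavage_pos(ops: str, site_end: int) -> int:
    """Transcript position paired with miRNA position 10, by a path walk."""
    i, t = 0, site_end
    for op in ops:
        if op == "M":
            i += 1
            if i == 10:
                return t
            t -= 1
        elif op == "b":
            i += 1
        else:
            t -= 1
    raise ValueError("path exhausted before miRNA position 10")


def simulate_transcriptome(
    config: SimConfig, families: Sequence[MirnaFamily] | None = None
) -> TranscriptomeSim:
    """Random-background transcripts with one planted site per target.

    Site structure follows ``config.site_mutation_spec`` (keyed by target
    id) when given, otherwise random specs within the mutation budget.  A
    ``sharing_rate`` fraction of sites have their sequence context copied
    into a sibling target, creating a second, identically scoring site whose
    PARE signature maps to both loci.
    """
    if families is None:
        families = simulate_families(config)
    rng = config.rng(_STREAM_TRANSCRIPTOME)
    mirnas = {iso: seq for fam in families for iso, seq in fam.mature_isoforms.items()}
    transcripts: dict[str, str] = {}
    rows: list[dict] = []
    sig_counter = 0

    for fam in families:
        isoform_ids = list(fam.mature_isoforms)
        for j in range(config.n_targets_per_family):
            tid = f"{fam.name}_t{j}"
            iso = isoform_ids[j % len(isoform_ids)]
            mir = normalize(fam.mature_isoforms[iso])
            if config.site_mutation_spec and tid in config.site_mutation_spec:
                spec = [(int(p), str(k)) for p, k in config.site_mutation_spec[tid]]
            else:
                spec = _draw_mutation_spec(rng, mir, config)
            site, ops, score = _build_site(mir, spec)
            length = config.transcript_length
            if len(site) + 100 > length:
                raise ValueError("transcript_length too small for the planted site")
            start = int(rng.integers(50, length - len(site) - 50))  # 0-based
            seq = _random_seq(rng, length)
            seq = seq[:start] + site + seq[start + len(site) :]
            transcripts[tid] = seq
            site_start, site_end = start + 1, start + len(site)
            rows.append(
                {
                    "site_id": f"{tid}_s0",
                    "mirna": iso,
                    "family": fam.name,
                    "transcript": tid,
                    "site_start": site_start,
                    "site_end": site_end,
                    "ops": ops,
                    "score": score,
                    "cleavage_pos": _truth_cleavage_pos(ops, site_end),
                    "mutations": ";".join(f"{p}:{k}" for p, k in spec) or ".",
                    "signature_group": f"sig{sig_counter}",
                }
            )
            sig_counter += 1

    # shared signatures: copy site context into a sibling target
    base_rows = list(rows)
    for row in base_rows:
        if rng.random() >= config.sharing_rate:
            continue
        fam_name = row["family"]
        siblings = [
            r["transcript"]
            for r in base_rows
            if r["family"] == fam_name and r["transcript"] != row["transcript"]
        ]
        if not siblings:
            continue
        other = siblings[int(rng.integers(0, len(siblings)))]
        src = transcripts[row["transcript"]]
        ctx_lo = max(0, row["site_start"] - 1 - 5)
        ctx_hi = min(len(src), row["site_end"] + 5)
        context = src[ctx_lo:ctx_hi]
        other_row = next(r for r in base_rows if r["transcript"] == other)
        dest_seq = transcripts[other]
        # place the copy clear of the sibling's own site
        candidate_starts = [
            p
            for p in range(20, len(dest_seq) - len(context) - 20)
            if p + len(context) < other_row["site_start"] - 40
            or p > other_row["site_end"] + 40
        ]
        if not candidate_starts:
            continue
        dest0 = candidate_starts[int(rng.integers(0, len(candidate_starts)))]
        transcripts[other] = (
            dest_seq[:dest0] + context + dest_seq[dest0 + len(context) :]
        )
        offset = row["site_start"] - 1 - ctx_lo  # site offset within the context
        new_start = dest0 + offset + 1
        new_end = new_start + (row["site_end"] - row["site_start"])
        rows.append(
            {
                "site_id": f"{other}_shared_{row['site_id']}",
                "mirna": row["mirna"],
                "family": fam_name,
                "transcript": other,
                "site_start": new_start,
                "site_end": new_end,
                "ops": row["ops"],
                "score": row["score"],
                "cleavage_pos": _truth_cleavage_pos(row["ops"], new_end),
                "mutations": row["mutations"],
                "signature_group": row["signature_group"],
            }
        )

    truth = pd.DataFrame(rows)
    return TranscriptomeSim(list(families), mirnas, transcripts, truth)


def sites_from_truth(
    truth: pd.DataFrame, mirnas: Mapping[str, str], transcripts: Mapping[str, str]
) -> list[TargetSite]:
    """Reconstruct :class:`TargetSite` objects from a generator truth table."""
    sites = []
    for _, row in truth.iterrows():
        seq = normalize(transcripts[row["transcript"]])
        sites.append(
            TargetSite(
                mirna_id=row["mirna"],
                transcript_id=row["transcript"],
                site_start=int(row["site_start"]),
                site_end=int(row["site_end"]),
                score=float(row["score"]),
                ops=row["ops"],
                mirna_seq=normalize(mirnas[row["mirna"]]),
                site_seq=seq[int(row["site_start"]) - 1 : int(row["site_end"])],
            )
        )
    return sites


# ---------------------------------------------------------------------------
# PARE libraries
# ---------------------------------------------------------------------------


@dataclass
class PareSim:
    library: PareLibrary
    truth: pd.DataFrame  # site truth + cleaved flag and peak mean


def simulate_pare(
    config: SimConfig,
    truth: pd.DataFrame,
    atlas: AtlasSim,
) -> PareSim:
    """Replicated PARE tag counts: Poisson background plus peaks at true sites.

    Peak mean per replicate is ``peak_height_scale`` times a site strength
    (family precursor sum x target expression in the precursor domain,
    normalised to geometric mean 1 and clipped to ``peak_clip``).  A
    ``decoy_fraction`` of signatures is marked uncleaved and receives
    background only.  Peak tags of a shared signature are drawn once per
    replicate and placed at every member locus, the way multi-mapping tags
    are counted at each compatible position.
    """
    rng = config.rng(_STREAM_PARE)
    domains = list(APEX_DOMAINS)
    fam_by_name = {f.name: f for f in atlas.families}

    # per-signature strengths from the atlas
    strengths: dict[str, float] = {}
    for grp, sub in truth.groupby("signature_group", sort=True):
        row = sub.iloc[0]
        fam = fam_by_name[row["family"]]
        weights = np.array(
            [ARCHETYPES[atlas.archetypes[fam.name]][d] for d in domains]
        )
        dom = domains[int(np.argmax(weights))]
        prec_sum = float(
            atlas.precursor_atlas.data.loc[
                [p for p in fam.all_precursors], dom
            ].sum()
        )
        tgt_expr = float(atlas.target_atlas.data.loc[row["transcript"], dom])
        strengths[grp] = prec_sum * tgt_expr
    values = np.array([max(v, 1e-12) for v in strengths.values()])
    geomean = float(np.exp(np.mean(np.log(values)))) if len(values) else 1.0
    lo, hi = config.peak_clip
    peak_mean = {
        grp: config.peak_height_scale * float(np.clip(v / geomean, lo, hi))
        for grp, v in strengths.items()
    }

    groups = sorted(strengths)
    cleaved = {grp: bool(rng.random() >= config.decoy_fraction) for grp in groups}

    lengths = {tid: config.transcript_length for tid in truth["transcript"].unique()}
    # transcripts may have been returned by simulate_transcriptome with the
    # configured uniform length; keep the mapping overridable
    replicates = [f"rep{r + 1}" for r in range(config.replicates)]
    counts: dict[tuple[str, str], np.ndarray] = {}
    for tid in sorted(lengths):
        for rep in replicates:
            counts[(tid, rep)] = rng.poisson(
                config.background_rate, size=lengths[tid]
            ).astype(np.int64)
    for grp in groups:
        if not cleaved[grp]:
            continue
        peak_counts = rng.poisson(peak_mean[grp], size=config.replicates)
        for _, row in truth[truth["signature_group"] == grp].iterrows():
            for rep, ct in zip(replicates, peak_counts):
                counts[(row["transcript"], rep)][int(row["cleavage_pos"]) - 1] += int(ct)

    library = PareLibrary(transcript_lengths=lengths, replicates=replicates, counts=counts)
    out = truth.copy()
    out["cleaved"] = out["signature_group"].map(cleaved)
    out["peak_mean"] = out["signature_group"].map(peak_mean)
    return PareSim(library, out)


# ---------------------------------------------------------------------------
# one-call fixture
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    config: SimConfig
    families: list[MirnaFamily]
    mirnas: dict[str, str]
    transcripts: dict[str, str]
    atlas: AtlasSim
    pare: PareSim

    @property
    def truth(self) -> pd.DataFrame:
        return self.pare.truth


def simulate_fixture(config: SimConfig) -> Fixture:
    """Run all three generators coherently from one config."""
    families = simulate_families(config)
    txome = simulate_transcriptome(config, families)
    atlas = simulate_atlas(config, families)
    pare_sim = simulate_pare(config, txome.truth, atlas)
    return Fixture(config, families, txome.mirnas, txome.transcripts, atlas, pare_sim)


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write a fixture to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": outdir / "mirnas.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "precursor_atlas": outdir / "precursor_atlas.tsv",
        "target_atlas": outdir / "target_atlas.tsv",
        "mature": outdir / "mature_mirnas.tsv",
        "pare": outdir / "pare_tags.bed",
        "families": outdir / "families.tsv",
        "truth": outdir / "truth_sites.tsv",
    }
    write_fasta(fixture.mirnas, paths["mirnas"])
    write_fasta(fixture.transcripts, paths["transcripts"])
    write_expression_tsv(fixture.atlas.precursor_atlas, paths["precursor_atlas"])
    write_expression_tsv(fixture.atlas.target_atlas, paths["target_atlas"])
    write_smallrna_tsv(fixture.atlas.mature, paths["mature"])
    write_pare_bed(fixture.pare.library, paths["pare"])
    fam_rows = [
        {"family": fam.name, "isoform": iso, "precursor": prec}
        for fam in fixture.families
        for prec, iso in fam.precursors.items()
    ]
    write_family_tsv(pd.DataFrame(fam_rows), paths["families"])
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
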