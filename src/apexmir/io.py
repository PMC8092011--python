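"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* FASTA for sequences (DNA or RNA alphabet; ``U`` and ``T`` are both accepted
  and preserved as written).
* TSV with a header row for expression matrices and small RNA tables.
* BED-like TSV for PARE tag 5'-end positions: 6 columns
  ``transcript  start  end  name  count  replicate`` with 0-based half-open
  file coordinates.  A 5-column variant without the name column is accepted
  on read.
* All in-memory transcript coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 12 shoot-apex domains of the expression atlas, in canonical order.
APEX_DOMAINS = (
    "meristem",
    "CZ",
    "L1",
    "L2",
    "P0",
    "P1",
    "P2",
    "P3",
    "internode",
    "vasculature",
    "adaxial",
    "abaxial",
)

#: Domains that do not overlap each other and together represent the tissue
#: sampled for whole-apex small RNA sequencing.
NONOVERLAPPING_DOMAINS = ("meristem", "internode", "P1", "P2", "P3", "vasculature")


class ApexMirIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionAtlas:
    """A gene x domain matrix of nonnegative RPM expression values."""

    data: pd.DataFrame  # index: gene ids, columns: domain names

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ApexMirIOError(f"duplicate gene id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ApexMirIOError(f"duplicate domain name {dup!r}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ApexMirIOError("expression matrix contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ApexMirIOError(
                f"negative expression for gene {df.index[i]!r} in domain {df.columns[j]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def domains(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, genes: Sequence[str]) -> "ExpressionAtlas":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from atlas: {missing[:5]}")
        return ExpressionAtlas(self.data.loc[list(genes)].copy())


@dataclass
class PareLibrary:
    """Replicated per-transcript, per-position PARE tag 5'-end counts.

    ``counts[(transcript, replicate)]`` is an integer vector indexed by
    1-based transcript position (slot 0 of the array is position 1).
    """

    transcript_lengths: dict[str, int]
    replicates: list[str]
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (tid, rep), vec in self.counts.items():
            if tid not in self.transcript_lengths:
                raise ApexMirIOError(f"unknown transcript {tid!r} in PARE counts")
            if len(vec) != self.transcript_lengths[tid]:
                raise ApexMirIOError(
                    f"count vector length {len(vec)} != transcript length "
                    f"{self.transcript_lengths[tid]} for {tid!r}"
                )
            if (np.asarray(vec) < 0).any():
                raise ApexMirIOError(f"negative tag count for {tid!r}/{rep!r}")

    def vector(self, transcript_id: str, replicate: str) -> np.ndarray:
        """Count vector for one transcript/replicate (zeros if no tags seen)."""
        if transcript_id not in self.transcript_lengths:
            raise KeyError(f"transcript {transcript_id!r} not in PARE library")
        key = (transcript_id, replicate)
        if key not in self.counts:
            return np.zeros(self.transcript_lengths[transcript_id], dtype=np.int64)
        return self.counts[key]

    @property
    def library_sizes(self) -> dict[str, int]:
        sizes = {rep: 0 for rep in self.replicates}
        for (tid, rep), vec in self.counts.items():
            sizes[rep] += int(np.asarray(vec).sum())
        return sizes


@dataclass
class SmallRnaTable:
    """Mature miRNA raw read counts and RPM values.

    ``library_total`` is the total number of mapped reads in the library
    (not the sum of the table, which covers miRNAs only); when provided, the
    invariant ``rpm == raw * 1e6 / library_total`` is enforced.
    """

    data: pd.DataFrame  # index: mature miRNA id; columns: raw, rpm
    library_total: int | None = None

    def __post_init__(self) -> None:
        df = self.data
        for col in ("raw", "rpm"):
            if col not in df.columns:
                raise ApexMirIOError(f"small RNA table missing column {col!r}")
        if (df["raw"] < 0).any() or (df["rpm"] < 0).any():
            raise ApexMirIOError("negative small RNA counts")
        if self.library_total:
            expected = df["raw"].to_numpy(dtype=float) * 1e6 / self.library_total
            if not np.allclose(expected, df["rpm"].to_numpy(dtype=float), rtol=1e-6, atol=1e-6):
                raise ApexMirIOError("RPM column inconsistent with raw counts / library total")

    @classmethod
    def from_raw(cls, raw: Mapping[str, int], library_total: int | None = None) -> "SmallRnaTable":
        df = pd.DataFrame({"raw": pd.Series(raw, dtype=np.int64)})
        total = library_total if library_total is not None else int(df["raw"].sum())
        df["rpm"] = df["raw"] * 1e6 / total if total > 0 else 0.0
        return cls(df, library_total=total)

    @property
    def raw(self) -> pd.Series:
        return self.data["raw"]

    @property
    def rpm(self) -> pd.Series:
        return self.data["rpm"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``, uppercased.

    ``U`` and ``T`` are both accepted and preserved as given (after
    uppercasing); duplicate identifiers and empty sequences are hard errors.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ApexMirIOError(f"duplicate id {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise ApexMirIOError(f"empty sequence for id {record.id}")
        sequences[record.id] = seq
    if not sequences:
        raise ApexMirIOError(f"no FASTA records in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path, expected_domains: Sequence[str] = APEX_DOMAINS
) -> ExpressionAtlas:
    """Read a gene x domain TSV (first column gene ids, header names domains).

    The returned atlas carries the domains in ``expected_domains`` order; a
    missing expected domain is an error, extra columns are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [d for d in expected_domains if d not in df.columns]
    if missing:
        raise ApexMirIOError(f"expression table missing domain column {missing[0]!r}")
    df = df[list(expected_domains)]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        gene, dom = bad[bad].index[0]
        raise ApexMirIOError(f"non-numeric expression value at gene {gene!r}, domain {dom!r}")
    numeric.index = numeric.index.astype(str)
    return ExpressionAtlas(numeric.astype(float))


def write_expression_tsv(atlas: ExpressionAtlas, path: str | Path) -> None:
    atlas.data.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# small RNA TSV
# ---------------------------------------------------------------------------


def read_smallrna_tsv(path: str | Path) -> SmallRnaTable:
    """Read a mature miRNA count table: columns ``mirna  raw  rpm``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SmallRnaTable(df[["raw", "rpm"]])


def write_smallrna_tsv(table: SmallRnaTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="mirna", float_format="%.10g")


# ---------------------------------------------------------------------------
# PARE BED
# ---------------------------------------------------------------------------


def read_pare_bed(path: str | Path, transcript_lengths: Mapping[str, int]) -> PareLibrary:
    """Read PARE tag positions from a BED-like TSV.

    File coordinates are 0-based half-open; every interval must be a single
    nucleotide (``end == start + 1``) marking the tag 5'-end.  Counts at the
    same position accumulate.
    """
    path = Path(path)
    lengths = dict(transcript_lengths)
    counts: dict[tuple[str, str], np.ndarray] = {}
    replicates: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 6:
                tid, start_s, end_s, _name, count_s, rep = fields
            elif len(fields) == 5:
                tid, start_s, end_s, count_s, rep = fields
            else:
                raise ApexMirIOError(
                    f"{path}:{lineno}: expected 5 or 6 columns, found {len(fields)}"
                )
            if tid not in lengths:
                raise ApexMirIOError(f"{path}:{lineno}: unknown transcript {tid!r}")
            start, end = int(start_s), int(end_s)
            if end != start + 1:
                raise ApexMirIOError(
                    f"{path}:{lineno}: interval [{start}, {end}) is not a single nucleotide"
                )
            pos = start + 1  # 1-based
            if not 1 <= pos <= lengths[tid]:
                raise ApexMirIOError(
                    f"{path}:{lineno}: position {pos} outside transcript {tid!r} "
                    f"(length {lengths[tid]})"
                )
            count = int(count_s)
            if count < 0:
                raise ApexMirIOError(f"{path}:{lineno}: negative count")
            key = (tid, rep)
            if key not in counts:
                counts[key] = np.zeros(lengths[tid], dtype=np.int64)
            counts[key][pos - 1] += count
            if rep not in replicates:
                replicates.append(rep)
    return PareLibrary(transcript_lengths=lengths, replicates=replicates, counts=counts)


def write_pare_bed(library: PareLibrary, path: str | Path) -> None:
    """Write nonzero tag positions back to 6-column BED-like TSV."""
    with open(path, "w") as fh:
        for (tid, rep) in sorted(library.counts):
            vec = library.counts[(tid, rep)]
            for idx in np.nonzero(vec)[0]:
                pos = int(idx) + 1
                fh.write(f"{tid}\t{pos - 1}\t{pos}\t.\t{int(vec[idx])}\t{rep}\n")


# ---------------------------------------------------------------------------
# target site and cleavage call tables
# ---------------------------------------------------------------------------


def write_sites_tsv(sites, path: str | Path) -> None:
    """Write predicted sites: mirna, transcript, start, end, score,
    cleavage_pos, ops, alignment."""
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript\tstart\tend\tscore\tcleavage_pos\tops\talignment\n")
        for s in sites:
            cpos = s.cleavage_pos if s.cleavage_pos is not None else "NA"
            fh.write(
                f"{s.mirna_id}\t{s.transcript_id}\t{s.site_start}\t{s.site_end}\t"
                f"{s.score:g}\t{cpos}\t{s.ops}\t{s.compact_alignment()}\n"
            )


def read_sites_tsv(
    path: str | Path, mirnas: Mapping[str, str], transcripts: Mapping[str, str]
):
    """Read a sites table back into TargetSite objects (sequences re-derived
    from the FASTA mappings)."""
    from .targets import TargetSite, normalize

    df = pd.read_csv(path, sep="\t", dtype={"ops": str})
    sites = []
    for _, row in df.iterrows():
        tid, mid = str(row["transcript"]), str(row["mirna"])
        if mid not in mirnas:
            raise ApexMirIOError(f"miRNA {mid!r} not in the provided FASTA")
        if tid not in transcripts:
            raise ApexMirIOError(f"transcript {tid!r} not in the provided FASTA")
        seq = normalize(transcripts[tid])
        sites.append(
            TargetSite(
                mirna_id=mid,
                transcript_id=tid,
                site_start=int(row["start"]),
                site_end=int(row["end"]),
                score=float(row["score"]),
                ops=str(row["ops"]),
                mirna_seq=normalize(mirnas[mid]),
                site_seq=seq[int(row["start"]) - 1 : int(row["end"])],
            )
        )
    return sites


def write_calls_tsv(calls, path: str | Path) -> None:
    """Write cleavage calls: site columns plus w_s, w_l, ratio, passed."""
    with open(path, "w") as fh:
        fh.write(
            "mirna\ttranscript\tstart\tend\tscore\tcleavage_pos\tops\t"
            "w_s\tw_l\tratio\tpassed\n"
        )
        for c in calls:
            s = c.site
            fh.write(
                f"{s.mirna_id}\t{s.transcript_id}\t{s.site_start}\t{s.site_end}\t"
                f"{s.score:g}\t{s.cleavage_pos}\t{s.ops}\t"
                f"{c.w_s:.10g}\t{c.w_l:.10g}\t{c.ratio:.10g}\t{int(c.passed)}\n"
            )


def read_calls_tsv(
    path: str | Path, mirnas: Mapping[str, str], transcripts: Mapping[str, str]
):
    """Read a calls table back into CleavageCall objects."""
    from .pare import CleavageCall
    from .targets import TargetSite, normalize

    df = pd.read_csv(path, sep="\t", dtype={"ops": str})
    calls = []
    for _, row in df.iterrows():
        tid, mid = str(row["transcript"]), str(row["mirna"])
        seq = normalize(transcripts[tid])
        site = TargetSite(
            mirna_id=mid,
            transcript_id=tid,
            site_start=int(row["start"]),
            site_end=int(row["end"]),
            score=float(row["score"]),
            ops=str(row["ops"]),
            mirna_seq=normalize(mirnas[mid]),
            site_seq=seq[int(row["start"]) - 1 : int(row["end"])],
        )
        calls.append(
            CleavageCall(
                site=site,
                w_s=float(row["w_s"]),
                w_l=float(row["w_l"]),
                ratio=float(row["ratio"]),
                passed=bool(int(row["passed"])),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# miRNA family table
# ---------------------------------------------------------------------------


def read_family_tsv(path: str | Path) -> pd.DataFrame:
    """Read family membership: columns ``family  isoform  precursor``.

    One row per precursor gene; an isoform may own several precursors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("family", "isoform", "precursor"):
        if col not in df.columns:
            raise ApexMirIOError(f"family table missing column {col!r}")
    if df["precursor"].duplicated().any():
        dup = df["precursor"][df["precursor"].duplicated()].iloc[0]
        raise ApexMirIOError(f"precursor {dup!r} assigned to more than one isoform")
    return df


def write_family_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["family", "isoform", "precursor"]].to_csv(path, sep="\t", index=False)
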