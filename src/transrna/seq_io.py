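"""Readers/writers for pipeline file formats, shared conventions, and configuration.

All coordinates in this package are 0-based half-open. Operations that emit
1-based display coordinates say so in their output header.

Formats handled here:

* FASTA (plain sequence sets: host transcripts, miRNAs, homolog sets),
  via :mod:`Bio.SeqIO`. ``U`` is normalized to ``T`` on read for nucleotide
  records so the whole pipeline works in DNA space.
* TSV count tables (collapsed sRNA reads: one ``seq`` column plus one count
  column per library).
* TSV transcript annotations (CDS interval + organellar flag).
* TSV degradome profiles (per-replicate 5'-end counts by transcript position).
* TSV locus alignment summaries (per-read 5' position / length / strand,
  a minimal stand-in for aligned-read BAMs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("transrna")

NUCLEOTIDES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file violates its expected dialect."""


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown, or out of range."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence, optionally with per-library read counts."""

    id: str
    seq: str
    counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.counts is not None and len(self.counts) == 0:
            raise ValueError(f"counts mapping for {self.id!r} has no libraries")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values()) if self.counts else 0


@dataclass
class TranscriptAnnotation:
    """Transcript sequence with CDS interval (0-based half-open) and organellar flag."""

    transcript_id: str
    seq: str
    cds_start: int
    cds_end: int
    organellar: bool
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside transcript of length {len(self.seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def cds_seq(self) -> str:
        return self.seq[self.cds_start : self.cds_end]


@dataclass
class DegradomeProfile:
    """5'-end read counts along one transcript for one replicate library."""

    transcript_id: str
    replicate_id: str
    condition: str  # "treatment" or "control"
    depth: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in ("treatment", "control"):
            raise ValueError(f"condition must be treatment/control, got {self.condition!r}")
        for pos, count in self.depth.items():
            if count < 0 or pos < 0:
                raise ValueError(
                    f"{self.transcript_id}/{self.replicate_id}: negative position or count"
                )


@dataclass
class LocusRead:
    """One aligned small-RNA read within a gene locus."""

    pos5: int  # 0-based 5'-end position
    length: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not 15 <= self.length <= 35:
            raise ValueError(f"read length {self.length} outside [15, 35]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class LocusAlignmentSummary:
    """Per-read alignment tuples for one gene in one library."""

    gene_id: str
    library_id: str
    reads: list[LocusRead] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA


def _normalize_nt(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, nucleotide: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    In nucleotide mode (default) sequences are uppercased and U is normalized
    to T; letters outside ACGTN raise :class:`ParseError`. The record id is
    the header token before the first whitespace.
    """
    path = Path(path)
    # Pre-scan for sequence data before any header so the error names a line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                break
            raise ParseError(f"{path}:{lineno}: sequence line before first FASTA header")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if nucleotide:
            seq = _normalize_nt(seq)
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise ParseError(
                    f"{path}: record {rec.id!r} contains non-nucleotide symbols {sorted(bad)}"
                )
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (id and sequence preserved byte-for-byte)."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; quality strings are discarded (the pipeline is count-based)."""
    return [
        SequenceRecord(id=rec.id, seq=_normalize_nt(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# TSV tables


def read_count_table(path: str | Path) -> list[SequenceRecord]:
    """Read a collapsed-read count table: header ``seq`` + one column per library.

    Rows with identical sequences are summed (collapsed-read dialects differ),
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"seq": str})
    if "seq" not in df.columns:
        raise ParseError(f"{path}: count table header must contain a 'seq' column")
    libs = [c for c in df.columns if c != "seq"]
    if not libs:
        raise ParseError(f"{path}: count table has no library columns")
    for lib in libs:
        col = pd.to_numeric(df[lib], errors="coerce")
        if col.isna().any() or (col < 0).any() or (col % 1 != 0).any():
            raise ParseError(f"{path}: column {lib!r} has negative or non-integer counts")
        df[lib] = col.astype(int)
    if df["seq"].duplicated().any():
        ndup = int(df["seq"].duplicated().sum())
        logger.warning("%s: %d duplicate sequence rows summed", path, ndup)
        df = df.groupby("seq", sort=False, as_index=False).sum()
    records = []
    for row in df.itertuples(index=False):
        seq = _normalize_nt(row.seq)
        counts = {lib: int(getattr(row, lib)) for lib in libs}
        records.append(SequenceRecord(id=seq, seq=seq, counts=counts))
    return records


def write_count_table(records: Iterable[SequenceRecord], path: str | Path) -> None:
    records = list(records)
    libs = sorted({lib for r in records for lib in (r.counts or {})})
    rows = [{"seq": r.seq, **{lib: (r.counts or {}).get(lib, 0) for lib in libs}} for r in records]
    pd.DataFrame(rows, columns=["seq", *libs]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path, transcripts: Mapping[str, str]) -> dict[str, TranscriptAnnotation]:
    """Read transcript annotation TSV (transcript_id, gene_id, cds_start, cds_end, organellar).

    ``transcripts`` maps transcript_id -> sequence (typically from ``read_fasta``).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "cds_start", "cds_end", "organellar"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: annotation table missing columns {sorted(missing)}")
    out: dict[str, TranscriptAnnotation] = {}
    for row in df.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in transcripts:
            raise ParseError(f"{path}: transcript {tid!r} has no sequence")
        out[tid] = TranscriptAnnotation(
            transcript_id=tid,
            seq=transcripts[tid],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            organellar=bool(row.organellar),
            gene_id=str(row.gene_id),
        )
    return out


def write_annotations(annotations: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": a.transcript_id,
            "gene_id": a.gene_id,
            "cds_start": a.cds_start,
            "cds_end": a.cds_end,
            "organellar": a.organellar,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_degradome(path: str | Path) -> list[DegradomeProfile]:
    """Read degradome TSV (transcript_id, replicate, condition, position, count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "replicate", "condition", "position", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: degradome table missing columns {sorted(missing)}")
    profiles: dict[tuple[str, str], DegradomeProfile] = {}
    for row in df.itertuples(index=False):
        key = (str(row.transcript_id), str(row.replicate))
        prof = profiles.get(key)
        if prof is None:
            prof = DegradomeProfile(key[0], key[1], str(row.condition))
            profiles[key] = prof
        prof.depth[int(row.position)] = prof.depth.get(int(row.position), 0) + int(row.count)
    return list(profiles.values())


def write_degradome(profiles: Iterable[DegradomeProfile], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": p.transcript_id,
            "replicate": p.replicate_id,
            "condition": p.condition,
            "position": pos,
            "count": count,
        }
        for p in profiles
        for pos, count in sorted(p.depth.items())
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "replicate", "condition", "position", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_locus_summaries(path: str | Path) -> list[LocusAlignmentSummary]:
    """Read locus alignment TSV (gene_id, library, pos5, length, strand)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "library", "pos5", "length", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: locus table missing columns {sorted(missing)}")
    loci: dict[tuple[str, str], LocusAlignmentSummary] = {}
    for row in df.itertuples(index=False):
        key = (str(row.gene_id), str(row.library))
        summary = loci.get(key)
        if summary is None:
            summary = LocusAlignmentSummary(key[0], key[1])
            loci[key] = summary
        summary.reads.append(LocusRead(int(row.pos5), int(row.length), str(row.strand)))
    return list(loci.values())


def write_locus_summaries(summaries: Iterable[LocusAlignmentSummary], path: str | Path) -> None:
    rows = [
        {
            "gene_id": s.gene_id,
            "library": s.library_id,
            "pos5": r.pos5,
            "length": r.length,
            "strand": r.strand,
        }
        for s in summaries
        for r in s.reads
    ]
    pd.DataFrame(rows, columns=["gene_id", "library", "pos5", "length", "strand"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Configuration

#: Pipeline thresholds. Defaults follow the published analysis conventions:
#: 20-24 nt size band, condensation radius 2 edits at 0.5 RPM, BH FDR 0.1,
#: superfamily distance 5, strict family distance 1, confirmation score <= 6,
#: motif-discovery score <= 3.
DEFAULT_CONFIG: dict[str, object] = {
    "min_len": 20,
    "max_len": 24,
    "condense_dist": 2,
    "rpm_min": 0.5,
    "fdr": 0.1,
    "superfamily_dist": 5,
    "family_dist": 1,
    "confirm_score": 6.0,
    "motif_score": 3.0,
    # secondary knobs, exposed because the published procedure leaves them open
    "host_mirna_dist": 2,  # "closely similar" radius for host miRNA filtering
    "core_start": 2,  # 5' core over which duplex penalties double (1-based, inclusive)
    "core_end": 13,
    "unstranded_min": 0.2,  # plus-strand fraction band counted as "unstranded"
    "unstranded_max": 0.8,
    "min_locus_depth": 20,
    "degradome_fold": 10.0,
    "degradome_min_site_start": 100,
    "peak_window": 0,  # +/- nt tolerance around the predicted cut when peak-matching
    "require_control_fold": True,  # disable when no control degradome exists
    "phase_length": 21,
    "aa_cluster_dist": 3,
}

_NONNEG = {
    "condense_dist", "rpm_min", "superfamily_dist", "family_dist", "confirm_score",
    "motif_score", "host_mirna_dist", "min_locus_depth", "degradome_fold",
    "degradome_min_site_start", "peak_window", "aa_cluster_dist",
}


def validate_config(cfg: Mapping[str, object]) -> dict[str, object]:
    """Merge ``cfg`` over the defaults, rejecting unknown keys and bad values."""
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **dict(cfg)}
    for key in _NONNEG:
        if merged[key] < 0:  # type: ignore[operator]
            raise ConfigError(f"{key} must be non-negative, got {merged[key]}")
    if not 0 < merged["fdr"] <= 1:  # type: ignore[operator]
        raise ConfigError(f"fdr must be in (0, 1], got {merged['fdr']}")
    if merged["min_len"] < 1 or merged["min_len"] > merged["max_len"]:  # type: ignore[operator]
        raise ConfigError(f"bad size band [{merged['min_len']}, {merged['max_len']}]")
    if not 0 <= merged["unstranded_min"] <= merged["unstranded_max"] <= 1:  # type: ignore[operator]
        raise ConfigError("unstranded band must satisfy 0 <= min <= max <= 1")
    if not 1 <= merged["core_start"] <= merged["core_end"]:  # type: ignore[operator]
        raise ConfigError("core positions must satisfy 1 <= core_start <= core_end")
    if merged["phase_length"] < 1:  # type: ignore[operator]
        raise ConfigError("phase_length must be >= 1")
    return merged


def load_config(path: str | Path | None = None) -> dict[str, object]:
    """Load a YAML config; every omitted threshold falls back to its default."""
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    return validate_config(data)
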