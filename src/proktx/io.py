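"""Interval and annotation I/O.

All internal coordinates are 0-based half-open (BED-native). GFF3 files use
1-based inclusive coordinates; conversion happens exactly once, at the GFF3
boundary, in :func:`read_reference_gff` and the writers. Strandedness is
mandatory throughout: a ``.`` strand or a mixed-strand merged region is a
hard error because the prediction algorithm is strand-separated by
construction.

Supported formats:

* BED6 per-read alignment intervals (one line per primary alignment, clipped
  portions already excluded upstream).
* The 5-column strand-aware merged-region dialect
  (``chrom  start  end  strand  read_count``) produced by a
  ``bedtools merge -s -c 6,4 -o distinct,count`` style pipeline.
* GFF3 reference annotation (CDS / gene / ncRNA features) in and predicted
  transcripts out, with a BED6 twin of the predictions.
* Optionally BAM: primary alignments only (flag mask 2308), clipped bases
  excluded by using the aligned reference span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from gffutils.feature import feature_from_line

if TYPE_CHECKING:  # pragma: no cover
    from .transcripts import Transcript

__all__ = [
    "ReadInterval",
    "RegionRecord",
    "CDSFeature",
    "BedFormatError",
    "GffFormatError",
    "read_read_bed",
    "read_read_bam",
    "read_region_bed",
    "read_reference_gff",
    "write_outputs",
]

_STRANDS = ("+", "-")


class BedFormatError(ValueError):
    """A BED line violated the expected dialect; carries the line number."""


class GffFormatError(ValueError):
    """A GFF3 line could not be parsed; carries the line number."""


@dataclass(frozen=True, slots=True)
class ReadInterval:
    """One primary alignment as a strand-specific half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str
    read_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read {self.read_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"read {self.read_id!r}: invalid strand {self.strand!r}")
        if not self.read_id:
            raise ValueError("read_id must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class RegionRecord:
    """A strand-pure merged coverage region with its supporting read count."""

    contig: str
    start: int
    end: int
    strand: str
    read_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region [{self.start}, {self.end}) is empty")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")


@dataclass(frozen=True, slots=True)
class CDSFeature:
    """A reference feature in internal 0-based half-open coordinates.

    ``feature_id`` comes from the ``ID`` or ``locus_tag`` attribute; joined
    CDS segments (multi-line CDS sharing an ID) yield one record per segment
    with the shared ``feature_id``.
    """

    contig: str
    start: int
    end: int
    strand: str
    feature_id: str
    feature_type: str  # CDS, gene, ncRNA or other

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.feature_id!r}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) for non-blank, non-comment lines."""
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track ", "browser ")):
                continue
            yield lineno, line


def _parse_coord(token: str, what: str, lineno: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise BedFormatError(f"line {lineno}: non-integer {what} {token!r}") from None
    if value < 0:
        raise BedFormatError(f"line {lineno}: negative {what} {value}")
    return value


def read_read_bed(path: str | Path) -> list[ReadInterval]:
    """Read per-read alignment intervals from a BED6 file.

    Column 4 is the read identifier and column 6 the strand; extra columns
    are ignored. Unstranded (``.``) records are rejected: every read must be
    assignable to a strand for strand-separated region construction.
    """
    reads: list[ReadInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise BedFormatError(
                f"line {lineno}: expected >=6 tab-separated columns, got {len(fields)}"
            )
        start = _parse_coord(fields[1], "start", lineno)
        end = _parse_coord(fields[2], "end", lineno)
        if start >= end:
            raise BedFormatError(f"line {lineno}: start {start} >= end {end}")
        strand = fields[5]
        if strand not in _STRANDS:
            raise BedFormatError(
                f"line {lineno}: strand must be '+' or '-', got {strand!r} "
                "(unstranded reads are not usable)"
            )
        if not fields[3]:
            raise BedFormatError(f"line {lineno}: empty read id")
        reads.append(ReadInterval(fields[0], start, end, strand, fields[3]))
    return reads


def read_read_bam(path: str | Path) -> list[ReadInterval]:
    """Convert primary alignments of a coordinate-accessible BAM/SAM to intervals.

    Secondary, supplementary and unmapped records (flag mask 2308) are
    skipped; soft/hard clipped bases are excluded because the interval is the
    aligned reference span of the primary alignment.
    """
    import pysam

    reads: list[ReadInterval] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.flag & 2308:
                continue
            if aln.reference_name is None or aln.reference_end is None:
                continue
            reads.append(
                ReadInterval(
                    contig=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    read_id=aln.query_name or f"read_{len(reads)}",
                )
            )
    return reads


def read_region_bed(path: str | Path) -> list[RegionRecord]:
    """Read the 5-column merged-region dialect (chrom, start, end, strand, count).

    A strand field holding a comma-joined set (e.g. ``+,-``) means the merge
    was not strand-separated and is rejected.
    """
    records: list[RegionRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 5:
            raise BedFormatError(
                f"line {lineno}: expected exactly 5 columns "
                f"(chrom, start, end, strand, count), got {len(fields)}"
            )
        start = _parse_coord(fields[1], "start", lineno)
        end = _parse_coord(fields[2], "end", lineno)
        if start >= end:
            raise BedFormatError(f"line {lineno}: start {start} >= end {end}")
        strand = fields[3]
        if "," in strand:
            raise BedFormatError(
                f"line {lineno}: mixed-strand merged region {strand!r}; "
                "regions must be merged per strand"
            )
        if strand not in _STRANDS:
            raise BedFormatError(f"line {lineno}: invalid strand {strand!r}")
        try:
            count = int(fields[4])
        except ValueError:
            raise BedFormatError(
                f"line {lineno}: non-integer read count {fields[4]!r}"
            ) from None
        if count < 0:
            raise BedFormatError(f"line {lineno}: negative read count {count}")
        records.append(RegionRecord(fields[0], start, end, strand, count))
    return records


_GFF_KEEP_TYPES = {"CDS", "gene", "ncRNA"}


def read_reference_gff(
    path: str | Path, keep_types: Iterable[str] | None = None
) -> list[CDSFeature]:
    """Parse a reference GFF3 into 0-based half-open :class:`CDSFeature` records.

    Only CDS / gene / ncRNA features are retained by default. The feature id
    is taken from ``ID=`` or, failing that, ``locus_tag=``; features with
    neither get a stable synthesized id from their coordinates.
    """
    keep = set(keep_types) if keep_types is not None else _GFF_KEEP_TYPES
    features: list[CDSFeature] = []
    saw_version = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##gff-version"):
                saw_version = True
                continue
            if line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GffFormatError(
                    f"line {lineno}: expected 9 tab-separated GFF3 columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GffFormatError(f"line {lineno}: unparseable GFF3 record: {exc}")
            if feat.featuretype not in keep:
                continue
            ids = feat.attributes.get("ID") or feat.attributes.get("locus_tag")
            if ids:
                feature_id = ids[0]
            else:
                feature_id = f"{feat.featuretype}:{feat.seqid}:{feat.start - 1}-{feat.end}"
            if feat.start > feat.end:
                raise GffFormatError(f"line {lineno}: start > end")
            strand = feat.strand if feat.strand in _STRANDS else "+"
            if feat.strand not in _STRANDS:
                warnings.warn(
                    f"line {lineno}: feature {feature_id} has strand "
                    f"{feat.strand!r}; treated as '+'",
                    stacklevel=2,
                )
            ftype = feat.featuretype if feat.featuretype in _GFF_KEEP_TYPES else "other"
            features.append(
                CDSFeature(
                    contig=feat.seqid,
                    start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                    end=feat.end,
                    strand=strand,
                    feature_id=feature_id,
                    feature_type=ftype,
                )
            )
    if not saw_version:
        warnings.warn(f"{path}: missing ##gff-version pragma", stacklevel=2)
    return features


def transcript_sort_key(t: "Transcript") -> tuple:
    return (t.contig, t.start, t.end, t.strand, t.transcript_id)


def write_outputs(
    transcripts: Sequence["Transcript"],
    gff_path: str | Path,
    bed_path: str | Path,
    classes: dict[str, str] | None = None,
) -> None:
    """Write predicted transcripts as a GFF3 file and its BED6 twin.

    Output order is deterministic — (contig, start, end, strand) — so
    identical inputs produce byte-identical files. ``classes`` optionally
    maps transcript ids to ``mRNA``/``ncRNA``; unclassified transcripts are
    typed ``transcript``.
    """
    ordered = sorted(transcripts, key=transcript_sort_key)
    classes = classes or {}
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for t in ordered:
            ftype = classes.get(t.transcript_id, "transcript")
            attrs = (
                f"ID={t.transcript_id};region_id={t.region_id};"
                f"N_tot={t.n_tot};N_ea={t.n_ea};ratio={t.ratio:.4f}"
            )
            gff.write(
                f"{t.contig}\tproktx\t{ftype}\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
    with open(bed_path, "w") as bed:
        for t in ordered:
            score = min(1000, int(round(t.ratio * 1000)))
            bed.write(
                f"{t.contig}\t{t.start}\t{t.end}\t{t.transcript_id}\t{score}\t{t.strand}\n"
            )
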