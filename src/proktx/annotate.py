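"""Transcript classification, UTR computation, annotation merge and summaries.

A predicted transcript is an mRNA when at least one annotated CDS lies
completely within its boundaries on the same strand, and a ncRNA otherwise.
Containment here is strict — no slack — and antisense CDSs never count. A
CDS annotated in several segments under one feature id (a joined CDS) only
counts when *all* its segments are contained: a partially contained joined
CDS is not a complete coding unit.

5'/3' UTR lengths are the strand-aware distances between the transcript
ends and the outermost contained CDS boundaries. Because CDS 5' ends are
frequently misannotated, a transcript whose classification could flip if a
CDS overhangs its 5' end by a few codons gets a ``borderline_5prime`` flag
instead of being reclassified.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import CDSFeature
from .regions import CTRegion
from .transcripts import Transcript

__all__ = [
    "ClassifiedTranscript",
    "UTRRecord",
    "SummaryStats",
    "classify_transcripts",
    "compute_utrs",
    "merge_annotations",
    "summarize",
]

logger = logging.getLogger(__name__)

#: a CDS overhanging the transcript 5' end by at most this many nt flags the
#: classification as sensitive to CDS N-terminus misannotation
BORDERLINE_5PRIME_NT = 30


@dataclass(frozen=True, slots=True)
class ClassifiedTranscript:
    transcript: Transcript
    klass: str  # mRNA | ncRNA
    contained_cds: tuple[CDSFeature, ...]
    known_ncrna_overlap: bool = False
    borderline_5prime: bool = False

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


@dataclass(frozen=True, slots=True)
class UTRRecord:
    transcript_id: str
    five_prime_len: int
    three_prime_len: int


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def classify_transcripts(
    transcripts: Sequence[Transcript],
    features: Sequence[CDSFeature],
    ncrna_overlap: float = 0.5,
) -> list[ClassifiedTranscript]:
    """Classify each transcript as mRNA or ncRNA against reference CDSs.

    A CDS segment is contained iff ``t.start <= c.start and c.end <= t.end``
    with equal strands on the same contig; a joined CDS (segments sharing a
    feature id on one contig/strand) counts only if every segment is
    contained. Predicted ncRNAs overlapping an annotated ncRNA reciprocally
    by at least ``ncrna_overlap`` are flagged as already known.
    """
    cds = [f for f in features if f.feature_type == "CDS"]
    known_ncrnas = [f for f in features if f.feature_type == "ncRNA"]
    cds_by_key: dict[tuple[str, str], list[CDSFeature]] = {}
    for f in cds:
        cds_by_key.setdefault((f.contig, f.strand), []).append(f)
    nc_by_key: dict[tuple[str, str], list[CDSFeature]] = {}
    for f in known_ncrnas:
        nc_by_key.setdefault((f.contig, f.strand), []).append(f)
    # segments of each joined CDS, for the all-segments-contained rule
    segments: dict[tuple[str, str, str], list[CDSFeature]] = {}
    for f in cds:
        segments.setdefault((f.contig, f.strand, f.feature_id), []).append(f)

    contigs_with_cds = {f.contig for f in features}
    out: list[ClassifiedTranscript] = []
    for t in transcripts:
        if t.contig not in contigs_with_cds:
            logger.warning(
                "contig %s absent from the annotation; transcript %s classified "
                "against an empty feature set",
                t.contig,
                t.transcript_id,
            )
        pool = cds_by_key.get((t.contig, t.strand), [])
        inside = [c for c in pool if t.start <= c.start and c.end <= t.end]
        contained = tuple(
            c
            for c in inside
            if all(
                t.start <= s.start and s.end <= t.end
                for s in segments[(c.contig, c.strand, c.feature_id)]
            )
        )
        klass = "mRNA" if contained else "ncRNA"
        borderline = False
        if klass == "ncRNA":
            # would any CDS fit if the transcript 5' end moved out slightly?
            for c in pool:
                if t.strand == "+":
                    fits = (
                        0 < t.start - c.start <= BORDERLINE_5PRIME_NT
                        and c.end <= t.end
                    )
                else:
                    fits = (
                        0 < c.end - t.end <= BORDERLINE_5PRIME_NT
                        and t.start <= c.start
                    )
                if fits:
                    borderline = True
                    break
        known = False
        if klass == "ncRNA":
            known = any(
                _reciprocal_overlap(t.start, t.end, f.start, f.end) >= ncrna_overlap
                for f in nc_by_key.get((t.contig, t.strand), [])
            )
        out.append(ClassifiedTranscript(t, klass, contained, known, borderline))
    return out


def compute_utrs(classified: Iterable[ClassifiedTranscript]) -> list[UTRRecord]:
    """Strand-aware UTR lengths for mRNAs.

    On the + strand the 5' UTR runs from the transcript start to the first
    contained CDS start and the 3' UTR from the last contained CDS end to
    the transcript end; on the - strand the roles swap. ncRNAs have no CDS
    and hence no UTRs — passing one is an error.
    """
    records: list[UTRRecord] = []
    for ct in classified:
        if ct.klass != "mRNA":
            raise ValueError(
                f"transcript {ct.transcript_id} is {ct.klass}; UTRs are defined "
                "only for mRNAs"
            )
        t = ct.transcript
        first = min(c.start for c in ct.contained_cds)
        last = max(c.end for c in ct.contained_cds)
        if t.strand == "+":
            five, three = first - t.start, t.end - last
        else:
            five, three = t.end - last, first - t.start
        records.append(UTRRecord(t.transcript_id, five, three))
    return records


def merge_annotations(
    classified: Sequence[ClassifiedTranscript],
    reference: Sequence[CDSFeature],
    out_path: str | Path,
) -> None:
    """Write one GFF3 holding the reference features plus typed transcripts.

    Contained CDSs gain ``Parent=`` links to every transcript that fully
    contains them. Ordering is deterministic; transcript ids colliding with
    reference ids are suffixed ``_tx`` (and logged).
    """
    def _key(f: CDSFeature) -> tuple:
        return (f.contig, f.start, f.end, f.strand, f.feature_type, f.feature_id)

    ref_ids = {f.feature_id for f in reference}
    parents: dict[tuple, list[str]] = {}
    tx_rows = []
    for ct in sorted(classified, key=lambda c: (c.transcript.contig, c.transcript.start,
                                                c.transcript.end, c.transcript.strand)):
        t = ct.transcript
        tx_id = t.transcript_id
        if tx_id in ref_ids:
            logger.info("transcript id %s collides with a reference id; suffixed", tx_id)
            tx_id += "_tx"
        attrs = f"ID={tx_id};region_id={t.region_id};ratio={t.ratio:.4f}"
        if ct.known_ncrna_overlap:
            attrs += ";known_ncRNA=true"
        if ct.borderline_5prime:
            attrs += ";borderline_5prime=true"
        tx_rows.append((t.contig, t.start, t.end, t.strand, ct.klass, attrs))
        for c in ct.contained_cds:
            parents.setdefault(_key(c), []).append(tx_id)

    rows = []
    for f in sorted(reference, key=lambda f: (f.contig, f.start, f.end, f.strand,
                                              f.feature_type, f.feature_id)):
        attrs = f"ID={f.feature_id}"
        if _key(f) in parents:
            attrs += ";Parent=" + ",".join(sorted(set(parents[_key(f)])))
        rows.append((f.contig, f.start, f.end, f.strand, f.feature_type, attrs))
    rows.extend(tx_rows)
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4], r[5]))
    with open(out_path, "w") as out:
        out.write("##gff-version 3\n")
        for contig, start, end, strand, ftype, attrs in rows:
            out.write(
                f"{contig}\tproktx\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def _size_stats(lengths: Sequence[int]) -> tuple[float, int, int]:
    if not lengths:
        return (0.0, 0, 0)
    return (statistics.fmean(lengths), min(lengths), max(lengths))


def _utr_stats(values: Sequence[int]) -> tuple[float, float, int]:
    if not values:
        return (0.0, 0.0, 0)
    return (statistics.fmean(values), statistics.median(values), max(values))


@dataclass(frozen=True, slots=True)
class SummaryStats:
    """Whole-run summary, every number recomputable from the inputs."""

    n_regions: int
    n_regions_plus: int
    n_regions_minus: int
    span_plus: int
    span_minus: int
    n_transcripts: int
    n_transcripts_plus: int
    n_transcripts_minus: int
    regions_with_one_transcript: int
    max_transcripts_per_region: int
    n_mrna: int
    n_ncrna: int
    n_known_ncrna: int
    mrna_size_mean: float
    mrna_size_min: int
    mrna_size_max: int
    ncrna_size_mean: float
    ncrna_size_min: int
    ncrna_size_max: int
    utr5_mean: float
    utr5_median: float
    utr5_max: int
    utr3_mean: float
    utr3_median: float
    utr3_max: int
    n_genes_in_transcripts: int
    max_genes_per_transcript: int
    max_transcripts_per_gene: int
    genes_per_transcript: dict[int, int]
    transcripts_per_gene: dict[int, int]

    def rows(self) -> list[tuple[str, object]]:
        return [
            ("Number of CT regions for predictions", self.n_regions),
            ("CT regions on (+)-strand", self.n_regions_plus),
            ("CT regions on (-)-strand", self.n_regions_minus),
            ("Span of (+)-strand CT regions (bp)", self.span_plus),
            ("Span of (-)-strand CT regions (bp)", self.span_minus),
            ("Number of transcripts", self.n_transcripts),
            ("Transcripts on (+)-strand", self.n_transcripts_plus),
            ("Transcripts on (-)-strand", self.n_transcripts_minus),
            ("Regions with a single transcript", self.regions_with_one_transcript),
            ("Max transcripts per region", self.max_transcripts_per_region),
            ("Number of predicted mRNAs", self.n_mrna),
            ("Number of predicted ncRNAs", self.n_ncrna),
            ("Predicted ncRNAs already annotated", self.n_known_ncrna),
            ("Mean mRNA size (bp)", round(self.mrna_size_mean, 1)),
            ("Smallest mRNA (bp)", self.mrna_size_min),
            ("Largest mRNA (bp)", self.mrna_size_max),
            ("Mean ncRNA size (bp)", round(self.ncrna_size_mean, 1)),
            ("Smallest ncRNA (bp)", self.ncrna_size_min),
            ("Largest ncRNA (bp)", self.ncrna_size_max),
            ("Mean 5'-UTR (bp)", round(self.utr5_mean, 1)),
            ("Median 5'-UTR (bp)", self.utr5_median),
            ("Max 5'-UTR (bp)", self.utr5_max),
            ("Mean 3'-UTR (bp)", round(self.utr3_mean, 1)),
            ("Median 3'-UTR (bp)", self.utr3_median),
            ("Max 3'-UTR (bp)", self.utr3_max),
            ("Genes contained in transcripts", self.n_genes_in_transcripts),
            ("Max genes per transcript", self.max_genes_per_transcript),
            ("Max transcripts per gene", self.max_transcripts_per_gene),
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("statistic\tvalue\n")
            for name, value in self.rows():
                out.write(f"{name}\t{value}\n")
            for k in sorted(self.genes_per_transcript):
                out.write(
                    f"Transcripts containing {k} gene(s)\t{self.genes_per_transcript[k]}\n"
                )
            for k in sorted(self.transcripts_per_gene):
                out.write(
                    f"Genes contained in {k} transcript(s)\t{self.transcripts_per_gene[k]}\n"
                )


def summarize(
    classified: Sequence[ClassifiedTranscript],
    regions: Sequence[CTRegion] = (),
    utrs: Sequence[UTRRecord] | None = None,
) -> SummaryStats:
    """Compute the run summary from classified transcripts, regions and UTRs."""
    if utrs is None:
        utrs = compute_utrs([c for c in classified if c.klass == "mRNA"])
    txs = [c.transcript for c in classified]
    per_region: dict[str, int] = {}
    for t in txs:
        per_region[t.region_id] = per_region.get(t.region_id, 0) + 1
    mrna = [c for c in classified if c.klass == "mRNA"]
    ncrna = [c for c in classified if c.klass == "ncRNA"]
    mrna_stats = _size_stats([c.transcript.length for c in mrna])
    ncrna_stats = _size_stats([c.transcript.length for c in ncrna])
    utr5 = _utr_stats([u.five_prime_len for u in utrs])
    utr3 = _utr_stats([u.three_prime_len for u in utrs])

    gene_tx: dict[str, set[str]] = {}
    genes_per_tx: dict[int, int] = {}
    for c in classified:
        genes = {f.feature_id for f in c.contained_cds}
        genes_per_tx[len(genes)] = genes_per_tx.get(len(genes), 0) + 1
        for g in genes:
            gene_tx.setdefault(g, set()).add(c.transcript_id)
    tx_per_gene: dict[int, int] = {}
    for g, txids in gene_tx.items():
        tx_per_gene[len(txids)] = tx_per_gene.get(len(txids), 0) + 1

    plus_regions = [g for g in regions if g.strand == "+"]
    minus_regions = [g for g in regions if g.strand == "-"]
    return SummaryStats(
        n_regions=len(regions),
        n_regions_plus=len(plus_regions),
        n_regions_minus=len(minus_regions),
        span_plus=sum(g.length for g in plus_regions),
        span_minus=sum(g.length for g in minus_regions),
        n_transcripts=len(txs),
        n_transcripts_plus=sum(1 for t in txs if t.strand == "+"),
        n_transcripts_minus=sum(1 for t in txs if t.strand == "-"),
        regions_with_one_transcript=sum(1 for v in per_region.values() if v == 1),
        max_transcripts_per_region=max(per_region.values(), default=0),
        n_mrna=len(mrna),
        n_ncrna=len(ncrna),
        n_known_ncrna=sum(1 for c in ncrna if c.known_ncrna_overlap),
        mrna_size_mean=mrna_stats[0],
        mrna_size_min=mrna_stats[1],
        mrna_size_max=mrna_stats[2],
        ncrna_size_mean=ncrna_stats[0],
        ncrna_size_min=ncrna_stats[1],
        ncrna_size_max=ncrna_stats[2],
        utr5_mean=utr5[0],
        utr5_median=utr5[1],
        utr5_max=utr5[2],
        utr3_mean=utr3[0],
        utr3_median=utr3[1],
        utr3_max=utr3[2],
        n_genes_in_transcripts=len(gene_tx),
        max_genes_per_transcript=max(genes_per_tx, default=0),
        max_transcripts_per_gene=max(tx_per_gene, default=0),
        genes_per_transcript=genes_per_tx,
        transcripts_per_gene=tx_per_gene,
    )
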