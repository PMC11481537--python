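"""Synthetic ground-truth transcriptomes and direct-RNA-like reads.

Nanopore direct RNA sequencing reads a native RNA 3'->5' from its ligated
3' adaptor, which leaves characteristic marks in the read set:

* reads are anchored at the transcript 3' end and frequently fail to reach
  the 5' end (5'-truncation), so depth rises from 5' to 3';
* some molecules are fragmented or degraded and lose part of the 3' end;
* shorter transcripts are preferentially sampled relative to longer ones;
* both read ends jitter by tens of bases around the true boundaries;
* very long molecules are not recovered as single reads (a hard cap).

The generator models these phenomena with simple parametric laws —
exponential truncation and fragmentation lengths, Gaussian end jitter, an
exponential length penalty on sampling weights. The laws themselves are this
module's own modelling choice; the phenomena are what matters, and each is
switchable so that noise-free data is a degenerate configuration.

Everything is driven by one integer seed: identical configuration in,
byte-identical read set out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ReadInterval
from .transcripts import Transcript

__all__ = [
    "GroundTruthTranscript",
    "LayoutSpec",
    "SimConfig",
    "EvalResult",
    "PRESETS",
    "simulate_transcriptome",
    "simulate_reads",
    "write_truth_table",
    "read_truth_table",
    "evaluate_predictions",
]

PRESETS = ("separated", "nested-3prime-shared", "internal-start", "antisense")


@dataclass(frozen=True, slots=True)
class GroundTruthTranscript:
    contig: str
    start: int
    end: int
    strand: str
    abundance_weight: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty transcript")
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be > 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class LayoutSpec:
    """Geometry of a synthetic transcriptome.

    ``preset`` picks one of four scenarios: well-``separated`` transcripts;
    ``nested-3prime-shared`` isoforms sharing a 3' end with distinct starts;
    ``internal-start`` — an operon-length transcript plus an isoform starting
    at an internal position, the classic internal-promoter geometry; and
    ``antisense`` — overlapping transcripts on opposite strands.
    """

    preset: str = "separated"
    n_transcripts: int = 20
    min_len: int = 500
    max_len: int = 4000
    gap: int = 2000
    origin: int = 1000
    contig: str = "chrSim"
    seed: int = 0
    internal_start_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.gap < 1:
            raise ValueError("gap must be >= 1 (transcripts must not merge)")
        if not (0.0 < self.internal_start_fraction < 1.0):
            raise ValueError("internal_start_fraction must be in (0, 1)")


def simulate_transcriptome(layout: LayoutSpec) -> list[GroundTruthTranscript]:
    """Lay out ground-truth transcripts deterministically from the layout seed."""
    rng = np.random.default_rng(layout.seed)
    txs: list[GroundTruthTranscript] = []
    if layout.preset == "separated":
        pos = layout.origin
        for i in range(layout.n_transcripts):
            length = int(rng.integers(layout.min_len, layout.max_len + 1))
            strand = "+" if i % 2 == 0 else "-"
            txs.append(
                GroundTruthTranscript(
                    layout.contig, pos, pos + length, strand, 1.0, f"tx{i + 1:03d}"
                )
            )
            pos += length + layout.gap
    elif layout.preset in ("nested-3prime-shared", "internal-start"):
        length = layout.max_len
        start = layout.origin
        end = start + length
        frac = (
            layout.internal_start_fraction
            if layout.preset == "internal-start"
            else 0.4
        )
        inner_start = start + int(round(frac * length))
        if end - inner_start < layout.min_len:
            raise ValueError("inner isoform shorter than min_len; layout infeasible")
        txs = [
            GroundTruthTranscript(layout.contig, start, end, "+", 1.0, "iso_long"),
            GroundTruthTranscript(layout.contig, inner_start, end, "+", 1.0, "iso_short"),
        ]
    elif layout.preset == "antisense":
        length = layout.max_len
        start = layout.origin
        shift = int(round(0.5 * length))
        txs = [
            GroundTruthTranscript(layout.contig, start, start + length, "+", 1.0, "sense"),
            GroundTruthTranscript(
                layout.contig, start + shift, start + shift + length, "-", 1.0, "antisense"
            ),
        ]
    return txs


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Read-generation parameters.

    ``p_full_5prime`` — probability a read reaches the transcript 5' end;
    otherwise it stops an Exp(``trunc_scale_5prime``) distance short.
    ``p_frag_3prime`` — probability of losing an Exp(``frag_scale``) stretch
    from the 3' end. ``jitter_sd`` — Gaussian sd of boundary jitter (nt).
    ``length_bias_scale`` — transcripts are sampled with weight proportional
    to abundance * exp(-L / scale), so short molecules are over-represented.
    ``max_read_len`` — reads longer than this are trimmed from the 5' side
    (the far end of the pore traversal).
    """

    seed: int = 0
    n_reads: int = 1000
    p_full_5prime: float = 0.5
    trunc_scale_5prime: float = 500.0
    p_frag_3prime: float = 0.1
    frag_scale: float = 200.0
    jitter_sd: float = 10.0
    length_bias_scale: float = 3000.0
    max_read_len: int = 9000
    min_read_len: int = 20

    def __post_init__(self) -> None:
        for p in (self.p_full_5prime, self.p_frag_3prime):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        for s in (self.trunc_scale_5prime, self.frag_scale, self.length_bias_scale):
            if s <= 0:
                raise ValueError("scales must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def sampling_weights(
    truth: Sequence[GroundTruthTranscript], length_bias_scale: float
) -> np.ndarray:
    """Normalized sampling weights: abundance x exp(-L / scale)."""
    w = np.array(
        [t.abundance_weight * math.exp(-t.length / length_bias_scale) for t in truth]
    )
    return w / w.sum()


def _draw_read(
    t: GroundTruthTranscript, config: SimConfig, rng: np.random.Generator
) -> tuple[int, int] | None:
    """One read attempt in genomic coordinates, or None if degenerate."""
    jit = config.jitter_sd
    # offsets measured outward from the transcript ends (positive = beyond)
    d3 = rng.normal(0.0, jit) if jit > 0 else 0.0
    if config.p_frag_3prime > 0 and rng.random() < config.p_frag_3prime:
        d3 -= rng.exponential(config.frag_scale)
    if config.p_full_5prime >= 1.0 or rng.random() < config.p_full_5prime:
        d5 = rng.normal(0.0, jit) if jit > 0 else 0.0
    else:
        d5 = -rng.exponential(config.trunc_scale_5prime)
    # reads never overhang the true boundary by more than 3 sd of jitter
    d3 = min(d3, 3.0 * jit)
    d5 = min(d5, 3.0 * jit)
    if t.strand == "+":
        start = t.start - d5
        end = t.end + d3
    else:
        start = t.start - d3
        end = t.end + d5
    start, end = int(round(start)), int(round(end))
    start = max(start, 0)
    if end - start < config.min_read_len:
        return None
    if end - start > config.max_read_len:
        # 3'-anchored: trim the 5' (pore-distal) side
        if t.strand == "+":
            start = end - config.max_read_len
        else:
            end = start + config.max_read_len
    return start, end


def simulate_reads(
    truth: Sequence[GroundTruthTranscript],
    config: SimConfig = SimConfig(),
    reads_per_transcript: int | None = None,
) -> tuple[list[ReadInterval], pd.DataFrame]:
    """Generate 3'-anchored reads and a per-read truth table.

    Transcripts are sampled with length-biased weights unless
    ``reads_per_transcript`` fixes an exact per-transcript count (useful for
    controlled coverage experiments). Degenerate draws (below
    ``min_read_len``) are redrawn, up to 1000 attempts each.

    The truth table columns are: ``read_id``, ``transcript_label``,
    ``contig``, ``start``, ``end`` (0-based half-open), ``strand``.
    """
    if not truth:
        raise ValueError("empty ground truth")
    rng = np.random.default_rng(config.seed)
    if reads_per_transcript is None:
        weights = sampling_weights(truth, config.length_bias_scale)
        choices = rng.choice(len(truth), size=config.n_reads, p=weights)
    else:
        choices = np.repeat(np.arange(len(truth)), reads_per_transcript)
    reads: list[ReadInterval] = []
    rows: list[tuple] = []
    for i, ti in enumerate(choices):
        t = truth[int(ti)]
        interval = None
        for _ in range(1000):
            interval = _draw_read(t, config, rng)
            if interval is not None:
                break
        if interval is None:
            raise RuntimeError(
                f"could not draw a valid read for transcript {t.label!r}; "
                "check min_read_len against the noise scales"
            )
        start, end = interval
        read_id = f"read{i + 1:07d}"
        reads.append(ReadInterval(t.contig, start, end, t.strand, read_id))
        rows.append((read_id, t.label, t.contig, start, end, t.strand))
    table = pd.DataFrame(
        rows, columns=["read_id", "transcript_label", "contig", "start", "end", "strand"]
    )
    return reads, table


def write_truth_table(
    truth: Sequence[GroundTruthTranscript], path: str | Path
) -> None:
    """TSV of the ground-truth transcripts (label, contig, start, end, strand, weight)."""
    df = pd.DataFrame(
        [(t.label, t.contig, t.start, t.end, t.strand, t.abundance_weight) for t in truth],
        columns=["label", "contig", "start", "end", "strand", "abundance_weight"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[GroundTruthTranscript]:
    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruthTranscript(
            str(r.contig), int(r.start), int(r.end), str(r.strand),
            float(r.abundance_weight), str(r.label),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True, slots=True)
class MatchedPair:
    truth_label: str
    transcript_id: str
    error_5prime: int
    error_3prime: int


@dataclass(frozen=True, slots=True)
class EvalResult:
    recall: float
    precision: float
    matches: tuple[MatchedPair, ...]
    n_truth: int
    n_predicted: int
    no_predictions: bool = False

    @property
    def boundary_errors_5prime(self) -> list[int]:
        return [m.error_5prime for m in self.matches]

    @property
    def boundary_errors_3prime(self) -> list[int]:
        return [m.error_3prime for m in self.matches]


def evaluate_predictions(
    predicted: Sequence[Transcript],
    truth: Sequence[GroundTruthTranscript],
    tol: int = 100,
) -> EvalResult:
    """Greedy one-to-one matching of predictions to truth by boundary error.

    A (truth, prediction) pair is admissible when contigs and strands agree
    and both strand-aware boundary errors are <= ``tol``; admissible pairs
    are consumed in order of increasing total error (deterministic
    tie-break). Recall is matched/|truth|; precision matched/|predicted|,
    reported as 0 with a flag when there are no predictions.
    """
    pairs: list[tuple[int, int, int, int, int]] = []
    for i, t in enumerate(truth):
        for j, p in enumerate(predicted):
            if p.contig != t.contig or p.strand != t.strand:
                continue
            err_start = abs(p.start - t.start)
            err_end = abs(p.end - t.end)
            e5, e3 = (err_start, err_end) if t.strand == "+" else (err_end, err_start)
            if e5 <= tol and e3 <= tol:
                pairs.append((e5 + e3, i, j, e5, e3))
    pairs.sort()
    used_truth: set[int] = set()
    used_pred: set[int] = set()
    matches: list[MatchedPair] = []
    for total, i, j, e5, e3 in pairs:
        if i in used_truth or j in used_pred:
            continue
        used_truth.add(i)
        used_pred.add(j)
        matches.append(MatchedPair(truth[i].label, predicted[j].transcript_id, e5, e3))
    recall = len(matches) / len(truth) if truth else 0.0
    precision = len(matches) / len(predicted) if predicted else 0.0
    return EvalResult(
        recall=recall,
        precision=precision,
        matches=tuple(matches),
        n_truth=len(truth),
        n_predicted=len(predicted),
        no_predictions=not predicted,
    )
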