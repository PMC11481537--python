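# Methods

## Model and procedure

`proktx` predicts transcripts from per-read alignment intervals alone. The
unit of work is the strand-specific contiguously transcribed (CT) region: a
maximal run of positions covered by at least one read on one strand of one
contig. Within a region the per-position depth counts every base of every
read equally, using only the interval's start/end — alignment mismatches
and indels are ignored on purpose, so base modifications (abundant in
prokaryotic RNA) or reference divergence cannot dent the profile. Depth is
computed exactly with a difference array (+1 at each read start, −1 at each
end, prefix sum), so all quantities are integers and the deltas over the
zero-padded range sum to zero by construction.

Boundary sites are positions where the depth step |ΔD| reaches the delta
threshold; the region termini are always sites. "Reaches" is implemented
as ≥ by default (a step of exactly the threshold is treated as evidence);
`--strict-gt` switches to >, since the two conventions are one read apart
and neither is observably better. A positive step between n and n+1 puts
the start site at n+1 (the first covered base) and a negative step puts the
stop site at n+1 in half-open coordinates, so site pairs are directly
usable as `[start, end)` transcript intervals.

Because ONT read ends jitter, same-side sites are chained by single linkage
with gaps up to the grouping distance, and each chain is represented by its
max-magnitude member — the mode of read ends is the best single estimate of
the underlying boundary. Ties go to the position nearest the region
terminus when the chain contains a forced terminus site, otherwise to the
leftmost position. Start and stop sites are never grouped with each other:
merging a start with a stop has no meaning for the candidate enumeration
that follows.

Candidates are all (start, stop) representative pairs at least
`min_length` apart, processed shortest to longest (ties by left
coordinate, applied consistently in processing order and read assignment).
`N_tot` counts reads contained in a candidate within the containment slack
and is computed once; `N_ea` counts reads whose current exclusive home the
candidate is, and is recomputed from the live assignment as each candidate
comes up. A candidate with `N_ea/N_tot` below the ratio threshold (or with
no reads) is discarded and its reads re-home immediately to their
next-shortest surviving container; reads with no surviving container drop
out of all counts rather than being force-assigned. Immediate (rather than
deferred) re-homing is what lets reads from a rejected short candidate
support a longer transcript within the same pass.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `delta_threshold` | 4 | reads | minimum depth step to call a boundary site |
| `group_distance` | 100 | nt | single-linkage chaining distance for nearby sites |
| `ratio` | 0.2 | — | minimum `N_ea/N_tot` to retain a candidate |
| `min_depth` | 2 | reads | subdivide regions below this depth |
| `min_region_reads` | 20 | reads | pipeline prefilter on contained reads per region (the algorithm-level floor is 2) |
| `min_length` | 50 | nt | shortest candidate considered |
| `containment_slack` | 100 | nt | read overhang tolerated at candidate bounds |

The containment slack defaults to the grouping distance deliberately: a
grouped site represents member read ends up to that far from the
representative, and strict containment would orphan exactly the reads the
group was built from. Setting it to 0 restores the strict reading of
"fully contains". `min_length` = 50 keeps degenerate micro-candidates from
adjacent grouped sites out of the Cartesian product while staying below the
smallest ncRNAs of interest (~52 nt); it is configurable down to 1.
`min_region_reads` uses ≥; a strict > is one flag value away.

## Subdivision and discarded reads

Reads that straddle a low-depth split point are discarded — they are not
"completely contained" in either side, and assigning them to the larger
side would silently break containment semantics. Discarding can itself
drag depth below the cutoff, so subdivision iterates to a fixed point
(bounded by region length); afterwards every surviving region has depth ≥
`min_depth` everywhere with respect to its retained reads. Discard counts
are logged and reported in the prediction run record.

## Classification and UTRs

mRNA/ncRNA classification uses strict, strand-matched containment of CDS
features; a CDS annotated as several segments under one feature id counts
only when every segment is contained, because a partial joined CDS is not a
complete coding unit. Since CDS 5′ ends are often misannotated, a ncRNA
whose classification would flip if a CDS overhung its 5′ end by ≤ 30 nt is
flagged `borderline_5prime` rather than reclassified. Predicted ncRNAs
matching an annotated ncRNA at ≥ 50% reciprocal overlap (configurable) are
flagged as already known. UTR lengths satisfy, for every mRNA, the identity
5′UTR + (outermost CDS span) + 3′UTR = transcript length.

## The simulator

The generator emulates the documented read phenomena, not their unknown
true laws; the distributional choices are the module's own:

* transcripts are sampled with weight ∝ abundance × exp(−L/λ), λ = 3000 nt
  (short-molecule preference);
* each read is 3′-anchored: its 3′ end is the transcript 3′ end plus
  N(0, 10 nt) jitter, minus an Exp(200 nt) loss with probability 0.1
  (fragmentation/degradation);
* with probability 0.5 the read reaches the 5′ end (plus jitter), otherwise
  it stops Exp(500 nt) short — truncated reads never overshoot the 5′ end;
* reads are clipped to the transcript ± 3σ of jitter, capped at 9 kb by
  trimming the 5′ (pore-distal) side, and redrawn below 20 nt.

Four layout presets cover the geometries that matter: `separated`
(independent transcripts), `nested-3prime-shared` and `internal-start`
(isoforms sharing a 3′ end with distinct starts — the internal-promoter
case), and `antisense` (opposite-strand overlap). What the simulator does
*not* model: basecalling errors, squiggle-level signal, chimeric reads
(assumed removed upstream by clipping primary alignments), polyA tails, and
expression heterogeneity beyond a per-transcript abundance weight. Passing
tests on simulated data therefore demonstrate the interval algorithm's
correctness under the stated biases, not end-to-end accuracy on a real
flow cell.

## Numerical and design notes

* Coordinates are uniformly 0-based half-open internally; conversion to
  GFF3's 1-based inclusive convention happens only in the readers/writers,
  and the round trip is lossless (property-tested).
* All outputs are deterministically ordered and byte-stable; every source
  of randomness flows from one integer seed.
* Precision/recall against ground truth use greedy one-to-one matching by
  total boundary error with a 100 nt tolerance per boundary (the grouping
  distance — errors below it are indistinguishable from grouping).
* The retained set is not monotone as a *set* in the ratio threshold:
  discarding a short candidate at a higher threshold re-homes its reads and
  can rescue a longer candidate. The retained *count* is non-increasing on
  all tested instances, and that is the property the suite asserts.
* Test and acceptance problem sizes (≤ 10 kbp regions, ≤ 10³ reads per
  oracle instance, 20-transcript layouts at 120–300× coverage) were chosen
  as the smallest scales at which every modelled phenomenon is clearly
  expressed; the whole suite runs in seconds.

## Known limitations

Boundary estimates inherit ONT end imprecision; no attempt is made to
polish single-base TSSs or detect promoter/terminator motifs. Long, lowly
covered transcripts can be discarded when nearly all their reads are
truncated (the full-length candidate's `N_ea` starves), mirroring the
method's behaviour on real data. Predicted ncRNAs may be stable degradation
products rather than functional RNAs; the package classifies, it does not
interpret.
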