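# Methods

This note documents the models and numerical choices behind `squigmap`: how
raw signal becomes events, events become hash seeds, seeds become chains,
and chains become a real-time mapping decision; what the simulator does and
does not emulate; and the reasoning behind defaults where the design was
genuinely open.

## Signal model and segmentation

A nanopore read is modelled as a piecewise-constant current: while one
k-mer context occupies the pore the current fluctuates around that k-mer's
expected level (from the pore model), then steps when the molecule
advances. Segmentation recovers the steps with the two-window t-statistic
detector used across the squiggle-analysis lineage: at every candidate
boundary position the Welch t-statistic between the `w` samples before and
after is computed for a short window (`w_short = 4` samples, threshold 4.5)
and a long window (`w_long = 16`, threshold 3.0); the per-position score is
the larger threshold-normalized statistic, and boundaries are score peaks
that survive non-maximum suppression with radius `w_short` (ties resolve
leftmost). A variance floor of 1e-12 keeps the statistic finite on flat
signal, so a constant read yields exactly one event. Events shorter than
`min_dwell = 3` samples are merged into their successor (stutter
suppression); the read's final event, having no successor, merges backward.

The window sizes target DNA chemistry at roughly 9 samples/base (450 b/s at
4 kHz): the short window resolves one-base dwells, the long window
stabilizes detection under noise. All five parameters are configuration
(`SegmenterParams`), not claims about optimality; they are not tuned for
RNA or for newer flow-cell chemistries.

**Streaming identity.** Everything in the detector is causal with bounded
lookahead: the statistic at position i depends on samples
[i − w_long, i + w_long), suppression on a w_short radius, and dwell-merging
on earlier boundaries only. The streaming segmenter therefore emits an
event only once its end lies more than `w_long + w_short` samples behind
the stream head, which makes chunked output provably identical to
single-shot segmentation — the property the real-time loop relies on, and
the suite tests directly.

**Normalization.** Event levels are z-scored (mean 0, population sd 1) over
*all events seen so far in the read*, recomputed each chunk. Per-chunk-only
statistics would make early decisions depend on which chunk boundary a read
happened to get; whole-read running statistics converge to the reference
frame as evidence accumulates. Mean/sd was chosen over median/MAD: the
simulator produces no heavy-tailed artefacts that would motivate robust
statistics, and mean/sd matches the z-scaling applied to the reference at
index time. Reference levels are normalized once with *global* statistics
over both strands of all contigs (stored in the index), keeping the two
sides in comparable frames.

## Adaptive quantization and seeds

Normalized levels concentrate near zero, so uniform quantization wastes
resolution on empty tails. The adaptive scheme splits the line into a fine
range [f_min, f_max] given fraction f_r of the resolution and a coarse
outer range at c_r = (1 − f_r) × 0.5 (see README for the formula). The
formula is implemented branch-verbatim with the result clamped into [0, n];
as written, the coarse branches can overlap the fine branch's output
interval for some parameter choices, so only *per-branch* monotonicity is
guaranteed (and tested). This is harmless for hashing — quantization is a
bucketing, not an ordering — and the clamp is the faithful reading of an
output range defined as [0, n].

Defaults: `n = 15` (4 bits/value), `f_r = 0.8`, `[f_min, f_max] = [−2, 2]`,
`e = 6` events per seed, 64-bit invertible mixer on. The governing
trade-off is bucket width versus event-level noise: with dwell ~9 samples
and per-sample noise equal to the model stdv (~2 pA against a ~12 pA level
spread), the sd of an event's mean level is ~0.06 normalized units. The
fine-range bucket width is (f_max − f_min)/(n·f_r) ≈ 0.33, about five times
that noise, so a single event re-quantizes identically with high
probability and a 6-event seed survives intact often enough to anchor every
read region. Much finer grids (say n = 127, width ≈ 0.04) put the bucket
width *below* the noise; exact 6-gram matches then essentially never occur
and mapping collapses — which is why the default is deliberately coarse.
Finer quantization buys specificity only together with shorter seeds or
higher noise tolerance elsewhere; all knobs are exposed.

Seed positions are end-anchored (index of the window's last event), so an
anchor's matching interval is [pos − w + 1, pos] on both axes.

## Index, minimizers, frequency filters

Both strands are indexed; minus-strand postings are stored in the reverse
complement's own coordinates so that chaining stays colinear for reverse
reads (x and y both increase along the read), and are converted to forward
PAF coordinates only at output. Postings pack (contig, position, strand)
into one int64; lookup is binary search over a sorted unique hash array.

Minimizer sketching keeps a seed iff its hash is the minimum of at least
one window of `w_min` consecutive seeds (leftmost on ties), the standard
O(n) monotonic-queue construction; expected density on random hashes is
2/(w_min + 1). Sketching is off by default — it trades sensitivity for
index size and is provided for exactly that trade.

Frequency filtering is two-step: reference-side, hashes with more than
`max_ref_occ` postings are dropped at build time (default off; `AUTO`
picks the smallest cap retaining 99.8% of distinct hashes, the usual
repeat-masking fraction); query-side, hashes occurring more than
`max_query_occ = 5` times within a read's seeds are dropped before lookup.
Repetitive seeds dominate chaining cost while carrying little positional
information.

## Chaining and mapping quality

The DP is exact over admissible predecessors (x and y strictly increasing,
both gaps ≤ `max_gap`), with the usual scan heuristics (`max_skip = 25`
non-improving steps, `max_iter = 5000`); with heuristics disabled it equals
brute-force enumeration of all increasing anchor subsequences, which the
suite verifies on random instances. γ(0) = 0 by definition — the log term
is undefined at zero gap, and a perfectly colinear extension must cost
nothing. The log base is 2. The span *w* in the penalty is the incoming
anchor's span. Reference coordinates are event-grid positions (one level
per base) and query coordinates are event indices; the DP treats them as
commensurate, which holds to within the segmentation's event-rate error.

Backtracking assigns each anchor to at most one chain, greedily from the
highest-scoring chain end; a chain that runs into an already-claimed anchor
keeps only its unclaimed suffix score. Chains need `min_score = 40` and
`min_anchors = 4`. These two thresholds, with `max_gap = 500` events, are
the false-positive control: a spurious chain needs ~7 random anchors
colinear within gap bounds on both axes, which on a 100 kb reference is
vanishingly rare, while true loci accumulate tens of anchors within one
chunk. Mapping quality follows the familiar form
`40·(1 − f2/f1)·min(1, m/10)·ln f1`, clamped to [0, 60], primary chain
only; 30 is treated as "high confidence" by the decision layer.

## Weighted decision

The three ratios and their caps (cap₂ = cap₃ = 5), weights (0.4, 0.3, 0.3)
and threshold τ = 0.6 are configuration. A single surviving chain saturates
r₂ = r₃ = 1, so with the default weights a lone chain maps as soon as its
mapq is positive — intentional: the chain score/anchor thresholds above
already guarantee that a lone chain is strong evidence, and demanding more
only delays the decision (costing sequenced bases) without improving
specificity. With several chains, the best/mean ratios discount ambiguous
repeats. Raising τ trades mean decision latency for caution; the decision
is monotone in τ by construction.

Reads that exhaust their signal or the `max_chunks = 30` budget without a
confident mapping are *reported* unmapped (target `*`,
`dc:Z:unmapped_max_chunks`) rather than dropped, so sequencing-length
accounting (`bb` tag = chunks × chunk_samples / samples_per_base) covers
every read. Query base coordinates in PAF are estimates via the observed
events-per-base rate; signal space has no exact base positions.

## Simulator

The simulator emulates clean single-pass translocation: uniform read start
and strand; Gamma dwell per k-mer with mean sampling_rate/bases_per_second
(≈8.89 samples/base at defaults) and coefficient of variation
`dwell_dispersion = 0.25` (Gamma rather than geometric for the
over-dispersion of real dwells); Gaussian per-sample noise with sd =
`noise_sd_scale` × the k-mer's model stdv (default 1.0 — noise exactly as
the pore model describes it); per-read affine distortion (scale sd 0.05,
shift sd 2 pA) mimicking calibration differences, which read-level
z-scoring removes by design; samples snapped to a ~0.12 pA digitization
grid so SLOW5 round-trips are exact. Read lengths are Gamma(shape 3) around
5 kb, floored at 500 b.

Not modelled: stalls, skips and re-reads, adapter/barcode signal, current
drift within a read, RNA kinetics, basecalling errors. Consequently,
passing the end-to-end tests demonstrates the pipeline's internal
consistency and its noise/dispersion tolerance under this signal model — it
does not certify accuracy on real flow-cell data, where segmentation error
modes are richer. The default test scenario (100 kb random genome, 200
reads, the noise above) was sized to exercise every stage, including
multi-chunk decisions and reverse-strand mapping, while keeping the whole
suite interactive (~10 s); the acceptance script uses the same scenario
plus a foreign-genome negative control and a three-genome abundance
mixture.

## Degenerate inputs and numerical details

- Sequences shorter than k (or segments between N's shorter than k) yield
  no levels; N never contributes to a seed.
- A constant read segments into one event; normalization of constant levels
  raises, and such reads are reported unmapped.
- A constant *reference* (e.g. poly-A) gets identity scaling with a warning
  instead of failing, so frequency-filter behaviour on pathological repeats
  remains testable.
- Variance floor 1e-12 in the t-statistic; floating-point ties in
  non-maximum suppression resolve leftmost, making segmentation fully
  deterministic.
- The hash mixer is an invertible 64-bit xorshift-multiply finalizer:
  dispersion for table behaviour, zero information loss, exact-match
  semantics preserved.

## Known limitations

- Segmentation windows and thresholds are not calibrated for RNA or for
  chemistries with sampling-to-speed ratios far from ~9 samples/base.
- Seeding is exact-match over quantized levels; systematic level shifts
  larger than a bucket (e.g. uncorrected drift) degrade recall.
- The chaining DP ignores the residual scale difference between the
  reference event grid (one event per base) and the query's observed event
  rate; for long chains this is absorbed by the gap tolerance.
- Binary signal containers (FAST5/POD5/BLOW5) are not parsed natively; any
  iterable of `RawRead` can be supplied instead.
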