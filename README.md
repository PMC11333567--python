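# squigmap

Real-time mapping of raw nanopore current signals ("squiggles") to a
reference genome — without basecalling.

Nanopore sequencers report an ionic-current time series as a molecule
transits the pore, and they can eject a molecule mid-read ("Read Until" /
adaptive sampling). Acting on that capability requires deciding where a read
maps while it is still being sequenced, faster than the pore produces
signal, which rules out basecalling on modest hardware. `squigmap` maps the
raw signal directly: it is aimed at people prototyping selective-sequencing
pipelines, studying signal-domain seeding strategies, or needing a
transparent, fully testable reference implementation of hash-based squiggle
mapping — with a built-in simulator so everything runs and is verified
without any sequencing data.

## Method

Every stage has a signal-domain analogue of a classic seed-and-chain mapper:

1. **Event segmentation.** Raw samples are cut into *events* (one per pore
   context) at peaks of a two-window Welch t-statistic, with non-maximum
   suppression; each event's level is the mean of its samples. Event levels
   are z-score normalized per read.

2. **Adaptive quantization.** A normalized level *s* is quantized into an
   integer in [0, n]. A *fine range* [f_min, f_max] — where most of the
   (non-uniform) level mass lies — receives resolution f_r; outside it, the
   coarse resolution is c_r = (1 − f_r) × 0.5:

       q(s) = ⌊ n · f_r · (s − f_min) / (f_max − f_min) ⌋   f_min ≤ s ≤ f_max
       q(s) = ⌊ n · (f_r + c_r · s) ⌋                       s < f_min
       q(s) = ⌊ n · (f_r + c_r + c_r · s) ⌋                 s > f_max

   clamped into [0, n].

3. **Hash seeds.** Each window of *e* consecutive quantized levels is packed
   into a 64-bit hash. The reference is translated into expected levels via
   a k-mer pore model and indexed the same way (both strands), optionally
   sketched with minimizers (keep each window-of-w minimum) and frequency
   filtered on both the reference side (drop hashes with more than
   `max_ref_occ` postings) and the query side (`max_query_occ`).

4. **Chaining.** Exact hash matches become anchors (x, y, w) chained by the
   gap-penalty dynamic program

       f(i) = max( max_{j<i} { f(j) + α(j,i) − β(j,i) },  w_i ),
       α(j,i) = min(min(y_i − y_j, x_i − x_j), w_i),
       β(j,i) = γ(l) = 0.01·w·|l| + 0.5·log₂|l|,   l = (y_i−y_j) − (x_i−x_j),

   with γ(0) = 0 and minimap2-style heuristics and mapping quality.

5. **Weighted mapping decision.** After every signal chunk (default 4000
   samples ≈ 1 s), three ratios — r₁ = mapq/30 (capped at 1), r₂ = best/mean
   mapping quality, r₃ = best/mean chain score (both capped and normalized)
   — are combined as w_sum = Σ rᵢ·wᵢ; the read is reported mapped as soon as
   w_sum exceeds a threshold τ, otherwise sequencing continues up to a chunk
   budget.

The package also contains a squiggle **simulator** (Gamma dwell times,
pore-model noise, per-read affine distortion, ground-truth PAF) and a
pafstats-style **evaluator** (precision/recall/F1 and relative-abundance
Euclidean distance).

## Worked example

Simulate 20 reads from a random 50 kb genome, index it, map, and evaluate:

```sh
squigmap sim -o demo --random-genome-len 50000 --n-reads 20 \
    --read-len-mean 3000 --seed 42
squigmap index demo.ref.fasta -o demo.idx.npz
squigmap map demo.idx.npz demo.slow5 -o demo.paf
squigmap eval demo.paf --truth demo.truth.paf
```

which prints (elided):

```
indexed 1 contig(s): 93814 distinct hashes, 99980 postings
mapped 20/20 reads
{ "TP": 20, "FP": 0, "FN": 0, "precision": 1.0, "recall": 1.0, "f1": 1.0 }
```

The PAF output carries decision metadata as tags, e.g.

```
sim_00000  450  0  447  +  chr1  50000  4024  4469  28  447  60  ch:i:1  ev:i:365  ws:f:1.0  bb:f:450.0  dc:Z:mapped
```

read `sim_00000` mapped to chr1:4024–4469 (+) with mapping quality 60 after
a single chunk (`ch:i:1`, 365 events): the decision statistic saturated
(`ws:f:1.0`) after processing an estimated 450 bases (`bb:f:450.0`) — the
read was resolved using ~1 s of signal instead of being sequenced to its
full 3 kb, which is exactly the saving adaptive sampling is after. The
query coordinates (0–447 of an estimated 450-base consumed prefix) are
event-count estimates, not basecalled positions.

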