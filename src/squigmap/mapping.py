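"""Real-time read mapping: chunked signal → seeds → chains → decision → PAF.

The mapper consumes a read the way a sequencer delivers it: in fixed-size
chunks of raw samples.  After each chunk the accumulated events are
(re-)normalized, quantized into seeds, frequency-filtered on the query side,
matched against the reference index, and chained per contig and strand.  A
*weighted decision statistic* then asks whether the evidence is strong
enough to stop sequencing this read: three ratios are combined,

    r1 = min(1, mapq_best / mapq_ref)            (mapq_ref = 30)
    r2 = min(cap2, mapq_best / mean mapq) / cap2
    r3 = min(cap3, score_best / mean score) / cap3

(means over all current chains; a single chain saturates r2 = r3 = 1), and
the read maps as soon as ``w_sum = sum(r_i * w_i) > tau`` with normalized
weights.  Reads that exhaust their signal or the chunk budget without a
confident mapping are reported as unmapped so downstream sequencing-length
accounting covers every read.

Query PAF coordinates are an estimate: event indices are converted to bases
through the observed events-per-base rate (events seen / bases consumed),
since the signal domain has no exact base coordinate before basecalling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from squigmap.chaining import (
    Anchor,
    Chain,
    ChainParams,
    chain_anchors,
    mapping_quality,
)
from squigmap.indexing import ReferenceIndex, unpack_postings
from squigmap.quantization import seeds_from_events
from squigmap.segmentation import SegmenterParams, StreamingSegmenter
from squigmap.signal_io import RawRead

logger = logging.getLogger(__name__)

__all__ = ["DecisionParams", "ChunkParams", "MappingRecord",
           "query_frequency_filter", "weighted_decision", "map_read",
           "write_paf", "read_paf"]


@dataclass(frozen=True)
class DecisionParams:
    """Weighted mapping decision configuration.

    ``weights`` are normalized to sum to 1 on construction; ``mapq_ref`` is
    the "sufficiently high" mapping quality anchoring r1; ``cap_2``/``cap_3``
    bound the best-vs-mean ratios before normalizing them into [0, 1].
    """

    mapq_ref: float = 30.0
    weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    tau: float = 0.6
    cap_2: float = 5.0
    cap_3: float = 5.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
        object.__setattr__(self, "weights", tuple(w / w.sum()))
        if self.mapq_ref <= 0 or self.cap_2 <= 0 or self.cap_3 <= 0:
            raise ValueError("mapq_ref and ratio caps must be positive")


@dataclass(frozen=True)
class ChunkParams:
    """Real-time chunking: samples per chunk and the chunk budget.

    ``chunk_samples=4000`` is about one second of DNA signal at 4 kHz;
    ``bases_per_second`` (450 for the common DNA chemistry) with the read's
    sampling rate gives samples-per-base for sequencing-length accounting.
    """

    chunk_samples: int = 4000
    max_chunks: int = 30
    bases_per_second: float = 450.0

    def __post_init__(self) -> None:
        if self.chunk_samples < 1 or self.max_chunks < 1:
            raise ValueError("chunk_samples and max_chunks must be >= 1")
        if self.bases_per_second <= 0:
            raise ValueError("bases_per_second must be positive")

    def samples_per_base(self, sampling_rate: float) -> float:
        return sampling_rate / self.bases_per_second


@dataclass
class MappingRecord:
    """One PAF row plus real-time decision metadata."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int
    tags: dict[str, float | int | str] = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return self.tname != "*"


def query_frequency_filter(seeds: list[tuple[int, int]],
                           max_query_occ: int) -> list[tuple[int, int]]:
    """Drop query seeds whose hash occurs more than ``max_query_occ`` times
    within this query (0 disables the filter)."""
    if max_query_occ <= 0 or not seeds:
        return list(seeds)
    hashes = np.array([h for _, h in seeds], dtype=np.uint64)
    uniq, inv, counts = np.unique(hashes, return_inverse=True,
                                  return_counts=True)
    keep = counts[inv] <= max_query_occ
    return [s for s, k in zip(seeds, keep.tolist()) if k]


def weighted_decision(chains: list[Chain],
                      dp: DecisionParams | None = None) -> tuple[str, float]:
    """Combine chain evidence into (decision, w_sum); decision is ``"map"``
    iff the weighted sum exceeds ``tau``, else ``"continue"``.

    Chains must already carry mapping qualities.  No chains → continue, 0.
    """
    dp = dp or DecisionParams()
    if not chains:
        return "continue", 0.0
    best = max(chains, key=lambda c: c.score)
    r1 = min(1.0, best.mapq / dp.mapq_ref)
    if len(chains) == 1:
        r2 = r3 = 1.0
    else:
        mean_mapq = float(np.mean([c.mapq for c in chains]))
        mean_score = float(np.mean([c.score for c in chains]))
        if best.mapq <= 0:
            r2 = 0.0
        else:
            r2 = min(dp.cap_2, best.mapq / mean_mapq) / dp.cap_2
        r3 = min(dp.cap_3, best.score / mean_score) / dp.cap_3
    w1, w2, w3 = dp.weights
    w_sum = r1 * w1 + r2 * w2 + r3 * w3
    return ("map" if w_sum > dp.tau else "continue"), w_sum


def _chains_from_events(levels: np.ndarray, index: ReferenceIndex,
                        chain_params: ChainParams,
                        max_query_occ: int) -> list[Chain]:
    """Events-so-far → normalized seeds → anchors → chains (all contigs)."""
    sd = float(levels.std())
    if len(levels) < 2 or sd == 0.0:
        return []
    normalized = (levels - levels.mean()) / sd
    seeds = seeds_from_events(normalized, index.qp, index.sp)
    seeds = query_frequency_filter(seeds, max_query_occ)
    if not seeds:
        return []
    qpos = np.array([p for p, _ in seeds], dtype=np.int64)
    hashes = np.array([h for _, h in seeds], dtype=np.uint64)
    rows, postings = index.lookup_many(hashes)
    if len(rows) == 0:
        return []
    cid, rpos, sbit = unpack_postings(postings)
    y = qpos[rows]
    e = index.sp.e
    chains: list[Chain] = []
    # group anchors by (contig, strand); chain each group separately
    group = cid * 2 + sbit
    order = np.lexsort((y, rpos, group))
    group, x_arr, y_arr = group[order], rpos[order], y[order]
    bounds = np.nonzero(np.diff(group))[0] + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(group)]))
    for s, t in zip(starts, ends):
        g = int(group[s])
        strand = "-" if g & 1 else "+"
        cname = index.contigs[g >> 1][0]
        anchors = [Anchor(x=int(xv), y=int(yv), w=e, strand=strand)
                   for xv, yv in zip(x_arr[s:t], y_arr[s:t])]
        for c in chain_anchors(anchors, chain_params):
            c.tname = cname
            chains.append(c)
    return mapping_quality(chains)


def map_read(
    read: RawRead,
    index: ReferenceIndex,
    seg_params: SegmenterParams | None = None,
    chunk_params: ChunkParams | None = None,
    chain_params: ChainParams | None = None,
    decision_params: DecisionParams | None = None,
    max_query_occ: int = 5,
) -> MappingRecord:
    """Map one raw read against the index, chunk by chunk.

    Decision metadata is attached as PAF tags: ``ch`` chunks consumed,
    ``ev`` events used, ``ws`` the decision statistic, ``bb`` bases
    processed before the decision (= ch x chunk_samples / samples_per_base),
    ``dc`` the decision (``mapped`` / ``unmapped_max_chunks``).
    """
    seg_params = seg_params or SegmenterParams()
    chunk_params = chunk_params or ChunkParams()
    chain_params = chain_params or ChainParams()
    decision_params = decision_params or DecisionParams()

    spb = chunk_params.samples_per_base(read.sampling_rate)
    seg = StreamingSegmenter(seg_params)
    samples = np.asarray(read.samples, dtype=np.float64)
    n = len(samples)
    levels: list[float] = []
    chunks_used = 0
    best_chain: Chain | None = None
    w_sum = 0.0
    decided = False

    while chunks_used < chunk_params.max_chunks and not decided:
        start = chunks_used * chunk_params.chunk_samples
        if start >= n:
            break
        chunk = samples[start:start + chunk_params.chunk_samples]
        chunks_used += 1
        final = (start + len(chunk) >= n
                 or chunks_used == chunk_params.max_chunks)
        new_events = seg.feed(chunk)
        if final:
            new_events = new_events + seg.finish()
        levels.extend(ev.level for ev in new_events)
        if len(levels) < index.sp.e + 1:
            continue
        chains = _chains_from_events(np.asarray(levels), index,
                                     chain_params, max_query_occ)
        decision, w_sum = weighted_decision(chains, decision_params)
        if decision == "map":
            best_chain = chains[0]
            decided = True

    if not levels:
        warnings.warn(f"read {read.read_id!r}: no usable events")

    samples_consumed = min(n, chunks_used * chunk_params.chunk_samples)
    qlen = max(1, round(samples_consumed / spb))
    bases_before = chunks_used * chunk_params.chunk_samples / spb
    tags: dict[str, float | int | str] = {
        "ch": chunks_used,
        "ev": len(levels),
        "ws": round(float(w_sum), 4),
        "bb": round(bases_before, 2),
    }

    if best_chain is None:
        tags["dc"] = "unmapped_max_chunks"
        return MappingRecord(read.read_id, qlen, 0, 0, "*", "*", 0, 0, 0,
                             0, 0, 0, tags)

    tags["dc"] = "mapped"
    cname = best_chain.tname
    tlen = dict(index.contigs)[cname]
    k = index.k
    ra, rb = best_chain.ref_interval  # strand-local level indices, half-open
    if best_chain.strand == "+":
        tstart, tend = ra, rb + k - 1
    else:
        tstart, tend = tlen - (rb + k - 1), tlen - ra
    tstart = max(0, tstart)
    tend = min(tlen, tend)
    qa, qb = best_chain.query_interval
    events_per_base = len(levels) / max(samples_consumed / spb, 1.0)
    qstart = int(qa / events_per_base)
    qend = int(np.ceil(qb / events_per_base))
    qend = min(max(qend, qstart + 1), qlen)
    qstart = min(qstart, qend - 1)
    return MappingRecord(
        qname=read.read_id, qlen=qlen, qstart=qstart, qend=qend,
        strand=best_chain.strand, tname=cname, tlen=tlen,
        tstart=int(tstart), tend=int(tend),
        matches=best_chain.n_anchors,
        block_len=max(tend - tstart, qend - qstart),
        mapq=best_chain.mapq, tags=tags,
    )


_TAG_TYPES = {"ch": "i", "ev": "i", "ws": "f", "bb": "f", "dc": "Z"}


def _format_tag(key: str, value) -> str:
    t = _TAG_TYPES.get(key)
    if t is None:
        t = "i" if isinstance(value, int) else (
            "f" if isinstance(value, float) else "Z")
    return f"{key}:{t}:{value}"


def write_paf(records: Iterable[MappingRecord], path) -> None:
    """Write records as PAF: 12 mandatory columns + SAM-style typed tags."""
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        for r in records:
            cols = [r.qname, r.qlen, r.qstart, r.qend, r.strand, r.tname,
                    r.tlen, r.tstart, r.tend, r.matches, r.block_len, r.mapq]
            cols += [_format_tag(k, v) for k, v in r.tags.items()]
            fh.write("\t".join(map(str, cols)) + "\n")
    finally:
        if own:
            fh.close()


def read_paf(path) -> list[MappingRecord]:
    """Parse a PAF file; malformed rows are skipped with a warning."""
    records: list[MappingRecord] = []
    own = isinstance(path, (str, Path))
    fh = open(path) if own else path
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                logger.warning("PAF line %d: %d columns (<12), skipped",
                               lineno, len(fields))
                continue
            try:
                tags: dict[str, float | int | str] = {}
                for tag in fields[12:]:
                    key, typ, val = tag.split(":", 2)
                    tags[key] = int(val) if typ == "i" else (
                        float(val) if typ == "f" else val)
                records.append(MappingRecord(
                    qname=fields[0], qlen=int(fields[1]),
                    qstart=int(fields[2]), qend=int(fields[3]),
                    strand=fields[4], tname=fields[5], tlen=int(fields[6]),
                    tstart=int(fields[7]), tend=int(fields[8]),
                    matches=int(fields[9]), block_len=int(fields[10]),
                    mapq=int(fields[11]), tags=tags,
                ))
            except ValueError:
                logger.warning("PAF line %d unparseable, skipped", lineno)
    finally:
        if own:
            fh.close()
    return records
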