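"""Reference index: genome → expected levels → quantized hash seeds.

Indexing runs the reference through the same signal-domain pipeline a read
will traverse: each contig (both strands) is translated into expected
current levels via the pore model, normalized with *global* reference-level
statistics (stored in the index so queries remain comparable), adaptively
quantized, and packed into seed hashes.  Optionally the seed set is sketched
with minimizers (keep only each window's smallest hash) and/or frequency
filtered (drop hashes occurring more than ``max_ref_occ`` times — repetitive
seeds produce enormous anchor sets and little mapping information).

Postings are stored strand-locally: for the minus strand the position is the
seed-end index in the reverse complement's own coordinates, which keeps
chaining colinear for reverse reads; conversion to forward PAF coordinates
happens at output time.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from squigmap.pore_model import PoreModel, levels_with_offsets
from squigmap.quantization import (
    QuantizationParams,
    SeedParams,
    _pack_windows,
    quantize_array,
)

logger = logging.getLogger(__name__)

__all__ = ["MinimizerParams", "ReferenceIndex", "build_index",
           "select_minimizers", "save_index", "load_index", "read_fasta"]

_INDEX_MAGIC = "squigmap-index"
_INDEX_VERSION = 2

# posting packing: contig_id << 33 | strand_pos << 1 | strand_bit
_POS_SHIFT = 1
_CONTIG_SHIFT = 33


@dataclass(frozen=True)
class MinimizerParams:
    """Minimizer sketching: keep each window-of-``w_min``-seeds minimum."""

    w_min: int = 5
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.w_min < 1:
            raise ValueError("w_min must be >= 1")


@dataclass
class ReferenceIndex:
    """Hash → reference postings table plus everything needed to query it.

    ``hashes`` is sorted unique uint64; ``offsets[i]:offsets[i+1]`` delimits
    the postings of ``hashes[i]`` inside ``postings`` (packed int64, see
    :func:`pack_posting`).  ``level_mean``/``level_sd`` are the global
    reference-level statistics applied at build time; queries must be
    normalized in their own frame, which this global frame mirrors.
    """

    hashes: np.ndarray
    offsets: np.ndarray
    postings: np.ndarray
    contigs: list[tuple[str, int]]
    qp: QuantizationParams
    sp: SeedParams
    mp: MinimizerParams
    k: int
    max_ref_occ: int
    level_mean: float
    level_sd: float

    def lookup(self, h: int) -> np.ndarray:
        """Postings (packed) for one hash; empty array when absent."""
        i = np.searchsorted(self.hashes, np.uint64(h))
        if i < len(self.hashes) and self.hashes[i] == np.uint64(h):
            return self.postings[self.offsets[i]:self.offsets[i + 1]]
        return self.postings[:0]

    def lookup_many(self, hs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup.

        Returns (query_row, packed_posting) pairs: for every input hash that
        is present, one entry per posting, with ``query_row`` the index into
        ``hs`` it came from.
        """
        hs = hs.astype(np.uint64)
        idx = np.searchsorted(self.hashes, hs)
        idx_c = np.minimum(idx, len(self.hashes) - 1)
        hit = (len(self.hashes) > 0) & (self.hashes[idx_c] == hs)
        rows = np.nonzero(hit)[0]
        if len(rows) == 0:
            return rows, self.postings[:0]
        starts = self.offsets[idx_c[rows]]
        ends = self.offsets[idx_c[rows] + 1]
        counts = (ends - starts).astype(np.int64)
        out_rows = np.repeat(rows, counts)
        take = np.concatenate(
            [np.arange(s, e) for s, e in zip(starts, ends)]
        ) if len(rows) else np.empty(0, dtype=np.int64)
        return out_rows, self.postings[take]

    @property
    def n_postings(self) -> int:
        return len(self.postings)

    @property
    def n_distinct_hashes(self) -> int:
        return len(self.hashes)


def pack_posting(contig_id: int, pos: int, strand: str) -> int:
    return (contig_id << _CONTIG_SHIFT) | (pos << _POS_SHIFT) | (
        1 if strand == "-" else 0)


def unpack_posting(p: int) -> tuple[int, int, str]:
    return (p >> _CONTIG_SHIFT,
            (p >> _POS_SHIFT) & ((1 << (_CONTIG_SHIFT - _POS_SHIFT)) - 1),
            "-" if p & 1 else "+")


def unpack_postings(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized unpack → (contig_id, strand_pos, strand_bit) arrays."""
    p = p.astype(np.int64)
    cid = p >> _CONTIG_SHIFT
    pos = (p >> _POS_SHIFT) & ((1 << (_CONTIG_SHIFT - _POS_SHIFT)) - 1)
    return cid, pos, (p & 1)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA into (name, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def select_minimizers(seeds: list[tuple[int, int]],
                      w_min: int) -> list[tuple[int, int]]:
    """Keep every seed whose hash is the minimum of at least one window of
    ``w_min`` consecutive seeds (ties: leftmost), sorted and deduplicated.

    ``w_min=1`` returns the input unchanged.  Uses the standard monotonic
    deque sliding-window minimum, O(n).
    """
    if w_min < 1:
        raise ValueError("w_min must be >= 1")
    n = len(seeds)
    if w_min == 1:
        return list(seeds)
    if n < w_min:  # no full window exists
        return []
    keep: set[int] = set()
    dq: deque[int] = deque()  # indices, hashes increasing
    for i in range(n):
        while dq and seeds[dq[-1]][1] > seeds[i][1]:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - w_min:
            dq.popleft()
        if i >= w_min - 1:
            keep.add(dq[0])
    return [seeds[i] for i in sorted(keep)]


def auto_frequency_cap(counts: np.ndarray, keep_frac: float = 0.998) -> int:
    """Smallest occurrence threshold keeping ≥ keep_frac of distinct hashes."""
    if len(counts) == 0:
        return 0
    return int(np.quantile(counts, keep_frac, method="higher"))


def build_index(
    ref: str | Path | list[tuple[str, str]],
    model: PoreModel,
    qp: QuantizationParams | None = None,
    sp: SeedParams | None = None,
    mp: MinimizerParams | None = None,
    max_ref_occ: int = 0,
) -> ReferenceIndex:
    """Build the reference seed index over both strands of every contig.

    ``max_ref_occ > 0`` drops hashes with more postings than the cap;
    ``max_ref_occ = -1`` selects the cap automatically (smallest threshold
    retaining ≥99.8% of distinct hashes).  Contigs too short to host one
    seed (< k + e - 1 bases) are skipped with a warning; an empty reference
    is an error.
    """
    qp = qp or QuantizationParams()
    sp = sp or SeedParams()
    mp = mp or MinimizerParams()
    contigs = read_fasta(ref) if isinstance(ref, (str, Path)) else list(ref)
    if not contigs:
        raise ValueError("empty reference: no contigs")
    k, e = model.k, sp.e
    min_len = k + e - 1
    usable = []
    for name, seq in contigs:
        if len(seq) < min_len:
            warnings.warn(f"contig {name!r} shorter than k+e-1={min_len}; skipped")
            continue
        usable.append((name, seq))
    if not usable:
        raise ValueError("no contig is long enough to index")

    # pass 1: global level statistics over both strands of all contigs
    total, total2, count = 0.0, 0.0, 0
    per_strand_segments: list[tuple[int, str, int, np.ndarray]] = []
    for cid, (name, seq) in enumerate(usable):
        for strand in "+-":
            for off, levels in levels_with_offsets(seq, model, strand):
                per_strand_segments.append((cid, strand, off, levels))
                total += float(levels.sum())
                total2 += float((levels ** 2).sum())
                count += len(levels)
    mean = total / count
    sd = float(np.sqrt(max(total2 / count - mean ** 2, 0.0)))
    if sd == 0.0:
        # degenerate (e.g. single-base) reference: identity scale so the
        # build still succeeds; such an index has one hash per strand
        warnings.warn("reference levels have zero variance; skipping scaling")
        sd = 1.0

    bits = sp.resolve_bits(qp)
    all_hashes: list[np.ndarray] = []
    all_postings: list[np.ndarray] = []
    for cid, strand, off, levels in per_strand_segments:
        if len(levels) < e:
            continue
        q = quantize_array((levels - mean) / sd, qp)
        hashes = _pack_windows(q, sp, bits)
        positions = np.arange(e - 1, len(levels)) + off
        if mp.enabled and mp.w_min > 1:
            seeds = select_minimizers(
                list(zip(positions.tolist(), hashes.tolist())), mp.w_min)
            if not seeds:
                continue
            positions = np.array([p for p, _ in seeds], dtype=np.int64)
            hashes = np.array([h for _, h in seeds], dtype=np.uint64)
        packed = ((np.int64(cid) << _CONTIG_SHIFT)
                  | (positions.astype(np.int64) << _POS_SHIFT)
                  | np.int64(1 if strand == "-" else 0))
        all_hashes.append(hashes.astype(np.uint64))
        all_postings.append(packed)

    h = np.concatenate(all_hashes)
    p = np.concatenate(all_postings)
    order = np.lexsort((p, h))
    h, p = h[order], p[order]
    uniq, starts, counts = np.unique(h, return_index=True, return_counts=True)

    cap = max_ref_occ
    if cap == -1:
        cap = auto_frequency_cap(counts)
        logger.info("auto frequency cap: %d", cap)
    if cap > 0:
        keep = counts <= cap
        row_keep = np.repeat(keep, counts)
        h, p = h[row_keep], p[row_keep]
        uniq, starts, counts = uniq[keep], None, counts[keep]
    offsets = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)

    return ReferenceIndex(
        hashes=uniq, offsets=offsets, postings=p,
        contigs=[(name, len(seq)) for name, seq in usable],
        qp=qp, sp=sp, mp=mp, k=k,
        max_ref_occ=cap,
        level_mean=mean, level_sd=sd,
    )


def save_index(index: ReferenceIndex, path: str | Path) -> None:
    """Write a versioned portable archive (NumPy .npz + JSON params)."""
    meta = {
        "magic": _INDEX_MAGIC,
        "version": _INDEX_VERSION,
        "contigs": index.contigs,
        "qp": {"n": index.qp.n, "f_r": index.qp.f_r,
               "f_min": index.qp.f_min, "f_max": index.qp.f_max},
        "sp": {"e": index.sp.e, "bits_per_value": index.sp.bits_per_value,
               "mix": index.sp.mix},
        "mp": {"w_min": index.mp.w_min, "enabled": index.mp.enabled},
        "k": index.k,
        "max_ref_occ": index.max_ref_occ,
        "level_mean": index.level_mean,
        "level_sd": index.level_sd,
    }
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        hashes=index.hashes, offsets=index.offsets, postings=index.postings,
    )


def load_index(path: str | Path) -> ReferenceIndex:
    """Load an index written by :func:`save_index`; checks magic/version."""
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            hashes, offsets, postings = z["hashes"], z["offsets"], z["postings"]
    except Exception as exc:
        raise ValueError(f"{path}: not a readable index archive: {exc}") from exc
    if meta.get("magic") != _INDEX_MAGIC:
        raise ValueError(f"{path}: not a squigmap index")
    if meta.get("version") != _INDEX_VERSION:
        raise ValueError(
            f"{path}: index version {meta.get('version')} unsupported "
            f"(expected {_INDEX_VERSION})")
    return ReferenceIndex(
        hashes=hashes, offsets=offsets, postings=postings,
        contigs=[tuple(c) for c in meta["contigs"]],
        qp=QuantizationParams(**meta["qp"]),
        sp=SeedParams(**meta["sp"]),
        mp=MinimizerParams(**meta["mp"]),
        k=meta["k"],
        max_ref_occ=meta["max_ref_occ"],
        level_mean=meta["level_mean"],
        level_sd=meta["level_sd"],
    )
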