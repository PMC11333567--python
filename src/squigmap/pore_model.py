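"""k-mer pore model: expected current level per k-mer.

A pore model is the lookup table a signal mapper uses to translate reference
bases into the signal domain: for every k-mer over {A,C,G,T} it records the
mean current level observed while that k-mer occupies the pore, plus the
level's standard deviation.  Model files are plain TSV (``kmer<TAB>mean<TAB>
stdv``), the format community k-mer models are distributed in.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

__all__ = ["PoreModel", "load_pore_model", "sequence_to_levels",
           "reverse_complement", "PoreModelFormatError"]


class PoreModelFormatError(ValueError):
    """Raised when a k-mer model file is malformed or incomplete."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PoreModel:
    """Complete k-mer → (level_mean, level_stdv) table.

    ``k`` is the k-mer length; ``levels`` maps each of the 4**k k-mers to its
    expected current level and stdv in the model's native units (units are
    never converted — all comparisons downstream happen after z-score
    normalization, so only relative level geometry matters).
    """

    k: int
    levels: dict[str, tuple[float, float]]
    # dense lookup table indexed by 2-bit-encoded k-mer, built lazily
    _mean_table: np.ndarray = field(init=False, repr=False, compare=False)
    _stdv_table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        expected = 4 ** self.k
        if len(self.levels) != expected:
            raise PoreModelFormatError(
                f"model has {len(self.levels)} k-mers, expected {expected}"
            )
        means = np.empty(expected)
        stdvs = np.empty(expected)
        for kmer, (m, s) in self.levels.items():
            if len(kmer) != self.k:
                raise PoreModelFormatError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected {self.k}"
                )
            if not s > 0:
                raise PoreModelFormatError(f"non-positive stdv for {kmer!r}")
            means[_encode(kmer)] = m
            stdvs[_encode(kmer)] = s
        object.__setattr__(self, "_mean_table", means)
        object.__setattr__(self, "_stdv_table", stdvs)

    def mean(self, kmer: str) -> float:
        return self.levels[kmer.upper()][0]

    def stdv(self, kmer: str) -> float:
        return self.levels[kmer.upper()][1]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(kmer: str) -> int:
    code = 0
    for b in kmer.upper():
        code = (code << 2) | _BASE_CODE[b]
    return code


def load_pore_model(path: str | Path) -> PoreModel:
    """Load a k-mer model TSV.

    Accepts an optional header line (any line whose first field is not a
    valid k-mer, e.g. ``kmer\\tlevel_mean\\tlevel_stdv``) and skips
    ``#``-prefixed comments.  ``k`` is inferred from the first k-mer; the
    file must contain every one of the 4**k k-mers exactly once.
    """
    levels: dict[str, tuple[float, float]] = {}
    k: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PoreModelFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            kmer = fields[0].strip().upper()
            if not kmer or any(b not in "ACGT" for b in kmer):
                if not levels:
                    continue  # header line
                raise PoreModelFormatError(
                    f"{path}:{lineno}: invalid k-mer {fields[0]!r}"
                )
            if k is None:
                k = len(kmer)
            try:
                mean, stdv = float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise PoreModelFormatError(
                    f"{path}:{lineno}: non-numeric level for {kmer!r}"
                ) from exc
            if kmer in levels:
                raise PoreModelFormatError(
                    f"{path}:{lineno}: duplicate k-mer {kmer!r}"
                )
            levels[kmer] = (mean, stdv)
    if k is None:
        raise PoreModelFormatError(f"{path}: no k-mer rows found")
    if len(levels) != 4 ** k:
        raise PoreModelFormatError(
            f"{path}: {len(levels)} k-mers present, expected {4 ** k} "
            f"(k={k} inferred from first row)"
        )
    return PoreModel(k=k, levels=levels)


def make_synthetic_model(k: int, seed: int = 0,
                         mean_center: float = 90.0,
                         mean_spread: float = 12.0,
                         stdv_low: float = 1.0,
                         stdv_high: float = 3.0) -> PoreModel:
    """Build a synthetic pore model for testing and simulation.

    Levels are drawn once per k-mer from Normal(mean_center, mean_spread)
    with stdv uniform in [stdv_low, stdv_high] — roughly the geometry of
    published DNA models (levels spanning ~60–130 pA, per-k-mer noise of a
    few pA).  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    kmers = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
    means = rng.normal(mean_center, mean_spread, size=len(kmers))
    stdvs = rng.uniform(stdv_low, stdv_high, size=len(kmers))
    return PoreModel(k=k, levels={km: (float(m), float(s))
                                  for km, m, s in zip(kmers, means, stdvs)})


def sequence_to_levels(
    seq: str,
    model: PoreModel,
    strand: str = "+",
) -> list[np.ndarray]:
    """Translate a nucleotide sequence into expected current levels.

    Returns a list of level segments.  For an N-free sequence this is a
    single array of length ``len(seq) - k + 1`` whose entry i is the model
    mean of ``seq[i:i+k]``.  Ambiguous bases (N) produce no level and split
    the output into segments, so no seed ever spans an N.  ``strand='-'``
    returns the forward levels of the reverse complement, in the reverse
    complement's own 5'→3' order.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        seq = reverse_complement(seq)
    seq = seq.upper()
    k = model.k
    if len(seq) < k:
        warnings.warn(f"sequence shorter than k={k}; no levels produced")
        return []
    # split on N, keep only segments long enough to hold one k-mer
    return [model._mean_table[_encode_kmers(part, k)]
            for _, part in _split_on_n(seq) if len(part) >= k]


def segment_offsets(seq: str, k: int) -> list[int]:
    """Starting base offset (within ``seq``) of each level segment."""
    return [s for s, part in _split_on_n(seq.upper()) if len(part) >= k]


def levels_with_offsets(
    seq: str, model: PoreModel, strand: str = "+",
) -> list[tuple[int, np.ndarray]]:
    """Like :func:`sequence_to_levels` but pairing each segment with the
    base offset of its first k-mer in the (strand-oriented) sequence."""
    if strand == "-":
        seq = reverse_complement(seq)
    seq = seq.upper()
    k = model.k
    return [(off, model._mean_table[_encode_kmers(part, k)])
            for off, part in _split_on_n(seq) if len(part) >= k]


def _split_on_n(seq: str):
    pos = 0
    for part in seq.split("N"):
        if part:
            yield pos, part
        pos += len(part) + 1


_CODE_LUT = np.zeros(128, dtype=np.int64)
for _b, _c in _BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit-encode every k-mer of an N-free sequence (vectorized)."""
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):  # k is small; each shift is a vector op
        idx += codes[j:j + n] << (2 * (k - 1 - j))
    return idx


def kmer_stdvs(seq: str, model: PoreModel) -> np.ndarray:
    """Per-position level stdv for an N-free sequence (simulation helper)."""
    return model._stdv_table[_encode_kmers(seq.upper(), model.k)]
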