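"""Adaptive quantization of normalized event levels, and seed hashing.

Normalized current levels are far from uniformly distributed: most mass sits
within a couple of standard deviations of zero.  Adaptive quantization
therefore splits the real line into a *fine range* ``[f_min, f_max]`` that
receives a fraction ``f_r`` of the quantization resolution, and a *coarse
range* outside it quantized at low resolution ``c_r = (1 - f_r) * 0.5``.
With ``q(s)`` the quantized value of a normalized level ``s`` and ``n`` the
top of the integer output range::

    q(s) = floor(n * f_r * (s - f_min) / (f_max - f_min))   f_min <= s <= f_max
    q(s) = floor(n * (f_r + c_r * s))                       s < f_min
    q(s) = floor(n * (f_r + c_r + c_r * s))                 s > f_max

and the result is clamped into ``[0, n]`` (the branch formulas can escape
that range for extreme ``s``; quantized values are defined to live in
``[0, n]``, so clamping is the faithful reading).  Note the coarse branches
as written can overlap the fine branch's output interval for some parameter
choices; this is a property of the formula, implemented verbatim, and is
harmless for hashing (quantization is a bucketing, not an ordering).

Seeds pack ``e`` consecutive quantized values into one 64-bit integer
(big-endian, first event in the most significant bits), optionally passed
through an invertible 64-bit bit-mixer so that hash-table keys are well
dispersed while exact-match semantics are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizationParams", "SeedParams", "quantize", "quantize_array",
           "pack_seed", "seeds_from_events"]


@dataclass(frozen=True)
class QuantizationParams:
    """Adaptive quantization configuration.

    ``n`` is the top of the output range [0, n]; ``f_r`` the fraction of
    resolution spent on the fine range ``[f_min, f_max]`` (normalized
    units); ``c_r`` is derived, never user-set.
    """

    n: int = 15
    f_r: float = 0.8
    f_min: float = -2.0
    f_max: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.f_r < 1.0:
            raise ValueError("f_r must be in (0, 1)")
        if not self.f_min < self.f_max:
            raise ValueError("need f_min < f_max")

    @property
    def c_r(self) -> float:
        """Coarse-range resolution, (1 - f_r) x 0.5."""
        return (1.0 - self.f_r) * 0.5

    @property
    def bits_per_value(self) -> int:
        return max(1, math.ceil(math.log2(self.n + 1)))


@dataclass(frozen=True)
class SeedParams:
    """Seed construction: ``e`` consecutive quantized events per hash.

    ``bits_per_value`` defaults to None, meaning "use the quantizer's
    bits_per_value"; set it explicitly only when packing raw integers
    without a :class:`QuantizationParams` at hand.
    """

    e: int = 6
    bits_per_value: int | None = None
    mix: bool = True

    def __post_init__(self) -> None:
        if self.e < 1:
            raise ValueError("e must be >= 1")
        if self.bits_per_value is not None:
            if not 1 <= self.bits_per_value or self.e * self.bits_per_value > 64:
                raise ValueError("need 1 <= bits and e * bits <= 64")

    def resolve_bits(self, qp: "QuantizationParams | None" = None) -> int:
        bits = self.bits_per_value
        if bits is None:
            if qp is None:
                raise ValueError("bits_per_value unset and no quantizer given")
            bits = qp.bits_per_value
        if self.e * bits > 64:
            raise ValueError("e * bits_per_value exceeds 64 bits")
        return bits


def quantize(s: float, p: QuantizationParams) -> int:
    """Quantize one normalized level into [0, n] (scalar convenience)."""
    return int(quantize_array(np.array([s]), p)[0])


def quantize_array(s: np.ndarray, p: QuantizationParams) -> np.ndarray:
    """Vectorized adaptive quantization of normalized levels."""
    s = np.asarray(s, dtype=np.float64)
    n, f_r, c_r = p.n, p.f_r, p.c_r
    fine = n * f_r * (s - p.f_min) / (p.f_max - p.f_min)
    below = n * (f_r + c_r * s)
    above = n * (f_r + c_r + c_r * s)
    q = np.where(s < p.f_min, below, np.where(s > p.f_max, above, fine))
    return np.clip(np.floor(q), 0, n).astype(np.int64)


def _mix64(h: np.ndarray) -> np.ndarray:
    """Invertible 64-bit finalizer (xorshift-multiply); disperses packed keys."""
    h = h.astype(np.uint64)
    with np.errstate(over="ignore"):
        h ^= h >> np.uint64(33)
        h *= np.uint64(0xFF51AFD7ED558CCD)
        h ^= h >> np.uint64(33)
        h *= np.uint64(0xC4CEB9FE1A85EC53)
        h ^= h >> np.uint64(33)
    return h


def pack_seed(q_values, sp: SeedParams,
              qp: QuantizationParams | None = None) -> int:
    """Pack ``e`` quantized values into one 64-bit hash.

    Big-endian bit concatenation: the first event occupies the most
    significant bits.  With the mixer off the packing is the hash (and is
    injective); with it on, an invertible 64-bit mixer is applied.
    """
    bits_per_value = sp.resolve_bits(qp)
    q = np.asarray(q_values, dtype=np.int64)
    if len(q) != sp.e:
        raise ValueError(f"expected {sp.e} values, got {len(q)}")
    if np.any((q < 0) | (q >= (1 << bits_per_value))):
        raise ValueError("quantized value out of range for bits_per_value")
    h = 0
    for v in q.tolist():
        h = (h << bits_per_value) | int(v)
    if sp.mix:
        h = int(_mix64(np.array([h], dtype=np.uint64))[0])
    return h


def seeds_from_events(levels, qp: QuantizationParams,
                      sp: SeedParams) -> list[tuple[int, int]]:
    """Quantize normalized levels and hash every window of ``e`` of them.

    Returns ``(position, hash)`` pairs, one per sliding window, where
    *position* is the index of the window's **last** event — end-anchored,
    so an anchor's matching interval is ``[pos - e + 1, pos]``.  Input
    shorter than ``e`` yields an empty list.
    """
    levels = np.asarray(levels, dtype=np.float64)
    if len(levels) < sp.e:
        return []
    q = quantize_array(levels, qp)
    hashes = _pack_windows(q, sp, sp.resolve_bits(qp))
    positions = np.arange(sp.e - 1, len(levels))
    return list(zip(positions.tolist(), hashes.tolist()))


def _pack_windows(q: np.ndarray, sp: SeedParams,
                  bits_per_value: int) -> np.ndarray:
    """Vectorized sliding-window pack of quantized values (uint64 hashes)."""
    if sp.e * bits_per_value > 64:
        raise ValueError("e * bits_per_value exceeds 64 bits")
    e = sp.e
    n_out = len(q) - e + 1
    h = np.zeros(n_out, dtype=np.uint64)
    qu = q.astype(np.uint64)
    for j in range(e):
        h |= qu[j:j + n_out] << np.uint64(bits_per_value * (e - 1 - j))
    if sp.mix:
        h = _mix64(h)
    return h
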