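"""Squiggle simulator: synthetic raw reads with known ground truth.

Generates raw nanopore-style signals from a reference so the whole mapping
stack can be exercised without external data.  The signal model follows the
pore-model assumptions the mapper itself relies on: a read is a walk along
the reference; each k-mer context holds the pore for a Gamma-distributed
dwell (mean sampling_rate / bases_per_second samples, the ~8.9 samples/base
of common DNA chemistry at 4 kHz / 450 b/s; Gamma rather than geometric to
match the over-dispersion of real dwell times), emitting the k-mer's model
level plus Gaussian noise scaled from the model's own per-k-mer stdv, under
a per-read affine distortion (scale a ~ N(1, sd), shift b ~ N(0, sd)) that
mimics pore-to-pore calibration differences.

Not modelled: stalls, skips, re-reads, adapter/barcode signal, RNA
kinetics — the simulator emulates clean single-pass translocation only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from squigmap.mapping import MappingRecord
from squigmap.pore_model import (
    PoreModel,
    kmer_stdvs,
    reverse_complement,
    sequence_to_levels,
)
from squigmap.signal_io import RawRead

__all__ = ["SimParams", "simulate_reads", "random_genome"]

# digitization grid applied to simulated samples so that SLOW5 round-trips
# are exact: samples are snapped to range/digitisation pA steps (~0.12 pA)
_DIGITISATION = 8192.0
_RANGE = 1000.0


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.

    ``noise_sd_scale`` multiplies each k-mer's model ``level_stdv`` to give
    the per-sample noise sd (1.0 = noise as the model describes it);
    ``dwell_dispersion`` is the coefficient of variation of the Gamma dwell
    (0 = constant dwell).
    """

    n_reads: int = 200
    read_len_mean: float = 5000.0
    read_len_min: int = 500
    bases_per_second: float = 450.0
    sampling_rate: float = 4000.0
    dwell_dispersion: float = 0.25
    noise_sd_scale: float = 1.0
    per_read_shift_sd: float = 2.0
    per_read_scale_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bases_per_second <= 0 or self.sampling_rate <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd_scale < 0 or self.dwell_dispersion < 0:
            raise ValueError("noise_sd_scale and dwell_dispersion must be >= 0")

    @property
    def samples_per_base(self) -> float:
        return self.sampling_rate / self.bases_per_second


def random_genome(length: int, seed: int = 0,
                  name: str = "chr1") -> tuple[str, str]:
    """Uniform-random nucleotide contig (name, sequence)."""
    rng = np.random.default_rng(seed)
    return name, "".join(np.array(list("ACGT"))[
        rng.integers(0, 4, size=length)])


def simulate_reads(
    ref: list[tuple[str, str]],
    model: PoreModel,
    sp: SimParams | None = None,
) -> tuple[list[RawRead], list[MappingRecord]]:
    """Simulate reads and their ground-truth mappings.

    Returns (reads, truth) where truth[i] is a PAF-shaped record giving
    read i's origin contig, forward-coordinate interval and strand.  Fully
    determined by ``sp.rng_seed``.  Read lengths are Gamma(shape 3) around
    ``read_len_mean``, clipped at ``read_len_min``; a read that cannot be
    placed on any contig after 100 start draws raises ``ValueError``.
    """
    sp = sp or SimParams()
    if not ref:
        raise ValueError("empty reference")
    rng = np.random.default_rng(sp.rng_seed)
    k = model.k
    contigs = [(n, s) for n, s in ref if len(s) >= max(sp.read_len_min, k)]
    if not contigs:
        raise ValueError("no contig long enough to simulate from")
    lengths = np.array([len(s) for n, s in contigs], dtype=np.float64)
    weights = lengths / lengths.sum()
    mu_dwell = sp.samples_per_base
    scale_grid = _RANGE / _DIGITISATION

    reads: list[RawRead] = []
    truth: list[MappingRecord] = []
    for i in range(sp.n_reads):
        read_len = int(max(sp.read_len_min,
                           rng.gamma(3.0, sp.read_len_mean / 3.0)))
        read_len = max(read_len, k)
        for attempt in range(100):
            ci = int(rng.choice(len(contigs), p=weights))
            cname, cseq = contigs[ci]
            if len(cseq) < read_len:
                continue
            start = int(rng.integers(0, len(cseq) - read_len + 1))
            seq = cseq[start:start + read_len]
            if "N" not in seq:
                break
        else:
            raise ValueError(f"could not place read {i} after 100 tries")
        strand = "+" if rng.random() < 0.5 else "-"
        template = seq if strand == "+" else reverse_complement(seq)

        segments = sequence_to_levels(template, model)
        levels = segments[0]  # template is N-free by construction
        stdvs = kmer_stdvs(template, model)
        n_lv = len(levels)
        if sp.dwell_dispersion > 0:
            shape = 1.0 / sp.dwell_dispersion ** 2
            dwells = rng.gamma(shape, mu_dwell / shape, size=n_lv)
        else:
            dwells = np.full(n_lv, mu_dwell)
        dwells = np.maximum(np.rint(dwells), 1).astype(np.int64)

        sig = np.repeat(levels, dwells)
        a = 1.0 + rng.normal(0.0, sp.per_read_scale_sd)
        b = rng.normal(0.0, sp.per_read_shift_sd)
        sig = a * sig + b
        if sp.noise_sd_scale > 0:
            sig = sig + rng.normal(
                0.0, 1.0, size=len(sig)) * np.repeat(
                    stdvs * sp.noise_sd_scale, dwells)
        sig = scale_grid * np.rint(sig / scale_grid)  # digitization grid

        read_id = f"sim_{i:05d}"
        reads.append(RawRead(
            read_id=read_id, samples=sig,
            sampling_rate=sp.sampling_rate,
            digitisation=_DIGITISATION, offset=0.0, range=_RANGE,
        ))
        truth.append(MappingRecord(
            qname=read_id, qlen=read_len, qstart=0, qend=read_len,
            strand=strand, tname=cname, tlen=len(cseq),
            tstart=start, tend=start + read_len,
            matches=read_len, block_len=read_len, mapq=60,
            tags={"dc": "truth"},
        ))
    return reads, truth


def write_manifest(path: str | Path, sp: SimParams,
                   extra: dict | None = None) -> None:
    """Dump the simulation parameters (plus extras) as JSON."""
    payload = {"sim_params": asdict(sp)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
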