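"""Raw-signal I/O: the ASCII dialect of SLOW5.

SLOW5 stores one nanopore read per tab-separated row: a read id, the
digitisation/offset/range/sampling-rate attributes needed to convert raw
DAC values to picoamperes, and the raw signal as comma-separated integers.
Only the ASCII dialect is implemented natively; binary containers (BLOW5,
FAST5, POD5) add nothing algorithmic and can be bridged by any adapter that
yields :class:`RawRead` objects — the mapper accepts any such iterable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["RawRead", "read_slow5", "write_slow5", "Slow5FormatError"]

_COLUMNS = [
    "read_id", "read_group", "digitisation", "offset", "range",
    "sampling_rate", "len_raw_signal", "raw_signal",
]


class Slow5FormatError(ValueError):
    """Raised when a file does not look like ASCII SLOW5."""


@dataclass
class RawRead:
    """One raw nanopore read.

    ``samples`` holds current values in picoamperes (or whatever unit the
    conversion attributes produce); on disk the signal is stored as integers
    ``round(sample / scale - offset)`` with ``scale = range/digitisation``,
    the format's convention.  The defaults give an identity conversion.
    """

    read_id: str
    samples: np.ndarray
    sampling_rate: float = 4000.0
    digitisation: float = 1.0
    offset: float = 0.0
    range: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def scale(self) -> float:
        return self.range / self.digitisation


def read_slow5(path: str | Path) -> Iterator[RawRead]:
    """Iterate over reads in an ASCII SLOW5 file.

    The file must start with a ``#slow5_version`` header.  Rows with the
    wrong column count or an empty signal are skipped with a logged warning;
    iteration continues.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#slow5_version"):
            raise Slow5FormatError(
                f"{path}: missing '#slow5_version' header line"
            )
        columns = _COLUMNS
        for line in fh:
            if line.startswith("#"):
                if "read_id" in line:
                    columns = line.lstrip("#").rstrip("\n").split("\t")
                continue
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(columns):
                logger.warning(
                    "skipping SLOW5 row with %d fields (expected %d)",
                    len(fields), len(columns),
                )
                continue
            row = dict(zip(columns, fields))
            if not row.get("raw_signal", "").strip():
                logger.warning("skipping read %r with empty signal",
                               row.get("read_id"))
                continue
            try:
                digitisation = float(row.get("digitisation", 1.0))
                offset = float(row.get("offset", 0.0))
                rng = float(row.get("range", 1.0))
                rate = float(row.get("sampling_rate", 4000.0))
                raw = np.array(row["raw_signal"].split(","),
                               dtype=np.float64)
            except ValueError:
                logger.warning("skipping unparseable read %r",
                               row.get("read_id"))
                continue
            scale = rng / digitisation if digitisation else 1.0
            yield RawRead(
                read_id=row["read_id"],
                samples=(raw + offset) * scale,
                sampling_rate=rate,
                digitisation=digitisation,
                offset=offset,
                range=rng,
            )


def write_slow5(reads: Iterable[RawRead], path: str | Path) -> None:
    """Write reads as ASCII SLOW5, inverting the pA conversion exactly."""
    with open(path, "w") as fh:
        fh.write("#slow5_version\t2.0\n")
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for read in reads:
            scale = read.scale
            raw = np.rint(read.samples / scale - read.offset).astype(np.int64)
            fh.write("\t".join([
                read.read_id,
                "0",
                repr(read.digitisation),
                repr(read.offset),
                repr(read.range),
                repr(read.sampling_rate),
                str(len(raw)),
                ",".join(map(str, raw.tolist())),
            ]) + "\n")
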