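"""Sequence data model, FASTA I/O and elementary nucleotide comparisons.

Every downstream stage (spliced-leader scanning, tandem-array detection,
the repeat census, coding statistics) works on :class:`SequenceRecord`
objects and the handful of primitives defined here.

Conventions
-----------
* Coordinates are 0-based, half-open everywhere (:class:`Interval`).
* Sequences are uppercase DNA over ``{A, C, G, T, N}``; ``U`` is mapped to
  ``T`` on input (spliced-leader consensus sequences are often quoted as
  RNA).
* ``N`` is handled conservatively: it never matches any base (not even
  another ``N``) and is excluded from GC-content entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "Source",
    "SequenceRecord",
    "Interval",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "gc_content",
    "ungapped_identity",
    "iupac_identity",
    "find_polyA_start",
    "seq_to_array",
    "match_array",
    "round_half_up",
]

_ALLOWED = frozenset("ACGTN")

#: IUPAC ambiguity code -> frozenset of concrete bases it stands for.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

_N_BYTE = ord("N")


class Source(str, enum.Enum):
    """Provenance of a sequence record."""

    EST = "est"
    GSS = "gss"
    CDS = "cds"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence.

    The sequence is normalised on construction: uppercased, ``U`` mapped to
    ``T``. Construction fails on empty sequences or characters outside
    ``{A, C, G, T, N}``.
    """

    id: str
    seq: str
    source: Source = Source.SYNTHETIC

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", Source(self.source))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open span ``[start, end)`` with an optional label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, source: Source | str = Source.SYNTHETIC) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Lowercase is accepted and uppercased, ``U`` mapped to ``T``. Record
    order is preserved. Raises :class:`ValueError` on duplicate ids or
    empty sequences.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), source=source))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to ``path`` in FASTA format (lines wrapped at *width*)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Elementary comparisons


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return str(Seq(seq).reverse_complement())


def seq_to_array(seq: str) -> np.ndarray:
    """Sequence as a uint8 byte array, for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_array(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Positionwise match between equal-length byte arrays; N matches nothing."""
    return (a == b) & (a != _N_BYTE) & (b != _N_BYTE)


def gc_content(seq: str) -> float:
    """GC fraction with N excluded from numerator and denominator.

    Raises :class:`ValueError` for sequences with no informative base
    (all-N), where the quantity is undefined.
    """
    gc = seq.count("G") + seq.count("C")
    informative = gc + seq.count("A") + seq.count("T")
    if informative == 0:
        raise ValueError("GC content undefined: no A/C/G/T bases")
    return gc / informative


def ungapped_identity(a: str, b: str) -> float:
    """Fraction of matching positions between equal-length sequences."""
    if len(a) != len(b) or not a:
        raise ValueError(
            f"ungapped identity requires equal non-zero lengths (got {len(a)}, {len(b)})"
        )
    return int(match_array(seq_to_array(a), seq_to_array(b)).sum()) / len(a)


def iupac_identity(pattern: str, seq_window: str) -> float:
    """Identity of a concrete sequence window against an IUPAC pattern.

    A position matches when the window base is in the expansion of the
    pattern's IUPAC code (``D`` matches A/G/T, etc.). ``N`` in the window
    matches nothing. Unknown pattern codes raise :class:`ValueError`.
    """
    if len(pattern) != len(seq_window) or not pattern:
        raise ValueError(
            f"pattern/window length mismatch ({len(pattern)} vs {len(seq_window)})"
        )
    matches = 0
    for code, base in zip(pattern.upper(), seq_window.upper()):
        try:
            expansion = IUPAC_EXPANSION[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r} in pattern") from None
        if base in expansion:
            matches += 1
    return matches / len(pattern)


def find_polyA_start(seq: str, min_run: int = 10, max_mismatch: int = 1) -> int | None:
    """Locate the start of the 3'-terminal polyA run, or ``None``.

    Walks leftward from the 3' end. The run must begin with an ``A``;
    up to *max_mismatch* non-A bases may be crossed provided further ``A``
    lie beyond them. The run qualifies when it contains at least *min_run*
    ``A`` bases.
    """
    mismatches = 0
    start: int | None = None
    n_a = 0
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] == "A":
            start = i
            n_a += 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
    if start is not None and n_a >= min_run:
        return start
    return None


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero, matching conventional table rounding."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(exp, rounding=ROUND_HALF_UP))
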