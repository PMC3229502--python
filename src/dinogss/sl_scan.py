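"""Spliced-leader (SL) detection and relict-SL cascade scanning.

Dinoflagellate nuclear mRNAs carry a conserved 22-nt spliced leader at
their 5' end. Because processed mRNAs are recycled back into the genome
(reverse transcription followed by reintegration), re-expressed copies
accumulate *relict* SLs: truncated copies of the leader — everything after
nucleotide 7, i.e. downstream of the AG splice-acceptor dinucleotide —
chained directly downstream of the canonical SL, with sequence identity
decaying with age.

This module finds the canonical SL at EST 5' ends, deduplicates and trims
the SL-bearing set, and greedily chains relict copies 5'→3' with a
configurable identity floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_core import Interval, SequenceRecord, iupac_identity, ungapped_identity

__all__ = [
    "DINOFLAGELLATE_SL",
    "SLConfig",
    "SLMatch",
    "RelictChain",
    "find_canonical_sl",
    "dedupe_and_trim",
    "scan_relict_chain",
    "classify_chain_counts",
]

#: The conserved dinoflagellate spliced leader (22 nt; 5' ambiguity code D,
#: ending in the CAAG splice donor context). Exposed as the default but
#: overridable in :class:`SLConfig`.
DINOFLAGELLATE_SL = "DCCGTAGCCATTTTGGCTCAAG"

#: Position after which relict SLs are truncated (the AG splice-acceptor
#: site lies at positions 5-6 of the canonical leader).
TRUNCATION_POINT = 7


@dataclass(frozen=True)
class SLConfig:
    """Parameters of the SL / relict-SL search.

    ``relict_motif`` is derived: the canonical leader truncated after
    nucleotide 7 (15 nt). ``max_offset`` is the slack, in bases, allowed
    between consecutive copies (small insertions between relicts are
    observed in real alignments).
    """

    sl_consensus: str = DINOFLAGELLATE_SL
    canonical_min_identity: float = 0.90
    relict_floor: float = 0.50
    max_offset: int = 3
    search_window: int = 60

    def __post_init__(self) -> None:
        if len(self.sl_consensus) != 22:
            raise ValueError("SL consensus must be 22 nt")
        if not (0.0 < self.relict_floor <= 1.0):
            raise ValueError("relict_floor must be in (0, 1]")
        if self.max_offset < 0:
            raise ValueError("max_offset must be >= 0")

    @property
    def relict_motif(self) -> str:
        return self.sl_consensus[TRUNCATION_POINT:]


@dataclass(frozen=True)
class SLMatch:
    record_id: str
    interval: Interval
    identity: float


@dataclass(frozen=True)
class RelictChain:
    """Ordered relict-SL hits downstream of a canonical SL.

    ``copies`` holds ``(interval, identity)`` pairs ordered 5'→3';
    ``k = len(copies)`` is the cascade depth. ``too_short`` flags records
    that could not hold even one relict window.
    """

    record_id: str
    copies: tuple[tuple[Interval, float], ...]
    too_short: bool = False

    @property
    def k(self) -> int:
        return len(self.copies)

    @property
    def identities(self) -> tuple[float, ...]:
        return tuple(identity for _, identity in self.copies)


def find_canonical_sl(record: SequenceRecord, cfg: SLConfig | None = None) -> SLMatch | None:
    """Best 22-nt window vs the SL consensus within the 5'-most bases.

    Scans start positions ``0 .. search_window - 1``, scores each window by
    IUPAC-aware identity and returns the best window at or above
    ``canonical_min_identity`` (ties broken leftmost), or ``None``.
    """
    cfg = cfg or SLConfig()
    sl_len = len(cfg.sl_consensus)
    last_start = min(cfg.search_window, len(record.seq) - sl_len)
    if last_start < 0:
        return None
    best_identity = -1.0
    best_start = -1
    for start in range(last_start + 1):
        identity = iupac_identity(cfg.sl_consensus, record.seq[start : start + sl_len])
        if identity > best_identity:
            best_identity = identity
            best_start = start
    if best_identity >= cfg.canonical_min_identity:
        return SLMatch(
            record_id=record.id,
            interval=Interval(best_start, best_start + sl_len, "SL"),
            identity=best_identity,
        )
    return None


def dedupe_and_trim(
    records: Sequence[SequenceRecord],
    matches: Mapping[str, SLMatch],
    min_identity: float = 0.95,
) -> list[SequenceRecord]:
    """Trim each record to start at its SL and collapse redundant copies.

    Every record must have an :class:`SLMatch`. After trimming, a record is
    considered redundant when it matches a longer kept representative at
    ``>= min_identity`` over their full shared prefix; the longest
    representative survives. Deterministic: candidates are processed longest
    first, ties by id.
    """
    trimmed: list[SequenceRecord] = []
    for rec in records:
        match = matches[rec.id]
        seq = rec.seq[match.interval.start :]
        trimmed.append(SequenceRecord(id=rec.id, seq=seq, source=rec.source))
    trimmed.sort(key=lambda r: (-len(r.seq), r.id))
    kept: list[SequenceRecord] = []
    for rec in trimmed:
        duplicate = False
        for rep in kept:
            n = min(len(rec.seq), len(rep.seq))
            if ungapped_identity(rec.seq[:n], rep.seq[:n]) >= min_identity:
                duplicate = True
                break
        if not duplicate:
            kept.append(rec)
    return kept


def scan_relict_chain(record: SequenceRecord, cfg: SLConfig | None = None) -> RelictChain:
    """Greedy 5'→3' chaining of relict SL copies in a trimmed record.

    The record is assumed to start with its canonical SL. From the end of
    the previous copy (initially the canonical SL end), start offsets
    ``0 .. max_offset`` are examined; at each, a window the length of the
    relict motif is scored by IUPAC-aware identity. The highest-identity
    window at or above ``relict_floor`` is accepted (ties → smallest
    offset) and the scan resumes from its end, until no window qualifies.
    """
    cfg = cfg or SLConfig()
    motif = cfg.relict_motif
    m = len(motif)
    sl_len = len(cfg.sl_consensus)
    if len(record.seq) < sl_len + m:
        return RelictChain(record_id=record.id, copies=(), too_short=True)
    copies: list[tuple[Interval, float]] = []
    pos = sl_len
    while True:
        best_identity = -1.0
        best_start = -1
        for offset in range(cfg.max_offset + 1):
            start = pos + offset
            if start + m > len(record.seq):
                break
            identity = iupac_identity(motif, record.seq[start : start + m])
            if identity > best_identity:
                best_identity = identity
                best_start = start
        if best_start < 0 or best_identity < cfg.relict_floor:
            break
        copies.append((Interval(best_start, best_start + m, "relict_SL"), best_identity))
        pos = best_start + m
    return RelictChain(record_id=record.id, copies=tuple(copies))


def classify_chain_counts(chains: Iterable[RelictChain]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of cascade depths and per-rank identity ranges.

    Returns ``(depth_table, rank_table)``. ``depth_table`` has columns
    ``k, count, fraction`` (fractions over the SL-containing set, summing
    to 1). ``rank_table`` has, per relict rank (1-based), the number of
    chains reaching that rank and the min/max identity observed.
    """
    chains = list(chains)
    if not chains:
        raise ValueError("no chains to classify")
    depth_counts: dict[int, int] = {}
    rank_ids: dict[int, list[float]] = {}
    for chain in chains:
        depth_counts[chain.k] = depth_counts.get(chain.k, 0) + 1
        for rank, identity in enumerate(chain.identities, start=1):
            rank_ids.setdefault(rank, []).append(identity)
    total = len(chains)
    depth_table = pd.DataFrame(
        [
            {"k": k, "count": c, "fraction": c / total}
            for k, c in sorted(depth_counts.items())
        ]
    )
    rank_table = pd.DataFrame(
        [
            {
                "rank": rank,
                "n": len(ids),
                "min_identity": min(ids),
                "max_identity": max(ids),
            }
            for rank, ids in sorted(rank_ids.items())
        ]
    )
    return depth_table, rank_table
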