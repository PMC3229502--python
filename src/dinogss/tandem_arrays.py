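"""Tandem-repeat-array detection, repeat families and genome-fraction estimates.

The sampled dinoflagellate genome is dominated by head-to-tail arrays of a
very small set of 79-97 bp units, interspersed with copies diverged by a
few to ~12 percent from the major type. This module:

* detects the repeat period of a sequence by self-comparison at all lags,
* extracts the unit consensus and per-copy identities of an array,
* annotates maximal arrays within a read or contig,
* groups arrays into repeat families and estimates each family's share of
  the total sequence sample (copies x unit length x read count, over total
  bp),
* finds the best ungapped shared segment between two units, and
* predicts restriction-digest fragment ladders (a unit-length ladder is
  the wet-lab diagnostic for a tandem array).

The four repeat units recovered by the original survey are provided as
module constants (``REPEAT_UNITS``) and serve as the default repeat
families of the synthetic read generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_core import (
    Interval,
    SequenceRecord,
    match_array,
    revcomp,
    seq_to_array,
)

__all__ = [
    "REPEAT_UNITS",
    "REPEAT_UNIT_GENOME_PCT",
    "TandemArray",
    "RepeatFamily",
    "detect_period",
    "extract_unit_consensus",
    "annotate_arrays",
    "group_families",
    "estimate_family_fraction",
    "shared_segment",
    "in_silico_digest",
    "canonical_unit",
]

#: The four tandem-repeat units of the genomic survey (97, 79, 88, 88 bp).
REPEAT_UNITS: dict[str, str] = {
    "repeat1": (
        "AATAGCGCTTGAGGTGCGCGCGCGTTTCTTCCGAATGCCCAAGACGGTT"
        "TTGGCGTTTTCAGTGGCGGAGCCTCGCGGCGCCCCGAAGCCCGGAGCG"
    ),
    "repeat2": (
        "CCGCTCAGCCGCCTGAGCGAGCAATTCCTCGAGCGAGTCCTCCATGGTA"
        "TGTCCACAAAGTGGCTACGCCCTCTTTGGC"
    ),
    "repeat3": (
        "GTCCGGAGCCAGAAGCAAGAGAAGCAAT"
        "TGAAATTGACCGCAAGAGTGCCCTTTTACTGGCTCCGGCCTAAAGCTTGTCGCGAGCGAG"
    ),
    "repeat4": (
        "TGAAATTGACCGCAATAGTGCCCTTTTTGTGGCTCCGGCCTAAAGCGTGTCGCGAGCGAG"
        "GTCCGGAGCCAGAAGCAGGAGAAGCAAT"
    ),
}

#: Estimated percent of the total genomic sample attributed to each unit
#: in the original survey; used as the default planting proportions of the
#: synthetic clone-end read generator.
REPEAT_UNIT_GENOME_PCT: dict[str, float] = {
    "repeat1": 14.79,
    "repeat2": 11.15,
    "repeat3": 3.75,
    "repeat4": 28.11,
}


@dataclass(frozen=True)
class TandemArray:
    """A detected tandem array within one record.

    ``n_units`` counts complete units (``floor(span / unit_length)``); the
    fractional trailing part is reported via ``trailing_fraction``.
    ``per_unit_identity`` holds each complete copy's identity against the
    extracted consensus.
    """

    record_id: str
    span: Interval
    unit_length: int
    n_units: int
    unit_consensus: str
    per_unit_identity: tuple[float, ...]
    trailing_fraction: float = 0.0


@dataclass
class RepeatFamily:
    family_id: str
    unit_consensus: str
    arrays: list[TandemArray] = field(default_factory=list)
    estimated_fraction: float = 0.0


# ---------------------------------------------------------------------------
# Period detection and consensus extraction


def _lag_match(arr: np.ndarray, p: int) -> np.ndarray:
    return match_array(arr[:-p], arr[p:])


def detect_period(
    seq: str,
    min_p: int = 20,
    max_p: int = 300,
    min_identity: float = 0.85,
    tolerance: float = 0.02,
) -> int | None:
    """Repeat period by self-comparison at all lags.

    Scores each lag ``p`` by the mean match fraction between ``seq[i]``
    and ``seq[i+p]`` over the full overlap and returns the *smallest* lag
    whose score is within *tolerance* of the best (exact ties at 0), so a
    noisy array reports its fundamental period rather than a multiple
    whose score fluctuates marginally higher. ``None`` when no lag reaches
    *min_identity*.
    """
    arr = seq_to_array(seq)
    n = len(arr)
    if n < 2 * min_p:
        return None
    scores: dict[int, float] = {}
    for p in range(min_p, min(max_p, n // 2) + 1):
        scores[p] = float(_lag_match(arr, p).mean())
    if not scores:
        return None
    best = max(scores.values())
    if best < min_identity:
        return None
    for p in sorted(scores):
        if scores[p] >= max(best - tolerance, min_identity):
            return p
    return None


_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_BASES = "ACGT"


def _consensus_of_frames(frames: np.ndarray) -> tuple[str, list[float]]:
    """Majority consensus per column (ties alphabetical; N excluded from
    votes) and each frame's identity vs the consensus."""
    k, p = frames.shape
    consensus = np.empty(p, dtype=np.uint8)
    for j in range(p):
        col = frames[:, j]
        counts = [0, 0, 0, 0]
        for byte in col:
            code = _CODE.get(int(byte))
            if code is not None:
                counts[code] += 1
        best = max(range(4), key=lambda c: (counts[c], -c))
        consensus[j] = ord(_BASES[best])
    identities = [
        float(match_array(frames[i], consensus).mean()) for i in range(k)
    ]
    return consensus.tobytes().decode("ascii"), identities


def extract_unit_consensus(
    seq: str, p: int, phase: int | None = None
) -> tuple[str, list[float]]:
    """Unit consensus and per-copy identities of a p-periodic span.

    When *phase* is ``None`` the phase (0..p-1) maximising the mean
    adjacent-copy identity is chosen; only complete p-length frames are
    used. Raises :class:`ValueError` with fewer than 2 complete units.
    """
    arr = seq_to_array(seq)
    n = len(arr)
    if phase is None:
        scores: dict[int, float] = {}
        for ph in range(p):
            k = (n - ph) // p
            if k < 2:
                continue
            frames = arr[ph : ph + k * p].reshape(k, p)
            scores[ph] = float(
                match_array(frames[:-1].ravel(), frames[1:].ravel()).mean()
            )
        if not scores:
            raise ValueError(f"fewer than 2 complete units of length {p}")
        # smallest phase within tolerance of the best: phase 0 keeps the
        # most complete frames and wins unless clearly worse
        best = max(scores.values())
        phase = min(ph for ph, s in scores.items() if s >= best - 0.02)
    k = (n - phase) // p
    if k < 2:
        raise ValueError(f"fewer than 2 complete units of length {p}")
    frames = arr[phase : phase + k * p].reshape(k, p)
    return _consensus_of_frames(frames)


# ---------------------------------------------------------------------------
# Array annotation


def _is_short_periodic(unit: str, max_simple_unit: int = 6, thresh: float = 0.90) -> bool:
    """True when the unit is itself a simple repeat (period <= 6 bp);
    such spans belong to the simple-repeat annotator, not to tandem arrays."""
    arr = seq_to_array(unit)
    for q in range(1, min(max_simple_unit, len(arr) - 1) + 1):
        if float(_lag_match(arr, q).mean()) >= thresh:
            return True
    return False


def annotate_arrays(
    record: SequenceRecord,
    min_p: int = 20,
    max_p: int = 300,
    divergent_floor: float = 0.85,
) -> list[TandemArray]:
    """Maximal non-overlapping tandem arrays within a record.

    Detection is period-agnostic first: for every candidate lag, positions
    where the sequence matches itself at that lag (smoothed over one unit
    length, fraction at or above *divergent_floor*) mark a periodic
    region; the union over lags is split into maximal spans. Each span's
    period is then re-estimated by :func:`detect_period` restricted to the
    span (smallest lag within tolerance of the best, so noisy arrays
    report the fundamental unit, not a multiple), the consensus and
    per-copy identities extracted, and spans whose unit is itself a
    short-period simple repeat are discarded. Arrays are returned sorted
    by start.
    """
    arr = seq_to_array(record.seq)
    n = len(arr)
    periodic = np.zeros(n, dtype=bool)
    for p in range(min_p, min(max_p, n // 2) + 1):
        m = _lag_match(arr, p).astype(np.int32)
        if len(m) < p:
            continue
        # fraction of matches in each p-wide window of the lag profile
        cs = np.concatenate(([0], np.cumsum(m)))
        frac = (cs[p:] - cs[:-p]) / p
        flag = frac >= divergent_floor
        if not flag.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], flag.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            # window starts a..b-1 flagged -> lag pairs cover a..b+p-2,
            # hence the array spans [a, b + 2p - 1)
            end = min(n, int(b) + 2 * p - 1)
            if end - int(a) >= 2 * p:
                periodic[int(a) : end] = True
    if not periodic.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], periodic.view(np.int8), [0]))))
    arrays: list[TandemArray] = []
    for a, end in zip(edges[::2], edges[1::2]):
        a, end = int(a), int(end)
        sub_arr = arr[a:end]
        # period from the best lag score (the raw span may include flank
        # bases, so no floor yet); the span is then trimmed to the longest
        # run matching at that period before the floor applies
        p = detect_period(
            record.seq[a:end], min_p, min(max_p, (end - a) // 2), min_identity=0.0
        )
        if p is None:
            continue
        m = _lag_match(sub_arr, p).astype(np.int32)
        if len(m) < p:
            continue
        cs = np.concatenate(([0], np.cumsum(m)))
        frac = (cs[p:] - cs[:-p]) / p
        flag = frac >= divergent_floor
        if not flag.any():
            continue
        f_edges = np.flatnonzero(
            np.diff(np.concatenate(([0], flag.view(np.int8), [0])))
        )
        runs = list(zip(f_edges[::2], f_edges[1::2]))
        # windows crossing a divergent copy dip below the floor; merge runs
        # separated by less than two units so one array stays one span
        merged = [list(runs[0])]
        for r0, r1 in runs[1:]:
            if r0 - merged[-1][1] <= 2 * p:
                merged[-1][1] = r1
            else:
                merged.append([r0, r1])
        ra, rb = max(merged, key=lambda r: r[1] - r[0])
        start = a + int(ra)
        stop = min(end, a + int(rb) + 2 * p - 1)
        if stop - start < 2 * p:
            continue
        a, end = start, stop
        sub = record.seq[a:end]
        try:
            consensus, identities = extract_unit_consensus(sub, p)
        except ValueError:
            continue
        if _is_short_periodic(consensus):
            continue
        arrays.append(
            TandemArray(
                record_id=record.id,
                span=Interval(a, end, "tandem_array"),
                unit_length=p,
                n_units=(end - a) // p,
                unit_consensus=consensus,
                per_unit_identity=tuple(identities),
                trailing_fraction=((end - a) % p) / p,
            )
        )
    return arrays


# ---------------------------------------------------------------------------
# Unit comparison, families, fractions


def shared_segment(
    unit_a: str,
    unit_b: str,
    min_len: int = 20,
    min_identity: float = 0.80,
) -> tuple[Interval, Interval, float] | None:
    """Longest ungapped shared window between two repeat units.

    Slides *unit_b* (both strands) against *unit_a* at every linear offset
    and returns the longest window of length >= *min_len* whose identity
    reaches *min_identity* (ties -> higher identity, then smaller offset),
    as ``(interval_in_a, interval_in_b, identity)``, or ``None``.
    """
    if min_len < 1:
        raise ValueError("min_len must be positive")
    a = seq_to_array(unit_a)
    best: tuple[int, float, Interval, Interval] | None = None
    for strand, b_seq in ((1, unit_b), (-1, revcomp(unit_b))):
        b = seq_to_array(b_seq)
        la, lb = len(a), len(b)
        for shift in range(-(lb - min_len), la - min_len + 1):
            a0, b0 = max(0, shift), max(0, -shift)
            overlap = min(la - a0, lb - b0)
            if overlap < min_len:
                continue
            m = match_array(a[a0 : a0 + overlap], b[b0 : b0 + overlap]).astype(np.int32)
            cs = np.concatenate(([0], np.cumsum(m)))
            # longest window with mismatch fraction <= 1 - min_identity
            for w in range(overlap, min_len - 1, -1):
                if best is not None and w < best[0]:
                    break
                counts = cs[w:] - cs[:-w]
                i = int(np.argmax(counts))
                identity = float(counts[i]) / w
                if identity < min_identity:
                    continue
                if best is None or (w, identity) > (best[0], best[1]):
                    iv_a = Interval(a0 + i, a0 + i + w, "shared")
                    if strand == 1:
                        iv_b = Interval(b0 + i, b0 + i + w, "shared")
                    else:
                        iv_b = Interval(lb - (b0 + i + w), lb - (b0 + i), "shared(-)")
                    best = (w, identity, iv_a, iv_b)
                break  # only the longest qualifying w per shift matters
    if best is None:
        return None
    return best[2], best[3], best[1]


def canonical_unit(unit: str) -> str:
    """Rotation- and strand-invariant canonical form of a repeat unit
    (lexicographically minimal rotation over both strands)."""
    best = None
    for s in (unit, revcomp(unit)):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i : i + len(s)]
            if best is None or rot < best:
                best = rot
    return best  # type: ignore[return-value]


def _rotation_aware_similar(
    unit_a: str, unit_b: str, min_cov: float = 0.80, min_identity: float = 0.90
) -> bool:
    """True when the units share a window covering >= min_cov of the shorter
    unit at >= min_identity, allowing any rotation/strand of unit_b."""
    short = min(len(unit_a), len(unit_b))
    w = max(1, int(np.ceil(min_cov * short)))
    a = seq_to_array(unit_a)
    for b_seq in (unit_b, revcomp(unit_b)):
        b = seq_to_array(b_seq + b_seq)
        for shift in range(len(b_seq)):
            overlap = min(len(a), len(b) - shift)
            if overlap < w:
                continue
            m = match_array(a[:overlap], b[shift : shift + overlap]).astype(np.int32)
            cs = np.concatenate(([0], np.cumsum(m)))
            counts = cs[w:] - cs[:-w]
            if counts.size and counts.max() >= min_identity * w:
                return True
    return False


def group_families(
    arrays: Iterable[TandemArray],
    min_cov: float = 0.80,
    min_identity: float = 0.90,
) -> list[RepeatFamily]:
    """Group arrays into repeat families by unit-consensus similarity.

    Units are first reduced to a rotation/strand-invariant canonical form;
    distinct canonical units are then merged when a rotation-aware
    comparison finds a shared window covering at least *min_cov* of the
    shorter unit at *min_identity*. Families are numbered by descending
    total array bp (``family1`` largest).
    """
    arrays = list(arrays)
    groups: dict[str, list[TandemArray]] = {}
    for array in arrays:
        groups.setdefault(canonical_unit(array.unit_consensus), []).append(array)
    reps = sorted(groups, key=lambda u: (-sum(a.span.length for a in groups[u]), u))
    # union-find over distinct canonical units
    parent = {u: u for u in reps}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, u in enumerate(reps):
        for v in reps[i + 1 :]:
            if find(u) == find(v):
                continue
            if _rotation_aware_similar(u, v, min_cov, min_identity):
                parent[find(v)] = find(u)
    merged: dict[str, list[TandemArray]] = {}
    for u in reps:
        merged.setdefault(find(u), []).extend(groups[u])
    ordered = sorted(
        merged.items(), key=lambda kv: (-sum(a.span.length for a in kv[1]), kv[0])
    )
    families = []
    for idx, (rep, members) in enumerate(ordered, start=1):
        members = sorted(members, key=lambda a: (a.record_id, a.span.start))
        families.append(
            RepeatFamily(family_id=f"family{idx}", unit_consensus=rep, arrays=members)
        )
    return families


def estimate_family_fraction(
    family: RepeatFamily,
    reads_per_contig: Mapping[str, int] | None,
    total_bp: int,
) -> float:
    """Percent of the total sample attributed to a repeat family.

    Implements the survey's accounting: per contig (or read), the number
    of complete repeat copies times the unit length times the number of
    reads behind that contig, summed over the family and divided by the
    total sample bp. *reads_per_contig* maps record ids to read counts
    (``None`` -> every record counts as a single read).
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    bp = 0
    for array in family.arrays:
        n_reads = 1 if reads_per_contig is None else reads_per_contig.get(array.record_id, 1)
        bp += array.n_units * array.unit_length * n_reads
    return 100.0 * bp / total_bp


# ---------------------------------------------------------------------------
# In-silico restriction digest


def in_silico_digest(seq: str, recognition_site: str) -> list[int]:
    """Fragment lengths from cutting at every occurrence of a site.

    Both strands are searched (i.e. the site and its reverse complement on
    the given strand); the cut is placed at the site start — a documented
    simplification, since only the fragment-ladder periodicity matters for
    diagnosing tandem arrays. Fragments always partition the sequence.
    """
    site = recognition_site.upper()
    if len(site) < 4 or set(site) - set("ACGT"):
        raise ValueError("recognition site must be >= 4 bases over {A,C,G,T}")
    cuts: set[int] = set()
    for probe in {site, revcomp(site)}:
        start = seq.find(probe)
        while start != -1:
            if start > 0:
                cuts.add(start)
            start = seq.find(probe, start + 1)
    bounds = [0, *sorted(cuts), len(seq)]
    return sorted(b - a for a, b in zip(bounds[:-1], bounds[1:]))
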