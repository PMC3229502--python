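"""Repetitiveness census of clone-end (GSS) read sets.

A low-coverage genome survey cannot be assembled, but overlap clustering
of fosmid/BAC-end reads still reveals which sequences occur many times in
the genome: with only a ~0.006% sample, any overlap cluster of two or more
reads represents sequence present at least twice genome-wide. This module
provides

* greedy ungapped overlap clustering (seeded by exact 16-mers, both
  strands),
* read-level repetitiveness classes (unique / repetitive, i.e. clusters of
  at least 2 reads / highly repetitive, clusters of more than 20 reads),
* simple-repeat (unit 1-6 bp) and low-complexity (entropy) annotation,
* the feature census with its two percentage views: "pie" percentages over
  the summed per-feature bp (features may double-count reads, so this
  denominator exceeds the sample size) and "actual" percentages over the
  true sample bp,
* genome-size arithmetic from DNA content in picograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_core import Interval, SequenceRecord, match_array, revcomp, seq_to_array

__all__ = [
    "ClusterParams",
    "GENOMIC_CLUSTER_PARAMS",
    "EST_CLUSTER_PARAMS",
    "FeatureCensus",
    "greedy_overlap_cluster",
    "classify_repetitiveness",
    "find_simple_repeats",
    "find_low_complexity",
    "read_feature_labels",
    "feature_census",
    "genome_size_from_pg",
    "sample_fraction",
]

#: bp of genome per picogram of DNA, the standard flow-cytometry conversion.
BP_PER_PG = 0.921e9


@dataclass(frozen=True)
class ClusterParams:
    """Overlap-clustering stringency.

    ``max_mismatches`` of ``None`` means unlimited (identity alone decides).
    """

    min_overlap: int = 100
    min_identity: float = 0.90
    max_mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.min_overlap < 20:
            raise ValueError("min_overlap must be >= 20")
        if not (0.5 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0.5, 1]")


#: Stringency used for the genomic clone-end reads.
GENOMIC_CLUSTER_PARAMS = ClusterParams(min_overlap=100, min_identity=0.90)
#: Stringency used for EST clustering.
EST_CLUSTER_PARAMS = ClusterParams(min_overlap=40, min_identity=0.95, max_mismatches=30)

_KMER = 16


def _kmer_positions(seq: str, k: int = _KMER) -> dict[str, int]:
    """First occurrence of each k-mer (one anchor position is enough to
    seed the diagonal)."""
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], i)
    return out


def _diagonal_overlap_ok(
    a: np.ndarray, b: np.ndarray, diag: int, params: ClusterParams
) -> bool:
    """Test the full ungapped overlap of two reads at one diagonal
    (``diag`` = position in a minus position in b of aligned bases)."""
    a0, b0 = max(0, diag), max(0, -diag)
    overlap = min(len(a) - a0, len(b) - b0)
    if overlap < params.min_overlap:
        return False
    m = match_array(a[a0 : a0 + overlap], b[b0 : b0 + overlap])
    matches = int(m.sum())
    mismatches = overlap - matches
    if params.max_mismatches is not None and mismatches > params.max_mismatches:
        return False
    return matches / overlap >= params.min_identity


class _OverlapIndex:
    """Precomputed per-read arrays, k-mer anchors and a shared k-mer index."""

    def __init__(self, reads: Sequence[SequenceRecord]):
        self.reads = reads
        self.fwd = [seq_to_array(r.seq) for r in reads]
        self.rev = [seq_to_array(revcomp(r.seq)) for r in reads]
        self.fwd_kmers = [_kmer_positions(r.seq) for r in reads]
        self.rev_kmers = [_kmer_positions(revcomp(r.seq)) for r in reads]
        self.index: dict[str, set[int]] = {}
        for i, kmers in enumerate(self.fwd_kmers):
            for km in kmers:
                self.index.setdefault(km, set()).add(i)

    def retire(self, i: int) -> None:
        for km in self.fwd_kmers[i]:
            bucket = self.index.get(km)
            if bucket is not None:
                bucket.discard(i)

    def candidates(self, i: int) -> set[int]:
        """Unretired reads sharing a forward or reverse k-mer with read i."""
        out: set[int] = set()
        for kmers in (self.fwd_kmers[i], self.rev_kmers[i]):
            for km in kmers:
                bucket = self.index.get(km)
                if bucket:
                    out |= bucket
        out.discard(i)
        return out

    def overlaps(self, i: int, j: int, params: ClusterParams) -> bool:
        """True when reads i and j share a qualifying ungapped overlap on
        either strand. Diagonals are voted by shared k-mer anchors and
        tested best-first."""
        a = self.fwd[i]
        for b, j_kmers in ((self.fwd[j], self.fwd_kmers[j]), (self.rev[j], self.rev_kmers[j])):
            votes: dict[int, int] = {}
            i_kmers = self.fwd_kmers[i]
            shared = i_kmers.keys() & j_kmers.keys()
            for km in shared:
                diag = i_kmers[km] - j_kmers[km]
                votes[diag] = votes.get(diag, 0) + 1
            for diag, _ in sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:25]:
                if _diagonal_overlap_ok(a, b, diag, params):
                    return True
        return False


def greedy_overlap_cluster(
    reads: Sequence[SequenceRecord], params: ClusterParams | None = None
) -> list[list[str]]:
    """Greedy single-linkage overlap clustering of reads.

    The longest unclustered read seeds a cluster (ties by id); any read
    sharing an ungapped overlap of at least ``min_overlap`` bases at
    ``min_identity`` (and within ``max_mismatches`` when set) with any
    cluster member — either orientation, any offset — joins, transitively,
    until stable. Deterministic and invariant to input order. Returns
    clusters in seed order, member ids sorted.
    """
    if not reads:
        raise ValueError("no reads to cluster")
    params = params or GENOMIC_CLUSTER_PARAMS
    idx = _OverlapIndex(reads)
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i].seq), reads[i].id))
    assigned = [False] * len(reads)
    clusters: list[list[str]] = []
    for seed in order:
        if assigned[seed]:
            continue
        assigned[seed] = True
        idx.retire(seed)
        members = [seed]
        frontier = [seed]
        while frontier:
            cand: set[int] = set()
            for m in frontier:
                cand |= idx.candidates(m)
            newly: list[int] = []
            for r in sorted(cand, key=lambda i: (-len(reads[i].seq), reads[i].id)):
                if assigned[r]:
                    continue
                if any(idx.overlaps(r, m, params) for m in frontier):
                    assigned[r] = True
                    idx.retire(r)
                    members.append(r)
                    newly.append(r)
            frontier = newly
        clusters.append(sorted(reads[i].id for i in members))
    return clusters


def classify_repetitiveness(
    clusters: Iterable[Sequence[str]], highly_repetitive_min: int = 21
) -> dict[str, str]:
    """Read id -> repetitiveness category.

    Singletons are ``unique``; clusters of at least two reads are
    ``repetitive``; clusters larger than 20 reads are ``highly_repetitive``
    (which subsumes repetitive).
    """
    out: dict[str, str] = {}
    for cluster in clusters:
        if len(cluster) >= highly_repetitive_min:
            cat = "highly_repetitive"
        elif len(cluster) >= 2:
            cat = "repetitive"
        else:
            cat = "unique"
        for read_id in cluster:
            out[read_id] = cat
    return out


# ---------------------------------------------------------------------------
# Simple repeats and low complexity


def _phase_consensus_fraction(arr: np.ndarray, u: int) -> float:
    """Fraction of positions (over complete u-frames) matching the
    per-column majority unit."""
    k = len(arr) // u
    if k < 2:
        return 0.0
    frames = arr[: k * u].reshape(k, u)
    matches = 0
    for j in range(u):
        col = frames[:, j]
        counts = np.bincount(col, minlength=256)
        matches += int(counts.max())
    return matches / (k * u)


def _smallest_period(unit: str) -> str:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return unit[:p]
    return unit


def _min_rotation(unit: str) -> str:
    doubled = unit + unit
    return min(doubled[i : i + len(unit)] for i in range(len(unit)))


def find_simple_repeats(
    seq: str, max_unit: int = 6, min_span: int = 12, min_phase_identity: float = 0.90
) -> list[tuple[Interval, str]]:
    """Maximal simple-repeat runs (unit length 1-6 bp).

    A run is a span where at least *min_phase_identity* of positions match
    the base one unit earlier *and* match a single per-phase consensus unit
    (pure lag-matching would chain heterogeneous homopolymer blocks, which
    all match themselves at every lag, into one bogus call). Overlapping
    calls across unit lengths are resolved toward the longer span; the
    unit is reported with its smallest period in its lexicographically
    minimal rotation.
    """
    arr = seq_to_array(seq)
    n = len(arr)
    candidates: list[tuple[int, int, int, int]] = []  # (span, u, start, end)
    for u in range(1, max_unit + 1):
        if n < max(min_span, 2 * u):
            break
        m = match_array(arr[:-u], arr[u:]).astype(np.int32)
        # local windowed flags keep a long run from creeping into flanking
        # sequence on the strength of its global match fraction
        w = max(min_span - u, u)
        if len(m) < w:
            continue
        cs = np.concatenate(([0], np.cumsum(m)))
        frac = (cs[w:] - cs[:-w]) / w
        flag = frac >= min_phase_identity - 1e-9
        if not flag.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], flag.view(np.int8), [0]))))
        runs = [[int(a), int(b)] for a, b in zip(edges[::2], edges[1::2])]
        merged = [runs[0]]
        for a, b in runs[1:]:
            if a - merged[-1][1] <= u:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            end = min(n, b + w + u - 1)
            span = end - a
            if span >= max(min_span, 2 * u) and _phase_consensus_fraction(
                arr[a:end], u
            ) >= min_phase_identity:
                candidates.append((span, u, a, end))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    chosen: list[tuple[int, int, int]] = []
    for span, u, start, end in candidates:
        # trim boundary slop against already-accepted longer spans
        for s, e, _ in chosen:
            if s <= start < e:
                start = e
            if s < end <= e:
                end = s
            if start >= end:
                break
        if start < end and end - start >= max(min_span, 2 * u) and all(
            end <= s or start >= e for s, e, _ in chosen
        ):
            chosen.append((start, end, u))
    out: list[tuple[Interval, str]] = []
    for start, end, u in sorted(chosen):
        frames = arr[start : start + ((end - start) // u) * u].reshape(-1, u)
        consensus = bytes(
            int(np.argmax(np.bincount(frames[:, j], minlength=256)))
            for j in range(u)
        ).decode("ascii")
        unit = _min_rotation(_smallest_period(consensus))
        out.append((Interval(start, end, f"({unit})n"), unit))
    return out


_ENTROPY_BASES = "ACGT"


def _window_entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 2.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def find_low_complexity(
    seq: str, window: int = 64, entropy_thresh: float = 1.5
) -> list[tuple[Interval, str]]:
    """Low-complexity intervals by mononucleotide Shannon entropy.

    Windows (stepped by a quarter window) whose base-composition entropy
    falls below *entropy_thresh* bits are merged; each merged interval is
    labelled by its dominant base (``C-rich``) or, when no single base
    reaches half the interval, its two most frequent bases (``GA-rich``).
    """
    n = len(seq)
    w = min(window, n)
    if w == 0:
        return []
    arr = seq_to_array(seq)
    codes = np.full(n, -1, dtype=np.int8)
    for c, base in enumerate(_ENTROPY_BASES):
        codes[arr == ord(base)] = c
    step = max(1, w // 4)
    starts = list(range(0, max(1, n - w + 1), step))
    if starts[-1] != n - w:
        starts.append(n - w)
    flagged: list[tuple[int, int]] = []
    for s in starts:
        counts = np.bincount(codes[s : s + w][codes[s : s + w] >= 0], minlength=4)
        if _window_entropy(counts) < entropy_thresh:
            if flagged and s <= flagged[-1][1]:
                flagged[-1] = (flagged[-1][0], s + w)
            else:
                flagged.append((s, s + w))
    out: list[tuple[Interval, str]] = []
    for s, e in flagged:
        counts = np.bincount(codes[s:e][codes[s:e] >= 0], minlength=4)
        order = np.argsort(-counts, kind="stable")
        # a clearly dominant base names the interval alone; otherwise the
        # two most frequent bases do (e.g. GA-rich)
        if counts[order[0]] >= 0.5 * counts.sum() and counts[order[0]] >= 2 * counts[order[1]]:
            label = f"{_ENTROPY_BASES[order[0]]}-rich"
        else:
            label = f"{_ENTROPY_BASES[order[0]]}{_ENTROPY_BASES[order[1]]}-rich"
        out.append((Interval(s, e, label), label))
    return out


def read_feature_labels(
    record: SequenceRecord,
    tandem_spans: Sequence[Interval] | None = None,
    max_unit: int = 6,
    min_span: int = 12,
    window: int = 64,
    min_label_span: int = 20,
) -> set[str]:
    """Computed feature labels for one read.

    ``tandem_array`` when *tandem_spans* is non-empty; ``simple_repeats``
    and ``low_complexity`` from their annotators, with two restrictions:
    intervals contained within a tandem-array span are ignored
    (microsatellite-sized repeats and skewed stretches inside a long
    repeat unit are part of the array, not independent features), and an
    interval must reach *min_label_span* bases before it labels the whole
    read — a minimum-score convention mirroring library annotators, since
    a lone two-copy hexamer occurs freely in random sequence.
    """
    spans = list(tandem_spans or [])

    def counts(interval: Interval) -> bool:
        inside = any(
            interval.start >= s.start and interval.end <= s.end for s in spans
        )
        return not inside and interval.length >= min_label_span

    labels: set[str] = set()
    if spans:
        labels.add("tandem_array")
    if any(counts(iv) for iv, _ in find_simple_repeats(record.seq, max_unit, min_span)):
        labels.add("simple_repeats")
    if any(counts(iv) for iv, _ in find_low_complexity(record.seq, window)):
        labels.add("low_complexity")
    return labels


# ---------------------------------------------------------------------------
# Census and genome-size arithmetic


@dataclass
class FeatureCensus:
    """Per-feature read/bp tallies with pie and actual percentage views.

    ``pct_actual`` is computed over the true sample bp; ``pct_pie`` over
    the sum of per-feature bp. Because a read carrying several features
    contributes its full length to each, the pie denominator is an
    overestimate of the sample (its documented property).
    """

    table: pd.DataFrame
    actual_total_bp: int
    pie_total_bp: int

    @classmethod
    def from_tallies(
        cls, tallies: Mapping[str, tuple[int, int]], actual_total_bp: int
    ) -> "FeatureCensus":
        """Build a census from ``{feature: (n_reads, total_bp)}`` tallies."""
        pie_total = sum(bp for _, bp in tallies.values())
        rows = [
            {
                "feature": feat,
                "n_reads": n,
                "total_bp": bp,
                "pct_pie": 100.0 * bp / pie_total if pie_total else 0.0,
                "pct_actual": 100.0 * bp / actual_total_bp,
            }
            for feat, (n, bp) in tallies.items()
        ]
        table = pd.DataFrame(rows).sort_values("total_bp", ascending=False, kind="stable")
        return cls(table=table.reset_index(drop=True), actual_total_bp=actual_total_bp,
                   pie_total_bp=pie_total)

    def pct(self, feature: str, view: str = "actual") -> float:
        row = self.table[self.table["feature"] == feature]
        if row.empty:
            return 0.0
        return float(row.iloc[0]["pct_pie" if view == "pie" else "pct_actual"])


def feature_census(
    reads: Sequence[SequenceRecord],
    annotations: Mapping[str, Iterable[str]],
) -> FeatureCensus:
    """Tally reads and bp per feature, whole-read accounting.

    *annotations* maps read id to its feature labels (possibly several,
    possibly computed and pass-through labels mixed). A read's full length
    is counted for every feature it carries; reads with no label fall into
    ``no_feature``.
    """
    tallies: dict[str, list[int]] = {}
    actual_total = 0
    for rec in reads:
        actual_total += len(rec.seq)
        labels = sorted(set(annotations.get(rec.id, ()))) or ["no_feature"]
        for label in labels:
            t = tallies.setdefault(label, [0, 0])
            t[0] += 1
            t[1] += len(rec.seq)
    return FeatureCensus.from_tallies(
        {k: (v[0], v[1]) for k, v in tallies.items()}, actual_total
    )


def genome_size_from_pg(dna_pg: float) -> float:
    """Genome size in bp from DNA content in pg (0.921e9 bp per pg)."""
    if dna_pg <= 0:
        raise ValueError("DNA content must be positive")
    return BP_PER_PG * dna_pg


def sample_fraction(sample_bp: int, dna_pg: float) -> float:
    """Percent of the genome covered by a sequenced sample."""
    if sample_bp <= 0:
        raise ValueError("sample_bp must be positive")
    return 100.0 * sample_bp / genome_size_from_pg(dna_pg)
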