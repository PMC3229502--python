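"""Stop-codon usage, EST abundance tables and polyA-upstream motif scans.

Dinoflagellates favour TGA as a stop codon and — unusually among
eukaryotes — show no conserved polyadenylation signal in mature mRNA.
This module tabulates stop-codon usage per transcript set, builds
abundance tables from cluster→annotation maps, and performs an exhaustive
k-mer enrichment scan (k = 5..9) on the windows immediately upstream of
the polyA tail, with a mononucleotide background model and Bonferroni
correction, designed to reproduce the field's negative result cleanly on
null data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seq_core import SequenceRecord, find_polyA_start, round_half_up

__all__ = [
    "STOP_CODONS",
    "MotifScanResult",
    "infer_stop_codon",
    "stop_codon_table",
    "abundance_table",
    "polyA_motif_scan",
]

STOP_CODONS = ("TAA", "TAG", "TGA")


def infer_stop_codon(transcript: str, frame_hint: int | None = None) -> str | None:
    """Stop codon of a transcript in mRNA sense.

    With *frame_hint* (0/1/2): the first in-frame stop codon. Without: the
    terminal codon of the longest ATG-initiated open reading frame over the
    three forward frames (ties → earliest start). ``None`` when no stop is
    found.
    """
    seq = transcript.upper().replace("U", "T")
    if frame_hint is not None:
        for i in range(frame_hint, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                return codon
        return None
    best: tuple[int, int, str] | None = None  # (orf_len, -start, stop)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in STOP_CODONS and start is not None:
                orf_len = i + 3 - start
                cand = (orf_len, -start, codon)
                if best is None or cand > best:
                    best = cand
                start = None
    return best[2] if best else None


def stop_codon_table(codons_per_set: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Counts and percentages of TAA/TAG/TGA per labelled transcript set.

    Percentages are to one decimal (half-up), matching conventional
    reporting. Codons outside the three stops raise :class:`ValueError`.
    """
    rows = []
    for label, codons in codons_per_set.items():
        bad = set(codons) - set(STOP_CODONS)
        if bad:
            raise ValueError(f"set {label!r}: non-stop codons {sorted(bad)}")
        total = len(codons)
        if total == 0:
            raise ValueError(f"set {label!r}: empty codon list")
        for stop in STOP_CODONS:
            n = sum(1 for c in codons if c == stop)
            rows.append(
                {
                    "set": label,
                    "stop_codon": stop,
                    "count": n,
                    "percent": round_half_up(100.0 * n / total, 1),
                    "total": total,
                }
            )
    return pd.DataFrame(rows)


def abundance_table(
    clusters: Mapping[str, int],
    annotations: Mapping[str, str],
    total_ests: int,
) -> pd.DataFrame:
    """Ranked transcript-abundance table.

    *clusters* maps cluster (tentative-consensus) id to its EST count,
    *annotations* maps cluster id to an annotation string. Clusters
    sharing an annotation are pooled; per annotation the table reports the
    number of clusters, the number of ESTs and the percent of *total_ests*
    (2 decimals, half-up), sorted by EST count descending.
    """
    if total_ests <= 0:
        raise ValueError("total_ests must be positive")
    pooled: dict[str, list[int]] = {}
    for tc, n_ests in clusters.items():
        annot = annotations.get(tc, "unannotated")
        t = pooled.setdefault(annot, [0, 0])
        t[0] += 1
        t[1] += n_ests
    rows = [
        {
            "annotation": annot,
            "n_TCs": n_tc,
            "n_ESTs": n_est,
            "pct_total_ESTs": round_half_up(100.0 * n_est / total_ests, 2),
        }
        for annot, (n_tc, n_est) in pooled.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["n_ESTs", "annotation"], ascending=[False, True], kind="stable"
    )
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class MotifScanResult:
    motif: str
    observed: int
    expected: float
    p_value: float
    p_adjusted: float
    significant: bool


def _upstream_windows(
    transcripts: Iterable[SequenceRecord],
    window: int,
    min_run: int,
    max_mismatch: int,
) -> list[str]:
    windows = []
    for rec in transcripts:
        start = find_polyA_start(rec.seq, min_run=min_run, max_mismatch=max_mismatch)
        if start is None:
            continue
        windows.append(rec.seq[max(0, start - window) : start])
    return windows


def polyA_motif_scan(
    transcripts: Sequence[SequenceRecord],
    window: int = 60,
    k_range: tuple[int, int] = (5, 9),
    alpha: float = 0.05,
    min_run: int = 10,
    max_mismatch: int = 1,
) -> list[MotifScanResult]:
    """Exhaustive k-mer enrichment scan of polyA-upstream windows.

    For each transcript with a detectable polyA tail, the *window* bases
    immediately 5' of the tail (clipped at the transcript start) are
    collected. For each k in *k_range*, every k-mer is scored by the
    number of windows containing it at least once, against its expectation
    under a mononucleotide background (pooled window base composition,
    independent positions). Presence-per-window rather than raw occurrence
    counts keeps self-overlapping motifs (whose occurrences clump) from
    producing anti-conservative tails. One-sided binomial p-values are
    Bonferroni-corrected over the full motif family (all 4^k motifs of
    every k scanned), so a null data set yields no significant motif at
    level alpha. Raises :class:`ValueError` when no transcript has a
    polyA.
    """
    windows = _upstream_windows(transcripts, window, min_run, max_mismatch)
    if not windows:
        raise ValueError("no polyA-bearing transcripts")
    pooled = "".join(windows)
    base_freq = {
        b: max(pooled.count(b), 1) / max(len(pooled), 1) for b in "ACGT"
    }
    raw: list[tuple[str, int, float, float]] = []
    for k in range(k_range[0], k_range[1] + 1):
        lengths = np.array([max(0, len(w) - k + 1) for w in windows])
        n_windows = int((lengths > 0).sum())
        if n_windows == 0:
            continue
        counts: dict[str, int] = {}
        for w in windows:
            seen = set()
            for i in range(len(w) - k + 1):
                kmer = w[i : i + k]
                if "N" not in kmer:
                    seen.add(kmer)
            for kmer in seen:
                counts[kmer] = counts.get(kmer, 0) + 1
        motifs = sorted(counts)
        observed = np.array([counts[m] for m in motifs])
        p_motifs = np.array([math.prod(base_freq[b] for b in m) for m in motifs])
        # mean per-window presence probability under the background
        uniq_len, len_counts = np.unique(lengths[lengths > 0], return_counts=True)
        miss = (1.0 - p_motifs)[:, None] ** uniq_len[None, :]
        p_window = 1.0 - (miss * len_counts).sum(axis=1) / n_windows
        p_values = stats.binom.sf(observed - 1, n_windows, p_window)
        for motif, obs, pw, p_value in zip(motifs, observed, p_window, p_values):
            raw.append((motif, int(obs), float(n_windows * pw), float(p_value)))
    n_tests = sum(4**k for k in range(k_range[0], k_range[1] + 1))
    results = []
    for motif, obs, expected, p_value in raw:
        p_adj = min(1.0, p_value * n_tests)
        results.append(
            MotifScanResult(
                motif=motif,
                observed=obs,
                expected=expected,
                p_value=p_value,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.motif))
    return results
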