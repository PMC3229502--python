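"""Synthetic EST, CDS and clone-end read generators with ground truth.

The generators emulate the statistical structure the analysis stages
assume, so every stage can be exercised and its recovery measured without
any external data:

* **SL ESTs** — a resolved spliced-leader consensus, followed by 0-4
  relict (truncated) SL copies whose substitution load grows with rank
  (older copies are more diverged: copy r carries Binomial(15, r * rate)
  substitutions), a random UTR/CDS tail, and a polyA tail.
* **GSS reads** — clone-end-style reads of 300-1200 bp drawn from a
  configurable mixture of tandem-array reads (noisy copies of the four
  survey repeat units by default, planted at their published genome
  shares), simple-repeat reads, low-complexity reads and unique
  background.
* **CDS sets** — ATG-initiated open reading frames with configurable
  stop-codon frequencies and third-position GC bias, plus polyA tails.

Determinism: every record draws from its own child stream of
``numpy.random.SeedSequence(seed)``, so record *i* is identical no matter
how many records are requested, and the same seed reproduces byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seq_core import SequenceRecord, Source, revcomp
from .sl_scan import SLConfig
from .tandem_arrays import REPEAT_UNITS, REPEAT_UNIT_GENOME_PCT

__all__ = [
    "SyntheticTruth",
    "DEFAULT_DEPTH_PROBS",
    "DEFAULT_GSS_COMPOSITION",
    "DEFAULT_STOP_PROBS",
    "generate_sl_ests",
    "generate_gss_reads",
    "generate_cds_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Relict-cascade depth distribution (depths 0..4), echoing the observed
#: cascade frequencies in the surveyed SL-bearing transcript set.
DEFAULT_DEPTH_PROBS = (0.74, 0.21, 0.04, 0.008, 0.002)

#: Default clone-end read composition: the four survey repeat units at
#: their published genome shares, plus simple repeats, low complexity and
#: unique background.
DEFAULT_GSS_COMPOSITION: dict[str, float] = {
    **{name: pct / 100.0 for name, pct in REPEAT_UNIT_GENOME_PCT.items()},
    "simple_repeat": 0.13,
    "low_complexity": 0.08,
}
DEFAULT_GSS_COMPOSITION["unique"] = round(
    1.0 - sum(DEFAULT_GSS_COMPOSITION.values()), 6
)

#: Stop-codon frequencies (TAA, TAG, TGA) echoing the tabulated usage.
DEFAULT_STOP_PROBS = (0.072, 0.165, 0.763)

#: Simple-repeat unit pool with weights echoing the most abundant units.
_SIMPLE_UNITS = (("CACG", 0.35), ("CATG", 0.30), ("CGTG", 0.30), ("CAG", 0.05))

#: Low-complexity styles: (label, base probabilities ACGT, weight).
_LOWC_STYLES = (
    ("GA-rich", (0.46, 0.04, 0.46, 0.04), 0.40),
    ("GC-rich", (0.04, 0.46, 0.46, 0.04), 0.35),
    ("C-rich", (0.10, 0.70, 0.10, 0.10), 0.25),
)


@dataclass
class SyntheticTruth:
    """Planted parameters: global generator settings plus one entry per
    generated record (cascade depth, intervals, codons, ... as applicable)."""

    seed: int
    params: dict
    records: dict[str, dict] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute n_subs distinct positions, always to a different base."""
    if n_subs <= 0:
        return seq
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for pos in positions:
        current = arr[pos]
        choices = [b for b in b"ACGT" if b != current]
        arr[pos] = choices[rng.integers(len(choices))]
    return arr.decode("ascii")


def _resolve_iupac(rng: np.random.Generator, pattern: str) -> str:
    from .seq_core import IUPAC_EXPANSION

    out = []
    for code in pattern:
        expansion = sorted(IUPAC_EXPANSION[code])
        out.append(expansion[rng.integers(len(expansion))])
    return "".join(out)


def _polya_tail(rng: np.random.Generator, min_len: int = 15, max_len: int = 30) -> str:
    return "A" * int(rng.integers(min_len, max_len + 1))


def _non_a_guard(rng: np.random.Generator, length: int = 2) -> str:
    # simulated cleavage context: no A immediately upstream of the tail, so
    # the planted tail start is recovered exactly by the polyA locator
    pool = np.frombuffer(b"CGT", dtype=np.uint8)
    return pool[rng.integers(0, 3, size=length)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# SL ESTs


def generate_sl_ests(
    n: int,
    cfg: SLConfig | None = None,
    depth_probs: Sequence[float] = DEFAULT_DEPTH_PROBS,
    per_cycle_sub_rate: float = 0.05,
    seed: int = 0,
    n_transcripts: int | None = None,
    resequencing_noise: float = 0.0,
    tail_gc: float = 0.531,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """ESTs carrying a canonical SL and a planted relict cascade.

    ``depth_probs`` gives the probabilities of cascade depths ``0..len-1``;
    relict copy *r* (1-based, 5'→3') carries ``Binomial(15, r * rate)``
    substitutions, so identity decays with rank. With *n_transcripts* set,
    that many distinct templates are built and records are resampled from
    them with *resequencing_noise* per-base substitution probability
    (emulating redundant single-pass reads).
    """
    if not np.isclose(sum(depth_probs), 1.0):
        raise ValueError("depth_probs must sum to 1")
    if not (0.0 <= per_cycle_sub_rate <= 0.3):
        raise ValueError("per_cycle_sub_rate must be in [0, 0.3]")
    cfg = cfg or SLConfig()
    motif = cfg.relict_motif
    truth = SyntheticTruth(
        seed=seed,
        params={
            "kind": "sl_ests",
            "n": n,
            "depth_probs": list(depth_probs),
            "per_cycle_sub_rate": per_cycle_sub_rate,
            "n_transcripts": n_transcripts,
            "resequencing_noise": resequencing_noise,
        },
    )
    n_templates = n if n_transcripts is None else n_transcripts
    streams = np.random.SeedSequence(seed).spawn(max(n_templates, 1) + 1)
    templates: list[tuple[str, dict]] = []
    for t in range(n_templates):
        rng = np.random.default_rng(streams[t])
        depth = int(rng.choice(len(depth_probs), p=np.asarray(depth_probs)))
        sl = _resolve_iupac(rng, cfg.sl_consensus)
        parts = [sl]
        copy_subs: list[int] = []
        for rank in range(1, depth + 1):
            n_subs = int(rng.binomial(len(motif), min(1.0, rank * per_cycle_sub_rate)))
            parts.append(_mutate(rng, motif, n_subs))
            copy_subs.append(n_subs)
        tail_len = int(rng.integers(150, 401))
        parts.append(_random_seq(rng, tail_len, gc=tail_gc))
        parts.append(_non_a_guard(rng))
        body = "".join(parts)
        tail = _polya_tail(rng)
        seq = body + tail
        info = {
            "depth": depth,
            "copy_substitutions": copy_subs,
            "copy_identities": [
                (len(motif) - s) / len(motif) for s in copy_subs
            ],
            "polyA_start": len(body),
            "template": t,
        }
        templates.append((seq, info))
    records: list[SequenceRecord] = []
    if n_transcripts is None:
        for i, (seq, info) in enumerate(templates):
            rec_id = f"est{i:05d}"
            records.append(SequenceRecord(id=rec_id, seq=seq, source=Source.SYNTHETIC))
            truth.records[rec_id] = info
    else:
        rng = np.random.default_rng(streams[-1])
        for i in range(n):
            t = int(rng.integers(n_templates))
            seq, info = templates[t]
            n_err = int(rng.binomial(len(seq), resequencing_noise))
            noisy = _mutate(rng, seq, n_err)
            rec_id = f"est{i:05d}"
            records.append(SequenceRecord(id=rec_id, seq=noisy, source=Source.SYNTHETIC))
            truth.records[rec_id] = {**info, "template": t, "n_errors": n_err}
    return records, truth


# ---------------------------------------------------------------------------
# GSS clone-end reads


def _tandem_read(
    rng: np.random.Generator,
    unit: str,
    length: int,
    divergence: tuple[float, float],
    divergent_copy_prob: float,
) -> tuple[str, dict]:
    p = len(unit)
    phase = int(rng.integers(p))
    n_copies = length // p + 2
    copies = []
    divergences = []
    for _ in range(n_copies):
        if rng.random() < divergent_copy_prob:
            rate = rng.uniform(*divergence)
            n_subs = int(rng.binomial(p, rate))
        else:
            n_subs = 0
        copies.append(_mutate(rng, unit, n_subs))
        divergences.append(n_subs / p)
    seq = "".join(copies)[phase : phase + length]
    info = {"phase": phase, "copy_divergences": divergences, "n_full_units": length // p}
    if rng.random() < 0.5:
        seq = revcomp(seq)
        info["strand"] = "-"
    else:
        info["strand"] = "+"
    return seq, info


def generate_gss_reads(
    n: int,
    length_range: tuple[int, int] = (300, 1200),
    composition: Mapping[str, float] | None = None,
    families: Mapping[str, str] | None = None,
    divergence: tuple[float, float] = (0.02, 0.12),
    divergent_copy_prob: float = 0.3,
    seed: int = 0,
    unique_gc: float = 0.60,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Clone-end reads from a planted feature mixture.

    *composition* maps category names — repeat-family names from
    *families*, plus ``simple_repeat``, ``low_complexity`` and ``unique``
    — to proportions summing to 1. Tandem reads are fully tiled with unit
    copies: each copy is exact with probability ``1 - divergent_copy_prob``
    and otherwise diverged at a rate drawn uniformly from *divergence*
    (emulating a major repeat type interspersed with 88-98%-identity
    copies); half the reads are reverse-complemented.
    """
    composition = dict(composition or DEFAULT_GSS_COMPOSITION)
    families = dict(families or REPEAT_UNITS)
    for name, unit in families.items():
        if len(unit) < 20:
            raise ValueError(f"family {name!r}: unit shorter than 20 bp")
    if not np.isclose(sum(composition.values()), 1.0):
        raise ValueError("composition proportions must sum to 1")
    categories = sorted(composition)
    probs = np.array([composition[c] for c in categories])
    truth = SyntheticTruth(
        seed=seed,
        params={
            "kind": "gss_reads",
            "n": n,
            "length_range": list(length_range),
            "composition": composition,
            "divergence": list(divergence),
            "divergent_copy_prob": divergent_copy_prob,
        },
    )
    records: list[SequenceRecord] = []
    if n == 0:
        return records, truth
    streams = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        category = categories[int(rng.choice(len(categories), p=probs))]
        info: dict = {"category": category, "length": length}
        if category in families:
            seq, extra = _tandem_read(
                rng, families[category], length, divergence, divergent_copy_prob
            )
            info["family"] = category
            info.update(extra)
        elif category == "simple_repeat":
            units, weights = zip(*_SIMPLE_UNITS)
            unit = units[int(rng.choice(len(units), p=np.array(weights)))]
            span = int(length * rng.uniform(0.6, 0.9))
            span -= span % len(unit)
            left = int(rng.integers(0, length - span + 1))
            core = (unit * (span // len(unit) + 1))[:span]
            seq = (
                _random_seq(rng, left, gc=unique_gc)
                + core
                + _random_seq(rng, length - left - span, gc=unique_gc)
            )
            info.update({"unit": unit, "span_start": left, "span_end": left + span})
        elif category == "low_complexity":
            labels = [s[0] for s in _LOWC_STYLES]
            style_probs = np.array([s[2] for s in _LOWC_STYLES])
            style = int(rng.choice(len(labels), p=style_probs))
            base_p = np.array(_LOWC_STYLES[style][1])
            seq = _BASES[rng.choice(4, size=length, p=base_p)].tobytes().decode("ascii")
            info["style"] = labels[style]
        elif category == "unique":
            seq = _random_seq(rng, length, gc=unique_gc)
        else:
            raise ValueError(f"unknown composition category {category!r}")
        rec_id = f"gss{i:05d}"
        records.append(SequenceRecord(id=rec_id, seq=seq, source=Source.SYNTHETIC))
        truth.records[rec_id] = info
    return records, truth


# ---------------------------------------------------------------------------
# CDS sets


def generate_cds_set(
    n: int,
    stop_probs: Sequence[float] = DEFAULT_STOP_PROBS,
    gc3: float = 0.7,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Transcripts with an ATG-initiated ORF, planted stop codon and polyA.

    *stop_probs* are the probabilities of (TAA, TAG, TGA); *gc3* is the
    probability that a codon's third position is G or C. Truth records the
    reading frame (offset of the ORF start modulo 3), the planted stop and
    the polyA start.
    """
    if not np.isclose(sum(stop_probs), 1.0):
        raise ValueError("stop_probs must sum to 1")
    truth = SyntheticTruth(
        seed=seed,
        params={"kind": "cds_set", "n": n, "stop_probs": list(stop_probs), "gc3": gc3},
    )
    records: list[SequenceRecord] = []
    if n == 0:
        return records, truth
    streams = np.random.SeedSequence(seed).spawn(n)
    stops = ("TAA", "TAG", "TGA")
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        # short 5' UTR (< one codon) so no spurious in-frame stop precedes
        # the ORF; the reading frame is still non-trivial
        utr5 = _random_seq(rng, int(rng.integers(0, 3)))
        n_codons = int(rng.integers(50, 201))
        codons = []
        while len(codons) < n_codons:
            first_two = _BASES[rng.integers(0, 4, size=2)].tobytes().decode("ascii")
            if rng.random() < gc3:
                third = "GC"[int(rng.integers(2))]
            else:
                third = "AT"[int(rng.integers(2))]
            codon = first_two + third
            if codon in stops:
                continue
            codons.append(codon)
        stop = stops[int(rng.choice(3, p=np.asarray(stop_probs)))]
        # the 3' UTR is at least one motif-scan window (60 bp) long, so the
        # polyA-proximal window is free of coding signal (stop codons)
        utr3 = _random_seq(rng, int(rng.integers(60, 121))) + _non_a_guard(rng)
        body = utr5 + "ATG" + "".join(codons) + stop + utr3
        seq = body + _polya_tail(rng)
        rec_id = f"cds{i:05d}"
        records.append(SequenceRecord(id=rec_id, seq=seq, source=Source.SYNTHETIC))
        truth.records[rec_id] = {
            "frame": len(utr5) % 3,
            "orf_start": len(utr5),
            "stop_codon": stop,
            "polyA_start": len(body),
        }
    return records, truth
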