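import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinogss.seq_core import Interval, SequenceRecord, ungapped_identity
from dinogss.tandem_arrays import (
    REPEAT_UNITS,
    RepeatFamily,
    TandemArray,
    annotate_arrays,
    detect_period,
    estimate_family_fraction,
    extract_unit_consensus,
    group_families,
    in_silico_digest,
    shared_segment,
)
from dinogss.synthetic_data import generate_gss_reads

from conftest import random_dna


def _mutate_at_rate(rng, seq, rate):
    arr = bytearray(seq, "ascii")
    n = int(round(rate * len(arr)))
    for pos in rng.choice(len(arr), size=n, replace=False):
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return arr.decode("ascii")


class TestDetectPeriod:
    def test_exact_survey_unit(self):
        assert detect_period(REPEAT_UNITS["repeat1"] * 5) == 97

    def test_random_sequence_none_and_oracle_agrees(self, rng):
        seq = random_dna(rng, 500)
        assert detect_period(seq) is None
        # exhaustive oracle: no lag reaches the 0.85 floor
        best = max(
            ungapped_identity(seq[: len(seq) - p], seq[p:])
            for p in range(20, 251)
        )
        assert best < 0.85

    def test_noisy_copies_report_unit_length(self, rng):
        unit = random_dna(rng, 64)
        copies = [_mutate_at_rate(rng, unit, 0.05) for _ in range(4)]
        assert detect_period("".join(copies)) == 64

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(20, 300), st.integers(3, 6), st.randoms(use_true_random=False))
    def test_exact_array_property(self, unit_len, k, rand):
        unit = "".join(rand.choice("ACGT") for _ in range(unit_len))
        if detect_period(unit, min_p=1, max_p=unit_len - 1, min_identity=0.9):
            return  # degenerate unit, itself periodic
        assert detect_period(unit * k) == unit_len


class TestExtractUnitConsensus:
    def test_exact_array(self):
        unit = REPEAT_UNITS["repeat2"]
        consensus, identities = extract_unit_consensus(unit * 5, 79)
        assert consensus == unit
        assert identities == [1.0] * 5

    def test_divergent_copy_flagged(self, rng):
        unit = REPEAT_UNITS["repeat3"]
        copies = [unit] * 4
        copies[2] = _mutate_at_rate(rng, unit, 0.10)
        consensus, identities = extract_unit_consensus("".join(copies), 88)
        assert consensus == unit
        assert identities[2] == pytest.approx(0.90, abs=0.03)
        assert all(i == 1.0 for n, i in enumerate(identities) if n != 2)

    def test_majority_vote_recovers_unit_from_noise(self, rng):
        unit = random_dna(rng, 80)
        copies = [_mutate_at_rate(rng, unit, 0.02) for _ in range(6)]
        consensus, _ = extract_unit_consensus("".join(copies), 80)
        assert consensus == unit

    def test_fewer_than_two_units_error(self):
        with pytest.raises(ValueError):
            extract_unit_consensus("ACGT" * 10, 30)


class TestAnnotateArrays:
    def test_embedded_array_found(self, rng):
        unit = REPEAT_UNITS["repeat2"]
        seq = random_dna(rng, 100) + unit * 4 + random_dna(rng, 100)
        arrays = annotate_arrays(SequenceRecord(id="r", seq=seq))
        assert len(arrays) == 1
        a = arrays[0]
        assert a.unit_length == 79
        assert a.n_units in (3, 4, 5)
        assert abs(a.span.start - 100) <= 79
        assert abs(a.span.end - (100 + 4 * 79)) <= 79

    def test_pure_random_empty(self, rng):
        for _ in range(5):
            rec = SequenceRecord(id="r", seq=random_dna(rng, 800))
            assert annotate_arrays(rec) == []

    def test_two_arrays_separated(self, rng):
        seq = (
            REPEAT_UNITS["repeat1"] * 3
            + random_dna(rng, 200)
            + REPEAT_UNITS["repeat2"] * 3
        )
        arrays = annotate_arrays(SequenceRecord(id="r", seq=seq))
        assert len(arrays) == 2
        assert [a.unit_length for a in arrays] == [97, 79]

    def test_simple_repeat_spans_not_reported_as_arrays(self, rng):
        seq = random_dna(rng, 100) + "CACG" * 50 + random_dna(rng, 100)
        assert annotate_arrays(SequenceRecord(id="r", seq=seq)) == []


class TestEstimateFamilyFraction:
    def _family(self, n_units, unit_len, record_id="c1"):
        unit = "ACGT" * (unit_len // 4)
        return RepeatFamily(
            family_id="f",
            unit_consensus=unit,
            arrays=[
                TandemArray(
                    record_id=record_id,
                    span=Interval(0, n_units * unit_len),
                    unit_length=unit_len,
                    n_units=n_units,
                    unit_consensus=unit,
                    per_unit_identity=tuple([1.0] * n_units),
                )
            ],
        )

    def test_arithmetic(self):
        fam = self._family(10, 100)
        assert estimate_family_fraction(fam, {"c1": 5}, 100_000) == pytest.approx(5.0)

    def test_zero_arrays(self):
        fam = RepeatFamily(family_id="f", unit_consensus="ACGT" * 10, arrays=[])
        assert estimate_family_fraction(fam, None, 1000) == 0.0

    def test_linear_in_units_and_reads(self):
        f1 = estimate_family_fraction(self._family(5, 100), {"c1": 2}, 100_000)
        f2 = estimate_family_fraction(self._family(10, 100), {"c1": 2}, 100_000)
        f3 = estimate_family_fraction(self._family(5, 100), {"c1": 4}, 100_000)
        assert f2 == pytest.approx(2 * f1)
        assert f3 == pytest.approx(2 * f1)

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            estimate_family_fraction(self._family(1, 100), None, 0)

    def test_planted_three_family_recovery(self, rng):
        units = {
            "famA": random_dna(rng, 100),
            "famB": random_dna(rng, 90),
            "famC": random_dna(rng, 80),
        }
        planted = {"famA": 0.30, "famB": 0.10, "famC": 0.05, "unique": 0.55}
        reads, truth = generate_gss_reads(
            700, composition=planted, families=units, seed=17
        )
        arrays = []
        for rec in reads:
            arrays.extend(annotate_arrays(rec))
        families = group_families(arrays)
        total_bp = sum(len(r.seq) for r in reads)
        planted_bp = collections.Counter()
        for rec in reads:
            cat = truth.records[rec.id]["category"]
            if cat in units:
                planted_bp[cat] += len(rec.seq)
        recovered = sorted(
            (estimate_family_fraction(f, None, total_bp) for f in families),
            reverse=True,
        )[:3]
        expected = sorted(
            (100 * planted_bp[c] / total_bp for c in units), reverse=True
        )
        for rec_pct, exp_pct in zip(recovered, expected):
            assert rec_pct == pytest.approx(exp_pct, rel=0.10)


class TestSharedSegment:
    def test_survey_repeats_3_and_4(self):
        result = shared_segment(REPEAT_UNITS["repeat3"], REPEAT_UNITS["repeat4"])
        assert result is not None
        iv_a, iv_b, identity = result
        assert iv_a.length == 60
        assert identity == pytest.approx(56 / 60)
        assert (iv_a.start, iv_b.start) == (28, 0)

    def test_self_full_length(self):
        unit = REPEAT_UNITS["repeat1"]
        iv_a, iv_b, identity = shared_segment(unit, unit)
        assert iv_a.length == len(unit)
        assert identity == 1.0

    def test_random_units_none(self, rng):
        for _ in range(3):
            a, b = random_dna(rng, 88), random_dna(rng, 88)
            assert shared_segment(a, b, min_len=40) is None


class TestInSilicoDigest:
    def test_one_site_per_unit(self):
        unit = "A" * 40 + "GCGC" + "A" * 53  # 97 bp, one site
        frags = in_silico_digest(unit * 10, "GCGC")
        # nine full-unit fragments plus two terminal pieces summing to one unit
        assert len(frags) == 11
        assert frags.count(97) == 9
        terminal = [f for f in frags if f != 97]
        assert sum(terminal) == 97
        assert sum(frags) == 970

    def test_no_site_single_fragment(self):
        assert in_silico_digest("A" * 500, "GGCC") == [500]

    def test_matches_naive_oracle(self, rng):
        seq = random_dna(rng, 2000)
        site = "GATC"
        from dinogss.seq_core import revcomp

        cuts = set()
        for probe in {site, revcomp(site)}:
            for i in range(len(seq) - len(probe) + 1):
                if seq[i : i + len(probe)] == probe and i > 0:
                    cuts.add(i)
        bounds = [0, *sorted(cuts), len(seq)]
        oracle = sorted(b - a for a, b in zip(bounds, bounds[1:]))
        assert in_silico_digest(seq, site) == oracle

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=500))
    def test_fragments_partition_sequence(self, seq):
        assert sum(in_silico_digest(seq, "GATC")) == len(seq)

    def test_invalid_site(self):
        with pytest.raises(ValueError):
            in_silico_digest("ACGT" * 10, "GN")
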