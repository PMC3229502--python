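import collections
import random

import numpy as np
import pytest

from dinogss.repeat_census import (
    FeatureCensus,
    classify_repetitiveness,
    feature_census,
    find_low_complexity,
    find_simple_repeats,
    genome_size_from_pg,
    greedy_overlap_cluster,
    read_feature_labels,
    sample_fraction,
)
from dinogss.seq_core import SequenceRecord, revcomp
from dinogss.synthetic_data import generate_gss_reads
from dinogss.tandem_arrays import annotate_arrays

from conftest import random_dna


def _noisy(rng, seq, rate):
    arr = bytearray(seq, "ascii")
    for pos in rng.choice(len(arr), size=int(rate * len(arr)), replace=False):
        choices = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return arr.decode("ascii")


class TestGreedyOverlapCluster:
    def test_identical_reads_one_cluster(self, rng):
        seq = random_dna(rng, 600)
        reads = [SequenceRecord(id=f"r{i}", seq=seq) for i in range(10)]
        clusters = greedy_overlap_cluster(reads)
        assert len(clusters) == 1 and len(clusters[0]) == 10

    def test_noisy_family_plus_singletons(self, rng):
        template = random_dna(rng, 800)
        reads = [
            SequenceRecord(id=f"fam{i:02d}", seq=_noisy(rng, template, 0.02))
            for i in range(25)
        ] + [
            SequenceRecord(id=f"uni{i:02d}", seq=random_dna(rng, 700))
            for i in range(30)
        ]
        clusters = greedy_overlap_cluster(reads)
        sizes = sorted((len(c) for c in clusters), reverse=True)
        assert sizes == [25] + [1] * 30
        big = next(c for c in clusters if len(c) == 25)
        assert all(rid.startswith("fam") for rid in big)

    def test_minimum_overlap_boundary(self, rng):
        base = random_dna(rng, 200)
        just_short = SequenceRecord(id="b", seq=base[101:] + random_dna(rng, 150))
        long_enough = SequenceRecord(id="c", seq=base[100:] + random_dna(rng, 150))
        a = SequenceRecord(id="a", seq=base)
        assert len(greedy_overlap_cluster([a, just_short])) == 2  # 99 bp overlap
        assert len(greedy_overlap_cluster([a, long_enough])) == 1  # 100 bp overlap

    def test_reverse_complement_overlap_found(self, rng):
        seq = random_dna(rng, 500)
        reads = [
            SequenceRecord(id="f", seq=seq),
            SequenceRecord(id="r", seq=revcomp(seq)),
        ]
        assert len(greedy_overlap_cluster(reads)) == 1

    def test_partition_and_permutation_invariance(self, rng):
        reads, _ = generate_gss_reads(80, seed=23)
        clusters = greedy_overlap_cluster(reads)
        ids = sorted(i for c in clusters for i in c)
        assert ids == sorted(r.id for r in reads)
        shuffled = reads[:]
        random.Random(99).shuffle(shuffled)
        clusters2 = greedy_overlap_cluster(shuffled)
        assert sorted(map(tuple, clusters)) == sorted(map(tuple, clusters2))


class TestClassifyRepetitiveness:
    def test_boundary_at_twenty_reads(self):
        clusters = [[f"a{i}" for i in range(21)], [f"b{i}" for i in range(20)], ["c"]]
        cats = classify_repetitiveness(clusters)
        assert cats["a0"] == "highly_repetitive"
        assert cats["b0"] == "repetitive"
        assert cats["c"] == "unique"

    def test_planted_family_sizes(self, rng):
        template = random_dna(rng, 600)
        reads = [
            SequenceRecord(id=f"big{i:02d}", seq=_noisy(rng, template, 0.01))
            for i in range(25)
        ]
        small_template = random_dna(rng, 500)
        reads += [SequenceRecord(id=f"sm{i}", seq=_noisy(rng, small_template, 0.01)) for i in range(3)]
        reads += [SequenceRecord(id=f"un{i:02d}", seq=random_dna(rng, 550)) for i in range(10)]
        cats = classify_repetitiveness(greedy_overlap_cluster(reads))
        assert all(cats[f"big{i:02d}"] == "highly_repetitive" for i in range(25))
        assert all(cats[f"sm{i}"] == "repetitive" for i in range(3))
        assert all(cats[f"un{i:02d}"] == "unique" for i in range(10))


class TestSimpleRepeats:
    def test_embedded_cacg_run(self, rng):
        seq = random_dna(rng, 120) + "CACG" * 6 + random_dna(rng, 120)
        calls = find_simple_repeats(seq)
        assert len(calls) == 1
        interval, unit = calls[0]
        assert unit == "ACGC"  # CACG in minimal rotation
        assert interval.length >= 24 - 3

    def test_dinucleotide_unit_not_mononucleotide(self):
        calls = find_simple_repeats("G" * 30 + "AT" * 10 + "C" * 30)
        units = {u for _, u in calls}
        assert "AT" in units

    def test_random_sequence_low_background(self, rng):
        total = 0
        flagged = 0
        for _ in range(5):
            seq = random_dna(rng, 1000)
            total += len(seq)
            flagged += sum(iv.length for iv, _ in find_simple_repeats(seq))
        assert flagged / total < 0.05


class TestLowComplexity:
    def test_homopolymer(self):
        calls = find_low_complexity("C" * 100)
        assert len(calls) == 1
        assert calls[0][1] == "C-rich"

    def test_ga_repeat(self):
        calls = find_low_complexity("GA" * 100)
        assert calls and calls[0][1] in ("GA-rich", "AG-rich")

    def test_uniform_random_mostly_clean(self, rng):
        seq = random_dna(rng, 10_000)
        flagged = sum(iv.length for iv, _ in find_low_complexity(seq))
        assert flagged / len(seq) < 0.01


class TestFeatureCensus:
    def test_survey_table_arithmetic(self):
        # the published census: highly repetitive reads cover 3,712,171 bp
        # of a 6,208,876 bp sample and 8,898,763 bp of summed feature bp
        tallies = {
            "genes": (16, 12366),
            "virus": (1, 610),
            "highly_repetitive": (1204, 3712171),
            "repetitive": (722, 802600),
            "LTR_retrotransposons": (8, 5709),
            "DNA_transposons": (5, 3567),
            "snRNA": (22, 27131),
            "scRNA": (1, 773),
            "rRNA": (4, 3503),
            "tRNA_derived": (299, 1301387),
            "satellites": (5, 4852),
            "simple_repeats": (1452, 1145806),
            "low_complexity": (739, 677401),
            "no_feature": (2871, 1200887),
        }
        census = FeatureCensus.from_tallies(tallies, actual_total_bp=6_208_876)
        assert census.pie_total_bp == 8_898_763
        assert round(census.pct("highly_repetitive", "actual"), 2) == 59.79
        assert round(census.pct("highly_repetitive", "pie"), 2) == 41.72
        assert census.table["pct_pie"].sum() == pytest.approx(100.0)

    def test_single_read_single_feature(self):
        reads = [SequenceRecord(id="r", seq="ACGT" * 25)]
        census = feature_census(reads, {"r": ["genes"]})
        assert census.pct("genes", "pie") == 100.0
        assert census.pct("genes", "actual") == 100.0

    def test_unlabelled_reads_fall_into_no_feature(self, rng):
        reads = [SequenceRecord(id=f"r{i}", seq=random_dna(rng, 100)) for i in range(4)]
        census = feature_census(reads, {"r0": ["x"]})
        assert census.pct("no_feature", "actual") == pytest.approx(75.0)

    def test_exclusive_categories_sum_to_100(self, rng):
        reads, _ = generate_gss_reads(60, seed=31)
        cats = classify_repetitiveness(greedy_overlap_cluster(reads))
        census = feature_census(reads, {rid: [c] for rid, c in cats.items()})
        assert census.table["pct_actual"].sum() == pytest.approx(100.0)

    def test_planted_composition_recovered(self):
        planted = {
            "repeat4": 0.50,
            "simple_repeat": 0.15,
            "low_complexity": 0.10,
            "unique": 0.25,
        }
        reads, truth = generate_gss_reads(400, composition=planted, seed=41)
        annotations = {}
        for rec in reads:
            spans = [a.span for a in annotate_arrays(rec)]
            annotations[rec.id] = read_feature_labels(rec, spans)
        census = feature_census(reads, annotations)
        n = len(reads)
        planted_reads = collections.Counter(
            t["category"] for t in truth.records.values()
        )
        pairs = [
            ("tandem_array", planted_reads["repeat4"]),
            ("simple_repeats", planted_reads["simple_repeat"]),
        ]
        for feature, expected_reads in pairs:
            row = census.table[census.table["feature"] == feature]
            observed = int(row.iloc[0]["n_reads"]) if not row.empty else 0
            assert observed == pytest.approx(expected_reads, rel=0.15)


class TestGenomeArithmetic:
    def test_size_formula(self):
        assert genome_size_from_pg(1.0) == pytest.approx(9.21e8)

    def test_errors(self):
        with pytest.raises(ValueError):
            genome_size_from_pg(0)
        with pytest.raises(ValueError):
            sample_fraction(0, 114.9)

    def test_fraction_linear_in_sample(self):
        assert sample_fraction(2_000_000, 10.0) == pytest.approx(
            2 * sample_fraction(1_000_000, 10.0)
        )
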