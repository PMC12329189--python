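import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amfgen.filtering import (
    DereplicatedSequence,
    cluster_greedy,
    cluster_table,
    dereplicate,
    expected_errors,
    filter_reads,
    pairwise_identity,
    remove_rare,
)
from amfgen.io_formats import ReadRecord


def _read(seq, q=40, rid="r"):
    return ReadRecord(rid, seq, (q,) * len(seq))


class TestExpectedErrors:
    @pytest.mark.parametrize(
        "quals, expected",
        [
            ((20,) * 10, 0.1),
            ((0,), 1.0),
            ((10, 20, 30), 0.111),
            ((), 0.0),
        ],
    )
    def test_values(self, quals, expected):
        assert expected_errors(quals) == pytest.approx(expected, abs=5e-4)

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            expected_errors([10, -1])


class TestFilterReads:
    def test_length_boundary(self):
        retained, stats = filter_reads([_read("A" * 169), _read("A" * 170)])
        assert [len(r) for r in retained] == [170]
        assert stats.n_short == 1

    def test_ee_boundary_inclusive(self):
        # a read at EXACTLY the expected-error bound is retained
        # ("more than one" expected error is strict >)
        read = _read("A" * 170, q=20)
        ee = expected_errors(read.qualities)
        retained, _ = filter_reads([read], max_ee=ee)
        assert retained == [read]
        rejected, stats = filter_reads([read], max_ee=ee - 1e-12)
        assert rejected == [] and stats.n_high_ee == 1

    def test_low_quality_rejected(self):
        read = _read("A" * 250, q=2)
        assert 250 * 10 ** (-0.2) > 1
        retained, stats = filter_reads([read])
        assert retained == [] and stats.n_high_ee == 1

    def test_no_thresholds_is_identity(self):
        reads = [_read("ACGT", q=2, rid="a"), _read("A" * 300, rid="b")]
        retained, _ = filter_reads(reads, min_length=0, max_ee=math.inf)
        assert retained == reads


class TestDereplicate:
    def test_groups_and_order(self):
        reads = {"s": [_read("ACGT"), _read("ACGT"), _read("ACGA")]}
        out = dereplicate(reads)
        assert [(e.sequence, e.total_abundance) for e in out] == [
            ("ACGT", 2),
            ("ACGA", 1),
        ]

    def test_cross_sample_provenance(self):
        reads = {"s1": [_read("ACGT")] * 3, "s2": [_read("ACGT")] * 4}
        (entry,) = dereplicate(reads)
        assert entry.total_abundance == 7
        assert entry.source_counts == {"s1": 3, "s2": 4}

    def test_empty(self):
        assert dereplicate({}) == []

    def test_tie_broken_lexicographically(self):
        reads = {"s": [_read("TTTT"), _read("AAAA")]}
        out = dereplicate(reads)
        assert [e.sequence for e in out] == ["AAAA", "TTTT"]


class TestRemoveRare:
    def test_boundary(self):
        entries = [
            DereplicatedSequence("AAAA", 3, {"s": 3}),
            DereplicatedSequence("CCCC", 2, {"s": 2}),
            DereplicatedSequence("GGGG", 1, {"s": 1}),
        ]
        assert [e.sequence for e in remove_rare(entries)] == ["AAAA"]

    def test_global_total_across_samples(self):
        # abundance 2 in each of two samples: global total 4, retained
        entry = DereplicatedSequence("AAAA", 4, {"s1": 2, "s2": 2})
        assert remove_rare([entry]) == [entry]


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("A" * 170, "A" * 170) == 1.0

    def test_mismatches_no_gaps(self):
        a = "A" * 170
        b = "C" * 20 + "A" * 150
        assert pairwise_identity(a, b) == pytest.approx(150 / 170)

    def test_terminal_gap_counted(self):
        assert pairwise_identity("ACGTACGT", "ACGTACG") == pytest.approx(7 / 8)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=28))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


def _entries(seq_abund):
    entries = [
        DereplicatedSequence(s, a, {"s": a}) for s, a in seq_abund
    ]
    return sorted(entries, key=lambda e: (-e.total_abundance, e.sequence))


class TestClusterGreedy:
    def test_all_identical(self):
        out = cluster_greedy(_entries([("ACGT" * 50, 5)]))
        assert out.n_clusters == 1

    def test_below_threshold_split(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=170))
        b = list(a)
        pos = rng.choice(170, size=20, replace=False)
        for i in pos:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        assert pairwise_identity(a, b) < 0.97
        out = cluster_greedy(_entries([(a, 5), (b, 3)]))
        assert out.n_clusters == 2

    def test_greedy_first_centroid_wins(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=170))

        def mutate(seq, n):
            s = list(seq)
            for i in rng.choice(170, size=n, replace=False):
                s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
            return "".join(s)

        b = mutate(a, 2)   # ~98.8% to a
        c = mutate(a, 10)  # ~94.1% to a
        assert pairwise_identity(b, c) < 0.97
        out = cluster_greedy(_entries([(a, 5), (b, 3), (c, 2)]))
        assert out.n_clusters == 2
        assert out.assignment[b] == out.assignment[a]
        assert out.assignment[c] != out.assignment[a]

    def test_threshold_one_equals_dereplication(self, rng):
        seqs = {"".join(rng.choice(list("ACGT"), size=40)) for _ in range(8)}
        entries = _entries([(s, 2) for s in seqs])
        out = cluster_greedy(entries, threshold=1.0)
        assert out.n_clusters == len(seqs)

    def test_threshold_zero_single_cluster(self, rng):
        seqs = {"".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)}
        out = cluster_greedy(_entries([(s, 1) for s in seqs]), threshold=1e-9)
        assert out.n_clusters == 1

    def test_unsorted_input_rejected(self):
        entries = [
            DereplicatedSequence("AAAA", 1, {"s": 1}),
            DereplicatedSequence("CCCC", 5, {"s": 5}),
        ]
        with pytest.raises(ValueError, match="sorted"):
            cluster_greedy(entries)

    def test_count_conservation_and_identity_invariant(self, rng):
        # every member within threshold of its centroid; total abundance conserved
        base = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
        seqs = set(base)
        for s in base:
            mutant = list(s)
            i = int(rng.integers(60))
            mutant[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[i]]
            seqs.add("".join(mutant))
        entries = _entries([(s, int(rng.integers(1, 9))) for s in seqs])
        out = cluster_greedy(entries, threshold=0.9)
        for e in entries:
            centroid = out.centroids[out.assignment[e.sequence]]
            assert pairwise_identity(e.sequence, centroid) >= 0.9
        table, _ = cluster_table(entries, out)
        assert table.total_reads() == sum(e.total_abundance for e in entries)
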