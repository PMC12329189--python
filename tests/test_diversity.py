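import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from amfgen.diversity import (
    expected_rarefied_richness,
    gamma_aggregate,
    mean_rarefied_richness,
    rarefy_once,
)
from amfgen.io_formats import OtuTable
from conftest import make_metadata


def brute_force_expected_richness(counts, depth):
    """Independent oracle: E[S] = sum_j (1 - C(N-N_j, n)/C(N, n))."""
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    return sum(
        1 - comb(total - c, depth, exact=True) / comb(total, depth, exact=True)
        for c in counts
    )


class TestRarefyOnce:
    def test_depth_equals_total(self, rng):
        counts = np.array([5, 3, 2])
        assert (rarefy_once(counts, 10, rng) == counts).all()

    def test_single_category(self, rng):
        assert rarefy_once(np.array([5, 0]), 3, rng).tolist() == [3, 0]

    def test_sums_and_bounds(self, rng):
        counts = np.array([7, 1, 4, 0, 9])
        for _ in range(20):
            sub = rarefy_once(counts, 6, rng)
            assert sub.sum() == 6
            assert (sub <= counts).all() and (sub >= 0).all()

    def test_depth_exceeds_total(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            rarefy_once(np.array([2, 2]), 5, rng)


class TestClosedForm:
    def test_two_even_otus(self):
        # 2 - 2*C(5,2)/C(10,2) = 2 - 2*10/45
        assert expected_rarefied_richness(np.array([5, 5]), 2) == pytest.approx(
            2 - 2 * 10 / 45
        )

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 40, size=6)
            total = counts.sum()
            if total == 0:
                continue
            depth = int(rng.integers(1, total + 1))
            assert expected_rarefied_richness(counts, depth) == pytest.approx(
                brute_force_expected_richness(counts.tolist(), depth)
            )


class TestMeanRarefiedRichness:
    def test_single_otu_exact(self):
        t = OtuTable(pd.DataFrame({"a": [50]}, index=["s1"]))
        (s,) = mean_rarefied_richness(t, iterations=20, depth=10, seed=0)
        assert s.mean_richness == 1.0

    def test_full_depth_is_observed_richness(self, small_table):
        out = mean_rarefied_richness(
            small_table, iterations=10, depth=None, seed=0
        )
        by_id = {s.unit_id: s for s in out}
        # depth = min total = 6; s2 has total 6 so it is returned exactly
        assert by_id["s2"].depth == 6
        assert by_id["s2"].mean_richness == 2.0
        assert by_id["s2"].sd_richness == 0.0

    def test_monte_carlo_matches_closed_form(self):
        t = OtuTable(pd.DataFrame({"a": [5], "b": [5]}, index=["s1"]))
        (s,) = mean_rarefied_richness(t, iterations=500, depth=2, seed=42)
        exact = expected_rarefied_richness(np.array([5, 5]), 2)
        se = s.sd_richness / np.sqrt(s.iterations)
        assert abs(s.mean_richness - exact) <= 3 * se

    def test_reproducible_and_order_invariant(self, small_table):
        a = mean_rarefied_richness(small_table, iterations=50, seed=7)
        b = mean_rarefied_richness(small_table, iterations=50, seed=7)
        assert [(s.unit_id, s.mean_richness) for s in a] == [
            (s.unit_id, s.mean_richness) for s in b
        ]
        # permuting rows leaves each sample's stream untouched
        permuted = OtuTable(small_table.counts.iloc[[2, 0, 1]])
        c = mean_rarefied_richness(permuted, iterations=50, seed=7)
        assert {s.unit_id: s.mean_richness for s in c} == {
            s.unit_id: s.mean_richness for s in a
        }

    def test_monotone_in_depth(self, rng):
        counts = pd.DataFrame(
            {f"o{j}": rng.integers(0, 60, size=1) for j in range(8)},
            index=["s1"],
        )
        t = OtuTable(counts)
        total = int(t.sample_depths().iloc[0])
        means = [
            mean_rarefied_richness(t, iterations=300, depth=d, seed=3)[0].mean_richness
            for d in sorted({max(1, total // 8), total // 2, total})
        ]
        assert means == sorted(means)


class TestGammaAggregate:
    def test_disjoint_union(self):
        t = OtuTable(
            pd.DataFrame(
                [[1, 1, 0, 0, 0], [0, 0, 3, 4, 5]],
                index=["s1", "s2"],
                columns=list("abcde"),
            )
        )
        meta = make_metadata([("s1", "spA", "M1"), ("s2", "spB", "M1")])
        agg = gamma_aggregate(t, meta)
        assert agg.sample_ids == ["M1"]
        assert int((agg.counts.loc["M1"] > 0).sum()) == 5

    def test_elementwise_sum(self):
        t = OtuTable(
            pd.DataFrame(
                [[3, 0, 1], [2, 4, 0]], index=["s1", "s2"], columns=list("abc")
            )
        )
        meta = make_metadata([("s1", "spA", "M1"), ("s2", "spB", "M1")])
        agg = gamma_aggregate(t, meta)
        assert agg.counts.loc["M1"].tolist() == [5, 4, 1]

    def test_single_sample_mesocosm(self, small_table, small_metadata):
        agg = gamma_aggregate(small_table, small_metadata)
        assert agg.counts.loc["C02M1"].tolist() == small_table.counts.loc[
            "s3"
        ].tolist()

    def test_orphan_sample_errors(self, small_table):
        meta = make_metadata([("s1", "spA", "M1"), ("s2", "spB", "M1")])
        with pytest.raises(KeyError):
            gamma_aggregate(small_table, meta)

    def test_gamma_at_least_max_alpha(self, rng):
        counts = rng.integers(0, 30, size=(4, 6))
        t = OtuTable(
            pd.DataFrame(
                counts, index=[f"s{i}" for i in range(4)], columns=list("abcdef")
            )
        )
        meta = make_metadata([(f"s{i}", "spA", "M1") for i in range(4)])
        agg = gamma_aggregate(t, meta)
        assert int((agg.counts.loc["M1"] > 0).sum()) >= int(
            (t.counts > 0).sum(axis=1).max()
        )
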