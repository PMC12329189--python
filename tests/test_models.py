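import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special

from amfgen.models import (
    ModelCandidate,
    ModelSpec,
    dredge,
    enumerate_submodels,
    fit_lmm,
    fit_zib,
    marginality_violations,
    select_best,
)


def spec_of(*terms, response="y", family="gaussian"):
    return ModelSpec(response, frozenset(terms), family=family)


def brute_force_marginal_subsets(terms):
    """Oracle: enumerate every subset and keep the marginality-closed ones."""
    terms = [tuple(sorted(t)) for t in terms]
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            s = set(combo)
            ok = all(
                all(
                    tuple(sorted(sub)) in s
                    for k in range(1, len(t))
                    for sub in itertools.combinations(t, k)
                )
                for t in s
            )
            if ok:
                out.append(frozenset(s))
    return set(out)


class TestEnumerateSubmodels:
    def test_two_way(self):
        specs = enumerate_submodels(spec_of(("A",), ("B",), ("A", "B")))
        got = {s.fixed_terms for s in specs}
        assert got == {
            frozenset(),
            frozenset({("A",)}),
            frozenset({("B",)}),
            frozenset({("A",), ("B",)}),
            frozenset({("A",), ("B",), ("A", "B")}),
        }

    def test_single_term(self):
        assert len(enumerate_submodels(spec_of(("A",)))) == 2

    def test_three_way_matches_brute_force(self):
        terms = [
            ("A",), ("B",), ("C",),
            ("A", "B"), ("A", "C"), ("B", "C"),
            ("A", "B", "C"),
        ]
        specs = enumerate_submodels(spec_of(*terms))
        got = {s.fixed_terms for s in specs}
        expected = brute_force_marginal_subsets(terms)
        assert got == expected
        assert len(specs) == 19

    def test_null_and_maximal_present(self):
        maximal = spec_of(("A",), ("B",), ("A", "B"))
        specs = enumerate_submodels(maximal)
        assert frozenset() in {s.fixed_terms for s in specs}
        assert maximal.fixed_terms in {s.fixed_terms for s in specs}
        assert all(not marginality_violations(s.fixed_terms) for s in specs)

    def test_always_keep_pinned(self):
        specs = enumerate_submodels(
            spec_of(("A",), ("H",)), always_keep=[("H",)]
        )
        assert all(("H",) in s.fixed_terms for s in specs)
        assert len(specs) == 2

    def test_marginality_violation_rejected(self):
        with pytest.raises(ValueError, match="marginality"):
            spec_of(("A", "B"))


def cand(aic, df, tag):
    return ModelCandidate(spec_of((f"x{tag}",)), aic, df, pd.DataFrame())


def brute_force_select(cands):
    """Oracle: explicit filter + argmin."""
    best = min(c.aic for c in cands)
    window = [c for c in cands if c.aic - best < 2.0]
    window.sort(key=lambda c: (c.df, c.aic, c.spec.sort_key()))
    return window[0]


class TestSelectBest:
    def test_single_candidate(self):
        c = cand(10.0, 3, 0)
        assert select_best([c]) is c

    def test_strict_delta_window_and_lowest_df(self):
        cands = [cand(99.5, 6, 0), cand(100.0, 5, 1), cand(101.5, 4, 2)]
        # 101.5 - 99.5 = 2.0 fails strict < 2; df 5 wins in the window
        assert select_best(cands).df == 5

    def test_equal_aic_prefers_lower_df(self):
        cands = [cand(50.0, 4, 0), cand(50.0, 3, 1)]
        assert select_best(cands).df == 3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_matches_brute_force_on_random_lists(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            cands = [
                cand(float(np.round(rng.uniform(0, 20), 2)), int(rng.integers(1, 9)), i)
                for i in range(n)
            ]
            got = select_best(cands)
            want = brute_force_select(cands)
            assert (got.aic, got.df) == (want.aic, want.df)


def lmm_data(seed, n_groups=20, per_group=20, slope=2.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    x = rng.normal(size=n_groups * per_group)
    eff = rng.normal(0, 1.0, size=n_groups)
    y = slope * x + eff[g] + rng.normal(0, 1.0, size=len(x))
    return pd.DataFrame({"y": y, "x": x, "noise": rng.normal(size=len(x)),
                         "g": [f"g{i}" for i in g]})


RANDOM_G = (("group", "0 + C(g)"),)


class TestFitLmm:
    def test_slope_recovery(self):
        df = lmm_data(0)
        c = fit_lmm(ModelSpec("y", frozenset({("x",)}), RANDOM_G), df)
        row = c.fit_summary.set_index("term").loc["x"]
        assert abs(row["estimate"] - 2.0) <= 3 * row["se"]
        assert c.converged
        assert c.df == 2 + 1 + 1  # intercept + slope, 1 vc, residual

    def test_constant_response(self):
        df = lmm_data(1)
        df["y"] = 5.0
        c = fit_lmm(ModelSpec("y", frozenset({("x",)}), RANDOM_G), df)
        got = c.fit_summary.set_index("term")
        assert got.loc["Intercept", "estimate"] == pytest.approx(5.0, abs=1e-6)
        assert got.loc["x", "estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_noise_predictor_raises_aic_in_expectation(self):
        deltas = []
        for seed in range(15):
            df = lmm_data(seed, n_groups=10, per_group=10)
            small = fit_lmm(ModelSpec("y", frozenset({("x",)}), RANDOM_G), df)
            big = fit_lmm(
                ModelSpec("y", frozenset({("x",), ("noise",)}), RANDOM_G), df
            )
            deltas.append(big.aic - small.aic)
        assert np.mean(deltas) > 0

    def test_aic_reproducible(self):
        df = lmm_data(3)
        spec = ModelSpec("y", frozenset({("x",)}), RANDOM_G)
        assert fit_lmm(spec, df).aic == pytest.approx(fit_lmm(spec, df).aic, abs=1e-6)

    def test_dredge_selects_true_predictor(self):
        df = lmm_data(4, slope=2.0)
        maximal = ModelSpec(
            "y", frozenset({("x",), ("noise",), ("noise", "x")}), RANDOM_G
        )
        best, candidates = dredge(maximal, df)
        assert len(candidates) == 5
        assert ("x",) in best.spec.fixed_terms
        assert ("noise", "x") not in best.spec.fixed_terms


def zib_data(seed, n=500, pi=0.3, mu=0.4, phi=5.0, beta_x=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    zero = rng.random(n) < pi
    eta = special.logit(mu) + beta_x * x
    m = special.expit(eta)
    y = rng.beta(m * phi, (1 - m) * phi)
    y[zero] = 0.0
    return pd.DataFrame({"y": np.clip(y, 0, 1 - 1e-9), "x": x})


class TestFitZib:
    def test_parameter_recovery(self):
        df = zib_data(0)
        c = fit_zib(spec_of(("x",), family="zero_inflated_beta"), df)
        assert c.converged
        zi = c.fit_summary.set_index("term").loc["zi_intercept"]
        pi_hat = special.expit(zi["estimate"])
        # delta-method SE on the probability scale
        se_pi = zi["se"] * pi_hat * (1 - pi_hat)
        assert abs(pi_hat - 0.3) <= 3 * se_pi
        assert c.params["precision"] == pytest.approx(5.0, rel=0.5)

    def test_all_zero_response_flagged(self):
        df = pd.DataFrame({"y": np.zeros(50), "x": np.arange(50.0)})
        c = fit_zib(spec_of(("x",), family="zero_inflated_beta"), df)
        assert not c.converged

    def test_response_one_rejected(self):
        df = pd.DataFrame({"y": [0.5, 1.0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="shrinkage"):
            fit_zib(spec_of(("x",), family="zero_inflated_beta"), df)

    def test_null_covariate_coverage(self):
        covered = 0
        n_sim = 60
        for seed in range(n_sim):
            df = zib_data(seed, n=200, beta_x=0.0)
            c = fit_zib(spec_of(("x",), family="zero_inflated_beta"), df)
            row = c.fit_summary.set_index("term").loc["x"]
            lo = row["estimate"] - 1.96 * row["se"]
            hi = row["estimate"] + 1.96 * row["se"]
            covered += lo <= 0.0 <= hi
        assert covered / n_sim >= 0.9
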