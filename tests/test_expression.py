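"""Unit tests for the differential-expression screen components."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oncoscreen import (
    CountMatrix, GeneSet, apply_de_gates, benjamini_hochberg,
    ddct_relative_expression, differential_expression, estimate_size_factors,
    group_expression_comparison, overlap_test, simulate_counts,
    SimulationConfig,
)
from oncoscreen.expression import hypergeom_upper_tail


def brute_force_size_factors(counts):
    """Independent median-of-ratios computation, gene by gene."""
    counts = np.asarray(counts, dtype=float)
    keep = np.all(counts > 0, axis=1)
    ref = counts[keep]
    geo = np.array([math.exp(np.mean([math.log(v) for v in row])) for row in ref])
    factors = []
    for j in range(counts.shape[1]):
        factors.append(np.median([ref[i, j] / geo[i] for i in range(len(ref))]))
    return np.array(factors)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [5]]), (1, 4))
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_column_has_double_factor(self):
        base = np.array([[10, 10], [30, 30], [7, 7]], dtype=float)
        counts = np.column_stack([base, 2 * base[:, 0]])
        f = estimate_size_factors(counts)
        assert np.allclose(f[2] / f[0], 2.0)

    def test_matches_brute_force_on_random_matrix(self, rng):
        counts = rng.integers(1, 1000, size=(50, 6))
        assert np.allclose(estimate_size_factors(counts),
                           brute_force_size_factors(counts))

    def test_no_all_positive_gene_raises(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(counts)

    def test_cross_checked_against_pydeseq2(self, rng):
        """Independent route: pydeseq2's median-of-ratios normalization.

        pydeseq2 interpolates the median in log space, ours in linear
        space, so agreement is to ~1% at even gene counts rather than
        machine precision.
        """
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        import warnings as _w
        counts = rng.integers(1, 500, size=(41, 8))
        frame = pd.DataFrame(counts.T, index=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({"condition": ["a"] * 4 + ["b"] * 4},
                            index=frame.index)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            dds = pydeseq2.DeseqDataSet(counts=frame, metadata=meta,
                                        design="~condition", quiet=True)
            dds.fit_size_factors()
        ref = dds.obs["size_factors"].to_numpy()
        assert np.allclose(estimate_size_factors(counts), ref, rtol=0.01)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_step_up_formula(self, p, expected):
        assert np.allclose(benjamini_hochberg(p), expected)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, float("nan")])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjustment_is_monotone_step_up_and_idempotent_upward(self, p):
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in rank
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        # re-adjusting already-adjusted values never decreases any value
        again = benjamini_hochberg(adj)
        assert np.all(again >= adj - 1e-12)


class TestDifferentialExpression:
    def test_constant_gene_has_zero_lfc(self):
        # flat genes dominate the size-factor median, so identical counts
        # across all samples yield exactly zero fold change
        counts = np.vstack([np.full(8, 50), np.full(8, 80), np.full(8, 20),
                            [10, 20, 30, 40, 35, 25, 15, 45]])
        cm = CountMatrix(["flat1", "flat2", "flat3", "noisy"],
                         [f"s{i}" for i in range(8)],
                         counts, ["a"] * 4 + ["b"] * 4)
        res = differential_expression(cm)
        assert res.loc["flat1", "log2_fold_change"] == pytest.approx(0.0)
        assert res.loc["flat1", "p_value"] == pytest.approx(1.0)

    def test_all_zero_gene_reported_untested(self):
        counts = np.vstack([np.zeros(8, dtype=int), np.full(8, 100)])
        cm = CountMatrix(["dead", "ok"], [f"s{i}" for i in range(8)],
                         counts, ["a"] * 4 + ["b"] * 4)
        res = differential_expression(cm)
        assert not res.loc["dead", "tested"]
        assert np.isnan(res.loc["dead", "p_value"])

    def test_planted_fourfold_recovered(self):
        cfg = SimulationConfig(seed=7, n_genes=500, samples_per_group=10,
                               de_fraction=0.1, lfc_effect=2.0, depth_mean=1e6)
        cm, truth = simulate_counts(cfg)
        res = differential_expression(cm)
        med_up = res.loc[sorted(truth.de_up), "log2_fold_change"].median()
        assert med_up == pytest.approx(2.0, abs=0.15)

    def test_log_t_engine_available(self):
        cfg = SimulationConfig(seed=3, n_genes=100, samples_per_group=5)
        cm, _ = simulate_counts(cfg)
        res = differential_expression(cm, engine="log_t")
        assert res["p_value"].dropna().between(0, 1).all()


class TestDEGates:
    def _frame(self, rows):
        df = pd.DataFrame(rows, columns=["log2_fold_change", "p_adjusted"])
        df.index = [f"g{i}" for i in range(len(rows))]
        df["p_value"] = df["p_adjusted"]
        df["tested"] = True
        df["direction"] = "none"
        return df

    def test_fold_change_boundary_inclusive_alpha_exclusive(self):
        df = self._frame([(1.0, 0.049), (1.0, 0.05), (0.999, 0.01)])
        up, down = apply_de_gates(df, lfc_min=1.0, alpha=0.05)
        assert up.members == {"g0"}  # lfc exactly 1.0 is in; padj 0.05 is out
        assert down.members == set()

    def test_down_needs_both_gates(self):
        df = self._frame([(-3.0, 0.2), (-1.5, 0.001)])
        up, down = apply_de_gates(df)
        assert down.members == {"g1"}
        assert up.members == set()

    def test_empty_input_gives_empty_sets(self):
        df = self._frame([])
        up, down = apply_de_gates(df)
        assert len(up) == 0 and len(down) == 0


def enumerated_overlap_p(universe, size_a, size_b, k):
    """Exhaustive enumeration over all C(universe, size_b) draws."""
    a = set(range(size_a))
    total = hits = 0
    for draw in itertools.combinations(range(universe), size_b):
        total += 1
        if len(a & set(draw)) >= k:
            hits += 1
    return hits / total


class TestOverlapTest:
    def test_worked_example_from_rbp_screen(self):
        """223 and 275 upregulated sets, 58 shared, universe of 1542 RBPs."""
        a = GeneSet("gbm", {f"g{i}" for i in range(223)}, 1542)
        b = GeneSet("gsc", {f"g{i}" for i in range(58)}
                    | {f"h{i}" for i in range(217)}, 1542)
        inter, p = overlap_test(a, b)
        assert len(inter) == 58
        assert 0.00055 <= p <= 0.00065

    def test_identical_sets_give_minimal_tail(self):
        a = {f"g{i}" for i in range(4)}
        inter, p = overlap_test(a, a, universe_size=10)
        assert inter.members == a
        # minimal achievable tail for |A|=|B|=4 in a universe of 10
        assert p == pytest.approx(1 / math.comb(10, 4) * math.comb(4, 4)
                                  * math.comb(6, 0), rel=1e-9)

    def test_matches_enumeration_universe_10(self):
        a = {f"g{i}" for i in range(4)}
        b = {"g0", "g1", "g2", "x0", "x1"}
        _, p = overlap_test(a, b, universe_size=10)
        assert p == pytest.approx(enumerated_overlap_p(10, 4, 5, 3), abs=1e-12)

    def test_set_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test({f"g{i}" for i in range(12)}, {"g1"}, universe_size=10)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_exhaustive_enumeration_small_universes(self, data):
        n = data.draw(st.integers(2, 9))
        ka = data.draw(st.integers(0, n))
        kb = data.draw(st.integers(0, n))
        a = {f"g{i}" for i in range(ka)}
        b = {f"g{i}" for i in data.draw(
            st.permutations(range(n)))[:kb]}
        inter, p = overlap_test(a, b, universe_size=n)
        expected = enumerated_overlap_p(n, ka, kb, len(inter.members)) if kb else 1.0
        assert p == pytest.approx(expected, abs=1e-12)


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        (ma, mb), p = group_expression_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_groups(self):
        (ma, mb), p = group_expression_comparison([1, 2, 3], [4, 5, 6])
        assert (ma, mb) == (2.0, 5.0)
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = group_expression_comparison(a, b)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_expression_comparison([], [1.0])


class TestDdct:
    @pytest.mark.parametrize(
        "ct, expected",
        [
            ((20, 20, 20, 20), 1.0),
            ((21, 20, 20, 20), 0.5),
            ((25, 20, 22, 20), 0.125),
        ],
    )
    def test_formula(self, ct, expected):
        assert ddct_relative_expression(*ct) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_expression(float("inf"), 20, 20, 20)
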