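"""Rank tests against enumeration oracles; ART ANOVA construction properties."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from serotonin_presynapse import (
    art_align,
    art_anova,
    art_posthoc,
    chi_square_independence,
    kruskal_wallis,
    mann_whitney,
    normality_screen,
)
from serotonin_presynapse.stats import alignment_diagnostics, significance_label


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def kw_oracle(groups):
    """Direct Σ-formula Kruskal-Wallis H with mid-ranks and tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def mw_enumeration(x, y):
    """Exact U null distribution by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            for idx in itertools.combinations(range(n), n1)
        ]
    )
    p = 2 * min((us >= u_obs).mean(), (us <= u_obs).mean())
    return u_obs, min(1.0, p)


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0, abs=1e-10)
        assert res.df == 2

    def test_degenerate_identical_values(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_agrees_with_oracle_on_all_small_instances(self):
        """Statistic matches the Σ-formula oracle for every random instance
        with total n <= 8, ties included."""
        rng = np.random.default_rng(10)
        layouts = [(2, 2), (2, 3), (3, 3), (2, 2, 2), (2, 3, 3), (2, 2, 4)]
        for sizes in layouts:
            for _ in range(20):
                groups = [rng.integers(0, 4, size=s).astype(float) for s in sizes]
                if np.all(np.concatenate(groups) == groups[0][0]):
                    continue
                res = kruskal_wallis(groups)
                assert res.statistic == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_multisets_give_half_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, list(x))
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_exact_p_matches_enumeration_on_small_instances(self):
        rng = np.random.default_rng(11)
        for n1, n2 in [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (3, 5), (2, 6)]:
            for _ in range(10):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                u, p = mw_enumeration(x, y)
                res = mann_whitney(x, y)
                assert "exact" in res.method
                assert res.statistic == pytest.approx(u, abs=1e-10)
                assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_tied_data_uses_midranks(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.integers(0, 3, size=4).astype(float)
            y = rng.integers(0, 3, size=4).astype(float)
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            u = ranks[:4].sum() - 4 * 5 / 2
            assert mann_whitney(x, y).statistic == pytest.approx(u, abs=1e-10)


class TestChiSquare:
    def test_reproduces_published_sex_table(self):
        """Yates-corrected chi-square on the 2x2 sex-by-attempt-status
        counts (118/57 vs 140/77)."""
        res = chi_square_independence([[118, 57], [140, 77]], yates=True)
        assert round(res.statistic, 2) == 0.25
        assert res.p_value == pytest.approx(0.619, abs=0.002)
        assert res.df == 1

    def test_perfect_independence(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_expected_table_gives_zero(self):
        # rows proportional -> observed equals expected
        res = chi_square_independence([[20, 40], [10, 20]], yates=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [5, 5]])


class TestNormalityScreen:
    def test_calibration_on_normal_samples(self):
        rng = np.random.default_rng(13)
        verdicts = [
            "normal" in normality_screen(rng.standard_normal(500)).method
            for _ in range(100)
        ]
        assert np.mean(verdicts) >= 0.90

    def test_detects_exponential(self):
        rng = np.random.default_rng(14)
        verdicts = [
            "non-normal" in normality_screen(rng.exponential(size=500)).method
            for _ in range(100)
        ]
        assert np.mean(verdicts) >= 0.99

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normality_screen([1.0] * 10)
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])


def _factorial(n_per_cell=4):
    a = np.repeat(["a1", "a2", "a3"], 2 * n_per_cell)
    b = np.tile(np.repeat(["b1", "b2"], n_per_cell), 3)
    return a, b


class TestARTAlignment:
    def test_pure_main_effect_leaves_no_trace_elsewhere(self):
        """Stripping the A effect: B- and interaction-aligned responses have
        equal cell means on noiseless additive data."""
        a, b = _factorial()
        y = np.where(a == "a1", 0.0, np.where(a == "a2", 3.0, 7.0))
        diag = alignment_diagnostics(y, a, b)
        assert diag["B"] <= 1e-10
        assert diag["A:B"] <= 1e-10

    def test_constant_response_aligns_constant(self):
        a, b = _factorial()
        aligned = art_align(np.full(len(a), 2.5), a, b)
        for arr in aligned.values():
            assert np.allclose(arr, arr[0])

    def test_aligned_columns_sum_to_zero(self):
        rng = np.random.default_rng(15)
        a, b = _factorial()
        y = rng.normal(size=len(a))
        for effect, arr in art_align(y, a, b).items():
            assert abs(arr.mean()) <= 1e-10, effect

    def test_empty_cell_rejected(self):
        a = np.array(["a1", "a1", "a2", "a2"])
        b = np.array(["b1", "b1", "b1", "b2"])
        with pytest.raises(ValueError, match="empty cell"):
            art_align(np.arange(4.0), a, b)


class TestARTAnova:
    def test_three_effects_with_factorial_dfs(self):
        rng = np.random.default_rng(16)
        a, b = _factorial()
        res = art_anova(rng.normal(size=len(a)), a, b, a_name="diag", b_name="sa")
        assert set(res.effects) == {"diag", "sa", "diag:sa"}
        assert res.effects["diag"].df == (2, len(a) - 6)
        assert res.effects["sa"].df == (1, len(a) - 6)
        assert res.effects["diag:sa"].df == (2, len(a) - 6)
        for tr in res.effects.values():
            assert tr.statistic >= 0.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(17)
        a, b = _factorial()
        y = rng.normal(size=len(a))
        perm = rng.permutation(len(a))
        r1 = art_anova(y, a, b)
        r2 = art_anova(y[perm], a[perm], b[perm])
        for k in r1.effects:
            assert r1.effects[k].statistic == pytest.approx(
                r2.effects[k].statistic, rel=1e-9
            )

    def test_injected_main_effect_detected_interaction_quiet(self):
        rng = np.random.default_rng(18)
        a, b = _factorial(n_per_cell=10)
        p_a, p_int = [], []
        for _ in range(50):
            y = rng.normal(size=len(a)) + np.where(a == "a3", 2.0, 0.0)
            res = art_anova(y, a, b)
            p_a.append(res.effects["A"].p_value)
            p_int.append(res.effects["A:B"].p_value)
        assert np.median(p_a) < 1e-4
        # no injected interaction: rejection stays near the nominal level
        assert np.mean(np.array(p_int) < 0.05) <= 0.15

    def test_effect_scaling_never_raises_median_p(self):
        rng = np.random.default_rng(19)
        a, b = _factorial(n_per_cell=8)
        medians = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            ps = []
            for _ in range(40):
                y = rng.normal(size=len(a)) + np.where(a == "a1", shift, 0.0)
                ps.append(art_anova(y, a, b).effects["A"].p_value)
            medians.append(np.median(ps))
        assert all(m2 <= m1 + 0.05 for m1, m2 in zip(medians, medians[1:]))

    def test_unbalanced_cells_supported(self):
        rng = np.random.default_rng(20)
        a = np.array(["x"] * 12 + ["y"] * 7 + ["x"] * 5 + ["y"] * 9)
        b = np.array(["u"] * 19 + ["v"] * 14)
        res = art_anova(rng.normal(size=len(a)), a, b)
        assert all(0 <= tr.p_value <= 1 for tr in res.effects.values())


class TestARTPosthoc:
    def test_three_level_factor_gives_three_contrasts(self):
        rng = np.random.default_rng(21)
        a, b = _factorial(n_per_cell=6)
        out = art_posthoc(rng.normal(size=len(a)), a, b, factor="A")
        assert len(out) == 3
        assert set(out.columns) >= {"group1", "group2", "p_adj", "direction"}

    def test_lowered_group_direction_flagged(self):
        rng = np.random.default_rng(22)
        a = np.repeat(["BD", "MDD", "SCH"], 40)
        b = np.tile(np.repeat(["SA", "NONSA"], 20), 3)
        y = rng.normal(size=len(a)) - np.where(a == "BD", 3.0, 0.0)
        out = art_posthoc(y, a, b, factor="A")
        row = out[(out["group1"] == "BD") & (out["group2"] == "SCH")].iloc[0]
        assert row["direction"] == "group1 lower"
        assert row["p_adj"] < 0.01

    def test_null_adjusted_p_roughly_uniform(self):
        rng = np.random.default_rng(23)
        a, b = _factorial(n_per_cell=8)
        ps = []
        for _ in range(60):
            out = art_posthoc(rng.normal(size=len(a)), a, b, factor="A")
            ps.extend(out["p_adj"].tolist())
        # Tukey-adjusted null p-values are stochastically >= uniform
        assert np.mean(np.array(ps) < 0.05) <= 0.08


class TestLabels:
    def test_significance_bands(self):
        assert significance_label(0.01) == "significant"
        assert significance_label(0.07) == "trend"
        assert significance_label(0.2) == "ns"
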