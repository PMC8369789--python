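"""Atom-percent formula, ISA mixture fit, and group-statistics ANOVAs.

Independent oracles: scipy.stats.f_oneway for the one-way ANOVA and a
statsmodels OLS anova_lm fit for the two-way decomposition; the ISA fit is
checked by forward-model self-consistency.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipotrace.lipogenesis_metrics import (
    EVEN_K,
    PalmitateMID,
    anova_one_way,
    anova_two_way,
    atom_percent,
    fit_isa,
    isa_doublet_model,
    total_de_novo,
)
from lipotrace.synthetic_data import true_mid_from_isa


def mid_from(parts: dict[int, float]) -> PalmitateMID:
    p = np.zeros(17)
    for k, v in parts.items():
        p[k] = v
    return PalmitateMID(p)


class TestAtomPercent:
    def test_fully_unlabeled(self):
        assert atom_percent(mid_from({0: 1.0})).atom_percent == 0.0

    def test_fully_labeled(self):
        assert atom_percent(mid_from({16: 1.0})).atom_percent == 1.0

    def test_hand_evaluated_example(self):
        """(0.3*2 + 0.2*4) / ((0.5 + 0.5) * 16) = 0.0875."""
        mid = mid_from({0: 0.5, 2: 0.3, 4: 0.2})
        assert atom_percent(mid).atom_percent == pytest.approx(0.0875, abs=1e-12)

    def test_odd_channels_excluded(self):
        """Odd-k mass changes neither numerator nor denominator."""
        with_odd = mid_from({0: 0.45, 1: 0.05, 2: 0.3, 3: 0.05, 4: 0.15})
        # even-only renormalized comparison: same even fractions, p0 scaled
        expected = (0.3 * 2 + 0.15 * 4) / ((0.45 + 0.3 + 0.15) * 16)
        assert atom_percent(with_odd).atom_percent == pytest.approx(expected, abs=1e-12)

    def test_all_odd_mass_is_error(self):
        with pytest.raises(ValueError):
            atom_percent(mid_from({1: 0.5, 3: 0.5}))

    def test_monotone_in_mass_shift(self):
        """Moving mass from lower to higher even k never decreases the result."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(9)
            p /= p.sum()
            parts = {0: p[0], **{k: p[i + 1] for i, k in enumerate(EVEN_K)}}
            base = atom_percent(mid_from(parts)).atom_percent
            lo, hi = sorted(rng.choice(list(EVEN_K), size=2, replace=False))
            moved = dict(parts)
            delta = moved[lo] * 0.5
            moved[lo] -= delta
            moved[hi] += delta
            assert atom_percent(mid_from(moved)).atom_percent >= base - 1e-12

    def test_gd_identity_on_grid(self):
        """Noiseless ISA-model MIDs satisfy atom_percent = g*D exactly."""
        for g in np.linspace(0, 1, 11):
            for d in np.linspace(0, 1, 11):
                mid = PalmitateMID(true_mid_from_isa(g, d))
                assert atom_percent(mid).atom_percent == pytest.approx(
                    g * d, abs=1e-9
                )


class TestTotalDeNovo:
    def test_labeled_share(self):
        mid = mid_from({0: 0.6, 2: 0.3, 4: 0.1})
        assert total_de_novo(mid) == pytest.approx(0.4, abs=1e-12)

    def test_matches_g_on_noiseless_model(self):
        mid = PalmitateMID(true_mid_from_isa(0.3, 0.6))
        # 1 - p0 overstates g only by the unlabeled de novo molecules
        q0_new = (1 - 0.6) ** 8
        expected = 0.3 * (1 - q0_new)
        assert total_de_novo(mid) == pytest.approx(expected, abs=1e-12)


class TestIsaFit:
    def test_doublet_model_is_mixture(self):
        q = isa_doublet_model(0.4, 0.7)
        assert q.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            q[1:], 0.4 * stats.binom.pmf(np.arange(1, 9), 8, 0.7), atol=1e-15
        )

    def test_recovers_exact_parameters(self):
        fit = fit_isa(PalmitateMID(true_mid_from_isa(0.5, 0.5)))
        assert fit.g == pytest.approx(0.5, abs=1e-6)
        assert fit.D == pytest.approx(0.5, abs=1e-6)
        assert fit.sse < 1e-12

    def test_saturated_labeling(self):
        fit = fit_isa(mid_from({16: 1.0}))
        assert fit.g == pytest.approx(1.0, abs=1e-6)
        assert fit.D == pytest.approx(1.0, abs=1e-6)

    def test_unlabeled_pool_flags_d(self):
        fit = fit_isa(mid_from({0: 1.0}))
        assert fit.g == pytest.approx(0.0, abs=1e-6)
        assert not fit.d_identifiable

    def test_degenerate_mid_is_error(self):
        with pytest.raises(ValueError):
            fit_isa(mid_from({1: 1.0}))

    def test_recovery_across_grid(self):
        for g, d in [(0.2, 0.8), (0.8, 0.2), (0.35, 0.55), (0.9, 0.9)]:
            fit = fit_isa(PalmitateMID(true_mid_from_isa(g, d)))
            assert fit.g == pytest.approx(g, abs=1e-5)
            assert fit.D == pytest.approx(d, abs=1e-5)


class TestOneWayAnova:
    def test_identical_groups(self):
        res = anova_one_way({"A": [1.0, 1.0], "B": [1.0, 1.0]})
        assert res.F == 0.0 and res.p == 1.0

    def test_hand_computed_f(self):
        """SSB = 1 (df 1), SSW = 1 (df 2) -> F = 2."""
        res = anova_one_way({"A": [0.0, 1.0], "B": [1.0, 2.0]})
        assert res.F == pytest.approx(2.0, abs=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(size=5) for g in "ABC"}
        shifted = {g: v + 17.3 for g, v in groups.items()}
        assert anova_one_way(groups).F == pytest.approx(
            anova_one_way(shifted).F, rel=1e-12
        )

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(2, 8))
            groups = {f"g{i}": rng.normal(i * 0.3, 1.0, size=n) for i in range(k)}
            res = anova_one_way(groups)
            F, p = stats.f_oneway(*groups.values())
            assert res.F == pytest.approx(F, rel=1e-9)
            assert res.p == pytest.approx(p, rel=1e-9)

    def test_zero_within_variance_flagged(self):
        res = anova_one_way({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert res.p == 0.0 and res.zero_within_variance

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_one_way({"A": [1.0], "B": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_one_way({"A": [1.0, 2.0]})


def balanced_table(rng, a_levels=4, b_levels=3, n=3, effects=None):
    rows = []
    for i in range(a_levels):
        for j in range(b_levels):
            mean = effects(i, j) if effects else rng.normal()
            for _ in range(n):
                rows.append({"isotopologue": f"m{2 * (i + 1)}", "group": f"g{j}",
                             "value": mean + rng.normal(scale=0.5)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_constant_cells_give_zero_f(self):
        rows = [{"isotopologue": a, "group": b, "value": 3.0}
                for a in "xy" for b in "uv" for _ in range(3)]
        res = anova_two_way(pd.DataFrame(rows))
        assert res.F_a == 0.0 and res.F_b == 0.0 and res.F_interaction == 0.0

    def test_pure_main_effect_has_no_interaction(self):
        """Additive construction: group shifts only, zero interaction."""
        rng = np.random.default_rng(4)
        rows = []
        for i, a in enumerate(("m2", "m4", "m6")):
            for j, b in enumerate(("g0", "g1")):
                for _ in range(4):
                    rows.append({"isotopologue": a, "group": b,
                                 "value": 0.1 * i + 1.0 * j})
        res = anova_two_way(pd.DataFrame(rows))
        assert res.F_interaction == pytest.approx(0.0, abs=1e-18)
        assert res.F_b == np.inf or res.F_b > 0  # noiseless: infinite F

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(12)
        for _ in range(10):
            df = balanced_table(rng)
            res = anova_two_way(df)
            fit = smf.ols("value ~ C(isotopologue) * C(group)", data=df).fit()
            table = anova_lm(fit, typ=2)
            assert res.F_a == pytest.approx(table.loc["C(isotopologue)", "F"], rel=1e-9)
            assert res.F_b == pytest.approx(table.loc["C(group)", "F"], rel=1e-9)
            assert res.F_interaction == pytest.approx(
                table.loc["C(isotopologue):C(group)", "F"], rel=1e-9
            )

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(6)
        df = balanced_table(rng)
        shifted = df.assign(value=df["value"] + 100.0)
        a, b = anova_two_way(df), anova_two_way(shifted)
        assert a.F_a == pytest.approx(b.F_a, rel=1e-9)
        assert a.F_interaction == pytest.approx(b.F_interaction, rel=1e-9)

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(1)
        df = balanced_table(rng)
        with pytest.raises(ValueError, match="balanced"):
            anova_two_way(df.iloc[:-1])

    def test_single_replicate_rejected(self):
        rows = [{"isotopologue": a, "group": b, "value": 1.0}
                for a in "xy" for b in "uv"]
        with pytest.raises(ValueError):
            anova_two_way(pd.DataFrame(rows))
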