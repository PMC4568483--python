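"""Boltzmann fitting, IC50 extraction, Z', ANOVA, Tukey HSD and the screen report."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spherotox.dose_response import (
    DoseResponseFit,
    FitConfig,
    boltzmann,
    fit_boltzmann,
    ic50_from_fit,
    one_way_anova,
    screen_report,
    tukey_hsd,
    z_prime,
)
from spherotox.errors import (
    FitError,
    FitNotConvergedError,
    UndefinedSeparationError,
    ValidationError,
)
from spherotox.plate_io import PlateLayout, WellSpec

DOSES = np.array([2.6, 7.8, 23.3, 69.9, 210.0, 629.0, 1887.0])  # 7-point 1:3 series


def exact_responses(conc, a1=1.0, a2=0.0, ic50=82.8, dx=0.3):
    return boltzmann(np.log10(conc), a1, a2, np.log10(ic50), dx)


def grid_search_oracle(conc, y, anchor_decades=1.0):
    """Dense (x0, dx) grid with analytic (A1, A2): independent fit oracle.

    For fixed (x0, dx) the Boltzmann model is linear in (A1, A2); solving that
    2-parameter least-squares problem on a dense grid brackets the global
    optimum without trusting any iterative optimizer.
    """
    c = np.asarray(conc, dtype=float)
    x = np.where(c > 0, np.log10(np.maximum(c, 1e-300)), np.log10(c[c > 0].min()) - anchor_decades)
    best = None
    for x0 in np.linspace(x.min() - 0.5, x.max() + 0.5, 241):
        for dx in np.geomspace(0.02, 2.0, 61):
            g = 1.0 / (1.0 + np.exp((x - x0) / dx))  # response = A2 + (A1-A2) g
            design = np.column_stack([g, 1.0 - g])  # coefficients (A1, A2)
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            ss = float(np.sum((design @ coef - y) ** 2))
            if best is None or ss < best[0]:
                best = (ss, x0, dx, coef)
    return best


class TestFitBoltzmann:
    def test_exact_model_recovered_to_1e6(self):
        conc = np.repeat(DOSES, 3)
        y = exact_responses(conc)
        fit = fit_boltzmann(conc, y)
        assert fit.converged
        assert fit.a1 == pytest.approx(1.0, abs=1e-6)
        assert fit.a2 == pytest.approx(0.0, abs=1e-6)
        assert fit.dx == pytest.approx(0.3, rel=1e-6)
        assert ic50_from_fit(fit) == pytest.approx(82.8, rel=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        conc = np.repeat(DOSES, 3)
        y = exact_responses(conc) + rng.normal(0, 0.05, conc.shape)
        fit = fit_boltzmann(conc, y)
        ss_oracle, x0_oracle, _, _ = grid_search_oracle(conc, y)
        assert fit.residual_ss <= ss_oracle + 1e-9  # at least as good as the grid
        assert fit.x0 == pytest.approx(x0_oracle, abs=0.05)
        assert abs(np.log10(ic50_from_fit(fit) / 82.8)) <= 0.1

    def test_vehicle_points_anchored_below_lowest_dose(self):
        conc = np.concatenate([[0.0, 0.0, 0.0], np.repeat(DOSES, 3)])
        y = np.concatenate([[1.0, 1.0, 1.0], exact_responses(np.repeat(DOSES, 3))])
        fit = fit_boltzmann(conc, y)
        # the anchored control points sit just off the true curve, so recovery
        # is close but not exact
        assert ic50_from_fit(fit) == pytest.approx(82.8, rel=1e-2)

    def test_flat_responses_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann(np.repeat(DOSES, 2), np.ones(14))

    def test_too_few_distinct_concentrations_rejected(self):
        conc = np.array([1.0, 1.0, 10.0, 10.0, 100.0, 100.0])
        with pytest.raises(FitError):
            fit_boltzmann(conc, exact_responses(conc))

    def test_use_means_option_matches_on_balanced_exact_data(self):
        conc = np.repeat(DOSES, 3)
        y = exact_responses(conc)
        f_all = fit_boltzmann(conc, y)
        f_mean = fit_boltzmann(conc, y, FitConfig(use_means=True))
        assert f_mean.x0 == pytest.approx(f_all.x0, abs=1e-6)
        assert f_mean.n_points == len(DOSES)

    def test_decreasing_response_gives_top_above_bottom_and_x0_in_range(self):
        rng = np.random.default_rng(3)
        conc = np.repeat(DOSES, 3)
        y = exact_responses(conc, ic50=50.0) + rng.normal(0, 0.03, conc.shape)
        fit = fit_boltzmann(conc, y)
        assert fit.a1 > fit.a2
        assert np.log10(DOSES[0]) <= fit.x0 <= np.log10(DOSES[-1])


class TestIC50:
    def test_x0_two_is_100_uM(self):
        fit = DoseResponseFit(1, 0, 2.0, 0.3, 0.0, True, 10)
        assert ic50_from_fit(fit) == pytest.approx(100.0)

    def test_printed_scale_exemplar(self):
        fit = DoseResponseFit(1, 0, np.log10(281.8), 0.3, 0.0, True, 10)
        assert ic50_from_fit(fit) == pytest.approx(281.8)

    def test_non_converged_signalled_distinctly(self):
        fit = DoseResponseFit(1, 0, 2.0, 0.3, 0.0, False, 10)
        with pytest.raises(FitNotConvergedError):
            ic50_from_fit(fit)


class TestZPrime:
    def test_zero_variance_limit(self):
        assert z_prime([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_hand_computed_example(self):
        assert z_prime([0.9, 1.0, 1.1], [-0.1, 0.0, 0.1]) == pytest.approx(0.4)

    def test_equal_means_undefined(self):
        with pytest.raises(UndefinedSeparationError):
            z_prime([1.0, 2.0], [2.0, 1.0])

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 500))
    @settings(max_examples=50, derandomize=True)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(1, 0.05, 6)
        neg = rng.normal(0, 0.05, 6)
        z0 = z_prime(pos, neg)
        z1 = z_prime(a * pos + b, a * neg + b)
        assert z1 == pytest.approx(z0, rel=1e-9)


def brute_force_anova(groups):
    """Sums-of-squares oracle computed with plain Python loops."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum((v - m) ** 2 for g, m in zip(groups, means) for v in g)
    df1, df2 = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2)


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert f == pytest.approx(1.5, abs=1e-12)  # SSB = 1.5, SSW = 4, df 1 and 4

    def test_huge_separation(self):
        _, p = one_way_anova([[0.0, 0.001, -0.001], [1000.0, 1000.001, 999.999]])
        assert p < 1e-10

    def test_matches_brute_force_and_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            groups = [list(rng.normal(rng.uniform(-1, 1), 1, rng.integers(2, 8)))
                      for _ in range(rng.integers(2, 6))]
            f, p = one_way_anova(groups)
            assert f == pytest.approx(brute_force_anova(groups), abs=1e-10 * max(1, abs(f)))
            f_sp, p_sp = stats.f_oneway(*groups)
            assert f == pytest.approx(f_sp, rel=1e-10)
            assert p == pytest.approx(p_sp, rel=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_identical_groups_not_significant(self):
        tk = tukey_hsd([[1.0, 2.0, 3.0]] * 3, ["a", "b", "c"])
        assert not tk["significant"].any()

    def test_one_shifted_group_flags_exactly_its_two_pairs(self):
        rng = np.random.default_rng(5)
        g1 = list(rng.normal(0, 1, 6))
        g2 = list(rng.normal(0, 1, 6))
        g3 = list(rng.normal(10, 1, 6))  # shifted by ~10 sigma
        tk = tukey_hsd([g1, g2, g3], ["a", "b", "c"])
        sig = tk[tk["significant"]]
        assert len(sig) == 2
        assert all("c" in (r.group_i, r.group_j) for r in sig.itertuples())

    def test_two_group_decision_matches_pooled_t_test(self):
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(200):
            n1, n2 = rng.integers(3, 9, 2)
            shift = rng.uniform(0, 2)
            g1 = rng.normal(0, 1, n1)
            g2 = rng.normal(shift, 1, n2)
            tk = tukey_hsd([list(g1), list(g2)], ["a", "b"])
            t_p = stats.ttest_ind(g1, g2, equal_var=True).pvalue
            assert bool(tk["significant"].iloc[0]) == (t_p < 0.05)
            assert tk["p_value"].iloc[0] == pytest.approx(t_p, abs=1e-6)
            agree += 1
        assert agree == 200

    def test_p_values_match_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(11)
        groups = [list(rng.normal(m, 1, 5)) for m in (0.0, 0.8, 2.0, -0.5)]
        labels = ["g0", "g1", "g2", "g3"]
        tk = tukey_hsd(groups, labels)
        data = np.concatenate(groups)
        codes = np.repeat(labels, [len(g) for g in groups])
        sm = pairwise_tukeyhsd(data, codes, alpha=0.05)
        # statsmodels orders pairs the same way (sorted labels)
        for ours, theirs in zip(tk["p_value"], sm.pvalues):
            assert ours == pytest.approx(theirs, abs=1e-6)


class TestScreenReport:
    def _rates(self, ic50=50.0, flat=False, seed=0):
        rng = np.random.default_rng(seed)
        doses = [400.0, 66.7, 11.1, 1.85]
        rows = []
        for d in doses:
            resp = 1.0 if flat else float(exact_responses(np.array([d]), ic50=ic50)[0])
            for rep in range(3):
                rows.append({"compound": "cmpd", "concentration_uM": d, "role": "treatment",
                             "solvent": "PBS",
                             "normalized_rate": resp + rng.normal(0, 0.02)})
        for rep in range(4):
            rows.append({"compound": "", "concentration_uM": 0.0, "role": "vehicle",
                         "solvent": "PBS", "normalized_rate": 1.0 + rng.normal(0, 0.02)})
        return pd.DataFrame(rows)

    def _layout(self):
        wells = [WellSpec(f"A{i+1}", 0, i, "cmpd", 10.0, "treatment", 1, "PBS") for i in range(2)]
        wells.append(WellSpec("A3", 0, 2, None, 0.0, "vehicle", 1, "PBS"))
        return PlateLayout(wells=tuple(wells), n_rows=1, n_cols=3)

    def test_dose_responsive_compound_reported_significant_with_ic50(self):
        rep = screen_report(self._rates(ic50=50.0), self._layout())
        assert len(rep) == 1
        row = rep.iloc[0]
        assert row["status"] == "significant" and row["significant"]
        assert abs(np.log10(row["ic50_uM"] / 50.0)) < 0.1
        assert row["n_sig_vs_vehicle"] >= 1

    def test_flat_compound_reported_ns(self):
        rep = screen_report(self._rates(flat=True), self._layout())
        assert rep.iloc[0]["status"] == "n.s."
        assert not rep.iloc[0]["significant"]
        assert np.isnan(rep.iloc[0]["ic50_uM"])

    def test_single_concentration_unevaluable(self):
        rates = self._rates()
        rates = rates[(rates["concentration_uM"].isin([0.0, 400.0]))]
        rep = screen_report(rates, self._layout())
        assert rep.iloc[0]["status"] == "unevaluable"
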