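"""The five estimators: closed forms, ordering invariants, band refinement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amprisk import (
    LIFETIME,
    HazardTable,
    amp_estimate,
    amp_proxy_survival,
    cumulative_rate,
    cumulative_risk,
    current_probability,
    fine_grid_oracle,
    format_percent,
    gold_standard,
    make_bands,
    method_comparison,
    one_in_x,
)

from conftest import counts_from_hazards, random_hazard_table


def constant_table(lam_c, lam_x, lam_cd=0.0, n_bands=18, width=5.0) -> HazardTable:
    bands = make_bands(np.arange(0.0, n_bands * width + 1, width))
    k = len(bands)
    return HazardTable(
        bands=bands,
        lambda_C=np.full(k, lam_c),
        lambda_X=np.full(k, lam_x),
        lambda_M=np.full(k, lam_x + lam_cd),
    )


class TestCumulativeRate:
    def test_zero_rates_sum_to_zero(self):
        assert cumulative_rate(constant_table(0.0, 0.01), 90).value == 0.0

    def test_single_band_width_times_rate(self):
        h = HazardTable(bands=make_bands([0, 5]), lambda_C=[0.002, 0.0], lambda_X=[0.0, 0.0])
        assert cumulative_rate(h, 5).value == pytest.approx(0.01)

    def test_matches_hand_summed_rates(self):
        h = random_hazard_table(np.random.default_rng(1))
        expected = sum(
            b.width * lc for b, lc in zip(h.bands, h.lambda_C) if not b.is_open and b.end <= 75
        )
        assert cumulative_rate(h, 75).value == pytest.approx(expected, rel=1e-14)

    def test_off_boundary_age_names_neighbours(self):
        h = constant_table(0.01, 0.01)
        with pytest.raises(ValueError, match="70.*75"):
            cumulative_rate(h, 72)

    def test_open_band_inside_range_rejected(self):
        h = constant_table(0.01, 0.01, n_bands=4)  # closed to 20, then open
        with pytest.raises(ValueError):
            cumulative_rate(h, 50)


class TestCumulativeRisk:
    def test_zero_rate_zero_risk(self):
        assert cumulative_risk(0.0) == 0.0

    @pytest.mark.parametrize(
        "rate, percent_1dp", [(0.70, "50.3"), (0.51, "40.0"), (0.36, "30.2"), (0.31, "26.7")]
    )
    def test_rate_to_risk_conversion(self, rate, percent_1dp):
        assert format_percent(cumulative_risk(rate)) == percent_1dp

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            cumulative_risk(-0.1)

    def test_risk_below_rate(self):
        for rate in (0.01, 0.3, 1.2):
            assert cumulative_risk(rate) < rate


class TestOneInX:
    def test_reciprocal_formatting(self):
        x, s = one_in_x(0.5)
        assert x == 2.0 and s == "1 in 2.0"

    def test_half_offset_between_rate_and_risk(self):
        # a rate of 1 in 10 corresponds to a risk of about 1 in 10.5
        risk = cumulative_risk(1 / 10)
        assert one_in_x(risk)[0] - 10.0 == pytest.approx(0.5, abs=0.01)

    def test_half_offset_improves_with_x(self):
        errors = [abs(1 / cumulative_risk(1 / x) - (x + 0.5)) for x in (3, 5, 10, 50)]
        assert errors == sorted(errors, reverse=True)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            one_in_x(0.0)


class TestCurrentProbability:
    def test_no_incidence_no_risk(self):
        assert current_probability(constant_table(0.0, 0.02), LIFETIME).value == 0.0

    def test_no_mortality_equals_cumulative_rate(self):
        h = random_hazard_table(np.random.default_rng(2))
        h = HazardTable(
            bands=h.bands,
            lambda_C=h.lambda_C,
            lambda_X=np.zeros(h.n_bands),
            lambda_M=np.zeros(h.n_bands),
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # the mean count may exceed 1 here
            value = current_probability(h, 60).value
        assert value == pytest.approx(cumulative_rate(h, 60).value, rel=1e-12)

    def test_constant_hazards_mean_count_c_over_m(self):
        # cancer never fatal: expected diagnoses per lifetime is c/m
        c, m_rate = 0.03, 0.02
        h = constant_table(c, m_rate)
        with pytest.warns(UserWarning, match="exceeds 1"):
            est = current_probability(h, LIFETIME)
        assert est.value == pytest.approx(c / m_rate, rel=1e-12)

    def test_non_integrable_tail_rejected(self):
        h = constant_table(0.01, 0.0)
        with pytest.raises(ValueError, match="does not converge"):
            current_probability(h, LIFETIME)


class TestAmp:
    def test_no_incidence_no_risk(self):
        assert amp_estimate(constant_table(0.0, 0.02)).value == 0.0

    def test_sole_absorbing_cause_certain_registration(self):
        assert amp_estimate(constant_table(0.02, 0.0)).value == pytest.approx(1.0, abs=1e-12)

    def test_competing_exponentials_closed_form(self):
        c, x = 0.012, 0.034
        assert amp_estimate(constant_table(c, x)).value == pytest.approx(c / (c + x), rel=1e-12)

    def test_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            h = random_hazard_table(rng)
            a = amp_estimate(h).value
            o = fine_grid_oracle(h)
            assert abs(a - o) / o < 1e-10

    def test_zero_hazard_band_contributes_nothing(self):
        h = HazardTable(
            bands=make_bands([0, 5, 10]),
            lambda_C=[0.0, 0.01, 0.01],
            lambda_X=[0.0, 0.02, 0.02],
        )
        assert amp_estimate(h).value == pytest.approx(0.01 / 0.03, rel=1e-12)

    def test_truncated_has_no_tail_term(self):
        h = constant_table(0.01, 0.02)
        full = amp_estimate(h).value
        truncated = amp_estimate(h, 90).value
        assert truncated < full

    def test_refinement_invariance(self):
        """Halving every band leaves the exact-within-band estimate unchanged."""
        h = random_hazard_table(np.random.default_rng(4), n_bands=10)
        starts = [b.start for b in h.bands]
        fine_bounds = sorted(set(starts) | {(a + b) / 2 for a, b in zip(starts, starts[1:])})

        def split_values(arr):
            # every closed band twice, the open band once
            return np.append(np.repeat(arr[:-1], 2), arr[-1])

        split = HazardTable(
            bands=make_bands(fine_bounds),
            lambda_C=split_values(h.lambda_C),
            lambda_X=split_values(h.lambda_X),
            lambda_M=split_values(h.lambda_M),
        )
        assert amp_estimate(split).value == pytest.approx(amp_estimate(h).value, rel=1e-13)

    def test_trapezoid_variant_close_but_different(self):
        h = random_hazard_table(np.random.default_rng(5))
        exact = amp_estimate(h).value
        trap = amp_estimate(h, rule="trapezoid").value
        assert trap != exact
        assert trap == pytest.approx(exact, rel=0.02)


class TestProxySurvival:
    def test_no_hazards_flat_at_one(self):
        curve = amp_proxy_survival(constant_table(0.0, 0.0))
        np.testing.assert_allclose(curve.values, 1.0)

    def test_single_band_exponential_step(self):
        h = HazardTable(bands=make_bands([0, 1]), lambda_C=[0.04, 0.0], lambda_X=[0.06, 0.0])
        curve = amp_proxy_survival(h)
        assert curve.values[1] == pytest.approx(math.exp(-0.1), rel=1e-14)

    def test_terminal_log_survival_is_hazard_sum(self):
        h = random_hazard_table(np.random.default_rng(6))
        curve = amp_proxy_survival(h)
        expected = -sum(
            (lc + lx) * b.width
            for b, lc, lx in zip(h.bands, h.lambda_C, h.lambda_X)
            if not b.is_open
        )
        assert math.log(curve.values[-1]) == pytest.approx(expected, rel=1e-12)


class TestGoldStandard:
    def test_same_algorithm_as_current_probability(self):
        counts = counts_from_hazards(constant_table(0.004, 0.02, lam_cd=0.002))
        first = counts.with_mode("first-primaries-only")
        assert gold_standard(first).value == current_probability(counts).value

    def test_all_primaries_table_rejected(self):
        counts = counts_from_hazards(constant_table(0.004, 0.02))
        with pytest.raises(ValueError, match="first-primaries"):
            gold_standard(counts)


class TestMethodComparison:
    def make_counts(self, seed=7):
        h = random_hazard_table(np.random.default_rng(seed))
        return counts_from_hazards(h)

    def test_grid_shape_and_monotone_columns(self):
        counts = self.make_counts()
        first = counts.with_mode("first-primaries-only")
        grid = method_comparison(counts, first, ages=[60, 75, 90, LIFETIME])
        assert set(grid["method"]) == {
            "cumulative_rate",
            "cumulative_risk",
            "current_probability",
            "amp",
            "gold_standard",
        }
        assert len(grid) == 5 * 4
        for method, sub in grid.groupby("method"):
            vals = sub.sort_values("upper_age")["value"].dropna().to_numpy()
            assert np.all(np.diff(vals) >= -1e-12), f"{method} not monotone in age"

    def test_identical_tables_make_cp_equal_gold(self):
        counts = self.make_counts(8)
        first = counts.with_mode("first-primaries-only")
        grid = method_comparison(counts, first, ages=[75]).set_index("method")
        assert grid.loc["current_probability", "value"] == pytest.approx(
            grid.loc["gold_standard", "value"]
        )
        assert grid.loc["amp", "value"] <= grid.loc["current_probability", "value"]

    def test_band_mismatch_rejected(self):
        counts = self.make_counts(9)
        other = counts_from_hazards(random_hazard_table(np.random.default_rng(9), n_bands=10))
        other = other.with_mode("first-primaries-only")
        with pytest.raises(ValueError, match="different bands"):
            method_comparison(counts, other, ages=[50])


@st.composite
def hazard_tables(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    lam_c = draw(st.lists(st.floats(0.0, 0.08), min_size=n, max_size=n))
    lam_x = draw(st.lists(st.floats(0.0, 0.1), min_size=n, max_size=n))
    lam_d = draw(st.lists(st.floats(0.0, 0.02), min_size=n, max_size=n))
    bands = make_bands(np.arange(0.0, 5.0 * n - 4.9, 5.0))
    return HazardTable(
        bands=bands,
        lambda_C=np.array(lam_c),
        lambda_X=np.array(lam_x),
        lambda_M=np.array(lam_x) + np.array(lam_d),
    )


class TestOrderingInvariants:
    @given(h=hazard_tables())
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_risk_below_rate_and_amp_below_cp(self, h):
        """cumulative_risk <= cumulative_rate and amp <= CP on any table with R >= D."""
        age = h.bands[-1].start
        rate = cumulative_rate(h, age).value
        assert cumulative_risk(rate) <= rate + 1e-15
        # amp's proxy survival is never above all-cause survival when
        # registrations dominate cancer deaths, which counts_from_hazards ensures
        amp = amp_estimate(h, age).value
        cp = current_probability(h, age).value
        if np.all(h.lambda_C >= h.lambda_M - h.lambda_X):
            assert amp <= cp + 1e-12
        assert 0.0 <= amp <= 1.0

    @given(h=hazard_tables())
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_amp_reduction_bounded_by_cumulative_rate_factor(self, h):
        """The multiple-primaries correction removes at most a rate-sized fraction of CP.

        With registrations at least as frequent as cancer deaths, the proxy
        survival is below all-cause survival by at most the factor
        exp(-cumulative rate), so cp - amp <= cp * (1 - exp(-cum_rate)).
        For realistic site-level tables the cumulative rate is close to cp
        itself, which recovers the familiar cp^2-sized ceiling.
        """
        age = h.bands[-1].start
        if not np.all(h.lambda_C >= h.lambda_M - h.lambda_X):
            return
        amp = amp_estimate(h, age).value
        cp = current_probability(h, age).value
        rate = cumulative_rate(h, age).value
        assert cp - amp <= cp * -math.expm1(-rate) + 1e-12
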