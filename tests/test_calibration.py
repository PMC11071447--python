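"""Calibration statistics: Welch tests, LOD, 4PL fits, tiers, dilutions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from capflow import synth
from capflow.calibration import (
    CalibrationFit,
    Concentration,
    DoseResponse,
    classify_tier,
    convert_dilution,
    find_lod,
    fit_sigmoid,
    group_comparison,
    linear_range,
    signal_at_frame,
    welch_t_test,
)
from capflow.flow_tracking import FlowProfile


def make_dr(concs, means, sd=0.0, n=8, rng=None):
    rng = rng or np.random.default_rng(0)
    reps = tuple(
        np.full(n, m) if sd == 0 else rng.normal(m, sd, n) for m in means
    )
    return DoseResponse(np.array(concs, float), reps)


class TestSignalAtFrame:
    def test_closed_form_sqrt_profile(self, sqrt4_profile):
        assert signal_at_frame(sqrt4_profile, 25) == pytest.approx(
            math.sqrt(4 * 25 / 30), rel=1e-12)

    def test_frame_zero_is_dry(self, sqrt4_profile):
        assert signal_at_frame(sqrt4_profile, 0) == 0.0

    def test_saturated_frame_returns_channel_length(self):
        cfg = synth.SynthConfig(noise_sd_cm=0.0, D_early=4.0, D_late=4.0)  # 2.1 cm channel
        prof, _ = synth.gen_profile(cfg)
        assert signal_at_frame(prof, 200) == cfg.layout.channel_length_cm

    def test_frame_beyond_profile_raises(self, sqrt4_profile):
        with pytest.raises(IndexError):
            signal_at_frame(sqrt4_profile, 10_000)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.t == 0.0 and res.p == 1.0

    def test_huge_shift_significant(self):
        res = welch_t_test([1, 2, 3, 4], [11, 12, 13, 14])
        assert res.p < 0.001

    def test_matches_textbook_formula_and_scipy(self):
        a = np.array([2.1, 2.3, 1.9, 2.2])
        b = np.array([2.8, 3.1, 2.9, 3.3])
        res = welch_t_test(a, b)
        # independent recomputation straight from the Welch formulas
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 4 + vb / 4
        t_ref = (a.mean() - b.mean()) / math.sqrt(se2)
        df_ref = se2**2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.df == pytest.approx(df_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        sp = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(sp.statistic, abs=1e-10)
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_zero_variance_edge_cases(self):
        assert welch_t_test([2, 2, 2], [2, 2, 2]).p == 1.0
        with pytest.warns(UserWarning):
            res = welch_t_test([3, 3, 3], [2, 2, 2])
        assert res.p == 0.0 and math.isinf(res.t)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2, 3])


class TestFindLOD:
    def test_requires_negative_control(self):
        dr = make_dr([1, 10], [0.5, 0.9], sd=0.01)
        with pytest.raises(ValueError, match="control"):
            find_lod(dr)

    def test_no_effect_returns_none(self):
        rng = np.random.default_rng(11)
        dr = make_dr([0, 5, 10, 20], [0.7] * 4, sd=0.01, rng=rng)
        assert find_lod(dr) is None

    def test_five_sd_effect_from_10_upward(self):
        """Effect of 5 sd injected at >= 10 pg/mL is detected exactly there."""
        rng = np.random.default_rng(2)
        sd = 0.01
        concs = [0, 5, 10, 20, 40]
        means = [0.7, 0.7, 0.7 + 5 * sd, 0.7 + 5 * sd, 0.7 + 5 * sd]
        dr = make_dr(concs, means, sd=sd, rng=rng)
        assert find_lod(dr) == 10.0

    def test_effect_only_at_highest_concentration(self):
        rng = np.random.default_rng(5)
        dr = make_dr([0, 5, 10, 20], [0.7, 0.7, 0.7, 0.9], sd=0.01, rng=rng)
        assert find_lod(dr) == 20.0


def four_pl(conc, lower, upper, ec50, slope, log_floor):
    x = np.where(conc > 0, np.log10(np.maximum(conc, 1e-300)), log_floor)
    return lower + (upper - lower) / (1 + np.exp(-slope * (x - math.log10(ec50))))


class TestFitSigmoid:
    def test_noiseless_4pl_parameters_recovered(self):
        concs = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        truth = (0.6, 1.4, 30.0, 2.5)
        means = four_pl(concs, *truth, log_floor=-1.0)
        dr = make_dr(concs, means, n=2)
        fit = fit_sigmoid(dr)
        assert fit.model == "4PL sigmoid"
        for got, want in zip(fit.params, truth):
            assert got == pytest.approx(want, rel=1e-6)
        assert fit.direction == "increasing"

    def test_noisy_ec50_recovery(self):
        rng = np.random.default_rng(4)
        concs = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        truth = (0.6, 1.4, 30.0, 2.5)
        means = four_pl(concs, *truth, log_floor=-1.0)
        dr = make_dr(concs, means, sd=0.02, n=8, rng=rng)
        fit = fit_sigmoid(dr)
        assert fit.params[2] == pytest.approx(30.0, rel=0.15)

    def test_flat_response_falls_back_with_flag(self):
        dr = make_dr([0, 1, 10, 100, 1000], [0.7] * 5)
        with pytest.warns(UserWarning, match="falling back"):
            fit = fit_sigmoid(dr)
        assert fit.fallback and fit.model == "linear"

    def test_decreasing_data_detected(self):
        concs = np.array([0.0, 1, 3, 10, 30, 100])
        means = four_pl(concs, 1.4, 0.6, 10.0, 2.5, log_floor=-1.0)  # flipped trend
        fit = fit_sigmoid(make_dr(concs, means, n=2))
        assert fit.direction == "decreasing"

    def test_hook_limb_excluded_from_fit(self):
        concs = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        means = np.array([0.60, 0.62, 0.70, 0.85, 1.0, 1.1, 0.9, 0.7])  # hook past 100
        fit = fit_sigmoid(make_dr(concs, means, n=2))
        assert fit.excluded_hook_concentrations == (300.0, 1000.0)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(make_dr([0, 1, 10, 100], [0.6, 0.7, 0.8, 0.9]))


class TestLinearRange:
    def test_perfect_line_spans_everything(self):
        concs = [0, 5, 10, 20, 40]
        dr = make_dr(concs, [0.1 + 0.02 * c for c in concs])
        res = linear_range(dr)
        assert (res.conc_lo, res.conc_hi) == (0.0, 40.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.02)

    def test_hook_excludes_post_peak_limb(self):
        concs = [0, 5, 10, 20, 40, 80, 160]
        means = [0.1, 0.2, 0.3, 0.5, 0.9, 0.6, 0.3]  # rise then fall
        res = linear_range(make_dr(concs, means), r2_min=0.95)
        assert res.conc_hi <= 40.0

    def test_matches_exhaustive_enumeration(self):
        """Search result equals brute-force over all contiguous windows."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            concs = np.sort(rng.choice(np.arange(1, 100), size=7, replace=False)).astype(float)
            means = rng.normal(0.5, 0.2, 7)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                got = linear_range(DoseResponse(concs, tuple(np.full(3, m) for m in means)),
                                   r2_min=0.6)
            best = None
            for i in range(7):
                for j in range(i + 3, 8):
                    r = stats.linregress(concs[i:j], means[i:j])
                    if r.rvalue**2 >= 0.6:
                        key = (j - i, r.rvalue**2)
                        if best is None or key > best[0]:
                            best = (key, (concs[i], concs[j - 1]))
            if best is None:
                assert got is None
            else:
                assert (got.conc_lo, got.conc_hi) == best[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_range(make_dr([0, 10], [0.1, 0.2]))


@pytest.fixture
def increasing_calib():
    concs = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
    means = four_pl(concs, 0.6, 1.4, 30.0, 2.5, log_floor=-1.0)
    return fit_sigmoid(make_dr(concs, means, n=2))


class TestClassifyTier:
    def test_low_signal_maps_to_low_tier(self, increasing_calib):
        sig = increasing_calib.predict(2.0)
        tier = classify_tier(float(sig), increasing_calib, cuts=(15.0, 60.0))
        assert tier.label == "low"
        assert tier.concentration == pytest.approx(2.0, rel=1e-6)

    def test_signal_at_cut_goes_to_higher_tier(self, increasing_calib):
        sig = float(increasing_calib.predict(15.0))
        assert classify_tier(sig, increasing_calib, (15.0, 60.0)).label == "middle"
        sig = float(increasing_calib.predict(60.0))
        assert classify_tier(sig, increasing_calib, (15.0, 60.0)).label == "high"

    def test_decreasing_calibration_inverts_ordering(self):
        concs = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        means = four_pl(concs, 1.4, 0.6, 30.0, 2.5, log_floor=-1.0)
        calib = fit_sigmoid(make_dr(concs, means, n=2))
        assert calib.direction == "decreasing"
        high_signal = float(calib.predict(2.0))  # decreasing: high signal = low conc
        assert classify_tier(high_signal, calib, (15.0, 60.0)).label == "low"

    def test_out_of_span_signal_flagged(self, increasing_calib):
        tier = classify_tier(10.0, increasing_calib, (15.0, 60.0))
        assert tier.extrapolated


class TestConvertDilution:
    @pytest.mark.parametrize(
        "conc, unit, frac, direction, want",
        [
            (50, "pg/mL", 0.01, "to_undiluted", Concentration(5.0, "ng/mL")),
            (50, "pg/mL", 0.001, "to_undiluted", Concentration(50.0, "ng/mL")),
            (20, "pg/mL", 0.10, "to_undiluted", Concentration(0.2, "ng/mL")),
            (1, "pg/mL", 0.01, "to_undiluted", Concentration(0.1, "ng/mL")),
            (2, "ng/mL", 0.0001, "to_diluted", Concentration(0.2, "pg/mL")),
        ],
    )
    def test_printed_dilution_pairs(self, conc, unit, frac, direction, want):
        got = convert_dilution(conc, frac, direction, unit=unit)
        assert got.unit == want.unit
        assert got.value == pytest.approx(want.value, rel=1e-12)

    def test_identity_at_full_strength(self):
        got = convert_dilution(42.0, 1.0, "to_diluted")
        assert got == Concentration(42.0, "pg/mL")

    @given(conc=st.floats(0.01, 1e6), frac=st.floats(0.0001, 1.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_round_trip_is_identity(self, conc, frac):
        up = convert_dilution(conc, frac, "to_undiluted")
        back = convert_dilution(up.value, frac, "to_diluted", unit=up.unit)
        factor = 1000.0 if back.unit == "ng/mL" else 1.0
        assert back.value * factor == pytest.approx(conc, rel=1e-9)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            convert_dilution(1.0, 0.0, "to_diluted")
        with pytest.raises(ValueError):
            convert_dilution(1.0, 0.5, "sideways")


class TestGroupComparison:
    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(1)
        groups = {
            "low": rng.normal(0.0, 1.0, 8),
            "middle": rng.normal(10.0, 1.0, 8),
            "high": rng.normal(20.0, 1.0, 8),
        }
        res = group_comparison(groups)
        assert all(flag for _, flag in res.values())
        assert len(res) == 3

    def test_only_shifted_pair_significant(self):
        base = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0])
        groups = {"a": base, "b": base.copy(), "c": base + 10}
        res = group_comparison(groups)
        assert not res[("a", "b")][1]
        assert res[("a", "c")][1] and res[("b", "c")][1]

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison({"a": [1.0], "b": [1, 2, 3]})
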