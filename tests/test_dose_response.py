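"""4PL curve evaluation, fitting, censoring and resistance ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from effluxkit import io
from effluxkit.dose_response import (
    CensoredIC50Error,
    DoseResponseData,
    FourPLFit,
    InsufficientDataError,
    InvalidPlateError,
    fit_dose_response,
    four_pl,
    ic50_ratio,
    tc_fraction,
)
from effluxkit.simulate import SINGLE_AGENT_GRID, SyntheticTruth, ViabilityTruth, gen_viability_plate


def _series_from_plate(df):
    df = df.copy()
    df["conc_a_M"] = df["conc_a"] * 1e-9
    df["conc_b_M"] = df["conc_b"] * 1e-6
    return io.plate_to_dose_response(df)[0]


class TestFourPL:
    @pytest.mark.parametrize(
        "conc, expected",
        [
            (1e-9, 0.5),        # at the midpoint concentration
            (9e-9, 0.1),        # 1/(1+9) with hill 1
            (1e-15, 1.0),       # conc -> 0 limit approaches top
        ],
    )
    def test_curve_values(self, conc, expected):
        assert four_pl(conc, 1.0, 0.0, 1e-9, 1.0) == pytest.approx(expected, abs=1e-6)

    def test_midpoint_is_plateau_mean_for_any_parameters(self):
        fit = FourPLFit(top=0.9, bottom=0.12, ic50_rel=3.7e-9, hill=2.3)
        assert fit.predict(fit.ic50_rel) == pytest.approx((0.9 + 0.12) / 2)

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            four_pl(0.0, 1.0, 0.0, 1e-9, 1.0)

    @given(st.floats(0.2, 8.0), st.integers(0, 10_000))
    def test_monotone_decreasing_for_positive_hill(self, hill, i):
        conc = np.logspace(-12, -4, 50)
        resp = four_pl(conc, 1.0, 0.0, 10 ** (-10 + 6 * (i / 10_000)), hill)
        assert np.all(np.diff(resp) <= 1e-12)


class TestTCFraction:
    def test_equal_to_control_mean_is_one(self):
        assert tc_fraction(500.0, [400.0, 600.0]) == 1.0

    def test_examples(self):
        assert tc_fraction(0.0, [100.0]) == 0.0
        assert tc_fraction(450.0, [500.0, 500.0]) == pytest.approx(0.9)
        assert tc_fraction(550.0, [500.0]) == pytest.approx(1.1)  # not clipped

    def test_invalid_controls_raise(self):
        with pytest.raises(InvalidPlateError):
            tc_fraction(100.0, [])
        with pytest.raises(InvalidPlateError):
            tc_fraction(100.0, [0.0, 0.0])


class TestFitDoseResponse:
    def test_noiseless_recovers_truth_within_one_percent(self, quiet_truth):
        df = gen_viability_plate(quiet_truth, SINGLE_AGENT_GRID, [0.0],
                                 replicates=2, efflux_factor=0.0)
        fit = fit_dose_response(_series_from_plate(df))
        assert fit.censored == "none"
        assert fit.ic50_rel == pytest.approx(2e-9, rel=0.01)
        assert fit.top == pytest.approx(1.0, abs=0.01)
        assert fit.bottom == pytest.approx(0.0, abs=0.01)
        assert fit.hill == pytest.approx(1.5, rel=0.01)

    def test_noisy_duplicates_recover_ic50_within_25pct_most_seeds(self):
        truth = SyntheticTruth(seed=0, viability=ViabilityTruth(ic50=2e-9,
                                                                hill=1.5))
        ok = 0
        n_seeds = 200
        for s in range(n_seeds):
            df = gen_viability_plate(truth, SINGLE_AGENT_GRID, [0.0],
                                     replicates=2, seed=1000 + s,
                                     efflux_factor=0.0)
            fit = fit_dose_response(_series_from_plate(df))
            if fit.censored == "none" and abs(fit.ic50_rel / 2e-9 - 1) <= 0.25:
                ok += 1
        assert ok >= 0.90 * n_seeds

    def test_flat_inactive_compound_censored_above_max(self):
        # a ritonavir-like agent inactive up to 30 uM
        truth = SyntheticTruth(seed=2, viability=ViabilityTruth(
            ic50=300e-6, hill=1.5, noise_cv=0.05))
        grid = np.array([0.3, 0.949, 3, 9.49, 30]) * 1e-6
        df = gen_viability_plate(truth, grid, [0.0], replicates=2, seed=7,
                                 efflux_factor=0.0, drug_a="ritonavir")
        fit = fit_dose_response(_series_from_plate(df))
        assert fit.censored == "above_max"
        assert fit.format_ic50("uM") == "> 30.0000"

    def test_identical_signals_never_yield_interior_ic50(self):
        data = DoseResponseData("a", "line", "drug",
                                points=[(c, 800.0, 1) for c in
                                        (1e-9, 1e-8, 1e-7, 1e-6)],
                                controls=[800.0])
        fit = fit_dose_response(data)
        assert fit.censored in ("above_max", "below_min")

    def test_fit_invariant_to_signal_rescaling(self, quiet_truth):
        df = gen_viability_plate(quiet_truth, SINGLE_AGENT_GRID, [0.0],
                                 replicates=2, efflux_factor=0.0)
        fit1 = fit_dose_response(_series_from_plate(df))
        df2 = df.copy()
        df2["signal"] = df2["signal"] * 1000.0
        fit2 = fit_dose_response(_series_from_plate(df2))
        assert fit1.ic50_rel == pytest.approx(fit2.ic50_rel, rel=1e-6)
        assert fit1.hill == pytest.approx(fit2.hill, rel=1e-6)

    def test_too_few_concentrations_raise(self):
        data = DoseResponseData("a", "line", "drug",
                                points=[(1e-9, 1.0, 1), (1e-8, 0.5, 1),
                                        (1e-7, 0.1, 1)],
                                controls=[1.0])
        with pytest.raises(InsufficientDataError):
            fit_dose_response(data)


class TestIC50Ratio:
    @pytest.mark.parametrize(
        "num_nM, den_nM, fold",
        [
            (54.6, 1.3, 42.0),   # resistant over parental
            (9.5, 2.9, 3.3),     # resistant over parental, second line
            (9.5, 2.8, 3.4),     # fold sensitization by the inhibitor
            (1.5, 0.6, 2.5),     # second taxane, cross-resistance
            (9.5, 0.7, 13.6),
        ],
    )
    def test_printed_relative_resistance_values(self, num_nM, den_nM, fold):
        assert ic50_ratio(num_nM * 1e-9, den_nM * 1e-9).fold_1dp == fold

    def test_reciprocal_identity_exact(self):
        a, b = 5.46e-8, 1.3e-9
        assert ic50_ratio(a, b).fold * ic50_ratio(b, a).fold == 1.0

    def test_self_ratio_is_one(self):
        assert ic50_ratio(3e-9, 3e-9).fold == 1.0

    def test_censored_fit_raises_with_guidance(self):
        censored = FourPLFit(top=1.0, bottom=0.9, ic50_rel=30e-6, hill=1.0,
                             censored="above_max")
        good = FourPLFit(top=1.0, bottom=0.0, ic50_rel=1e-9, hill=1.0)
        with pytest.raises(CensoredIC50Error, match="bound"):
            ic50_ratio(censored, good)
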