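"""Bliss neutral/index arithmetic, matrix analysis and assay classification."""

import numpy as np
import pytest

from effluxkit.simulate import (
    DOCETAXEL_GRID_8,
    MechanismTruth,
    RITONAVIR_GRID_2,
    SyntheticTruth,
    ViabilityTruth,
    simulate_tc_matrix,
)
from effluxkit.synergy import (
    TCMatrix,
    analyze_matrix,
    bliss_index,
    bliss_neutral,
    classify_assay,
    clip_for_display,
    modeled_tc,
    read_matrix_csv,
    write_matrix_csv,
)


class TestBlissArithmetic:
    @pytest.mark.parametrize("e1, e2, expected",
                             [(0.5, 0.5, 0.25), (1.0, 0.37, 0.37),
                              (0.9, 0.6, 0.54)])
    def test_neutral_is_product(self, e1, e2, expected):
        assert bliss_neutral(e1, e2) == pytest.approx(expected)

    def test_neutral_rejects_negative(self):
        with pytest.raises(ValueError):
            bliss_neutral(-0.1, 0.5)

    @pytest.mark.parametrize("neutral, combo, expected",
                             [(0.54, 0.54, 0.0), (0.54, 0.30, 0.24),
                              (0.54, 0.80, -0.26)])
    def test_index_is_difference(self, neutral, combo, expected):
        assert bliss_index(neutral, combo) == pytest.approx(expected)

    def test_modeled_tc_mean_and_display_clip(self):
        assert modeled_tc([0.4, 0.6]) == pytest.approx(0.5)
        assert modeled_tc([0.32, 0.28, 0.30]) == pytest.approx(0.30)
        assert modeled_tc([1.1]) == pytest.approx(1.1)  # retained unclipped
        assert clip_for_display(1.1) == 1.0

    def test_modeled_tc_empty_raises(self):
        with pytest.raises(ValueError):
            modeled_tc([])


def _null_matrix(tc_a, tc_b):
    """Exact multiplicative checkerboard from single-agent effects."""
    ca = np.concatenate([[0.0], np.logspace(-9, -7, len(tc_a))])
    cb = np.concatenate([[0.0], np.logspace(-6, -5, len(tc_b))])
    ea = np.concatenate([[1.0], tc_a])
    eb = np.concatenate([[1.0], tc_b])
    grid = np.outer(ea, eb)
    return TCMatrix(conc_a=ca, conc_b=cb, replicates=grid[:, :, None])


class TestAnalyzeMatrix:
    def test_multiplicative_null_gives_zero_index_and_additive(self):
        m = _null_matrix(np.linspace(0.9, 0.1, 5), np.linspace(0.95, 0.3, 5))
        result = analyze_matrix(m)
        assert np.nanmax(np.abs(result.index)) == pytest.approx(0.0, abs=1e-12)
        assert result.call == "additive"
        assert result.counts["n_total"] == 25

    def test_transpose_invariance(self, truth):
        m = simulate_tc_matrix(truth, replicates=2, seed=11)
        r1 = analyze_matrix(m)
        r2 = analyze_matrix(m.transpose())
        assert r1.call == r2.call
        np.testing.assert_allclose(r1.index, r2.index.T, equal_nan=True)

    def test_efflux_mechanism_fixed_seed_called_synergy(self):
        # resistant line with efflux factor 30 and inhibitor Ki 5 uM
        truth = SyntheticTruth(
            seed=0, viability=ViabilityTruth(noise_cv=0.05),
            mechanism=MechanismTruth(efflux_factor=30.0, inhibitor_ki=5e-6))
        m = simulate_tc_matrix(truth, replicates=2, seed=0)
        assert analyze_matrix(m).call == "synergy"

    def test_missing_single_agent_axis_raises(self, truth):
        m = simulate_tc_matrix(truth, replicates=2, seed=1)
        m.replicates[0, 1, :] = np.nan
        with pytest.raises(ValueError, match="single-agent"):
            analyze_matrix(m)

    def test_cell_with_lost_replicate_uses_survivor(self, truth):
        m = simulate_tc_matrix(truth, replicates=2, seed=2)
        m.replicates[2, 2, 1] = np.nan
        result = analyze_matrix(m)
        assert result.counts["n_total"] == 25
        assert np.isfinite(result.index[2, 2])

    def test_cell_with_no_data_excluded_from_total(self, truth):
        m = simulate_tc_matrix(truth, replicates=2, seed=2)
        m.replicates[2, 2, :] = np.nan
        assert analyze_matrix(m).counts["n_total"] == 24


class TestClassifyAssay:
    @pytest.mark.parametrize(
        "n_syn, n_ant, n_total, expected",
        [
            (4, 0, 25, "synergy"),          # > 3 of 25 conditions
            (3, 0, 25, "slight_synergy"),   # exactly 3 of 25
            (0, 4, 25, "antagonism"),
            (0, 3, 25, "slight_antagonism"),
            (0, 0, 25, "additive"),
            (2, 0, 25, "additive"),         # 23 neutral > 22
            (4, 4, 25, "mixed"),
            (3, 0, 16, "synergy"),          # 8x2 layout: k = ceil(0.12*16) = 2
            (2, 0, 16, "slight_synergy"),
        ],
    )
    def test_counting_rules(self, n_syn, n_ant, n_total, expected):
        counts = {"n_synergy": n_syn, "n_antagonism": n_ant,
                  "n_neutral": n_total - n_syn - n_ant, "n_total": n_total}
        assert classify_assay(counts) == expected

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            classify_assay({"n_synergy": 0, "n_antagonism": 0,
                            "n_neutral": 0, "n_total": 0})


class TestRatesUnderSimulator:
    def test_noisy_null_additive_and_low_false_synergy(self, truth):
        n = 200
        calls = []
        for s in range(n):
            m = simulate_tc_matrix(truth, replicates=2, seed=5_000 + s,
                                   efflux_factor=0.0, noise_cv=0.05,
                                   bliss_null=True)
            calls.append(analyze_matrix(m).call)
        assert calls.count("additive") >= 0.90 * n
        assert calls.count("synergy") <= 0.05 * n

    def test_resistant_vs_parental_contrast(self, truth):
        n = 100
        syn = add = 0
        for s in range(n):
            m = simulate_tc_matrix(truth, conc_a=DOCETAXEL_GRID_8,
                                   conc_b=RITONAVIR_GRID_2, replicates=2,
                                   seed=6_000 + s, noise_cv=0.05)
            syn += analyze_matrix(m).call == "synergy"
            m = simulate_tc_matrix(truth, conc_a=DOCETAXEL_GRID_8,
                                   conc_b=RITONAVIR_GRID_2, replicates=2,
                                   seed=7_000 + s, efflux_factor=0.0,
                                   noise_cv=0.05)
            add += analyze_matrix(m).call == "additive"
        assert syn >= 0.95 * n
        assert add >= 0.90 * n


class TestMatrixCSV:
    def test_heatmap_csv_roundtrip_bitwise(self, truth, tmp_path):
        m = simulate_tc_matrix(truth, replicates=2, seed=3)
        result = analyze_matrix(m)
        path = tmp_path / "bliss_index.csv"
        write_matrix_csv(path, result.index, m.conc_a, m.conc_b)
        grid, ca, cb = read_matrix_csv(path)
        assert np.array_equal(grid, result.index, equal_nan=True)
        assert np.array_equal(ca, m.conc_a)
        assert np.array_equal(cb, m.conc_b)
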