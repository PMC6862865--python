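"""Bioenergetics: phase summaries, PPR/ATP formulas, normalization, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant import flux, synthetic
from mitoquant.errors import NormalizationError, SummaryError

from conftest import make_recovery_plate

rates = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestSummarizePhases:
    def test_noise_free_worked_example(self, noise_free_plate):
        s = flux.summarize_phases(noise_free_plate).iloc[0]
        assert s["ocr_basal"] == 100.0
        assert s["ocr_post_oligo"] == pytest.approx(40.0)
        assert s["ocr_max"] == 180.0
        assert s["ocr_rot_aa"] == 20.0
        assert s["ocr_mito"] == pytest.approx(80.0)
        assert s["ocr_coupled"] == pytest.approx(60.0)
        assert s["ocr_leak"] == pytest.approx(20.0)
        assert s["src_pct"] == pytest.approx(180.0)

    def test_src_is_100_when_maximal_equals_basal(self):
        truth = synthetic.FluxGroundTruth(100, 20, 0.75, 100, 10)
        s = flux.summarize_phases(synthetic.generate_flux_plate([truth]))
        assert s["src_pct"].iloc[0] == pytest.approx(100.0)

    def test_basal_is_mean_of_basal_cycles(self):
        data = pd.DataFrame({
            "well": "W01", "cycle": range(1, 14),
            "phase": ["basal"] * 4 + ["oligo"] * 3 + ["fccp"] * 3 + ["rot_aa"] * 3,
            "time_min": np.arange(13) * 3.5,
            "OCR": [90, 100, 110, 100] + [40] * 3 + [180] * 3 + [20] * 3,
            "ECAR": 10.0,
        })
        s = flux.summarize_phases(flux.FluxPlate(data))
        assert s["ocr_basal"].iloc[0] == pytest.approx(100.0)

    def test_last_cycle_mode_uses_final_post_injection_point(self):
        data = pd.DataFrame({
            "well": "W01", "cycle": range(1, 14),
            "phase": ["basal"] * 4 + ["oligo"] * 3 + ["fccp"] * 3 + ["rot_aa"] * 3,
            "time_min": np.arange(13) * 3.5,
            "OCR": [100] * 4 + [60, 45, 42] + [180] * 3 + [20] * 3,
            "ECAR": 10.0,
        })
        s = flux.summarize_phases(flux.FluxPlate(data), mode="last")
        assert s["ocr_post_oligo"].iloc[0] == 42.0

    def test_missing_phase_names_well_and_phase(self):
        data = pd.DataFrame({
            "well": "A1", "cycle": range(1, 11),
            "phase": ["basal"] * 4 + ["oligo"] * 3 + ["fccp"] * 3,
            "time_min": np.arange(10) * 3.5, "OCR": 50.0, "ECAR": 5.0,
        })
        with pytest.raises(SummaryError, match="A1.*rot_aa"):
            flux.summarize_phases(flux.FluxPlate(data))

    def test_decomposition_coupled_plus_leak_is_mito(self):
        plate, _ = make_recovery_plate(n_wells=8, seed=13)
        s = flux.summarize_phases(plate)
        np.testing.assert_allclose(s["ocr_coupled"] + s["ocr_leak"],
                                   s["ocr_mito"], rtol=1e-12)
        np.testing.assert_allclose(s["ocr_basal"],
                                   s["ocr_coupled"] + s["ocr_leak"] + s["ocr_rot_aa"],
                                   rtol=1e-12)


class TestPprGlyc:
    def test_hand_computed_example(self, constants):
        # 10/0.1 - 80 * 1 * 10^1.307 / (1 + 10^1.307) = 23.7599...
        val = flux.compute_ppr_glyc(80.0, 10.0, constants)
        assert val == pytest.approx(23.76, abs=0.005)

    def test_zero_mito_ocr_gives_ecar_over_bp(self, constants):
        assert flux.compute_ppr_glyc(0.0, 10.0, constants) == pytest.approx(100.0)

    def test_co2_factor_is_half_at_ph_equal_pk1(self):
        k = flux.BioenergeticConstants(ph=6.5, pk1=6.5, buffering_power=1.0,
                                       max_h_per_o2=1.0)
        # ECAR/BP = 0, so PPR = -OCR_mito * 0.5
        assert flux.compute_ppr_glyc(10.0, 0.0, k) == pytest.approx(-5.0)

    def test_negative_result_returned_not_clamped(self, constants):
        assert flux.compute_ppr_glyc(1000.0, 1.0, constants) < 0

    def test_monotone_in_ecar(self, constants):
        vals = flux.compute_ppr_glyc(80.0, np.array([5.0, 10.0, 20.0]), constants)
        assert np.all(np.diff(vals) > 0)


class TestAtpRates:
    def test_oxidative_worked_example(self, constants):
        r = flux.compute_atp_rates(60.0, 80.0, 0.0, constants)
        assert r["atp_ox"] == pytest.approx(316.0)  # 60*2*2.5 + 80*2*0.1

    def test_glycolytic_worked_example(self, constants):
        r = flux.compute_atp_rates(0.0, 80.0, 20.0, constants)
        assert r["atp_glyc"] == pytest.approx(36.0)  # 20*1 + 80*2*0.1

    def test_all_zero_summary_gives_zero_rates(self, constants):
        r = flux.compute_atp_rates(0.0, 0.0, 0.0, constants)
        assert r["atp_ox"] == r["atp_glyc"] == r["atp_total"] == 0.0

    @given(coupled=rates, mito=rates, ppr=st.floats(-1e4, 1e4))
    @settings(max_examples=200, derandomize=True)
    def test_conservation_total_is_sum(self, coupled, mito, ppr):
        k = flux.BioenergeticConstants(po_oxphos=2.5, po_tca=0.1, po_glyc=0.1)
        r = flux.compute_atp_rates(coupled, mito, ppr, k)
        assert r["atp_total"] == r["atp_ox"] + r["atp_glyc"]

    def test_fully_coupled_no_nonmito_limit(self, constants):
        # coupled fraction -> 1 and OCR_R/A -> 0: both terms use OCR_tot
        truth = synthetic.FluxGroundTruth(100, 0, 1.0, 180, 10)
        s = flux.summarize_phases(synthetic.generate_flux_plate([truth]))
        r = flux.compute_atp_rates(s["ocr_coupled"], s["ocr_mito"], 0.0, constants)
        expected = 100 * 2 * constants.po_oxphos + 100 * 2 * constants.po_tca
        assert r["atp_ox"][0] == pytest.approx(expected)


class TestNormalization:
    def test_equal_signals_leave_results_unchanged(self, noise_free_plate, constants):
        s = flux.add_atp_rates(flux.summarize_phases(noise_free_plate), constants)
        signal = pd.Series(500.0, index=s.index)
        out = flux.normalize_by_signal(s, signal)
        pd.testing.assert_frame_equal(out, s)

    def test_double_signal_halves_rates(self, constants):
        truths = [synthetic.FluxGroundTruth(100, 20, 0.75, 180, 10)] * 2
        plate = synthetic.generate_flux_plate(truths)
        s = flux.summarize_phases(plate)
        signal = pd.Series([1000.0, 2000.0], index=s.index)
        out = flux.normalize_by_signal(s, signal)
        # factors are signal / mean(signal) = (2/3, 4/3)
        assert out["ocr_basal"].iloc[1] == pytest.approx(
            s["ocr_basal"].iloc[1] / (4 / 3))
        assert (out["ocr_basal"].iloc[1] / out["ocr_basal"].iloc[0]
                == pytest.approx(0.5))

    def test_src_is_scale_free_and_not_divided(self):
        truths = [synthetic.FluxGroundTruth(100, 20, 0.75, 180, 10,
                                            cell_scale=s) for s in (1.0, 2.0)]
        plate = synthetic.generate_flux_plate(truths)
        s = flux.summarize_phases(plate)
        out = flux.normalize_by_signal(s, plate.normalization)
        np.testing.assert_allclose(out["src_pct"], 180.0)

    def test_cell_scale_variation_recovered_by_normalization(self):
        rng = np.random.default_rng(21)
        truths = [synthetic.FluxGroundTruth(
            100, 20, 0.75, 180, 10, noise_sd=5.0,
            cell_scale=sc, seed=int(rng.integers(2 ** 31)))
            for sc in np.linspace(1.0, 2.0, 24)]
        plate = synthetic.generate_flux_plate(truths)
        s = flux.normalize_by_signal(flux.summarize_phases(plate),
                                     plate.normalization)
        # normalized basal = per-cell basal * mean cell_scale (common factor)
        scale_mean = np.mean(np.linspace(1.0, 2.0, 24))
        assert s["ocr_basal"].mean() == pytest.approx(100.0 * scale_mean, rel=0.03)
        assert s["ocr_basal"].std() < 10.0  # 2-fold scatter removed

    def test_nonpositive_signal_names_well(self, noise_free_plate):
        s = flux.summarize_phases(noise_free_plate)
        with pytest.raises(NormalizationError, match="W01"):
            flux.normalize_by_signal(s, pd.Series(0.0, index=s.index))


class TestParameterRecovery:
    def test_96_wells_5pct_noise(self):
        plate, truth = make_recovery_plate(n_wells=96, noise_sd=5.0, seed=0)
        s = flux.summarize_phases(plate)
        n = len(s)
        # analytic sd of each plate-mean estimator from the cycle structure
        sd_basal = 5.0 / np.sqrt(4) / np.sqrt(n)
        sd_max = 5.0 / np.sqrt(3) / np.sqrt(n)
        sd_coupled = 5.0 * np.sqrt(1 / 4 + 1 / 3) / np.sqrt(n)
        assert abs(s["ocr_basal"].mean() - 100.0) < 3 * sd_basal
        assert abs(s["ocr_max"].mean() - 180.0) < 3 * sd_max
        assert abs(s["ocr_coupled"].mean() - 60.0) < 3 * sd_coupled
        assert abs(s["src_pct"].mean() - 180.0) < 5.0


class TestPlateIO:
    def test_csv_round_trip(self, noise_free_plate, tmp_path):
        path = tmp_path / "plate.csv"
        noise_free_plate.to_csv(path)
        back = flux.read_flux_csv(path)
        pd.testing.assert_frame_equal(back.data, noise_free_plate.data)

    def test_phase_order_validated(self):
        data = pd.DataFrame({
            "well": "W01", "cycle": [1, 2], "phase": ["fccp", "basal"],
            "time_min": [0.5, 4.0], "OCR": 1.0, "ECAR": 1.0})
        with pytest.raises(ValueError, match="order"):
            flux.FluxPlate(data)

    def test_constants_recorded_in_output(self, noise_free_plate, constants):
        out = flux.add_atp_rates(flux.summarize_phases(noise_free_plate), constants)
        assert out.attrs["constants"]["po_oxphos"] == 2.5
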