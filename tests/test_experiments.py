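"""Sensitivity studies: directions, normalizations, determinism."""

import math

import numpy as np
import pytest

from fdgkin.experiments import (
    blood_correction_study,
    calibration_study,
    k1_k2_tradeoff,
    smoothing_study,
    time_shift_study,
    vb_sweep_study,
)
from fdgkin.synthetic_data import ProtocolSpec, make_fixture


@pytest.fixture(scope="module")
def scans(scan):
    return [scan]


@pytest.fixture(scope="module")
def sweep(scans):
    return vb_sweep_study(scans, n_starts=2)


@pytest.fixture(scope="module")
def shift(scans):
    return time_shift_study(scans, n_starts=2)


@pytest.fixture(scope="module")
def smoothing_res(scans):
    return smoothing_study(scans, n_replicates=10)


@pytest.fixture(scope="module")
def bc_res(scans):
    return blood_correction_study(scans, n_starts=2)


class TestVbSweep:
    def test_chi2_minimal_at_generating_vb(self, sweep, scan):
        assert sweep.summary["best_vb"][0] == pytest.approx(scan.truth.vb)

    def test_free_fit_recovers_vb_noise_free(self, sweep, scan):
        assert sweep.summary["free_vb"][0] == pytest.approx(scan.truth.vb, abs=1e-3)

    def test_transport_constants_decrease_with_assumed_vb(self, sweep):
        t = sweep.table
        for name in ("K1", "k2"):
            assert np.all(np.diff(t[name].to_numpy()) <= 1e-9), name

    def test_all_rate_constants_negatively_correlated_with_vb(self):
        """With dephosphorylation in the model (k4 fitted), every rate
        constant falls monotonically as the assumed blood volume rises."""
        from fdgkin.kinetics import KineticParams

        truth = KineticParams(K1=0.27, k2=0.57, k3=0.08, k4=0.018, vb=0.055)
        res = vb_sweep_study([make_fixture(0, truth=truth)], n_starts=2)
        t = res.table
        for name in ("K1", "k2", "k3", "k4"):
            assert np.corrcoef(t["vb"], t[name])[0, 1] < -0.9, name

    def test_normalized_cmrglc_near_one_at_generating_vb(self, sweep, scan):
        t = sweep.table
        row = t.loc[np.isclose(t["vb"], scan.truth.vb)]
        assert row["cmrglc_norm"].iloc[0] == pytest.approx(1.0, abs=0.1)


class TestTimeShift:
    def test_zero_shift_normalizes_to_one(self, shift):
        t = shift.table
        row = t.loc[t["shift_s"] == 0.0]
        for name in ("K1_norm", "k2_norm", "k3_norm", "cmrglc_norm"):
            assert row[name].iloc[0] == 1.0

    def test_goodness_of_fit_best_at_zero_delay(self, shift):
        t = shift.table
        assert shift.summary["chi2_argmin_shift"] == 0.0
        assert t.loc[t["shift_s"] == 0.0, "chi2"].iloc[0] == min(t["chi2"])

    def test_twenty_second_error_distorts_rate_constants(self, shift):
        """A 20-s timing error misestimates at least one constant by >=20%."""
        t = shift.table
        for s in (-20.0, 20.0):
            row = t.loc[t["shift_s"] == s].iloc[0]
            worst = max(abs(row[f"{n}_norm"] - 1.0) for n in ("K1", "k2", "k3"))
            assert worst >= 0.20

    def test_grid_must_contain_zero(self, scans):
        with pytest.raises(ValueError):
            time_shift_study(scans, shifts=[-10.0, 10.0])


class TestCalibration:
    def test_factor_absorbed_by_K1_at_zero_vb(self, scans):
        res = calibration_study(scans, vb=0.0, n_starts=2)
        t = res.table
        for c in (0.95, 1.05):
            row = t.loc[t["factor"] == c].iloc[0]
            assert row["K1_ratio"] == pytest.approx(c, abs=1e-3)
            assert row["k2_ratio"] == pytest.approx(1.0, rel=1e-3)
            assert row["k3_ratio"] == pytest.approx(1.0, rel=1e-3)

    def test_unit_factor_changes_nothing(self, scans):
        res = calibration_study(scans, factors=(), vb=0.055, n_starts=2)
        row = res.table.iloc[0]
        assert row["factor"] == 1.0
        assert row["K1_ratio"] == 1.0

    def test_standard_vb_K1_dominates_response(self, scans):
        res = calibration_study(scans, vb=0.055, n_starts=2)
        t = res.table
        for c in (0.95, 1.05):
            row = t.loc[t["factor"] == c].iloc[0]
            k1_shift = abs(row["K1_ratio"] - 1.0)
            assert k1_shift == pytest.approx(abs(c - 1.0), abs=0.02)
            for name in ("k2", "k3"):
                assert abs(row[f"{name}_ratio"] - 1.0) < k1_shift


class TestSmoothing:
    def test_five_arms_present(self, smoothing_res):
        assert set(smoothing_res.table["arm"]) == {
            "orig", "half_tac", "smooth_tac", "smooth_if", "smooth_both",
        }

    def test_deletion_arm_uses_half_the_frames(self, smoothing_res, scan):
        t = smoothing_res.table
        n = len(scan.tac)
        assert (t.loc[t["arm"] == "half_tac", "n_frames_used"] == math.ceil(n / 2)).all()
        assert (t.loc[t["arm"] == "orig", "n_frames_used"] == n).all()

    def test_smoothing_noise_free_tac_leaves_fit_unchanged(self, scan):
        """LOWESS on already-smooth frame data is near-identity."""
        from fdgkin.experiments import _lowess_tac
        from fdgkin.fitting import fit_2tc

        sm = _lowess_tac(scan.tac, 0.1, 2)
        res = fit_2tc(sm, scan.plasma, scan.blood, vb=0.055, fit_k4=False, n_starts=2)
        for name in ("K1", "k2", "k3"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(scan.truth, name), rel=5e-3
            )

    def test_if_smoothing_shifts_rate_constants(self, smoothing_res):
        """Smoothing the IF flattens the infusion-stop peak and biases the
        transport constants (significant vs the unsmoothed arm)."""
        p = smoothing_res.summary["p_bonferroni"]["smooth_both"]
        assert p["K1"] < 0.05
        means = smoothing_res.table.groupby("arm")["K1"].mean()
        assert means["smooth_both"] > means["orig"]


class TestBloodCorrection:
    def test_whole_blood_overestimates_K1(self, bc_res):
        t = bc_res.table
        assert t.loc[t["method"] == "whole_blood", "K1_ratio"].iloc[0] > 1.0

    def test_mouse_and_rat_corrections_similar(self, bc_res):
        t = bc_res.table
        rat = t.loc[t["method"] == "rat_biexp"].iloc[0]
        wb = t.loc[t["method"] == "whole_blood"].iloc[0]
        rat_dev = max(abs(rat[f"{n}_ratio"] - 1) for n in ("K1", "k2", "k3"))
        wb_dev = max(abs(wb[f"{n}_ratio"] - 1) for n in ("K1", "k2", "k3"))
        assert rat_dev < wb_dev

    def test_constant_scaling_keeps_kfdg_within_20pc(self, bc_res):
        t = bc_res.table
        ratio = t.loc[t["method"] == "constant_scale", "kfdg_ratio"].iloc[0]
        assert 0.8 < ratio < 1.2


class TestTradeoff:
    def test_unit_factor_is_identity(self, scan):
        res = k1_k2_tradeoff(
            scan.truth.replace(k4=0.0, vb=0.0), scan.plasma, scan.frames, k1_factor=1.0
        )
        assert res.k2_factor == 1.0
        assert res.ssd == 0.0

    def test_closed_form_oracle(self, scan):
        """Search lands in the flat valley around the K_FDG-preserving
        multiplier (c*(k2+k3)-k3)/k2."""
        base = scan.truth.replace(k4=0.0, vb=0.0)
        res = k1_k2_tradeoff(base, scan.plasma, scan.frames)
        assert res.closed_form_k2_factor == pytest.approx(1.1144, abs=5e-4)
        assert res.k2_factor == pytest.approx(res.closed_form_k2_factor, abs=0.01)

    def test_reversible_base_rejected(self, scan):
        with pytest.raises(ValueError):
            k1_k2_tradeoff(scan.truth.replace(k4=0.01), scan.plasma, scan.frames)

    def test_residual_shrinks_with_longer_infusion(self, scan, scan_900):
        """The K1/k2-separating signal around the infusion stop dissipates
        as the infusion lengthens."""
        base = scan.truth.replace(k4=0.0, vb=0.0)
        r300 = k1_k2_tradeoff(base, scan.plasma, scan.frames)
        r900 = k1_k2_tradeoff(base, scan_900.plasma, scan_900.frames)
        assert r900.ssd < r300.ssd
        assert np.abs(r900.residual.values).max() < np.abs(r300.residual.values).max()


class TestDeterminism:
    def test_studies_reproduce_bit_identically(self):
        a = calibration_study([make_fixture(3)], n_starts=2)
        b = calibration_study([make_fixture(3)], n_starts=2)
        assert a.table.equals(b.table)
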