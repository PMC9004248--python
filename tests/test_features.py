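import numpy as np
import pytest

from hemowave.beats import Beat, detect_fiducials
from hemowave.features import (
    FEATURE_NAMES, FEATURE_DEFINITIONS, compute_features, estimate_zc,
    separate_waves, liljestrand_zander, feature_dictionary_json,
)

from conftest import two_gaussian_beat


@pytest.fixture(scope="module")
def gauss_beat():
    p, _ = two_gaussian_beat()
    b = Beat(p=p, fs=400.0)
    return b, detect_fiducials(b)


def test_ledger_has_45_uniquely_named_features():
    assert len(FEATURE_NAMES) == 45
    assert len(set(FEATURE_NAMES)) == 45
    import json
    assert set(json.loads(feature_dictionary_json())) == set(FEATURE_NAMES)


class TestComputeFeatures:
    def test_pulse_pressure_identity(self):
        # beat rolled to start at its minimum, scaled so SBP/DBP hit 140/74
        p, _ = two_gaussian_beat()
        p = np.roll(p, -int(np.argmin(p)))
        p = 74.0 + (p - p.min()) * (140.0 - 74.0) / (p.max() - p.min())
        b = Beat(p=p, fs=400.0)
        f = compute_features(b, detect_fiducials(b))
        assert f["sbp"] == pytest.approx(140.0)
        assert f["dbp"] == pytest.approx(74.0)
        assert f["pp"] == pytest.approx(66.0)

    def test_feature_identities(self, gauss_beat):
        b, fid = gauss_beat
        f = compute_features(b, fid)
        assert f["pp"] == f["sbp"] - f["dbp"]
        assert f["augmentation_index"] == pytest.approx(f["augmented_pressure"] / f["pp"])
        assert f["dicrotic_notch_index"] == pytest.approx(
            f["relative_dicrotic_pressure"] / f["pp"])
        assert f["descending_index"] == pytest.approx(f["descending_pressure"] / f["pp"])
        assert f["systolic_duration"] + f["diastolic_duration"] == pytest.approx(
            f["beat_duration"])
        assert f["myocardial_oxygen_ratio"] == pytest.approx(
            f["diastolic_area"] / f["systolic_area"])
        assert 0 < f["systolic_duration"] <= f["beat_duration"]
        assert f["downstroke_slope"] < 0

    def test_absent_anacrotic_notch_gives_zero_augmentation(self):
        fs, dur = 400.0, 0.9
        t = np.arange(0.0, dur, 1.0 / fs)
        p = 70 + 60 * np.exp(-((t - 0.15) / 0.05) ** 2)
        p[t > 0.15] = 70 + 60 * np.exp(-(t[t > 0.15] - 0.15) / 0.25)
        b = Beat(p=p, fs=fs)
        fid = detect_fiducials(b)
        f = compute_features(b, fid)
        assert f["augmented_pressure"] == 0.0
        assert f["augmentation_index"] == 0.0

    def test_myocardial_ratio_forced_by_rectangular_areas(self):
        # flat beat with a one-sample spike; notch pinned at exactly 1/3
        fs, n = 400.0, 360
        p = np.full(n, 80.0)
        p[30] = 90.0
        b = Beat(p=p, fs=fs)
        fid = detect_fiducials(b)
        assert fid.dicrotic_fallback and fid.dicrotic_notch.index == n // 3
        f = compute_features(b, fid)
        assert f["myocardial_oxygen_ratio"] == pytest.approx(
            f["diastolic_area"] / f["systolic_area"])
        assert f["myocardial_oxygen_ratio"] == pytest.approx(2.0, rel=0.01)

    def test_zero_pulse_pressure_names_degenerate_features(self, gauss_beat):
        b, fid = gauss_beat
        flat = Beat(p=np.full(b.p.size, 80.0), fs=b.fs)
        with pytest.raises(ValueError, match="index"):
            compute_features(flat, fid)

    def test_wave_features_flagged_absent_without_flow(self, gauss_beat):
        b, fid = gauss_beat
        f = compute_features(b, fid)
        assert np.isnan(f["zc"]) and np.isnan(f["forward_peak"])

    def test_scale_equivariance_under_affine_pressure_maps(self, gauss_beat):
        b, _ = gauss_beat
        a, off = 1.7, 12.0
        b2 = Beat(p=a * b.p + off, fs=b.fs)
        f1 = compute_features(b, detect_fiducials(b))
        f2 = compute_features(b2, detect_fiducials(b2))
        for name in ("pp", "augmented_pressure", "relative_systolic_area",
                     "relative_diastolic_area", "descending_pressure"):
            assert f2[name] == pytest.approx(a * f1[name], abs=1e-9)
        for name in ("augmentation_index", "dicrotic_notch_index",
                     "descending_index", "relative_myocardial_oxygen_ratio",
                     "beat_duration", "systolic_duration"):
            assert f2[name] == pytest.approx(f1[name], abs=1e-9)


class TestCharacteristicImpedance:
    def test_proportional_signals_recover_the_resistance(self):
        fs, T = 400.0, 0.9
        t = np.arange(0.0, T, 1.0 / fs)
        q = 200 * np.abs(np.sin(np.pi * t / T)) + 10
        assert estimate_zc(1.09 * q, q, fs) == pytest.approx(1.09)

    def test_three_element_windkessel_band_average(self):
        fs, T = 1000.0, 0.9
        n = int(T * fs)
        t = np.arange(n) / fs
        q = np.where(t < 0.33, 300 * np.sin(np.pi * t / 0.33), 0.0)
        zc_wk, r, c = 0.05, 1.0, 1.5
        f = np.fft.rfftfreq(n, 1.0 / fs)
        z = zc_wk + r / (1 + 1j * 2 * np.pi * f * r * c)
        p = np.fft.irfft(np.fft.rfft(q) * z, n)
        est = estimate_zc(p, q, fs)
        band = (f >= 5) & (f <= 15)
        band[0] = False
        analytic = float(np.abs(z[band]).mean())
        assert abs(est - analytic) / analytic <= 0.10

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_zc(np.ones(400), np.zeros(400), 400.0)

    def test_band_without_harmonics_rejected(self):
        # 4 samples at 8 Hz -> bins at 0, 2, 4 Hz: none inside 5-15 Hz
        with pytest.raises(ValueError, match="harmonic"):
            estimate_zc(np.arange(4.0), np.arange(4.0) + 1, 8.0)


class TestWaveSeparation:
    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(7)
        p = 90 + 20 * rng.standard_normal(500)
        q = 100 + 50 * rng.standard_normal(500)
        split = separate_waves(p, q, 0.07)
        assert np.max(np.abs(split.reconstruct() - p)) <= 1e-9

    def test_matched_load_has_no_reflection(self):
        t = np.linspace(0, 0.9, 360)
        p = 100 + 25 * np.sin(2 * np.pi * t / 0.9)
        zc = 0.08
        q = (p - p.mean()) / zc + 90.0
        split = separate_waves(p, q, zc)
        assert np.max(np.abs(split.p_backward)) <= 1e-9

    def test_occluded_line_reflects_everything(self):
        t = np.linspace(0, 0.9, 360)
        p = 100 + 25 * np.sin(2 * np.pi * t / 0.9)
        split = separate_waves(p, np.zeros_like(p), 0.08)
        pt = p - p.mean()
        assert np.allclose(split.p_forward, pt / 2, atol=1e-12)
        assert np.allclose(split.p_backward, pt / 2, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            separate_waves(np.ones(10), np.ones(11), 0.1)


class TestLiljestrandZander:
    def test_reference_arithmetic(self):
        sv, co = liljestrand_zander(140.0, 74.0, 65.0)
        assert sv == pytest.approx(3.5 * 66.0 / 214.0)
        assert co == pytest.approx(sv * 65.0)

    def test_zero_pulse_pressure_gives_zero_output(self):
        assert liljestrand_zander(90.0, 90.0, 60.0) == (0.0, 0.0)

    def test_linear_in_the_calibration_factor(self):
        sv1, co1 = liljestrand_zander(120.0, 80.0, 70.0, k=3.5)
        sv2, co2 = liljestrand_zander(120.0, 80.0, 70.0, k=7.0)
        assert sv2 == pytest.approx(2 * sv1)
        assert co2 == pytest.approx(2 * co1)

    def test_invalid_pressures_rejected(self):
        with pytest.raises(ValueError):
            liljestrand_zander(80.0, 90.0, 60.0)
        with pytest.raises(ValueError):
            liljestrand_zander(90.0, 80.0, 0.0)
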