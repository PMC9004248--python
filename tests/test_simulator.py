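import numpy as np
import pandas as pd
import pytest

from hemowave import build_subject, simulate, Overrides, detect_equilibrium
from hemowave.simulator import HemoTrace, FS_OUT


def _dummy_trace(subject, maps, cos):
    """Minimal trace whose per-beat table is given (for equilibrium tests)."""
    beats = pd.DataFrame({
        "beat": np.arange(len(maps)),
        "t_onset_s": np.arange(len(maps)) * 0.9,
        "map": maps, "co_l_min": cos,
    })
    return HemoTrace(time=np.zeros(1), p_art=np.zeros(1), q_art=np.zeros(1),
                     fs=FS_OUT, beats=beats, volumes=np.zeros((1, 10)),
                     subject=subject, overrides=Overrides(), period_s=0.9)


class TestSimulate:
    def test_sampling_grid_is_exactly_400_hz(self, control_trace):
        dt = np.diff(control_trace.time)
        assert np.allclose(dt, 1.0 / 400.0, rtol=0, atol=1e-12)

    def test_pressure_ordering_every_beat(self, control_trace):
        b = control_trace.beats
        assert (b["dbp"] <= b["map"]).all()
        assert (b["map"] <= b["sbp"]).all()
        assert (b["pp"] == b["sbp"] - b["dbp"]).all()

    def test_closed_loop_conserves_volume_over_60s(self, subject60):
        tr = simulate(subject60, Overrides(), duration=60.0)
        tv = tr.total_volume
        drift = (tv.max() - tv.min()) / tv.mean()
        assert drift <= 1e-3

    def test_steady_state_beats_are_periodic(self, control_trace):
        n = int(round(control_trace.period_s * control_trace.fs))
        b1 = control_trace.p_art[-2 * n:-n]
        b2 = control_trace.p_art[-n:]
        assert np.sqrt(np.mean((b1 - b2) ** 2)) < 0.5

    def test_identical_inputs_give_bit_identical_traces(self, subject60):
        a = simulate(subject60, Overrides(svr=0.8), duration=10.0)
        b = simulate(subject60, Overrides(svr=0.8), duration=10.0)
        assert np.array_equal(a.p_art, b.p_art)
        assert np.array_equal(a.volumes, b.volumes)

    def test_zero_blood_volume_factor_rejected(self, subject60):
        with pytest.raises(ValueError, match="factor"):
            Overrides(blood_volume=0.0)

    def test_short_duration_rejected(self, subject60):
        with pytest.raises(ValueError, match=">= 10 s"):
            simulate(subject60, Overrides(), duration=5.0)

    def test_unfillable_volume_deficit_names_the_problem(self, subject60):
        with pytest.raises(ValueError, match="stressed volume"):
            simulate(subject60, Overrides(blood_volume=0.5), duration=10.0)

    def test_older_subject_has_larger_pulsatility(self):
        res = {}
        for age in (20, 80):
            tr = simulate(build_subject(age), Overrides(), duration=14.0)
            b = tr.beats.iloc[-3:]
            res[age] = (b["pp"] / b["map"]).mean()
        assert res[80] > res[20]

    def test_respiration_modulates_the_pressure_envelope(self, subject60, control_trace):
        from hemowave import Respiration
        tr = simulate(subject60, Overrides(respiration=Respiration()),
                      duration=30.0)
        ctrl_tr = simulate(subject60, Overrides(), duration=30.0)

        def detrended_std(sbp):
            # quadratic detrend removes the slow settling of the venous
            # reservoir but keeps the ~6-beat respiratory oscillation
            x = np.arange(sbp.size)
            return float((sbp - np.polyval(np.polyfit(x, sbp, 2), x)).std())

        swing = detrended_std(tr.beats["sbp"].iloc[-12:].to_numpy())
        ctrl = detrended_std(ctrl_tr.beats["sbp"].iloc[-12:].to_numpy())
        assert swing > 2 * ctrl


class TestDetectEquilibrium:
    def test_identical_beats_equilibrate_at_first_beat(self, subject60):
        tr = _dummy_trace(subject60, [100.0] * 8, [5.0] * 8)
        assert detect_equilibrium(tr) == 0

    def test_exponential_decay_matches_brute_force_rule(self, subject60):
        # MAP relaxes toward an asymptote with a 2 s time constant
        T, tau = 0.9, 2.0
        k = np.arange(40)
        maps = 80.0 + 30.0 * np.exp(-k * T / tau)
        cos = np.full(40, 5.0)
        tr = _dummy_trace(subject60, maps, cos)
        # oracle: exhaustive scan of the 1%-over-3-consecutive-beats rule
        expected = None
        for i in range(len(maps) - 3):
            if all(abs(maps[j + 1] - maps[j]) <= 0.01 * maps[j]
                   for j in range(i, i + 3)):
                expected = i
                break
        assert expected is not None
        assert detect_equilibrium(tr) == expected

    def test_persistent_drift_raises_with_advice(self, subject60):
        maps = 100.0 * (0.98 ** np.arange(20))  # -2% every beat, forever
        tr = _dummy_trace(subject60, maps, np.full(20, 5.0))
        with pytest.raises(RuntimeError, match="longer"):
            detect_equilibrium(tr)

    def test_too_few_beats_rejected(self, subject60):
        tr = _dummy_trace(subject60, [100.0] * 4, [5.0] * 4)
        with pytest.raises(ValueError, match="5"):
            detect_equilibrium(tr)

    def test_simulated_control_run_reaches_equilibrium(self, control_trace):
        eq = detect_equilibrium(control_trace)
        assert 0 <= eq < len(control_trace.beats) - 3
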