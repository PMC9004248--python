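"""Closed-loop circulation simulator producing peripheral arterial waveforms.

Stands in for a real-time lumped-parameter cardiovascular simulator: a
conservative electrical-analog network driven by double-Hill
time-varying elastance, sampled at 400 Hz at the peripheral artery.
Five physiological knobs are exposed as multiplicative overrides —
blood volume (preload), left-ventricular contractility, systemic
vascular resistance (afterload), heart rate, venous compliance — plus
sinusoidal spontaneous respiration via pleural pressure.

Unstressed volumes are frozen at the baseline subject, so a blood-volume
override acts on stressed volume: modest volume loss translates into a
marked preload/pressure response, as in hemorrhage.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import engine as eng
from .subjects import SubjectParams

__all__ = [
    "Respiration", "Overrides", "HemoTrace",
    "simulate", "detect_equilibrium", "FS_OUT",
]

FS_OUT = 400.0      # Hz, monitoring output rate
FS_INT = 2000.0     # Hz, internal integration rate


@dataclasses.dataclass(frozen=True)
class Respiration:
    """Sinusoidal spontaneous breathing applied as pleural pressure."""
    rate: float = 11.0          # breaths/min
    tidal_volume: float = 0.5   # liter


@dataclasses.dataclass(frozen=True)
class Overrides:
    """Multiplicative factors on subject knobs; 1.0 leaves it unchanged."""
    blood_volume: float = 1.0
    lv_contractility: float = 1.0
    svr: float = 1.0
    hr: float = 1.0
    venous_compliance: float = 1.0
    respiration: Optional[Respiration] = None

    def __post_init__(self) -> None:
        for name in ("blood_volume", "lv_contractility", "svr", "hr", "venous_compliance"):
            v = getattr(self, name)
            if not (0.0 < v <= 2.0):
                raise ValueError(f"override factor {name}={v!r} outside (0, 2]")


@dataclasses.dataclass
class HemoTrace:
    """A simulated trace plus per-beat clinical aggregates.

    ``time``/``p_art``/``q_art`` are uniformly sampled at ``fs`` (400 Hz);
    ``beats`` has one row per complete cardiac cycle with columns
    t_onset_s, sbp, dbp, map, pp [mmHg], sv_ml, co_l_min, lvef,
    cvp, lap, rap, pap [mmHg].  ``volumes`` are the ten compartment
    volumes [ml] at each sample; their row-sum is the total blood volume.
    """
    time: np.ndarray
    p_art: np.ndarray
    q_art: np.ndarray
    fs: float
    beats: pd.DataFrame
    volumes: np.ndarray
    subject: SubjectParams
    overrides: Overrides
    period_s: float

    @property
    def total_volume(self) -> np.ndarray:
        return self.volumes.sum(axis=1)

    def beat_slice(self, beat_index: int) -> slice:
        """Sample slice of one complete cardiac cycle."""
        i0 = int(round(beat_index * self.period_s * self.fs))
        i1 = int(round((beat_index + 1) * self.period_s * self.fs))
        return slice(i0, min(i1, self.time.size))


def _load_calibration() -> dict:
    text = resources.files("hemowave").joinpath("data/calibration.yaml").read_text()
    return yaml.safe_load(text)


_CAL = None


def calibration() -> dict:
    """The versioned internal-constant set (read once from package data)."""
    global _CAL
    if _CAL is None:
        _CAL = _load_calibration()
    return _CAL


def _pack(subject: SubjectParams, ov: Overrides) -> tuple[np.ndarray, np.ndarray]:
    """Build the packed parameter vector and initial state."""
    cal = calibration()
    art, val, hrt = cal["arterial"], cal["valves"], cal["heart"]
    ven, pul, act = cal["venous"], cal["pulmonary"], cal["activation"]
    tho, ini = cal["thorax"], cal["init_pressures"]

    p = np.zeros(eng.NP_PARAMS)
    hr = subject.hr * ov.hr
    p[eng.I_T] = 60.0 / hr
    # The tabulated contractility is a clinical index; the model's peak
    # elastance follows it through a power law anchored at the reference
    # value, so that deep contractility deficits depress ejection
    # fraction as steeply as observed clinically.
    lvc = subject.lv_contractility * ov.lv_contractility
    p[eng.I_EES_LV] = hrt["ees_anchor_lv"] * (lvc / hrt["ees_anchor_lv"]) ** hrt["ees_gamma"]
    p[eng.I_S_LV] = hrt["s_scale_lv"] * subject.lv_stiffness
    p[eng.I_LAM_LV] = hrt["lam_lv"]
    p[eng.I_V0_LV] = hrt["v0_lv"]
    p[eng.I_EES_RV] = subject.rv_contractility
    p[eng.I_S_RV] = hrt["s_scale_rv"] * subject.rv_stiffness
    p[eng.I_LAM_RV] = hrt["lam_rv"]
    p[eng.I_V0_RV] = hrt["v0_rv"]
    p[eng.I_E_LA] = hrt["e_la"]
    p[eng.I_V0_LA] = hrt["v0_la"]
    p[eng.I_E_RA] = hrt["e_ra"]
    p[eng.I_V0_RA] = hrt["v0_ra"]

    # arterial walls stiffen with distension: exponential P-V law whose
    # compliance matches the subject's tabulated total arterial
    # compliance at the anchor pressure
    c_total = 1.0 / subject.sys_art_stiffness
    b_art = art["b_nonlin"]
    anchor = art["p_anchor"] + b_art
    p[eng.I_B_ART] = b_art
    p[eng.I_VS_AO] = art["f_ao"] * c_total * anchor
    p[eng.I_V0_AO] = art["v0_ao"]
    p[eng.I_VS_A1] = art["f_a1"] * c_total * anchor
    p[eng.I_V0_A1] = art["v0_a1"]
    p[eng.I_VS_A2] = art["f_a2"] * c_total * anchor
    p[eng.I_V0_A2] = art["v0_a2"]
    p[eng.I_C_SV] = subject.venous_compliance * ov.venous_compliance
    p[eng.I_C_PA] = 1.0 / subject.pulm_art_stiffness
    p[eng.I_V0_PA] = pul["v0_pa"]
    p[eng.I_C_PV] = pul["c_pv"]
    p[eng.I_V0_PV] = pul["v0_pv"]

    p[eng.I_R_MV] = val["r_mitral"]
    p[eng.I_R_AV] = val["r_aortic"]
    p[eng.I_L_AV] = art["l_av"]
    p[eng.I_R1] = art["r_seg1"]
    p[eng.I_L1] = art["l_seg1"]
    p[eng.I_R2] = art["r_seg2"]
    p[eng.I_L2] = art["l_seg2"]
    p[eng.I_R_SVR] = ven["svr_scale"] * subject.svr * ov.svr
    p[eng.I_R_VEN] = ven["r_venous_return"]
    p[eng.I_R_TV] = val["r_tricuspid"]
    p[eng.I_R_PVAL] = val["r_pulmonary"]
    p[eng.I_R_PVR] = subject.pvr
    p[eng.I_R_PVEIN] = pul["r_pv_la"]

    p[eng.I_PPL0] = tho["ppl0"]
    if ov.respiration is not None:
        p[eng.I_RESP_AMP] = tho["resp_mmhg_per_l"] * ov.respiration.tidal_volume
        p[eng.I_RESP_HZ] = ov.respiration.rate / 60.0
    p[eng.I_TAU1] = act["tau1_frac"]
    p[eng.I_M1] = act["m1"]
    p[eng.I_TAU2] = act["tau2_frac"]
    p[eng.I_M2] = act["m2"]
    p[eng.I_EDV_REF] = act["edv_ref"]
    p[eng.I_ACT_EDV_EXP] = act["edv_exponent"]
    p[eng.I_ACT_NORM] = 1.0
    p[eng.I_ACT_NORM] = eng.activation_peak(p)

    # Initial volumes follow target distending pressures.  The baseline
    # subject (all pressures at their nominal targets) fixes the venous
    # unstressed volume; a blood-volume override then rescales every
    # initial distending pressure by a common factor k, found by
    # bisection so that the compartments sum to the overridden total.
    # Unstressed volumes stay fixed, so volume changes act on stressed
    # volume, and the start-up deficit is shared by the whole circuit
    # instead of draining one compartment during the transient.
    ppl0 = tho["ppl0"]

    def volumes(k: float, c_sv: float, v0_sv: float) -> np.ndarray:
        y = np.zeros(13)
        y[0] = p[eng.I_V0_LA] + k * (ini["p_la"] - ppl0) / p[eng.I_E_LA]
        y[1] = hrt["v0_lv"] + k * (ini["v_lv_init"] - hrt["v0_lv"])
        y[2] = p[eng.I_V0_AO] + p[eng.I_VS_AO] * np.log1p(k * (ini["p_ao"] - ppl0) / b_art)
        y[3] = p[eng.I_V0_A1] + p[eng.I_VS_A1] * np.log1p(k * ini["p_a1"] / b_art)
        y[4] = p[eng.I_V0_A2] + p[eng.I_VS_A2] * np.log1p(k * ini["p_a2"] / b_art)
        y[5] = v0_sv + c_sv * k * ini["p_sv"]
        y[6] = p[eng.I_V0_RA] + k * (ini["p_ra"] - ppl0) / p[eng.I_E_RA]
        y[7] = hrt["v0_rv"] + k * (ini["v_rv_init"] - hrt["v0_rv"])
        y[8] = p[eng.I_V0_PA] + p[eng.I_C_PA] * k * (ini["p_pa"] - ppl0)
        y[9] = p[eng.I_V0_PV] + p[eng.I_C_PV] * k * (ini["p_pv"] - ppl0)
        return y

    # venous unstressed volume from the baseline subject at k = 1
    base_no_sv = volumes(1.0, 0.0, 0.0).sum()
    v0_sv = subject.blood_volume - base_no_sv - subject.venous_compliance * ini["p_sv"]
    if v0_sv <= 0:
        raise ValueError("calibration inconsistent: negative venous unstressed volume")
    p[eng.I_V0_SV] = v0_sv

    target = ov.blood_volume * subject.blood_volume
    c_sv = p[eng.I_C_SV]
    lo, hi = 1e-3, 2.5
    if volumes(lo, c_sv, v0_sv).sum() > target:
        raise ValueError(
            "blood volume override removes more than the stressed volume; "
            "the circulation cannot be filled")
    if volumes(hi, c_sv, v0_sv).sum() < target:
        raise ValueError("blood volume override exceeds the fillable range")
    for _ in range(80):
        k = 0.5 * (lo + hi)
        if volumes(k, c_sv, v0_sv).sum() < target:
            lo = k
        else:
            hi = k
    y0 = volumes(0.5 * (lo + hi), c_sv, v0_sv)
    return p, y0


def _beat_table(t: np.ndarray, Y: np.ndarray, p: np.ndarray,
                period: float, hr: float) -> pd.DataFrame:
    pr = eng.passive_pressures(Y, p, t)
    p_art = pr["p_art"]
    n_beats = int(np.floor(t[-1] / period))
    rows = []
    fs = FS_OUT
    for k in range(n_beats):
        i0 = int(round(k * period * fs))
        i1 = int(round((k + 1) * period * fs))
        if i1 > t.size:
            break
        sl = slice(i0, i1)
        vlv = Y[sl, 1]
        sv = float(vlv.max() - vlv.min())
        sbp = float(p_art[sl].max())
        dbp = float(p_art[sl].min())
        rows.append({
            "beat": k,
            "t_onset_s": t[i0],
            "sbp": sbp,
            "dbp": dbp,
            "map": float(p_art[sl].mean()),
            "pp": sbp - dbp,
            "sv_ml": sv,
            "co_l_min": sv * hr / 1000.0,
            "lvef": sv / float(vlv.max()),
            "cvp": float(pr["p_sv"][sl].mean()),
            "lap": float(pr["p_la"][sl].mean()),
            "rap": float(pr["p_ra"][sl].mean()),
            "pap": float(pr["p_pa"][sl].mean()),
        })
    return pd.DataFrame(rows)


def simulate(subject: SubjectParams, overrides: Overrides | None = None,
             duration: float = 20.0) -> HemoTrace:
    """Run the closed loop and return the 400 Hz peripheral trace.

    Parameters
    ----------
    subject
        Baseline parameter set (see :func:`hemowave.subjects.build_subject`).
    overrides
        Multiplicative knob factors and optional respiration; defaults to
        the unmodified subject.
    duration
        Simulated time in seconds, at least 10 s so that equilibrium
        detection has enough beats to work with.

    Raises
    ------
    ValueError
        On invalid inputs.
    RuntimeError
        If a compartment volume turns negative or the state loses
        finiteness during integration (message names compartment and time).
    """
    ov = overrides if overrides is not None else Overrides()
    if duration < 10.0:
        raise ValueError(f"duration must be >= 10 s, got {duration}")
    p, y0 = _pack(subject, ov)

    dt = 1.0 / FS_INT
    rec_every = int(round(FS_INT / FS_OUT))
    n_steps = int(round(duration * FS_INT))
    Y, status, fail_comp, fail_t = eng.integrate(y0, p, dt, n_steps, rec_every)
    if status == 1:
        raise RuntimeError(
            f"negative volume in compartment '{eng.COMPARTMENTS[fail_comp]}' at t={fail_t:.3f} s")
    if status == 2:
        raise RuntimeError(
            f"non-finite state in compartment '{eng.COMPARTMENTS[fail_comp]}' at t={fail_t:.3f} s")

    t = np.arange(Y.shape[0]) / FS_OUT
    pr = eng.passive_pressures(Y, p, t)
    hr = subject.hr * ov.hr
    period = 60.0 / hr
    beats = _beat_table(t, Y, p, period, hr)
    return HemoTrace(
        time=t, p_art=pr["p_art"], q_art=Y[:, 12].copy(), fs=FS_OUT,
        beats=beats, volumes=Y[:, :10].copy(), subject=subject,
        overrides=ov, period_s=period,
    )


def detect_equilibrium(trace: HemoTrace, rel_tol: float = 0.01,
                       n_consecutive: int = 3) -> int:
    """First beat index from which MAP and CO are beat-to-beat stable.

    Stability means every beat-to-beat relative change of MAP and of CO
    over ``n_consecutive`` consecutive beat pairs stays below ``rel_tol``.
    Downstream feature extraction uses beats at or after this index.
    """
    beats = trace.beats
    if len(beats) < 5:
        raise ValueError("trace must contain at least 5 complete beats")
    maps = beats["map"].to_numpy()
    cos = beats["co_l_min"].to_numpy()
    for i in range(len(beats) - n_consecutive):
        ok = True
        for j in range(i, i + n_consecutive):
            if (abs(maps[j + 1] - maps[j]) > rel_tol * abs(maps[j])
                    or abs(cos[j + 1] - cos[j]) > rel_tol * abs(cos[j])):
                ok = False
                break
        if ok:
            return i
    raise RuntimeError(
        "no equilibrium found: MAP/CO still changing by >= "
        f"{rel_tol:.0%} per beat; run the simulation longer")
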