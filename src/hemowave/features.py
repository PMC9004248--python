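"""Per-beat waveform-morphology features, wave separation and pulse-contour
stroke-volume estimation.

Forty-five named scalars are computed for each beat, organized in eight
groups: absolute pressures at the fiducial points (7), relative
pressures between them (6), indices — relative pressures over pulse
pressure (4), durations of the cardiac-cycle phases (6), slopes (3),
areas and the myocardial oxygen supply/demand ratio (7), hemodynamic
estimates (Liljestrand–Zander stroke volume and cardiac output,
characteristic impedance; 3), and forward/backward wave-separation
features (9).

Wave separation uses the water-hammer split on the mean-removed
pulsatile components,

    Pf = (p̃ + Zc·q̃)/2,    Pb = (p̃ − Zc·q̃)/2,

with the characteristic impedance Zc estimated in the frequency domain
as the central tendency of |P(f)/Q(f)| over the beat harmonics between
5 and 15 Hz, where the arterial input impedance approaches Zc.

The Liljestrand–Zander stroke-volume estimate, SV = k·PP/(SBP+DBP) with
calibration factor k = 3.5, is a *relative* pulse-contour quantity used
for trend features only, never as absolute milliliters.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from .beats import Beat, FiducialPoints

__all__ = [
    "FEATURE_NAMES", "FEATURE_DEFINITIONS", "WaveSplit",
    "compute_features", "estimate_zc", "separate_waves",
    "liljestrand_zander", "feature_dictionary_json",
]

ZC_BAND = (5.0, 15.0)  # Hz

FEATURE_DEFINITIONS: dict[str, str] = {
    # (A) absolute pressures [mmHg]
    "dbp": "pressure at beat onset (diastolic blood pressure)",
    "sbp": "maximum pressure of the beat (systolic blood pressure)",
    "anacrotic_pressure": "pressure at the anacrotic notch",
    "dicrotic_pressure": "pressure at the dicrotic notch",
    "diastolic_peak_pressure": "pressure at the dicrotic-wave (diastolic) peak",
    "diastolic_end_pressure": "minimum pressure after the systolic peak",
    "map": "time-averaged pressure over the beat (mean arterial pressure)",
    # (B) relative pressures [mmHg]
    "pp": "pulse pressure: sbp - dbp",
    "augmented_pressure": ("reflection contribution at the anacrotic notch: "
                           "sbp - anacrotic pressure for an A-type notch, "
                           "anacrotic pressure - sbp for a C-type notch, 0 if absent"),
    "systolic_downstroke_pressure": "sbp - dicrotic notch pressure",
    "descending_pressure": "sbp - diastolic end pressure",
    "diastolic_upswing_pressure": "diastolic peak pressure - dicrotic notch pressure",
    "relative_dicrotic_pressure": "dicrotic notch pressure - diastolic end pressure",
    # (C) indices (relative pressure / pulse pressure) [-]
    "augmentation_index": "augmented_pressure / pp",
    "dicrotic_notch_index": "relative_dicrotic_pressure / pp",
    "descending_index": "descending_pressure / pp",
    "diastolic_upswing_index": "diastolic_upswing_pressure / pp",
    # (D) durations [s]
    "beat_duration": "duration of the full beat",
    "systolic_duration": "onset to dicrotic notch",
    "diastolic_duration": "dicrotic notch to beat end",
    "upstroke_duration": "onset to systolic peak",
    "downstroke_duration": "systolic peak to dicrotic notch",
    "time_to_anacrotic": "onset to anacrotic notch",
    # (E) slopes [mmHg/s]
    "dpdt_max": "maximum of the first derivative during the upstroke",
    "upstroke_slope": "pp / upstroke duration (mean systolic upstroke slope)",
    "downstroke_slope": ("(dicrotic pressure - sbp) / downstroke duration "
                         "(mean systolic downstroke slope, negative)"),
    # (F) areas [mmHg*s] and ratios [-]
    "total_area": "trapezoidal area under the full beat",
    "systolic_area": "area under the beat from onset to dicrotic notch",
    "diastolic_area": "area under the beat from dicrotic notch to end",
    "relative_systolic_area": "systolic area above the onset-pressure baseline",
    "relative_diastolic_area": "diastolic area above the onset-pressure baseline",
    "myocardial_oxygen_ratio": "diastolic_area / systolic_area (supply/demand)",
    "relative_myocardial_oxygen_ratio": "relative_diastolic_area / relative_systolic_area",
    # (G) hemodynamic estimates
    "sv_lz": "Liljestrand-Zander stroke volume: 3.5*pp/(sbp+dbp) [relative units]",
    "co_lz": "sv_lz * heart rate [relative units/min]",
    "zc": "characteristic impedance from 5-15 Hz harmonics of p and q [mmHg*s/ml]",
    # (H) wave separation
    "forward_peak": "maximum of the forward pressure wave (pulsatile) [mmHg]",
    "backward_peak": "maximum of the backward (reflected) pressure wave [mmHg]",
    "forward_peak_time": "time of the forward-wave peak from beat onset [s]",
    "backward_peak_time": "time of the backward-wave peak from beat onset [s]",
    "forward_area": "trapezoidal area under the forward wave [mmHg*s]",
    "backward_area": "trapezoidal area under the backward wave [mmHg*s]",
    "relative_forward_peak": "forward_peak / pp [-]",
    "relative_backward_peak": "backward_peak / pp [-]",
    "reflection_magnitude": "backward_peak / forward_peak [-]",
}

FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_DEFINITIONS)
assert len(FEATURE_NAMES) == 45

WAVE_FEATURES = FEATURE_NAMES[36:]


@dataclasses.dataclass(frozen=True)
class WaveSplit:
    """Forward/backward decomposition of one beat's pressure."""
    zc: float
    p_forward: np.ndarray
    p_backward: np.ndarray
    offset: float

    def reconstruct(self) -> np.ndarray:
        return self.p_forward + self.p_backward + self.offset


def estimate_zc(p: np.ndarray, q: np.ndarray, fs: float,
                band: tuple[float, float] = ZC_BAND) -> float:
    """Characteristic impedance from beat harmonics inside ``band``.

    Returns the median of |P(f_k)/Q(f_k)| over harmonics f_k = k/T of
    the beat that fall in the band, where the input impedance of the
    arterial tree flattens toward Zc.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size != q.size:
        raise ValueError("p and q length mismatch")
    if np.allclose(q, 0.0):
        raise ValueError("flow is identically zero: Zc undefined")
    n = p.size
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    sel[0] = False
    if not np.any(sel):
        raise ValueError(
            f"no beat harmonic falls in {band} Hz (beat of {n} samples at {fs} Hz)")
    # remove the endpoint mismatch of a single-beat window before the
    # FFT; without it spectral leakage dominates the band ratios
    ramp = np.arange(n) / n
    p = p - (p[0] + (p[-1] - p[0]) * ramp)
    q = q - (q[0] + (q[-1] - q[0]) * ramp)
    P = np.fft.rfft(p - p.mean())
    Q = np.fft.rfft(q - q.mean())
    mag_q = np.abs(Q[sel])
    if np.any(mag_q < 1e-12 * np.abs(Q).max()):
        raise ValueError("flow harmonic vanishes inside the Zc band")
    zc = float(np.median(np.abs(P[sel]) / mag_q))
    if not (np.isfinite(zc) and zc > 0):
        raise ValueError("characteristic impedance estimate is not positive/finite")
    return zc


def separate_waves(p: np.ndarray, q: np.ndarray, zc: float) -> WaveSplit:
    """Water-hammer forward/backward split on mean-removed components."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size != q.size:
        raise ValueError("p and q length mismatch")
    if not zc > 0:
        raise ValueError("zc must be positive")
    offset = float(p.mean())
    pt = p - offset
    qt = q - q.mean()
    pf = 0.5 * (pt + zc * qt)
    pb = 0.5 * (pt - zc * qt)
    return WaveSplit(zc=float(zc), p_forward=pf, p_backward=pb, offset=offset)


def liljestrand_zander(sbp: float, dbp: float, hr: float,
                       k: float = 3.5) -> tuple[float, float]:
    """Pulse-contour stroke volume and cardiac output (relative units)."""
    if not sbp > dbp:
        if sbp == dbp:
            return 0.0, 0.0
        raise ValueError("requires sbp >= dbp")
    if dbp < 0 or hr <= 0:
        raise ValueError("requires dbp >= 0 and hr > 0")
    if sbp + dbp == 0:
        raise ValueError("sbp + dbp must be nonzero")
    sv = k * (sbp - dbp) / (sbp + dbp)
    return sv, sv * hr


def compute_features(beat: Beat, fid: FiducialPoints,
                     split: Optional[WaveSplit] = None) -> dict[str, float]:
    """The 45-feature vector of one beat as an ordered name->value dict.

    The nine wave-separation features are NaN when ``split`` is omitted
    (no co-located flow available).
    """
    p, t, fs = beat.p, beat.t, beat.fs
    n = p.size
    i_pk = fid.systolic_peak.index
    i_dic = fid.dicrotic_notch.index
    i_ana = fid.anacrotic_notch.index
    i_dpk = fid.diastolic_peak.index
    i_de = fid.diastolic_end.index

    sbp = float(p[i_pk])
    dbp = float(p[0])
    pp = sbp - dbp
    if pp <= 0:
        raise ValueError("degenerate beat: pulse pressure is zero; "
                         "index features (augmentation_index, ...) undefined")

    if fid.anacrotic_type == "A":
        ap = sbp - float(p[i_ana])
    elif fid.anacrotic_type == "C":
        ap = float(p[i_ana]) - sbp
    else:
        ap = 0.0

    dt = 1.0 / fs
    area = float(np.trapezoid(p, dx=dt))
    sys_sl = slice(0, i_dic + 1)
    dia_sl = slice(i_dic, n)
    a_sys = float(np.trapezoid(p[sys_sl], dx=dt))
    a_dia = float(np.trapezoid(p[dia_sl], dx=dt))
    ra_sys = a_sys - dbp * (t[i_dic] - t[0])
    ra_dia = a_dia - dbp * (t[-1] - t[i_dic])

    d1 = np.gradient(p, dt)
    dpdt_max = float(d1[: i_pk + 1].max()) if i_pk > 0 else float(d1.max())

    up_dur = max(float(t[i_pk]), dt)
    down_dur = max(float(t[i_dic] - t[i_pk]), dt)
    hr = 60.0 / beat.duration
    sv, co = liljestrand_zander(sbp, dbp, hr)

    f: dict[str, float] = {
        "dbp": dbp,
        "sbp": sbp,
        "anacrotic_pressure": float(p[i_ana]),
        "dicrotic_pressure": float(p[i_dic]),
        "diastolic_peak_pressure": float(p[i_dpk]),
        "diastolic_end_pressure": float(p[i_de]),
        "map": area / beat.duration,
        "pp": pp,
        "augmented_pressure": ap,
        "systolic_downstroke_pressure": sbp - float(p[i_dic]),
        "descending_pressure": sbp - float(p[i_de]),
        "diastolic_upswing_pressure": float(p[i_dpk]) - float(p[i_dic]),
        "relative_dicrotic_pressure": float(p[i_dic]) - float(p[i_de]),
        "augmentation_index": ap / pp,
        "dicrotic_notch_index": (float(p[i_dic]) - float(p[i_de])) / pp,
        "descending_index": (sbp - float(p[i_de])) / pp,
        "diastolic_upswing_index": (float(p[i_dpk]) - float(p[i_dic])) / pp,
        "beat_duration": beat.duration,
        "systolic_duration": float(t[i_dic]),
        "diastolic_duration": beat.duration - float(t[i_dic]),
        "upstroke_duration": float(t[i_pk]),
        "downstroke_duration": float(t[i_dic] - t[i_pk]),
        "time_to_anacrotic": float(t[i_ana]),
        "dpdt_max": dpdt_max,
        "upstroke_slope": pp / up_dur,
        "downstroke_slope": (float(p[i_dic]) - sbp) / down_dur,
        "total_area": area,
        "systolic_area": a_sys,
        "diastolic_area": a_dia,
        "relative_systolic_area": ra_sys,
        "relative_diastolic_area": ra_dia,
        "myocardial_oxygen_ratio": a_dia / a_sys,
        "relative_myocardial_oxygen_ratio": (ra_dia / ra_sys) if ra_sys != 0 else np.nan,
        "sv_lz": sv,
        "co_lz": co,
    }

    if split is not None:
        pf, pb = split.p_forward, split.p_backward
        f["zc"] = split.zc
        f["forward_peak"] = float(pf.max())
        f["backward_peak"] = float(pb.max())
        f["forward_peak_time"] = float(t[int(np.argmax(pf))])
        f["backward_peak_time"] = float(t[int(np.argmax(pb))])
        f["forward_area"] = float(np.trapezoid(pf, dx=dt))
        f["backward_area"] = float(np.trapezoid(pb, dx=dt))
        f["relative_forward_peak"] = float(pf.max()) / pp
        f["relative_backward_peak"] = float(pb.max()) / pp
        f["reflection_magnitude"] = float(pb.max()) / float(pf.max()) if pf.max() != 0 else np.nan
    else:
        f["zc"] = np.nan
        for name in WAVE_FEATURES:
            f[name] = np.nan

    return {name: f[name] for name in FEATURE_NAMES}


def beat_features(beat: Beat) -> dict[str, float]:
    """Convenience: fiducials + (if flow present) wave split + features."""
    from .beats import detect_fiducials
    fid = detect_fiducials(beat)
    split = None
    if beat.q is not None:
        zc = estimate_zc(beat.p, beat.q, beat.fs)
        split = separate_waves(beat.p, beat.q, zc)
    return compute_features(beat, fid, split)


def feature_dictionary_json() -> str:
    """Machine-readable feature dictionary (name -> definition)."""
    return json.dumps(FEATURE_DEFINITIONS, indent=2)
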