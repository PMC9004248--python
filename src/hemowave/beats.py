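"""Beat segmentation and fiducial-point detection on arterial pressure waves.

A pressure trace is cut into beats at successive feet (the local minimum
preceding each steepest upstroke).  Within one beat, six landmarks are
located:

* onset — first sample (diastolic pressure of the beat),
* systolic peak — global pressure maximum,
* anacrotic notch — reflection shoulder before (A-type) or after
  (C-type) the systolic peak, found on the third derivative, with the
  second-derivative inflection as fallback; set at the peak (type
  ``none``) when neither exists,
* dicrotic notch — end-systolic incisura: explicit post-peak pressure
  minimum, else first-derivative maximum, else second-derivative
  minimum; falls back to one third of the beat when undetectable,
* diastolic peak — the dicrotic-wave maximum after the notch (flagged
  absent when diastole decays monotonically),
* diastolic end — pressure minimum after the systolic peak.

Derivatives are taken with a Savitzky–Golay smoothing differentiator
(~25 ms window, order 3); raw finite differences are too noisy for the
third-derivative shoulder rules.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["Beat", "FiducialPoints", "segment_beats", "detect_fiducials"]

MIN_BEAT_S = 0.25
SG_WINDOW_S = 0.025
DICROTIC_MIN_DELAY_S = 0.020
DICROTIC_MAX_FRAC = 0.60


@dataclasses.dataclass(frozen=True)
class Beat:
    """One segmented heartbeat, uniformly sampled at ``fs``."""
    p: np.ndarray               # mmHg
    fs: float                   # Hz
    q: Optional[np.ndarray] = None   # ml/s, co-located flow (optional)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.size < int(MIN_BEAT_S * self.fs):
            raise ValueError(f"beat shorter than {MIN_BEAT_S} s at fs={self.fs}")
        if not np.all(np.isfinite(p)):
            raise ValueError("beat pressure contains non-finite samples")
        if self.q is not None:
            q = np.asarray(self.q, dtype=float)
            if q.size != p.size:
                raise ValueError("pressure and flow length mismatch")
            object.__setattr__(self, "q", q)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.p.size) / self.fs

    @property
    def duration(self) -> float:
        return self.p.size / self.fs


@dataclasses.dataclass(frozen=True)
class Landmark:
    time: float       # s from beat onset
    pressure: float   # mmHg
    index: int


@dataclasses.dataclass(frozen=True)
class FiducialPoints:
    """The landmark set of one beat (times relative to beat onset)."""
    onset: Landmark
    systolic_peak: Landmark
    anacrotic_notch: Landmark
    anacrotic_type: str            # "A", "C" or "none"
    dicrotic_notch: Landmark
    dicrotic_fallback: bool        # True when set at 1/3 of the beat by rule
    diastolic_peak: Landmark
    diastolic_peak_present: bool
    diastolic_end: Landmark


def _sg(p: np.ndarray, fs: float, deriv: int) -> np.ndarray:
    win = int(round(SG_WINDOW_S * fs))
    win = max(win | 1, 5 + (deriv > 1) * 2)  # odd, long enough for the order
    order = 3 if deriv <= 2 else 4
    if win <= order:
        win = order + 2 - (order % 2)
        win |= 1
    return savgol_filter(p, win, order, deriv=deriv, delta=1.0 / fs, mode="interp")


def _local_minima(x: np.ndarray) -> np.ndarray:
    i = np.arange(1, x.size - 1)
    return i[(x[i] <= x[i - 1]) & (x[i] < x[i + 1])]


def _local_maxima(x: np.ndarray) -> np.ndarray:
    return _local_minima(-x)


def segment_beats(pressure: np.ndarray, fs: float,
                  hr_hint: float | None = None,
                  flow: np.ndarray | None = None) -> list[Beat]:
    """Cut a pressure series into beats at successive pressure feet.

    The foot of each beat is the local minimum preceding the steepest
    part of the systolic upstroke.  Partial first and last cycles are
    discarded.  ``hr_hint`` (beats/min) tightens the minimum distance
    between detected feet; without it a conservative 0.25 s refractory
    period is used.  ``flow``, when given, is cut at the same feet and
    attached to each beat (for wave separation).
    """
    p = np.asarray(pressure, dtype=float)
    if p.size < 2 * fs:
        raise ValueError("pressure series must be at least 2 s long")
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure contains non-finite samples")
    rng = float(p.max() - p.min())
    if rng < 1e-9:
        raise RuntimeError("flat signal: no pressure feet detectable")

    d1 = _sg(p, fs, 1)
    min_dist = int(0.6 * fs * 60.0 / hr_hint) if hr_hint else int(MIN_BEAT_S * fs)
    # steep upstrokes: d1 above half of its robust maximum
    thr = 0.5 * np.percentile(d1, 98)
    if thr <= 0:
        raise RuntimeError("no systolic upstrokes found")
    steep = d1 > thr
    # rising edges of the steep mask
    edges = np.flatnonzero(steep[1:] & ~steep[:-1]) + 1
    feet = []
    for e in edges:
        if feet and e - feet[-1] < min_dist:
            continue
        # walk back to the preceding local minimum of p
        i = e
        while i > 0 and p[i - 1] <= p[i]:
            i -= 1
        if feet and i - feet[-1] < min_dist:
            continue
        feet.append(i)
    if len(feet) < 2:
        raise RuntimeError("fewer than 2 pressure feet: cannot segment beats")
    beats = []
    for a, b in zip(feet[:-1], feet[1:]):
        if b - a >= int(MIN_BEAT_S * fs):
            q = None if flow is None else np.asarray(flow, dtype=float)[a:b].copy()
            beats.append(Beat(p=p[a:b].copy(), fs=fs, q=q))
    if not beats:
        raise RuntimeError("no complete beats between detected feet")
    return beats


def _detect_dicrotic(beat: Beat, i_peak: int) -> tuple[int, bool]:
    """Earliest incisura candidate in the search window.

    Candidates are (a) explicit local pressure minima, (b) local maxima
    of dp/dt while the pressure still falls (the decay transiently
    slowing at end-systole), (c) local minima of the second derivative.
    Derivative candidates need a minimal prominence so smoothing noise
    cannot fire the rule; the earliest surviving candidate of any kind
    wins.
    """
    from scipy.signal import find_peaks

    p, fs, n = beat.p, beat.fs, beat.p.size
    lo = i_peak + int(DICROTIC_MIN_DELAY_S * fs)
    hi = int(DICROTIC_MAX_FRAC * n)
    if hi - lo >= 3:
        w = slice(lo, hi)
        cands: list[int] = [lo + int(i) for i in _local_minima(p[w])]
        d1 = _sg(p, fs, 1)
        prom1 = 0.03 * float(np.ptp(d1[w])) if np.ptp(d1[w]) > 0 else None
        if prom1:
            pk, _ = find_peaks(d1[w], prominence=prom1)
            cands += [lo + int(i) for i in pk if d1[lo + int(i)] < 0]
        d2 = _sg(p, fs, 2)
        prom2 = 0.03 * float(np.ptp(d2[w])) if np.ptp(d2[w]) > 0 else None
        if prom2:
            pk, _ = find_peaks(-d2[w], prominence=prom2)
            cands += [lo + int(i) for i in pk]
        if cands:
            return min(cands), False
    return int(round(n / 3.0)), True


def _shoulder_candidates(beat: Beat, w: slice, kind: str) -> np.ndarray:
    """Third-derivative extrema inside ``w``, gated on a genuine slope
    plateau (an interior extremum of dp/dt of the matching sense)."""
    d1 = _sg(beat.p, beat.fs, 1)
    d3 = _sg(beat.p, beat.fs, 3)
    seg1 = d1[w]
    if kind == "A":
        gate = _local_minima(seg1)       # upstroke briefly slows
        cand = _local_maxima(d3[w])
    else:
        gate = _local_maxima(seg1)       # downstroke briefly slows
        cand = _local_minima(d3[w])
    if gate.size == 0 or cand.size == 0:
        return np.empty(0, dtype=int)
    # keep third-derivative extrema within 40 ms of a slope plateau
    tol = int(0.040 * beat.fs)
    keep = [c for c in cand if np.min(np.abs(gate - c)) <= tol]
    return np.asarray(keep, dtype=int)


def detect_fiducials(beat: Beat) -> FiducialPoints:
    """Locate the landmark set of one segmented beat.

    Fallback rules make detection total: an undetectable dicrotic notch
    is placed at one third of the beat (flagged), an undetectable
    anacrotic notch at the systolic peak (type ``none``), and an absent
    dicrotic wave pins the diastolic peak to the notch.
    """
    p, fs, n = beat.p, beat.fs, beat.p.size
    t = beat.t

    def lm(i: int) -> Landmark:
        return Landmark(time=float(t[i]), pressure=float(p[i]), index=int(i))

    i_peak = int(np.argmax(p))
    i_dic, dic_fb = _detect_dicrotic(beat, i_peak)

    # anacrotic notch: A-type shoulder on the upstroke first, then
    # C-type shoulder between peak and dicrotic notch, then inflection.
    margin = max(int(0.010 * fs), 2)
    ana_type = "none"
    i_ana = i_peak
    d3 = _sg(p, fs, 3)
    wA = slice(margin, max(i_peak - margin, margin))
    if wA.stop - wA.start > 4:
        cand = _shoulder_candidates(beat, wA, "A")
        if cand.size:
            best = cand[int(np.argmax(d3[wA.start + cand]))]
            i_ana, ana_type = wA.start + int(best), "A"
    if ana_type == "none":
        wC = slice(i_peak + margin, max(i_dic - margin, i_peak + margin))
        if wC.stop - wC.start > 4:
            cand = _shoulder_candidates(beat, wC, "C")
            if cand.size:
                best = cand[int(np.argmin(d3[wC.start + cand]))]
                i_ana, ana_type = wC.start + int(best), "C"
    if ana_type == "none" and wA.stop - wA.start > 4:
        # inflection fallback: a secondary maximum of d2 on the upstroke
        d2 = _sg(p, fs, 2)
        cand = _local_maxima(d2[wA])
        gate = _local_minima(_sg(p, fs, 1)[wA])
        tol = int(0.040 * fs)
        cand = np.asarray([c for c in cand if gate.size and np.min(np.abs(gate - c)) <= tol],
                          dtype=int)
        if cand.size:
            i_ana, ana_type = wA.start + int(cand[0]), "A"

    # diastolic end: minimum after the systolic peak
    i_dend = i_peak + int(np.argmin(p[i_peak:]))

    # diastolic peak: maximum strictly after the dicrotic notch
    dia_present = False
    i_dpk = i_dic
    if i_dic + 2 < n:
        post = p[i_dic:]
        cand = _local_maxima(post)
        if cand.size:
            i_dpk = i_dic + int(cand[0])
            dia_present = True

    return FiducialPoints(
        onset=lm(0),
        systolic_peak=lm(i_peak),
        anacrotic_notch=lm(i_ana),
        anacrotic_type=ana_type,
        dicrotic_notch=lm(i_dic),
        dicrotic_fallback=dic_fb,
        diastolic_peak=lm(i_dpk),
        diastolic_peak_present=dia_present,
        diastolic_end=lm(i_dend),
    )
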