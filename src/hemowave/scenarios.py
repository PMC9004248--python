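"""Experiment designs: stepwise deficit scenarios, baroreflex compensation,
age cohort and spontaneous-breathing runs.

A *reduction* scenario lowers one input variable — blood volume (BV,
preload), left-ventricular contractility (LVC) or systemic vascular
resistance (SVR, afterload) — in fixed steps of the baseline value (2%
for BV, which the circulation is most sensitive to, 5% for LVC and
SVR), re-equilibrating the model at every step, until diastolic or
pulse pressure drops below 20 mmHg or mean pressure below 30 mmHg.  The
violating step is excluded from the results.

A *baroreflex* scenario starts from a deficit tuned to MAP ~= 60 mmHg
and gradually changes one sympathetic compensator (heart rate, LVC or
SVR up; venous compliance down) in 2%-of-baseline sub-steps until MAP
recovers to 70 mmHg or the compensator hits its +/-100% cap.
Compensating a deficit with its own knob is rejected (it would simply
remove the cause).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .beats import Beat, segment_beats, detect_fiducials
from .features import beat_features, FEATURE_NAMES
from .simulator import Overrides, Respiration, HemoTrace, simulate, detect_equilibrium
from .subjects import SubjectParams, build_subject

log = logging.getLogger("hemowave")

__all__ = [
    "VARIABLES", "CAUSES", "StepResult", "ScenarioResult",
    "equilibrium_beat", "run_reduction", "run_baroreflex", "run_study",
    "StudyBundle",
]

# reduction variable -> (override knob, cause label, step size)
VARIABLES = {
    "BV": ("blood_volume", "preload", 0.02),
    "LVC": ("lv_contractility", "contractility", 0.05),
    "SVR": ("svr", "afterload", 0.05),
}
CAUSES = {cause: var for var, (_, cause, _) in VARIABLES.items()}

COMPENSATORS = {
    "HR": ("hr", +1),
    "LVC": ("lv_contractility", +1),
    "SVR": ("svr", +1),
    "VC": ("venous_compliance", -1),
}
# compensating a cause with its own knob just removes the cause
EXCLUDED_PAIRS = {
    ("contractility", "LVC"),
    ("afterload", "SVR"),
    ("preload", "VC"),
}

DEFAULT_LIMITS = {"dbp": 20.0, "pp": 20.0, "map": 30.0}


@dataclasses.dataclass
class StepResult:
    factor: float
    beat: Beat
    features: dict[str, float]
    aggregates: dict[str, float]


@dataclasses.dataclass
class ScenarioResult:
    scenario_id: str
    cause: str
    steps: list[StepResult]
    stop_reason: str

    def feature_table(self) -> pd.DataFrame:
        rows = []
        for i, st in enumerate(self.steps):
            row = {"scenario": self.scenario_id, "cause": self.cause,
                   "step": i, "factor": st.factor}
            row.update(st.features)
            rows.append(row)
        return pd.DataFrame(rows)


def _aggregates(trace: HemoTrace, eq_index: int) -> dict[str, float]:
    tail = trace.beats.iloc[max(eq_index, len(trace.beats) - 3):]
    return {k: float(tail[k].mean()) for k in
            ("sbp", "dbp", "map", "pp", "sv_ml", "co_l_min", "lvef",
             "cvp", "lap", "rap", "pap")}


def equilibrium_beat(subject: SubjectParams, overrides: Overrides,
                     duration: float = 15.0) -> tuple[Beat, dict[str, float]]:
    """Simulate, wait for MAP/CO equilibrium, return one settled beat
    (with co-located flow) and the equilibrium clinical aggregates."""
    trace = simulate(subject, overrides, duration=duration)
    try:
        eq = detect_equilibrium(trace)
    except RuntimeError:
        trace = simulate(subject, overrides, duration=2.5 * duration)
        eq = detect_equilibrium(trace)
    hr = subject.hr * overrides.hr
    beats = segment_beats(trace.p_art, trace.fs, hr_hint=hr, flow=trace.q_art)
    # the last complete segmented beat is the most settled one at/after
    # the equilibrium index
    return beats[-1], _aggregates(trace, eq)


def _violated(agg: dict[str, float], limits: dict[str, float]) -> Optional[str]:
    if agg["dbp"] < limits["dbp"]:
        return "dbp_limit"
    if agg["pp"] < limits["pp"]:
        return "pp_limit"
    if agg["map"] < limits["map"]:
        return "map_limit"
    return None


def run_reduction(subject: SubjectParams, variable: str,
                  limits: dict[str, float] | None = None,
                  step_size: float | None = None,
                  max_steps: int = 60,
                  step_duration: float = 15.0,
                  scenario_id: str | None = None) -> ScenarioResult:
    """Stepwise reduction of one input variable until a pressure limit.

    Returns the compliant steps only (factor 1.0 included); the first
    violating step fires the stop rule and is excluded.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {list(VARIABLES)}")
    knob, cause, default_step = VARIABLES[variable]
    step = default_step if step_size is None else step_size
    if not 0 < step < 1:
        raise ValueError("step size must be in (0, 1)")
    lim = DEFAULT_LIMITS if limits is None else limits
    sid = scenario_id or f"age{subject.age:.0f}_{cause}_reduction"

    steps: list[StepResult] = []
    stop_reason = "max_steps"
    for k in range(max_steps):
        factor = 1.0 - k * step
        if factor <= 0:
            stop_reason = "max_steps"
            break
        ov = Overrides(**{knob: factor})
        try:
            beat, agg = equilibrium_beat(subject, ov, duration=step_duration)
        except RuntimeError as e:
            log.info("scenario %s: circulation collapsed at factor %.2f (%s)",
                     sid, factor, e)
            stop_reason = "collapse"
            break
        reason = _violated(agg, lim)
        if reason is not None:
            stop_reason = reason
            break
        steps.append(StepResult(factor=factor, beat=beat,
                                features=beat_features(beat), aggregates=agg))
        log.debug("scenario %s step %d factor %.2f MAP %.1f", sid, k, factor, agg["map"])
    return ScenarioResult(scenario_id=sid, cause=cause, steps=steps,
                          stop_reason=stop_reason)


def _map_at(subject: SubjectParams, knob: str, factor: float,
            extra: dict[str, float] | None = None,
            duration: float = 15.0) -> tuple[float, Beat, dict[str, float]]:
    kw = dict(extra or {})
    kw[knob] = factor
    beat, agg = equilibrium_beat(subject, Overrides(**kw), duration=duration)
    return agg["map"], beat, agg


def find_factor_for_map(subject: SubjectParams, variable: str,
                        target_map: float = 60.0, tol: float = 1.0,
                        duration: float = 15.0) -> float:
    """Bisection on a reduction knob for a target mean pressure."""
    knob, _, _ = VARIABLES[variable]
    lo, hi = 0.05, 1.0  # MAP increases with the factor
    m_hi, _, _ = _map_at(subject, knob, hi, duration=duration)
    if m_hi < target_map:
        raise RuntimeError(f"baseline MAP {m_hi:.1f} already below target {target_map}")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        try:
            m, _, _ = _map_at(subject, knob, mid, duration=duration)
        except RuntimeError:
            lo = mid
            continue
        if abs(m - target_map) <= tol:
            return mid
        if m > target_map:
            hi = mid
        else:
            lo = mid
    raise RuntimeError(f"no {variable} factor found for MAP {target_map} +/- {tol} mmHg")


def run_baroreflex(subject: SubjectParams, cause: str, compensator: str,
                   unstable_map: float = 60.0, recovery_map: float = 70.0,
                   cap: float = 1.0, substep: float = 0.02,
                   step_duration: float = 15.0,
                   scenario_id: str | None = None) -> ScenarioResult:
    """Sympathetic compensation of a deficit tuned to MAP ~= 60 mmHg.

    ``cap`` is the maximal relative change of the compensator (1.0 means
    +100% for increases; decreases are capped at half the baseline).
    """
    if cause not in CAUSES:
        raise ValueError(f"unknown cause {cause!r}; expected one of {list(CAUSES)}")
    if compensator not in COMPENSATORS:
        raise ValueError(f"unknown compensator {compensator!r}")
    if (cause, compensator) in EXCLUDED_PAIRS:
        raise ValueError(
            f"compensator {compensator} is excluded for a {cause} deficit: "
            "raising it would simply remove the underlying cause")
    var = CAUSES[cause]
    cause_knob, _, _ = VARIABLES[var]
    comp_knob, sense = COMPENSATORS[compensator]
    sid = scenario_id or f"age{subject.age:.0f}_{cause}_baroreflex_{compensator}"

    cause_factor = find_factor_for_map(subject, var, target_map=unstable_map,
                                       duration=step_duration)
    extra = {cause_knob: cause_factor}
    cap_hi = 1.0 + cap if sense > 0 else 1.0
    cap_lo = 1.0 if sense > 0 else max(1.0 - cap, 0.5)

    steps: list[StepResult] = []
    stop_reason = "cap_reached"
    k = 0
    prev_factor = 1.0
    while True:
        factor = 1.0 + sense * k * substep
        factor = min(max(factor, cap_lo), cap_hi)
        m, beat, agg = _map_at(subject, comp_knob, factor, extra=extra,
                               duration=step_duration)
        steps.append(StepResult(factor=factor, beat=beat,
                                features=beat_features(beat), aggregates=agg))
        if m >= recovery_map:
            if m <= recovery_map + 1.0:
                stop_reason = "recovered"
                break
            # overshoot beyond tolerance: bisect between the last two factors
            f_lo, f_hi = (prev_factor, factor) if sense > 0 else (factor, prev_factor)
            for _ in range(20):
                fm = 0.5 * (f_lo + f_hi)
                m2, beat2, agg2 = _map_at(subject, comp_knob, fm, extra=extra,
                                          duration=step_duration)
                if abs(m2 - recovery_map) <= 1.0:
                    steps.append(StepResult(factor=fm, beat=beat2,
                                            features=beat_features(beat2),
                                            aggregates=agg2))
                    break
                if (m2 > recovery_map) == (sense > 0):
                    f_hi = fm
                else:
                    f_lo = fm
            stop_reason = "recovered"
            break
        if factor in (cap_lo, cap_hi) and k > 0:
            stop_reason = "cap_reached"
            break
        prev_factor = factor
        k += 1
    return ScenarioResult(scenario_id=sid, cause=cause, steps=steps,
                          stop_reason=stop_reason)


@dataclasses.dataclass
class StudyBundle:
    """All scenario results plus pooled tables for the analysis stage."""
    scenarios: dict[str, ScenarioResult]
    feature_table: pd.DataFrame       # one row per retained beat/step
    breathing_features: Optional[pd.DataFrame]  # per-beat features, 60 s run
    failures: dict[str, str]
    complete: bool


def breathing_features(subject: SubjectParams, rate: float = 11.0,
                       tidal_volume: float = 0.5,
                       duration: float = 70.0) -> pd.DataFrame:
    """Per-beat features of a control run with spontaneous breathing.

    The run is long enough to hold 60 s of equilibrated beats after the
    initial transient.
    """
    ov = Overrides(respiration=Respiration(rate=rate, tidal_volume=tidal_volume))
    trace = simulate(subject, ov, duration=duration)
    eq = detect_equilibrium(trace, rel_tol=0.05)
    t_eq = float(trace.beats["t_onset_s"].iloc[eq])
    sel = trace.time >= t_eq
    beats = segment_beats(trace.p_art[sel], trace.fs, hr_hint=subject.hr,
                          flow=trace.q_art[sel])
    rows = [beat_features(b) for b in beats]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "beat", np.arange(len(df)))
    return df


def run_study(config) -> StudyBundle:
    """Run the full experiment grid described by a StudyConfig."""
    from .config import StudyConfig
    if not isinstance(config, StudyConfig):
        raise TypeError("config must be a StudyConfig")
    scenarios: dict[str, ScenarioResult] = {}
    failures: dict[str, str] = {}
    tables = []

    for age in config.ages:
        subject = build_subject(age)
        # control point (factor 1.0 only)
        sid = f"age{age}_control"
        try:
            beat, agg = equilibrium_beat(subject, Overrides(),
                                         duration=config.step_duration_s)
            res = ScenarioResult(scenario_id=sid, cause="control",
                                 steps=[StepResult(1.0, beat, beat_features(beat), agg)],
                                 stop_reason="max_steps")
            scenarios[sid] = res
            tables.append(res.feature_table().assign(age=age))
        except Exception as e:  # pragma: no cover - defensive
            failures[sid] = str(e)
        for cause in config.causes:
            var = CAUSES[cause]
            sid = f"age{age}_{cause}_reduction"
            try:
                res = run_reduction(
                    subject, var,
                    limits=config.limits.model_dump(),
                    step_size=config.step_sizes[var],
                    max_steps=config.max_steps,
                    step_duration=config.step_duration_s,
                    scenario_id=sid)
                scenarios[sid] = res
                tables.append(res.feature_table().assign(age=age))
            except Exception as e:
                failures[sid] = str(e)
                log.warning("scenario %s failed: %s", sid, e)

    if config.baroreflex.enabled:
        subject = build_subject(config.baroreflex.age)
        for cause in config.causes:
            for comp in config.baroreflex.compensators:
                if (cause, comp) in EXCLUDED_PAIRS:
                    continue
                sid = f"age{config.baroreflex.age}_{cause}_baroreflex_{comp}"
                try:
                    res = run_baroreflex(
                        subject, cause, comp,
                        unstable_map=config.baroreflex.unstable_map,
                        recovery_map=config.baroreflex.recovery_map,
                        cap=config.baroreflex.cap,
                        substep=config.baroreflex.substep,
                        step_duration=config.step_duration_s,
                        scenario_id=sid)
                    scenarios[sid] = res
                    tables.append(res.feature_table().assign(age=config.baroreflex.age))
                except Exception as e:
                    failures[sid] = str(e)
                    log.warning("scenario %s failed: %s", sid, e)

    breathing = None
    if config.breathing.enabled:
        try:
            breathing = breathing_features(
                build_subject(config.breathing.age),
                rate=config.breathing.rate,
                tidal_volume=config.breathing.tidal_volume,
                duration=config.breathing.duration_s + 10.0)
        except Exception as e:
            failures["breathing"] = str(e)

    feature_table = (pd.concat(tables, ignore_index=True)
                     if tables else pd.DataFrame())
    return StudyBundle(scenarios=scenarios, feature_table=feature_table,
                       breathing_features=breathing, failures=failures,
                       complete=not failures)
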