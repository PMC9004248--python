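"""Fixed-step integrator core of the closed-loop circulation.

The circulation is an electrical-analog network of ten compliant
compartments (four heart chambers with time-varying elastance, a
three-segment systemic arterial chain, systemic veins, pulmonary artery
and veins) joined by resistances, three inertances and four
pressure-gated valves.  State vector (13 entries):

    0..9   compartment volumes [ml]:
           LA, LV, aorta, conduit artery, peripheral artery,
           systemic veins, RA, RV, pulmonary artery, pulmonary veins
    10     aortic valve flow [ml/s]          (inertial branch)
    11     aorta -> conduit artery flow
    12     conduit -> peripheral artery flow

Integration is classical RK4 at a fixed internal step (2 kHz), output
decimated to the 400 Hz monitoring rate.  The loop is JIT-compiled; the
network is strictly conservative (compartment volume derivatives are
pairwise flows), so total blood volume is conserved to round-off.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# parameter-vector layout (indices into the packed float64 array)
# systemic arterial compartments are exponential-elastic:
#   P(V) = B * (exp((V - V0)/Vs) - 1),  dV/dP = Vs/(P + B)
# so compliance falls with distension; Vs anchors the compliance at the
# reference pressure P_ANCHOR, B sets how nonlinear the wall is.
# Systolic duration follows ventricular filling: the activation curve is
# dilated per beat by (EDV/EDV_ref)^exp, mirroring the shortened
# ejection time of an underfilled ventricle.
NP_PARAMS = 49
(
    I_T, I_EES_LV, I_S_LV, I_LAM_LV, I_V0_LV,
    I_EES_RV, I_S_RV, I_LAM_RV, I_V0_RV,
    I_E_LA, I_V0_LA, I_E_RA, I_V0_RA,
    I_VS_AO, I_V0_AO, I_VS_A1, I_V0_A1, I_VS_A2, I_V0_A2,
    I_C_SV, I_V0_SV, I_C_PA, I_V0_PA, I_C_PV, I_V0_PV,
    I_R_MV, I_R_AV, I_L_AV, I_R1, I_L1, I_R2, I_L2,
    I_R_SVR, I_R_VEN, I_R_TV, I_R_PVAL, I_R_PVR, I_R_PVEIN,
    I_PPL0, I_RESP_AMP, I_RESP_HZ,
    I_ACT_NORM, I_TAU1, I_M1, I_TAU2, I_M2,
    I_B_ART, I_EDV_REF, I_ACT_EDV_EXP,
) = range(NP_PARAMS)

COMPARTMENTS = (
    "left_atrium", "left_ventricle", "aorta", "conduit_artery",
    "peripheral_artery", "systemic_veins", "right_atrium",
    "right_ventricle", "pulmonary_artery", "pulmonary_veins",
)


@njit(cache=True)
def _activation(tc: float, T: float, p: np.ndarray) -> float:
    """Double-Hill ventricular activation, normalized to peak 1."""
    x1 = (tc / (p[I_TAU1] * T)) ** p[I_M1]
    x2 = (tc / (p[I_TAU2] * T)) ** p[I_M2]
    return (x1 / (1.0 + x1)) / (1.0 + x2) / p[I_ACT_NORM]


def activation_peak(p: np.ndarray) -> float:
    """Unnormalized peak of the double-Hill product (set p[I_ACT_NORM]=1)."""
    T = p[I_T]
    t = np.linspace(0.0, T, 4001)
    x1 = (t / (p[I_TAU1] * T)) ** p[I_M1]
    x2 = (t / (p[I_TAU2] * T)) ** p[I_M2]
    return float(np.max((x1 / (1.0 + x1)) / (1.0 + x2)))


@njit(cache=True)
def _rhs(t: float, y: np.ndarray, p: np.ndarray, act_scale: float,
         out: np.ndarray) -> None:
    T = p[I_T]
    tc = (t % T) / act_scale
    a = _activation(tc, T, p)
    ppl = p[I_PPL0] - 0.5 * p[I_RESP_AMP] * (1.0 - math.cos(2.0 * math.pi * p[I_RESP_HZ] * t))

    vla, vlv, vao, va1, va2, vsv, vra, vrv, vpa, vpv = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8], y[9])
    qav, q1, q2 = y[10], y[11], y[12]

    pla = p[I_E_LA] * (vla - p[I_V0_LA]) + ppl
    ped = p[I_S_LV] * (math.exp(p[I_LAM_LV] * (vlv - p[I_V0_LV])) - 1.0)
    plv = ped + a * (p[I_EES_LV] * (vlv - p[I_V0_LV]) - ped) + ppl
    b = p[I_B_ART]
    pao = b * (math.expm1((vao - p[I_V0_AO]) / p[I_VS_AO])) + ppl
    pa1 = b * (math.expm1((va1 - p[I_V0_A1]) / p[I_VS_A1]))
    pa2 = b * (math.expm1((va2 - p[I_V0_A2]) / p[I_VS_A2]))
    psv = (vsv - p[I_V0_SV]) / p[I_C_SV]
    pra = p[I_E_RA] * (vra - p[I_V0_RA]) + ppl
    pedr = p[I_S_RV] * (math.exp(p[I_LAM_RV] * (vrv - p[I_V0_RV])) - 1.0)
    prv = pedr + a * (p[I_EES_RV] * (vrv - p[I_V0_RV]) - pedr) + ppl
    ppa = (vpa - p[I_V0_PA]) / p[I_C_PA] + ppl
    ppv = (vpv - p[I_V0_PV]) / p[I_C_PV] + ppl

    qmv = max(pla - plv, 0.0) / p[I_R_MV]
    qtv = max(pra - prv, 0.0) / p[I_R_TV]
    qpval = max(prv - ppa, 0.0) / p[I_R_PVAL]
    qsvr = (pa2 - psv) / p[I_R_SVR]
    qven = (psv - pra) / p[I_R_VEN]
    qpul = (ppa - ppv) / p[I_R_PVR]
    qpvla = (ppv - pla) / p[I_R_PVEIN]

    if qav > 0.0 or plv > pao:
        dqav = (plv - pao - p[I_R_AV] * qav) / p[I_L_AV]
    else:
        dqav = 0.0

    out[0] = qpvla - qmv
    out[1] = qmv - qav
    out[2] = qav - q1
    out[3] = q1 - q2
    out[4] = q2 - qsvr
    out[5] = qsvr - qven
    out[6] = qven - qtv
    out[7] = qtv - qpval
    out[8] = qpval - qpul
    out[9] = qpul - qpvla
    out[10] = dqav
    out[11] = (pao - pa1 - p[I_R1] * q1) / p[I_L1]
    out[12] = (pa1 - pa2 - p[I_R2] * q2) / p[I_L2]


@njit(cache=True)
def integrate(y0: np.ndarray, p: np.ndarray, dt: float, n_steps: int,
              rec_every: int):
    """RK4 march; returns (states at decimation points, status, fail info).

    status 0 ok, 1 negative compartment volume, 2 non-finite state;
    fail_comp is the offending compartment index, fail_t the time [s].
    """
    n_rec = n_steps // rec_every
    Y = np.empty((n_rec, y0.size))
    y = y0.copy()
    k1 = np.empty_like(y)
    k2 = np.empty_like(y)
    k3 = np.empty_like(y)
    k4 = np.empty_like(y)
    yt = np.empty_like(y)
    status = 0
    fail_comp = -1
    fail_t = 0.0
    irec = 0
    T = p[I_T]
    act_scale = 1.0
    beat_idx = -1
    for i in range(n_steps):
        t = i * dt
        bi = int(t / T)
        if bi != beat_idx:
            beat_idx = bi
            s = (y[1] / p[I_EDV_REF]) ** p[I_ACT_EDV_EXP]
            act_scale = min(max(s, 0.6), 1.35)
        if i % rec_every == 0:
            for j in range(10):
                if not math.isfinite(y[j]):
                    status = 2
                    fail_comp = j
                    fail_t = t
                    break
                if y[j] < 0.0:
                    status = 1
                    fail_comp = j
                    fail_t = t
                    break
            if status != 0:
                break
            Y[irec] = y
            irec += 1
        _rhs(t, y, p, act_scale, k1)
        for j in range(y.size):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(t + 0.5 * dt, yt, p, act_scale, k2)
        for j in range(y.size):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(t + 0.5 * dt, yt, p, act_scale, k3)
        for j in range(y.size):
            yt[j] = y[j] + dt * k3[j]
        _rhs(t + dt, yt, p, act_scale, k4)
        for j in range(y.size):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if y[10] < 0.0:
            y[10] = 0.0  # aortic valve closes; no retrograde flow
    return Y[:irec], status, fail_comp, fail_t


def passive_pressures(Y: np.ndarray, p: np.ndarray, t: np.ndarray) -> dict:
    """Vectorized pressures of the passive compartments at output times."""
    ppl = p[I_PPL0] - 0.5 * p[I_RESP_AMP] * (1.0 - np.cos(2.0 * np.pi * p[I_RESP_HZ] * t))
    b = p[I_B_ART]
    return {
        "p_la": p[I_E_LA] * (Y[:, 0] - p[I_V0_LA]) + ppl,
        "p_ao": b * np.expm1((Y[:, 2] - p[I_V0_AO]) / p[I_VS_AO]) + ppl,
        "p_art": b * np.expm1((Y[:, 4] - p[I_V0_A2]) / p[I_VS_A2]),
        "p_sv": (Y[:, 5] - p[I_V0_SV]) / p[I_C_SV],
        "p_ra": p[I_E_RA] * (Y[:, 6] - p[I_V0_RA]) + ppl,
        "p_pa": (Y[:, 8] - p[I_V0_PA]) / p[I_C_PA] + ppl,
        "p_pv": (Y[:, 9] - p[I_V0_PV]) / p[I_C_PV] + ppl,
    }
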