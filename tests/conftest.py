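"""Shared fixtures: expensive simulation runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from hemowave import build_subject, simulate, Overrides


@pytest.fixture(scope="session")
def subject60():
    return build_subject(60)


@pytest.fixture(scope="session")
def control_trace(subject60):
    """16 s control run of the 60-year subject."""
    return simulate(subject60, Overrides(), duration=16.0)


@pytest.fixture(scope="session")
def reduction_results(subject60):
    """The three 60-year stepwise reduction scenarios."""
    from hemowave.scenarios import run_reduction
    return {v: run_reduction(subject60, v) for v in ("BV", "LVC", "SVR")}


@pytest.fixture(scope="session")
def feature_table_60(reduction_results):
    import pandas as pd
    return pd.concat([r.feature_table() for r in reduction_results.values()],
                     ignore_index=True)


def two_gaussian_beat(fs=400.0, t_main=0.20, w_main=0.07, a_main=60.0,
                      t_refl=0.45, w_refl=0.09, a_refl=25.0,
                      base=70.0, duration=0.9):
    """Analytic beat: main systolic pulse plus delayed reflected pulse.

    Returns (pressure samples, exact time of the inter-pulse minimum
    found by dense evaluation of the closed form).
    """
    t = np.arange(0.0, duration, 1.0 / fs)

    def f(x):
        return (base + a_main * np.exp(-((x - t_main) / w_main) ** 2)
                + a_refl * np.exp(-((x - t_refl) / w_refl) ** 2))

    dense = np.arange(t_main, t_refl, 1e-5)
    t_min = dense[np.argmin(f(dense))]
    return f(t), float(t_min)


def two_logistic_beat(fs=400.0, t1=0.08, k1=0.012, a1=40.0,
                      t2=0.20, k2=0.012, a2=30.0, base=70.0, duration=0.9):
    """Beat with a pre-peak shoulder: sum of two logistic upstrokes with a
    linear fall-off after the plateau.  Returns (samples, exact time of
    the shoulder's third-derivative maximum, located on a dense grid
    with closed-form logistic derivatives: the d3 maximum nearest the
    slope minimum between the rises)."""
    t = np.arange(0.0, duration, 1.0 / fs)

    def logi(x, t0, k):
        return 1.0 / (1.0 + np.exp(-(x - t0) / k))

    def f(x):
        return (base + a1 * logi(x, t1, k1) + a2 * logi(x, t2, k2)
                - 35.0 * np.clip(x - 0.30, 0.0, None))

    def d1(x):
        s1, s2 = logi(x, t1, k1), logi(x, t2, k2)
        return a1 / k1 * s1 * (1 - s1) + a2 / k2 * s2 * (1 - s2)

    def d3(x):
        out = 0.0
        for a, t0, k in ((a1, t1, k1), (a2, t2, k2)):
            s = logi(x, t0, k)
            out = out + a / k ** 3 * s * (1 - s) * (1 - 6 * s + 6 * s ** 2)
        return out

    dense = np.arange(t1, t2, 1e-5)
    t_dip = dense[np.argmin(d1(dense))]
    win = np.arange(t_dip - 0.04, t_dip + 0.04, 1e-5)
    t_sh = win[np.argmax(d3(win))]
    return f(t), float(t_sh)
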