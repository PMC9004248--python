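"""Feature-analysis stage: one-at-a-time sensitivity, waveform
normalization, principal-component analysis and the respiratory
stability check.

Sensitivity of a feature to an input variable is the percent change of
the feature divided by the percent change of the variable (signed;
undefined when the baseline feature is zero).  PCA is run either on
single beats normalized to the unit square (morphology only, pressure
level removed) or on the z-scored feature table; the "correlation" of a
PC is the Pearson correlation between each input column (time sample or
feature) and the PC score vector, and variables with |r| > 0.25 are
reported as the screening hits.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .beats import Beat

__all__ = [
    "sensitivity", "sensitivity_table", "normalize_beat",
    "PCAResult", "pca", "pc_correlations", "screen_correlations",
    "respiratory_stability",
]

PERTURBATIONS = (10.0, -10.0, -30.0)  # percent change of the input variable
SCREEN_THRESHOLD = 0.25


def sensitivity(f_base: float, f_changed: float, input_change_pct: float) -> float:
    """Percent feature change over percent input change, signed.

    Returns NaN (recorded as missing, never as 0) when the baseline
    feature is zero or either value is not finite.
    """
    if input_change_pct == 0:
        raise ValueError("input change must be nonzero")
    if not (np.isfinite(f_base) and np.isfinite(f_changed)) or f_base == 0:
        return float("nan")
    return ((f_changed - f_base) / abs(f_base) * 100.0) / input_change_pct


def sensitivity_table(base_features: dict[str, float],
                      perturbed: dict[tuple[str, float], dict[str, float]],
                      ) -> pd.DataFrame:
    """Tidy sensitivity grid: feature x variable x perturbation.

    ``perturbed`` maps (variable, perturbation_pct) to that run's
    feature dict; the baseline is the unperturbed feature dict.
    """
    rows = []
    for (var, pct), feats in perturbed.items():
        for name, f1 in feats.items():
            rows.append({
                "feature": name, "variable": var, "perturbation_pct": pct,
                "sensitivity": sensitivity(base_features.get(name, np.nan), f1, pct),
            })
    return pd.DataFrame(rows)


def normalize_beat(beat: Beat | np.ndarray, n_samples: int = 200) -> np.ndarray:
    """Resample one beat to the unit square: time and pressure in [0, 1].

    Affine transformations of pressure (a·p + b, a > 0) leave the result
    unchanged, so normalized curves compare morphology only.
    """
    p = beat.p if isinstance(beat, Beat) else np.asarray(beat, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("beat must be a 1-D series of at least 2 samples")
    rng = float(p.max() - p.min())
    if rng <= 0:
        raise ValueError("constant beat: zero pressure range, cannot normalize")
    x_new = np.linspace(0.0, 1.0, n_samples)
    x_old = np.linspace(0.0, 1.0, p.size)
    r = np.interp(x_new, x_old, p)
    return (r - r.min()) / (r.max() - r.min())


@dataclasses.dataclass
class PCAResult:
    """Scores, explained variance [%], components and PC correlations."""
    scores: np.ndarray             # observations x components
    explained_variance: np.ndarray  # percent, non-increasing, sums to 100
    components: np.ndarray         # components x variables
    mean: np.ndarray
    scale: np.ndarray | None       # per-variable std when standardized
    correlations: np.ndarray       # variables x components (Pearson r)

    def reconstruct(self) -> np.ndarray:
        x = self.scores @ self.components
        if self.scale is not None:
            x = x * self.scale
        return x + self.mean


def pc_correlations(matrix: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of every input column with every PC score.

    Zero-variance columns yield NaN (undefined, excluded from screening).
    """
    X = np.asarray(matrix, dtype=float)
    S = np.asarray(scores, dtype=float)
    Xc = X - X.mean(axis=0)
    Sc = S - S.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    ss = np.sqrt((Sc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Sc) / np.outer(sx, ss)
    r[sx == 0, :] = np.nan
    r[:, ss == 0] = np.nan
    return r


def pca(matrix: np.ndarray, standardize: bool = False) -> PCAResult:
    """Centered (optionally z-scored) principal-component decomposition.

    Keeps all components, so the explained-variance percentages sum to
    100 and the decomposition reconstructs the input exactly.  Component
    signs are fixed deterministically: the largest-magnitude column
    correlation of each PC is made positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 3 observations and >= 2 variables")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains missing/non-finite values")
    mean = X.mean(axis=0)
    scale = None
    Xw = X - mean
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = int(np.flatnonzero(scale == 0)[0])
            raise ValueError(f"constant column {bad} cannot be standardized")
        Xw = Xw / scale

    k = min(Xw.shape)
    sk = _SkPCA(n_components=k, svd_solver="full")
    scores = sk.fit_transform(Xw)
    components = sk.components_
    var = sk.explained_variance_
    total = var.sum()
    explained = 100.0 * var / total if total > 0 else np.full(k, np.nan)

    r = pc_correlations(X, scores)
    for j in range(k):
        col = r[:, j]
        if np.all(np.isnan(col)):
            continue
        i = int(np.nanargmax(np.abs(col)))
        if col[i] < 0:
            scores[:, j] *= -1.0
            components[j, :] *= -1.0
            r[:, j] *= -1.0
    return PCAResult(scores=scores, explained_variance=explained,
                     components=components, mean=mean, scale=scale,
                     correlations=r)


def screen_correlations(result: PCAResult, names: list[str],
                        n_components: int = 2,
                        threshold: float = SCREEN_THRESHOLD) -> dict[str, list[str]]:
    """Variables with |r| above threshold per leading PC."""
    out = {}
    for j in range(min(n_components, result.correlations.shape[1])):
        col = result.correlations[:, j]
        hits = [names[i] for i in np.argsort(-np.abs(col))
                if np.isfinite(col[i]) and abs(col[i]) > threshold]
        out[f"PC{j + 1}"] = hits
    return out


def respiratory_stability(features: pd.DataFrame) -> pd.Series:
    """Relative standard deviation [%] of each feature over the run.

    RSD = sd / |mean| * 100 per feature column; NaN (missing) where the
    mean is zero or the feature is undefined.  At least 10 beats are
    required for a meaningful spread estimate.
    """
    num = features.select_dtypes("number").drop(columns=["beat"], errors="ignore")
    if len(num) < 10:
        raise ValueError("need at least 10 beats of features")
    mean = num.mean()
    sd = num.std(ddof=0)
    rsd = sd / mean.abs() * 100.0
    rsd[mean == 0] = np.nan
    return rsd
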