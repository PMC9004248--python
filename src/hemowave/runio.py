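"""Trace/feature serialization and run-bundle export with provenance.

CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header with
unit-suffixed column names (times in seconds, pressures in mmHg, flows
in ml/s).  Every trace CSV travels with a JSON sidecar holding the
per-beat aggregates and the full parameter provenance (subject and
override factors), so any written file can be traced back to the run
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulator import HemoTrace, Overrides, Respiration
from .subjects import SubjectParams

__all__ = [
    "write_trace", "read_trace", "write_features", "read_features",
    "export_bundle",
]

TRACE_COLUMNS = ("time_s", "p_art_mmHg", "q_art_ml_s")


def write_trace(trace: HemoTrace, path: str | Path) -> Path:
    """Write a trace CSV plus its JSON sidecar (returns the CSV path)."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "p_art_mmHg": trace.p_art,
        "q_art_ml_s": trace.q_art,
    })
    df.to_csv(path, index=False, float_format="%.17g")
    ov = dataclasses.asdict(trace.overrides)
    if trace.overrides.respiration is not None:
        ov["respiration"] = dataclasses.asdict(trace.overrides.respiration)
    sidecar = {
        "fs_hz": trace.fs,
        "subject": dataclasses.asdict(trace.subject),
        "overrides": ov,
        "beats": trace.beats.to_dict(orient="records"),
        "software_version": __version__,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path: str | Path) -> HemoTrace:
    """Reload a written trace (round-trips within 1e-12)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns {sorted(missing)}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    ov_d = dict(sidecar["overrides"])
    resp = ov_d.pop("respiration", None)
    ov = Overrides(**ov_d, respiration=Respiration(**resp) if resp else None)
    subject = SubjectParams(**sidecar["subject"])
    t = df["time_s"].to_numpy()
    fs = float(sidecar["fs_hz"])
    return HemoTrace(
        time=t, p_art=df["p_art_mmHg"].to_numpy(),
        q_art=df["q_art_ml_s"].to_numpy(), fs=fs,
        beats=pd.DataFrame(sidecar["beats"]),
        volumes=np.empty((0, 10)), subject=subject, overrides=ov,
        period_s=60.0 / (subject.hr * ov.hr),
    )


def write_features(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.12g")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_bundle(bundle, out_dir: str | Path, config=None) -> dict:
    """Write a study bundle to a run directory and return its manifest.

    Layout: one feature CSV per scenario, the pooled feature table, the
    breathing feature table, and ``manifest.json`` with config hash,
    software version and per-file checksums.  A bundle with recorded
    per-scenario failures is marked incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise RuntimeError(f"output directory {out} is not writable: {e}") from e

    files: dict[str, str] = {}
    for sid, res in bundle.scenarios.items():
        p = write_features(res.feature_table(), out / f"{sid}_features.csv")
        files[p.name] = _sha256(p)
    if not bundle.feature_table.empty:
        p = write_features(bundle.feature_table, out / "feature_table.csv")
        files[p.name] = _sha256(p)
    if bundle.breathing_features is not None:
        p = write_features(bundle.breathing_features, out / "breathing_features.csv")
        files[p.name] = _sha256(p)

    cfg_dump = config.model_dump() if config is not None else None
    manifest = {
        "software_version": __version__,
        "config": cfg_dump,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dump, sort_keys=True).encode()).hexdigest(),
        "complete": bundle.complete,
        "failures": bundle.failures,
        "scenarios": {sid: {"cause": r.cause, "n_steps": len(r.steps),
                            "stop_reason": r.stop_reason}
                      for sid, r in bundle.scenarios.items()},
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
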