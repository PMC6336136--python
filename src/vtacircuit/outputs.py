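"""Serialization of traces, session summaries and run manifests.

One tidy CSV per trial trace, one summary CSV per session, and a JSON
manifest listing every emitted file together with the config hash, the seed
and the package version, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .circuit import TrialTrace
from .config import RunConfig, config_to_dict
from .plasticity import SessionResult

__all__ = [
    "trace_frame",
    "session_frame",
    "write_outputs",
    "config_hash",
    "make_fixtures",
]

TRACE_COLUMNS = [
    "time_s",
    "nu_pfc",
    "nu_pptg",
    "nu_g",
    "nu_d",
    "adaptation",
    "ach_uM",
    "nic_uM",
    "receptor_a",
    "receptor_s",
]


def trace_frame(trace: TrialTrace) -> pd.DataFrame:
    """Tidy per-step record of one trial."""
    return pd.DataFrame(
        {
            "time_s": trace.time,
            "nu_pfc": trace.nu_pfc,
            "nu_pptg": trace.nu_pptg,
            "nu_g": trace.nu_g,
            "nu_d": trace.nu_d,
            "adaptation": trace.adaptation,
            "ach_uM": trace.ach,
            "nic_uM": trace.nic,
            "receptor_a": trace.receptor_a,
            "receptor_s": trace.receptor_s,
        }
    )


def session_frame(session: SessionResult) -> pd.DataFrame:
    """One row per conditioning trial: weights used and measurements."""
    rows = []
    for n, (w, m) in enumerate(zip(session.weights, session.measures), start=1):
        rows.append(
            {
                "trial": n,
                "j_pfc": w.j_pfc,
                "w_pfc_d": w.w_pfc_d,
                "delta": m.delta,
                "dt_da": m.dt_da,
                "cs_peak": m.cs_peak,
                "us_peak": m.us_peak,
            }
        )
    return pd.DataFrame(rows)


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical YAML dump of the configuration."""
    canonical = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    # full-precision floats; fixed format keeps reruns byte-identical
    frame.to_csv(path, index=False, float_format="%.17g")


def write_outputs(
    out_dir: str | Path,
    cfg: RunConfig,
    *,
    session: SessionResult | None = None,
    traces: dict[str, TrialTrace] | None = None,
    extra_json: dict[str, dict] | None = None,
) -> dict:
    """Write all artifacts of a run plus a manifest; returns the manifest.

    ``traces`` maps file stems to traces; ``extra_json`` maps file stems to
    JSON-serializable payloads (e.g. decision summaries).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    if session is not None:
        path = out / "session_summary.csv"
        _write_csv(session_frame(session), path)
        files.append(path.name)
        for n, trace in sorted(session.traces.items()):
            path = out / f"trace_trial_{n + 1:03d}.csv"
            _write_csv(trace_frame(trace), path)
            files.append(path.name)
    for stem, trace in (traces or {}).items():
        path = out / f"{stem}.csv"
        _write_csv(trace_frame(trace), path)
        files.append(path.name)
    for stem, payload in (extra_json or {}).items():
        path = out / f"{stem}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        files.append(path.name)

    (out / "config.yaml").write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    )
    files.append("config.yaml")

    manifest = {
        "config_sha256": config_hash(cfg),
        "seed": cfg.seed,
        "package_version": __version__,
        "python_version": platform.python_version(),
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Generate the small YAML configs used by the test suite.

    default        : empty file, resolving to full defaults
    mini           : a 5-trial conditioning setup (fast end-to-end runs)
    receptor_only  : pharmacology-focused config (nicotine bath)
    decision_equal : decision task with equal rewards (symmetry fixture)
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = {
        "default": "",
        "mini": yaml.safe_dump(
            {"protocol": {"reward_size": 4.0}, "seed": 1}, sort_keys=True
        ),
        "receptor_only": yaml.safe_dump(
            {
                "pharmacology": {
                    "pre_exposure_duration": 300.0,
                    "pre_exposure_concentration": 1.0,
                }
            },
            sort_keys=True,
        ),
        "decision_equal": yaml.safe_dump(
            {"decision": {"reward_sizes": [4.0, 4.0, 4.0], "n_choices": 2000}},
            sort_keys=True,
        ),
    }
    paths = {}
    for name, text in fixtures.items():
        path = out / f"{name}.yaml"
        path.write_text(text)
        paths[name] = path
    return paths
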