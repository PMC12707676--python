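"""Configuration files, CSV dialects and run manifests.

Times are hours, doses nM and fractions live in [0, 1] in every file.  Runs
write a JSON manifest (config hash, seed, package version) next to their
outputs so any result is reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import params as _params
from .calibration import TrajectoryData
from .params import BaselineParams, G2MTreatmentParams, STreatmentParams

__all__ = ["load_config", "resolve_model", "write_manifest",
           "write_trajectory", "read_trajectory", "write_curves"]

_MODEL_KINDS = ("untreated", "g2m", "s", "combination")


def load_config(path) -> dict:
    """Load and validate a YAML run configuration.

    Recognized keys: ``model`` (untreated|g2m|s|combination), ``preset``
    (model1|model2|model3), ``baseline``/``g2m``/``s`` parameter blocks,
    ``doses`` (nM list), ``grid`` ({step, horizon}), ``seed``.
    Raises ``ValueError`` naming the first failing invariant.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    kind = cfg.get("model", "untreated")
    if kind not in _MODEL_KINDS:
        raise ValueError(f"model must be one of {_MODEL_KINDS}")
    if "preset" in cfg and cfg["preset"] not in _params.PRESETS:
        raise ValueError(f"unknown preset {cfg['preset']!r}")
    doses = cfg.get("doses", [])
    if any(d < 0 for d in doses):
        raise ValueError("doses must be nonnegative")
    grid = cfg.get("grid", {})
    if grid.get("step", 0.1) <= 0:
        raise ValueError("grid.step must be positive")
    if grid.get("horizon", 72.0) <= 0:
        raise ValueError("grid.horizon must be positive")
    return cfg


def resolve_model(cfg: dict):
    """Return (baseline, g2m_params or None, s_params or None) from a config."""
    if "preset" in cfg:
        preset = _params.PRESETS[cfg["preset"]]
        base, g2m, s = preset["baseline"], preset["g2m"], preset["s"]
    else:
        base = g2m = s = None
    if "baseline" in cfg:
        base = BaselineParams(**cfg["baseline"])
    if "g2m" in cfg:
        g2m = G2MTreatmentParams(**cfg["g2m"])
    if "s" in cfg:
        s = STreatmentParams(**cfg["s"])
    if base is None:
        raise ValueError("config must supply a baseline (or a preset)")
    kind = cfg.get("model", "untreated")
    if kind in ("g2m", "combination") and g2m is None:
        raise ValueError(f"model {kind!r} needs a g2m parameter block")
    if kind in ("s", "combination") and s is None:
        raise ValueError(f"model {kind!r} needs an s parameter block")
    return base, g2m, s


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, cfg: dict, seed, extra=None) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(cfg), "seed": seed,
                "version": __version__, "config": cfg}
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def write_trajectory(data: TrajectoryData, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_trajectory(path, steady_state=None) -> TrajectoryData:
    return TrajectoryData.from_frame(pd.read_csv(path), steady_state)


def write_curves(curves, outdir, stem: str) -> None:
    """Write fraction and tidy per-state CSVs for a PopulationCurves."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves.fractions_frame().to_csv(outdir / f"{stem}_fractions.csv",
                                    index=False)
    curves.to_frame().to_csv(outdir / f"{stem}_states.csv", index=False)
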