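"""Experiment configuration: flat TOML sections, dispatch, run manifests.

A config has three sections::

    [model]     # ModelParams fields
    [forcing]   # ForcingSpec fields
    [run]       # mode + mode-specific settings

``mode`` is one of ``simulate``, ``classify``, ``diagram``, ``map``,
``lyapunov``, ``critical``.  ``run_experiment`` dispatches to the matching
module, writes CSV/JSON artifacts to the output directory and a manifest
recording the fully resolved configuration.
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .forcing import ForcingSpec
from .model import ModelParams

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]

MODES = ("simulate", "classify", "diagram", "map", "lyapunov", "critical")

_RUN_DEFAULTS = dict(
    mode="simulate",
    g=None,
    h=None,
    h_values=None,
    g_values=None,
    t_transient=20_000.0,
    t_record=40_000.0,
    dt=0.1,
    record_stride=10,
    direction="up",
    h_bracket=None,
    output_dir="out",
    seed=0,
)


@dataclass
class ExperimentConfig:
    model: ModelParams = field(default_factory=ModelParams)
    forcing: ForcingSpec = field(default_factory=ForcingSpec)
    run: dict = field(default_factory=lambda: dict(_RUN_DEFAULTS))

    def validate(self) -> None:
        bad = []
        mode = self.run.get("mode")
        if mode not in MODES:
            bad.append(f"run.mode must be one of {MODES}, got {mode!r}")
        if mode in ("simulate", "classify", "lyapunov"):
            for key in ("g", "h"):
                if self.run.get(key) is None:
                    bad.append(f"run.{key} is required for mode {mode}")
        if mode in ("diagram", "map"):
            hv = self.run.get("h_values")
            if not hv:
                bad.append(f"run.h_values (non-empty list) is required for mode {mode}")
        if mode == "map" and not self.run.get("g_values"):
            bad.append("run.g_values (non-empty list) is required for mode map")
        if mode == "critical" and not self.run.get("h_bracket"):
            bad.append("run.h_bracket is required for mode critical")
        if bad:
            raise ValueError("invalid config: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(), "forcing": self.forcing.to_dict(),
                "run": dict(self.run)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        run = dict(_RUN_DEFAULTS)
        run.update(d.get("run", {}))
        return cls(
            model=ModelParams.from_dict(d.get("model", {})),
            forcing=ForcingSpec.from_dict(d.get("forcing", {})),
            run=run,
        )


def load_config(path, overrides: Optional[dict] = None) -> ExperimentConfig:
    """Read a TOML config file; ``overrides`` maps dotted keys
    (``model.h``, ``run.mode``) to replacement values."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for key, val in (overrides or {}).items():
        section, _, name = key.partition(".")
        if not name:
            raise ValueError(f"override key {key!r} must be section.field")
        data.setdefault(section, {})[name] = val
    cfg = ExperimentConfig.from_dict(data)
    cfg.validate()
    return cfg


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Execute the configured run; returns a manifest dict (also written to
    ``<output_dir>/manifest.json`` together with the result artifacts)."""
    config.validate()
    run = config.run
    out = Path(out_dir if out_dir is not None else run["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    params = config.model.with_(
        **{k: run[k] for k in ("g", "h") if run.get(k) is not None}
    )
    spec = config.forcing
    artifacts = {}

    mode = run["mode"]
    if mode == "simulate":
        from .integrate import default_ic, settle

        traj = settle(params, spec, default_ic(params),
                      t_transient=run["t_transient"], t_record=run["t_record"],
                      dt=run["dt"], record_stride=run["record_stride"])
        path = out / "trajectory.csv"
        traj.write_csv(path)
        artifacts["trajectory"] = str(path)
    elif mode == "classify":
        from .classify import classify_fixed, classify_forced

        if spec.protocol == "fixed":
            lab = classify_fixed(params, spec.J_max)
        else:
            lab = classify_forced(params, spec)
        path = out / "regime.json"
        path.write_text(json.dumps(lab.to_dict(), indent=2))
        artifacts["regime"] = str(path)
        artifacts["label"] = lab.label
    elif mode == "diagram":
        from .bifurcate import sweep_diagram

        rows = sweep_diagram(run["g"] if run.get("g") is not None else params.g,
                             run["h_values"],
                             spec=None if spec.protocol == "fixed" else spec,
                             params_base=params, J=spec.J_max,
                             direction=run["direction"])
        path = out / "diagram.csv"
        _write_sweep_csv(rows, path, run["direction"])
        artifacts["diagram"] = str(path)
    elif mode == "map":
        from .bifurcate import regime_map

        rmap = regime_map(run["g_values"], run["h_values"],
                          spec=None if spec.protocol == "fixed" else spec,
                          params_base=params, J=spec.J_max)
        path = out / "regime_map.csv"
        rmap.to_frame().to_csv(path, index=False)
        artifacts["regime_map"] = str(path)
        bpath = out / "boundaries.csv"
        rmap.boundary_frame().to_csv(bpath, index=False)
        artifacts["boundaries"] = str(bpath)
    elif mode == "lyapunov":
        from .classify import lyapunov_max

        le = lyapunov_max(params, spec, tangent_seed=int(run.get("seed", 0)))
        path = out / "lyapunov.json"
        path.write_text(json.dumps(
            {"g": params.g, "h": params.h, "protocol": spec.protocol,
             "lyapunov_per_ms": le, "lyapunov_per_s": 1000.0 * le}, indent=2))
        artifacts["lyapunov"] = str(path)
    elif mode == "critical":
        from .bifurcate import find_critical_h

        h_crit, width = find_critical_h(params.g, tuple(run["h_bracket"]),
                                        J=spec.J_max, params_base=params)
        path = out / "critical_h.json"
        path.write_text(json.dumps(
            {"g": params.g, "h_critical": h_crit, "bracket_width": width},
            indent=2))
        artifacts["critical"] = str(path)

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "mode": mode,
        "artifacts": artifacts,
        "wall_time_s": time.time() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_sweep_csv(rows, path, direction):
    import pandas as pd

    recs = []
    for row in rows:
        if direction == "both":
            h, up, down = row
            recs.append({"h": h, "label_up": up.label, "label_down": down.label,
                         "period_up_ms": up.period_ms, "period_down_ms": down.period_ms,
                         "skip_up": up.skip_cycles, "skip_down": down.skip_cycles})
        else:
            h, lab = row
            recs.append({"h": h, "label": lab.label, "period_ms": lab.period_ms,
                         "skip_cycles": lab.skip_cycles,
                         "lyapunov_per_ms": lab.lyapunov})
    pd.DataFrame(recs).to_csv(path, index=False)
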