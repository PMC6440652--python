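"""Run configuration, logging and report serialization.

A run is described by a YAML (or JSON) mapping with a fixed schema; unknown
keys are rejected with the offending key named, missing keys take defaults,
and the effective configuration is echoed into every report directory next to
the seed so any artifact can be re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fim import FIMResult
from .objectives import FitDiagnostics
from .oed import OEDResult

__all__ = ["RunConfig", "load_config", "write_report", "setup_logging"]

log = logging.getLogger("hsoed")


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Timestamped logging to stderr and, when given, a per-run log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Validated, fully defaulted description of one pipeline run."""

    model: str = "unbuffered"
    load_factor: float = 1.0
    params: dict = field(default_factory=dict)
    input: dict = field(default_factory=lambda: {
        "kind": "step", "magnitude": 20.0, "onset": 0.0, "period": None,
    })
    design: dict = field(default_factory=lambda: {
        "u_bounds": [1.0, 30.0], "t_f": 3000.0, "n_m": 50,
        "n_m_grid": list(range(10, 101, 10)), "lam": 0.8,
    })
    hs: dict = field(default_factory=lambda: {
        "hms": 15, "hmcr": 0.8, "par": 0.2,
        "bandwidth_frac": 0.05, "max_iter": 2000,
    })
    ga: dict = field(default_factory=lambda: {
        "pop_size": 50, "mutation_rate": 0.8, "crossover_rate": 0.2,
    })
    pso: dict = field(default_factory=lambda: {
        "swarm_size": 30, "weight": 1.0, "c1": 1.0, "c2": 1.0,
    })
    noise: dict = field(default_factory=lambda: {
        "sigma_rel": 0.05, "sigma_floor": 1e-3, "clip_negative": False,
    })
    free_params: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "hsoed_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _merge_checked(defaults: dict, given: dict, path: str) -> dict:
    merged = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key '{path}{key}'")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            merged[key] = _merge_checked(defaults[key], value, f"{path}{key}.")
        else:
            merged[key] = value
    return merged


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    # "params" holds model-specific overrides and is deliberately free-form at
    # this level; make_circuit validates the names against the chosen model.
    params = dict(data.pop("params", None) or {})
    defaults = RunConfig().to_dict()
    merged = _merge_checked(defaults, data, "")
    merged["params"] = params
    cfg = RunConfig(**merged)
    if cfg.model not in ("unbuffered", "buffered"):
        raise ValueError(f"model must be 'unbuffered' or 'buffered', got {cfg.model!r}")
    log.info("effective configuration: %s", json.dumps(cfg.to_dict(), default=str))
    return cfg


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_report(result, out_dir, config: RunConfig | None = None,
                 seed: int | None = None) -> list[Path]:
    """Persist a result (OED / FIM / diagnostics) as JSON plus CSV traces,
    together with the effective configuration and the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(result, OEDResult):
        payload = result.to_dict()
        kind = "oed"
        trace_path = out_dir / "outer_trace.csv"
        _write_trace(trace_path, result.outer_trace)
        written.append(trace_path)
        inner_path = out_dir / "inner_trace.csv"
        _write_trace(inner_path, result.inner_trace)
        written.append(inner_path)
        if result.cost_curve is not None:
            p = out_dir / "cost_curve.csv"
            result.cost_curve.to_csv(p, index=False, float_format="%.17g")
            written.append(p)
    elif isinstance(result, FIMResult):
        payload = result.to_dict()
        kind = "fim"
    elif isinstance(result, FitDiagnostics):
        payload = result.to_dict()
        kind = "diagnostics"
        qq = out_dir / "qq_points.csv"
        import pandas as pd

        pd.DataFrame({"theoretical": result.qq_theoretical,
                      "sample": result.qq_sample}).to_csv(
            qq, index=False, float_format="%.17g")
        written.append(qq)
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")

    payload["seed"] = seed if seed is not None else payload.get("seed")
    report = out_dir / f"{kind}_report.json"
    report.write_text(json.dumps(payload, indent=2, cls=_Encoder))
    written.append(report)

    if config is not None:
        cfg_path = out_dir / "effective_config.yaml"
        cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
        written.append(cfg_path)
    return written


def _write_trace(path: Path, trace) -> None:
    import pandas as pd

    trace = np.asarray(trace, dtype=float)
    pd.DataFrame({"iteration": np.arange(len(trace)),
                  "best_fitness": trace}).to_csv(
        path, index=False, float_format="%.17g")
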