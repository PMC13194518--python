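"""Run configuration: defaults, YAML overrides, CLI overrides.

Keys are dotted (``section.name``).  Every key has a default; unknown
keys are rejected so typos fail loudly.  The effective configuration is
echoed into the output directory of every batch run.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "echo_config"]

DEFAULTS = {
    "smoothing.window_points": 100,
    "start.persistence_s": 270.0,
    "start.search_margin_s": 30.0,
    "baseline.window_points": 800,
    "filter.band_hz": [1.0, 20.0],
    "filter.order": 4,
    "window.duration_s": 360.0,
    "score.threshold_g": 0.792,
    "score.envelope_span_s": 0.25,
    "score.min_bout_s": 0.0,
    "calibration.grid_step_g": 0.001,
    "calibration.seed": 42,
    "photometry.min_prominence": 0.5,
    "photometry.half_window_s": 1.0,
}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- explicit overrides.

    YAML files may use either nested sections or dotted keys.  Any key not
    present in :data:`DEFAULTS` raises ``ValueError``.
    """
    cfg = dict(DEFAULTS)
    for source in (
        _flatten(yaml.safe_load(Path(path).read_text()) or {}) if path else {},
        dict(overrides or {}),
    ):
        for k, v in source.items():
            if k not in DEFAULTS:
                raise ValueError(f"unknown config key {k!r}")
            if v is not None:
                cfg[k] = v
    return cfg


def echo_config(cfg: dict, out_dir) -> Path:
    """Write the effective configuration next to the run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "effective_config.yaml"
    path.write_text(yaml.safe_dump(dict(sorted(cfg.items())), sort_keys=False))
    return path
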