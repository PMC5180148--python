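"""Run configuration: YAML file + CLI-flag overrides, validated up front.

Precedence is flags > config file > defaults. Validation happens before any
data are read so an invalid configuration never produces partial outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError

_ANALYZE_DEFAULTS: dict = {
    "input": {"path": None, "format": "csv", "time_column": "time"},
    "size_of_state": {"mode": None, "k": 2.0, "stable_period": None,
                      "values": None},
    "window": {"width": 8, "increment": 1},
    "tightening": {"mode": "strict"},
    "smoothing": {"block": 1},
    "summary": {"periods": []},
    "output": {"fi": None, "summary": None},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if val is None:
            continue
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config_file(path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return data


@dataclass
class RunConfig:
    """Validated settings for one analyze run."""

    input_path: str
    input_format: str
    time_column: str
    sos_mode: str
    sos_k: float
    sos_stable_period: tuple | None
    sos_values: list | None
    window_width: int
    window_increment: int
    tightening_mode: str
    smoothing_block: int
    summary_periods: list
    out_fi: str | None
    out_summary: str | None
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def for_analyze(cls, config_path=None, **flags) -> "RunConfig":
        """Merge defaults <- config file <- non-None flag values and validate."""
        cfg = dict(_ANALYZE_DEFAULTS)
        if config_path is not None:
            cfg = _deep_merge(cfg, load_config_file(config_path))
        flag_map = {
            "input_path": ("input", "path"),
            "input_format": ("input", "format"),
            "time_column": ("input", "time_column"),
            "sos_mode": ("size_of_state", "mode"),
            "k": ("size_of_state", "k"),
            "stable_period": ("size_of_state", "stable_period"),
            "deltas": ("size_of_state", "values"),
            "window": ("window", "width"),
            "increment": ("window", "increment"),
            "tightening": ("tightening", "mode"),
            "smoothing_block": ("smoothing", "block"),
            "out_fi": ("output", "fi"),
            "out_summary": ("output", "summary"),
        }
        override: dict = {}
        for flag, (sect, key) in flag_map.items():
            if flags.get(flag) is not None:
                override.setdefault(sect, {})[key] = flags[flag]
        if flags.get("periods"):
            override.setdefault("summary", {})["periods"] = flags["periods"]
        cfg = _deep_merge(cfg, override)
        return cls._validate(cfg)

    @classmethod
    def _validate(cls, cfg: dict) -> "RunConfig":
        inp = cfg["input"]
        if not inp.get("path"):
            raise ConfigError("input.path is required")
        if inp.get("format") not in ("csv", "gistemp"):
            raise ConfigError(
                f"input.format must be 'csv' or 'gistemp', "
                f"got {inp.get('format')!r}")

        win = cfg["window"]
        try:
            width = int(win["width"])
            increment = int(win["increment"])
        except (TypeError, ValueError):
            raise ConfigError("window.width/increment must be integers") from None
        if width < 2:
            raise ConfigError(f"window.width must be >= 2, got {width}")
        if increment < 1:
            raise ConfigError(
                f"window.increment must be >= 1, got {increment}")
        if increment > width:
            raise ConfigError(
                f"window.increment ({increment}) must not exceed "
                f"window.width ({width})")

        sos = cfg["size_of_state"]
        mode = sos.get("mode")
        if mode is None:  # infer from what was supplied
            mode = "explicit" if sos.get("values") else (
                "estimate" if sos.get("stable_period") else None)
        if mode not in ("estimate", "explicit"):
            raise ConfigError(
                "size_of_state.mode must be 'estimate' (with stable_period) "
                "or 'explicit' (with values)")
        if mode == "explicit":
            vals = sos.get("values")
            if not vals:
                raise ConfigError(
                    "size_of_state.values required in explicit mode")
            if any((not isinstance(v, (int, float))) or v < 0 for v in vals):
                raise ConfigError(
                    "size_of_state.values must be non-negative numbers")
        else:
            sp = sos.get("stable_period")
            if not sp or len(sp) != 2:
                raise ConfigError(
                    "size_of_state.stable_period = [start, end] required in "
                    "estimate mode")
            if float(sos.get("k", 0)) <= 0:
                raise ConfigError("size_of_state.k must be positive")

        tl = cfg["tightening"].get("mode")
        if tl not in ("strict", "averaged"):
            raise ConfigError(
                f"tightening.mode must be 'strict' or 'averaged', got {tl!r}")

        block = cfg["smoothing"].get("block", 1)
        if not isinstance(block, int) or block < 1:
            raise ConfigError(
                f"smoothing.block must be a positive integer, got {block!r}")

        periods = cfg["summary"].get("periods") or []
        for p in periods:
            if len(p) != 2:
                raise ConfigError(
                    f"summary period must be [start, end], got {p!r}")

        sp = sos.get("stable_period")
        return cls(
            input_path=str(inp["path"]),
            input_format=inp["format"],
            time_column=str(inp.get("time_column", "time")),
            sos_mode=mode,
            sos_k=float(sos.get("k", 2.0)),
            sos_stable_period=tuple(sp) if mode == "estimate" else None,
            sos_values=list(sos["values"]) if mode == "explicit" else None,
            window_width=width,
            window_increment=increment,
            tightening_mode=tl,
            smoothing_block=block,
            summary_periods=[tuple(p) for p in periods],
            out_fi=cfg["output"].get("fi"),
            out_summary=cfg["output"].get("summary"),
            raw=cfg,
        )


def parse_period(text: str) -> tuple:
    """Parse 'start:end' (or 'start,end') into a 2-tuple of numbers."""
    parts = text.replace(",", ":").split(":")
    if len(parts) != 2:
        raise ConfigError(f"period must be start:end, got {text!r}")

    def _num(s):
        s = s.strip()
        try:
            return int(s)
        except ValueError:
            try:
                return float(s)
            except ValueError:
                raise ConfigError(f"period bound {s!r} is not numeric") from None
    return _num(parts[0]), _num(parts[1])


def load_scenario(path) -> dict:
    """Load and validate a simulate scenario config (regimes + seed)."""
    data = load_config_file(path)
    if "regimes" not in data or not data["regimes"]:
        raise ConfigError(f"scenario {path} must define at least one regime")
    for r in data["regimes"]:
        for key in ("start", "end", "means", "sds"):
            if key not in r:
                raise ConfigError(f"regime missing key {key!r} in {path}")
    if "seed" in data and not isinstance(data["seed"], int):
        raise ConfigError("scenario seed must be an integer")
    return data
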