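"""Configuration files and session logs (versioned JSON round-trips)."""

from __future__ import annotations

import json
from dataclasses import fields as dataclass_fields

from .data import Observation, ObservationSet
from .exceptions import (
    ConfigValidationError,
    InvalidParameterError,
    UnsupportedVersionError,
)
from .gp import RigidityGP, RigidityGPResults
from .kernels import KernelParams
from .preference import PreferenceDataset, PreferencePair
from .session import SessionConfig, SessionState

__all__ = [
    "SESSION_FORMAT_VERSION",
    "load_config",
    "save_config",
    "write_session_log",
    "read_session_log",
]

SESSION_FORMAT_VERSION = 1

_CONFIG_FIELDS = {f.name for f in dataclass_fields(SessionConfig)}


def load_config(path) -> SessionConfig:
    """Load a session configuration from JSON.

    An empty file yields the all-defaults configuration (seeds 30/80/90/140,
    8 iterations, 5 Hz grid, exploration ratio 0.5, 25 pGP restarts).
    Schema violations raise ``ConfigValidationError`` listing the offending
    fields.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return SessionConfig()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigValidationError(
            f"config is not valid JSON (line {exc.lineno}, column {exc.colno}): {exc.msg}"
        ) from exc
    if not isinstance(raw, dict):
        raise ConfigValidationError("config must be a JSON object")
    raw.pop("format_version", None)
    unknown = sorted(set(raw) - _CONFIG_FIELDS)
    if unknown:
        raise ConfigValidationError(f"unknown config fields: {unknown}", fields=unknown)
    if "seeds" in raw:
        raw["seeds"] = tuple(float(f) for f in raw["seeds"])
    try:
        return SessionConfig(**raw)
    except InvalidParameterError as exc:
        raise ConfigValidationError(str(exc), fields=sorted(raw)) from exc


def save_config(config: SessionConfig, path) -> None:
    d = {"format_version": SESSION_FORMAT_VERSION}
    for f in dataclass_fields(SessionConfig):
        value = getattr(config, f.name)
        d[f.name] = list(value) if isinstance(value, tuple) else value
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def _config_to_dict(config: SessionConfig) -> dict:
    return {
        f.name: (list(v) if isinstance(v := getattr(config, f.name), tuple) else v)
        for f in dataclass_fields(SessionConfig)
    }


def write_session_log(state: SessionState, path) -> None:
    """Lossless JSON dump of a session: config, history, preferences, model."""
    d = {
        "format_version": SESSION_FORMAT_VERSION,
        "status": state.status,
        "config": _config_to_dict(state.config),
        "ceiling_hz": state.ceiling,
        "mean_const": state.mean_const,
        "history": [
            {"frequency_hz": o.x, "romar": o.y, "order_index": o.order_index,
             "source": o.source}
            for o in state.history
        ],
        "preferences": [
            {"step_index": p.step_index, "frequency_a_hz": p.a,
             "frequency_b_hz": p.b, "winner": "a"}
            for p in state.preferences
        ],
        "events": state.events,
        "model": state.model.to_dict() if state.model is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def read_session_log(path) -> SessionState:
    """Rebuild a ``SessionState`` (including the fitted GP) from a log file."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigValidationError(
                f"session log is not valid JSON (line {exc.lineno}, column {exc.colno}): "
                f"{exc.msg}"
            ) from exc
    version = d.get("format_version")
    if version != SESSION_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"session log format_version {version!r} unsupported "
            f"(expected {SESSION_FORMAT_VERSION})"
        )
    cfg = dict(d.get("config", {}))
    if "seeds" in cfg:
        cfg["seeds"] = tuple(float(f) for f in cfg["seeds"])
    config = SessionConfig(**cfg)
    history = ObservationSet(
        [
            Observation(
                float(h["frequency_hz"]), float(h["romar"]),
                int(h.get("order_index", i)), str(h.get("source", "bayesopt")),
            )
            for i, h in enumerate(d.get("history", []))
        ]
    )
    prefs = PreferenceDataset()
    for p in d.get("preferences", []) or []:
        fa, fb = float(p["frequency_a_hz"]), float(p["frequency_b_hz"])
        if str(p.get("winner", "a")) == "b":
            fa, fb = fb, fa
        prefs.append(PreferencePair(fa, fb, int(p.get("step_index", 0))))
    model = None
    if d.get("model") is not None:
        md = d["model"]
        gp = RigidityGP(history.x, history.y, mean_const=md["mean_const"])
        params = KernelParams(
            nu=md["nu"], ell=md["ell"], signal_var=md["signal_var"],
            noise_var=md["noise_var"],
        )
        model = RigidityGPResults(gp, params, md.get("llf", gp.loglike(params)))
    return SessionState(
        config=config,
        history=history,
        preferences=prefs,
        ceiling=d.get("ceiling_hz"),
        mean_const=d.get("mean_const"),
        model=model,
        events=list(d.get("events", [])),
        status=str(d.get("status", "complete")),
    )
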