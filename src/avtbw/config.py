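"""Run configuration: packaged defaults, presets, and YAML overrides."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .design import Condition
from .errors import InvalidArgumentError
from .observer import CohortPriors

__all__ = ["RunConfig", "load_defaults"]


def load_defaults() -> dict[str, Any]:
    """Packaged default configuration (deep copy per call)."""
    text = importlib.resources.files("avtbw").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _conditions_from(entries: list[dict[str, Any]]) -> list[Condition]:
    return [
        Condition(
            label=e["label"],
            mode=e["mode"],
            freq_hz=float(e["freq_hz"]),
            stream_mode=e.get("stream_mode", "fixed_duration"),
            stream_value=float(e.get("stream_value", 3)),
            envelope_label=e.get("envelope_label"),
        )
        for e in entries
    ]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from a preset name or a
    user YAML file. Presets: exp1 (3 s rhythmic streams at 1/2/3 Hz), exp2
    (3-pulse streams, durations 3/1.5/1 s), exp3 (3 Hz rhythmic vs.
    speech-like)."""

    conditions: list[Condition]
    soa_grid_ms: list[float]
    n_reps: int
    sample_rate_hz: float
    audio_sample_rate_hz: int
    carrier_hz: float
    max_soa_ms: float
    fft_band_hz: tuple[float, float]
    speech_target_hz: float
    speech_tol_hz: float
    speech_jitter_cv: float
    speech_amp_cv: float
    n_speech_tokens: int
    gauss_r2_threshold: float
    logistic_r2_threshold: float
    priors: CohortPriors
    preset: str = "custom"

    @classmethod
    def from_preset(cls, preset: str = "exp1", overrides: dict[str, Any] | None = None) -> "RunConfig":
        cfg = load_defaults()
        if preset != "custom":
            if preset not in cfg["presets"]:
                raise InvalidArgumentError(
                    f"unknown preset {preset!r}; choose from {sorted(cfg['presets'])} or 'custom'"
                )
            cfg["conditions"] = cfg["presets"][preset]["conditions"]
        cfg.update(overrides or {})
        if "conditions" not in cfg:
            raise InvalidArgumentError("custom configs must supply a conditions list")
        priors_cfg = cfg.get("priors", {})
        priors = CohortPriors(
            a_range=tuple(priors_cfg.get("a_range", (0.85, 1.0))),
            b_mean=float(priors_cfg.get("b_mean", 50.0)),
            b_sd=float(priors_cfg.get("b_sd", 40.0)),
            c_range=tuple(priors_cfg.get("c_range", (200.0, 500.0))),
            unsure_range=tuple(priors_cfg.get("unsure_range", (0.0, 0.15))),
            confident_range=tuple(priors_cfg.get("confident_range", (0.55, 0.9))),
        )
        return cls(
            conditions=_conditions_from(cfg["conditions"]),
            soa_grid_ms=[float(s) for s in cfg["soa_grid_ms"]],
            n_reps=int(cfg["n_reps"]),
            sample_rate_hz=float(cfg["sample_rate_hz"]),
            audio_sample_rate_hz=int(cfg["audio_sample_rate_hz"]),
            carrier_hz=float(cfg["carrier_hz"]),
            max_soa_ms=float(cfg["max_soa_ms"]),
            fft_band_hz=tuple(cfg["fft_band_hz"]),
            speech_target_hz=float(cfg["speech_target_hz"]),
            speech_tol_hz=float(cfg["speech_tol_hz"]),
            speech_jitter_cv=float(cfg["speech_jitter_cv"]),
            speech_amp_cv=float(cfg["speech_amp_cv"]),
            n_speech_tokens=int(cfg["n_speech_tokens"]),
            gauss_r2_threshold=float(cfg["gauss_r2_threshold"]),
            logistic_r2_threshold=float(cfg["logistic_r2_threshold"]),
            priors=priors,
            preset=preset,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        preset = user.pop("preset", "custom")
        return cls.from_preset(preset, overrides=user)
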