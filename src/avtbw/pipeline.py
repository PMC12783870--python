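"""End-to-end orchestration: stimuli -> design -> simulate/ingest -> code ->
fit -> exclude -> summarize, with a JSON manifest for reproducibility."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .coding import proportions_frame, sj_proportions
from .config import RunConfig
from .design import build_design, design_to_frame
from .envelopes import (
    Envelope,
    make_quasi_rhythmic_envelope,
    make_sinusoidal_envelope,
    make_stream_spec,
    select_speech_like,
)
from .errors import InvalidDataError
from .fitting import apply_exclusion, fit_subject, summarize_by_condition
from .io import write_envelope_csv, write_manifest
from .observer import simulate_cohort

__all__ = ["build_stimuli", "validate_responses", "run_pipeline"]

log = logging.getLogger("avtbw")

RESPONSE_COLUMNS = ["subject_id", "condition_label", "freq_hz", "mode", "soa_ms", "rating"]


def build_stimuli(config: RunConfig, seed: int = 0) -> dict[str, Envelope]:
    """One modulation envelope per condition (speech-like conditions get
    ``n_speech_tokens`` jittered tokens, each passing the ~3 Hz gate)."""
    stimuli: dict[str, Envelope] = {}
    for cond in config.conditions:
        duration, _ = make_stream_spec(cond.stream_mode, cond.freq_hz, cond.stream_value)
        if cond.mode == "rhythmic":
            stimuli[cond.label] = make_sinusoidal_envelope(
                cond.freq_hz, duration, config.sample_rate_hz, label=cond.label
            )
        else:
            tokens: list[Envelope] = []
            candidate_seed = seed
            # draw jittered tokens until enough pass the dominant-frequency gate
            while len(tokens) < config.n_speech_tokens and candidate_seed < seed + 1000:
                env = make_quasi_rhythmic_envelope(
                    config.speech_target_hz,
                    config.speech_jitter_cv,
                    config.speech_amp_cv,
                    duration,
                    config.sample_rate_hz,
                    seed=candidate_seed,
                    label=f"{cond.label}-{len(tokens) + 1:02d}",
                )
                tokens.extend(
                    select_speech_like(
                        [env], config.speech_target_hz, config.speech_tol_hz, config.fft_band_hz
                    )
                )
                candidate_seed += 1
            for i, token in enumerate(tokens):
                stimuli[f"{cond.label}-{i + 1:02d}"] = token
            stimuli[cond.label] = tokens[0]
    return stimuli


def validate_responses(responses: pd.DataFrame, soa_grid: list[float]) -> list[str]:
    """Row-addressed schema check for a trial-level response table."""
    errors: list[str] = []
    missing = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing:
        return [f"missing column(s): {', '.join(missing)}"]
    grid = set(float(s) for s in soa_grid)
    for i, row in responses.iterrows():
        if float(row["soa_ms"]) not in grid:
            errors.append(f"row {i}: soa_ms {row['soa_ms']} not in the design grid")
        rating = row["rating"]
        try:
            ok = int(rating) == rating and 1 <= int(rating) <= 5
        except (TypeError, ValueError):
            ok = False
        if not ok:
            errors.append(f"row {i}: rating {rating!r} not an integer in 1-5")
    return errors


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    seed: int = 0,
    n_subjects: int | None = None,
    responses_csv: str | Path | None = None,
    condition_tbw_scale: Mapping[str, float] | None = None,
    write_stimuli: bool = False,
) -> Path:
    """Run the full analysis and write its artifact directory.

    Either simulate ``n_subjects`` synthetic observers or ingest a
    trial-level response CSV. Outputs: trial list, responses (+ ground truth
    when simulated), tidy proportions, per-subject parameter table with kept
    flags, exclusion log, condition summaries, and a manifest with all seeds.
    A failure writes a FAILED sentinel file rather than leaving partial
    output unmarked.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sentinel = out / "FAILED"
    try:
        artifacts = _run(config, out, seed, n_subjects, responses_csv,
                         condition_tbw_scale, write_stimuli)
    except Exception as exc:
        sentinel.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if sentinel.exists():
        sentinel.unlink()
    write_manifest(out / "manifest.json", artifacts)
    return out


def _run(config, out, seed, n_subjects, responses_csv, condition_tbw_scale, write_stimuli):
    if (n_subjects is None) == (responses_csv is None):
        raise InvalidDataError("provide exactly one of n_subjects or responses_csv")

    if write_stimuli:
        stim_dir = out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        for label, env in build_stimuli(config, seed).items():
            write_envelope_csv(env, stim_dir / f"{label}.csv")

    design = build_design(config.soa_grid_ms, config.conditions, config.n_reps, seed)
    design_to_frame(design).to_csv(out / "trial_list.csv", index=False)

    if responses_csv is not None:
        responses = pd.read_csv(responses_csv)
        problems = validate_responses(responses, config.soa_grid_ms)
        if problems:
            raise InvalidDataError("; ".join(problems[:20]))
        truth = None
    else:
        responses, truth = simulate_cohort(
            n_subjects, design, config.priors, seed=seed,
            condition_tbw_scale=condition_tbw_scale,
        )
        responses.to_csv(out / "responses.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)

    proportions = proportions_frame(responses)
    proportions.to_csv(out / "proportions.csv", index=False)

    fit_frames = [
        fit_subject(sj_proportions(sub), subject_id)
        for subject_id, sub in responses.groupby("subject_id", sort=True)
    ]
    fits, reasons = apply_exclusion(
        pd.concat(fit_frames, ignore_index=True),
        config.gauss_r2_threshold,
        config.logistic_r2_threshold,
    )
    fits.to_csv(out / "parameters.csv", index=False)
    (out / "exclusions.txt").write_text("\n".join(reasons) + ("\n" if reasons else ""))
    for line in reasons:
        log.warning("excluded: %s", line)

    summary = summarize_by_condition(fits)
    summary.to_csv(out / "summary.csv", index=False)

    return {
        "package_version": __version__,
        "preset": config.preset,
        "seed": seed,
        "n_subjects": n_subjects,
        "ingested": str(responses_csv) if responses_csv else None,
        "n_trials_per_subject": len(design),
        "n_conditions": len(config.conditions),
        "soa_grid_ms": config.soa_grid_ms,
        "n_reps": config.n_reps,
        "thresholds": {
            "gaussian_adj_r2": config.gauss_r2_threshold,
            "logistic_adj_r2": config.logistic_r2_threshold,
        },
        "n_excluded_gauss": int((~fits.groupby("subject_id")["kept_gauss"].first()).sum()),
        "n_excluded_logistic": int((~fits.groupby("subject_id")["kept_logistic"].first()).sum()),
    }
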