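"""Synthetic rating-scale observers for simultaneity-judgement tasks.

Each observer carries a ground-truth Gaussian simultaneity curve

    p_sync(soa) = a * exp(-((soa - b) / c)**2)

with peak synchrony probability ``a``, point of subjective simultaneity
``b`` (ms) and width ``c`` (ms, the temporal binding window). Ratings on the
5-point scale (1 = certainly synchronous ... 5 = certainly asynchronous) are
produced by a two-stage mechanism: with probability ``unsure_rate`` the
trial lapses to "not sure" (rating 3); otherwise a synchronous judgement is
drawn as Bernoulli(p_sync) and routed to the extreme or moderate rating by
``confident_split``. Coding ratings {1,2} as synchronous and {4,5} as
asynchronous (dropping 3s) therefore recovers exactly the Gaussian curve the
downstream fits assume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import TrialSpec, design_to_frame
from .errors import InvalidArgumentError

__all__ = [
    "ObserverParams",
    "TrialResponse",
    "CohortPriors",
    "p_sync",
    "simulate_responses",
    "simulate_cohort",
    "responses_to_frame",
]


@dataclass(frozen=True)
class ObserverParams:
    a_peak: float  # peak synchrony probability, (0, 1]
    b_pss: float  # point of subjective simultaneity, ms
    c_tbw: float  # Gaussian width (temporal binding window), ms
    unsure_rate: float = 0.05  # P(rating 3), [0, 0.5)
    confident_split: float = 0.7  # P(extreme rating | judgement), [0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.a_peak <= 1:
            raise InvalidArgumentError("a_peak must be in (0, 1]")
        if self.c_tbw <= 0:
            raise InvalidArgumentError("c_tbw must be positive")
        if not 0 <= self.unsure_rate < 0.5:
            raise InvalidArgumentError("unsure_rate must be in [0, 0.5)")
        if not 0 <= self.confident_split <= 1:
            raise InvalidArgumentError("confident_split must be in [0, 1]")


@dataclass(frozen=True)
class TrialResponse:
    trial: TrialSpec
    rating: int

    def __post_init__(self) -> None:
        if self.rating not in (1, 2, 3, 4, 5):
            raise InvalidArgumentError(f"rating must be 1-5, got {self.rating}")


def p_sync(params: ObserverParams, soa_ms: float | np.ndarray) -> float | np.ndarray:
    """Ground-truth probability of a synchronous judgement at an SOA."""
    z = (np.asarray(soa_ms, dtype=float) - params.b_pss) / params.c_tbw
    out = params.a_peak * np.exp(-(z ** 2))
    return float(out) if np.isscalar(soa_ms) else out


def simulate_responses(
    params: ObserverParams,
    design: Sequence[TrialSpec],
    seed: int | np.random.Generator = 0,
) -> list[TrialResponse]:
    """Draw one 5-point rating per designed trial; seeded and reproducible."""
    if not design:
        raise InvalidArgumentError("design must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    responses = []
    for trial in design:
        if rng.random() < params.unsure_rate:
            rating = 3
        else:
            synchronous = rng.random() < p_sync(params, trial.soa_ms)
            extreme = rng.random() < params.confident_split
            if synchronous:
                rating = 1 if extreme else 2
            else:
                rating = 5 if extreme else 4
        responses.append(TrialResponse(trial, rating))
    return responses


def responses_to_frame(
    responses: Sequence[TrialResponse], subject_id: str
) -> pd.DataFrame:
    """Tidy per-trial response table for one subject."""
    frame = design_to_frame([r.trial for r in responses], subject_id=subject_id)
    frame["rating"] = [r.rating for r in responses]
    return frame


@dataclass(frozen=True)
class CohortPriors:
    """Sampling distributions for observer parameters.

    Defaults: a ~ U(0.85, 1), b ~ N(+50, 40) ms (a modest visual-leading
    bias), c ~ U(200, 500) ms spanning typical adult binding windows,
    unsure_rate ~ U(0, 0.15), confident_split ~ U(0.55, 0.9).
    """

    a_range: tuple[float, float] = (0.85, 1.0)
    b_mean: float = 50.0
    b_sd: float = 40.0
    c_range: tuple[float, float] = (200.0, 500.0)
    unsure_range: tuple[float, float] = (0.0, 0.15)
    confident_range: tuple[float, float] = (0.55, 0.9)

    def __post_init__(self) -> None:
        if self.c_range[0] <= 0 or self.c_range[1] < self.c_range[0]:
            raise InvalidArgumentError("c_range must be positive with low <= high")
        if not (0 < self.a_range[0] <= self.a_range[1] <= 1):
            raise InvalidArgumentError("a_range must lie in (0, 1]")
        if not (0 <= self.unsure_range[0] <= self.unsure_range[1] < 0.5):
            raise InvalidArgumentError("unsure_range must lie in [0, 0.5)")

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        return ObserverParams(
            a_peak=float(rng.uniform(*self.a_range)),
            b_pss=float(rng.normal(self.b_mean, self.b_sd)),
            c_tbw=float(rng.uniform(*self.c_range)),
            unsure_rate=float(rng.uniform(*self.unsure_range)),
            confident_split=float(rng.uniform(*self.confident_range)),
        )


def simulate_cohort(
    n_observers: int,
    design: Sequence[TrialSpec],
    priors: CohortPriors | None = None,
    seed: int = 0,
    condition_tbw_scale: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (responses, ground_truth) tables.

    Each observer's parameters are drawn from ``priors``; an optional
    ``condition_tbw_scale`` maps condition labels to multipliers on the
    drawn c (so e.g. a 1 Hz stream can carry a wider true binding window
    than a 3 Hz one). Ground truth is recorded per (subject, condition) so
    no simulated dataset is ever separated from its generating parameters.
    One random stream is derived per subject from (seed, subject index), so
    cohorts are reproducible under partial re-runs.
    """
    if n_observers < 1:
        raise InvalidArgumentError("n_observers must be >= 1")
    if not design:
        raise InvalidArgumentError("design must be non-empty")
    priors = priors or CohortPriors()
    scale = dict(condition_tbw_scale or {})
    labels = sorted({t.condition.label for t in design})
    unknown = set(scale) - set(labels)
    if unknown:
        raise InvalidArgumentError(f"condition_tbw_scale names unknown conditions: {unknown}")

    response_frames = []
    truth_rows = []
    for i in range(n_observers):
        subject_rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        base = priors.draw(subject_rng)
        subject_id = f"S{i + 1:03d}"
        per_condition = {
            label: replace(base, c_tbw=base.c_tbw * scale.get(label, 1.0))
            for label in labels
        }
        responses = []
        for trial in design:
            responses.extend(
                simulate_responses(per_condition[trial.condition.label], [trial], subject_rng)
            )
        response_frames.append(responses_to_frame(responses, subject_id))
        for label in labels:
            p = per_condition[label]
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "condition_label": label,
                    "a_peak": p.a_peak,
                    "b_pss": p.b_pss,
                    "c_tbw": p.c_tbw,
                    "unsure_rate": p.unsure_rate,
                    "confident_split": p.confident_split,
                }
            )
    return pd.concat(response_frames, ignore_index=True), pd.DataFrame(truth_rows)
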