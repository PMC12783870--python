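"""Recoding of 5-point simultaneity ratings into binary judgements.

Ratings 1-2 code synchronous, 4-5 asynchronous; the "not sure" rating 3 is
dropped from the analysis (it carries no information about perceived
synchrony). The per-cell proportion of synchronous judgements among the
remaining valid trials is the quantity the psychometric fits consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDataError

__all__ = ["SJCurve", "recode", "sj_proportions", "proportions_frame"]

SYNC, ASYNC, EXCLUDED = "sync", "async", "excluded"
_RECODE = {1: SYNC, 2: SYNC, 3: EXCLUDED, 4: ASYNC, 5: ASYNC}


@dataclass(frozen=True)
class SJCurve:
    """Per-condition simultaneity curve: proportion synchronous vs SOA.

    ``props`` is NaN where a cell has no valid (non-"not sure") trials;
    such points are passed to the fitter as missing, never imputed.
    """

    condition_label: str
    soas: np.ndarray  # ms, unique, ascending
    props: np.ndarray  # proportion synchronous among valid trials
    n_valid: np.ndarray  # count of non-excluded trials per cell

    def __post_init__(self) -> None:
        for name in ("soas", "props", "n_valid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.soas) > 0):
            raise InvalidDataError("soas must be unique and ascending")

    def defined(self) -> tuple[np.ndarray, np.ndarray]:
        """(soas, props) restricted to cells with at least one valid trial."""
        mask = ~np.isnan(self.props)
        return self.soas[mask], self.props[mask]


def recode(rating: int, row: object = None) -> str:
    """Map a 5-point rating to sync / async / excluded."""
    try:
        return _RECODE[int(rating)]
    except (KeyError, TypeError, ValueError):
        where = f" (row {row})" if row is not None else ""
        raise InvalidDataError(f"rating must be an integer 1-5, got {rating!r}{where}") from None


def sj_proportions(responses: pd.DataFrame) -> list[SJCurve]:
    """One SJCurve per condition from a single subject's response table.

    ``responses`` needs columns condition_label, soa_ms, rating. The
    proportion is #sync / (#sync + #async); rating-3 trials shrink the
    denominator rather than counting as asynchronous.
    """
    if responses.empty:
        raise InvalidDataError("responses table is empty")
    coded = [recode(r, row=i) for i, r in zip(responses.index, responses["rating"])]
    work = responses.assign(_coded=coded)
    curves = []
    for label, group in work.groupby("condition_label", sort=True):
        soas = np.sort(group["soa_ms"].unique())
        props = np.full(soas.size, np.nan)
        n_valid = np.zeros(soas.size)
        for k, soa in enumerate(soas):
            cell = group.loc[group["soa_ms"] == soa, "_coded"]
            n_sync = int((cell == SYNC).sum())
            n_async = int((cell == ASYNC).sum())
            n_valid[k] = n_sync + n_async
            if n_valid[k] > 0:
                props[k] = n_sync / n_valid[k]
        curves.append(SJCurve(str(label), soas, props, n_valid))
    return curves


def proportions_frame(responses: pd.DataFrame) -> pd.DataFrame:
    """Tidy multi-subject proportions table (subject x condition x SOA)."""
    frames = []
    for subject_id, sub in responses.groupby("subject_id", sort=True):
        for curve in sj_proportions(sub):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "condition_label": curve.condition_label,
                        "soa_ms": curve.soas,
                        "prop_sync": curve.props,
                        "n_valid": curve.n_valid.astype(int),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
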