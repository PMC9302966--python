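"""Windowed scalar responses at trial and participant level.

Compensation is the mean normalized F1 in the 150–250 ms window of
perturbed trials — after the typical onset latency of feedback-based
correction.  One-shot adaptation is the mean normalized F1 in the first
100 ms of unperturbed trials directly following a perturbed trial —
before auditory feedback can influence the current vowel (an alternative
50–150 ms window that skips the consonant transition is available).

Windows are half-open ``[t0, t1)``.  Sign correction multiplies responses
from up-shifted (or post-up) trials by −1 so that, in both directions,
positive values oppose the shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import NormalizedTrial, _pointwise_mean
from .trials import Perturbation, Role, Trajectory

__all__ = [
    "COMPENSATION_WINDOW",
    "ADAPTATION_WINDOW",
    "ADAPTATION_WINDOW_ALT",
    "RESPONSE_COLUMNS",
    "window_mean",
    "trial_compensation",
    "trial_adaptation",
    "participant_average_trajectory",
    "participant_response",
    "sign_correct",
    "response_frame",
]

COMPENSATION_WINDOW = (150.0, 250.0)
ADAPTATION_WINDOW = (0.0, 100.0)
ADAPTATION_WINDOW_ALT = (50.0, 150.0)

RESPONSE_COLUMNS = [
    "participant_id",
    "study_id",
    "trial_index",
    "direction",
    "measure",
    "window_t0_ms",
    "window_t1_ms",
    "value_mels",
    "sign_corrected",
    "shift_magnitude_mels",
    "paired_prev_trial_index",
]


def window_mean(
    traj: Trajectory,
    t0_ms: float,
    t1_ms: float,
    min_coverage: float = 0.5,
) -> float:
    """Mean of the samples with ``t0 <= t < t1``.

    Returns NaN when the fraction of the window covered by samples is
    below ``min_coverage`` (partial vowels are used as long as they cover
    enough of the window).
    """
    if t0_ms >= t1_ms:
        raise ValueError(f"need t0 < t1, got [{t0_ms}, {t1_ms})")
    t = traj.times_ms
    mask = (t >= t0_ms) & (t < t1_ms)
    n_in = int(mask.sum())
    coverage = n_in * traj.step_ms / (t1_ms - t0_ms)
    if coverage < min_coverage or n_in == 0:
        return math.nan
    return float(traj.values[mask].mean())


def _row(
    nt: NormalizedTrial,
    measure: str,
    window: tuple[float, float],
    value: float,
    direction: Perturbation,
    paired_prev: int | None = None,
) -> dict:
    return {
        "participant_id": nt.source.participant_id,
        "study_id": nt.source.study_id,
        "trial_index": nt.source.trial_index,
        "direction": direction.value,
        "measure": measure,
        "window_t0_ms": window[0],
        "window_t1_ms": window[1],
        "value_mels": value,
        "sign_corrected": False,
        "shift_magnitude_mels": nt.source.shift_magnitude_mels,
        "paired_prev_trial_index": paired_prev,
    }


def trial_compensation(
    nt: NormalizedTrial,
    window: tuple[float, float] = COMPENSATION_WINDOW,
    min_coverage: float = 0.5,
) -> dict:
    """Compensation response of one perturbed trial (a ResponseTable row)."""
    if Role.PERTURBED_UP in nt.labels:
        direction = Perturbation.UP
    elif Role.PERTURBED_DOWN in nt.labels:
        direction = Perturbation.DOWN
    else:
        raise ValueError(
            f"trial {nt.source.key} is not perturbed; compensation undefined"
        )
    value = window_mean(nt.normalized, *window, min_coverage=min_coverage)
    return _row(nt, "compensation", window, value, direction)


def trial_adaptation(
    nt: NormalizedTrial,
    window: tuple[float, float] = ADAPTATION_WINDOW,
    min_coverage: float = 0.5,
    prev_magnitude_mels: float = math.nan,
) -> dict:
    """One-shot adaptation response of one post-perturbation trial.

    The row's direction is that of the *previous* trial's perturbation,
    and ``paired_prev_trial_index`` points at that trial.  Post trials are
    themselves unperturbed, so the recorded shift magnitude is the
    previous (perturbed) trial's, passed as ``prev_magnitude_mels``.
    """
    if Role.POST_UP in nt.labels:
        direction = Perturbation.UP
    elif Role.POST_DOWN in nt.labels:
        direction = Perturbation.DOWN
    else:
        raise ValueError(
            f"trial {nt.source.key} is not post-perturbation; adaptation undefined"
        )
    value = window_mean(nt.normalized, *window, min_coverage=min_coverage)
    row = _row(nt, "adaptation", window, value, direction,
               paired_prev=nt.source.trial_index - 1)
    row["shift_magnitude_mels"] = prev_magnitude_mels
    return row


def participant_average_trajectory(
    nts: Sequence[NormalizedTrial], min_n: int = 1
) -> Trajectory:
    """Pointwise mean of normalized trajectories of one participant/role,
    truncated at the last time point with >= ``min_n`` contributing trials
    (same rule as the baseline construction; a single trial is allowed)."""
    if not nts:
        raise ValueError("no trials to average")
    steps = {nt.normalized.step_ms for nt in nts}
    if len(steps) != 1:
        raise ValueError(f"inconsistent sampling steps {sorted(steps)}")
    mean = _pointwise_mean([nt.normalized.values for nt in nts], max(1, min_n))
    return Trajectory(step_ms=steps.pop(), values=mean)


def participant_response(
    avg: Trajectory,
    measure: str,
    window: tuple[float, float],
    min_coverage: float = 0.5,
) -> float:
    """Participant-level response: the window mean of the *averaged*
    trajectory (average-then-window, which differs from window-then-average
    when trials have unequal lengths)."""
    return window_mean(avg, *window, min_coverage=min_coverage)


def sign_correct(rows: pd.DataFrame) -> pd.DataFrame:
    """Multiply responses from up-direction rows by −1 and set the flag.

    After correction, positive responses oppose the perturbation in both
    directions.  Applying it twice is an error.
    """
    if rows["sign_corrected"].any():
        raise ValueError("rows are already sign-corrected")
    out = rows.copy()
    up = out["direction"] == "up"
    out.loc[up, "value_mels"] = -out.loc[up, "value_mels"]
    out["sign_corrected"] = True
    return out


def response_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble response rows into a ResponseTable DataFrame."""
    df = pd.DataFrame(list(rows), columns=RESPONSE_COLUMNS)
    return df
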