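"""Trial labeling, exclusion rules, baseline construction and normalization.

Analysis roles follow the trial sequence within each (participant, study)
session: perturbed trials split by direction; unperturbed trials directly
following a perturbed trial are post-perturbation trials (the carriers of
one-shot adaptation); unperturbed trials following another unperturbed
trial are the adaptation-analysis baseline.  The compensation-analysis
baseline is, by default, *all* unperturbed trials — post-perturbation
trials included — with switches to restrict it.

Each trial is normalized by subtracting its participant- and
word-specific baseline mean trajectory, so all downstream responses are
deviations in mels from that speaker's habitual production of that word.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trials import Perturbation, Role, Trajectory, TrialRecord

__all__ = [
    "NormalizedTrial",
    "BaselineError",
    "label_trials",
    "filter_short_vowels",
    "baseline_trajectory",
    "normalize_trial",
    "build_baselines",
    "exclude_outlier_participants",
    "qc_report",
]


class BaselineError(ValueError):
    """Raised when a baseline trajectory cannot be constructed."""


@dataclass(frozen=True)
class NormalizedTrial:
    """A trial expressed as deviation (mels) from its baseline trajectory."""

    source: TrialRecord
    labels: frozenset[Role]
    normalized: Trajectory

    @property
    def direction(self) -> Perturbation:
        """Direction relevant to the trial's analysis role: its own shift
        for perturbed trials, the previous trial's shift for post trials."""
        if Role.PERTURBED_UP in self.labels or Role.POST_UP in self.labels:
            return Perturbation.UP
        if Role.PERTURBED_DOWN in self.labels or Role.POST_DOWN in self.labels:
            return Perturbation.DOWN
        return Perturbation.NONE


def label_trials(
    trials: Sequence[TrialRecord],
) -> dict[tuple[str, str, int], frozenset[Role]]:
    """Assign analysis roles to every trial, keyed by
    (participant_id, study_id, trial_index).

    Adjacency is by consecutive ``trial_index`` within a session; the
    first trial of a session is never a post-perturbation or
    baseline-after-baseline trial.  Duplicate indices raise ``ValueError``.
    """
    sessions: dict[tuple[str, str], dict[int, TrialRecord]] = defaultdict(dict)
    for tr in trials:
        sess = sessions[(tr.participant_id, tr.study_id)]
        if tr.trial_index in sess:
            raise ValueError(f"duplicate trial_index {tr.key}")
        sess[tr.trial_index] = tr

    labels: dict[tuple[str, str, int], frozenset[Role]] = {}
    for (pid, sid), sess in sessions.items():
        for idx, tr in sess.items():
            roles: set[Role] = set()
            prev = sess.get(idx - 1)
            if tr.perturbation is Perturbation.UP:
                roles.add(Role.PERTURBED_UP)
            elif tr.perturbation is Perturbation.DOWN:
                roles.add(Role.PERTURBED_DOWN)
            else:
                roles.add(Role.BASELINE_COMP)
                if prev is not None:
                    if prev.perturbation is Perturbation.UP:
                        roles.add(Role.POST_UP)
                    elif prev.perturbation is Perturbation.DOWN:
                        roles.add(Role.POST_DOWN)
                    else:
                        roles.add(Role.BASELINE_ADAPT)
            labels[(pid, sid, idx)] = frozenset(roles)
    return labels


def filter_short_vowels(
    trials: Sequence[TrialRecord], min_ms: float = 100.0
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Split trials into (kept, dropped) by vowel duration.

    Trials with ``vowel_duration_ms >= min_ms`` are kept (the boundary is
    inclusive).
    """
    if min_ms < 0:
        raise ValueError("min_ms must be >= 0")
    kept = [t for t in trials if t.vowel_duration_ms >= min_ms]
    dropped = [t for t in trials if t.vowel_duration_ms < min_ms]
    return kept, dropped


def _pointwise_mean(values: list[np.ndarray], min_n: int) -> np.ndarray:
    """Mean at each time index over the arrays that reach it, truncated at
    the last index with >= min_n contributors."""
    max_len = max(len(v) for v in values)
    counts = np.zeros(max_len, dtype=int)
    sums = np.zeros(max_len, dtype=float)
    for v in values:
        counts[: len(v)] += 1
        sums[: len(v)] += v
    ok = counts >= min_n
    if not ok[0]:
        raise BaselineError(f"fewer than {min_n} trials contribute at t=0")
    n_keep = int(np.argmin(ok)) if not ok.all() else max_len
    return sums[:n_keep] / counts[:n_keep]


def baseline_trajectory(
    trials: Sequence[TrialRecord | Trajectory], min_n: int = 3
) -> Trajectory:
    """Pointwise-mean baseline over a set of trials of one
    (participant, word) pair.

    At each time point the mean is taken over the trials that have a
    sample there; the baseline is truncated at the last time point with at
    least ``min_n`` contributing trials.  Raises :class:`BaselineError`
    when fewer than ``min_n`` trials exist at vowel onset.
    """
    trajs = [t.trajectory if isinstance(t, TrialRecord) else t for t in trials]
    if not trajs:
        raise BaselineError("no baseline trials")
    steps = {t.step_ms for t in trajs}
    if len(steps) != 1:
        raise BaselineError(f"inconsistent sampling steps {sorted(steps)}")
    if len(trajs) < min_n:
        raise BaselineError(
            f"only {len(trajs)} baseline trials, need at least {min_n}"
        )
    mean = _pointwise_mean([t.values for t in trajs], min_n)
    return Trajectory(step_ms=trajs[0].step_ms, values=mean)


def normalize_trial(
    trial: TrialRecord, baseline: Trajectory, labels: frozenset[Role] = frozenset()
) -> NormalizedTrial:
    """Subtract the baseline mean trajectory on the common time support."""
    if trial.trajectory.step_ms != baseline.step_ms:
        raise ValueError("trial and baseline sampling steps differ")
    n = min(len(trial.trajectory), len(baseline))
    if n == 0:
        raise ValueError("empty common support between trial and baseline")
    diff = trial.trajectory.values[:n] - baseline.values[:n]
    return NormalizedTrial(
        source=trial,
        labels=labels,
        normalized=Trajectory(step_ms=baseline.step_ms, values=diff),
    )


def build_baselines(
    trials: Sequence[TrialRecord],
    labels: Mapping[tuple[str, str, int], frozenset[Role]],
    baseline_role: Role,
    min_n: int = 3,
    exclude_post: bool = False,
) -> dict[tuple[str, str, str], Trajectory]:
    """Participant- and word-specific baseline trajectories.

    ``baseline_role`` selects the trials that define the baseline:
    ``Role.BASELINE_COMP`` (all unperturbed trials; used for the
    compensation analysis) or ``Role.BASELINE_ADAPT`` (unperturbed trials
    following unperturbed trials; used for the adaptation analysis).
    ``exclude_post`` additionally removes post-perturbation trials from a
    ``BASELINE_COMP`` set.  Pairs with fewer than ``min_n`` trials are
    omitted (callers treat missing pairs as unanalyzable).
    """
    groups: dict[tuple[str, str, str], list[TrialRecord]] = defaultdict(list)
    for tr in trials:
        roles = labels.get(tr.key, frozenset())
        if baseline_role not in roles:
            continue
        if exclude_post and (Role.POST_UP in roles or Role.POST_DOWN in roles):
            continue
        groups[(tr.participant_id, tr.study_id, tr.word)].append(tr)
    out: dict[tuple[str, str, str], Trajectory] = {}
    for key, grp in groups.items():
        if len(grp) < min_n:
            continue
        out[key] = baseline_trajectory(grp, min_n=min_n)
    return out


def exclude_outlier_participants(
    responses: pd.DataFrame,
    k_sd: float = 4.0,
    measures: Sequence[str] = ("compensation", "adaptation"),
) -> tuple[list[str], pd.DataFrame]:
    """Single-pass outlier screen on per-participant average responses.

    ``responses`` has one row per participant with a ``participant_id``
    column and one column per measure (sign-corrected averages collapsed
    across directions).  A participant is excluded when
    ``|value - mean| > k_sd * SD`` on *either* measure, with mean and SD
    computed over all participants.  Returns (kept participant ids,
    DataFrame of exclusions with the triggering measure).  An all-equal
    measure (zero SD) excludes no one.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if len(responses) < 3:
        raise ValueError("need at least 3 participants for the outlier screen")
    excluded: list[dict] = []
    flagged: set[str] = set()
    for m in measures:
        vals = responses[m].to_numpy(dtype=float)
        mean, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        for pid, v in zip(responses["participant_id"], vals):
            if np.isfinite(v) and abs(v - mean) > k_sd * sd:
                excluded.append(
                    {"participant_id": pid, "measure": m, "value": v,
                     "z": (v - mean) / sd}
                )
                flagged.add(pid)
    kept = [p for p in responses["participant_id"] if p not in flagged]
    return kept, pd.DataFrame(excluded, columns=["participant_id", "measure", "value", "z"])


def qc_report(
    labels: Mapping[tuple[str, str, int], frozenset[Role]],
    dropped_short: Sequence[TrialRecord],
    excluded_participants: pd.DataFrame,
) -> pd.DataFrame:
    """Counts per analysis role plus exclusion tallies, as a tidy table."""
    counts: dict[str, int] = defaultdict(int)
    for roles in labels.values():
        for r in roles:
            counts[r.value] += 1
    rows = [{"item": f"role:{k}", "count": v} for k, v in sorted(counts.items())]
    rows.append({"item": "dropped_short_vowels", "count": len(dropped_short)})
    rows.append(
        {"item": "excluded_participants",
         "count": int(excluded_participants["participant_id"].nunique())
         if len(excluded_participants) else 0}
    )
    return pd.DataFrame(rows)
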