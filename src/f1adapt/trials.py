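"""Core data types and I/O for per-trial vowel F1 trajectories.

A trial is one utterance of a monosyllabic /ɛ/ word under (possibly
perturbed) auditory feedback.  Its F1 trajectory is stored on a uniform
time grid starting at vowel onset (t = 0), in mels.  Trial tables are
exchanged as long-format CSV/TSV with one row per (trial, time) sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .units import hz_to_mel

__all__ = [
    "Perturbation",
    "Role",
    "Trajectory",
    "TrialRecord",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "trials_to_frame",
]


class Perturbation(str, enum.Enum):
    """Direction of the real-time F1 shift applied to auditory feedback."""

    NONE = "none"
    UP = "up"
    DOWN = "down"

    @property
    def sign(self) -> int:
        """+1 for an upward shift, -1 for downward, 0 for unperturbed."""
        return {"none": 0, "up": 1, "down": -1}[self.value]


class Role(str, enum.Enum):
    """Analysis roles a trial can play.  A trial may carry several.

    ``POST_UP``/``POST_DOWN`` mark unperturbed trials directly preceded by
    a perturbed trial; ``BASELINE_ADAPT`` marks unperturbed trials directly
    preceded by another unperturbed trial and is a subset of
    ``BASELINE_COMP`` (all unperturbed trials).
    """

    PERTURBED_UP = "perturbed_up"
    PERTURBED_DOWN = "perturbed_down"
    POST_UP = "post_up"
    POST_DOWN = "post_down"
    BASELINE_COMP = "baseline_comp"
    BASELINE_ADAPT = "baseline_adapt"
    OTHER = "other"


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled F1 (mels) versus time from vowel onset.

    Sample ``k`` represents time ``k * step_ms`` after vowel onset; the
    grid therefore starts at 0 and is strictly increasing.
    """

    step_ms: float
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.step_ms <= 0:
            raise ValueError(f"step_ms must be positive, got {self.step_ms}")
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("trajectory needs at least one sample")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trajectory values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms from vowel onset."""
        return np.arange(len(self)) * self.step_ms

    @property
    def duration_ms(self) -> float:
        """Time of the last sample."""
        return (len(self) - 1) * self.step_ms

    def allclose(self, other: "Trajectory", atol: float = 1e-9) -> bool:
        return (
            self.step_ms == other.step_ms
            and len(self) == len(other)
            and np.allclose(self.values, other.values, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True)
class TrialRecord:
    """One utterance: metadata plus its F1 trajectory."""

    participant_id: str
    study_id: str
    trial_index: int
    word: str
    perturbation: Perturbation
    shift_magnitude_mels: float
    vowel_duration_ms: float
    trajectory: Trajectory

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbation", Perturbation(self.perturbation))
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        if self.vowel_duration_ms <= 0:
            raise ValueError("vowel_duration_ms must be positive")
        if self.shift_magnitude_mels < 0:
            raise ValueError("shift_magnitude_mels must be >= 0")
        if (self.perturbation is Perturbation.NONE) != (self.shift_magnitude_mels == 0):
            raise ValueError(
                "shift_magnitude_mels must be 0 exactly for unperturbed trials "
                f"(got {self.perturbation.value}, {self.shift_magnitude_mels})"
            )
        tr = self.trajectory
        if len(tr) * tr.step_ms > self.vowel_duration_ms + tr.step_ms:
            raise ValueError(
                f"trajectory ({len(tr)} samples at {tr.step_ms} ms) extends past "
                f"vowel duration {self.vowel_duration_ms} ms"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.participant_id, self.study_id, self.trial_index)


TRIAL_COLUMNS = [
    "study_id",
    "participant_id",
    "trial_index",
    "word",
    "perturbation",
    "shift_magnitude_mels",
    "vowel_duration_ms",
    "time_ms",
    "f1",
]

#: metadata columns that must be constant within a trial
_META = TRIAL_COLUMNS[:7]


class TrialTableError(ValueError):
    """Raised when a trial table violates the long-format schema."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_trials(path: str | Path, units: str | None = None) -> list[TrialRecord]:
    """Read a long-format trial table (CSV/TSV) into TrialRecords.

    The F1 column is ``f1`` (mels) or ``f1_hz`` (Hertz; converted to mels
    on read).  ``units`` may be ``"mels"`` or ``"hz"`` to override the
    column-name declaration.

    Raises :class:`TrialTableError` on missing columns, duplicate
    (participant, study, trial, time) rows, or a non-uniform time grid,
    naming the offending trial.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    f1_col = "f1"
    if units is None:
        if "f1" in df.columns:
            units = "mels"
        elif "f1_hz" in df.columns:
            units, f1_col = "hz", "f1_hz"
        else:
            raise TrialTableError(f"{path}: no 'f1' or 'f1_hz' column")
    elif units == "hz" and "f1_hz" in df.columns:
        f1_col = "f1_hz"
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "f1"]
    if missing:
        raise TrialTableError(f"{path}: missing required column(s) {missing}")
    if f1_col not in df.columns:
        raise TrialTableError(f"{path}: no '{f1_col}' column for units={units}")

    key_cols = ["participant_id", "study_id", "trial_index"]
    dupes = df.duplicated(subset=key_cols + ["time_ms"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise TrialTableError(
            f"{path}: duplicate sample for trial "
            f"({row['participant_id']}, {row['study_id']}, {row['trial_index']}) "
            f"at time {row['time_ms']} ms"
        )

    records: list[TrialRecord] = []
    for (pid, sid, idx), grp in df.groupby(key_cols, sort=False):
        grp = grp.sort_values("time_ms")
        t = grp["time_ms"].to_numpy(dtype=float)
        if t[0] != 0:
            raise TrialTableError(
                f"{path}: trial ({pid}, {sid}, {idx}) time grid does not start at 0"
            )
        if len(t) > 1:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9) or steps[0] <= 0:
                raise TrialTableError(
                    f"{path}: trial ({pid}, {sid}, {idx}) has a non-uniform time grid"
                )
            step = float(steps[0])
        else:
            step = 5.0  # single-sample trial: nominal step
        vals = grp[f1_col].to_numpy(dtype=float)
        if units == "hz":
            vals = hz_to_mel(vals)
        meta = grp.iloc[0]
        records.append(
            TrialRecord(
                participant_id=str(pid),
                study_id=str(sid),
                trial_index=int(idx),
                word=str(meta["word"]),
                perturbation=Perturbation(meta["perturbation"]),
                shift_magnitude_mels=float(meta["shift_magnitude_mels"]),
                vowel_duration_ms=float(meta["vowel_duration_ms"]),
                trajectory=Trajectory(step_ms=step, values=vals),
            )
        )
    _check_unique(records)
    return records


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Long-format DataFrame (one row per sample) for a trial collection."""
    parts = []
    for tr in trials:
        n = len(tr.trajectory)
        parts.append(
            pd.DataFrame(
                {
                    "study_id": np.repeat(tr.study_id, n),
                    "participant_id": np.repeat(tr.participant_id, n),
                    "trial_index": np.repeat(tr.trial_index, n),
                    "word": np.repeat(tr.word, n),
                    "perturbation": np.repeat(tr.perturbation.value, n),
                    "shift_magnitude_mels": np.repeat(tr.shift_magnitude_mels, n),
                    "vowel_duration_ms": np.repeat(tr.vowel_duration_ms, n),
                    "time_ms": tr.trajectory.times_ms,
                    "f1": tr.trajectory.values,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(parts, ignore_index=True)[TRIAL_COLUMNS]


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> Path:
    """Write trials as a long-format table; inverse of :func:`read_trials`."""
    path = Path(path)
    trials_to_frame(trials).to_csv(path, sep=_sep_for(path), index=False)
    return path


def _check_unique(records: Sequence[TrialRecord]) -> None:
    seen: set[tuple[str, str, int]] = set()
    for r in records:
        if r.key in seen:
            raise TrialTableError(f"duplicate trial_index {r.key}")
        seen.add(r.key)
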