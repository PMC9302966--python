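"""Synthetic formant-perturbation experiments with known ground truth.

The generator emulates the structure of the multi-study dataset the
analysis is designed for: sessions of 120-800 trials per participant, a
pseudorandom 25-50% of trials carrying an upward or downward F1 shift of
roughly 94-126 mels, monosyllabic /ɛ/ words cycling over a small word
list, and vowel durations of ~100-400 ms.

Each trial's produced F1 trajectory is modeled as

    f1(t) = b_w(t) + eps_trial + smooth_noise(t) + c(t) + a(t)

where ``b_w(t) = target - dip * exp(-t / tau)`` is the participant- and
word-specific baseline (an exponential consonant-to-vowel transition),
``c(t)`` is within-trial compensation — a piecewise-linear ramp opposing
the current shift, starting at ``comp_latency_ms`` and saturating after
``comp_rise_ms`` — and ``a(t)`` is one-shot adaptation: a constant offset
opposing the *previous* trial's shift, present only on trials directly
following a perturbed trial.  Per-participant compensation and adaptation
gains are drawn from a bivariate normal with configurable correlation,
which is what the trial- and participant-level relationship analyses are
meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trials import Perturbation, Trajectory, TrialRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ScheduleError",
    "compensation_ramp",
    "generate_schedule",
    "generate_trial",
    "generate_experiment",
    "generate_study_set",
    "study_set_configs",
]


class ScheduleError(ValueError):
    """Raised when schedule constraints cannot be satisfied."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study session design.

    Defaults give a mid-sized study: 20 participants, 160 trials at 50%
    perturbed with ~115-mel shifts, compensation gain ~4% of the shift
    and one-shot adaptation gain ~1.2%, correlated 0.4 across
    participants.
    """

    n_participants: int = 20
    n_studies: int = 1
    study_id: str = "study1"
    words: tuple[str, ...] = ("bed", "dead", "head")
    n_trials: int = 160
    p_perturbed: float = 0.5
    shift_mean_mels: float = 115.0
    shift_sd_mels: float = 10.0
    # baseline trajectory: /ɛ/ vowel target ~680 mels (~580 Hz)
    baseline_f1_mels: float = 680.0
    baseline_participant_sd_mels: float = 40.0
    baseline_word_sd_mels: float = 15.0
    onset_dip_mels: float = 150.0
    transition_tau_ms: float = 40.0
    # noise
    noise_trial_sd_mels: float = 30.0
    noise_sample_sd_mels: float = 8.0
    noise_smooth_ms: float = 25.0
    # behavioral effects
    comp_gain_mean: float = 0.04
    comp_gain_sd: float = 0.02
    comp_latency_ms: float = 120.0
    comp_rise_ms: float = 80.0
    adapt_gain_mean: float = 0.012
    adapt_gain_sd: float = 0.008
    gain_correlation: float = 0.4
    # vowel durations: lognormal body with an explicit short-vowel mixture
    duration_median_ms: float = 320.0
    duration_log_sd: float = 0.5
    duration_max_ms: float = 600.0
    short_vowel_fraction: float = 0.01
    # sampling and schedule constraints
    step_ms: float = 5.0
    min_post_up: int = 3
    min_post_down: int = 3
    min_baseline_adapt: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_perturbed <= 1.0):
            raise ScheduleError(f"p_perturbed must be in [0,1], got {self.p_perturbed}")
        if abs(self.gain_correlation) > 1:
            raise ScheduleError("|gain_correlation| must be <= 1")
        for name in ("shift_sd_mels", "noise_trial_sd_mels", "noise_sample_sd_mels",
                     "comp_gain_sd", "adapt_gain_sd", "baseline_participant_sd_mels",
                     "baseline_word_sd_mels"):
            if getattr(self, name) < 0:
                raise ScheduleError(f"{name} must be >= 0")
        if not (0.0 <= self.short_vowel_fraction <= 1.0):
            raise ScheduleError("short_vowel_fraction must be in [0,1]")


@dataclass
class GroundTruth:
    """Injected parameters of a simulated experiment.

    ``participants`` has one row per participant (gains, shift magnitude);
    ``trials`` one row per trial (injected compensation plateau and
    adaptation offset, in mels).
    """

    participants: pd.DataFrame
    trials: pd.DataFrame


def generate_schedule(
    cfg: SimConfig, rng: np.random.Generator, max_attempts: int = 1000
) -> list[tuple[str, Perturbation]]:
    """Draw a pseudorandom (word, perturbation) sequence for one session.

    The perturbed-trial count is ``round(p_perturbed * n_trials)`` with up
    and down counts balanced within one; the draw is repeated until the
    sequence contains at least the configured minimum numbers of post-up,
    post-down and baseline (unperturbed-after-unperturbed) trials.  Words
    cycle in shuffled blocks over the word list.
    """
    n = cfg.n_trials
    n_pert = int(round(cfg.p_perturbed * n))
    n_unpert = n - n_pert
    if n_unpert == 0 and (cfg.min_post_up or cfg.min_post_down or cfg.min_baseline_adapt):
        raise ScheduleError(
            "p_perturbed leaves no unperturbed trials but post/baseline minima are > 0"
        )
    if n_unpert < cfg.min_post_up + cfg.min_post_down + cfg.min_baseline_adapt:
        raise ScheduleError("not enough unperturbed trials for the requested minima")

    n_up = n_pert // 2 + (int(rng.integers(2)) if n_pert % 2 else 0)
    n_down = n_pert - n_up

    perts = np.array(
        [Perturbation.UP] * n_up + [Perturbation.DOWN] * n_down
        + [Perturbation.NONE] * n_unpert,
        dtype=object,
    )
    for _ in range(max_attempts):
        seq = rng.permutation(perts)
        post_up = post_down = base_adapt = 0
        for i in range(1, n):
            if seq[i] is Perturbation.NONE:
                if seq[i - 1] is Perturbation.UP:
                    post_up += 1
                elif seq[i - 1] is Perturbation.DOWN:
                    post_down += 1
                else:
                    base_adapt += 1
        if (
            post_up >= cfg.min_post_up
            and post_down >= cfg.min_post_down
            and base_adapt >= cfg.min_baseline_adapt
        ):
            words = _word_cycle(cfg.words, n, rng)
            return list(zip(words, seq.tolist()))
    raise ScheduleError(
        f"could not satisfy schedule minima in {max_attempts} attempts "
        f"(p_perturbed={cfg.p_perturbed}, n_trials={n})"
    )


def _word_cycle(words: Sequence[str], n: int, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        out.extend(rng.permutation(np.asarray(words, dtype=object)).tolist())
    return out[:n]


def compensation_ramp(t_ms: np.ndarray, latency_ms: float, rise_ms: float) -> np.ndarray:
    """Piecewise-linear 0→1 ramp starting at ``latency_ms``."""
    if rise_ms <= 0:
        return (np.asarray(t_ms, float) >= latency_ms).astype(float)
    return np.clip((np.asarray(t_ms, float) - latency_ms) / rise_ms, 0.0, 1.0)


def generate_trial(
    *,
    word_target_mels: float,
    onset_dip_mels: float,
    transition_tau_ms: float,
    perturbation: Perturbation,
    shift_magnitude_mels: float,
    prev_perturbation: Perturbation,
    prev_magnitude_mels: float,
    comp_gain: float,
    adapt_gain: float,
    comp_latency_ms: float,
    comp_rise_ms: float,
    duration_ms: float,
    step_ms: float,
    noise_trial_sd_mels: float,
    noise_sample_sd_mels: float,
    noise_smooth_ms: float,
    rng: np.random.Generator,
) -> tuple[Trajectory, float, float]:
    """Simulate one trial's F1 trajectory.

    Returns ``(trajectory, comp_plateau_mels, adapt_offset_mels)`` where
    the last two are the injected effect amplitudes (0 where absent).
    """
    n = int(np.floor(duration_ms / step_ms)) + 1
    t = np.arange(n) * step_ms
    f1 = word_target_mels - onset_dip_mels * np.exp(-t / transition_tau_ms)

    if noise_trial_sd_mels > 0:
        f1 = f1 + rng.normal(0.0, noise_trial_sd_mels)
    if noise_sample_sd_mels > 0:
        w = max(1, int(round(noise_smooth_ms / step_ms)))
        white = rng.normal(0.0, noise_sample_sd_mels, size=n)
        # moving average shrinks marginal SD by sqrt(w); rescale to keep it
        smooth = np.convolve(white, np.ones(w) / w, mode="same") * np.sqrt(w)
        f1 = f1 + smooth

    comp_plateau = 0.0
    if perturbation is not Perturbation.NONE:
        comp_plateau = -perturbation.sign * comp_gain * shift_magnitude_mels
        f1 = f1 + comp_plateau * compensation_ramp(t, comp_latency_ms, comp_rise_ms)

    adapt_offset = 0.0
    if prev_perturbation is not Perturbation.NONE:
        adapt_offset = -prev_perturbation.sign * adapt_gain * prev_magnitude_mels
        f1 = f1 + adapt_offset

    return Trajectory(step_ms=step_ms, values=f1), comp_plateau, adapt_offset


def _draw_gains(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) array of per-participant (comp_gain, adapt_gain)."""
    mean = [cfg.comp_gain_mean, cfg.adapt_gain_mean]
    cs, as_ = cfg.comp_gain_sd, cfg.adapt_gain_sd
    rho = cfg.gain_correlation
    cov = np.array([[cs**2, rho * cs * as_], [rho * cs * as_, as_**2]])
    return rng.multivariate_normal(mean, cov, size=n)


def _draw_durations(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    short = rng.random(n) < cfg.short_vowel_fraction
    body = np.exp(rng.normal(np.log(cfg.duration_median_ms), cfg.duration_log_sd, n))
    dur = np.clip(body, 100.0, cfg.duration_max_ms)
    dur[short] = rng.uniform(60.0, 99.0, size=short.sum())
    return dur


def generate_experiment(
    cfg: SimConfig, seed: int | None = None
) -> tuple[list[TrialRecord], GroundTruth]:
    """Simulate a complete experiment (``n_studies`` sessions of
    ``n_participants`` each), deterministically from the seed.

    Returns the trial records and a :class:`GroundTruth` with the drawn
    per-participant gains and per-trial injected effects.
    """
    base_seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    study_seeds = ss.spawn(cfg.n_studies)

    trials: list[TrialRecord] = []
    prows: list[dict] = []
    trows: list[dict] = []
    for s in range(cfg.n_studies):
        sid = cfg.study_id if cfg.n_studies == 1 else f"{cfg.study_id}{s + 1}"
        _simulate_study(cfg, sid, study_seeds[s], trials, prows, trows)
    truth = GroundTruth(
        participants=pd.DataFrame(prows),
        trials=pd.DataFrame(trows),
    )
    return trials, truth


def _simulate_study(
    cfg: SimConfig,
    study_id: str,
    seedseq: np.random.SeedSequence,
    trials: list[TrialRecord],
    prows: list[dict],
    trows: list[dict],
) -> None:
    study_rng = np.random.default_rng(seedseq)
    part_seeds = seedseq.spawn(cfg.n_participants)
    gains = _draw_gains(cfg, cfg.n_participants, study_rng)
    word_means = {
        w: cfg.baseline_f1_mels + study_rng.normal(0.0, cfg.baseline_word_sd_mels)
        for w in cfg.words
    }
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(part_seeds[i])
        pid = f"{study_id}_p{i + 1:02d}"
        comp_gain, adapt_gain = gains[i]
        shift = max(20.0, rng.normal(cfg.shift_mean_mels, cfg.shift_sd_mels))
        p_offset = rng.normal(0.0, cfg.baseline_participant_sd_mels)
        targets = {w: word_means[w] + p_offset for w in cfg.words}
        prows.append(
            {
                "study_id": study_id,
                "participant_id": pid,
                "comp_gain": comp_gain,
                "adapt_gain": adapt_gain,
                "shift_magnitude_mels": shift,
            }
        )
        schedule = generate_schedule(cfg, rng)
        durations = _draw_durations(cfg, cfg.n_trials, rng)
        prev = Perturbation.NONE
        for k, (word, pert) in enumerate(schedule):
            mag = shift if pert is not Perturbation.NONE else 0.0
            traj, comp_off, adapt_off = generate_trial(
                word_target_mels=targets[word],
                onset_dip_mels=cfg.onset_dip_mels,
                transition_tau_ms=cfg.transition_tau_ms,
                perturbation=pert,
                shift_magnitude_mels=mag,
                prev_perturbation=prev,
                prev_magnitude_mels=shift,
                comp_gain=comp_gain,
                adapt_gain=adapt_gain,
                comp_latency_ms=cfg.comp_latency_ms,
                comp_rise_ms=cfg.comp_rise_ms,
                duration_ms=durations[k],
                step_ms=cfg.step_ms,
                noise_trial_sd_mels=cfg.noise_trial_sd_mels,
                noise_sample_sd_mels=cfg.noise_sample_sd_mels,
                noise_smooth_ms=cfg.noise_smooth_ms,
                rng=rng,
            )
            trials.append(
                TrialRecord(
                    participant_id=pid,
                    study_id=study_id,
                    trial_index=k + 1,
                    word=word,
                    perturbation=pert,
                    shift_magnitude_mels=mag,
                    vowel_duration_ms=durations[k],
                    trajectory=traj,
                )
            )
            trows.append(
                {
                    "study_id": study_id,
                    "participant_id": pid,
                    "trial_index": k + 1,
                    "word": word,
                    "perturbation": pert.value,
                    "comp_plateau_mels": comp_off,
                    "adapt_offset_mels": adapt_off,
                }
            )
            prev = pert


def study_set_configs(
    participant_counts: Sequence[int] = (14, 13, 40, 40, 11, 15),
    trial_counts: Sequence[int] = (160, 120, 240, 240, 400, 800),
    p_perturbed: Sequence[float] = (0.5, 0.5, 1 / 3, 1 / 3, 0.25, 0.5),
    shift_means: Sequence[float] = (123.6, 125.0, 125.0, 125.0, 107.9, 94.3),
    shift_sds: Sequence[float] = (10.0, 0.0, 0.0, 0.0, 29.9, 6.8),
    **overrides,
) -> list[SimConfig]:
    """Six per-study configurations emulating the published multi-study
    design (participant counts, session lengths, perturbed fractions and
    shift magnitudes).  Keyword overrides apply to every study; pass
    scaled-down counts for quick runs.
    """
    word_lists = (
        ("beck", "bet", "deck", "debt", "pet", "tech"),
        ("dead", "fed", "said", "shed"),
        ("bed", "dead", "head"),
        ("bed", "dead", "head"),
        ("bed", "bet", "dead", "deb", "debt", "ped", "tech", "ted"),
        ("head",),
    )
    cfgs = []
    for i in range(6):
        cfgs.append(
            SimConfig(
                study_id=f"study{i + 1}",
                n_participants=participant_counts[i],
                n_trials=trial_counts[i],
                p_perturbed=p_perturbed[i],
                shift_mean_mels=shift_means[i],
                shift_sd_mels=shift_sds[i],
                words=word_lists[i],
                **overrides,
            )
        )
    return cfgs


def generate_study_set(
    cfgs: Sequence[SimConfig], seed: int = 0
) -> tuple[list[TrialRecord], GroundTruth]:
    """Simulate several studies (e.g. from :func:`study_set_configs`) under
    one master seed, concatenating trials and ground truth."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(cfgs))
    all_trials: list[TrialRecord] = []
    pparts, tparts = [], []
    for cfg, s in zip(cfgs, seeds):
        tr, truth = generate_experiment(cfg, seed=int(s) % (2**31))
        all_trials.extend(tr)
        pparts.append(truth.participants)
        tparts.append(truth.trials)
    return all_trials, GroundTruth(
        participants=pd.concat(pparts, ignore_index=True),
        trials=pd.concat(tparts, ignore_index=True),
    )
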