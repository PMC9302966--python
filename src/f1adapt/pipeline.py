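"""End-to-end orchestration: trials in, statistics out.

The pipeline runs the analysis in the order the measures are defined:
label trials by role, drop short vowels, build participant- and
word-specific baselines, normalize, compute windowed responses at trial
and participant level, screen outlier participants, and fit the
inference battery (direction mixed models, paired/one-sample t-tests,
cluster permutation tests, relationship models, per-participant
correlations).  Every random element (simulation, permutations) derives
from the single config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import preprocess, responses
from .inference import (
    ClusterResult,
    CorrelationResult,
    ModelResult,
    TestResult,
    cluster_permutation,
    fit_direction_model,
    fit_relationship_model,
    paired_and_one_sample_tests,
    per_participant_correlation,
)
from .preprocess import NormalizedTrial
from .simulate import SimConfig, generate_experiment
from .trials import Role, TrialRecord

log = logging.getLogger("f1adapt")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ResponseBundle",
    "compute_responses",
    "run_pipeline",
    "write_outputs",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every analysis constant in one place.

    Defaults follow the analysis conventions: 150–250 ms compensation
    window, first-100-ms adaptation window (50–150 ms alternative),
    100 ms minimum vowel duration, 4-SD participant outlier screen.
    """

    compensation_window: tuple[float, float] = responses.COMPENSATION_WINDOW
    adaptation_window: tuple[float, float] = responses.ADAPTATION_WINDOW
    use_alt_adaptation_window: bool = False
    min_vowel_duration_ms: float = 100.0
    outlier_k_sd: float = 4.0
    baseline_min_n: int = 3
    min_coverage: float = 0.5
    # compensation baseline: all unperturbed trials, or restrict
    comp_baseline_role: str = "baseline_comp"  # or "baseline_adapt"
    exclude_post_from_comp_baseline: bool = False
    same_word_pairs_only: bool = False
    min_pairs_per_participant: int = 10
    # cluster permutation
    n_perm: int = 10_000
    alpha_point: float = 0.05
    cluster_t_max_ms: float = 250.0
    run_cluster_tests: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.compensation_window, self.adaptation_window):
            if not (0 <= w[0] < w[1] <= 300):
                raise ValueError(f"window {w} out of range")
        if self.min_vowel_duration_ms < 0 or self.outlier_k_sd <= 0:
            raise ValueError("thresholds must be positive")
        if self.comp_baseline_role not in {"baseline_comp", "baseline_adapt"}:
            raise ValueError("comp_baseline_role must be baseline_comp|baseline_adapt")

    @property
    def adaptation_window_eff(self) -> tuple[float, float]:
        return (responses.ADAPTATION_WINDOW_ALT if self.use_alt_adaptation_window
                else self.adaptation_window)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        section = raw.get("analyze", raw)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        for key in ("compensation_window", "adaptation_window"):
            if key in section:
                section[key] = tuple(section[key])
        return cls(**section)


@dataclass
class PipelineResult:
    """Everything the pipeline computes, ready for serialization."""

    config: PipelineConfig
    qc: pd.DataFrame
    comp_trials: pd.DataFrame  # trial-level compensation ResponseTable
    adapt_trials: pd.DataFrame  # trial-level adaptation ResponseTable
    participant_responses: pd.DataFrame
    excluded_participants: pd.DataFrame
    direction_model_comp: ModelResult
    direction_model_adapt: ModelResult
    tests_comp: dict[str, TestResult]
    tests_adapt: dict[str, TestResult]
    cluster_tests: dict[str, ClusterResult]
    relationship_trial: ModelResult | None
    relationship_participant: ModelResult | None
    correlation: CorrelationResult | None
    participant_avg_trajectories: dict[tuple[str, str, str], np.ndarray] = field(
        default_factory=dict
    )  # (participant_id, measure, direction) -> averaged normalized trajectory
    step_ms: float = 5.0


def _normalize_set(
    trials: Sequence[TrialRecord],
    labels: Mapping,
    roles: tuple[Role, Role],
    baselines: Mapping[tuple[str, str, str], "preprocess.Trajectory"],
) -> list[NormalizedTrial]:
    out = []
    for tr in trials:
        rs = labels.get(tr.key, frozenset())
        if roles[0] not in rs and roles[1] not in rs:
            continue
        base = baselines.get((tr.participant_id, tr.study_id, tr.word))
        if base is None:
            continue
        out.append(preprocess.normalize_trial(tr, base, rs))
    return out


@dataclass
class ResponseBundle:
    """Intermediate products of the response-computation stage."""

    comp_nts: list[NormalizedTrial]
    adapt_nts: list[NormalizedTrial]
    comp_trials: pd.DataFrame
    adapt_trials: pd.DataFrame
    participant_responses: pd.DataFrame
    avg_trajectories: dict[tuple[str, str, str], np.ndarray]
    dropped_short: list[TrialRecord]
    labels: dict
    step_ms: float


def compute_responses(
    trials: Sequence[TrialRecord], cfg: PipelineConfig | None = None
) -> ResponseBundle:
    """Label, filter, normalize and compute trial- and participant-level
    responses — everything up to (but excluding) outlier screening and
    statistical inference."""
    cfg = cfg or PipelineConfig()
    trials = list(trials)
    by_key = {tr.key: tr for tr in trials}

    # 1. label on the full session sequence, then drop short vowels
    labels = preprocess.label_trials(trials)
    kept, dropped = preprocess.filter_short_vowels(trials, cfg.min_vowel_duration_ms)
    log.info("trials: %d total, %d dropped (<%g ms)", len(trials), len(dropped),
             cfg.min_vowel_duration_ms)
    if not kept:
        raise ValueError("no trials survive the duration filter")
    step_ms = kept[0].trajectory.step_ms

    # 2. compensation: baseline over unperturbed trials, normalize perturbed
    comp_base = preprocess.build_baselines(
        kept, labels, Role(cfg.comp_baseline_role), cfg.baseline_min_n,
        exclude_post=cfg.exclude_post_from_comp_baseline,
    )
    comp_nts = _normalize_set(kept, labels,
                              (Role.PERTURBED_UP, Role.PERTURBED_DOWN), comp_base)
    comp_rows = [
        responses.trial_compensation(nt, cfg.compensation_window, cfg.min_coverage)
        for nt in comp_nts
    ]
    comp_trials_tbl = responses.response_frame(comp_rows)

    # 3. adaptation: baseline over unperturbed-after-unperturbed trials,
    #    normalize post-perturbation trials
    adapt_base = preprocess.build_baselines(kept, labels, Role.BASELINE_ADAPT,
                                            cfg.baseline_min_n)
    adapt_nts = _normalize_set(kept, labels, (Role.POST_UP, Role.POST_DOWN), adapt_base)
    if cfg.same_word_pairs_only:
        adapt_nts = [
            nt for nt in adapt_nts
            if (prev := by_key.get((nt.source.participant_id, nt.source.study_id,
                                    nt.source.trial_index - 1))) is not None
            and prev.word == nt.source.word
        ]
    adapt_rows = []
    for nt in adapt_nts:
        prev = by_key.get((nt.source.participant_id, nt.source.study_id,
                           nt.source.trial_index - 1))
        adapt_rows.append(
            responses.trial_adaptation(
                nt, cfg.adaptation_window_eff, cfg.min_coverage,
                prev_magnitude_mels=prev.shift_magnitude_mels if prev else np.nan,
            )
        )
    adapt_trials_tbl = responses.response_frame(adapt_rows)

    # 4. participant-level averages (average trajectory, then window)
    part_rows, avg_trajs = [], {}
    for measure, nts, window in (
        ("compensation", comp_nts, cfg.compensation_window),
        ("adaptation", adapt_nts, cfg.adaptation_window_eff),
    ):
        grouped: dict[tuple[str, str, str], list[NormalizedTrial]] = {}
        for nt in nts:
            d = nt.direction.value
            grouped.setdefault(
                (nt.source.participant_id, nt.source.study_id, d), []
            ).append(nt)
        for (pid, sid, d), group in grouped.items():
            avg = responses.participant_average_trajectory(group)
            value = responses.participant_response(avg, measure, window,
                                                   cfg.min_coverage)
            avg_trajs[(pid, measure, d)] = avg.values
            part_rows.append(
                {"participant_id": pid, "study_id": sid, "measure": measure,
                 "direction": d, "value_mels": value, "n_trials": len(group)}
            )
    part_tbl = pd.DataFrame(part_rows)
    return ResponseBundle(
        comp_nts=comp_nts,
        adapt_nts=adapt_nts,
        comp_trials=comp_trials_tbl,
        adapt_trials=adapt_trials_tbl,
        participant_responses=part_tbl,
        avg_trajectories=avg_trajs,
        dropped_short=dropped,
        labels=labels,
        step_ms=step_ms,
    )


def run_pipeline(
    trials: Sequence[TrialRecord] | None = None,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a trial collection (or simulate one first)."""
    cfg = config or PipelineConfig()
    if trials is None:
        if sim_config is None:
            raise ValueError("provide trials or a simulation config")
        trials, _ = generate_experiment(sim_config, seed=cfg.seed)
    bundle = compute_responses(trials, cfg)
    comp_trials_tbl = bundle.comp_trials
    adapt_trials_tbl = bundle.adapt_trials
    part_tbl = bundle.participant_responses
    comp_nts, adapt_nts = bundle.comp_nts, bundle.adapt_nts
    avg_trajs = bundle.avg_trajectories
    labels, dropped = bundle.labels, bundle.dropped_short
    step_ms = bundle.step_ms

    # 5. outlier screen on sign-corrected averages collapsed across directions
    collapsed = _collapsed_participant_means(part_tbl)
    kept_pids, excluded = preprocess.exclude_outlier_participants(
        collapsed, cfg.outlier_k_sd
    )
    if len(excluded):
        log.info("excluded outlier participants: %s",
                 sorted(excluded["participant_id"].unique()))
    keep = set(kept_pids)
    comp_trials_tbl = comp_trials_tbl[comp_trials_tbl["participant_id"].isin(keep)]
    adapt_trials_tbl = adapt_trials_tbl[adapt_trials_tbl["participant_id"].isin(keep)]
    part_tbl = part_tbl[part_tbl["participant_id"].isin(keep)]
    comp_nts = [nt for nt in comp_nts if nt.source.participant_id in keep]
    adapt_nts = [nt for nt in adapt_nts if nt.source.participant_id in keep]
    avg_trajs = {k: v for k, v in avg_trajs.items() if k[0] in keep}

    qc = preprocess.qc_report(labels, dropped, excluded)

    # 6. inference
    dm_comp = fit_direction_model(comp_trials_tbl)
    dm_adapt = fit_direction_model(adapt_trials_tbl)
    tests_comp = _participant_tests(part_tbl, "compensation")
    tests_adapt = _participant_tests(part_tbl, "adaptation")

    cluster_tests: dict[str, ClusterResult] = {}
    if cfg.run_cluster_tests:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        for measure in ("compensation", "adaptation"):
            sets = {
                d: {k[0]: v for k, v in avg_trajs.items()
                    if k[1] == measure and k[2] == d}
                for d in ("up", "down")
            }
            for d in ("up", "down"):
                if len(sets[d]) >= 3:
                    cluster_tests[f"{measure}_{d}_vs_zero"] = cluster_permutation(
                        list(sets[d].values()), step_ms=step_ms,
                        t_max_ms=cfg.cluster_t_max_ms, alpha_point=cfg.alpha_point,
                        n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
                    )
            both = sorted(set(sets["up"]) & set(sets["down"]))
            if len(both) >= 3:
                cluster_tests[f"{measure}_up_vs_down"] = cluster_permutation(
                    [sets["up"][p] for p in both], [sets["down"][p] for p in both],
                    step_ms=step_ms, t_max_ms=cfg.cluster_t_max_ms,
                    alpha_point=cfg.alpha_point, n_perm=cfg.n_perm,
                    seed=int(rng.integers(2**31)),
                )

    # 7. relationship between compensation and subsequent adaptation
    pairs = pair_responses(comp_trials_tbl, adapt_trials_tbl)
    rel_trial = rel_part = corr = None
    if len(pairs) >= 10 and pairs["participant_id"].nunique() >= 2:
        rel_trial = fit_relationship_model(pairs, level="trial")
        try:
            corr = per_participant_correlation(pairs, cfg.min_pairs_per_participant)
        except ValueError as exc:
            log.info("per-participant correlation skipped: %s", exc)
    ppairs = participant_pairs(part_tbl, comp_trials_tbl)
    if len(ppairs) >= 6 and ppairs["participant_id"].nunique() >= 3:
        rel_part = fit_relationship_model(ppairs, level="participant")

    return PipelineResult(
        config=cfg,
        qc=qc,
        comp_trials=comp_trials_tbl.reset_index(drop=True),
        adapt_trials=adapt_trials_tbl.reset_index(drop=True),
        participant_responses=part_tbl.reset_index(drop=True),
        excluded_participants=excluded,
        direction_model_comp=dm_comp,
        direction_model_adapt=dm_adapt,
        tests_comp=tests_comp,
        tests_adapt=tests_adapt,
        cluster_tests=cluster_tests,
        relationship_trial=rel_trial,
        relationship_participant=rel_part,
        correlation=corr,
        participant_avg_trajectories=avg_trajs,
        step_ms=step_ms,
    )


def _collapsed_participant_means(part_tbl: pd.DataFrame) -> pd.DataFrame:
    """Per-participant sign-corrected averages collapsed across directions."""
    t = part_tbl.copy()
    t["corrected"] = np.where(t["direction"] == "up", -t["value_mels"], t["value_mels"])
    wide = (
        t.groupby(["participant_id", "measure"])["corrected"].mean().unstack()
        .reset_index()
    )
    for m in ("compensation", "adaptation"):
        if m not in wide:
            wide[m] = np.nan
    return wide


def _participant_tests(part_tbl: pd.DataFrame, measure: str) -> dict[str, TestResult]:
    sub = part_tbl[part_tbl["measure"] == measure]
    wide = sub.pivot_table(index="participant_id", columns="direction",
                           values="value_mels", aggfunc="mean")
    for d in ("up", "down"):
        if d not in wide:
            wide[d] = np.nan
    return paired_and_one_sample_tests(
        wide["up"].to_numpy(), wide["down"].to_numpy(), prefix=f"{measure} "
    )


def pair_responses(
    comp_trials: pd.DataFrame, adapt_trials: pd.DataFrame
) -> pd.DataFrame:
    """Pair each adaptation response with the compensation response of the
    immediately preceding perturbed trial, sign-correcting both."""
    comp = responses.sign_correct(comp_trials)[
        ["participant_id", "study_id", "trial_index", "value_mels"]
    ].rename(columns={"value_mels": "compensation", "trial_index": "prev_index"})
    adapt = responses.sign_correct(adapt_trials).rename(
        columns={"value_mels": "adaptation",
                 "paired_prev_trial_index": "prev_index"}
    )
    merged = adapt.merge(comp, on=["participant_id", "study_id", "prev_index"],
                         how="inner")
    merged = merged.dropna(subset=["compensation", "adaptation"])
    merged["sign_corrected"] = True
    return merged[
        ["participant_id", "study_id", "trial_index", "prev_index", "direction",
         "shift_magnitude_mels", "compensation", "adaptation", "sign_corrected"]
    ]


def participant_pairs(
    part_tbl: pd.DataFrame, comp_trials: pd.DataFrame
) -> pd.DataFrame:
    """Participant-level pairs: each participant contributes two points
    (their average up- and down-direction responses), sign-corrected, with
    the participant's mean shift magnitude per direction."""
    wide = part_tbl.pivot_table(
        index=["participant_id", "study_id", "direction"], columns="measure",
        values="value_mels", aggfunc="mean",
    ).reset_index()
    if "compensation" not in wide or "adaptation" not in wide:
        return pd.DataFrame(columns=["participant_id"])
    mags = (
        comp_trials.groupby(["participant_id", "direction"])["shift_magnitude_mels"]
        .mean().rename("shift_magnitude_mels").reset_index()
    )
    out = wide.merge(mags, on=["participant_id", "direction"], how="left")
    up = out["direction"] == "up"
    out.loc[up, "compensation"] = -out.loc[up, "compensation"]
    out.loc[up, "adaptation"] = -out.loc[up, "adaptation"]
    out["sign_corrected"] = True
    return out.dropna(subset=["compensation", "adaptation", "shift_magnitude_mels"])


# ---------------------------------------------------------------------------
# serialization

def _tests_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for measure, tests in (("compensation", result.tests_comp),
                           ("adaptation", result.tests_adapt)):
        for key, t in tests.items():
            rows.append({"measure": measure, "test": key, "name": t.name,
                         "t": t.statistic, "df": t.df, "p": t.pvalue,
                         "cohen_d": t.cohen_d, "mean": t.mean, "sd": t.sd,
                         "n": t.n, "note": t.note})
    return pd.DataFrame(rows)


def _clusters_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for key, cr in result.cluster_tests.items():
        if not cr.clusters:
            rows.append({"contrast": key, "start_ms": np.nan, "end_ms": np.nan,
                         "mass": np.nan, "p": np.nan, "n_perm": cr.n_perm})
        for c in cr.clusters:
            rows.append({"contrast": key, "start_ms": c.start_ms, "end_ms": c.end_ms,
                         "mass": c.mass, "p": c.pvalue, "n_perm": cr.n_perm})
    return pd.DataFrame(rows)


def _models_frame(result: PipelineResult) -> pd.DataFrame:
    parts = []
    for name, m in (
        ("direction_compensation", result.direction_model_comp),
        ("direction_adaptation", result.direction_model_adapt),
        ("relationship_trial", result.relationship_trial),
        ("relationship_participant", result.relationship_participant),
    ):
        if m is None:
            continue
        t = m.terms.copy()
        t.insert(0, "model", name)
        t["residual_sd"] = m.residual_sd
        t["converged"] = m.converged
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write CSV tables and a text report; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "qc.csv": result.qc,
        "compensation_trials.csv": result.comp_trials,
        "adaptation_trials.csv": result.adapt_trials,
        "participant_responses.csv": result.participant_responses,
        "excluded_participants.csv": result.excluded_participants,
        "models.csv": _models_frame(result),
        "tests.csv": _tests_frame(result),
        "clusters.csv": _clusters_frame(result),
    }
    if result.correlation is not None:
        tables["correlations.csv"] = result.correlation.per_participant
    for name, df in tables.items():
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = p
    report = out / "report.txt"
    report.write_text(format_report(result))
    paths["report.txt"] = report
    return paths


def format_report(result: PipelineResult) -> str:
    """Human-readable summary of the main statistics."""
    lines = ["F1 perturbation analysis report", "=" * 32, ""]
    for name, m in (("Compensation ~ direction", result.direction_model_comp),
                    ("Adaptation ~ direction", result.direction_model_adapt)):
        b = m.term("direction")
        lines.append(
            f"{name}: beta={b.estimate:.3f} mels (up-down), SE={b.se:.3f}, "
            f"t({b.df:.1f})={b.tvalue:.2f}, p={b.pvalue:.3g}, d={b.effect_size_d:.3f}"
        )
    for measure, tests in (("compensation", result.tests_comp),
                           ("adaptation", result.tests_adapt)):
        t = tests["paired"]
        lines.append(
            f"Participant-level {measure} paired t: t({t.df:.0f})={t.statistic:.2f}, "
            f"p={t.pvalue:.3g}, d={t.cohen_d:.2f} "
            f"(mean up-down diff {t.mean:.2f} mels, n={t.n})"
        )
    for key, cr in result.cluster_tests.items():
        sig = cr.significant()
        desc = "; ".join(f"[{c.start_ms:.0f},{c.end_ms:.0f}] ms p={c.pvalue:.3g}"
                         for c in sig) or "none"
        lines.append(f"Clusters {key} (p<0.05): {desc}")
    if result.relationship_participant is not None:
        b = result.relationship_participant.term("compensation")
        lines.append(
            f"Participant-level adaptation ~ compensation: beta={b.estimate:.3f}, "
            f"SE={b.se:.3f}, p={b.pvalue:.3g}, eta2={b.eta_sq_partial:.3g}"
        )
    if result.relationship_trial is not None:
        b = result.relationship_trial.term("compensation")
        lines.append(
            f"Trial-level adaptation ~ compensation: beta={b.estimate:.3f}, "
            f"SE={b.se:.3f}, p={b.pvalue:.3g}"
        )
    if result.correlation is not None:
        c = result.correlation
        lines.append(
            f"Per-participant correlation: mean r={c.mean_r:.3f}, "
            f"{c.n_positive}/{c.n_participants} r>0, t({c.df:.0f})={c.statistic:.2f}, "
            f"p={c.pvalue:.3g}, d={c.cohen_d:.2f}"
        )
    lines.append("")
    lines.append("QC:")
    for _, row in result.qc.iterrows():
        lines.append(f"  {row['item']}: {row['count']}")
    return "\n".join(lines) + "\n"
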