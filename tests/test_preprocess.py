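"""Role labeling, exclusion rules, baseline construction, normalization."""

import numpy as np
import pandas as pd
import pytest

from f1adapt import (
    Perturbation,
    Role,
    SimConfig,
    Trajectory,
    TrialRecord,
    baseline_trajectory,
    exclude_outlier_participants,
    filter_short_vowels,
    generate_experiment,
    label_trials,
    normalize_trial,
)
from f1adapt.preprocess import BaselineError, build_baselines


def _seq(perts, pid="p1", sid="s1"):
    out = []
    for i, p in enumerate(perts, start=1):
        p = Perturbation(p)
        out.append(
            TrialRecord(
                participant_id=pid, study_id=sid, trial_index=i, word="head",
                perturbation=p,
                shift_magnitude_mels=0.0 if p is Perturbation.NONE else 100.0,
                vowel_duration_ms=200.0,
                trajectory=Trajectory(5.0, np.full(41, 600.0)),
            )
        )
    return out


class TestLabeling:
    def test_post_and_baseline_assignment(self):
        trials = _seq(["none", "up", "none", "none", "down", "none"])
        labels = label_trials(trials)
        key = lambda i: ("p1", "s1", i)
        assert Role.POST_UP in labels[key(3)]
        assert Role.BASELINE_ADAPT in labels[key(4)]
        assert Role.POST_DOWN in labels[key(6)]
        # first unperturbed trial is baseline_comp but not baseline_adapt
        assert Role.BASELINE_COMP in labels[key(1)]
        assert Role.BASELINE_ADAPT not in labels[key(1)]
        assert Role.POST_UP not in labels[key(1)]

    def test_all_unperturbed_has_no_post(self):
        labels = label_trials(_seq(["none"] * 5))
        assert all(
            Role.POST_UP not in r and Role.POST_DOWN not in r for r in labels.values()
        )
        n_adapt = sum(Role.BASELINE_ADAPT in r for r in labels.values())
        assert n_adapt == 4

    def test_roles_partition_consistency(self, small_experiment):
        trials, _ = small_experiment
        labels = label_trials(trials)
        n_pert = n_post = 0
        for tr in trials:
            roles = labels[tr.key]
            perturbed = tr.perturbation is not Perturbation.NONE
            is_post = Role.POST_UP in roles or Role.POST_DOWN in roles
            if perturbed:
                n_pert += 1
                assert not is_post
                assert Role.BASELINE_COMP not in roles
            if Role.BASELINE_ADAPT in roles:
                assert Role.BASELINE_COMP in roles
            n_post += is_post
        assert n_post <= n_pert

    def test_duplicate_index_rejected(self):
        trials = _seq(["none", "up"])
        trials.append(trials[0])
        with pytest.raises(ValueError, match="duplicate"):
            label_trials(trials)


class TestDurationFilter:
    def test_boundary_inclusive(self):
        trials = []
        for i, d in enumerate([95.0, 100.0, 250.0], start=1):
            trials.append(
                TrialRecord("p1", "s1", i, "head", Perturbation.NONE, 0.0, d,
                            Trajectory(5.0, np.full(int(d // 5) + 1, 600.0)))
            )
        kept, dropped = filter_short_vowels(trials, 100.0)
        assert [t.trial_index for t in kept] == [2, 3]
        assert [t.trial_index for t in dropped] == [1]

    def test_zero_threshold_is_identity(self):
        trials = _seq(["none", "up"])
        kept, dropped = filter_short_vowels(trials, 0.0)
        assert kept == trials and dropped == []

    def test_simulated_short_fraction_dropped(self):
        cfg = SimConfig(n_participants=10, n_trials=100, short_vowel_fraction=0.01,
                        seed=8)
        trials, _ = generate_experiment(cfg)
        kept, dropped = filter_short_vowels(trials)
        assert len(dropped) / len(trials) == pytest.approx(0.01, abs=0.01)


def _traj(vals):
    return Trajectory(5.0, np.asarray(vals, dtype=float))


class TestBaseline:
    def test_identical_trials(self):
        t = _traj(np.linspace(500, 650, 30))
        base = baseline_trajectory([t, t], min_n=2)
        assert base.allclose(t)

    def test_truncation_at_min_n(self):
        # 200 ms and 300 ms trials (41 and 61 samples): baseline stops at 200 ms
        t1 = _traj(np.full(41, 600.0))
        t2 = _traj(np.full(61, 610.0))
        base = baseline_trajectory([t1, t2], min_n=2)
        assert len(base) == 41
        np.testing.assert_allclose(base.values, 605.0)

    def test_pointwise_mean_matches_brute_force(self, rng):
        lengths = [30, 45, 45, 50, 60]
        trajs = [_traj(rng.normal(600, 20, n)) for n in lengths]
        base = baseline_trajectory(trajs, min_n=3)
        # brute force: per time index, average over trials reaching it
        for k in range(len(base)):
            vals = [t.values[k] for t in trajs if len(t) > k]
            assert len(vals) >= 3
            assert base.values[k] == pytest.approx(np.mean(vals), rel=1e-12)
        # counts drop to 2 at index 45 (only the 50- and 60-sample trials)
        assert len(base) == 45

    def test_too_few_trials_raises(self):
        with pytest.raises(BaselineError):
            baseline_trajectory([_traj(np.full(10, 600.0))], min_n=3)


class TestNormalize:
    def _trial(self, vals):
        return TrialRecord("p1", "s1", 1, "head", Perturbation.NONE, 0.0, 300.0,
                           _traj(vals))

    def test_trial_equal_to_baseline_gives_zeros(self):
        vals = np.linspace(500, 650, 40)
        nt = normalize_trial(self._trial(vals), _traj(vals))
        np.testing.assert_allclose(nt.normalized.values, 0.0, atol=1e-12)

    def test_constant_offset(self):
        vals = np.linspace(500, 650, 40)
        nt = normalize_trial(self._trial(vals + 3.0), _traj(vals))
        np.testing.assert_allclose(nt.normalized.values, 3.0, atol=1e-12)

    def test_common_support(self):
        nt = normalize_trial(self._trial(np.full(40, 603.0)), _traj(np.full(25, 600.0)))
        assert len(nt.normalized) == 25

    def test_baseline_trials_average_to_zero(self, small_experiment):
        # normalization is mean-zero over the trials that built the baseline
        trials, _ = small_experiment
        labels = label_trials(trials)
        baselines = build_baselines(trials, labels, Role.BASELINE_COMP, min_n=3)
        (pid, sid, word), base = next(iter(baselines.items()))
        members = [
            t for t in trials
            if t.participant_id == pid and t.word == word
            and Role.BASELINE_COMP in labels[t.key]
        ]
        acc = np.zeros(len(base))
        count = np.zeros(len(base))
        for t in members:
            nt = normalize_trial(t, base)
            acc[: len(nt.normalized)] += nt.normalized.values
            count[: len(nt.normalized)] += 1
        full = count == len(members)
        assert full.any()
        np.testing.assert_allclose(acc[full] / count[full], 0.0, atol=1e-9)


class TestOutlierScreen:
    def _frame(self, comp, adapt=None):
        n = len(comp)
        return pd.DataFrame(
            {"participant_id": [f"p{i}" for i in range(n)],
             "compensation": comp,
             "adaptation": adapt if adapt is not None else np.zeros(n)}
        )

    def test_identical_values_excluded_nobody(self):
        kept, excl = exclude_outlier_participants(self._frame([5.0] * 6))
        assert len(kept) == 6 and excl.empty

    def test_extreme_participant_flagged(self, rng):
        comp = list(rng.normal(5, 1, 19))
        mean, sd = np.mean(comp), np.std(comp, ddof=1)
        # 20x the clean SD: still >4 SD after the outlier inflates the pooled SD
        comp.append(mean + 20 * sd)
        kept, excl = exclude_outlier_participants(self._frame(comp))
        assert list(excl["participant_id"]) == ["p19"]
        assert excl.iloc[0]["measure"] == "compensation"
        assert len(kept) == 19

    def test_matches_brute_force_zscores(self, rng):
        comp = rng.normal(5, 2, 50)
        adapt = rng.normal(1, 0.5, 50)
        comp[7] += 30
        adapt[31] -= 20
        kept, excl = exclude_outlier_participants(self._frame(comp, adapt), k_sd=4.0)
        flagged = set(excl["participant_id"])
        for i in range(50):
            zc = abs(comp[i] - comp.mean()) / comp.std(ddof=1)
            za = abs(adapt[i] - adapt.mean()) / adapt.std(ddof=1)
            assert ((zc > 4) or (za > 4)) == (f"p{i}" in flagged)
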