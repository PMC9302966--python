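"""Windowed responses, participant averaging, sign correction."""

import math

import numpy as np
import pandas as pd
import pytest

from f1adapt import (
    Perturbation,
    Role,
    Trajectory,
    TrialRecord,
    participant_average_trajectory,
    participant_response,
    sign_correct,
    trial_adaptation,
    trial_compensation,
    window_mean,
)
from f1adapt.preprocess import NormalizedTrial
from f1adapt.simulate import compensation_ramp


def _traj(vals, step=5.0):
    return Trajectory(step, np.asarray(vals, dtype=float))


def _nt(vals, roles, pert="none", mag=0.0, idx=5):
    n = len(vals)
    tr = TrialRecord("p1", "s1", idx, "head", Perturbation(pert), mag,
                     (n + 5) * 5.0, _traj(np.full(n, 600.0)))
    return NormalizedTrial(tr, frozenset(roles), _traj(vals))


class TestWindowMean:
    def test_constant_trajectory(self):
        t = _traj(np.full(60, 3.0))
        assert window_mean(t, 150, 250) == pytest.approx(3.0)
        assert window_mean(t, 0, 100) == pytest.approx(3.0)

    def test_partial_coverage_uses_available_samples(self):
        # trajectory ends at 200 ms: window [150, 250) covered 150-200 only
        vals = np.arange(41, dtype=float)  # value = index, times 0..200
        t = _traj(vals)
        got = window_mean(t, 150, 250, min_coverage=0.4)
        assert got == pytest.approx(np.mean(vals[30:41]))

    def test_insufficient_coverage_is_missing(self):
        t = _traj(np.full(41, 5.0))  # ends 200 ms
        assert math.isnan(window_mean(t, 150, 250, min_coverage=0.8))

    def test_half_open_boundary(self):
        # t = 100 ms sample belongs to [100, 200) but not [0, 100)
        vals = np.zeros(41)
        vals[20] = 100.0  # the t=100ms sample
        t = _traj(vals)
        assert window_mean(t, 0, 100) == pytest.approx(0.0)
        assert window_mean(t, 100, 200) == pytest.approx(100.0 / 20)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            window_mean(_traj(np.zeros(10)), 100, 100)

    def test_brute_force_on_random_fixtures(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 80))
            vals = rng.normal(0, 5, n)
            t = _traj(vals)
            t0 = float(rng.integers(0, 150))
            t1 = t0 + float(rng.integers(25, 150))
            expected = [v for k, v in enumerate(vals) if t0 <= k * 5.0 < t1]
            got = window_mean(t, t0, t1, min_coverage=0.0)
            if expected:
                assert got == pytest.approx(np.mean(expected), rel=1e-12)
            else:
                assert math.isnan(got)


class TestTrialResponses:
    def test_compensation_matches_ramp_integral(self):
        # noise-free up trial: normalized trajectory is -gain*mag*ramp(t)
        gain, mag = 0.05, 125.0
        t = np.arange(61) * 5.0
        vals = -gain * mag * compensation_ramp(t, 120.0, 80.0)
        row = trial_compensation(_nt(vals, {Role.PERTURBED_UP}, "up", mag))
        in_win = (t >= 150) & (t < 250)
        expected = -gain * mag * compensation_ramp(t[in_win], 120.0, 80.0).mean()
        assert row["value_mels"] == pytest.approx(expected, rel=1e-12)
        # closed form: ramp means 0.65625 over 150-195, 1.0 over 200-245
        assert expected == pytest.approx(-6.25 * 0.828125, rel=1e-12)
        assert row["direction"] == "up"

    def test_zero_gain_gives_zero(self):
        row = trial_compensation(_nt(np.zeros(61), {Role.PERTURBED_DOWN}, "down", 100.0))
        assert row["value_mels"] == pytest.approx(0.0)

    def test_down_mirror_negates(self):
        vals = np.linspace(0, -8, 61)
        up = trial_compensation(_nt(vals, {Role.PERTURBED_UP}, "up", 100.0))
        down = trial_compensation(_nt(-vals, {Role.PERTURBED_DOWN}, "down", 100.0))
        assert up["value_mels"] == pytest.approx(-down["value_mels"])

    def test_non_perturbed_rejected(self):
        with pytest.raises(ValueError, match="not perturbed"):
            trial_compensation(_nt(np.zeros(61), {Role.BASELINE_COMP}))

    def test_adaptation_constant_offset(self):
        row = trial_adaptation(_nt(np.full(41, 2.5), {Role.POST_DOWN}),
                               prev_magnitude_mels=125.0)
        assert row["value_mels"] == pytest.approx(2.5)
        assert row["direction"] == "down"
        assert row["paired_prev_trial_index"] == 4
        assert row["shift_magnitude_mels"] == 125.0

    def test_alternative_window_same_on_constant(self):
        nt = _nt(np.full(41, 2.5), {Role.POST_DOWN})
        a = trial_adaptation(nt, window=(0, 100))
        b = trial_adaptation(nt, window=(50, 150))
        assert a["value_mels"] == pytest.approx(b["value_mels"])

    def test_non_post_rejected(self):
        with pytest.raises(ValueError, match="not post"):
            trial_adaptation(_nt(np.zeros(41), {Role.PERTURBED_UP}, "up", 100.0))


class TestParticipantLevel:
    def test_single_trial_average_is_identity(self):
        nt = _nt(np.linspace(0, 5, 30), {Role.POST_UP})
        avg = participant_average_trajectory([nt])
        np.testing.assert_allclose(avg.values, nt.normalized.values)

    def test_mirrored_trials_cancel(self):
        a = _nt(np.linspace(0, 5, 30), {Role.POST_UP})
        b = _nt(-np.linspace(0, 5, 30), {Role.POST_UP})
        avg = participant_average_trajectory([a, b])
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-12)

    def test_average_then_window_differs_from_window_then_average(self, rng):
        # unequal-length trials: the two orders of operation disagree
        short = _nt(rng.normal(0, 1, 21), {Role.POST_UP})  # ends 100 ms
        long = _nt(rng.normal(5, 1, 61), {Role.POST_UP})
        avg = participant_average_trajectory([short, long])
        atw = participant_response(avg, "adaptation", (0, 150), min_coverage=0.5)
        # brute force pointwise mean then window
        brute = []
        for k in range(30):  # t in [0, 150)
            vals = [nt.normalized.values[k] for nt in (short, long)
                    if len(nt.normalized) > k]
            brute.append(np.mean(vals))
        assert atw == pytest.approx(np.mean(brute), rel=1e-12)
        wta = np.mean([window_mean(nt.normalized, 0, 150, 0.5) for nt in (short, long)])
        assert atw != pytest.approx(wta)

    def test_constant_trajectories_give_constant(self):
        nts = [_nt(np.full(40, 2.0), {Role.POST_UP}) for _ in range(3)]
        avg = participant_average_trajectory(nts)
        assert participant_response(avg, "adaptation", (0, 100)) == pytest.approx(2.0)


class TestSignCorrection:
    def _rows(self):
        return pd.DataFrame(
            {"direction": ["up", "down"], "value_mels": [-3.0, 2.0],
             "sign_corrected": [False, False]}
        )

    def test_up_negated_down_unchanged(self):
        out = sign_correct(self._rows())
        assert out["value_mels"].tolist() == [3.0, 2.0]
        assert out["sign_corrected"].all()

    def test_double_application_rejected(self):
        out = sign_correct(self._rows())
        with pytest.raises(ValueError, match="already"):
            sign_correct(out)

    def test_input_not_mutated(self):
        rows = self._rows()
        sign_correct(rows)
        assert rows["value_mels"].tolist() == [-3.0, 2.0]
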