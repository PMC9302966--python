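"""t-tests, relationship models, and correlation aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from f1adapt import (
    fit_relationship_model,
    paired_and_one_sample_tests,
    per_participant_correlation,
)


class TestPairedAndOneSample:
    def test_hand_computed_fixture(self):
        # textbook paired t on 5 values, worked by hand:
        # diff = up - down = [-1, 0, -1, 1, -1]; mean = -0.4
        # sd = sqrt(sum((d + 0.4)^2) / 4) = sqrt(3.2/4) = 0.894427...
        # t = -0.4 / (0.894427 / sqrt(5)) = -1.0
        up = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        down = np.array([2.0, 2.0, 4.0, 3.0, 6.0])
        res = paired_and_one_sample_tests(up, down)
        t = res["paired"]
        assert t.statistic == pytest.approx(-1.0, rel=1e-12)
        assert t.df == 4
        assert t.cohen_d == pytest.approx(-0.4 / math.sqrt(0.8), rel=1e-12)
        # one-sample: up mean 3, sd sqrt(2.5), t = 3/(sqrt(2.5)/sqrt(5))
        u = res["up_vs_zero"]
        assert u.statistic == pytest.approx(3.0 / (math.sqrt(2.5) / math.sqrt(5)),
                                            rel=1e-12)
        assert u.cohen_d == pytest.approx(3.0 / math.sqrt(2.5), rel=1e-12)

    def test_mirrored_vectors_give_negative_t(self, rng):
        up = -3.0 + rng.normal(0, 0.01, 12)
        down = 3.0 + rng.normal(0, 0.01, 12)
        res = paired_and_one_sample_tests(up, down)
        assert res["paired"].statistic < -100
        assert res["paired"].cohen_d < -10

    def test_zero_variance_reported_undefined(self):
        res = paired_and_one_sample_tests(np.zeros(5), np.zeros(5))
        assert math.isnan(res["paired"].statistic)
        assert "undefined" in res["paired"].note

    def test_nan_pairs_dropped(self):
        up = np.array([1.0, np.nan, 3.0, 4.0])
        down = np.array([0.0, 1.0, np.nan, 2.0])
        res = paired_and_one_sample_tests(up, down)
        assert res["paired"].n == 2
        assert res["up_vs_zero"].n == 3

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_and_one_sample_tests(np.zeros(3), np.zeros(4))


def _pairs(rng, n_participants=30, n_pairs=40, slope=0.2, noise=1.0,
           magnitudes=None, intercept_sd=0.5):
    rows = []
    for p in range(n_participants):
        mag = (magnitudes[p % len(magnitudes)] if magnitudes is not None else 100.0)
        u = rng.normal(0, intercept_sd)
        for k in range(n_pairs):
            comp = rng.normal(5, 2)
            adapt = slope * comp + u + rng.normal(0, noise)
            rows.append(
                {"participant_id": f"p{p}", "study_id": "s1",
                 "direction": "up" if k % 2 else "down",
                 "compensation": comp, "adaptation": adapt,
                 "shift_magnitude_mels": mag, "sign_corrected": True}
            )
    return pd.DataFrame(rows)


class TestRelationshipModel:
    def test_recovers_slope_single_magnitude(self, rng):
        df = _pairs(rng, slope=0.2)
        m = fit_relationship_model(df)
        b = m.term("compensation")
        assert b.estimate == pytest.approx(0.2, abs=2 * b.se)
        assert b.pvalue < 0.001

    def test_zero_adaptation_gives_null_betas(self, rng):
        df = _pairs(rng, slope=0.0, intercept_sd=0.0)
        m = fit_relationship_model(df)
        b = m.term("compensation")
        assert abs(b.estimate) <= 3 * b.se

    def test_magnitude_scale_invariance(self, rng):
        # normalizing by the mean magnitude makes the fit invariant to
        # rescaling the magnitude column
        df = _pairs(rng, magnitudes=[80.0, 100.0, 125.0])
        m1 = fit_relationship_model(df)
        df2 = df.assign(shift_magnitude_mels=df["shift_magnitude_mels"] * 2.0)
        m2 = fit_relationship_model(df2)
        pd.testing.assert_frame_equal(m1.terms, m2.terms, atol=1e-6, rtol=1e-6)

    def test_interaction_recovered(self, rng):
        # adaptation depends on compensation only at high magnitude
        rows = []
        for p in range(40):
            mag = 80.0 if p % 2 else 160.0
            for k in range(30):
                comp = rng.normal(5, 2)
                slope = 0.3 if mag > 100 else 0.0
                rows.append(
                    {"participant_id": f"p{p}", "study_id": "s1",
                     "direction": "up" if k % 2 else "down",
                     "compensation": comp,
                     "adaptation": slope * comp + rng.normal(0, 1),
                     "shift_magnitude_mels": mag, "sign_corrected": True}
                )
        m = fit_relationship_model(pd.DataFrame(rows))
        inter = m.term("compensation:magnitude_norm")
        assert inter.estimate > 0
        assert inter.pvalue < 0.05

    def test_not_sign_corrected_rejected(self, rng):
        df = _pairs(rng, n_participants=4, n_pairs=5)
        df["sign_corrected"] = False
        with pytest.raises(ValueError, match="sign-corrected"):
            fit_relationship_model(df)


class TestPerParticipantCorrelation:
    def test_constant_r_aggregates_exactly(self, rng):
        # identical data per participant -> identical r -> tanh(mean z) = r
        comp = rng.normal(0, 1, 30)
        adapt = 0.5 * comp + rng.normal(0, 1, 30)
        r_true = np.corrcoef(comp, adapt)[0, 1]
        rows = []
        for p in range(8):
            for c, a in zip(comp, adapt):
                rows.append({"participant_id": f"p{p}", "compensation": c,
                             "adaptation": a})
        res = per_participant_correlation(pd.DataFrame(rows))
        assert res.mean_r == pytest.approx(r_true, rel=1e-12)
        assert res.n_participants == 8
        assert res.n_positive == 8

    def test_perfect_correlation_clamped(self, rng):
        rows = []
        for p in range(3):
            comp = rng.normal(0, 1, 15)
            for c in comp:
                rows.append({"participant_id": f"p{p}", "compensation": c,
                             "adaptation": 2 * c + 1})
        res = per_participant_correlation(pd.DataFrame(rows))
        assert len(res.clamped) == 3
        assert all(np.isfinite(res.per_participant["z"]))

    def test_independent_noise_mean_r_near_zero(self, rng):
        rows = []
        for p in range(400):
            for _ in range(50):
                rows.append({"participant_id": f"p{p}",
                             "compensation": rng.normal(), "adaptation": rng.normal()})
        res = per_participant_correlation(pd.DataFrame(rows))
        assert abs(res.mean_r) < 0.025
        assert res.pvalue > 0.01

    def test_min_pairs_enforced(self, rng):
        rows = []
        for p, n in (("a", 30), ("b", 30), ("c", 5)):
            for _ in range(n):
                rows.append({"participant_id": p, "compensation": rng.normal(),
                             "adaptation": rng.normal()})
        res = per_participant_correlation(pd.DataFrame(rows), min_pairs=10)
        assert set(res.per_participant["participant_id"]) == {"a", "b"}

    def test_magnitude_relation_reported(self, rng):
        rows = []
        for p in range(20):
            for _ in range(25):
                c = rng.normal()
                rows.append({"participant_id": f"p{p}", "compensation": c,
                             "adaptation": 0.3 * c + rng.normal()})
        res = per_participant_correlation(pd.DataFrame(rows))
        assert np.isfinite(res.magnitude_r)
        assert -1 <= res.magnitude_r <= 1
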