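"""Statistical inference for compensation and one-shot adaptation.

Four families of analysis:

* direction mixed models — ``response ~ direction + (1|participant) +
  (1|study)``, REML with Satterthwaite df; effect size d = beta divided
  by the residual SD and partial eta^2 = t^2 / (t^2 + df) per term;
* paired and one-sample t-tests on participant-level averages with
  Cohen's d;
* cluster-based permutation tests over the 0-250 ms window: per-timepoint
  t statistics, clusters as maximal same-sign suprathreshold runs with
  mass = sum of t, and a max-|mass| null from whole-trajectory
  sign flips (vs. zero) or per-participant condition swaps (between);
* the compensation–adaptation relationship — a mixed model of adaptation
  on compensation, normalized shift magnitude and direction (random
  intercept for participant only), and per-participant Pearson r
  aggregated through the Fisher transform.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import MixedFit, fit_random_intercepts
from .trials import Trajectory

__all__ = [
    "ModelResult",
    "TestResult",
    "Cluster",
    "ClusterResult",
    "CorrelationResult",
    "fit_direction_model",
    "paired_and_one_sample_tests",
    "cluster_permutation",
    "fit_relationship_model",
    "per_participant_correlation",
]


@dataclass
class ModelResult:
    """Mixed-model coefficients with Satterthwaite inference and effect sizes."""

    terms: pd.DataFrame  # term, estimate, se, df, tvalue, pvalue, effect_size_d, eta_sq_partial
    residual_sd: float
    vcomp: dict[str, float]
    converged: bool
    method: str
    n_obs: int
    warnings: list[str] = field(default_factory=list)

    def term(self, name_part: str) -> pd.Series:
        hit = self.terms[self.terms["term"].str.contains(name_part, regex=False)]
        if hit.empty:
            raise KeyError(f"no term matching {name_part!r}")
        return hit.iloc[0]


@dataclass
class TestResult:
    """A t-test with Cohen's d (one-sample: mean/sd; paired: on differences)."""

    name: str
    statistic: float
    df: float
    pvalue: float
    cohen_d: float
    mean: float
    sd: float
    n: int
    note: str = ""


@dataclass
class Cluster:
    start_ms: float
    end_ms: float  # inclusive last suprathreshold time point
    mass: float  # sum of t over the cluster
    pvalue: float


@dataclass
class ClusterResult:
    times_ms: np.ndarray
    tvalues: np.ndarray
    n_per_time: np.ndarray
    clusters: list[Cluster]
    n_perm: int
    alpha_point: float
    exhaustive: bool
    truncated_at_ms: float | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.pvalue < alpha]


@dataclass
class CorrelationResult:
    """Per-participant trial-level correlations, Fisher-aggregated."""

    per_participant: pd.DataFrame  # participant_id, n, r, z
    mean_z: float
    mean_r: float  # tanh(mean_z)
    statistic: float
    df: float
    pvalue: float
    cohen_d: float
    n_participants: int
    n_positive: int
    # relation between a participant's r and their overall adaptation level
    magnitude_r: float = math.nan
    magnitude_t: float = math.nan
    magnitude_p: float = math.nan
    clamped: list[str] = field(default_factory=list)


def _finish_model(fit: MixedFit) -> ModelResult:
    terms = fit.terms.copy()
    if fit.residual_sd > 0:
        terms["effect_size_d"] = terms["estimate"] / fit.residual_sd
    else:
        terms["effect_size_d"] = np.nan
    terms["eta_sq_partial"] = terms["tvalue"] ** 2 / (terms["tvalue"] ** 2 + terms["df"])
    return ModelResult(
        terms=terms,
        residual_sd=fit.residual_sd,
        vcomp=fit.vcomp,
        converged=fit.converged,
        method=fit.method,
        n_obs=fit.n_obs,
        warnings=fit.warnings,
    )


def fit_direction_model(rows: pd.DataFrame, include_study: bool = True) -> ModelResult:
    """Effect of perturbation direction on a trial-level response:
    ``value ~ direction + (1|participant) + (1|study)``.

    ``rows`` is a trial-level ResponseTable for one measure (raw, not
    sign-corrected).  Direction is treatment-coded with *down* as the
    reference, so the direction coefficient estimates up − down.  A
    degenerate zero-residual fit raises ``ValueError``.
    """
    data = rows.dropna(subset=["value_mels"]).copy()
    if data["direction"].nunique() < 2:
        raise ValueError("need both perturbation directions")
    if data["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if data["sign_corrected"].any():
        raise ValueError("direction model expects raw (not sign-corrected) responses")
    factors = ["participant_id"]
    if include_study and data["study_id"].nunique() > 1:
        factors.append("study_id")
    fit = fit_random_intercepts(
        data, "value_mels ~ C(direction, Treatment('down'))", factors
    )
    scale = float(data["value_mels"].abs().max()) or 1.0
    if fit.residual_sd <= 1e-7 * scale:
        raise ValueError("degenerate fit: zero residual variance")
    return _finish_model(fit)


def _one_sample(x: np.ndarray, name: str) -> TestResult:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError(f"{name}: need at least 2 observations")
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    if s == 0:
        return TestResult(name, math.nan, n - 1, math.nan, math.nan, m, s, n,
                          note="zero variance; t undefined")
    t, p = stats.ttest_1samp(x, 0.0)
    return TestResult(name, float(t), n - 1, float(p), m / s, m, s, n)


def paired_and_one_sample_tests(
    up_means: np.ndarray, down_means: np.ndarray, prefix: str = ""
) -> dict[str, TestResult]:
    """Participant-level tests: paired t (up vs down) and one-sample t per
    direction against 0.  Cohen's d is mean/sd (one-sample) or
    mean(diff)/sd(diff) (paired).  NaN pairs are dropped pairwise."""
    up = np.asarray(up_means, float)
    down = np.asarray(down_means, float)
    if up.shape != down.shape:
        raise ValueError("up and down vectors must be paired (same participants)")
    ok = np.isfinite(up) & np.isfinite(down)
    diff = up[ok] - down[ok]
    out = {
        "paired": _one_sample(diff, f"{prefix}paired up-down"),
        "up_vs_zero": _one_sample(up[np.isfinite(up)], f"{prefix}up vs 0"),
        "down_vs_zero": _one_sample(down[np.isfinite(down)], f"{prefix}down vs 0"),
    }
    return out


def _clusters_from_t(tvals: np.ndarray, tcrit: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal same-sign runs of |t| > tcrit; returns (start, end, mass)."""
    supra = np.abs(tvals) > tcrit
    sign = np.sign(tvals)
    out = []
    i, n = 0, tvals.size
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            out.append((i, j, float(tvals[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def _t_by_time(data0: np.ndarray, counts: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """One-sample t per column for NaN-padded data (data0: NaN->0)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        m = data0.sum(axis=0) / counts
        var = (sumsq - counts * m**2) / (counts - 1)
        var = np.maximum(var, 0.0)
        t = m / np.sqrt(var / counts)
    return t


def _max_mass(tvals: np.ndarray, tcrit: np.ndarray) -> float:
    cl = _clusters_from_t(tvals, tcrit)
    return max((abs(c[2]) for c in cl), default=0.0)


def cluster_permutation(
    trajectories: list[Trajectory | np.ndarray],
    trajectories_b: list[Trajectory | np.ndarray] | None = None,
    *,
    step_ms: float = 5.0,
    t_max_ms: float = 250.0,
    alpha_point: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool | None = None,
    min_n: int = 3,
) -> ClusterResult:
    """Cluster-based permutation test on per-participant average
    trajectories over ``[0, t_max_ms]``.

    With one trajectory set the contrast is against zero and the null is
    built from independent whole-trajectory sign flips per participant.
    With two (paired by participant) the per-participant difference is
    tested — equivalent to per-participant condition-label swaps.

    Per time point, a one-sample t across participants is compared with
    the two-tailed critical value at ``alpha_point`` (df = n_t − 1);
    clusters are maximal same-sign suprathreshold runs with mass = sum of
    t; the null distribution is the max |mass| over permutations.  Cluster
    p is ``(1 + b) / (1 + n_perm)`` for random permutations, or ``b / m``
    over all ``m`` assignments when run exhaustively (the identity
    assignment keeps p > 0).  Time points with fewer than ``min_n``
    contributing participants truncate the tested range.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    def to_arr(tr):
        return tr.values if isinstance(tr, Trajectory) else np.asarray(tr, float)

    arrs = [to_arr(t) for t in trajectories]
    if trajectories_b is not None:
        arrs_b = [to_arr(t) for t in trajectories_b]
        if len(arrs_b) != len(arrs):
            raise ValueError("condition sets must be paired by participant")
        diffs = []
        for a, b in zip(arrs, arrs_b):
            n = min(len(a), len(b))
            diffs.append(a[:n] - b[:n])
        arrs = diffs

    n_part = len(arrs)
    if n_part < 2:
        raise ValueError("need at least 2 participants")
    n_t = int(np.floor(t_max_ms / step_ms)) + 1
    data = np.full((n_part, n_t), np.nan)
    for i, a in enumerate(arrs):
        k = min(len(a), n_t)
        data[i, :k] = a[:k]

    counts = np.sum(np.isfinite(data), axis=0)
    truncated_at = None
    valid = counts >= min_n
    if not valid[0]:
        raise ValueError(f"fewer than {min_n} participants at t=0")
    if not valid.all():
        cut = int(np.argmin(valid))
        truncated_at = cut * step_ms
        data = data[:, :cut]
        counts = counts[:cut]
        n_t = cut
        warnings.warn(
            f"cluster test range truncated at {truncated_at} ms (n < {min_n})",
            stacklevel=2,
        )

    data0 = np.nan_to_num(data)
    sumsq = np.nansum(data**2, axis=0)
    tcrit = stats.t.ppf(1 - alpha_point / 2, counts - 1)
    tvals = _t_by_time(data0, counts, sumsq)
    obs_clusters = _clusters_from_t(tvals, tcrit)

    if exhaustive is None:
        exhaustive = 2**n_part <= n_perm
    if exhaustive:
        signs_iter = itertools.product((1.0, -1.0), repeat=n_part)
        m_total = 2**n_part
    else:
        rng = np.random.default_rng(seed)
        signs_iter = (rng.choice([1.0, -1.0], size=n_part) for _ in range(n_perm))
        m_total = n_perm

    null_max = np.empty(m_total)
    for k, s in enumerate(signs_iter):
        s = np.asarray(s)
        flipped = s[:, None] * data0
        t_p = _t_by_time(flipped, counts, sumsq)
        null_max[k] = _max_mass(t_p, tcrit)

    times = np.arange(n_t) * step_ms
    clusters = []
    for (i0, i1, mass) in obs_clusters:
        b = int(np.sum(null_max >= abs(mass) - 1e-12))
        p = b / m_total if exhaustive else (1 + b) / (1 + m_total)
        clusters.append(
            Cluster(start_ms=times[i0], end_ms=times[i1], mass=mass, pvalue=p)
        )
    return ClusterResult(
        times_ms=times,
        tvalues=tvals,
        n_per_time=counts,
        clusters=clusters,
        n_perm=m_total,
        alpha_point=alpha_point,
        exhaustive=exhaustive,
        truncated_at_ms=truncated_at,
    )


def fit_relationship_model(rows: pd.DataFrame, level: str = "trial") -> ModelResult:
    """Mixed model of one-shot adaptation on the preceding compensation.

    ``rows`` holds sign-corrected paired responses with columns
    ``participant_id``, ``compensation``, ``adaptation``,
    ``shift_magnitude_mels`` and ``direction``.  Fixed effects are
    compensation, shift magnitude normalized by the mean magnitude
    (so its mean is exactly 1) and direction; at the trial level the
    compensation × magnitude interaction is added (at the participant
    level, with two points per participant, it is nearly collinear with
    the compensation main effect and is omitted).  The only random
    intercept is participant (study is collinear with participant and
    magnitude).
    """
    required = {"participant_id", "compensation", "adaptation",
                "shift_magnitude_mels", "direction", "sign_corrected"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if not rows["sign_corrected"].all():
        raise ValueError("relationship model requires sign-corrected responses")
    data = rows.dropna(subset=["compensation", "adaptation"]).copy()
    data["magnitude_norm"] = (
        data["shift_magnitude_mels"] / data["shift_magnitude_mels"].mean()
    )
    if level == "trial":
        formula = ("adaptation ~ compensation * magnitude_norm "
                   "+ C(direction, Treatment('down'))")
    else:
        formula = ("adaptation ~ compensation + magnitude_norm "
                   "+ C(direction, Treatment('down'))")
    one_magnitude = data["magnitude_norm"].std() < 1e-10
    if one_magnitude:
        # a single shift magnitude aliases the magnitude terms with the
        # intercept and compensation; drop them
        formula = "adaptation ~ compensation + C(direction, Treatment('down'))"
    fit = fit_random_intercepts(data, formula, ["participant_id"])
    if one_magnitude:
        fit.warnings.append("single shift magnitude; magnitude terms dropped")
    fit.warnings.append(f"level={level}")
    return _finish_model(fit)


def per_participant_correlation(
    rows: pd.DataFrame, min_pairs: int = 10
) -> CorrelationResult:
    """Within-participant Pearson correlation of trial-level compensation
    with the subsequent one-shot adaptation, aggregated via Fisher z.

    Participants contribute if they have at least ``min_pairs`` complete
    pairs.  Each r is Fisher-transformed (|r| = 1 is clamped to
    1 − 1e-12 and flagged), a one-sample t is run on the z-scores, and
    the mean z is transformed back to r.  Also reports the correlation
    between participants' r and their overall mean adaptation (a check
    that the trial-level coupling is not confined to strong adapters).
    """
    clamped: list[str] = []
    recs = []
    for pid, grp in rows.groupby("participant_id"):
        g = grp.dropna(subset=["compensation", "adaptation"])
        n = len(g)
        if n < min_pairs:
            continue
        if g["compensation"].std() == 0 or g["adaptation"].std() == 0:
            continue
        r = float(stats.pearsonr(g["compensation"], g["adaptation"])[0])
        if abs(r) >= 1.0 - 1e-12:
            clamped.append(str(pid))
            r = math.copysign(1.0 - 1e-12, r)
        recs.append(
            {"participant_id": pid, "n": n, "r": r, "z": math.atanh(r),
             "mean_adaptation": float(g["adaptation"].mean())}
        )
    pp = pd.DataFrame(recs, columns=["participant_id", "n", "r", "z", "mean_adaptation"])
    if len(pp) < 2:
        raise ValueError("fewer than 2 participants with enough trial pairs")
    z = pp["z"].to_numpy()
    t, p = stats.ttest_1samp(z, 0.0)
    sd = float(np.std(z, ddof=1))
    mag_r = mag_t = mag_p = math.nan
    if len(pp) >= 3 and pp["mean_adaptation"].std() > 0 and sd > 0:
        mag_r, mag_p = stats.pearsonr(pp["r"], pp["mean_adaptation"])
        dfm = len(pp) - 2
        mag_t = mag_r * math.sqrt(dfm / max(1e-300, 1 - mag_r**2))
    return CorrelationResult(
        per_participant=pp,
        mean_z=float(z.mean()),
        mean_r=float(np.tanh(z.mean())),
        statistic=float(t),
        df=len(pp) - 1,
        pvalue=float(p),
        cohen_d=float(z.mean() / sd) if sd > 0 else math.nan,
        n_participants=len(pp),
        n_positive=int((pp["r"] > 0).sum()),
        magnitude_r=float(mag_r),
        magnitude_t=float(mag_t),
        magnitude_p=float(mag_p),
        clamped=clamped,
    )
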