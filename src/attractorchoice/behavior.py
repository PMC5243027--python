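"""Behavioral analysis: decisions, psychometrics, and choice hysteresis.

This module turns trial tables (simulated or human-format) into the
standard measures of the paradigm:

* decision read-out from population rate traces (first threshold crossing),
* outlier filtering of decision/response times (median ± k·MAD),
* Weibull accuracy thresholds (coherence needed for 80% correct),
* decision-time difference regressions against coherence,
* indecision-point shifts conditioned on the previous choice, and
* the sequential logistic model of choice hysteresis

      P(right) = 1 / (1 + exp(−(a0 + a1·c + a2·(δ_prev,R − δ_prev,L))))

  whose previous-choice coefficient a2 > 0 quantifies the tendency to
  repeat the preceding choice, normalized as the ratio a2/a1.

Model fitting follows the statsmodels idiom: model classes are built from
data (``from_trials``), ``fit()`` returns a results object carrying
estimates, standard errors and a ``summary()`` table.  Plain functions
matching each analysis step are provided as thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm

from .neural import RateTrace

__all__ = [
    "TestResult",
    "PsychometricFit",
    "WeibullFit",
    "HysteresisCoefficients",
    "RegressionFit",
    "detect_decision",
    "filter_trials",
    "WeibullPsychometric",
    "weibull_accuracy_threshold",
    "dt_difference_regression",
    "PsychometricLogit",
    "indecision_points",
    "HysteresisLogit",
    "hysteresis_logistic",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "anova_oneway",
]

_MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma under normality


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Outcome of a nonparametric or F test."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    test_name: str

    def __repr__(self) -> str:  # compact, paper-style
        dof = ", ".join(str(x) for x in self.n)
        return f"{self.test_name}({dof}) = {self.statistic:g}, p = {self.p_value:.4g}"


@dataclass
class PsychometricFit:
    """Two-parameter logistic psychometric function of signed coherence."""

    slope: float
    indecision_point: float
    converged: bool

    def predict(self, c):
        return 1.0 / (1.0 + np.exp(-self.slope * (np.asarray(c) - self.indecision_point)))


@dataclass
class WeibullFit:
    """Weibull accuracy function ``P(correct) = 1 − 0.5 exp(−(c/α)^β)``."""

    alpha: float
    beta: float
    accuracy_threshold: float
    target: float = 0.8
    converged: bool = True

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        return 1.0 - 0.5 * np.exp(-((c / self.alpha) ** self.beta))

    def summary(self) -> str:
        """Plain-text fit table."""
        return (
            "Weibull accuracy function\n"
            + "-" * 36
            + f"\nalpha (scale)      {self.alpha:10.4f}"
            + f"\nbeta (shape)       {self.beta:10.4f}"
            + f"\nthreshold @ {self.target:.0%}    {self.accuracy_threshold:10.4f}"
            + ("" if self.converged else "\nflags: non-converged")
        )


@dataclass
class HysteresisCoefficients:
    """Coefficients of the sequential logistic choice model."""

    a0: float
    a1: float
    a2: float
    converged: bool
    regularized: bool = False
    bse: tuple[float, float, float] | None = None

    @property
    def ratio(self) -> float:
        """Previous-choice influence normalized by the coherence influence."""
        if self.a1 <= 0:
            return np.nan
        return self.a2 / self.a1

    def summary(self) -> str:
        """Plain-text coefficient table."""
        lines = ["Sequential logistic choice model", "-" * 44]
        names = ("a0 (intercept)", "a1 (coherence)", "a2 (previous choice)")
        for i, (name, val) in enumerate(zip(names, (self.a0, self.a1, self.a2))):
            se = f"{self.bse[i]:10.3f}" if self.bse else "        --"
            lines.append(f"{name:<22}{val:10.3f}  se {se}")
        lines.append(f"{'a2/a1':<22}{self.ratio:10.3f}")
        flags = []
        if not self.converged:
            flags.append("non-converged")
        if self.regularized:
            flags.append("L2-regularized")
        if flags:
            lines.append("flags: " + ", ".join(flags))
        return "\n".join(lines)


@dataclass
class RegressionFit:
    """OLS fit of decision-time differences against coherence."""

    beta0: float
    beta1: float
    p_slope: float
    n: int = 0


# ---------------------------------------------------------------------------
# decision read-out and trial filtering
# ---------------------------------------------------------------------------

def detect_decision(
    trace_left: RateTrace,
    trace_right: RateTrace,
    threshold: float,
    response_window: tuple[float, float],
    tiebreak_seed: int = 0,
):
    """First-threshold-crossing decision read-out.

    The first smoothed population rate to reach ``threshold`` (Hz) inside
    ``response_window`` (ms, on the traces' common grid) determines the
    choice; the decision time is the crossing time minus the window start
    (input onset).  A simultaneous first crossing is broken by the higher
    rate at that step, then by a seeded coin flip.

    Returns ``(choice, decision_time_ms)`` with ``("none", None)`` when no
    trace crosses.
    """
    if threshold <= 0:
        raise ValueError("response threshold must be positive")
    t = np.asarray(trace_left.times)
    if len(t) != len(trace_right.times) or not np.allclose(t, trace_right.times):
        raise ValueError("traces must share a common time grid")
    start, end = response_window
    mask = (t >= start) & (t <= end)
    if not mask.any():
        raise ValueError("response window outside the trace")
    tw = t[mask]
    lw = np.asarray(trace_left.rates)[mask]
    rw = np.asarray(trace_right.rates)[mask]

    lx = np.nonzero(lw >= threshold)[0]
    rx = np.nonzero(rw >= threshold)[0]
    il = lx[0] if len(lx) else None
    ir = rx[0] if len(rx) else None
    if il is None and ir is None:
        return "none", None
    if ir is None or (il is not None and il < ir):
        return "left", float(tw[il] - start)
    if il is None or ir < il:
        return "right", float(tw[ir] - start)
    # simultaneous crossing
    if lw[il] > rw[ir]:
        return "left", float(tw[il] - start)
    if rw[ir] > lw[il]:
        return "right", float(tw[ir] - start)
    choice = "left" if np.random.default_rng(tiebreak_seed).random() < 0.5 else "right"
    return choice, float(tw[il] - start)


def filter_trials(
    records: pd.DataFrame,
    k_mad: float = 3.0,
    group_cols: tuple[str, ...] = ("subject_id", "condition"),
    time_col: str = "decision_time",
) -> pd.DataFrame:
    """Flag valid trials: responded, and not a decision-time outlier.

    Within each subject × condition group, trials whose decision time
    deviates from the group median by more than ``k_mad`` × 1.4826 × MAD
    are invalidated (an epsilon floor on the MAD protects degenerate
    groups where all times coincide).  Non-response trials are always
    invalid.  Returns a copy with a boolean ``valid`` column.
    """
    out = records.copy()
    responded = out["choice"].isin(["left", "right"]) & out[time_col].notna()
    valid = responded.copy()
    cols = [c for c in group_cols if c in out.columns]
    grouped = out[responded].groupby(cols) if cols else [((), out[responded])]
    for _, grp in grouped:
        if grp.empty:
            warnings.warn("empty trial group in outlier filtering", stacklevel=2)
            continue
        times = grp[time_col].to_numpy(dtype=float)
        med = np.median(times)
        mad = _MAD_SCALE * np.median(np.abs(times - med))
        mad = max(mad, 1e-9)
        bad = np.abs(times - med) > k_mad * mad
        # guard: never remove more than half of a group
        if bad.sum() > len(times) // 2:
            order = np.argsort(-np.abs(times - med))
            keep_bad = order[: len(times) // 2]
            mask = np.zeros(len(times), dtype=bool)
            mask[keep_bad] = True
            bad = bad & mask
        valid.loc[grp.index[bad]] = False
    out["valid"] = valid
    return out


# ---------------------------------------------------------------------------
# Weibull accuracy threshold
# ---------------------------------------------------------------------------

class WeibullPsychometric:
    """Least-squares Weibull fit of accuracy against coherence.

    ``P(correct | c) = 1 − 0.5 exp(−(c/α)^β)`` — the standard
    two-alternative forced-choice form with a 50% floor.  The accuracy
    threshold at ``target`` follows from the closed-form inverse
    ``α · (−ln(2(1−target)))^(1/β)``.
    """

    def __init__(self, coherence, accuracy, n_trials=None):
        self.coherence = np.asarray(coherence, dtype=float)
        self.accuracy = np.asarray(accuracy, dtype=float)
        self.n_trials = (
            np.ones_like(self.coherence) if n_trials is None else np.asarray(n_trials, float)
        )
        if len(self.coherence) < 3:
            raise ValueError("need at least three coherence levels")

    @classmethod
    def from_trials(cls, records: pd.DataFrame) -> "WeibullPsychometric":
        valid = records[records.get("valid", True) & records["choice"].isin(["left", "right"])]
        grp = valid.groupby(valid["coherence_signed"].abs())["correct"]
        return cls(grp.mean().index.to_numpy(), grp.mean().to_numpy(), grp.size().to_numpy())

    def fit(self, target: float = 0.8) -> WeibullFit:
        if not 0.5 < target < 1.0:
            raise ValueError("target accuracy must lie in (0.5, 1)")
        c, acc, w = self.coherence, self.accuracy, self.n_trials

        converged = True
        # degenerate inputs: accuracy at ceiling everywhere, or at/above
        # target already at the lowest coherence with no upward trend
        if np.all(acc >= 0.999) or (acc[np.argmin(c)] >= target and np.all(np.diff(acc[np.argsort(c)]) <= 0)):
            converged = False

        def model(c_, alpha, beta):
            return 1.0 - 0.5 * np.exp(-((c_ / alpha) ** beta))

        try:
            popt, _ = scipy.optimize.curve_fit(
                model,
                c,
                acc,
                p0=[np.median(c), 2.0],
                sigma=1.0 / np.sqrt(w),
                bounds=([1e-6, 0.05], [10.0, 50.0]),
                maxfev=10000,
            )
            alpha, beta = popt
        except RuntimeError:
            alpha, beta, converged = float(np.median(c)), 1.0, False

        thr = alpha * (-np.log(2.0 * (1.0 - target))) ** (1.0 / beta)
        if not converged or not np.isfinite(thr):
            thr = float(np.clip(thr, c.min(), c.max())) if np.isfinite(thr) else float(c.max())
        return WeibullFit(float(alpha), float(beta), float(thr), target, converged)


def weibull_accuracy_threshold(per_coherence, target: float = 0.8) -> WeibullFit:
    """Fit a Weibull accuracy function and invert it at ``target``.

    ``per_coherence`` is a sequence of ``(coherence, proportion_correct,
    n_trials)`` tuples.
    """
    arr = np.asarray(per_coherence, dtype=float)
    return WeibullPsychometric(arr[:, 0], arr[:, 1], arr[:, 2]).fit(target)


# ---------------------------------------------------------------------------
# decision-time difference regression
# ---------------------------------------------------------------------------

def dt_difference_regression(stim_means, control_means, coherences=None) -> RegressionFit:
    """OLS of per-coherence decision-time differences on coherence.

    ``DT_stim − DT_control = β0 + β1·c``.  Inputs may be 1-D (one subject)
    or 2-D ``(n_subjects, n_coherences)`` arrays of cell means on a matched
    coherence grid; subject cells are pooled.  ``coherences`` defaults to
    an evenly indexed grid only if omitted — pass the real levels.
    """
    stim = np.atleast_2d(np.asarray(stim_means, dtype=float))
    ctrl = np.atleast_2d(np.asarray(control_means, dtype=float))
    if stim.shape != ctrl.shape:
        raise ValueError("stimulation and control grids must match")
    if coherences is None:
        coherences = np.arange(stim.shape[1], dtype=float)
    c = np.asarray(coherences, dtype=float)
    if len(np.unique(c)) < 2:
        raise ValueError("need at least two distinct coherence levels")
    diff = (stim - ctrl).ravel()
    cc = np.tile(c, stim.shape[0])
    keep = np.isfinite(diff)
    diff, cc = diff[keep], cc[keep]
    X = sm.add_constant(cc)
    res = sm.OLS(diff, X).fit()
    p1 = float(res.pvalues[1]) if len(res.params) > 1 else np.nan
    return RegressionFit(float(res.params[0]), float(res.params[1]), p1, n=len(diff))


# ---------------------------------------------------------------------------
# psychometric logistic and indecision points
# ---------------------------------------------------------------------------

class PsychometricLogit:
    """Two-parameter logistic choice function of signed coherence.

    ``P(right | c) = 1/(1 + exp(−k(c − c0)))`` fitted by maximum
    likelihood; the indecision point ``c0`` is the signed coherence at
    which rightward choices are made 50% of the time.
    """

    def __init__(self, chose_right, coherence_signed):
        self.endog = np.asarray(chose_right, dtype=float)
        self.coherence = np.asarray(coherence_signed, dtype=float)

    @classmethod
    def from_trials(cls, records: pd.DataFrame) -> "PsychometricLogit":
        valid = records[records.get("valid", True) & records["choice"].isin(["left", "right"])]
        return cls((valid["choice"] == "right").to_numpy(), valid["coherence_signed"].to_numpy())

    def fit(self) -> PsychometricFit:
        y, c = self.endog, self.coherence
        if len(np.unique(y)) < 2:
            return PsychometricFit(np.nan, np.nan, converged=False)
        X = sm.add_constant(c)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            b0, b1 = res.params
            converged = bool(res.mle_retvals.get("converged", True)) and b1 > 0
        except Exception:
            return PsychometricFit(np.nan, np.nan, converged=False)
        if not np.isfinite(b1) or b1 == 0:
            return PsychometricFit(np.nan, np.nan, converged=False)
        return PsychometricFit(float(b1), float(-b0 / b1), converged)


def indecision_points(records: pd.DataFrame):
    """Indecision points split by the previous choice, and their shift.

    Fits the logistic choice function separately on trials following a
    left choice (Left*) and a right choice (Right*).  The shift
    ``c0(Left*) − c0(Right*)`` is positive under a repetition bias: after
    a left choice more rightward motion is needed before the subject
    switches to "right".

    Returns ``(ip_after_left, ip_after_right, shift)``; values are NaN when
    a group's fit does not converge.
    """
    valid = records[records.get("valid", True) & records["choice"].isin(["left", "right"])]
    fits = {}
    for prev in ("left", "right"):
        grp = valid[valid["previous_choice"] == prev]
        if len(grp) < 4 or grp["coherence_signed"].nunique() < 2:
            fits[prev] = PsychometricFit(np.nan, np.nan, converged=False)
            continue
        fits[prev] = PsychometricLogit.from_trials(grp).fit()
    ip_l = fits["left"].indecision_point
    ip_r = fits["right"].indecision_point
    shift = ip_l - ip_r if fits["left"].converged and fits["right"].converged else np.nan
    return ip_l, ip_r, shift


# ---------------------------------------------------------------------------
# sequential logistic hysteresis model
# ---------------------------------------------------------------------------

class HysteresisLogit:
    """Sequential logistic model of choice with a previous-choice term.

    The right-choice indicator is regressed on signed coherence
    (proportion units, so a1 is of order 10) and the ±1 previous-choice
    regressor ``δ_prev,R − δ_prev,L``.  Fitted by maximum likelihood
    (statsmodels Logit); on perfect separation the fit is retried with a
    weak L2 penalty and flagged ``regularized``.
    """

    def __init__(self, chose_right, coherence_signed, prev_term):
        self.endog = np.asarray(chose_right, dtype=float)
        self.exog = np.column_stack(
            [
                np.ones(len(self.endog)),
                np.asarray(coherence_signed, dtype=float),
                np.asarray(prev_term, dtype=float),
            ]
        )

    @classmethod
    def from_trials(cls, records: pd.DataFrame, min_trials: int = 20) -> "HysteresisLogit":
        """Build from a trial table, using valid trials with a defined previous choice.

        The first trial of each block has no previous choice and is
        excluded, as are non-response and outlier trials.
        """
        r = records
        ok = (
            r.get("valid", pd.Series(True, index=r.index))
            & r["choice"].isin(["left", "right"])
            & r["previous_choice"].isin(["left", "right"])
        )
        r = r[ok]
        if len(r) < min_trials:
            raise ValueError(
                f"need at least {min_trials} valid trials with a previous choice, got {len(r)}"
            )
        prev = np.where(r["previous_choice"] == "right", 1.0, -1.0)
        return cls((r["choice"] == "right").to_numpy(), r["coherence_signed"].to_numpy(), prev)

    def fit(self, l2_fallback: float = 1e-3) -> HysteresisCoefficients:
        y, X = self.endog, self.exog
        if len(np.unique(y)) < 2:
            raise ValueError("all choices identical: perfect separation")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=500)
            params = res.params
            converged = bool(res.mle_retvals.get("converged", True))
            if converged and np.all(np.abs(params) < 1e3):
                return HysteresisCoefficients(
                    float(params[0]),
                    float(params[1]),
                    float(params[2]),
                    converged=True,
                    bse=tuple(float(b) for b in res.bse),
                )
        except Exception:
            pass
        # separation or non-convergence: weak ridge penalty
        params = self._ridge_fit(l2_fallback)
        return HysteresisCoefficients(
            float(params[0]), float(params[1]), float(params[2]),
            converged=True, regularized=True,
        )

    def _ridge_fit(self, l2: float) -> np.ndarray:
        y, X = self.endog, self.exog

        def nll(beta):
            z = X @ beta
            # log(1+e^z) computed stably
            ll = y * z - np.logaddexp(0.0, z)
            return -ll.sum() + 0.5 * l2 * beta @ beta

        def grad(beta):
            p = scipy.special.expit(X @ beta)
            return -X.T @ (y - p) + l2 * beta

        res = scipy.optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B")
        return res.x


def hysteresis_logistic(records: pd.DataFrame) -> HysteresisCoefficients:
    """Fit the sequential logistic hysteresis model to a trial table."""
    return HysteresisLogit.from_trials(records).fit()


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test, W = min(W+, W−).

    Zero differences are dropped.  For n ≤ 12 the p-value is computed by
    exact enumeration over all 2^n sign assignments of the observed ranks
    (valid with ties); above that, a normal approximation with tie
    correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.isnan(d).any():
        raise ValueError("NaN differences passed to the signed-rank test")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: degenerate sample")
    if n < 1:
        raise ValueError("need at least one nonzero difference")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)

    if n <= 12:
        # enumerate all sign patterns of the observed (possibly tied) ranks
        signs = np.array(
            np.meshgrid(*([[0.0, 1.0]] * n), indexing="ij")
        ).reshape(n, -1)
        w_all = ranks @ signs  # W+ under each pattern
        total = ranks.sum()
        w_min_all = np.minimum(w_all, total - w_all)
        p = float(np.mean(w_min_all <= W + 1e-12))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = ((counts**3 - counts).sum()) / 48.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
        z = (W - mean + 0.5) / sd
        p = float(min(1.0, 2.0 * scipy.stats.norm.cdf(z)))
    return TestResult(W, p, (n,), "W")


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test (independent samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not _has_ties(a, b)) else "auto"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), (len(a), len(b)), "U")


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def anova_oneway(groups) -> TestResult:
    """One-way between-groups ANOVA."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups with at least two values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("zero total variance: degenerate input")
    stat, p = scipy.stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return TestResult(float(stat), float(p), (df1, df2), "F")
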