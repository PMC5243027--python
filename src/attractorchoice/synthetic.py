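"""Synthetic behavioral sessions with known ground truth.

Generates trial tables with exactly the statistical structure the analysis
pipeline assumes — sequential logistic choices with a previous-choice term,
coherence-dependent response times, non-response and outlier trials — so
every analysis stage can be validated against known generating parameters
without running the spiking network.

The choice model is the same sequential logistic the analysis fits:

    P(right on trial n) = 1 / (1 + exp(−(a0 + a1·c_n + a2·h_n)))

with ``h_n = +1`` after a right choice, ``−1`` after a left choice and 0 on
the first trial (or after a non-response).  The response-time model is
deliberately simple plumbing — linear in |coherence| with Gaussian noise —
sufficient to exercise the outlier filter and the decision-time
regressions, not a cognitive claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import HysteresisLogit, filter_trials

__all__ = ["SyntheticSpec", "generate_session", "recovery_experiment"]

DEFAULT_COHERENCES = (0.032, 0.064, 0.128, 0.256, 0.512)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for one synthetic session."""

    a0: float = 0.0
    a1: float = 10.0
    a2: float = 0.5
    coherences: tuple[float, ...] = DEFAULT_COHERENCES
    reps: int = 10  # trials per (coherence, direction) cell
    rt_base: float = 0.6  # s
    rt_slope: float = 0.4  # s per unit |coherence|
    rt_noise_sd: float = 0.08  # s
    p_nonresponse: float = 0.0
    p_outlier: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0
    subject_id: int = 0

    def __post_init__(self) -> None:
        for name in ("p_nonresponse", "p_outlier"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.rt_base <= 0:
            raise ValueError("rt_base must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def generate_session(spec: SyntheticSpec, condition: str = "synthetic") -> pd.DataFrame:
    """One randomized balanced session drawn from the generating model.

    Returns the standard trial-record table.  Trials are in randomized
    order; the first trial (and any trial following a non-response) carries
    no history term.  Response times are floored at 50 ms; outlier trials
    have their RT multiplied by ``outlier_scale``.
    """
    rng = np.random.default_rng(spec.seed)
    cells = [
        (c, d) for c in spec.coherences for d in (-1.0, 1.0) for _ in range(spec.reps)
    ]
    order = rng.permutation(len(cells))
    rows = []
    prev_choice = "none"
    for ti, idx in enumerate(order):
        c_abs, sign = cells[idx]
        c = c_abs * sign
        h = {"right": 1.0, "left": -1.0}.get(prev_choice, 0.0)
        if rng.random() < spec.p_nonresponse:
            choice, rt = "none", np.nan
        else:
            p_right = 1.0 / (1.0 + np.exp(-(spec.a0 + spec.a1 * c + spec.a2 * h)))
            choice = "right" if rng.random() < p_right else "left"
            rt = spec.rt_base - spec.rt_slope * c_abs + rng.normal(0.0, spec.rt_noise_sd)
            rt = max(rt, 0.05)
            if rng.random() < spec.p_outlier:
                rt *= spec.outlier_scale
        direction = "right" if sign > 0 else "left"
        rows.append(
            {
                "subject_id": spec.subject_id,
                "block": 0,
                "condition": condition,
                "trial_index": ti,
                "coherence_signed": c,
                "direction": direction,
                "choice": choice,
                "responded": int(choice != "none"),
                "decision_time_s": rt,
                "prestim_rate_chosen_hz": np.nan,
                "prestim_rate_unchosen_hz": np.nan,
                "previous_choice": prev_choice,
                "correct": int(choice == direction) if choice != "none" else 0,
            }
        )
        prev_choice = choice
    return pd.DataFrame(rows)


def recovery_experiment(spec: SyntheticSpec, n_replicates: int = 20) -> pd.DataFrame:
    """Repeatedly generate sessions and refit the hysteresis model.

    Returns one row per replicate with the fitted (a0, a1, a2); the
    ``attrs`` of the frame carry per-coefficient bias and RMSE against the
    generating truth plus the count of failed fits.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    failures = 0
    for rep in range(n_replicates):
        rep_spec = SyntheticSpec(
            **{**spec.__dict__, "seed": spec.seed + 1000 * rep}
        )
        records = generate_session(rep_spec)
        records = filter_trials(
            records.rename(columns={"decision_time_s": "decision_time"}),
            time_col="decision_time",
        )
        try:
            fit = HysteresisLogit.from_trials(records).fit()
            rows.append(
                {"replicate": rep, "a0": fit.a0, "a1": fit.a1, "a2": fit.a2,
                 "ratio": fit.ratio, "regularized": fit.regularized}
            )
        except ValueError:
            failures += 1
            rows.append(
                {"replicate": rep, "a0": np.nan, "a1": np.nan, "a2": np.nan,
                 "ratio": np.nan, "regularized": False}
            )
    out = pd.DataFrame(rows)
    truth = {"a0": spec.a0, "a1": spec.a1, "a2": spec.a2}
    summary = {}
    for k, v in truth.items():
        est = out[k].dropna()
        summary[f"bias_{k}"] = float(est.mean() - v) if len(est) else np.nan
        summary[f"rmse_{k}"] = float(np.sqrt(((est - v) ** 2).mean())) if len(est) else np.nan
    summary["n_failures"] = failures
    out.attrs.update(summary)
    return out
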