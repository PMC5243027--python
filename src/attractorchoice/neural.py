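"""Population rate traces and prestimulus activity-bias measures.

The link between network dynamics and behavior runs through smoothed
population firing rates: decisions are read out from rate-threshold
crossings, and choice hysteresis is traced back to residual (decaying tail)
activity in the 500 ms window before the task input arrives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateTrace",
    "PrestimBias",
    "gaussian_kernel",
    "population_rate_trace",
    "prestimulus_bias",
    "bias_condition_summary",
]


@dataclass
class RateTrace:
    """A uniformly sampled population mean firing-rate trace.

    ``times`` are bin-end times in ms (step = integration dt); ``rates`` are
    in Hz, averaged over the population and smoothed with a truncated
    Gaussian kernel.
    """

    times: np.ndarray
    rates: np.ndarray
    population: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times, "rate_hz": self.rates, "population": self.population}
        )


@dataclass
class PrestimBias:
    """Chosen-minus-unchosen mean rate over the pre-input window of one trial."""

    trial_index: int
    bias: float  # Hz
    repeated: bool


def gaussian_kernel(dt: float, halfwidth: float = 5.0, sigma: float | None = None) -> np.ndarray:
    """Unit-area Gaussian kernel truncated at ``±halfwidth`` ms.

    ``sigma`` defaults to ``halfwidth / 3`` so the kernel has decayed to
    about 1% of its peak at the cut-off ("5 ms wide at the tails").
    """
    if halfwidth <= 0:
        raise ValueError("kernel halfwidth must be positive")
    if sigma is None:
        sigma = halfwidth / 3.0
    half_bins = int(round(halfwidth / dt))
    x = np.arange(-half_bins, half_bins + 1) * dt
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def population_rate_trace(
    spike_counts: np.ndarray,
    n_neurons: int,
    dt: float,
    kernel_halfwidth: float = 5.0,
    sigma: float | None = None,
    t0: float = 0.0,
    population: str = "",
) -> RateTrace:
    """Smoothed population mean rate from per-step spike counts.

    The instantaneous rate in bin ``k`` is ``counts[k] / (n_neurons * dt)``
    (dt in ms, rate in Hz after the 1000x unit conversion), convolved with a
    unit-area truncated Gaussian.  Convolution uses reflective padding so
    the smoothing conserves total spike count in the interior.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    counts = np.asarray(spike_counts, dtype=float)
    inst = counts / (n_neurons * dt * 1e-3)
    kernel = gaussian_kernel(dt, kernel_halfwidth, sigma)
    half = len(kernel) // 2
    padded = np.pad(inst, half, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    times = t0 + (np.arange(len(inst)) + 1) * dt
    return RateTrace(times=times, rates=smoothed, population=population)


def rate_trace_from_spikes(
    spike_times: np.ndarray,
    n_neurons: int,
    dt: float,
    duration: float,
    kernel_halfwidth: float = 5.0,
    t0: float = 0.0,
    population: str = "",
) -> RateTrace:
    """Smoothed population rate from raw spike times (ms) of one population."""
    n_bins = int(round(duration / dt))
    edges = t0 + np.arange(n_bins + 1) * dt
    counts, _ = np.histogram(spike_times, bins=edges)
    return population_rate_trace(
        counts, n_neurons, dt, kernel_halfwidth, t0=t0, population=population
    )


def prestimulus_bias(
    trace_chosen: dict[str, np.ndarray] | pd.DataFrame,
    records: pd.DataFrame,
    window: float = 500.0,
) -> list[PrestimBias]:
    """Per-trial chosen-minus-unchosen mean rate before input onset.

    Parameters
    ----------
    trace_chosen : DataFrame
        Long-format per-trial traces with columns ``trial_index``,
        ``time_ms`` (relative to input onset, negative = pre-input),
        ``rate_left_hz``, ``rate_right_hz``.
    records : DataFrame
        Trial records with ``trial_index``, ``choice`` and
        ``previous_choice`` columns; trials without a choice are skipped.
    window : float
        Length (ms) of the averaging window ending at input onset.
    """
    traces = trace_chosen
    out: list[PrestimBias] = []
    grouped = dict(tuple(traces.groupby("trial_index")))
    for rec in records.itertuples():
        if rec.choice not in ("left", "right"):
            continue
        tr = grouped.get(rec.trial_index)
        if tr is None:
            continue
        pre = tr[(tr["time_ms"] > -window) & (tr["time_ms"] <= 0.0)]
        if pre.empty:
            raise ValueError(f"trial {rec.trial_index} has no pre-input samples")
        mean_l = float(pre["rate_left_hz"].mean())
        mean_r = float(pre["rate_right_hz"].mean())
        bias = mean_l - mean_r if rec.choice == "left" else mean_r - mean_l
        repeated = rec.previous_choice == rec.choice
        out.append(PrestimBias(int(rec.trial_index), bias, bool(repeated)))
    return out


def bias_condition_summary(
    biases_by_condition: dict[str, pd.DataFrame], baseline: str = "none"
):
    """Per-subject mean prestimulus bias per condition plus paired tests.

    ``biases_by_condition`` maps condition name to a DataFrame with columns
    ``subject_id`` and ``bias_hz``.  Returns ``(summary, tests)``: the
    per-subject condition means, and Wilcoxon signed-rank comparisons of
    each condition against the baseline over matched subjects.
    """
    from .behavior import wilcoxon_signed_rank

    rows = []
    for cond, df in biases_by_condition.items():
        means = df.groupby("subject_id")["bias_hz"].mean()
        for sid, m in means.items():
            rows.append({"condition": cond, "subject_id": sid, "mean_bias_hz": m})
    summary = pd.DataFrame(rows)
    tests = {}
    if baseline in biases_by_condition:
        base = summary[summary["condition"] == baseline].set_index("subject_id")[
            "mean_bias_hz"
        ]
        for cond in biases_by_condition:
            if cond == baseline:
                continue
            other = summary[summary["condition"] == cond].set_index("subject_id")[
                "mean_bias_hz"
            ]
            common = base.index.intersection(other.index)
            if len(common) == 0:
                continue
            tests[cond] = wilcoxon_signed_rank(
                other.loc[common].to_numpy(), base.loc[common].to_numpy()
            )
    return summary, tests
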