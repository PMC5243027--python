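"""Task protocol: inputs, virtual subjects, sessions, and trial records.

A session is a sequence of random-dot-motion trials run through the
attractor network.  Each trial lasts 3 s with task-related input applied
from 1–2 s; the two selective pools receive Poisson input whose mean rates
vary linearly with motion coherence and always sum to 80 Hz.  Instantaneous
rates are resampled at the monitor refresh rate (60 Hz) with Gaussian
jitter (σ = 4 Hz, truncated at zero).

Virtual subjects capture between-participant variability: each gets its own
probabilistic wiring, a background input rate sampled from 880–950 Hz and a
response threshold from 18–22 Hz (accumulator architecture: 855–870 Hz with
the threshold mapped affinely into 19–36 Hz).

Sessions run *continuously* by default: the network state at the end of a
trial is the starting state of the next, so decaying tail activity from the
previous decision can bias the next one — the mechanism behind choice
hysteresis.  ``reinitialized`` sessions reset the state at every trial
start.  Simulated stimulation injects constant currents into every neuron
for the entire session (depolarizing: +0.75 pA into pyramidal cells,
−0.375 pA into interneurons; hyperpolarizing: the signs flipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import detect_decision
from .network import (
    Network,
    NetworkState,
    build_network,
)
from .neural import population_rate_trace
from .params import Architecture, NetworkConfig, StimulationCurrents

__all__ = [
    "InputSpec",
    "TrialSpec",
    "SessionSpec",
    "VirtualSubject",
    "STIMULATION_CONDITIONS",
    "coherence_to_rates",
    "sample_rate_trace",
    "make_trial_list",
    "sample_virtual_subject",
    "stimulation_currents",
    "run_session",
    "SessionResult",
]

#: The five coherence levels of the behavioral task.
DEFAULT_COHERENCES = (0.032, 0.064, 0.128, 0.256, 0.512)

#: Stimulation magnitudes (pA): pyramidal / interneuron injected currents.
_I_PYR, _I_INT = 0.75, 0.375

STIMULATION_CONDITIONS = {
    "none": StimulationCurrents(0.0, 0.0),
    "depolarizing": StimulationCurrents(+_I_PYR, -_I_INT),
    "hyperpolarizing": StimulationCurrents(-_I_PYR, +_I_INT),
    "pyramidal_only_depol": StimulationCurrents(+_I_PYR, 0.0),
    "pyramidal_only_hyper": StimulationCurrents(-_I_PYR, 0.0),
    "interneuron_only_depol": StimulationCurrents(0.0, -_I_INT),
    "interneuron_only_hyper": StimulationCurrents(0.0, +_I_INT),
    "uniform_depol": StimulationCurrents(+_I_PYR, +_I_PYR),
    "uniform_hyper": StimulationCurrents(-_I_PYR, -_I_PYR),
}


def stimulation_currents(name: str) -> StimulationCurrents:
    """Injected-current pair for a named stimulation condition.

    ``depolarizing`` injects +0.75 pA into pyramidal cells and −0.375 pA
    into interneurons (the physiological pattern of anodal polarization);
    ``hyperpolarizing`` flips both signs.  ``*_only`` variants zero the
    other population's current; ``uniform_*`` controls apply the pyramidal
    current to both populations with the same sign, violating the known
    physiology on purpose.
    """
    try:
        return STIMULATION_CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown stimulation condition {name!r}; "
            f"known: {sorted(STIMULATION_CONDITIONS)}"
        ) from None


@dataclass(frozen=True)
class InputSpec:
    """Task-related and background input statistics.

    ``total_rate`` is the sum of the two mean task-input rates (Hz); the
    per-pool means split linearly with coherence.  ``sigma`` is the
    per-refresh-frame rate jitter, ``refresh_hz`` the resampling rate.
    ``background_rate`` is the subject-level background rate (Hz).

    The two convergence factors are structural constants of the input
    pathways: each neuron receives the background pool through
    ``background_convergence`` independent fibers at the subject rate, and
    each selective neuron receives the task stream through
    ``task_convergence`` fibers at the frame rate.  Both are calibrated
    once against the circuit's operating regime (spontaneous pyramidal
    rates of a few Hz, winner-take-all ignition above 20 Hz) and are not
    per-experiment dials.
    """

    total_rate: float = 80.0
    sigma: float = 4.0
    refresh_hz: float = 60.0
    background_rate: float = 900.0
    background_convergence: float = 2.8
    task_convergence: float = 8.0

    def __post_init__(self) -> None:
        if self.total_rate <= 0:
            raise ValueError("total task-input rate must be positive")
        if self.sigma < 0:
            raise ValueError("rate jitter must be non-negative")
        if self.refresh_hz <= 0:
            raise ValueError("refresh rate must be positive")


@dataclass(frozen=True)
class TrialSpec:
    """One trial: coherence, motion direction, and timing (seconds)."""

    coherence: float
    direction: str  # "left" or "right"
    trial_duration: float = 3.0
    input_onset: float = 1.0
    input_offset: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        if not 0.0 <= self.input_onset < self.input_offset <= self.trial_duration:
            raise ValueError("need 0 <= onset < offset <= duration")

    @property
    def coherence_signed(self) -> float:
        return self.coherence if self.direction == "right" else -self.coherence


@dataclass(frozen=True)
class SessionSpec:
    """An ordered block of trials with ISI, continuity and stimulation.

    The inter-stimulus interval is measured from task-input offset to the
    next trial's input onset.  The post-input tail of each trial is fixed
    (trial_duration − input_offset, 1 s by default); the pre-input period
    of the following trials is stretched or shrunk so that the ISI comes
    out right.
    """

    trials: tuple[TrialSpec, ...]
    isi: float = 2.0
    continuity: str = "continuous"  # or "reinitialized"
    stimulation: str = "none"

    def __post_init__(self) -> None:
        if self.continuity not in ("continuous", "reinitialized"):
            raise ValueError("continuity must be 'continuous' or 'reinitialized'")
        stimulation_currents(self.stimulation)
        if self.trials:
            post = self.trials[0].trial_duration - self.trials[0].input_offset
            if self.isi < post:
                raise ValueError(
                    f"isi {self.isi} s shorter than the post-input tail {post} s"
                )


@dataclass(frozen=True)
class VirtualSubject:
    """One model instantiation standing in for a human participant."""

    subject_id: int
    background_rate: float  # Hz
    response_threshold: float  # Hz
    wiring_seed: int
    session_seed: int
    architecture: Architecture = Architecture.attractor


# ---------------------------------------------------------------------------
# input construction
# ---------------------------------------------------------------------------

def coherence_to_rates(c: float, total_rate: float = 80.0) -> tuple[float, float]:
    """Mean task-input rates (high, low) for a coherence level.

    The two rates vary linearly with coherence and always sum to
    ``total_rate``: ``(total/2)(1+c)`` and ``(total/2)(1−c)``.  At zero
    coherence both inputs equal ``total/2``; at c = 0.512 with the 80 Hz
    default they are 60.48 and 19.52 Hz.  The high rate goes to the pool
    matching the trial's motion direction.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"coherence must lie in [0, 1], got {c}")
    if total_rate <= 0:
        raise ValueError("total rate must be positive")
    return total_rate / 2.0 * (1.0 + c), total_rate / 2.0 * (1.0 - c)


def sample_rate_trace(
    mu: float, sigma: float, refresh_hz: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame instantaneous rates: one truncated-normal draw per frame.

    Returns an array with one entry per refresh frame over ``duration``
    seconds; rates are drawn N(mu, sigma²) and truncated at zero, and held
    constant within a frame.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(np.ceil(duration * refresh_hz - 1e-9))
    return np.maximum(rng.normal(mu, sigma, size=n_frames), 0.0)


def _frames_to_steps(frame_rates: np.ndarray, refresh_hz: float, n_steps: int, dt_ms: float):
    """Expand per-frame rates onto the integration grid."""
    step_times = (np.arange(n_steps) + 0.5) * dt_ms / 1000.0
    idx = np.minimum((step_times * refresh_hz).astype(int), len(frame_rates) - 1)
    return frame_rates[idx]


def make_trial_list(
    coherences=DEFAULT_COHERENCES,
    reps_per_direction: int = 10,
    rng: np.random.Generator | None = None,
    **trial_kwargs,
) -> list[TrialSpec]:
    """Balanced, randomly ordered trial list.

    ``reps_per_direction`` trials per (coherence, direction) cell — the
    default design is 5 coherences × 2 directions × 10 repetitions = 100
    trials per block.
    """
    if len(coherences) == 0:
        raise ValueError("need at least one coherence level")
    if reps_per_direction < 1:
        raise ValueError("reps_per_direction must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    trials = [
        TrialSpec(coherence=c, direction=d, **trial_kwargs)
        for c in coherences
        for d in ("left", "right")
        for _ in range(reps_per_direction)
    ]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def sample_virtual_subject(
    subject_id: int,
    architecture: Architecture | str = Architecture.attractor,
    rng: np.random.Generator | None = None,
) -> VirtualSubject:
    """Draw one virtual subject's parameters.

    Attractor: background rate ~ U[880, 950] Hz and response threshold
    ~ U[18, 22] Hz, independent.  Accumulator: background ~ U[855, 870] Hz
    with the response threshold tied to it affinely (855 → 19 Hz,
    870 → 36 Hz), since that network is more sensitive to the background
    level.
    """
    architecture = Architecture(architecture)
    rng = np.random.default_rng() if rng is None else rng
    if architecture is Architecture.attractor:
        bg = rng.uniform(880.0, 950.0)
        thr = rng.uniform(18.0, 22.0)
    else:
        bg = rng.uniform(855.0, 870.0)
        thr = 19.0 + (bg - 855.0) / (870.0 - 855.0) * (36.0 - 19.0)
    wiring_seed = int(rng.integers(2**31 - 1))
    session_seed = int(rng.integers(2**31 - 1))
    return VirtualSubject(subject_id, float(bg), float(thr), wiring_seed, session_seed, architecture)


# ---------------------------------------------------------------------------
# session runner
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Output of one session: trial records plus per-trial rate traces.

    ``records`` is the standard trial-record table (one row per trial).
    ``traces`` is a long DataFrame with per-trial smoothed selective-pool
    rates on a grid relative to input onset (``time_ms`` ≤ 0 is
    pre-input), used by the prestimulus-bias analyses.
    """

    records: pd.DataFrame
    traces: pd.DataFrame


def run_session(
    subject: VirtualSubject,
    session: SessionSpec,
    config: NetworkConfig | None = None,
    input_spec: InputSpec | None = None,
    network: Network | None = None,
    condition_label: str | None = None,
    block: int = 0,
    keep_trace_ms: float = 600.0,
) -> SessionResult:
    """Simulate a full session and extract one record per trial.

    The network is wired from ``subject.wiring_seed`` (unless a pre-built
    ``network`` is passed); per-trial input realizations derive from
    ``subject.session_seed``.  Continuous sessions carry the full network
    state across trials; reinitialized sessions reset it at each trial
    start.  Stimulation currents apply at every integration step.
    """
    if config is None:
        config = NetworkConfig(architecture=subject.architecture)
    if config.architecture is not subject.architecture:
        raise ValueError("subject and config disagree on the architecture")
    if input_spec is None:
        input_spec = InputSpec(background_rate=subject.background_rate)
    net = network if network is not None else build_network(config, subject.wiring_seed)
    stim = stimulation_currents(session.stimulation)

    dt = config.dt
    rng = np.random.default_rng(subject.session_seed)
    state = net.initial_state()
    n_sel = config.n_selective

    records = []
    trace_rows = []
    prev_choice = "none"
    post_s = None

    for ti, trial in enumerate(session.trials):
        post_s = trial.trial_duration - trial.input_offset
        pre_s = trial.input_onset if ti == 0 else session.isi - post_s
        input_s = trial.input_offset - trial.input_onset
        n_pre = int(round(pre_s * 1000.0 / dt))
        n_in = int(round(input_s * 1000.0 / dt))
        n_post = int(round(post_s * 1000.0 / dt))
        n_steps = n_pre + n_in + n_post

        if session.continuity == "reinitialized":
            net.reinitialize(state)

        mu_hi, mu_lo = coherence_to_rates(trial.coherence, input_spec.total_rate)
        mu_l, mu_r = (mu_hi, mu_lo) if trial.direction == "left" else (mu_lo, mu_hi)
        frames_l = sample_rate_trace(mu_l, input_spec.sigma, input_spec.refresh_hz, input_s, rng)
        frames_r = sample_rate_trace(mu_r, input_spec.sigma, input_spec.refresh_hz, input_s, rng)
        rates_l = np.zeros(n_steps)
        rates_r = np.zeros(n_steps)
        k = input_spec.task_convergence
        rates_l[n_pre : n_pre + n_in] = k * _frames_to_steps(
            frames_l, input_spec.refresh_hz, n_in, dt
        )
        rates_r[n_pre : n_pre + n_in] = k * _frames_to_steps(
            frames_r, input_spec.refresh_hz, n_in, dt
        )

        step_seed = int(rng.integers(2**31 - 1))
        counts, _ = net.run_steps(
            state,
            n_steps,
            background_rate=subject.background_rate * input_spec.background_convergence,
            task_rates=(rates_l, rates_r),
            stim=stim,
            seed=step_seed,
        )

        trace_l = population_rate_trace(counts[:, 0], n_sel, dt, population="left")
        trace_r = population_rate_trace(counts[:, 1], n_sel, dt, population="right")
        onset_ms = n_pre * dt
        end_ms = n_steps * dt
        choice, dt_ms = detect_decision(
            trace_l,
            trace_r,
            subject.response_threshold,
            response_window=(onset_ms, end_ms),
            tiebreak_seed=step_seed,
        )

        win_pre = (trace_l.times > onset_ms - 500.0) & (trace_l.times <= onset_ms)
        prestim_l = float(trace_l.rates[win_pre].mean())
        prestim_r = float(trace_r.rates[win_pre].mean())
        if choice == "left":
            pres_chosen, pres_unchosen = prestim_l, prestim_r
        elif choice == "right":
            pres_chosen, pres_unchosen = prestim_r, prestim_l
        else:
            pres_chosen = pres_unchosen = np.nan

        records.append(
            {
                "subject_id": subject.subject_id,
                "block": block,
                "condition": condition_label or session.stimulation,
                "trial_index": ti,
                "coherence_signed": trial.coherence_signed,
                "direction": trial.direction,
                "choice": choice,
                "responded": int(choice != "none"),
                "decision_time_s": (dt_ms / 1000.0) if dt_ms is not None else np.nan,
                "prestim_rate_chosen_hz": pres_chosen,
                "prestim_rate_unchosen_hz": pres_unchosen,
                "previous_choice": prev_choice,
                "correct": int(choice == trial.direction) if choice != "none" else 0,
            }
        )

        keep = trace_l.times > onset_ms - keep_trace_ms
        trace_rows.append(
            pd.DataFrame(
                {
                    "trial_index": ti,
                    "time_ms": trace_l.times[keep] - onset_ms,
                    "rate_left_hz": trace_l.rates[keep],
                    "rate_right_hz": trace_r.rates[keep],
                }
            )
        )
        prev_choice = choice  # literal previous-trial choice ("none" if no response)

    records = pd.DataFrame(records)
    traces = (
        pd.concat(trace_rows, ignore_index=True)
        if trace_rows
        else pd.DataFrame(columns=["trial_index", "time_ms", "rate_left_hz", "rate_right_hz"])
    )
    return SessionResult(records=records, traces=traces)
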