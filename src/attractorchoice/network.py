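"""Conductance-based exponential integrate-and-fire attractor network.

The circuit is the classic two-pool decision network: two selective pyramidal
populations receive task-related input and compete through a shared pool of
inhibitory interneurons (winner-take-all), or — in the ``accumulator``
control architecture — through split interneuron pools that remove the
mutual inhibition.

Membrane dynamics follow the exponential integrate-and-fire equation

    C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) − I_syn + I_inj

where ``I_syn = Σ g(t)(V − E)`` sums AMPA, NMDA (with magnesium-block
voltage gating) and GABA_A currents, so excitatory synaptic currents are
negative (inward).  ``I_inj`` is the constant injected current emulating
tDCS, written in the physiological convention (positive depolarizes).

Synaptic conductances decay exponentially (bi-exponentially for NMDA); a
presynaptic spike *sets* the conductance to its maximal value ``G`` rather
than incrementing it (an ``add`` mode is available for sensitivity checks).
One state variable is kept per (neuron, synapse kind).  Spikes reach their
targets after a 0.5 ms axonal delay, quantized to integration steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    Architecture,
    NetworkConfig,
    NeuronParams,
    StimulationCurrents,
    SynapseKind,
)

__all__ = [
    "exp_conductance",
    "biexp_conductance",
    "synaptic_current",
    "nmda_gating",
    "total_current",
    "membrane_derivative",
    "steady_state_polarization",
    "build_network",
    "Network",
    "NetworkState",
    "NumericalInstabilityError",
]

#: Index of the conductance state rows in ``NetworkState.g``.
G_EXT, G_BG, G_REC, H_NMDA_RISE, H_NMDA_DECAY, G_GABA = range(6)

#: Population group codes used in spike-count outputs.
POP_LEFT, POP_RIGHT, POP_NONSEL, POP_INH = range(4)
POP_LABELS = ("left", "right", "nonselective", "interneuron")


class NumericalInstabilityError(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""

    def __init__(self, neuron: int, t: float):
        self.neuron = neuron
        self.t = t
        super().__init__(
            f"non-finite membrane potential in neuron {neuron} at t = {t:.3f} ms"
        )


# ---------------------------------------------------------------------------
# biophysical primitives
# ---------------------------------------------------------------------------

def exp_conductance(G: float, tau: float, t):
    """Mono-exponential synaptic conductance ``G exp(−t/τ)`` (nS).

    ``t`` is the time since the last presynaptic spike, at which the
    conductance was set to its maximal value ``G``.
    """
    if tau <= 0:
        raise ValueError(f"decay time constant must be positive, got {tau}")
    if G < 0:
        raise ValueError(f"maximal conductance must be non-negative, got {G}")
    return G * np.exp(-np.asarray(t, dtype=float) / tau)


def biexp_conductance(G: float, tau_1: float, tau_2: float, t):
    """Bi-exponential (NMDA-type) conductance waveform (nS).

    Normalized difference of exponentials rising with ``tau_1`` and decaying
    with ``tau_2``::

        g(t) = G · τ₂/(τ₂−τ₁) · (exp(−t/τ₂) − exp(−t/τ₁))

    Zero at t = 0, non-negative, and peaking at
    ``t* = τ₁τ₂/(τ₂−τ₁) · ln(τ₂/τ₁)``.
    """
    if not 0 < tau_1 < tau_2:
        raise ValueError(f"need 0 < tau_1 < tau_2, got ({tau_1}, {tau_2})")
    t = np.asarray(t, dtype=float)
    return G * tau_2 / (tau_2 - tau_1) * (np.exp(-t / tau_2) - np.exp(-t / tau_1))


def synaptic_current(g, V_m, E: float):
    """Ohmic synaptic current ``g (V_m − E)`` in pA (g in nS, voltages mV).

    Excitatory currents (E = 0 mV, V_m below rest) come out negative: the
    convention is inward-negative, matched by the minus sign in front of the
    synaptic total in :func:`membrane_derivative`.
    """
    return np.asarray(g, dtype=float) * (np.asarray(V_m, dtype=float) - E)


def nmda_gating(V_m, Mg: float = 1.0):
    """Voltage-dependent magnesium unblock factor of the NMDA conductance.

    ``1 / (1 + [Mg²⁺] exp(−0.062 V_m) / 3.57)`` with V_m in mV and [Mg²⁺]
    in mM; strictly within (0, 1] and increasing in V_m.
    """
    if Mg < 0:
        raise ValueError("magnesium concentration must be non-negative")
    V_m = np.asarray(V_m, dtype=float)
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * V_m) / 3.57)


def total_current(I_AMPA, I_NMDA, I_GABA, I_stim=0.0):
    """Total transmembrane current: synaptic sum plus the stimulation term.

    With ``I_stim = 0`` this is exactly the synaptic total.  Note that a
    *depolarizing* injected current must be passed here already in the
    inward-negative convention of :func:`synaptic_current` (the session
    runner handles this sign internally).
    """
    return (
        np.asarray(I_AMPA, dtype=float)
        + np.asarray(I_NMDA, dtype=float)
        + np.asarray(I_GABA, dtype=float)
        + np.asarray(I_stim, dtype=float)
    )


def membrane_derivative(V_m, I_total, p: NeuronParams):
    """Exponential integrate-and-fire membrane derivative, in mV/ms.

    ``dV/dt = [−g_L(V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T) − I_total] / C``

    ``I_total`` follows the inward-negative convention, so excitation
    (negative I) depolarizes.  With zero input a stable fixed point sits
    slightly above ``E_L`` (the exponential term contributes a small
    depolarizing drive there).
    """
    V_m = np.asarray(V_m, dtype=float)
    I_total = np.asarray(I_total, dtype=float)
    drive = (
        -p.g_L * (V_m - p.E_L)
        + p.g_L * p.Delta_T * np.exp((V_m - p.V_T) / p.Delta_T)
        - I_total
    )
    return drive / p.C_pF


def steady_state_polarization(I_stim: float, g_L: float) -> float:
    """Leak-dominated steady-state voltage shift ``I/g_L`` (mV).

    Sanity check for injected-current magnitudes: e.g. 0.375 pA against a
    20 nS leak polarizes by 0.01875 ≈ 0.019 mV.
    """
    if g_L <= 0:
        raise ValueError("leak conductance must be positive")
    return I_stim / g_L


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

def _csr_from_adjacency(adj: np.ndarray):
    """Row-wise CSR (indptr, indices) from a boolean adjacency matrix."""
    counts = adj.sum(axis=1)
    indptr = np.zeros(adj.shape[0] + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.nonzero(adj)[1].astype(np.int64)
    return indptr, indices


@dataclass
class Wiring:
    """Probabilistic wiring realized as CSR adjacency.

    ``exc_*`` maps each pyramidal neuron (row) to its targets, which receive
    both recurrent AMPA and NMDA; ``inh_*`` maps each interneuron (row,
    indexed from 0 within the interneuron population) to its GABA_A targets.
    Target ids are global neuron indices.
    """

    exc_indptr: np.ndarray
    exc_indices: np.ndarray
    inh_indptr: np.ndarray
    inh_indices: np.ndarray
    seed: int


def build_network(config: NetworkConfig, rng_seed: int) -> "Network":
    """Wire a network with Bernoulli connectivity at the configured probabilities.

    The attractor architecture connects both selective pools to the common
    interneuron pool and back.  The accumulator architecture splits the
    interneurons into two halves, each wired exclusively with the
    corresponding selective pool.  Non-selective pyramidal cells exchange
    connections with the whole pyramidal population at the baseline
    probability and project to interneurons (both halves, in the
    accumulator); they receive no task input.  Identical seeds yield
    identical wiring.
    """
    rng = np.random.default_rng(rng_seed)
    n_sel = config.n_selective
    n_pyr = config.n_pyramidal
    n_inh = config.n_interneurons
    n = config.n_total
    c = config.connectivity

    sel_L = slice(0, n_sel)
    sel_R = slice(n_sel, 2 * n_sel)
    nonsel = slice(2 * n_sel, n_pyr)
    inh = slice(n_pyr, n)

    # pyramidal -> (pyramidal, interneuron) adjacency
    exc = np.zeros((n_pyr, n), dtype=bool)
    draw = lambda rows, cols, p: rng.random((rows, cols)) < p  # noqa: E731

    # selective recurrence stays within each pool
    exc[sel_L, sel_L] = draw(n_sel, n_sel, c.p_pyr_recurrent)
    exc[sel_R, sel_R] = draw(n_sel, n_sel, c.p_pyr_recurrent)
    if config.n_nonselective and config.nonselective_policy == "recurrent":
        exc[nonsel, 0:n_pyr] = draw(config.n_nonselective, n_pyr, c.p_pyr_recurrent)
        exc[sel_L, nonsel] = draw(n_sel, config.n_nonselective, c.p_pyr_recurrent)
        exc[sel_R, nonsel] = draw(n_sel, config.n_nonselective, c.p_pyr_recurrent)
    np.fill_diagonal(exc[:, :n_pyr], False)  # no autapses

    # interneuron -> (pyramidal, interneuron) adjacency
    gaba = np.zeros((n_inh, n), dtype=bool)

    if config.architecture is Architecture.attractor:
        exc[0:n_pyr, inh] = draw(n_pyr, n_inh, c.p_pyr_to_int)
        gaba[:, 0:n_pyr] = draw(n_inh, n_pyr, c.p_int_to_pyr)
        gaba[:, inh] = draw(n_inh, n_inh, c.p_int_recurrent)
    else:
        half = n_inh // 2
        inh_A = slice(n_pyr, n_pyr + half)
        inh_B = slice(n_pyr + half, n)
        # selective pools wire exclusively with their own interneuron half
        exc[sel_L, inh_A] = draw(n_sel, half, c.p_pyr_to_int)
        exc[sel_R, inh_B] = draw(n_sel, half, c.p_pyr_to_int)
        if config.n_nonselective:
            exc[nonsel, inh] = draw(config.n_nonselective, n_inh, c.p_pyr_to_int)
        gaba[0:half, sel_L] = draw(half, n_sel, c.p_int_to_pyr)
        gaba[half:, sel_R] = draw(half, n_sel, c.p_int_to_pyr)
        if config.n_nonselective:
            gaba[:, nonsel] = draw(n_inh, config.n_nonselective, c.p_int_to_pyr)
        # inhibitory recurrence stays within each half
        gaba[0:half, inh_A] = draw(half, half, c.p_int_recurrent)
        gaba[half:, inh_B] = draw(half, half, c.p_int_recurrent)
    np.fill_diagonal(gaba[:, inh], False)

    exc_indptr, exc_indices = _csr_from_adjacency(exc)
    inh_indptr, inh_indices = _csr_from_adjacency(gaba)
    wiring = Wiring(exc_indptr, exc_indices, inh_indptr, inh_indices, seed=rng_seed)
    return Network(config, wiring)


# ---------------------------------------------------------------------------
# state and network
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Evolving simulation state.

    ``g`` holds one row per synaptic state variable (see ``G_EXT`` ...
    ``G_GABA``); the two NMDA rows are the dimensionless rise/decay states
    whose normalized difference, scaled by the maximal conductance, gives
    the NMDA conductance.  ``pending_exc`` / ``pending_inh`` are delay-line
    ring buffers of spike arrivals (delay_steps × n, uint8).
    """

    V: np.ndarray
    g: np.ndarray
    refractory_until: np.ndarray
    pending_exc: np.ndarray
    pending_inh: np.ndarray
    t: float
    step_index: int

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.V.copy(),
            self.g.copy(),
            self.refractory_until.copy(),
            self.pending_exc.copy(),
            self.pending_inh.copy(),
            self.t,
            self.step_index,
        )


class Network:
    """A wired attractor (or accumulator) network ready to simulate.

    Per-neuron constant arrays are materialized once at construction so the
    integration kernel works on flat vectors.  Neuron order: the two
    selective pools, then non-selective pyramidal cells, then interneurons.
    """

    def __init__(self, config: NetworkConfig, wiring: Wiring):
        self.config = config
        self.wiring = wiring
        n = config.n_total
        n_pyr = config.n_pyramidal
        n_sel = config.n_selective

        self.sel_L = slice(0, n_sel)
        self.sel_R = slice(n_sel, 2 * n_sel)
        self.nonsel = slice(2 * n_sel, n_pyr)
        self.inh = slice(n_pyr, n)

        group = np.empty(n, dtype=np.int8)
        group[self.sel_L] = POP_LEFT
        group[self.sel_R] = POP_RIGHT
        group[self.nonsel] = POP_NONSEL
        group[self.inh] = POP_INH
        self.group = group
        self.is_pyramidal = np.arange(n) < n_pyr

        def per_neuron(pyr_val: float, int_val: float) -> np.ndarray:
            out = np.full(n, pyr_val, dtype=np.float64)
            out[self.inh] = int_val
            return out

        pp, ip = config.pyramidal, config.interneuron
        self.C_pF = per_neuron(pp.C_pF, ip.C_pF)
        self.g_L = per_neuron(pp.g_L, ip.g_L)
        self.E_L = per_neuron(pp.E_L, ip.E_L)
        self.Delta_T = per_neuron(pp.Delta_T, ip.Delta_T)
        self.V_T = per_neuron(pp.V_T, ip.V_T)
        self.V_s = per_neuron(pp.V_s, ip.V_s)
        self.V_r = per_neuron(pp.V_r, ip.V_r)
        self.tau_r = per_neuron(pp.tau_r, ip.tau_r)

        syn = config.synapses
        get = lambda kind, tgt: syn[(kind, tgt)]  # noqa: E731
        self.G_ext = per_neuron(
            get(SynapseKind.AMPA_ext, "pyramidal").G,
            get(SynapseKind.AMPA_ext, "interneuron").G,
        )
        self.G_bg = per_neuron(
            get(SynapseKind.AMPA_background, "pyramidal").G,
            get(SynapseKind.AMPA_background, "interneuron").G,
        )
        self.G_rec = per_neuron(
            get(SynapseKind.AMPA_recurrent, "pyramidal").G,
            get(SynapseKind.AMPA_recurrent, "interneuron").G,
        )
        self.G_nmda = per_neuron(
            get(SynapseKind.NMDA, "pyramidal").G, get(SynapseKind.NMDA, "interneuron").G
        )
        self.G_gaba = per_neuron(
            get(SynapseKind.GABA_A, "pyramidal").G,
            get(SynapseKind.GABA_A, "interneuron").G,
        )

        nmda = get(SynapseKind.NMDA, "pyramidal")
        self.Mg = nmda.Mg if nmda.Mg is not None else 1.0
        self.nmda_tau_1 = nmda.tau_1
        self.nmda_tau_2 = nmda.tau_2
        self.nmda_norm = nmda.tau_2 / (nmda.tau_2 - nmda.tau_1)
        self.E_exc = get(SynapseKind.AMPA_recurrent, "pyramidal").E
        self.E_gaba = get(SynapseKind.GABA_A, "pyramidal").E

        dt = config.dt
        self.decay = np.array(
            [
                math.exp(-dt / get(SynapseKind.AMPA_ext, "pyramidal").tau),
                math.exp(-dt / get(SynapseKind.AMPA_background, "pyramidal").tau),
                math.exp(-dt / get(SynapseKind.AMPA_recurrent, "pyramidal").tau),
                math.exp(-dt / nmda.tau_1),
                math.exp(-dt / nmda.tau_2),
                math.exp(-dt / get(SynapseKind.GABA_A, "pyramidal").tau),
            ]
        )
        self.additive = config.synaptic_update == "add"

        # Each realized recurrent connection stands for a calibrated number of
        # synaptic contacts (pathway-specific, see NetworkConfig): delivered
        # recurrent conductance and the NMDA rise/decay jump are scaled by the
        # contact count of the (source, target) pathway.  External synapses
        # are unaffected; their convergence is a property of the input streams.
        self.exc_gain = per_neuron(config.contacts_ee, config.contacts_ei)
        # within-selective-pool contacts carry the potentiated efficacy; with
        # non-selective feedback to the pools gated off, the excitatory input
        # of a selective cell comes only from its own pool, so the
        # potentiation can be folded into the target-side gain
        if config.nonselective_policy == "passive":
            self.exc_gain[: 2 * n_sel] *= config.w_plus
        self.inh_gain = per_neuron(config.contacts_ie, config.contacts_ii)
        self.G_rec_eff = self.G_rec * self.exc_gain * config.ampa_rec_scale
        self.G_gaba_eff = self.G_gaba * self.inh_gain

        # NMDA saturation: with every presynaptic contact saturated, the
        # summed rise/decay state cannot exceed (excitatory in-degree x
        # contacts); jumps are scaled by the remaining capacity, which keeps
        # the accumulation linear at low rates and bounded at high rates.
        indeg = np.zeros(n, dtype=np.float64)
        np.add.at(indeg, wiring.exc_indices, 1.0)
        self.nmda_cap = np.maximum(indeg, 1.0) * self.exc_gain

        # lookup tables for the kernel: spike-initiation term per class and
        # the NMDA magnesium gating, on a 0.02 mV grid with interpolation
        self._v_tab0 = -130.0
        self._dv_tab = 0.02
        vg = self._v_tab0 + self._dv_tab * np.arange(int((30.0 - self._v_tab0) / self._dv_tab) + 2)
        self._spike_tab = np.vstack(
            [
                p.g_L * p.Delta_T * np.exp((vg - p.V_T) / p.Delta_T)
                for p in (config.pyramidal, config.interneuron)
            ]
        )
        self._gate_tab = 1.0 / (1.0 + self.Mg * np.exp(-0.062 * vg) / 3.57)

    # -- state ------------------------------------------------------------

    def initial_state(self) -> NetworkState:
        """Baseline state: every neuron at rest, conductances zero, empty queue."""
        n = self.config.n_total
        ring = self.config.delay_steps + 1
        return NetworkState(
            V=self.E_L.copy(),
            g=np.zeros((6, n)),
            refractory_until=np.full(n, -np.inf),
            pending_exc=np.zeros((ring, n), dtype=np.uint8),
            pending_inh=np.zeros((ring, n), dtype=np.uint8),
            t=0.0,
            step_index=0,
        )

    def reinitialize(self, state: NetworkState) -> None:
        """Reset membrane/conductance state in place (reinitialized sessions)."""
        state.V[:] = self.E_L
        state.g[:] = 0.0
        state.refractory_until[:] = -np.inf
        state.pending_exc[:] = 0
        state.pending_inh[:] = 0

    # -- single-step reference integrator ---------------------------------

    def nmda_conductance(self, state: NetworkState) -> np.ndarray:
        """Per-neuron NMDA conductance (nS) implied by the rise/decay states."""
        return self.G_nmda * self.nmda_norm * (
            state.g[H_NMDA_DECAY] - state.g[H_NMDA_RISE]
        )

    def step(
        self,
        state: NetworkState,
        external_spikes: dict[str, np.ndarray] | None = None,
        stim: StimulationCurrents = StimulationCurrents(),
    ) -> np.ndarray:
        """Advance the state by one integration step of ``config.dt``.

        ``external_spikes`` maps synapse-kind names (``"AMPA_ext"``,
        ``"AMPA_background"``) to boolean per-neuron arrival arrays for this
        step.  Returns the boolean array of neurons that spiked.  This is
        the plain-numpy reference integrator; sessions use the compiled
        kernel in :mod:`attractorchoice._kernels`, which implements
        identical semantics.
        """
        cfg = self.config
        dt = cfg.dt
        g = state.g

        # 1. decay all conductance states
        g *= self.decay[:, None]

        # 2. deliver delayed recurrent arrivals for this step
        ring = state.pending_exc.shape[0]
        slot = state.step_index % ring
        enq = (state.step_index + cfg.delay_steps) % ring
        exc_count = state.pending_exc[slot].astype(np.int64)
        inh_count = state.pending_inh[slot].astype(np.int64)
        exc_arr = exc_count > 0
        inh_arr = inh_count > 0
        state.pending_exc[slot] = 0
        state.pending_inh[slot] = 0

        # 3. external (Poisson) arrivals
        ext = bg = None
        if external_spikes:
            ext = external_spikes.get("AMPA_ext")
            bg = external_spikes.get("AMPA_background")

        if self.additive:
            if ext is not None:
                g[G_EXT, ext] += self.G_ext[ext]
            if bg is not None:
                g[G_BG, bg] += self.G_bg[bg]
            g[G_REC] += exc_count * self.G_rec_eff
            sat = np.maximum(1.0 - g[H_NMDA_DECAY] / self.nmda_cap, 0.0)
            jump = exc_count * self.exc_gain * sat
            g[H_NMDA_RISE] += jump
            g[H_NMDA_DECAY] += jump
            g[G_GABA] += inh_count * self.G_gaba_eff
        else:
            if ext is not None:
                g[G_EXT, ext] = self.G_ext[ext]
            if bg is not None:
                g[G_BG, bg] = self.G_bg[bg]
            g[G_REC, exc_arr] = self.G_rec_eff[exc_arr]
            g[H_NMDA_RISE, exc_arr] = self.exc_gain[exc_arr]
            g[H_NMDA_DECAY, exc_arr] = self.exc_gain[exc_arr]
            g[G_GABA, inh_arr] = self.G_gaba_eff[inh_arr]

        # 4. currents and Euler update
        V = state.V
        I_ampa = (g[G_EXT] + g[G_BG] + g[G_REC]) * (V - self.E_exc)
        I_nmda = self.nmda_conductance(state) * nmda_gating(V, self.Mg) * (V - self.E_exc)
        I_gaba = g[G_GABA] * (V - self.E_gaba)
        I_inj = np.where(self.is_pyramidal, stim.I_pyr, stim.I_int)
        I_total = I_ampa + I_nmda + I_gaba - I_inj

        drive = (
            -self.g_L * (V - self.E_L)
            + self.g_L * self.Delta_T * np.exp((V - self.V_T) / self.Delta_T)
            - I_total
        )
        refractory = state.t < state.refractory_until
        V_new = np.where(refractory, self.V_r, V + dt * drive / self.C_pF)

        bad = ~np.isfinite(V_new)
        if bad.any():
            idx = int(np.argmax(bad))
            raise NumericalInstabilityError(idx, state.t)

        # 5. spike detection, reset, refractoriness
        spiked = (V_new >= self.V_s) & ~refractory
        V_new[spiked] = self.V_r[spiked]
        state.refractory_until[spiked] = state.t + dt + self.tau_r[spiked]
        state.V = V_new

        # 6. enqueue recurrent deliveries
        if spiked.any():
            w = self.wiring
            pyr_spikes = np.nonzero(spiked[: cfg.n_pyramidal])[0]
            for i in pyr_spikes:
                tgt = w.exc_indices[w.exc_indptr[i] : w.exc_indptr[i + 1]]
                np.add.at(state.pending_exc[enq], tgt, 1)
            inh_spikes = np.nonzero(spiked[self.inh])[0]
            for i in inh_spikes:
                tgt = w.inh_indices[w.inh_indptr[i] : w.inh_indptr[i + 1]]
                np.add.at(state.pending_inh[enq], tgt, 1)

        state.t += dt
        state.step_index += 1
        return spiked

    # -- compiled multi-step integrator -----------------------------------

    def run_steps(
        self,
        state: NetworkState,
        n_steps: int,
        *,
        background_rate: float = 0.0,
        background_rate_int: float | None = None,
        task_rates: tuple[np.ndarray, np.ndarray] | None = None,
        stim: StimulationCurrents = StimulationCurrents(),
        seed: int = 0,
        record_spikes: bool = False,
        max_spikes: int = 2_000_000,
    ):
        """Advance ``n_steps`` with the compiled kernel, mutating ``state``.

        Parameters
        ----------
        background_rate : float
            Rate (Hz) of the independent background Poisson train each
            pyramidal cell receives through its AMPA_background synapse.
        background_rate_int : float, optional
            Background rate for interneurons; defaults to ``background_rate``.
        task_rates : (rates_L, rates_R) or None
            Per-step instantaneous rates (Hz) of the task-related Poisson
            inputs targeting the two selective pools; ``None`` means no
            task input.
        stim : StimulationCurrents
            Constant injected currents (positive depolarizes).
        seed : int
            Seed for the external Poisson draws of this call.
        record_spikes : bool
            Also return individual spike events (neuron id, time in ms).

        Returns
        -------
        counts : ndarray of shape (n_steps, 4)
            Spike counts per step for the left-selective, right-selective,
            non-selective and interneuron groups.
        spikes : (ids, times) or None
        """
        from ._kernels import simulate_steps

        cfg = self.config
        dt = cfg.dt
        if background_rate_int is None:
            background_rate_int = background_rate
        p_bg = 1.0 - math.exp(-background_rate * dt / 1000.0)
        p_bg_int = 1.0 - math.exp(-background_rate_int * dt / 1000.0)
        if task_rates is None:
            p_L = np.zeros(n_steps)
            p_R = np.zeros(n_steps)
        else:
            rates_L, rates_R = task_rates
            if len(rates_L) != n_steps or len(rates_R) != n_steps:
                raise ValueError("task rate arrays must have one entry per step")
            p_L = 1.0 - np.exp(-np.maximum(np.asarray(rates_L, float), 0.0) * dt / 1000.0)
            p_R = 1.0 - np.exp(-np.maximum(np.asarray(rates_R, float), 0.0) * dt / 1000.0)

        I_inj = np.where(self.is_pyramidal, stim.I_pyr, stim.I_int)
        counts = np.zeros((n_steps, 4), dtype=np.int32)
        cap = max_spikes if record_spikes else 1
        rec_n = np.empty(cap, dtype=np.int32)
        rec_t = np.empty(cap, dtype=np.float64)
        w = self.wiring

        gT = np.ascontiguousarray(state.g.T)
        n_rec, err_neuron, t_end = simulate_steps(
            n_steps,
            dt,
            state.t,
            state.step_index,
            state.V,
            gT,
            state.refractory_until,
            state.pending_exc,
            state.pending_inh,
            1.0 / self.C_pF,
            self.g_L,
            self.E_L,
            self.V_s,
            self.V_r,
            self.tau_r,
            self._v_tab0,
            1.0 / self._dv_tab,
            self._spike_tab,
            self._gate_tab,
            self.G_ext,
            self.G_bg,
            self.G_rec_eff,
            self.G_nmda,
            self.G_gaba_eff,
            I_inj,
            self.exc_gain,
            1.0 / self.nmda_cap,
            self.nmda_norm,
            self.E_exc,
            self.E_gaba,
            self.decay,
            w.exc_indptr,
            w.exc_indices,
            w.inh_indptr,
            w.inh_indices,
            cfg.delay_steps,
            cfg.n_pyramidal,
            cfg.n_selective,
            p_bg,
            p_bg_int,
            p_L,
            p_R,
            self.additive,
            self.group,
            counts,
            record_spikes,
            rec_n,
            rec_t,
            int(seed) % (2**31),
        )
        state.g[:] = gT.T
        if err_neuron >= 0:
            raise NumericalInstabilityError(int(err_neuron), float(t_end))
        state.t = t_end
        state.step_index += n_steps
        spikes = (rec_n[:n_rec].copy(), rec_t[:n_rec].copy()) if record_spikes else None
        return counts, spikes
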