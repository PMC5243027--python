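"""Biophysical parameters for the competitive attractor network.

Two neuron classes (pyramidal cells and inhibitory interneurons) are modelled
as conductance-based exponential integrate-and-fire units.  Synapses come in
five kinds: AMPA driven by the task-related inputs (``AMPA_ext``), AMPA driven
by the background Poisson pool (``AMPA_background``), recurrent AMPA
(``AMPA_recurrent``), recurrent NMDA, and GABA_A from the interneurons.
Maximal conductances are target-class specific.

All values are expressed in the units neurophysiologists quote them in:
capacitance in nF, conductances in nS, voltages in mV, times in ms and
currents in pA.  This unit system is internally consistent once capacitance
is converted to pF (1 pA / 1 pF = 1 mV/ms), which is what the integrator
does.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

__all__ = [
    "SynapseKind",
    "Architecture",
    "NeuronParams",
    "SynapseParams",
    "ConnectivitySpec",
    "StimulationCurrents",
    "NetworkConfig",
    "PYRAMIDAL",
    "INTERNEURON",
    "default_synapses",
    "load_preset",
]


class SynapseKind(str, enum.Enum):
    """The five synapse kinds of the network."""

    AMPA_ext = "AMPA_ext"
    AMPA_background = "AMPA_background"
    AMPA_recurrent = "AMPA_recurrent"
    NMDA = "NMDA"
    GABA_A = "GABA_A"


class Architecture(str, enum.Enum):
    """Network wiring scheme.

    ``attractor``
        Both selective pyramidal pools project to, and receive inhibition
        from, one common interneuron pool; recurrent excitation plus shared
        inhibition yields winner-take-all competition.
    ``accumulator``
        The interneuron pool is split into two halves, each exclusively
        wired to the corresponding selective pool, so the pools integrate
        their inputs without mutual inhibition (a control architecture in
        the spirit of race/drift-diffusion models).
    """

    attractor = "attractor"
    accumulator = "accumulator"


@dataclass(frozen=True)
class NeuronParams:
    """Exponential integrate-and-fire neuron constants.

    Attributes
    ----------
    C : float
        Membrane capacitance (nF).
    g_L : float
        Leak conductance (nS).
    E_L : float
        Resting (leak reversal) potential (mV).
    Delta_T : float
        Slope factor of the exponential spike-initiation term (mV).
    V_T : float
        Threshold voltage of the exponential term (mV).
    V_s : float
        Spike-detection threshold (mV); crossing it registers a spike.
    V_r : float
        Post-spike reset voltage (mV).
    tau_r : float
        Absolute refractory period (ms).
    """

    C: float
    g_L: float
    E_L: float
    Delta_T: float
    V_T: float
    V_s: float
    V_r: float
    tau_r: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"membrane capacitance must be positive, got {self.C}")
        if self.g_L <= 0:
            raise ValueError(f"leak conductance must be positive, got {self.g_L}")
        if self.Delta_T <= 0:
            raise ValueError(f"slope factor must be positive, got {self.Delta_T}")
        if self.V_r >= self.V_s:
            raise ValueError("reset voltage must lie below the spike threshold")
        if self.tau_r < 0:
            raise ValueError("refractory period must be non-negative")

    @property
    def C_pF(self) -> float:
        """Capacitance in pF, the unit the integrator uses."""
        return self.C * 1e3


#: Pyramidal-cell constants.
PYRAMIDAL = NeuronParams(
    C=0.5, g_L=25.0, E_L=-70.0, Delta_T=3.0, V_T=-55.0, V_s=-20.0, V_r=-53.0, tau_r=2.0
)

#: Inhibitory-interneuron constants.
INTERNEURON = NeuronParams(
    C=0.2, g_L=20.0, E_L=-70.0, Delta_T=3.0, V_T=-55.0, V_s=-20.0, V_r=-53.0, tau_r=1.0
)


@dataclass(frozen=True)
class SynapseParams:
    """One synapse kind's kinetic constants for a given target class.

    ``tau`` is the mono-exponential decay constant (AMPA/GABA_A); NMDA uses
    the bi-exponential pair ``tau_1`` (rise) / ``tau_2`` (decay) and the
    magnesium-block voltage dependence parameterised by ``Mg``.
    """

    kind: SynapseKind
    G: float  # maximal conductance, nS
    E: float  # reversal potential, mV
    tau: float | None = None  # ms, mono-exponential kinds
    tau_1: float | None = None  # ms, NMDA rise
    tau_2: float | None = None  # ms, NMDA decay
    Mg: float | None = None  # mM, NMDA only

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError(f"maximal conductance must be non-negative, got {self.G}")
        if self.kind is SynapseKind.NMDA:
            if self.tau_1 is None or self.tau_2 is None:
                raise ValueError("NMDA synapses need tau_1 and tau_2")
            if not 0 < self.tau_1 < self.tau_2:
                raise ValueError("NMDA requires 0 < tau_1 < tau_2")
        else:
            if self.tau is None or self.tau <= 0:
                raise ValueError(f"{self.kind.value} needs a positive decay tau")


def default_synapses() -> dict[tuple[SynapseKind, str], SynapseParams]:
    """Synaptic constants keyed by (kind, target class).

    Target classes are ``"pyramidal"`` and ``"interneuron"``; excitatory
    reversal is 0 mV, GABA_A reversal −70 mV, [Mg2+] = 1 mM.
    """
    tab: dict[tuple[SynapseKind, str], SynapseParams] = {}
    for target, g_bg, g_rec, g_nmda, g_gaba in [
        ("pyramidal", 2.1, 0.05, 0.145, 1.3),
        ("interneuron", 1.53, 0.04, 0.13, 1.0),
    ]:
        tab[(SynapseKind.AMPA_ext, target)] = SynapseParams(
            SynapseKind.AMPA_ext, G=1.6, E=0.0, tau=2.0
        )
        tab[(SynapseKind.AMPA_background, target)] = SynapseParams(
            SynapseKind.AMPA_background, G=g_bg, E=0.0, tau=2.0
        )
        tab[(SynapseKind.AMPA_recurrent, target)] = SynapseParams(
            SynapseKind.AMPA_recurrent, G=g_rec, E=0.0, tau=2.0
        )
        tab[(SynapseKind.NMDA, target)] = SynapseParams(
            SynapseKind.NMDA, G=g_nmda, E=0.0, tau_1=2.0, tau_2=100.0, Mg=1.0
        )
        tab[(SynapseKind.GABA_A, target)] = SynapseParams(
            SynapseKind.GABA_A, G=g_gaba, E=-70.0, tau=5.0
        )
    return tab


@dataclass(frozen=True)
class ConnectivitySpec:
    """Bernoulli wiring probabilities and the axonal conduction delay."""

    p_pyr_recurrent: float = 0.08
    p_int_recurrent: float = 0.1
    p_pyr_to_int: float = 0.1
    p_int_to_pyr: float = 0.2
    delay: float = 0.5  # ms

    def __post_init__(self) -> None:
        for name in ("p_pyr_recurrent", "p_int_recurrent", "p_pyr_to_int", "p_int_to_pyr"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.delay <= 0:
            raise ValueError("axonal delay must be positive")


@dataclass(frozen=True)
class StimulationCurrents:
    """Constant injected transmembrane currents emulating tDCS (pA).

    Positive values depolarize (the physiological sign convention): a current
    ``I`` injected into a neuron with leak conductance ``g_L`` shifts its
    resting potential by ``+I/g_L`` at steady state.
    """

    I_pyr: float = 0.0
    I_int: float = 0.0

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.I_pyr) and math.isfinite(self.I_int)):
            raise ValueError("stimulation currents must be finite")


@dataclass(frozen=True)
class NetworkConfig:
    """Full architecture + parameter bundle for one network instance."""

    n_pyramidal: int = 1600
    n_selective: int = 240
    n_interneurons: int = 400
    architecture: Architecture = Architecture.attractor
    connectivity: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    pyramidal: NeuronParams = PYRAMIDAL
    interneuron: NeuronParams = INTERNEURON
    synapses: dict[tuple[SynapseKind, str], SynapseParams] = field(
        default_factory=default_synapses
    )
    dt: float = 0.5  # ms
    synaptic_update: str = "add"  # "add": conductance incremented on arrival; "set": set to max
    # Synaptic contacts per realized connection, per pathway.  The printed
    # per-contact conductances descend from a dense reference circuit; at the
    # sparse wiring probabilities the per-neuron totals are restored by
    # multiplying each delivered conductance by roughly 1/p for its pathway
    # (with the excitatory-to-excitatory pathway additionally carrying the
    # potentiated within-pool efficacy of that circuit).
    contacts_ee: float = 12.5  # pyramidal -> pyramidal
    contacts_ei: float = 6.8  # pyramidal -> interneuron
    contacts_ie: float = 7.0  # interneuron -> pyramidal
    contacts_ii: float = 20.0  # interneuron -> interneuron
    w_plus: float = 1.48  # potentiation of within-selective-pool contacts
    ampa_rec_scale: float = 2.0  # extra scaling of fast recurrent AMPA efficacy
    # Role of the non-selective pyramidal cells.  "passive": they receive
    # background input only and project to the interneurons, supplying tonic
    # excitatory drive without recurrent loops of their own.  "recurrent":
    # they exchange connections with the whole pyramidal pool at the
    # baseline probability.  Passive is the default: a recurrently coupled
    # non-selective pool of 1120 cells forms a third, larger attractor that
    # either ignites itself or routes its tonic drive through the selective
    # cells' saturating NMDA state, swamping the within-pool feedback that
    # decision competition rests on.
    nonselective_policy: str = "passive"

    def __post_init__(self) -> None:
        if 2 * self.n_selective > self.n_pyramidal:
            raise ValueError("selective pools cannot exceed the pyramidal population")
        if self.architecture is Architecture.accumulator and self.n_interneurons % 2:
            raise ValueError("accumulator architecture needs an even interneuron count")
        if self.dt <= 0:
            raise ValueError("integration step must be positive")
        steps = self.connectivity.delay / self.dt
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("axonal delay must be a positive multiple of dt")
        if self.synaptic_update not in ("set", "add"):
            raise ValueError("synaptic_update must be 'set' or 'add'")
        if min(self.contacts_ee, self.contacts_ei, self.contacts_ie, self.contacts_ii) <= 0:
            raise ValueError("synaptic contact counts must be positive")
        if self.w_plus <= 0:
            raise ValueError("w_plus must be positive")
        if self.ampa_rec_scale < 0:
            raise ValueError("ampa_rec_scale must be non-negative")
        if self.nonselective_policy not in ("passive", "recurrent"):
            raise ValueError("nonselective_policy must be 'passive' or 'recurrent'")

    @property
    def n_nonselective(self) -> int:
        return self.n_pyramidal - 2 * self.n_selective

    @property
    def n_total(self) -> int:
        return self.n_pyramidal + self.n_interneurons

    @property
    def delay_steps(self) -> int:
        return round(self.connectivity.delay / self.dt)

    def replace(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)


def _config_from_dict(d: dict) -> NetworkConfig:
    syn = default_synapses()
    for entry in d.get("synapses", []):
        kind = SynapseKind(entry["kind"])
        target = entry["target"]
        base = syn[(kind, target)]
        syn[(kind, target)] = replace(
            base, **{k: v for k, v in entry.items() if k not in ("kind", "target")}
        )
    neurons = {}
    for cls in ("pyramidal", "interneuron"):
        base = PYRAMIDAL if cls == "pyramidal" else INTERNEURON
        neurons[cls] = replace(base, **d.get("neurons", {}).get(cls, {}))
    conn = ConnectivitySpec(**d.get("connectivity", {}))
    top = {
        k: d[k]
        for k in (
            "n_pyramidal",
            "n_selective",
            "n_interneurons",
            "dt",
            "synaptic_update",
            "contacts_ee",
            "contacts_ei",
            "contacts_ie",
            "contacts_ii",
            "w_plus",
            "ampa_rec_scale",
            "nonselective_policy",
        )
        if k in d
    }
    arch = Architecture(d.get("architecture", "attractor"))
    return NetworkConfig(
        architecture=arch,
        connectivity=conn,
        pyramidal=neurons["pyramidal"],
        interneuron=neurons["interneuron"],
        synapses=syn,
        **top,
    )


def load_preset(name: str = "default") -> NetworkConfig:
    """Load a packaged network configuration preset by name."""
    ref = resources.files("attractorchoice") / "presets" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError as err:
        raise KeyError(f"no packaged preset named {name!r}") from err
    return _config_from_dict(yaml.safe_load(text) or {})


def load_config(path: str) -> NetworkConfig:
    """Read a network configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh) or {})
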