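"""Bilateral rhythm-generating circuit: populations, connectivity, dynamics.

The circuit couples two rhythm generators (RGs), one per hindlimb.  Each RG
is a pair of conditional bursters -- a flexor (RG-F) and an extensor (RG-E)
half-center -- that inhibit each other through relay populations InF and
InE.  The two sides interact through commissural pathways carried by
genetically identified interneuron classes: V0D (direct crossed inhibition
of the contralateral flexor), V2a->V0V->Ini (indirect crossed inhibition),
V3-F (crossed flexor-to-flexor excitation) and V3-E (crossed
extensor-to-extensor excitation, which also carries sensory-feedback
effects to the other side).

Supraspinal drives alpha (to flexor half-centers, ipsi- and contralaterally,
and to V2a) and gamma (to the ipsilateral extensor half-center) set the
excitability of the network; two speed- and load-dependent feedback signals
per limb (SF-E1, SF-E2) enter during the ipsilateral stance phase.

Population dynamics are activity-based (non-spiking): each population has a
membrane voltage V, bursters additionally carry a slow persistent-sodium
(NaP) inactivation variable h, and the population output is a piecewise
linear function of V normalised to [0, 1].

Units: mV, ms, nS, pF; outputs and weights dimensionless conductance scales.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "PopulationSpec",
    "PopulationState",
    "Connection",
    "NetworkSpec",
    "CircuitParams",
    "CONDITIONS",
    "DRIVE_SOURCES",
    "FEEDBACK_SOURCES",
    "build_network",
    "output_function",
    "population_rhs",
    "synaptic_inputs",
]

CONDITIONS = ("intact", "hemisected", "transected")

#: external (non-population) input sources
DRIVE_SOURCES = ("drive-alpha-L", "drive-alpha-R", "drive-gamma-L", "drive-gamma-R")
FEEDBACK_SOURCES = ("SF-E1-L", "SF-E1-R", "SF-E2-L", "SF-E2-R")

#: population roster of one side, in canonical order
_SIDE_ROSTER = (
    "RG-F", "RG-E", "InF", "InE", "V0D", "V2a", "V0V", "Ini", "V3-F", "V3-E",
)
_BURSTERS = ("RG-F", "RG-E")


def _side_of(name: str) -> str:
    if name.endswith("-L"):
        return "left"
    if name.endswith("-R"):
        return "right"
    raise ValueError(f"cannot infer side from {name!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Biophysical parameters of one population (conditional burster or relay)."""

    id: str
    side: str                 # "left" | "right"
    kind: str                 # "burster" | "relay"
    C: float = 20.0           # pF
    gNaP: float = 0.0         # nS; 0 for relays
    gL: float = 4.5           # nS
    ENa: float = 50.0         # mV
    EL: float = -64.0         # mV
    EsynE: float = -10.0      # mV
    EsynI: float = -75.0      # mV
    Vm_half: float = -40.0    # mV, NaP activation midpoint
    km: float = -6.0          # mV, activation slope (negative: m grows with V)
    Vh_half: float = -45.0    # mV, NaP inactivation midpoint
    kh: float = 4.0           # mV, inactivation slope (positive: h falls with V)
    tau0: float = 500.0       # ms, peak inactivation time constant
    Vtau: float = -45.0       # mV
    ktau: float = 8.0         # mV
    Vout_min: float = -50.0   # mV, output-function foot
    Vout_max: float = 0.0     # mV, output-function saturation

    def __post_init__(self) -> None:
        if self.kind not in ("burster", "relay"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.kind == "relay" and self.gNaP != 0.0:
            raise ValueError(f"{self.id}: relay populations must have gNaP = 0")
        if not (self.Vout_min < self.Vout_max):
            raise ValueError(f"{self.id}: Vout_min must be < Vout_max")
        if self.C <= 0 or self.gL <= 0:
            raise ValueError(f"{self.id}: C and gL must be positive")


@dataclass
class PopulationState:
    """Dynamic state of one population: voltage, NaP inactivation, output."""

    V: float
    h: float = 1.0
    out: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"h = {self.h} outside [0, 1]")


@dataclass(frozen=True)
class Connection:
    """One signed, weighted synaptic pathway (population or external source)."""

    source: str
    target: str
    weight: float
    sign: str                 # "excitatory" | "inhibitory"
    crossed: bool = False

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"{self.source}->{self.target}: weight must be >= 0")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown synaptic sign {self.sign!r}")


@dataclass(frozen=True)
class CircuitParams:
    """Free connection weights and burster parameters of the circuit.

    The published description of this network is qualitative; the weights
    below are calibration parameters constrained by the behavioural
    acceptance suite (operating-regime thresholds, speed-sweep shapes), not
    measured quantities.  All synaptic weights are in nS per unit source
    output.
    """

    # within-side half-center wiring
    w_rgf_inf: float = 10.0       # RG-F -> InF (exc)
    w_inf_rge: float = 4.0        # InF -| RG-E (inh)
    w_rge_ine: float = 8.0        # RG-E -> InE (exc)
    w_ine_rgf: float = 5.0        # InE -| RG-F (inh)
    # commissural pathways
    w_rgf_v0d: float = 12.0       # RG-F -> V0D (exc)
    w_v0d_rgf: float = 0.3        # V0D -| contra RG-F (inh, crossed)
    w_rgf_v2a: float = 2.0        # RG-F -> V2a (exc)
    w_v2a_v0v: float = 6.0        # V2a -> V0V (exc)
    w_v0v_ini: float = 6.0        # V0V -> contra Ini (exc, crossed)
    w_ini_rgf: float = 1.2        # Ini -| RG-F (inh)
    w_rgf_v3f: float = 5.0        # RG-F -> V3-F (exc)
    w_v3f_rgf: float = 0.1        # V3-F -> contra RG-F (exc, crossed)
    w_rge_v3e: float = 5.0        # RG-E -> V3-E (exc)
    w_v3e_rge: float = 0.5        # V3-E -> contra RG-E (exc, crossed)
    # supraspinal drive targets
    w_alpha_rgf: float = 1.55     # alpha -> ipsi RG-F
    w_alpha_rgf_contra: float = 0.1    # alpha -> contra RG-F
    w_alpha_v2a: float = 6.0      # alpha -> ipsi V2a
    w_gamma_rge: float = 10.0     # gamma -> ipsi RG-E
    # sensory feedback targets (values arrive already scaled by presynaptic
    # inhibition; see hemigait.feedback)
    w_sfe1_rgf: float = 4.0       # SF-E1 -> ipsi RG-F (exc)
    w_sfe1_rgf_contra: float = 0.2     # SF-E1 -| contra RG-F (inh, crossed)
    w_sfe2_rge: float = 8.0       # SF-E2 -> ipsi RG-E (exc)
    w_sfe2_v3e: float = 1.5       # SF-E2 -> ipsi V3-E (exc; crossed conduit)
    # burster biophysics; slow-inactivation kinetics set the locomotor
    # time scale.  The flexor half-center recovers quickly at rest and
    # holds a long plateau at weak drive (state-machine flexion hold);
    # the extensor half-center inactivates deeply and steadily during its
    # plateau, providing the extension-duration clock.
    gNaP: float = 5.0             # nS, flexor
    gL_burster: float = 4.5       # nS
    Vm_half: float = -40.0        # mV
    km: float = -6.0              # mV
    tau0: float = 6000.0          # ms, flexor
    Vh_half: float = -45.0        # mV, flexor
    kh: float = 4.0               # mV, flexor
    Vtau: float = -40.0           # mV, flexor
    ktau: float = 5.5             # mV, flexor
    gNaP_e: float = 5.0           # nS, extensor
    tau0_e: float = 2000.0        # ms, extensor
    Vh_half_e: float = -40.0      # mV, extensor
    kh_e: float = 4.0             # mV, extensor
    Vtau_e: float = -30.0         # mV, extensor
    ktau_e: float = 10.0          # mV, extensor
    # commissural interneurons respond gradedly to weak drive
    cin_Vout_min: float = -55.0   # mV
    cin_Vout_max: float = -20.0   # mV


DEFAULT_PARAMS = CircuitParams()


def _roster(params: CircuitParams) -> list[PopulationSpec]:
    pops = []
    for suffix, side in (("-L", "left"), ("-R", "right")):
        for base in _SIDE_ROSTER:
            kind = "burster" if base in _BURSTERS else "relay"
            if kind == "burster":
                flexor = base == "RG-F"
                pops.append(
                    PopulationSpec(
                        id=base + suffix, side=side, kind=kind,
                        gNaP=params.gNaP if flexor else params.gNaP_e,
                        gL=params.gL_burster,
                        Vm_half=params.Vm_half, km=params.km,
                        tau0=params.tau0 if flexor else params.tau0_e,
                        Vh_half=params.Vh_half if flexor else params.Vh_half_e,
                        kh=params.kh if flexor else params.kh_e,
                        Vtau=params.Vtau if flexor else params.Vtau_e,
                        ktau=params.ktau if flexor else params.ktau_e,
                    )
                )
            elif base in ("InF", "InE"):
                pops.append(PopulationSpec(id=base + suffix, side=side, kind=kind))
            else:
                pops.append(
                    PopulationSpec(
                        id=base + suffix, side=side, kind=kind,
                        Vout_min=params.cin_Vout_min,
                        Vout_max=params.cin_Vout_max,
                    )
                )
    return pops


def _connection_table(params: CircuitParams) -> list[tuple[str, str, float, str]]:
    """(source, target, weight, sign) for one side; '%' is the ipsilateral
    suffix placeholder, '!' the contralateral one."""
    p = params
    return [
        # half-center core
        ("RG-F%", "InF%", p.w_rgf_inf, "excitatory"),
        ("InF%", "RG-E%", p.w_inf_rge, "inhibitory"),
        ("RG-E%", "InE%", p.w_rge_ine, "excitatory"),
        ("InE%", "RG-F%", p.w_ine_rgf, "inhibitory"),
        # commissural pathways
        ("RG-F%", "V0D%", p.w_rgf_v0d, "excitatory"),
        ("V0D%", "RG-F!", p.w_v0d_rgf, "inhibitory"),
        ("RG-F%", "V2a%", p.w_rgf_v2a, "excitatory"),
        ("V2a%", "V0V%", p.w_v2a_v0v, "excitatory"),
        ("V0V%", "Ini!", p.w_v0v_ini, "excitatory"),
        ("Ini%", "RG-F%", p.w_ini_rgf, "inhibitory"),
        ("RG-F%", "V3-F%", p.w_rgf_v3f, "excitatory"),
        ("V3-F%", "RG-F!", p.w_v3f_rgf, "excitatory"),
        ("RG-E%", "V3-E%", p.w_rge_v3e, "excitatory"),
        ("V3-E%", "RG-E!", p.w_v3e_rge, "excitatory"),
        # supraspinal drives
        ("drive-alpha%", "RG-F%", p.w_alpha_rgf, "excitatory"),
        ("drive-alpha%", "RG-F!", p.w_alpha_rgf_contra, "excitatory"),
        ("drive-alpha%", "V2a%", p.w_alpha_v2a, "excitatory"),
        ("drive-gamma%", "RG-E%", p.w_gamma_rge, "excitatory"),
        # sensory feedback
        ("SF-E1%", "RG-F%", p.w_sfe1_rgf, "excitatory"),
        ("SF-E1%", "RG-F!", p.w_sfe1_rgf_contra, "inhibitory"),
        ("SF-E2%", "RG-E%", p.w_sfe2_rge, "excitatory"),
        ("SF-E2%", "V3-E%", p.w_sfe2_v3e, "excitatory"),
    ]


@dataclass
class NetworkSpec:
    """The full bilateral circuit for one experimental condition."""

    populations: list[PopulationSpec]
    connections: list[Connection]
    condition: str
    params: CircuitParams = field(default_factory=CircuitParams)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        ids = {p.id for p in self.populations}
        for c in self.connections:
            if c.target not in ids:
                raise ValueError(f"connection targets unknown population {c.target!r}")
            if (
                c.source not in ids
                and c.source not in DRIVE_SOURCES
                and c.source not in FEEDBACK_SOURCES
            ):
                raise ValueError(f"connection references unknown source {c.source!r}")

    # -- lookups ---------------------------------------------------------

    def population(self, pop_id: str) -> PopulationSpec:
        for p in self.populations:
            if p.id == pop_id:
                return p
        raise KeyError(pop_id)

    @property
    def population_ids(self) -> list[str]:
        return [p.id for p in self.populations]

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "condition": self.condition,
            "params": asdict(self.params),
            "populations": [asdict(p) for p in self.populations],
            "connections": [asdict(c) for c in self.connections],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        doc = json.loads(text)
        return cls(
            populations=[PopulationSpec(**p) for p in doc["populations"]],
            connections=[Connection(**c) for c in doc["connections"]],
            condition=doc["condition"],
            params=CircuitParams(**doc["params"]),
        )


def build_network(condition: str, params: CircuitParams | None = None) -> NetworkSpec:
    """Assemble the bilateral circuit for ``condition``.

    ``hemisected`` zeroes every connection sourced at the right supraspinal
    drives (drive-alpha-R, drive-gamma-R); ``transected`` zeroes all four
    drive sources.  No other weight differs from the intact roster.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    params = params or DEFAULT_PARAMS
    pops = _roster(params)
    conns: list[Connection] = []
    for ipsi, contra in (("-L", "-R"), ("-R", "-L")):
        for src, tgt, w, sign in _connection_table(params):
            source = src.replace("%", ipsi).replace("!", contra)
            target = tgt.replace("%", ipsi).replace("!", contra)
            conns.append(
                Connection(
                    source=source,
                    target=target,
                    weight=w,
                    sign=sign,
                    crossed=_side_of(source) != _side_of(target),
                )
            )
    zeroed: tuple[str, ...] = ()
    if condition == "hemisected":
        zeroed = ("drive-alpha-R", "drive-gamma-R")
    elif condition == "transected":
        zeroed = DRIVE_SOURCES
    if zeroed:
        conns = [
            replace(c, weight=0.0) if c.source in zeroed else c for c in conns
        ]
    return NetworkSpec(populations=pops, connections=conns, condition=condition, params=params)


def output_function(V: float, spec: PopulationSpec) -> float:
    """Normalised population output: piecewise-linear in V on
    [Vout_min, Vout_max], clipped to [0, 1]."""
    x = (V - spec.Vout_min) / (spec.Vout_max - spec.Vout_min)
    return min(1.0, max(0.0, x))


def m_inf(V: float, spec: PopulationSpec) -> float:
    """NaP activation steady state (instantaneous)."""
    return 1.0 / (1.0 + math.exp((V - spec.Vm_half) / spec.km))


def h_inf(V: float, spec: PopulationSpec) -> float:
    """NaP inactivation steady state."""
    return 1.0 / (1.0 + math.exp((V - spec.Vh_half) / spec.kh))


def tau_h(V: float, spec: PopulationSpec) -> float:
    """NaP inactivation time constant (ms), peaking at Vtau."""
    return spec.tau0 / math.cosh((V - spec.Vtau) / spec.ktau)


def population_rhs(
    state: PopulationState,
    spec: PopulationSpec,
    gE: float,
    gI: float,
) -> tuple[float, float]:
    """Time derivatives (dV/dt in mV/ms, dh/dt in 1/ms) of one population.

    Bursters follow the persistent-sodium conditional-burster formulation:

        C dV/dt = -gNaP * m_inf(V) * h * (V - ENa) - gL (V - EL)
                  - gE (V - EsynE) - gI (V - EsynI)
        dh/dt   = (h_inf(V) - h) / tau_h(V)

    Relays have gNaP = 0 and h frozen at 1.
    """
    if gE < 0 or gI < 0:
        raise ValueError("input conductances must be nonnegative")
    if not (0.0 <= state.h <= 1.0):
        raise ValueError(f"corrupt state: h = {state.h} outside [0, 1]")
    V = state.V
    I_nap = spec.gNaP * m_inf(V, spec) * state.h * (V - spec.ENa)
    dV = (
        -I_nap
        - spec.gL * (V - spec.EL)
        - gE * (V - spec.EsynE)
        - gI * (V - spec.EsynI)
    ) / spec.C
    if spec.kind == "relay" or spec.gNaP == 0.0:
        dh = 0.0
    else:
        dh = (h_inf(V, spec) - state.h) / tau_h(V, spec)
    return dV, dh


def synaptic_inputs(
    network: NetworkSpec,
    outputs: dict[str, float],
    drives: dict[str, float],
    feedback: dict[str, float],
) -> dict[str, tuple[float, float]]:
    """Total excitatory/inhibitory input conductance per population.

    ``outputs`` maps every population id to its current normalised output;
    ``drives`` maps drive sources to scalar drive values; ``feedback`` maps
    feedback sources to their current values, already scaled by presynaptic
    inhibition (see :mod:`hemigait.feedback`).
    """
    missing = set(network.population_ids) - set(outputs)
    if missing:
        raise ValueError(f"outputs missing for populations: {sorted(missing)}")
    g: dict[str, list[float]] = {pid: [0.0, 0.0] for pid in network.population_ids}
    for c in network.connections:
        if c.source in outputs:
            x = outputs[c.source]
        elif c.source in DRIVE_SOURCES:
            x = drives.get(c.source, 0.0)
        elif c.source in FEEDBACK_SOURCES:
            x = feedback.get(c.source, 0.0)
        else:  # pragma: no cover - guarded in __post_init__
            raise ValueError(f"unknown source {c.source!r}")
        contrib = c.weight * x
        if c.sign == "excitatory":
            g[c.target][0] += contrib
        else:
            g[c.target][1] += contrib
    return {pid: (ge, gi) for pid, (ge, gi) in g.items()}
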