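"""Conductance-based prefrontal-cortex working-memory network.

The circuit holds 80 four-compartment pyramidal cells (apical-distal,
proximal, soma, basal; 40 of them receive the memory stimulus) and 40
two-compartment fast-spiking interneurons.  All pyramidal cells connect
recurrently (AMPA + NMDA) to the whole pyramidal population and to all
interneurons; 60% of the interneurons project GABA-A synapses to
pyramidal cells and all interneurons inhibit each other; the remaining
40% form an interneuron-only recurrent subnetwork.

Intrinsic currents follow Hodgkin-Huxley-style kinetics: fast Na+ and
delayed-rectifier K+ everywhere, plus persistent Na+, slowly
inactivating K+ (Ks), high-voltage-activated Ca2+ (HVA) and
Ca2+-dependent K+ (KCa) on pyramidal compartments.  NMDA conductances
carry the voltage-dependent Mg2+ block; an mGluR5-type
after-depolarization (alpha-function) current sustains the stimulated
ensemble after the brief stimulus at t = 2 s.  Background synaptic
noise is an independent Poisson excitatory train per neuron.

A (graph, seed) pair fully determines the spike raster.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from qspwm import _netkernel

__all__ = [
    "ChannelKinetics",
    "CompartmentSpec",
    "SynapseSpec",
    "NetworkConfig",
    "NetworkGraph",
    "SimulationResult",
    "StimulusSpec",
    "gating_rates",
    "synaptic_conductance",
    "mg_block",
    "adp_current",
    "build_network",
    "run_simulation",
    "CHANNELS",
    "AMPA",
    "NMDA",
    "GABA",
    "SimulationError",
]

AMPA, NMDA, GABA = 0, 1, 2
KIND_NAMES = {AMPA: "AMPA", NMDA: "NMDA", GABA: "GABA-A"}


class SimulationError(RuntimeError):
    """Numerical instability during network integration."""


# ---------------------------------------------------------------------------
# channel gating
# ---------------------------------------------------------------------------

def _linoid_neg(x, a, q):
    """a*x / (exp(-x/q) - 1), removable singularity patched (limit -a*q)."""
    x = np.asarray(x, dtype=float)
    safe = np.where(np.abs(x) < 1e-9, 1.0, x)
    with np.errstate(over="ignore", invalid="ignore"):
        val = a * safe / np.expm1(-safe / q)
    return np.where(np.abs(x) < 1e-9, -a * q, val)


def _linoid_pos(x, a, q):
    """a*x / (exp(x/q) - 1), removable singularity patched (limit a*q)."""
    x = np.asarray(x, dtype=float)
    safe = np.where(np.abs(x) < 1e-9, 1.0, x)
    with np.errstate(over="ignore", invalid="ignore"):
        val = a * safe / np.expm1(safe / q)
    return np.where(np.abs(x) < 1e-9, a * q, val)


def _from_ab(alpha, beta, tau_floor=0.0):
    denom = alpha + beta
    xinf = alpha / denom
    tau = 1.0 / denom
    if tau_floor > 0.0:
        tau = np.maximum(tau, tau_floor)
    return xinf, tau


def _pyr_naf_m(V):
    alpha = _linoid_neg(V + 28.0, -0.2816, 9.3)
    beta = _linoid_pos(V + 1.0, 0.2464, 6.0)
    return _from_ab(alpha, beta)


def _pyr_naf_h(V):
    alpha = 0.098 * np.exp(-(V + 43.1) / 20.0)
    beta = 1.4 / (1.0 + np.exp(-(V + 13.1) / 10.0))
    return _from_ab(alpha, beta)


def _pyr_kdr_m(V):
    alpha = _linoid_neg(V - 13.0, -0.018, 25.0)
    beta = _linoid_pos(V - 23.0, 0.0054, 12.0)
    return _from_ab(alpha, beta)


def _pyr_nap_m(V):
    alpha = _linoid_neg(V + 17.0, -0.2816, 9.3)
    beta = _linoid_pos(V - 10.0, 0.2464, 6.0)
    return _from_ab(alpha, beta)


def _pyr_nap_h(V):
    alpha = 2.0e-5 * np.exp(-(V + 42.8477) / 4.0248)
    beta = 0.014286 / (1.0 + np.exp(-(V - 413.9284) / 148.2589))
    return _from_ab(alpha, beta)


def _pyr_hva_m(V):
    xinf = 1.0 / (1.0 + np.exp(-(V + 24.6) / 11.3))
    tau = 1.25 / np.cosh(0.031 * (V + 37.1))
    return xinf, tau


def _pyr_hva_h(V):
    xinf = 1.0 / (1.0 + np.exp((V + 12.6) / 18.9))
    tau = np.full_like(np.asarray(V, dtype=float), 420.0)
    return xinf, tau


def _pyr_ks_m(V):
    xinf = 1.0 / (1.0 + np.exp(-(V + 34.0) / 6.5))
    tau = np.full_like(np.asarray(V, dtype=float), 6.0)
    return xinf, tau


def _pyr_ks_h(V):
    xinf = 1.0 / (1.0 + np.exp((V + 65.0) / 6.6))
    tau = 200.0 + 3200.0 / (1.0 + np.exp(-(V + 63.6) / 4.0))
    return xinf, tau


def _pyr_kca_m(Vs):
    alpha = _linoid_neg(Vs + 18.0, -0.00642, 12.0)
    beta = 1.7 * np.exp(-(Vs + 152.0) / 30.0)
    return _from_ab(alpha, beta, tau_floor=1.1)


def _int_naf_m(V):
    alpha = 4.2 * np.exp((V + 34.5) / 11.57)
    beta = 4.2 * np.exp(-(V + 34.5) / 27.0)
    return _from_ab(alpha, beta)


def _int_naf_h(V):
    alpha = 0.09 * np.exp(-(V + 45.0) / 33.0)
    beta = 0.09 * np.exp((V + 45.0) / 12.2)
    return _from_ab(alpha, beta)


def _int_kdr_m(V):
    alpha = 0.3 * np.exp((V + 35.0) / 10.67)
    beta = 0.3 * np.exp(-(V + 35.0) / 42.68)
    return _from_ab(alpha, beta)


@dataclass(frozen=True)
class ChannelKinetics:
    """A voltage-gated channel: gate functions and powers."""

    name: str
    gates: tuple[tuple[str, int, object], ...]  # (gate name, power, rate fn)
    reversal: str  # 'na', 'k' or 'ca'


CHANNELS: dict[str, ChannelKinetics] = {
    "Naf": ChannelKinetics(
        "Naf", (("m", 3, _pyr_naf_m), ("h", 1, _pyr_naf_h)), "na"
    ),
    "Nap": ChannelKinetics(
        "Nap", (("m", 1, _pyr_nap_m), ("h", 1, _pyr_nap_h)), "na"
    ),
    "Kdr": ChannelKinetics("Kdr", (("m", 4, _pyr_kdr_m),), "k"),
    "Ks": ChannelKinetics("Ks", (("m", 1, _pyr_ks_m), ("h", 1, _pyr_ks_h)), "k"),
    "KCa": ChannelKinetics("KCa", (("m", 2, _pyr_kca_m),), "k"),
    "Hva": ChannelKinetics(
        "Hva", (("m", 2, _pyr_hva_m), ("h", 2, _pyr_hva_h)), "ca"
    ),
    "Naf_int": ChannelKinetics(
        "Naf_int", (("m", 3, _int_naf_m), ("h", 1, _int_naf_h)), "na"
    ),
    "Kdr_int": ChannelKinetics("Kdr_int", (("m", 4, _int_kdr_m),), "k"),
}


def gating_rates(channel: ChannelKinetics | str, V) -> dict[str, tuple]:
    """(x_inf, tau_ms) per gate of a channel at membrane voltage V (mV).

    Removable singularities of the alpha/beta rate expressions are
    patched by their limits; for the KCa channel V is the
    calcium-shifted voltage ``Vs = V + 40 log10(1e4 [Ca]_i)``.
    """
    if isinstance(channel, str):
        channel = CHANNELS[channel]
    V = np.asarray(V, dtype=float)
    if not np.isfinite(V).all():
        raise ValueError("V must be finite")
    return {gname: fn(V) for gname, _, fn in channel.gates}


def synaptic_conductance(spec: "SynapseSpec", t_since_pre: float) -> float:
    """Difference-of-exponentials conductance of one synaptic release.

    ``gbar * modulation_scale * (exp(-t/tau_decay) - exp(-t/tau_rise))``;
    zero at t = 0, peaking at ``t* = tau_r tau_d/(tau_d - tau_r) *
    ln(tau_d/tau_r)``.  Multiple releases superpose linearly.
    """
    if t_since_pre < 0:
        raise ValueError("t_since_pre must be >= 0")
    return (
        spec.gbar
        * spec.modulation_scale
        * (
            math.exp(-t_since_pre / spec.tau_decay)
            - math.exp(-t_since_pre / spec.tau_rise)
        )
    )


def mg_block(V: float, mg_mM: float = 1.0) -> float:
    """Voltage-dependent Mg2+ block factor of the NMDA conductance.

    ``1 / (1 + (mg/3.57) exp(-0.062 V))``; 1 with no Mg2+, -> 0 at
    strongly hyperpolarized potentials.
    """
    if mg_mM < 0:
        raise ValueError("mg_mM must be >= 0")
    return 1.0 / (1.0 + (mg_mM / 3.57) * math.exp(-0.062 * V))


def adp_current(t_since_stim: float, amplitude: float, tau_ms: float) -> float:
    """mGluR5 after-depolarization alpha-function current.

    ``amplitude * (t/tau) * exp(1 - t/tau)``; zero at t = 0, maximal
    (= amplitude) at t = tau.
    """
    if t_since_stim < 0:
        raise ValueError("t_since_stim must be >= 0")
    x = t_since_stim / tau_ms
    return amplitude * x * math.exp(1.0 - x)


# ---------------------------------------------------------------------------
# network structure
# ---------------------------------------------------------------------------

#: Table of compartment geometry (um) and maximal conductances (S/cm2):
#: (length, diameter, gNaf, gNap, gHva, gKdr, gKs, gKCa)
PYR_COMPARTMENTS = {
    "apical-distal": (400.0, 2.6, 0.028, 0.0, 0.000255, 0.0092, 0.00018, 0.0022),
    "proximal": (400.0, 2.6, 0.028, 0.001, 0.00063, 0.0092, 0.00018, 0.0038),
    "soma": (86.3, 6.14, 0.086, 0.0022, 0.000306, 0.0338, 0.000105, 0.0022),
    "basal": (150.0, 16.0, 0.028, 0.001, 0.00063, 0.0092, 0.00018, 0.0038),
}
INT_COMPARTMENTS = {
    "soma": (15.0, 15.0, 0.1, 0.0, 0.0, 0.04, 0.0, 0.0),
    "dendrite": (150.0, 10.0, 0.02, 0.0, 0.0, 0.008, 0.0, 0.0),
}
#: order of compartments per cell type (chained in this order)
PYR_ORDER = ("apical-distal", "proximal", "soma", "basal")
INT_ORDER = ("soma", "dendrite")


@dataclass
class CompartmentSpec:
    """Geometry and conductance densities of one compartment."""

    role: str
    length_um: float
    diameter_um: float
    g_bar: dict[str, float]  # S/cm2 per channel name

    @property
    def area_cm2(self) -> float:
        return math.pi * self.length_um * self.diameter_um * 1e-8


@dataclass
class SynapseSpec:
    """One chemical synapse between two neurons."""

    kind: int  # AMPA / NMDA / GABA
    pre: int
    post: int
    gbar: float
    tau_rise: float
    tau_decay: float
    reversal_mV: float
    mg_block: bool = False
    modulation_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if not self.modulation_scale > 0:
            raise ValueError("modulation_scale must be > 0")


@dataclass
class StimulusSpec:
    """Brief suprathreshold current into the stimulated somata."""

    start_ms: float = 2000.0
    duration_ms: float = 200.0
    amplitude_uA_cm2: float = 20.0


@dataclass
class NetworkConfig:
    """All structural and biophysical parameters of the network."""

    n_pyramidal: int = 80
    n_stimulated: int = 40
    n_interneurons: int = 40
    frac_int_projecting: float = 0.6
    contacts_per_pair: int = 1
    self_connections: bool = True

    # membrane
    cm_uF_cm2: float = 1.0
    g_leak_S_cm2: float = 7.0e-5
    e_leak_mV: float = -70.0
    axial_resistivity_ohm_cm: float = 150.0
    e_na_mV: float = 55.0
    e_k_mV: float = -80.0
    e_ca_mV: float = 120.0

    # calcium pool
    ca_rest_M: float = 5.0e-8
    ca_tau_ms: float = 250.0
    ca_phi: float = 1.0e-9  # M per (uA/cm2 * ms)

    # synapses: kinetics (ms) and reversals (mV)
    ampa_tau: tuple[float, float] = (0.5, 2.0)
    nmda_tau: tuple[float, float] = (2.3, 95.0)
    gaba_tau: tuple[float, float] = (0.5, 8.0)
    nmda_ceiling_mS_cm2: float = 0.3
    e_glu_mV: float = 0.0
    e_gaba_pyr_mV: float = -70.0
    e_gaba_int_mV: float = -75.0
    mg_mM: float = 1.0
    syn_delay_ms: float = 1.0

    # per-connection conductance increments, mS/cm2 at the target
    # compartment (calibrated to span targets; see docs/methods.md)
    g_ampa_pp: float = 0.001
    g_nmda_pp: float = 0.0055
    g_ampa_pi: float = 0.006
    g_nmda_pi: float = 0.001
    g_gaba_ip: float = 0.025
    g_gaba_ii: float = 0.002

    # background noise (separate event size for interneurons so the
    # inhibitory tone keeps a pyramid-independent floor)
    noise_rate_hz: float = 500.0
    noise_g_mS_cm2: float = 0.012
    noise_g_int_mS_cm2: float = 0.012

    # ADP current on stimulated cells
    adp_amplitude_uA_cm2: float = 4.0
    adp_tau_ms: float = 4000.0

    # numerics
    dt_ms: float = 0.025
    settle_ms: float = 1000.0
    spike_threshold_mV: float = -20.0
    refractory_ms: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_pyramidal, self.n_interneurons, self.n_stimulated) <= 0:
            raise ValueError("population counts must be positive")
        if self.n_stimulated > self.n_pyramidal:
            raise ValueError("cannot stimulate more pyramidal cells than exist")
        if not 0.0 <= self.frac_int_projecting <= 1.0:
            raise ValueError("frac_int_projecting must be in [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class NetworkGraph:
    """Explicit cell and synapse tables of one network instance.

    ``synapses`` is a structured array with fields pre, post, kind,
    gbar, scale, alive.  ``alive`` flags on neurons implement lesions;
    ``kdr_scale`` carries the muscarinic membrane-rule scaling of the
    delayed-rectifier conductance per neuron.
    """

    config: NetworkConfig
    seed: int
    is_pyr: np.ndarray
    stimulated: np.ndarray
    projecting: np.ndarray  # interneuron -> projects to pyramids
    alive: np.ndarray
    synapses: np.ndarray
    kdr_scale: np.ndarray  # per neuron

    @property
    def n_cells(self) -> int:
        return self.is_pyr.size

    @property
    def pyramidal_ids(self) -> np.ndarray:
        return np.where(self.is_pyr)[0]

    @property
    def interneuron_ids(self) -> np.ndarray:
        return np.where(~self.is_pyr)[0]

    @property
    def stimulated_ids(self) -> np.ndarray:
        return np.where(self.stimulated & self.alive)[0]

    def copy(self) -> "NetworkGraph":
        return NetworkGraph(
            config=self.config,
            seed=self.seed,
            is_pyr=self.is_pyr.copy(),
            stimulated=self.stimulated.copy(),
            projecting=self.projecting.copy(),
            alive=self.alive.copy(),
            synapses=self.synapses.copy(),
            kdr_scale=self.kdr_scale.copy(),
        )

    def live_synapses(self) -> np.ndarray:
        s = self.synapses
        return s[s["alive"] & self.alive[s["pre"]] & self.alive[s["post"]]]

    def graph_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.alive.tobytes())
        h.update(self.synapses.tobytes())
        h.update(self.kdr_scale.tobytes())
        return h.hexdigest()[:16]


@dataclass
class SimulationResult:
    """Spike raster of one network run."""

    neuron: np.ndarray
    time_ms: np.ndarray
    duration_ms: float
    seed: int
    voltage: np.ndarray | None = None
    voltage_t_ms: np.ndarray | None = None

    def raster(self) -> np.ndarray:
        return np.column_stack([self.time_ms, self.neuron])

    def spike_count(self, ids=None) -> int:
        if ids is None:
            return self.neuron.size
        return int(np.isin(self.neuron, ids).sum())


SYN_DTYPE = np.dtype(
    [
        ("pre", np.int32),
        ("post", np.int32),
        ("kind", np.int8),
        ("gbar", np.float64),
        ("scale", np.float64),
        ("alive", np.bool_),
    ]
)


def build_network(seed: int, cfg: NetworkConfig | None = None) -> NetworkGraph:
    """Construct the deterministic-given-seed network graph.

    Connectivity rule: every pyramidal cell sends AMPA+NMDA synapses to
    the whole pyramidal population (recurrent attractor) and to every
    interneuron; a seeded random 60% subset of interneurons sends GABA-A
    synapses to every pyramidal cell; all interneurons inhibit all other
    interneurons.
    """
    cfg = cfg or NetworkConfig()
    rng = np.random.default_rng(seed)
    n_pyr, n_int = cfg.n_pyramidal, cfg.n_interneurons
    n_cells = n_pyr + n_int

    is_pyr = np.zeros(n_cells, dtype=bool)
    is_pyr[:n_pyr] = True
    stimulated = np.zeros(n_cells, dtype=bool)
    stimulated[: cfg.n_stimulated] = True
    alive = np.ones(n_cells, dtype=bool)

    n_proj = int(round(cfg.frac_int_projecting * n_int))
    proj_ids = rng.choice(n_int, size=n_proj, replace=False)
    projecting = np.zeros(n_cells, dtype=bool)
    projecting[n_pyr + proj_ids] = True

    rows = []
    contacts = cfg.contacts_per_pair
    for _ in range(contacts):
        for pre in range(n_pyr):
            for post in range(n_pyr):
                if pre == post and not cfg.self_connections:
                    continue
                rows.append((pre, post, AMPA, cfg.g_ampa_pp))
                rows.append((pre, post, NMDA, cfg.g_nmda_pp))
            for post in range(n_pyr, n_cells):
                rows.append((pre, post, AMPA, cfg.g_ampa_pi))
                rows.append((pre, post, NMDA, cfg.g_nmda_pi))
        for pre in range(n_pyr, n_cells):
            if projecting[pre]:
                for post in range(n_pyr):
                    rows.append((pre, post, GABA, cfg.g_gaba_ip))
            for post in range(n_pyr, n_cells):
                if post != pre:
                    rows.append((pre, post, GABA, cfg.g_gaba_ii))

    syn = np.zeros(len(rows), dtype=SYN_DTYPE)
    for i, (pre, post, kind, g) in enumerate(rows):
        syn[i] = (pre, post, kind, g, 1.0, True)

    return NetworkGraph(
        config=cfg,
        seed=seed,
        is_pyr=is_pyr,
        stimulated=stimulated,
        projecting=projecting,
        alive=alive,
        synapses=syn,
        kdr_scale=np.ones(n_cells),
    )


# ---------------------------------------------------------------------------
# packing and simulation
# ---------------------------------------------------------------------------

_V_LO, _V_HI, _DV = -200.0, 100.0, 0.05

_PYR_GATE_FNS = (
    _pyr_naf_m, _pyr_naf_h, _pyr_kdr_m, _pyr_nap_m, _pyr_nap_h,
    _pyr_ks_m, _pyr_ks_h, _pyr_hva_m, _pyr_hva_h,
)
_INT_GATE_FNS = (_int_naf_m, _int_naf_h, _int_kdr_m)

_table_cache: dict[float, tuple] = {}


def _gate_tables(dt: float):
    """Per-dt exponential-Euler update tables a=exp(-dt/tau), b=xinf(1-a)."""
    if dt in _table_cache:
        return _table_cache[dt]
    V = np.arange(_V_LO, _V_HI + _DV / 2, _DV)
    n = V.size

    def ab(fn):
        xinf, tau = fn(V)
        a = np.exp(-dt / np.maximum(tau, 1e-6))
        return a, xinf * (1.0 - a)

    pyr_a = np.empty((n, 9))
    pyr_b = np.empty((n, 9))
    for g, fn in enumerate(_PYR_GATE_FNS):
        pyr_a[:, g], pyr_b[:, g] = ab(fn)
    int_a = np.empty((n, 3))
    int_b = np.empty((n, 3))
    for g, fn in enumerate(_INT_GATE_FNS):
        int_a[:, g], int_b[:, g] = ab(fn)
    kca_a, kca_b = ab(_pyr_kca_m)
    out = (V, pyr_a, pyr_b, int_a, int_b, kca_a, kca_b)
    _table_cache[dt] = out
    return out


def _compartment_arrays(cfg: NetworkConfig, net: NetworkGraph):
    """Flatten compartments to kernel arrays; returns a dict of arrays."""
    n_pyr, n_int = cfg.n_pyramidal, cfg.n_interneurons
    n_comp = 4 * n_pyr + 2 * n_int
    area = np.zeros(n_comp)
    g = {name: np.zeros(n_comp) for name in ("naf", "nap", "hva", "kdr", "ks", "kca")}
    is_pyr_comp = np.zeros(n_comp, dtype=np.bool_)
    kdr_scale = np.ones(n_comp)

    soma_comp = np.zeros(n_pyr + n_int, dtype=np.int64)
    exc_comp = np.zeros(n_pyr + n_int, dtype=np.int64)
    inh_comp = np.zeros(n_pyr + n_int, dtype=np.int64)
    comp_neuron = np.zeros(n_comp, dtype=np.int64)

    def comp_id(neuron: int, local: int) -> int:
        if neuron < n_pyr:
            return 4 * neuron + local
        return 4 * n_pyr + 2 * (neuron - n_pyr) + local

    for q in range(n_pyr):
        for local, role in enumerate(PYR_ORDER):
            L, d, gnaf, gnap, ghva, gkdr, gks, gkca = PYR_COMPARTMENTS[role]
            c = comp_id(q, local)
            comp_neuron[c] = q
            area[c] = math.pi * L * d * 1e-8
            g["naf"][c] = gnaf * 1e3
            g["nap"][c] = gnap * 1e3
            g["hva"][c] = ghva * 1e3
            g["kdr"][c] = gkdr * 1e3
            g["ks"][c] = gks * 1e3
            g["kca"][c] = gkca * 1e3
            is_pyr_comp[c] = True
            kdr_scale[c] = net.kdr_scale[q]
        soma_comp[q] = comp_id(q, PYR_ORDER.index("soma"))
        exc_comp[q] = comp_id(q, PYR_ORDER.index("proximal"))
        inh_comp[q] = comp_id(q, PYR_ORDER.index("soma"))
    for j in range(n_int):
        q = n_pyr + j
        for local, role in enumerate(INT_ORDER):
            L, d, gnaf, gnap, ghva, gkdr, gks, gkca = INT_COMPARTMENTS[role]
            c = comp_id(q, local)
            comp_neuron[c] = q
            area[c] = math.pi * L * d * 1e-8
            g["naf"][c] = gnaf * 1e3
            g["kdr"][c] = gkdr * 1e3
            kdr_scale[c] = net.kdr_scale[q]
        soma_comp[q] = comp_id(q, INT_ORDER.index("soma"))
        exc_comp[q] = comp_id(q, INT_ORDER.index("dendrite"))
        inh_comp[q] = comp_id(q, INT_ORDER.index("soma"))

    # axial coupling: chains apical-proximal-soma-basal / soma-dendrite
    pairs = []
    Ra = cfg.axial_resistivity_ohm_cm

    def couple(n_id, la, lb, dims_a, dims_b):
        ca_, cb = comp_id(n_id, la), comp_id(n_id, lb)
        La, da_ = dims_a[0] * 1e-4, dims_a[1] * 1e-4  # cm
        Lb, db = dims_b[0] * 1e-4, dims_b[1] * 1e-4
        # series half-cylinder resistances
        r = Ra * ((La / 2) / (math.pi * da_**2 / 4) + (Lb / 2) / (math.pi * db**2 / 4))
        G = 1.0 / r  # siemens
        pairs.append((ca_, cb, G * 1e3 / area[ca_]))  # mS/cm2 of target
        pairs.append((cb, ca_, G * 1e3 / area[cb]))

    for q in range(n_pyr):
        for a_role, b_role in zip(PYR_ORDER[:-1], PYR_ORDER[1:]):
            couple(
                q,
                PYR_ORDER.index(a_role),
                PYR_ORDER.index(b_role),
                PYR_COMPARTMENTS[a_role][:2],
                PYR_COMPARTMENTS[b_role][:2],
            )
    for j in range(n_int):
        couple(
            n_pyr + j, 0, 1, INT_COMPARTMENTS["soma"][:2], INT_COMPARTMENTS["dendrite"][:2]
        )

    ax_ptr = np.zeros(n_comp + 1, dtype=np.int64)
    for ca_, _, _ in pairs:
        ax_ptr[ca_ + 1] += 1
    ax_ptr = np.cumsum(ax_ptr)
    ax_idx = np.zeros(len(pairs), dtype=np.int64)
    ax_g = np.zeros(len(pairs))
    fill = ax_ptr[:-1].copy()
    for ca_, cb, gax in pairs:
        ax_idx[fill[ca_]] = cb
        ax_g[fill[ca_]] = gax
        fill[ca_] += 1

    return {
        "n_comp": n_comp,
        "area": area,
        "g": g,
        "is_pyr_comp": is_pyr_comp,
        "kdr_scale": kdr_scale,
        "comp_neuron": comp_neuron,
        "soma_comp": soma_comp,
        "exc_comp": exc_comp,
        "inh_comp": inh_comp,
        "ax_ptr": ax_ptr,
        "ax_idx": ax_idx,
        "ax_g": ax_g,
    }


def _weight_matrices(net: NetworkGraph):
    cfg = net.config
    n_pyr, n_int = cfg.n_pyramidal, cfg.n_interneurons
    n_cells = n_pyr + n_int
    w_ampa = np.zeros((n_pyr, n_cells))
    w_nmda = np.zeros((n_pyr, n_cells))
    w_gaba = np.zeros((n_int, n_cells))
    live = net.live_synapses()
    for s in live:
        w = s["gbar"] * s["scale"]
        if s["kind"] == AMPA:
            w_ampa[s["pre"], s["post"]] += w
        elif s["kind"] == NMDA:
            w_nmda[s["pre"], s["post"]] += w
        else:
            w_gaba[s["pre"] - n_pyr, s["post"]] += w
    return w_ampa, w_nmda, w_gaba


def run_simulation(
    net: NetworkGraph,
    duration_s: float,
    stim: StimulusSpec | None = None,
    seed: int = 0,
    record_v: bool = False,
    v_record_every_ms: float = 1.0,
) -> SimulationResult:
    """Integrate the network and return its spike raster.

    The stimulus (default: 200 ms, 10 uA/cm2 at t = 2 s into the
    stimulated somata) ignites the attractor; identical (graph, seed)
    pairs produce bit-identical rasters.  Raises
    :class:`SimulationError` on numerical blow-up (|V| > 200 mV).
    """
    cfg = net.config
    stim = stim or StimulusSpec()
    if duration_s * 1000.0 < stim.start_ms:
        raise ValueError("duration must cover the stimulus time")
    dt = cfg.dt_ms
    n_steps = int(round(duration_s * 1000.0 / dt))
    comp = _compartment_arrays(cfg, net)
    Vgrid, pyr_a, pyr_b, int_a, int_b, kca_a, kca_b = _gate_tables(dt)
    w_ampa, w_nmda, w_gaba = _weight_matrices(net)

    def decay(tau):
        return math.exp(-dt / tau)

    stim_cells = np.where(net.stimulated)[0].astype(np.int64)
    n_comp = comp["n_comp"]
    g = comp["g"]
    max_spikes = int(net.n_cells * duration_s * 400) + 1000
    v_rec_comp = comp["soma_comp"].astype(np.int64) if record_v else np.zeros(1, np.int64)

    # the ADP cascade is triggered by the stimulus; without ignition
    # there is no mGluR5 activation and hence no ADP drive
    has_stim = stim.amplitude_uA_cm2 > 0 and stim.duration_ms > 0
    adp_amp = cfg.adp_amplitude_uA_cm2 if has_stim else 0.0

    (status, spk_n, spk_t, v_trace, t_fail, q_fail) = _netkernel.run_network_kernel(
        n_steps, int(round(cfg.settle_ms / dt)), dt, seed,
        n_comp,
        np.full(n_comp, cfg.cm_uF_cm2),
        np.full(n_comp, cfg.g_leak_S_cm2 * 1e3),
        np.full(n_comp, cfg.e_leak_mV),
        comp["area"],
        g["naf"], g["nap"], g["kdr"], g["ks"], g["kca"], g["hva"],
        comp["kdr_scale"],
        comp["is_pyr_comp"],
        comp["ax_ptr"], comp["ax_idx"], comp["ax_g"],
        _V_LO, 1.0 / _DV, Vgrid.size,
        pyr_a, pyr_b, int_a, int_b, kca_a, kca_b,
        1.0 / (1.0 + (cfg.mg_mM / 3.57) * np.exp(-0.062 * Vgrid)),
        cfg.ca_phi, cfg.ca_tau_ms, cfg.ca_rest_M, cfg.e_ca_mV,
        cfg.e_na_mV, cfg.e_k_mV,
        decay(cfg.ampa_tau[0]), decay(cfg.ampa_tau[1]),
        decay(cfg.nmda_tau[0]), decay(cfg.nmda_tau[1]),
        decay(cfg.gaba_tau[0]), decay(cfg.gaba_tau[1]),
        cfg.nmda_ceiling_mS_cm2,
        cfg.e_glu_mV, cfg.e_gaba_pyr_mV, cfg.e_gaba_int_mV, cfg.mg_mM,
        cfg.n_pyramidal, cfg.n_interneurons,
        comp["comp_neuron"],
        comp["soma_comp"], comp["exc_comp"], comp["inh_comp"],
        w_ampa, w_nmda, w_gaba,
        net.alive,
        max(1, int(round(cfg.syn_delay_ms / dt))),
        cfg.noise_rate_hz / 1000.0,
        np.concatenate([
            np.full(cfg.n_pyramidal, cfg.noise_g_mS_cm2),
            np.full(cfg.n_interneurons, cfg.noise_g_int_mS_cm2),
        ]),
        stim_cells, stim.start_ms, stim.duration_ms, stim.amplitude_uA_cm2,
        adp_amp, cfg.adp_tau_ms,
        cfg.spike_threshold_mV, max(1, int(round(cfg.refractory_ms / dt))),
        max_spikes,
        record_v, max(1, int(round(v_record_every_ms / dt))), v_rec_comp,
    )
    if status != _netkernel.OK:
        raise SimulationError(
            f"numerical blow-up at t = {t_fail:.2f} ms in neuron {q_fail}"
        )
    order = np.argsort(spk_t, kind="stable")
    result = SimulationResult(
        neuron=spk_n[order],
        time_ms=spk_t[order],
        duration_ms=n_steps * dt,
        seed=seed,
    )
    if record_v:
        result.voltage = v_trace
        result.voltage_t_ms = np.arange(v_trace.shape[0]) * v_record_every_ms
    return result
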