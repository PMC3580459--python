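"""Receptor-competition model of a single synapse.

Neurotransmitter, drug, metabolite and tracer molecules compete for one
or more receptor populations.  For ligand *i* with association rate
``kon_i`` and equilibrium dissociation constant ``Kd_i`` the bound
receptor concentration follows::

    d[R_i]/dt = kon_i [C_i] [R_f] - kon_i Kd_i [R_i]

with the continuity constraint ``R_f = R_o - sum_i R_i``.  Because the
equations are linear in the bound fractions ``R_i / R_o``, the total
receptor concentration drops out and the model is integrated on
fractions directly.

Free neurotransmitter decays exponentially with a configurable
half-life and is incremented by quantal release at each presynaptic
spike.  Release is regulated by two multiplicative mechanisms:

* an autoreceptor law ``r0 * (1 + rmax * (1 - 2 A^S / (A^S + B0^S)))``
  where ``A`` is the autoreceptor occupancy read 150 ms before the
  spike, and
* a spike-history facilitation/depression factor
  ``1 + sum_prev [wf e^{-kf dt} - wd e^{-kd dt}]``.

The simulation protocol has three phases: equilibration against a
constant 500 nM free transmitter (solved in closed form), a 5 s
transient at the tonic firing rate, and a 10 s averaging window over
which mean occupancies are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from qspwm import _kernels

__all__ = [
    "LigandSpec",
    "ReceptorPool",
    "PresynapticPhysiology",
    "SynapseSimConfig",
    "SynapseTrace",
    "equilibrium_occupancy",
    "integrate_binding",
    "release_amount",
    "facilitation_factor",
    "simulate_synapse",
    "simulate_forced_firing",
    "IntegrationError",
]

LIGAND_ROLES = ("neurotransmitter", "drug", "metabolite", "tracer")


class IntegrationError(RuntimeError):
    """Numerical fault during synapse integration (e.g. dt too large)."""


@dataclass
class LigandSpec:
    """One ligand competing for a receptor pool.

    Parameters
    ----------
    name : str
    role : {'neurotransmitter', 'drug', 'metabolite', 'tracer'}
        The neurotransmitter's concentration follows the simulated free
        transmitter trace; all other roles are held at ``concentration``.
    kon : float
        Association rate, per nM per ms.
    Kd : float
        Equilibrium dissociation constant, nM.  The dissociation rate is
        always the derived ``koff = kon * Kd``.
    concentration : float
        Free concentration in nM (ignored for the neurotransmitter
        during dynamic simulation).
    """

    name: str
    role: str
    kon: float
    Kd: float
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in LIGAND_ROLES:
            raise ValueError(f"unknown ligand role {self.role!r}")
        if not self.kon > 0:
            raise ValueError("kon must be > 0")
        if not self.Kd > 0:
            raise ValueError("Kd must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def koff(self) -> float:
        """Dissociation rate per ms, derived as kon * Kd."""
        return self.kon * self.Kd


@dataclass
class ReceptorPool:
    """A receptor population and the ligands competing for it."""

    name: str
    ligands: list[LigandSpec]
    R_total: float = 1.0
    bound: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.R_total > 0:
            raise ValueError("R_total must be > 0")
        for lig in self.ligands:
            self.bound.setdefault(lig.name, 0.0)
        if self.free < -1e-12:
            raise ValueError("bound amounts exceed R_total")

    @property
    def free(self) -> float:
        """Free receptor concentration R_f = R_o - sum(bound)."""
        return self.R_total - sum(self.bound.values())

    def occupancy(self, name: str) -> float:
        """Bound fraction of one ligand, R_i / R_o."""
        return self.bound[name] / self.R_total

    def ligand(self, name: str) -> LigandSpec:
        for lig in self.ligands:
            if lig.name == name:
                return lig
        raise KeyError(name)

    @property
    def nt_name(self) -> str:
        for lig in self.ligands:
            if lig.role == "neurotransmitter":
                return lig.name
        raise ValueError(f"pool {self.name!r} has no neurotransmitter ligand")


@dataclass
class PresynapticPhysiology:
    """Release-regulation parameters of the presynaptic terminal.

    ``S`` (the release sensitivity, "RelSens") and ``B0`` shape the
    autoreceptor feedback; ``wf``/``wd`` and the two half-lives shape
    spike-history facilitation and depression.  Decay rates are always
    derived from the half-lives as ``ln 2 / t_half``.
    """

    r0: float = 1.0
    rmax: float = 0.5
    S: float = 7.75
    B0: float = 0.2
    wf: float = 1.1
    wd: float = 0.42
    f_halflife_ms: float = 90.0
    d_halflife_ms: float = 120.0
    autoreceptor_lag_ms: float = 150.0

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError("r0 must be > 0")
        if not 0.0 <= self.rmax <= 1.0:
            raise ValueError("rmax must be in [0, 1]")
        if not self.S > 0:
            raise ValueError("S must be > 0")
        if not 0.0 < self.B0 <= 1.0:
            raise ValueError("B0 must be in (0, 1]")
        if self.wf < 0 or self.wd < 0:
            raise ValueError("facilitation/depression weights must be >= 0")
        if not (self.f_halflife_ms > 0 and self.d_halflife_ms > 0):
            raise ValueError("half-lives must be > 0")

    @property
    def kf(self) -> float:
        """Facilitation decay rate per ms."""
        return math.log(2.0) / self.f_halflife_ms

    @property
    def kd(self) -> float:
        """Depression decay rate per ms."""
        return math.log(2.0) / self.d_halflife_ms


@dataclass
class SynapseSimConfig:
    """Full configuration of a synapse simulation.

    ``pools`` lists every receptor population exposed to the cleft; the
    pool named by ``autoreceptor`` provides the release-regulating
    activation signal.  ``quantal_increment_nM`` converts one unit of
    release into a cleft concentration step.
    """

    pools: list[ReceptorPool]
    autoreceptor: str
    presyn: PresynapticPhysiology
    tonic_rate_hz: float
    nt_halflife_ms: float
    equilibration_conc_nM: float = 500.0
    transient_s: float = 5.0
    averaging_s: float = 10.0
    dt_ms: float = 0.01
    quantal_increment_nM: float = 100.0
    trace_every_ms: float = 1.0

    def __post_init__(self) -> None:
        if not self.dt_ms > 0:
            raise ValueError("dt must be > 0")
        if self.transient_s < 0 or self.averaging_s < 0:
            raise ValueError("phase durations must be non-negative")
        if self.tonic_rate_hz < 0:
            raise ValueError("tonic rate must be >= 0")
        if not self.nt_halflife_ms > 0:
            raise ValueError("NT half-life must be > 0")
        names = [p.name for p in self.pools]
        if self.autoreceptor not in names:
            raise ValueError(f"autoreceptor pool {self.autoreceptor!r} not in pools")

    def pool(self, name: str) -> ReceptorPool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)

    def with_overrides(self, **kwargs) -> "SynapseSimConfig":
        return replace(self, **kwargs)


@dataclass
class SynapseTrace:
    """Decimated simulation trace plus averaged occupancies.

    ``occupancy[pool][ligand]`` is a time series aligned with ``t_ms``;
    ``mean_activation[pool][ligand]`` averages the occupancy over the
    final averaging window.
    """

    t_ms: np.ndarray
    free_nM: np.ndarray
    occupancy: dict[str, dict[str, np.ndarray]]
    mean_activation: dict[str, dict[str, float]]
    peak_free_nM: float
    release_per_spike: np.ndarray

    def to_frame(self):
        """Trace as a pandas DataFrame (time_ms, free_nM, occupancies)."""
        import pandas as pd

        cols = {"time_ms": self.t_ms, "free_nM": self.free_nM}
        for pool, ligs in self.occupancy.items():
            for lig, series in ligs.items():
                cols[f"occ_{pool}_{lig}"] = series
        return pd.DataFrame(cols)


def equilibrium_occupancy(
    ligands: list[LigandSpec], R_total: float = 1.0
) -> dict[str, float]:
    """Closed-form competitive-binding steady state.

    Returns the occupancy fraction per ligand,
    ``(C_i/Kd_i) / (1 + sum_j C_j/Kd_j)``; independent of ``R_total``.
    """
    ratios = {lig.name: lig.concentration / lig.Kd for lig in ligands}
    denom = 1.0 + sum(ratios.values())
    return {name: r / denom for name, r in ratios.items()}


def integrate_binding(
    pool: ReceptorPool, ligands: list[LigandSpec] | None = None, dt: float = 0.01
) -> ReceptorPool:
    """One RK4 step of the coupled bound-fraction ODEs for a pool.

    Ligand concentrations are held constant over the step.  Raises
    :class:`IntegrationError` if the step drives any bound amount or the
    free pool negative (dt too large for the rate constants).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    ligands = pool.ligands if ligands is None else ligands
    names = [lig.name for lig in ligands]
    kon = np.array([lig.kon for lig in ligands])
    koff = np.array([lig.koff for lig in ligands])
    conc = np.array([lig.concentration for lig in ligands])
    f = np.array([pool.occupancy(n) for n in names])

    def deriv(fv: np.ndarray) -> np.ndarray:
        free = 1.0 - fv.sum()
        return kon * conc * free - koff * fv

    k1 = deriv(f)
    k2 = deriv(f + 0.5 * dt * k1)
    k3 = deriv(f + 0.5 * dt * k2)
    k4 = deriv(f + dt * k3)
    f_new = f + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if (f_new < -1e-12).any() or f_new.sum() > 1.0 + 1e-12:
        raise IntegrationError("negative bound amount or depleted pool: reduce dt")
    new_bound = dict(pool.bound)
    for name, fi in zip(names, f_new):
        new_bound[name] = fi * pool.R_total
    return ReceptorPool(
        name=pool.name, ligands=pool.ligands, R_total=pool.R_total, bound=new_bound
    )


def release_amount(A: float, phys: PresynapticPhysiology) -> float:
    """Autoreceptor-regulated release r0*(1 + rmax*(1 - 2 A^S/(A^S+B0^S))).

    Strictly decreasing in the lagged autoreceptor activation ``A``;
    equals ``r0`` at ``A = B0``.
    """
    if not 0.0 <= A <= 1.0:
        raise ValueError("activation A must be in [0, 1]")
    if A == 0.0:
        frac = 0.0
    else:
        aS = A**phys.S
        frac = aS / (aS + phys.B0**phys.S)
    return phys.r0 * (1.0 + phys.rmax * (1.0 - 2.0 * frac))


def facilitation_factor(
    spike_times: np.ndarray | list[float], now: float, phys: PresynapticPhysiology
) -> float:
    """Spike-history multiplier 1 + sum_i [wf e^{-kf dt_i} - wd e^{-kd dt_i}].

    ``spike_times`` are the previous firing times (strictly increasing,
    all before ``now``); an empty history gives 1.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return 1.0
    if (np.diff(st) <= 0).any():
        raise ValueError("spike times must be strictly increasing")
    if (st >= now).any():
        raise ValueError("all spike times must precede `now`")
    dt = now - st
    return float(
        1.0
        + np.sum(phys.wf * np.exp(-phys.kf * dt) - phys.wd * np.exp(-phys.kd * dt))
    )


def _pack_pools(cfg: SynapseSimConfig):
    """Flatten pool/ligand structure into kernel arrays."""
    n_pools = len(cfg.pools)
    max_lig = max(len(p.ligands) for p in cfg.pools)
    kon = np.zeros((n_pools, max_lig))
    koff = np.zeros((n_pools, max_lig))
    conc = np.zeros((n_pools, max_lig))
    is_nt = np.zeros((n_pools, max_lig), dtype=np.bool_)
    n_lig = np.zeros(n_pools, dtype=np.int64)
    for p, pool in enumerate(cfg.pools):
        n_lig[p] = len(pool.ligands)
        for l, lig in enumerate(pool.ligands):
            kon[p, l] = lig.kon
            koff[p, l] = lig.koff
            conc[p, l] = lig.concentration
            is_nt[p, l] = lig.role == "neurotransmitter"
    return kon, koff, conc, is_nt, n_lig


def _equilibrium_fractions(cfg: SynapseSimConfig, nt_conc: float) -> np.ndarray:
    n_pools = len(cfg.pools)
    max_lig = max(len(p.ligands) for p in cfg.pools)
    f0 = np.zeros((n_pools, max_lig))
    for p, pool in enumerate(cfg.pools):
        ligs = [
            replace(lig, concentration=nt_conc)
            if lig.role == "neurotransmitter"
            else lig
            for lig in pool.ligands
        ]
        occ = equilibrium_occupancy(ligs)
        for l, lig in enumerate(pool.ligands):
            f0[p, l] = occ[lig.name]
    return f0


def _run_kernel(cfg: SynapseSimConfig, spike_steps: np.ndarray, n_steps: int,
                avg_start: int, C0: float, f0: np.ndarray) -> SynapseTrace:
    kon, koff, conc, is_nt, n_lig = _pack_pools(cfg)
    auto_pool = [p.name for p in cfg.pools].index(cfg.autoreceptor)
    pool_obj = cfg.pools[auto_pool]
    auto_lig = [lig.name for lig in pool_obj.ligands].index(pool_obj.nt_name)
    phys = cfg.presyn

    # stability guard: sub-step stiff binding rates (e.g. very high drug
    # concentrations) so kon*C*dt stays well below the RK4 limit
    c_nt = max(C0, cfg.quantal_increment_nM * 5.0)
    rates = kon * np.where(is_nt, c_nt, conc) + koff
    max_rate = float(rates.max()) if rates.size else 0.0
    substeps = max(1, int(math.ceil(cfg.dt_ms * max_rate / 0.5)))
    dt_ms = cfg.dt_ms / substeps
    n_steps *= substeps
    avg_start *= substeps
    spike_steps = spike_steps * substeps
    cfg = replace(cfg, dt_ms=dt_ms)

    lag_steps = max(1, int(round(phys.autoreceptor_lag_ms / cfg.dt_ms)))
    trace_every = max(1, int(round(cfg.trace_every_ms / cfg.dt_ms)))
    lam_nt = math.log(2.0) / cfg.nt_halflife_ms

    status, mean_act, peak_free, t_tr, free_tr, occ_tr, rel = (
        _kernels.run_synapse_kernel(
            n_steps,
            cfg.dt_ms,
            lam_nt,
            C0,
            spike_steps,
            cfg.quantal_increment_nM,
            phys.r0,
            phys.rmax,
            phys.S,
            phys.B0,
            lag_steps,
            phys.wf,
            phys.wd,
            phys.kf,
            phys.kd,
            n_lig,
            kon,
            koff,
            conc,
            is_nt,
            f0,
            auto_pool,
            auto_lig,
            avg_start,
            trace_every,
        )
    )
    if status != _kernels.OK:
        raise IntegrationError("synapse integration fault: reduce dt")

    occupancy: dict[str, dict[str, np.ndarray]] = {}
    mean_activation: dict[str, dict[str, float]] = {}
    for p, pool in enumerate(cfg.pools):
        occupancy[pool.name] = {}
        mean_activation[pool.name] = {}
        for l, lig in enumerate(pool.ligands):
            occupancy[pool.name][lig.name] = occ_tr[p, l]
            mean_activation[pool.name][lig.name] = float(mean_act[p, l])
    return SynapseTrace(
        t_ms=t_tr,
        free_nM=free_tr,
        occupancy=occupancy,
        mean_activation=mean_activation,
        peak_free_nM=float(peak_free),
        release_per_spike=rel,
    )


def simulate_synapse(cfg: SynapseSimConfig, seed: int = 0) -> SynapseTrace:
    """Run the three-phase synapse protocol.

    Phase 1 (equilibration at the configured constant free transmitter,
    500 nM by default) is solved in closed form; phase 2 runs for
    ``transient_s`` at the tonic firing rate; phase 3 continues firing
    for ``averaging_s`` during which mean occupancies are accumulated.
    The tonic drive is a deterministic regular spike train, so the trace
    is reproducible for any ``seed``; the argument is accepted for
    interface symmetry with the stochastic network simulator.
    """
    del seed  # deterministic protocol
    dt = cfg.dt_ms
    total_ms = (cfg.transient_s + cfg.averaging_s) * 1000.0
    n_steps = int(round(total_ms / dt))
    avg_start = int(round(cfg.transient_s * 1000.0 / dt))
    if cfg.tonic_rate_hz > 0:
        period = 1000.0 / cfg.tonic_rate_hz
        times = np.arange(0.0, total_ms, period)
        spike_steps = np.unique(np.round(times / dt).astype(np.int64))
    else:
        spike_steps = np.empty(0, dtype=np.int64)
    f0 = _equilibrium_fractions(cfg, cfg.equilibration_conc_nM)
    return _run_kernel(
        cfg, spike_steps, n_steps, avg_start, cfg.equilibration_conc_nM, f0
    )


def simulate_forced_firing(
    cfg: SynapseSimConfig,
    frequency_hz: float,
    n_pulses: int,
    settle_s: float = 1.0,
    tail_s: float = 0.5,
) -> SynapseTrace:
    """Forced-firing (voltammetry-style) protocol.

    After ``settle_s`` at the tonic rate the terminal is driven with
    ``n_pulses`` at ``frequency_hz``; the trace's ``peak_free_nM`` is
    the quantity comparable to fast-cyclic-voltammetry peak transmitter
    measurements.
    """
    if frequency_hz <= 0 or n_pulses < 1:
        raise ValueError("need frequency_hz > 0 and n_pulses >= 1")
    dt = cfg.dt_ms
    settle_ms = settle_s * 1000.0
    train_ms = n_pulses * 1000.0 / frequency_hz
    total_ms = settle_ms + train_ms + tail_s * 1000.0
    n_steps = int(round(total_ms / dt))
    steps = []
    if cfg.tonic_rate_hz > 0:
        period = 1000.0 / cfg.tonic_rate_hz
        steps.extend(np.arange(0.0, settle_ms, period))
    period = 1000.0 / frequency_hz
    steps.extend(settle_ms + np.arange(n_pulses) * period)
    spike_steps = np.unique(np.round(np.array(steps) / dt).astype(np.int64))
    # tonic equilibrium as the starting point; peak read over the train
    f0 = _equilibrium_fractions(cfg, cfg.equilibration_conc_nM)
    trace = _run_kernel(
        cfg,
        spike_steps,
        n_steps,
        int(round(settle_ms / dt)),
        cfg.equilibration_conc_nM,
        f0,
    )
    # peak over the train window only (exclude the equilibration start)
    mask = trace.t_ms >= settle_ms
    trace.peak_free_nM = float(trace.free_nM[mask].max())
    return trace
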