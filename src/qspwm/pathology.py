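"""Disease states and drug interventions as network/activation transforms.

Alzheimer pathology is modeled as (i) loss of pyramidal neurons at a
rate tau_N per week and of pyramidal-origin synapses at tau_S per week
on top of a baseline (5%/5% at trial start; 3%/4% for the prodromal
MCI state), (ii) a cholinergic deficit reducing ACh release, and
(iii) a dopaminergic placebo surge from week 12 on.  The ApoE4
genotype adds 3% (one allele) or 5% (two alleles) synapse loss and,
for homozygotes, an extra cholinergic reduction.  Memantine is a small
differential reduction of NMDA conductance, larger on
excitatory-to-inhibitory than on excitatory-to-excitatory synapses.

Every intervention is reduced to a :class:`Condition` bundle —
pathology state, receptor activations (computed through the
receptor-competition synapse model), and structural transforms — that
the readout layer turns into simulated working-memory spans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from qspwm.coupling import ReceptorActivations
from qspwm.network import AMPA, NMDA, NetworkGraph
from qspwm.pharmacology import (
    SB742457_5HT6_ACTIVATION,
    ache_inhibitor_chain,
)
from qspwm.presets import make_cholinergic_synapse
from qspwm.receptor import simulate_synapse

__all__ = [
    "PathologyState",
    "Genotype",
    "Intervention",
    "Condition",
    "PathologyRates",
    "progress_pathology",
    "apply_lesion",
    "apply_apoe",
    "apply_memantine",
    "build_condition",
    "cholinergic_activations",
    "AD_BASELINE",
    "MCI_BASELINE",
    "DEFAULT_RATES",
]

#: default progression rates, fraction per week (0.04%/wk synapses on
#: top of neuronal loss; 0.25%/wk neurons)
DEFAULT_RATES = (0.0004, 0.0025)


@dataclass
class PathologyState:
    """Structural and neurochemical disease state at one trial week."""

    week: float = 0.0
    synapse_loss: float = 0.0
    neuron_loss: float = 0.0
    ach_deficit: float = 0.0
    ach_compensation: float = 0.0
    da_placebo: float = 0.0

    def __post_init__(self) -> None:
        for name in ("synapse_loss", "neuron_loss", "ach_deficit",
                     "ach_compensation", "da_placebo"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")


#: calibrated trial-entry baseline: 5% synapse and 5% neuron loss
AD_BASELINE = PathologyState(synapse_loss=0.05, neuron_loss=0.05)
#: prodromal MCI: 3% synapses, 4% neurons, cholinergic compensation +10%
MCI_BASELINE = PathologyState(
    synapse_loss=0.03, neuron_loss=0.04, ach_compensation=0.10
)


@dataclass
class PathologyRates:
    """Weekly progression slopes (fractions per week)."""

    tau_s: float = DEFAULT_RATES[0]
    tau_n: float = DEFAULT_RATES[1]

    def __post_init__(self) -> None:
        if self.tau_s < 0 or self.tau_n < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class Genotype:
    """ApoE4 allele count."""

    apoe4_alleles: int = 0

    def __post_init__(self) -> None:
        if self.apoe4_alleles not in (0, 1, 2):
            raise ValueError("apoe4_alleles must be 0, 1 or 2")


@dataclass
class Intervention:
    """A drug arm of the clinical table."""

    drug: str
    dose_mg: float = 0.0
    mechanism: str = "placebo"  # AChE-I | 5HT6-antagonist | memantine | placebo

    MECHANISMS = ("AChE-I", "5HT6-antagonist", "memantine", "placebo")

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose must be >= 0")
        if self.mechanism not in self.MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; known: {self.MECHANISMS}"
            )


@dataclass
class Condition:
    """A fully specified runnable condition."""

    label: str
    pathology: PathologyState
    activations: ReceptorActivations
    memantine: tuple[float, float] | None = None


def progress_pathology(
    week: float,
    rates: PathologyRates | tuple[float, float] = DEFAULT_RATES,
    baseline: PathologyState = AD_BASELINE,
) -> PathologyState:
    """Linear accumulation of synapse and neuron loss over trial weeks."""
    if week < 0:
        raise ValueError("week must be >= 0")
    if isinstance(rates, tuple):
        rates = PathologyRates(*rates)
    return replace(
        baseline,
        week=week,
        synapse_loss=min(baseline.synapse_loss + rates.tau_s * week, 0.999),
        neuron_loss=min(baseline.neuron_loss + rates.tau_n * week, 0.999),
    )


def _pick_balanced_deletions(net: NetworkGraph, n_delete: int, rng) -> np.ndarray:
    """Pyramidal cells to delete, split equally between halves.

    Odd counts are rounded half-to-even per half; the extra cell comes
    from the unstimulated half so the stimulated population driving the
    span metric is preserved.
    """
    stim_pool = np.where(net.stimulated & net.alive)[0]
    unstim_pool = np.where(net.is_pyr & ~net.stimulated & net.alive)[0]
    n_stim_del = n_delete // 2
    n_unstim_del = n_delete - n_stim_del  # extra (odd) from unstimulated half
    if n_stim_del > stim_pool.size or n_unstim_del > unstim_pool.size:
        raise ValueError("neuron loss infeasible for surviving populations")
    picks = np.concatenate(
        [
            rng.choice(stim_pool, size=n_stim_del, replace=False),
            rng.choice(unstim_pool, size=n_unstim_del, replace=False),
        ]
    )
    return picks


def apply_lesion(
    net: NetworkGraph, state: PathologyState, seed: int
) -> NetworkGraph:
    """Delete neurons and synapses per the pathology state.

    ``round(neuron_loss * n_pyramidal)`` pyramidal cells are removed
    (balanced across stimulated/unstimulated halves; interneurons are
    spared), then a ``synapse_loss`` fraction of the surviving
    pyramidal-origin glutamatergic contacts is removed,
    excitatory-excitatory and excitatory-inhibitory at the same rate.
    An AMPA/NMDA pair at the same (pre, post) is one anatomical contact
    and is removed together.  Uniformly random given ``seed``.
    """
    out = net.copy()
    if state.neuron_loss == 0.0 and state.synapse_loss == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n_delete = round(state.neuron_loss * net.config.n_pyramidal)
    if n_delete > 0:
        out.alive[_pick_balanced_deletions(out, n_delete, rng)] = False

    if state.synapse_loss > 0.0:
        syn = out.synapses
        n_pyr = net.config.n_pyramidal
        glu = (syn["kind"] == AMPA) | (syn["kind"] == NMDA)
        survivor = out.alive[syn["pre"]] & out.alive[syn["post"]] & syn["alive"]
        for post_pyr in (True, False):  # e-e and e-i at the same rate
            cls = glu & survivor & (
                (syn["post"] < n_pyr) if post_pyr else (syn["post"] >= n_pyr)
            )
            idx = np.where(cls)[0]
            # group AMPA+NMDA rows into anatomical contacts
            pairs = syn["pre"][idx].astype(np.int64) * 10_000 + syn["post"][idx]
            uniq = np.unique(pairs)
            n_del = round(state.synapse_loss * uniq.size)
            if n_del == 0:
                continue
            chosen = rng.choice(uniq, size=n_del, replace=False)
            kill = idx[np.isin(pairs, chosen)]
            syn["alive"][kill] = False
    return out


def apply_apoe(
    state: PathologyState,
    genotype: Genotype,
    act: ReceptorActivations | None = None,
    extra_ach_decrease: float = 0.10,
    ach_halflife_scale: float = 1.0,
) -> tuple[PathologyState, ReceptorActivations | None]:
    """ApoE4 genotype effects: extra synapse loss, homozygote ACh drop.

    One allele adds 3% synapse loss, two alleles 5%; homozygotes also
    lose an additional fraction of free ACh (default 10%), which is
    propagated through the cholinergic synapse model onto the
    muscarinic/nicotinic activations.
    """
    extra = {0: 0.0, 1: 0.03, 2: 0.05}[genotype.apoe4_alleles]
    new_state = replace(
        state, synapse_loss=min(state.synapse_loss + extra, 0.999)
    )
    new_act = act
    if genotype.apoe4_alleles == 2 and act is not None:
        eff_deficit = 1.0 - (1.0 - state.ach_deficit) * (1.0 - extra_ach_decrease)
        treated = dict(act.treated)
        treated.update(
            cholinergic_activations(
                deficit=eff_deficit,
                halflife_scale=ach_halflife_scale,
                compensation=state.ach_compensation,
            )
        )
        new_act = ReceptorActivations(dict(act.control), treated)
    return new_state, new_act


def apply_memantine(
    net: NetworkGraph, ee_frac: float = 0.005, ei_frac: float = 0.01
) -> NetworkGraph:
    """Scale NMDA conductances down: e-e by (1-ee_frac), e-i by (1-ei_frac)."""
    if not (0.0 <= ee_frac < 1.0 and 0.0 <= ei_frac < 1.0):
        raise ValueError("fractions must be in [0, 1)")
    out = net.copy()
    syn = out.synapses
    n_pyr = net.config.n_pyramidal
    nmda = syn["kind"] == NMDA
    syn["gbar"][nmda & (syn["post"] < n_pyr)] *= 1.0 - ee_frac
    syn["gbar"][nmda & (syn["post"] >= n_pyr)] *= 1.0 - ei_frac
    return out


# --------------------------------------------------------------------------
# receptor activations per condition
# --------------------------------------------------------------------------

_chol_cache: dict[tuple[float, float, float], dict[str, float]] = {}


def cholinergic_activations(
    deficit: float = 0.0,
    halflife_scale: float = 1.0,
    compensation: float = 0.0,
) -> dict[str, float]:
    """Mean M1/M2/alpha7/alpha4beta2 activation from the synapse model.

    The cholinergic deficit reduces the amount of ACh released per
    action potential; MCI compensation raises it; AChE inhibition
    stretches the free-ACh half-life.  Results are cached on the
    rounded parameter triple.
    """
    key = (round(deficit, 6), round(halflife_scale, 6), round(compensation, 6))
    if key in _chol_cache:
        return dict(_chol_cache[key])
    cfg = make_cholinergic_synapse()
    release = (1.0 - deficit) * (1.0 + compensation)
    cfg = cfg.with_overrides(
        quantal_increment_nM=cfg.quantal_increment_nM * release,
        nt_halflife_ms=cfg.nt_halflife_ms * halflife_scale,
    )
    trace = simulate_synapse(cfg)
    out = {
        "M1": trace.mean_activation["M1"]["ACh"],
        "M2": trace.mean_activation["M2"]["ACh"],
        "a7": trace.mean_activation["a7"]["ACh"],
        "a4b2": trace.mean_activation["a4b2"]["ACh"],
    }
    _chol_cache[key] = dict(out)
    return out


def _da_activation(tone_increase: float) -> float:
    """Dopamine-receptor activation under a fractional DA tone change.

    The control operating point sits at half occupancy (tone = Kd);
    a tone increase shifts the competitive-binding isotherm.
    """
    x = 1.0 + tone_increase
    return x / (1.0 + x)


def control_activations() -> ReceptorActivations:
    """Healthy (untreated, no-pathology) control activation set."""
    chol = cholinergic_activations()
    control = dict(chol)
    control.update(
        {
            "D1": 0.5, "D2": 0.5, "D4": 0.5, "a2A": 0.5,
            "5-HT1A": 0.5, "5-HT2A": 0.5, "5-HT3": 0.5, "5-HT4": 0.5,
            "5-HT6": SB742457_5HT6_ACTIVATION[0.0],
        }
    )
    return ReceptorActivations(control=control, treated=dict(control))


def build_condition(
    drug: Intervention,
    week: float,
    genotype: Genotype = Genotype(0),
    rates: PathologyRates | tuple[float, float] = DEFAULT_RATES,
    baseline: PathologyState = AD_BASELINE,
    ach_deficit: float = 0.175,
    da_placebo: float = 0.075,
    placebo_transient: bool = False,
) -> Condition:
    """Compose pathology, dose chains and genotype into one condition.

    The AChE-I chain (dose -> inhibition -> ACh half-life -> cholinergic
    activations), the SB742457 5-HT6 activation presets, the week-12
    dopaminergic placebo surge (persisting at later weeks unless
    ``placebo_transient``) and ApoE adjustments are all folded into a
    single :class:`Condition`.
    """
    state = progress_pathology(week, rates, baseline)
    placebo_on = week == 12 if placebo_transient else week >= 12
    state = replace(
        state,
        ach_deficit=ach_deficit,
        da_placebo=da_placebo if placebo_on else 0.0,
    )

    act = control_activations()
    treated = dict(act.treated)

    halflife_scale = 1.0
    memantine = None
    if drug.mechanism == "AChE-I":
        chain = ache_inhibitor_chain(drug.drug, drug.dose_mg)
        halflife_scale = 1.0 / (1.0 - chain.inhibition)
    elif drug.mechanism == "5HT6-antagonist":
        if drug.dose_mg not in SB742457_5HT6_ACTIVATION:
            raise KeyError(
                f"no 5-HT6 activation preset for dose {drug.dose_mg} mg"
            )
        treated["5-HT6"] = SB742457_5HT6_ACTIVATION[drug.dose_mg]
    elif drug.mechanism == "memantine":
        memantine = (0.005, 0.01)

    treated.update(
        cholinergic_activations(
            deficit=state.ach_deficit,
            halflife_scale=halflife_scale,
            compensation=state.ach_compensation,
        )
    )
    if state.da_placebo > 0:
        da = _da_activation(state.da_placebo)
        for r in ("D1", "D2", "D4"):
            treated[r] = da

    act = ReceptorActivations(control=act.control, treated=treated)
    state, act2 = apply_apoe(state, genotype, act, ach_halflife_scale=halflife_scale)
    if act2 is not None:
        act = act2

    label = f"{drug.drug}_{drug.dose_mg:g}mg_wk{week:g}"
    if genotype.apoe4_alleles:
        label += f"_apoe{genotype.apoe4_alleles}"
    return Condition(
        label=label, pathology=state, activations=act, memantine=memantine
    )
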