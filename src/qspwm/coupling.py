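"""Map receptor-activation changes onto network biophysics.

Receptor effects enter the network in three ways:

* synaptic scaling — every synapse class carries multiplicative factors
  ``(1 + P ε)`` where ``ε = (A - C)/C`` is the relative activation
  change of the controlling receptor between the treated and control
  condition (D1 and α7 on glutamatergic synapses onto pyramids, D4
  additionally on AMPA onto interneurons, D1/α4β2 on GABA-A onto
  pyramids, 5-HT3 additionally on interneuron-interneuron GABA-A);

* the muscarinic membrane rule — M1 and M2 activation set a resting
  membrane change ``ΔM(mV) = -4 + 6 A_M1 + 2 (1 - A_M2)`` which scales
  the delayed-rectifier conductance as ``g' = g (1 + ΔM P_M1)``;

* the 5-HT6 cascade — 5-HT6 antagonism raises cortical ACh, DA and NE,
  implemented as a multiplicative boost of the dopaminergic,
  muscarinic and nicotinic activations before the rules above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from qspwm.network import AMPA, GABA, NMDA, NetworkGraph

__all__ = [
    "ReceptorActivations",
    "CouplingParams",
    "relative_change",
    "apply_5ht6_cascade",
    "membrane_delta",
    "scale_kdr",
    "apply_couplings",
    "RECEPTORS",
]

#: the receptor set tracked per condition
RECEPTORS = (
    "D1", "D2", "D4",
    "M1", "M2", "a7", "a4b2",
    "a2A",
    "5-HT1A", "5-HT2A", "5-HT3", "5-HT4", "5-HT6",
)

#: receptors touched by the 5-HT6 cascade (DA, ACh mediated)
_CASCADE_TARGETS = ("D1", "D2", "D4", "M1", "M2", "a7", "a4b2")


@dataclass
class ReceptorActivations:
    """Control and treated activation fractions per receptor."""

    control: dict[str, float] = field(default_factory=dict)
    treated: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.control, self.treated):
            for name, a in d.items():
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"activation {name}={a} outside [0, 1]")

    def epsilon(self, receptor: str) -> float:
        """Relative activation change (A - C)/C; 0 if untracked."""
        if receptor not in self.treated or receptor not in self.control:
            return 0.0
        return relative_change(self.treated[receptor], self.control[receptor])

    def copy(self) -> "ReceptorActivations":
        return ReceptorActivations(dict(self.control), dict(self.treated))


@dataclass
class CouplingParams:
    """Calibrated coupling strengths of the receptor rules.

    ``p_m1`` is the Table-level AChE-I coupling (per mV of ΔM);
    ``p_a7`` defaults to twice ``p_a4b2`` (the calibrated relative α7
    versus α4β2 effectiveness of 2).  ``p_5ht6`` is the cascade gain;
    by default antagonism (a *drop* in 5-HT6 activation) *raises* the
    cascade targets, matching the slice pharmacology of 5-HT6 blockers.
    """

    p_d1_syn: float = 0.4
    p_d1_gaba: float = 0.4
    p_d4: float = 0.2
    p_a4b2: float = 0.2
    p_a7: float = 0.4
    p_5ht3: float = 0.2
    p_m1: float = 0.075
    p_5ht6: float = 0.025
    antagonism_raises_modulators: bool = True
    #: a depolarizing ΔM closes K+ channels (raises excitability); the
    #: membrane rule then enters the Kdr scaling with -ΔM.  Switch off
    #: to use the literal printed sign.
    kdr_depolarizing_closes: bool = True


def relative_change(treated: float, control: float) -> float:
    """Normalized activation change (A - C)/C."""
    if control <= 0.0:
        raise ZeroDivisionError("control activation must be > 0")
    return (treated - control) / control


def apply_5ht6_cascade(
    act: ReceptorActivations, p_5ht6: float, antagonism_raises_modulators: bool = True
) -> ReceptorActivations:
    """Propagate a 5-HT6 activation change onto DA/ACh receptor activations.

    Each dopaminergic, muscarinic and nicotinic treated activation is
    multiplied by ``(1 + p_5ht6 * eps)``; with the default sign
    convention ``eps = (C - A)/C`` so that antagonist-reduced 5-HT6
    activation boosts the modulator tone.  Results are clipped to
    [0, 1].
    """
    out = act.copy()
    eps = act.epsilon("5-HT6")
    if antagonism_raises_modulators:
        eps = -eps
    if eps == 0.0:
        return out
    factor = 1.0 + p_5ht6 * eps
    for r in _CASCADE_TARGETS:
        if r in out.treated:
            out.treated[r] = float(np.clip(out.treated[r] * factor, 0.0, 1.0))
    return out


def membrane_delta(a_m1: float, a_m2: float) -> float:
    """Muscarinic resting-membrane change ΔM(mV) = -4 + 6 A_M1 + 2 (1 - A_M2)."""
    if not (0.0 <= a_m1 <= 1.0 and 0.0 <= a_m2 <= 1.0):
        raise ValueError("activations must be in [0, 1]")
    return -4.0 + 6.0 * a_m1 + 2.0 * (1.0 - a_m2)


def scale_kdr(g_kdr: float, delta_m: float, p_m1: float) -> float:
    """Delayed-rectifier scaling g' = g (1 + ΔM * P_M1)."""
    factor = 1.0 + delta_m * p_m1
    if factor <= 0.0:
        raise ValueError("Kdr scaling factor must stay positive; coupling too strong")
    return g_kdr * factor


def apply_couplings(
    net: NetworkGraph,
    act: ReceptorActivations,
    params: CouplingParams | None = None,
) -> NetworkGraph:
    """Return a copy of the network with receptor modulations applied.

    Only the per-synapse ``scale`` column and the per-neuron Kdr scale
    are touched; topology, conductances and every other parameter are
    bit-identical.  Scales are always recomputed from 1, so repeated
    application with the same activations is idempotent.
    """
    params = params or CouplingParams()
    act = apply_5ht6_cascade(
        act, params.p_5ht6, params.antagonism_raises_modulators
    )
    eps = {r: act.epsilon(r) for r in RECEPTORS}

    out = net.copy()
    syn = out.synapses
    syn["scale"] = 1.0
    n_pyr = net.config.n_pyramidal
    post_is_pyr = syn["post"] < n_pyr
    pre_is_int = syn["pre"] >= n_pyr

    f_d1 = 1.0 + params.p_d1_syn * eps["D1"]
    f_a7 = 1.0 + params.p_a7 * eps["a7"]
    f_d4 = 1.0 + params.p_d4 * eps["D4"]
    f_d1g = 1.0 + params.p_d1_gaba * eps["D1"]
    f_a4b2 = 1.0 + params.p_a4b2 * eps["a4b2"]
    f_5ht3 = 1.0 + params.p_5ht3 * eps["5-HT3"]

    glu = (syn["kind"] == AMPA) | (syn["kind"] == NMDA)
    # excitatory onto pyramids: D1 and alpha7 (presynaptic glutamate release)
    m = glu & post_is_pyr
    syn["scale"][m] *= f_d1 * f_a7
    # excitatory onto interneurons: alpha7; AMPA additionally D4
    m = glu & ~post_is_pyr
    syn["scale"][m] *= f_a7
    m = (syn["kind"] == AMPA) & ~post_is_pyr
    syn["scale"][m] *= f_d4
    # GABA-A onto pyramids: D1 (independent coupling) and alpha4beta2
    m = (syn["kind"] == GABA) & post_is_pyr
    syn["scale"][m] *= f_d1g * f_a4b2
    # GABA-A interneuron -> interneuron: alpha4beta2 plus 5-HT3
    m = (syn["kind"] == GABA) & ~post_is_pyr & pre_is_int
    syn["scale"][m] *= f_a4b2 * f_5ht3
    if (syn["scale"] <= 0.0).any():
        raise ValueError("coupling produced a non-positive synaptic scale")

    # muscarinic membrane rule on pyramidal Kdr, relative to the control
    # condition (the calibrated healthy network is the reference state)
    if "M1" in act.treated and "M2" in act.treated:
        dm_treated = membrane_delta(act.treated["M1"], act.treated["M2"])
        dm_control = membrane_delta(act.control["M1"], act.control["M2"])
        dm = dm_treated - dm_control
        if params.kdr_depolarizing_closes:
            dm = -dm
        factor = scale_kdr(1.0, dm, params.p_m1)
        out.kdr_scale[:] = 1.0
        out.kdr_scale[:n_pyr] = factor
    return out
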