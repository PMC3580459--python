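"""Receptor-competition synapse model: binding ODEs, release laws."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qspwm.receptor import (
    IntegrationError,
    LigandSpec,
    PresynapticPhysiology,
    ReceptorPool,
    equilibrium_occupancy,
    facilitation_factor,
    integrate_binding,
    release_amount,
    simulate_synapse,
)


def lig(name, role, kon, kd, conc=0.0):
    return LigandSpec(name, role, kon=kon, Kd=kd, concentration=conc)


class TestEquilibriumOccupancy:
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ([(0.0, 1.0)], [0.0]),                       # no ligand -> no binding
            ([(3.0, 1.0)], [0.75]),                      # C = 3 Kd -> 3/4
            ([(1.0, 1.0), (1.0, 1.0), (2.0, 1.0)], [0.2, 0.2, 0.4]),
            ([(1.0, 1.0), (2.0, 1.0)], [0.25, 0.5]),
        ],
    )
    def test_closed_form(self, ratios, expected):
        ligands = [
            lig(f"L{i}", "drug", 1e-3, kd, conc * kd)
            for i, (conc, kd) in enumerate(ratios)
        ]
        occ = equilibrium_occupancy(ligands)
        assert [occ[f"L{i}"] for i in range(len(ratios))] == pytest.approx(expected)

    def test_koff_is_derived(self):
        ligand = lig("x", "drug", 2e-4, 50.0)
        assert ligand.koff == pytest.approx(2e-4 * 50.0)


class TestIntegrateBinding:
    def _steady_state(self, ligands, dt=0.05, steps=200_000):
        pool = ReceptorPool("p", ligands)
        for _ in range(steps):
            pool = integrate_binding(pool, dt=dt)
        return pool

    def test_single_ligand_at_kd_reaches_half_occupancy(self):
        pool = self._steady_state([lig("a", "drug", 1e-3, 100.0, 100.0)], steps=50_000)
        assert pool.occupancy("a") == pytest.approx(0.5, abs=1e-6)

    def test_two_ligand_competition_matches_oracle(self):
        ligands = [
            lig("a", "drug", 1e-3, 100.0, 100.0),    # C/Kd = 1
            lig("b", "tracer", 5e-4, 50.0, 100.0),   # C/Kd = 2
        ]
        pool = self._steady_state(ligands, steps=50_000)
        assert pool.occupancy("a") == pytest.approx(0.25, abs=1e-6)
        assert pool.occupancy("b") == pytest.approx(0.5, abs=1e-6)
        assert pool.free / pool.R_total == pytest.approx(0.25, abs=1e-6)

    def test_unbinding_only_decays_exponentially(self):
        ligand = lig("a", "drug", 1e-3, 100.0, 0.0)
        pool = ReceptorPool("p", [ligand], bound={"a": 0.5})
        dt, n = 0.05, 2000
        for _ in range(n):
            pool = integrate_binding(pool, dt=dt)
        expected = 0.5 * math.exp(-ligand.koff * dt * n)
        assert pool.occupancy("a") == pytest.approx(expected, rel=1e-6)

    def test_continuity_preserved(self):
        ligands = [lig("a", "drug", 1e-3, 10.0, 50.0), lig("b", "tracer", 1e-3, 5.0, 20.0)]
        pool = ReceptorPool("p", ligands)
        for _ in range(1000):
            pool = integrate_binding(pool, dt=0.02)
            total = sum(pool.bound.values()) + pool.free
            assert total == pytest.approx(pool.R_total, rel=1e-9)

    def test_too_large_step_raises(self):
        pool = ReceptorPool("p", [lig("a", "drug", 1.0, 1000.0, 1000.0)])
        with pytest.raises(IntegrationError):
            p = pool
            for _ in range(100):
                p = integrate_binding(p, dt=10.0)


class TestReleaseAmount:
    def test_at_b0_release_is_baseline(self, simple_phys):
        assert release_amount(simple_phys.B0, simple_phys) == pytest.approx(
            simple_phys.r0
        )

    def test_zero_activation_gives_max(self):
        phys = PresynapticPhysiology(r0=1.0, rmax=0.5, S=2.0, B0=0.5)
        assert release_amount(0.0, phys) == pytest.approx(1.5)

    def test_full_activation_with_sharp_sensitivity(self):
        phys = PresynapticPhysiology(r0=1.0, rmax=0.5, S=7.75, B0=0.2)
        assert release_amount(1.0, phys) == pytest.approx(0.5, abs=1e-4)

    def test_bounded_and_strictly_decreasing(self, simple_phys):
        grid = np.linspace(0.0, 1.0, 101)
        vals = np.array([release_amount(a, simple_phys) for a in grid])
        lo = simple_phys.r0 * (1 - simple_phys.rmax)
        hi = simple_phys.r0 * (1 + simple_phys.rmax)
        assert (vals >= lo - 1e-12).all() and (vals <= hi + 1e-12).all()
        assert (np.diff(vals) < 0).all()

    def test_domain_error(self, simple_phys):
        with pytest.raises(ValueError):
            release_amount(1.5, simple_phys)


class TestFacilitationFactor:
    def test_empty_history_is_unity(self, simple_phys):
        assert facilitation_factor([], now=100.0, phys=simple_phys) == 1.0

    def test_fitted_serotonergic_values(self):
        # one prior spike 90 ms back with the fitted presynaptic set:
        # 1 + 1.1 * 2^-1 - 0.42 * 2^(-90/120)
        phys = PresynapticPhysiology(
            wf=1.1, wd=0.42, f_halflife_ms=90.0, d_halflife_ms=120.0
        )
        expected = 1.0 + 1.1 * 0.5 - 0.42 * 2 ** (-0.75)
        got = facilitation_factor([0.0], now=90.0, phys=phys)
        assert got == pytest.approx(expected, abs=1e-4)
        assert got == pytest.approx(1.3003, abs=1e-3)

    def test_distant_past_decays_to_unity(self, simple_phys):
        assert facilitation_factor([-1e9], now=0.0, phys=simple_phys) == pytest.approx(
            1.0
        )

    def test_unordered_spikes_rejected(self, simple_phys):
        with pytest.raises(ValueError):
            facilitation_factor([10.0, 5.0], now=20.0, phys=simple_phys)


class TestSimulateSynapse:
    def test_deterministic(self, coarse_synapse):
        a = simulate_synapse(coarse_synapse, seed=1)
        b = simulate_synapse(coarse_synapse, seed=1)
        np.testing.assert_array_equal(a.free_nM, b.free_nM)
        for pool in a.occupancy:
            for ligand in a.occupancy[pool]:
                np.testing.assert_array_equal(
                    a.occupancy[pool][ligand], b.occupancy[pool][ligand]
                )

    def test_no_firing_decays_to_zero(self, coarse_synapse):
        cfg = coarse_synapse.with_overrides(tonic_rate_hz=0.0)
        trace = simulate_synapse(cfg)
        assert (np.diff(trace.free_nM) <= 1e-12).all()
        assert trace.free_nM[-1] < 1e-3
        assert trace.occupancy["post"]["NT"][-1] < 1e-3

    def test_constant_concentration_matches_oracle(self, coarse_synapse):
        # no decay, no firing: free NT stays at its initial level and the
        # occupancies must relax to the closed-form competitive equilibrium
        pools = coarse_synapse.pools
        drug = LigandSpec("D", "drug", 1e-3, 50.0, concentration=100.0)
        pools = [replace(pools[0], ligands=pools[0].ligands + [drug], bound={})] + pools[1:]
        cfg = coarse_synapse.with_overrides(
            pools=pools,
            tonic_rate_hz=0.0,
            nt_halflife_ms=1e15,
            equilibration_conc_nM=200.0,
            transient_s=1.0,
            averaging_s=0.0,
        )
        trace = simulate_synapse(cfg)
        expected = equilibrium_occupancy(
            [replace(pools[0].ligands[0], concentration=200.0), drug]
        )
        assert trace.occupancy["post"]["NT"][-1] == pytest.approx(
            expected["NT"], abs=1e-6
        )
        assert trace.occupancy["post"]["D"][-1] == pytest.approx(
            expected["D"], abs=1e-6
        )

    def test_mean_activation_monotone_in_halflife(self, coarse_synapse):
        acts = []
        for hl in (10.0, 20.0, 40.0):
            cfg = coarse_synapse.with_overrides(nt_halflife_ms=hl)
            acts.append(simulate_synapse(cfg).mean_activation["post"]["NT"])
        assert acts[0] < acts[1] < acts[2]

    def test_rk4_step_halving_converges(self, coarse_synapse):
        a = simulate_synapse(coarse_synapse.with_overrides(dt_ms=0.02))
        b = simulate_synapse(coarse_synapse.with_overrides(dt_ms=0.01))
        ma = a.mean_activation["post"]["NT"]
        mb = b.mean_activation["post"]["NT"]
        assert ma == pytest.approx(mb, rel=1e-6)

    def test_autoreceptor_fixed_point(self, coarse_synapse):
        """Tonic release settles where the release law balances decay.

        Independent oracle: solve the self-consistency equation for the
        steady mean autoreceptor activation with a scalar root finder on
        the release-to-activation map.
        """
        from scipy.optimize import brentq

        phys = coarse_synapse.presyn
        cfg = coarse_synapse.with_overrides(
            transient_s=4.0, averaging_s=4.0, quantal_increment_nM=400.0
        )
        trace = simulate_synapse(cfg)
        A_sim = trace.mean_activation["auto"]["NT"]

        kd_auto = cfg.pool("auto").ligands[0].Kd
        period_ms = 1000.0 / cfg.tonic_rate_hz
        tau = cfg.nt_halflife_ms / math.log(2.0)

        def mean_conc(release):
            return release * cfg.quantal_increment_nM * tau / period_ms

        def residual(A):
            c = mean_conc(release_amount(A, phys))
            return c / (c + kd_auto) - A

        A_star = brentq(residual, 1e-6, 1 - 1e-6)
        # the mean-field oracle ignores within-cycle nonlinearity; the
        # simulated mean must sit close to the fixed point
        assert A_sim == pytest.approx(A_star, abs=0.05)


@settings(max_examples=25, deadline=None)
@given(
    a=st.floats(0.0, 1.0),
    rmax=st.floats(0.0, 1.0),
    s=st.floats(0.5, 10.0),
    b0=st.floats(0.05, 1.0),
)
def test_release_amount_always_within_bounds(a, rmax, s, b0):
    phys = PresynapticPhysiology(r0=2.0, rmax=rmax, S=s, B0=b0)
    r = release_amount(a, phys)
    assert 2.0 * (1 - rmax) - 1e-9 <= r <= 2.0 * (1 + rmax) + 1e-9
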