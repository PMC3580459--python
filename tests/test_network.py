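"""Conductance-based network: gating, synapses, structure, integration."""

import math

import numpy as np
import pytest

from qspwm import _netkernel
from qspwm.network import (
    AMPA,
    CHANNELS,
    GABA,
    NMDA,
    NetworkConfig,
    StimulusSpec,
    SynapseSpec,
    adp_current,
    build_network,
    gating_rates,
    mg_block,
    run_simulation,
    synaptic_conductance,
)


class TestGating:
    def test_bounds_over_full_voltage_grid(self):
        V = np.arange(-120.0, 60.001, 1.0)
        for name, channel in CHANNELS.items():
            for gate, (xinf, tau) in gating_rates(channel, V).items():
                assert np.all((xinf >= 0.0) & (xinf <= 1.0)), f"{name}.{gate} xinf"
                assert np.all(tau > 0.0), f"{name}.{gate} tau"
                assert np.all(np.isfinite(xinf)) and np.all(np.isfinite(tau))

    def test_naf_activation_alpha_limit_at_singularity(self):
        # alpha = xinf / tau has a removable singularity at V = -28 mV
        # whose limit is 0.2816 * 9.3
        xinf, tau = gating_rates("Naf", np.array([-28.0]))["m"]
        alpha = xinf / tau
        assert alpha[0] == pytest.approx(0.2816 * 9.3, rel=1e-3)

    def test_ks_activation_midpoint(self):
        xinf, _ = gating_rates("Ks", np.array([-34.0]))["m"]
        assert xinf[0] == pytest.approx(0.5)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            gating_rates("Naf", np.array([np.nan]))


class TestSynapticConductance:
    def spec(self, **kw):
        args = dict(kind=AMPA, pre=0, post=1, gbar=1.0, tau_rise=2.0,
                    tau_decay=10.0, reversal_mV=0.0)
        args.update(kw)
        return SynapseSpec(**args)

    def test_zero_at_release_time(self):
        assert synaptic_conductance(self.spec(), 0.0) == 0.0

    def test_peak_time_closed_form(self):
        s = self.spec()
        t_star = 2.5 * math.log(5.0)  # tau_r tau_d/(tau_d-tau_r) ln(tau_d/tau_r)
        grid = np.linspace(0.01, 30.0, 3000)
        vals = [synaptic_conductance(s, t) for t in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(t_star, abs=0.02)

    def test_vanishes_at_late_times(self):
        assert synaptic_conductance(self.spec(), 1e4) == pytest.approx(0.0, abs=1e-12)

    def test_modulation_scale_multiplies(self):
        s1 = self.spec()
        s2 = self.spec(modulation_scale=1.5)
        assert synaptic_conductance(s2, 5.0) == pytest.approx(
            1.5 * synaptic_conductance(s1, 5.0)
        )

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            self.spec(tau_rise=10.0, tau_decay=2.0)


class TestMgBlock:
    def test_no_magnesium_no_block(self):
        for v in (-80.0, 0.0, 40.0):
            assert mg_block(v, 0.0) == 1.0

    def test_full_block_at_hyperpolarized(self):
        assert mg_block(-200.0, 1.0) < 1e-4

    def test_value_at_zero_mv(self):
        assert mg_block(0.0, 1.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57), rel=1e-6)

    def test_monotone_in_voltage(self):
        vals = [mg_block(v, 1.0) for v in np.linspace(-90, 40, 27)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestAdpCurrent:
    def test_alpha_function_shape(self):
        assert adp_current(0.0, 5.0, 100.0) == 0.0
        assert adp_current(100.0, 5.0, 100.0) == pytest.approx(5.0)
        assert adp_current(500.0, 5.0, 100.0) == pytest.approx(
            5.0 * 5.0 * math.exp(-4.0), rel=1e-9
        )


class TestBuildNetwork:
    def test_population_counts(self):
        net = build_network(0)
        assert net.pyramidal_ids.size == 80
        assert net.interneuron_ids.size == 40
        assert net.stimulated.sum() == 40

    def test_forty_percent_of_interneurons_never_touch_pyramids(self):
        net = build_network(3)
        syn = net.synapses
        n_silent = 0
        for iid in net.interneuron_ids:
            onto_pyr = (syn["pre"] == iid) & (syn["post"] < 80)
            if onto_pyr.sum() == 0:
                n_silent += 1
                assert not net.projecting[iid]
        assert n_silent == 16

    def test_all_to_all_pyramidal_recurrence(self):
        net = build_network(0)
        syn = net.synapses
        pp_ampa = (syn["kind"] == AMPA) & (syn["pre"] < 80) & (syn["post"] < 80)
        assert pp_ampa.sum() == 80 * 80
        pp_nmda = (syn["kind"] == NMDA) & (syn["pre"] < 80) & (syn["post"] < 80)
        assert pp_nmda.sum() == 80 * 80

    def test_synapse_kinds_follow_cell_types(self):
        net = build_network(0)
        syn = net.synapses
        assert (syn["kind"][syn["pre"] < 80] != GABA).all()
        assert (syn["kind"][syn["pre"] >= 80] == GABA).all()

    def test_graph_deterministic_given_seed(self):
        assert build_network(5).graph_hash() == build_network(5).graph_hash()


class TestSingleCompartmentOracle:
    def test_leak_only_relaxation(self):
        """An isolated passive compartment relaxes to the leak reversal
        with the analytic exponential time constant (<= 0.1% error)."""
        dt, n_steps = 0.025, 40_000  # 1 s
        cm, gl, el = 1.0, 0.1, -55.0
        n_tab = 3
        zeros9 = np.zeros((9, n_tab))
        zeros3 = np.zeros((3, n_tab))
        ones9 = np.ones((9, n_tab))
        status, spk_n, spk_t, v_trace, _, _ = _netkernel.run_network_kernel(
            n_steps, 0, dt, 0,
            1, np.array([cm]), np.array([gl]), np.array([el]), np.array([1e-6]),
            np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1),
            np.zeros(1), np.ones(1),
            np.zeros(1, dtype=np.bool_),
            np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64), np.zeros(0),
            -200.0, 1.0, n_tab,
            ones9 * 0.999, zeros9, zeros3 + 0.999, zeros3, np.full(n_tab, 0.999),
            np.zeros(n_tab), np.ones(n_tab),
            0.0, 250.0, 5e-8, 120.0,
            55.0, -80.0,
            0.9, 0.99, 0.9, 0.99, 0.9, 0.99,
            0.3,
            0.0, -70.0, -75.0, 1.0,
            1, 0,
            np.zeros(1, dtype=np.int64),
            np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64),
            np.zeros(1, dtype=np.int64),
            np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((0, 1)),
            np.ones(1, dtype=np.bool_),
            1,
            0.0, np.zeros(1),
            np.zeros(0, dtype=np.int64), 1e9, 0.0, 0.0,
            0.0, 1.0,
            1e9, 80,
            1_000_000,
            True, 40, np.zeros(1, dtype=np.int64),
        )
        assert status == 0
        n_filled = n_steps // 40
        t = np.arange(n_filled)  # ms
        tau = cm / gl  # ms
        expected = el + (-70.0 - el) * np.exp(-t / tau)
        np.testing.assert_allclose(v_trace[:n_filled, 0], expected, rtol=2e-3, atol=0.05)


class TestRunSimulation:
    def test_fixed_seed_bit_identical_raster(self, fast_network_cfg):
        net = build_network(0, fast_network_cfg)
        a = run_simulation(net, 3.5, seed=11)
        b = run_simulation(net, 3.5, seed=11)
        np.testing.assert_array_equal(a.neuron, b.neuron)
        np.testing.assert_array_equal(a.time_ms, b.time_ms)

    def test_different_seed_different_raster(self, fast_network_cfg):
        net = build_network(0, fast_network_cfg)
        a = run_simulation(net, 3.5, seed=11)
        b = run_simulation(net, 3.5, seed=12)
        assert a.neuron.size != b.neuron.size or not np.array_equal(
            a.time_ms, b.time_ms
        )

    def test_raster_sorted_and_in_range(self, fast_network_cfg):
        net = build_network(0, fast_network_cfg)
        res = run_simulation(net, 3.0, seed=2)
        assert (np.diff(res.time_ms) >= 0).all()
        assert res.time_ms.min() >= 0 and res.time_ms.max() <= res.duration_ms

    def test_duration_must_cover_stimulus(self, fast_network_cfg):
        net = build_network(0, fast_network_cfg)
        with pytest.raises(ValueError):
            run_simulation(net, 1.0, seed=0)

    def test_silencing_interneurons_disinhibits(self, fast_network_cfg):
        net = build_network(0, fast_network_cfg)
        res_full = run_simulation(net, 3.5, seed=4)
        silenced = net.copy()
        silenced.alive[80:] = False
        res_dis = run_simulation(silenced, 3.5, seed=4)
        pyr = np.arange(80)
        assert res_dis.spike_count(pyr) > res_full.spike_count(pyr)

    def test_integrator_step_halving_on_isolated_cells(self):
        """Halving dt moves isolated-cell firing by bounded amounts.

        The coupled network is chaotic, so convergence is checked on
        synaptically isolated, noise-free cells under a step current:
        spike counts must agree within 10% and the first spike within
        10 ms across a dt halving (latency to the first spike from a
        slow threshold approach is the most step-sensitive quantity).
        """
        kw = dict(noise_rate_hz=0.0, settle_ms=200.0,
                  g_ampa_pp=0, g_nmda_pp=0, g_ampa_pi=0, g_nmda_pi=0,
                  g_gaba_ip=0, g_gaba_ii=0, adp_amplitude_uA_cm2=0.0)
        stim = StimulusSpec(start_ms=500.0, duration_ms=2000.0,
                            amplitude_uA_cm2=12.0)
        runs = {}
        for dt in (0.025, 0.0125):
            cfg = NetworkConfig(dt_ms=dt, **kw)
            net = build_network(0, cfg)
            runs[dt] = run_simulation(net, 3.0, stim=stim, seed=0)
        a, b = runs[0.025], runs[0.0125]
        ta = a.time_ms[a.neuron == 0]
        tb = b.time_ms[b.neuron == 0]
        assert ta.size == pytest.approx(tb.size, rel=0.10)
        assert abs(ta[0] - tb[0]) < 10.0
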