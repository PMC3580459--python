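"""Span metric, clinical correlation, DOE screening and optimization."""

import numpy as np
import pytest

from qspwm.network import SimulationResult
from qspwm.readout import (
    ClinicalRecord,
    SpanResult,
    correlate_clinical,
    doe_screen,
    load_clinical_table,
    optimize_response_surface,
    sensitivity_scan,
    working_memory_span,
)


def raster(pairs, duration_ms=15000.0):
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        return SimulationResult(
            neuron=np.empty(0, dtype=np.int64),
            time_ms=np.empty(0),
            duration_ms=duration_ms,
            seed=0,
        )
    order = np.argsort(pairs[:, 0])
    return SimulationResult(
        neuron=pairs[order, 1].astype(np.int64),
        time_ms=pairs[order, 0],
        duration_ms=duration_ms,
        seed=0,
    )


def dense_raster(ids, t0_ms, t1_ms, every_ms=50.0):
    return [
        (t, q)
        for q in ids
        for t in np.arange(t0_ms + 1.0, t1_ms, every_ms)
    ]


class TestSpanMetric:
    def test_six_second_block(self):
        """All 40 stimulated cells firing every 50 ms on [2 s, 8 s]."""
        res = raster(dense_raster(range(40), 2000.0, 8000.0))
        assert working_memory_span(res, range(40)) == pytest.approx(6.0)

    def test_exactly_half_does_not_qualify(self):
        # 20 of 40 = M/2 exactly: strict inequality -> span 0
        res = raster(dense_raster(range(20), 2000.0, 8000.0))
        assert working_memory_span(res, range(40)) == 0.0

    def test_twenty_one_qualifies(self):
        res = raster(dense_raster(range(21), 2000.0, 4000.0))
        assert working_memory_span(res, range(40)) == pytest.approx(2.0)

    def test_empty_raster_is_zero(self):
        assert working_memory_span(raster([]), range(40)) == 0.0

    def test_invariant_to_row_order_and_distractors(self):
        spikes = dense_raster(range(40), 2000.0, 8000.0)
        res_sorted = raster(spikes)
        rng = np.random.default_rng(0)
        shuffled = [spikes[i] for i in rng.permutation(len(spikes))]
        # distractor spikes from non-stimulated neurons
        shuffled += dense_raster(range(50, 90), 500.0, 14000.0, every_ms=20.0)
        res_noisy = raster(shuffled)
        assert working_memory_span(res_sorted, range(40)) == working_memory_span(
            res_noisy, range(40)
        )

    def test_gap_counts_end_to_end(self):
        # qualifying bins at [2, 4] and [8, 10] s: the span runs from the
        # first to the last transition
        spikes = dense_raster(range(40), 2000.0, 4000.0)
        spikes += dense_raster(range(40), 8000.0, 10000.0)
        res = raster(spikes)
        assert working_memory_span(res, range(40)) == pytest.approx(8.0)


def spanres(label, mean):
    return SpanResult(label=label, spans_s=np.array([mean]), n_trials=1)


class TestCorrelation:
    def test_perfect_collinear_points(self):
        spans = [spanres(f"c{i}", x) for i, x in enumerate([1.0, 2.0, 3.0])]
        recs = [ClinicalRecord("d", 0, 12, y) for y in [-1.0, -2.0, -3.0]]
        fit = correlate_clinical(spans, recs)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        spans = [spanres(f"c{i}", 2.0) for i in range(4)]
        recs = [ClinicalRecord("d", 0, 12, y) for y in [1.0, 2.0, 3.0, 4.0]]
        with pytest.raises(ValueError, match="variance"):
            correlate_clinical(spans, recs)

    def test_four_point_normal_equation_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([0.5, -1.0, -2.5, -4.5])
        # closed-form least squares
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        spans = [spanres(f"c{i}", xi) for i, xi in enumerate(x)]
        recs = [ClinicalRecord("d", 0, 12, yi) for yi in y]
        fit = correlate_clinical(spans, recs)
        assert fit.slope == pytest.approx(beta[0])
        assert fit.intercept == pytest.approx(beta[1])

    def test_quadratic_never_fits_worse(self):
        rng = np.random.default_rng(1)
        x = np.linspace(1, 10, 12)
        y = -2 * x + rng.normal(0, 1.0, 12)
        spans = [spanres(f"c{i}", xi) for i, xi in enumerate(x)]
        recs = [ClinicalRecord("d", 0, 12, yi) for yi in y]
        f1 = correlate_clinical(spans, recs, degree=1)
        f2 = correlate_clinical(spans, recs, degree=2)
        assert f2.r2 >= f1.r2

    def test_too_few_points(self):
        spans = [spanres("a", 1.0), spanres("b", 2.0)]
        recs = [ClinicalRecord("d", 0, 12, 0.0)] * 2
        with pytest.raises(ValueError):
            correlate_clinical(spans, recs)


class TestDoeScreen:
    def ranges(self, n=7):
        return {f"p{i}": (0.0, 1.0) for i in range(n)}

    def test_seven_factors_fourteen_runs(self):
        table = doe_screen(self.ranges(), lambda p: 0.0)
        assert table.attrs["n_runs"] == 14

    def test_planted_factor_tops_pareto(self):
        table = doe_screen(self.ranges(), lambda p: 5.0 * p["p3"] + 0.1 * p["p0"])
        assert table.iloc[0]["parameter"] == "p3"
        # fold-over cyclic designs carry a small (1/n) cross-factor
        # contamination from the secondary effect
        assert table.iloc[0]["effect"] == pytest.approx(5.0, abs=0.05)

    def test_constant_response_all_zero(self):
        table = doe_screen(self.ranges(), lambda p: 42.0)
        assert np.allclose(table["effect"], 0.0)

    def test_nonfinite_responses_flagged(self):
        calls = {"n": 0}

        def resp(p):
            calls["n"] += 1
            return np.nan if calls["n"] == 1 else p["p0"]

        table = doe_screen(self.ranges(), resp)
        assert table["flagged"].any()

    def test_identical_levels_rejected(self):
        with pytest.raises(ValueError):
            doe_screen({"a": (1.0, 1.0), "b": (0.0, 1.0)}, lambda p: 0.0)


class TestResponseSurface:
    def test_quadratic_bowl_optimum(self):
        target = {"a": 2.0, "b": -3.0}

        def resp(p):
            return -((p["a"] - 2.0) ** 2) - (p["b"] + 3.0) ** 2

        best, trace = optimize_response_surface(
            {"a": 1.0, "b": -2.0}, resp, budget=50
        )
        assert len(trace) <= 50
        assert best["a"] == pytest.approx(2.0, rel=0.02, abs=0.02)
        assert best["b"] == pytest.approx(-3.0, rel=0.02, abs=0.02)

    def test_budget_one_returns_start(self):
        best, trace = optimize_response_surface({"a": 1.0}, lambda p: p["a"], budget=1)
        assert best == {"a": 1.0}
        assert len(trace) == 1

    def test_trace_never_exceeds_budget(self):
        _, trace = optimize_response_surface(
            {"a": 1.0, "b": 1.0}, lambda p: p["a"] + p["b"], budget=17
        )
        assert len(trace) <= 17


class TestSensitivityScan:
    def test_single_point_equals_base_response(self):
        curve = sensitivity_scan("a", [1.0], {"a": 1.0, "b": 2.0},
                                 lambda p: p["a"] + p["b"])
        assert curve.iloc[0]["response"] == 3.0

    def test_monotone_response_monotone_curve(self):
        curve = sensitivity_scan("a", [1, 2, 3, 4], {"a": 0.0},
                                 lambda p: 2 * p["a"])
        assert (np.diff(curve["response"]) > 0).all()

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_scan("a", [], {"a": 1.0}, lambda p: 0.0)


class TestClinicalTable:
    def test_shipped_fixture_has_28_conditions(self):
        records = load_clinical_table()
        assert len(records) == 28
        assert {r.weeks for r in records} == {12.0, 26.0, 52.0, 78.0}
        drugs = {r.drug.lower() for r in records}
        assert drugs == {
            "placebo", "donepezil", "galantamine", "rivastigmine", "sb-742457"
        }

    def test_known_rows(self):
        records = load_clinical_table()
        by_key = {(r.drug.lower(), r.dose_mg, r.weeks): r.adascog_effect
                  for r in records}
        assert by_key[("placebo", 0.0, 12.0)] == pytest.approx(0.27)
        assert by_key[("donepezil", 5.0, 12.0)] == pytest.approx(-1.77)
        assert by_key[("placebo", 0.0, 78.0)] == pytest.approx(7.10)
        assert by_key[("sb-742457", 35.0, 26.0)] == pytest.approx(-1.12)
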