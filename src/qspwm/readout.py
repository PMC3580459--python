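"""Working-memory span readout, condition runner and clinical calibration.

The span metric divides the time axis into 200 ms bins, counts the
distinct stimulated neurons firing in each bin, and takes the time
between the first and last bin in which that count strictly exceeds
M/2 (M = number of stimulated cells).  Conditions from the clinical
table are simulated over multiple seeds and correlated against the
printed ADAS-Cog effects; the free parameters are screened with a
two-level factorial design and refined on the local response surface.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from qspwm.coupling import CouplingParams, apply_couplings
from qspwm.network import (
    NetworkConfig,
    SimulationResult,
    StimulusSpec,
    build_network,
    run_simulation,
)
from qspwm.pathology import (
    Condition,
    Intervention,
    apply_lesion,
    apply_memantine,
    build_condition,
)

__all__ = [
    "ClinicalRecord",
    "SpanResult",
    "CalibrationResult",
    "working_memory_span",
    "run_condition",
    "correlate_clinical",
    "doe_screen",
    "optimize_response_surface",
    "sensitivity_scan",
    "load_clinical_table",
    "clinical_conditions",
    "MECHANISM_BY_DRUG",
]

MECHANISM_BY_DRUG = {
    "placebo": "placebo",
    "donepezil": "AChE-I",
    "galantamine": "AChE-I",
    "rivastigmine": "AChE-I",
    "sb-742457": "5HT6-antagonist",
    "memantine": "memantine",
}


@dataclass
class ClinicalRecord:
    """One row of the clinical calibration table."""

    drug: str
    dose_mg: float
    weeks: float
    adascog_effect: float


@dataclass
class SpanResult:
    """Per-seed spans of one condition."""

    label: str
    spans_s: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.spans_s = np.asarray(self.spans_s, dtype=float)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def mean(self) -> float:
        return float(self.spans_s.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation; NaN flags a single-trial result."""
        if self.n_trials < 2:
            return float("nan")
        return float(self.spans_s.std(ddof=1))


@dataclass
class CalibrationResult:
    """Linear (or quadratic) fit of ADAS-Cog effects against spans."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    degree: int
    coeffs: np.ndarray
    n_points: int
    per_week: dict[float, dict[str, float]] = field(default_factory=dict)


def working_memory_span(
    result: SimulationResult,
    stimulated_ids,
    M: int | None = None,
    bin_ms: float = 200.0,
) -> float:
    """Span (s) of sustained synchronous firing of the stimulated set.

    Counts distinct stimulated neurons per ``bin_ms`` window; a bin
    qualifies when the count strictly exceeds M/2.  The span runs from
    the start of the first qualifying bin to the end of the last; no
    qualifying bin (or an empty raster) gives 0.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    stimulated_ids = np.asarray(list(stimulated_ids), dtype=np.int64)
    if M is None:
        M = stimulated_ids.size
    if result.neuron.size == 0:
        return 0.0
    mask = np.isin(result.neuron, stimulated_ids)
    t = result.time_ms[mask]
    n = result.neuron[mask]
    n_bins = int(result.duration_ms // bin_ms)
    if n_bins == 0:
        return 0.0
    bins = (t // bin_ms).astype(np.int64)
    ok = bins < n_bins
    bins, n = bins[ok], n[ok]
    # distinct neurons per bin
    pair = bins * 1_000_000 + n
    uniq_bins = np.unique(pair) // 1_000_000
    counts = np.bincount(uniq_bins.astype(np.int64), minlength=n_bins)
    qual = np.where(counts > M / 2.0)[0]
    if qual.size == 0:
        return 0.0
    return float((qual[-1] + 1 - qual[0]) * bin_ms / 1000.0)


def run_condition(
    condition: Condition,
    n_trials: int = 10,
    base_seed: int = 0,
    cfg: NetworkConfig | None = None,
    params: CouplingParams | None = None,
    duration_s: float = 15.0,
    stim: StimulusSpec | None = None,
    graph_seed: int = 0,
) -> SpanResult:
    """Simulate a condition over ``n_trials`` seeded trials.

    Per trial k the lesion and the network noise both derive from
    ``base_seed + k``, so the whole result is reproducible from
    (condition, n_trials, base_seed).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = cfg or NetworkConfig()
    base_net = build_network(graph_seed, cfg)
    spans = np.empty(n_trials)
    for k in range(n_trials):
        seed = base_seed + k
        try:
            net = apply_lesion(base_net, condition.pathology, seed)
            net = apply_couplings(net, condition.activations, params)
            if condition.memantine is not None:
                net = apply_memantine(net, *condition.memantine)
            res = run_simulation(net, duration_s, stim=stim, seed=seed)
        except Exception as exc:  # annotate with condition context
            raise RuntimeError(
                f"condition {condition.label!r} failed at seed {seed}"
            ) from exc
        sids = np.where(net.stimulated & net.alive)[0]
        spans[k] = working_memory_span(res, sids)
    return SpanResult(label=condition.label, spans_s=spans, n_trials=n_trials)


def correlate_clinical(
    spans: list[SpanResult],
    clinical: list[ClinicalRecord],
    degree: int = 1,
) -> CalibrationResult:
    """Least-squares fit of ADAS-Cog effect against mean span.

    Returns the global slope (ADAS-Cog points per span-second for
    degree 1), r-squared and the regression F-test p-value, plus
    per-week sub-fits for weeks 12/26/52 when enough points exist.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(spans) != len(clinical):
        raise ValueError("need exactly one span result per clinical record")
    if len(spans) < 3:
        raise ValueError("need at least 3 points to fit")
    x = np.array([s.mean for s in spans])
    y = np.array([c.adascog_effect for c in clinical])
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero span variance: fit undefined")

    def fit(xv, yv, deg):
        coeffs = np.polyfit(xv, yv, deg)
        yhat = np.polyval(coeffs, xv)
        ss_res = float(np.sum((yv - yhat) ** 2))
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        n, k = len(xv), deg
        if ss_res <= 0 or n <= k + 1:
            p = 0.0
        else:
            f = (ss_tot - ss_res) / k / (ss_res / (n - k - 1))
            p = float(stats.f.sf(f, k, n - k - 1))
        return coeffs, r2, p

    coeffs, r2, p = fit(x, y, degree)
    slope = float(coeffs[-2])
    per_week: dict[float, dict[str, float]] = {}
    for week in (12.0, 26.0, 52.0):
        idx = [i for i, c in enumerate(clinical) if c.weeks == week]
        if len(idx) >= 3 and np.std(x[idx]) > 0:
            cw, r2w, pw = fit(x[idx], y[idx], 1)
            per_week[week] = {"slope": float(cw[0]), "r2": r2w, "p": pw}
    return CalibrationResult(
        slope=slope,
        intercept=float(coeffs[-1]),
        r2=r2,
        p_value=p,
        degree=degree,
        coeffs=coeffs,
        n_points=len(x),
        per_week=per_week,
    )


# --------------------------------------------------------------------------
# design of experiments
# --------------------------------------------------------------------------

def _two_level_design(n_factors: int) -> np.ndarray:
    """Cyclic two-level design with fold-over: 2n runs for n factors."""
    base = np.full(n_factors, -1.0)
    # quadratic residues mod n mark the + levels of the generator row
    residues = {(i * i) % n_factors for i in range(1, n_factors)}
    for r in residues:
        base[r] = 1.0
    rows = [np.roll(base, k) for k in range(n_factors)]
    X = np.array(rows)
    return np.vstack([X, -X])  # fold-over pairs


def doe_screen(
    param_ranges: dict[str, tuple[float, float]],
    response,
) -> pd.DataFrame:
    """Two-level factorial screening of the calibration drivers.

    Evaluates ``response(params_dict)`` on a 2n-run fold-over design
    (n = number of factors) and returns the main effects ranked by
    magnitude (a Pareto table).  Non-finite responses are dropped from
    the effect estimate with a flag.
    """
    names = list(param_ranges)
    for nm, (lo, hi) in param_ranges.items():
        if lo == hi:
            raise ValueError(f"range for {nm!r} has identical levels")
    n = len(names)
    design = _two_level_design(n)
    lows = np.array([param_ranges[nm][0] for nm in names])
    highs = np.array([param_ranges[nm][1] for nm in names])
    ys = np.empty(design.shape[0])
    for i, row in enumerate(design):
        values = np.where(row > 0, highs, lows)
        ys[i] = response(dict(zip(names, values)))
    finite = np.isfinite(ys)
    effects = []
    for j, nm in enumerate(names):
        hi_mask = (design[:, j] > 0) & finite
        lo_mask = (design[:, j] < 0) & finite
        if hi_mask.sum() == 0 or lo_mask.sum() == 0:
            effects.append((nm, np.nan, True))
            continue
        eff = ys[hi_mask].mean() - ys[lo_mask].mean()
        effects.append((nm, eff, not finite.all()))
    table = pd.DataFrame(effects, columns=["parameter", "effect", "flagged"])
    table["abs_effect"] = table["effect"].abs()
    table = table.sort_values("abs_effect", ascending=False, ignore_index=True)
    table.attrs["n_runs"] = design.shape[0]
    table.attrs["responses"] = ys
    return table


def optimize_response_surface(
    start: dict[str, float],
    response,
    budget: int = 50,
    rel_step: float = 0.15,
) -> tuple[dict[str, float], list[tuple[dict[str, float], float]]]:
    """Local response-surface ascent of the calibration objective.

    Greedy coordinate refinement: each iteration probes one parameter
    up/down by ``rel_step`` (shrinking on failure) and keeps strict
    improvements; stops when the evaluation budget is exhausted.
    Returns the best parameter vector and the full evaluation trace.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    names = list(start)
    x = dict(start)
    trace: list[tuple[dict[str, float], float]] = []

    def ev(p):
        val = response(dict(p))
        trace.append((dict(p), float(val)))
        return val

    best = ev(x)
    step = rel_step
    j = 0
    while len(trace) < budget:
        nm = names[j % len(names)]
        improved = False
        for sign in (+1.0, -1.0):
            if len(trace) >= budget:
                break
            cand = dict(x)
            base = cand[nm]
            cand[nm] = base * (1.0 + sign * step) if base != 0 else sign * step
            val = ev(cand)
            if val > best:
                x, best = cand, val
                improved = True
                break
        if not improved and j % len(names) == len(names) - 1:
            step *= 0.5
            if step < 1e-4:
                break
        j += 1
    return x, trace


def sensitivity_scan(
    param: str,
    values,
    base: dict[str, float],
    response,
) -> pd.DataFrame:
    """One-at-a-time response curve around a base parameter vector."""
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    rows = []
    for v in values:
        p = dict(base)
        p[param] = v
        rows.append((v, float(response(p))))
    return pd.DataFrame(rows, columns=[param, "response"])


# --------------------------------------------------------------------------
# clinical table
# --------------------------------------------------------------------------

def load_clinical_table(path=None) -> list[ClinicalRecord]:
    """The 28-condition ADAS-Cog table (drug, dose, week, effect)."""
    if path is None:
        ref = importlib.resources.files("qspwm.data") / "clinical_adascog.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        ClinicalRecord(
            drug=str(r.drug),
            dose_mg=float(r.dose_mg),
            weeks=float(r.weeks),
            adascog_effect=float(r.adascog_effect),
        )
        for r in df.itertuples()
    ]


def clinical_conditions(
    records: list[ClinicalRecord] | None = None, **build_kwargs
) -> list[tuple[ClinicalRecord, Condition]]:
    """Turn clinical rows into runnable conditions."""
    records = records if records is not None else load_clinical_table()
    out = []
    for rec in records:
        mech = MECHANISM_BY_DRUG[rec.drug.lower()]
        drug = Intervention(rec.drug.lower(), rec.dose_mg, mech)
        cond = build_condition(drug, rec.weeks, **build_kwargs)
        out.append((rec, cond))
    return out
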