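"""Trace-level degradation kinetics.

The central routine is an exhaustive grid-search fit of normalized decay
traces to a sum of two exponentials,

    F(t) = A * [ f * exp(-dt / tau1) + (1 - f) * exp(-dt / tau2) ],

with dt the time since inducer addition.  The amplitude A is fixed to the
normalized reference value (1.0 by construction), so the search has exactly
three parameters: the two time constants and the fraction f.  The reported
headline constant is that of the major pool (fraction >= 0.5); minor pools
are typically an order of magnitude slower and absorb secondary processes
such as photobleaching.

Also here: normalization to the last pre-inducer time point, two-level
population averaging (synapses -> neuron -> population), initial-rate
linear fits over the first five post-inducer points, per-synapse
correlation and loss-delta analyses, and the group statistics (Welch t,
Wilcoxon rank-sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedTrace",
    "GridSpec",
    "BiexpFit",
    "InitialRate",
    "CorrelationResult",
    "normalize_to_reference",
    "normalize_table",
    "population_average",
    "biexp_model",
    "fit_biexponential",
    "fit_initial_rate",
    "per_synapse_correlation",
    "loss_delta_analysis",
    "group_compare",
]


@dataclass
class NormalizedTrace:
    """A fluorescence trace divided by its last pre-inducer value."""

    trace_id: int | str
    times_h: np.ndarray
    values: np.ndarray
    reference_index: int
    inducer_time_h: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def normalize_to_reference(
    times_h,
    values,
    inducer_time_h: float,
    trace_id: int | str = 0,
) -> NormalizedTrace:
    """Divide a trace by its value at the last time point before the inducer.

    Raises if no pre-inducer point exists or the reference value is not a
    positive finite number (such traces are dropped by the table-level
    wrapper with a log entry).
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    pre = np.flatnonzero(t < inducer_time_h)
    if pre.size == 0:
        raise ValueError("no time point precedes the inducer")
    ref_idx = int(pre[-1])
    ref = v[ref_idx]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"non-positive reference value {ref}")
    return NormalizedTrace(trace_id, t, v / ref, ref_idx, inducer_time_h)


def normalize_table(
    table: pd.DataFrame,
    inducer_time_h: float,
    id_cols: tuple[str, ...] = ("punctum_id", "channel"),
    time_col: str = "time_h",
    value_col: str = "corrected",
) -> pd.DataFrame:
    """Apply reference normalization per trace in a long-format table.

    Traces with a non-positive reference value are dropped (logged).
    Adds a ``normalized`` column.
    """
    out = []
    present = [c for c in id_cols if c in table.columns]
    for key, grp in table.groupby(list(present), sort=False):
        grp = grp.sort_values(time_col)
        try:
            tr = normalize_to_reference(
                grp[time_col].to_numpy(), grp[value_col].to_numpy(),
                inducer_time_h,
            )
        except ValueError as e:
            log.warning("dropping trace %s: %s", key, e)
            continue
        grp = grp.copy()
        grp["normalized"] = tr.values
        out.append(grp)
    if not out:
        return table.iloc[0:0].assign(normalized=np.nan)
    return pd.concat(out, ignore_index=True)


def population_average(
    table: pd.DataFrame,
    time_col: str = "time_h",
    value_col: str = "normalized",
    neuron_col: str = "neuron_id",
    synapse_col: str = "punctum_id",
) -> pd.DataFrame:
    """Two-level average: synapses within a neuron first, then across neurons.

    Matches the convention of plotting one mean trace per neuron and a
    population mean +/- sd across neurons.  All traces must share a common
    time grid.  Returns columns ``time_h, mean, sd, n_neurons``.
    """
    if neuron_col not in table.columns:
        table = table.assign(**{neuron_col: 0})
    per_neuron = (
        table.groupby([neuron_col, time_col])[value_col].mean().reset_index()
    )
    grids = per_neuron.groupby(neuron_col)[time_col].apply(
        lambda s: tuple(np.sort(s.unique()))
    )
    if grids.nunique() != 1:
        raise ValueError("traces do not share a common time grid")
    pop = per_neuron.groupby(time_col)[value_col].agg(
        mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
        n_neurons="count",
    )
    return pop.reset_index()


# --------------------------------------------------------------------------
# biexponential grid-search fitter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Search grid for the biexponential fitter.

    Time constants are laid out logarithmically with ``steps_per_decade``
    points per decade over ``[tau_min, tau_max]`` hours; the fraction f is
    stepped linearly.  tau1 <= tau2 is enforced, which halves the search
    without loss of generality (the model is symmetric under swapping
    (tau1, f) with (tau2, 1-f)).
    """

    tau_min: float = 0.1
    tau_max: float = 1000.0
    steps_per_decade: int = 40
    f_step: float = 0.01

    def tau_grid(self) -> np.ndarray:
        n_dec = np.log10(self.tau_max / self.tau_min)
        n = int(round(n_dec * self.steps_per_decade)) + 1
        return np.logspace(
            np.log10(self.tau_min), np.log10(self.tau_max), n
        )

    def f_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.f_step)) + 1
        return np.linspace(0.0, 1.0, n)

    def refine(self, factor: int = 2) -> "GridSpec":
        return GridSpec(
            self.tau_min, self.tau_max,
            self.steps_per_decade * factor, self.f_step / factor,
        )


@dataclass
class BiexpFit:
    """Result of the two-pool exponential grid fit.

    Components are ordered so the major pool (fraction >= 0.5) is reported
    first; ties go to the faster component.  ``boundary_hit`` is set when
    an optimal time constant lies on a grid edge, ``non_decaying`` when the
    best model declines by less than 1% over the fitted window.
    """

    f_major: float
    tau_major: float
    tau_minor: float
    amplitude: float
    ssr: float
    grid: GridSpec
    boundary_hit: bool = False
    non_decaying: bool = False
    n_points: int = 0

    def predict(self, dt_h) -> np.ndarray:
        return biexp_model(
            np.asarray(dt_h, dtype=float), self.amplitude,
            self.f_major, self.tau_major, self.tau_minor,
        )


def biexp_model(dt: np.ndarray, amplitude: float, f: float,
                tau1: float, tau2: float) -> np.ndarray:
    """Two-pool exponential decay evaluated at times since inducer."""
    return amplitude * (
        f * np.exp(-dt / tau1) + (1.0 - f) * np.exp(-dt / tau2)
    )


def fit_biexponential(
    times_h,
    values,
    inducer_time_h: float = 0.0,
    grid: GridSpec | None = None,
    amplitude: float = 1.0,
) -> BiexpFit:
    """Exhaustive grid search minimising the sum of squared residuals.

    Only points at or after the inducer time enter the fit (dt >= 0); at
    least four are required.  The search covers every (tau1 <= tau2, f)
    grid combination; the quadratic structure in f lets the SSR over the
    whole grid be evaluated from two Gram matrices, so exhaustiveness costs
    only milliseconds.

    Pairs with a missing (NaN) value are dropped, not interpolated.
    """
    grid = grid or GridSpec()
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y) & (t >= inducer_time_h)
    t, y = t[keep], y[keep]
    if t.size < 4:
        raise ValueError("need at least 4 post-inducer points")
    dt = t - inducer_time_h

    taus = grid.tau_grid()
    fs = grid.f_grid()
    # E[i, k] = exp(-dt_k / tau_i); model = A (f E_i + (1-f) E_j)
    E = np.exp(-dt[None, :] / taus[:, None])
    G = (amplitude**2) * (E @ E.T)          # Gram matrix over tau pairs
    b = amplitude * (E @ y)                 # cross terms with the data
    yy = float(y @ y)

    Gd = np.diag(G)
    best = (np.inf, 0, 0, 0.0)
    iu = np.triu_indices(len(taus))         # tau1 index <= tau2 index
    for f in fs:
        g = 1.0 - f
        ssr = (
            f * f * Gd[:, None] + g * g * Gd[None, :]
            + 2.0 * f * g * G - 2.0 * f * b[:, None] - 2.0 * g * b[None, :]
            + yy
        )
        ssr_u = ssr[iu]
        k = int(np.argmin(ssr_u))
        if ssr_u[k] < best[0]:
            best = (float(ssr_u[k]), int(iu[0][k]), int(iu[1][k]), float(f))

    ssr_min, i1, i2, f1 = best
    tau1, tau2 = float(taus[i1]), float(taus[i2])
    # two components within one grid step are not identifiable: collapse
    # to a single pool at the fraction-weighted (geometric) time constant
    step = taus[1] / taus[0]
    if 0.0 < f1 < 1.0 and tau2 / tau1 <= step * (1 + 1e-9):
        tau1 = tau2 = float(np.exp(
            f1 * np.log(tau1) + (1.0 - f1) * np.log(tau2)
        ))
        f1 = 1.0
    # report the major pool (fraction >= 0.5); tie -> faster component
    if f1 > 0.5 or (f1 == 0.5 and tau1 <= tau2):
        f_major, tau_major, tau_minor = f1, tau1, tau2
    else:
        f_major, tau_major, tau_minor = 1.0 - f1, tau2, tau1

    edge = {0, len(taus) - 1}
    boundary = (f1 > 0 and i1 in edge) or (f1 < 1 and i2 in edge)
    # a trace whose OLS slope over the fitted window is non-negative does
    # not decay; the fitter then parks tau at the upper grid bound
    slope = np.polyfit(dt, y, 1)[0] if np.ptp(dt) > 0 else 0.0
    non_decaying = bool(slope >= -1e-12 * max(1.0, float(np.abs(y).max())))
    return BiexpFit(
        f_major=f_major, tau_major=tau_major, tau_minor=tau_minor,
        amplitude=amplitude, ssr=max(ssr_min, 0.0), grid=grid,
        boundary_hit=bool(boundary), non_decaying=non_decaying,
        n_points=int(t.size),
    )


# --------------------------------------------------------------------------
# initial rates, correlations, group statistics
# --------------------------------------------------------------------------

@dataclass
class InitialRate:
    """OLS slope over the first five post-inducer points (absolute units)."""

    slope: float           # a.u. per hour
    intercept: float       # a.u.
    n_points: int
    residual_ss: float


def fit_initial_rate(times_h, values, inducer_time_h: float) -> InitialRate:
    """Linear fit to the first 5 time points after inducer addition.

    Operates on absolute (non-normalized) fluorescence, which scales
    linearly with protein quantity.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    post = np.flatnonzero(t > inducer_time_h)
    if post.size < 5:
        raise ValueError("need at least 5 post-inducer points")
    sel = post[:5]
    slope, intercept = np.polyfit(t[sel], y[sel], 1)
    resid = y[sel] - (slope * t[sel] + intercept)
    return InitialRate(float(slope), float(intercept), 5,
                       float(resid @ resid))


@dataclass
class CorrelationResult:
    """Pooled Pearson correlation plus per-group correlations."""

    r: float
    p: float
    n: int
    per_group_r: list[float] = field(default_factory=list)
    per_group_mean: float = np.nan
    per_group_sd: float = np.nan


def per_synapse_correlation(
    values_a, values_b, grouping=None
) -> CorrelationResult:
    """Pearson correlation pooled across synapses, and per neuron.

    ``grouping`` assigns each pair to a neuron; per-neuron correlations are
    summarised as mean +/- sd (groups with fewer than 3 pairs or zero
    variance are skipped).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(a, b)
    res = CorrelationResult(float(r), float(p), int(a.size))
    if grouping is not None:
        g = np.asarray(grouping)
        rs = []
        for key in pd.unique(g):
            m = g == key
            if m.sum() < 3 or np.std(a[m]) == 0 or np.std(b[m]) == 0:
                continue
            rs.append(float(stats.pearsonr(a[m], b[m])[0]))
        res.per_group_r = rs
        if rs:
            res.per_group_mean = float(np.mean(rs))
            res.per_group_sd = float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0
    return res


def loss_delta_analysis(
    ref_a, end_a, ref_b, end_b, ids=None, grouping=None
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Per-synapse absolute fluorescence loss in two channels.

    Delta = value at the reference time point minus value at the end time
    point, per channel, in absolute units.  The ratio delta_b / delta_a is
    reported where delta_a is nonzero (NaN otherwise), and the co-loss
    correlation is computed with :func:`per_synapse_correlation`.
    """
    ra = np.asarray(ref_a, dtype=float)
    ea = np.asarray(end_a, dtype=float)
    rb = np.asarray(ref_b, dtype=float)
    eb = np.asarray(end_b, dtype=float)
    if not (ra.shape == ea.shape == rb.shape == eb.shape):
        raise ValueError("all four inputs must have equal length")
    if np.any(~np.isfinite(ea)) or np.any(~np.isfinite(eb)):
        raise ValueError("missing end-point measurements")
    da, db = ra - ea, rb - eb
    ratio = np.where(da != 0, db / np.where(da == 0, np.nan, da), np.nan)
    table = pd.DataFrame(
        {
            "synapse_id": np.arange(da.size) if ids is None else ids,
            "delta_a": da,
            "delta_b": db,
            "ratio": ratio,
        }
    )
    try:
        corr = per_synapse_correlation(da, db, grouping)
    except ValueError as e:
        log.warning("co-loss correlation undefined: %s", e)
        corr = None
    return table, corr


def group_compare(group_a, group_b, test: str = "welch_t"):
    """Two-sided comparison of two samples.

    ``welch_t``: unequal-variance t-test (Welch-Satterthwaite df).
    ``wilcoxon``: Wilcoxon rank-sum / Mann-Whitney U, exact for small
    samples without ties, normal approximation otherwise.
    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("welch t-test needs >= 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="auto")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
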