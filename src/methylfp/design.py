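"""Assay design: signal window, optimal reporter concentration, standard curve.

The ΔFP window is the difference between the reporter titration curves against
pure product and pure substrate tracer; it is the usable signal of the coupled
enzyme assay.  In the trace-tracer limit the window is maximised at a reporter
concentration equal to the geometric mean of the two dissociation constants,
√(K_A·K_B); at finite tracer the true optimum shifts slightly, so the numeric
argmax is computed and compared against the analytic value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq, minimize_scalar

from .binding import (LigandMixture, ReporterSpec, _free_protein_grid,
                      fp_signal, solve_equilibrium)
from .exceptions import ValidationError

__all__ = [
    "delta_fp",
    "OptimumResult",
    "optimal_reporter_conc",
    "working_window",
    "StandardCurve",
    "standard_curve",
]

#: numeric optimum flagged when it deviates from √(K_A·K_B) by more than this
ANALYTIC_DEVIATION_FLAG = 0.05
#: log-spaced grid size for the coarse argmax search
_GRID_POINTS = 400


def delta_fp(reporter: ReporterSpec, tracer_total: float,
             reporter_conc: float) -> float:
    """Signal window ΔFP = FP(100% product) − FP(0% product), in mP.

    Non-negative whenever ``K_A >= K_B`` (the enforced convention) and zero at
    ``reporter_conc = 0`` or ``K_A = K_B``.
    """
    if reporter_conc < 0:
        raise ValidationError("reporter_conc must be >= 0")
    if reporter_conc == 0:
        return 0.0
    mp = [
        fp_signal(reporter, solve_equilibrium(
            reporter, LigandMixture(tracer_total, x), reporter_conc))
        for x in (0.0, 1.0)
    ]
    return mp[1] - mp[0]


def _delta_fp_grid(reporter: ReporterSpec, tracer_total: float,
                   concs: np.ndarray) -> np.ndarray:
    """ΔFP on an array of reporter concentrations via vectorized bisection."""
    concs = np.asarray(concs, dtype=float)
    p1 = _free_protein_grid(concs, (tracer_total,), (reporter.kd_product,))
    p0 = _free_protein_grid(concs, (tracer_total,), (reporter.kd_substrate,))
    frac1 = p1 / (reporter.kd_product + p1)
    frac0 = p0 / (reporter.kd_substrate + p0)
    return reporter.window * (frac1 - frac0)


@dataclass(frozen=True)
class OptimumResult:
    """Numeric ΔFP optimum with the analytic trace-limit reference."""

    conc: float             # numeric argmax of ΔFP, µM
    analytic_conc: float    # √(K_A·K_B), µM
    delta_fp_max: float     # ΔFP at the numeric optimum, mP
    relative_deviation: float
    zero_window: bool = False


def optimal_reporter_conc(reporter: ReporterSpec, tracer_total: float,
                          full_output: bool = False):
    """Reporter concentration maximising ΔFP.

    Coarse search on a 400-point log grid spanning [K_B/100, K_A·100] followed
    by bounded scalar refinement in log-concentration.  Returns the numeric
    optimum (float), or an :class:`OptimumResult` when ``full_output=True``
    which also carries √(K_A·K_B) and the relative deviation between the two;
    a deviation above 5% (ligand depletion at finite tracer) is warned about.
    """
    ka, kb = reporter.kd_substrate, reporter.kd_product
    analytic = math.sqrt(ka * kb)
    if ka == kb:
        warnings.warn("K_A = K_B: zero signal window, optimum degenerate")
        result = OptimumResult(analytic, analytic, 0.0, 0.0, zero_window=True)
        return result if full_output else analytic

    grid = np.geomspace(kb / 100.0, ka * 100.0, _GRID_POINTS)
    vals = _delta_fp_grid(reporter, tracer_total, grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda logc: -delta_fp(reporter, tracer_total, math.exp(logc)),
        bounds=(math.log(lo), math.log(hi)), method="bounded",
        options={"xatol": 1e-12})
    conc = math.exp(res.x)
    dmax = -res.fun
    deviation = abs(conc - analytic) / analytic
    if deviation > ANALYTIC_DEVIATION_FLAG:
        warnings.warn(
            f"numeric ΔFP optimum {conc:.4g} µM deviates {deviation:.1%} from "
            f"the trace-limit value √(K_A·K_B) = {analytic:.4g} µM "
            "(ligand depletion at finite tracer)")
    result = OptimumResult(conc, analytic, dmax, deviation)
    return result if full_output else conc


def working_window(reporter: ReporterSpec, tracer_total: float,
                   min_fraction_of_max: float = 0.8) -> tuple[float, float]:
    """Reporter-concentration interval where ΔFP ≥ fraction · ΔFP_max.

    This is the "proper concentration" band drawn on titration figures; the
    default retains 80% of the maximal window.  The interval always contains
    the numeric optimum.
    """
    if not 0.0 < min_fraction_of_max < 1.0:
        raise ValidationError("min_fraction_of_max must lie strictly in (0, 1)")
    opt = optimal_reporter_conc(reporter, tracer_total, full_output=True)
    if opt.zero_window or opt.delta_fp_max <= 0.0:
        raise ValidationError("working window undefined: ΔFP_max is zero")
    threshold = min_fraction_of_max * opt.delta_fp_max

    ka, kb = reporter.kd_substrate, reporter.kd_product
    grid = np.geomspace(kb / 1e4, ka * 1e4, 2 * _GRID_POINTS)
    # the optimum itself sits above any threshold < 1, guaranteeing a bracket
    grid = np.sort(np.append(grid, opt.conc))
    vals = _delta_fp_grid(reporter, tracer_total, grid)
    vals[np.searchsorted(grid, opt.conc)] = opt.delta_fp_max
    above = vals >= threshold

    def crossing(c_out: float, c_in: float) -> float:
        try:
            return brentq(
                lambda c: delta_fp(reporter, tracer_total, c) - threshold,
                c_out, c_in, xtol=1e-14, rtol=8.9e-16)
        except ValueError:
            # scalar/vector solver disagreement within float noise at a node
            return c_in

    idx = np.nonzero(above)[0]
    first, last = int(idx[0]), int(idx[-1])
    low = (grid[0] if first == 0
           else crossing(grid[first - 1], grid[first]))
    high = (grid[-1] if last == grid.size - 1
            else crossing(grid[last + 1], grid[last]))
    return (min(low, opt.conc), max(high, opt.conc))


@dataclass(frozen=True)
class StandardCurve:
    """FP-vs-conversion calibration with OLS linearity diagnostics."""

    fractions: np.ndarray
    mp: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def invert(self, mp_observed: float) -> float:
        """Product fraction predicted by the linear fit for an mP reading."""
        return (mp_observed - self.intercept) / self.slope


def standard_curve(reporter: ReporterSpec, tracer_total: float,
                   reporter_conc: float, fractions) -> StandardCurve:
    """Simulate the mP readout over a product-fraction series and fit a line.

    This is the calibration experiment performed with chemically synthesised
    substrate/product mixtures: each fraction is solved through the full
    competitive equilibrium (no trace-limit shortcut) and an ordinary
    least-squares line mP ~ fraction is reported with R².
    """
    fr = np.asarray(list(fractions), dtype=float)
    if np.unique(fr).size < 3:
        raise ValidationError("standard curve needs >= 3 distinct fractions")
    mp = np.array([
        fp_signal(reporter, solve_equilibrium(
            reporter, LigandMixture(tracer_total, float(x)), reporter_conc))
        for x in fr
    ])
    fit = stats.linregress(fr, mp)
    return StandardCurve(fractions=fr, mp=mp, slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2))
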