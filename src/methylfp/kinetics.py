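"""Enzyme reaction simulation and conversion quantitation.

The methylation/demethylation reaction is modelled as a single irreversible
substrate→product conversion with Michaelis–Menten saturation in both the
oligonucleotide substrate and the cofactor (SAM or 2-OG), multiplicative:

    dS/dt = −kcat·[E] · S/(Km,S + S) · C/(Km,C + C)

The cofactor is treated as unconsumed (it is in large excess over the ~tens of
nM oligo).  Inhibitors act through one of three textbook mechanisms: inflation
of the substrate Km, inflation of the cofactor Km, or scaling of Vmax.  Adding
the reporter protein quenches the reaction instantly, so a well's readout is
the conversion at its quench time pushed through the binding model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .binding import LigandMixture, ReporterSpec, fp_signal, solve_equilibrium
from .exceptions import ValidationError

__all__ = [
    "Inhibitor",
    "ReactionSystem",
    "TimeCourseDesign",
    "effective_rate_factor",
    "simulate_conversion",
    "run_time_course",
    "KineticFit",
    "fit_km_kcat",
    "ConversionEstimate",
    "estimate_conversion",
]

MECHANISMS = ("cofactor_competitive", "substrate_competitive",
              "noncompetitive", "none")

Mechanism = Literal["cofactor_competitive", "substrate_competitive",
                    "noncompetitive", "none"]


@dataclass(frozen=True)
class Inhibitor:
    """An inhibitor with its mechanism, Ki (µM) and assay concentration (µM)."""

    mechanism: Mechanism
    ki: float
    conc: float

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"unknown inhibitor mechanism {self.mechanism!r}; "
                f"expected one of {MECHANISMS}")
        if self.mechanism != "none":
            if not (math.isfinite(self.ki) and self.ki > 0):
                raise ValidationError("inhibitor ki must be finite and > 0")
            if not (math.isfinite(self.conc) and self.conc >= 0):
                raise ValidationError("inhibitor conc must be finite and >= 0")

    @property
    def occupancy_term(self) -> float:
        """1 + [I]/Ki, the competitive Km-inflation / Vmax-scaling factor."""
        if self.mechanism == "none":
            return 1.0
        return 1.0 + self.conc / self.ki


@dataclass(frozen=True)
class ReactionSystem:
    """One enzyme reaction: kinetic constants, concentrations, inhibitor."""

    km_substrate: float      # µM
    kcat: float              # 1/min
    enzyme_total: float      # µM
    substrate_total: float   # µM (the fluorescent tracer)
    cofactor_conc: float     # µM
    cofactor_km: float       # µM; 0 means cofactor saturation is not modelled
    inhibitor: Inhibitor | None = None

    def __post_init__(self) -> None:
        for name in ("km_substrate", "kcat", "enzyme_total", "substrate_total",
                     "cofactor_conc", "cofactor_km"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")

    def _effective_terms(self) -> tuple[float, float]:
        """(km_substrate_eff, vmax_eff) after cofactor and inhibitor terms."""
        inh = self.inhibitor
        km_s = self.km_substrate
        km_c = self.cofactor_km
        vmax = self.kcat * self.enzyme_total
        if inh is not None and inh.mechanism != "none":
            if inh.mechanism == "substrate_competitive":
                km_s = km_s * inh.occupancy_term
            elif inh.mechanism == "cofactor_competitive":
                km_c = km_c * inh.occupancy_term
            elif inh.mechanism == "noncompetitive":
                vmax = vmax / inh.occupancy_term
        if km_c > 0:
            vmax *= self.cofactor_conc / (km_c + self.cofactor_conc)
        return km_s, vmax


def effective_rate_factor(inhibitor: Inhibitor | None, *, substrate_conc: float,
                          km_substrate: float, cofactor_conc: float,
                          cofactor_km: float) -> float:
    """Rate with inhibitor divided by rate without, at the given concentrations.

    Always in (0, 1]: 1 at [I] = 0; for the competitive mechanisms it is the
    ratio of the relevant saturation terms with and without Km inflation, and
    for a noncompetitive inhibitor it is 1/(1 + [I]/Ki) independent of
    substrate and cofactor.
    """
    if inhibitor is None or inhibitor.mechanism == "none" or inhibitor.conc == 0:
        return 1.0
    t = inhibitor.occupancy_term
    if inhibitor.mechanism == "noncompetitive":
        return 1.0 / t
    if inhibitor.mechanism == "substrate_competitive":
        return ((km_substrate + substrate_conc)
                / (km_substrate * t + substrate_conc))
    if inhibitor.mechanism == "cofactor_competitive":
        if cofactor_km == 0:
            return 1.0
        return (cofactor_km + cofactor_conc) / (cofactor_km * t + cofactor_conc)
    raise ValidationError(f"unknown mechanism {inhibitor.mechanism!r}")


def simulate_conversion(sys: ReactionSystem, t):
    """Fraction of substrate converted to product at time(s) ``t`` (minutes).

    Integrates the rate law with an adaptive RK45 integrator (rtol 1e-8).
    Accepts a scalar or an array of times; conversion is monotone
    non-decreasing in t with asymptote ≤ 1.
    """
    t_in = np.asarray(t, dtype=float)
    scalar = t_in.ndim == 0
    times = np.atleast_1d(t_in)
    if np.any(~np.isfinite(times)) or np.any(times < 0):
        raise ValidationError("reaction times must be finite and >= 0")

    s0 = sys.substrate_total
    km_s, vmax = sys._effective_terms()
    if s0 == 0 or vmax == 0 or times.max() == 0:
        out = np.zeros_like(times)
        return float(out[0]) if scalar else out

    def rhs(_t, y):
        s = max(y[0], 0.0)
        return [-vmax * s / (km_s + s)] if km_s > 0 else [-vmax * (s > 0)]

    t_eval = np.unique(times)
    if t_eval[0] != 0.0:
        t_eval = np.insert(t_eval, 0, 0.0)
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [s0], t_eval=t_eval,
                    rtol=1e-8, atol=1e-14, method="RK45")
    if not sol.success:
        raise ValidationError(f"reaction integration failed: {sol.message}")
    s_at = dict(zip(sol.t, np.clip(sol.y[0], 0.0, s0)))
    frac = np.array([(s0 - s_at[tt]) / s0 for tt in times])
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac[0]) if scalar else frac


@dataclass(frozen=True)
class TimeCourseDesign:
    """Staggered-start time course: enzyme added at offsets, quench at span end.

    A well whose offset equals the total span is the 0-minute control: the
    reporter is added *before* the enzyme, so no conversion occurs.
    """

    start_offsets: Sequence[float]   # minutes
    total_span: float                # minutes
    enzyme_concs: Sequence[float]    # µM

    def __post_init__(self) -> None:
        if self.total_span <= 0:
            raise ValidationError("total_span must be > 0")
        for o in self.start_offsets:
            if not 0 <= o <= self.total_span:
                raise ValidationError(
                    f"start offset {o} outside [0, {self.total_span}]")
        if len(self.enzyme_concs) == 0:
            raise ValidationError("need at least one enzyme concentration")


def run_time_course(sys: ReactionSystem, design: TimeCourseDesign,
                    reporter: ReporterSpec, reporter_conc: float,
                    direction: str = "methylation") -> pd.DataFrame:
    """Simulate a staggered-start time course read out through the FP assay.

    Returns a table (enzyme_conc, start_offset, reaction_time, conversion, mp).
    For a methyltransferase the product is the tight binder and mP rises with
    reaction time; for a demethylase it falls.
    """
    if direction not in ("methylation", "demethylation"):
        raise ValidationError("direction must be 'methylation' or 'demethylation'")
    rows = []
    for e in design.enzyme_concs:
        sys_e = replace(sys, enzyme_total=float(e))
        for offset in design.start_offsets:
            rt = design.total_span - float(offset)
            conv = simulate_conversion(sys_e, rt) if rt > 0 else 0.0
            tight = conv if direction == "methylation" else 1.0 - conv
            state = solve_equilibrium(
                reporter, LigandMixture(sys.substrate_total, tight),
                reporter_conc)
            rows.append((float(e), float(offset), rt, conv,
                         fp_signal(reporter, state)))
    return pd.DataFrame(rows, columns=["enzyme_conc", "start_offset",
                                       "reaction_time", "conversion", "mp"])


@dataclass(frozen=True)
class KineticFit:
    """Michaelis–Menten fit of an initial-rate table."""

    km: float
    vmax: float
    kcat: float | None
    km_stderr: float | None
    vmax_stderr: float | None
    km_ci95: tuple[float, float] | None
    r_squared: float
    flags: frozenset[str]


def fit_km_kcat(initial_rate_table: Iterable[tuple[float, float]] | pd.DataFrame,
                enzyme_total: float | None = None) -> KineticFit:
    """Nonlinear least squares of v = Vmax·S/(Km+S) over an initial-rate table.

    ``initial_rate_table`` is an iterable of (substrate_conc, v0) pairs or a
    two-column DataFrame.  If ``enzyme_total`` is given, kcat = Vmax/[E] is
    reported.  Poorly constrained fits (substrate range that does not span Km,
    or Km standard error above 50%) are flagged ``"poorly_constrained"``.
    """
    if isinstance(initial_rate_table, pd.DataFrame):
        data = initial_rate_table.iloc[:, :2].to_numpy(dtype=float)
    else:
        data = np.asarray([(float(s), float(v)) for s, v in initial_rate_table])
    if data.shape[0] < 5 or np.unique(data[:, 0]).size < 5:
        raise ValidationError("need >= 5 distinct substrate concentrations")
    s, v = data[:, 0], data[:, 1]

    model = lmfit.Model(lambda x, vmax, km: vmax * x / (km + x),
                        independent_vars=["x"])
    params = model.make_params(
        vmax={"value": float(v.max()), "min": 0},
        km={"value": float(np.median(s)), "min": 1e-12},
    )
    out = model.fit(v, params, x=s, method="leastsq",
                    fit_kws={"xtol": 1e-14, "ftol": 1e-14})
    km = float(out.params["km"].value)
    vmax = float(out.params["vmax"].value)
    km_se = out.params["km"].stderr
    vm_se = out.params["vmax"].stderr
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(out.residual ** 2)) / ss_tot if ss_tot > 0 else 1.0

    flags: set[str] = set()
    if km_se is None or (km > 0 and km_se / km > 0.5):
        flags.add("poorly_constrained")
    if s.max() < km / 5 or s.min() > km * 5:
        flags.add("poorly_constrained")
    ci = ((km - 1.96 * km_se, km + 1.96 * km_se)
          if km_se is not None else None)
    return KineticFit(
        km=km, vmax=vmax,
        kcat=vmax / enzyme_total if enzyme_total else None,
        km_stderr=float(km_se) if km_se is not None else None,
        vmax_stderr=float(vm_se) if vm_se is not None else None,
        km_ci95=ci, r_squared=r2, flags=frozenset(flags))


class ConversionEstimate(NamedTuple):
    """Conversion percent (clamped to [0, 100]) with the raw unclamped value."""

    percent: float
    raw: float


def estimate_conversion(mp_observed: float, mp_negative: float,
                        mp_positive: float) -> ConversionEstimate:
    """Substrate conversion from a signal and its 0%/100% reaction controls.

    conversion% = (S − S_N)/(S_P − S_N) × 100, where S_N is the no-reaction
    (negative) control and S_P the full-product (positive) control.  Works for
    any linear readout (HPLC peak area or mP).
    """
    span = mp_positive - mp_negative
    if span == 0 or not math.isfinite(span):
        raise ValidationError("degenerate controls: S_P equals S_N")
    raw = (mp_observed - mp_negative) / span * 100.0
    return ConversionEstimate(percent=float(np.clip(raw, 0.0, 100.0)), raw=raw)
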