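"""Competitive binding equilibria of a methyl-reader protein and FP signal coupling.

The model: a reporter protein P (a methyl-binding domain such as tri-MBD1, or an
m6A reader such as GST-YTHDF1) binds two fluorescent oligonucleotide species --
the reaction substrate A (weak binder, dissociation constant ``K_A``) and the
reaction product B (tight binder, ``K_B``), with ``K_A >= K_B`` by convention.
Optionally a third protein (the enzyme itself) competes for the same oligos.

All binding is 1:1 mass action.  The fluorescence-polarization readout (in mP)
is taken to be linear in the fraction of tracer bound to protein, interpolating
between ``mp_min`` (all tracer free) and ``mp_max`` (all tracer bound).  This is
the standard anisotropy-with-equal-quantum-yields approximation and is what the
linearity of measured standard curves implies.

Concentrations are in µM throughout; mP values are plain numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import NumericalError, ValidationError

__all__ = [
    "ReporterSpec",
    "CompetitorSpec",
    "LigandMixture",
    "EquilibriumState",
    "solve_equilibrium",
    "fp_signal",
    "binding_curve",
]

#: relative tolerance for mass-balance verification of solved states
MASS_BALANCE_RTOL = 1e-9


def _require_finite(name: str, value: float, minimum: float | None = None,
                    strict: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if minimum is not None:
        if strict and value <= minimum:
            raise ValidationError(f"{name} must be > {minimum}, got {value}")
        if not strict and value < minimum:
            raise ValidationError(f"{name} must be >= {minimum}, got {value}")
    return value


@dataclass(frozen=True)
class ReporterSpec:
    """Binding parameters of one methyl-reader protein.

    ``kd_substrate`` (K_A) and ``kd_product`` (K_B) are the dissociation
    constants for the reaction-substrate and reaction-product oligonucleotides
    in the binding-assay convention: the *product* is the tight binder, so
    ``kd_substrate >= kd_product``.  If the caller passes them the other way
    round they are swapped with a warning.
    """

    kd_substrate: float  # µM
    kd_product: float    # µM
    mp_max: float        # mP, fully-bound tracer
    mp_min: float        # mP, free tracer

    def __post_init__(self) -> None:
        _require_finite("kd_substrate", self.kd_substrate, 0.0, strict=True)
        _require_finite("kd_product", self.kd_product, 0.0, strict=True)
        _require_finite("mp_max", self.mp_max)
        _require_finite("mp_min", self.mp_min)
        if self.mp_max <= self.mp_min:
            raise ValidationError(
                f"mp_max ({self.mp_max}) must exceed mp_min ({self.mp_min})")
        if self.kd_substrate < self.kd_product:
            warnings.warn(
                "kd_substrate < kd_product: swapping so the product is the "
                "tight binder (K_A/K_B >= 1 convention)", stacklevel=3)
            ka, kb = float(self.kd_product), float(self.kd_substrate)
            object.__setattr__(self, "kd_substrate", ka)
            object.__setattr__(self, "kd_product", kb)

    @property
    def selectivity(self) -> float:
        """K_A / K_B; large values make the reporter behave like an antibody."""
        return self.kd_substrate / self.kd_product

    @property
    def window(self) -> float:
        """mp_max - mp_min, the full signal window in mP."""
        return self.mp_max - self.mp_min


@dataclass(frozen=True)
class CompetitorSpec:
    """A second protein (typically the enzyme) competing for the oligos.

    High-salt assay buffers suppress this binding experimentally; the model
    keeps it optional with a per-condition Kd pair supplied by the user.
    """

    total: float         # µM
    kd_substrate: float  # µM
    kd_product: float    # µM

    def __post_init__(self) -> None:
        _require_finite("competitor total", self.total, 0.0)
        _require_finite("competitor kd_substrate", self.kd_substrate, 0.0, strict=True)
        _require_finite("competitor kd_product", self.kd_product, 0.0, strict=True)


@dataclass(frozen=True)
class LigandMixture:
    """Tracer composition: total concentration and product fraction x.

    ``fraction_product`` is the mole fraction of the tight-binding (product)
    oligo; x = 0 is pure substrate, x = 1 pure product.  For a methylation
    reaction x equals the conversion; for a demethylation reaction x = 1 -
    conversion (the substrate is the tight binder there).
    """

    total_tracer: float           # µM
    fraction_product: float       # dimensionless in [0, 1]
    competitor: CompetitorSpec | None = None

    def __post_init__(self) -> None:
        _require_finite("total_tracer", self.total_tracer, 0.0, strict=True)
        x = _require_finite("fraction_product", self.fraction_product)
        if not 0.0 <= x <= 1.0:
            raise ValidationError(f"fraction_product must lie in [0, 1], got {x}")

    @property
    def substrate_total(self) -> float:
        return self.total_tracer * (1.0 - self.fraction_product)

    @property
    def product_total(self) -> float:
        return self.total_tracer * self.fraction_product


@dataclass(frozen=True)
class EquilibriumState:
    """Solved species concentrations (µM) of a reporter/tracer equilibrium."""

    free_reporter: float
    bound_substrate: float
    bound_product: float
    free_substrate: float
    free_product: float
    free_competitor: float = 0.0
    competitor_bound_substrate: float = 0.0
    competitor_bound_product: float = 0.0

    @property
    def total_tracer(self) -> float:
        return (self.free_substrate + self.free_product
                + self.bound_substrate + self.bound_product
                + self.competitor_bound_substrate + self.competitor_bound_product)

    @property
    def bound_tracer(self) -> float:
        """Tracer bound to any protein (reporter or competitor)."""
        return (self.bound_substrate + self.bound_product
                + self.competitor_bound_substrate + self.competitor_bound_product)

    @property
    def bound_fraction(self) -> float:
        total = self.total_tracer
        if total == 0.0:
            raise ValidationError("bound fraction undefined for zero tracer")
        return self.bound_tracer / total


def _free_protein(p_total: float, ligand_totals: Sequence[float],
                  kds: Sequence[float]) -> float:
    """Free concentration of one protein binding independent 1:1 ligands.

    Root of  p + sum_i L_i * p / (K_i + p) - p_total  on [0, p_total];
    the left side is strictly increasing in p, so the bracket is guaranteed.
    """
    if p_total == 0.0:
        return 0.0

    def balance(p: float) -> float:
        return p + sum(l * p / (k + p) for l, k in zip(ligand_totals, kds)) - p_total

    try:
        return brentq(balance, 0.0, p_total, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise NumericalError(
            f"free-protein root search failed on [0, {p_total}]: {exc}") from exc


def _free_protein_grid(p_totals: np.ndarray, ligand_totals: Sequence[float],
                       kds: Sequence[float], iterations: int = 90) -> np.ndarray:
    """Vectorized bisection counterpart of :func:`_free_protein`.

    Used by grid evaluations in the assay-design module where thousands of
    reporter concentrations are solved at once.
    """
    p_totals = np.asarray(p_totals, dtype=float)
    lo = np.zeros_like(p_totals)
    hi = p_totals.copy()
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        g = mid - p_totals
        for l, k in zip(ligand_totals, kds):
            g = g + l * mid / (k + mid)
        low_side = g < 0.0
        lo = np.where(low_side, mid, lo)
        hi = np.where(low_side, hi, mid)
    return 0.5 * (lo + hi)


def solve_equilibrium(reporter: ReporterSpec, mix: LigandMixture,
                      reporter_total: float) -> EquilibriumState:
    """Solve the reporter / substrate / product (/ competitor) equilibrium.

    The two-ligand system reduces to a single unknown, the free reporter
    concentration, whose mass balance is strictly monotone -- solved by a
    bracketed root search on [0, reporter_total].  With an enzyme competitor a
    second, nested bracketed search on the free competitor is layered on top.

    Returns an :class:`EquilibriumState`; mass balances are verified to
    ``MASS_BALANCE_RTOL`` relative and a :class:`NumericalError` is raised on
    violation.
    """
    p_total = _require_finite("reporter_total", reporter_total, 0.0)
    a_tot = mix.substrate_total
    b_tot = mix.product_total
    ka, kb = reporter.kd_substrate, reporter.kd_product
    comp = mix.competitor

    if comp is None or comp.total == 0.0:
        p_free = _free_protein(p_total, (a_tot, b_tot), (ka, kb))
        e_free = 0.0
        kea = keb = math.inf
    else:
        kea, keb = comp.kd_substrate, comp.kd_product

        def outer(e: float) -> float:
            # reporter balance given e: ligand Kds inflated by competitor term
            p = _free_protein(p_total, (a_tot, b_tot),
                              (ka * (1.0 + e / kea), kb * (1.0 + e / keb)))
            fa = a_tot / (1.0 + p / ka + e / kea)
            fb = b_tot / (1.0 + p / kb + e / keb)
            return e + e * fa / kea + e * fb / keb - comp.total

        try:
            e_free = brentq(outer, 0.0, comp.total, xtol=1e-15, rtol=8.9e-16,
                            maxiter=200)
        except Exception as exc:
            raise NumericalError(
                f"competitor root search failed on [0, {comp.total}]: {exc}"
            ) from exc
        p_free = _free_protein(p_total, (a_tot, b_tot),
                               (ka * (1.0 + e_free / kea),
                                kb * (1.0 + e_free / keb)))

    free_a = a_tot / (1.0 + p_free / ka + (e_free / kea if e_free else 0.0))
    free_b = b_tot / (1.0 + p_free / kb + (e_free / keb if e_free else 0.0))
    state = EquilibriumState(
        free_reporter=p_free,
        bound_substrate=p_free * free_a / ka,
        bound_product=p_free * free_b / kb,
        free_substrate=free_a,
        free_product=free_b,
        free_competitor=e_free,
        competitor_bound_substrate=e_free * free_a / kea if e_free else 0.0,
        competitor_bound_product=e_free * free_b / keb if e_free else 0.0,
    )
    _check_balances(state, p_total, a_tot, b_tot,
                    comp.total if comp is not None else 0.0)
    return state


def _check_balances(state: EquilibriumState, p_total: float, a_tot: float,
                    b_tot: float, e_total: float) -> None:
    checks = [
        ("reporter", p_total,
         state.free_reporter + state.bound_substrate + state.bound_product),
        ("substrate", a_tot,
         state.free_substrate + state.bound_substrate
         + state.competitor_bound_substrate),
        ("product", b_tot,
         state.free_product + state.bound_product
         + state.competitor_bound_product),
        ("competitor", e_total,
         state.free_competitor + state.competitor_bound_substrate
         + state.competitor_bound_product),
    ]
    for name, total, recovered in checks:
        scale = max(abs(total), 1e-300)
        if abs(recovered - total) > MASS_BALANCE_RTOL * scale + 1e-15:
            raise NumericalError(
                f"{name} mass balance violated: total {total}, "
                f"recovered {recovered}")


def fp_signal(reporter: ReporterSpec, state: EquilibriumState) -> float:
    """FP signal (mP) of a solved state: linear in the bound tracer fraction.

    mP = mp_min + (mp_max - mp_min) * bound/total.  Tracer bound to the enzyme
    competitor also counts as bound -- that is the background signal high-salt
    buffers are designed to suppress.
    """
    if state.total_tracer == 0.0:
        raise ValidationError("FP signal undefined: no tracer in the system")
    return reporter.mp_min + reporter.window * state.bound_fraction


def binding_curve(reporter: ReporterSpec, mix: LigandMixture,
                  reporter_concs: Sequence[float]) -> pd.DataFrame:
    """Titrate the reporter against a fixed tracer mixture.

    Returns a DataFrame with columns ``reporter_conc`` and ``mp``; the curve is
    monotone non-decreasing in reporter concentration with asymptote mp_max.
    """
    concs = np.asarray(list(reporter_concs), dtype=float)
    if concs.size == 0:
        raise ValidationError("reporter_concs must be non-empty")
    if np.any(~np.isfinite(concs)) or np.any(concs < 0):
        raise ValidationError("reporter concentrations must be finite and >= 0")
    if np.any(np.diff(concs) < 0):
        raise ValidationError("reporter concentrations must be sorted ascending")
    mps = [fp_signal(reporter, solve_equilibrium(reporter, mix, c)) for c in concs]
    return pd.DataFrame({"reporter_conc": concs, "mp": mps})
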