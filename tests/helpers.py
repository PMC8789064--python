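"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the one-site solution is
the closed-form quadratic, the two-ligand oracle is a brute-force residual
scan, and the reaction oracle is the implicit Lambert-W progress curve.
"""

import numpy as np
from scipy.special import lambertw


def one_site_bound(protein_total: float, ligand_total: float,
                   kd: float) -> float:
    """Closed-form 1:1 complex concentration (quadratic root).

    Uses the cancellation-free form 2ab/(s + sqrt(s^2 - 4ab)) so the small
    root stays accurate when the complex is far below the totals.
    """
    s = protein_total + ligand_total + kd
    prod = protein_total * ligand_total
    return 2.0 * prod / (s + np.sqrt(s * s - 4.0 * prod))


def brute_force_free_reporter(p_total: float, a_total: float, ka: float,
                              b_total: float, kb: float,
                              n_grid: int = 4001, rounds: int = 6) -> float:
    """Free-reporter concentration by residual scan on successively finer grids.

    Minimises |p + A·p/(K_A+p) + B·p/(K_B+p) − P_T| over p ∈ [0, P_T] without
    any root bracketing; precision after the refinement rounds is far below
    the 1e-6 comparison tolerance.
    """
    lo, hi = 0.0, p_total
    best = 0.0
    for _ in range(rounds):
        grid = np.linspace(lo, hi, n_grid)
        resid = np.abs(grid + a_total * grid / (ka + grid)
                       + b_total * grid / (kb + grid) - p_total)
        i = int(np.argmin(resid))
        best = grid[i]
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
    return float(best)


def lambertw_progress(s0: float, km: float, vmax: float, t):
    """Implicit Michaelis–Menten progress curve S(t) via the Lambert W function.

    Solves Km·ln(S0/S) + (S0 − S) = Vmax·t in closed form.
    """
    t = np.asarray(t, dtype=float)
    arg = (s0 / km) * np.exp((s0 - vmax * t) / km)
    return np.real(km * lambertw(arg))


def four_pl(dose, bottom, top, ic50, hill):
    """Reference 4PL curve y(dose) used to generate fitting fixtures."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((np.log10(ic50) - np.log10(dose)) * hill))
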