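"""Plate-level screening analytics: Z′, normalization, 4PL, Ki, QC, triage.

Role conventions follow standard HTS usage for inhibitor screens:

* ``neg_ctrl`` — uninhibited full reaction (DMSO); defines 0% inhibition.
* ``pos_ctrl`` — fully inhibited / no-reaction well; defines 100% inhibition.

The Z′ factor 1 − (3σ_P + 3σ_N)/|μ_P − μ_N| is computed with the sample
(n−1) standard deviation; values above 0.5 indicate an excellent assay window.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "PlateRead",
    "DoseResponseResult",
    "ChengPrusoffResult",
    "PlateReport",
    "parse_well",
    "z_prime",
    "percent_inhibition",
    "fit_ic50",
    "cheng_prusoff_ki",
    "qc_fluorescence",
    "counter_screen_verdict",
    "analyze_plate",
    "triage",
]

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
ROLES = frozenset({"pos_ctrl", "neg_ctrl", "sample", "blank"})
PLATE_COLUMNS = ["row", "col", "mp", "fi", "role", "compound_id",
                 "compound_conc"]

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


def parse_well(well: str) -> tuple[str, int]:
    """Split a 384-well id like ``"B17"`` into (row letter, column number)."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValidationError(
            f"malformed well id {well!r}: expected row A-P + column 1-24")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= N_COLS:
        raise ValidationError(f"well {well!r}: column {col} outside 1-24")
    return row, col


@dataclass
class PlateRead:
    """One 384-well FP/FI plate read.

    ``wells`` is a DataFrame indexed by well id with at least the columns
    row, col, mp, fi, role, compound_id, compound_conc; extra columns are
    carried along untouched.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"plate table missing columns: {missing}")
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate wells: {dupes}")
        for well in df.index:
            parse_well(well)
        bad_roles = set(df["role"]) - ROLES
        if bad_roles:
            raise ValidationError(f"unknown well roles: {sorted(bad_roles)}")
        nonblank = df[df["role"] != "blank"]
        if nonblank["mp"].isna().any():
            raise ValidationError("missing mP values on non-blank wells")
        if not (nonblank["fi"] > 0).all():
            raise ValidationError("FI must be > 0 on non-blank wells")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "PlateRead":
        df = pd.DataFrame(list(records)).set_index("well")
        if "row" not in df.columns or "col" not in df.columns:
            parsed = [parse_well(w) for w in df.index]
            df["row"] = [p[0] for p in parsed]
            df["col"] = [p[1] for p in parsed]
        return cls(df[PLATE_COLUMNS + [c for c in df.columns
                                       if c not in PLATE_COLUMNS]])

    def mp(self, role: str) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == role, "mp"].to_numpy(float)

    @property
    def samples(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "sample"]


def z_prime(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Screening-window statistic Z′ = 1 − (3σ_P + 3σ_N)/|μ_P − μ_N|.

    Sample (ddof=1) standard deviations.  Returns −inf with a warning when the
    group means coincide (undefined window); always ≤ 1.
    """
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValidationError("z_prime needs >= 2 values per control group")
    window = abs(p.mean() - n.mean())
    if window == 0:
        warnings.warn("Z' undefined: control means coincide")
        return -math.inf
    return 1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / window


def percent_inhibition(mp_well, mp_neg_mean: float, mp_pos_mean: float):
    """Normalize mP to percent inhibition between the plate controls.

    0% at the uninhibited (neg) control mean, 100% at the no-reaction (pos)
    control mean, linear in mP.  Accepts a scalar or array of well values.
    """
    span = mp_pos_mean - mp_neg_mean
    if span == 0 or not math.isfinite(span):
        raise ValidationError("degenerate controls: pos and neg means equal")
    out = (np.asarray(mp_well, dtype=float) - mp_neg_mean) / span * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseResponseResult:
    """Four-parameter-logistic dose-response fit."""

    ic50: float        # µM (NaN when flagged inactive / not converged)
    hill: float
    top: float         # percent
    bottom: float      # percent
    r_squared: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)


def _four_pl(logd, bottom, span, logic50, hill):
    return bottom + span / (1.0 + 10.0 ** ((logic50 - logd) * hill))


def fit_ic50(doses: Sequence[float], responses: Sequence[float],
             inactive_span: float = 5.0) -> DoseResponseResult:
    """Fit the log(inhibitor)-vs-response variable-slope (4PL) model.

    y = bottom + (top − bottom)/(1 + 10^((logIC50 − logD)·hill)).  Requires
    ≥ 5 dose points spanning ≥ 1 decade.  Fits are initialised from the data
    extremes with hill bounded to [0.2, 5] and IC50 to the dosed range ±1
    decade.  A response span below ``inactive_span`` percent is flagged
    ``"inactive"`` (NaN IC50); non-convergence yields ``"not_converged"``.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size != y.size:
        raise ValidationError("doses and responses must have equal length")
    if np.unique(d).size < 5:
        raise ValidationError("need >= 5 distinct dose points")
    if np.any(d <= 0):
        raise ValidationError("doses must be > 0")
    logd = np.log10(d)
    if logd.max() - logd.min() < 1.0:
        raise ValidationError("dose series must span at least one decade")

    span_obs = float(y.max() - y.min())
    if span_obs < inactive_span:
        return DoseResponseResult(math.nan, math.nan, float(y.max()),
                                  float(y.min()), 0.0,
                                  frozenset({"inactive"}))

    mid = y.min() + span_obs / 2.0
    logic50_init = float(logd[np.argmin(np.abs(y - mid))])
    model = lmfit.Model(_four_pl, independent_vars=["logd"])
    params = model.make_params(
        bottom={"value": float(y.min()), "min": float(y.min()) - 50,
                "max": float(y.max())},
        span={"value": span_obs, "min": 0.0, "max": 3 * max(span_obs, 1.0)},
        logic50={"value": logic50_init, "min": logd.min() - 1.0,
                 "max": logd.max() + 1.0},
        hill={"value": 1.0, "min": 0.2, "max": 5.0},
    )
    try:
        out = model.fit(y, params, logd=logd, method="leastsq",
                        fit_kws={"xtol": 1e-14, "ftol": 1e-14})
    except Exception:
        return DoseResponseResult(math.nan, math.nan, math.nan, math.nan, 0.0,
                                  frozenset({"not_converged"}))
    bottom = float(out.params["bottom"].value)
    span = float(out.params["span"].value)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(out.residual ** 2)) / ss_tot if ss_tot > 0 else 1.0
    flags: set[str] = set()
    if not out.success:
        flags.add("not_converged")
    logic50 = float(out.params["logic50"].value)
    if not (logd.min() <= logic50 <= logd.max()):
        flags.add("extrapolated_ic50")
    return DoseResponseResult(
        ic50=10.0 ** logic50, hill=float(out.params["hill"].value),
        top=bottom + span, bottom=bottom, r_squared=r2,
        qc_flags=frozenset(flags))


@dataclass(frozen=True)
class ChengPrusoffResult:
    """IC50-vs-[S] regression: IC50 = Ki·(1 + [S]/Km)."""

    ki: float          # y-intercept, µM
    slope: float       # Ki/Km, dimensionless
    r_squared: float
    km: float          # intercept/slope, µM (NaN if slope <= 0)
    qc_flags: frozenset[str] = field(default_factory=frozenset)


def cheng_prusoff_ki(ic50_vs_substrate: Iterable[tuple[float, float]]
                     ) -> ChengPrusoffResult:
    """Ki of a competitive inhibitor from IC50s at several substrate levels.

    Ordinary least squares of IC50 on [S]; the y-intercept is Ki and the slope
    Ki/Km.  A negative intercept is flagged (inconsistent with a competitive
    mechanism).
    """
    pairs = np.asarray([(float(s), float(i)) for s, i in ic50_vs_substrate])
    if pairs.shape[0] < 3:
        raise ValidationError("need >= 3 substrate concentrations")
    fit = stats.linregress(pairs[:, 0], pairs[:, 1])
    ki = float(fit.intercept)
    slope = float(fit.slope)
    flags: set[str] = set()
    if ki < 0:
        flags.add("negative_intercept")
    return ChengPrusoffResult(
        ki=ki, slope=slope, r_squared=float(fit.rvalue ** 2),
        km=ki / slope if slope > 0 else math.nan,
        qc_flags=frozenset(flags))


def qc_fluorescence(plate: PlateRead, threshold: float = 0.30) -> pd.Series:
    """Flag wells whose total FI deviates more than ``threshold`` from reference.

    The reference FI is the median over negative-control wells; deviations
    beyond 30% indicate pipetting faults or fluorescent/quenching compounds
    and should be analysed critically.  Returns a boolean Series
    ``fluorescence_artifact`` indexed by well.
    """
    neg = plate.wells[plate.wells["role"] == "neg_ctrl"]
    if neg.empty:
        raise ValidationError("plate has no negative controls for FI reference")
    ref = float(neg["fi"].median())
    rel = (plate.wells["fi"] - ref).abs() / ref
    flags = rel > threshold
    flags.name = "fluorescence_artifact"
    return flags


def counter_screen_verdict(primary_hit_inhibition: float, counter_mp: float,
                           reference_counter_mp: float, sigma_counter: float,
                           k: float = 3.0) -> str:
    """Classify a primary hit using the no-enzyme 50/50-mix counter screen.

    A compound that still shifts the FP of an enzyme-free half-converted
    tracer mix interferes with the readout rather than the enzyme: if
    |counter mP − reference| > k·σ_counter the verdict is ``"false_positive"``,
    otherwise ``"true_hit"``.  Missing counter data gives ``"untested"``.
    """
    if counter_mp is None or (isinstance(counter_mp, float)
                              and math.isnan(counter_mp)):
        return "untested"
    if abs(counter_mp - reference_counter_mp) > k * sigma_counter:
        return "false_positive"
    return "true_hit"


@dataclass(frozen=True)
class PlateReport:
    """Summary analytics of one screening plate."""

    z_prime: float
    neg_mean: float
    pos_mean: float
    n_hits: int
    table: pd.DataFrame  # per sample well: inhibition, fi_artifact, hit

    def summary(self) -> dict:
        return {
            "z_prime": self.z_prime,
            "neg_mean_mp": self.neg_mean,
            "pos_mean_mp": self.pos_mean,
            "n_samples": int(len(self.table)),
            "n_hits": self.n_hits,
            "n_fi_flagged": int(self.table["fi_artifact"].sum()),
        }


def analyze_plate(plate: PlateRead, fi_threshold: float = 0.30,
                  hit_k: float = 3.0) -> PlateReport:
    """Z′, per-well percent inhibition, FI QC and hit calls for one plate.

    A sample well is a hit when its inhibition exceeds ``hit_k`` sample
    standard deviations of the negative-control inhibition distribution (a
    robust 3σ rule; negative controls sit at 0% by construction).
    """
    neg = plate.mp("neg_ctrl")
    pos = plate.mp("pos_ctrl")
    if neg.size < 2 or pos.size < 2:
        raise ValidationError("plate needs >= 2 wells per control group")
    zp = z_prime(pos, neg)
    neg_mean, pos_mean = float(neg.mean()), float(pos.mean())
    samples = plate.samples
    inhibition = percent_inhibition(samples["mp"].to_numpy(float),
                                    neg_mean, pos_mean)
    sigma_inh = float(np.std(
        percent_inhibition(neg, neg_mean, pos_mean), ddof=1))
    fi_flags = qc_fluorescence(plate, fi_threshold).loc[samples.index]
    table = pd.DataFrame({
        "compound_id": samples["compound_id"],
        "compound_conc": samples["compound_conc"],
        "inhibition": inhibition,
        "fi_artifact": fi_flags,
        "hit": inhibition > hit_k * sigma_inh,
    }, index=samples.index)
    return PlateReport(z_prime=zp, neg_mean=neg_mean, pos_mean=pos_mean,
                       n_hits=int(table["hit"].sum()), table=table)


def triage(primary: PlateRead, counter: PlateRead, fi_threshold: float = 0.30,
           counter_k: float = 3.0, hit_k: float = 3.0) -> pd.DataFrame:
    """Join a primary screen with its counter screen and call verdicts.

    The counter plate holds the enzyme-free 50/50 substrate/product mix; its
    negative-control wells (DMSO mix) give the reference mP and the noise
    scale σ_counter.  Per compound the output records the primary inhibition
    and hit call, the FI artifact flag, the counter-screen verdict, whether
    the compound is excluded (FI artifact or counter false positive) and the
    final hit call.
    """
    report = analyze_plate(primary, fi_threshold=fi_threshold, hit_k=hit_k)
    ref_wells = counter.mp("neg_ctrl")
    if ref_wells.size < 2:
        raise ValidationError("counter plate needs >= 2 reference (DMSO) wells")
    ref_mean = float(ref_wells.mean())
    sigma = float(ref_wells.std(ddof=1))

    # replicate counter wells for one compound are averaged
    counter_mp = counter.samples.groupby("compound_id")["mp"].mean()
    rows = []
    for well, rec in report.table.iterrows():
        cid = rec["compound_id"]
        cmp_mp = counter_mp.get(cid, math.nan)
        verdict = counter_screen_verdict(rec["inhibition"], float(cmp_mp),
                                         ref_mean, sigma, k=counter_k)
        excluded = bool(rec["fi_artifact"]) or verdict == "false_positive"
        rows.append({
            "well": well, "compound_id": cid,
            "inhibition": rec["inhibition"], "hit": bool(rec["hit"]),
            "fi_artifact": bool(rec["fi_artifact"]),
            "counter_mp": float(cmp_mp),
            "counter_delta": float(cmp_mp) - ref_mean,
            "verdict": verdict, "excluded": excluded,
            "final_hit": bool(rec["hit"]) and not excluded,
        })
    return pd.DataFrame(rows).set_index("well")
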