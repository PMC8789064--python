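"""Synthetic assay data: presets, compound libraries, plates, oligo sequences.

This module generates everything needed to exercise the full analysis chain
without laboratory data: named parameter presets emulating the four published
assay configurations (DNMT1, TET2, METTL3/14, ALKBH5), compound libraries with
labelled mechanisms (true inhibitors plus the false-positive classes an FP
screen attracts), and noisy 384-well plate reads produced by the full physics
chain reaction → equilibrium → mP/FI.

All randomness flows from a single integer seed through
:class:`numpy.random.Generator`; identical seeds give byte-identical plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import LigandMixture, ReporterSpec, fp_signal, solve_equilibrium
from .exceptions import ValidationError
from .kinetics import Inhibitor, ReactionSystem, simulate_conversion
from .screening import (ROWS, ChengPrusoffResult, PlateRead, cheng_prusoff_ki,
                        fit_ic50, percent_inhibition)

__all__ = [
    "AssayPreset",
    "make_assay_presets",
    "CompoundSpec",
    "NoiseModel",
    "make_compound_library",
    "default_layout",
    "simulate_plate",
    "zprime_monte_carlo",
    "simulate_dose_response",
    "cheng_prusoff_experiment",
    "write_oligo_fasta",
]

INHIBITOR_CLASSES = ("cofactor_competitive", "substrate_competitive",
                     "noncompetitive")
ARTIFACT_CLASSES = ("quencher", "oligo_binder", "reporter_disruptor")
COMPOUND_CLASSES = INHIBITOR_CLASSES + ARTIFACT_CLASSES + ("inactive",)

#: nominal total-fluorescence counts of an unperturbed well
FI_BASELINE = 10_000.0


@dataclass(frozen=True)
class AssayPreset:
    """One enzyme-assay configuration: reporter, tracer, reaction constants.

    ``direction`` states whether the enzymatic reaction creates the reporter's
    tight binder ("methylation": mP rises with conversion) or destroys it
    ("demethylation": mP falls).
    """

    name: str
    reporter: ReporterSpec
    tracer_total: float       # µM
    reporter_conc: float      # µM
    enzyme_conc: float        # µM
    km_substrate: float       # µM
    kcat: float               # 1/min
    cofactor_name: str
    cofactor_conc: float      # µM
    cofactor_km: float        # µM
    reaction_time: float      # minutes
    direction: str            # "methylation" | "demethylation"

    def reaction_system(self, inhibitor: Inhibitor | None = None,
                        enzyme_conc: float | None = None) -> ReactionSystem:
        return ReactionSystem(
            km_substrate=self.km_substrate, kcat=self.kcat,
            enzyme_total=self.enzyme_conc if enzyme_conc is None else enzyme_conc,
            substrate_total=self.tracer_total,
            cofactor_conc=self.cofactor_conc, cofactor_km=self.cofactor_km,
            inhibitor=inhibitor)

    def tight_fraction(self, conversion: float) -> float:
        """Map reaction conversion to the tight-binder tracer fraction."""
        return conversion if self.direction == "methylation" else 1.0 - conversion


def make_assay_presets() -> dict[str, AssayPreset]:
    """The four named assay configurations.

    Reporter/tracer concentrations follow the published assay conditions
    (tri-MBD1 1.5 µM with 20 nM DNA tracer for DNMT1, tri-MBD1 500 nM for
    TET2, GST-YTHDF1 750 nM with 40 nM RNA tracer for METTL3/14 and ALKBH5);
    each reporter has ≥100-fold product selectivity with a ~100 mP window for
    the MBD reader and ~250 mP for the GST-YTH reader, and every reporter
    concentration equals the ΔFP optimum √(K_A·K_B) for its Kd pair.  Enzyme
    kinetic constants are order-of-magnitude placeholders (the measured values
    are not reproduced here) chosen so the uninhibited reaction approaches
    completion within the stated reaction time.
    """
    mbd_small = dict(mp_min=50.0, mp_max=150.0)    # ~100 mP window
    yth_large = dict(mp_min=60.0, mp_max=310.0)    # ~250 mP window
    return {
        "DNMT1": AssayPreset(
            name="DNMT1",
            reporter=ReporterSpec(kd_substrate=15.0, kd_product=0.15,
                                  **mbd_small),
            tracer_total=0.020, reporter_conc=1.5, enzyme_conc=0.020,
            km_substrate=0.1, kcat=0.5,
            cofactor_name="SAM", cofactor_conc=1.0, cofactor_km=1.0,
            reaction_time=70.0, direction="methylation"),
        "TET2": AssayPreset(
            name="TET2",
            reporter=ReporterSpec(kd_substrate=5.0, kd_product=0.05,
                                  **mbd_small),
            tracer_total=0.020, reporter_conc=0.5, enzyme_conc=0.040,
            km_substrate=0.1, kcat=0.5,
            cofactor_name="2-OG", cofactor_conc=1000.0, cofactor_km=30.0,
            reaction_time=60.0, direction="demethylation"),
        "METTL3_14": AssayPreset(
            name="METTL3_14",
            reporter=ReporterSpec(kd_substrate=7.5, kd_product=0.075,
                                  **yth_large),
            tracer_total=0.040, reporter_conc=0.75, enzyme_conc=0.040,
            km_substrate=0.1, kcat=0.5,
            cofactor_name="SAM", cofactor_conc=1.0, cofactor_km=1.0,
            reaction_time=60.0, direction="methylation"),
        "ALKBH5": AssayPreset(
            name="ALKBH5",
            reporter=ReporterSpec(kd_substrate=7.5, kd_product=0.075,
                                  **yth_large),
            tracer_total=0.040, reporter_conc=0.75, enzyme_conc=0.020,
            km_substrate=0.1, kcat=0.5,
            cofactor_name="2-OG", cofactor_conc=200.0, cofactor_km=30.0,
            reaction_time=50.0, direction="demethylation"),
    }


@dataclass(frozen=True)
class CompoundSpec:
    """A library compound with its mechanistic class and effect size.

    ``potency`` means: Ki in µM for the inhibitor classes; fractional FI
    reduction (0-1) for a quencher; mP shift for an oligo binder; fold
    inflation of the reporter's product Kd for a reporter disruptor; unused
    for ``inactive``.
    """

    id: str
    compound_class: str
    potency: float | None = None
    stock_conc: float = 10_000.0   # µM

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(
                f"unknown compound class {self.compound_class!r}")
        if self.compound_class != "inactive":
            if self.potency is None or not (math.isfinite(self.potency)
                                            and self.potency > 0):
                raise ValidationError(
                    f"{self.compound_class} compound needs potency > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian plate-read noise; all randomness flows from ``seed``.

    The default mP standard deviation (2.5 mP, about 3% of the usable control
    window of the MBD presets) puts control-plate Z′ in the high-0.8s, the
    regime the assay was validated in.
    """

    mp_sd: float = 2.5
    fi_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mp_sd < 0 or self.fi_cv < 0:
            raise ValidationError("noise scales must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_compound_library(n: int, seed: int = 0,
                          class_weights: dict[str, float] | None = None,
                          ki_range: tuple[float, float] = (0.5, 20.0),
                          quench_fraction: float = 0.5,
                          binder_shift_mp: float = 40.0,
                          disruptor_fold: float = 10.0) -> list[CompoundSpec]:
    """Random labelled compound library.

    Default class mix: 60% inactive, 8% per artifact class, 16% split across
    the inhibitor mechanisms.  Inhibitor Ki is drawn log-uniformly from
    ``ki_range`` (µM); artifact effect sizes are fixed at the generator
    defaults (50% FI quench, +40 mP oligo-binder shift, 10-fold product-Kd
    inflation, the strong disruption a counter screen is designed to catch).
    """
    if class_weights is None:
        class_weights = {
            "cofactor_competitive": 0.08, "substrate_competitive": 0.04,
            "noncompetitive": 0.04, "quencher": 0.08, "oligo_binder": 0.08,
            "reporter_disruptor": 0.08, "inactive": 0.60,
        }
    classes = list(class_weights)
    w = np.asarray([class_weights[c] for c in classes], dtype=float)
    rng = np.random.default_rng(seed)
    assigned = rng.choice(classes, size=n, p=w / w.sum())
    lo, hi = ki_range
    out = []
    for i, cls in enumerate(assigned):
        if cls in INHIBITOR_CLASSES:
            potency = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif cls == "quencher":
            potency = quench_fraction
        elif cls == "oligo_binder":
            potency = binder_shift_mp
        elif cls == "reporter_disruptor":
            potency = disruptor_fold
        else:
            potency = None
        out.append(CompoundSpec(id=f"CPD{i + 1:04d}", compound_class=str(cls),
                                potency=potency))
    return out


def default_layout(n_compounds: int = 0) -> pd.DataFrame:
    """Control layout of the published Z′ plates plus sample wells.

    50 positive and 50 negative controls arranged in 5 columns × 10 rows each
    (rows A-J; columns 1-5 and 20-24) of a 384-well plate.  Sample wells fill
    the remaining wells row-major; unused wells are blank.
    """
    records = []
    ctrl_rows = ROWS[:10]
    for r in ctrl_rows:
        for c in range(1, 6):
            records.append((f"{r}{c}", "pos_ctrl", None))
        for c in range(20, 25):
            records.append((f"{r}{c}", "neg_ctrl", None))
    taken = {w for w, _, _ in records}
    free = [f"{r}{c}" for r in ROWS for c in range(1, 25)
            if f"{r}{c}" not in taken]
    if n_compounds > len(free):
        raise ValidationError(
            f"{n_compounds} compounds do not fit: {len(free)} free wells")
    for i in range(n_compounds):
        records.append((free[i], "sample", i))
    for w in free[n_compounds:]:
        records.append((w, "blank", None))
    return pd.DataFrame(records, columns=["well", "role", "compound_index"])


def _effective_reporter(preset: AssayPreset,
                        compound: CompoundSpec | None) -> ReporterSpec:
    if compound is not None and compound.compound_class == "reporter_disruptor":
        return replace(preset.reporter,
                       kd_product=preset.reporter.kd_product * compound.potency)
    return preset.reporter


def _well_physics(preset: AssayPreset, role: str,
                  compound: CompoundSpec | None, screening_conc: float,
                  mode: str, full_conversion: float) -> tuple[float, float]:
    """Deterministic (mp, fi_factor) for one well before noise."""
    if mode == "counter":
        tight = 0.5  # half substrate replaced by product, no enzyme
    elif role == "pos_ctrl":
        tight = preset.tight_fraction(0.0)
    else:
        conv = full_conversion
        if (compound is not None
                and compound.compound_class in INHIBITOR_CLASSES):
            sys = preset.reaction_system(
                Inhibitor(compound.compound_class, compound.potency,
                          screening_conc))
            conv = simulate_conversion(sys, preset.reaction_time)
        tight = preset.tight_fraction(conv)

    reporter = _effective_reporter(preset, compound)
    mp = fp_signal(reporter, solve_equilibrium(
        reporter, LigandMixture(preset.tracer_total, tight),
        preset.reporter_conc))
    fi_factor = 1.0
    if compound is not None:
        if compound.compound_class == "oligo_binder":
            mp += compound.potency
        elif compound.compound_class == "quencher":
            # quenching hits free and bound tracer equally: FI drops, mP holds
            fi_factor = 1.0 - compound.potency
    return mp, fi_factor


def simulate_plate(preset: AssayPreset,
                   compounds: Sequence[CompoundSpec] = (),
                   layout: pd.DataFrame | None = None,
                   noise: NoiseModel | None = None,
                   screening_conc: float = 10.0,
                   mode: str = "primary") -> tuple[PlateRead, pd.DataFrame]:
    """Simulate a 384-well plate read with ground-truth labels.

    Every well is produced by the full physics chain (reaction kinetics →
    competitive equilibrium → mP, FI) plus class-specific perturbations, then
    Gaussian noise.  ``mode="counter"`` simulates the false-positive counter
    screen: an enzyme-free 50/50 substrate/product mix in every well, where
    only readout-interfering compounds move the signal.

    Returns ``(plate, truth)`` where ``truth`` maps wells to compound class
    and potency.
    """
    if mode not in ("primary", "counter"):
        raise ValidationError("mode must be 'primary' or 'counter'")
    noise = noise or NoiseModel()
    if layout is None:
        layout = default_layout(len(compounds))
    if layout["well"].duplicated().any():
        clash = sorted(layout.loc[layout["well"].duplicated(), "well"])
        raise ValidationError(f"layout collision on wells: {clash}")
    rng = noise.rng()

    full_conversion = simulate_conversion(preset.reaction_system(),
                                          preset.reaction_time)
    records, truth = [], []
    cache: dict[tuple, tuple[float, float]] = {}
    for well, role, idx in layout.itertuples(index=False):
        if role == "blank":
            records.append(dict(well=well, mp=np.nan, fi=np.nan, role=role,
                                compound_id="", compound_conc=np.nan))
            continue
        compound = compounds[int(idx)] if role == "sample" else None
        key = (role, None if compound is None
               else (compound.compound_class, compound.potency))
        if key not in cache:
            cache[key] = _well_physics(preset, role, compound, screening_conc,
                                       mode, full_conversion)
        mp0, fi_factor = cache[key]
        mp = mp0 + rng.normal(0.0, noise.mp_sd)
        fi = FI_BASELINE * fi_factor * (1.0 + rng.normal(0.0, noise.fi_cv))
        records.append(dict(
            well=well, mp=mp, fi=max(fi, 1e-6), role=role,
            compound_id=compound.id if compound is not None else "DMSO",
            compound_conc=screening_conc if compound is not None else 0.0))
        if compound is not None:
            truth.append(dict(well=well, compound_id=compound.id,
                              compound_class=compound.compound_class,
                              potency=compound.potency))
    plate = PlateRead.from_records(records)
    truth_df = pd.DataFrame(truth, columns=["well", "compound_id",
                                            "compound_class", "potency"])
    return plate, truth_df


def zprime_monte_carlo(preset: AssayPreset, n_plates: int,
                       noise: NoiseModel | None = None,
                       n_per_group: int = 50) -> np.ndarray:
    """Z′ distribution over control-only plates.

    The deterministic control signals are computed once through the physics
    chain; per-plate Gaussian noise is then drawn for ``n_per_group`` wells in
    each control group, matching :func:`simulate_plate` well-for-well.
    """
    noise = noise or NoiseModel()
    conv = simulate_conversion(preset.reaction_system(), preset.reaction_time)
    mp_neg, _ = _well_physics(preset, "neg_ctrl", None, 0.0, "primary", conv)
    mp_pos, _ = _well_physics(preset, "pos_ctrl", None, 0.0, "primary", conv)
    rng = noise.rng()
    pos = mp_pos + rng.normal(0.0, noise.mp_sd, size=(n_plates, n_per_group))
    neg = mp_neg + rng.normal(0.0, noise.mp_sd, size=(n_plates, n_per_group))
    window = np.abs(pos.mean(axis=1) - neg.mean(axis=1))
    return 1.0 - 3.0 * (pos.std(axis=1, ddof=1)
                        + neg.std(axis=1, ddof=1)) / window


def _uninhibited_pseudo_rate(preset: AssayPreset) -> float:
    """Pseudo-first-order rate constant (1/min) of the uninhibited reaction."""
    sys = preset.reaction_system()
    _, vmax = sys._effective_terms()
    return vmax / (sys.km_substrate + sys.substrate_total)


def simulate_dose_response(preset: AssayPreset, inhibitor_mechanism: str,
                           ki: float, doses: Sequence[float],
                           cofactor_conc: float | None = None,
                           reaction_time: float | None = None,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None,
                           n_control_wells: int = 8,
                           n_replicates: int = 1) -> pd.DataFrame:
    """Inhibitor dose series through reaction, readout and normalization.

    Each dose is read in ``n_replicates`` wells (triplicate is the usual
    bench practice) and averaged.  Returns a table (dose, mp, inhibition)
    where inhibition is normalized to noisy on-plate control means
    (``n_control_wells`` replicates per group).
    """
    rng = rng or np.random.default_rng(0)
    if cofactor_conc is not None:
        preset = replace(preset, cofactor_conc=float(cofactor_conc))
    if reaction_time is not None:
        preset = replace(preset, reaction_time=float(reaction_time))
    conv_full = simulate_conversion(preset.reaction_system(),
                                    preset.reaction_time)

    def read(conv: float) -> float:
        state = solve_equilibrium(
            preset.reporter,
            LigandMixture(preset.tracer_total, preset.tight_fraction(conv)),
            preset.reporter_conc)
        return fp_signal(preset.reporter, state)

    neg = read(conv_full) + rng.normal(0.0, noise_sd, n_control_wells)
    pos = read(0.0) + rng.normal(0.0, noise_sd, n_control_wells)
    rows = []
    for dose in doses:
        sys = preset.reaction_system(
            Inhibitor(inhibitor_mechanism, ki, float(dose)))
        conv = simulate_conversion(sys, preset.reaction_time)
        mp = float(np.mean(read(conv) + rng.normal(0.0, noise_sd,
                                                   n_replicates)))
        rows.append((float(dose), mp,
                     percent_inhibition(mp, neg.mean(), pos.mean())))
    return pd.DataFrame(rows, columns=["dose", "mp", "inhibition"])


def cheng_prusoff_experiment(preset: AssayPreset, ki: float,
                             cofactor_concs: Sequence[float],
                             mechanism: str = "cofactor_competitive",
                             n_doses: int = 10,
                             target_conversion: float = 0.08,
                             noise_sd: float = 0.0,
                             n_replicates: int = 1,
                             seed: int = 0
                             ) -> tuple[pd.DataFrame, ChengPrusoffResult]:
    """Full competitive-inhibition pipeline: dose series → 4PL → Ki regression.

    At each cofactor concentration an inhibitor dose series is simulated and
    fitted with the 4PL model; the fitted IC50s are then regressed on the
    cofactor concentration (the competed species), whose y-intercept estimates
    Ki.  The reaction time is set so the uninhibited conversion is
    ``target_conversion``: endpoint readouts are linear in rate only for small
    conversions, and the Ki intercept is unbiased only in that regime.
    """
    rng = np.random.default_rng(seed)
    ic50s = []
    for c in cofactor_concs:
        p = replace(preset, cofactor_conc=float(c))
        # keep the *uninhibited* conversion at the target for every cofactor level
        t = -math.log(1.0 - target_conversion) / _uninhibited_pseudo_rate(p)
        expected_ic50 = ki * (1.0 + c / preset.cofactor_km)
        doses = np.geomspace(expected_ic50 / 30.0, expected_ic50 * 30.0,
                             n_doses)
        dr = simulate_dose_response(p, mechanism, ki, doses,
                                    reaction_time=t, noise_sd=noise_sd,
                                    rng=rng, n_replicates=n_replicates)
        fit = fit_ic50(dr["dose"], dr["inhibition"])
        ic50s.append((float(c), fit.ic50, fit.hill, fit.r_squared))
    table = pd.DataFrame(ic50s, columns=["cofactor_conc", "ic50", "hill",
                                         "fit_r_squared"])
    result = cheng_prusoff_ki(table[["cofactor_conc", "ic50"]].itertuples(
        index=False, name=None))
    return table, result


# --- assay oligonucleotides -------------------------------------------------

_DNA_TOP = "TAXGACCAGGAT"       # X at position 3
_DNA_BOTTOM = "ATCCTGGTXGTA"    # X at position 9
_RNA = "GAACCGGYCUGUCUUA"       # Y at position 8
_DNA_MODS = ("C", "5mC", "5hmC", "5caC")
_RNA_MODS = ("A", "m6A")


def write_oligo_fasta(out) -> int:
    """Write the assay oligonucleotide sequences as FASTA.

    The 12-bp DNA duplex strands (5'-FAM on the top strand) carry a variable
    cytosine X ∈ {C, 5mC, 5hmC, 5caC} and the 16-nt RNA a variable adenosine
    Y ∈ {A, m6A}; the modification identity and position are annotated in the
    record description.  Returns the number of records written.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for mod in _DNA_MODS:
        records.append(SeqRecord(
            Seq(_DNA_TOP.replace("X", "C")), id=f"dna_top_{mod}",
            description=f"12-bp duplex top strand 5'-FAM X={mod} position 3"))
        records.append(SeqRecord(
            Seq(_DNA_BOTTOM.replace("X", "C")), id=f"dna_bottom_{mod}",
            description=f"12-bp duplex bottom strand X={mod} position 9"))
    for mod in _RNA_MODS:
        records.append(SeqRecord(
            Seq(_RNA.replace("Y", "A")), id=f"rna_{mod}",
            description=f"16-nt RNA 5'-FAM Y={mod} position 8"))
    return SeqIO.write(records, out, "fasta")
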