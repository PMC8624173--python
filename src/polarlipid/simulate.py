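"""Synthetic LC-MS and microplate data with known ground truth.

Emulates a HILIC-LC-MS acquisition of the six-solvent extraction comparison
(CM, DM, DE, E, E+USB, E+USP; five replicates each) over the bundled
128-species polar lipidome:

* one MS1 feature per species per sample at the theoretical quantification
  adduct m/z perturbed by Normal(0, ppm SD), retention time at the class
  center plus jitter, and area = base x group multiplier x log-normal noise
  x a smooth injection-order batch trend;
* MS2 spectra per species and acquisition channel carrying the
  class-diagnostic fragments plus uniform noise peaks;
* internal-standard peaks at fixed nominal areas with their own noise;
* near-mass decoys placed at least 15 ppm from every library and standard
  m/z, and a handful of sub-floor junk features exercising the intensity
  filter.

Class retention-time centers follow HILIC head-group elution logic (neutral
glycolipids early, charged phospholipids late), spaced 2 min apart so class
windows never overlap; they are generator constants, not claims about any
real instrument.

Solvent effects are multiplicative depletions relative to the CM reference.
The default design concentrates depletion in the PI, PG, DGDG and SQDG
classes for the ethanol-containing solvents (strongest for E and DE,
intermediate for the ultrasound-assisted extracts) and plants stronger
effects on 16 discriminant species (6 PG, 5 PI, 3 DGDG, 1 PE, 1 PC).  The
discriminant design applies effects to ONLY those 16 species, leaving every
other species null, for FDR-controlled recovery experiments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (DEFAULT_TOLERANCE_PPM, MS1Feature, MS2Spectrum,
                         RTWindow, expected_fragments, ms2_channels)
from .antioxidant import KineticSeries
from .chem import LipidSpecies, adduct_mz
from .quantification import InternalStandard, default_standards

__all__ = [
    "GROUPS", "CLASS_RT_CENTERS", "STANDARD_RT", "SimulationDesign",
    "GroundTruth", "default_design", "discriminant_design",
    "DISCRIMINANT_SPECIES", "simulate_lcms", "default_rt_windows",
    "AssayDesign", "default_assay_design", "simulate_assay", "sample_ids",
]

GROUPS = ("CM", "DM", "DE", "E", "E+USB", "E+USP")

CLASS_RT_CENTERS: dict[str, float] = {
    "MGDG": 2.0, "DGDG": 4.0, "SQDG": 6.0, "MGMG": 8.0, "DGMG": 10.0,
    "SQMG": 12.0, "DGTS": 14.0, "MGTS": 16.0, "PG": 18.0, "PI": 20.0,
    "PE": 22.0, "PC": 24.0, "LPC": 26.0, "PI-Cer": 28.0,
}

# canonical internal-standard elution (generator constants)
STANDARD_RT: dict[str, float] = {
    "dMPC": 24.3, "dMPE": 22.3, "SM(d18:1/17:0)": 24.7, "LPC(19:0)": 26.3,
    "dPPI": 20.3, "dMPG": 18.3, "dMPS": 21.2, "dMPA": 17.3,
    "C17-Ceramide": 27.7,
}

# the 16 planted discriminant species: 6 PG, 5 PI, 3 DGDG, 1 PE, 1 PC
DISCRIMINANT_SPECIES: tuple[str, ...] = (
    "PG(14:0_20:5)", "PG(16:0_20:5)", "PG(16:1_20:5)",
    "PG(16:0_18:1)", "PG(18:1_20:5)", "PG(20:5_20:5)",
    "PI(16:0_16:1)", "PI(16:0_18:1)", "PI(16:1_18:1)",
    "PI(16:0_20:5)", "PI(16:1_20:5)",
    "DGDG(20:5/14:0)", "DGDG(20:5/16:0)", "DGDG(20:5/16:1)",
    "PE(16:0_20:5)", "PC(16:0_20:5)",
)

_CLASS_DEPLETION = {"DM": 1.0, "DE": 0.5, "E": 0.4, "E+USB": 0.85,
                    "E+USP": 0.88}
_SPECIES_DEPLETION = {"DM": 1.0, "DE": 0.45, "E": 0.35, "E+USB": 0.80,
                      "E+USP": 0.82}


@dataclass
class SimulationDesign:
    """Study conditions for one synthetic LC-MS dataset.

    Effect maps give per-group abundance multipliers relative to the CM
    reference (CM is always 1); species-level entries override class-level
    ones.  All multipliers must be positive.
    """
    replicates: int = 5
    class_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    species_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    ppm_sd: float = 1.0
    rt_jitter_sd: float = 0.1
    noise_sd: float = 0.25        # log-scale multiplicative
    standard_noise_sd: float = 0.1  # log-scale noise of IS peak areas
    batch_sd: float = 0.15        # strength of the injected batch trend
    n_decoys: int = 20
    n_subfloor: int = 10          # junk features below the intensity floor
    seed: int = 20211021

    def __post_init__(self):
        for emap in (self.class_effects, self.species_effects):
            for key, per_group in emap.items():
                if per_group.get("CM", 1.0) != 1.0:
                    raise ValueError("CM is the reference group; its "
                                     f"multiplier must be 1 ({key})")
                if any(m <= 0 for m in per_group.values()):
                    raise ValueError(f"non-positive multiplier for {key}")

    def multiplier(self, species: LipidSpecies, group: str) -> float:
        if species.name in self.species_effects:
            return self.species_effects[species.name].get(group, 1.0)
        if species.class_code in self.class_effects:
            return self.class_effects[species.class_code].get(group, 1.0)
        return 1.0


def default_design(seed: int = 20211021) -> SimulationDesign:
    """Class-level depletion of PI/PG/DGDG/SQDG in the ethanol-containing
    solvents plus stronger planted effects on the 16 discriminant species."""
    return SimulationDesign(
        class_effects={c: dict(_CLASS_DEPLETION)
                       for c in ("PI", "PG", "DGDG", "SQDG")},
        species_effects={s: dict(_SPECIES_DEPLETION)
                         for s in DISCRIMINANT_SPECIES},
        seed=seed,
    )


def discriminant_design(seed: int = 20211021) -> SimulationDesign:
    """Only the 16 discriminant species carry effects; all others are null."""
    return SimulationDesign(
        species_effects={s: dict(_SPECIES_DEPLETION)
                         for s in DISCRIMINANT_SPECIES},
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Everything needed to score recovery exactly."""
    sample_groups: dict[str, str]
    true_areas: pd.DataFrame          # species x samples, before noise
    standard_areas: pd.DataFrame      # standard x samples, as generated
    discriminant_species: tuple[str, ...]
    batch_trend: np.ndarray           # per-sample trend values
    decoy_mzs: np.ndarray
    design: SimulationDesign


def sample_ids(replicates: int = 5) -> list[str]:
    return [f"{g}_{r}" for g in GROUPS for r in range(1, replicates + 1)]


def default_rt_windows(half_width: float = 1.0) -> dict[str, RTWindow]:
    return {c: RTWindow(c, center, half_width)
            for c, center in CLASS_RT_CENTERS.items()}


def _decoy_mz(rng: np.random.Generator, protected: np.ndarray) -> float:
    """A near-mass decoy: 20-80 ppm off a random protected m/z, rejected
    until it is >= 15 ppm away from every protected m/z."""
    while True:
        base = float(rng.choice(protected))
        delta = rng.uniform(20.0, 80.0) * (1 if rng.random() < 0.5 else -1)
        mz = base * (1.0 + delta * 1e-6)
        if np.min(np.abs(mz - protected) / protected) * 1e6 >= 15.0:
            return mz


def simulate_lcms(design: SimulationDesign,
                  library: Sequence[LipidSpecies],
                  standards: Sequence[InternalStandard] | None = None,
                  ) -> tuple[list[MS1Feature], list[MS2Spectrum], GroundTruth]:
    """Generate MS1 feature tables, MS2 spectra and ground truth.

    Refuses ppm-error SDs of half the matching tolerance or more, which
    would break recovery by construction.
    """
    if design.ppm_sd >= DEFAULT_TOLERANCE_PPM / 2:
        raise ValueError(
            f"ppm-error SD {design.ppm_sd} >= tolerance/2 "
            f"({DEFAULT_TOLERANCE_PPM / 2}); recovery would fail by design")
    rng = np.random.default_rng(design.seed)
    if standards is None:
        standards = default_standards(STANDARD_RT)
    samples = sample_ids(design.replicates)
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    n = len(samples)

    lib_mzs = np.array([sp.quant_mz() for sp in library])
    protected = np.concatenate([lib_mzs, [s.mz for s in standards]])

    # smooth drift over injection order; samples are injected in randomized
    # order (standard practice: keeps acquisition drift from confounding
    # with the extraction groups)
    injection_order = rng.permutation(n)
    ramp = np.linspace(-1.0, 1.0, n)
    trend = ramp[injection_order]
    trend -= trend.mean()
    trend_loadings = rng.normal(0.0, 1.0, size=len(library))

    base_area = 10.0 ** rng.uniform(5.8, 7.0, size=len(library))

    features: list[MS1Feature] = []
    true_rows = {}
    for i, sp in enumerate(library):
        center = CLASS_RT_CENTERS[sp.class_code]
        theo_mz = lib_mzs[i]
        row = {}
        for j, sid in enumerate(samples):
            mult = design.multiplier(sp, groups[sid])
            true_area = base_area[i] * mult
            row[sid] = true_area
            area = (true_area
                    * math.exp(rng.normal(0.0, design.noise_sd))
                    * math.exp(design.batch_sd * trend_loadings[i] * trend[j]))
            mz = theo_mz * (1.0 + rng.normal(0.0, design.ppm_sd) * 1e-6)
            rt = max(0.0, center + rng.normal(0.0, design.rt_jitter_sd))
            features.append(MS1Feature(mz=mz, rt=rt, area=area,
                                       raw_intensity=area / 5.0,
                                       sample_id=sid))
        true_rows[sp.name] = row
    true_areas = pd.DataFrame(true_rows).T.loc[[sp.name for sp in library],
                                               samples]

    # internal standards: fixed nominal area scaled by spiked amount
    std_rows = {}
    for std in standards:
        nominal = 5.0e6 * std.amount_ug / 0.02
        row = {}
        for sid in samples:
            area = nominal * math.exp(rng.normal(0.0, design.standard_noise_sd))
            row[sid] = area
            mz = std.mz * (1.0 + rng.normal(0.0, design.ppm_sd) * 1e-6)
            rt = max(0.0, std.expected_rt
                     + rng.normal(0.0, design.rt_jitter_sd))
            features.append(MS1Feature(mz=mz, rt=rt, area=area,
                                       raw_intensity=area / 5.0,
                                       sample_id=sid))
        std_rows[std.name] = row
    standard_areas = pd.DataFrame(std_rows).T

    # decoys: one near-mass interference per decoy, present in every sample
    decoy_mzs = np.array([_decoy_mz(rng, protected)
                          for _ in range(design.n_decoys)])
    for mz0 in decoy_mzs:
        rt0 = rng.uniform(1.0, 29.0)
        for sid in samples:
            area = 10.0 ** rng.uniform(5.0, 6.0)
            features.append(MS1Feature(
                mz=mz0 * (1.0 + rng.normal(0.0, design.ppm_sd) * 1e-6),
                rt=max(0.0, rt0 + rng.normal(0.0, design.rt_jitter_sd)),
                area=area, raw_intensity=area / 5.0, sample_id=sid))

    # sub-floor junk exercising the raw-intensity filter
    for _ in range(design.n_subfloor):
        mz0 = _decoy_mz(rng, protected)
        sid = samples[int(rng.integers(0, n))]
        area = rng.uniform(1.0e3, 4.9e4)   # intensity = area/5 < 1e4
        features.append(MS1Feature(mz=mz0, rt=rng.uniform(1.0, 29.0),
                                   area=area, raw_intensity=area / 5.0,
                                   sample_id=sid))

    # MS2: one spectrum per species per distinct acquisition channel
    spectra: list[MS2Spectrum] = []
    for sp in library:
        channels = ms2_channels(sp)
        done = set()
        frags = expected_fragments(sp)
        for part, (adduct_label, polarity) in channels.items():
            if (adduct_label, polarity) in done:
                continue
            done.add((adduct_label, polarity))
            served = {p for p, chan in channels.items()
                      if chan == (adduct_label, polarity)}
            theo = adduct_mz(sp.neutral_mass, adduct_label)
            prec = theo * (1.0 + rng.normal(0.0, design.ppm_sd) * 1e-6)
            peaks = []
            for fr in frags:
                fr_part = "headgroup" if fr.group == "headgroup" else "chains"
                if fr_part not in served:
                    continue
                mz = prec - fr.value if fr.is_neutral_loss else fr.value
                if 50.0 < mz < prec + 5.0:
                    peaks.append((mz, float(rng.uniform(1e3, 1e5))))
            for _ in range(5):   # uniform noise peaks
                peaks.append((float(rng.uniform(100.0, prec)),
                              float(rng.uniform(1e2, 1e3))))
            spectra.append(MS2Spectrum(
                precursor_mz=prec, rt=CLASS_RT_CENTERS[sp.class_code],
                peaks=tuple(sorted(peaks)), polarity=polarity))

    truth = GroundTruth(sample_groups=groups, true_areas=true_areas,
                        standard_areas=standard_areas,
                        discriminant_species=DISCRIMINANT_SPECIES,
                        batch_trend=trend, decoy_mzs=decoy_mzs, design=design)
    return features, spectra, truth


# ---------------------------------------------------------------------------
# Microplate radical-scavenging assay
# ---------------------------------------------------------------------------

@dataclass
class AssayDesign:
    """Plate layout and kinetics for a synthetic ABTS/DPPH assay.

    ``strengths`` are scavenging potencies per extract group; endpoint
    inhibition follows the saturating dose response
    100 * (1 - exp(-strength * conc / 300)), a non-linear antioxidant
    response.  Concentrations are final in-well values in ug/mL.
    """
    radical: str = "ABTS"
    strengths: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.0, "E": 0.45, "E+USB": 0.95,
                                 "E+USP": 0.97})
    concentrations: tuple[float, ...] = (50.0, 250.0, 500.0)
    trolox_concentrations: tuple[float, ...] = (5.0, 15.0, 30.0, 50.0, 75.0)
    trolox_slope: float = 1.2        # % inhibition per umol/L
    a_radical: float = 0.9           # working-solution absorbance
    blank_decline: float = 0.05      # fractional decline of the blank
    noise_sd: float = 0.004          # absorbance noise per read
    n_replicates: int = 3
    read_interval: float = 5.0       # minutes
    duration: float = 120.0
    seed: int = 20211021


def default_assay_design(seed: int = 20211021, radical: str = "ABTS"
                         ) -> AssayDesign:
    return AssayDesign(radical=radical, seed=seed)


def _curve(rng, times, a0, a_end, noise_sd):
    if a0 <= a_end:
        vals = np.full_like(times, a0)
    else:
        k = -math.log(max(a_end, 1e-9) / a0) / times[-1]
        vals = a0 * np.exp(-k * times)
        vals = np.maximum(vals, a_end)
    vals = vals + rng.normal(0.0, noise_sd, size=len(times))
    return tuple((float(t), float(max(v, 0.0)))
                 for t, v in zip(times, vals))


def simulate_assay(design: AssayDesign) -> list[KineticSeries]:
    """Triplicate sample/control/standard/blank wells with decay kinetics."""
    rng = np.random.default_rng(design.seed)
    times = np.arange(0.0, design.duration + design.read_interval / 2,
                      design.read_interval)
    wells: list[KineticSeries] = []
    w = 0

    def well_id():
        nonlocal w
        w += 1
        return f"W{w:03d}"

    a_rad = design.a_radical
    for _ in range(16):   # radical stability blanks
        end = a_rad * (1.0 - design.blank_decline)
        wells.append(KineticSeries(well=well_id(), role="radical_blank",
                                   reads=_curve(rng, times, a_rad, end,
                                                design.noise_sd)))
    for conc in design.trolox_concentrations:
        inhib = min(design.trolox_slope * conc, 99.0)
        end = a_rad * (1.0 - inhib / 100.0)
        for _ in range(design.n_replicates):
            wells.append(KineticSeries(
                well=well_id(), role="trolox_standard", concentration=conc,
                label="Trolox",
                reads=_curve(rng, times, a_rad, end, design.noise_sd)))
    for group, strength in design.strengths.items():
        for conc in design.concentrations:
            a_ctrl = 0.002 * conc / 50.0      # extract colour, no radical
            inhib = 100.0 * (1.0 - math.exp(-strength * conc / 300.0))
            end = a_ctrl + a_rad * (1.0 - inhib / 100.0)
            for _ in range(design.n_replicates):
                wells.append(KineticSeries(
                    well=well_id(), role="sample", concentration=conc,
                    label=group,
                    reads=_curve(rng, times, a_ctrl + a_rad, end,
                                 design.noise_sd)))
                wells.append(KineticSeries(
                    well=well_id(), role="control", concentration=conc,
                    label=group,
                    reads=_curve(rng, times, a_ctrl, a_ctrl,
                                 design.noise_sd)))
    return wells
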