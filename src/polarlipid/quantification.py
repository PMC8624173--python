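"""Internal-standard normalization of identified lipid XIC areas.

Each species' XIC area is divided, per sample, by the area of a spiked
internal standard.  Standards are assigned by lipid class when a chemically
matching standard exists (PC->dMPC, LPC->LPC(19:0), PE->dMPE, PI->dPPI,
PG->dMPG, PI-Cer->C17-Ceramide); classes without a matching standard
(glycolipids and betaine lipids) fall back to the standard with the closest
retention time, ties broken by standard name order.  The resulting abundance
matrix is dimensionless and invariant to any uniform rescaling of a sample's
signal — the property IS normalization exists to provide.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MS1Feature, ppm_error
from .chem import adduct_mz, constants, monoisotopic_mass

__all__ = [
    "InternalStandard", "AbundanceMatrix", "default_standards",
    "assign_internal_standard", "extract_standard_areas",
    "normalize_abundances", "CLASS_STANDARD_MAP",
]

log = logging.getLogger(__name__)

# inferred from the composition of the spiked IS mix; all other classes use
# the closest-retention-time fallback
CLASS_STANDARD_MAP = {
    "PC": "dMPC",
    "LPC": "LPC(19:0)",
    "PE": "dMPE",
    "PI": "dPPI",
    "PG": "dMPG",
    "PI-Cer": "C17-Ceramide",
}


@dataclass
class InternalStandard:
    name: str
    represents: str | None       # lipid class, or None (fallback-only)
    amount_ug: float
    expected_rt: float           # minutes
    mz: float                    # quantification adduct m/z
    ion_mode: str                # "+" or "-"
    areas: dict[str, float] = field(default_factory=dict)  # per sample

    def __post_init__(self):
        if self.amount_ug <= 0:
            raise ValueError("spiked amount must be positive")


def default_standards(rt_by_name: Mapping[str, float]) -> list[InternalStandard]:
    """Build the spiked IS mix from the constants file.

    ``rt_by_name`` supplies the expected retention time of each standard
    (instrument-specific; the synthetic generator provides its canonical
    values).  m/z is [M+H]+ for positive-mode standards, [M-H]- for negative.
    """
    out = []
    for entry in constants()["internal_standards"]:
        mass = monoisotopic_mass(entry["formula"])
        adduct = "[M+H]+" if entry["ion_mode"] == "+" else "[M-H]-"
        out.append(InternalStandard(
            name=entry["name"],
            represents=entry["represents"],
            amount_ug=float(entry["amount_ug"]),
            expected_rt=float(rt_by_name[entry["name"]]),
            mz=adduct_mz(mass, adduct),
            ion_mode=entry["ion_mode"],
        ))
    return out


def assign_internal_standard(class_code: str, rt: float,
                             standards: Sequence[InternalStandard]
                             ) -> InternalStandard:
    """The standard for a species: class-mapped if available, else closest RT."""
    if not standards:
        raise ValueError("empty internal standard list")
    by_name = {s.name: s for s in standards}
    mapped = CLASS_STANDARD_MAP.get(class_code)
    if mapped is not None and mapped in by_name:
        return by_name[mapped]
    return min(standards, key=lambda s: (abs(s.expected_rt - rt), s.name))


def extract_standard_areas(features: Iterable[MS1Feature],
                           standards: Sequence[InternalStandard],
                           tolerance_ppm: float = 10.0,
                           rt_half_width: float = 1.0) -> None:
    """Fill each standard's per-sample area from the feature tables in place.

    A standard's peak is the largest-area feature within tolerance of its m/z
    and within ``rt_half_width`` minutes of its expected retention time.
    """
    for feat in features:
        for std in standards:
            if (abs(ppm_error(feat.mz, std.mz)) <= tolerance_ppm
                    and abs(feat.rt - std.expected_rt) <= rt_half_width):
                prev = std.areas.get(feat.sample_id, 0.0)
                if feat.area > prev:
                    std.areas[feat.sample_id] = feat.area


@dataclass
class AbundanceMatrix:
    """Species x samples normalized abundances with group labels.

    ``data`` rows are species names, columns sample ids.  ``groups`` maps each
    retained sample to its extraction-method group.  ``missing`` flags
    (species, sample) cells where the species had no identified feature;
    ``flagged_samples`` lists samples excluded for invalid standard areas.
    """
    data: pd.DataFrame
    groups: pd.Series
    species_class: pd.Series
    missing: pd.DataFrame
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValueError("normalized abundances must be non-negative")
        if set(self.data.columns) - set(self.groups.index):
            raise ValueError("every sample column needs a group label")


def normalize_abundances(identifications: pd.DataFrame,
                         standards: Sequence[InternalStandard],
                         sample_groups: Mapping[str, str],
                         rt_windows: Mapping[str, object] | None = None,
                         ) -> AbundanceMatrix:
    """Area-ratio abundance matrix from an identification table.

    value = species XIC area / assigned internal-standard area, per sample.
    Species absent in a sample get 0 with a missingness flag.  Samples where
    any required standard has non-positive area are flagged and excluded.
    """
    if identifications.empty:
        raise ValueError("empty identification table")
    species_names = sorted(identifications["species"].unique())
    samples = sorted(sample_groups)
    sp_class = (identifications.drop_duplicates("species")
                .set_index("species")["class_code"])

    # species RT: mean observed RT, used for closest-RT standard fallback
    sp_rt = identifications.groupby("species")["rt"].mean()
    assignment = {name: assign_internal_standard(sp_class[name], sp_rt[name],
                                                 standards)
                  for name in species_names}

    flagged = []
    for sample in samples:
        needed = {std.name: std for std in assignment.values()}
        bad = [n for n, s in needed.items() if s.areas.get(sample, 0.0) <= 0]
        if bad:
            warnings.warn(
                f"sample {sample}: internal standard(s) {', '.join(sorted(bad))} "
                "missing or non-positive; sample excluded from statistics",
                stacklevel=2)
            flagged.append(sample)
    kept = [s for s in samples if s not in flagged]

    area = identifications.pivot_table(index="species", columns="sample_id",
                                       values="area", aggfunc="max")
    data = pd.DataFrame(0.0, index=species_names, columns=kept)
    missing = pd.DataFrame(False, index=species_names, columns=kept)
    for name in species_names:
        std = assignment[name]
        for sample in kept:
            a = area.at[name, sample] if sample in area.columns else np.nan
            if pd.isna(a):
                missing.at[name, sample] = True
            else:
                data.at[name, sample] = a / std.areas[sample]
    groups = pd.Series({s: sample_groups[s] for s in kept})
    return AbundanceMatrix(data=data, groups=groups,
                           species_class=sp_class.loc[species_names],
                           missing=missing, flagged_samples=flagged)
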