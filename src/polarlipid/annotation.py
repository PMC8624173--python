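"""MS1/MS2 rule-based lipid annotation.

MS1 features are matched to library species at a ppm tolerance (default 5)
inside class-specific retention-time windows, after an absolute raw-intensity
floor (default 1e4; features exactly at the floor are kept — the exclusion
rule is strict "lower than").  Identities are then confirmed against
class-specific MS/MS diagnostics:

* PC/LPC — phosphocholine head-group ion in [M+H]+; acyl chains as
  carboxylate anions (RCOO-) in the acetate adduct [M+CH3COO]-.
* PE — head-group neutral loss in [M+H]+; chains as RCOO- in [M-H]-.
* DGTS/MGTS — betaine head-group ions in [M+H]+; chains as neutral losses of
  the free acid (RCOOH) or ketene (R=C=O).
* MGDG/MGMG/DGDG/DGMG — galactosyl head-group loss from [M+NH4]+; chains as
  acylium-plus-74 ions ([RCO+74]+).
* SQDG/SQMG/PG/PI — class head-group ion and RCOO- chains in [M-H]-.
* PI-Cer — inositol-phosphate head-group ion in [M-H]-; no chain-level
  fragment is diagnostic, so chain evidence is not required (the class is
  identified at sum-composition level).

A species is reported only when, given MS2 coverage of its precursor, both
head group and chains are confirmed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .chem import (ADDUCTS, ATOMIC_MASS, ELECTRON_MASS, AcylChain,
                   LipidSpecies, adduct_mz, class_definitions, constants,
                   monoisotopic_mass)

__all__ = [
    "MS1Feature", "MS2Spectrum", "AnnotationHit", "RTWindow", "ExpectedFragment",
    "ppm_error", "filter_features", "match_ms1", "expected_fragments",
    "validate_ms2", "validate_hits", "assemble_identifications",
    "DEFAULT_TOLERANCE_PPM", "DEFAULT_INTENSITY_FLOOR",
    "DEFAULT_FRAG_TOLERANCE_DA", "DEFAULT_PRECURSOR_TOLERANCE_PPM",
    "MS2_STATUS_ORDER",
]

log = logging.getLogger(__name__)

DEFAULT_TOLERANCE_PPM = 5.0
DEFAULT_INTENSITY_FLOOR = 1e4
DEFAULT_FRAG_TOLERANCE_DA = 0.01   # Orbitrap MS2 at 17,500 resolution
DEFAULT_PRECURSOR_TOLERANCE_PPM = 10.0

MS2_STATUS_ORDER = ["ms1_only", "confirmed_headgroup", "confirmed_chains",
                    "confirmed_both"]

_OH = ATOMIC_MASS["O"] + ATOMIC_MASS["H"]
_H2O = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
_PROTON = ATOMIC_MASS["H"] - ELECTRON_MASS
_C3H6O2 = 3 * ATOMIC_MASS["C"] + 6 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["O"]


@dataclass(frozen=True)
class MS1Feature:
    mz: float
    rt: float                 # minutes
    area: float               # integrated XIC area
    raw_intensity: float
    sample_id: str

    def __post_init__(self):
        if self.mz <= 0 or self.rt < 0 or self.area < 0:
            raise ValueError("invalid MS1 feature")


@dataclass(frozen=True)
class MS2Spectrum:
    precursor_mz: float
    rt: float
    peaks: tuple[tuple[float, float], ...]   # (fragment m/z, intensity), sorted
    polarity: str                            # "+" or "-"

    def __post_init__(self):
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks",
                               tuple(sorted(self.peaks, key=lambda p: p[0])))
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("negative fragment intensity")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")


@dataclass(frozen=True)
class RTWindow:
    class_code: str
    center: float
    half_width: float

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def contains(self, rt: float) -> bool:
        return abs(rt - self.center) <= self.half_width


@dataclass(frozen=True)
class AnnotationHit:
    species: LipidSpecies
    feature: MS1Feature
    adduct: str
    ppm_error: float
    ms2_status: str = "ms1_only"
    matched_fragments: tuple[str, ...] = ()
    ms2_seen: bool = False    # an MS2 spectrum covered this species' precursor


@dataclass(frozen=True)
class ExpectedFragment:
    label: str
    value: float              # fragment m/z, or neutral-loss mass in Da
    is_neutral_loss: bool
    group: str                # "headgroup" or chain token, e.g. "20:5"
    requirement: str          # "mandatory" or "any_of"


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def filter_features(features: Iterable[MS1Feature],
                    intensity_floor: float = DEFAULT_INTENSITY_FLOOR
                    ) -> list[MS1Feature]:
    """Drop features with raw intensity strictly below the floor."""
    if intensity_floor < 0:
        raise ValueError("intensity floor must be non-negative")
    return [f for f in features if f.raw_intensity >= intensity_floor]


def match_ms1(features: Iterable[MS1Feature],
              library: Sequence[LipidSpecies],
              tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
              rt_windows: Mapping[str, RTWindow] | None = None,
              ) -> list[AnnotationHit]:
    """All (feature, species) pairs within tolerance and class RT window.

    A feature matching several species keeps every candidate at this stage;
    competition is resolved in :func:`assemble_identifications`.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if rt_windows is None:
        rt_windows = {}
    hits: list[AnnotationHit] = []
    classes = {sp.class_code for sp in library}
    missing = classes - set(rt_windows)
    if missing:
        raise ValueError(
            "no retention-time window configured for class(es): "
            + ", ".join(sorted(missing)))
    targets = [(sp, sp.quant_mz(), class_definitions()[sp.class_code].quant_adduct,
                rt_windows[sp.class_code]) for sp in library]
    for feat in features:
        for sp, theo_mz, adduct, window in targets:
            err = ppm_error(feat.mz, theo_mz)
            if abs(err) <= tolerance_ppm and window.contains(feat.rt):
                hits.append(AnnotationHit(species=sp, feature=feat,
                                          adduct=adduct, ppm_error=err))
    return hits


def _ion_mz(spec: Mapping) -> float:
    mass = monoisotopic_mass(spec["formula"])
    return mass - int(spec["charge"]) * ELECTRON_MASS


def expected_fragments(species: LipidSpecies) -> list[ExpectedFragment]:
    """Fully enumerated class-diagnostic fragments for a species.

    Chain fragments: carboxylate RCOO- = FA - proton; acylium-plus-74 =
    (FA - OH - e) + C3H6O2; acid loss = FA; ketene loss = FA - H2O.
    Head-group ions/losses come from the constants file.
    """
    cd = class_definitions()[species.class_code]
    try:
        rule = constants()["rules"][cd.ms2_rule]
    except KeyError:
        raise KeyError(f"unknown diagnostic rule {cd.ms2_rule!r}") from None
    out: list[ExpectedFragment] = []
    for ion in rule["headgroup"]["ions"]:
        out.append(ExpectedFragment(
            label=f"headgroup ion {ion['formula']}", value=_ion_mz(ion),
            is_neutral_loss=False, group="headgroup", requirement="any_of"))
    for loss in rule["headgroup"]["losses"]:
        out.append(ExpectedFragment(
            label=f"headgroup loss {loss}", value=monoisotopic_mass(loss),
            is_neutral_loss=True, group="headgroup", requirement="any_of"))
    kind = rule["chains"]["kind"]
    if kind != "none" and species.chains is not None:
        for ch in set(species.chains):
            fa = ch.mass
            token = str(ch)
            if kind == "carboxylate":
                out.append(ExpectedFragment(
                    label=f"RCOO- {token}", value=fa - _PROTON,
                    is_neutral_loss=False, group=token, requirement="any_of"))
            elif kind == "acyl74":
                acylium = fa - _OH - ELECTRON_MASS
                out.append(ExpectedFragment(
                    label=f"[RCO+74]+ {token}", value=acylium + _C3H6O2,
                    is_neutral_loss=False, group=token, requirement="any_of"))
            elif kind == "acid_or_ketene":
                out.append(ExpectedFragment(
                    label=f"acid loss {token}", value=fa,
                    is_neutral_loss=True, group=token, requirement="any_of"))
                out.append(ExpectedFragment(
                    label=f"ketene loss {token}", value=fa - _H2O,
                    is_neutral_loss=True, group=token, requirement="any_of"))
            else:
                raise KeyError(f"unknown chain rule kind {kind!r}")
    return out


def ms2_channels(species: LipidSpecies) -> dict[str, tuple[str, str]]:
    """MS2 acquisition channels for a species.

    Returns {"headgroup": (adduct, polarity), "chains": (adduct, polarity)}.
    The chain channel may use a different adduct than quantification (acetate
    adducts for PC/LPC).
    """
    cd = class_definitions()[species.class_code]
    rule = constants()["rules"][cd.ms2_rule]
    out = {}
    for part in ("headgroup", "chains"):
        adduct = rule[part]["adduct"]
        polarity = "+" if ADDUCTS[adduct].charge > 0 else "-"
        out[part] = (adduct, polarity)
    return out


def _chains_required(species: LipidSpecies) -> bool:
    cd = class_definitions()[species.class_code]
    rule = constants()["rules"][cd.ms2_rule]
    return rule["chains"]["kind"] != "none" and species.chains is not None


def _status(headgroup_ok: bool, chains_ok: bool) -> str:
    if headgroup_ok and chains_ok:
        return "confirmed_both"
    if chains_ok:
        return "confirmed_chains"
    if headgroup_ok:
        return "confirmed_headgroup"
    return "ms1_only"


def _served_parts(species: LipidSpecies, spectrum: MS2Spectrum,
                  precursor_tolerance_ppm: float) -> set[str]:
    """Which evidence channels ("headgroup"/"chains") a spectrum serves."""
    out = set()
    for part, (adduct, polarity) in ms2_channels(species).items():
        theo = adduct_mz(species.neutral_mass, adduct)
        if (spectrum.polarity == polarity and
                abs(ppm_error(spectrum.precursor_mz, theo)) <=
                precursor_tolerance_ppm):
            out.add(part)
    return out


def _match_spectrum(species: LipidSpecies, spectrum: MS2Spectrum,
                    frag_tolerance: float, served: set[str]
                    ) -> tuple[bool, set[str], list[str]]:
    """Evaluate one spectrum: (headgroup_ok, confirmed chain tokens, labels).

    Only fragments belonging to a channel the spectrum serves are credited:
    chain diagnostics of a dual-adduct class never count in the head-group
    channel and vice versa.
    """
    frags = expected_fragments(species)
    peak_mzs = [p[0] for p in spectrum.peaks]
    matched_groups: dict[str, bool] = {}
    labels: list[str] = []

    def present(mz: float) -> bool:
        return any(abs(p - mz) <= frag_tolerance for p in peak_mzs)

    for frag in frags:
        part = "headgroup" if frag.group == "headgroup" else "chains"
        if part not in served:
            continue
        target = (spectrum.precursor_mz - frag.value if frag.is_neutral_loss
                  else frag.value)
        if present(target):
            matched_groups[frag.group] = True
            labels.append(frag.label)
    chains = {g for g in matched_groups if g != "headgroup"}
    return matched_groups.get("headgroup", False), chains, labels


def validate_ms2(hit: AnnotationHit, spectrum: MS2Spectrum,
                 frag_tolerance: float = DEFAULT_FRAG_TOLERANCE_DA,
                 precursor_tolerance_ppm: float = DEFAULT_PRECURSOR_TOLERANCE_PPM,
                 ) -> AnnotationHit:
    """Update one hit's MS2 status from a single spectrum.

    The spectrum must match one of the species' MS2 channels (precursor within
    tolerance of that channel's adduct m/z, same polarity); otherwise the hit
    is returned unchanged with the reason logged.
    """
    sp = hit.species
    served = _served_parts(sp, spectrum, precursor_tolerance_ppm)
    if not served:
        log.debug("spectrum at m/z %.4f (%s) does not match any MS2 channel "
                  "of %s; hit left %s", spectrum.precursor_mz,
                  spectrum.polarity, sp.name, hit.ms2_status)
        return hit
    hg_ok, chain_tokens, labels = _match_spectrum(sp, spectrum,
                                                  frag_tolerance, served)
    hit = replace(hit, ms2_seen=True)
    prev_hg = hit.ms2_status in ("confirmed_headgroup", "confirmed_both")
    prev_ch = hit.ms2_status in ("confirmed_chains", "confirmed_both")
    hg_ok = hg_ok or prev_hg
    if _chains_required(sp):
        need = {str(c) for c in set(sp.chains)}
        have = chain_tokens | (need if prev_ch else set())
        chains_ok = need <= have
    else:
        chains_ok = True
    return replace(hit, ms2_status=_status(hg_ok, chains_ok),
                   matched_fragments=tuple(hit.matched_fragments) + tuple(labels))


def validate_hits(hits: Iterable[AnnotationHit],
                  spectra: Sequence[MS2Spectrum],
                  frag_tolerance: float = DEFAULT_FRAG_TOLERANCE_DA,
                  precursor_tolerance_ppm: float = DEFAULT_PRECURSOR_TOLERANCE_PPM,
                  ) -> list[AnnotationHit]:
    """Validate hits against a spectra collection, pooling evidence per species.

    Evidence is aggregated across spectra (e.g. PC head group from [M+H]+ and
    chains from the acetate adduct).  Species with no matching spectrum stay
    ms1_only.
    """
    # group spectra by polarity with sorted precursors for fast lookup
    by_pol: dict[str, list[MS2Spectrum]] = {"+": [], "-": []}
    for s in spectra:
        by_pol[s.polarity].append(s)
    for pol in by_pol:
        by_pol[pol].sort(key=lambda s: s.precursor_mz)

    # evaluate each species once
    cache: dict[str, tuple[str, tuple[str, ...], bool]] = {}
    out: list[AnnotationHit] = []
    for hit in hits:
        sp = hit.species
        if sp.name not in cache:
            hg_ok = False
            chain_tokens: set[str] = set()
            labels: list[str] = []
            ms2_seen = False
            for part, (adduct, polarity) in ms2_channels(sp).items():
                theo = adduct_mz(sp.neutral_mass, adduct)
                tol = theo * precursor_tolerance_ppm * 1e-6
                for s in by_pol[polarity]:
                    if abs(s.precursor_mz - theo) > tol:
                        continue
                    ms2_seen = True
                    hg, ch, lab = _match_spectrum(sp, s, frag_tolerance,
                                                  {part})
                    hg_ok = hg_ok or hg
                    chain_tokens |= ch
                    labels.extend(lab)
            if _chains_required(sp):
                chains_ok = {str(c) for c in set(sp.chains)} <= chain_tokens
            else:
                chains_ok = True
            cache[sp.name] = (_status(hg_ok, chains_ok),
                              tuple(dict.fromkeys(labels)), ms2_seen)
        status, labels, seen = cache[sp.name]
        out.append(replace(hit, ms2_status=status, matched_fragments=labels,
                           ms2_seen=seen))
    return out


def assemble_identifications(hits: Iterable[AnnotationHit],
                             rt_windows: Mapping[str, RTWindow] | None = None,
                             require_ms2: bool = True):
    """One best hit per (species, sample) as a deterministic table.

    Competition is resolved by (1) highest MS2 status, (2) smallest absolute
    ppm error, (3) smallest RT distance to the class window center.  When MS2
    spectra existed for a species' precursor, only confirmed_both species are
    reported (``require_ms2``); species with no MS2 coverage are kept as
    ms1_only.
    """
    import pandas as pd

    rank = {s: i for i, s in enumerate(MS2_STATUS_ORDER)}
    best: dict[tuple[str, str], AnnotationHit] = {}
    for hit in hits:
        if require_ms2 and hit.ms2_seen and hit.ms2_status != "confirmed_both":
            continue
        key = (hit.species.name, hit.feature.sample_id)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = hit
            continue
        def sortkey(h: AnnotationHit):
            center = (rt_windows[h.species.class_code].center
                      if rt_windows else 0.0)
            return (-rank[h.ms2_status], abs(h.ppm_error),
                    abs(h.feature.rt - center))
        if sortkey(hit) < sortkey(incumbent):
            best[key] = hit
    rows = []
    for (name, sample_id), hit in sorted(best.items()):
        rows.append({
            "species": name,
            "class_code": hit.species.class_code,
            "sum_composition": hit.species.sum_composition,
            "sample_id": sample_id,
            "adduct": hit.adduct,
            "mz": hit.feature.mz,
            "rt": hit.feature.rt,
            "area": hit.feature.area,
            "raw_intensity": hit.feature.raw_intensity,
            "ppm_error": hit.ppm_error,
            "ms2_status": hit.ms2_status,
        })
    cols = ["species", "class_code", "sum_composition", "sample_id", "adduct",
            "mz", "rt", "area", "raw_intensity", "ppm_error", "ms2_status"]
    return pd.DataFrame(rows, columns=cols)
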