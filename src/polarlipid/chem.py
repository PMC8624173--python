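"""In-silico polar lipid database: formulas, masses, adducts, species libraries.

The 14 lipid classes covered are the polar lipidome of *Nannochloropsis*:
galactolipids (MGDG/MGMG/DGDG/DGMG), the sulfolipid pair (SQDG/SQMG), betaine
lipids (DGTS/MGTS), and the phospholipids PC/LPC, PE, PG, PI and PI-Cer.
A species is composed as

    formula = backbone + sum(free fatty acid formulas) - n_acyl * H2O

where the backbone is the fully hydroxylated glycerol+headgroup core (for
PI-Cer, the sphingoid-base+inositol-phosphate core; the amide-linked fatty
acid plays the role of the single "acyl" chain).  Backbones live in
``constants.yaml``, each verified against a LIPID MAPS record.

Monoisotopic masses use IUPAC atomic masses of the most abundant isotopes;
adduct m/z values include the electron mass (charged-species convention),
which at 5 ppm on m/z ~500 (0.0025 Da) is borderline significant.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ATOMIC_MASS", "ELECTRON_MASS", "ADDUCTS", "AdductSpec", "AcylChain",
    "LipidClassDef", "LipidSpecies", "parse_formula", "format_formula",
    "formula_add", "formula_sub", "monoisotopic_mass", "compose_formula",
    "adduct_mz", "make_species", "enumerate_species", "load_library",
    "write_library", "default_library", "class_definitions", "constants",
]

# most abundant isotope, IUPAC 2013
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}
ELECTRON_MASS = 0.00054857990946

H2O = {"H": 2, "O": 1}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a formula contains an element outside the supported set."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``C42H82NO8P`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise UnknownElementError(f"unknown element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
    if pos != len(text) or not counts:
        raise ValueError(f"malformed formula {text!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Hill order: C, H, then remaining elements alphabetically."""
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def formula_add(a: Mapping[str, int], b: Mapping[str, int]) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + n
    return {el: n for el, n in out.items() if n}


def formula_sub(a: Mapping[str, int], b: Mapping[str, int]) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) - n
        if out[el] < 0:
            raise ValueError(
                f"negative count for {el} subtracting {format_formula(b)} "
                f"from {format_formula(a)}"
            )
    return {el: n for el, n in out.items() if n}


def formula_scale(a: Mapping[str, int], k: int) -> dict[str, int]:
    return {el: n * k for el, n in a.items() if n * k}


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass in Da of an elemental composition."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise ValueError("empty formula")
    mass = 0.0
    for el, n in formula.items():
        if el not in ATOMIC_MASS:
            raise UnknownElementError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative count for {el}")
        mass += ATOMIC_MASS[el] * n
    return mass


@dataclass(frozen=True)
class AdductSpec:
    label: str
    mass_delta: float
    charge: int

    def mz(self, neutral_mass: float) -> float:
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return neutral_mass + self.mass_delta


def _proton() -> float:
    return ATOMIC_MASS["H"] - ELECTRON_MASS


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", _proton(), +1),
    "[M+NH4]+": AdductSpec(
        "[M+NH4]+", ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] - ELECTRON_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -_proton(), -1),
    "[M+CH3COO]-": AdductSpec(
        "[M+CH3COO]-",
        2 * ATOMIC_MASS["C"] + 3 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["O"]
        + ELECTRON_MASS, -1),
}


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged adduct of a neutral species."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(f"unknown adduct label {adduct!r}") from None
    return adduct.mz(neutral_mass)


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty acyl chain in C:D shorthand; free acid formula C_c H_(2c-2d) O2."""
    carbons: int
    double_bonds: int

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        if not 0 <= self.double_bonds <= (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the maximum "
                f"double-bond count for {self.carbons} carbons")

    @property
    def formula(self) -> dict[str, int]:
        return {"C": self.carbons,
                "H": 2 * self.carbons - 2 * self.double_bonds,
                "O": 2}

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, token: str) -> "AcylChain":
        m = re.fullmatch(r"(\d+):(\d+)", token.strip())
        if not m:
            raise ValueError(f"malformed C:D token {token!r}")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class LipidClassDef:
    class_code: str
    n_acyl: int
    backbone: dict[str, int] = field(compare=False)
    quant_adduct: str
    ms2_rule: str

    @property
    def quant_mode(self) -> str:
        return "+" if ADDUCTS[self.quant_adduct].charge > 0 else "-"


def _load_constants() -> dict:
    with resources.files("polarlipid").joinpath("constants.yaml").open() as fh:
        return yaml.safe_load(fh)


_CONSTANTS: dict | None = None


def constants() -> dict:
    global _CONSTANTS
    if _CONSTANTS is None:
        _CONSTANTS = _load_constants()
    return _CONSTANTS


_CLASSDEFS: dict[str, LipidClassDef] | None = None


def class_definitions() -> dict[str, LipidClassDef]:
    """The 14 polar lipid class definitions, keyed by class code."""
    global _CLASSDEFS
    if _CLASSDEFS is None:
        _CLASSDEFS = {}
        for code, cfg in constants()["classes"].items():
            _CLASSDEFS[code] = LipidClassDef(
                class_code=code,
                n_acyl=int(cfg["n_acyl"]),
                backbone=parse_formula(cfg["backbone"]),
                quant_adduct=cfg["quant_adduct"],
                ms2_rule=cfg["rule"],
            )
    return _CLASSDEFS


# PI-Cer sum compositions include the sphingoid base (d18:1 by default):
# the stored chain is the amide-linked fatty acid only.
PICER_BASE_CARBONS = 18
PICER_BASE_DOUBLE_BONDS = 1


def compose_formula(classdef: LipidClassDef,
                    chains: Iterable[AcylChain]) -> dict[str, int]:
    """Elemental formula of a species: backbone + FAs - n_acyl * H2O."""
    chains = list(chains)
    if len(chains) != classdef.n_acyl:
        raise ValueError(
            f"{classdef.class_code} takes {classdef.n_acyl} chain(s), "
            f"got {len(chains)}")
    out = dict(classdef.backbone)
    for ch in chains:
        out = formula_add(out, ch.formula)
    return formula_sub(out, formula_scale(H2O, classdef.n_acyl))


def _compose_formula_sum(classdef: LipidClassDef, carbons: int,
                         double_bonds: int) -> dict[str, int]:
    # sum of n_acyl FA formulas depends only on (total C, total DB)
    fa_sum = {"C": carbons, "H": 2 * carbons - 2 * double_bonds,
              "O": 2 * classdef.n_acyl}
    out = formula_add(classdef.backbone, fa_sum)
    return formula_sub(out, formula_scale(H2O, classdef.n_acyl))


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species: class + acyl composition with derived formula/mass.

    ``chains`` is None when only the sum composition (total C : total DB of
    the acyl part) is known.  For PI-Cer the chain/sum refers to the
    amide-linked fatty acid; the rendered name includes the d18:1 base.
    """
    class_code: str
    chains: tuple[AcylChain, ...] | None
    sum_carbons: int
    sum_double_bonds: int
    sn_resolved: bool
    formula: dict[str, int] = field(compare=False)
    neutral_mass: float = field(compare=False)

    @property
    def name(self) -> str:
        if self.class_code == "PI-Cer":
            c = self.sum_carbons + PICER_BASE_CARBONS
            d = self.sum_double_bonds + PICER_BASE_DOUBLE_BONDS
            return f"PI-Cer(d{c}:{d})"
        if self.chains is None:
            body = f"{self.sum_carbons}:{self.sum_double_bonds}"
        else:
            sep = "/" if self.sn_resolved else "_"
            shown = self.chains if self.sn_resolved else tuple(sorted(self.chains))
            body = sep.join(str(ch) for ch in shown)
        return f"{self.class_code}({body})"

    @property
    def sum_composition(self) -> str:
        return f"{self.sum_carbons}:{self.sum_double_bonds}"

    def quant_mz(self) -> float:
        cd = class_definitions()[self.class_code]
        return adduct_mz(self.neutral_mass, cd.quant_adduct)


def make_species(class_code: str,
                 chains: Iterable[AcylChain] | None = None,
                 sum_composition: tuple[int, int] | None = None,
                 sn_resolved: bool = False) -> LipidSpecies:
    """Build a LipidSpecies from explicit chains or a sum composition."""
    try:
        cd = class_definitions()[class_code]
    except KeyError:
        raise KeyError(f"unknown lipid class {class_code!r}") from None
    if chains is not None:
        chains = tuple(chains)
        formula = compose_formula(cd, chains)
        carbons = sum(ch.carbons for ch in chains)
        dbs = sum(ch.double_bonds for ch in chains)
    elif sum_composition is not None:
        carbons, dbs = sum_composition
        formula = _compose_formula_sum(cd, carbons, dbs)
        sn_resolved = False
    else:
        raise ValueError("either chains or sum_composition is required")
    return LipidSpecies(
        class_code=class_code, chains=chains, sum_carbons=carbons,
        sum_double_bonds=dbs, sn_resolved=bool(sn_resolved),
        formula=formula, neutral_mass=monoisotopic_mass(formula))


def enumerate_species(classdef: LipidClassDef,
                      chain_pool: Iterable[AcylChain]) -> list[LipidSpecies]:
    """All distinct chain multisets from the pool for the class's n_acyl."""
    pool = sorted(set(chain_pool))
    if not pool:
        raise ValueError("empty chain pool")
    out: list[LipidSpecies] = []
    if classdef.n_acyl == 1:
        combos = [(ch,) for ch in pool]
    else:
        combos = [(pool[i], pool[j])
                  for i in range(len(pool)) for j in range(i, len(pool))]
    for chains in combos:
        out.append(make_species(classdef.class_code, chains=chains))
    return out


# ---------------------------------------------------------------------------
# Library file IO: tab-separated text with columns class_code, chains,
# sn_resolved.  "chains" is either "c1:d1_c2:d2" (or with "/" when the
# sn-position is resolved), a single "c:d" for one-chain classes, or a bare
# sum composition "C:D" for a 2-acyl species whose chains are unresolved.
# ---------------------------------------------------------------------------

def _parse_chain_field(cd: LipidClassDef, text: str, sn_resolved: bool):
    text = text.strip()
    sep = "/" if "/" in text else "_"
    tokens = text.split(sep)
    if len(tokens) == cd.n_acyl:
        return tuple(AcylChain.parse(t) for t in tokens), None
    if len(tokens) == 1 and cd.n_acyl == 2:
        c, d = text.split(":")
        return None, (int(c), int(d))
    raise ValueError(f"chain field {text!r} does not fit class {cd.class_code}")


def load_library(path: str | Path) -> list[LipidSpecies]:
    """Load a species library from a tab-separated text file.

    Duplicate (class, sum composition) rows are collapsed with a warning.
    """
    path = Path(path)
    species: list[LipidSpecies] = []
    seen: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                expected = ["class_code", "chains", "sn_resolved"]
                if header != expected:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {expected}, "
                        f"got {header}")
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, "
                                 f"got {len(fields)}")
            code, chain_field, sn_field = (f.strip() for f in fields)
            if code not in class_definitions():
                raise ValueError(f"{path}:{lineno}: unknown class code {code!r}")
            cd = class_definitions()[code]
            sn = sn_field == "1" or "/" in chain_field
            try:
                chains, sumcomp = _parse_chain_field(cd, chain_field, sn)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            sp = make_species(code, chains=chains, sum_composition=sumcomp,
                              sn_resolved=sn)
            key = (sp.class_code, sp.sum_composition)
            if key in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate species "
                    f"{code} {sp.sum_composition} collapsed", stacklevel=2)
                continue
            seen[key] = sp.name
            species.append(sp)
    if not species:
        warnings.warn(f"{path}: empty library", stacklevel=2)
    return species


def write_library(species: Iterable[LipidSpecies], path: str | Path) -> None:
    """Write a library in the same tab-separated dialect load_library reads."""
    with open(path, "w") as fh:
        fh.write("class_code\tchains\tsn_resolved\n")
        for sp in species:
            if sp.chains is None:
                chain_field = sp.sum_composition
            else:
                sep = "/" if sp.sn_resolved else "_"
                shown = sp.chains if sp.sn_resolved else tuple(sorted(sp.chains))
                chain_field = sep.join(str(ch) for ch in shown)
            fh.write(f"{sp.class_code}\t{chain_field}\t"
                     f"{1 if sp.sn_resolved else 0}\n")


def default_library() -> list[LipidSpecies]:
    """The bundled 128-species *N. oceanica* polar lipidome fixture."""
    path = resources.files("polarlipid").joinpath("data/noceanica_library.tsv")
    with resources.as_file(path) as p:
        return load_library(p)
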