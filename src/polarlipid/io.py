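"""File formats, configuration and provenance for the pipeline.

Formats are plain text: TSV for feature tables, libraries, identification
tables, abundance matrices and statistics; MGF (via pyteomics) for MS2
spectra; YAML for configuration.  Writers are deterministic — rows sorted,
floats in shortest round-trip representation — so identical inputs yield
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .annotation import (DEFAULT_FRAG_TOLERANCE_DA, DEFAULT_INTENSITY_FLOOR,
                         DEFAULT_PRECURSOR_TOLERANCE_PPM,
                         DEFAULT_TOLERANCE_PPM, MS1Feature, MS2Spectrum)
from .antioxidant import KineticSeries

__all__ = [
    "PipelineConfig", "read_ms1_table", "write_ms1_table", "read_mgf",
    "write_mgf", "read_identifications", "write_identifications",
    "write_matrix", "read_matrix", "write_stats", "read_groups",
    "write_groups", "read_plate", "write_plate",
]

log = logging.getLogger(__name__)

MS1_COLUMNS = ["sample_id", "mz", "rt", "area", "raw_intensity"]


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters; serialized into every output directory."""
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR
    frag_tolerance_da: float = DEFAULT_FRAG_TOLERANCE_DA
    precursor_tolerance_ppm: float = DEFAULT_PRECURSOR_TOLERANCE_PPM
    rt_half_width: float = 1.0
    glog_lambda: float | None = None     # None -> minimum positive value
    eigenms_permutations: int = 500
    eigenms_alpha: float = 0.05
    q_threshold: float = 0.05
    q_method: str = "bh"
    seed: int = 20211021

    def __post_init__(self):
        for name in ("tolerance_ppm", "intensity_floor", "frag_tolerance_da",
                     "precursor_tolerance_ppm", "rt_half_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _parse_float(path, lineno, name, value) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: field {name!r}: not a number: {value!r}"
        ) from None


def read_ms1_table(path: str | Path) -> list[MS1Feature]:
    """Read an MS1 feature table (TSV).  Empty tables are not an error."""
    path = Path(path)
    features: list[MS1Feature] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header != MS1_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: expected header "
                                     f"{MS1_COLUMNS}, got {header}")
                continue
            if len(fields) != len(MS1_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(MS1_COLUMNS)} fields, got {len(fields)}")
            row = dict(zip(MS1_COLUMNS, fields))
            features.append(MS1Feature(
                sample_id=row["sample_id"].strip(),
                mz=_parse_float(path, lineno, "mz", row["mz"]),
                rt=_parse_float(path, lineno, "rt", row["rt"]),
                area=_parse_float(path, lineno, "area", row["area"]),
                raw_intensity=_parse_float(path, lineno, "raw_intensity",
                                           row["raw_intensity"])))
    return features


def write_ms1_table(features: Iterable[MS1Feature], path: str | Path) -> None:
    rows = sorted(features, key=lambda f: (f.sample_id, f.mz, f.rt))
    with open(path, "w") as fh:
        fh.write("\t".join(MS1_COLUMNS) + "\n")
        for f in rows:
            fh.write(f"{f.sample_id}\t{float(f.mz)!r}\t{float(f.rt)!r}\t"
                     f"{float(f.area)!r}\t{float(f.raw_intensity)!r}\n")


def write_mgf(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    """Write MS2 spectra as MGF (BEGIN IONS/PEPMASS/RTINSECONDS/CHARGE)."""
    entries = []
    for i, s in enumerate(sorted(spectra,
                                 key=lambda s: (s.precursor_mz, s.rt))):
        entries.append({
            "m/z array": np.array([p[0] for p in s.peaks]),
            "intensity array": np.array([p[1] for p in s.peaks]),
            "params": {
                "title": f"scan_{i + 1}",
                "pepmass": (s.precursor_mz,),
                "rtinseconds": s.rt * 60.0,
                "charge": "1+" if s.polarity == "+" else "1-",
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Read MS2 spectra from MGF; PEPMASS is mandatory per entry."""
    path = Path(path)
    spectra: list[MS2Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            if "pepmass" not in params or params["pepmass"] is None:
                raise ValueError(
                    f"{path}: spectrum {params.get('title', '?')!r} "
                    "has no PEPMASS")
            pepmass = params["pepmass"][0]
            if pepmass is None:
                raise ValueError(
                    f"{path}: spectrum {params.get('title', '?')!r} "
                    "has an empty PEPMASS")
            charge = params.get("charge")
            polarity = "+"
            if charge is not None and len(charge) and int(charge[0]) < 0:
                polarity = "-"
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            peaks = tuple(zip((float(x) for x in entry["m/z array"]),
                              (float(y) for y in entry["intensity array"])))
            spectra.append(MS2Spectrum(precursor_mz=float(pepmass), rt=rt,
                                       peaks=peaks, polarity=polarity))
    return spectra


def write_identifications(table: pd.DataFrame, path: str | Path) -> None:
    out = table.sort_values(["species", "sample_id"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def read_identifications(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(df: pd.DataFrame, path: str | Path,
                 index_name: str = "species") -> None:
    out = df.sort_index()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid in sorted(groups):
            fh.write(f"{sid}\t{groups[sid]}\n")


def read_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["group"]))


def write_stats(results: dict, outdir: str | Path,
                prefix: str = "species") -> None:
    """Write the statistics-chain outputs of :func:`stats.run_statistics`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tests = results["tests"]
    per = tests.per_species.sort_index()
    per.to_csv(outdir / f"{prefix}_tests.tsv", sep="\t")
    tests.pairwise.sort_values(["species", "group_a", "group_b"]).to_csv(
        outdir / f"{prefix}_dunn.tsv", sep="\t", index=False)
    p = results["pca"]
    p.scores.to_csv(outdir / f"{prefix}_pca_scores.tsv", sep="\t")
    p.loadings.sort_index().to_csv(outdir / f"{prefix}_pca_loadings.tsv",
                                   sep="\t")
    pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(p.variance_explained))],
        "variance_explained_pct": p.variance_explained,
    }).to_csv(outdir / f"{prefix}_pca_variance.tsv", sep="\t", index=False)


PLATE_COLUMNS = ["well", "role", "label", "concentration", "time_min",
                 "absorbance"]


def write_plate(wells: Sequence[KineticSeries], path: str | Path) -> None:
    """Long-format TSV of microplate kinetic reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(PLATE_COLUMNS) + "\n")
        for s in sorted(wells, key=lambda s: s.well):
            label = s.label if s.label is not None else ""
            conc = "" if s.concentration is None else repr(s.concentration)
            for t, a in s.reads:
                fh.write(f"{s.well}\t{s.role}\t{label}\t{conc}\t"
                         f"{t!r}\t{a!r}\n")


def read_plate(path: str | Path) -> list[KineticSeries]:
    df = pd.read_csv(path, sep="\t",
                     dtype={"label": str, "concentration": float})
    wells = []
    for (well, role), grp in df.groupby(["well", "role"], sort=True):
        grp = grp.sort_values("time_min")
        label = grp["label"].iloc[0]
        if pd.isna(label):
            label = None
        conc = grp["concentration"].iloc[0]
        wells.append(KineticSeries(
            well=well, role=role,
            concentration=None if pd.isna(conc) else float(conc),
            label=label,
            reads=tuple(zip(grp["time_min"].astype(float),
                            grp["absorbance"].astype(float)))))
    return wells
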