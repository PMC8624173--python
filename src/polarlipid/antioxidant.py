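"""ABTS/DPPH radical-scavenging calculators from microplate kinetics.

Works on time-resolved absorbance series (734 nm for ABTS, 517 nm for DPPH,
reads every 5 min over 120 min).  Endpoint quantities:

    % remaining  = 100 * Abs(t_end) / Abs(t_0)
    % inhibition = 100 * (Abs_radical - (Abs_sample - Abs_control)) / Abs_radical

A radical working solution is stable when its blank declines by strictly less
than 10% over the window.  Trolox standards give a least-squares inhibition
vs concentration line for expressing results as Trolox equivalents.
Concentrations are final in-well values (the 1:1 mixing of extract and
radical halves the prepared dilutions).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KineticSeries", "AssayResult", "percent_remaining", "radical_stability",
    "percent_inhibition", "trolox_calibration", "summarize_inhibition",
]

ROLES = ("radical_blank", "sample", "control", "trolox_standard")


@dataclass(frozen=True)
class KineticSeries:
    well: str
    role: str
    reads: tuple[tuple[float, float], ...]   # (time min, absorbance AU)
    concentration: float | None = None       # ug/mL extracts, umol/L Trolox
    label: str | None = None                 # extract group / standard id

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        times = [t for t, _ in self.reads]
        if not times or times[0] != 0 or any(b <= a for a, b in
                                             zip(times, times[1:])):
            raise ValueError("read times must strictly increase from 0")
        if any(a < 0 for _, a in self.reads):
            raise ValueError("absorbance must be non-negative")

    @property
    def a0(self) -> float:
        return self.reads[0][1]

    @property
    def a_end(self) -> float:
        return self.reads[-1][1]


@dataclass
class AssayResult:
    """Replicate-aggregated endpoint results per (label, concentration)."""
    table: pd.DataFrame   # label, concentration, inhibition_mean, inhibition_sd, n


def percent_remaining(series: KineticSeries) -> float:
    """Fraction (in %) of the initial absorbance left at the endpoint."""
    if series.a0 <= 0:
        raise ValueError("initial absorbance must be positive")
    return 100.0 * series.a_end / series.a0


def radical_stability(blank: KineticSeries) -> bool:
    """Stable iff the blank's absorbance declined by strictly less than 10%."""
    return percent_remaining(blank) > 90.0


def percent_inhibition(abs_radical: float, abs_sample: float,
                       abs_control: float = 0.0) -> float:
    """Radical-scavenging activity at the endpoint, in percent."""
    if abs_radical <= 0:
        raise ValueError("radical absorbance must be positive")
    return 100.0 * (abs_radical - (abs_sample - abs_control)) / abs_radical


def trolox_calibration(standards: Sequence[KineticSeries],
                       abs_radical: float,
                       controls: dict[float, float] | None = None
                       ) -> tuple[float, float, float]:
    """Least-squares line of % inhibition vs Trolox concentration.

    Returns (slope, intercept, R^2).  Trolox equivalents of a measured
    inhibition are (inhibition - intercept) / slope.
    """
    conc = np.array([s.concentration for s in standards], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need standards at >= 3 distinct concentrations")
    inhib = np.array([
        percent_inhibition(abs_radical, s.a_end,
                           (controls or {}).get(s.concentration, 0.0))
        for s in standards])
    fit = sps.linregress(conc, inhib)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def summarize_inhibition(series: Iterable[KineticSeries],
                         abs_radical: float) -> AssayResult:
    """Mean +/- SD endpoint inhibition over replicate sample wells.

    Control wells (extract + solvent, no radical) matching a sample's label
    and concentration supply the colour correction term.
    """
    if abs_radical <= 0:
        raise ValueError("radical absorbance must be positive")
    samples, controls = [], {}
    for s in series:
        if s.role == "sample":
            samples.append(s)
        elif s.role == "control":
            controls.setdefault((s.label, s.concentration), []).append(s.a_end)
    rows = {}
    for s in samples:
        key = (s.label, s.concentration)
        ctrl = float(np.mean(controls.get(key, [0.0])))
        rows.setdefault(key, []).append(
            percent_inhibition(abs_radical, s.a_end, ctrl))
    out = []
    for (label, conc), vals in sorted(rows.items(),
                                      key=lambda kv: (kv[0][0], kv[0][1])):
        arr = np.asarray(vals)
        out.append({"label": label, "concentration": conc,
                    "inhibition_mean": float(arr.mean()),
                    "inhibition_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                    "n": len(arr)})
    return AssayResult(table=pd.DataFrame(
        out, columns=["label", "concentration", "inhibition_mean",
                      "inhibition_sd", "n"]))
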