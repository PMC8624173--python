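"""End-to-end orchestration: annotate -> quantify -> statistics.

These functions tie the stage modules together on in-memory objects; the
command-line interface is a thin shell over them.
"""
from __future__ import annotations

import logging
import time
from typing import Mapping, Sequence

import pandas as pd

from . import annotation, quantification, simulate, stats
from .annotation import MS1Feature, MS2Spectrum, RTWindow
from .chem import LipidSpecies, default_library
from .io import PipelineConfig
from .quantification import InternalStandard

__all__ = ["annotate_dataset", "quantify_dataset", "run_pipeline"]

log = logging.getLogger(__name__)


def annotate_dataset(features: Sequence[MS1Feature],
                     spectra: Sequence[MS2Spectrum],
                     library: Sequence[LipidSpecies],
                     config: PipelineConfig | None = None,
                     rt_windows: Mapping[str, RTWindow] | None = None,
                     ) -> pd.DataFrame:
    """Filter, match, MS2-validate and assemble the identification table."""
    config = config or PipelineConfig()
    if rt_windows is None:
        rt_windows = simulate.default_rt_windows(config.rt_half_width)
    kept = annotation.filter_features(features, config.intensity_floor)
    log.info("intensity floor %.0f: %d of %d features kept",
             config.intensity_floor, len(kept), len(features))
    hits = annotation.match_ms1(kept, library, config.tolerance_ppm,
                                rt_windows)
    hits = annotation.validate_hits(
        hits, spectra, config.frag_tolerance_da,
        config.precursor_tolerance_ppm)
    table = annotation.assemble_identifications(hits, rt_windows)
    log.info("identified %d species across %d samples",
             table["species"].nunique() if len(table) else 0,
             table["sample_id"].nunique() if len(table) else 0)
    return table


def quantify_dataset(identifications: pd.DataFrame,
                     features: Sequence[MS1Feature],
                     sample_groups: Mapping[str, str],
                     standards: Sequence[InternalStandard] | None = None,
                     ) -> quantification.AbundanceMatrix:
    """Extract internal-standard areas and normalize XIC areas."""
    if standards is None:
        standards = quantification.default_standards(simulate.STANDARD_RT)
    quantification.extract_standard_areas(features, standards)
    return quantification.normalize_abundances(identifications, standards,
                                               sample_groups)


def run_pipeline(library: Sequence[LipidSpecies] | None = None,
                 design: simulate.SimulationDesign | None = None,
                 config: PipelineConfig | None = None) -> dict:
    """Simulate a dataset and run the full chain on it.

    Returns a dict with features, spectra, truth, identifications, abundance,
    class_matrix, species_stats, class_stats and discriminants.
    """
    t0 = time.perf_counter()
    config = config or PipelineConfig()
    if library is None:
        library = default_library()
    if design is None:
        design = simulate.default_design(seed=config.seed)

    features, spectra, truth = simulate.simulate_lcms(design, library)
    log.info("simulated %d features, %d MS2 spectra [%.1fs]",
             len(features), len(spectra), time.perf_counter() - t0)

    identifications = annotate_dataset(features, spectra, library, config)
    abundance = quantify_dataset(identifications, features,
                                 truth.sample_groups)

    species_stats = stats.run_statistics(
        abundance.data, abundance.groups,
        glog_lambda=config.glog_lambda,
        eigenms_permutations=config.eigenms_permutations,
        eigenms_alpha=config.eigenms_alpha,
        q_method=config.q_method, seed=config.seed)
    class_matrix = stats.class_abundances(abundance.data,
                                          abundance.species_class)
    class_stats = stats.run_statistics(
        class_matrix, abundance.groups,
        glog_lambda=config.glog_lambda,
        eigenms_permutations=config.eigenms_permutations,
        eigenms_alpha=config.eigenms_alpha,
        q_method=config.q_method, seed=config.seed)
    discriminants = stats.discriminant_species(
        species_stats["tests"], species_stats["pca"],
        q_threshold=config.q_threshold, top_n=16)
    log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return {
        "features": features, "spectra": spectra, "truth": truth,
        "identifications": identifications, "abundance": abundance,
        "class_matrix": class_matrix, "species_stats": species_stats,
        "class_stats": class_stats, "discriminants": discriminants,
        "config": config,
    }
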