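"""High-level validation studies chaining the full pipeline.

Each study simulates its own inputs, runs the complete workflow
(standards -> fingerprint library -> calibration -> quantitation) and
returns the summary statistics a method-validation report would tabulate:
calibration linearity, recovery bias/CV on replicate unknowns, relative
peak-area fractions, and method detection limits. All randomness derives
from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from .composition import CompositionBounds
from .library import AnnotationConfig, annotate_run, build_library, match_peaks
from .quant import calibrate, measure_top3, quantify, relative_quant, validation_stats
from .simulate import (
    DEFAULT_POLYSACCHARIDES,
    SimConfig,
    SimPolysaccharide,
    max_apex_height,
    simulate_calibration_series,
    simulate_run,
)

#: annotation settings matched to the nine supported polysaccharides
DEFAULT_ANNOTATION = AnnotationConfig(
    bounds=CompositionBounds(max_dp=21, max_hxa=1, max_hexnac=8),
    adducts=("sodium",),
)


def _derived_seed(seed: int, offset: int) -> int:
    return (seed * 7919 + offset) % (2**31 - 1)


def build_standard_library(
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    seed: int = 0,
    standard_conc: float = 2000.0,
    config: SimConfig = SimConfig(),
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
):
    """Simulate one standard run per polysaccharide and build the library."""
    runs = {}
    for i, poly in enumerate(polysaccharides):
        cfg = replace(config, seed=_derived_seed(seed, 100 + i))
        runs[poly.name] = simulate_run({poly.name: standard_conc}, polysaccharides, cfg)[0]
    return build_library(runs, annotation)


def recovery_study(
    seed: int = 0,
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    levels: Sequence[float] = (2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5),
    unknown_conc: float = 500.0,
    n_replicates: int = 3,
    area_cv: float = 0.05,
    noise_rel: float = 0.005,
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
) -> pd.DataFrame:
    """Full-method validation: calibration linearity plus replicate recovery.

    Simulates a dilution series (every polysaccharide at every level), fits
    the top-3 zero-intercept curves, then quantifies ``n_replicates``
    independent unknown runs at ``unknown_conc`` and reports per
    polysaccharide: r², slope, MDL, accuracy (% bias) and precision (% CV).
    """
    sim = SimConfig(seed=_derived_seed(seed, 1), noise_rel=noise_rel, area_cv=area_cv)
    library = build_standard_library(
        polysaccharides, seed=seed, config=replace(sim, area_cv=0.0), annotation=annotation
    )
    series, _design = simulate_calibration_series(polysaccharides, levels, sim)
    level_runs = [(float(c), run) for c, (run, _) in zip(levels, series)]

    unknowns = []
    for rep in range(n_replicates):
        cfg = replace(sim, seed=_derived_seed(seed, 500 + rep))
        run, _ = simulate_run(
            {p.name: unknown_conc for p in polysaccharides}, polysaccharides, cfg
        )
        unknowns.append(run)

    rows = []
    for poly in polysaccharides:
        curve = calibrate(
            level_runs, library, poly.name,
            tolerance_ppm=annotation.tolerance_ppm,
            min_points=annotation.min_points,
        )
        measured = []
        for run in unknowns:
            area, _, _ = measure_top3(
                run, library, poly.name, curve.top3,
                tolerance_ppm=annotation.tolerance_ppm,
                min_points=annotation.min_points,
            )
            measured.append(quantify(area, curve).conc_ugml)
        stats = validation_stats(measured, unknown_conc, poly.name)
        rows.append(
            {
                "polysaccharide": poly.name,
                "r2": curve.r2,
                "slope": curve.slope,
                "mdl_ugml": curve.mdl_ugml,
                "snr_at_mdl": curve.snr_at_mdl,
                "bias_pct": stats.bias_pct,
                "cv_pct": stats.cv_pct,
                "n_replicates": stats.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def mixture_concentrations_for_area_fractions(
    fractions: Mapping[str, float],
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    total_conc: float = 1000.0,
) -> dict[str, float]:
    """Concentrations that make each species' total peak area hit a target fraction.

    A species' summed area per unit concentration is its response slope times
    the sum of its ladder weights; inverting that gives the concentration
    ratio that realizes the requested area fractions.
    """
    by_name = {p.name: p for p in polysaccharides}
    concs = {}
    for name, frac in fractions.items():
        poly = by_name[name]
        area_per_conc = poly.response_slope * sum(w for _, w, _ in poly.oligomers())
        concs[name] = frac / area_per_conc
    scale = total_conc / sum(concs.values())
    return {k: v * scale for k, v in concs.items()}


def relative_mixture_study(
    seed: int = 0,
    fractions: Mapping[str, float] = None,
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    noise_rel: float = 0.002,
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
) -> tuple[dict[str, float], dict[str, float]]:
    """Relative quantitation of a simulated mixture.

    Returns (target area fractions, measured fractions). The mixture is
    composed so the per-species total areas realize ``fractions`` exactly
    (70/20/10 starch/arabinan/chitin by default); the measured values come
    from annotation, library matching and peak-area fractions.
    """
    if fractions is None:
        fractions = {"starch": 0.7, "arabinan": 0.2, "chitin": 0.1}
    sim = SimConfig(seed=_derived_seed(seed, 3), noise_rel=noise_rel)
    library = build_standard_library(
        polysaccharides, seed=seed, config=sim, annotation=annotation
    )
    concs = mixture_concentrations_for_area_fractions(fractions, polysaccharides)
    run, _ = simulate_run(concs, polysaccharides, replace(sim, seed=_derived_seed(seed, 4)))
    assignments = match_peaks(
        annotate_run(run, annotation), library, annotation.rt_tolerance
    )
    return dict(fractions), relative_quant(assignments)


def mdl_study(
    seed: int,
    noise_rel: float,
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    levels: Sequence[float] = (2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5),
    annotation: AnnotationConfig = DEFAULT_ANNOTATION,
) -> dict[str, float]:
    """Method detection limit per polysaccharide at a given noise level.

    The calibration series carries absolute baseline noise pinned to the top
    level, so diluting degrades S/N and the MDL is the lowest level whose
    averaged top-3 peak S/N still exceeds 3. A polysaccharide with no
    qualifying level maps to ``inf``.
    """
    base = SimConfig(seed=_derived_seed(seed, 5), noise_rel=noise_rel)
    sim = replace(
        base,
        noise_abs=noise_rel * max_apex_height(polysaccharides, max(levels), base),
    )
    # the library comes from clean high-concentration standards and must not
    # depend on the noise level under study
    library = build_standard_library(
        polysaccharides, seed=seed, config=SimConfig(seed=0, noise_rel=0.002),
        annotation=annotation,
    )
    series, _ = simulate_calibration_series(polysaccharides, levels, sim)
    level_runs = [(float(c), run) for c, (run, _) in zip(levels, series)]
    out = {}
    for poly in polysaccharides:
        curve = calibrate(
            level_runs, library, poly.name,
            tolerance_ppm=annotation.tolerance_ppm,
            min_points=annotation.min_points,
        )
        out[poly.name] = float("inf") if curve.mdl_ugml is None else curve.mdl_ugml
    return out
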