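"""Absolute and relative polysaccharide quantitation.

Absolute quantitation follows the external-calibration convention of the
assay: for each polysaccharide the peak areas of its three most abundant
unique oligosaccharides are averaged, the averaged area is regressed on
concentration through the origin with equal weights (>= 5 levels), and
sample concentrations are read off as area/slope. The method detection
limit (MDL) is the lowest calibration level whose averaged peak S/N
exceeds 3. Relative quantitation is the peak-area fraction per
polysaccharide, including the unassigned-oligosaccharide pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .composition import GlycanComposition
from .lcms import Run, extract_eic, snr_at
from .library import Assignment, LibraryEntry

SNR_THRESHOLD = 3.0  # S/N that a level must exceed to qualify as the MDL


@dataclass(frozen=True)
class CalibrationCurve:
    """Zero-intercept external calibration for one polysaccharide."""

    polysaccharide: str
    top3: tuple[GlycanComposition, ...]
    levels: tuple[tuple[float, float], ...]  # (concentration µg/mL, mean top-3 area)
    slope: float
    r2: float
    mdl_ugml: float | None = None
    snr_at_mdl: float | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 5:
            raise ValueError("calibration curve needs at least five levels")
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 out of [0, 1]")
        if self.mdl_ugml is not None and all(
            abs(self.mdl_ugml - c) > 1e-9 for c, _ in self.levels
        ):
            raise ValueError("MDL must equal one of the level concentrations")


@dataclass(frozen=True)
class QuantResult:
    polysaccharide: str
    conc_ugml: float
    conc_dry_pct: float  # % wt/wt on dry matter
    conc_fresh: float  # g per 100 g fresh weight
    below_mdl: bool


@dataclass(frozen=True)
class ValidationStats:
    polysaccharide: str
    bias_pct: float
    cv_pct: float | None  # None when only a single replicate
    n_replicates: int


def select_top3(
    entries: Sequence[LibraryEntry], restrict_unique: bool = True
) -> tuple[GlycanComposition, ...]:
    """The three most abundant (by library mean area) oligosaccharides.

    Evaluated on the standards' library areas, not per sample, so the same
    three oligosaccharides quantify every sample and level. Ties break to
    the lower DP, then lexicographic composition text.
    """
    pool = [e for e in entries if e.unique] if restrict_unique else list(entries)
    if len(pool) < 3:
        hint = "; retry with restrict_unique=False" if restrict_unique else ""
        raise ValueError(
            f"need at least 3 {'unique ' if restrict_unique else ''}library entries, "
            f"have {len(pool)}{hint}"
        )
    pool.sort(key=lambda e: (-e.mean_area, e.composition.dp, str(e.composition)))
    return tuple(e.composition for e in pool[:3])


def fit_calibration(levels: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Equal-weight linear fit through the origin.

    slope = Σxy / Σx²; r² = 1 − Σ(y − ŷ)² / Σy² with the uncentered total
    sum of squares (the through-origin convention — the centered version can
    go negative and is nonstandard for forced-zero intercepts).
    """
    if len(levels) < 5:
        raise ValueError("at least five calibration points are required")
    x = np.array([c for c, _ in levels], dtype=float)
    y = np.array([a for _, a in levels], dtype=float)
    if np.any(x <= 0) or len(set(x.tolist())) != len(x):
        raise ValueError("level concentrations must be positive and distinct")
    if not np.any(y != 0):
        raise ValueError("all areas are zero; nothing to fit")
    slope = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot
    if not (np.isfinite(slope) and np.isfinite(r2)):
        raise ValueError("calibration fit did not produce finite parameters")
    return slope, r2


def quantify(
    mean_top3_area: float,
    curve: CalibrationCurve,
    dry_loading_mg_per_ml: float = 25.0,
    moisture_fraction: float = 0.0,
) -> QuantResult:
    """Concentration = area / slope, with unit conversions and MDL flag."""
    conc = mean_top3_area / curve.slope
    dry_pct, fresh = convert_units(conc, dry_loading_mg_per_ml, moisture_fraction)
    below = curve.mdl_ugml is not None and conc < curve.mdl_ugml
    if curve.mdl_ugml is None:
        below = conc <= 0
    return QuantResult(curve.polysaccharide, conc, dry_pct, fresh, below)


def compute_mdl(level_snrs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Lowest level concentration whose averaged peak S/N exceeds 3.

    ``level_snrs`` pairs each level concentration with the mean S/N of the
    top-3 peaks at that level. Returns (MDL µg/mL, S/N at the MDL).
    """
    qualifying = [(c, s) for c, s in level_snrs if s > SNR_THRESHOLD]
    if not qualifying:
        raise ValueError("no calibration level has S/N > 3; MDL undefined")
    return min(qualifying, key=lambda t: t[0])


def convert_units(
    conc_ugml: float, dry_loading_mg_per_ml: float, moisture_fraction: float = 0.0
) -> tuple[float, float]:
    """µg/mL in the reacted solution -> (% wt/wt dry basis, g/100 g fresh).

    ``dry_loading_mg_per_ml`` is the dry matter reacted per mL. The dry-basis
    percentage is conc / (loading × 1000) × 100; the fresh-weight value
    scales by the dry fraction (1 − moisture).
    """
    if dry_loading_mg_per_ml <= 0:
        raise ValueError("dry-matter loading must be positive")
    if not (0.0 <= moisture_fraction < 1.0):
        raise ValueError("moisture fraction must be in [0, 1)")
    dry_pct = conc_ugml / (dry_loading_mg_per_ml * 1000.0) * 100.0
    fresh = dry_pct * (1.0 - moisture_fraction)
    return dry_pct, fresh


def relative_quant(assignments: Sequence[Assignment]) -> dict[str, float]:
    """Peak-area fraction per polysaccharide, unassigned pool included."""
    if not assignments:
        raise ValueError("no assignments to quantify")
    totals: dict[str, float] = {}
    for a in assignments:
        totals[a.polysaccharide] = totals.get(a.polysaccharide, 0.0) + a.peak.area
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total assigned area is zero")
    return {k: v / grand for k, v in sorted(totals.items())}


def validation_stats(
    measured: Sequence[float], expected: float, polysaccharide: str = ""
) -> ValidationStats:
    """Accuracy (% bias of the replicate mean) and precision (% CV, sample SD)."""
    if expected <= 0:
        raise ValueError("expected concentration must be positive")
    m = np.asarray(measured, dtype=float)
    if m.size < 1:
        raise ValueError("at least one replicate required")
    bias = (float(m.mean()) - expected) / expected * 100.0
    cv = float(m.std(ddof=1) / m.mean() * 100.0) if m.size >= 2 and m.mean() != 0 else None
    return ValidationStats(polysaccharide, bias, cv, int(m.size))


def measure_top3(
    run: Run,
    library: Sequence[LibraryEntry],
    polysaccharide: str,
    top3: Sequence[GlycanComposition],
    tolerance_ppm: float = 15.0,
    integration_halfwidth: float = 0.35,
    min_points: int = 5,
) -> tuple[float, float, int]:
    """Mean area and mean S/N of a polysaccharide's top-3 peaks in one run.

    Targeted integration: each top-3 composition's EIC is integrated over a
    fixed window of ``±integration_halfwidth`` minutes around the library
    retention time after subtracting the flanking-baseline median. The
    fixed geometry keeps the estimate unbiased at any S/N — noise averages
    to zero instead of being clipped by data-driven peak boundaries — so
    below-MDL signal is integrated rather than censored; the MDL flag on
    the quantitation result carries the detectability judgement. S/N is
    rated at the library RT (see :func:`~glycoquant.lcms.snr_at`) and
    ``n_found`` counts the top-3 positions with S/N above 3, flagging
    n < 3 quantitation.
    """
    entries = {
        e.composition: e for e in library if e.polysaccharide == polysaccharide
    }
    areas, snrs, n_found = [], [], 0
    for comp in top3:
        e = entries.get(comp)
        if e is None:
            continue
        eic = extract_eic(run, e.mz, tolerance_ppm)
        if eic.intensity.size < min_points:
            continue
        snr = snr_at(eic, e.rt)
        snrs.append(snr)
        if snr > SNR_THRESHOLD:
            n_found += 1
        d = np.abs(eic.rt - e.rt)
        window = d <= integration_halfwidth
        flank = (d > 2 * integration_halfwidth) & (d <= 2.0)
        baseline = float(np.median(eic.intensity[flank])) if np.any(flank) else 0.0
        area = float(np.trapezoid(eic.intensity[window] - baseline, eic.rt[window]))
        areas.append(max(area, 0.0))
    if not snrs:
        return 0.0, 0.0, 0
    return float(np.mean(areas)), float(np.mean(snrs)), n_found


def calibrate(
    level_runs: Sequence[tuple[float, Run]],
    library: Sequence[LibraryEntry],
    polysaccharide: str,
    restrict_unique: bool = True,
    tolerance_ppm: float = 15.0,
    min_points: int = 5,
) -> CalibrationCurve:
    """Build a full calibration curve (fit + MDL) from level runs.

    ``level_runs`` pairs each level's concentration with its run. Levels
    where none of the top-3 peaks are found still enter the fit with zero
    area (the regression is through the origin, so absent signal at low
    levels is informative), but only levels with peaks get an S/N.
    """
    entries = [e for e in library if e.polysaccharide == polysaccharide]
    if not entries:
        raise ValueError(f"library has no entries for {polysaccharide!r}")
    top3 = select_top3(entries, restrict_unique)
    levels, level_snrs = [], []
    for conc, run in level_runs:
        area, snr, n_found = measure_top3(
            run, library, polysaccharide, top3, tolerance_ppm, min_points=min_points
        )
        levels.append((conc, area))
        level_snrs.append((conc, snr))
    slope, r2 = fit_calibration(levels)
    try:
        mdl, snr_at_mdl = compute_mdl(level_snrs)
    except ValueError:
        # every level sits below S/N 3: the curve is still usable for
        # quantitation but carries no MDL
        mdl = snr_at_mdl = None
    return CalibrationCurve(
        polysaccharide=polysaccharide,
        top3=tuple(top3),
        levels=tuple(levels),
        slope=slope,
        r2=r2,
        mdl_ugml=mdl,
        snr_at_mdl=snr_at_mdl,
    )
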