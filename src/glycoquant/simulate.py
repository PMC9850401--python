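"""Synthetic LC-MS runs with ground truth for pipeline validation.

The generator emulates the data structure of a bottom-up polysaccharide
assay on a PGC-QTOF: each polysaccharide standard depolymerizes into an
oligomer ladder (e.g. starch Hex3..Hex21, arabinan Pnt3..Pnt15) whose
members elute as Gaussian peaks, with retention increasing with degree of
polymerization, peak area proportional to concentration, carbohydrate-like
isotope envelopes, additive baseline noise, and optional data-dependent MS2
with top-N selection, dynamic exclusion and a linear collision-energy ramp.

What it deliberately does not emulate: reaction-yield chemistry, matrix ion
suppression, retention prediction from structure, or detector saturation —
so passing recovery tests demonstrate the correctness of the computational
pipeline, not of the wet-lab assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import GlycanComposition, enumerate_fragments, mz_of
from .lcms import Run, SpectrumRecord

_SQRT2PI = math.sqrt(2.0 * math.pi)
_ISOTOPE_SPACING = 1.0033548  # 13C - 12C


@dataclass(frozen=True)
class AcquisitionModel:
    """Data-dependent acquisition settings of the simulated QTOF method.

    The collision-energy ramp is linear in precursor m/z,
    CE(m/z) = ce_slope * (m/z) + ce_intercept, stored as configured;
    nothing downstream depends on its absolute scale.
    """

    ce_slope: float = 1.45
    ce_intercept: float = -3.5
    top_n: int = 5
    dynamic_exclusion_s: float = 30.0

    def collision_energy(self, mz: float) -> float:
        return self.ce_slope * mz + self.ce_intercept


@dataclass(frozen=True)
class SimPolysaccharide:
    """Ground-truth model of one polysaccharide's oligomer ladder.

    ``abundance_decay`` is the per-DP geometric factor (<1 makes the lowest
    DP the most abundant); ``response_slope`` is area per (µg/mL) for the
    most abundant oligomer.
    """

    name: str
    residue_class: str  # "Hex" | "Pnt" | "HexNAc"
    dp_range: tuple[int, int]
    rt_base: float  # minutes
    rt_per_dp: float  # minutes per residue
    abundance_decay: float = 0.75
    response_slope: float = 30000.0
    composition_for_dp: Callable[[int], GlycanComposition] | None = None
    extra_oligomers: tuple[tuple[str, float, float], ...] = ()
    # (composition text, relative weight, rt minutes) beyond the main ladder

    def __post_init__(self) -> None:
        if self.response_slope <= 0:
            raise ValueError(f"{self.name}: response_slope must be positive")
        lo, hi = self.dp_range
        if not (1 <= lo <= hi):
            raise ValueError(f"{self.name}: invalid dp_range {self.dp_range}")

    def _composition(self, dp: int) -> GlycanComposition:
        if self.composition_for_dp is not None:
            return self.composition_for_dp(dp)
        return GlycanComposition(**{self.residue_class.lower(): dp}, reduced=True)

    def oligomers(self) -> list[tuple[GlycanComposition, float, float]]:
        """(composition, relative weight, retention time) for the ladder."""
        lo, hi = self.dp_range
        out = [
            (self._composition(dp), self.abundance_decay ** (dp - lo), self.rt_base + self.rt_per_dp * dp)
            for dp in range(lo, hi + 1)
        ]
        out.extend(
            (GlycanComposition.parse(txt), w, rt) for txt, w, rt in self.extra_oligomers
        )
        return out


def _xyloglucan_comp(dp: int) -> GlycanComposition:
    # glucan backbone with xylose branches, roughly Glc4Xyl3 stoichiometry
    pnt = dp // 3
    return GlycanComposition(hex=dp - pnt, pnt=pnt, reduced=True)


#: The nine supported polysaccharide standards. Retention bases are offset
#: so ladders sharing compositions (the five Hex-type polymers, the two
#: Pnt-type) stay >= 2 min apart at equal DP — isomer separation on PGC.
DEFAULT_POLYSACCHARIDES: tuple[SimPolysaccharide, ...] = (
    SimPolysaccharide("starch", "Hex", (3, 21), rt_base=5.0, rt_per_dp=1.0, response_slope=34000.0),
    SimPolysaccharide("cellulose", "Hex", (3, 12), rt_base=7.0, rt_per_dp=1.0, response_slope=10000.0),
    SimPolysaccharide("beta-glucan", "Hex", (3, 12), rt_base=9.0, rt_per_dp=1.0, response_slope=55000.0),
    SimPolysaccharide("mannan", "Hex", (3, 10), rt_base=11.0, rt_per_dp=1.0, response_slope=36000.0),
    SimPolysaccharide("galactan", "Hex", (3, 12), rt_base=13.0, rt_per_dp=1.0, response_slope=25000.0),
    SimPolysaccharide("arabinan", "Pnt", (3, 15), rt_base=4.0, rt_per_dp=1.0, response_slope=70000.0),
    SimPolysaccharide(
        "xylan", "Pnt", (3, 12), rt_base=6.5, rt_per_dp=1.0, response_slope=52000.0,
        extra_oligomers=(
            ("Pnt3HxA1Me1-red", 0.4, 11.2), ("Pnt4HxA1Me1-red", 0.3, 12.2),
            ("Pnt5HxA1Me1-red", 0.22, 13.2),
        ),
    ),
    SimPolysaccharide(
        "xyloglucan", "Hex", (4, 14), rt_base=8.3, rt_per_dp=1.0, response_slope=27000.0,
        composition_for_dp=_xyloglucan_comp,
    ),
    SimPolysaccharide("chitin", "HexNAc", (3, 8), rt_base=10.0, rt_per_dp=1.2, response_slope=117000.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and noise settings; all randomness flows from ``seed``."""

    seed: int = 0
    scan_rate: float = 0.63  # MS1 spectra per second
    gradient_min: float = 45.0
    peak_sigma_min: float = 0.1
    noise_rel: float = 0.005  # baseline noise sigma, relative to tallest peak apex
    noise_abs: float | None = None  # absolute noise sigma in counts; overrides noise_rel
    area_cv: float = 0.0  # multiplicative per-oligomer area noise (fractional)
    mass_error_ppm: float = 0.0  # per-oligomer m/z perturbation sigma
    isotopes: bool = True
    include_ms2: bool = False
    adduct: str = "sodium"
    charge: int = 1
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)

    def __post_init__(self) -> None:
        if self.scan_rate <= 0 or self.gradient_min <= 0 or self.peak_sigma_min <= 0:
            raise ValueError("scan_rate, gradient_min and peak_sigma_min must be positive")
        if self.noise_rel < 0 or self.area_cv < 0 or self.mass_error_ppm < 0:
            raise ValueError("noise settings must be non-negative")


def _carbon_oxygen_counts(comp: GlycanComposition) -> tuple[int, int]:
    c = 6 * comp.hex + 5 * comp.pnt + 6 * comp.hxa + 8 * comp.hexnac + comp.me
    o = 5 * comp.hex + 4 * comp.pnt + 6 * comp.hxa + 5 * comp.hexnac + 1
    return c, o


def _isotope_fractions(comp: GlycanComposition) -> list[float]:
    """Crude carbohydrate envelope: M, M+1, M+2 relative to M=1."""
    c, o = _carbon_oxygen_counts(comp)
    f1 = 0.0107 * c
    f2 = 0.5 * f1 * f1 + 0.00205 * o
    return [1.0, f1, f2]


def simulate_run(
    mixture: Mapping[str, float],
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    config: SimConfig = SimConfig(),
) -> tuple[Run, pd.DataFrame]:
    """Simulate one LC-MS run of a mixture (polysaccharide name -> µg/mL).

    Returns the in-memory :class:`~glycoquant.lcms.Run` plus a ground-truth
    table with one row per oligomer (composition, adduct, m/z, RT, true
    baseline-free area, concentration). Deterministic per config seed.
    """
    if not mixture:
        raise ValueError("mixture must name at least one polysaccharide")
    by_name = {p.name: p for p in polysaccharides}
    unknown = set(mixture) - set(by_name)
    if unknown:
        raise ValueError(f"unknown polysaccharide(s) in mixture: {sorted(unknown)}")
    for name, conc in mixture.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name}")

    rng = np.random.default_rng(config.seed)
    sigma = config.peak_sigma_min
    dt_min = 1.0 / config.scan_rate / 60.0
    n_scans = int(config.gradient_min * 60.0 * config.scan_rate)
    scan_rt = np.arange(n_scans) * dt_min

    # ground truth rows and per-channel signal traces
    rows = []
    channels: list[tuple[float, np.ndarray, GlycanComposition, float]] = []
    for name in sorted(mixture):
        conc = mixture[name]
        poly = by_name[name]
        for comp, weight, rt in poly.oligomers():
            jitter = (
                float(np.exp(rng.normal(0.0, config.area_cv))) if config.area_cv > 0 else 1.0
            )
            ppm_shift = (
                float(rng.normal(0.0, config.mass_error_ppm)) if config.mass_error_ppm > 0 else 0.0
            )
            if conc <= 0:
                continue
            area = conc * poly.response_slope * weight * jitter
            mz = mz_of(comp, config.adduct, config.charge) * (1.0 + ppm_shift * 1e-6)
            height = area / (sigma * _SQRT2PI)
            trace = height * np.exp(-0.5 * ((scan_rt - rt) / sigma) ** 2)
            channels.append((mz, trace, comp, rt))
            rows.append(
                {
                    "polysaccharide": name,
                    "composition": str(comp),
                    "dp": comp.dp,
                    "adduct": config.adduct,
                    "charge": config.charge,
                    "mz": mz,
                    "rt": rt,
                    "true_area": area,
                    "concentration_ugml": conc,
                }
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "polysaccharide", "composition", "dp", "adduct", "charge",
            "mz", "rt", "true_area", "concentration_ugml",
        ],
    )

    # instrument noise: absolute when configured (one instrument, one noise
    # level across a dilution series), else relative to this run's tallest apex
    if config.noise_abs is not None:
        noise_sigma = config.noise_abs
    else:
        max_height = max((float(t.max()) for _, t, _, _ in channels), default=0.0)
        noise_sigma = config.noise_rel * max_height
    baseline = 5.0 * noise_sigma

    # baseline + detector noise belongs to the m/z channel, not the analyte:
    # species sharing a composition (hence an m/z) see one noise trace
    unique_mz: dict[float, list[int]] = {}
    for idx, (mz, _, _, _) in enumerate(channels):
        unique_mz.setdefault(mz, []).append(idx)
    mz_order = sorted(unique_mz)

    spectra: list[SpectrumRecord] = []
    exclusion: dict[float, float] = {}
    for k in range(n_scans):
        rt = float(scan_rt[k])
        mzs: list[float] = []
        ints: list[float] = []
        for mz in mz_order:
            level = baseline + sum(float(channels[i][1][k]) for i in unique_mz[mz])
            if noise_sigma > 0:
                level += noise_sigma * float(rng.standard_normal())
            level = max(level, 0.0)
            if level > 0:
                mzs.append(mz)
                ints.append(level)
        for mz, trace, comp, center in channels:
            signal = float(trace[k])
            if config.isotopes and signal > 0 and abs(rt - center) <= 4.0 * sigma:
                for j, frac in enumerate(_isotope_fractions(comp)[1:], start=1):
                    mzs.append(mz + j * _ISOTOPE_SPACING / config.charge)
                    ints.append(signal * frac)
        order = np.argsort(mzs, kind="stable")
        rec = SpectrumRecord(
            scan_id=f"scan={k + 1}",
            ms_level=1,
            rt=rt,
            mz=np.asarray(mzs)[order] if mzs else np.empty(0),
            intensity=np.asarray(ints)[order] if mzs else np.empty(0),
        )
        spectra.append(rec)
        if config.include_ms2:
            spectra.extend(
                _schedule_ms2(rec, channels, rt, exclusion, config, rng)
            )
    return Run(spectra), truth


def _schedule_ms2(ms1, channels, rt, exclusion, config: SimConfig, rng) -> list[SpectrumRecord]:
    """Top-N data-dependent MS2 with dynamic exclusion (times in minutes)."""
    acq = config.acquisition
    excl_min = acq.dynamic_exclusion_s / 60.0
    out = []
    # current per-channel signal at this MS1 scan
    k = int(round(rt * 60.0 * config.scan_rate))
    ranked = sorted(
        ((float(tr[min(k, tr.size - 1)]), mz, comp) for mz, tr, comp, _ in channels),
        key=lambda t: -t[0],
    )
    n_picked = 0
    for signal, mz, comp in ranked:
        if n_picked >= acq.top_n or signal <= 0:
            break
        last = exclusion.get(round(mz, 4))
        if last is not None and rt - last < excl_min:
            continue
        exclusion[round(mz, 4)] = rt
        n_picked += 1
        if comp.dp >= 2:
            frags = enumerate_fragments(comp, config.adduct, config.charge)
            fmz = np.array([f.mz for f in frags])
            fint = signal * 0.1 * np.linspace(1.0, 0.3, fmz.size)
            order = np.argsort(fmz, kind="stable")
            out.append(
                SpectrumRecord(
                    scan_id=f"{ms1.scan_id}.ms2.{n_picked}",
                    ms_level=2,
                    rt=rt + 1e-4 * n_picked,
                    mz=fmz[order],
                    intensity=fint[order],
                    precursor_mz=mz,
                    precursor_charge=config.charge,
                    collision_energy=acq.collision_energy(mz),
                )
            )
    return out


def max_apex_height(
    polysaccharides: Sequence[SimPolysaccharide], conc: float, config: SimConfig
) -> float:
    """Tallest chromatographic apex across species at one concentration."""
    best = 0.0
    for p in polysaccharides:
        w = max(w for _, w, _ in p.oligomers())
        best = max(best, conc * p.response_slope * w)
    return best / (config.peak_sigma_min * _SQRT2PI)


def simulate_calibration_series(
    polysaccharides: Sequence[SimPolysaccharide] = DEFAULT_POLYSACCHARIDES,
    levels: Sequence[float] = (2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5),
    config: SimConfig = SimConfig(),
) -> tuple[list[tuple[Run, pd.DataFrame]], pd.DataFrame]:
    """One run per calibration level with every polysaccharide at that level.

    Returns the runs (with their ground-truth tables) and the calibration
    design table (polysaccharide, level, concentration_ugml, run_id). Each
    level gets a seed derived from the config seed.
    """
    levels = [float(c) for c in levels]
    if len(levels) < 5:
        raise ValueError("calibration needs at least five levels")
    if any(c <= 0 for c in levels):
        raise ValueError("calibration level concentrations must be positive")
    runs = []
    design_rows = []
    for i, conc in enumerate(levels):
        cfg = replace(config, seed=(config.seed * 1000 + i) % (2**31 - 1))
        run_id = f"cal_level_{i + 1}"
        mixture = {p.name: conc for p in polysaccharides}
        runs.append(simulate_run(mixture, polysaccharides, cfg))
        design_rows.extend(
            {"polysaccharide": p.name, "level": i + 1, "concentration_ugml": conc, "run_id": run_id}
            for p in polysaccharides
        )
    return runs, pd.DataFrame(design_rows)
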