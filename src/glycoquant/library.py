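"""Oligosaccharide fingerprint library: construction, matching, persistence.

A library entry records which oligosaccharide composition elutes at which
retention time for a given polysaccharide standard. Because isomeric
polysaccharides (starch vs. cellulose) depolymerize to identical
compositions, composition alone is ambiguous; the (composition, RT) pair on
a PGC column is the fingerprint. Entries whose composition and RT collide
with another polysaccharide's, at matching tolerance, are flagged
non-unique and excluded from quantitation by default. Annotated sample
peaks that match no library fingerprint are reported as unassigned
oligosaccharides.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition import (
    AnnotationCandidate,
    CompositionBounds,
    GlycanComposition,
    mz_of,
    score_msms,
)
from .lcms import ChromPeak, Run, detect_peaks, extract_eic, observed_mz

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

_TSV_HEADER = ["polysaccharide", "composition", "adduct", "mz", "rt", "mean_area", "unique"]


@dataclass(frozen=True)
class LibraryEntry:
    polysaccharide: str
    composition: GlycanComposition
    adduct: str
    mz: float
    rt: float
    mean_area: float
    unique: bool = True

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"{self.polysaccharide} {self.composition}: rt must be positive")
        if self.mean_area <= 0:
            raise ValueError(f"{self.polysaccharide} {self.composition}: mean_area must be positive")


@dataclass(frozen=True)
class Assignment:
    peak: ChromPeak
    candidate: AnnotationCandidate
    polysaccharide: str  # library polysaccharide name or UNASSIGNED
    rt_delta: float  # peak apex RT minus library RT (0 for unassigned)


@dataclass(frozen=True)
class AnnotationConfig:
    """Shared settings for targeted annotation of runs against composition space."""

    tolerance_ppm: float = 15.0
    bounds: CompositionBounds = CompositionBounds()
    adducts: tuple[str, ...] = ("sodium",)
    charge: int = 1
    min_snr: float = 3.0
    min_points: int = 5
    min_ms2_score: float = 0.5
    rt_tolerance: float = 0.5  # minutes


def annotate_run(run: Run, config: AnnotationConfig = AnnotationConfig()) -> list[tuple[ChromPeak, AnnotationCandidate]]:
    """Detect and annotate oligosaccharide peaks on every annotatable m/z.

    For each composition within bounds and each adduct, the monoisotopic
    EIC is extracted and integrated; detected peaks become (peak, candidate)
    records. When the run carries MS2 spectra, a peak is kept only if a
    matching MS2 (precursor within tolerance, RT inside the peak) scores at
    least ``min_ms2_score`` fragment-intensity coverage. Records whose m/z
    windows overlap at the same RT are deduplicated, keeping the candidate
    with the smallest |ppm error|.
    """
    ms2 = run.ms2
    records: list[tuple[ChromPeak, AnnotationCandidate]] = []
    for comp in config.bounds.iter_compositions():
        for adduct in config.adducts:
            target = mz_of(comp, adduct, config.charge)
            eic = extract_eic(run, target, config.tolerance_ppm)
            if eic.intensity.size < config.min_points or not np.any(eic.intensity > 0):
                continue
            for peak in detect_peaks(eic, config.min_snr, config.min_points):
                if _is_isotope_satellite(run, target, peak, config):
                    continue
                if ms2 and not _ms2_confirms(ms2, comp, adduct, peak, config):
                    continue
                obs = observed_mz(run, target, config.tolerance_ppm, peak.apex_rt)
                ppm = 0.0 if obs is None else (obs - target) / target * 1e6
                records.append(
                    (peak, AnnotationCandidate(comp, adduct, config.charge, target, ppm))
                )
    return _dedupe_records(records, config.tolerance_ppm)


_ISOTOPE_SPACING = 1.0033548  # 13C - 12C


def _is_isotope_satellite(run: Run, target: float, peak: ChromPeak, config: AnnotationConfig) -> bool:
    """True when the peak sits on an isotopologue of a larger coeluting ion.

    Checks the channel one isotope spacing below the target: a coeluting
    signal there of comparable height means the target trace is an M+n
    satellite, not a monoisotopic species.
    """
    below = target - _ISOTOPE_SPACING / config.charge
    eic = extract_eic(run, below, config.tolerance_ppm)
    if eic.intensity.size == 0:
        return False
    scan = int(np.argmin(np.abs(eic.rt - peak.apex_rt)))
    level = float(eic.intensity[scan]) - float(np.median(eic.intensity))
    return level >= 0.3 * peak.height


def _ms2_confirms(ms2, comp, adduct, peak, config: AnnotationConfig) -> bool:
    target = mz_of(comp, adduct, config.charge)
    tol = target * config.tolerance_ppm * 1e-6
    for s in ms2:
        if (
            s.precursor_mz is not None
            and abs(s.precursor_mz - target) <= tol
            and peak.rt_start <= s.rt <= peak.rt_end
        ):
            if score_msms(s.mz, s.intensity, comp, adduct, config.charge, config.tolerance_ppm) >= config.min_ms2_score:
                return True
    return False


def _dedupe_records(records, tolerance_ppm: float):
    """Collapse records sharing an m/z window and overlapping RT spans."""
    records = sorted(records, key=lambda r: (r[1].theoretical_mz, r[0].apex_rt))
    kept: list[tuple[ChromPeak, AnnotationCandidate]] = []
    for peak, cand in records:
        merged = False
        for i, (kp, kc) in enumerate(kept):
            mz_close = abs(cand.theoretical_mz - kc.theoretical_mz) <= (
                2e-6 * tolerance_ppm * kc.theoretical_mz
            )
            rt_overlap = peak.rt_start < kp.rt_end and kp.rt_start < peak.rt_end
            if mz_close and rt_overlap:
                if _candidate_rank(peak, cand) < _candidate_rank(kp, kc):
                    kept[i] = (peak, cand)
                merged = True
                break
        if not merged:
            kept.append((peak, cand))
    kept.sort(key=lambda r: (r[0].apex_rt, r[1].theoretical_mz))
    return kept


def _candidate_rank(peak, cand):
    return (abs(cand.ppm_error), cand.composition.n_residue_classes, cand.composition.dp)


def build_library(
    standard_runs: Mapping[str, Run | Sequence[Run]],
    config: AnnotationConfig = AnnotationConfig(),
) -> list[LibraryEntry]:
    """Construct the fingerprint library from per-polysaccharide standard runs.

    Each polysaccharide may supply one or more replicate runs; replicate
    RTs are pooled by area-weighted mean and areas by plain mean. After
    pooling, entries colliding across polysaccharides (m/z within ppm
    tolerance and RT within RT tolerance) are flagged ``unique=False``.
    """
    pooled: list[LibraryEntry] = []
    for name, runs in standard_runs.items():
        runs_seq = [runs] if isinstance(runs, Run) else list(runs)
        groups: dict[tuple[GlycanComposition, str], list[tuple[float, float]]] = {}
        for run in runs_seq:
            for peak, cand in annotate_run(run, config):
                groups.setdefault((cand.composition, cand.adduct), []).append(
                    (peak.apex_rt, peak.area)
                )
        if not groups:
            raise ValueError(f"no qualifying oligosaccharide peaks found for {name!r}")
        for (comp, adduct), hits in sorted(groups.items(), key=lambda kv: str(kv[0][0])):
            rts = np.array([rt for rt, _ in hits])
            areas = np.array([a for _, a in hits])
            pooled.append(
                LibraryEntry(
                    polysaccharide=name,
                    composition=comp,
                    adduct=adduct,
                    mz=mz_of(comp, adduct, config.charge),
                    rt=float(np.average(rts, weights=areas)),
                    mean_area=float(areas.mean()),
                )
            )
    return flag_shared_entries(pooled, config.tolerance_ppm, config.rt_tolerance)


def flag_shared_entries(
    entries: Sequence[LibraryEntry], tolerance_ppm: float = 15.0, rt_tolerance: float = 0.5
) -> list[LibraryEntry]:
    """Mark entries non-unique when another polysaccharide has a colliding one."""
    out = list(entries)
    shared = set()
    for i, a in enumerate(out):
        for j in range(i + 1, len(out)):
            b = out[j]
            if a.polysaccharide == b.polysaccharide:
                continue
            if (
                abs(a.mz - b.mz) <= tolerance_ppm * 1e-6 * a.mz
                and abs(a.rt - b.rt) <= rt_tolerance
            ):
                shared.update((i, j))
    return [replace(e, unique=i not in shared) for i, e in enumerate(out)]


def match_peaks(
    annotated_peaks: Sequence[tuple[ChromPeak, AnnotationCandidate]],
    library: Sequence[LibraryEntry],
    rt_tolerance: float = 0.5,
) -> list[Assignment]:
    """Assign each annotated peak to a polysaccharide, or to UNASSIGNED.

    A peak matches a library entry when composition and adduct agree and the
    apex RT is within tolerance; the closest-RT entry wins, with ties broken
    toward the larger library mean_area (and a warning logged). Every input
    peak yields exactly one assignment; order of inputs does not matter.
    """
    if not library:
        raise ValueError("fingerprint library is empty")
    by_key: dict[tuple[GlycanComposition, str], list[LibraryEntry]] = {}
    for e in library:
        by_key.setdefault((e.composition, e.adduct), []).append(e)
    out = []
    for peak, cand in annotated_peaks:
        entries = by_key.get((cand.composition, cand.adduct), [])
        best = None
        for e in entries:
            delta = peak.apex_rt - e.rt
            if abs(delta) > rt_tolerance:
                continue
            if best is None:
                best = (e, delta)
            else:
                prev_e, prev_d = best
                if abs(delta) < abs(prev_d) - 1e-12:
                    best = (e, delta)
                elif abs(abs(delta) - abs(prev_d)) <= 1e-12 and e.mean_area > prev_e.mean_area:
                    logger.warning(
                        "peak at %.3f min equidistant between %s and %s; "
                        "assigning to the more abundant fingerprint %s",
                        peak.apex_rt, prev_e.polysaccharide, e.polysaccharide, e.polysaccharide,
                    )
                    best = (e, delta)
        if best is None:
            out.append(Assignment(peak, cand, UNASSIGNED, 0.0))
        else:
            out.append(Assignment(peak, cand, best[0].polysaccharide, best[1]))
    out.sort(key=lambda a: (a.peak.apex_rt, a.candidate.theoretical_mz))
    return out


def save_library(entries: Sequence[LibraryEntry], path) -> None:
    """Write the library as TSV (or JSON when the suffix is .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "polysaccharide": e.polysaccharide,
                "composition": str(e.composition),
                "adduct": e.adduct,
                "mz": e.mz,
                "rt": e.rt,
                "mean_area": e.mean_area,
                "unique": e.unique,
            }
            for e in entries
        ]
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for e in entries:
            fh.write(
                f"{e.polysaccharide}\t{e.composition}\t{e.adduct}\t{e.mz!r}\t{e.rt!r}\t"
                f"{e.mean_area!r}\t{str(e.unique).lower()}\n"
            )


def load_library(path) -> list[LibraryEntry]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        return [_entry_from_fields(r, i + 1) for i, r in enumerate(rows)]
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise ValueError(
                f"{path}: line 1: bad library header {header!r}; expected {_TSV_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TSV_HEADER):
                raise ValueError(f"{path}: line {lineno}: expected {len(_TSV_HEADER)} columns")
            out.append(_entry_from_fields(dict(zip(_TSV_HEADER, fields)), lineno))
    return out


def _entry_from_fields(r: Mapping[str, object], lineno: int) -> LibraryEntry:
    try:
        unique = r["unique"]
        if isinstance(unique, str):
            unique = unique.strip().lower() == "true"
        return LibraryEntry(
            polysaccharide=str(r["polysaccharide"]),
            composition=GlycanComposition.parse(str(r["composition"])),
            adduct=str(r["adduct"]),
            mz=float(r["mz"]),
            rt=float(r["rt"]),
            mean_area=float(r["mean_area"]),
            unique=bool(unique),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"library record at line {lineno}: {exc}") from exc
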