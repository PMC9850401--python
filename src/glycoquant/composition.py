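"""Glycan composition arithmetic and composition-level MS/MS annotation.

A :class:`GlycanComposition` counts residue classes (Hex, Pnt, HxA, HexNAc),
4-O-methyl groups riding on hexuronic acids, and whether the reducing end
was converted to an alditol by borohydride reduction. Compositions are the
unit of annotation: precursor m/z values are matched combinatorially against
all compositions within configurable bounds, and tandem spectra are scored
against composition-level glycosidic (B/Y) fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .masses import DEFAULT_MASS_TABLE, ResidueMassTable

_RESIDUE_FIELDS = ("hex", "pnt", "hxa", "hexnac")
_TOKEN_NAMES = {"hex": "Hex", "pnt": "Pnt", "hxa": "HxA", "hexnac": "HexNAc"}
_COMP_RE = re.compile(
    r"^(?:Hex(?!NAc)(?P<hex>\d+))?(?:Pnt(?P<pnt>\d+))?(?:HxA(?P<hxa>\d+))?"
    r"(?:HexNAc(?P<hexnac>\d+))?(?:Me(?P<me>\d+))?(?P<red>-red)?$"
)

DEFAULT_ADDUCTS: tuple[str, ...] = ("sodium", "proton", "ammonium")


class InvalidCompositionError(ValueError):
    """Raised for compositions violating count invariants (DP >= 1, me <= hxa)."""


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide residue classes plus modifications.

    ``me`` counts 4-O-methyl groups and may not exceed ``hxa`` (methylation
    rides on hexuronic acid). ``reduced`` marks the alditol terminus.
    The canonical text form concatenates non-zero tokens, e.g. ``Hex3``,
    ``Pnt4HxA1Me1``, ``Hex3-red``; parsing round-trips formatting.
    """

    hex: int = 0
    pnt: int = 0
    hxa: int = 0
    hexnac: int = 0
    me: int = 0
    reduced: bool = False

    def __post_init__(self) -> None:
        for name in (*_RESIDUE_FIELDS, "me"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidCompositionError(f"{name} count must be a non-negative integer, got {v!r}")
        if self.dp < 1:
            raise InvalidCompositionError("composition must contain at least one residue (DP >= 1)")
        if self.me > self.hxa:
            raise InvalidCompositionError(
                f"Me count ({self.me}) exceeds HxA count ({self.hxa}); methyl groups ride on hexuronic acid"
            )

    @property
    def dp(self) -> int:
        """Degree of polymerization: total residue count."""
        return self.hex + self.pnt + self.hxa + self.hexnac

    @property
    def n_residue_classes(self) -> int:
        return sum(1 for f in _RESIDUE_FIELDS if getattr(self, f) > 0)

    def __str__(self) -> str:
        parts = [
            f"{_TOKEN_NAMES[f]}{getattr(self, f)}" for f in _RESIDUE_FIELDS if getattr(self, f) > 0
        ]
        if self.me:
            parts.append(f"Me{self.me}")
        return "".join(parts) + ("-red" if self.reduced else "")

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        m = _COMP_RE.match(text.strip())
        if m is None or not text.strip():
            raise InvalidCompositionError(f"cannot parse composition {text!r}")
        g = {k: int(v) for k, v in m.groupdict().items() if k != "red" and v is not None}
        return cls(reduced=m.group("red") is not None, **g)


def neutral_mass(comp: GlycanComposition, table: ResidueMassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic neutral mass: residue sum + water (+ H2 if reduced, + CH2 per methyl)."""
    m = table.water
    m += comp.hex * table.residue_masses["Hex"]
    m += comp.pnt * table.residue_masses["Pnt"]
    m += comp.hxa * table.residue_masses["HxA"]
    m += comp.hexnac * table.residue_masses["HexNAc"]
    m += comp.me * table.modification_masses["Me"]
    if comp.reduced:
        m += table.modification_masses["red"]
    return m


def mz_of(
    comp: GlycanComposition,
    adduct: str = "sodium",
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z of ``[M + n·cation]^n+``."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass(comp, table) + charge * table.adduct_mass(adduct)) / charge


@dataclass(frozen=True)
class AnnotationCandidate:
    """One composition/adduct hypothesis for an observed precursor m/z."""

    composition: GlycanComposition
    adduct: str
    charge: int
    theoretical_mz: float
    ppm_error: float  # signed: (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class CompositionBounds:
    """Search space for combinatorial composition enumeration.

    Defaults follow positive-mode PGC oligosaccharide practice: DP up to 25,
    at most 3 hexuronic acids, methylation only on HxA, and HexNAc only in
    pure chitin-type series. Keeps enumeration well below 1e5 candidates.
    """

    max_dp: int = 25
    max_hex: int = 25
    max_pnt: int = 25
    max_hxa: int = 3
    max_hexnac: int = 10
    pure_hexnac: bool = True
    reduced_states: tuple[bool, ...] = (True,)

    def __iter__(self) -> Iterator[GlycanComposition]:
        return self.iter_compositions()

    def iter_compositions(self) -> Iterator[GlycanComposition]:
        """Every valid composition within bounds (exhaustive, deterministic order)."""
        for n in range(1, min(self.max_hexnac, self.max_dp) + 1):
            for red in self.reduced_states:
                yield GlycanComposition(hexnac=n, reduced=red)
        hexnac_range = (0,) if self.pure_hexnac else range(0, self.max_hexnac + 1)
        for h in range(0, self.max_hex + 1):
            for p in range(0, self.max_pnt + 1):
                for x in range(0, self.max_hxa + 1):
                    for n in hexnac_range:
                        dp = h + p + x + n
                        if dp < 1 or dp > self.max_dp or (n > 0 and h + p + x == 0):
                            continue
                        for me in range(0, x + 1):
                            for red in self.reduced_states:
                                yield GlycanComposition(
                                    hex=h, pnt=p, hxa=x, hexnac=n, me=me, reduced=red
                                )


def annotate_precursor(
    mz: float,
    charge: int = 1,
    tolerance_ppm: float = 15.0,
    bounds: CompositionBounds = CompositionBounds(),
    adducts: Sequence[str] = DEFAULT_ADDUCTS,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[AnnotationCandidate]:
    """Exhaustively enumerate compositions/adducts matching a precursor m/z.

    Returns candidates sorted by |ppm error|, ties broken by fewer residue
    classes, then lower DP (and adduct order for full determinism). An empty
    list is a valid result.
    """
    if mz <= 0:
        raise ValueError("precursor m/z must be positive")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    out: list[AnnotationCandidate] = []
    adduct_order = {a: i for i, a in enumerate(adducts)}
    for comp in bounds.iter_compositions():
        nm = neutral_mass(comp, table)
        for adduct in adducts:
            theo = (nm + charge * table.adduct_mass(adduct)) / charge
            ppm = (mz - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                out.append(AnnotationCandidate(comp, adduct, charge, theo, ppm))
    out.sort(
        key=lambda c: (
            abs(c.ppm_error),
            c.composition.n_residue_classes,
            c.composition.dp,
            adduct_order[c.adduct],
            str(c.composition),
        )
    )
    return out


class Fragment(NamedTuple):
    composition: GlycanComposition
    ion_type: str  # "B" or "Y"
    mz: float


def enumerate_fragments(
    comp: GlycanComposition,
    adduct: str = "sodium",
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> list[Fragment]:
    """Composition-level glycosidic (B/Y) fragments of a precursor.

    Every proper sub-composition (>= 1 residue removed) yields a Y ion
    (residues + water, keeping the parent's alditol end) and a B ion
    (bare residue sum, never carrying the reduced end). Methyl groups
    range over 0..min(parent me, fragment hxa) since their placement
    among the hexuronic acids is unknown. Duplicates are collapsed.
    """
    if comp.dp < 2:
        raise InvalidCompositionError("fragmentation needs at least one glycosidic bond (DP >= 2)")
    cation = table.adduct_mass(adduct)
    seen: set[tuple[GlycanComposition, str]] = set()
    out: list[Fragment] = []
    for h in range(0, comp.hex + 1):
        for p in range(0, comp.pnt + 1):
            for x in range(0, comp.hxa + 1):
                for n in range(0, comp.hexnac + 1):
                    dp = h + p + x + n
                    if dp < 1 or dp >= comp.dp:
                        continue  # proper, non-empty sub-compositions only
                    for me in range(0, min(comp.me, x) + 1):
                        residue_sum = (
                            h * table.residue_masses["Hex"]
                            + p * table.residue_masses["Pnt"]
                            + x * table.residue_masses["HxA"]
                            + n * table.residue_masses["HexNAc"]
                            + me * table.modification_masses["Me"]
                        )
                        y_comp = GlycanComposition(h, p, x, n, me, reduced=comp.reduced)
                        y_neutral = residue_sum + table.water + (
                            table.modification_masses["red"] if comp.reduced else 0.0
                        )
                        b_comp = GlycanComposition(h, p, x, n, me, reduced=False)
                        b_neutral = residue_sum
                        for c, ion, neutral in ((y_comp, "Y", y_neutral), (b_comp, "B", b_neutral)):
                            key = (c, ion)
                            if key in seen:
                                continue
                            seen.add(key)
                            out.append(Fragment(c, ion, (neutral + charge * cation) / charge))
    out.sort(key=lambda f: (f.mz, f.ion_type))
    return out


def score_msms(
    ms2_mz: Iterable[float],
    ms2_intensity: Iterable[float],
    comp: GlycanComposition,
    adduct: str = "sodium",
    charge: int = 1,
    tolerance_ppm: float = 15.0,
    table: ResidueMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Fraction of total MS2 intensity explained by theoretical B/Y fragments.

    A coverage-style score in [0, 1]; deterministic for fixed input. This is
    a documented stand-in for annotation tools whose internal scoring is
    unpublished.
    """
    mz = np.asarray(list(ms2_mz), dtype=float)
    inten = np.asarray(list(ms2_intensity), dtype=float)
    if mz.size == 0 or inten.size == 0:
        raise ValueError("empty MS2 spectrum")
    if mz.size != inten.size:
        raise ValueError("m/z and intensity arrays differ in length")
    total = float(inten.sum())
    if total <= 0:
        raise ValueError("MS2 spectrum has zero total intensity")
    frags = np.array([f.mz for f in enumerate_fragments(comp, adduct, charge, table)])
    matched = np.zeros(mz.size, dtype=bool)
    for fmz in frags:
        matched |= np.abs(mz - fmz) <= fmz * tolerance_ppm * 1e-6
    return float(inten[matched].sum() / total)
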