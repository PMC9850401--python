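"""Monoisotopic masses for monosaccharide residue classes and adduct cations.

Residue masses are the masses of the dehydrated residue as it sits in a
glycosidic chain, i.e. the free monosaccharide minus one water. Residue
classes rather than individual sugars are used because mass spectrometry
cannot distinguish isomers (glucose vs. galactose are both ``Hex``);
chromatographic retention time carries the isomer information instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

# Fundamental monoisotopic constants (Da)
WATER = 18.010565          # H2O
PROTON = 1.007276          # H+ (proton, electron mass removed)
SODIUM_CATION = 22.989218  # Na+ = 22.98976928 - m_e
AMMONIUM_CATION = 18.033823  # NH4+

# Residue-class masses: free monosaccharide minus water
HEX = 162.052824      # hexose residue, C6H10O5
PNT = 132.042259      # pentose residue, C5H8O4
HXA = 176.032088      # hexuronic acid residue, C6H8O6
HEXNAC = 203.079373   # N-acetylhexosamine residue, C8H13NO5

# Modifications
METHYL = 14.015650     # O-methylation, +CH2
REDUCTION = 2.015650   # alditol end from borohydride reduction, +H2

ADDUCT_MASSES: Mapping[str, float] = MappingProxyType({
    "proton": PROTON,
    "sodium": SODIUM_CATION,
    "ammonium": AMMONIUM_CATION,
})


@dataclass(frozen=True)
class ResidueMassTable:
    """Immutable lookup of residue-class, modification and cation masses.

    The defaults cover the four residue classes seen in plant/fungal cell
    wall polysaccharides (Hex, Pnt, HxA, HexNAc) plus 4-O-methylation of
    hexuronic acid and the borohydride-reduced (alditol) terminus.
    Override from JSON with :meth:`from_json` for exotic residue sets.
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {"Hex": HEX, "Pnt": PNT, "HxA": HXA, "HexNAc": HEXNAC}
        )
    )
    modification_masses: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {"Me": METHYL, "red": REDUCTION}
        )
    )
    water: float = WATER
    adduct_masses: Mapping[str, float] = field(default_factory=lambda: ADDUCT_MASSES)

    def __post_init__(self) -> None:
        for name, m in {
            **dict(self.residue_masses),
            **dict(self.modification_masses),
            **dict(self.adduct_masses),
            "water": self.water,
        }.items():
            if not m > 0:
                raise ValueError(f"mass for {name!r} must be strictly positive, got {m}")
        # freeze the mappings so the table is immutable after construction
        object.__setattr__(self, "residue_masses", MappingProxyType(dict(self.residue_masses)))
        object.__setattr__(self, "modification_masses", MappingProxyType(dict(self.modification_masses)))
        object.__setattr__(self, "adduct_masses", MappingProxyType(dict(self.adduct_masses)))

    def adduct_mass(self, adduct: str) -> float:
        try:
            return self.adduct_masses[adduct]
        except KeyError:
            raise ValueError(
                f"unknown adduct {adduct!r}; known: {sorted(self.adduct_masses)}"
            ) from None

    @classmethod
    def from_json(cls, text: str) -> "ResidueMassTable":
        """Build a table from a JSON config block, filling omitted entries
        from the defaults."""
        cfg = json.loads(text)
        base = cls()
        return cls(
            residue_masses={**base.residue_masses, **cfg.get("residue_masses", {})},
            modification_masses={**base.modification_masses, **cfg.get("modification_masses", {})},
            water=cfg.get("water", base.water),
            adduct_masses={**base.adduct_masses, **cfg.get("adduct_masses", {})},
        )


DEFAULT_MASS_TABLE = ResidueMassTable()
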