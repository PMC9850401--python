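"""Reference values for NIST SRM 3233 (Fortified Breakfast Cereal).

The certificate of analysis (COA) reports carbohydrate mass fractions on a
fresh-weight basis; subtracting free sugars and low-molecular-weight
soluble dietary fiber from total carbohydrates estimates the polysaccharide
fraction, the benchmark against which a direct polysaccharide assay's
summed total is compared. The per-polysaccharide values bundled here are an
example measured dataset for this material (g/100 g fresh weight, mean of
triplicates) used by the worked example and the totals arithmetic.
"""

from __future__ import annotations

#: COA mass fractions, g per 100 g fresh weight
SRM3233_COA: dict[str, float] = {
    "total_carbohydrates": 79.23,
    "total_sugars": 16.07,
    "lmw_soluble_dietary_fiber": 3.07,
}

#: Example assayed polysaccharide content, g per 100 g fresh weight
SRM3233_POLYSACCHARIDES: dict[str, float] = {
    "starch": 55.92,
    "cellulose": 1.88,
    "beta-glucan": 1.48,
    "xylan": 0.59,
    "arabinan": 0.10,
    "mannan": 0.03,
    "chitin": 0.01,
}


def coa_polysaccharide_estimate(coa: dict[str, float] = SRM3233_COA) -> float:
    """Polysaccharides by difference: total carbohydrates − sugars − LMW SDF."""
    return (
        coa["total_carbohydrates"]
        - coa["total_sugars"]
        - coa["lmw_soluble_dietary_fiber"]
    )


def total_polysaccharide(measured: dict[str, float] = SRM3233_POLYSACCHARIDES) -> float:
    """Sum of the individually assayed polysaccharides, g/100 g fresh."""
    return sum(measured.values())
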