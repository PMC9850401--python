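"""Composition mass arithmetic, annotation and fragment enumeration.

Expected masses come from an elemental-formula oracle built on atomic
monoisotopic masses, independent of the residue-mass table under test.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycoquant as gq
from glycoquant.composition import (
    CompositionBounds,
    Fragment,
    InvalidCompositionError,
    annotate_precursor,
    enumerate_fragments,
    score_msms,
)
from glycoquant.masses import AMMONIUM_CATION, PROTON, SODIUM_CATION

# atomic monoisotopic masses (CODATA/AME); the oracle sums formulas directly
_H, _C, _N, _O = 1.0078250319, 12.0, 14.0030740052, 15.9949146221


def formula_mass(c: int, h: int, o: int, n: int = 0) -> float:
    return c * _C + h * _H + o * _O + n * _N


class TestNeutralMass:
    @pytest.mark.parametrize(
        "comp, formula",
        [
            (gq.GlycanComposition(hex=1), (6, 12, 6)),            # glucose C6H12O6
            (gq.GlycanComposition(hex=3, reduced=True), (18, 34, 16)),  # maltotriitol
            (gq.GlycanComposition(pnt=2), (10, 18, 9)),           # xylobiose
            (gq.GlycanComposition(hxa=1, me=1), (7, 12, 7)),      # 4-O-methyl glucuronic acid
            (gq.GlycanComposition(hexnac=2), (16, 28, 11, 2)),    # chitobiose C16H28N2O11
        ],
    )
    def test_matches_elemental_formula(self, comp, formula):
        assert gq.neutral_mass(comp) == pytest.approx(formula_mass(*formula[:3], *formula[3:]), abs=1e-4)

    def test_known_values(self):
        assert gq.neutral_mass(gq.GlycanComposition(hex=1)) == pytest.approx(180.0634, abs=1e-4)
        hex3red = gq.GlycanComposition(hex=3, reduced=True)
        assert gq.neutral_mass(hex3red) == pytest.approx(506.1847, abs=1e-4)

    def test_empty_composition_rejected(self):
        with pytest.raises(InvalidCompositionError):
            gq.GlycanComposition()

    def test_methyl_requires_hexuronic_acid(self):
        with pytest.raises(InvalidCompositionError):
            gq.GlycanComposition(hex=2, me=1)

    @given(
        a=st.tuples(st.integers(0, 6), st.integers(0, 6), st.integers(0, 2), st.integers(0, 3)),
        b=st.tuples(st.integers(0, 6), st.integers(0, 6), st.integers(0, 2), st.integers(0, 3)),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_additivity_glycosidic_condensation(self, a, b):
        """neutral(A ⊎ B) = neutral(A) + neutral(B) − water for non-reduced A, B."""
        if sum(a) == 0 or sum(b) == 0:
            return
        ca = gq.GlycanComposition(*a)
        cb = gq.GlycanComposition(*b)
        cab = gq.GlycanComposition(*(x + y for x, y in zip(a, b)))
        assert gq.neutral_mass(cab) == pytest.approx(
            gq.neutral_mass(ca) + gq.neutral_mass(cb) - 18.010565, abs=1e-9
        )


class TestMzOf:
    def test_sodium_and_proton_adducts(self):
        hex3red = gq.GlycanComposition(hex=3, reduced=True)
        assert gq.mz_of(hex3red, "sodium", 1) == pytest.approx(529.1739, abs=1e-4)
        assert gq.mz_of(hex3red, "proton", 1) == pytest.approx(507.1920, abs=1e-4)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            gq.mz_of(gq.GlycanComposition(hex=1), "sodium", 0)

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValueError, match="unknown adduct"):
            gq.mz_of(gq.GlycanComposition(hex=1), "potassium", 1)


def brute_force_annotate(mz, tolerance_ppm, bounds: CompositionBounds, adducts):
    """Independent oracle: explicit nested loops + formula-based masses."""
    residue = {
        "hex": formula_mass(6, 10, 5),
        "pnt": formula_mass(5, 8, 4),
        "hxa": formula_mass(6, 8, 6),
        "hexnac": formula_mass(8, 13, 5, 1),
    }
    water = formula_mass(0, 2, 1)
    h2 = 2 * _H
    ch2 = formula_mass(1, 2, 0)
    cation = {"sodium": SODIUM_CATION, "proton": PROTON, "ammonium": AMMONIUM_CATION}
    hits = set()
    for h in range(bounds.max_hex + 1):
        for p in range(bounds.max_pnt + 1):
            for x in range(bounds.max_hxa + 1):
                for n in range(bounds.max_hexnac + 1):
                    dp = h + p + x + n
                    if dp < 1 or dp > bounds.max_dp:
                        continue
                    if bounds.pure_hexnac and n > 0 and dp != n:
                        continue
                    for me in range(x + 1):
                        for red in bounds.reduced_states:
                            neutral = (
                                h * residue["hex"] + p * residue["pnt"]
                                + x * residue["hxa"] + n * residue["hexnac"]
                                + me * ch2 + water + (h2 if red else 0)
                            )
                            for adduct in adducts:
                                theo = neutral + cation[adduct]
                                if abs(mz - theo) / theo * 1e6 <= tolerance_ppm:
                                    hits.add((h, p, x, n, me, red, adduct))
    return hits


class TestAnnotatePrecursor:
    BOUNDS = CompositionBounds(max_dp=12, max_hex=12, max_pnt=12, max_hxa=2, max_hexnac=6)
    ADDUCTS = ("sodium", "proton", "ammonium")

    def test_recovers_planted_composition_first(self):
        cands = annotate_precursor(529.1739, bounds=self.BOUNDS, adducts=self.ADDUCTS)
        top = cands[0]
        assert str(top.composition) == "Hex3-red"
        assert top.adduct == "sodium"

    def test_below_smallest_mass_empty(self):
        assert annotate_precursor(100.0, bounds=self.BOUNDS) == []

    def test_tight_tolerance_excludes_perturbed_mz(self):
        mz = 529.1739 * (1 + 50e-6)
        assert annotate_precursor(mz, tolerance_ppm=0.1, bounds=self.BOUNDS) == []

    def test_agrees_with_brute_force_oracle(self):
        """Exact set equality against the formula-based enumeration oracle."""
        rng = np.random.default_rng(1234)
        mzs = rng.uniform(150.0, 2100.0, size=100)
        for mz in mzs:
            got = {
                (c.composition.hex, c.composition.pnt, c.composition.hxa,
                 c.composition.hexnac, c.composition.me, c.composition.reduced, c.adduct)
                for c in annotate_precursor(float(mz), tolerance_ppm=15,
                                            bounds=self.BOUNDS, adducts=self.ADDUCTS)
            }
            expected = brute_force_annotate(float(mz), 15, self.BOUNDS, self.ADDUCTS)
            assert got == expected, f"mismatch at m/z {mz}"

    def test_ppm_error_self_consistent(self):
        mz = 529.1739
        for c in annotate_precursor(mz, tolerance_ppm=15, bounds=self.BOUNDS, adducts=self.ADDUCTS):
            recomputed = (mz - c.theoretical_mz) / c.theoretical_mz * 1e6
            assert abs(recomputed - c.ppm_error) < 1e-9

    def test_sorted_by_abs_ppm(self):
        cands = annotate_precursor(1000.0, tolerance_ppm=200, bounds=self.BOUNDS, adducts=self.ADDUCTS)
        errs = [abs(c.ppm_error) for c in cands]
        assert errs == sorted(errs)


class TestFragments:
    def test_hex3_reduced_fragment_set(self):
        frags = enumerate_fragments(gq.GlycanComposition(hex=3, reduced=True), "sodium", 1)
        labelled = {(str(f.composition), f.ion_type) for f in frags}
        assert labelled == {
            ("Hex1-red", "Y"), ("Hex2-red", "Y"), ("Hex1", "B"), ("Hex2", "B"),
        }
        y_hex2 = next(f for f in frags if f.ion_type == "Y" and f.composition.hex == 2)
        assert y_hex2.mz == pytest.approx(367.1211, abs=1e-4)

    def test_monosaccharide_cannot_fragment(self):
        with pytest.raises(InvalidCompositionError):
            enumerate_fragments(gq.GlycanComposition(hex=1))

    def test_pnt2_reduced_gives_four_records(self):
        frags = enumerate_fragments(gq.GlycanComposition(pnt=2, reduced=True))
        assert len(frags) == 2  # B1 and Y1 (compositions collapse within ion type)
        assert {f.ion_type for f in frags} == {"B", "Y"}

    def test_fragments_below_precursor_and_no_full_y(self):
        comp = gq.GlycanComposition(hex=2, pnt=2, hxa=1, me=1, reduced=True)
        precursor = gq.neutral_mass(comp)
        for f in enumerate_fragments(comp, "proton", 1):
            assert f.mz - PROTON <= precursor + 1e-9
            assert f.composition.dp < comp.dp  # the intact Y "fragment" never appears


class TestScoreMsms:
    COMP = gq.GlycanComposition(hex=3, reduced=True)

    def _theoretical(self):
        return np.array([f.mz for f in enumerate_fragments(self.COMP, "sodium", 1)])

    def test_perfect_spectrum_scores_one(self):
        mzs = self._theoretical()
        assert score_msms(mzs, np.ones_like(mzs), self.COMP) == pytest.approx(1.0)

    def test_no_matches_scores_zero(self):
        assert score_msms([50.0, 60.0], [5.0, 5.0], self.COMP) == 0.0

    def test_half_intensity_on_matches(self):
        mzs = np.concatenate([self._theoretical()[:1], [77.7]])
        assert score_msms(mzs, [10.0, 10.0], self.COMP) == pytest.approx(0.5)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            score_msms([], [], self.COMP)


class TestTextForm:
    @given(
        st.integers(0, 9), st.integers(0, 9), st.integers(0, 3),
        st.integers(0, 5), st.booleans(), st.data()
    )
    @settings(max_examples=150, derandomize=True)
    def test_parse_format_round_trip(self, h, p, x, n, red, data):
        if h + p + x + n == 0:
            return
        me = data.draw(st.integers(0, x))
        comp = gq.GlycanComposition(h, p, x, n, me, red)
        assert gq.GlycanComposition.parse(str(comp)) == comp

    @pytest.mark.parametrize("bad", ["", "Hex", "hex3", "Me1", "Hex2Me1", "Pnt-3"])
    def test_rejects_malformed_text(self, bad):
        with pytest.raises(InvalidCompositionError):
            gq.GlycanComposition.parse(bad)
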