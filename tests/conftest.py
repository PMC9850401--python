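"""Shared fixtures: small synthetic polysaccharide sets and prebuilt libraries.

All fixtures are generated programmatically and seeded; session scope keeps
the expensive simulations to one execution per run.
"""

from __future__ import annotations

import pytest

import glycoquant as gq
from glycoquant.library import AnnotationConfig

# Compact three-polysaccharide world on a short gradient: distinct residue
# classes so every composition is unique, DP 3-6 ladders.
TOY_POLYS = (
    gq.SimPolysaccharide("starchlet", "Hex", (3, 6), rt_base=2.0, rt_per_dp=1.0,
                         response_slope=30000.0),
    gq.SimPolysaccharide("arabinlet", "Pnt", (3, 6), rt_base=3.5, rt_per_dp=1.0,
                         response_slope=30000.0),
    gq.SimPolysaccharide("chitinlet", "HexNAc", (3, 6), rt_base=5.0, rt_per_dp=1.0,
                         response_slope=30000.0),
)

TOY_SIM = gq.SimConfig(seed=42, gradient_min=12.0, noise_rel=0.002)
TOY_ANNOT = AnnotationConfig(
    bounds=gq.CompositionBounds(max_dp=8, max_hxa=1, max_hexnac=6),
    adducts=("sodium",),
)


@pytest.fixture(scope="session")
def toy_polys():
    return TOY_POLYS


@pytest.fixture(scope="session")
def toy_annot():
    return TOY_ANNOT


@pytest.fixture(scope="session")
def toy_standard_runs(toy_polys):
    """One clean standard run per toy polysaccharide at 1000 µg/mL."""
    return {
        p.name: gq.simulate_run({p.name: 1000.0}, toy_polys, TOY_SIM)[0]
        for p in toy_polys
    }


@pytest.fixture(scope="session")
def toy_library(toy_standard_runs, toy_annot):
    return gq.build_library(toy_standard_runs, toy_annot)


@pytest.fixture(scope="session")
def nine_standard_runs():
    """The nine supported polysaccharides, noiseless standards (full gradient)."""
    cfg = gq.SimConfig(seed=7, noise_rel=0.0)
    return {
        p.name: gq.simulate_run({p.name: 2000.0}, config=cfg)[0]
        for p in gq.DEFAULT_POLYSACCHARIDES
    }


@pytest.fixture(scope="session")
def nine_annot():
    return AnnotationConfig(
        bounds=gq.CompositionBounds(max_dp=21, max_hxa=1, max_hexnac=8),
        adducts=("sodium",),
    )


@pytest.fixture(scope="session")
def nine_library(nine_standard_runs, nine_annot):
    return gq.build_library(nine_standard_runs, nine_annot)
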