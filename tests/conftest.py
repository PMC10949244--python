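"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from motifscaffold import fixtures as fx
from motifscaffold.hallucination import RestraintCompiler, SurrogateOracle
from motifscaffold.restraint_map import MotifSpec, ScaffoldLayout, WeightCategory
from motifscaffold.template_geometry import (
    BinningScheme,
    bin_geometry,
    compute_6d,
    parse_structure,
)


@pytest.fixture(scope="session")
def toy_template():
    """(pdb_text, sequence, author numbering) of the idealized template."""
    return fx.toy_template_pdb(seed=0)


@pytest.fixture(scope="session")
def toy_structure(toy_template):
    pdb, _, _ = toy_template
    return parse_structure(pdb, "A")


@pytest.fixture(scope="session")
def toy_maps(toy_structure):
    return compute_6d(toy_structure)


@pytest.fixture(scope="session")
def coarse_scheme():
    """Small bin counts keep per-step MCMC evaluation cheap in tests."""
    return BinningScheme(n_dist_bins=12, n_omega_bins=8, n_theta_bins=8, n_phi_bins=4)


@pytest.fixture(scope="session")
def toy_binned(toy_maps, coarse_scheme):
    return bin_geometry(toy_maps, coarse_scheme)


@pytest.fixture(scope="session")
def toy_motifs(toy_structure):
    """Three motifs covering the template segments, with heavy weights and
    one fixed identity per motif."""
    aa_of = {r.number: r.aa for r in toy_structure.residues}
    motifs = []
    for i, (start, end, _) in enumerate(fx.toy_template_segments()):
        motifs.append(
            MotifSpec(
                name=f"m{i + 1}",
                span=(start, end),
                weights={start + 1: WeightCategory.HEAVY, start + 2: WeightCategory.MEDIUM},
                fixed={start + 1: aa_of[start + 1]},
            )
        )
    return motifs


@pytest.fixture(scope="session")
def toy_layout(toy_motifs):
    total = sum(m.length for m in toy_motifs)
    return ScaffoldLayout(
        length=total + 6,
        motifs=toy_motifs,
        linker_bounds=[(0, 3), (1, 3), (1, 3), (0, 3)],
    )


@pytest.fixture(scope="session")
def compiler(toy_binned, toy_structure, toy_layout):
    return RestraintCompiler(toy_binned, toy_structure.numbering, toy_layout)


@pytest.fixture(scope="session")
def reference(toy_structure):
    return {r.number: r.aa for r in toy_structure.residues}


@pytest.fixture(scope="session")
def oracle(reference):
    return SurrogateOracle(reference)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
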