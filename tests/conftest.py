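"""Shared fixtures: synthetic ensembles are built once per session (the
layer geometry solver caches per layer class, so later builds are cheap)."""
import numpy as np
import pytest

from tetrahelix.synthetic import StackSpec, build_quartet_stack


@pytest.fixture(scope="session")
def gaga_stack():
    """Two stacked GAGA quartets, rise 3.4 A, twist 25 deg."""
    return build_quartet_stack(
        StackSpec(layer_classes=["GAGA", "GAGA"], rise=3.4, twist=25.0)
    )


@pytest.fixture(scope="session")
def mixed_stack():
    """GCGC-minor / GAGA / GGGG stack used for recovery tests."""
    return build_quartet_stack(
        StackSpec(layer_classes=["GCGC_MINOR", "GAGA", "GGGG"],
                  rise=3.4, twist=[0.0, 25.0, 25.0])
    )


@pytest.fixture(scope="session")
def tetramer_core_stack():
    """Six-layer core mimicking a tetrameric AGCGA-quadruplex stack order:
    major-groove GCGC / GGGG / GAGA / GAGA / GGGG / major-groove GCGC."""
    return build_quartet_stack(
        StackSpec(
            layer_classes=["GCGC_MAJOR", "GGGG", "GAGA", "GAGA", "GGGG",
                           "GCGC_MAJOR"],
            rise=3.4, twist=[0.0, 20.0, 25.0, 25.0, 25.0, 20.0],
        )
    )


@pytest.fixture(scope="session")
def backbone_pair_stack():
    """Two stacked Watson-Crick G-C pair layers with sugar-phosphate
    backbone attached (for torsion / NOE tests)."""
    return build_quartet_stack(
        StackSpec(layer_classes=["GC_PAIR", "GC_PAIR"], rise=3.4,
                  twist=36.0, backbone=True)
    )


def analytic_b_duplex(n=20, radius=9.05, twist=36.0, rise=3.38,
                      strand_offset=154.0):
    """Phosphate-only antiparallel duplex with canonical B-form helical
    parameters (used for groove-width checks)."""
    from tetrahelix.structio import AtomRecord, Chain, Model, Residue

    chA, chB = Chain(id="A"), Chain(id="B")
    for i in range(n):
        phi_a = np.radians(twist * i)
        ra = Residue(name="DG", number=i + 1, chain_id="A")
        ra.add(AtomRecord("P", "P",
                          [radius * np.cos(phi_a), radius * np.sin(phi_a),
                           rise * i]))
        chA.residues.append(ra)
        phi_b = np.radians(twist * i - strand_offset)
        rb = Residue(name="DC", number=n - i, chain_id="B")
        rb.add(AtomRecord("P", "P",
                          [radius * np.cos(phi_b), radius * np.sin(phi_b),
                           rise * i]))
        chB.residues.append(rb)
    chB.residues.reverse()
    return Model(index=1, chains=[chA, chB])
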