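import numpy as np
import pytest

import calmscape as cs


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_alignment():
    """5 columns: invariant, invariant, 50/50 binary, uniform-ish, gapped."""
    rows = ["AAWKA", "AAWRA", "AARK-", "AARR-"]
    return cs.alignment_from_rows(rows)


@pytest.fixture
def backbone_pair():
    """Noise-free structure pair related by a known rigid transform."""
    spec = cs.StructurePairSpec(
        n_residues=30, rotation_axis=(0.0, 0.0, 1.0),
        rotation_angle=np.pi / 2, translation=(1.0, 2.0, 3.0), seed=7,
    )
    return cs.generate_structure_pair(spec)


@pytest.fixture
def contact_complex():
    model, truth = cs.generate_complex(
        cs.ComplexSpec(chain_sizes=(16, 16), interface_spacing=4.0,
                       hydrophobic_fraction_at_interface=1.0, seed=11))
    return model, truth


@pytest.fixture
def separated_complex():
    model, truth = cs.generate_complex(
        cs.ComplexSpec(chain_sizes=(16, 16), interface_spacing=100.0,
                       hydrophobic_fraction_at_interface=1.0, seed=11))
    return model, truth
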