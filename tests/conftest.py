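import dataclasses

import numpy as np
import pytest

from aromstack import template_phe
from aromstack.ring_geometry import AromaticRing, transform_ring


def make_ring(
    R=np.eye(3), t=(0.0, 0.0, 0.0), chain="A", seq_index=1, resname="PHE"
) -> AromaticRing:
    """Template Phe ring under a rigid motion, relabelled for contact tests."""
    ring = transform_ring(template_phe(), np.asarray(R, float), np.asarray(t, float))
    return dataclasses.replace(
        ring, residue_ref=(chain, seq_index, resname), auth_seqid=str(seq_index)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
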