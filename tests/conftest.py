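import numpy as np
import pytest

from tisdiv import CodonAlignment, ProfileParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def ecoli_like_params():
    """Curve parameters matching the reference species estimates:
    effect length 76 bases, effect size 2.2 log2 units."""
    return ProfileParams.from_effects(Le=76.0, Se=2.2, dmax=0.05)


@pytest.fixture
def small_config():
    return SimConfig(n_strains=20, n_genes=40, gene_length_distribution=(50, 200, 1.0), seed=7)


def make_alignment(seqs, gene_id="g", ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return CodonAlignment(gene_id=gene_id, strain_ids=ids, sequences=list(seqs))


@pytest.fixture
def make_aln():
    return make_alignment
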