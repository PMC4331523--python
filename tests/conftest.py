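import numpy as np
import pytest

from sigscreen import Bioset, BiosetRecord, GeneSignature
from sigscreen.synthetic_data import gene_name


@pytest.fixture
def small_signature():
    return GeneSignature(
        up=[("a", 2.0), ("b", 1.6)], down=[("c", -1.8)], name="SIG"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_bioset(rng, n=50, universe=20000, seed_genes=None):
    """Uniform random bioset: n distinct genes, random signs and magnitudes."""
    idx = rng.choice(universe, n, replace=False)
    fcs = rng.choice([-1.0, 1.0], n) * np.exp2(rng.uniform(0.3, 2.5, n))
    records = [
        BiosetRecord(gene=gene_name(i), fold_change=float(f),
                     adj_p=float(rng.uniform(0, 0.01)))
        for i, f in zip(idx, fcs)
    ]
    return Bioset(records=records, universe_size=universe)


def signature_from_truth(truth):
    """Directional signature straight from a SyntheticTruth's planted program."""
    return GeneSignature(
        up=[(g, 2.0) for g in sorted(truth.program_up)],
        down=[(g, -2.0) for g in sorted(truth.program_down)],
        name="planted",
    )
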