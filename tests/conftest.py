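import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from taxogenomics.seqio import extract_genes
from taxogenomics.synthetic import EvolutionParams, generate_ancestor, synthetic_pair


@pytest.fixture(scope="session")
def small_ancestor():
    """20 genes of ~300 bp at 60% G+C — shared read-only fixture."""
    genome, ann = generate_ancestor(20, mean_gene_length=300, gc_target=0.6, seed=7)
    genes = extract_genes(genome, ann)
    return genome, ann, genes


@pytest.fixture(scope="session")
def evolved_pair():
    """Ancestor/derived gene sets at p=0.02, no indels or gain/loss."""
    params = EvolutionParams(substitution_p=0.02, seed=11)
    return synthetic_pair(30, params, mean_gene_length=300, gc_target=0.5)
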