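import pytest

from exocrac import (BindingModel, GenomeSpec, build_flanked_trna_db,
                     build_toy_genome, simulate_library)
from exocrac.preprocess import preprocess_reads


@pytest.fixture(scope="session")
def toy():
    """Toy genome with 5 tRNA families x 3 copies plus RNAPII classes."""
    spec = GenomeSpec(seed=3)
    genome, ann, design = build_toy_genome(spec)
    return genome, ann, design


@pytest.fixture(scope="session")
def trna_db(toy):
    genome, ann, _ = toy
    return build_flanked_trna_db(ann, genome)


@pytest.fixture(scope="session")
def trna_library(toy):
    """Collapsed tRNA-only library with truth, shared across tests."""
    genome, ann, _ = toy
    model = BindingModel("Rrp44-exo", class_weights={"tRNA": 1.0},
                         adapter_truncation_frac=0.0)
    reads, truth = simulate_library(genome, ann, model, 1500, seed=7)
    collapsed, report = preprocess_reads(reads, model.adapter,
                                         apply_lc_filter=False)
    return collapsed, truth, report


def molecule_of(read_id: str) -> str:
    """Map a simulated read id back to its molecule id."""
    return read_id.rsplit("_d", 1)[0]
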