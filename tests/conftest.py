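import pytest

from terminus.end_annotation import annotate_ends
from terminus.synthetic_data import (
    COMPARTMENTS,
    SimConfig,
    impa1_fixture,
    shift_study_loci,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def impa1_dataset():
    """Simulated three-isoform IMPA1 locus, two compartments x two replicates."""
    return simulate_dataset([impa1_fixture()], SimConfig(seed=11))


@pytest.fixture(scope="session")
def impa1_annotation(impa1_dataset):
    pooled = {c: impa1_dataset.pooled_track(c) for c in COMPARTMENTS}
    return annotate_ends(pooled, impa1_dataset.transcripts)


@pytest.fixture(scope="session")
def small_shift_dataset():
    """20 two-isoform loci (6 shifted) plus 10 background loci."""
    loci = shift_study_loci(n_loci=20, n_shift=6, n_background=10)
    return simulate_dataset(loci, SimConfig(seed=5), plant_pas=False)
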