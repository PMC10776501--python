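import numpy as np
import pytest
from hypothesis import settings

from cfmotif.simulation import (
    ReferenceSequence,
    SimulationConfig,
    make_reference,
    reference_motif_freqs,
    simulate_cohort_profiles,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference() -> ReferenceSequence:
    """A 20 kb random reference; long enough that all 256 4-mers occur."""
    return make_reference(20_000, gc_content=0.5, seed=101)


@pytest.fixture(scope="session")
def reference_files(reference, tmp_path_factory):
    """The session reference written as FASTA with its .fai index."""
    from cfmotif.simulation import write_reference_fasta

    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    write_reference_fasta(reference, path)
    return path


@pytest.fixture(scope="session")
def base_freqs(reference) -> np.ndarray:
    return reference_motif_freqs(reference)


@pytest.fixture(scope="session")
def small_cohort(base_freqs):
    """30+30 samples with the default planted 13-motif effect."""
    config = SimulationConfig(
        n_cancer=30,
        n_healthy=30,
        base_freqs=base_freqs,
        fragments_per_sample=50_000,
        seed=202,
    )
    matrix, metas = simulate_cohort_profiles(config)
    return matrix, metas


@pytest.fixture(scope="session")
def null_cohort(base_freqs):
    """30+30 samples with no class effect (fold change 1)."""
    config = SimulationConfig(
        n_cancer=30,
        n_healthy=30,
        base_freqs=base_freqs,
        fold_change=1.0,
        fragments_per_sample=50_000,
        seed=23,
    )
    matrix, metas = simulate_cohort_profiles(config)
    return matrix, metas
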