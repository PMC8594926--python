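import pytest

from fivexp import (
    PreprocessParams,
    SimulationParams,
    make_reference_bundle,
    simulate_reads,
)


def ideal_params(**kw) -> SimulationParams:
    """Zero-noise simulation: no sequencing errors, flat Q40 qualities."""
    defaults = dict(seed=7, n_reads=2000, p_tagged=0.5, error_rate=0.0,
                    quality_sd=0.0, quality_mean=40.0, low_quality_fraction=0.0)
    defaults.update(kw)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def bundle():
    """A small all-biotype reference bundle (seeded)."""
    return make_reference_bundle(
        11,
        {"miRNA": 6, "Mt_tRNA": 2, "tRNA": 4, "MT_rRNA": 1, "rRNA": 2,
         "piRNA": 8, "other_sncRNA": 3},
    )


@pytest.fixture(scope="session")
def zero_noise_run(bundle):
    """Reads + truth simulated without noise; biotype recovery is exact."""
    reads, truth = simulate_reads(bundle, ideal_params())
    return reads, truth


@pytest.fixture()
def params():
    return PreprocessParams()
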