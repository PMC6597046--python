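import numpy as np
import pytest

from pedcurate.datamodel import GenotypeMatrix, Individual, Pedigree
from pedcurate.pipeline import PipelineConfig, run_pipeline
from pedcurate.simulate import SimulationConfig, simulate_dataset


def make_matrix(calls: dict[str, dict[str, str]]) -> GenotypeMatrix:
    """Build a small matrix from {marker: {individual: 'AA'|'AB'|'BB'|'--'}}."""
    import pandas as pd

    frame = pd.DataFrame(calls).T.fillna("--")
    return GenotypeMatrix.from_frame(frame)


@pytest.fixture
def trio_ped() -> Pedigree:
    return Pedigree(
        [
            Individual("mom", selected=True),
            Individual("dad", selected=True),
            Individual("kid", mother="mom", father="dad"),
        ]
    )


# one small cohort without injected errors, shared by phasing/haploblock tests
_SMALL_CLEAN = SimulationConfig(
    seed=11,
    n_founders=12,
    generation_sizes=(20, 30),
    n_linkage_groups=2,
    n_markers_per_lg=120,
    missing_rate=0.0,
    random_miscall_rate=0.0,
    cluster_shift_fraction=0.0,
    n_wrong_parents=0,
    n_duplicate_pairs=0,
    n_triploids=0,
    n_bad_quality=0,
)


@pytest.fixture(scope="session")
def clean_sim():
    return simulate_dataset(_SMALL_CLEAN)


@pytest.fixture(scope="session")
def default_sim():
    """The standard scenario: 200 individuals, 5 LGs x 200 markers, all
    error types injected."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline run on the standard scenario (shared; ~20 s)."""
    ds = default_sim
    return run_pipeline(ds.gm, ds.pedigree, ds.gmap, ds.baf, PipelineConfig(seed=1))
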