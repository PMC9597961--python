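import numpy as np
import pytest

from mirmod.io import LibraryDesign, full_factorial_design
from mirmod.pipeline import PipelineConfig, run_pipeline, study_from_simulation
from mirmod.sim import SimConfig, simulate_study


@pytest.fixture(scope="session")
def design48():
    return full_factorial_design()


@pytest.fixture()
def contrast_design():
    """Six libraries covering one (ST, 3 h) NaCl-vs-control contrast."""
    return [
        LibraryDesign(f"ST_T3_{cond}_r{r}", "ST", 3.0, cond, r)
        for cond in ("CT", "NaCl") for r in (1, 2, 3)
    ]


@pytest.fixture(scope="session")
def small_study():
    """A fast synthetic study for unit-level checks."""
    cfg = SimConfig(seed=11, n_mirna=20, n_transcripts=60, n_true_modules=8)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The full-scale synthetic study: 60 miRNAs, 300 transcripts, 24 modules."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_study):
    """The complete pipeline run on the full-scale study (computed once)."""
    cfg = PipelineConfig(sim=default_study.config)
    return run_pipeline(study_from_simulation(default_study), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
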