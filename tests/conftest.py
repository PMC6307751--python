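import numpy as np
import pytest

from colonyquant.config import PipelineConfig
from colonyquant.invitro_fixed import build_fixed_result
from colonyquant.invivo import analyze_section
from colonyquant.synthgen import GeneratorConfig, generate_fixed_well, generate_lung_section


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def fixed_well_seed1():
    """One rendered fixed well (seed 1) with its truth, analyzed once."""
    channels, truth = generate_fixed_well(seed=1)
    result = build_fixed_result(channels)
    return channels, truth, result


@pytest.fixture(scope="session")
def exclusion_section():
    """Lung section with micro clusters at controlled boundary gaps
    {20, 39, 41, 100} px from a single macro lesion."""
    cfg = GeneratorConfig(
        height=640,
        width=768,
        n_macro=1,
        macro_radius_px=(30.0, 30.0),
        micro_gaps_px=[20, 39, 41, 100],
    )
    channels, truth, lung = generate_lung_section(cfg, seed=7)
    result = analyze_section(channels)
    return truth, result


def match_to_truth(colony, truth_objects):
    """Truth row whose center is nearest to a detected colony."""
    d2 = (truth_objects.row - colony.centroid[0]) ** 2 + (
        truth_objects.col - colony.centroid[1]
    ) ** 2
    return truth_objects.iloc[int(np.argmin(d2))]
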