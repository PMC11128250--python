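import numpy as np
import pytest

from dcplan import beamlets, pipeline, targets


@pytest.fixture(scope="session")
def beam_nrs5() -> beamlets.BeamSpec:
    """78.3 MeV beam treating 5 cm depth without the range shifter."""
    return beamlets.beam_from_table(78.3, False)


@pytest.fixture(scope="session")
def library_nrs5(beam_nrs5) -> beamlets.KernelLibrary:
    return beamlets.build_library(beam_nrs5, tsd=5.0)


@pytest.fixture(scope="session")
def circle3() -> targets.TargetGeometry:
    return targets.make_circle_target(30.0, spacing=0.5)


@pytest.fixture(scope="session")
def circle3_pair() -> pipeline.PairResult:
    """Optimized open/collimated pair on the 3 cm circle (fast scenario)."""
    cfg = pipeline.PipelineConfig(shape="circle3")
    return pipeline.plan_pair(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
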