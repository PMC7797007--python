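import numpy as np
import pytest

from eprime.cases import CaseSpec, ScannerSpec
from eprime.estimator import EngineConfig
from eprime.phantom import GridSpec, VesselSpec


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec(clinical_pixel_size=0.45, hyper_factor=10, field_of_view=12.8)


@pytest.fixture
def vessel() -> VesselSpec:
    return VesselSpec(
        reference_lumen_diameter=3.0,
        stenosis_fraction=0.5,
        plaque_material="mixed",
        lumen_hu=450.0,
    )


@pytest.fixture
def engine() -> EngineConfig:
    return EngineConfig()


def make_case(**kwargs) -> CaseSpec:
    """Mid-range reference case with direct diameter/velocity overrides."""
    scanner_kwargs = dict(sigma_hu=30.0, pixel_size_mm=0.45, rotation_time_s=0.33)
    case_kwargs = dict(
        diameter_mm=3.0,
        velocity_mm_s=20.0,
        stenosis_severity_pct=50.0,
        plaque_material="mixed",
        lumen_enhancement=450.0,
    )
    for key, val in kwargs.items():
        if key in scanner_kwargs or key in ScannerSpec.__dataclass_fields__:
            scanner_kwargs[key] = val
        else:
            case_kwargs[key] = val
    return CaseSpec(scanner=ScannerSpec(**scanner_kwargs), **case_kwargs)


@pytest.fixture
def case_factory():
    return make_case


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
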