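import numpy as np
import pytest

from mesosheet.beam_models import (
    AirySheetSpec,
    GaussianSheetSpec,
    OpticalMedium,
    design_gaussian_sheet,
)


@pytest.fixture(scope="session")
def medium():
    """488 nm illumination in BABB-cleared tissue / LDF oil (n = 1.515)."""
    return OpticalMedium(0.488, 1.515)


@pytest.fixture(scope="session")
def airy_sheet(medium):
    """The calibrated Airy illuminator: 7.8 um main lobe at the focus."""
    return AirySheetSpec(a=0.05, alpha=0.7, effective_na=0.043,
                         transverse_scale=4.672, medium=medium)


@pytest.fixture(scope="session")
def gaussian_sheet_3mm(medium):
    """Gaussian sheet designed so its confocal region spans 3 mm."""
    return design_gaussian_sheet(3000.0, medium)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
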