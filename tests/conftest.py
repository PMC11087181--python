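import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scintshot import AnalysisConfig, PhantomSpec


@pytest.fixture
def camera_scale_spec() -> PhantomSpec:
    """Phantom at the camera's operating scale: 0.16 mm/px, six beams."""
    return PhantomSpec()


@pytest.fixture
def camera_scale_config(camera_scale_spec) -> AnalysisConfig:
    return AnalysisConfig(
        pixel_pitch_mm=camera_scale_spec.pixel_pitch_mm,
        gantry_angles_deg=camera_scale_spec.gantry_angles_deg,
    )
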