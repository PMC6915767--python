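import numpy as np
import pytest

from arraytomo.stacks import BinaryStack
from arraytomo.synthetic import SynthParams, generate_stack


@pytest.fixture(scope="session")
def default_field():
    """One default synthetic field (stack + truth), shared read-only."""
    return generate_stack(SynthParams(seed=11))


@pytest.fixture(scope="session")
def subpixel_field():
    return generate_stack(SynthParams(seed=12, subpixel_shifts=True,
                                      shift_sd_px=1.0))


def make_binary(mask: np.ndarray, channel: str = "test",
                px: float = 0.1, dz: float = 0.07) -> BinaryStack:
    return BinaryStack(mask=np.asarray(mask, dtype=bool), channel=channel,
                       pixel_size_xy=px, section_thickness=dz)
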