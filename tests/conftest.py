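import numpy as np
import pytest

from ppolung.hu_volumetrics import (
    HUVolume,
    LungLabelMap,
    RegionVolumetrics,
    SegmentInfo,
)
from ppolung.synthetic_data import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default-spec phantom with its label map and exact class ground truth."""
    return make_phantom(PhantomSpec(seed=42))


@pytest.fixture
def two_segment_lung():
    """Hand-built volumetrics: segment 1 = 600 mL all well-aerated,
    segment 2 = 400 mL of which 100 mL well-aerated, both right-sided."""
    table = {1: SegmentInfo("right", "right upper lobe", "S1"),
             2: SegmentInfo("right", "right upper lobe", "S2")}

    def region(code, total, well, emph, non):
        return RegionVolumetrics(
            region_id=f"segment:{code}", laterality="right",
            lobe="right upper lobe", segment=f"S{code}",
            volume_total=total, volume_well_aerated=well,
            volume_emphysematous=emph, volume_non_aerated=non,
            label_codes=frozenset({code}))

    rows = [region(1, 600.0, 600.0, 0.0, 0.0),
            region(2, 400.0, 100.0, 200.0, 100.0)]
    return rows, table


def small_uniform_volume(hu_value, shape=(6, 6, 6), spacing=(1.0, 1.0, 1.0)):
    """A single-segment lung at a constant HU, with a right/S1 label table."""
    vol = HUVolume(values=np.full(shape, float(hu_value)), spacing=spacing)
    labels = LungLabelMap(
        labels=np.ones(shape, dtype=np.int16),
        table={1: SegmentInfo("right", "right upper lobe", "S1")})
    return vol, labels
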