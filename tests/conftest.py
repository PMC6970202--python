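import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mmrimmune as mi
from mmrimmune.records import (
    Compartment,
    Marker,
    Pdl1Pattern,
    Specimen,
    TumorRecord,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(
    tumor_id="T1",
    cohort="MMRP",
    specimen=Specimen.HYSTERECTOMY,
    fill=10,
    **kwargs,
):
    """A valid record with constant ROI counts unless overridden."""
    compartments = (
        list(Compartment) if Specimen(specimen) is Specimen.HYSTERECTOMY else [Compartment.CT]
    )
    roi = {(m, c): [fill] * 4 for m in Marker for c in compartments}
    roi.update(kwargs.pop("roi_overrides", {}))
    return TumorRecord(
        tumor_id=tumor_id,
        cohort=cohort,
        specimen=specimen,
        roi_counts=roi,
        pdl1_tumor_pct_by_intensity={1: 5.0, 2: 2.0, 3: 0.0},
        pdl1_immune_pattern=Pdl1Pattern.FOCAL,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions (n = 93)."""
    return mi.generate_cohort(mi.GeneratorConfig(seed=20))


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return mi.assemble_design(default_cohort)
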