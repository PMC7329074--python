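import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sfprog.indices import BLIND_SPOT_LOCATIONS, PointwiseField, garway_heath_map

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_field(db=30.0, eye_id="eye1", laterality="right", overrides=None, **kwargs):
    """A full 54-location 24-2 field at a constant sensitivity, with overrides."""
    sens = {loc: float(db) for loc in garway_heath_map().assignment}
    if overrides:
        sens.update(overrides)
    return PointwiseField(
        eye_id=eye_id, laterality=laterality, sensitivities=sens,
        fp=0.05, fn=0.05, fl=0.05, **kwargs,
    )


@pytest.fixture
def full_field():
    return make_field()


@pytest.fixture
def blind_spot():
    return BLIND_SPOT_LOCATIONS


def make_flag_table(flag_map, visit_months=None):
    """Build a FlagTable from {criterion: {length: {eye: bool}}}."""
    from sfprog.evaluation import FlagTable

    rows = [
        {"eye_id": eye, "series_length": k, "criterion": crit, "flag": bool(v)}
        for crit, by_len in flag_map.items()
        for k, by_eye in by_len.items()
        for eye, v in by_eye.items()
    ]
    vt = None
    if visit_months is not None:
        vt = pd.DataFrame(
            [
                {"eye_id": eye, "visit": i + 1, "month": m}
                for eye, months in visit_months.items()
                for i, m in enumerate(months)
            ]
        )
    return FlagTable(pd.DataFrame(rows), vt)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
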