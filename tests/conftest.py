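import numpy as np
import pytest

from benzrisk import (
    CompartmentParams,
    MetabolismParams,
    PBPKParameters,
    Physiology,
    default_parameters,
)
from benzrisk.pbpk_core import CompartmentName


@pytest.fixture(scope="session")
def params():
    return default_parameters()[0]


@pytest.fixture(scope="session")
def phys():
    return default_parameters()[1]


def random_parameter_set(rng: np.random.Generator) -> tuple[PBPKParameters, Physiology]:
    """A physically plausible random parameter draw for property tests."""
    comps = tuple(
        CompartmentParams(
            name=name,
            Q=float(rng.uniform(0.05, 3.0)),
            V=float(rng.uniform(0.3, 30.0)),
            P=float(rng.uniform(0.5, 60.0)),
        )
        for name in CompartmentName
    )
    met = MetabolismParams(
        Vmax=float(rng.uniform(0.05, 2.0)),
        Km=float(rng.uniform(0.05, 2.0)),
        f_ttma=float(rng.uniform(0.005, 0.2)),
    )
    phys = Physiology(
        age=float(rng.uniform(6, 12)),
        body_weight=float(rng.uniform(18, 45)),
        P_blood_air=float(rng.uniform(5.0, 12.0)),
        Q_alv=float(rng.uniform(1.0, 4.0)),
        Q_card=float(rng.uniform(2.0, 5.0)),
        urine_void_volume=float(rng.uniform(0.05, 0.4)),
        urinary_creatinine=float(rng.uniform(0.4, 1.8)),
    )
    return PBPKParameters(compartments=comps, metabolism=met), phys
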