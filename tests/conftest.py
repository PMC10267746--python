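import numpy as np
import pytest

from sitpress import reference
from sitpress.frames import PlanarForce, SeatConfig


@pytest.fixture(scope="session")
def seat_configs():
    return reference.seat_configs()


@pytest.fixture(scope="session")
def exp_forces():
    return reference.force_table("exp")


@pytest.fixture(scope="session")
def sim_forces():
    return reference.force_table("sim")


def global_forces_for(table, condition):
    """Assemble the three global-frame surface forces of one table row."""
    return [
        PlanarForce(
            fx=table.loc[condition, f"Fx_{s}_G"],
            fz=table.loc[condition, f"Fz_{s}_G"],
            frame="global",
            surface=s,
        )
        for s in ("SB", "SP", "FS")
    ]
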