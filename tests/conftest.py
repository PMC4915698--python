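from datetime import datetime, timedelta

import pytest

from crossingmon.records import TriggerRecord
from crossingmon.simulate import SimulationConfig, StructureSpec


def rec(
    ts: str | datetime,
    species: str = "wolf",
    count: int = 3,
    structure: str = "OSM",
    camera: str = "cam1",
) -> TriggerRecord:
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts)
    return TriggerRecord(
        structure_id=structure,
        camera_id=camera,
        timestamp=ts,
        species=species,
        count=count,
    )


@pytest.fixture
def base_time() -> datetime:
    return datetime(2010, 6, 15, 21, 0, 0)


@pytest.fixture
def small_config_factory():
    """Factory for a single-structure simulation config."""

    def make(
        seed: int = 0,
        pack_size: int = 3,
        rate: float = 0.01,
        miss_prob: float = 0.0,
        n_cameras: int = 2,
        prey_rates: dict | None = None,
        **overrides,
    ) -> SimulationConfig:
        kwargs = dict(
            structures=[StructureSpec("S1", "green_bridge", n_cameras)],
            pack_map={"S1": "PackA"},
            pack_trajectories={"PackA": {"2009/2010": pack_size}},
            crossing_rate_per_wolf=rate,
            miss_prob=miss_prob,
            prey_rates=prey_rates or {},
            dwell_mean_s=60.0,
            seed=seed,
        )
        kwargs.update(overrides)
        return SimulationConfig(**kwargs)

    return make
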