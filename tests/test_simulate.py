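import hashlib
from datetime import datetime

import numpy as np
import pytest

from crossingmon.events import collapse_events, count_events, minimal_group_size
from crossingmon.records import read_trigger_records
from crossingmon.simulate import (
    ConfigError,
    SimulationConfig,
    StructureSpec,
    TruthTable,
    simulate_trigger_records,
    study_default_config,
    write_fixture,
)


class TestConfigValidation:
    def test_pack_map_must_reference_known_structures(self, small_config_factory):
        with pytest.raises(ConfigError, match="unknown structures"):
            small_config_factory(pack_map={"S1": "PackA", "GHOST": "PackB"})

    def test_every_structure_needs_a_pack(self, small_config_factory):
        with pytest.raises(ConfigError, match="not assigned"):
            small_config_factory(pack_map={})

    def test_empty_trajectories_rejected(self, small_config_factory):
        with pytest.raises(ConfigError, match="empty"):
            small_config_factory(pack_trajectories={})

    def test_trajectories_must_cover_identical_years(self, small_config_factory):
        with pytest.raises(ConfigError, match="identical"):
            small_config_factory(
                structures=[("S1", "green_bridge", 2), ("S2", "viaduct", 1)],
                pack_map={"S1": "PackA", "S2": "PackB"},
                pack_trajectories={
                    "PackA": {"2009/2010": 3},
                    "PackB": {"2010/2011": 3},
                },
            )

    @pytest.mark.parametrize(
        "field, value",
        [
            ("miss_prob", 1.0),
            ("miss_prob", -0.1),
            ("crossing_rate_per_wolf", -0.01),
            ("mean_group_fraction", 0.0),
            ("mean_group_fraction", 1.5),
            ("dwell_mean_s", 0.0),
        ],
    )
    def test_rate_and_probability_bounds(self, small_config_factory, field, value):
        with pytest.raises(ConfigError):
            small_config_factory(**{field: value})


class TestNullProcesses:
    def test_zero_rates_give_zero_records_and_zero_truth(self, small_config_factory):
        config = small_config_factory(rate=0.0, prey_rates={"roe_deer": 0.0})
        records, truth = simulate_trigger_records(config)
        assert records == []
        assert (truth.frame["n_crossings"] == 0).all()
        assert (truth.frame["max_group_size"] == 0).all()

    def test_zero_pack_size_gives_no_wolf_records(self, small_config_factory):
        config = small_config_factory(
            pack_size=0, rate=0.5, prey_rates={"roe_deer": 0.3}, seed=5
        )
        records, truth = simulate_trigger_records(config)
        assert all(r.species != "wolf" for r in records)
        assert any(r.species == "roe_deer" for r in records)
        assert truth.lookup("PackA", "2009/2010")["n_crossings"] == 0


def test_poisson_crossing_mean(small_config_factory):
    """With rate*days = 100 expected crossings, the mean over 50 seeded
    replicates lies within 4*sqrt(100) of 100."""
    total = 0
    for i in range(50):
        config = small_config_factory(
            seed=1000 + i, pack_size=1, rate=100.0 / 365.0, miss_prob=0.0
        )
        _, truth = simulate_trigger_records(config)
        total += int(truth.frame["n_crossings"].sum())
    assert abs(total / 50 - 100.0) < 40.0


class TestDeterminism:
    def test_same_seed_reproduces_record_stream(self, small_config_factory):
        records_a, truth_a = simulate_trigger_records(
            small_config_factory(seed=11, rate=0.1, prey_rates={"roe_deer": 0.2})
        )
        records_b, truth_b = simulate_trigger_records(
            small_config_factory(seed=11, rate=0.1, prey_rates={"roe_deer": 0.2})
        )
        assert records_a == records_b
        assert truth_a.frame.equals(truth_b.frame)

    def test_same_seed_gives_identical_file_digests(
        self, small_config_factory, tmp_path
    ):
        digests = []
        for sub in ("a", "b"):
            config = small_config_factory(seed=3, rate=0.1)
            records, truth = simulate_trigger_records(config)
            paths = write_fixture(records, truth, tmp_path / sub, config=config)
            digests.append(
                [hashlib.sha256(p.read_bytes()).hexdigest() for p in paths.values()]
            )
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self, small_config_factory):
        a, _ = simulate_trigger_records(small_config_factory(seed=1, rate=0.2))
        b, _ = simulate_trigger_records(small_config_factory(seed=2, rate=0.2))
        assert a != b


class TestRecordStructure:
    def test_per_camera_spacing_respects_trigger_delay(self, small_config_factory):
        config = small_config_factory(seed=9, pack_size=5, rate=0.3, dwell_mean_s=200.0)
        records, _ = simulate_trigger_records(config)
        by_camera: dict[str, list[datetime]] = {}
        for r in records:
            by_camera.setdefault(r.camera_id, []).append(r.timestamp)
        for times in by_camera.values():
            ordered = sorted(times)
            gaps = [
                (b - a).total_seconds() for a, b in zip(ordered, ordered[1:])
            ]
            assert all(g >= config.trigger_delay_s for g in gaps)

    def test_group_size_never_exceeds_pack_size(self, small_config_factory):
        for seed in range(5):
            config = small_config_factory(seed=seed, pack_size=4, rate=0.3)
            records, truth = simulate_trigger_records(config)
            wolf_counts = [r.count for r in records if r.species == "wolf"]
            assert all(1 <= c <= 4 for c in wolf_counts)
            assert truth.lookup("PackA", "2009/2010")["max_group_size"] <= 4

    def test_timestamps_fall_inside_monitoring_years(self, small_config_factory):
        config = small_config_factory(seed=2, rate=0.2)
        records, _ = simulate_trigger_records(config)
        calendar = config.calendar()
        for r in records:
            assert calendar.label_of(r.timestamp) == "2009/2010"

    def test_outage_window_suppresses_records(self, small_config_factory):
        outage = ("2009-06-01T00:00:00", "2009-08-31T23:59:59")
        config = small_config_factory(
            seed=4, rate=0.3, outages={"S1": [outage]}
        )
        records, truth = simulate_trigger_records(config)
        a = datetime.fromisoformat(outage[0])
        b = datetime.fromisoformat(outage[1])
        assert all(not (a <= r.timestamp <= b) for r in records)
        # crossings during the outage still count as truth
        config_no = small_config_factory(seed=4, rate=0.3)
        _, truth_no = simulate_trigger_records(config_no)
        assert truth.frame.equals(truth_no.frame)


class TestTruthRecovery:
    def test_events_equal_truth_crossings_when_nothing_is_missed(
        self, small_config_factory
    ):
        # low rate keeps crossings separated beyond the dedup window
        config = small_config_factory(
            seed=21, pack_size=2, rate=0.005, miss_prob=0.0, dwell_mean_s=30.0
        )
        records, truth = simulate_trigger_records(config)
        events = collapse_events(records, calendar=config.calendar())
        assert count_events(events, {"wolf"}) == int(
            truth.frame["n_crossings"].sum()
        )

    def test_missed_crossings_only_lose_events(self, small_config_factory):
        for seed in range(8):
            config = small_config_factory(
                seed=100 + seed, pack_size=3, rate=0.05, miss_prob=0.3,
                dwell_mean_s=30.0,
            )
            records, truth = simulate_trigger_records(config)
            events = collapse_events(records, calendar=config.calendar())
            assert count_events(events, {"wolf"}) <= int(
                truth.frame["n_crossings"].sum()
            )

    def test_minimal_group_size_bounded_by_true_pack_size(
        self, small_config_factory
    ):
        for seed in range(10):
            config = small_config_factory(seed=200 + seed, pack_size=6, rate=0.1)
            records, truth = simulate_trigger_records(config)
            events = collapse_events(records, calendar=config.calendar())
            observed = minimal_group_size(events, "wolf", "2009/2010", ["S1"])
            assert observed <= truth.lookup("PackA", "2009/2010")["pack_size"]


class TestFixtureIO:
    def test_empty_fixture_requires_explicit_permission(
        self, small_config_factory, tmp_path
    ):
        config = small_config_factory(rate=0.0)
        records, truth = simulate_trigger_records(config)
        with pytest.raises(ValueError, match="allow_empty"):
            write_fixture(records, truth, tmp_path)
        paths = write_fixture(records, truth, tmp_path, allow_empty=True)
        assert read_trigger_records(paths["triggers"]) == []

    def test_fixture_round_trips_through_readers(
        self, small_config_factory, tmp_path
    ):
        config = small_config_factory(seed=1, rate=0.1, prey_rates={"roe_deer": 0.2})
        records, truth = simulate_trigger_records(config)
        paths = write_fixture(records, truth, tmp_path, config=config)
        assert read_trigger_records(paths["triggers"]) == records
        assert TruthTable.read_csv(paths["truth"]).frame.equals(truth.frame)
        assert paths["config"].exists()


def test_study_default_config_mirrors_study_design():
    config = study_default_config(0)
    greens = [s for s in config.structures if s.structure_class == "green_bridge"]
    viaducts = [s for s in config.structures if s.structure_class == "viaduct"]
    assert len(greens) == 6 and len(viaducts) == 4
    assert all(s.n_cameras == 4 for s in greens)
    assert sum(s.n_cameras for s in config.structures) == 34
    assert len(set(config.pack_map.values())) == 5
    assert len(config.year_labels) == 5
    # viaducts monitored two years only
    for s in viaducts:
        assert len(config.years_of(s.structure_id)) == 2
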