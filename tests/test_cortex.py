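"""Feature extraction: layer rules, planning/dedup, caching, built-ins."""

import math
import random

import networkx as nx
import pandas as pd
import pytest

from phenokit import (
    CountingSource,
    Deployment,
    FeatureRegistry,
    FeatureSpec,
    build_graph,
    default_registry,
    deployment_source,
    execute,
    haversine_km,
    ingest_events,
    plan,
    run_features,
)
from phenokit.cortex import (
    ACTIVITY_STREAM,
    Ctx,
    CycleError,
    FeatureError,
    table_to_csv,
    table_to_vega,
)
from phenokit.query import MS_PER_DAY, MS_PER_HOUR
from tests.conftest import START, make_sensor_doc, random_stream

WINDOW = (START, START + 3 * MS_PER_DAY)


def naive_execute(registry, names, participants, window, source,
                  resolution=MS_PER_DAY):
    """Independent no-cache oracle: recompute every feature from scratch,
    fetching raw data once per (feature, raw dependency)."""

    def compute(name, pid):
        spec = registry.get(name)
        inputs = {}
        for dep in spec.dependencies:
            dspec = registry.get(dep)
            if dspec.layer == "raw":
                inputs[dep] = source(pid, dep, window)
            else:
                inputs[dep] = compute(dep, pid)
        ctx = Ctx(participant_id=pid, window=window, resolution=resolution,
                  params=spec.params)
        return spec.compute(inputs, ctx)

    return {name: pd.concat([compute(name, pid) for pid in participants],
                            ignore_index=True)
            for name in names}


def ingest_one(deployment, pid, sensor, ts, data, platform="other"):
    doc = {"id": f"{sensor}-{ts}", "sensor": sensor, "participant_id": pid,
           "timestamp": ts, "data": data, "source_platform": platform}
    report = ingest_events(deployment, pid, [doc])
    assert report.accepted == 1, report.errors


class TestRegistry:
    def test_secondary_composed_of_primaries_registers(self):
        reg = default_registry()
        reg.register(FeatureSpec(
            name="engagement_index", layer="secondary",
            dependencies=["screen_on_count_per_day",
                          "activity_duration_per_day"],
            compute=lambda inputs, ctx: inputs["screen_on_count_per_day"]))
        assert "engagement_index" in reg

    def test_secondary_touching_raw_is_layer_violation(self):
        reg = default_registry()
        with pytest.raises(FeatureError, match="layer violation"):
            reg.register(FeatureSpec(
                name="bad", layer="secondary", dependencies=["lamp.gps"],
                compute=lambda i, c: None))

    def test_unresolvable_dependency_rejected(self):
        reg = default_registry()
        with pytest.raises(FeatureError, match="unresolvable"):
            reg.register(FeatureSpec(
                name="bad", layer="primary", dependencies=["lamp.ghost"],
                compute=lambda i, c: None))

    def test_duplicate_name_rejected(self):
        reg = default_registry()
        with pytest.raises(FeatureError, match="duplicate"):
            reg.register(FeatureSpec(name="gps_distance_per_day",
                                     layer="primary",
                                     dependencies=["lamp.gps"],
                                     compute=lambda i, c: None))


class TestPlanner:
    def test_shared_raw_dependency_fetched_once(self):
        reg = default_registry()
        for name in ("mobility_a", "mobility_b"):
            reg.register(FeatureSpec(
                name=name, layer="secondary",
                dependencies=["gps_distance_per_day"],
                compute=lambda i, c: i["gps_distance_per_day"]))
        p = plan(build_graph(reg, ["mobility_a", "mobility_b"]))
        assert sorted(p.fetch_set) == ["lamp.gps"]

    def test_single_primary_is_two_node_chain(self):
        reg = default_registry()
        p = plan(build_graph(reg, ["call_duration_per_day"]))
        assert [n for n, _ in p.nodes] == ["lamp.telephony",
                                           "call_duration_per_day"]
        assert p.fetch_set == {"lamp.telephony"}

    def test_plan_is_topological_and_deterministic(self):
        reg = default_registry()
        names = ["activity_duration_per_day", "gps_distance_per_day",
                 "screen_on_count_per_day"]
        p1 = plan(build_graph(reg, names))
        p2 = plan(build_graph(reg, list(reversed(names))))
        assert p1.nodes == p2.nodes  # lexicographic tie-break
        position = {n: i for i, (n, _) in enumerate(p1.nodes)}
        for name, _ in p1.nodes:
            for dep in reg.get(name).dependencies:
                assert position[dep] < position[name]

    def test_cycle_detected_and_named(self):
        graph = nx.DiGraph()
        graph.add_edge("a", "b")
        graph.add_edge("b", "a")
        nx.set_node_attributes(graph, "secondary", "layer")
        with pytest.raises(CycleError, match="a") as exc:
            plan(graph)
        assert set(exc.value.members) >= {"a", "b"}


class TestExecutor:
    def _populated(self, n=3):
        d = Deployment(seed=2)
        r = d.create_resource("Researcher", None, {})
        s = d.create_resource("Study", r.id, {})
        pids = []
        for k in range(n):
            p = d.create_resource("Participant", s.id, {})
            random_stream(d, p.id, seed=200 + k, n_events=40)
            pids.append(p.id)
        return d, pids

    def test_shared_fetch_counter_is_one_per_participant(self):
        d, pids = self._populated()
        reg = default_registry()
        for name in ("m1", "m2", "m3"):
            reg.register(FeatureSpec(
                name=name, layer="secondary",
                dependencies=["gps_distance_per_day"],
                compute=lambda i, c: i["gps_distance_per_day"]))
        source = CountingSource(deployment_source(d))
        p = plan(build_graph(reg, ["m1", "m2", "m3"]))
        execute(p, pids, WINDOW, MS_PER_DAY, source, reg)
        gps_calls = [c for c in source.calls if c[1] == "lamp.gps"]
        assert len(gps_calls) == len(pids)  # one per participant, not three

    def test_results_equal_naive_oracle(self):
        d, pids = self._populated()
        reg = default_registry()
        names = ["call_duration_per_day", "gps_distance_per_day",
                 "screen_on_count_per_day", "unique_nearby_devices_per_day"]
        cached = execute(plan(build_graph(reg, names)), pids, WINDOW,
                         MS_PER_DAY, deployment_source(d), reg)
        naive = naive_execute(reg, names, pids, WINDOW, deployment_source(d))
        for name in names:
            pd.testing.assert_frame_equal(cached[name], naive[name])

    def test_empty_window_tables_well_formed(self):
        d, pids = self._populated(n=1)
        res = run_features(d, ["call_duration_per_day"], participants=pids,
                           window=(START, START + MS_PER_DAY))
        table = res["call_duration_per_day"]
        assert list(table.columns)[:3] == ["participant_id", "bin_start",
                                           "value"]
        assert (table["value"] == 0).all() or len(table) == 1

    def test_fetch_failure_isolates_participant(self):
        d, pids = self._populated(n=2)
        inner = deployment_source(d)

        def flaky(pid, stream, window):
            if pid == pids[0] and stream == "lamp.gps":
                raise OSError("backend unavailable")
            return inner(pid, stream, window)

        reg = default_registry()
        names = ["gps_distance_per_day", "call_duration_per_day"]
        res = execute(plan(build_graph(reg, names)), pids, WINDOW,
                      MS_PER_DAY, flaky, reg)
        assert len(res.failures) == 1
        failure = res.failures[0]
        assert (failure.participant_id, failure.stream) == (pids[0],
                                                            "lamp.gps")
        assert "gps_distance_per_day" in failure.unavailable_features
        gps = res["gps_distance_per_day"]
        assert set(gps["participant_id"]) == {pids[1]}  # other completes
        calls = res["call_duration_per_day"]
        assert set(calls["participant_id"]) == set(pids)


class TestBuiltinFeatures:
    def _fresh(self):
        d = Deployment(seed=3)
        r = d.create_resource("Researcher", None, {})
        s = d.create_resource("Study", r.id, {})
        p = d.create_resource("Participant", s.id, {})
        return d, p.id

    def _one(self, d, pid, feature, window=WINDOW):
        return run_features(d, [feature], participants=[pid],
                            window=window)[feature]

    def test_call_duration_sums_per_day(self):
        d, pid = self._fresh()
        ingest_one(d, pid, "lamp.telephony", START + MS_PER_HOUR,
                   {"call_type": "incoming", "call_duration": 60.0})
        ingest_one(d, pid, "lamp.telephony", START + 2 * MS_PER_HOUR,
                   {"call_type": "outgoing", "call_duration": 90.0})
        table = self._one(d, pid, "call_duration_per_day")
        assert table["value"].tolist() == [150.0, 0, 0]

    def test_call_straddling_midnight_attributed_to_start_day(self):
        d, pid = self._fresh()
        ingest_one(d, pid, "lamp.telephony", START + MS_PER_DAY - 1000,
                   {"call_type": "incoming", "call_duration": 120.0})
        table = self._one(d, pid, "call_duration_per_day")
        assert table["value"].tolist() == [120.0, 0, 0]

    def test_steps_rolling_24h_steady_state(self):
        """Constant 100 steps/hour ⇒ every bin at or past start+24h reads
        2400 (closed form)."""
        d, pid = self._fresh()
        docs = [{"id": f"st{h}", "sensor": "lamp.steps",
                 "participant_id": pid,
                 "timestamp": START + h * MS_PER_HOUR,
                 "data": {"steps": 100}, "source_platform": "other"}
                for h in range(72)]
        assert ingest_events(d, pid, docs).accepted == 72
        table = self._one(d, pid, "steps_rolling_24h")
        steady = table[table["bin_start"] >= START + MS_PER_DAY]
        assert (steady["value"] == 2400).all()
        # ramp-up: at start+1h only the first hour's steps are inside
        assert table[table["bin_start"] == START + MS_PER_HOUR][
            "value"].item() == 200  # events at t-24h< ts <= t: hours 0 and 1

    def test_steps_burst_covers_exactly_24_bins(self):
        d, pid = self._fresh()
        ingest_one(d, pid, "lamp.steps", START + 90_000, {"steps": 500})
        table = self._one(d, pid, "steps_rolling_24h")
        assert (table["value"] == 500).sum() == 24
        assert table["value"].sum() == 500 * 24

    def test_screen_on_transition_count_with_debounce(self):
        d, pid = self._fresh()
        states = ["on", "off", "on", "on", "off", "locked", "on"]
        docs = [{"id": f"sc{i}", "sensor": "lamp.screen_state",
                 "participant_id": pid, "timestamp": START + i * 1000,
                 "data": {"state": st}, "source_platform": "other"}
                for i, st in enumerate(states)]
        ingest_events(d, pid, docs)
        table = self._one(d, pid, "screen_on_count_per_day")
        # hand trace: on (1), off, on (2), on (debounced), off, locked, on (3)
        assert table["value"].tolist() == [3, 0, 0]

    def test_all_off_stream_counts_zero(self):
        d, pid = self._fresh()
        for i in range(4):
            ingest_one(d, pid, "lamp.screen_state", START + i * 1000,
                       {"state": "off"})
        table = self._one(d, pid, "screen_on_count_per_day")
        assert (table["value"] == 0).all()

    def test_unique_nearby_devices_union_semantics(self):
        d, pid = self._fresh()
        sightings = [("A", "wifi"), ("B", "bluetooth"), ("A", "wifi"),
                     ("C", "wifi"), ("A", "bluetooth")]
        for i, (addr, radio) in enumerate(sightings):
            ingest_one(d, pid, "lamp.nearby_device", START + i * 1000,
                       {"type": radio, "address": addr})
        table = self._one(d, pid, "unique_nearby_devices_per_day")
        assert table["value"].tolist() == [3, 0, 0]  # {A,B,C}; A counted once

    def test_gps_distance_haversine_closed_form(self):
        d, pid = self._fresh()
        ingest_one(d, pid, "lamp.gps", START,
                   {"latitude": 0.0, "longitude": 0.0, "accuracy": 5.0})
        ingest_one(d, pid, "lamp.gps", START + 60_000,
                   {"latitude": 0.01, "longitude": 0.0, "accuracy": 5.0})
        table = self._one(d, pid, "gps_distance_per_day")
        expected = 2 * 6371.0088 * math.asin(math.sin(math.radians(0.01) / 2))
        assert table["value"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert table["value"].iloc[0] == pytest.approx(1.11195, abs=5e-4)

    def test_single_or_stationary_fixes_travel_nothing(self):
        d, pid = self._fresh()
        ingest_one(d, pid, "lamp.gps", START,
                   {"latitude": 42.0, "longitude": -71.0, "accuracy": 5.0})
        table = self._one(d, pid, "gps_distance_per_day")
        assert (table["value"] == 0).all()
        for i in range(3):  # repeated identical fixes
            ingest_one(d, pid, "lamp.gps", START + (i + 1) * 60_000,
                       {"latitude": 42.0, "longitude": -71.0, "accuracy": 5.0})
        table = self._one(d, pid, "gps_distance_per_day")
        assert (table["value"] == 0).all()

    def test_poor_accuracy_fixes_dropped_before_pairing(self):
        d, pid = self._fresh()
        fixes = [(0.0, 5.0), (5.0, 500.0), (0.01, 5.0)]  # middle fix is junk
        for i, (lat, acc) in enumerate(fixes):
            ingest_one(d, pid, "lamp.gps", START + i * 60_000,
                       {"latitude": lat, "longitude": 0.0, "accuracy": acc})
        table = self._one(d, pid, "gps_distance_per_day")
        assert table["value"].iloc[0] == pytest.approx(
            haversine_km(0.0, 0.0, 0.01, 0.0), rel=1e-9)

    def test_activity_duration_secondary_filters_by_spec(self):
        d = Deployment(seed=4)
        r = d.create_resource("Researcher", None, {})
        s = d.create_resource("Study", r.id, {})
        p = d.create_resource("Participant", s.id, {})
        breathe = d.create_resource("Activity", s.id,
                                    {"spec_name": "lamp.breathe"})
        survey = d.create_resource("Activity", s.id, {
            "spec_name": "lamp.survey", "settings": {"questions": []}})
        docs = []
        for i, (aid, spec, dur) in enumerate([
                (breathe.id, "lamp.breathe", 300_000),
                (breathe.id, "lamp.breathe", 600_000),
                (survey.id, "lamp.survey", 45_000)]):
            docs.append({"id": f"a{i}", "participant_id": p.id,
                         "activity_id": aid, "spec_name": spec,
                         "timestamp": START + i * MS_PER_HOUR,
                         "duration": dur, "static_data": {"done": True},
                         "temporal_slices": []})
        assert ingest_events(d, p.id, docs).accepted == 3
        table = run_features(d, ["activity_duration_per_day"],
                             participants=[p.id], window=WINDOW)[
            "activity_duration_per_day"]
        assert table["value"].tolist() == [900.0, 0, 0]  # surveys excluded

    def test_per_day_features_permutation_invariant(self):
        rng = random.Random(77)
        base_docs = [make_sensor_doc(rng, "PID", "lamp.telephony",
                                     START + rng.randrange(3 * MS_PER_DAY))
                     for _ in range(25)]
        tables = []
        for order_seed in (1, 2):
            d = Deployment(seed=5)
            r = d.create_resource("Researcher", None, {})
            s = d.create_resource("Study", r.id, {})
            p = d.create_resource("Participant", s.id, {"id": "PID"})
            docs = list(base_docs)
            random.Random(order_seed).shuffle(docs)
            ingest_events(d, p.id, docs)
            tables.append(run_features(d, ["call_duration_per_day"],
                                       participants=["PID"],
                                       window=WINDOW)["call_duration_per_day"])
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_out_of_range_coordinates_rejected(self):
        from phenokit.cortex import _gps_distance_per_day
        from phenokit.model import SensorEvent

        bad = SensorEvent(id="g", participant_id="p", sensor="lamp.gps",
                          timestamp=START,
                          data={"latitude": 95.0, "longitude": 0.0},
                          source_platform="other", harmonized=True)
        ctx = Ctx(participant_id="p", window=WINDOW, resolution=MS_PER_DAY,
                  params={})
        with pytest.raises(FeatureError, match="out of range"):
            _gps_distance_per_day({"lamp.gps": [bad]}, ctx)


def test_table_exports():
    table = pd.DataFrame({"participant_id": ["p"], "bin_start": [START],
                          "value": [3]})
    csv = table_to_csv(table)
    assert csv.splitlines()[0] == "participant_id,bin_start,value"
    assert "2024-01-01" in csv
    vega = table_to_vega(table)
    assert vega["values"][0]["value"] == 3
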