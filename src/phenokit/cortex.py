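"""Behavioral feature extraction over harmonized event streams.

Features are organized in three layers.  *Raw* nodes are the sensor or
activity event streams themselves.  *Primary* features are computed
directly from raw events (call duration per day, screen-on count per
day, GPS distance per day, ...).  *Secondary* features are composed of
primary/secondary features only — they never touch raw data, which
keeps them source-agnostic and cheap to recompute.

Requesting a set of features builds a dependency graph, topologically
orders it (lexicographic tie-break, so plans are reproducible), and
deduplicates the raw fetch set: however many features transitively need
the same raw stream, each (participant, stream, window) is downloaded
exactly once per execution and served from an in-memory cache to every
dependent.

Feature outputs are tidy pandas frames with columns
``participant_id, bin_start, value`` (plus feature-specific extras),
one row per (participant, bin), bins tiling the requested half-open
window.  Windows should be aligned to local midnight in the reporting
time zone for "per day" features to mean calendar days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Optional, Protocol, Sequence

import networkx as nx
import pandas as pd

from .model import ActivityEvent, Event, SensorEvent
from .query import MS_PER_DAY, MS_PER_HOUR, QuerySelector, iso8601, query_events
from .store import Deployment

#: pseudo-stream name under which activity events are fetched as raw input
ACTIVITY_STREAM = "activity_events"

EARTH_RADIUS_KM = 6371.0088

Layer = str  # "raw" | "primary" | "secondary"


class FeatureError(ValueError):
    pass


class CycleError(FeatureError):
    def __init__(self, members: list[str]):
        self.members = members
        super().__init__(f"dependency cycle: {' -> '.join(members)}")


@dataclass(frozen=True)
class Ctx:
    """Per-(feature, participant) computation context."""

    participant_id: str
    window: tuple[int, int]
    resolution: int
    params: Mapping[str, Any]


ComputeFn = Callable[[Mapping[str, Any], Ctx], pd.DataFrame]


@dataclass
class FeatureSpec:
    name: str
    layer: Layer
    dependencies: list[str] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)
    compute: Optional[ComputeFn] = None


class DataSource(Protocol):
    def __call__(self, participant_id: str, stream: str,
                 window: tuple[int, int]) -> list[Event]: ...


class FeatureRegistry:
    """Layer-checked registry of raw/primary/secondary feature specs."""

    def __init__(self) -> None:
        self._specs: dict[str, FeatureSpec] = {}

    def register(self, spec: FeatureSpec) -> str:
        if spec.name in self._specs:
            raise FeatureError(f"duplicate feature name {spec.name!r}")
        if spec.layer not in ("raw", "primary", "secondary"):
            raise FeatureError(f"unknown layer {spec.layer!r}")
        if spec.layer == "raw" and spec.dependencies:
            raise FeatureError("raw features must not declare dependencies")
        for dep in spec.dependencies:
            if dep not in self._specs:
                raise FeatureError(f"unresolvable dependency {dep!r} "
                                   f"of feature {spec.name!r}")
            dep_layer = self._specs[dep].layer
            if spec.layer == "primary" and dep_layer != "raw":
                raise FeatureError(
                    f"primary feature {spec.name!r} may depend only on raw "
                    f"streams, not {dep_layer} {dep!r}")
            if spec.layer == "secondary" and dep_layer == "raw":
                raise FeatureError(
                    f"layer violation: secondary feature {spec.name!r} may "
                    f"not depend on raw stream {dep!r}")
        if spec.layer != "raw" and spec.compute is None:
            raise FeatureError(f"feature {spec.name!r} needs a compute function")
        self._specs[spec.name] = spec
        return spec.name

    def get(self, name: str) -> FeatureSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise FeatureError(f"unknown feature {name!r}") from None

    def names(self, layer: Optional[Layer] = None) -> list[str]:
        return sorted(n for n, s in self._specs.items()
                      if layer is None or s.layer == layer)

    def __contains__(self, name: str) -> bool:
        return name in self._specs


# ---------------------------------------------------------------------------
# Planning

@dataclass
class ExecutionPlan:
    nodes: list[tuple[str, Layer]]
    fetch_set: frozenset[str]


def build_graph(registry: FeatureRegistry,
                names: Iterable[str]) -> "nx.DiGraph":
    """Dependency graph (edge dep -> feature) closed over transitive deps."""
    graph = nx.DiGraph()
    stack = list(names)
    while stack:
        name = stack.pop()
        spec = registry.get(name)
        graph.add_node(name, layer=spec.layer)
        for dep in spec.dependencies:
            if dep not in graph:
                stack.append(dep)
            graph.add_edge(dep, name)
    return graph


def plan(graph: "nx.DiGraph") -> ExecutionPlan:
    """Topological, deterministic execution order + deduplicated fetch set."""
    try:
        order = list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(graph)
        members = [u for u, _ in cycle] + [cycle[-1][1]]
        raise CycleError(members) from None
    nodes = [(n, graph.nodes[n]["layer"]) for n in order]
    fetch = frozenset(n for n, layer in nodes if layer == "raw")
    return ExecutionPlan(nodes=nodes, fetch_set=fetch)


# ---------------------------------------------------------------------------
# Execution with raw-fetch caching

@dataclass
class RawCache:
    """Per-execution cache: each (participant, stream, window) fetched once."""

    entries: dict[tuple[str, str, tuple[int, int]], list[Event]] = \
        field(default_factory=dict)
    status: dict[tuple[str, str, tuple[int, int]], str] = \
        field(default_factory=dict)

    def fetch(self, source: DataSource, participant_id: str, stream: str,
              window: tuple[int, int]) -> list[Event]:
        key = (participant_id, stream, window)
        if self.status.get(key) == "ready":
            return self.entries[key]
        self.status[key] = "pending"
        events = source(participant_id, stream, window)
        self.entries[key] = events
        self.status[key] = "ready"
        return events


@dataclass
class FetchFailure:
    participant_id: str
    stream: str
    error: str
    unavailable_features: list[str]


class ExecutionResult(Mapping[str, pd.DataFrame]):
    """Feature name -> tidy table, plus any per-participant fetch failures."""

    def __init__(self, tables: dict[str, pd.DataFrame],
                 failures: list[FetchFailure]):
        self.tables = tables
        self.failures = failures

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __iter__(self):
        return iter(self.tables)

    def __len__(self):
        return len(self.tables)


def execute(plan_: ExecutionPlan, participants: Sequence[str],
            window: tuple[int, int], resolution: int,
            source: DataSource, registry: FeatureRegistry) -> ExecutionResult:
    """Run a plan over participants; raw streams are fetched exactly once.

    A failing fetch marks the failing (participant, stream) and every
    transitively dependent feature unavailable for that participant;
    other participants and independent features still complete.
    """
    cache = RawCache()
    failures: list[FetchFailure] = []
    frames: dict[str, list[pd.DataFrame]] = {
        name: [] for name, layer in plan_.nodes if layer != "raw"}

    graph = nx.DiGraph()
    for name, _ in plan_.nodes:
        graph.add_node(name)
        for dep in registry.get(name).dependencies:
            graph.add_edge(dep, name)

    for pid in participants:
        outputs: dict[str, Any] = {}
        dead: set[str] = set()
        for name, layer in plan_.nodes:
            if any(dep in dead for dep in registry.get(name).dependencies):
                dead.add(name)
                continue
            spec = registry.get(name)
            if layer == "raw":
                try:
                    outputs[name] = cache.fetch(source, pid, name, window)
                except Exception as exc:  # noqa: BLE001 - surfaced in result
                    downstream = sorted(nx.descendants(graph, name))
                    failures.append(FetchFailure(
                        participant_id=pid, stream=name, error=str(exc),
                        unavailable_features=downstream))
                    dead.add(name)
                continue
            ctx = Ctx(participant_id=pid, window=window,
                      resolution=resolution, params=spec.params)
            inputs = {dep: outputs[dep] for dep in spec.dependencies}
            outputs[name] = spec.compute(inputs, ctx)
            frames[name].append(outputs[name])

    tables = {}
    for name, chunks in frames.items():
        tables[name] = (pd.concat(chunks, ignore_index=True) if chunks
                        else _empty_table())
    return ExecutionResult(tables, failures)


def _empty_table(extra: Sequence[str] = ()) -> pd.DataFrame:
    return pd.DataFrame(columns=["participant_id", "bin_start", "value",
                                 *extra])


def run_features(deployment: Deployment, names: Sequence[str],
                 participants: Optional[Sequence[str]] = None,
                 window: Optional[tuple[int, int]] = None,
                 resolution: int = MS_PER_DAY,
                 registry: Optional[FeatureRegistry] = None,
                 ) -> ExecutionResult:
    """Convenience front door: plan + execute against a deployment."""
    registry = registry or default_registry()
    pids = list(participants) if participants is not None else \
        [p.id for p in deployment.participants()]
    if window is None:
        stamps = [e.timestamp for pid in pids for e in deployment.stream(pid)]
        if not stamps:
            window = (0, MS_PER_DAY)
        else:
            lo = (min(stamps) // MS_PER_DAY) * MS_PER_DAY
            hi = (max(stamps) // MS_PER_DAY + 1) * MS_PER_DAY
            window = (lo, hi)
    source = deployment_source(deployment)
    return execute(plan(build_graph(registry, names)), pids, window,
                   resolution, source, registry)


def deployment_source(deployment: Deployment) -> DataSource:
    """DataSource answering raw queries from a deployment's streams."""

    def fetch(participant_id: str, stream: str,
              window: tuple[int, int]) -> list[Event]:
        if stream == ACTIVITY_STREAM:
            sel = QuerySelector(participant_ids=[participant_id],
                                event_kind="activity",
                                start=window[0], end=window[1])
        else:
            sel = QuerySelector(participant_ids=[participant_id],
                                event_kind="sensor", type_names=[stream],
                                start=window[0], end=window[1])
        return query_events(deployment, sel)

    return fetch


class CountingSource:
    """Instrumented wrapper recording every raw fetch (for dedup checks)."""

    def __init__(self, inner: DataSource):
        self.inner = inner
        self.calls: list[tuple[str, str, tuple[int, int]]] = []

    def __call__(self, participant_id: str, stream: str,
                 window: tuple[int, int]) -> list[Event]:
        self.calls.append((participant_id, stream, window))
        return self.inner(participant_id, stream, window)


# ---------------------------------------------------------------------------
# Binning helpers shared by the built-in features

def _bins(window: tuple[int, int], bin_ms: int) -> list[int]:
    start, end = window
    return [start + i * bin_ms
            for i in range(math.ceil((end - start) / bin_ms))]


def _per_bin_table(ctx: Ctx, bin_ms: int,
                   totals: Mapping[int, Any],
                   default: Any = 0) -> pd.DataFrame:
    starts = _bins(ctx.window, bin_ms)
    return pd.DataFrame({
        "participant_id": ctx.participant_id,
        "bin_start": starts,
        "value": [totals.get(s, default) for s in starts],
    })


def _bin_of(ts: int, window: tuple[int, int], bin_ms: int) -> int:
    return window[0] + ((ts - window[0]) // bin_ms) * bin_ms


# ---------------------------------------------------------------------------
# Built-in features

def _call_duration_per_day(inputs: Mapping[str, Any], ctx: Ctx) -> pd.DataFrame:
    """Total seconds spent in calls per day; calls straddling midnight are
    attributed to the day the call started."""
    bin_ms = int(ctx.params.get("bin_ms", MS_PER_DAY))
    totals: dict[int, float] = {}
    for ev in inputs["lamp.telephony"]:
        b = _bin_of(ev.timestamp, ctx.window, bin_ms)
        totals[b] = totals.get(b, 0) + ev.data.get("call_duration", 0)
    return _per_bin_table(ctx, bin_ms, totals)


def _steps_rolling_24h(inputs: Mapping[str, Any], ctx: Ctx) -> pd.DataFrame:
    """Hourly-sampled rolling sum: value at bin start t = steps in (t-24h, t].

    Early bins (before a full day of history inside the window) use only
    the data available within the window.
    """
    events = inputs["lamp.steps"]
    rows = []
    for t in _bins(ctx.window, MS_PER_HOUR):
        total = sum(e.data.get("steps", 0) for e in events
                    if t - MS_PER_DAY < e.timestamp <= t)
        rows.append((ctx.participant_id, t, total))
    return pd.DataFrame(rows, columns=["participant_id", "bin_start", "value"])


def _screen_on_count_per_day(inputs: Mapping[str, Any],
                             ctx: Ctx) -> pd.DataFrame:
    """Transitions into the "on" state per day, de-bouncing consecutive
    duplicate "on" reports."""
    bin_ms = int(ctx.params.get("bin_ms", MS_PER_DAY))
    events = sorted(inputs["lamp.screen_state"],
                    key=lambda e: (e.timestamp, e.id))
    totals: dict[int, int] = {}
    prev_state = None
    for ev in events:
        state = ev.data.get("state")
        if state == "on" and prev_state != "on":
            b = _bin_of(ev.timestamp, ctx.window, bin_ms)
            totals[b] = totals.get(b, 0) + 1
        prev_state = state
    return _per_bin_table(ctx, bin_ms, totals)


def _unique_nearby_devices_per_day(inputs: Mapping[str, Any],
                                   ctx: Ctx) -> pd.DataFrame:
    """Cardinality of distinct device identifiers per day, Wi-Fi and
    Bluetooth pooled (an id seen on both radios counts once)."""
    bin_ms = int(ctx.params.get("bin_ms", MS_PER_DAY))
    seen: dict[int, set[str]] = {}
    for ev in inputs["lamp.nearby_device"]:
        b = _bin_of(ev.timestamp, ctx.window, bin_ms)
        seen.setdefault(b, set()).add(ev.data.get("address"))
    return _per_bin_table(ctx, bin_ms, {b: len(s) for b, s in seen.items()})


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + \
        math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def _gps_distance_per_day(inputs: Mapping[str, Any], ctx: Ctx) -> pd.DataFrame:
    """Sum of haversine distances (km) between consecutive accepted fixes
    per day; fixes with accuracy worse than ``accuracy_m`` (default 100 m)
    are dropped before pairing.  A segment is attributed to the day of its
    earlier fix."""
    bin_ms = int(ctx.params.get("bin_ms", MS_PER_DAY))
    threshold = float(ctx.params.get("accuracy_m", 100.0))
    fixes = []
    for ev in sorted(inputs["lamp.gps"], key=lambda e: (e.timestamp, e.id)):
        lat, lon = ev.data["latitude"], ev.data["longitude"]
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise FeatureError(
                f"latitude/longitude out of range: ({lat}, {lon})")
        if ev.data.get("accuracy", 0.0) > threshold:
            continue
        fixes.append((ev.timestamp, lat, lon))
    totals: dict[int, float] = {}
    for (t1, la1, lo1), (_t2, la2, lo2) in zip(fixes, fixes[1:]):
        b = _bin_of(t1, ctx.window, bin_ms)
        totals[b] = totals.get(b, 0.0) + haversine_km(la1, lo1, la2, lo2)
    return _per_bin_table(ctx, bin_ms, totals, default=0.0)


def _activity_session_durations(inputs: Mapping[str, Any],
                                ctx: Ctx) -> pd.DataFrame:
    """Primary per-event extraction: one row per activity session with its
    duration (ms) and spec name; downstream secondaries aggregate these."""
    rows = [(ctx.participant_id, ev.timestamp, ev.duration, ev.spec_name)
            for ev in inputs[ACTIVITY_STREAM]
            if isinstance(ev, ActivityEvent)]
    return pd.DataFrame(rows, columns=["participant_id", "bin_start",
                                       "value", "spec_name"])


def _activity_duration_per_day(inputs: Mapping[str, Any],
                               ctx: Ctx) -> pd.DataFrame:
    """Secondary: total seconds per day spent in sessions whose activity
    spec matches the ``spec_filter`` param (e.g. "lamp.breathe")."""
    bin_ms = int(ctx.params.get("bin_ms", MS_PER_DAY))
    spec_filter = ctx.params.get("spec_filter")
    sessions = inputs["activity_session_durations"]
    totals: dict[int, float] = {}
    for _, row in sessions.iterrows():
        if spec_filter is not None and row["spec_name"] != spec_filter:
            continue
        b = _bin_of(int(row["bin_start"]), ctx.window, bin_ms)
        totals[b] = totals.get(b, 0.0) + row["value"] / 1000.0
    return _per_bin_table(ctx, bin_ms, totals, default=0.0)


def default_registry(spec_filter: Optional[str] = "lamp.breathe",
                     ) -> FeatureRegistry:
    """Registry preloaded with raw streams and the built-in feature set."""
    reg = FeatureRegistry()
    for raw in ("lamp.accelerometer", "lamp.gps", "lamp.screen_state",
                "lamp.steps", "lamp.telephony", "lamp.nearby_device",
                ACTIVITY_STREAM):
        reg.register(FeatureSpec(name=raw, layer="raw"))
    reg.register(FeatureSpec(
        name="call_duration_per_day", layer="primary",
        dependencies=["lamp.telephony"], compute=_call_duration_per_day))
    reg.register(FeatureSpec(
        name="steps_rolling_24h", layer="primary",
        dependencies=["lamp.steps"], compute=_steps_rolling_24h))
    reg.register(FeatureSpec(
        name="screen_on_count_per_day", layer="primary",
        dependencies=["lamp.screen_state"], compute=_screen_on_count_per_day))
    reg.register(FeatureSpec(
        name="unique_nearby_devices_per_day", layer="primary",
        dependencies=["lamp.nearby_device"],
        compute=_unique_nearby_devices_per_day))
    reg.register(FeatureSpec(
        name="gps_distance_per_day", layer="primary",
        dependencies=["lamp.gps"], params={"accuracy_m": 100.0},
        compute=_gps_distance_per_day))
    reg.register(FeatureSpec(
        name="activity_session_durations", layer="primary",
        dependencies=[ACTIVITY_STREAM], compute=_activity_session_durations))
    reg.register(FeatureSpec(
        name="activity_duration_per_day", layer="secondary",
        dependencies=["activity_session_durations"],
        params={"spec_filter": spec_filter},
        compute=_activity_duration_per_day))
    return reg


# ---------------------------------------------------------------------------
# Exports

def table_to_csv(table: pd.DataFrame) -> str:
    """FeatureTable → CSV with ISO-8601 bin_start timestamps."""
    out = table.copy()
    out["bin_start"] = out["bin_start"].map(lambda t: iso8601(int(t)))
    return out.to_csv(index=False)


def table_to_vega(table: pd.DataFrame) -> dict[str, Any]:
    """FeatureTable → Vega-compatible data records (no chart rendering)."""
    out = table.copy()
    out["bin_start"] = out["bin_start"].map(lambda t: iso8601(int(t)))
    return {"values": out.to_dict(orient="records")}
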