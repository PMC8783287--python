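"""Temporal-resolution queries, subscriptions, triggers, study configs.

The analysis surface over event streams is a small pipeline: *select*
(participants, event kind, activity/sensor type, half-open time
window), *bin* at any temporal resolution with a named aggregator,
optionally *transform* through a registry of named pure
transformations, and *subscribe* so newly ingested events matching a
selector are delivered as they arrive.  Automation rules (triggers)
evaluate named predicates against each accepted event and append audit
records — the testable stand-in for notification/intervention
delivery.

All windows and bins are half-open ``[start, end)``; bin ``i`` covers
``[start + i*r, start + (i+1)*r)`` intersected with the window.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Callable, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import ActivityEvent, Event, ScheduleEntry, SensorEvent
from .specs import ActivitySpec, SensorSpec, TagSpec
from .store import Deployment, StoreError

MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000


def iso8601(ms: int) -> str:
    """Millisecond epoch timestamp → ISO-8601 UTC string."""
    return datetime.fromtimestamp(ms / 1000, tz=timezone.utc).isoformat()


class QuerySelector(BaseModel):
    """Filter over event streams; an empty field means 'no constraint'."""

    model_config = ConfigDict(extra="forbid")

    participant_ids: list[str] = Field(default_factory=list)
    event_kind: Literal["activity", "sensor", "both"] = "both"
    type_names: list[str] = Field(default_factory=list)
    start: Optional[int] = None
    end: Optional[int] = None

    @model_validator(mode="after")
    def _window_ok(self) -> "QuerySelector":
        if self.start is not None and self.end is not None \
                and not self.start < self.end:
            raise ValueError("invalid window: start must be < end")
        return self

    def matches(self, event: Event) -> bool:
        if self.participant_ids and \
                event.participant_id not in self.participant_ids:
            return False
        is_activity = isinstance(event, ActivityEvent)
        if self.event_kind == "activity" and not is_activity:
            return False
        if self.event_kind == "sensor" and is_activity:
            return False
        if self.type_names:
            tname = event.spec_name if is_activity else event.sensor
            if tname not in self.type_names:
                return False
        if self.start is not None and event.timestamp < self.start:
            return False
        if self.end is not None and event.timestamp >= self.end:
            return False
        return True


def query_events(deployment: Deployment,
                 selector: QuerySelector) -> list[Event]:
    """All events matching the selector, in chronological order."""
    pids = selector.participant_ids or \
        [p.id for p in deployment.participants()]
    hits: list[Event] = []
    for pid in pids:
        hits.extend(e for e in deployment.stream(pid) if selector.matches(e))
    hits.sort(key=lambda e: (e.timestamp, e.kind, e.id))
    return hits


# ---------------------------------------------------------------------------
# Binning

@dataclass
class BinnedSeries:
    """Events aggregated onto a regular time grid tiling the window."""

    resolution: int
    aggregator: str
    window: tuple[int, int]
    bins: list[tuple[int, Any]]

    def values(self) -> list[Any]:
        return [v for _, v in self.bins]

    def to_csv(self) -> str:
        lines = ["bin_start,value"]
        for start, v in self.bins:
            lines.append(f"{iso8601(start)},{'' if v is None else v}")
        return "\n".join(lines) + "\n"

    def to_vega(self) -> dict[str, Any]:
        """Chart-ready record table (Vega data model; no rendering)."""
        return {"values": [{"bin_start": iso8601(s), "value": v}
                           for s, v in self.bins]}


def _field_value(event: Event, fieldname: str) -> Any:
    if isinstance(event, SensorEvent):
        if fieldname in event.data:
            return event.data[fieldname]
    else:
        if fieldname in event.static_data:
            return event.static_data[fieldname]
    raise KeyError(f"unknown field {fieldname!r} on {event.kind}")


def bin_events(events: Sequence[Event], window: tuple[int, int],
               resolution: int, aggregator: str = "count") -> BinnedSeries:
    """Aggregate events onto ``ceil((end-start)/resolution)`` bins.

    Aggregators: ``count``, ``sum:<field>``, ``mean:<field>``,
    ``duration_sum``.  Empty bins hold the neutral aggregate (0 for
    count/sum/duration_sum, None for mean).
    """
    start, end = window
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not start < end:
        raise ValueError("invalid window: start must be < end")
    name, _, fieldname = aggregator.partition(":")
    if name not in ("count", "sum", "mean", "duration_sum"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if name in ("sum", "mean") and not fieldname:
        raise ValueError(f"aggregator {name!r} requires a field: '{name}:<field>'")

    n_bins = math.ceil((end - start) / resolution)
    buckets: dict[int, list[Event]] = {}
    for ev in events:
        if start <= ev.timestamp < end:
            buckets.setdefault((ev.timestamp - start) // resolution,
                               []).append(ev)

    bins: list[tuple[int, Any]] = []
    for i in range(n_bins):
        bucket = buckets.get(i, [])
        bin_start = start + i * resolution
        if name == "count":
            value: Any = len(bucket)
        elif name == "duration_sum":
            value = sum(getattr(e, "duration", 0) for e in bucket)
        else:
            vals = [_field_value(e, fieldname) for e in bucket]
            if name == "sum":
                value = sum(vals)
            else:
                value = (sum(vals) / len(vals)) if vals else None
        bins.append((bin_start, value))
    return BinnedSeries(resolution=resolution, aggregator=aggregator,
                        window=(start, end), bins=bins)


# ---------------------------------------------------------------------------
# Named transformations (pure; arbitrary code is deliberately not accepted)

Transform = Callable[[Event], Any]

_TRANSFORMS: dict[str, Transform] = {}


def register_transformation(name: str, fn: Transform) -> None:
    if name in _TRANSFORMS:
        raise ValueError(f"duplicate transformation {name!r}")
    _TRANSFORMS[name] = fn


def get_transformation(name: str) -> Transform:
    try:
        return _TRANSFORMS[name]
    except KeyError:
        raise KeyError(f"unknown transformation {name!r}") from None


def _flatten_slices(event: Event) -> Any:
    if not isinstance(event, ActivityEvent):
        return event
    return [{"participant_id": event.participant_id,
             "activity_id": event.activity_id,
             "timestamp": event.timestamp, **s.model_dump()}
            for s in event.temporal_slices]


_TRANSFORMS.update({
    "identity": lambda e: e,
    "to_dict": lambda e: e.model_dump(mode="json"),
    "flatten_slices": _flatten_slices,
})


# ---------------------------------------------------------------------------
# Subscriptions and triggers

@dataclass
class Subscription:
    id: str
    selector: QuerySelector
    callback: Callable[[Any], None]
    transform: Optional[str] = None


@dataclass
class TriggerRule:
    """Automation rule: when predicate(event) holds, append an audit record."""

    id: str
    selector: QuerySelector
    predicate: str
    params: dict[str, Any] = field(default_factory=dict)


Predicate = Callable[[Event, dict[str, Any], "Router"], bool]

_PREDICATES: dict[str, Predicate] = {}


def register_predicate(name: str, fn: Predicate) -> None:
    if name in _PREDICATES:
        raise ValueError(f"duplicate predicate {name!r}")
    _PREDICATES[name] = fn


def _dig(doc: Any, path: str) -> Any:
    cur = doc
    for part in path.split("."):
        cur = cur[part]
    return cur


def _field_gte(event: Event, params: dict[str, Any], _router) -> bool:
    try:
        return _dig(event.model_dump(), params["field"]) >= params["threshold"]
    except (KeyError, TypeError):
        return False


def _any_slice_value_gte(event: Event, params: dict[str, Any], _router) -> bool:
    if not isinstance(event, ActivityEvent):
        return False
    return any(isinstance(s.value, (int, float)) and not isinstance(s.value, bool)
               and s.value >= params["threshold"]
               for s in event.temporal_slices)


def _inactivity_gap(event: Event, params: dict[str, Any],
                    router: "Router") -> bool:
    prev = router.last_seen.get(event.participant_id)
    router.last_seen[event.participant_id] = event.timestamp
    return prev is not None and event.timestamp - prev > params["window_ms"]


_PREDICATES.update({
    "field_gte": _field_gte,
    "any_slice_value_gte": _any_slice_value_gte,
    "inactivity_gap": _inactivity_gap,
})


class Router:
    """Per-deployment dispatcher for subscriptions and trigger rules.

    Hooks into the deployment's accepted-event notification: each
    accepted event is delivered exactly once to every matching
    subscription and evaluated exactly once per trigger rule.
    """

    def __init__(self, deployment: Deployment) -> None:
        self.deployment = deployment
        self.subscriptions: dict[str, Subscription] = {}
        self.triggers: dict[str, TriggerRule] = {}
        self.audit: list[dict[str, Any]] = []
        self.last_seen: dict[str, int] = {}
        self._counter = itertools.count(1)
        deployment.add_listener(self._on_event)

    def _on_event(self, event: Event) -> None:
        for sub in list(self.subscriptions.values()):
            if sub.selector.matches(event):
                payload = event if sub.transform is None else \
                    get_transformation(sub.transform)(event)
                sub.callback(payload)
        for rule in list(self.triggers.values()):
            if rule.selector.matches(event) and \
                    _PREDICATES[rule.predicate](event, rule.params, self):
                self.audit.append({
                    "rule_id": rule.id,
                    "event_id": event.id,
                    "participant_id": event.participant_id,
                    "timestamp": event.timestamp,
                    "predicate": rule.predicate,
                })

    def subscribe(self, selector: QuerySelector,
                  callback: Callable[[Any], None],
                  transform: Optional[str] = None) -> Subscription:
        if transform is not None:
            get_transformation(transform)  # fail fast on unknown names
        sub = Subscription(id=f"sub-{next(self._counter)}", selector=selector,
                           callback=callback, transform=transform)
        self.subscriptions[sub.id] = sub
        return sub

    def unsubscribe(self, subscription_id: str) -> None:
        self.subscriptions.pop(subscription_id, None)

    def register_trigger(self, selector: QuerySelector, predicate: str,
                         params: Optional[dict[str, Any]] = None) -> str:
        if predicate not in _PREDICATES:
            raise KeyError(f"unknown predicate {predicate!r}")
        rule = TriggerRule(id=f"rule-{next(self._counter)}", selector=selector,
                           predicate=predicate, params=dict(params or {}))
        self.triggers[rule.id] = rule
        return rule.id

    def audit_log(self) -> list[dict[str, Any]]:
        return list(self.audit)

    def audit_log_json(self) -> str:
        return json.dumps(self.audit, indent=2)


def router(deployment: Deployment) -> Router:
    """The deployment's router, created on first use."""
    existing = getattr(deployment, "_router", None)
    if existing is None:
        existing = Router(deployment)
        deployment._router = existing  # type: ignore[attr-defined]
    return existing


# ---------------------------------------------------------------------------
# Schedules

def evaluate_schedule(entries: Sequence[ScheduleEntry],
                      window: tuple[int, int]) -> list[int]:
    """Expected delivery timestamps of a schedule within [start, end)."""
    start, end = window
    period = {"hourly": MS_PER_HOUR, "daily": MS_PER_DAY,
              "weekly": 7 * MS_PER_DAY}
    times: set[int] = set()
    for entry in entries:
        if entry.repeat == "custom":
            times.update(t for t in entry.custom_times if start <= t < end)
            continue
        if entry.repeat == "none":
            if start <= entry.start_time < end:
                times.add(entry.start_time)
            continue
        step = period[entry.repeat]
        t = entry.start_time
        if t < start:
            t += ((start - t + step - 1) // step) * step
        while t < end:
            times.add(t)
            t += step
    return sorted(times)


# ---------------------------------------------------------------------------
# Study configuration round trip

def export_study_config(deployment: Deployment, study_id: str) -> dict[str, Any]:
    """Portable configuration document for one study.

    Captures activities (spec, settings, schedule), sensors (spec,
    settings) and embeds every referenced spec so the document can be
    reimported into an empty deployment.
    """
    if deployment.kind_of(study_id) != "Study":
        raise StoreError(f"{study_id!r} is not a Study")
    study = deployment.get(study_id)
    researcher = deployment.get(study.researcher_id)
    activities = deployment.resolve_children(study_id, "Activity")
    sensors = deployment.resolve_children(study_id, "Sensor")
    spec_names = sorted({a.spec_name for a in activities} |
                        {s.spec_name for s in sensors})
    specs = {}
    for name in spec_names:
        spec = deployment.registry.get(name)
        kind = type(spec).__name__
        specs[name] = {"kind": kind,
                       "definition": spec.model_dump(mode="json", by_alias=True)}
    return {
        "format": "phenokit.study-config.v1",
        "researcher_name": researcher.name,
        "study_name": study.name,
        "activities": [{"spec_name": a.spec_name, "settings": a.settings,
                        "schedule": [s.model_dump() for s in a.schedule]}
                       for a in activities],
        "sensors": [{"spec_name": s.spec_name, "settings": s.settings}
                    for s in sensors],
        "specs": specs,
    }


def import_study_config(deployment: Deployment, doc: dict[str, Any]) -> str:
    """Recreate a study (and owning researcher) from a config document."""
    if doc.get("format") != "phenokit.study-config.v1":
        raise StoreError("unrecognized study configuration document")
    spec_classes = {"ActivitySpec": ActivitySpec, "SensorSpec": SensorSpec,
                    "TagSpec": TagSpec}
    referenced = {a["spec_name"] for a in doc.get("activities", [])} | \
                 {s["spec_name"] for s in doc.get("sensors", [])}
    embedded = doc.get("specs", {})
    for name in sorted(referenced):
        if name in deployment.registry:
            continue
        if name not in embedded:
            raise StoreError(f"dangling spec reference {name!r}: not "
                             f"registered and not embedded in the document")
        entry = embedded[name]
        deployment.registry.register(
            spec_classes[entry["kind"]](**entry["definition"]))
    researcher = deployment.create_resource(
        "Researcher", None, {"name": doc.get("researcher_name", "")})
    study = deployment.create_resource(
        "Study", researcher.id, {"name": doc.get("study_name", "")})
    for a in doc.get("activities", []):
        deployment.create_resource("Activity", study.id, {
            "spec_name": a["spec_name"], "settings": a.get("settings", {}),
            "schedule": a.get("schedule", [])})
    for s in doc.get("sensors", []):
        deployment.create_resource("Sensor", study.id, {
            "spec_name": s["spec_name"], "settings": s.get("settings", {})})
    return study.id
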