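"""Event ingestion: spec validation, sensor harmonization, stream append.

The platform is push-based: devices stream activity sessions and sensor
samples as JSON documents.  On receipt each document is (1) validated
against its activity/sensor spec — reporting *every* violation rather
than the first, (2) harmonized into canonical units and reference
frames, and (3) merged into the participant's chronologically ordered
event stream.  Late-arriving (out-of-order) pushes are tolerated: the
stream is maintained time-sorted, so analysis code downstream never has
to reason about arrival order.

Accelerometer harmonization
---------------------------
Apple devices report acceleration in units of gravity (G) with a frame
of reference in which a stationary face-up device reads −1 G on the
downward-facing axis; Android devices report m/s² in the opposite frame
(a stationary face-up device reads +9.80665 m/s² on z).  The canonical
convention here is the Apple G-frame, so Android samples are divided by
standard gravity (9.80665 m/s²) and negated, axis-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

from pydantic import ValidationError

from .model import ActivityEvent, Event, SensorEvent, TemporalSlice
from .specs import ActivitySpec, SensorSpec, SpecRegistry
from .store import Deployment, StoreError
from .validation import Violation, validate_document

#: standard gravity, m/s² per G
STANDARD_GRAVITY = 9.80665

ACCELEROMETER_SPEC = "lamp.accelerometer"


class HarmonizationError(ValueError):
    """Raised when a sample cannot be mapped to canonical units/frame."""


@dataclass
class ValidationReport:
    """Outcome of a failed validation: every violated schema path."""

    violations: list[Violation]
    raw: Any = None

    def __bool__(self) -> bool:  # truthy only when clean — reports are falsy
        return False

    def paths(self) -> list[str]:
        return [v.path for v in self.violations]


@dataclass
class IngestReport:
    accepted: int = 0
    rejected: int = 0
    stream_length: int = 0
    errors: list[tuple[int, list[Violation]]] = field(default_factory=list)


def validate_event(raw: Union[dict[str, Any], Event],
                   spec: Union[ActivitySpec, SensorSpec],
                   ) -> Union[Event, ValidationReport]:
    """Validate a raw event document against its spec.

    Returns a typed :class:`ActivityEvent`/:class:`SensorEvent` on
    success, or a :class:`ValidationReport` listing all violations.
    Nothing is raised: invalid client data is reportable, not fatal.
    """
    doc = raw.model_dump() if isinstance(raw, (ActivityEvent, SensorEvent)) \
        else dict(raw)
    violations: list[Violation] = []

    if isinstance(spec, ActivitySpec):
        for i, sl in enumerate(doc.get("temporal_slices", [])):
            violations.extend(validate_document(
                sl, spec.output_schema, base_path=f"$.temporal_slices[{i}]"))
            if isinstance(sl, dict) and isinstance(sl.get("duration"), int) \
                    and sl["duration"] < 0:
                violations.append(Violation(
                    f"$.temporal_slices[{i}].duration",
                    "slice duration must be >= 0"))
        try:
            event: Event = ActivityEvent(**doc)
        except ValidationError as exc:
            violations.extend(_pydantic_violations(exc))
            return ValidationReport(_dedupe(violations), raw=doc)
        if sum(s.duration for s in event.temporal_slices) > event.duration:
            violations.append(Violation(
                "$.duration",
                "sum of slice durations exceeds session duration"))
    else:
        violations.extend(validate_document(
            doc.get("data", {}), spec.output_schema, base_path="$.data"))
        try:
            event = SensorEvent(**doc)
        except ValidationError as exc:
            violations.extend(_pydantic_violations(exc))
            return ValidationReport(_dedupe(violations), raw=doc)
        if event.sensor != spec.name:
            violations.append(Violation(
                "$.sensor", f"expected sensor {spec.name!r}"))

    if violations:
        return ValidationReport(_dedupe(violations), raw=doc)
    return event


def _pydantic_violations(exc: ValidationError) -> list[Violation]:
    out = []
    for err in exc.errors():
        path = "$" + "".join(
            f"[{p}]" if isinstance(p, int) else f".{p}" for p in err["loc"])
        out.append(Violation(path, err["msg"]))
    return out


def _dedupe(violations: list[Violation]) -> list[Violation]:
    seen: dict[tuple, None] = {}
    for v in violations:
        seen.setdefault(tuple(v), None)
    return [Violation(*k) for k in seen]


def harmonize_sensor_event(event: SensorEvent,
                           registry: Optional["SpecRegistry"] = None,
                           ) -> SensorEvent:
    """Map a sensor sample to canonical units/frame; idempotent.

    Accelerometer samples from Android are converted axis-wise by
    ``g_axis = -(ms2_axis / 9.80665)``; Apple samples are already in the
    canonical G-frame.  All other sensors pass through with a unit
    annotation only.
    """
    if event.harmonized:
        return event
    data = dict(event.data)
    if event.sensor == ACCELEROMETER_SPEC:
        if event.source_platform == "android":
            for axis in ("x", "y", "z"):
                data[axis] = -(data[axis] / STANDARD_GRAVITY)
        elif event.source_platform != "apple":
            raise HarmonizationError(
                f"cannot harmonize accelerometer sample from unknown "
                f"platform {event.source_platform!r}")
    data["units"] = _canonical_units(event.sensor, registry)
    return event.model_copy(update={"data": data, "harmonized": True})


def _canonical_units(sensor: str,
                     registry: Optional["SpecRegistry"]) -> dict[str, str]:
    from .specs import builtin_registry

    reg = registry if registry is not None else builtin_registry()
    try:
        return dict(reg.sensor(sensor).canonical_units)
    except KeyError:
        return {}


def package_session(deployment: Deployment, participant_id: str,
                    activity_id: str, start: int,
                    slices: Sequence[Union[TemporalSlice, dict]],
                    static_data: Optional[dict[str, Any]] = None,
                    duration: Optional[int] = None) -> ActivityEvent:
    """Package an interaction session's slices into one ActivityEvent.

    The event duration is the sum of slice durations unless a larger
    session-wide duration is supplied explicitly.
    """
    activity = deployment.get(activity_id)
    if deployment.kind_of(activity_id) != "Activity":
        raise StoreError(f"{activity_id!r} is not an Activity")
    static_data = dict(static_data or {})
    slices = [s if isinstance(s, TemporalSlice) else TemporalSlice(**s)
              for s in slices]
    if not slices and not static_data:
        raise StoreError("nothing recorded: empty slices and static_data")
    slice_total = sum(s.duration for s in slices)
    return ActivityEvent(
        id=deployment.new_id(),
        participant_id=participant_id,
        activity_id=activity_id,
        spec_name=activity.spec_name,
        timestamp=start,
        duration=max(slice_total, duration or 0),
        static_data=static_data,
        temporal_slices=slices,
    )


def _resolve_spec(deployment: Deployment, doc: dict[str, Any]):
    if "sensor" in doc:
        return deployment.registry.sensor(doc["sensor"])
    if "activity_id" in doc:
        if doc.get("spec_name"):
            return deployment.registry.activity(doc["spec_name"])
        activity = deployment.get(doc["activity_id"])
        return deployment.registry.activity(activity.spec_name)
    raise KeyError("event document names neither a sensor nor an activity")


def ingest_events(deployment: Deployment, participant_id: str,
                  events: Sequence[Union[dict[str, Any], Event]],
                  ) -> IngestReport:
    """Validate, harmonize and merge a batch into a participant's stream.

    Duplicate event ids are rejected idempotently; accepted events are
    announced to registered subscriptions and triggers in batch order.
    Conservation holds: ``accepted + rejected == len(events)``.
    """
    stream = deployment.stream(participant_id)  # raises for unknown participant
    report = IngestReport()
    for i, raw in enumerate(events):
        doc = raw.model_dump() if isinstance(raw, (ActivityEvent, SensorEvent)) \
            else dict(raw)
        doc.setdefault("participant_id", participant_id)
        doc.setdefault("id", deployment.new_id())
        try:
            spec = _resolve_spec(deployment, doc)
        except (KeyError, StoreError) as exc:
            report.rejected += 1
            report.errors.append((i, [Violation("$", str(exc))]))
            continue
        if isinstance(spec, ActivitySpec):
            doc.setdefault("spec_name", spec.name)
        result = validate_event(doc, spec)
        if isinstance(result, ValidationReport):
            report.rejected += 1
            report.errors.append((i, result.violations))
            continue
        if isinstance(result, SensorEvent):
            try:
                result = harmonize_sensor_event(result, deployment.registry)
            except HarmonizationError as exc:
                report.rejected += 1
                report.errors.append((i, [Violation("$.source_platform",
                                                    str(exc))]))
                continue
        if result.id in stream:
            report.rejected += 1
            report.errors.append((i, [Violation("$.id", "duplicate event id")]))
            continue
        stream.append(result)
        report.accepted += 1
        deployment.notify(result)
    report.stream_length = len(stream)
    return report


def events_to_ndjson(events: Sequence[Event]) -> str:
    """Serialize events as newline-delimited JSON, one object per line."""
    import json

    return "\n".join(json.dumps(e.model_dump(mode="json"), sort_keys=True)
                     for e in events) + ("\n" if events else "")


def events_from_ndjson(text: str) -> list[dict[str, Any]]:
    """Parse a newline-delimited JSON batch into raw event documents."""
    import json

    return [json.loads(line) for line in text.splitlines() if line.strip()]
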