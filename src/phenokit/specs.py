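"""Activity, sensor and tag specifications and their registry.

A *spec* is the semantic contract for a class of data: an activity spec
describes an interactive instrument (its configuration parameters and
the per-slice output it produces), a sensor spec describes a passive
measurement stream (its payload shape and the canonical unit of every
numeric field), and a tag spec constrains extension documents.  All
schema documents are JSON Schema (draft 2020-12).

The built-in catalog mirrors the common smartphone instrument and
sensor set: surveys, breathing/meditation sessions, a leveled cognitive
test, and the accelerometer / GPS / screen-state / pedometer /
call-log / nearby-device sensors.
"""

from __future__ import annotations

from typing import Any, Optional

from jsonschema import Draft202012Validator
from jsonschema.exceptions import SchemaError
from pydantic import BaseModel, ConfigDict, Field

DIALECT = "https://json-schema.org/draft/2020-12/schema"


class SpecValidationError(ValueError):
    """A spec document is malformed or violates a registry invariant."""


class ActivitySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    input_schema: dict[str, Any] = Field(default_factory=dict)
    output_schema: dict[str, Any] = Field(default_factory=dict)


class SensorSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    output_schema: dict[str, Any] = Field(default_factory=dict)
    canonical_units: dict[str, str] = Field(default_factory=dict)


class TagSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    name: str
    schema_doc: dict[str, Any] = Field(default_factory=dict, alias="schema")


Spec = ActivitySpec | SensorSpec | TagSpec


def _schema(properties: dict[str, Any], required: list[str],
            additional: bool = True) -> dict[str, Any]:
    return {
        "$schema": DIALECT,
        "type": "object",
        "properties": properties,
        "required": required,
        "additionalProperties": additional,
    }


def numeric_fields(schema: dict[str, Any]) -> list[str]:
    """Top-level property names whose schema type is number or integer."""
    out = []
    for name, sub in schema.get("properties", {}).items():
        t = sub.get("type")
        types = t if isinstance(t, list) else [t]
        if "number" in types or "integer" in types:
            out.append(name)
    return sorted(out)


class SpecRegistry:
    """Mutable registry of activity/sensor/tag specs, unique by name."""

    def __init__(self) -> None:
        self._specs: dict[str, Spec] = {}

    def register(self, spec: Spec) -> str:
        if spec.name in self._specs:
            raise SpecValidationError(f"duplicate spec name: {spec.name!r}")
        for doc in self._schemas_of(spec):
            try:
                Draft202012Validator.check_schema(doc)
            except SchemaError as exc:
                raise SpecValidationError(
                    f"malformed schema in spec {spec.name!r}: {exc.message}"
                ) from exc
        if isinstance(spec, SensorSpec):
            missing = [f for f in numeric_fields(spec.output_schema)
                       if f not in spec.canonical_units]
            if missing:
                raise SpecValidationError(
                    f"sensor spec {spec.name!r} lacks canonical_units for "
                    f"numeric fields: {missing}"
                )
        self._specs[spec.name] = spec
        return spec.name

    @staticmethod
    def _schemas_of(spec: Spec) -> list[dict[str, Any]]:
        if isinstance(spec, ActivitySpec):
            return [spec.input_schema, spec.output_schema]
        if isinstance(spec, SensorSpec):
            return [spec.output_schema]
        return [spec.schema_doc]

    def get(self, name: str) -> Spec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(f"no spec registered under {name!r}") from None

    def activity(self, name: str) -> ActivitySpec:
        spec = self.get(name)
        if not isinstance(spec, ActivitySpec):
            raise KeyError(f"{name!r} is not an ActivitySpec")
        return spec

    def sensor(self, name: str) -> SensorSpec:
        spec = self.get(name)
        if not isinstance(spec, SensorSpec):
            raise KeyError(f"{name!r} is not a SensorSpec")
        return spec

    def tag(self, name: str) -> TagSpec:
        spec = self.get(name)
        if not isinstance(spec, TagSpec):
            raise KeyError(f"{name!r} is not a TagSpec")
        return spec

    def names(self, kind: Optional[type] = None) -> list[str]:
        return sorted(n for n, s in self._specs.items()
                      if kind is None or isinstance(s, kind))

    def __contains__(self, name: str) -> bool:
        return name in self._specs


# ---------------------------------------------------------------------------
# Built-in catalog

_SLICE_SCHEMA_SURVEY = _schema(
    {
        "item": {"type": "string"},
        "value": {"type": ["string", "number", "boolean", "null"]},
        "type": {"type": "string"},
        "duration": {"type": "integer", "minimum": 0},
    },
    required=["item", "value", "duration"],
)

_SLICE_SCHEMA_BREATHE = _schema(
    {
        "item": {"type": "string"},
        "value": {"type": ["string", "number", "null"]},
        "type": {"type": "string"},
        "duration": {"type": "integer", "minimum": 0},
    },
    required=["item", "duration"],
)

_SLICE_SCHEMA_JEWELS = _schema(
    {
        "item": {"type": "string"},
        "value": {"type": "number"},
        "type": {"type": "string"},
        "duration": {"type": "integer", "minimum": 0},
        "level": {"type": "integer", "minimum": 1},
    },
    required=["item", "value", "duration", "level"],
)


def builtin_specs() -> list[Spec]:
    """The built-in activity and sensor specification catalog."""
    return [
        ActivitySpec(
            name="lamp.survey",
            input_schema=_schema(
                {
                    "questions": {
                        "type": "array",
                        "items": _schema(
                            {
                                "text": {"type": "string"},
                                "type": {
                                    "type": "string",
                                    "enum": ["likert", "boolean", "list", "text"],
                                },
                                "options": {"type": "array"},
                            },
                            required=["text", "type"],
                        ),
                    }
                },
                required=["questions"],
            ),
            output_schema=_SLICE_SCHEMA_SURVEY,
        ),
        ActivitySpec(
            name="lamp.breathe",
            input_schema=_schema(
                {"duration_seconds": {"type": "integer", "minimum": 1}},
                required=[],
            ),
            output_schema=_SLICE_SCHEMA_BREATHE,
        ),
        ActivitySpec(
            name="lamp.jewels",
            input_schema=_schema(
                {"levels": {"type": "integer", "minimum": 1}},
                required=[],
            ),
            output_schema=_SLICE_SCHEMA_JEWELS,
        ),
        SensorSpec(
            name="lamp.accelerometer",
            output_schema=_schema(
                {
                    "x": {"type": "number"},
                    "y": {"type": "number"},
                    "z": {"type": "number"},
                },
                required=["x", "y", "z"],
            ),
            canonical_units={"x": "G", "y": "G", "z": "G"},
        ),
        SensorSpec(
            name="lamp.gps",
            output_schema=_schema(
                {
                    "latitude": {"type": "number", "minimum": -90, "maximum": 90},
                    "longitude": {"type": "number", "minimum": -180, "maximum": 180},
                    "accuracy": {"type": "number", "minimum": 0},
                    "altitude": {"type": "number"},
                },
                required=["latitude", "longitude"],
            ),
            canonical_units={
                "latitude": "degrees",
                "longitude": "degrees",
                "accuracy": "m",
                "altitude": "m",
            },
        ),
        SensorSpec(
            name="lamp.screen_state",
            output_schema=_schema(
                {"state": {"type": "string",
                           "enum": ["on", "off", "locked", "unlocked"]}},
                required=["state"],
            ),
            canonical_units={},
        ),
        SensorSpec(
            name="lamp.steps",
            output_schema=_schema(
                {"steps": {"type": "integer", "minimum": 0}},
                required=["steps"],
            ),
            canonical_units={"steps": "count"},
        ),
        SensorSpec(
            name="lamp.telephony",
            output_schema=_schema(
                {
                    "call_type": {"type": "string",
                                  "enum": ["incoming", "outgoing", "missed"]},
                    "call_duration": {"type": "number", "minimum": 0},
                },
                required=["call_type", "call_duration"],
            ),
            canonical_units={"call_duration": "s"},
        ),
        SensorSpec(
            name="lamp.nearby_device",
            output_schema=_schema(
                {
                    "type": {"type": "string", "enum": ["wifi", "bluetooth"]},
                    "address": {"type": "string"},
                    "rssi": {"type": "number"},
                },
                required=["type", "address"],
            ),
            canonical_units={"rssi": "dBm"},
        ),
    ]


def builtin_registry() -> SpecRegistry:
    """A fresh registry preloaded with the built-in catalog."""
    reg = SpecRegistry()
    for spec in builtin_specs():
        reg.register(spec)
    return reg
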