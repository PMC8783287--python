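"""Core patient-generated-health-data (PGHD) resource model.

The platform's data model is deliberately small: twelve resource kinds
arranged in a shallow hierarchy.  ``Researcher`` owns ``Study``; a study
owns its ``Participant``s and the ``Activity``/``Sensor`` configurations
they interact with; ``ActivityEvent``/``SensorEvent`` hold the recorded
data under a participant; ``ActivitySpec``/``SensorSpec``/``TagSpec``
describe the semantic context of data and metadata; ``Credential``
grants access and ``Tag`` attaches namespaced extension documents to any
resource.
"""

from __future__ import annotations

import enum
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

#: The fixed, ordered list of core resource kinds.  This tuple is the
#: single source of truth for :func:`core_resource_kinds`.
RESOURCE_KINDS: tuple[str, ...] = (
    "Researcher",
    "Study",
    "Participant",
    "Activity",
    "Sensor",
    "ActivityEvent",
    "SensorEvent",
    "ActivitySpec",
    "SensorSpec",
    "Credential",
    "Tag",
    "TagSpec",
)

#: Parent kind required for each child kind in the resource hierarchy.
#: Kinds absent from this map are roots (Researcher) or registry/eventual
#: attachments handled specially (specs, tags, credentials, events).
HIERARCHY: dict[str, str] = {
    "Study": "Researcher",
    "Participant": "Study",
    "Activity": "Study",
    "Sensor": "Study",
    "ActivityEvent": "Participant",
    "SensorEvent": "Participant",
}


def core_resource_kinds() -> list[str]:
    """Return the fixed, ordered list of the 12 core resource kind names.

    Pure function: successive calls return equal, independent lists.
    """
    return list(RESOURCE_KINDS)


class Action(str, enum.Enum):
    """Access-control actions grantable through a credential."""

    read = "read"
    write = "write"
    admin = "admin"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Researcher(_Model):
    id: str
    name: str = ""


class Study(_Model):
    id: str
    researcher_id: str
    name: str = ""
    activity_ids: list[str] = Field(default_factory=list)
    sensor_ids: list[str] = Field(default_factory=list)


class Participant(_Model):
    id: str
    study_id: str


class ScheduleEntry(_Model):
    """One schedule line for a configured activity.

    ``start_time`` is milliseconds since the Unix epoch (UTC); ``repeat``
    is one of ``none``/``hourly``/``daily``/``weekly``/``custom``; for
    ``custom``, ``custom_times`` lists the explicit delivery timestamps.
    """

    start_time: int
    repeat: Literal["none", "hourly", "daily", "weekly", "custom"] = "none"
    custom_times: list[int] = Field(default_factory=list)


class Activity(_Model):
    id: str
    study_id: str
    spec_name: str
    settings: dict[str, Any] = Field(default_factory=dict)
    schedule: list[ScheduleEntry] = Field(default_factory=list)


class Sensor(_Model):
    id: str
    study_id: str
    spec_name: str
    settings: dict[str, Any] = Field(default_factory=dict)


class Grant(_Model):
    resource_id: str
    action: Action


class Credential(_Model):
    id: str
    principal: str
    secret_hash: str = ""
    grants: list[Grant] = Field(default_factory=list)


class Tag(_Model):
    id: str
    target_id: str
    key: str
    spec_name: Optional[str] = None
    value: Any = None


class TemporalSlice(_Model):
    """One validated interaction atom inside an activity session.

    ``item`` labels the interactive element (a survey question, a test
    level), ``value`` carries the answer or score, ``duration`` the
    milliseconds the participant spent on the element and ``level`` an
    optional difficulty level for leveled cognitive tests.
    """

    item: str
    value: Any = None
    type: str = ""
    duration: int = 0
    level: Optional[int] = None

    @field_validator("duration")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("slice duration must be >= 0")
        return v


class ActivityEvent(_Model):
    """A completed interaction session: who, what, when, plus its slices."""

    id: str
    participant_id: str
    activity_id: str
    spec_name: str = ""
    timestamp: int
    duration: int = 0
    static_data: dict[str, Any] = Field(default_factory=dict)
    temporal_slices: list[TemporalSlice] = Field(default_factory=list)

    @property
    def kind(self) -> str:
        return "ActivityEvent"


class SensorEvent(_Model):
    """One passive measurement sample, tied to its sensor spec.

    ``data`` holds the measurement; after ingestion ``harmonized`` is
    true and numeric fields use the spec's canonical units.
    """

    id: str
    participant_id: str
    sensor: str
    timestamp: int
    data: dict[str, Any] = Field(default_factory=dict)
    source_platform: Literal["apple", "android", "other"] = "other"
    harmonized: bool = False

    @property
    def kind(self) -> str:
        return "SensorEvent"


Event = ActivityEvent | SensorEvent

#: pydantic model used to validate each kind's creation payload
KIND_MODELS: dict[str, type[BaseModel]] = {
    "Researcher": Researcher,
    "Study": Study,
    "Participant": Participant,
    "Activity": Activity,
    "Sensor": Sensor,
    "ActivityEvent": ActivityEvent,
    "SensorEvent": SensorEvent,
    "Credential": Credential,
    "Tag": Tag,
}
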