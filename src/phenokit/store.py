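"""In-memory document store and deployment facade.

A :class:`Deployment` is one self-contained installation: the resource
forest (researchers down to participants and their configured
activities/sensors), the spec registry, per-participant event streams,
tags and credentials.  The production systems this models put a
CouchDB-class document database here; at desk scale a dict-backed store
behind the same surface is sufficient and keeps everything testable.

Event streams are append-only and kept globally time-ordered: ties are
broken by (event kind, id) so iteration order is deterministic even for
simultaneous events.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import random
import secrets
from typing import Any, Callable, Iterable, Optional

from pydantic import ValidationError

from .model import (
    Action,
    Activity,
    ActivityEvent,
    Credential,
    Event,
    Grant,
    HIERARCHY,
    KIND_MODELS,
    Participant,
    RESOURCE_KINDS,
    Researcher,
    Sensor,
    SensorEvent,
    Study,
    Tag,
)
from .specs import (
    ActivitySpec,
    SensorSpec,
    Spec,
    SpecRegistry,
    TagSpec,
    builtin_registry,
)
from .validation import validate_document


class StoreError(ValueError):
    """Raised for hierarchy violations, unknown ids, and bad payloads."""


def _event_sort_key(ev: Event) -> tuple[int, str, str]:
    return (ev.timestamp, ev.kind, ev.id)


class EventStream:
    """Chronologically ordered, append-only event sequence of one participant."""

    def __init__(self, participant_id: str) -> None:
        self.participant_id = participant_id
        self._events: list[Event] = []
        self._ids: set[str] = set()

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self):
        return iter(self._events)

    def __contains__(self, event_id: str) -> bool:
        return event_id in self._ids

    def append(self, event: Event) -> None:
        if event.id in self._ids:
            raise StoreError(f"duplicate event id {event.id!r}")
        bisect.insort(self._events, event, key=_event_sort_key)
        self._ids.add(event.id)

    def events(self) -> list[Event]:
        return list(self._events)


class Deployment:
    """One installation: resources, specs, streams, tags, credentials."""

    def __init__(self, seed: Optional[int] = None,
                 registry: Optional[SpecRegistry] = None) -> None:
        # seedable so simulated deployments are byte-reproducible
        self._rng = random.Random(seed if seed is not None
                                  else secrets.randbits(64))
        self.registry = registry if registry is not None else builtin_registry()
        self._resources: dict[str, Any] = {}
        self._kind: dict[str, str] = {}
        self._parent: dict[str, Optional[str]] = {}
        self._children: dict[str, list[str]] = {}
        self._tags: dict[tuple[str, str], Tag] = {}
        self._streams: dict[str, EventStream] = {}
        self._retired_ids: set[str] = set()
        # accepted-event listeners (subscriptions, triggers) hook in here
        self._listeners: list[Callable[[Event], None]] = []

    # -- ids ---------------------------------------------------------------
    def new_id(self) -> str:
        """Fresh random 128-bit hex id, never reused within the deployment."""
        while True:
            rid = f"{self._rng.getrandbits(128):032x}"
            if rid not in self._resources and rid not in self._retired_ids:
                return rid

    # -- resource CRUD -----------------------------------------------------
    def create_resource(self, kind: str, parent_id: Optional[str],
                        payload: Optional[dict[str, Any]] = None) -> Any:
        payload = dict(payload or {})
        if kind not in RESOURCE_KINDS:
            raise StoreError(f"unknown resource kind {kind!r}")
        if kind in ("ActivitySpec", "SensorSpec", "TagSpec"):
            spec_cls = {"ActivitySpec": ActivitySpec, "SensorSpec": SensorSpec,
                        "TagSpec": TagSpec}[kind]
            spec = spec_cls(**payload)
            self.registry.register(spec)
            return spec
        if kind == "Tag":
            return self.attach_tag(payload["target_id"], payload["key"],
                                   payload.get("value"),
                                   payload.get("spec_name"))

        required_parent = HIERARCHY.get(kind)
        if required_parent is None:
            if parent_id is not None:
                raise StoreError(f"{kind} is a root resource; no parent allowed")
        else:
            if parent_id is None:
                raise StoreError(f"{kind} requires a parent {required_parent}")
            actual = self._kind.get(parent_id)
            if actual is None:
                raise StoreError(f"parent {parent_id!r} does not exist")
            if actual != required_parent:
                raise StoreError(
                    f"parent of wrong kind: {kind} requires {required_parent}, "
                    f"got {actual}")

        payload.setdefault("id", self.new_id())
        link_field = {"Study": "researcher_id", "Participant": "study_id",
                      "Activity": "study_id", "Sensor": "study_id",
                      "ActivityEvent": "participant_id",
                      "SensorEvent": "participant_id"}.get(kind)
        if link_field and parent_id is not None:
            payload.setdefault(link_field, parent_id)

        try:
            resource = KIND_MODELS[kind](**payload)
        except ValidationError as exc:
            raise StoreError(f"invalid {kind} payload: {exc}") from exc

        if kind in ("Activity", "Sensor"):
            self._check_spec_settings(kind, resource)

        self._resources[resource.id] = resource
        self._kind[resource.id] = kind
        self._parent[resource.id] = parent_id
        if parent_id is not None:
            self._children.setdefault(parent_id, []).append(resource.id)
        if kind == "Participant":
            self._streams[resource.id] = EventStream(resource.id)
        elif kind == "Activity":
            self._resources[parent_id].activity_ids.append(resource.id)
        elif kind == "Sensor":
            self._resources[parent_id].sensor_ids.append(resource.id)
        elif kind in ("ActivityEvent", "SensorEvent"):
            self._streams[parent_id].append(resource)
        return resource

    def _check_spec_settings(self, kind: str, resource: Any) -> None:
        if kind == "Activity":
            try:
                spec = self.registry.activity(resource.spec_name)
            except KeyError as exc:
                raise StoreError(str(exc)) from exc
            report = validate_document(resource.settings, spec.input_schema)
            if report:
                raise StoreError(
                    f"activity settings fail {resource.spec_name!r} "
                    f"input_schema: {report}")
        else:
            try:
                self.registry.sensor(resource.spec_name)
            except KeyError as exc:
                raise StoreError(str(exc)) from exc

    def get(self, resource_id: str) -> Any:
        try:
            return self._resources[resource_id]
        except KeyError:
            raise StoreError(f"unknown resource id {resource_id!r}") from None

    def kind_of(self, resource_id: str) -> str:
        self.get(resource_id)
        return self._kind[resource_id]

    def parent_of(self, resource_id: str) -> Optional[str]:
        self.get(resource_id)
        return self._parent[resource_id]

    def ancestors(self, resource_id: str) -> list[str]:
        """Parent chain from direct parent up to the root, exclusive of self."""
        chain = []
        cur = self.parent_of(resource_id)
        while cur is not None:
            chain.append(cur)
            cur = self._parent.get(cur)
        return chain

    def resolve_children(self, resource_id: str, kind: str) -> list[Any]:
        """All direct descendants of the given kind, in creation order."""
        self.get(resource_id)
        if kind not in RESOURCE_KINDS:
            raise StoreError(f"unknown resource kind {kind!r}")
        return [self._resources[cid]
                for cid in self._children.get(resource_id, [])
                if self._kind[cid] == kind]

    def delete(self, resource_id: str) -> None:
        """Remove a leaf resource; its id is retired, never reused."""
        self.get(resource_id)
        if self._children.get(resource_id):
            raise StoreError("cannot delete a resource with children")
        parent = self._parent.pop(resource_id, None)
        if parent is not None and parent in self._children:
            self._children[parent].remove(resource_id)
        del self._resources[resource_id]
        del self._kind[resource_id]
        self._retired_ids.add(resource_id)

    def participants(self) -> list[Participant]:
        return [r for i, r in self._resources.items()
                if self._kind[i] == "Participant"]

    # -- streams -----------------------------------------------------------
    def stream(self, participant_id: str) -> EventStream:
        if self._kind.get(participant_id) != "Participant":
            raise StoreError(f"unknown participant {participant_id!r}")
        return self._streams[participant_id]

    def add_listener(self, callback: Callable[[Event], None]) -> None:
        self._listeners.append(callback)

    def remove_listener(self, callback: Callable[[Event], None]) -> None:
        self._listeners.remove(callback)

    def notify(self, event: Event) -> None:
        for cb in list(self._listeners):
            cb(event)

    # -- credentials -------------------------------------------------------
    @staticmethod
    def hash_secret(secret: str, salt: Optional[str] = None) -> str:
        salt = salt if salt is not None else secrets.token_hex(8)
        digest = hashlib.sha256((salt + secret).encode()).hexdigest()
        return f"{salt}${digest}"

    @staticmethod
    def verify_secret(secret: str, secret_hash: str) -> bool:
        salt, _, digest = secret_hash.partition("$")
        return Deployment.hash_secret(secret, salt) == f"{salt}${digest}"

    def create_credential(self, principal: str, secret: str = "",
                          grants: Iterable[tuple[str, str]] = ()) -> Credential:
        cred = Credential(
            id=self.new_id(), principal=principal,
            secret_hash=self.hash_secret(secret) if secret else "",
            grants=[Grant(resource_id=r, action=Action(a)) for r, a in grants])
        self._resources[cred.id] = cred
        self._kind[cred.id] = "Credential"
        self._parent[cred.id] = None
        return cred

    def check_access(self, credential: Credential, resource_id: str,
                     action: str | Action) -> bool:
        """Allow iff a grant covers the resource or any ancestor of it.

        ``admin`` implies ``read`` and ``write``; grants never propagate
        upward in the hierarchy.
        """
        action = Action(action)
        scope = {resource_id, *self.ancestors(resource_id)}
        for grant in credential.grants:
            if grant.resource_id in scope and (
                    grant.action == action or grant.action == Action.admin):
                return True
        return False

    # -- tags --------------------------------------------------------------
    def attach_tag(self, target_id: str, key: str, value: Any,
                   spec_name: Optional[str] = None) -> Tag:
        self.get(target_id)
        if spec_name is not None:
            tag_spec = self.registry.tag(spec_name)
            report = validate_document(value, tag_spec.schema_doc)
            if report:
                raise StoreError(
                    f"tag value fails TagSpec {spec_name!r}: {report}")
        existing = self._tags.get((target_id, key))
        tag = Tag(id=existing.id if existing else self.new_id(),
                  target_id=target_id, key=key, spec_name=spec_name,
                  value=value)
        self._tags[(target_id, key)] = tag
        self._resources[tag.id] = tag
        self._kind[tag.id] = "Tag"
        self._parent[tag.id] = target_id
        return tag

    def get_tag(self, target_id: str, key: str) -> Any:
        try:
            return self._tags[(target_id, key)].value
        except KeyError:
            raise StoreError(f"no tag {key!r} on {target_id!r}") from None

    def tags_of(self, target_id: str) -> dict[str, Any]:
        return {k: t.value for (tid, k), t in self._tags.items()
                if tid == target_id}

    # -- serialization -----------------------------------------------------
    def dump_resources(self) -> str:
        """All non-event resources as a JSON document (debug/persistence aid)."""
        out = []
        for rid, res in self._resources.items():
            kind = self._kind[rid]
            if kind in ("ActivityEvent", "SensorEvent"):
                continue
            out.append({"kind": kind, "parent_id": self._parent.get(rid),
                        "resource": res.model_dump(mode="json")})
        return json.dumps(out, indent=2, sort_keys=True)
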