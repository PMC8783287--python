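"""Lossless, bidirectional FHIR R4 export of internal resources/events.

Mapping table (internal → FHIR R4):

====================  =====================
Participant           Patient
Researcher            Practitioner
Study                 Group
ActivityEvent         QuestionnaireResponse (slices as items)
SensorEvent           Observation (canonical units in the value quantity)
Activity              Questionnaire (definition stub)
Sensor                Device (definition stub)
Tag / Credential      Basic
====================  =====================

Every exported resource carries four components: the native FHIR
rendering of its raw data, provenance metadata (``meta``), a schema
identifier coding naming the internal spec/kind (``meta.tag``), and a
generated human-readable narrative (``text.div``).  Fields with no
native FHIR element ride in one namespaced extension holding the full
internal JSON payload, which is what makes the round trip lossless:
``from_fhir(to_fhir(x)) == x`` field-for-field, ids included.

A hand-built bundle without the extension is also accepted for the
mapped event types, reconstructed from the native FHIR elements alone.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from typing import Any, Iterable, Optional, Sequence, Union

from .model import (
    Activity,
    ActivityEvent,
    Credential,
    Participant,
    Researcher,
    Sensor,
    SensorEvent,
    Study,
    Tag,
    TemporalSlice,
)
from .fhir_schemas import R4_SCHEMAS
from .specs import SensorSpec, SpecRegistry, builtin_registry
from .validation import Violation, validate_document

EXT_URL = "urn:phenokit:internal"
SPEC_SYSTEM = "urn:phenokit:spec"
KIND_SYSTEM = "urn:phenokit:kind"
UCUM = "http://unitsofmeasure.org"

Exportable = Union[Researcher, Study, Participant, Activity, Sensor,
                   ActivityEvent, SensorEvent, Tag, Credential]

_KIND_TO_FHIR = {
    "Participant": "Patient",
    "Researcher": "Practitioner",
    "Study": "Group",
    "ActivityEvent": "QuestionnaireResponse",
    "SensorEvent": "Observation",
    "Activity": "Questionnaire",
    "Sensor": "Device",
    "Tag": "Basic",
    "Credential": "Basic",
}

_MODEL_BY_KIND = {
    "Researcher": Researcher, "Study": Study, "Participant": Participant,
    "Activity": Activity, "Sensor": Sensor, "ActivityEvent": ActivityEvent,
    "SensorEvent": SensorEvent, "Tag": Tag, "Credential": Credential,
}


class FhirMappingError(ValueError):
    pass


def _iso(ms: int) -> str:
    return datetime.fromtimestamp(ms / 1000, tz=timezone.utc).isoformat()


def _ms(iso: str) -> int:
    return int(datetime.fromisoformat(iso).timestamp() * 1000)


def render_narrative(raw_data: dict[str, Any],
                     units: Optional[dict[str, str]] = None) -> str:
    """Deterministic human-readable rendering: one 'field = value unit'
    clause per field, sorted by field name."""
    units = units or {}
    parts = []
    for key in sorted(raw_data):
        if key == "units":
            continue
        value = raw_data[key]
        unit = units.get(key, "")
        parts.append(f"{key} = {json.dumps(value, sort_keys=True)}"
                     + (f" {unit}" if unit else ""))
    return "; ".join(parts) if parts else "(no data recorded)"


def _narrative_element(text: str) -> dict[str, Any]:
    escaped = (text.replace("&", "&amp;").replace("<", "&lt;")
               .replace(">", "&gt;"))
    return {"status": "generated",
            "div": f'<div xmlns="http://www.w3.org/1999/xhtml">{escaped}</div>'}


def _kind_of(obj: Exportable) -> str:
    return type(obj).__name__


def _base(obj: Exportable, schema_code: str, narrative: str) -> dict[str, Any]:
    kind = _kind_of(obj)
    return {
        "resourceType": _KIND_TO_FHIR[kind],
        "id": obj.id,
        "meta": {"source": "urn:phenokit",
                 "tag": [{"system": KIND_SYSTEM, "code": kind},
                         {"system": SPEC_SYSTEM, "code": schema_code}]},
        "text": _narrative_element(narrative),
        "extension": [{"url": EXT_URL,
                       "valueString": json.dumps(
                           {"kind": kind,
                            "resource": obj.model_dump(mode="json")},
                           sort_keys=True)}],
    }


def _export_one(obj: Exportable, registry: SpecRegistry) -> dict[str, Any]:
    kind = _kind_of(obj)
    if kind == "Participant":
        doc = _base(obj, "Participant", f"participant {obj.id}")
        doc["active"] = True
    elif kind == "Researcher":
        doc = _base(obj, "Researcher", obj.name or f"researcher {obj.id}")
        doc["name"] = [{"text": obj.name}]
    elif kind == "Study":
        doc = _base(obj, "Study", obj.name or f"study {obj.id}")
        doc.update({"type": "person", "actual": True, "name": obj.name,
                    "managingEntity": {
                        "reference": f"Practitioner/{obj.researcher_id}"}})
    elif kind == "Activity":
        doc = _base(obj, obj.spec_name, f"activity {obj.spec_name}")
        doc.update({"status": "active", "name": obj.spec_name})
    elif kind == "Sensor":
        doc = _base(obj, obj.spec_name, f"sensor {obj.spec_name}")
        doc["status"] = "active"
    elif kind == "ActivityEvent":
        narrative = render_narrative(
            obj.static_data) if obj.static_data or not obj.temporal_slices \
            else "; ".join(f"{s.item} = {json.dumps(s.value)}"
                           for s in obj.temporal_slices)
        doc = _base(obj, obj.spec_name or "activity", narrative)
        doc.update({
            "status": "completed",
            "subject": {"reference": f"Patient/{obj.participant_id}"},
            "authored": _iso(obj.timestamp),
            "item": [_slice_item(i, s)
                     for i, s in enumerate(obj.temporal_slices)],
        })
    elif kind == "SensorEvent":
        if not obj.harmonized:
            raise FhirMappingError(
                f"SensorEvent {obj.id} must be harmonized before FHIR export")
        units = _sensor_units(obj.sensor, registry)
        doc = _base(obj, obj.sensor, render_narrative(obj.data, units))
        doc.update({
            "status": "final",
            "category": [{"coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/observation-category",
                "code": "activity"}]}],
            "code": {"coding": [{"system": SPEC_SYSTEM, "code": obj.sensor}]},
            "subject": {"reference": f"Patient/{obj.participant_id}"},
            "effectiveDateTime": _iso(obj.timestamp),
        })
        numeric = {k: v for k, v in obj.data.items()
                   if isinstance(v, (int, float)) and not isinstance(v, bool)}
        if len(numeric) == 1:
            ((k, v),) = numeric.items()
            doc["valueQuantity"] = {"value": v, "unit": units.get(k, ""),
                                    "system": UCUM}
        elif numeric:
            doc["component"] = [
                {"code": {"coding": [{"system": SPEC_SYSTEM, "code": k}]},
                 "valueQuantity": {"value": v, "unit": units.get(k, ""),
                                   "system": UCUM}}
                for k, v in sorted(numeric.items())]
    else:  # Tag, Credential → Basic
        doc = _base(obj, kind, f"{kind.lower()} {obj.id}")
        doc["code"] = {"coding": [{"system": KIND_SYSTEM, "code": kind}]}
    return doc


def _slice_item(index: int, sl: TemporalSlice) -> dict[str, Any]:
    answer: dict[str, Any] = {}
    v = sl.value
    if isinstance(v, bool):
        answer = {"valueBoolean": v}
    elif isinstance(v, int):
        answer = {"valueInteger": v}
    elif isinstance(v, float):
        answer = {"valueDecimal": v}
    elif isinstance(v, str):
        answer = {"valueString": v}
    return {"linkId": str(index), "text": sl.item,
            "answer": [answer] if answer else []}


def _sensor_units(sensor: str, registry: SpecRegistry) -> dict[str, str]:
    try:
        spec = registry.sensor(sensor)
    except KeyError:
        return {}
    return dict(spec.canonical_units)


def to_fhir(items: Iterable[Exportable],
            registry: Optional[SpecRegistry] = None) -> dict[str, Any]:
    """Export internal resources/events as a FHIR R4 collection bundle."""
    registry = registry or builtin_registry()
    entries = [{"resource": _export_one(obj, registry)} for obj in items]
    return {"resourceType": "Bundle", "type": "collection", "entry": entries}


def from_fhir(bundle: dict[str, Any]) -> list[Exportable]:
    """Reconstruct internal resources/events from a FHIR bundle.

    Prefers the lossless internal extension; falls back to the native
    elements for hand-built Observation/QuestionnaireResponse entries.
    """
    if bundle.get("resourceType") != "Bundle":
        raise FhirMappingError("document is not a FHIR Bundle")
    out: list[Exportable] = []
    for i, entry in enumerate(bundle.get("entry", [])):
        res = entry.get("resource", {})
        rtype = res.get("resourceType")
        ext = [e for e in res.get("extension", [])
               if e.get("url") == EXT_URL]
        if ext:
            payload = json.loads(ext[0]["valueString"])
            kind = payload["kind"]
            if _KIND_TO_FHIR.get(kind) != rtype:
                raise FhirMappingError(
                    f"entry {i}: extension kind {kind!r} does not match "
                    f"resourceType {rtype!r}")
            out.append(_MODEL_BY_KIND[kind](**payload["resource"]))
            continue
        if rtype == "Observation":
            out.append(_observation_to_event(res))
        elif rtype == "QuestionnaireResponse":
            out.append(_response_to_event(res))
        else:
            raise FhirMappingError(
                f"entry {i}: unmapped FHIR resource type {rtype!r}")
    return out


def _subject_id(res: dict[str, Any]) -> str:
    ref = res.get("subject", {}).get("reference", "")
    return ref.split("/", 1)[1] if "/" in ref else ref


def _observation_to_event(res: dict[str, Any]) -> SensorEvent:
    codings = res.get("code", {}).get("coding", [])
    if not codings:
        raise FhirMappingError("Observation without a code coding")
    sensor = codings[0].get("code", "")
    data: dict[str, Any] = {}
    if "valueQuantity" in res:
        spec_fields = _single_numeric_field(sensor)
        data[spec_fields] = res["valueQuantity"].get("value")
    for comp in res.get("component", []):
        key = comp.get("code", {}).get("coding", [{}])[0].get("code", "")
        data[key] = comp.get("valueQuantity", {}).get("value")
    return SensorEvent(
        id=res.get("id", ""), participant_id=_subject_id(res), sensor=sensor,
        timestamp=_ms(res["effectiveDateTime"]), data=data,
        source_platform="other", harmonized=True)


def _single_numeric_field(sensor: str) -> str:
    from .specs import numeric_fields

    try:
        spec = builtin_registry().sensor(sensor)
    except KeyError:
        return "value"
    fields = numeric_fields(spec.output_schema)
    return fields[0] if len(fields) == 1 else "value"


def _response_to_event(res: dict[str, Any]) -> ActivityEvent:
    slices = []
    for item in res.get("item", []):
        answers = item.get("answer", [])
        value = None
        if answers:
            a = answers[0]
            value = (a.get("valueBoolean") if "valueBoolean" in a else
                     a.get("valueInteger") if "valueInteger" in a else
                     a.get("valueDecimal") if "valueDecimal" in a else
                     a.get("valueString"))
        slices.append(TemporalSlice(item=item.get("text", ""), value=value))
    return ActivityEvent(
        id=res.get("id", ""), participant_id=_subject_id(res),
        activity_id="", timestamp=_ms(res["authored"]),
        temporal_slices=slices)


def validate_fhir(doc: dict[str, Any]) -> list[Violation]:
    """Structural R4 validation against the conformance schema subset."""
    rtype = doc.get("resourceType")
    if rtype not in R4_SCHEMAS:
        return [Violation("$.resourceType",
                          f"no conformance schema for {rtype!r}")]
    violations = validate_document(doc, R4_SCHEMAS[rtype])
    if rtype == "Bundle":
        for i, entry in enumerate(doc.get("entry", [])):
            violations.extend(
                Violation(f"$.entry[{i}].resource{v.path[1:]}", v.message)
                for v in validate_fhir(entry.get("resource", {})))
    return violations
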