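"""Compact structural schemas for the FHIR R4 resource types we emit.

These are hand-written conformance schemas covering the subset of FHIR
R4 this package exports: required elements and element types for the
mapped resource types, per the R4 standard.  They are deliberately not
the full R4 schema corpus — they check that exported documents are
structurally valid instances of their claimed types (required fields
present, correct JSON types, status codes from the R4 value sets).
"""

from __future__ import annotations

from typing import Any

_REFERENCE = {"type": "object",
              "properties": {"reference": {"type": "string"}}}

_CODING = {
    "type": "object",
    "properties": {"system": {"type": "string"}, "code": {"type": "string"},
                   "display": {"type": "string"}},
}

_CODEABLE_CONCEPT = {
    "type": "object",
    "properties": {"coding": {"type": "array", "items": _CODING},
                   "text": {"type": "string"}},
}

_NARRATIVE = {
    "type": "object",
    "properties": {
        "status": {"type": "string",
                   "enum": ["generated", "extensions", "additional", "empty"]},
        "div": {"type": "string", "pattern": "^<div"},
    },
    "required": ["status", "div"],
}

_EXTENSION = {
    "type": "array",
    "items": {
        "type": "object",
        "properties": {"url": {"type": "string"},
                       "valueString": {"type": "string"}},
        "required": ["url"],
    },
}

_META = {
    "type": "object",
    "properties": {"source": {"type": "string"},
                   "tag": {"type": "array", "items": _CODING}},
}

_QUANTITY = {
    "type": "object",
    "properties": {"value": {"type": "number"}, "unit": {"type": "string"},
                   "system": {"type": "string"}, "code": {"type": "string"}},
}


def _resource(type_name: str, extra_props: dict[str, Any],
              required: list[str]) -> dict[str, Any]:
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "type": "object",
        "properties": {
            "resourceType": {"const": type_name},
            "id": {"type": "string", "pattern": "^[A-Za-z0-9\\-\\.]{1,64}$"},
            "meta": _META,
            "text": _NARRATIVE,
            "extension": _EXTENSION,
            **extra_props,
        },
        "required": ["resourceType", *required],
    }


R4_SCHEMAS: dict[str, dict[str, Any]] = {
    "Patient": _resource("Patient", {
        "identifier": {"type": "array"},
        "active": {"type": "boolean"},
    }, required=[]),
    "Practitioner": _resource("Practitioner", {
        "name": {"type": "array",
                 "items": {"type": "object",
                           "properties": {"text": {"type": "string"}}}},
    }, required=[]),
    "Group": _resource("Group", {
        "type": {"type": "string",
                 "enum": ["person", "animal", "practitioner", "device",
                          "medication", "substance"]},
        "actual": {"type": "boolean"},
        "name": {"type": "string"},
        "managingEntity": _REFERENCE,
    }, required=["type", "actual"]),
    "Observation": _resource("Observation", {
        "status": {"type": "string",
                   "enum": ["registered", "preliminary", "final", "amended",
                            "corrected", "cancelled", "entered-in-error",
                            "unknown"]},
        "category": {"type": "array", "items": _CODEABLE_CONCEPT},
        "code": _CODEABLE_CONCEPT,
        "subject": _REFERENCE,
        "effectiveDateTime": {"type": "string"},
        "valueQuantity": _QUANTITY,
        "component": {
            "type": "array",
            "items": {"type": "object",
                      "properties": {"code": _CODEABLE_CONCEPT,
                                     "valueQuantity": _QUANTITY},
                      "required": ["code"]},
        },
    }, required=["status", "code"]),
    "QuestionnaireResponse": _resource("QuestionnaireResponse", {
        "status": {"type": "string",
                   "enum": ["in-progress", "completed", "amended",
                            "entered-in-error", "stopped"]},
        "subject": _REFERENCE,
        "authored": {"type": "string"},
        "questionnaire": {"type": "string"},
        "item": {
            "type": "array",
            "items": {"type": "object",
                      "properties": {"linkId": {"type": "string"},
                                     "text": {"type": "string"},
                                     "answer": {"type": "array"}},
                      "required": ["linkId"]},
        },
    }, required=["status"]),
    "Questionnaire": _resource("Questionnaire", {
        "status": {"type": "string",
                   "enum": ["draft", "active", "retired", "unknown"]},
        "name": {"type": "string"},
        "title": {"type": "string"},
    }, required=["status"]),
    "Device": _resource("Device", {
        "status": {"type": "string",
                   "enum": ["active", "inactive", "entered-in-error",
                            "unknown"]},
        "deviceName": {"type": "array"},
    }, required=[]),
    "Basic": _resource("Basic", {
        "code": _CODEABLE_CONCEPT,
    }, required=["code"]),
    "Bundle": {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "type": "object",
        "properties": {
            "resourceType": {"const": "Bundle"},
            "type": {"type": "string",
                     "enum": ["document", "message", "transaction",
                              "transaction-response", "batch",
                              "batch-response", "history", "searchset",
                              "collection"]},
            "entry": {"type": "array",
                      "items": {"type": "object",
                                "properties": {"resource": {"type": "object"}},
                                "required": ["resource"]}},
        },
        "required": ["resourceType", "type"],
    },
}
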