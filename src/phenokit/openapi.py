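"""Generated OpenAPI 3.1 description of the public resource surface.

Transport is in-process (library calls and the CLI), but the resource
model is described as an OpenAPI document so other systems can see the
same surface a networked deployment would expose: one collection and
one item path per resource kind, with schemas generated from the
pydantic resource models.
"""

from __future__ import annotations

from typing import Any

from .model import KIND_MODELS, RESOURCE_KINDS


def generate_openapi() -> dict[str, Any]:
    components: dict[str, Any] = {}
    paths: dict[str, Any] = {}
    for kind in RESOURCE_KINDS:
        model = KIND_MODELS.get(kind)
        if model is None:  # spec kinds live in the registry, not the store
            continue
        schema = model.model_json_schema(
            ref_template="#/components/schemas/{model}")
        components.update(schema.pop("$defs", {}))
        components[kind] = schema
        ref = {"$ref": f"#/components/schemas/{kind}"}
        collection = f"/{kind.lower()}s"
        paths[collection] = {
            "get": {"summary": f"List {kind} resources",
                    "responses": {"200": {"description": f"{kind} list",
                                          "content": {"application/json": {
                                              "schema": {"type": "array",
                                                         "items": ref}}}}}},
            "post": {"summary": f"Create a {kind}",
                     "requestBody": {"content": {"application/json":
                                                 {"schema": ref}}},
                     "responses": {"201": {"description": "created"}}},
        }
        paths[f"{collection}/{{id}}"] = {
            "get": {"summary": f"Fetch one {kind}",
                    "parameters": [{"name": "id", "in": "path",
                                    "required": True,
                                    "schema": {"type": "string"}}],
                    "responses": {"200": {"description": kind,
                                          "content": {"application/json":
                                                      {"schema": ref}}},
                                  "404": {"description": "unknown id"}}},
        }
    return {
        "openapi": "3.1.0",
        "info": {"title": "phenokit PGHD resource API", "version": "0.1.0",
                 "description": "In-process resource surface of the "
                                "digital-phenotyping data model."},
        "paths": paths,
        "components": {"schemas": components},
    }
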