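"""Thin JSON-Schema validation layer used across the package.

Validation never stops at the first failure: every violated schema path
is collected, which makes client-side (device) debugging tractable.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Any

from jsonschema import Draft202012Validator


class Violation(tuple):
    """(json_path, message) pair for one schema violation."""

    __slots__ = ()

    def __new__(cls, path: str, message: str):
        return super().__new__(cls, (path, message))

    @property
    def path(self) -> str:
        return self[0]

    @property
    def message(self) -> str:
        return self[1]

    def __repr__(self) -> str:  # compact, stable rendering for reports
        return f"{self.path}: {self.message}"


@lru_cache(maxsize=256)
def _validator_for(schema_json: str) -> Draft202012Validator:
    import json

    return Draft202012Validator(json.loads(schema_json))


def validate_document(document: Any, schema: dict[str, Any],
                      base_path: str = "$") -> list[Violation]:
    """Validate ``document`` against ``schema``; return ALL violations.

    An empty list means the document is valid.
    """
    import json

    validator = _validator_for(json.dumps(schema, sort_keys=True))
    violations = []
    for err in sorted(validator.iter_errors(document),
                      key=lambda e: list(map(str, e.absolute_path))):
        path = base_path + "".join(
            f"[{p}]" if isinstance(p, int) else f".{p}"
            for p in err.absolute_path)
        violations.append(Violation(path, err.message))
    return violations
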