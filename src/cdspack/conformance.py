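"""Conformance checking of engine payloads against bundled JSON schemas.

The bundled schemas describe the CDS-Hooks discovery and response documents
this engine emits.  Validation is a small structural checker for the schema
subset those files use (type, required, properties, items, enum, minItems,
minLength, maxLength, local $ref into $defs); messages carry JSON paths.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

_SCHEMA_DIR = Path(__file__).parent / "schemas"

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "number": (int, float),
    "integer": int,
}


def load_schema(name: str) -> dict:
    """Load a bundled schema by stem, e.g. ``cds-hooks-response``."""
    return json.loads((_SCHEMA_DIR / f"{name}.schema.json").read_text(encoding="utf-8"))


def _deref(schema: dict, root: dict) -> dict:
    ref = schema.get("$ref")
    if not ref:
        return schema
    if not ref.startswith("#/"):
        raise ValueError(f"only local $refs are supported: {ref}")
    node: Any = root
    for part in ref[2:].split("/"):
        node = node[part]
    return node


def _check(instance: Any, schema: dict, root: dict, path: str, errors: list[str]) -> None:
    schema = _deref(schema, root)
    expected = schema.get("type")
    if expected is not None:
        py = _TYPES[expected]
        ok = isinstance(instance, py)
        if expected in ("number", "integer") and isinstance(instance, bool):
            ok = False
        if not ok:
            errors.append(f"{path}: expected {expected}, got {type(instance).__name__}")
            return
    if "enum" in schema and instance not in schema["enum"]:
        errors.append(f"{path}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, str):
        if "minLength" in schema and len(instance) < schema["minLength"]:
            errors.append(f"{path}: shorter than {schema['minLength']}")
        if "maxLength" in schema and len(instance) > schema["maxLength"]:
            errors.append(f"{path}: longer than {schema['maxLength']}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required property {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], subschema, root, f"{path}.{key}", errors)
    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            errors.append(f"{path}: fewer than {schema['minItems']} items")
        if "items" in schema:
            for i, item in enumerate(instance):
                _check(item, schema["items"], root, f"{path}[{i}]", errors)


def validate_against_schema(instance: Any, schema: dict) -> list[str]:
    errors: list[str] = []
    _check(instance, schema, schema, "$", errors)
    return errors


def validate_response(doc: dict) -> list[str]:
    """Violations of the CDS-Hooks response contract; empty when conformant.

    Beyond the schema, enforces the information-card contract: a card either
    has no ``suggestions`` key at all, or at least one suggestion with at
    least one action (both already schema-bound).
    """
    errors = validate_against_schema(doc, load_schema("cds-hooks-response"))
    for i, card in enumerate(doc.get("cards", []) if isinstance(doc, dict) else []):
        if isinstance(card, dict) and card.get("suggestions") == []:
            errors.append(f"$.cards[{i}]: information cards must omit 'suggestions'")
    return errors


def validate_discovery(doc: dict) -> list[str]:
    return validate_against_schema(doc, load_schema("cds-hooks-discovery"))
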