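"""JSON Schemas for the package's serialized artifacts.

Three artifact kinds are shipped: the per-sequence "large JSON" for one
species × fraction, the per-species "summary JSON", and the visualization
bundle consumed by 3D renderers. Writers validate on write; readers may
re-validate with :func:`validate`.
"""

from __future__ import annotations

import jsonschema

__all__ = ["LARGE_JSON_SCHEMA", "SUMMARY_JSON_SCHEMA", "BUNDLE_SCHEMA", "validate"]

_percent = {"type": ["number", "null"], "minimum": 0, "maximum": 100}
_count = {"type": "integer", "minimum": 0}

#: Per-sequence composition array for one species × fraction.
LARGE_JSON_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "gclandscape per-sequence composition (large JSON)",
    "type": "object",
    "required": ["species", "fraction", "sequences"],
    "additionalProperties": False,
    "properties": {
        "species": {"type": "string"},
        "fraction": {"enum": ["DNA", "cDNA", "cds"]},
        "sequences": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id", "length", "a", "c", "g", "t", "n", "other",
                             "gc_percent", "at_percent"],
                "additionalProperties": False,
                "properties": {
                    "id": {"type": "string"},
                    "length": _count,
                    "a": _count, "c": _count, "g": _count, "t": _count,
                    "n": _count, "other": _count,
                    "gc_percent": _percent,
                    "at_percent": _percent,
                },
            },
        },
    },
}

#: Per-species roll-up across fractions.
SUMMARY_JSON_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "gclandscape species summary JSON",
    "type": "object",
    "required": ["species", "group", "fractions"],
    "additionalProperties": False,
    "properties": {
        "species": {"type": "string"},
        "group": {"type": "string"},
        "fractions": {
            "type": "object",
            "additionalProperties": False,
            "patternProperties": {
                "^(DNA|cDNA|cds)$": {
                    "type": "object",
                    "required": ["n_seqs", "total_length", "gc_percent",
                                 "at_percent", "n_total"],
                    "additionalProperties": False,
                    "properties": {
                        "n_seqs": _count,
                        "total_length": _count,
                        "n_total": _count,
                        "gc_percent": _percent,
                        "at_percent": _percent,
                    },
                }
            },
        },
    },
}

#: Renderer-agnostic 3D visualization bundle (unit-cube coordinates).
BUNDLE_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "gclandscape GC-landscape visualization bundle",
    "type": "object",
    "required": ["mode", "axis_ranges", "palette", "coordinates"],
    "additionalProperties": False,
    "properties": {
        "mode": {"enum": ["fixed_0_100", "minmax_per_axis"]},
        "axis_ranges": {
            "type": "object",
            "required": ["x", "y", "z"],
            "additionalProperties": False,
            "properties": {
                axis: {
                    "type": "array",
                    "items": {"type": "number"},
                    "minItems": 2,
                    "maxItems": 2,
                }
                for axis in ("x", "y", "z")
            },
        },
        "palette": {"type": "object", "additionalProperties": {"type": "string"}},
        "coordinates": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "required": ["species", "abbreviation", "group",
                             "x", "y", "z", "color"],
                "additionalProperties": False,
                "properties": {
                    "species": {"type": "string"},
                    "abbreviation": {"type": "string"},
                    "group": {"type": "string"},
                    "x": {"type": "number", "minimum": 0, "maximum": 1},
                    "y": {"type": "number", "minimum": 0, "maximum": 1},
                    "z": {"type": "number", "minimum": 0, "maximum": 1},
                    "color": {"type": "string"},
                },
            },
        },
        "tree": {"type": "string"},
        "warnings": {"type": "array", "items": {"type": "string"}},
    },
}


def validate(instance: dict, schema: dict) -> None:
    """Raise ``jsonschema.ValidationError`` if the instance does not conform."""
    jsonschema.validate(instance=instance, schema=schema)
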