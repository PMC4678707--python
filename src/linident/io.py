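"""Model-spec files (YAML or JSON) and report serialization.

Spec schema::

    name: my-model
    states: [x1, x2]
    inputs: [u]
    outputs: [y]
    A: [["-(p1+p2)", "p3"], ["p2", "-(p3+p4)"]]
    B: [["1"], ["0"]]
    C: [["1/V", "0"]]
    D: [["0"]]
    params: [p1, p2, p3, p4, V]        # optional; inferred if omitted
    true_values: {p1: 0.7, ...}        # optional
    conditions:                        # optional
      - {x0: [15, 0], u0: [0]}
      - {x0: [x10, x20], u0: [u10]}    # symbols = generic nonzero entries

Matrix entries use the grammar ``+ - * / ( )`` with identifiers and
numeric literals.  Format is auto-detected (JSON if the file parses as
JSON, YAML otherwise; YAML is a superset, so .json/.yaml/.yml all work).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import (
    ExperimentCondition,
    LinearModel,
    TrueParameterSet,
    build_model,
)

__all__ = ["read_model_spec", "write_model_spec", "write_report", "ReportDocument"]


class SpecError(ValueError):
    """Schema violation in a model-spec file."""


def _load(path) -> dict:
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SpecError(f"{path}: neither valid JSON nor YAML ({exc})") from exc
    if not isinstance(data, dict):
        raise SpecError(f"{path}: top level must be a mapping")
    return data


def read_model_spec(path):
    """Parse and validate a model-spec file.

    Returns ``(model, conditions, true_values_or_None)``.
    """
    data = _load(path)
    for key in ("states", "outputs", "A"):
        if key not in data:
            raise SpecError(f"{path}: missing required key {key!r}")
    try:
        model = build_model(data)
    except ValueError as exc:
        raise SpecError(f"{path}: {exc}") from exc

    conditions = []
    for i, c in enumerate(data.get("conditions") or []):
        if not isinstance(c, dict) or "x0" not in c:
            raise SpecError(f"{path}: conditions[{i}] must be a mapping with x0")
        try:
            cond = ExperimentCondition(tuple(c["x0"]), tuple(c.get("u0") or ()))
            cond.validate(model)
        except ValueError as exc:
            raise SpecError(f"{path}: conditions[{i}]: {exc}") from exc
        conditions.append(cond)

    true_values = None
    if data.get("true_values"):
        try:
            true_values = TrueParameterSet.from_mapping(data["true_values"])
            true_values.validate(model)
        except ValueError as exc:
            raise SpecError(f"{path}: true_values: {exc}") from exc
    return model, conditions, true_values


def write_model_spec(model: LinearModel, path, conditions=(), true_values=None):
    """Write a model (plus conditions/true values) as a YAML spec file."""
    doc = model.to_dict()
    if conditions:
        doc["conditions"] = [
            {
                "x0": [_entry_out(e) for e in c.x0],
                "u0": [_entry_out(e) for e in c.u0],
            }
            for c in conditions
        ]
    if true_values is not None and len(true_values):
        doc["true_values"] = {str(k): v for k, v in true_values.values}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _entry_out(e):
    if hasattr(e, "is_Symbol") and e.is_Symbol:
        return str(e)
    return float(e) if float(e) != int(float(e)) else int(float(e))


class ReportDocument:
    """Serializable identifiability report (JSON or indented text)."""

    def __init__(self, payload: dict):
        self.payload = payload

    @classmethod
    def from_results(cls, results, verification: dict | None = None):
        payload = results.to_dict()
        if verification is not None:
            payload["verification"] = verification
        return cls(payload)

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"model: {self.payload.get('model')}"]
        for key in sorted(self.payload):
            if key == "model":
                continue
            val = self.payload[key]
            if isinstance(val, dict):
                lines.append(f"{key}:")
                lines.extend(f"  {k}: {v}" for k, v in val.items())
            elif isinstance(val, list):
                lines.append(f"{key}: {val}")
            else:
                lines.append(f"{key}: {val}")
        return "\n".join(lines)


def write_report(report: ReportDocument, path, format: str = "json") -> None:
    """Write a report document; JSON output has stable sorted keys."""
    if format == "json":
        Path(path).write_text(report.to_json() + "\n")
    elif format == "text":
        Path(path).write_text(report.to_text() + "\n")
    else:
        raise ValueError(f"format must be 'json' or 'text', got {format!r}")
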