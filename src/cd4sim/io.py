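"""JSON/CSV round trips for parameter sets, modulation sets and results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .agefun import (AgeModulationSet, BodyConstants, FeedbackConstants,
                     Modulation)
from .parameters import KineticParameterSet


class ParseError(ValueError):
    """Malformed input file; message names the offending field."""


def modulation_set_to_dict(mod: AgeModulationSet) -> dict:
    return {
        "variant": mod.variant,
        "modulations": [
            {"target": m.target, "direction": m.direction,
             "max_change": m.max_change, "half_effect": m.half_effect,
             "hill": m.hill, "form": m.form, "group": m.group}
            for m in mod.modulations],
        "feedback": asdict(mod.feedback),
        "body": asdict(mod.body),
    }


def modulation_set_from_dict(d: dict) -> AgeModulationSet:
    try:
        mods = tuple(Modulation(**m) for m in d.get("modulations", []))
        return AgeModulationSet(
            variant=d["variant"], modulations=mods,
            feedback=FeedbackConstants(**d.get("feedback", {})),
            body=BodyConstants(**d.get("body", {})))
    except (KeyError, TypeError) as e:
        raise ParseError(f"bad modulation-set field: {e}") from e


def save_model(params: KineticParameterSet, mod: AgeModulationSet,
               path: str | Path) -> None:
    """One JSON file holding kinetic rates and the modulation set."""
    doc = {"parameters": params.to_dict(),
           "modulations": modulation_set_to_dict(mod)}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> tuple[KineticParameterSet,
                                          AgeModulationSet]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON in {path}: {e}") from e
    try:
        params = KineticParameterSet.from_dict(doc["parameters"])
    except (KeyError, ValueError) as e:
        raise ParseError(f"bad parameter field: {e}") from e
    return params, modulation_set_from_dict(doc.get(
        "modulations", {"variant": "STATIC"}))
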