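"""Parameter-file parsing, validation and CSV/metadata round-trip.

Parameter files are YAML documents mirroring the reference parameter tables:
one component entry per current (e.g. ``I_KAch_CONST``, ``I_KAch_ACH``) with
fields ``f_1``, ``K_1``.. ``K_4`` and ``h_0_1``.. ``h_2_2``.  ``K_4`` may be
the literal token ``inf`` (a site that never binds).  ``f_2`` is derived as
``1 - f_1``.  An optional ``overrides`` block per component maps a voltage
(mV) to replacements of individual h factors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (DEFAULT_RECTIFICATION, ModelParams, ParameterError,
                   PopulationParams, RectificationParams, Scheme)

__all__ = ["ParameterFileError", "ParameterSet", "load_parameter_set",
           "load_params", "load_builtin", "dump_parameter_set",
           "model_to_fields", "write_metadata"]

COMPONENT_ALIASES = {"CONST": "I_KAch_CONST", "ACH": "I_KAch_ACH"}

_FIELDS = ("f_1", "K_1", "K_2", "K_3", "K_4",
           "h_0_1", "h_1_1", "h_2_1", "h_0_2", "h_1_2", "h_2_2")
_INF_TOKENS = {"inf", "+inf", "infinity", "∞"}

#: Default simulation voltage per drug (mV), matching the source protocols.
DEFAULT_VOLTAGE = {"ethanol": -110.0, "nicotine": -50.0}


class ParameterFileError(ParameterError):
    """Raised when a parameter file fails schema validation."""


@dataclass(frozen=True)
class ParameterSet:
    """A parsed parameter file: drug label, units and named component models."""

    drug: str
    units: str
    components: dict[str, ModelParams]
    voltage: float | None = None
    source: str | None = None

    def component(self, name: str) -> ModelParams:
        name = COMPONENT_ALIASES.get(name, name)
        if name not in self.components:
            raise ParameterFileError(
                f"unknown component {name!r}; available: {sorted(self.components)}")
        return self.components[name]

    def default_voltage(self) -> float:
        if self.voltage is not None:
            return self.voltage
        return DEFAULT_VOLTAGE.get(self.drug, -110.0)


def _parse_value(component: str, name: str, value) -> float:
    if isinstance(value, str):
        if value.strip().lower() in _INF_TOKENS:
            return math.inf
        raise ParameterFileError(
            f"component {component}: field {name} has non-numeric value {value!r}")
    if value is None or isinstance(value, bool):
        raise ParameterFileError(
            f"component {component}: field {name} has non-numeric value {value!r}")
    return float(value)


def _component_model(name: str, fields: dict,
                     rectification: RectificationParams) -> ModelParams:
    missing = [f for f in _FIELDS if f not in fields]
    if missing:
        raise ParameterFileError(
            f"component {name}: missing field(s) {', '.join(missing)}")
    vals = {f: _parse_value(name, f, fields[f]) for f in _FIELDS}
    f1 = vals["f_1"]
    if not 0.0 <= f1 <= 1.0:
        raise ParameterFileError(
            f"component {name}: f_1 must lie in [0, 1], got {f1}")
    for f in ("f_1", "K_1", "K_2", "K_3"):
        if not math.isfinite(vals[f]):
            raise ParameterFileError(
                f"component {name}: field {f} must be finite, got {vals[f]}")
    overrides = {}
    for volt, repl in (fields.get("overrides") or {}).items():
        overrides[float(volt)] = {str(k): _parse_value(name, str(k), v)
                                  for k, v in repl.items()}
    try:
        pop1 = PopulationParams(Scheme.SEQUENTIAL_POCKET,
                                K=(vals["K_1"], vals["K_2"]),
                                h=(vals["h_0_1"], vals["h_1_1"], vals["h_2_1"]))
        pop2 = PopulationParams(Scheme.TWO_SITE,
                                K=(vals["K_3"], vals["K_4"]),
                                h=(vals["h_0_2"], vals["h_1_2"], vals["h_2_2"]))
        return ModelParams(populations=((f1, pop1), (1.0 - f1, pop2)),
                           rectification=rectification,
                           U_K=float(fields.get("U_K", -85.0)),
                           overrides=overrides)
    except ParameterError as exc:
        raise ParameterFileError(f"component {name}: {exc}") from exc


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a YAML parameter file into a :class:`ParameterSet`."""
    path = Path(path)
    if not path.exists():
        raise ParameterFileError(f"parameter file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    return _parse_document(doc, source=str(path))


def _parse_document(doc, source: str | None = None) -> ParameterSet:
    if not isinstance(doc, dict):
        raise ParameterFileError("parameter file must be a YAML mapping")
    for key in ("drug", "units", "components"):
        if key not in doc:
            raise ParameterFileError(f"parameter file missing top-level field {key!r}")
    rect = DEFAULT_RECTIFICATION
    if "rectification" in doc:
        r = doc["rectification"]
        rect = RectificationParams(
            terms=tuple(tuple(map(float, t)) for t in r.get(
                "terms", DEFAULT_RECTIFICATION.terms)),
            prefactor=float(r.get("prefactor", DEFAULT_RECTIFICATION.prefactor)),
            global_scale=float(r.get("global_scale", 1.0)))
    comps = {str(name): _component_model(str(name), fields, rect)
             for name, fields in doc["components"].items()}
    if not comps:
        raise ParameterFileError("parameter file defines no components")
    voltage = doc.get("voltage")
    return ParameterSet(drug=str(doc["drug"]), units=str(doc["units"]),
                        components=comps,
                        voltage=None if voltage is None else float(voltage),
                        source=source)


def load_params(path: str | Path, component: str) -> ModelParams:
    """Load one named component model from a parameter file."""
    return load_parameter_set(path).component(component)


def load_builtin(name: str) -> ParameterSet:
    """Load a packaged parameter fixture (``table1_ethanol``, ``table2_nicotine``)."""
    ref = resources.files("kirpop.data") / f"{name}.yaml"
    if not ref.is_file():
        raise ParameterFileError(f"no builtin parameter set named {name!r}")
    doc = yaml.safe_load(ref.read_text())
    return _parse_document(doc, source=f"builtin:{name}")


def model_to_fields(m: ModelParams) -> dict:
    """Flatten a two-population model back to the table field layout."""
    if m.n_populations != 2:
        raise ParameterError("table layout requires a two-population model")
    (f1, pop1), (_, pop2) = m.populations
    out = {
        "f_1": f1,
        "K_1": pop1.K[0], "K_2": pop1.K[1],
        "K_3": pop2.K[0],
        "K_4": "inf" if math.isinf(pop2.K[1]) else pop2.K[1],
        "h_0_1": pop1.h[0], "h_1_1": pop1.h[1], "h_2_1": pop1.h[2],
        "h_0_2": pop2.h[0], "h_1_2": pop2.h[1], "h_2_2": pop2.h[2],
    }
    if m.U_K != -85.0:
        out["U_K"] = m.U_K
    if m.overrides:
        out["overrides"] = {float(v): dict(repl)
                            for v, repl in dict(m.overrides).items()}
    return out


def dump_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set back to YAML in the table layout (lossless)."""
    doc = {"drug": ps.drug, "units": ps.units}
    if ps.voltage is not None:
        doc["voltage"] = ps.voltage
    doc["components"] = {name: model_to_fields(m)
                         for name, m in ps.components.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_metadata(path: str | Path, **info) -> None:
    """Record run provenance (command, parameters, seed, versions) as JSON."""
    import scipy

    import kirpop

    meta = dict(info)
    meta["versions"] = {"kirpop": kirpop.__version__,
                        "numpy": np.__version__,
                        "scipy": scipy.__version__,
                        "pandas": pd.__version__}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
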