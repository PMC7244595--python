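"""Structured-text (TOML) round-trip for model + grid configurations.

Reading uses the stdlib ``tomllib``; writing is a minimal emitter that
prints floats with ``repr`` so that a write -> read round trip reproduces
the model bit-exactly.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np

from .model import AndersonModel, ImaginaryTimeGrid

__all__ = ["read_model_config", "write_model_config"]


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        r = repr(float(x))
        return r if ("." in r or "e" in r or "inf" in r or "nan" in r) else r + ".0"
    if isinstance(x, str):
        return '"' + x.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(x, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_fmt(v) for v in x) + "]"
    raise TypeError(f"cannot serialize {type(x)}")


def write_model_config(path, model: AndersonModel,
                       grid: ImaginaryTimeGrid | None = None) -> None:
    """Write a model (and optionally a time grid) as TOML."""
    lines = ["[model]",
             f"U = {_fmt(model.U)}",
             f"J = {_fmt(model.J)}",
             f"mu = {_fmt(model.mu)}"]
    if model.n_target is not None:
        lines.append(f"n_target = {_fmt(model.n_target)}")
    lines += ["", "[host]", f"energies = {_fmt(model.host_energies)}"]
    if model.host_labels is not None:
        lines.append(f"labels = {_fmt(list(model.host_labels))}")
    lines += ["", "[impurity]", f"energies = {_fmt(model.impurity_energies)}"]
    if model.orbital_labels is not None:
        lines.append(f"labels = {_fmt(list(model.orbital_labels))}")
    lines += ["", "[hybridization]"]
    lines.append("rows = [")
    for row in model.hybridization:
        lines.append("    " + _fmt(row) + ",")
    lines.append("]")
    if grid is not None:
        lines += ["", "[grid]",
                  f"T_kelvin = {_fmt(grid.temperature)}",
                  f"L = {_fmt(grid.L)}"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_config(path):
    """Read a TOML model config; returns (model, grid_or_None)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    m = doc["model"]
    host = doc.get("host", {})
    imp = doc["impurity"]
    model = AndersonModel(
        host_energies=np.array(host.get("energies", []), dtype=float),
        impurity_energies=np.array(imp["energies"], dtype=float),
        hybridization=np.array(doc["hybridization"]["rows"], dtype=float).reshape(
            len(host.get("energies", [])), len(imp["energies"])),
        U=float(m["U"]), J=float(m["J"]), mu=float(m.get("mu", 0.0)),
        n_target=m.get("n_target"),
        host_labels=tuple(host["labels"]) if "labels" in host else None,
        orbital_labels=tuple(imp["labels"]) if "labels" in imp else None,
    )
    grid = None
    if "grid" in doc:
        g = doc["grid"]
        if "L" in g:
            grid = ImaginaryTimeGrid.from_temperature(g["T_kelvin"], L=g["L"])
        else:
            grid = ImaginaryTimeGrid.from_temperature(g["T_kelvin"],
                                                      dtau=g["dtau"])
    return model, grid
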