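"""Configuration parsing and tabular output shared by the CLI subcommands.

One flat YAML schema serves every subcommand, so any analytic scenario can
be re-run as a simulation by switching subcommand only.  Command-line flags
override file values; unknown keys are rejected with the offending key
named.  All results are emitted as TSV with a deterministic column order,
floats at six significant figures, and a provenance footer (tool version,
seed, resolved parameters) in comment lines.
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
import sys
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .model import PolygenicModel, StudyDesign, TraitSpec, binary_trait, quantitative_trait

__all__ = ["RunConfig", "parse_config", "emit_report", "ConfigError"]


class ConfigError(ValueError):
    """A configuration problem; the CLI maps it to exit code 2."""


_MODEL_KEYS = {"m", "vg1", "vg2", "rho12", "pi0"}
_DESIGN_KEYS = {"n1", "n2", "q0", "q1", "estimator", "alpha"}
_TRAIT_KEYS = {"kind", "K", "P", "ascertained"}
_SIM_KEYS = {"maf_low", "maf_high", "effect_dist", "replicates"}
_TOP_KEYS = {"model", "design", "trait1", "trait2", "sim", "seed"}


@dataclass
class RunConfig:
    model: PolygenicModel
    design: StudyDesign
    sim: dict = field(default_factory=dict)
    seed: int = 0

    def resolved(self) -> dict:
        """Plain-dict view of every resolved parameter (for logs/round trips)."""
        def trait_dict(t: TraitSpec) -> dict:
            if t.is_binary:
                return {"kind": t.kind, "K": t.K, "P": t.P, "ascertained": t.ascertained}
            return {"kind": t.kind}
        d = self.design
        return {
            "model": {"m": self.model.m, "vg1": self.model.vg1, "vg2": self.model.vg2,
                      "rho12": self.model.rho12, "pi0": self.model.pi0},
            "design": {"n1": d.n1 if not math.isinf(d.n1) else "inf", "n2": d.n2,
                       "q0": d.q0, "q1": d.q1, "estimator": d.estimator,
                       "alpha": d.alpha},
            "trait1": trait_dict(d.trait1),
            "trait2": trait_dict(d.trait2),
            "sim": dict(self.sim),
            "seed": self.seed,
        }


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {where}")


def _build_trait(section: dict, where: str) -> TraitSpec:
    _check_keys(section, _TRAIT_KEYS, where)
    kind = section.get("kind", "quantitative")
    try:
        if kind == "quantitative":
            return quantitative_trait()
        if "K" not in section:
            raise ConfigError(f"missing required field 'K' in {where}")
        return binary_trait(section["K"], section.get("P"),
                            section.get("ascertained"))
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def parse_config(file_values: dict | None = None, **flag_values: Any) -> RunConfig:
    """Merge file values and flag overrides into a validated RunConfig.

    ``file_values`` is the loaded YAML mapping (sections ``model``,
    ``design``, ``trait1``, ``trait2``, ``sim``, ``seed``); ``flag_values``
    are dotted flat keys like ``model_vg1`` or ``design_n1`` whose non-None
    values override the file.
    """
    data = {k: (dict(v) if isinstance(v, dict) else v)
            for k, v in (file_values or {}).items()}
    _check_keys(data, _TOP_KEYS, "config")
    for key, value in flag_values.items():
        if value is None:
            continue
        if "_" not in key:
            data[key] = value
            continue
        section, name = key.split("_", 1)
        data.setdefault(section, {})[name] = value

    model_sec = data.get("model", {})
    _check_keys(model_sec, _MODEL_KEYS, "model")
    for req in ("m", "vg1"):
        if req not in model_sec:
            raise ConfigError(f"missing required field {req!r} in model")
    design_sec = data.get("design", {})
    _check_keys(design_sec, _DESIGN_KEYS, "design")
    for req in ("n1", "n2"):
        if req not in design_sec:
            raise ConfigError(f"missing required field {req!r} in design")
    sim_sec = data.get("sim", {})
    _check_keys(sim_sec, _SIM_KEYS, "sim")

    trait1 = _build_trait(data.get("trait1", {}), "trait1")
    trait2 = _build_trait(data.get("trait2", {}), "trait2")
    n1 = design_sec["n1"]
    if isinstance(n1, str):
        if n1 not in ("inf", "infinity"):
            raise ConfigError(f"design n1 must be a number or 'inf', got {n1!r}")
        n1 = math.inf
    try:
        model = PolygenicModel(**model_sec)
        design = StudyDesign(trait1=trait1, trait2=trait2,
                             **{**design_sec, "n1": n1})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    seed = data.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError(f"seed must be a nonnegative integer, got {seed!r}")
    return RunConfig(model=model, design=design, sim=dict(sim_sec), seed=seed)


def load_config_file(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        if math.isinf(value):
            return "inf"
        return f"{value:.6g}"
    if value is None:
        return "NA"
    return str(value)


def emit_report(report: Any, out=None, *, config: RunConfig | None = None,
                seed: int | None = None) -> str:
    """Serialise a report (dataclass, mapping, or DataFrame) as TSV.

    Identical inputs produce byte-identical output.  The provenance footer
    carries the tool version, the seed and the resolved configuration as
    comment lines.
    """
    buf = _io.StringIO()
    if isinstance(report, pd.DataFrame):
        cols = list(report.columns)
        buf.write("\t".join(cols) + "\n")
        for _, row in report.iterrows():
            buf.write("\t".join(_fmt(row[c]) for c in cols) + "\n")
    else:
        if dataclasses.is_dataclass(report) and not isinstance(report, type):
            items = dataclasses.asdict(report)
        elif isinstance(report, dict):
            items = report
        else:
            raise TypeError(f"cannot emit report of type {type(report)!r}")
        items = {k: v for k, v in items.items()
                 if not isinstance(v, (dict, list, tuple, pd.DataFrame)) or k == "flags"}
        buf.write("\t".join(items) + "\n")
        buf.write("\t".join(_fmt(";".join(v) if isinstance(v, tuple) else v)
                            for v in items.values()) + "\n")
    buf.write(f"# prspower {__version__}\n")
    if seed is not None:
        buf.write(f"# seed: {seed}\n")
    if config is not None:
        resolved = yaml.safe_dump(config.resolved(), default_flow_style=True,
                                  sort_keys=True).strip()
        buf.write(f"# config: {resolved}\n")
    text = buf.getvalue()
    if out is not None:
        if hasattr(out, "write"):
            out.write(text)
        else:
            with open(out, "w") as fh:
                fh.write(text)
    return text


def log(message: str, verbose: bool = True) -> None:
    if verbose:
        print(message, file=sys.stderr)
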