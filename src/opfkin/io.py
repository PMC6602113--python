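"""Readers and writers for the package's plain-text formats.

* Trace CSV: header ``time_s,o2_uM``; ``#``-prefixed comment lines (retained
  as metadata) and blank lines allowed; values written with 6 significant
  digits.
* Proteome TSV: columns ``protein_id``, ``abundance``, ``n_cys`` and one of
  ``deg_rate_per_min`` / ``half_life_min`` (half-lives converted via ln 2).
* Experiment manifest (YAML): per-trace initial concentrations and injection
  events; concentrations are μM unless the key carries an explicit ``_mM``
  suffix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .capacity import ProteomeEntry
from .fitting import ExperimentSet
from .model import SPECIES, AssayConditions, Injection, StateVector
from .traces import Trace

TRACE_HEADER = "time_s,o2_uM"


class ParseError(ValueError):
    pass


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    lines = []
    for key, value in trace.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append(TRACE_HEADER)
    for t, o2 in zip(trace.t, trace.o2):
        lines.append(f"{t:.6g},{o2:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    comments: list[str] = []
    metadata: dict = {}
    times: list[float] = []
    o2s: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comment = line.lstrip("#").strip()
            comments.append(comment)
            if ":" in comment:
                key, _, value = comment.partition(":")
                metadata[key.strip()] = value.strip()
            continue
        if not header_seen:
            if line.replace(" ", "") != TRACE_HEADER:
                raise ParseError(
                    f"{path}:{lineno}: expected header '{TRACE_HEADER}', got '{line}'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            t, o2 = float(parts[0]), float(parts[1])
        except ValueError as err:
            raise ParseError(f"{path}:{lineno}: non-numeric value: {err}") from None
        if times and t <= times[-1]:
            raise ParseError(f"{path}:{lineno}: time not strictly increasing")
        times.append(t)
        o2s.append(o2)
    if not header_seen:
        raise ParseError(f"{path}: missing header '{TRACE_HEADER}'")
    if len(times) < 2:
        raise ParseError(f"{path}: a trace needs at least 2 data rows")
    metadata["comments"] = comments
    return Trace(t=np.array(times), o2=np.array(o2s), metadata=metadata)


def write_proteome(entries: Sequence[ProteomeEntry], path: str | Path) -> None:
    path = Path(path)
    lines = ["protein_id\tabundance\tn_cys\tdeg_rate_per_min"]
    for e in entries:
        lines.append(f"{e.protein_id}\t{e.abundance:.6g}\t{e.n_cys}\t{e.deg_rate_per_min:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_proteome(path: str | Path) -> list[ProteomeEntry]:
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty proteome table")
    header = lines[0].rstrip().split("\t")
    required = {"protein_id", "abundance", "n_cys"}
    missing = required - set(header)
    if missing:
        raise ParseError(f"{path}: missing required columns: {sorted(missing)}")
    has_rate = "deg_rate_per_min" in header
    has_hl = "half_life_min" in header
    if not (has_rate or has_hl):
        raise ParseError(
            f"{path}: need one of 'deg_rate_per_min' or 'half_life_min' columns"
        )
    col = {name: i for i, name in enumerate(header)}
    entries = []
    for rowno, line in enumerate(lines[1:], start=2):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}: row {rowno}: expected {len(header)} fields")
        try:
            pid = parts[col["protein_id"]]
            abundance = float(parts[col["abundance"]])
            n_cys_f = float(parts[col["n_cys"]])
            if n_cys_f != int(n_cys_f):
                raise ValueError(f"cysteine count {n_cys_f} is not an integer")
            if has_rate:
                rate = float(parts[col["deg_rate_per_min"]])
            else:
                hl = float(parts[col["half_life_min"]])
                if hl <= 0:
                    raise ValueError(f"half-life {hl} must be > 0")
                rate = math.log(2.0) / hl
            entries.append(ProteomeEntry(pid, abundance, int(n_cys_f), rate))
        except ValueError as err:
            raise ParseError(f"{path}: row {rowno}: {err}") from None
    return entries


def _concentrations_from_mapping(mapping: dict) -> dict[str, float]:
    """Species keys with optional ``_mM`` suffix → μM values."""
    out: dict[str, float] = {}
    for key, value in mapping.items():
        if key.endswith("_mM"):
            name, factor = key[:-3], 1000.0
        elif key.endswith("_uM"):
            name, factor = key[:-3], 1.0
        else:
            name, factor = key, 1.0
        if name not in SPECIES:
            raise ParseError(f"unknown species '{key}' in manifest")
        out[name] = float(value) * factor
    return out


def read_manifest(path: str | Path) -> ExperimentSet:
    """Load an experiment manifest and its trace files.

    Structure::

        series_id: pdi_scan
        experiments:
          - trace: run01.csv            # path relative to the manifest
            initial: {PDI_ox: 5, GSH_mM: 40, O2: 258}
            injections:
              - {time: 100, ERO_rr: 1}
            duration: 900
            sample_interval: 1
            diffusion_on: true
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "experiments" not in doc:
        raise ParseError(f"{path}: manifest must contain an 'experiments' list")
    experiments = []
    for i, item in enumerate(doc["experiments"]):
        try:
            initial = StateVector(**_concentrations_from_mapping(item.get("initial", {})))
            injections = []
            for inj in item.get("injections", []):
                inj = dict(inj)
                time = float(inj.pop("time"))
                injections.append(Injection(time, _concentrations_from_mapping(inj)))
            conditions = AssayConditions(
                initial=initial,
                injections=tuple(injections),
                duration=float(item.get("duration", 900.0)),
                sample_interval=float(item.get("sample_interval", 1.0)),
                diffusion_on=bool(item.get("diffusion_on", True)),
            )
            trace = read_trace(path.parent / item["trace"])
        except (KeyError, TypeError, ValueError) as err:
            raise ParseError(f"{path}: experiment {i}: {err}") from None
        experiments.append((conditions, trace))
    return ExperimentSet(experiments=experiments, series_id=str(doc.get("series_id", "")))


def write_manifest(experiments: ExperimentSet, path: str | Path,
                   trace_names: Sequence[str]) -> None:
    """Write a manifest referring to already-written trace files."""
    path = Path(path)
    doc: dict = {"series_id": experiments.series_id, "experiments": []}
    for (conditions, _trace), name in zip(experiments, trace_names):
        initial = {
            s: float(getattr(conditions.initial, s))
            for s in SPECIES
            if getattr(conditions.initial, s) != 0
        }
        injections = [
            {"time": float(inj.time), **{s: float(v) for s, v in inj.increments.items()}}
            for inj in conditions.injections
        ]
        doc["experiments"].append(
            {
                "trace": name,
                "initial": initial,
                "injections": injections,
                "duration": float(conditions.duration),
                "sample_interval": float(conditions.sample_interval),
                "diffusion_on": bool(conditions.diffusion_on),
            }
        )
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class RunConfig:
    """Settings shared by the command-line pipeline stages."""

    output_dir: Path = Path(".")
    seed: int = 0
    n_repeats: int = 10
    window_s: float = 10.0
    baseline_s: float = 100.0
    log_level: str = "INFO"
    solver: dict = field(default_factory=dict)
    cell: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in doc.items():
            if not hasattr(cfg, key):
                raise ParseError(f"unknown config key '{key}'")
            if key == "output_dir":
                value = Path(value)
            setattr(cfg, key, value)
        return cfg
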