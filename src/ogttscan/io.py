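"""Readers, writers and report rendering.

Dataset CSV schema: metadata header lines (``# group=``, ``# age=``,
``# n_animals=``) followed by columns ``time_min, mean_glucose_mg_dl,
variance``.  Parameter sets, initial states and physiology records are
flat key->value JSON.  Scan reports render to JSON or to a markdown
table with three-significant-figure scores and a "-" mark for
hypotheses that could not beat the control set.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import InitialState, ModelParameters, PhysiologyRecord
from .objective import OGTTDataset
from .scan import FitResult, ScanReport

__all__ = [
    "DatasetFormatError",
    "load_dataset",
    "save_dataset",
    "load_parameters",
    "save_parameters",
    "load_initial_state",
    "save_initial_state",
    "load_physiology",
    "save_physiology",
    "load_cohort_spec",
    "render_report",
    "report_to_dict",
    "save_report",
    "load_report",
]

PathLike = Union[str, Path]

_COLUMNS = ["time_min", "mean_glucose_mg_dl", "variance"]
_NO_IMPROVEMENT = "-"


class DatasetFormatError(ValueError):
    """A dataset file violates the expected schema or its invariants."""


def load_dataset(path: PathLike, variance_kind: str = "sample") -> OGTTDataset:
    """Read a group-level OGTT dataset from CSV.

    ``variance_kind`` declares what the variance column holds: the
    between-animal sample variance (``"sample"``, the native convention)
    or the squared standard error of the mean (``"sem2"``, rescaled to a
    sample variance using the header's n_animals).
    """
    meta: dict[str, str] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("#").strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body.append(line)
    try:
        frame = pd.read_csv(_io.StringIO("".join(body)), float_precision="round_trip")
    except Exception as exc:
        raise DatasetFormatError(f"{path}: unparseable CSV body: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    n_animals = int(meta["n_animals"]) if "n_animals" in meta else None

    variance = frame["variance"].to_numpy(dtype=float)
    if variance_kind == "sem2":
        if n_animals is None:
            raise DatasetFormatError(
                f"{path}: variance_kind='sem2' needs an '# n_animals=' header"
            )
        variance = variance * n_animals
    elif variance_kind != "sample":
        raise ValueError("variance_kind must be 'sample' or 'sem2'")

    try:
        return OGTTDataset(
            group=meta.get("group", "unknown"),
            age=meta.get("age", "unknown"),
            timepoints=frame["time_min"].to_numpy(dtype=float),
            mean_glucose=frame["mean_glucose_mg_dl"].to_numpy(dtype=float),
            variance=variance,
            n_animals=n_animals,
        )
    except ValueError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc


def save_dataset(d: OGTTDataset, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# group={d.group}\n# age={d.age}\n")
        if d.n_animals is not None:
            fh.write(f"# n_animals={d.n_animals}\n")
        pd.DataFrame(
            {
                "time_min": d.timepoints,
                "mean_glucose_mg_dl": d.mean_glucose,
                "variance": d.variance,
            }
        ).to_csv(fh, index=False, float_format="%.17g")


def _load_flat_json(path: PathLike) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a flat JSON object")
    return doc


def _dump_json(doc: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_parameters(path: PathLike) -> ModelParameters:
    return ModelParameters(**_load_flat_json(path))


def save_parameters(k: ModelParameters, path: PathLike) -> None:
    _dump_json(k.as_dict(), path)


def load_initial_state(path: PathLike) -> InitialState:
    return InitialState(**_load_flat_json(path))


def save_initial_state(s0: InitialState, path: PathLike) -> None:
    _dump_json(s0.as_dict(), path)


def load_physiology(path: PathLike) -> PhysiologyRecord:
    doc = _load_flat_json(path)
    doc.pop("K", None)  # K is derived, never an input
    return PhysiologyRecord(**doc)


def save_physiology(phys: PhysiologyRecord, path: PathLike) -> None:
    _dump_json(phys.as_dict(), path)


def load_cohort_spec(path: PathLike):
    """Build a :class:`~ogttscan.cohort.CohortSpec` from a YAML document.

    The document may anchor on a published fixture (``age`` plus
    ``group``) and override any of: ``params``, ``init``, ``phys``
    (flat mappings), ``n_animals``, ``grid``, ``param_cv``, ``obs_sd``,
    ``seed``.
    """
    import yaml

    from . import fixtures
    from .cohort import CohortSpec

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    age = doc.get("age", "PND21")
    group = doc.get("group", "control")

    params = (
        ModelParameters(**doc["params"]) if "params" in doc
        else fixtures.get_parameters(age, group)
    )
    init = (
        InitialState(**doc["init"]) if "init" in doc
        else fixtures.get_initial_state(age)
    )
    if "phys" in doc:
        raw = dict(doc["phys"])
        raw.pop("K", None)
        phys = PhysiologyRecord(**raw)
    else:
        phys = fixtures.get_physiology(age)

    kwargs = dict(params=params, init=init, phys=phys, group=group, age=age)
    for key in ("n_animals", "obs_sd", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    if "grid" in doc:
        kwargs["grid"] = tuple(float(t) for t in doc["grid"])
    if "param_cv" in doc:
        kwargs["param_cv"] = {k: float(v) for k, v in doc["param_cv"].items()}
    if "n_animals" not in kwargs:
        try:
            kwargs["n_animals"] = fixtures.cohort_size(age, group)
        except KeyError:
            pass
    return CohortSpec(**kwargs)


def _sig3(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.3g}"


def report_to_dict(report: ScanReport) -> dict:
    """JSON-ready view of a scan report (full-precision scores)."""
    return {
        "dataset": report.dataset,
        "control_epsilon": report.control_epsilon,
        "best": report.best,
        "results": [
            {
                "hypothesis": r.hypothesis_id,
                "parameter": r.parameter,
                "fitted_value": r.fitted_value,
                "epsilon": r.epsilon,
                "improved": r.improved,
                "converged": r.converged,
                "n_evaluations": r.n_evaluations,
            }
            for r in report.results
        ],
    }


def save_report(report: ScanReport, path: PathLike) -> None:
    _dump_json(report_to_dict(report), path)


def load_report(path: PathLike) -> dict:
    return _load_flat_json(path)


def render_report(report: ScanReport, fmt: str = "markdown") -> str:
    """Render a scan report; scores shown to 3 significant figures.

    A hypothesis whose refit is no better than the control parameter set
    shows "-" instead of a score.
    """
    if fmt == "json":
        return json.dumps(report_to_dict(report), indent=1, sort_keys=True)
    if fmt != "markdown":
        raise ValueError("fmt must be 'markdown' or 'json'")
    lines = [
        f"Dataset: {report.dataset}",
        "",
        "| Hypothesis | Parameter | Fitted value | Goodness of fit |",
        "|---|---|---|---|",
        f"| No Hyp. | | | {_sig3(report.control_epsilon)} |",
    ]
    for r in report.results:
        score = _sig3(r.epsilon) if r.improved else _NO_IMPROVEMENT
        fitted = _sig3(r.fitted_value) if (r.improved and r.fitted_value is not None) else ""
        lines.append(f"| {r.hypothesis_id} | {r.parameter or ''} | {fitted} | {score} |")
    if report.best is not None:
        lines += ["", f"Best hypothesis: {report.best}"]
    return "\n".join(lines) + "\n"
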