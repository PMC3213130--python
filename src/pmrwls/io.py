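"""Reading and writing PMR tables, results and scenario configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import TestOutcome
from .scenarios import ScenarioSpec, scenario_from_dict, scenario_to_dict

__all__ = [
    "read_pmr_table",
    "write_pmr_table",
    "outcomes_to_frame",
    "write_outcomes",
    "load_scenario_config",
    "dump_scenario_config",
]

REQUIRED_COLUMNS = ("id", "pmr", "surrogate", "group")


class TableSchemaError(ValueError):
    """The input table is missing columns or contains invalid rows."""


def read_pmr_table(
    path, delimiter: str | None = None, orientation: str | None = None
) -> pd.DataFrame:
    """Read a delimited table of PMR observations.

    Requires columns ``id``, ``pmr``, ``surrogate``, ``group``.  The
    delimiter is inferred from the extension (.csv -> comma, otherwise tab)
    unless given.  Rows with unparseable or negative PMR, non-finite
    surrogate, or missing group are reported with their line numbers.  The
    declared surrogate ``orientation`` ('quantity' or 'ct') is stored in
    ``frame.attrs`` for downstream weighting.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=delimiter)

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableSchemaError(f"missing required column(s): {', '.join(missing)}")

    bad_lines: list[str] = []
    pmr = pd.to_numeric(frame["pmr"], errors="coerce")
    surrogate = pd.to_numeric(frame["surrogate"], errors="coerce")
    for idx in frame.index:
        line = idx + 2  # header is line 1
        if pd.isna(pmr[idx]) or pmr[idx] < 0:
            bad_lines.append(f"line {line}: invalid pmr {frame['pmr'][idx]!r}")
        if pd.isna(surrogate[idx]) or not np.isfinite(surrogate[idx]):
            bad_lines.append(
                f"line {line}: invalid surrogate {frame['surrogate'][idx]!r}"
            )
        if pd.isna(frame["group"][idx]):
            bad_lines.append(f"line {line}: missing group")
    if bad_lines:
        raise TableSchemaError("invalid rows:\n" + "\n".join(bad_lines))

    levels = frame["group"].nunique()
    if levels != 2:
        raise TableSchemaError(f"group must have exactly 2 levels, found {levels}")

    frame = frame.assign(pmr=pmr.astype(float), surrogate=surrogate.astype(float))
    if orientation is not None:
        frame.attrs["orientation"] = orientation
    return frame


def write_pmr_table(frame: pd.DataFrame, path, delimiter: str | None = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    frame.to_csv(path, sep=delimiter, index=False)


def outcomes_to_frame(outcomes: list[TestOutcome | Exception]) -> pd.DataFrame:
    rows = []
    for out in outcomes:
        if isinstance(out, Exception):
            rows.append({"method": type(out).__name__, "error": str(out)})
        else:
            rows.append(
                {
                    "method": out.method.label(),
                    "estimate": out.estimate,
                    "std_error": out.std_error,
                    "t_statistic": out.t_statistic,
                    "p_value": out.p_value,
                    "df": out.df,
                    "n_effective": out.n_effective,
                }
            )
    return pd.DataFrame(rows)


def write_outcomes(outcomes, path, fmt: str | None = None) -> None:
    """Write test outcomes as TSV or JSON (inferred from the extension)."""
    path = Path(path)
    frame = outcomes_to_frame(outcomes)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        frame.to_csv(path, sep="\t", index=False)


def load_scenario_config(path) -> ScenarioSpec:
    """Load a custom scenario from a YAML/JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return scenario_from_dict(data)


def dump_scenario_config(spec: ScenarioSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(spec), sort_keys=False))
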