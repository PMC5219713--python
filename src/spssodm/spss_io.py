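"""Dataset readers and writers.

Two dialects:

* binary ``.sav`` system files, delegated to pyreadstat when it is
  installed (optional extra ``spssodm[sav]``);
* a portable dialect — a JSON variable dictionary plus an RFC 4180 CSV
  data file — that needs no binary backend and round-trips a Dataset
  exactly.

Date/time cells stay raw epoch-seconds doubles at this layer; calendar
rendering is centralized in the forward converter.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from .dataset import (
    SYSMIS,
    Dataset,
    FormatSpec,
    MissingSpec,
    VariableDef,
    validate_dataset,
)
from .errors import InputFormatError, InvalidDatasetError, SavBackendUnavailableError
from .report import errors_only

log = logging.getLogger(__name__)

# CSV dialect is pinned: comma separator, double-quote quoting, UTF-8,
# mandatory header row.  An empty cell means system-missing for numeric
# variables and the empty string for A variables.
_CSV_KWARGS = dict(delimiter=",", quotechar='"', quoting=csv.QUOTE_MINIMAL)


def _require_valid(ds: Dataset) -> None:
    issues = errors_only(validate_dataset(ds))
    if issues:
        raise InvalidDatasetError(issues)


# ---------------------------------------------------------------------------
# Portable dialect
# ---------------------------------------------------------------------------

def _missing_to_json(m: MissingSpec | None):
    if m is None:
        return None
    out: dict = {"values": list(m.values)}
    if m.range is not None:
        out["range"] = [m.range[0], m.range[1]]
    return out


def _missing_from_json(obj) -> MissingSpec | None:
    if obj is None:
        return None
    values = tuple(obj.get("values", ()))
    rng = obj.get("range")
    return MissingSpec(values=values, range=tuple(rng) if rng else None)


def write_portable(ds: Dataset, dict_path, data_path) -> None:
    """Write ``ds`` as a JSON dictionary plus a CSV data file.

    ``read_portable`` on the written pair reproduces the dataset exactly
    (numeric cells equal as doubles).  System-missing in a string
    variable has no portable representation and is written as the empty
    string.
    """
    _require_valid(ds)
    doc = {
        "source_name": ds.source_name,
        "variables": [
            {
                "name": v.name,
                "label": v.label,
                "format": {
                    "code": v.format.code,
                    "width": v.format.width,
                    "decimals": v.format.decimals,
                },
                "value_labels": [
                    {"value": k, "label": lab} for k, lab in v.value_labels.items()
                ],
                "missing": _missing_to_json(v.missing),
                "measure": v.measure,
                "role": v.role,
                "columns": v.columns,
                "align": v.align,
            }
            for v in ds.variables
        ],
    }
    Path(dict_path).write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    with open(data_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, **_CSV_KWARGS)
        writer.writerow([v.name for v in ds.variables])
        for row in ds.cases:
            out = []
            for var, cell in zip(ds.variables, row):
                if cell is SYSMIS:
                    out.append("")
                elif var.is_string:
                    out.append(cell)
                else:
                    out.append(repr(float(cell)))
            writer.writerow(out)


def read_portable(dict_path, data_path) -> Dataset:
    """Read the portable JSON-dictionary + CSV pair back into a Dataset."""
    try:
        doc = json.loads(Path(dict_path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise InputFormatError(f"cannot read dictionary {dict_path}: {exc}") from exc

    variables = []
    for entry in doc.get("variables", []):
        fmt = entry["format"]
        var = VariableDef(
            name=entry["name"],
            label=entry.get("label"),
            format=FormatSpec(fmt["code"], fmt["width"], fmt.get("decimals", 0)),
            value_labels={
                (vl["value"] if isinstance(vl["value"], str) else float(vl["value"])):
                    vl["label"]
                for vl in entry.get("value_labels", [])
            },
            missing=_missing_from_json(entry.get("missing")),
            measure=entry.get("measure"),
            role=entry.get("role"),
            columns=entry.get("columns"),
            align=entry.get("align"),
        )
        variables.append(var)

    ds = Dataset(source_name=doc.get("source_name", str(dict_path)), variables=variables)

    try:
        fh = open(data_path, newline="", encoding="utf-8")
    except OSError as exc:
        raise InputFormatError(f"cannot read data file {data_path}: {exc}") from exc
    with fh:
        reader = csv.reader(fh, **_CSV_KWARGS)
        try:
            header = next(reader)
        except StopIteration:
            raise InputFormatError(f"{data_path}: missing header row") from None
        expected = [v.name for v in variables]
        if header != expected:
            bad = [
                f"column {i}: got {g!r}, expected {e!r}"
                for i, (g, e) in enumerate(zip(header, expected))
                if g != e
            ]
            if len(header) != len(expected):
                bad.append(
                    f"{len(header)} header columns vs {len(expected)} dictionary "
                    "variables"
                )
            raise InputFormatError(
                f"{data_path}: header does not match dictionary ({'; '.join(bad)})"
            )
        for r, row in enumerate(reader):
            if len(row) != len(variables):
                raise InputFormatError(
                    f"{data_path}: row {r} has {len(row)} cells, expected "
                    f"{len(variables)}"
                )
            cells = []
            for c, (var, token) in enumerate(zip(variables, row)):
                if var.is_string:
                    cells.append(token)
                elif token == "":
                    cells.append(SYSMIS)
                else:
                    try:
                        cells.append(float(token))
                    except ValueError:
                        raise InputFormatError(
                            f"{data_path}: row {r}, column {var.name!r} "
                            f"(index {c}): non-numeric token {token!r} under "
                            f"format {var.format}"
                        ) from None
            ds.cases.append(cells)

    issues = errors_only(validate_dataset(ds))
    if issues:
        raise InputFormatError(
            f"{dict_path}: dictionary violates dataset invariants: "
            + "; ".join(i.message for i in issues)
        )
    return ds


# ---------------------------------------------------------------------------
# Binary .sav dialect (optional backend)
# ---------------------------------------------------------------------------

def _backend():
    try:
        import pyreadstat  # type: ignore
    except ImportError as exc:
        raise SavBackendUnavailableError(
            "reading/writing binary .sav files requires pyreadstat "
            "(install spssodm[sav]); the portable JSON+CSV dialect "
            "(read_portable/write_portable) needs no backend"
        ) from exc
    return pyreadstat


_MEASURE_MAP = {"nominal": "nominal", "ordinal": "ordinal", "scale": "scale"}
_ALIGN_MAP = {"left": "left", "right": "right", "center": "center", "centre": "center"}


def read_sav(path) -> Dataset:
    """Read a binary .sav file through pyreadstat.

    Numeric cells are returned as raw doubles — date/time variables stay
    in epoch seconds.  Format codes pyreadstat reports but this package
    does not model are kept on the variable with a logged warning.
    """
    pyreadstat = _backend()
    try:
        df, meta = pyreadstat.read_sav(
            str(path), user_missing=True, disable_datetime_conversion=True
        )
    except Exception as exc:  # pyreadstat raises backend-specific errors
        raise InputFormatError(f"cannot read .sav file {path}: {exc}") from exc

    variables = []
    for i, name in enumerate(meta.column_names):
        fmt_text = (meta.original_variable_types or {}).get(name, "F8.2")
        try:
            fmt = FormatSpec.parse(fmt_text)
        except ValueError:
            log.warning("%s: unsupported format code %r, treating as F8.2", name, fmt_text)
            fmt = FormatSpec("F", 8, 2)
        labels = (meta.variable_value_labels or {}).get(name, {})
        missing = None
        user_vals = (meta.missing_user_values or {}).get(name)
        ranges = (meta.missing_ranges or {}).get(name)
        if ranges:
            rng = ranges[0]
            missing = MissingSpec(values=(), range=(rng["lo"], rng["hi"]))
        elif user_vals:
            missing = MissingSpec(values=tuple(user_vals[:3]))
        variables.append(
            VariableDef(
                name=name,
                label=(meta.column_labels[i] if meta.column_labels else None) or None,
                format=fmt,
                value_labels={
                    (k if isinstance(k, str) else float(k)): v
                    for k, v in labels.items()
                },
                missing=missing,
                measure=_MEASURE_MAP.get((meta.variable_measure or {}).get(name)),
                columns=(meta.variable_display_width or {}).get(name),
                align=_ALIGN_MAP.get((meta.variable_alignment or {}).get(name)),
            )
        )

    ds = Dataset(source_name=Path(path).name, variables=variables)
    str_cols = {v.name for v in variables if v.is_string}
    for record in df.itertuples(index=False):
        row = []
        for var, value in zip(variables, record):
            if var.name in str_cols:
                row.append("" if value is None else str(value))
            elif value is None or value != value:  # NaN → system-missing
                row.append(SYSMIS)
            else:
                row.append(float(value))
        ds.cases.append(row)

    issues = errors_only(validate_dataset(ds))
    if issues:
        raise InputFormatError(
            f"{path}: file contents violate dataset invariants: "
            + "; ".join(i.message for i in issues)
        )
    return ds


def write_sav(ds: Dataset, path) -> None:
    """Write a Dataset to a binary .sav file through pyreadstat.

    Refuses invalid datasets before touching the filesystem.  Attributes
    the backend cannot store (role) are logged as warnings.
    """
    _require_valid(ds)
    pyreadstat = _backend()
    import pandas as pd

    columns = {}
    for j, var in enumerate(ds.variables):
        col = []
        for row in ds.cases:
            cell = row[j]
            if cell is SYSMIS:
                col.append("" if var.is_string else float("nan"))
            else:
                col.append(cell)
        columns[var.name] = col
    df = pd.DataFrame(columns, columns=[v.name for v in ds.variables])

    formats = {v.name: str(v.format) for v in ds.variables}
    value_labels = {
        v.name: dict(v.value_labels) for v in ds.variables if v.value_labels
    }
    missing_ranges = {}
    for v in ds.variables:
        if v.missing is None:
            continue
        spans = [{"lo": x, "hi": x} for x in v.missing.values]
        if v.missing.range is not None:
            spans.append({"lo": v.missing.range[0], "hi": v.missing.range[1]})
        missing_ranges[v.name] = spans
        if v.role is not None:
            log.warning("%s: role attribute is not stored by the .sav backend", v.name)

    pyreadstat.write_sav(
        df,
        str(path),
        column_labels=[v.label or "" for v in ds.variables],
        variable_value_labels=value_labels,
        variable_format=formats,
        missing_ranges=missing_ranges or None,
        variable_display_width={
            v.name: v.columns for v in ds.variables if v.columns is not None
        },
        variable_measure={
            v.name: v.measure for v in ds.variables if v.measure is not None
        },
    )
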