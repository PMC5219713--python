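"""ODM → Dataset: the reverse transformation.

The metadata hierarchy is flattened back into a flat variable list in
Protocol → event → form → itemgroup → item reference order, with an
injected subject-key column in front.  Attributes ODM cannot carry
(measure, role, user-missing) come back absent; display attributes get
declared defaults (columns=8, alignment right for numeric / left for
string).  Only the single-event default hierarchy is reconstructable:
extra study events would need multiple rows per subject and are refused.
"""

from __future__ import annotations

import re

from . import odm
from .dataset import SYSMIS, Dataset, FormatSpec, VariableDef
from .errors import OdmStructureError
from .forward import iso_to_spss_seconds
from .report import UNMAPPABLE_FORMAT, ConversionReport, errors_only

_DEFAULT_COLUMNS = 8
_SUBJECT_WIDTH_MIN = 8


def map_datatype_to_format(
    datatype: str,
    length: int | None = None,
    significant_digits: int | None = None,
) -> tuple[FormatSpec, bool]:
    """Map an ODM DataType back to an SPSS print format.

    Returns (format, supported).  Unknown datatypes (e.g. boolean,
    hexFloat) fall back to (A, 255) with supported=False so the caller
    can record a warning.  Width is widened minimally when the declared
    decimals would not fit under it.
    """
    if datatype == "integer":
        return FormatSpec("F", length or 8, 0), True
    if datatype == "float":
        dec = 2 if significant_digits is None else significant_digits
        width = length or 8
        if dec >= width:
            width = dec + 2  # one integer digit + decimal point + decimals
        return FormatSpec("F", width, dec), True
    if datatype in ("string", "text"):
        return FormatSpec("A", length or 255, 0), True
    if datatype == "date":
        return FormatSpec("DATE", 11, 0), True
    if datatype == "time":
        return FormatSpec("TIME", 8, 0), True
    if datatype == "datetime":
        return FormatSpec("DATETIME", 20, 0), True
    return FormatSpec("A", 255, 0), False


_VALID_CHAR_RE = re.compile(r"[^A-Za-z0-9_@#$.]")
_FIRST_CHAR_RE = re.compile(r"[A-Za-z@#$]")


def sanitize_variable_name(oid: str, registry: set[str]) -> str:
    """Turn an OID into a valid, unique SPSS variable name.

    Invalid characters become "_"; a "V_" prefix is added when the first
    character cannot start a name; the result is truncated to 64
    characters; case-insensitive uniqueness against ``registry`` (a set
    of lowercased claimed names, updated in place) is enforced by a
    numeric suffix replacing the tail.
    """
    if not oid:
        raise ValueError("OID must be non-empty")
    name = _VALID_CHAR_RE.sub("_", oid)
    if not _FIRST_CHAR_RE.fullmatch(name[0]):
        name = "V_" + name
    name = name[:64]
    if name.lower() not in registry:
        registry.add(name.lower())
        return name
    n = 0
    while True:
        n += 1
        suffix = f"_{n}"
        candidate = name[: 64 - len(suffix)] + suffix
        if candidate.lower() not in registry:
            registry.add(candidate.lower())
            return candidate


def _flatten_item_oids(mdv: odm.MetaDataVersion) -> list[str]:
    """ItemDef OIDs in Protocol → event → form → itemgroup → item order.

    Refuses multi-event metadata (beyond the first event) and duplicate
    ItemRefs, either of which would need multiple rows or columns per
    subject.
    """
    events = sorted(mdv.protocol.studyevent_refs, key=lambda r: r.order_number)
    if len(events) > 1:
        extra = [r.oid for r in events[1:]]
        raise OdmStructureError(
            f"only the single-event default hierarchy can be reversed; "
            f"extra study events: {extra}"
        )
    forms_by_oid = {d.oid: d for d in mdv.form_defs}
    igs_by_oid = {d.oid: d for d in mdv.itemgroup_defs}
    events_by_oid = {d.oid: d for d in mdv.studyevent_defs}

    item_oids: list[str] = []
    seen: set[str] = set()
    for ev_ref in events:
        ev = events_by_oid[ev_ref.oid]
        for f_ref in sorted(ev.form_refs, key=lambda r: r.order_number):
            form = forms_by_oid[f_ref.oid]
            for g_ref in sorted(form.itemgroup_refs, key=lambda r: r.order_number):
                group = igs_by_oid[g_ref.oid]
                for i_ref in sorted(group.item_refs, key=lambda r: r.order_number):
                    if i_ref.oid in seen:
                        raise OdmStructureError(
                            f"duplicate ItemRef to {i_ref.oid!r}: reversing it "
                            "would create duplicate columns"
                        )
                    seen.add(i_ref.oid)
                    item_oids.append(i_ref.oid)
    return item_oids


def _parse_coded_value(coded: str, fmt: FormatSpec):
    if fmt.is_string:
        return coded
    try:
        return float(coded)
    except ValueError:
        return coded  # kept verbatim; validation will flag the mismatch


def _parse_value(value: str, fmt: FormatSpec):
    if fmt.is_string:
        return value
    if fmt.code in ("DATE",):
        return iso_to_spss_seconds(value, "date")
    if fmt.code == "TIME":
        return iso_to_spss_seconds(value, "time")
    if fmt.code == "DATETIME":
        return iso_to_spss_seconds(value, "datetime")
    return float(value)


def odm_to_dataset(
    odm_file: odm.OdmFile, subject_column_name: str = "SUBJECTKEY"
) -> tuple[Dataset, ConversionReport]:
    """Flatten an ODM file back into an SPSS-style dataset.

    Variables: the subject-key column first (A format, width = longest
    key but at least 8), then every ItemDef in flattened reference
    order.  One case per SubjectData; an absent ItemData is
    system-missing.  The input must be referentially intact.
    """
    from .odm_io import check_referential_integrity  # local: avoids cycle

    ref_errors = errors_only(check_referential_integrity(odm_file))
    if ref_errors:
        raise OdmStructureError(
            "ODM file is not referentially intact: "
            + "; ".join(i.message for i in ref_errors)
        )
    if not odm_file.studies or not odm_file.studies[0].metadata_versions:
        raise OdmStructureError("ODM file carries no study metadata")

    study = odm_file.studies[0]
    mdv = study.metadata_versions[0]
    report = ConversionReport()

    item_oids = _flatten_item_oids(mdv)
    items_by_oid = {d.oid: d for d in mdv.item_defs}
    codelists_by_oid = {c.oid: c for c in mdv.code_lists}

    subjects = (
        odm_file.clinical_data.subjects if odm_file.clinical_data is not None else []
    )
    key_width = max(
        [_SUBJECT_WIDTH_MIN] + [len(s.subject_key) for s in subjects]
    )

    registry: set[str] = set()
    subject_var = VariableDef(
        name=sanitize_variable_name(subject_column_name, registry),
        format=FormatSpec("A", key_width, 0),
        columns=_DEFAULT_COLUMNS,
        align="left",
    )
    variables = [subject_var]
    formats: list[FormatSpec] = []
    for oid in item_oids:
        item = items_by_oid[oid]
        fmt, supported = map_datatype_to_format(
            item.datatype, item.length, item.significant_digits
        )
        if not supported:
            report.warn(
                oid, UNMAPPABLE_FORMAT,
                f"datatype {item.datatype!r} has no SPSS counterpart; "
                "falling back to A255",
            )
        name = sanitize_variable_name(oid, registry)
        report.oid_registry[oid] = name
        value_labels = {}
        if item.codelist_oid is not None:
            cl = codelists_by_oid[item.codelist_oid]
            value_labels = {
                _parse_coded_value(ci.coded_value, fmt): ci.decode.text
                for ci in cl.items
            }
        variables.append(
            VariableDef(
                name=name,
                label=(item.question.text if item.question is not None
                       else item.name) or None,
                format=fmt,
                value_labels=value_labels,
                columns=_DEFAULT_COLUMNS,
                align="left" if fmt.is_string else "right",
            )
        )
        formats.append(fmt)

    ds = Dataset(source_name=study.study_name, variables=variables)
    column_of = {oid: j for j, oid in enumerate(item_oids)}
    for subject in subjects:
        row: list = [SYSMIS] * len(item_oids)
        for event in subject.events:
            for form in event.forms:
                for group in form.itemgroups:
                    for item in group.items:
                        j = column_of.get(item.item_oid)
                        if j is None:
                            continue
                        row[j] = _parse_value(item.value, formats[j])
        ds.cases.append([subject.subject_key] + row)
    return ds, report
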