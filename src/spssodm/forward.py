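"""Dataset → ODM: the core forward mapping.

An SPSS file is a flat list of variables; ODM is a hierarchy.  The
converter therefore wraps every variable into one default chain
Protocol → StudyEventDef → FormDef → ItemGroupDef, emits one ItemDef per
variable (the subject-key column, if designated, becomes the SubjectKey
attribute instead of an item) and one CodeList per variable with value
labels.  Statistical attributes (missing, measure, role) and display
parameters (columns, align) have no ODM counterpart and are dropped with
a warning each.  Cases become one SubjectData element per row.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from decimal import Decimal

from . import odm
from .dataset import (
    DATE_CODES,
    SYSMIS,
    Cell,
    Dataset,
    FormatSpec,
    VariableDef,
    find_variable,
    validate_dataset,
)
from .errors import (
    ConversionError,
    InvalidDatasetError,
    LanguageTagError,
    SubjectKeyError,
)
from .report import (
    DROPPED_ATTRIBUTE,
    DROPPED_DISPLAY_FORMAT,
    LOSSY_TYPE,
    UNMAPPABLE_FORMAT,
    ConversionReport,
    errors_only,
)

#: Seconds in SPSS numeric date/datetime cells count from this epoch
#: (proleptic Gregorian calendar), a fixed property of the .sav format:
#: October 14, 1582, the first day of the Gregorian calendar.
SPSS_EPOCH = datetime(1582, 10, 14)

_SECONDS_PER_DAY = 86400

# RFC 3066: 1–8 alpha primary subtag, then "-" + 1–8 alphanumerics each.
_LANG_RE = re.compile(r"[A-Za-z]{1,8}(-[A-Za-z0-9]{1,8})*\Z")


def validate_lang(code: str) -> str:
    """Accept an RFC 3066 language tag, or raise :class:`LanguageTagError`."""
    if not isinstance(code, str) or not _LANG_RE.fullmatch(code):
        raise LanguageTagError(code)
    return code


@dataclass(slots=True)
class ConvertOptions:
    """Knobs of a forward conversion.

    include_data
        Emit the ClinicalData section (metadata is always emitted).
    subjectkey
        Name (case-sensitive) of the variable holding the patient
        identifier; that column becomes the SubjectKey attribute and is
        not converted as a separate item.  When absent, subjects are
        keyed "1", "2", … in case order.
    lang
        RFC 3066 code attached to every TranslatedText; omitted from the
        XML when not given.
    string_datatype
        ODM type used for character variables: "string" (default) or
        "text".
    duplicate_key_policy
        "error" (default): duplicate subject keys abort the conversion —
        multiple rows per patient cannot be represented in the default
        single-event hierarchy.  "suffix": repeated keys get ".2", ".3"
        … appended.
    """

    include_data: bool = False
    subjectkey: str | None = None
    lang: str | None = None
    string_datatype: str = "string"
    duplicate_key_policy: str = "error"

    def __post_init__(self):
        if self.string_datatype not in ("string", "text"):
            raise ValueError("string_datatype must be 'string' or 'text'")
        if self.duplicate_key_policy not in ("error", "suffix"):
            raise ValueError("duplicate_key_policy must be 'error' or 'suffix'")
        if self.lang is not None:
            validate_lang(self.lang)


# ---------------------------------------------------------------------------
# Format → DataType
# ---------------------------------------------------------------------------

#: Formats that fall back to a character ODM type because no XML type
#: carries their calendar semantics (week-of-year, day-of-week, …).
STRING_FALLBACK_CODES = frozenset({"DTIME", "WKYR", "WKDAY", "MONTH", "MOYR", "QYR"})

#: Numeric display variants that flatten to plain float.
LOSSY_NUMERIC_CODES = frozenset({"COMMA", "DOT", "DOLLAR", "CC", "E", "PCT"})


def map_format_to_datatype(
    fmt: FormatSpec, opts: ConvertOptions | None = None
) -> tuple[str, int | None, int | None, bool]:
    """Map an SPSS print format to (datatype, length, significant_digits, lossy).

    Total over the format enumeration.  ``lossy`` is True whenever the
    ODM type is less specific than the SPSS format (grouping/currency
    variants, country-specific date displays, week/weekday formats).
    """
    string_dt = opts.string_datatype if opts is not None else "string"
    code = fmt.code
    if code == "A":
        return (string_dt, fmt.width, None, False)
    if code == "F":
        if fmt.decimals == 0:
            return ("integer", fmt.width, None, False)
        return ("float", fmt.width, fmt.decimals, False)
    if code in LOSSY_NUMERIC_CODES:
        sig = fmt.decimals if fmt.decimals else None
        return ("float", fmt.width, sig, True)
    if code in DATE_CODES:
        return ("date", None, None, True)
    if code == "TIME":
        return ("time", None, None, False)
    if code == "DATETIME":
        return ("datetime", None, None, False)
    # DTIME, WKYR, WKDAY, MONTH, MOYR, QYR
    return (string_dt, fmt.width, None, True)


# ---------------------------------------------------------------------------
# OID minting
# ---------------------------------------------------------------------------

_STRUCTURAL_OIDS = {
    "study": "S.1",
    "mdv": "MDV.1",
    "event": "SE.1",
    "form": "F.1",
    "itemgroup": "IG.1",
}


@dataclass(slots=True)
class OidRegistry:
    """Minted OIDs per class, with collision-free reuse of base names."""

    used: dict[str, set[str]] = field(default_factory=dict)
    mapping: dict[str, str] = field(default_factory=dict)

    def _claim(self, kind: str, candidate: str) -> str:
        pool = self.used.setdefault(kind, set())
        oid = candidate
        n = 0
        while oid in pool:
            n += 1
            oid = f"{candidate}.{n}"
        pool.add(oid)
        return oid


def make_oid(kind: str, base: str, registry: OidRegistry) -> str:
    """Mint an OID.

    Item OIDs are the variable name verbatim; codelist OIDs are
    "CL." + variable name; structural elements get fixed defaults
    (S.1, MDV.1, SE.1, F.1, IG.1).  A collision appends "." plus the
    smallest positive integer that makes the OID unique.
    """
    if not base:
        raise ValueError("OID base must be non-empty")
    if kind == "item":
        candidate = base
    elif kind == "codelist":
        candidate = f"CL.{base}"
    elif kind in _STRUCTURAL_OIDS:
        candidate = _STRUCTURAL_OIDS[kind]
    else:
        raise ValueError(f"unknown OID kind {kind!r}")
    oid = registry._claim(kind, candidate)
    registry.mapping[f"{kind}:{base}"] = oid
    return oid


# ---------------------------------------------------------------------------
# Value rendering
# ---------------------------------------------------------------------------

def spss_seconds_to_iso(seconds: float, target: str) -> str:
    """Render an SPSS numeric cell as an ISO 8601 date/time/datetime.

    ``date`` and ``datetime`` interpret the value as seconds elapsed
    since 1582-10-14 00:00:00; ``time`` as seconds since midnight
    (0 ≤ s < 86400).  Fractional seconds are truncated.
    """
    if not math.isfinite(seconds):
        raise ConversionError(f"non-finite seconds value {seconds!r}")
    if target == "time":
        if not 0 <= seconds < _SECONDS_PER_DAY:
            raise ConversionError(
                f"time-of-day value {seconds!r} outside [0, 86400)"
            )
        s = int(seconds)
        return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"
    dt = SPSS_EPOCH + timedelta(seconds=int(seconds))
    if target == "date":
        return f"{dt.year:04d}-{dt.month:02d}-{dt.day:02d}"
    if target == "datetime":
        return (
            f"{dt.year:04d}-{dt.month:02d}-{dt.day:02d}"
            f"T{dt.hour:02d}:{dt.minute:02d}:{dt.second:02d}"
        )
    raise ValueError(f"unknown target {target!r}")


def iso_to_spss_seconds(value: str, target: str) -> float:
    """Inverse of :func:`spss_seconds_to_iso` (dates land on midnight)."""
    if target == "time":
        h, m, s = value.split(":")
        return float(int(h) * 3600 + int(m) * 60 + int(s))
    if target == "date":
        dt = datetime.strptime(value, "%Y-%m-%d")
    elif target == "datetime":
        dt = datetime.strptime(value[:19], "%Y-%m-%dT%H:%M:%S")
    else:
        raise ValueError(f"unknown target {target!r}")
    return (dt - SPSS_EPOCH).total_seconds()


def _render_float(x: float) -> str:
    """Shortest decimal literal that round-trips the double.

    Plain positional notation (no exponent) for |x| < 10^15; grouping
    separators are never emitted, whatever the SPSS display format said.
    """
    s = repr(float(x))
    if ("e" in s or "E" in s) and abs(x) < 1e15:
        s = format(Decimal(s), "f")
    return s


def _render_numeric(x: float) -> str:
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e15:
        return str(int(xf))
    return _render_float(xf)


def convert_value(cell: Cell, fmt: FormatSpec, datatype: str) -> str | None:
    """Render one cell as an ODM Value string; None means "emit nothing".

    System-missing cells produce no ItemData element at all.  User-missing
    codes are NOT filtered here: they are stored values and are exported
    verbatim.
    """
    if cell is SYSMIS:
        return None
    if datatype == "integer":
        return _render_numeric(cell)
    if datatype == "float":
        xf = float(cell)
        if xf.is_integer() and abs(xf) < 1e15:
            return str(int(xf))
        return _render_float(xf)
    if datatype in ("date", "time", "datetime"):
        return spss_seconds_to_iso(float(cell), datatype)
    # string/text: character cells verbatim; numeric cells under the
    # string-fallback formats as a minimal decimal literal
    if isinstance(cell, str):
        return cell
    return _render_numeric(cell)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_DEFAULT_NAMES = {
    "event": "Default event",
    "form": "Default form",
    "itemgroup": "Default item group",
}


def _text(text: str, lang: str | None) -> odm.TranslatedText:
    return odm.TranslatedText(text=text, lang=lang)


def _warn_dropped(var: VariableDef, report: ConversionReport) -> None:
    if var.missing is not None:
        report.warn(
            var.name, DROPPED_ATTRIBUTE,
            "user-missing declaration is not represented in ODM and was "
            "dropped; data values matching it are exported verbatim",
        )
    if var.measure is not None:
        report.warn(var.name, DROPPED_ATTRIBUTE,
                    f"measure={var.measure!r} is not represented in ODM")
    if var.role is not None:
        report.warn(var.name, DROPPED_ATTRIBUTE,
                    f"role={var.role!r} is not represented in ODM")
    if var.columns is not None:
        report.warn(var.name, DROPPED_DISPLAY_FORMAT,
                    f"display width columns={var.columns} cannot be mapped")
    if var.align is not None:
        report.warn(var.name, DROPPED_DISPLAY_FORMAT,
                    f"alignment={var.align!r} cannot be mapped")


def _warn_format(var: VariableDef, datatype: str, lossy: bool,
                 report: ConversionReport) -> None:
    if not lossy:
        return
    code = var.format.code
    if code in LOSSY_NUMERIC_CODES:
        report.warn(
            var.name, LOSSY_TYPE,
            f"format {var.format} flattened to the less specific type "
            f"{datatype!r}; grouping/currency display is lost",
        )
    elif code in DATE_CODES:
        report.warn(
            var.name, DROPPED_DISPLAY_FORMAT,
            f"date display format {var.format} is lost; values use the "
            "XML date format",
        )
    else:
        report.warn(
            var.name, UNMAPPABLE_FORMAT,
            f"format {var.format} has no ODM counterpart; values exported "
            f"as {datatype!r}",
        )


def build_metadata(
    ds: Dataset,
    opts: ConvertOptions,
    *,
    timestamp: str | None = None,
) -> tuple[odm.OdmFile, ConversionReport]:
    """Build the metadata half of the ODM file (no ClinicalData yet).

    Exactly one Study → MetaDataVersion → Protocol → StudyEventDef →
    FormDef → ItemGroupDef chain is emitted; SPSS has no study-level
    structure, so these defaults supply the hierarchy ODM requires.
    """
    issues = errors_only(validate_dataset(ds))
    if issues:
        raise InvalidDatasetError(issues)
    if opts.lang is not None:
        validate_lang(opts.lang)

    excluded = None
    if opts.subjectkey is not None:
        excluded = find_variable(ds, opts.subjectkey)
        if excluded is None:
            raise SubjectKeyError(
                f"subjectkey variable {opts.subjectkey!r} not found "
                "(lookup is case-sensitive)"
            )

    report = ConversionReport()
    registry = OidRegistry()
    study_oid = make_oid("study", ds.source_name or "study", registry)
    mdv_oid = make_oid("mdv", ds.source_name or "study", registry)
    event_oid = make_oid("event", "event", registry)
    form_oid = make_oid("form", "form", registry)
    ig_oid = make_oid("itemgroup", "itemgroup", registry)

    item_defs: list[odm.ItemDef] = []
    code_lists: list[odm.CodeList] = []
    item_refs: list[odm.Ref] = []
    order = 0
    for i, var in enumerate(ds.variables):
        if i == excluded:
            continue
        datatype, length, sig, lossy = map_format_to_datatype(var.format, opts)
        _warn_format(var, datatype, lossy, report)
        _warn_dropped(var, report)
        item_oid = make_oid("item", var.name, registry)
        report.oid_registry[var.name] = item_oid
        codelist_oid = None
        if var.value_labels:
            codelist_oid = make_oid("codelist", var.name, registry)
            code_lists.append(
                odm.CodeList(
                    oid=codelist_oid,
                    name=f"Value labels of {var.name}",
                    datatype=datatype if datatype in odm.DATATYPES else "string",
                    items=[
                        odm.CodeListItem(
                            coded_value=(
                                k if isinstance(k, str) else _render_numeric(k)
                            ),
                            decode=_text(lab, opts.lang),
                        )
                        for k, lab in var.value_labels.items()
                    ],
                )
            )
        display = var.label if var.label else var.name
        item_defs.append(
            odm.ItemDef(
                oid=item_oid,
                name=display,
                datatype=datatype,
                length=length,
                significant_digits=sig,
                question=_text(display, opts.lang),
                codelist_oid=codelist_oid,
            )
        )
        order += 1
        item_refs.append(odm.Ref(oid=item_oid, order_number=order))

    mdv = odm.MetaDataVersion(
        oid=mdv_oid,
        name="Converted metadata",
        protocol=odm.Protocol(studyevent_refs=[odm.Ref(oid=event_oid, order_number=1)]),
        studyevent_defs=[
            odm.StudyEventDef(
                oid=event_oid,
                name=_DEFAULT_NAMES["event"],
                form_refs=[odm.Ref(oid=form_oid, order_number=1)],
            )
        ],
        form_defs=[
            odm.FormDef(
                oid=form_oid,
                name=_DEFAULT_NAMES["form"],
                itemgroup_refs=[odm.Ref(oid=ig_oid, order_number=1)],
            )
        ],
        itemgroup_defs=[
            odm.ItemGroupDef(
                oid=ig_oid, name=_DEFAULT_NAMES["itemgroup"], item_refs=item_refs
            )
        ],
        item_defs=item_defs,
        code_lists=code_lists,
    )
    study = odm.Study(
        oid=study_oid,
        study_name=ds.source_name or "Converted study",
        study_description=f"Converted from {ds.source_name}",
        protocol_name=ds.source_name or "Converted study",
        metadata_versions=[mdv],
    )
    if timestamp is None:
        timestamp = (
            datetime.now(timezone.utc).replace(microsecond=0).isoformat()
        )
    file_oid = _file_oid(ds.source_name, timestamp)
    odm_file = odm.OdmFile(
        file_oid=file_oid,
        creation_datetime=timestamp,
        studies=[study],
    )
    return odm_file, report


def _file_oid(source_name: str, timestamp: str) -> str:
    base = re.sub(r"[^A-Za-z0-9._-]+", "_", source_name or "dataset")
    return f"{base}.{timestamp}"


# ---------------------------------------------------------------------------
# Clinical data
# ---------------------------------------------------------------------------

def extract_subject_keys(
    ds: Dataset, opts: ConvertOptions
) -> tuple[list[str], int | None]:
    """Subject keys for each case, and the index of the excluded column.

    With a designated subjectkey column its rendered values become the
    keys and the column is excluded from item conversion; without one,
    the keys are the incrementing numbers "1" … "n".
    """
    if opts.subjectkey is None:
        return [str(i + 1) for i in range(len(ds.cases))], None

    idx = find_variable(ds, opts.subjectkey)
    if idx is None:
        raise SubjectKeyError(
            f"subjectkey variable {opts.subjectkey!r} not found "
            "(lookup is case-sensitive)"
        )
    var = ds.variables[idx]
    datatype, _, _, _ = map_format_to_datatype(var.format, opts)
    keys = []
    for r, row in enumerate(ds.cases):
        rendered = convert_value(row[idx], var.format, datatype)
        if rendered is None or rendered == "":
            raise SubjectKeyError(
                f"case {r}: subject key in column {var.name!r} is missing/empty"
            )
        keys.append(rendered)

    counts = Counter(keys)
    seen: dict[str, int] = {}
    duplicates = sorted(k for k, c in counts.items() if c > 1)
    if duplicates:
        if opts.duplicate_key_policy == "error":
            raise SubjectKeyError(
                "duplicate subject keys "
                f"{duplicates}: multiple cases per patient cannot be "
                "represented in the default single-event hierarchy "
                "(use duplicate_key_policy='suffix' to disambiguate)"
            )
        out = []
        for k in keys:
            seen[k] = seen.get(k, 0) + 1
            out.append(k if seen[k] == 1 else f"{k}.{seen[k]}")
        keys = out
    return keys, idx


def build_clinical_data(
    ds: Dataset,
    metadata: odm.OdmFile,
    keys: list[str],
    excluded_index: int | None,
    opts: ConvertOptions,
) -> odm.ClinicalData:
    """One SubjectData per case, each holding the single default
    StudyEventData → FormData → ItemGroupData chain; system-missing
    cells emit no ItemData."""
    if len(keys) != len(ds.cases):
        raise ValueError("one subject key per case is required")
    study = metadata.studies[0]
    mdv = study.metadata_versions[0]
    event_oid = mdv.studyevent_defs[0].oid
    form_oid = mdv.form_defs[0].oid
    ig_oid = mdv.itemgroup_defs[0].oid

    # Pre-compute per-column render plan for speed at registry scale.
    plan = []
    for i, var in enumerate(ds.variables):
        if i == excluded_index:
            continue
        datatype, _, _, _ = map_format_to_datatype(var.format, opts)
        plan.append((i, var.format, datatype, var.name))
    oid_of = {
        name: oid
        for name, oid in zip(
            (p[3] for p in plan), (r.oid for r in mdv.itemgroup_defs[0].item_refs)
        )
    }

    subjects = []
    for key, row in zip(keys, ds.cases):
        items = []
        for i, fmt, datatype, name in plan:
            value = convert_value(row[i], fmt, datatype)
            if value is None:
                continue
            items.append(odm.ItemData(item_oid=oid_of[name], value=value))
        subjects.append(
            odm.SubjectData(
                subject_key=key,
                events=[
                    odm.StudyEventData(
                        studyevent_oid=event_oid,
                        forms=[
                            odm.FormData(
                                form_oid=form_oid,
                                itemgroups=[
                                    odm.ItemGroupData(
                                        itemgroup_oid=ig_oid, items=items
                                    )
                                ],
                            )
                        ],
                    )
                ],
            )
        )
    return odm.ClinicalData(
        study_oid=study.oid,
        metadata_version_oid=mdv.oid,
        subjects=subjects,
    )


def convert(
    ds: Dataset,
    opts: ConvertOptions | None = None,
    *,
    timestamp: str | None = None,
) -> tuple[odm.OdmFile, ConversionReport]:
    """Full forward conversion: metadata always, ClinicalData on request.

    ``timestamp`` (ISO 8601) overrides CreationDateTime for reproducible
    output; FileOID derives from the source name and the timestamp.
    """
    if opts is None:
        opts = ConvertOptions()
    odm_file, report = build_metadata(ds, opts, timestamp=timestamp)
    if opts.include_data:
        keys, excluded = extract_subject_keys(ds, opts)
        odm_file.clinical_data = build_clinical_data(
            ds, odm_file, keys, excluded, opts
        )
    return odm_file, report
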