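"""Object model of a CDISC ODM 1.3.1 document.

Two halves mirror the standard: the *study metadata* hierarchy
(Study → MetaDataVersion → Protocol / StudyEventDef / FormDef /
ItemGroupDef / ItemDef / CodeList, wired together by referencing OIDs)
and the *clinical data* value hierarchy (SubjectData → StudyEventData →
FormData → ItemGroupData → ItemData).  AdminData, ReferenceData and
Association are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ODM_VERSION = "1.3.1"
ODM_NAMESPACE = "http://www.cdisc.org/ns/odm/v1.3"

#: The ODM DataType values the converter handles.  "text" and "string"
#: are both unbounded-character types in ODM 1.3.1; the forward
#: converter emits "string" by default with "text" available as an
#: option.
DATATYPES = frozenset({"string", "integer", "float", "date", "time", "datetime", "text"})

FILE_TYPES = frozenset({"Snapshot", "Transactional"})
EVENT_TYPES = frozenset({"Scheduled", "Unscheduled", "Common"})
YES_NO = frozenset({"Yes", "No"})


@dataclass(slots=True)
class TranslatedText:
    """Display text with an optional RFC 3066 language tag (xml:lang)."""

    text: str
    lang: str | None = None


@dataclass(slots=True)
class CodeListItem:
    coded_value: str
    decode: TranslatedText


@dataclass(slots=True)
class CodeList:
    """Permissible coded values of an item and their decodes."""

    oid: str
    name: str
    datatype: str
    items: list[CodeListItem] = field(default_factory=list)


@dataclass(slots=True)
class ItemDef:
    """Definition of a single data element (one eCRF field)."""

    oid: str
    name: str
    datatype: str
    length: int | None = None
    significant_digits: int | None = None
    question: TranslatedText | None = None
    description: TranslatedText | None = None
    codelist_oid: str | None = None


@dataclass(slots=True)
class Ref:
    """Ordered reference from a parent definition to a child definition."""

    oid: str
    order_number: int
    mandatory: str = "No"


@dataclass(slots=True)
class ItemGroupDef:
    oid: str
    name: str
    repeating: str = "No"
    item_refs: list[Ref] = field(default_factory=list)


@dataclass(slots=True)
class FormDef:
    oid: str
    name: str
    repeating: str = "No"
    itemgroup_refs: list[Ref] = field(default_factory=list)


@dataclass(slots=True)
class StudyEventDef:
    oid: str
    name: str
    repeating: str = "No"
    type: str = "Scheduled"
    form_refs: list[Ref] = field(default_factory=list)


@dataclass(slots=True)
class Protocol:
    studyevent_refs: list[Ref] = field(default_factory=list)


@dataclass(slots=True)
class MetaDataVersion:
    oid: str
    name: str
    protocol: Protocol = field(default_factory=Protocol)
    studyevent_defs: list[StudyEventDef] = field(default_factory=list)
    form_defs: list[FormDef] = field(default_factory=list)
    itemgroup_defs: list[ItemGroupDef] = field(default_factory=list)
    item_defs: list[ItemDef] = field(default_factory=list)
    code_lists: list[CodeList] = field(default_factory=list)


@dataclass(slots=True)
class Study:
    oid: str
    study_name: str
    study_description: str = ""
    protocol_name: str = ""
    metadata_versions: list[MetaDataVersion] = field(default_factory=list)


@dataclass(slots=True)
class ItemData:
    item_oid: str
    value: str


@dataclass(slots=True)
class ItemGroupData:
    itemgroup_oid: str
    items: list[ItemData] = field(default_factory=list)


@dataclass(slots=True)
class FormData:
    form_oid: str
    itemgroups: list[ItemGroupData] = field(default_factory=list)


@dataclass(slots=True)
class StudyEventData:
    studyevent_oid: str
    forms: list[FormData] = field(default_factory=list)


@dataclass(slots=True)
class SubjectData:
    """All captured values of one subject, keyed by SubjectKey."""

    subject_key: str
    events: list[StudyEventData] = field(default_factory=list)


@dataclass(slots=True)
class ClinicalData:
    study_oid: str
    metadata_version_oid: str
    subjects: list[SubjectData] = field(default_factory=list)


@dataclass(slots=True)
class OdmFile:
    """Root of an ODM document: file attributes, studies, optional data."""

    file_oid: str
    creation_datetime: str
    file_type: str = "Snapshot"
    odm_version: str = ODM_VERSION
    granularity: str | None = "All"
    studies: list[Study] = field(default_factory=list)
    clinical_data: ClinicalData | None = None


#: OID classes used by validators and by :func:`collect_oids`.
OID_CLASSES = ("studyevent", "form", "itemgroup", "item", "codelist")


def collect_oids(mdv: MetaDataVersion) -> dict[str, set[str]]:
    """All definition OIDs of a MetaDataVersion, grouped by class.

    Duplicate OIDs within a class collapse under set semantics, so a
    class set smaller than its definition list signals a duplicate.
    """
    return {
        "studyevent": {d.oid for d in mdv.studyevent_defs},
        "form": {d.oid for d in mdv.form_defs},
        "itemgroup": {d.oid for d in mdv.itemgroup_defs},
        "item": {d.oid for d in mdv.item_defs},
        "codelist": {d.oid for d in mdv.code_lists},
    }
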