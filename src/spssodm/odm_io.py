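"""ODM 1.3.1 XML serialization, parsing and semantic validation.

Serialization follows the ODM 1.3.1 element vocabulary and child order;
parsing is its inverse on converter output and warn-and-skips unknown
content so files from other EDC systems still parse usefully.  Two
validators mirror the checks usually done with external ODM tools:
``check_structure`` (required attributes, enumerations, duplicate OIDs,
order numbers) and ``check_referential_integrity`` (every OID reference
resolves against the metadata).  The official ODM XSD is not bundled;
``validate_against_schema`` accepts a user-supplied copy.
"""

from __future__ import annotations

from lxml import etree

from . import odm
from .errors import InputFormatError, OdmStructureError
from .report import Issue, errors_only

NS = odm.ODM_NAMESPACE
XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"

_NSMAP = {None: NS}


def _q(tag: str) -> str:
    return f"{{{NS}}}{tag}"


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _add_text(parent, tag: str, tt: odm.TranslatedText) -> None:
    wrapper = etree.SubElement(parent, _q(tag))
    el = etree.SubElement(wrapper, _q("TranslatedText"))
    if tt.lang is not None:
        el.set(XML_LANG, tt.lang)
    el.text = tt.text


def _add_refs(parent, tag: str, oid_attr: str, refs) -> None:
    for ref in refs:
        etree.SubElement(
            parent,
            _q(tag),
            {
                oid_attr: ref.oid,
                "OrderNumber": str(ref.order_number),
                "Mandatory": ref.mandatory,
            },
        )


def _serialize_mdv(study_el, mdv: odm.MetaDataVersion) -> None:
    mdv_el = etree.SubElement(
        study_el, _q("MetaDataVersion"), {"OID": mdv.oid, "Name": mdv.name}
    )
    protocol_el = etree.SubElement(mdv_el, _q("Protocol"))
    _add_refs(protocol_el, "StudyEventRef", "StudyEventOID",
              mdv.protocol.studyevent_refs)
    for ev in mdv.studyevent_defs:
        ev_el = etree.SubElement(
            mdv_el,
            _q("StudyEventDef"),
            {"OID": ev.oid, "Name": ev.name, "Repeating": ev.repeating,
             "Type": ev.type},
        )
        _add_refs(ev_el, "FormRef", "FormOID", ev.form_refs)
    for form in mdv.form_defs:
        form_el = etree.SubElement(
            mdv_el,
            _q("FormDef"),
            {"OID": form.oid, "Name": form.name, "Repeating": form.repeating},
        )
        _add_refs(form_el, "ItemGroupRef", "ItemGroupOID", form.itemgroup_refs)
    for group in mdv.itemgroup_defs:
        group_el = etree.SubElement(
            mdv_el,
            _q("ItemGroupDef"),
            {"OID": group.oid, "Name": group.name, "Repeating": group.repeating},
        )
        _add_refs(group_el, "ItemRef", "ItemOID", group.item_refs)
    for item in mdv.item_defs:
        attrs = {"OID": item.oid, "Name": item.name, "DataType": item.datatype}
        if item.length is not None:
            attrs["Length"] = str(item.length)
        if item.significant_digits is not None:
            attrs["SignificantDigits"] = str(item.significant_digits)
        item_el = etree.SubElement(mdv_el, _q("ItemDef"), attrs)
        if item.description is not None:
            _add_text(item_el, "Description", item.description)
        if item.question is not None:
            _add_text(item_el, "Question", item.question)
        if item.codelist_oid is not None:
            etree.SubElement(
                item_el, _q("CodeListRef"), {"CodeListOID": item.codelist_oid}
            )
    for cl in mdv.code_lists:
        cl_el = etree.SubElement(
            mdv_el,
            _q("CodeList"),
            {"OID": cl.oid, "Name": cl.name, "DataType": cl.datatype},
        )
        for ci in cl.items:
            ci_el = etree.SubElement(
                cl_el, _q("CodeListItem"), {"CodedValue": ci.coded_value}
            )
            _add_text(ci_el, "Decode", ci.decode)


def _serialize_clinical(root, cd: odm.ClinicalData) -> None:
    cd_el = etree.SubElement(
        root,
        _q("ClinicalData"),
        {"StudyOID": cd.study_oid, "MetaDataVersionOID": cd.metadata_version_oid},
    )
    q_subject = _q("SubjectData")
    q_event = _q("StudyEventData")
    q_form = _q("FormData")
    q_group = _q("ItemGroupData")
    q_item = _q("ItemData")
    for subject in cd.subjects:
        s_el = etree.SubElement(cd_el, q_subject, {"SubjectKey": subject.subject_key})
        for event in subject.events:
            e_el = etree.SubElement(
                s_el, q_event, {"StudyEventOID": event.studyevent_oid}
            )
            for form in event.forms:
                f_el = etree.SubElement(e_el, q_form, {"FormOID": form.form_oid})
                for group in form.itemgroups:
                    g_el = etree.SubElement(
                        f_el, q_group, {"ItemGroupOID": group.itemgroup_oid}
                    )
                    for item in group.items:
                        etree.SubElement(
                            g_el, q_item,
                            {"ItemOID": item.item_oid, "Value": item.value},
                        )


def serialize_odm(odm_file: odm.OdmFile, *, pretty: bool = True) -> str:
    """Serialize the model to ODM 1.3.1 XML (UTF-8, default namespace).

    Structural validity is enforced first; serializing a broken model
    raises with the validator's findings rather than emitting bad XML.
    """
    structure_errors = errors_only(check_structure(odm_file))
    if structure_errors:
        raise OdmStructureError(
            "refusing to serialize: " + "; ".join(map(str, structure_errors))
        )
    attrs = {
        "FileOID": odm_file.file_oid,
        "FileType": odm_file.file_type,
        "CreationDateTime": odm_file.creation_datetime,
        "ODMVersion": odm_file.odm_version,
    }
    if odm_file.granularity is not None:
        attrs["Granularity"] = odm_file.granularity
    root = etree.Element(_q("ODM"), attrs, nsmap=_NSMAP)
    for study in odm_file.studies:
        study_el = etree.SubElement(root, _q("Study"), {"OID": study.oid})
        gv = etree.SubElement(study_el, _q("GlobalVariables"))
        etree.SubElement(gv, _q("StudyName")).text = study.study_name
        etree.SubElement(gv, _q("StudyDescription")).text = study.study_description
        etree.SubElement(gv, _q("ProtocolName")).text = study.protocol_name
        for mdv in study.metadata_versions:
            _serialize_mdv(study_el, mdv)
    if odm_file.clinical_data is not None:
        _serialize_clinical(root, odm_file.clinical_data)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=pretty
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _warn(warnings: list[str] | None, message: str) -> None:
    if warnings is not None:
        warnings.append(message)


def _parse_translated(wrapper, warnings) -> odm.TranslatedText | None:
    tt = wrapper.find(_q("TranslatedText"))
    if tt is None:
        _warn(warnings, f"{etree.QName(wrapper).localname} without TranslatedText")
        return None
    return odm.TranslatedText(text=tt.text or "", lang=tt.get(XML_LANG))


def _parse_refs(parent, tag: str, oid_attr: str, warnings) -> list[odm.Ref]:
    refs = []
    for el in parent.findall(_q(tag)):
        try:
            order = int(el.get("OrderNumber", "0"))
        except ValueError:
            _warn(warnings, f"{tag}: non-integer OrderNumber "
                            f"{el.get('OrderNumber')!r}, using 0")
            order = 0
        refs.append(
            odm.Ref(
                oid=el.get(oid_attr, ""),
                order_number=order,
                mandatory=el.get("Mandatory", "No"),
            )
        )
    return refs


def _opt_int(el, attr: str):
    raw = el.get(attr)
    return None if raw is None else int(raw)


def _parse_mdv(el, warnings) -> odm.MetaDataVersion:
    mdv = odm.MetaDataVersion(oid=el.get("OID", ""), name=el.get("Name", ""))
    protocol_el = el.find(_q("Protocol"))
    if protocol_el is not None:
        mdv.protocol.studyevent_refs = _parse_refs(
            protocol_el, "StudyEventRef", "StudyEventOID", warnings
        )
    for ev_el in el.findall(_q("StudyEventDef")):
        mdv.studyevent_defs.append(
            odm.StudyEventDef(
                oid=ev_el.get("OID", ""),
                name=ev_el.get("Name", ""),
                repeating=ev_el.get("Repeating", "No"),
                type=ev_el.get("Type", "Scheduled"),
                form_refs=_parse_refs(ev_el, "FormRef", "FormOID", warnings),
            )
        )
    for form_el in el.findall(_q("FormDef")):
        mdv.form_defs.append(
            odm.FormDef(
                oid=form_el.get("OID", ""),
                name=form_el.get("Name", ""),
                repeating=form_el.get("Repeating", "No"),
                itemgroup_refs=_parse_refs(
                    form_el, "ItemGroupRef", "ItemGroupOID", warnings
                ),
            )
        )
    for group_el in el.findall(_q("ItemGroupDef")):
        mdv.itemgroup_defs.append(
            odm.ItemGroupDef(
                oid=group_el.get("OID", ""),
                name=group_el.get("Name", ""),
                repeating=group_el.get("Repeating", "No"),
                item_refs=_parse_refs(group_el, "ItemRef", "ItemOID", warnings),
            )
        )
    for item_el in el.findall(_q("ItemDef")):
        question_el = item_el.find(_q("Question"))
        description_el = item_el.find(_q("Description"))
        cl_ref = item_el.find(_q("CodeListRef"))
        mdv.item_defs.append(
            odm.ItemDef(
                oid=item_el.get("OID", ""),
                name=item_el.get("Name", ""),
                datatype=item_el.get("DataType", ""),
                length=_opt_int(item_el, "Length"),
                significant_digits=_opt_int(item_el, "SignificantDigits"),
                question=(
                    _parse_translated(question_el, warnings)
                    if question_el is not None else None
                ),
                description=(
                    _parse_translated(description_el, warnings)
                    if description_el is not None else None
                ),
                codelist_oid=(
                    cl_ref.get("CodeListOID") if cl_ref is not None else None
                ),
            )
        )
    for cl_el in el.findall(_q("CodeList")):
        items = []
        for ci_el in cl_el.findall(_q("CodeListItem")):
            decode_el = ci_el.find(_q("Decode"))
            decode = (
                _parse_translated(decode_el, warnings)
                if decode_el is not None
                else None
            )
            items.append(
                odm.CodeListItem(
                    coded_value=ci_el.get("CodedValue", ""),
                    decode=decode or odm.TranslatedText(text=""),
                )
            )
        mdv.code_lists.append(
            odm.CodeList(
                oid=cl_el.get("OID", ""),
                name=cl_el.get("Name", ""),
                datatype=cl_el.get("DataType", ""),
                items=items,
            )
        )
    return mdv


_KNOWN_MDV_CHILDREN = {
    "Protocol", "StudyEventDef", "FormDef", "ItemGroupDef", "ItemDef", "CodeList",
}


def _parse_clinical(el, warnings) -> odm.ClinicalData:
    cd = odm.ClinicalData(
        study_oid=el.get("StudyOID", ""),
        metadata_version_oid=el.get("MetaDataVersionOID", ""),
    )
    for s_el in el.findall(_q("SubjectData")):
        subject = odm.SubjectData(subject_key=s_el.get("SubjectKey", ""))
        for e_el in s_el.findall(_q("StudyEventData")):
            event = odm.StudyEventData(studyevent_oid=e_el.get("StudyEventOID", ""))
            for f_el in e_el.findall(_q("FormData")):
                form = odm.FormData(form_oid=f_el.get("FormOID", ""))
                for g_el in f_el.findall(_q("ItemGroupData")):
                    group = odm.ItemGroupData(
                        itemgroup_oid=g_el.get("ItemGroupOID", "")
                    )
                    group.items = [
                        odm.ItemData(
                            item_oid=i_el.get("ItemOID", ""),
                            value=i_el.get("Value", ""),
                        )
                        for i_el in g_el.findall(_q("ItemData"))
                    ]
                    form.itemgroups.append(group)
                event.forms.append(form)
            subject.events.append(event)
        cd.subjects.append(subject)
    return cd


def parse_odm(xml: str | bytes, warnings: list[str] | None = None) -> odm.OdmFile:
    """Parse ODM 1.3.1 XML back into the object model.

    Unknown elements are skipped with a warning (appended to the
    optional ``warnings`` list), never silently corrupted.  A file
    without an ODMVersion attribute is assumed to be 1.3.1, with a
    warning.
    """
    data = xml.encode("utf-8") if isinstance(xml, str) else xml
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise InputFormatError(f"malformed XML: {exc}") from exc
    qname = etree.QName(root)
    if qname.namespace != NS or qname.localname != "ODM":
        raise InputFormatError(
            f"not an ODM document: root is {{{qname.namespace}}}{qname.localname}, "
            f"expected {{{NS}}}ODM"
        )
    version = root.get("ODMVersion")
    if version is None:
        _warn(warnings, "file lacks ODMVersion; assuming 1.3.1")
        version = odm.ODM_VERSION
    odm_file = odm.OdmFile(
        file_oid=root.get("FileOID", ""),
        creation_datetime=root.get("CreationDateTime", ""),
        file_type=root.get("FileType", "Snapshot"),
        odm_version=version,
        granularity=root.get("Granularity"),
    )
    for child in root:
        local = etree.QName(child).localname
        if local == "Study":
            study = odm.Study(
                oid=child.get("OID", ""),
                study_name="",
            )
            gv = child.find(_q("GlobalVariables"))
            if gv is not None:
                study.study_name = gv.findtext(_q("StudyName"), default="")
                study.study_description = gv.findtext(
                    _q("StudyDescription"), default=""
                )
                study.protocol_name = gv.findtext(_q("ProtocolName"), default="")
            for mdv_el in child.findall(_q("MetaDataVersion")):
                for sub in mdv_el:
                    if etree.QName(sub).localname not in _KNOWN_MDV_CHILDREN:
                        _warn(
                            warnings,
                            f"skipping unknown MetaDataVersion child "
                            f"<{etree.QName(sub).localname}>",
                        )
                study.metadata_versions.append(_parse_mdv(mdv_el, warnings))
            odm_file.studies.append(study)
        elif local == "ClinicalData":
            if odm_file.clinical_data is not None:
                _warn(warnings, "multiple ClinicalData elements; keeping the first")
                continue
            odm_file.clinical_data = _parse_clinical(child, warnings)
        else:
            _warn(warnings, f"skipping unknown ODM child <{local}>")
    return odm_file


# ---------------------------------------------------------------------------
# Validators
# ---------------------------------------------------------------------------

def _check_required(value, locus: str, what: str, issues: list[Issue]) -> None:
    if not value:
        issues.append(Issue("error", locus, f"missing required {what}"))


def _check_refs_order(refs, locus: str, issues: list[Issue]) -> None:
    last = 0
    for ref in refs:
        _check_required(ref.oid, locus, "ref target OID", issues)
        if ref.order_number <= last:
            issues.append(
                Issue(
                    "error", locus,
                    f"order numbers not strictly increasing "
                    f"({ref.order_number} after {last})",
                )
            )
        last = ref.order_number
        if ref.mandatory not in odm.YES_NO:
            issues.append(
                Issue("error", locus, f"Mandatory must be Yes/No, got "
                                      f"{ref.mandatory!r}")
            )


def _check_duplicates(defs, kind: str, issues: list[Issue]) -> None:
    seen: set[str] = set()
    for d in defs:
        if d.oid in seen:
            issues.append(
                Issue("error", f"{kind} {d.oid}", f"duplicate {kind} OID {d.oid!r}")
            )
        seen.add(d.oid)


def check_structure(odm_file: odm.OdmFile) -> list[Issue]:
    """Structural findings: required attributes, enumerations, duplicate
    OIDs within a class, order-number monotonicity.  Pure; issues are
    data, never exceptions."""
    issues: list[Issue] = []
    _check_required(odm_file.file_oid, "ODM", "FileOID", issues)
    _check_required(odm_file.creation_datetime, "ODM", "CreationDateTime", issues)
    if odm_file.file_type not in odm.FILE_TYPES:
        issues.append(
            Issue("error", "ODM", f"FileType must be Snapshot/Transactional, "
                                  f"got {odm_file.file_type!r}")
        )
    if odm_file.odm_version != odm.ODM_VERSION:
        issues.append(
            Issue("error", "ODM", f"ODMVersion must be {odm.ODM_VERSION}, got "
                                  f"{odm_file.odm_version!r}")
        )
    for study in odm_file.studies:
        _check_required(study.oid, "Study", "OID", issues)
        _check_required(study.study_name, f"Study {study.oid}", "StudyName", issues)
        if not study.metadata_versions:
            issues.append(
                Issue("error", f"Study {study.oid}", "study has no MetaDataVersion")
            )
        for mdv in study.metadata_versions:
            _check_mdv_structure(mdv, issues)
    if odm_file.clinical_data is not None:
        for s, subject in enumerate(odm_file.clinical_data.subjects):
            if not subject.subject_key:
                issues.append(
                    Issue("error", f"SubjectData #{s}", "missing required SubjectKey")
                )
    return issues


def _check_mdv_structure(mdv: odm.MetaDataVersion, issues: list[Issue]) -> None:
    locus = f"MetaDataVersion {mdv.oid}"
    _check_required(mdv.oid, "MetaDataVersion", "OID", issues)
    _check_required(mdv.name, locus, "Name", issues)
    _check_refs_order(mdv.protocol.studyevent_refs, f"{locus}/Protocol", issues)
    for kind, defs in (
        ("StudyEventDef", mdv.studyevent_defs),
        ("FormDef", mdv.form_defs),
        ("ItemGroupDef", mdv.itemgroup_defs),
        ("ItemDef", mdv.item_defs),
        ("CodeList", mdv.code_lists),
    ):
        _check_duplicates(defs, kind, issues)
        for d in defs:
            _check_required(d.oid, kind, "OID", issues)
            _check_required(d.name, f"{kind} {d.oid}", "Name", issues)
    for ev in mdv.studyevent_defs:
        if ev.type not in odm.EVENT_TYPES:
            issues.append(
                Issue("error", f"StudyEventDef {ev.oid}",
                      f"Type must be one of {sorted(odm.EVENT_TYPES)}, got "
                      f"{ev.type!r}")
            )
        if ev.repeating not in odm.YES_NO:
            issues.append(
                Issue("error", f"StudyEventDef {ev.oid}", "Repeating must be Yes/No")
            )
        _check_refs_order(ev.form_refs, f"StudyEventDef {ev.oid}", issues)
    for form in mdv.form_defs:
        if form.repeating not in odm.YES_NO:
            issues.append(
                Issue("error", f"FormDef {form.oid}", "Repeating must be Yes/No")
            )
        _check_refs_order(form.itemgroup_refs, f"FormDef {form.oid}", issues)
    for group in mdv.itemgroup_defs:
        if group.repeating not in odm.YES_NO:
            issues.append(
                Issue("error", f"ItemGroupDef {group.oid}", "Repeating must be Yes/No")
            )
        _check_refs_order(group.item_refs, f"ItemGroupDef {group.oid}", issues)
    for item in mdv.item_defs:
        if item.datatype not in odm.DATATYPES:
            issues.append(
                Issue("error", f"ItemDef {item.oid}",
                      f"DataType {item.datatype!r} outside the supported "
                      f"enumeration")
            )
        if item.significant_digits is not None and item.datatype != "float":
            issues.append(
                Issue("error", f"ItemDef {item.oid}",
                      "SignificantDigits is only meaningful with DataType float")
            )
    for cl in mdv.code_lists:
        if cl.datatype not in odm.DATATYPES:
            issues.append(
                Issue("error", f"CodeList {cl.oid}",
                      f"DataType {cl.datatype!r} outside the supported enumeration")
            )
        seen_values: set[str] = set()
        for ci in cl.items:
            if not ci.coded_value:
                issues.append(
                    Issue("error", f"CodeList {cl.oid}", "empty CodedValue")
                )
            elif ci.coded_value in seen_values:
                issues.append(
                    Issue("error", f"CodeList {cl.oid}",
                          f"duplicate CodedValue {ci.coded_value!r}")
                )
            seen_values.add(ci.coded_value)


def check_referential_integrity(odm_file: odm.OdmFile) -> list[Issue]:
    """Every OID reference must resolve against the emitted metadata.

    Error issues are dangling references (metadata refs, CodeListRefs,
    and every OID used in ClinicalData); unreferenced definitions are
    reported as informational.
    """
    issues: list[Issue] = []
    study_oids = {s.oid for s in odm_file.studies}
    for study in odm_file.studies:
        for mdv in study.metadata_versions:
            _check_mdv_integrity(mdv, issues)

    cd = odm_file.clinical_data
    if cd is None:
        return issues
    if cd.study_oid not in study_oids:
        issues.append(
            Issue("error", "ClinicalData",
                  f"StudyOID {cd.study_oid!r} matches no emitted Study")
        )
        return issues
    study = next(s for s in odm_file.studies if s.oid == cd.study_oid)
    mdv_by_oid = {m.oid: m for m in study.metadata_versions}
    mdv = mdv_by_oid.get(cd.metadata_version_oid)
    if mdv is None:
        issues.append(
            Issue("error", "ClinicalData",
                  f"MetaDataVersionOID {cd.metadata_version_oid!r} matches no "
                  "MetaDataVersion")
        )
        return issues
    oids = odm.collect_oids(mdv)
    dangling: dict[tuple[str, str], int] = {}
    for subject in cd.subjects:
        for event in subject.events:
            if event.studyevent_oid not in oids["studyevent"]:
                dangling[("StudyEventData", event.studyevent_oid)] = (
                    dangling.get(("StudyEventData", event.studyevent_oid), 0) + 1
                )
            for form in event.forms:
                if form.form_oid not in oids["form"]:
                    dangling[("FormData", form.form_oid)] = (
                        dangling.get(("FormData", form.form_oid), 0) + 1
                    )
                for group in form.itemgroups:
                    if group.itemgroup_oid not in oids["itemgroup"]:
                        dangling[("ItemGroupData", group.itemgroup_oid)] = (
                            dangling.get(("ItemGroupData", group.itemgroup_oid), 0)
                            + 1
                        )
                    for item in group.items:
                        if item.item_oid not in oids["item"]:
                            dangling[("ItemData", item.item_oid)] = (
                                dangling.get(("ItemData", item.item_oid), 0) + 1
                            )
    for (kind, oid), count in dangling.items():
        issues.append(
            Issue("error", kind,
                  f"{kind} references undefined OID {oid!r} "
                  f"({count} occurrence{'s' if count > 1 else ''})")
        )
    return issues


def _check_mdv_integrity(mdv: odm.MetaDataVersion, issues: list[Issue]) -> None:
    oids = odm.collect_oids(mdv)
    referenced: dict[str, set[str]] = {k: set() for k in oids}

    def check(refs, cls: str, source: str) -> None:
        for ref in refs:
            referenced[cls].add(ref.oid)
            if ref.oid not in oids[cls]:
                issues.append(
                    Issue("error", source,
                          f"{source} references undefined {cls} OID {ref.oid!r}")
                )

    check(mdv.protocol.studyevent_refs, "studyevent", "Protocol")
    for ev in mdv.studyevent_defs:
        check(ev.form_refs, "form", f"StudyEventDef {ev.oid}")
    for form in mdv.form_defs:
        check(form.itemgroup_refs, "itemgroup", f"FormDef {form.oid}")
    for group in mdv.itemgroup_defs:
        check(group.item_refs, "item", f"ItemGroupDef {group.oid}")
    for item in mdv.item_defs:
        if item.codelist_oid is not None:
            referenced["codelist"].add(item.codelist_oid)
            if item.codelist_oid not in oids["codelist"]:
                issues.append(
                    Issue("error", f"ItemDef {item.oid}",
                          f"CodeListRef to undefined CodeList "
                          f"{item.codelist_oid!r}")
                )
    for cls in ("studyevent", "form", "itemgroup", "item", "codelist"):
        for oid in sorted(oids[cls] - referenced[cls]):
            issues.append(
                Issue("info", f"{cls} {oid}",
                      f"definition {oid!r} is never referenced")
            )


def validate_against_schema(xml: str | bytes, xsd_path) -> list[Issue]:
    """Validate XML against a user-supplied copy of the official ODM XSD.

    The XSD is not bundled with the package; pass the path to a local
    copy.  Returns one error issue per schema violation.
    """
    schema = etree.XMLSchema(etree.parse(str(xsd_path)))
    data = xml.encode("utf-8") if isinstance(xml, str) else xml
    doc = etree.fromstring(data)
    if schema.validate(doc):
        return []
    return [
        Issue("error", f"line {e.line}", e.message) for e in schema.error_log
    ]
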