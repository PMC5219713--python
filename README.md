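# spssodm

Bidirectional converter between SPSS-style statistical datasets and
CDISC ODM 1.3.1 XML.

Clinical registries and pilot studies are often captured in
spreadsheet-style statistics software (an SPSS file is a flat variable
dictionary plus one row of values per case), while regulated electronic
data capture (EDC) systems exchange study definitions and patient data
as CDISC ODM — an XML standard whose metadata is a hierarchy of study
events, forms, item groups and items wired together by referencing
OIDs. Migrating a spreadsheet-based study into an EDC system (or pulling
it back out for analysis) otherwise means rebuilding the database
structure by hand. `spssodm` automates both directions for data
managers and research-IT staff.

## The mapping

Forward (dataset → ODM), per variable:

| SPSS dictionary            | ODM                                        |
|----------------------------|--------------------------------------------|
| variable name (≤ 64 chars) | `ItemOID` (verbatim)                       |
| variable label             | `ItemDef/@Name` and `Question` text        |
| type F*w*.0 / F*w*.*d*     | `integer` / `float` + `Length`, `SignificantDigits` |
| type A*w*                  | `string` (or `text`) + `Length`            |
| DATE/ADATE/EDATE/SDATE/JDATE | `date` (display format dropped)          |
| TIME / DATETIME            | `time` / `datetime`                        |
| COMMA/DOT/DOLLAR/CC/E/PCT  | `float` (grouping/currency display lost)   |
| WKYR/WKDAY/MONTH/MOYR/QYR/DTIME | character fallback (no XML counterpart) |
| value labels               | one `CodeList` (`CL.<name>`) of `CodeListItem`s |
| missing / measure / role / columns / align | dropped, one warning each  |

Since SPSS stores no study structure, items are wrapped in one default
`Protocol → StudyEventDef → FormDef → ItemGroupDef` chain. Cases become
`SubjectData` elements: a designated identifier column (case-sensitive
name) supplies the `SubjectKey` and is not converted as a separate item;
without one, subjects are numbered "1", "2", …. Numeric date cells
(seconds since the SPSS epoch 1582-10-14) are rendered as ISO 8601.
The reverse direction flattens an ODM file back into a dataset,
injecting a subject-key column and applying declared defaults for the
attributes ODM cannot carry.

Binary `.sav` files are read/written through the optional `pyreadstat`
backend (`pip install spssodm[sav]`); a portable dialect — JSON variable
dictionary + RFC 4180 CSV — covers the same content with no binary
dependency and round-trips exactly.

## Worked example

```python
from spssodm.fixtures import make_sample_dataset
from spssodm.spss_io import write_portable

write_portable(make_sample_dataset(), "sample.json", "sample.csv")
```

```
$ spssodm convert sample.json --data --subjectkey PID --lang en \
      --fixed-timestamp 2017-01-07T00:00:00 -o sample_odm.xml
WARNING: sex [dropped_attribute]: user-missing declaration is not represented in ODM ...
WARNING: income [lossy_type]: format COMMA10.2 flattened to the less specific type 'float'; ...
WARNING: visit_date [dropped_display_format]: date display format DATE11 is lost; ...
INFO: converted 15 item definitions, 5 subjects
INFO: wrote sample_odm.xml
```

The sample dataset has 16 variables covering every supported print
format and 5 cases; `PID` becomes the `SubjectKey`, so 15 items remain.
Each warning names one piece of information the XML cannot carry.
An excerpt of the output:

```xml
<ItemDef OID="sex" Name="Sex" DataType="integer" Length="1">
  <Question>
    <TranslatedText xml:lang="en">Sex</TranslatedText>
  </Question>
  <CodeListRef CodeListOID="CL.sex"/>
</ItemDef>
...
<ClinicalData StudyOID="S.1" MetaDataVersionOID="MDV.1">
  <SubjectData SubjectKey="P001">
    ...
    <ItemData ItemOID="weight" Value="62.5"/>
    <ItemData ItemOID="visit_date" Value="2015-03-01"/>
    <ItemData ItemOID="visit_time" Value="09:00:00"/>
```

Back again, and checked:

```
$ spssodm reverse sample_odm.xml -O back --subject-column PID
INFO: reversed 16 variables, 5 cases
$ spssodm validate sample_odm.xml
0 error(s), 0 other finding(s)
```

`spssodm validate` checks structure (required attributes, datatype
enumeration, duplicate OIDs, order numbers) and referential integrity
(every `*Ref` and every OID used in `ClinicalData` must resolve);
`--xsd PATH` additionally validates against a locally supplied copy of
the official ODM 1.3.1 schema, which is not bundled.

The same operations are available as library calls
(`spssodm.convert`, `spssodm.odm_to_dataset`, `spssodm.serialize_odm`,
`spssodm.parse_odm`, …).

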