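# Methods

## The conversion model

`spssodm` treats an SPSS-style file as a flat, ordered variable
dictionary plus rectangular case data, and a CDISC ODM 1.3.1 file as
two OID-linked hierarchies (metadata: Study → MetaDataVersion →
Protocol/StudyEventDef/FormDef/ItemGroupDef/ItemDef/CodeList; data:
SubjectData → StudyEventData → FormData → ItemGroupData → ItemData).
The converter's central assumption is that a flat list can always be
embedded in the hierarchy by supplying one default chain — one
scheduled, non-repeating event ("Default event"), one form, one item
group — and that the embedding is invertible as long as the file keeps
that single-event shape. The converse is deliberately restricted: ODM
files with more than one study event would need several rows per
subject and are refused with the offending event OIDs, as are duplicate
ItemRefs (they would duplicate columns).

One subject per case is likewise an assumption, not a theorem: files
that store follow-up visits as extra rows per patient have duplicate
identifiers, and the converter refuses them by default
(`duplicate_key_policy="error"`); the `"suffix"` policy (".2", ".3", …)
is an explicit opt-in that makes such rows convertible at the cost of
inventing keys.

## Type mapping and its loss classes

Only four ODM value families exist for SPSS's twenty-one print formats,
so the mapping is total but not injective. Three loss classes are
tracked, and every lossy variable produces a categorized warning in the
`ConversionReport`:

* `lossy_type` — grouping/currency/scientific numeric displays
  (COMMA, DOT, DOLLAR, CC, E, PCT) flatten to `float`; values are
  re-rendered as plain decimal literals without separators.
* `dropped_display_format` — the five calendar display formats all map
  to `date` (ODM stores only the XML date form); columns/align are
  display-only and dropped.
* `unmappable_format` / `dropped_attribute` — week/weekday/month-style
  formats fall back to a character type; missing/measure/role have no
  ODM element at all.

User-missing *declarations* are dropped (with a warning), but data
values matching them are exported verbatim: a user-missing code is a
stored value flagged for analysis, and silently filtering it would be
data loss the receiving system could never detect.

Character variables are emitted as DataType `string` by default;
ODM 1.3.1 also defines `text`, and `string_datatype="text"` switches
the emission. Both parse back identically (A format).

## OIDs

Item OIDs are the variable name verbatim (names are unique and ≤ 64
characters, so this is collision-free in practice); codelists get
`CL.<name>`; structural elements use fixed defaults `S.1`, `MDV.1`,
`SE.1`, `F.1`, `IG.1`. Any collision appends `.<k>` with the smallest
positive `k`. Ref order numbers start at 1 and follow dictionary
(column) order; `Mandatory` defaults to `No`, since nothing in a
spreadsheet marks a column as required.

## Dates, times and numbers

Numeric date cells count seconds from the SPSS epoch, 1582-10-14
00:00:00 in the proleptic Gregorian calendar — a fixed property of the
.sav format. Rendering truncates fractional seconds and emits
`YYYY-MM-DD`, `hh:mm:ss` (time-of-day must lie in [0, 86400)) or the
combined `T` form. The test suite cross-checks 1000 seeded values
against an independent era-based civil-calendar computation (days-from-
civil/civil-from-days arithmetic, not the standard library). The
reverse direction parses ISO values back to epoch seconds; a `date`
lands on midnight, which is why round-trip value comparisons for
calendar cells use a 1-second tolerance and the generators emit
day-aligned date values.

Floats are rendered as the shortest decimal literal that round-trips
the double (no exponent below 10^15, integers without a trailing
`.0`), so ODM `Value` strings re-parse to bit-identical doubles.

## Reverse defaults

ODM carries no statistical or display attributes, so the reverse
converter sets declared defaults: `columns=8`, alignment `right` for
numeric and `left` for string variables, and no measure/role/missing.
Datatypes map back as integer→F*w*.0, float→F*w*.*d* (width widened to
`decimals + 2` — one integer digit plus the decimal point — when the
declared decimals would not fit), string/text→A, date→DATE11,
time→TIME8, datetime→DATETIME20; an unknown datatype falls back to
A255 with a warning. The subject-key column is injected first, A format,
width = longest key but at least 8.

## Portable dialect

The binary .sav reader/writer is an optional backend (pyreadstat); all
structural testing runs on a portable dialect instead: a JSON variable
dictionary plus an RFC 4180 CSV data file (comma, double-quote, UTF-8,
mandatory header — pinned to avoid locale drift). An empty CSV cell is
system-missing for numeric variables and the empty string for A
variables; consequently system-missing inside a *string* variable has
no portable representation, and the fixture generators never produce
it (they use empty strings). Numeric cells are written with the same
shortest-round-trip rendering, so the portable round-trip is exact.

## Synthetic data

Real registry exports cannot be redistributed, so two generators stand
in:

* `make_sample_dataset()` — deterministic, 16 variables covering every
  supported format family, a `PID` identifier, value labels, a
  user-missing declaration, 5 cases with one system-missing cell. This
  mirrors the shape of a typical "all data types" interchange test
  file.
* `make_random_dataset(n_vars, n_cases, seed)` — seeded; ~20% of
  variables carry value labels, ~10% a user-missing declaration, ~5% of
  numeric cells are system-missing; every format code is reachable.
  `mappable_only=True` restricts the pool to formats whose
  forward/reverse composition is the identity on format class, width
  and decimals (A, F, DATE11, TIME8, DATETIME20); `key_column` prepends
  a unique string identifier.

What the generators do **not** emulate: real variable-name conventions
and encodings, multi-row-per-patient layouts, long-string variables,
and any clinical plausibility of values. Passing tests therefore
demonstrate structural and numerical correctness of the mapping, not
robustness against every artefact of production registry files.

## Problem sizes and numerics

The round-trip and validator suites run over a 200-dataset seeded
corpus (1–15 variables, 0–15 cases each) — small enough to exercise
every format/label/missing combination many times while keeping the
suite fast. The scale check runs once at 645 variables × 3452 cases,
the largest registry shape the converter is sized for (~2.2 M cells,
~120 MB of XML, ~2.3 GB peak memory end-to-end). Validators are pure
functions returning issue records (never exceptions) and are
order-insensitive over sibling definitions; serialization refuses a
model that fails the structural validator rather than emitting bad XML.

## Known limitations

* Multi-event / repeating ODM structures do not reverse (by design).
* .sav support needs pyreadstat; without it the portable dialect is the
  only file interface, and sav-specific fidelity (e.g. long strings,
  encodings) is untested.
* The official ODM XSD is not bundled (licensing); `--xsd` accepts a
  local copy, and the built-in structural validator covers the elements
  this package emits.
* AdminData, ReferenceData, Association, signatures, audit records and
  measurement units are out of scope.
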