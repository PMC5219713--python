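"""Neutral in-memory model of an SPSS-style dataset.

An SPSS system file is a flat table: an ordered variable dictionary
(name, print format, labels, value labels, missing-value declarations
and display/statistical attributes) plus rectangular case data, one row
per case.  This module models that structure independently of any binary
reader so the rest of the package never touches .sav internals.

Cells are doubles, text strings, or the system-missing sentinel
:data:`SYSMIS`.  System-missing is a dedicated sentinel object — never a
magic number — and is distinct from the empty string and from every
float.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .report import Issue


class _SysMis:
    """Singleton sentinel for SPSS system-missing."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "SYSMIS"

    def __reduce__(self):  # keeps the singleton under pickling
        return (_SysMis, ())


SYSMIS = _SysMis()

#: A cell value: float, str, or the system-missing sentinel.
Cell = float | str | _SysMis


# ---------------------------------------------------------------------------
# Print formats
# ---------------------------------------------------------------------------

#: All supported SPSS print-format codes.
FORMAT_CODES = frozenset(
    {
        "F", "A", "COMMA", "DOT", "DOLLAR", "CC", "E", "PCT",
        "DATE", "ADATE", "EDATE", "SDATE", "JDATE",
        "TIME", "DTIME", "DATETIME",
        "WKYR", "WKDAY", "MONTH", "MOYR", "QYR",
    }
)

#: Codes on which a decimals component is meaningful.
DECIMAL_CODES = frozenset(
    {"F", "COMMA", "DOT", "DOLLAR", "CC", "E", "PCT", "TIME", "DTIME", "DATETIME"}
)

#: Calendar-date display formats (cells hold seconds since the SPSS epoch).
DATE_CODES = frozenset({"DATE", "ADATE", "EDATE", "SDATE", "JDATE"})

#: Plain numeric display formats (grouping/currency variants included).
NUMERIC_CODES = frozenset({"F", "COMMA", "DOT", "DOLLAR", "CC", "E", "PCT"})


@dataclass(frozen=True, slots=True)
class FormatSpec:
    """An SPSS print format: type code, display width, decimal places."""

    code: str
    width: int
    decimals: int = 0

    def __post_init__(self):
        if self.code not in FORMAT_CODES:
            raise ValueError(f"unknown format code {self.code!r}")
        if self.width < 1:
            raise ValueError(f"format width must be >= 1, got {self.width}")
        if self.decimals < 0:
            raise ValueError(f"decimals must be >= 0, got {self.decimals}")
        if self.decimals and self.code not in DECIMAL_CODES:
            raise ValueError(f"format {self.code} does not take decimals")
        if self.decimals >= self.width:
            raise ValueError(
                f"decimals ({self.decimals}) must be < width ({self.width})"
            )

    @property
    def is_string(self) -> bool:
        return self.code == "A"

    def __str__(self) -> str:
        if self.code in DECIMAL_CODES and self.decimals:
            return f"{self.code}{self.width}.{self.decimals}"
        return f"{self.code}{self.width}"

    @classmethod
    def parse(cls, text: str) -> "FormatSpec":
        """Parse a compact format string such as ``F8.2``, ``A10``, ``DATE11``."""
        m = re.fullmatch(r"([A-Z]+)(\d+)(?:\.(\d+))?", text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse format spec {text!r}")
        code, width, dec = m.group(1), int(m.group(2)), int(m.group(3) or 0)
        return cls(code, width, dec)


@dataclass(frozen=True, slots=True)
class MissingSpec:
    """SPSS user-missing declaration.

    Either up to three discrete values, or one low–high range plus at
    most one discrete value.  User-missing codes remain stored values;
    they are only *flagged* as missing for analysis.
    """

    values: tuple = ()
    range: tuple | None = None  # (low, high)

    def __post_init__(self):
        if self.range is None:
            if len(self.values) > 3:
                raise ValueError("at most 3 discrete user-missing values")
        else:
            if len(self.range) != 2:
                raise ValueError("missing range must be (low, high)")
            if len(self.values) > 1:
                raise ValueError("at most 1 discrete value alongside a range")


# SPSS variable-name rules: start with a letter or @ # $, then letters,
# digits, period, underscore, @ # $; no whitespace; at most 64 bytes.
MAX_NAME_LENGTH = 64
_NAME_RE = re.compile(r"[A-Za-z@#$][A-Za-z0-9._@#$]*\Z")

MEASURE_LEVELS = frozenset({"nominal", "ordinal", "scale"})
ROLES = frozenset({"input", "target", "both", "none", "partition", "split"})
ALIGNMENTS = frozenset({"left", "right", "center"})


def valid_variable_name(name: str) -> bool:
    return 0 < len(name) <= MAX_NAME_LENGTH and _NAME_RE.fullmatch(name) is not None


@dataclass(slots=True)
class VariableDef:
    """One SPSS variable with its print format and attributes.

    ``value_labels`` preserves dictionary order (insertion order of the
    mapping); keys are floats for numeric formats and strings for A.
    Statistical/display attributes (missing, measure, role, columns,
    align) are stored for fidelity even though ODM has no counterpart
    for them, so round-trip loss stays measurable.
    """

    name: str
    format: FormatSpec
    label: str | None = None
    value_labels: dict = field(default_factory=dict)
    missing: MissingSpec | None = None
    measure: str | None = None
    role: str | None = None
    columns: int | None = None
    align: str | None = None

    @property
    def is_string(self) -> bool:
        return self.format.is_string


@dataclass(slots=True)
class Dataset:
    """Ordered variable dictionary plus rectangular case rows."""

    source_name: str
    variables: list[VariableDef] = field(default_factory=list)
    cases: list[list[Cell]] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_cases(self) -> int:
        return len(self.cases)


def find_variable(ds: Dataset, name: str) -> int | None:
    """Index of the variable whose name equals ``name`` case-SENSITIVELY.

    Subject-identifier lookup is deliberately case-sensitive: ``PID`` and
    ``pid`` are different dictionary entries even though SPSS forbids
    both coexisting.
    """
    for i, v in enumerate(ds.variables):
        if v.name == name:
            return i
    return None


def _check_variable(i: int, var: VariableDef, issues: list[Issue]) -> None:
    name = var.name
    locus = name or f"variable #{i}"
    if not name:
        issues.append(Issue("error", locus, "variable name is empty"))
        return
    if len(name) > MAX_NAME_LENGTH:
        issues.append(
            Issue(
                "error",
                locus,
                f"variable name exceeds the {MAX_NAME_LENGTH}-character bound "
                f"({len(name)} characters)",
            )
        )
    if any(c.isspace() for c in name):
        issues.append(Issue("error", locus, "variable name contains whitespace"))
    elif not _NAME_RE.fullmatch(name[:MAX_NAME_LENGTH]):
        issues.append(
            Issue(
                "error",
                locus,
                "variable name must start with a letter or @ # $ and contain "
                "only letters, digits, and . _ @ # $",
            )
        )
    if var.measure is not None and var.measure not in MEASURE_LEVELS:
        issues.append(Issue("error", locus, f"unknown measure {var.measure!r}"))
    if var.role is not None and var.role not in ROLES:
        issues.append(Issue("error", locus, f"unknown role {var.role!r}"))
    if var.align is not None and var.align not in ALIGNMENTS:
        issues.append(Issue("error", locus, f"unknown alignment {var.align!r}"))
    if var.columns is not None and var.columns < 1:
        issues.append(Issue("error", locus, "columns must be a positive integer"))
    want_str = var.is_string
    for key in var.value_labels:
        if want_str and not isinstance(key, str):
            issues.append(
                Issue("error", locus, f"value-label key {key!r} must be a string "
                                      "under an A format")
            )
        elif not want_str and not isinstance(key, (int, float)):
            issues.append(
                Issue("error", locus, f"value-label key {key!r} must be numeric "
                                      f"under format {var.format}")
            )
    if var.missing is not None and want_str and var.missing.range is not None:
        issues.append(
            Issue("error", locus, "string variables cannot declare a missing range")
        )


def validate_dataset(ds: Dataset) -> list[Issue]:
    """Check every structural invariant; issues are data, not exceptions.

    Returns an empty list iff the dataset is valid.  Never mutates the
    dataset.  A valid empty dataset (0 variables, 0 cases) yields no
    issues.
    """
    issues: list[Issue] = []
    seen_lower: dict[str, str] = {}
    for i, var in enumerate(ds.variables):
        _check_variable(i, var, issues)
        low = var.name.lower()
        if low in seen_lower:
            issues.append(
                Issue(
                    "error",
                    var.name,
                    f"variable name collides case-insensitively with "
                    f"{seen_lower[low]!r}",
                )
            )
        else:
            seen_lower[low] = var.name

    n = len(ds.variables)
    for r, row in enumerate(ds.cases):
        if len(row) != n:
            issues.append(
                Issue(
                    "error",
                    f"row {r}",
                    f"row has {len(row)} cells but the dictionary defines "
                    f"{n} variables",
                )
            )
            continue
        for var, cell in zip(ds.variables, row):
            if cell is SYSMIS:
                continue
            if var.is_string:
                if not isinstance(cell, str):
                    issues.append(
                        Issue(
                            "error",
                            f"row {r}",
                            f"variable {var.name!r} is a string (A) variable "
                            f"but holds {cell!r}",
                        )
                    )
            else:
                if not isinstance(cell, (int, float)):
                    issues.append(
                        Issue(
                            "error",
                            f"row {r}",
                            f"variable {var.name!r} is numeric ({var.format}) "
                            f"but holds {cell!r}",
                        )
                    )
    return issues
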