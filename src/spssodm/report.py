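"""Issue and warning records shared by validators and converters."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, slots=True)
class Issue:
    """One finding from a validator.

    severity is "error", "warning" or "info"; locus names the variable,
    row, OID or element the finding refers to.
    """

    severity: str
    locus: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.locus}: {self.message}"


def errors_only(issues) -> list[Issue]:
    return [i for i in issues if i.severity == "error"]


# Warning categories used by the forward converter. SPSS attributes that
# have no ODM counterpart are dropped with one warning each so that the
# information loss of a conversion is enumerable.
LOSSY_TYPE = "lossy_type"
DROPPED_ATTRIBUTE = "dropped_attribute"
UNMAPPABLE_FORMAT = "unmappable_format"
DROPPED_DISPLAY_FORMAT = "dropped_display_format"

WARNING_CATEGORIES = frozenset(
    {LOSSY_TYPE, DROPPED_ATTRIBUTE, UNMAPPABLE_FORMAT, DROPPED_DISPLAY_FORMAT}
)


@dataclass(frozen=True, slots=True)
class ConversionWarning:
    variable: str
    category: str
    message: str

    def __post_init__(self):
        if self.category not in WARNING_CATEGORIES:
            raise ValueError(f"unknown warning category {self.category!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.variable} [{self.category}]: {self.message}"


@dataclass(slots=True)
class ConversionReport:
    """What a conversion dropped or approximated, plus the OID registry.

    ``oid_registry`` maps each source base name (variable name, or a
    structural kind) to the OID that was minted for it.
    """

    warnings: list[ConversionWarning] = field(default_factory=list)
    oid_registry: dict[str, str] = field(default_factory=dict)

    def warn(self, variable: str, category: str, message: str) -> None:
        self.warnings.append(ConversionWarning(variable, category, message))

    def by_category(self, category: str) -> list[ConversionWarning]:
        return [w for w in self.warnings if w.category == category]
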