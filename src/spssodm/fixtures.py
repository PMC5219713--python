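"""Synthetic dataset generators.

Real clinical registry files cannot be redistributed, so tests run on
two generators instead: a deterministic 16-variable / 5-case sample
covering every supported print-format family (the shape of a typical
"all data types" test file), and a seeded random generator that scales
up to registry dimensions (hundreds of variables, thousands of cases).

Generated datasets always pass ``validate_dataset``.  System-missing is
only placed in numeric columns — string columns use the empty string —
because the portable CSV dialect cannot distinguish the two for A
variables.
"""

from __future__ import annotations

import random
import string
from datetime import datetime

from .dataset import SYSMIS, Dataset, FormatSpec, MissingSpec, VariableDef
from .forward import SPSS_EPOCH

_DAY = 86400.0


def _epoch_seconds(year: int, month: int, day: int,
                   hour: int = 0, minute: int = 0, second: int = 0) -> float:
    return (datetime(year, month, day, hour, minute, second)
            - SPSS_EPOCH).total_seconds()


def make_sample_dataset() -> Dataset:
    """Deterministic sample: 16 variables covering all format families,
    5 cases, a PID identifier column, value labels, a user-missing
    declaration and one system-missing cell."""
    variables = [
        VariableDef("PID", FormatSpec("A", 5), label="Patient identifier"),
        VariableDef(
            "sex", FormatSpec("F", 1), label="Sex",
            value_labels={1.0: "male", 2.0: "female"},
            missing=MissingSpec(values=(9.0,)),
            measure="nominal",
        ),
        VariableDef("weight", FormatSpec("F", 6, 2), label="Body weight (kg)",
                    measure="scale", role="input"),
        VariableDef("income", FormatSpec("COMMA", 10, 2), label="Yearly income"),
        VariableDef("ratio", FormatSpec("DOT", 9, 2), label="Waist-hip ratio"),
        VariableDef("cost", FormatSpec("DOLLAR", 10, 2), label="Treatment cost"),
        VariableDef("titer", FormatSpec("E", 10, 3), label="Antibody titer"),
        VariableDef("visit_date", FormatSpec("DATE", 11), label="Visit date"),
        VariableDef("birth_date", FormatSpec("ADATE", 10), label="Date of birth"),
        VariableDef("entry_date", FormatSpec("EDATE", 10), label="Study entry"),
        VariableDef("exit_date", FormatSpec("SDATE", 10), label="Study exit"),
        VariableDef("julian_day", FormatSpec("JDATE", 7), label="Julian day"),
        VariableDef("visit_time", FormatSpec("TIME", 8), label="Visit time"),
        VariableDef("admission", FormatSpec("DATETIME", 20), label="Admission"),
        VariableDef("study_week", FormatSpec("WKYR", 10), label="Study week"),
        VariableDef("weekday", FormatSpec("WKDAY", 9), label="Day of week"),
    ]
    rows = []
    for i in range(5):
        rows.append([
            f"P{i + 1:03d}",                                   # PID
            float(1 + i % 2),                                  # sex
            62.5 + 3.25 * i if i != 2 else SYSMIS,             # weight (one sysmis)
            42000.0 + 1234.56 * i,                             # income
            0.8 + 0.01 * i,                                    # ratio
            199.99 + 50.0 * i,                                 # cost
            1.5e-3 * (i + 1),                                  # titer
            _epoch_seconds(2015, 3, 1) + i * _DAY,             # visit_date
            _epoch_seconds(1970 + 5 * i, 7, 14),               # birth_date
            _epoch_seconds(2014, 12, 24) + i * _DAY,           # entry_date
            _epoch_seconds(2016, 1, 31) + i * _DAY,            # exit_date
            _epoch_seconds(2015, 1, 1) + i * _DAY,             # julian_day
            float(3600 * 9 + 1800 * i),                        # visit_time
            _epoch_seconds(2015, 3, 1, 8, 30) + i * 3600,      # admission
            _epoch_seconds(2015, 2, 2) + i * 7 * _DAY,         # study_week
            _epoch_seconds(2015, 3, 2) + i * _DAY,             # weekday
        ])
    return Dataset(source_name="sample.sav", variables=variables, cases=rows)


# Format pool for the random generator.  The "mappable" subset is the
# one whose forward/reverse composition is the identity on format class,
# width and decimals (A, F, and the canonical DATE11/TIME8/DATETIME20).
_ALL_CODES = [
    "A", "F", "F", "COMMA", "DOT", "DOLLAR", "CC", "E", "PCT",
    "DATE", "ADATE", "EDATE", "SDATE", "JDATE",
    "TIME", "DTIME", "DATETIME", "WKYR", "WKDAY", "MONTH", "MOYR", "QYR",
]
_MAPPABLE_CODES = ["A", "F", "F", "DATE", "TIME", "DATETIME"]


def _random_word(rng: random.Random, lo: int = 3, hi: int = 12) -> str:
    n = rng.randint(lo, hi)
    return "".join(rng.choice(string.ascii_lowercase) for _ in range(n))


def _random_format(rng: random.Random, code: str) -> FormatSpec:
    if code == "A":
        return FormatSpec("A", rng.randint(1, 32))
    if code == "F":
        dec = rng.choice([0, 0, 1, 2, 3])
        return FormatSpec("F", rng.randint(dec + 1, dec + 10), dec)
    if code in ("COMMA", "DOT", "DOLLAR", "CC", "E", "PCT"):
        dec = rng.choice([0, 2])
        return FormatSpec(code, rng.randint(dec + 4, dec + 12), dec)
    if code == "DATE":
        return FormatSpec("DATE", 11)
    if code == "TIME":
        return FormatSpec("TIME", 8)
    if code == "DATETIME":
        return FormatSpec("DATETIME", 20)
    widths = {"ADATE": 10, "EDATE": 10, "SDATE": 10, "JDATE": 7, "DTIME": 13,
              "WKYR": 10, "WKDAY": 9, "MONTH": 3, "MOYR": 8, "QYR": 8}
    return FormatSpec(code, widths[code])


def _random_cell(rng: random.Random, fmt: FormatSpec):
    code = fmt.code
    if code == "A":
        if rng.random() < 0.05:
            return ""
        return _random_word(rng, 1, min(fmt.width, 12))
    if code == "F" and fmt.decimals == 0:
        return float(rng.randint(-10 ** min(fmt.width - 1, 6), 10 ** min(fmt.width - 1, 6)))
    if code in ("F", "COMMA", "DOT", "DOLLAR", "CC", "E", "PCT"):
        return rng.random() * 10 ** rng.randint(0, 4)
    if code == "TIME":
        return float(rng.randint(0, 86399))
    if code == "DTIME":
        return float(rng.randint(0, 86400 * 40))
    # calendar values: day-aligned for date display formats so the
    # XML date (no time-of-day) is exact; integral seconds otherwise
    days = rng.randint(116_000, 189_000)  # roughly years 1900–2100
    if code == "DATETIME":
        return days * _DAY + rng.randint(0, 86399)
    return days * _DAY


def make_random_dataset(
    n_vars: int,
    n_cases: int,
    seed: int,
    *,
    mappable_only: bool = False,
    key_column: str | None = None,
) -> Dataset:
    """Seeded, reproducible random dataset.

    About 20% of variables carry value labels, 10% a user-missing
    declaration; about 5% of numeric cells are system-missing.  With
    ``mappable_only`` the format pool is restricted to formats whose
    forward/reverse mapping composition is lossless.  ``key_column``
    prepends a string identifier variable with unique keys (named as
    given), counted inside ``n_vars``.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    rng = random.Random(seed)
    pool = _MAPPABLE_CODES if mappable_only else _ALL_CODES

    variables: list[VariableDef] = []
    used = set()
    if key_column is not None:
        variables.append(
            VariableDef(key_column, FormatSpec("A", 8))
        )
        used.add(key_column.lower())
    while len(variables) < n_vars:
        name = f"{_random_word(rng)}_{len(variables):03d}"
        if name.lower() in used:
            continue
        used.add(name.lower())
        fmt = _random_format(rng, rng.choice(pool))
        labels = {}
        if rng.random() < 0.20:
            n_labels = rng.randint(2, 5)
            if fmt.is_string:
                labels = {
                    _random_word(rng, 1, min(fmt.width, 8)): _random_word(rng)
                    for _ in range(n_labels)
                }
            else:
                labels = {
                    float(k): _random_word(rng)
                    for k in rng.sample(range(1, 50), n_labels)
                }
        missing = None
        if not fmt.is_string and rng.random() < 0.10:
            missing = MissingSpec(values=(float(rng.choice([9, 99, 999])),))
        variables.append(
            VariableDef(
                name=name,
                label=_random_word(rng, 4, 20).capitalize()
                      if (mappable_only or rng.random() < 0.8) else None,
                format=fmt,
                value_labels=labels,
                missing=missing,
                measure=rng.choice([None, "nominal", "ordinal", "scale"]),
                role=rng.choice([None, None, "input", "target"]),
                columns=rng.choice([None, 8, 10, 12]),
                align=rng.choice([None, "left", "right", "center"]),
            )
        )

    ds = Dataset(source_name=f"random_{seed}.sav", variables=variables)
    for r in range(n_cases):
        row = []
        for j, var in enumerate(variables):
            if key_column is not None and j == 0:
                row.append(f"K{r + 1:05d}")
                continue
            if not var.is_string and rng.random() < 0.05:
                row.append(SYSMIS)
            else:
                row.append(_random_cell(rng, var.format))
        ds.cases.append(row)
    return ds
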