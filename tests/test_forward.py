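"""Forward conversion: type mapping, OIDs, dates, values, subjects."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spssodm.dataset import SYSMIS, Dataset, FormatSpec, MissingSpec, VariableDef
from spssodm.errors import ConversionError, LanguageTagError, SubjectKeyError
from spssodm.forward import (
    ConvertOptions,
    OidRegistry,
    build_metadata,
    convert,
    convert_value,
    extract_subject_keys,
    make_oid,
    map_format_to_datatype,
    spss_seconds_to_iso,
    validate_lang,
)
from spssodm.report import DROPPED_ATTRIBUTE


def _f(code, width, dec=0):
    return FormatSpec(code, width, dec)


class TestFormatMapping:
    @pytest.mark.parametrize(
        "fmt,expected",
        [
            (("A", 10), ("string", 10, None, False)),
            (("F", 8), ("integer", 8, None, False)),
            (("F", 8, 2), ("float", 8, 2, False)),
            (("COMMA", 10, 2), ("float", 10, 2, True)),
            (("DOT", 12, 2), ("float", 12, 2, True)),
            (("DOLLAR", 10, 2), ("float", 10, 2, True)),
            (("CC", 10, 2), ("float", 10, 2, True)),
            (("E", 10, 3), ("float", 10, 3, True)),
            (("PCT", 6, 1), ("float", 6, 1, True)),
            (("DATE", 11), ("date", None, None, True)),
            (("ADATE", 10), ("date", None, None, True)),
            (("EDATE", 10), ("date", None, None, True)),
            (("SDATE", 10), ("date", None, None, True)),
            (("JDATE", 7), ("date", None, None, True)),
            (("TIME", 8), ("time", None, None, False)),
            (("DATETIME", 20), ("datetime", None, None, False)),
            (("DTIME", 13), ("string", 13, None, True)),
            (("WKYR", 10), ("string", 10, None, True)),
            (("WKDAY", 9), ("string", 9, None, True)),
            (("MONTH", 3), ("string", 3, None, True)),
            (("MOYR", 8), ("string", 8, None, True)),
            (("QYR", 8), ("string", 8, None, True)),
        ],
    )
    def test_total_mapping_table(self, fmt, expected):
        assert map_format_to_datatype(_f(*fmt)) == expected

    def test_text_option_switches_character_type(self):
        opts = ConvertOptions(string_datatype="text")
        assert map_format_to_datatype(_f("A", 5), opts)[0] == "text"
        assert map_format_to_datatype(_f("WKYR", 10), opts)[0] == "text"
        # numeric mapping unaffected
        assert map_format_to_datatype(_f("F", 8), opts)[0] == "integer"


class TestMakeOid:
    def test_item_oid_is_name_verbatim(self):
        assert make_oid("item", "age", OidRegistry()) == "age"

    def test_codelist_oid_prefixed(self):
        assert make_oid("codelist", "sex", OidRegistry()) == "CL.sex"

    def test_collision_appends_smallest_suffix(self):
        reg = OidRegistry()
        assert make_oid("item", "age", reg) == "age"
        assert make_oid("item", "age", reg) == "age.1"
        assert make_oid("item", "age", reg) == "age.2"

    def test_structural_defaults(self):
        reg = OidRegistry()
        assert make_oid("study", "whatever", reg) == "S.1"
        assert make_oid("mdv", "whatever", reg) == "MDV.1"
        assert make_oid("event", "x", reg) == "SE.1"
        assert make_oid("form", "x", reg) == "F.1"
        assert make_oid("itemgroup", "x", reg) == "IG.1"


def _days_from_civil(y, m, d):
    """Independent proleptic-Gregorian day count (era arithmetic)."""
    y -= m <= 2
    era = (y if y >= 0 else y - 399) // 400
    yoe = y - era * 400
    doy = (153 * (m + (-3 if m > 2 else 9)) + 2) // 5 + d - 1
    doe = yoe * 365 + yoe // 4 - yoe // 100 + doy
    return era * 146097 + doe


def _civil_from_days(z):
    era = (z if z >= 0 else z - 146096) // 146097
    doe = z - era * 146097
    yoe = (doe - doe // 1460 + doe // 36524 - doe // 146096) // 365
    y = yoe + era * 400
    doy = doe - (365 * yoe + yoe // 4 - yoe // 100)
    mp = (5 * doy + 2) // 153
    d = doy - (153 * mp + 2) // 5 + 1
    m = mp + (3 if mp < 10 else -9)
    return y + (m <= 2), m, d


_EPOCH_DAYS = _days_from_civil(1582, 10, 14)


class TestDates:
    def test_epoch_renders_first_gregorian_day(self):
        assert spss_seconds_to_iso(0, "date") == "1582-10-14"

    def test_one_day_after_epoch(self):
        assert spss_seconds_to_iso(86400, "date") == "1582-10-15"

    @pytest.mark.parametrize(
        "seconds,expected",
        [(0, "00:00:00"), (3661, "01:01:01"), (86399, "23:59:59")],
    )
    def test_time_of_day(self, seconds, expected):
        assert spss_seconds_to_iso(seconds, "time") == expected

    def test_time_out_of_range_rejected(self):
        with pytest.raises(ConversionError):
            spss_seconds_to_iso(86400, "time")
        with pytest.raises(ConversionError):
            spss_seconds_to_iso(-1, "time")

    def test_fractional_seconds_truncated(self):
        assert spss_seconds_to_iso(3661.9, "time") == "01:01:01"

    def test_datetime_rendering(self):
        # 2 days + 1h 2m 3s past the epoch
        s = 2 * 86400 + 3723
        assert spss_seconds_to_iso(s, "datetime") == "1582-10-16T01:02:03"

    def test_agrees_with_independent_calendar_arithmetic(self):
        """1000 seeded epoch-second values vs era-based civil arithmetic."""
        import random

        rng = random.Random(20170107)
        lo = (_days_from_civil(1900, 1, 1) - _EPOCH_DAYS) * 86400
        hi = (_days_from_civil(2100, 12, 31) - _EPOCH_DAYS) * 86400
        for _ in range(1000):
            s = rng.randint(lo, hi)
            y, m, d = _civil_from_days(_EPOCH_DAYS + s // 86400)
            assert spss_seconds_to_iso(s, "date") == f"{y:04d}-{m:02d}-{d:02d}"
            r = s % 86400
            expected_dt = (
                f"{y:04d}-{m:02d}-{d:02d}"
                f"T{r // 3600:02d}:{r % 3600 // 60:02d}:{r % 60:02d}"
            )
            assert spss_seconds_to_iso(s, "datetime") == expected_dt


class TestConvertValue:
    def test_integer_minimal_literal(self):
        assert convert_value(42.0, _f("F", 8), "integer") == "42"

    def test_sysmis_emits_nothing(self):
        assert convert_value(SYSMIS, _f("F", 8, 2), "float") is None

    def test_float_shortest_roundtrip(self):
        rendered = convert_value(0.1, _f("F", 8, 2), "float")
        assert rendered == "0.1"
        assert float(rendered) == 0.1

    def test_no_grouping_separators_for_dot_comma(self):
        rendered = convert_value(1234567.5, _f("DOT", 12, 2), "float")
        assert rendered == "1234567.5"
        rendered = convert_value(1234567.0, _f("COMMA", 12), "float")
        assert rendered == "1234567"

    def test_no_exponent_below_1e15(self):
        rendered = convert_value(1e-7, _f("E", 10, 3), "float")
        assert "e" not in rendered.lower()
        assert float(rendered) == 1e-7

    def test_string_verbatim(self):
        assert convert_value("ab c", _f("A", 8), "string") == "ab c"

    def test_numeric_under_string_fallback(self):
        assert convert_value(7.0, _f("WKYR", 10), "string") == "7"

    def test_user_missing_codes_exported_verbatim(self):
        # user-missing is an analysis flag, not absent data
        assert convert_value(999.0, _f("F", 8), "integer") == "999"


class TestLanguageTags:
    @pytest.mark.parametrize("code", ["en", "de-DE", "x-klingon", "zh-Hant-TW"])
    def test_well_formed_accepted(self, code):
        assert validate_lang(code) == code

    @pytest.mark.parametrize(
        "code", ["english language", "", "-en", "en-", "a" * 9, "en--US", "d e"]
    )
    def test_malformed_rejected_with_code(self, code):
        with pytest.raises(LanguageTagError) as err:
            validate_lang(code)
        assert err.value.code == code

    @given(
        st.lists(
            st.text(
                alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789",
                min_size=1,
                max_size=8,
            ),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_grammar_generated_tags(self, subtags):
        """Tags built from the grammar are accepted iff the primary
        subtag is purely alphabetic (the only extra constraint)."""
        tag = "-".join(subtags)
        primary_alpha = subtags[0].isalpha()
        if primary_alpha:
            assert validate_lang(tag) == tag
        else:
            with pytest.raises(LanguageTagError):
                validate_lang(tag)

    @given(st.text(max_size=20))
    @settings(max_examples=200, derandomize=True)
    def test_never_accepts_what_the_grammar_rejects(self, text):
        import re

        grammar = re.compile(r"[A-Za-z]{1,8}(-[A-Za-z0-9]{1,8})*\Z")
        if grammar.fullmatch(text) is None:
            with pytest.raises(LanguageTagError):
                validate_lang(text)


class TestSubjectKeys:
    def _ds(self, pids):
        return Dataset(
            "x",
            variables=[
                VariableDef("PID", _f("A", 5)),
                VariableDef("age", _f("F", 3)),
            ],
            cases=[[p, 30.0 + i] for i, p in enumerate(pids)],
        )

    def test_designated_column_becomes_keys(self):
        keys, excluded = extract_subject_keys(
            self._ds(["P1", "P2"]), ConvertOptions(subjectkey="PID")
        )
        assert keys == ["P1", "P2"]
        assert excluded == 0

    def test_default_incrementing_keys(self):
        keys, excluded = extract_subject_keys(self._ds(["a"] * 5), ConvertOptions())
        assert keys == ["1", "2", "3", "4", "5"]
        assert excluded is None

    def test_numeric_key_column_rendered_minimally(self):
        ds = Dataset(
            "x",
            variables=[VariableDef("ID", _f("F", 4))],
            cases=[[7.0], [8.0]],
        )
        keys, _ = extract_subject_keys(ds, ConvertOptions(subjectkey="ID"))
        assert keys == ["7", "8"]

    def test_case_sensitive_lookup(self):
        with pytest.raises(SubjectKeyError):
            extract_subject_keys(self._ds(["P1"]), ConvertOptions(subjectkey="pid"))

    def test_duplicate_keys_error_by_default(self):
        with pytest.raises(SubjectKeyError, match="multiple cases per patient"):
            extract_subject_keys(
                self._ds(["P1", "P1", "P2"]), ConvertOptions(subjectkey="PID")
            )

    def test_duplicate_keys_suffix_policy(self):
        keys, _ = extract_subject_keys(
            self._ds(["P1", "P1", "P2", "P1"]),
            ConvertOptions(subjectkey="PID", duplicate_key_policy="suffix"),
        )
        assert keys == ["P1", "P1.2", "P2", "P1.3"]


class TestBuildMetadata:
    def test_sample_default_hierarchy(self, sample_ds):
        odm_file, _ = build_metadata(sample_ds, ConvertOptions())
        mdv = odm_file.studies[0].metadata_versions[0]
        assert len(mdv.item_defs) == 16
        assert len(mdv.studyevent_defs) == 1
        assert len(mdv.form_defs) == 1
        assert len(mdv.itemgroup_defs) == 1
        assert len(mdv.protocol.studyevent_refs) == 1

    def test_subjectkey_column_not_a_separate_item(self, sample_ds):
        odm_file, _ = build_metadata(sample_ds, ConvertOptions(subjectkey="PID"))
        mdv = odm_file.studies[0].metadata_versions[0]
        assert len(mdv.item_defs) == 15
        assert all(i.oid != "PID" for i in mdv.item_defs)

    def test_value_labels_become_codelist(self, sample_ds):
        odm_file, _ = build_metadata(sample_ds, ConvertOptions())
        mdv = odm_file.studies[0].metadata_versions[0]
        (cl,) = mdv.code_lists
        assert cl.oid == "CL.sex"
        assert [(ci.coded_value, ci.decode.text) for ci in cl.items] == [
            ("1", "male"), ("2", "female"),
        ]
        sex = next(i for i in mdv.item_defs if i.oid == "sex")
        assert sex.codelist_oid == "CL.sex"

    def test_label_maps_to_name_and_question(self, sample_ds):
        odm_file, _ = build_metadata(
            sample_ds, ConvertOptions(lang="en")
        )
        mdv = odm_file.studies[0].metadata_versions[0]
        weight = next(i for i in mdv.item_defs if i.oid == "weight")
        assert weight.name == "Body weight (kg)"
        assert weight.question.text == "Body weight (kg)"
        assert weight.question.lang == "en"

    def test_name_fallback_when_label_empty(self):
        ds = Dataset("x", variables=[VariableDef("age", _f("F", 3))])
        odm_file, _ = build_metadata(ds, ConvertOptions())
        item = odm_file.studies[0].metadata_versions[0].item_defs[0]
        assert item.name == "age"
        assert item.question.text == "age"

    def test_no_lang_attribute_without_lang_option(self, sample_ds):
        odm_file, _ = build_metadata(sample_ds, ConvertOptions())
        mdv = odm_file.studies[0].metadata_versions[0]
        assert all(i.question.lang is None for i in mdv.item_defs)

    def test_zero_variable_dataset(self):
        odm_file, _ = build_metadata(Dataset("empty"), ConvertOptions())
        mdv = odm_file.studies[0].metadata_versions[0]
        assert mdv.item_defs == []
        assert mdv.itemgroup_defs[0].item_refs == []

    def test_unknown_subjectkey_names_the_parameter(self, sample_ds):
        with pytest.raises(SubjectKeyError, match="nope"):
            build_metadata(sample_ds, ConvertOptions(subjectkey="nope"))

    def test_width_and_decimals_become_length_and_significant_digits(
        self, sample_ds
    ):
        odm_file, _ = build_metadata(sample_ds, ConvertOptions())
        mdv = odm_file.studies[0].metadata_versions[0]
        weight = next(i for i in mdv.item_defs if i.oid == "weight")
        assert weight.datatype == "float"
        assert weight.length == 6
        assert weight.significant_digits == 2

    def test_dropped_attribute_warnings(self):
        ds = Dataset(
            "x",
            variables=[
                VariableDef(
                    "v", _f("F", 8), missing=MissingSpec(values=(9.0,)),
                    measure="scale", role="input",
                )
            ],
        )
        _, report = build_metadata(ds, ConvertOptions())
        assert len(report.by_category(DROPPED_ATTRIBUTE)) == 3


class TestConvert:
    def test_metadata_only_by_default(self, sample_ds):
        odm_file, _ = convert(sample_ds)
        assert odm_file.clinical_data is None
        assert odm_file.odm_version == "1.3.1"
        assert odm_file.file_type == "Snapshot"

    def test_data_conversion_counts(self, sample_odm):
        odm_file, _ = sample_odm
        assert len(odm_file.clinical_data.subjects) == 5
        mdv = odm_file.studies[0].metadata_versions[0]
        assert len(mdv.item_defs) == 15  # 16 variables minus the PID key

    def test_sysmis_cell_emits_no_itemdata(self, sample_odm):
        odm_file, _ = sample_odm
        # case index 2 has a system-missing weight
        subject = odm_file.clinical_data.subjects[2]
        items = subject.events[0].forms[0].itemgroups[0].items
        assert len(items) == 14  # 15 items minus the missing weight
        assert all(i.item_oid != "weight" for i in items)
        full = odm_file.clinical_data.subjects[0]
        assert len(full.events[0].forms[0].itemgroups[0].items) == 15

    def test_pid_becomes_subject_key(self, sample_odm):
        odm_file, _ = sample_odm
        assert [s.subject_key for s in odm_file.clinical_data.subjects] == [
            "P001", "P002", "P003", "P004", "P005",
        ]

    def test_conservation_counts(self):
        from spssodm.fixtures import make_random_dataset

        for seed in range(5):
            ds = make_random_dataset(10, 8, seed, key_column="PID")
            odm_file, _ = convert(
                ds, ConvertOptions(include_data=True, subjectkey="PID")
            )
            mdv = odm_file.studies[0].metadata_versions[0]
            assert len(mdv.item_defs) == ds.n_variables - 1
            assert len(odm_file.clinical_data.subjects) == ds.n_cases
            with_labels = sum(
                1 for v in ds.variables[1:] if v.value_labels
            )
            assert len(mdv.code_lists) == with_labels

    def test_invalid_dataset_refused(self):
        from spssodm.errors import InvalidDatasetError

        bad = Dataset("x", variables=[VariableDef("a b", _f("F", 8))])
        with pytest.raises(InvalidDatasetError):
            convert(bad)
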