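"""Data model, registry IO and the complete-case rule."""

import io
from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iciss import (
    Cohort,
    FormatError,
    IntegrityError,
    PatientRecord,
    ValidationError,
    complete_case_filter,
    normalize_icd,
    read_cohort,
    write_cohort,
)
from .conftest import record


class TestPatientRecord:
    def test_24h_death_implies_30d_death(self):
        with pytest.raises(IntegrityError):
            PatientRecord(patient_id="x", died_24h=True, died_30d=False)
        # missing 30-day outcome does not trigger the check
        PatientRecord(patient_id="x", died_24h=True, died_30d=None)

    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError):
            PatientRecord(patient_id="x", age=-1.0)

    def test_empty_injury_list_is_valid_not_missing(self):
        r = PatientRecord(patient_id="x", injuries=())
        assert r.injuries == ()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(IntegrityError):
            Cohort([record("a"), record("a")])


class TestNormalizeIcd:
    @pytest.mark.parametrize(
        "raw,truncation,expected",
        [
            ("s06.5", 0, "S065"),
            ("S0650", 3, "S06"),
            ("S0650", 4, "S065"),
            (" t14.1 ", 0, "T141"),
        ],
    )
    def test_examples(self, raw, truncation, expected):
        assert normalize_icd(raw, truncation) == expected

    def test_empty_code_rejected(self):
        with pytest.raises(ValidationError):
            normalize_icd("  ")

    @settings(max_examples=100, derandomize=True)
    @given(
        code=st.text(
            alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), max_codepoint=127),
            min_size=1,
            max_size=8,
        ),
        truncation=st.sampled_from([0, 3, 4]),
    )
    def test_idempotent(self, code, truncation):
        once = normalize_icd(code, truncation)
        assert normalize_icd(once, truncation) == once


class TestRegistryIO:
    def test_roundtrip_preserves_everything(self, tiny_cohort):
        # include missingness of every optional field
        cohort = Cohort(
            list(tiny_cohort)
            + [
                PatientRecord(
                    patient_id="p7",
                    arrival=None,
                    age=None,
                    sex=None,
                    mechanism=None,
                    transferred=None,
                    injuries=("S065", "S065", "T141"),
                    died_24h=None,
                    died_30d=True,
                )
            ]
        )
        buf = io.StringIO()
        write_cohort(cohort, buf)
        buf.seek(0)
        back = read_cohort(buf)
        assert len(back) == len(cohort)
        for a, b in zip(cohort, back):
            for f in (
                "patient_id",
                "arrival",
                "age",
                "sex",
                "mechanism",
                "transferred",
                "injuries",
                "died_24h",
                "died_30d",
            ):
                assert getattr(a, f) == getattr(b, f), f

    def test_row_count_preserved(self, tiny_cohort):
        buf = io.StringIO()
        write_cohort(tiny_cohort, buf)
        buf.seek(0)
        assert len(read_cohort(buf)) == 6

    def test_missing_required_column_raises(self):
        csv = "patient_id,arrival,age,sex,mechanism,transferred,injuries,died_24h\np1,,,,,,,\n"
        with pytest.raises(FormatError, match="died_30d"):
            read_cohort(io.StringIO(csv))

    def test_unparseable_cells_become_missing_never_defaults(self):
        header = "patient_id,arrival,age,sex,mechanism,transferred,injuries,died_24h,died_30d"
        csv = f"{header}\np1,not-a-date,minus five,robot,teleport,maybe,S065,?,1\n"
        (r,) = read_cohort(io.StringIO(csv))
        assert r.arrival is None and r.age is None and r.sex is None
        assert r.mechanism is None and r.transferred is None
        assert r.died_24h is None and r.died_30d is True
        assert r.injuries == ("S065",)

    def test_nesting_violation_rejected_at_load(self):
        header = "patient_id,arrival,age,sex,mechanism,transferred,injuries,died_24h,died_30d"
        csv = f"{header}\np1,,,,,,S065,1,0\n"
        with pytest.raises(IntegrityError):
            read_cohort(io.StringIO(csv))

    def test_empty_injuries_cell_reads_as_empty_list(self):
        header = "patient_id,arrival,age,sex,mechanism,transferred,injuries,died_24h,died_30d"
        csv = f"{header}\np1,2014-01-01T00:00:00,30,male,rti,0,,0,0\n"
        (r,) = read_cohort(io.StringIO(csv))
        assert r.injuries == ()


class TestCompleteCaseFilter:
    def test_outcome_missing_always_excluded(self, tiny_cohort):
        cohort = Cohort(list(tiny_cohort) + [record("p9", died_30d=None)])
        for req in (True, False):
            result = complete_case_filter(cohort, require_covariates=req)
            assert "p9" not in result.cohort.ids()
            assert result.exclusions_by_field.get("died_30d") == 1

    def test_missing_covariate_kept_only_without_requirement(self, tiny_cohort):
        cohort = Cohort(list(tiny_cohort) + [record("p9", mechanism=None)])
        strict = complete_case_filter(cohort, require_covariates=True)
        loose = complete_case_filter(cohort, require_covariates=False)
        assert "p9" not in strict.cohort.ids()
        assert "p9" in loose.cohort.ids()
        assert len(loose.cohort) >= len(strict.cohort)

    def test_fully_observed_cohort_is_identity(self, tiny_cohort):
        result = complete_case_filter(tiny_cohort)
        assert result.cohort.ids() == tiny_cohort.ids()
        assert result.n_excluded == 0

    def test_idempotent_and_order_preserving(self, small_synthetic):
        once = complete_case_filter(small_synthetic)
        twice = complete_case_filter(once.cohort)
        assert twice.cohort.ids() == once.cohort.ids()
        assert twice.n_excluded == 0
        # order preserved relative to the input
        kept = set(once.cohort.ids())
        assert [i for i in small_synthetic.ids() if i in kept] == once.cohort.ids()
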