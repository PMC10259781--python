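"""Exclusion cascade and covariate construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvonset as pv
from pvonset.cohort import AgeCat, DoseCat, ExclusionReason, LithiumCat

from .conftest import make_case


class TestCategorizeAge:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("0s", AgeCat.LE29),
            ("10s", AgeCat.LE29),
            ("20s", AgeCat.LE29),
            ("20代", AgeCat.LE29),
            ("30s", AgeCat.A30S),
            ("40s", AgeCat.A40S),
            ("50s", AgeCat.A50S),
            ("60s", AgeCat.GE60),
            ("70s", AgeCat.GE60),
            ("90s", AgeCat.GE60),
            ("adult", None),
            ("child", None),
            ("elderly", None),
            ("", None),
        ],
    )
    def test_decade_bands(self, raw, expected):
        assert pv.categorize_age(raw) is expected


class TestDoseBands:
    @pytest.mark.parametrize(
        "dose,expected",
        [
            (None, None),
            (199.9, DoseCat.LOW),
            (200.0, DoseCat.MEDIUM),  # band edges closed into medium
            (400.0, DoseCat.MEDIUM),
            (400.1, DoseCat.HIGH),
            (600.0, DoseCat.HIGH),
        ],
    )
    def test_edges(self, dose, expected):
        assert pv.categorize_cloz_dose(dose) is expected

    @settings(derandomize=True, max_examples=200)
    @given(dose=st.floats(min_value=0, max_value=5000, allow_nan=False))
    def test_bands_cover_all_nonnegative_doses(self, dose):
        assert pv.categorize_cloz_dose(dose) in (DoseCat.LOW, DoseCat.MEDIUM, DoseCat.HIGH)


class TestResolveDose:
    def _case(self, doses):
        return make_case(
            drugs=[("clozapine", "suspected", d, None) for d in doses]
        )

    def test_maximum_rule(self):
        assert pv.resolve_cloz_dose(self._case([100.0, 300.0])) == 300.0

    def test_all_missing(self):
        assert pv.resolve_cloz_dose(self._case([None])) is None

    def test_missing_ignored(self):
        assert pv.resolve_cloz_dose(self._case([None, 250.0])) == 250.0


class TestLithium:
    def test_no_row_is_none_level(self):
        case = make_case(drugs=[("clozapine", "suspected", 300.0, None)])
        assert pv.categorize_lithium(case) is LithiumCat.NONE

    @pytest.mark.parametrize(
        "dose,expected", [(600.0, LithiumCat.LOW), (900.0, LithiumCat.HIGH)]
    )
    def test_dose_edge(self, dose, expected):
        case = make_case(drugs=[("lithium", "concomitant", dose, None)])
        assert pv.categorize_lithium(case) is expected

    def test_user_with_unknown_dose_excluded(self):
        case = make_case(drugs=[("lithium", "concomitant", None, None)])
        assert pv.categorize_lithium(case) is None


class TestPolypharmacy:
    def test_other_antipsychotic_counts(self):
        case = make_case(
            drugs=[("clozapine", "suspected", None, None),
                   ("risperidone", "concomitant", None, None)]
        )
        assert pv.flag_polypharmacy(case)

    def test_non_antipsychotic_does_not(self):
        case = make_case(
            drugs=[("clozapine", "suspected", None, None),
                   ("lithium", "concomitant", None, None)]
        )
        assert not pv.flag_polypharmacy(case)

    def test_study_drug_itself_excluded(self):
        case = make_case(
            drugs=[("clozapine", "suspected", None, None),
                   ("clozapine", "concomitant", None, None)]
        )
        assert not pv.flag_polypharmacy(case)


class TestAntiepileptic:
    def _flags(self, case, terms):
        return pv.flag_case(case, terms)

    def test_started_after_onset_is_nonconcomitant(self, terms):
        case = make_case(
            drugs=[("clozapine", "suspected", None, (2020, 1, 1)),
                   ("sodium valproate", "concomitant", None, (2020, 6, 1))],
            reactions=[("Seizure", (2020, 3, 1))],
        )
        assert not pv.flag_antiepileptic(case, self._flags(case, terms))

    def test_started_before_onset_is_concomitant(self, terms):
        case = make_case(
            drugs=[("clozapine", "suspected", None, (2020, 1, 1)),
                   ("sodium valproate", "concomitant", None, (2020, 1, 15))],
            reactions=[("Seizure", (2020, 3, 1))],
        )
        assert pv.flag_antiepileptic(case, self._flags(case, terms))

    def test_missing_start_date_defaults_to_concomitant(self, terms):
        case = make_case(
            drugs=[("diazepam", "concomitant", None, None)],
            reactions=[("Nausea", (2020, 1, 1))],
        )
        assert pv.flag_antiepileptic(case, self._flags(case, terms))


class TestBuildCohort:
    def test_first_failing_rule_attribution(self, terms):
        case = make_case(
            sex=pv.Sex.UNKNOWN,
            age="20s",
            drugs=[("clozapine", "suspected", None, None)],  # dose missing too
            reactions=[("Nausea", (2020, 1, 1))],
        )
        flags = {case.case_id: pv.flag_case(case, terms)}
        rows, ledger = pv.build_cohort([case], flags)
        assert rows == []
        assert ledger.counts[ExclusionReason.UNKNOWN_SEX] == 1
        assert ledger.counts[ExclusionReason.UNKNOWN_DOSE] == 0

    def test_complete_case_yields_full_row(self, terms, seizure_case):
        flags = {seizure_case.case_id: pv.flag_case(seizure_case, terms)}
        rows, ledger = pv.build_cohort([seizure_case], flags)
        assert ledger.n_retained == 1
        (row,) = rows
        assert row.outcome_seizure and row.sex is pv.Sex.FEMALE
        assert row.age_cat is AgeCat.A30S
        assert row.cloz_dose_cat is DoseCat.MEDIUM
        assert row.polypharmacy and row.lithium_cat is LithiumCat.LOW
        assert not row.fluvoxamine and not row.antiepileptic
        assert not row.convulsive_history

    def test_ledger_matches_generator_truth(self, small_dump, terms):
        """Planted missingness produces exactly the predicted flow counts."""
        rows, ledger = _run_cohort(small_dump, terms)
        assert ledger.to_dict() == small_dump.truth.ledger.to_dict()
        assert sorted(r.case_id for r in rows) == sorted(
            r.case_id for r in small_dump.truth.cohort_rows
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_invariant(self, terms, seed):
        """n_input == n_retained + sum(exclusions) on random dumps."""
        res = pv.simulate(pv.SimConfig(n_cases=60, seed=seed))
        _, ledger = _run_cohort(res, terms)
        assert ledger.n_input == ledger.n_retained + ledger.n_excluded


def _run_cohort(res, terms):
    import io

    entries = {}
    for kind in pv.TableKind:
        buf = io.StringIO()
        res.tables[kind.value].to_csv(buf, index=False)
        buf.seek(0)
        entries[kind] = pv.read_table(buf, kind)
    cases, _ = pv.build_cases(
        entries[pv.TableKind.DEMO], entries[pv.TableKind.DRUG],
        entries[pv.TableKind.REAC], entries[pv.TableKind.HIST],
    )
    cloz = pv.filter_drug_cases(cases, "clozapine")
    flags = {c.case_id: pv.flag_case(c, terms) for c in cloz}
    return pv.build_cohort(cloz, flags)
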