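"""Cohort-builder rules: diagnosis dates, the 183-day treatment pair,
utilization blocks, CMS washout, full fixture walk and oracle equivalence."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from conftest import D, compliant_events, ev, patient
from efimm.cohort import (
    CohortCriteria,
    age_at,
    build_cohort,
    check_utilization,
    cms_washout,
    determine_index_date,
    evaluate_patient,
    mm_diagnosis_dates,
)
from efimm.model import CodeSystem, EventBundle, Source

CRIT = CohortCriteria()


class TestDiagnosisDates:
    def test_same_day_codes_dedup(self):
        d1, d2 = D(2010, 1, 1), D(2010, 2, 1)
        events = [
            ev("P", d1, "203.00", CodeSystem.ICD9),
            ev("P", d1, "203.01", CodeSystem.ICD9),
            ev("P", d2, "C90.00", CodeSystem.ICD10),
        ]
        assert mm_diagnosis_dates(events, CRIT) == [d1, d2]

    def test_prefix_boundary(self):
        events = [ev("P", D(2010, 1, 1), "203.1", CodeSystem.ICD9)]
        assert mm_diagnosis_dates(events, CRIT) == []

    def test_three_dates_pass_threshold(self):
        events = [ev("P", D(2010, 1, 1 + i), "203.00", CodeSystem.ICD9) for i in range(3)]
        assert len(mm_diagnosis_dates(events, CRIT)) >= CRIT.min_mm_dx_dates

    def test_wrong_system_prefix_not_matched(self):
        # an ICD-9-shaped code carried in the ICD-10 field must not match
        events = [ev("P", D(2010, 1, 1), "203.00", CodeSystem.ICD10)]
        assert mm_diagnosis_dates(events, CRIT) == []


class TestIndexDate:
    def _rx(self, dates):
        return [ev("P", d, "bortezomib", CodeSystem.RX) for d in dates]

    def test_eleven_day_gap(self):
        events = self._rx([D(2010, 1, 1), D(2010, 1, 12)])
        assert determine_index_date(events, CRIT) == D(2010, 1, 1)

    def test_244_day_gap_fails(self):
        events = self._rx([D(2010, 1, 1), D(2010, 9, 1)])
        assert (D(2010, 9, 1) - D(2010, 1, 1)).days == 243  # sanity: oracle day count
        events = self._rx([D(2010, 1, 1), D(2010, 9, 2)])
        assert (D(2010, 9, 2) - D(2010, 1, 1)).days == 244
        assert determine_index_date(events, CRIT) is None

    def test_exactly_183_days_passes(self):
        events = self._rx([D(2010, 1, 1), D(2010, 1, 1) + dt.timedelta(days=183)])
        assert determine_index_date(events, CRIT) == D(2010, 1, 1)
        events = self._rx([D(2010, 1, 1), D(2010, 1, 1) + dt.timedelta(days=184)])
        assert determine_index_date(events, CRIT) is None

    def test_single_date_fails(self):
        assert determine_index_date(self._rx([D(2010, 1, 1)]), CRIT) is None

    def test_cms_treatment_does_not_anchor_index(self):
        events = [
            ev("P", D(2010, 1, 1), "bortezomib", CodeSystem.RX, source=Source.CMS),
            ev("P", D(2010, 1, 12), "bortezomib", CodeSystem.RX),
            ev("P", D(2010, 1, 20), "bortezomib", CodeSystem.RX),
        ]
        assert determine_index_date(events, CRIT) == D(2010, 1, 12)


class TestUtilization:
    INDEX = D(2010, 6, 1)

    def _code_at(self, days_before, source=Source.VA):
        return ev("P", self.INDEX - dt.timedelta(days=days_before), "I10", source=source)

    def test_one_code_each_block(self):
        events = [self._code_at(100), self._code_at(500), self._code_at(900)]
        assert check_utilization(events, self.INDEX, CRIT)

    def test_gap_year_fails(self):
        events = [self._code_at(100), self._code_at(900)]
        assert not check_utilization(events, self.INDEX, CRIT)

    def test_cms_codes_do_not_count(self):
        events = [self._code_at(d, source=Source.CMS) for d in (100, 500, 900)]
        assert not check_utilization(events, self.INDEX, CRIT)

    def test_mm_codes_do_not_count(self):
        events = [
            ev("P", self.INDEX - dt.timedelta(days=d), "203.00", CodeSystem.ICD9)
            for d in (100, 500, 900)
        ]
        assert not check_utilization(events, self.INDEX, CRIT)

    def test_block_boundaries(self):
        # block 1 is [index-365, index): a code on the index date itself
        # belongs to no block
        assert not check_utilization([self._code_at(0), self._code_at(500), self._code_at(900)],
                                     self.INDEX, CRIT)
        # block k is [index-365k, index-365(k-1)): days 365/730/1095 are the
        # earliest days of blocks 1/2/3 respectively
        events = [self._code_at(365), self._code_at(730), self._code_at(1095)]
        assert check_utilization(events, self.INDEX, CRIT)
        # day 1096 falls outside block 3 entirely
        events = [self._code_at(365), self._code_at(730), self._code_at(1096)]
        assert not check_utilization(events, self.INDEX, CRIT)


class TestWashout:
    INDEX = D(2010, 6, 1)

    def _cms_rx(self, date):
        return [ev("P", date, "lenalidomide", CodeSystem.RX, source=Source.CMS)]

    def test_five_years_before_index_excludes(self):
        assert cms_washout(self._cms_rx(D(2005, 6, 1)), self.INDEX, CRIT)

    def test_200_days_after_index_allowed(self):
        assert not cms_washout(self._cms_rx(self.INDEX + dt.timedelta(days=200)), self.INDEX, CRIT)

    def test_exactly_183_days_after_excludes(self):
        assert cms_washout(self._cms_rx(self.INDEX + dt.timedelta(days=183)), self.INDEX, CRIT)

    def test_no_cms_codes(self):
        assert not cms_washout([], self.INDEX, CRIT)

    def test_va_treatment_does_not_wash_out(self):
        events = [ev("P", D(2005, 6, 1), "lenalidomide", CodeSystem.RX, source=Source.VA)]
        assert not cms_washout(events, self.INDEX, CRIT)


class TestBuildCohort:
    def test_six_patient_fixture(self, six_patient_bundle):
        bundle, index = six_patient_bundle
        decisions, attrition = build_cohort(bundle)
        by_id = {d.patient_id: d for d in decisions}
        assert by_id["PDX"].exclusion_reason == "insufficient_mm_dx_dates"
        assert by_id["PPAIR"].exclusion_reason == "no_index_date"
        assert by_id["PYEAR"].exclusion_reason == "index_year_out_of_range"
        assert by_id["PAGE"].exclusion_reason == "age_below_minimum"
        assert by_id["PUTIL"].exclusion_reason == "insufficient_va_utilization"
        assert by_id["PWASH"].exclusion_reason == "cms_washout"
        assert by_id["POK"].included and by_id["POK"].index_date == index
        reasons = [d.exclusion_reason for d in decisions if not d.included]
        assert len(set(reasons)) == 6  # each exclusion reason distinct
        assert attrition.final_n == 1
        ns = [n for _, n in attrition.rows]
        assert ns == sorted(ns, reverse=True)  # nonincreasing

    def test_age_just_below_threshold(self):
        # age 64.9 y at index -> excluded for age
        index = D(2010, 6, 1)
        birth = index - dt.timedelta(days=int(64.9 * 365.25))
        p = patient("P", birth=birth)
        assert age_at(birth, index) < 65.0
        d = evaluate_patient(p, compliant_events("P", index), CRIT)
        assert d.exclusion_reason == "age_below_minimum"

    def test_compliant_patient_included_with_first_treatment_index(self):
        index = D(2010, 6, 1)
        d = evaluate_patient(patient("P"), compliant_events("P", index), CRIT)
        assert d.included and d.index_date == index

    def test_death_on_index_excluded(self):
        index = D(2010, 6, 1)
        p = patient("P", death=index, last=index)
        d = evaluate_patient(p, compliant_events("P", index), CRIT)
        assert d.exclusion_reason == "nonpositive_followup"

    def test_row_order_invariance(self, six_patient_bundle):
        bundle, _ = six_patient_bundle
        shuffled = EventBundle(
            patients=list(reversed(bundle.patients)),
            events=list(reversed(bundle.events)),
            labs=[],
        )
        d1, a1 = build_cohort(bundle)
        d2, a2 = build_cohort(shuffled)
        assert d1 == d2 and a1.rows == a2.rows

    def test_adding_utilization_code_never_excludes(self, six_patient_bundle):
        """Monotonicity: a qualifying non-MM VA code cannot flip
        included -> excluded."""
        bundle, index = six_patient_bundle
        extra = ev("POK", index - dt.timedelta(days=600), "E11")
        augmented = EventBundle(
            patients=bundle.patients, events=bundle.events + [extra], labs=[]
        )
        d = {x.patient_id: x for x in build_cohort(augmented)[0]}
        assert d["POK"].included

    def test_attrition_consistency(self, small_bundle):
        bundle, _ = small_bundle
        decisions, attrition = build_cohort(bundle)
        assert attrition.final_n == sum(d.included for d in decisions)
        assert attrition.rows[0][1] == len(decisions)

    def test_oracle_equivalence_small_bundles(self, catalog):
        """Decisions match a self-contained re-evaluation of all criteria on
        randomly perturbed 20-patient bundles."""
        from efimm.simulate import SimulationConfig, simulate_cohort

        fractions = {
            "insufficient_mm_dx_dates": 0.1,
            "no_index_date": 0.1,
            "age_below_minimum": 0.1,
            "insufficient_va_utilization": 0.1,
            "cms_washout": 0.1,
        }
        bundle, truth = simulate_cohort(
            SimulationConfig(n_patients=20, seed=21, exclusion_fractions=fractions)
        )
        decisions, _ = build_cohort(bundle)
        events_by = bundle.events_by_patient()
        for d in decisions:
            expected = _oracle_decision(bundle.patient(d.patient_id), events_by[d.patient_id])
            assert (d.included, d.exclusion_reason) == expected, d.patient_id


def _oracle_decision(p, events):
    """Brute-force criterion evaluation, independent of the implementation."""
    dx = sorted({e.event_date for e in events
                 if (e.code_system is CodeSystem.ICD9 and e.code.replace(".", "").startswith("2030"))
                 or (e.code_system is CodeSystem.ICD10 and e.code.replace(".", "").upper().startswith("C900"))})
    if len(dx) < 3:
        return (False, "insufficient_mm_dx_dates")
    va_rx = sorted({e.event_date for e in events if e.code_system is CodeSystem.RX and e.source is Source.VA})
    index = None
    if len(va_rx) >= 2 and 0 < (va_rx[1] - va_rx[0]).days <= 183:
        index = va_rx[0]
    if index is None:
        return (False, "no_index_date")
    if not 2004 <= index.year <= 2017:
        return (False, "index_year_out_of_range")
    if (index - p.birth_date).days / 365.25 < 65.0:
        return (False, "age_below_minimum")
    for k in (1, 2, 3):
        lo, hi = index - dt.timedelta(days=365 * k), index - dt.timedelta(days=365 * (k - 1))
        found = any(
            e.source is Source.VA and lo <= e.event_date < hi
            and e.code_system is not CodeSystem.RX
            and not (e.code_system is CodeSystem.ICD9 and e.code.replace(".", "").startswith("2030"))
            and not (e.code_system is CodeSystem.ICD10 and e.code.replace(".", "").upper().startswith("C900"))
            for e in events
        )
        if not found:
            return (False, "insufficient_va_utilization")
    if any(e.code_system is CodeSystem.RX and e.source is Source.CMS
           and e.event_date <= index + dt.timedelta(days=183) for e in events):
        return (False, "cms_washout")
    if p.death_date is not None and p.death_date <= index:
        return (False, "nonpositive_followup")
    return (True, None)
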