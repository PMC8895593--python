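"""Threshold estimators vs an independent brute-force age scan, plus rule cases."""

import math
import random

import pytest

from menoderive import (
    DetailedStatus as DS,
    MenopauseResponse as MR,
    MHTUse,
    ThresholdMethod,
    ThresholdSpec,
    YesNoMissing as YN,
    classify_cohort_detailed,
    conservative_threshold,
    eligible_subcohort,
    estimate_threshold,
    least_conservative_threshold,
    reference_threshold,
)
from menoderive.io import AlignmentError

from conftest import make_record


def pairs_for(records, method=ThresholdMethod.REFERENCE, **spec_kwargs):
    spec = ThresholdSpec(method=method, **spec_kwargs)
    results = classify_cohort_detailed(records)
    return eligible_subcohort(records, results, spec), spec


# ----------------------------------------------------------- independent oracles
# Plain-Python scans, deliberately separate from the vectorised implementation.

def brute_reference(pairs, cut, lo=45, hi=100):
    ages = [r.age_at_menopause for r, _ in pairs]
    if not ages:
        return None
    for a in range(lo, hi + 1):
        if sum(1 for x in ages if x < a) / len(ages) >= cut:
            return a
    return None


def brute_conservative(pairs, cut, min_group_n, lo=45, hi=100):
    groups = {}
    for r, _ in pairs:
        if r.age_at_baseline is None:
            continue
        g = int(math.floor(r.age_at_baseline))
        if lo <= g <= hi:
            groups.setdefault(g, []).append(r)
    props = {
        g: sum(1 for r in members if r.menopause is MR.YES) / len(members)
        for g, members in groups.items()
        if len(members) >= min_group_n
    }
    for a in range(lo, hi + 1):
        tail = [p for g, p in props.items() if g >= a]
        if tail and all(p >= cut for p in tail):
            return a
    return None


def brute_least_conservative(pairs, cut, lo=45, hi=100):
    rows = [
        (r.age_at_baseline, res.detailed is DS.NATURAL_MENOPAUSE)
        for r, res in pairs
        if r.age_at_baseline is not None
    ]
    for a in range(lo, hi + 1):
        tail = [nat for age, nat in rows if age >= a]
        if tail and sum(tail) / len(tail) >= cut:
            return a
    return None


# ------------------------------------------------------------------- eligibility

def test_any_intervention_or_contraception_excludes_from_all_methods():
    records = [
        make_record(participant_id="mht", mht=MHTUse.FORMER),
        make_record(participant_id="hyst", hysterectomy=YN.YES, age_at_hysterectomy=40),
        make_record(participant_id="ooph", oophorectomy=YN.YES, age_at_oophorectomy=40),
        make_record(participant_id="oc", oc_current=YN.YES),
        make_record(participant_id="ok"),
    ]
    for method in ThresholdMethod:
        eligible, _ = pairs_for(records, method)
        assert [r.participant_id for r, _ in eligible] == ["ok"]


def test_reference_filter_additionally_requires_age_and_natural_menopause():
    records = [
        make_record(participant_id="ref", age_at_baseline=65.1, age_at_menopause=50),
        make_record(participant_id="young", age_at_baseline=50.0,
                    menopause=MR.NO, age_at_menopause=None),
        make_record(participant_id="no_age", age_at_baseline=70.0, age_at_menopause=None),
    ]
    reference, _ = pairs_for(records, ThresholdMethod.REFERENCE)
    assert [r.participant_id for r, _ in reference] == ["ref"]
    conservative, _ = pairs_for(records, ThresholdMethod.CONSERVATIVE)
    assert {r.participant_id for r, _ in conservative} == {"ref", "young", "no_age"}


def test_eligible_subcohort_rejects_misalignment():
    records = [make_record(participant_id="a"), make_record(participant_id="b")]
    results = classify_cohort_detailed(records)[::-1]
    with pytest.raises(AlignmentError):
        eligible_subcohort(records, results, ThresholdSpec())


# ------------------------------------------------------------------- rule cases

def _reference_cohort(menopause_ages):
    return [
        make_record(participant_id=f"w{i}", age_at_baseline=70.0, age_at_menopause=a)
        for i, a in enumerate(menopause_ages)
    ]


def test_reference_point_mass_jumps_just_above_it():
    eligible, spec = pairs_for(_reference_cohort([50.0] * 20))
    assert reference_threshold(eligible, spec).threshold_age == 51


def test_reference_ninety_percent_cut():
    eligible, spec = pairs_for(_reference_cohort([48.0] * 9 + [60.0]))
    result = reference_threshold(eligible, spec)
    assert result.threshold_age == 49
    assert result.n_eligible == 10


def test_reference_cumulative_table_is_monotone():
    eligible, spec = pairs_for(_reference_cohort([47.0, 49.0, 50.0, 52.0, 55.0]))
    result = reference_threshold(eligible, spec)
    props = [row[3] for row in result.cumulative_table]
    assert props == sorted(props)
    assert all(0.0 <= p <= 1.0 for p in props)


def test_reference_not_attained_on_empty_or_out_of_range():
    eligible, spec = pairs_for([])
    result = reference_threshold(eligible, spec)
    assert not result.attained and result.message
    # all reported ages beyond the scan range: proportion never reaches the cut
    eligible, spec = pairs_for(_reference_cohort([120.0] * 5))
    assert not reference_threshold(eligible, spec).attained


def _conservative_cohort(group_props, group_n=60):
    """One single-year group per (age, proportion-yes) pair."""
    records = []
    for age, prop in group_props.items():
        n_yes = round(prop * group_n)
        for i in range(group_n):
            records.append(
                make_record(
                    participant_id=f"g{age}_{i}",
                    age_at_baseline=age + 0.5,
                    menopause=MR.YES if i < n_yes else MR.NO,
                    age_at_menopause=45.0 if i < n_yes else None,
                )
            )
    return records


def test_conservative_every_group_from_threshold_onwards():
    props = {a: 0.5 for a in range(45, 57)}
    props.update({a: 1.0 for a in range(57, 70)})
    eligible, spec = pairs_for(
        _conservative_cohort(props), ThresholdMethod.CONSERVATIVE
    )
    assert conservative_threshold(eligible, spec).threshold_age == 57


def test_conservative_all_groups_passing_gives_scan_floor():
    eligible, spec = pairs_for(
        _conservative_cohort({60: 1.0, 61: 1.0}), ThresholdMethod.CONSERVATIVE
    )
    assert conservative_threshold(eligible, spec).threshold_age == 45


def test_conservative_single_failing_group_pushes_threshold_up():
    props = {55: 0.95, 56: 0.85, 57: 0.92, 58: 0.95, 59: 0.95}
    eligible, spec = pairs_for(
        _conservative_cohort(props, group_n=100), ThresholdMethod.CONSERVATIVE
    )
    assert conservative_threshold(eligible, spec).threshold_age == 57


def test_conservative_small_groups_are_ignored():
    records = _conservative_cohort({60: 1.0}, group_n=60)
    # a tiny 100%-no group above the threshold would block it if counted
    records += _conservative_cohort({65: 0.0}, group_n=5)
    eligible, spec = pairs_for(records, ThresholdMethod.CONSERVATIVE)
    assert conservative_threshold(eligible, spec).threshold_age == 45


def test_conservative_not_attained_without_qualifying_groups():
    eligible, spec = pairs_for(
        _conservative_cohort({60: 1.0}, group_n=10), ThresholdMethod.CONSERVATIVE
    )
    result = conservative_threshold(eligible, spec)
    assert not result.attained and "min_group_n" in result.message


def _least_cohort():
    """Tail proportions: >=54 -> 0.91, >=53 -> 0.80 => threshold 54."""
    records = []
    for i in range(91):
        records.append(make_record(participant_id=f"n{i}", age_at_baseline=54.5,
                                   age_at_menopause=50.0))
    for i in range(9):
        records.append(make_record(participant_id=f"p{i}", age_at_baseline=54.5,
                                   menopause=MR.NO, age_at_menopause=None))
    for i in range(5):
        records.append(make_record(participant_id=f"n2{i}", age_at_baseline=53.5,
                                   age_at_menopause=50.0))
    for i in range(15):
        records.append(make_record(participant_id=f"p2{i}", age_at_baseline=53.5,
                                   menopause=MR.NO, age_at_menopause=None))
    return records


def test_least_conservative_tail_scan():
    eligible, spec = pairs_for(_least_cohort(), ThresholdMethod.LEAST_CONSERVATIVE)
    result = least_conservative_threshold(eligible, spec)
    assert result.threshold_age == 54


def test_least_conservative_all_natural_gives_scan_floor():
    records = _reference_cohort([50.0] * 10)
    eligible, spec = pairs_for(records, ThresholdMethod.LEAST_CONSERVATIVE)
    assert least_conservative_threshold(eligible, spec).threshold_age == 45


def test_least_conservative_not_attained_when_tail_never_reaches_cut():
    records = [
        make_record(participant_id=f"w{i}", age_at_baseline=60.0,
                    menopause=MR.NO, age_at_menopause=None)
        for i in range(10)
    ]
    eligible, spec = pairs_for(records, ThresholdMethod.LEAST_CONSERVATIVE)
    assert not least_conservative_threshold(eligible, spec).attained


# -------------------------------------------------------------------- properties

def random_cohort(rng, n):
    records = []
    for i in range(n):
        menopause = rng.choice(list(MR))
        records.append(
            make_record(
                participant_id=f"r{i}",
                age_at_baseline=rng.choice([None, round(rng.uniform(45, 95), 1)]),
                menopause=menopause,
                mht=MHTUse.NEVER,
                oc_current=YN.NO,
                age_at_menopause=(
                    round(rng.uniform(40, 60), 1) if menopause is MR.YES and rng.random() < 0.9 else None
                ),
            )
        )
    return records


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_oracle_equivalence_on_random_cohorts(seed):
    rng = random.Random(seed)
    for _ in range(4):
        records = random_cohort(rng, rng.randint(20, 400))
        results = classify_cohort_detailed(records)
        cut = rng.choice([0.5, 0.8, 0.9, 0.95])
        for method in ThresholdMethod:
            spec = ThresholdSpec(method=method, cut_point=cut, min_group_n=10)
            eligible = eligible_subcohort(records, results, spec)
            got = estimate_threshold(records, results, spec).threshold_age
            if method is ThresholdMethod.REFERENCE:
                expected = brute_reference(eligible, cut)
            elif method is ThresholdMethod.CONSERVATIVE:
                expected = brute_conservative(eligible, cut, 10)
            else:
                expected = brute_least_conservative(eligible, cut)
            assert got == expected, f"{method} seed={seed}"


def test_raising_cut_point_never_lowers_a_threshold():
    rng = random.Random(7)
    records = random_cohort(rng, 500)
    results = classify_cohort_detailed(records)
    for method in ThresholdMethod:
        previous = None
        for cut in (0.5, 0.7, 0.9, 0.97):
            t = estimate_threshold(
                records, results, ThresholdSpec(method=method, cut_point=cut, min_group_n=10)
            ).threshold_age
            if previous is not None and t is not None:
                assert t >= previous
            previous = t if t is not None else previous
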