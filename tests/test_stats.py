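"""2x2 carrier statistics: Fisher exact, relative risk with continuity
correction, rank-sum tests, medians, trait tables."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import fisher_two_sided_enumerated, rank_sum_two_sided_enumerated

from taadvc.examples import (
    EXAMPLE_AGE_TABLE,
    EXAMPLE_NORMOTENSION_TABLE,
    EXAMPLE_PLP_ONSET_AGES,
)
from taadvc.model import CarrierClass
from taadvc.stats import (
    ContingencyTable,
    Trait,
    build_trait_tables,
    fisher_exact_two_sided,
    median,
    relative_risk,
    run_association_stage,
    wilcoxon_rank_sum,
)


# --- Fisher exact -----------------------------------------------------------------


def test_fisher_balanced_table_is_one():
    assert fisher_exact_two_sided(ContingencyTable(1, 2, 1, 2)) == pytest.approx(1.0)


def test_fisher_extreme_table_enumerated_value():
    # margins (5, 5, 5): 6 outcomes; the two extreme tables each have
    # probability 1/252, so the two-sided p is 2/252
    p = fisher_exact_two_sided(ContingencyTable(5, 5, 0, 5))
    assert p == pytest.approx(2 / 252, rel=1e-9)


@pytest.mark.parametrize("a,n1,b,n2", [(6, 22, 0, 77), (6, 32, 1, 70), (2, 9, 4, 7)])
def test_fisher_agrees_with_enumerator(a, n1, b, n2):
    assert fisher_exact_two_sided(ContingencyTable(a, n1, b, n2)) == pytest.approx(
        fisher_two_sided_enumerated(a, n1, b, n2), rel=1e-8
    )


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(3, 2, 0, 5)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 5)


# --- relative risk ------------------------------------------------------------------


def test_normotension_row_reproduced_to_four_decimals():
    """The zero-cell table (6/22 vs 0/77) with the 0.5 correction yields
    RR 44.0870, 95% CI (2.5793, 753.5646)."""
    res = relative_risk(EXAMPLE_NORMOTENSION_TABLE)
    assert res.corrected
    assert res.corrected_cells == (6.5, 23.0, 0.5, 78.0)
    assert res.rr == pytest.approx(44.0870, abs=1e-3)
    assert res.ci_low == pytest.approx(2.5793, abs=1e-3)
    assert res.ci_high == pytest.approx(753.5646, rel=1e-3)


def test_age_row_uncorrected():
    res = relative_risk(EXAMPLE_AGE_TABLE)
    assert not res.corrected
    assert res.rr == pytest.approx(13.1250, abs=1e-3)
    assert res.ci_low == pytest.approx(1.6474, abs=1e-3)
    assert res.ci_high == pytest.approx(104.5677, abs=1e-2)


def test_equal_risks_give_rr_one():
    res = relative_risk(ContingencyTable(3, 10, 3, 10))
    assert res.rr == pytest.approx(1.0)
    assert res.ci_low <= 1.0 <= res.ci_high


@given(
    a=st.integers(1, 20),
    extra1=st.integers(1, 20),
    b=st.integers(1, 20),
    extra2=st.integers(1, 20),
)
def test_uncorrected_rr_equals_cross_ratio(a, extra1, b, extra2):
    """Without zero cells, RR = (a*n2)/(b*n1) algebraically."""
    table = ContingencyTable(a, a + extra1, b, b + extra2)
    res = relative_risk(table)
    assert not res.corrected
    assert res.rr == pytest.approx((a * table.n2) / (b * table.n1), rel=1e-12)


def test_correction_applied_iff_zero_cell():
    assert relative_risk(ContingencyTable(0, 5, 2, 5)).corrected
    assert relative_risk(ContingencyTable(5, 5, 2, 5)).corrected  # n1 - a == 0
    assert not relative_risk(ContingencyTable(1, 5, 2, 5)).corrected


def test_double_zero_still_defined_after_correction():
    res = relative_risk(ContingencyTable(0, 10, 0, 10))
    assert res.rr == pytest.approx(1.0)
    assert math.isfinite(res.ci_low) and math.isfinite(res.ci_high)


# --- rank-sum and median --------------------------------------------------------------


def test_rank_sum_separated_samples():
    # U = 0; 2 * (1 / C(6,3)) = 2/20
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_rank_sum_identical_singletons():
    assert wilcoxon_rank_sum([5.0], [5.0]) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "x, y",
    [
        ([13, 20, 50, 47, 33, 30], [55, 58, 61, 49, 70, 66]),
        ([1, 2, 2, 3], [2, 4, 5]),  # midrank ties
        ([10, 12], [11, 13, 14, 9]),
    ],
)
def test_rank_sum_matches_enumeration_oracle(x, y):
    assert wilcoxon_rank_sum(x, y) == pytest.approx(
        rank_sum_two_sided_enumerated(x, y), abs=1e-12
    )


def test_rank_sum_large_sample_path():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    y = rng.normal(1, 1, 35)
    p = wilcoxon_rank_sum(x, y)
    assert 0 < p < 0.05


def test_rank_sum_rejects_empty():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def test_median_of_worked_example_ages():
    assert median(sorted(EXAMPLE_PLP_ONSET_AGES.values())) == pytest.approx(31.5)
    assert median([42]) == 42


@given(st.lists(st.floats(-100, 100), min_size=1, max_size=20), st.randoms())
def test_median_permutation_invariant(values, rnd):
    shuffled = list(values)
    rnd.shuffle(shuffled)
    assert median(shuffled) == pytest.approx(median(values), nan_ok=False)


# --- trait tables ------------------------------------------------------------------


def test_trait_tables_from_example_cohort(cohort_101, plp_variants):
    from taadvc.engine import classify_all
    from taadvc.pipeline import assign_carrier_classes

    cohort = assign_carrier_classes(cohort_101, classify_all(plp_variants))
    tables = build_trait_tables(cohort)
    normo = tables[Trait.NORMOTENSION]
    assert (normo.a, normo.n1, normo.b) == (6, 22, 0)
    assert normo.n1 + normo.n2 == len(cohort)
    # carrier conservation across every trait split
    for table in tables.values():
        assert table.a + table.b == 6
        assert table.n1 + table.n2 == len(cohort)


def test_all_carrier_cohort(cohort_101):
    cohort = [r.with_carrier_class(CarrierClass.P_LP) for r in cohort_101]
    for table in build_trait_tables(cohort).values():
        assert table.a == table.n1 and table.b == table.n2


def test_association_stage_order_invariant(cohort_101, plp_variants):
    from taadvc.engine import classify_all
    from taadvc.pipeline import assign_carrier_classes

    cohort = assign_carrier_classes(cohort_101, classify_all(plp_variants))
    forward = {r.trait: (r.rr, r.p_value) for r in run_association_stage(cohort)}
    backward = {
        r.trait: (r.rr, r.p_value) for r in run_association_stage(cohort[::-1])
    }
    assert forward == backward
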