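"""Variant- and sample-level filters: strict boundaries, partition and
order-independence properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from taadvc.filtering import (
    Decision,
    FilterReason,
    filter_by_consequence,
    filter_by_maf,
    run_filter_stage,
    sample_qc,
)
from taadvc.model import (
    ClinvarAssertion,
    Consequence,
    DepthSummary,
    PanelVariant,
)
from taadvc.synthetic import SimConfig, generate_cohort


def _variant(**kwargs):
    defaults = dict(
        patient_id="P1",
        gene="FBN1",
        cdna_hgvs="c.1A>G",
        protein_hgvs="p.Met1Val",
        consequence=Consequence.MISSENSE,
    )
    defaults.update(kwargs)
    return PanelVariant(**defaults)


@pytest.mark.parametrize(
    "world, eas, retained",
    [
        (0.000006, 0.000012, True),  # rare in both populations
        (0.002, None, False),  # above 0.1% worldwide
        (None, 0.002, False),  # above 0.1% in East Asia only
        (0.001, None, True),  # exactly 0.1%: "greater than" is strict
        (None, None, True),  # absent never excludes
        (0.0, 0.0, True),
    ],
)
def test_maf_filter_boundaries(world, eas, retained):
    outcome = filter_by_maf(_variant(maf_worldwide=world, maf_east_asian=eas))
    assert (outcome.decision is Decision.RETAINED) == retained
    if not retained:
        assert outcome.reason is FilterReason.MAF_ABOVE_THRESHOLD


def test_maf_filter_rejects_bad_threshold():
    with pytest.raises(ValueError):
        filter_by_maf(_variant(), threshold=0.0)


@pytest.mark.parametrize(
    "consequence, clinvar, hgmd, retained",
    [
        (Consequence.SYNONYMOUS, ClinvarAssertion.ABSENT, False, False),
        (Consequence.SYNONYMOUS, ClinvarAssertion.PATHOGENIC, False, True),
        (Consequence.SYNONYMOUS, ClinvarAssertion.LIKELY_PATHOGENIC, False, True),
        (Consequence.INTRONIC, ClinvarAssertion.ABSENT, True, True),  # HGMD rescue
        (Consequence.INTRONIC, ClinvarAssertion.VUS, False, False),
        (Consequence.MISSENSE, ClinvarAssertion.ABSENT, False, True),
        (Consequence.SPLICE_SITE, ClinvarAssertion.ABSENT, False, True),
    ],
)
def test_consequence_filter(consequence, clinvar, hgmd, retained):
    variant = _variant(
        protein_hgvs="",
        consequence=consequence,
        clinvar_assertion=clinvar,
        hgmd_dm=hgmd,
    )
    outcome = filter_by_consequence(variant)
    assert (outcome.decision is Decision.RETAINED) == retained


@pytest.mark.parametrize(
    "covered, total, passes",
    [
        (8, 10, True),  # exactly 80% is not "less than 80%"
        (7, 10, False),
        (10, 10, True),
        (0, 10, False),
    ],
)
def test_sample_qc_boundary(covered, total, passes):
    outcome = sample_qc(DepthSummary("S1", total, covered))
    assert (outcome.decision is Decision.RETAINED) == passes


def test_depth_counting_is_strict():
    """A base at exactly the depth bound does not count as covered, so a
    sample whose every base sits at depth 60 contributes zero covered bases."""
    all_at_60 = DepthSummary("S1", n_target_bases=10, n_bases_depth_gt60=0)
    assert sample_qc(all_at_60).reason is FilterReason.COVERAGE_FAIL


def test_zero_target_bases_rejected():
    with pytest.raises(ValueError):
        DepthSummary("S1", 0, 0)


def test_worked_example_all_retained(plp_variants, plp_depths):
    result = run_filter_stage(plp_variants, plp_depths)
    assert len(result.retained) == 6
    assert result.n_excluded == 0


def test_failing_sample_excludes_whole_patient(plp_variants, plp_depths):
    depths = [
        DepthSummary(d.sample_id, d.n_target_bases, int(0.5 * d.n_target_bases))
        if d.sample_id == "TAAD_61"
        else d
        for d in plp_depths
    ]
    result = run_filter_stage(plp_variants, depths)
    assert "TAAD_61" in result.failed_samples
    assert all(v.patient_id != "TAAD_61" for v in result.retained)
    excluded = [o for o in result.variant_log if o.decision is Decision.EXCLUDED]
    assert [o.reason for o in excluded] == [FilterReason.COVERAGE_FAIL]


def test_orphan_variant_is_an_error(plp_variants, plp_depths):
    with pytest.raises(ValueError, match="TAAD_102"):
        run_filter_stage(plp_variants, plp_depths[:-1])


def test_partition_conservation_on_random_variants():
    """Every input appears exactly once in the outcome log."""
    cohort = generate_cohort(SimConfig(n_patients=80, seed=5, vus_rate=1.2))
    result = run_filter_stage(list(cohort.variants), list(cohort.depths))
    assert len(result.variant_log) == len(cohort.variants)
    assert len(result.retained) + result.n_excluded == len(cohort.variants)


def test_order_independence():
    cohort = generate_cohort(SimConfig(n_patients=40, seed=9, vus_rate=1.0))
    variants = list(cohort.variants)
    depths = list(cohort.depths)
    forward = run_filter_stage(variants, depths)
    backward = run_filter_stage(variants[::-1], depths[::-1])
    decisions_fwd = {o.subject_id: o.decision for o in forward.variant_log}
    decisions_bwd = {o.subject_id: o.decision for o in backward.variant_log}
    assert decisions_fwd == decisions_bwd


@given(
    maf=st.one_of(st.none(), st.floats(min_value=0, max_value=0.01)),
    lo=st.floats(min_value=1e-6, max_value=0.5),
    hi=st.floats(min_value=1e-6, max_value=0.5),
)
def test_raising_threshold_never_excludes(maf, lo, hi):
    """Monotonicity: a variant retained at a low MAF threshold stays retained
    at any higher threshold."""
    lo, hi = min(lo, hi), max(lo, hi)
    variant = _variant(maf_worldwide=maf)
    at_lo = filter_by_maf(variant, lo).decision
    at_hi = filter_by_maf(variant, hi).decision
    if at_lo is Decision.RETAINED:
        assert at_hi is Decision.RETAINED
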