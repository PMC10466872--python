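"""Variant- and sample-level filters applied before classification.

Three filters, all with strict inequalities:

* population-frequency filter — a variant is excluded when its worldwide or
  East-Asian minor allele frequency is strictly greater than 0.1%; an absent
  frequency never excludes (absence from the reference population is itself
  evidence of rarity);
* consequence filter — synonymous and intronic variants are excluded unless
  rescued by a pathogenic/likely-pathogenic ClinVar assertion or an HGMD DM
  flag (splice-site variants, including intronic positions within the assay's
  15 bp padding, are retained);
* sample QC — a sample passes only if at least 80% of target bases are
  covered by more than 60 reads; all variants of a failing sample are
  excluded before any variant-level filter and the patient leaves the cohort
  denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    ClinvarAssertion,
    Consequence,
    DepthSummary,
    PanelConfig,
    PanelVariant,
)

DEFAULT_MAF_THRESHOLD = 0.001
DEFAULT_MIN_DEPTH = 60
DEFAULT_MIN_COVERED_FRACTION = 0.80


class FilterReason(str, enum.Enum):
    RETAINED = "retained"
    MAF_ABOVE_THRESHOLD = "maf_above_threshold"
    SYNONYMOUS_OR_INTRONIC_UNRESCUED = "synonymous_or_intronic_unrescued"
    COVERAGE_FAIL = "coverage_fail"


class Decision(str, enum.Enum):
    RETAINED = "retained"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class FilterOutcome:
    subject_id: str  # variant key or sample id
    decision: Decision
    reason: FilterReason

    def __post_init__(self) -> None:
        excluded = self.reason is not FilterReason.RETAINED
        if excluded != (self.decision is Decision.EXCLUDED):
            raise ValueError("decision=excluded iff reason is not 'retained'")


def _retained(subject: str) -> FilterOutcome:
    return FilterOutcome(subject, Decision.RETAINED, FilterReason.RETAINED)


def _excluded(subject: str, reason: FilterReason) -> FilterOutcome:
    return FilterOutcome(subject, Decision.EXCLUDED, reason)


def _variant_id(v: PanelVariant) -> str:
    return f"{v.patient_id}:{v.gene}:{v.cdna_hgvs or v.protein_hgvs}"


def filter_by_maf(
    variant: PanelVariant, threshold: float = DEFAULT_MAF_THRESHOLD
) -> FilterOutcome:
    """Exclude iff either population frequency is strictly above ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    for value in (variant.maf_worldwide, variant.maf_east_asian):
        if value is not None and value < 0:
            raise ValueError(f"negative frequency {value}")
        if value is not None and value > threshold:
            return _excluded(_variant_id(variant), FilterReason.MAF_ABOVE_THRESHOLD)
    return _retained(_variant_id(variant))


def filter_by_consequence(variant: PanelVariant) -> FilterOutcome:
    """Exclude synonymous/intronic variants unless rescued by a database
    assertion; every other consequence class is retained."""
    if variant.consequence in (Consequence.SYNONYMOUS, Consequence.INTRONIC):
        rescued = variant.hgmd_dm or variant.clinvar_assertion in (
            ClinvarAssertion.PATHOGENIC,
            ClinvarAssertion.LIKELY_PATHOGENIC,
        )
        if not rescued:
            return _excluded(
                _variant_id(variant), FilterReason.SYNONYMOUS_OR_INTRONIC_UNRESCUED
            )
    return _retained(_variant_id(variant))


def sample_qc(
    depth: DepthSummary,
    min_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> FilterOutcome:
    """Pass iff the fraction of target bases with depth > ``min_depth`` is at
    least ``min_fraction``.

    ``DepthSummary.n_bases_depth_gt60`` must already count bases with depth
    strictly greater than the depth bound; this function checks the fraction.
    A fraction of exactly 0.80 passes ("less than 80%" excludes).
    """
    if depth.n_target_bases <= 0:
        raise ValueError("n_target_bases must be positive")
    if depth.covered_fraction >= min_fraction:
        return _retained(depth.sample_id)
    return _excluded(depth.sample_id, FilterReason.COVERAGE_FAIL)


@dataclass(frozen=True)
class FilterStageResult:
    retained: tuple[PanelVariant, ...]
    variant_log: tuple[FilterOutcome, ...]
    sample_log: tuple[FilterOutcome, ...]
    failed_samples: frozenset[str]

    @property
    def n_excluded(self) -> int:
        return sum(1 for o in self.variant_log if o.decision is Decision.EXCLUDED)


def run_filter_stage(
    variants: Sequence[PanelVariant],
    depths: Iterable[DepthSummary],
    config: Optional[PanelConfig] = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    min_covered_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> FilterStageResult:
    """Run sample QC, then the variant-level filters.

    Every input variant appears exactly once in ``variant_log``.  Variants of
    a QC-failing sample are excluded with reason ``coverage_fail`` before any
    variant-level filter.  A variant whose patient has no depth record is a
    configuration error.
    """
    depth_by_sample: Mapping[str, DepthSummary] = {}
    sample_log = []
    failed = set()
    for depth in depths:
        depth_by_sample[depth.sample_id] = depth
        outcome = sample_qc(depth, min_covered_fraction, min_depth)
        sample_log.append(outcome)
        if outcome.decision is Decision.EXCLUDED:
            failed.add(depth.sample_id)

    retained: list[PanelVariant] = []
    variant_log: list[FilterOutcome] = []
    for variant in variants:
        if variant.patient_id not in depth_by_sample:
            raise ValueError(
                f"no depth summary for patient {variant.patient_id!r}"
            )
        if variant.patient_id in failed:
            variant_log.append(
                _excluded(_variant_id(variant), FilterReason.COVERAGE_FAIL)
            )
            continue
        outcome = filter_by_maf(variant, maf_threshold)
        if outcome.decision is Decision.RETAINED:
            outcome = filter_by_consequence(variant)
        variant_log.append(outcome)
        if outcome.decision is Decision.RETAINED:
            retained.append(variant)
    return FilterStageResult(
        retained=tuple(retained),
        variant_log=tuple(variant_log),
        sample_log=tuple(sample_log),
        failed_samples=frozenset(failed),
    )
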