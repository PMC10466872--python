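"""Carrier-phenotype association statistics.

For each of eight clinical traits the cohort is split into a trait-positive
(exposed) and a trait-negative (reference) group, and P/LP carrier counts
form a 2x2 table.  The relative risk RR = (a/n1)/(b/n2) gets a log-normal
95% confidence interval exp(ln RR +/- z*SE) with
SE = sqrt(1/a - 1/n1 + 1/b - 1/n2); when any cell of the table (a, n1-a, b,
n2-b) is zero, 0.5 is added to all four cells (Haldane-Anscombe) before both
the point estimate and the interval.  Significance uses the two-sided Fisher
exact test in its standard "sum of outcome probabilities not exceeding the
observed table's" form.  Onset-age comparisons use the unpaired two-sided
Wilcoxon rank-sum test, exact by enumeration for small samples.

Trait polarity matches the study's risk table: the exposed level is the
protective-sounding one (normotension, normolipidaemia, normoglycaemia), so
RR > 1 means carriers are enriched in that group.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .model import CarrierClass, CohortRecord, Sex, StanfordType

Z_95 = 1.959964  # normal 97.5th percentile
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: ``a`` of ``n1`` exposed, ``b`` of ``n2`` reference."""

    a: int
    n1: int
    b: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n2):
            raise ValueError("carrier counts exceed group totals")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both groups must be non-empty")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, n1-a, b, n2-b) — the four cells of the 2x2 table."""
        return (self.a, self.n1 - self.a, self.b, self.n2 - self.b)

    @property
    def has_zero_cell(self) -> bool:
        return 0 in self.cells


@dataclass(frozen=True)
class RiskResult:
    trait: str
    table: ContingencyTable
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool
    corrected_cells: tuple[float, float, float, float]  # a', n1', b', n2'

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rr <= self.ci_high:
            raise ValueError("point estimate outside its confidence interval")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for the 2x2 table.

    Sum of hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's.
    """
    a, c, b, d = table.cells
    return float(sps.fisher_exact([[a, c], [b, d]], alternative="two-sided")[1])


def relative_risk(
    table: ContingencyTable,
    z: float = Z_95,
    correction: float = 0.5,
    trait: str = "",
) -> RiskResult:
    """Relative risk with log-normal CI and zero-cell continuity correction.

    With a zero cell the correction is added to all four cells, i.e.
    a' = a + 0.5, n1' = n1 + 1, b' = b + 0.5, n2' = n2 + 1; the corrected
    cells feed both RR and SE.  Without zero cells the raw counts are used.
    """
    corrected = table.has_zero_cell
    if corrected:
        a = table.a + correction
        n1 = table.n1 + 2 * correction
        b = table.b + correction
        n2 = table.n2 + 2 * correction
    else:
        a, n1, b, n2 = float(table.a), float(table.n1), float(table.b), float(table.n2)
    if a == 0 or b == 0:
        raise ValueError("zero carrier count survived the continuity correction")
    se_sq = 1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2
    if se_sq < 0:
        raise ValueError("negative variance — invalid table")
    rr = (a / n1) / (b / n2)
    se = math.sqrt(se_sq)
    log_rr = math.log(rr)
    return RiskResult(
        trait=trait,
        table=table,
        rr=rr,
        ci_low=math.exp(log_rr - z * se),
        ci_high=math.exp(log_rr + z * se),
        p_value=fisher_exact_two_sided(table),
        corrected=corrected,
        corrected_cells=(a, n1, b, n2),
    )


def median(values: Sequence[float]) -> float:
    """Sample median (midpoint of the central order statistics for even n)."""
    if len(values) == 0:
        raise ValueError("median of an empty sequence")
    return float(np.median(np.asarray(values, dtype=float)))


def _rank_sum_u(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of all rank assignments (with midrank ties) when
    n1 + n2 <= 12; otherwise the normal approximation with tie correction.
    The exact two-sided p is 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    if n1 + n2 <= EXACT_RANKSUM_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # midranks for ties
        u_obs = _rank_sum_u(ranks[:n1], n1)
        us = np.array(
            [
                float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
                for idx in combinations(range(n1 + n2), n1)
            ]
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# --- trait tables --------------------------------------------------------------


class Trait(str, enum.Enum):
    AGE_LT_50 = "age_lt_50"
    FEMALE = "female"
    NORMOTENSION = "normotension"
    NORMOLIPIDAEMIA = "normolipidaemia"
    NORMOGLYCAEMIA = "normoglycaemia"
    Z_GT_2 = "aortic_z_gt_2"
    ANEURYSM = "aneurysm_present"
    STANFORD_A = "stanford_type_a"


TRAIT_PREDICATES: Mapping[Trait, Callable[[CohortRecord], bool]] = {
    Trait.AGE_LT_50: lambda r: r.age_at_onset < 50,
    Trait.FEMALE: lambda r: r.sex is Sex.F,
    Trait.NORMOTENSION: lambda r: not r.hypertension,
    Trait.NORMOLIPIDAEMIA: lambda r: not r.hyperlipidaemia,
    Trait.NORMOGLYCAEMIA: lambda r: not r.diabetes,
    Trait.Z_GT_2: lambda r: r.aortic_diameter_z > 2,
    Trait.ANEURYSM: lambda r: r.aneurysm_present,
    Trait.STANFORD_A: lambda r: r.stanford_type is StanfordType.A,
}


def build_trait_tables(
    cohort: Sequence[CohortRecord],
) -> dict[Trait, ContingencyTable]:
    """One carrier 2x2 table per trait: exposed = trait-positive patients,
    a = P/LP carriers among them; reference = trait-negative patients."""
    tables = {}
    for trait, predicate in TRAIT_PREDICATES.items():
        exposed = [r for r in cohort if predicate(r)]
        reference = [r for r in cohort if not predicate(r)]
        if not exposed or not reference:
            continue  # degenerate split: no contrast to test
        tables[trait] = ContingencyTable(
            a=sum(1 for r in exposed if r.carrier_class is CarrierClass.P_LP),
            n1=len(exposed),
            b=sum(1 for r in reference if r.carrier_class is CarrierClass.P_LP),
            n2=len(reference),
        )
    return tables


def run_association_stage(
    cohort: Sequence[CohortRecord], z: float = Z_95
) -> list[RiskResult]:
    """Relative risk + exact p for every trait with a non-degenerate split."""
    return [
        relative_risk(table, z=z, trait=trait.value)
        for trait, table in build_trait_tables(cohort).items()
    ]
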