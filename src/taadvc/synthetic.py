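"""Seed-reproducible synthetic TAAD cohorts.

The generator emulates a ~100-patient aortic-disease cohort sequenced on the
23-gene panel: a phenotype table (onset age, sex, cardiovascular risk
factors, aortic measurements), a per-patient variant table, and per-sample
depth summaries, so the whole pipeline runs with no external data.

Defaults mirror the study cohort's baseline characteristics: onset age from
a truncated normal (mean 57, SD 14, bounds 13-80), 18.8% female, 72.3%
hypertensive, 48.5% hyperlipidaemic, 49.5% diabetic, 45.5% with aortic
diameter Z score above 2, 65.3% with an aneurysm, 59.4% Stanford type A.
P/LP carrier status is drawn per (age<50, normotension) stratum, with
default per-stratum risks chosen to give ~6% overall carrier prevalence
strongly enriched among young and normotensive patients.  Carrier variants
are constructed to be classifiable P/LP by the rule engine (de novo
nonsense/frameshift, or an FBN1 cysteine missense with zero population
frequency); VUS are rare missense variants with no evidence.

Each output table draws from its own child stream of the master seed, so
regenerating one table never perturbs another.  The generator emulates the
study conditions; it does not fit them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import (
    CarrierClass,
    CohortRecord,
    COLLAGEN_GENES,
    DEFAULT_PANEL_GENES,
    Consequence,
    DepthSummary,
    PanelVariant,
    Sex,
    StanfordType,
)
from .stats import Trait

#: approximate protein lengths (residues) used to place synthetic variants
GENE_LENGTHS: Mapping[str, int] = {
    "FBN1": 2871,
    "FBN2": 2912,
    "TGFBR1": 503,
    "TGFBR2": 567,
    "SMAD2": 467,
    "SMAD3": 425,
    "TGFB2": 442,
    "TGFB3": 412,
    "COL1A1": 1464,
    "COL1A2": 1366,
    "COL3A1": 1466,
    "COL5A1": 1838,
    "COL5A2": 1499,
    "SLC2A10": 541,
    "SKI": 728,
    "EFEMP2": 443,
    "ELN": 786,
    "ACTA2": 377,
    "MYH11": 1972,
    "MYLK": 1914,
    "PRKG1": 686,
    "LOX": 417,
    "NOTCH1": 2555,
}

# residues used for synthetic substitutions: no Cys (reserved for the FBN1
# rule) and no Gly (reserved for the collagen rules)
_SAFE_RESIDUES = (
    "Ala Arg Asn Asp Gln Glu His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()


def _default_gene_weights() -> dict[str, float]:
    # FBN1 carries the largest share of panel variants in TAAD cohorts
    weights = {g: 0.75 / 22 for g in DEFAULT_PANEL_GENES}
    weights["FBN1"] = 0.25
    return weights


def _default_carrier_model() -> dict[tuple[bool, bool], float]:
    # keyed by (age_at_onset < 50, normotensive); ~6% overall prevalence
    return {
        (False, False): 0.005,
        (True, False): 0.03,
        (False, True): 0.10,
        (True, True): 0.35,
    }


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 101
    seed: int = 0
    # stratum fractions (study baseline table)
    frac_female: float = 19 / 101
    frac_hypertension: float = 0.723
    frac_hyperlipidaemia: float = 0.485
    frac_diabetes: float = 0.495
    frac_z_gt2: float = 0.455
    frac_aneurysm: float = 66 / 101
    frac_stanford_a: float = 0.594
    frac_stanford_b: float = 0.287
    frac_family_history: float = 0.01
    # onset-age model
    age_mean: float = 57.0
    age_sd: float = 14.0
    age_min: float = 13.0
    age_max: float = 80.0
    # carrier model: P/LP probability per (age<50, normotensive) stratum
    carrier_model: Mapping[tuple[bool, bool], float] = field(
        default_factory=_default_carrier_model
    )
    frac_carrier_null: float = 2 / 3  # null variant vs FBN1 cysteine missense
    vus_rate: float = 0.65  # expected VUS-class variants per patient
    # population-frequency mixture for VUS variants, supported on [0, 0.005]
    maf_absent_prob: float = 0.3
    maf_zero_prob: float = 0.2
    maf_max: float = 0.005
    gene_weights: Mapping[str, float] = field(default_factory=_default_gene_weights)
    # depth model
    n_target_bases: int = 100_000
    qc_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "frac_female",
            "frac_hypertension",
            "frac_hyperlipidaemia",
            "frac_diabetes",
            "frac_z_gt2",
            "frac_aneurysm",
            "frac_stanford_a",
            "frac_stanford_b",
            "frac_family_history",
            "frac_carrier_null",
            "maf_absent_prob",
            "maf_zero_prob",
            "qc_fail_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for stratum, prob in dict(self.carrier_model).items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"carrier probability {prob} for {stratum} outside [0, 1]")
        total = sum(self.gene_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"gene weights sum to {total}, expected 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    @property
    def p_age_lt50(self) -> float:
        """P(onset age < 50) under the truncated-normal age model."""
        a = (self.age_min - self.age_mean) / self.age_sd
        b = (self.age_max - self.age_mean) / self.age_sd
        return float(
            sps.truncnorm.cdf(50.0, a, b, loc=self.age_mean, scale=self.age_sd)
        )


@dataclass(frozen=True)
class SyntheticCohort:
    phenotypes: tuple[CohortRecord, ...]
    variants: tuple[PanelVariant, ...]
    depths: tuple[DepthSummary, ...]
    #: the generator's intended carrier tier per patient (ground truth)
    truth: Mapping[str, CarrierClass]


def _draw_ages(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    a = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    b = (cfg.age_max - cfg.age_mean) / cfg.age_sd
    return sps.truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )


def _draw_phenotype(
    rng: np.random.Generator, cfg: SimConfig, patient_id: str, age_raw: float
) -> CohortRecord:
    age = round(float(age_raw), 1)
    sex = Sex.F if rng.random() < cfg.frac_female else Sex.M
    hypertension = rng.random() < cfg.frac_hypertension
    hyperlip = rng.random() < cfg.frac_hyperlipidaemia
    diabetes = rng.random() < cfg.frac_diabetes
    if rng.random() < cfg.frac_z_gt2:
        z = round(2.05 + abs(rng.normal(0.0, 1.2)), 2)  # strictly above 2
    else:
        z = round(rng.uniform(-2.0, 2.0), 2)
    aneurysm = rng.random() < cfg.frac_aneurysm
    u = rng.random()
    if u < cfg.frac_stanford_a:
        stanford = StanfordType.A
    elif u < cfg.frac_stanford_a + cfg.frac_stanford_b:
        stanford = StanfordType.B
    else:
        stanford = StanfordType.NONE
    return CohortRecord(
        patient_id=patient_id,
        age_at_onset=age,
        sex=sex,
        hypertension=hypertension,
        hyperlipidaemia=hyperlip,
        diabetes=diabetes,
        aortic_diameter_z=z,
        aneurysm_present=aneurysm,
        stanford_type=stanford,
        family_history=rng.random() < cfg.frac_family_history,
    )


def _pick_gene(rng: np.random.Generator, cfg: SimConfig) -> str:
    genes = list(cfg.gene_weights)
    weights = np.array([cfg.gene_weights[g] for g in genes])
    return genes[int(rng.choice(len(genes), p=weights / weights.sum()))]


def _residue(rng: np.random.Generator) -> str:
    return _SAFE_RESIDUES[int(rng.integers(len(_SAFE_RESIDUES)))]


def _carrier_variant(
    rng: np.random.Generator, cfg: SimConfig, patient_id: str
) -> PanelVariant:
    if rng.random() < cfg.frac_carrier_null:
        gene = _pick_gene(rng, cfg)
        pos = int(rng.integers(1, GENE_LENGTHS.get(gene, 400)))
        ref = _residue(rng)
        if rng.random() < 0.5:
            protein = f"p.{ref}{pos}*"
            cons = Consequence.NONSENSE
            cdna = f"c.{3 * pos - 2}C>T"
        else:
            protein = f"p.{ref}{pos}fs"
            cons = Consequence.FRAMESHIFT
            cdna = f"c.{3 * pos - 2}delG"
        return PanelVariant(
            patient_id=patient_id,
            gene=gene,
            cdna_hgvs=cdna,
            protein_hgvs=protein,
            consequence=cons,
            maf_worldwide=None,
            maf_east_asian=None,
            de_novo=True,
            assertions=frozenset({"PVS1"}),
        )
    pos = int(rng.integers(1, GENE_LENGTHS["FBN1"]))
    alt = _residue(rng)
    return PanelVariant(
        patient_id=patient_id,
        gene="FBN1",
        cdna_hgvs=f"c.{3 * pos - 1}G>C",
        protein_hgvs=f"p.Cys{pos}{alt}",
        consequence=Consequence.MISSENSE,
        maf_worldwide=0.0,
        maf_east_asian=0.0,
        de_novo=False,
        assertions=frozenset({"PM2"}),
    )


def _draw_maf(rng: np.random.Generator, cfg: SimConfig) -> Optional[float]:
    u = rng.random()
    if u < cfg.maf_absent_prob:
        return None
    if u < cfg.maf_absent_prob + cfg.maf_zero_prob:
        return 0.0
    return round(float(rng.uniform(0.0, cfg.maf_max)), 8)


def _vus_variant(
    rng: np.random.Generator, cfg: SimConfig, patient_id: str
) -> PanelVariant:
    gene = _pick_gene(rng, cfg)
    pos = int(rng.integers(1, GENE_LENGTHS.get(gene, 400)))
    ref = _residue(rng)
    alt = _residue(rng)
    while alt == ref:
        alt = _residue(rng)
    maf_all = _draw_maf(rng, cfg)
    if maf_all is None:
        maf_eas: Optional[float] = None
    else:
        maf_eas = round(
            min(cfg.maf_max, maf_all * float(rng.uniform(0.5, 2.0))), 8
        )
    return PanelVariant(
        patient_id=patient_id,
        gene=gene,
        cdna_hgvs=f"c.{3 * pos}A>G",
        protein_hgvs=f"p.{ref}{pos}{alt}",
        consequence=Consequence.MISSENSE,
        maf_worldwide=maf_all,
        maf_east_asian=maf_eas,
        assertions=frozenset(),
    )


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate phenotypes, variants and depth summaries for one cohort.

    Identical configuration (including seed) yields identical output; the
    three tables draw from independent child streams of the master seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    pheno_rng, variant_rng, depth_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    width = max(3, len(str(cfg.n_patients)))
    ages = _draw_ages(pheno_rng, cfg, cfg.n_patients)
    phenotypes = [
        _draw_phenotype(pheno_rng, cfg, f"SYN_{i + 1:0{width}d}", ages[i])
        for i in range(cfg.n_patients)
    ]

    variants: list[PanelVariant] = []
    truth: dict[str, CarrierClass] = {}
    for record in phenotypes:
        stratum = (record.age_at_onset < 50, not record.hypertension)
        p_carrier = dict(cfg.carrier_model)[stratum]
        is_carrier = variant_rng.random() < p_carrier
        if is_carrier:
            variants.append(_carrier_variant(variant_rng, cfg, record.patient_id))
        n_vus = int(variant_rng.poisson(cfg.vus_rate))
        for _ in range(n_vus):
            variants.append(_vus_variant(variant_rng, cfg, record.patient_id))
        truth[record.patient_id] = (
            CarrierClass.P_LP
            if is_carrier
            else (CarrierClass.VUS if n_vus else CarrierClass.NV_LB)
        )

    depths = []
    for record in phenotypes:
        if depth_rng.random() < cfg.qc_fail_rate:
            frac = depth_rng.uniform(0.50, 0.79)
        else:
            frac = depth_rng.uniform(0.85, 0.995)
        depths.append(
            DepthSummary(
                sample_id=record.patient_id,
                n_target_bases=cfg.n_target_bases,
                n_bases_depth_gt60=int(round(frac * cfg.n_target_bases)),
            )
        )

    return SyntheticCohort(
        phenotypes=tuple(phenotypes),
        variants=tuple(variants),
        depths=tuple(depths),
        truth=truth,
    )


# --- known-truth injection -----------------------------------------------------

#: traits the stratified carrier model can target directly
INJECTABLE_TRAITS = (Trait.AGE_LT_50, Trait.NORMOTENSION)


def inject_known_truth(
    cfg: SimConfig,
    true_rr_by_trait: Mapping[Trait | str, float],
    base_risk: Optional[float] = None,
) -> SimConfig:
    """Return a config whose population relative risks equal the targets.

    The carrier model becomes multiplicative over the two stratification
    axes: risk(stratum) = base * rr_age^[age<50] * rr_nt^[normotensive].
    Because age and blood-pressure status are drawn independently, the
    population RR for each axis then equals its multiplier exactly.  Targets
    forcing any stratum risk above 1 raise a :class:`ValueError` naming the
    trait.
    """
    targets: dict[Trait, float] = {}
    for trait, rr in true_rr_by_trait.items():
        trait = Trait(trait)
        if trait not in INJECTABLE_TRAITS:
            raise ValueError(
                f"trait {trait.value!r} is not an axis of the carrier model"
            )
        if rr <= 0:
            raise ValueError(f"target RR for {trait.value!r} must be positive")
        targets[trait] = float(rr)

    if base_risk is None:
        base_risk = dict(cfg.carrier_model)[(False, False)]
    rr_age = targets.get(Trait.AGE_LT_50, 1.0)
    rr_nt = targets.get(Trait.NORMOTENSION, 1.0)
    model = {}
    for young in (False, True):
        for normo in (False, True):
            risk = base_risk * (rr_age if young else 1.0) * (rr_nt if normo else 1.0)
            if risk > 1.0:
                blame = Trait.AGE_LT_50 if young else Trait.NORMOTENSION
                raise ValueError(
                    f"target RR for {blame.value!r} implies stratum risk {risk} > 1"
                )
            model[(young, normo)] = risk
    return replace(cfg, carrier_model=model)


def population_rr(cfg: SimConfig, trait: Trait | str) -> float:
    """Exact population relative risk implied by the carrier model for one
    of the two stratification axes (marginalising over the other)."""
    trait = Trait(trait)
    if trait not in INJECTABLE_TRAITS:
        raise ValueError(f"trait {trait.value!r} is not an axis of the carrier model")
    model = dict(cfg.carrier_model)
    p_young = cfg.p_age_lt50
    p_normo = 1.0 - cfg.frac_hypertension

    def risk(young_val: Optional[bool], normo_val: Optional[bool]) -> float:
        total = 0.0
        for young in (False, True):
            if young_val is not None and young != young_val:
                continue
            for normo in (False, True):
                if normo_val is not None and normo != normo_val:
                    continue
                w = (p_young if young else 1 - p_young) * (
                    p_normo if normo else 1 - p_normo
                )
                total += w * model[(young, normo)]
        return total

    if trait is Trait.AGE_LT_50:
        return (risk(True, None) / p_young) / (risk(False, None) / (1 - p_young))
    return (risk(None, True) / p_normo) / (risk(None, False) / (1 - p_normo))
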