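"""Bundled worked example: a 101-patient TAAD panel cohort's six P/LP
variants and carrier counts.

The six variants (four de novo null alleles, one in-frame MYH11 deletion
with functional/segregation evidence, one FBN1 cysteine-destroying missense)
exercise every classification route: rule III (de novo null), rule IV (FBN1
cysteine), and plain ACMG combining.  The carrier counts by blood-pressure
status (6 of 22 normotensive vs 0 of 77 hypertensive) drive the worked
relative-risk example.  All values are encoded inputs, not computed results.
"""

from __future__ import annotations

from .model import CohortRecord, Consequence, DepthSummary, PanelVariant, Sex, StanfordType
from .stats import ContingencyTable


def example_plp_variants() -> list[PanelVariant]:
    """The six-variant P/LP worked example, one variant per patient."""
    null = dict(maf_worldwide=0.0, maf_east_asian=0.0, de_novo=True)
    return [
        PanelVariant(
            patient_id="TAAD_61",
            gene="FBN1",
            cdna_hgvs="c.114delA",
            protein_hgvs="p.Ala39fs",
            consequence=Consequence.FRAMESHIFT,
            assertions=frozenset({"PVS1"}),
            **null,
        ),
        PanelVariant(
            patient_id="TAAD_81",
            gene="FBN1",
            cdna_hgvs="c.1285C>T",
            protein_hgvs="p.Arg429*",
            consequence=Consequence.NONSENSE,
            assertions=frozenset({"PVS1"}),
            **null,
        ),
        PanelVariant(
            patient_id="TAAD_89",
            gene="MYLK",
            cdna_hgvs="c.2736delG",
            protein_hgvs="p.Lys913fs",
            consequence=Consequence.FRAMESHIFT,
            assertions=frozenset({"PVS1"}),
            **null,
        ),
        PanelVariant(
            patient_id="TAAD_90",
            gene="SMAD3",
            cdna_hgvs="c.139C>T",
            protein_hgvs="p.Gln47*",
            consequence=Consequence.NONSENSE,
            assertions=frozenset({"PVS1"}),
            **null,
        ),
        PanelVariant(
            patient_id="TAAD_98",
            gene="MYH11",
            cdna_hgvs="c.3787_3789delAAG",
            protein_hgvs="p.Lys1263del",
            consequence=Consequence.INFRAME_DEL,
            maf_worldwide=0.000006,
            maf_east_asian=0.000012,
            de_novo=False,
            assertions=frozenset({"PS3", "PM4", "PP1"}),
        ),
        PanelVariant(
            patient_id="TAAD_102",
            gene="FBN1",
            cdna_hgvs="c.7988G>C",
            protein_hgvs="p.Cys2663Ser",
            consequence=Consequence.MISSENSE,
            maf_worldwide=0.0,
            maf_east_asian=0.0,
            de_novo=False,
            assertions=frozenset({"PS1", "PM2", "PP2", "PP3"}),
        ),
    ]


#: onset age (years) of each P/LP carrier in the worked example
EXAMPLE_PLP_ONSET_AGES: dict[str, float] = {
    "TAAD_61": 13,
    "TAAD_81": 20,
    "TAAD_89": 50,
    "TAAD_90": 47,
    "TAAD_98": 33,
    "TAAD_102": 30,
}

#: carriers among normotensive vs hypertensive patients in the example cohort
EXAMPLE_NORMOTENSION_TABLE = ContingencyTable(a=6, n1=22, b=0, n2=77)

#: carriers by onset age (<50 vs >=50), group totals as printed in the
#: example's risk table (the implied reference group is 1 of 70)
EXAMPLE_AGE_TABLE = ContingencyTable(a=6, n1=32, b=1, n2=70)

EXAMPLE_COHORT_SIZE = 101
EXAMPLE_N_PLP_CARRIERS = 6


def example_depths(fraction: float = 0.95) -> list[DepthSummary]:
    """Passing depth summaries for the six example patients."""
    return [
        DepthSummary(
            sample_id=v.patient_id,
            n_target_bases=100_000,
            n_bases_depth_gt60=int(round(fraction * 100_000)),
        )
        for v in example_plp_variants()
    ]


def example_cohort() -> list[CohortRecord]:
    """A deterministic 101-patient phenotype table around the six carriers.

    The six carriers keep their example onset ages and are normotensive; the
    remaining 95 patients fill the cohort with 16 further normotensive and 79
    hypertensive records (the example's blood-pressure strata do not sum to
    the cohort size as printed — 22 + 77 = 99 — so the filler keeps the
    normotensive total at 22 and lets the hypertensive group absorb the
    difference)."""
    records = []
    for patient_id, age in EXAMPLE_PLP_ONSET_AGES.items():
        records.append(
            CohortRecord(
                patient_id=patient_id,
                age_at_onset=float(age),
                sex=Sex.M,
                hypertension=False,
                hyperlipidaemia=False,
                diabetes=False,
                aortic_diameter_z=2.5,
                aneurysm_present=True,
                stanford_type=StanfordType.A,
                family_history=patient_id == "TAAD_81",
            )
        )
    for i in range(95):
        records.append(
            CohortRecord(
                patient_id=f"TAAD_F{i + 1:02d}",
                age_at_onset=57.0,
                sex=Sex.M if i % 5 else Sex.F,
                hypertension=i >= 16,
                hyperlipidaemia=i % 2 == 0,
                diabetes=i % 2 == 1,
                aortic_diameter_z=1.5,
                aneurysm_present=i % 3 == 0,
                stanford_type=StanfordType.B if i % 2 else StanfordType.A,
                family_history=False,
            )
        )
    return records
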