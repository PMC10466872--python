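"""Domain types for the TAAD gene-panel variant analysis.

The pipeline revolves around a 23-gene thoracic-aortic-aneurysm/dissection
(TAAD) sequencing panel.  These dataclasses carry one observed variant per
patient (:class:`PanelVariant`), a structural description of its protein
change (:class:`ProteinChange`), per-sample coverage summaries used for
sample QC (:class:`DepthSummary`), the phenotype record used for the
carrier-risk statistics (:class:`CohortRecord`), and the panel configuration
(:class:`PanelConfig`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Optional, Sequence


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_DEL = "inframe_del"
    INFRAME_INS = "inframe_ins"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    SPLICE_SITE = "splice_site"


#: consequences that describe a protein-level change the HGVS-lite parser models
PROTEIN_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_DEL,
        Consequence.INFRAME_INS,
    }
)

#: "null" variant classes eligible for the de-novo pathogenicity rule (III)
NULL_LIKE_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_DEL,
        Consequence.INFRAME_INS,
        Consequence.SPLICE_SITE,
    }
)


class ClinvarAssertion(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    BENIGN = "benign"
    ABSENT = "absent"


class ChangeKind(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_DEL = "inframe_del"
    INFRAME_INS = "inframe_ins"


_KIND_TO_CONSEQUENCE = {
    ChangeKind.MISSENSE: Consequence.MISSENSE,
    ChangeKind.NONSENSE: Consequence.NONSENSE,
    ChangeKind.FRAMESHIFT: Consequence.FRAMESHIFT,
    ChangeKind.INFRAME_DEL: Consequence.INFRAME_DEL,
    ChangeKind.INFRAME_INS: Consequence.INFRAME_INS,
}


@dataclass(frozen=True)
class ProteinChange:
    """A parsed HGVS-lite protein change.

    Positions are 1-based residue indices.  ``alt_residue`` is a three-letter
    amino-acid code, ``"*"`` for a stop gain, or ``None`` when the change has
    no single substituted residue (frameshift, deletion, insertion).
    ``span_end`` equals ``position`` except for multi-residue deletions and
    for insertions, where the change sits between ``position`` and
    ``span_end``.  ``seq`` keeps the trailing deleted/inserted residue string
    exactly as printed so formatting round-trips losslessly.
    """

    kind: ChangeKind
    ref_residue: Optional[str]
    position: int
    alt_residue: Optional[str] = None
    span_end: Optional[int] = None
    span_end_residue: Optional[str] = None
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"protein position must be >= 1, got {self.position}")
        if self.span_end is None:
            object.__setattr__(self, "span_end", self.position)
        if self.span_end < self.position:
            raise ValueError(
                f"span_end {self.span_end} precedes position {self.position}"
            )
        if (self.kind is ChangeKind.NONSENSE) != (self.alt_residue == "*"):
            raise ValueError("kind is nonsense iff the alternate residue is a stop")

    @property
    def consequence(self) -> Consequence:
        return _KIND_TO_CONSEQUENCE[self.kind]

    @property
    def insert_length(self) -> int:
        """Number of inserted residues (0 unless kind is inframe_ins)."""
        if self.kind is not ChangeKind.INFRAME_INS or not self.seq:
            return 0
        return len(self.seq) // 3


@dataclass(frozen=True)
class PanelVariant:
    """One observed variant in one patient, as ingested from the variant table."""

    patient_id: str
    gene: str
    cdna_hgvs: str
    protein_hgvs: str
    consequence: Consequence
    maf_worldwide: Optional[float] = None
    maf_east_asian: Optional[float] = None
    clinvar_assertion: ClinvarAssertion = ClinvarAssertion.ABSENT
    hgmd_dm: bool = False
    de_novo: bool = False
    assertions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("maf_worldwide", "maf_east_asian"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not isinstance(self.assertions, frozenset):
            object.__setattr__(self, "assertions", frozenset(self.assertions))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene, self.cdna_hgvs, self.protein_hgvs)


@dataclass(frozen=True)
class DepthSummary:
    """Per-sample coverage over the panel's target bases."""

    sample_id: str
    n_target_bases: int
    n_bases_depth_gt60: int

    def __post_init__(self) -> None:
        if self.n_target_bases <= 0:
            raise ValueError("n_target_bases must be positive")
        if not 0 <= self.n_bases_depth_gt60 <= self.n_target_bases:
            raise ValueError("covered-base count outside [0, n_target_bases]")

    @property
    def covered_fraction(self) -> float:
        return self.n_bases_depth_gt60 / self.n_target_bases


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class StanfordType(str, enum.Enum):
    A = "A"
    B = "B"
    NONE = "none"


class CarrierClass(str, enum.Enum):
    """Patient-level carrier tier: the maximum classification over variants."""

    P_LP = "P_LP"
    VUS = "VUS"
    NV_LB = "NV_LB"


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    age_at_onset: float
    sex: Sex
    hypertension: bool
    hyperlipidaemia: bool
    diabetes: bool
    aortic_diameter_z: float
    aneurysm_present: bool
    stanford_type: StanfordType
    family_history: bool
    carrier_class: CarrierClass = CarrierClass.NV_LB

    def with_carrier_class(self, cls: CarrierClass) -> "CohortRecord":
        return dc_replace(self, carrier_class=cls)


#: the 23 genes of the panel (arterial tortuosity syndrome gene is SLC2A10;
#: a SLC1A10 typo circulates in some summaries of this panel)
DEFAULT_PANEL_GENES: tuple[str, ...] = (
    "FBN1",
    "FBN2",
    "TGFBR1",
    "TGFBR2",
    "SMAD2",
    "SMAD3",
    "TGFB2",
    "TGFB3",
    "COL1A1",
    "COL1A2",
    "COL3A1",
    "COL5A1",
    "COL5A2",
    "SLC2A10",
    "SKI",
    "EFEMP2",
    "ELN",
    "ACTA2",
    "MYH11",
    "MYLK",
    "PRKG1",
    "LOX",
    "NOTCH1",
)

COLLAGEN_GENES = frozenset(g for g in DEFAULT_PANEL_GENES if g.startswith("COL"))


@dataclass(frozen=True)
class CollagenDomain:
    """A triple-helical domain: 1-based inclusive residue interval plus the
    one-letter residue sequence covering it (Gly-X-Y register anchored at
    ``start``)."""

    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid domain interval")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                "domain sequence length does not match the residue interval"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class PanelConfig:
    """Panel definition and the gene-specific annotations the rule engine uses.

    ``collagen_domains`` maps a collagen gene to its triple-helical domain
    intervals; ``egf_consensus_positions`` lists the conserved EGF-consensus
    residue positions for FBN1 (empty by default — the cysteine clauses of the
    FBN1 rule are always active and do not need it); ``key_residues`` maps a
    gene to residue positions with a previously ascribed molecular mechanism.
    """

    genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    collagen_domains: Mapping[str, tuple[CollagenDomain, ...]] = field(
        default_factory=dict
    )
    egf_consensus_positions: frozenset[int] = frozenset()
    key_residues: Mapping[str, frozenset[int]] = field(default_factory=dict)
    splice_padding_bp: int = 15

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not isinstance(self.egf_consensus_positions, frozenset):
            object.__setattr__(
                self, "egf_consensus_positions", frozenset(self.egf_consensus_positions)
            )
        object.__setattr__(
            self,
            "key_residues",
            {g: frozenset(v) for g, v in dict(self.key_residues).items()},
        )
        domains = {}
        for gene, doms in dict(self.collagen_domains).items():
            doms = tuple(doms)
            ordered = sorted(doms, key=lambda d: d.start)
            for left, right in zip(ordered, ordered[1:]):
                if right.start <= left.end:
                    raise ValueError(f"overlapping collagen domains for {gene}")
            domains[gene] = doms
        object.__setattr__(self, "collagen_domains", domains)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def domains_for(self, gene: str) -> Sequence[CollagenDomain]:
        return self.collagen_domains.get(gene, ())
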