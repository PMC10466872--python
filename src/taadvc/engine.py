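"""Gene-aware pathogenicity classification for the TAAD panel.

Each filtered variant receives one of four categories — pathogenic, likely
pathogenic, VUS, likely benign — through two layers:

1. a set of gene-aware pathogenic rules (numbered I-VII) that assign
   *pathogenic* directly when any fires:

   I    asserted disease-causing in HGMD or pathogenic in ClinVar;
   II   same amino-acid substitution as a known pathogenic variant
        (injected lookup table, no live database);
   III  de novo null-type variant (nonsense, frameshift, in-frame
        insertion/deletion, or splice-site);
   IV   FBN1 missense that removes or creates a cysteine, or hits a
        configured conserved EGF-consensus residue;
   V    glycine substitution at an in-register Gly-X-Y position of a
        collagen triple-helical domain;
   VI   in-frame insertion that breaks the Gly-X-Y register of a collagen
        triple-helical domain;
   VII  alteration of a configured key residue with a previously ascribed
        molecular mechanism for that gene;

2. otherwise, combining of ACMG evidence codes (PVS1 / PS / PM / PP tiers)
   by the standard 2015 combining table, restricted to the pathogenic side
   (benign-side codes BA/BS/BP are not modelled; likely benign is reachable
   only as an explicit input assertion).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .hgvs import one_letter, parse_protein_hgvs
from .model import (
    CarrierClass,
    ChangeKind,
    ClinvarAssertion,
    CollagenDomain,
    Consequence,
    COLLAGEN_GENES,
    NULL_LIKE_CONSEQUENCES,
    PROTEIN_CONSEQUENCES,
    PanelConfig,
    PanelVariant,
    ProteinChange,
)


class ConfigurationError(ValueError):
    """The panel configuration disagrees with itself or with an input."""


class Tier(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class EvidenceCode(str, enum.Enum):
    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"

    @property
    def tier(self) -> Tier:
        if self is EvidenceCode.PVS1:
            return Tier.VERY_STRONG
        prefix = self.value[:2]
        return {"PS": Tier.STRONG, "PM": Tier.MODERATE, "PP": Tier.SUPPORTING}[prefix]


EvidenceSet = frozenset[EvidenceCode]

#: assertion token that marks an externally asserted likely-benign call
LIKELY_BENIGN_TOKEN = "LIKELY_BENIGN"


def parse_evidence(tokens: Iterable[str]) -> EvidenceSet:
    """Extract ACMG evidence codes from free assertion tokens.

    Tokens that are not evidence codes (segregation notes, functional facts,
    the likely-benign marker) are ignored here; they stay on the variant.
    """
    codes = set()
    valid = {c.value for c in EvidenceCode}
    for token in tokens:
        upper = token.strip().upper()
        if upper in valid:
            codes.add(EvidenceCode(upper))
    return frozenset(codes)


class Category(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"

    @property
    def rank(self) -> int:
        return {
            Category.PATHOGENIC: 3,
            Category.LIKELY_PATHOGENIC: 2,
            Category.VUS: 1,
            Category.LIKELY_BENIGN: 0,
        }[self]


class Provenance(str, enum.Enum):
    GENE_RULE = "gene_rule"
    ACMG_COMBINING = "acmg_combining"
    DEFAULT_VUS = "default_vus"


@dataclass(frozen=True)
class RuleHit:
    """One gene-aware rule that fired, with a human-readable detail."""

    rule: str  # "I".."VII"
    detail: str = ""

    _VALID = ("I", "II", "III", "IV", "V", "VI", "VII")

    def __post_init__(self) -> None:
        if self.rule not in self._VALID:
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class Classification:
    category: Category
    via: Provenance
    evidence: EvidenceSet = frozenset()
    rule_hits: tuple[RuleHit, ...] = ()

    def __post_init__(self) -> None:
        if self.via is Provenance.GENE_RULE and self.category is not Category.PATHOGENIC:
            raise ValueError("gene-rule classifications are always pathogenic")
        if self.via is Provenance.DEFAULT_VUS and (self.evidence or self.rule_hits):
            raise ValueError("default classifications carry no evidence or rule hits")


# --- known-pathogenic lookup for rule II ------------------------------------


class KnownPathogenicTable:
    """Injected table of known pathogenic amino-acid substitutions.

    Rule II fires when a missense variant produces the same substitution as
    an entry (matched on gene + reference residue + position + alternate
    residue).  Built from a TSV (columns: gene, protein_hgvs, source) or from
    in-memory pairs; replaces any live database query for reproducibility.
    """

    def __init__(self, entries: Iterable[tuple[str, str]] = ()) -> None:
        self._subs: set[tuple[str, str, int, str]] = set()
        for gene, protein_hgvs in entries:
            self.add(gene, protein_hgvs)

    def add(self, gene: str, protein_hgvs: str) -> None:
        change = parse_protein_hgvs(protein_hgvs)
        if change.kind is ChangeKind.MISSENSE:
            self._subs.add(
                (gene, change.ref_residue, change.position, change.alt_residue)
            )

    @classmethod
    def from_tsv(cls, path) -> "KnownPathogenicTable":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("gene", "protein_hgvs"):
            if col not in frame.columns:
                raise ValueError(f"{path}: missing column {col}")
        return cls(zip(frame["gene"], frame["protein_hgvs"]))

    def matches(self, gene: str, change: ProteinChange) -> bool:
        return (
            change.kind is ChangeKind.MISSENSE
            and (gene, change.ref_residue, change.position, change.alt_residue)
            in self._subs
        )

    def __len__(self) -> int:
        return len(self._subs)


# --- rule detectors ----------------------------------------------------------


def detect_glyxy_hit(
    change: ProteinChange,
    domains: Sequence[CollagenDomain],
) -> Optional[RuleHit]:
    """Collagen triple-helix rules: Gly substitution in register (V) or a
    register-breaking in-frame insertion (VI).

    The Gly-X-Y register is anchored at each domain's start residue, so a
    position is triplet-initial iff ``(position - start) % 3 == 0``.
    """
    for domain in domains:
        if not domain.contains(change.position):
            continue
        offset = change.position - domain.start
        if change.kind is ChangeKind.MISSENSE and change.ref_residue == "Gly":
            if domain.sequence[offset] != one_letter(change.ref_residue):
                raise ConfigurationError(
                    f"domain sequence has {domain.sequence[offset]!r} at residue "
                    f"{change.position}, variant reference is Gly"
                )
            if offset % 3 == 0:
                return RuleHit(
                    "V", f"Gly{change.position} is triplet-initial in the domain"
                )
        if change.kind is ChangeKind.INFRAME_INS and domain.contains(change.span_end):
            if change.insert_length % 3 != 0:
                return RuleHit(
                    "VI",
                    f"insertion of {change.insert_length} residue(s) breaks the "
                    "Gly-X-Y register",
                )
    return None


def detect_fbn1_hit(
    change: ProteinChange, config: PanelConfig
) -> Optional[RuleHit]:
    """FBN1 missense rule (IV): cysteine removed or created, or a configured
    conserved EGF-consensus residue affected."""
    if change.kind is not ChangeKind.MISSENSE:
        return None
    if change.ref_residue == "Cys":
        return RuleHit("IV", f"cysteine affected at {change.position}")
    if change.alt_residue == "Cys":
        return RuleHit("IV", f"cysteine created at {change.position}")
    if change.position in config.egf_consensus_positions:
        return RuleHit("IV", f"conserved EGF-consensus residue {change.position}")
    return None


def _key_residue_hit(
    gene: str, change: ProteinChange, config: PanelConfig
) -> Optional[RuleHit]:
    positions = config.key_residues.get(gene)
    if not positions:
        return None
    if change.kind in (ChangeKind.MISSENSE, ChangeKind.INFRAME_DEL):
        affected = range(change.position, change.span_end + 1)
        hit = sorted(positions.intersection(affected))
        if hit:
            return RuleHit("VII", f"key residue {hit[0]} altered")
    return None


def apply_gene_rules(
    variant: PanelVariant,
    change: Optional[ProteinChange],
    db_lookup: Optional[KnownPathogenicTable] = None,
    config: Optional[PanelConfig] = None,
) -> list[RuleHit]:
    """Evaluate rules I-VII and return every hit, in rule order."""
    config = config or PanelConfig()
    hits: list[RuleHit] = []
    if variant.clinvar_assertion is ClinvarAssertion.PATHOGENIC or variant.hgmd_dm:
        source = "HGMD DM" if variant.hgmd_dm else "ClinVar pathogenic"
        hits.append(RuleHit("I", source))
    if db_lookup is not None and change is not None and db_lookup.matches(
        variant.gene, change
    ):
        hits.append(RuleHit("II", "same substitution as a known pathogenic variant"))
    if variant.de_novo and variant.consequence in NULL_LIKE_CONSEQUENCES:
        hits.append(RuleHit("III", f"de novo {variant.consequence.value}"))
    if change is not None:
        if variant.gene == "FBN1":
            hit = detect_fbn1_hit(change, config)
            if hit:
                hits.append(hit)
        if variant.gene in COLLAGEN_GENES:
            hit = detect_glyxy_hit(change, config.domains_for(variant.gene))
            if hit:
                hits.append(hit)
        hit = _key_residue_hit(variant.gene, change, config)
        if hit:
            hits.append(hit)
    return hits


# --- ACMG combining -----------------------------------------------------------


def combine_acmg(evidence: Iterable[EvidenceCode | str]) -> Category:
    """Combine pathogenic-side ACMG evidence codes into a category.

    Implements the 2015 combining table for the pathogenic and likely
    pathogenic calls; with no qualifying combination the variant stays VUS.
    """
    codes = set()
    for code in evidence:
        if isinstance(code, str):
            try:
                code = EvidenceCode(code.upper())
            except ValueError:
                raise ValueError(f"unknown evidence code {code!r}") from None
        codes.add(code)
    vs = EvidenceCode.PVS1 in codes
    s = sum(1 for c in codes if c.tier is Tier.STRONG)
    m = sum(1 for c in codes if c.tier is Tier.MODERATE)
    p = sum(1 for c in codes if c.tier is Tier.SUPPORTING)

    pathogenic = (
        (vs and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    if pathogenic:
        return Category.PATHOGENIC
    likely = (
        (vs and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    if likely:
        return Category.LIKELY_PATHOGENIC
    return Category.VUS


# --- classification ------------------------------------------------------------


def classify(
    variant: PanelVariant,
    config: Optional[PanelConfig] = None,
    db_lookup: Optional[KnownPathogenicTable] = None,
) -> Classification:
    """Classify one filtered variant.

    Gene rules I-VII take precedence and assign pathogenic directly; otherwise
    the ACMG evidence codes found among the variant's assertion tokens are
    combined.  A variant with no rules and no evidence defaults to VUS, unless
    it carries an explicit likely-benign assertion token.
    """
    config = config or PanelConfig()
    change: Optional[ProteinChange] = None
    if variant.protein_hgvs and variant.consequence in PROTEIN_CONSEQUENCES:
        change = parse_protein_hgvs(variant.protein_hgvs)

    hits = tuple(apply_gene_rules(variant, change, db_lookup, config))
    evidence = parse_evidence(variant.assertions)
    if hits:
        return Classification(
            Category.PATHOGENIC, Provenance.GENE_RULE, evidence, hits
        )
    if evidence:
        return Classification(
            combine_acmg(evidence), Provenance.ACMG_COMBINING, evidence
        )
    if LIKELY_BENIGN_TOKEN in {t.upper() for t in variant.assertions}:
        return Classification(Category.LIKELY_BENIGN, Provenance.DEFAULT_VUS)
    return Classification(Category.VUS, Provenance.DEFAULT_VUS)


def classify_all(
    variants: Sequence[PanelVariant],
    config: Optional[PanelConfig] = None,
    db_lookup: Optional[KnownPathogenicTable] = None,
) -> list[tuple[PanelVariant, Classification]]:
    return [(v, classify(v, config, db_lookup)) for v in variants]


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts per category and per gene, plus per-gene P/LP proportions."""

    category_counts: Mapping[Category, int]
    gene_counts: Mapping[str, Mapping[Category, int]]

    @property
    def total(self) -> int:
        return sum(self.category_counts.values())

    def p_lp_fraction(self, gene: str) -> float:
        counts = self.gene_counts.get(gene, {})
        total = sum(counts.values())
        if total == 0:
            return 0.0
        plp = counts.get(Category.PATHOGENIC, 0) + counts.get(
            Category.LIKELY_PATHOGENIC, 0
        )
        return plp / total


def summarize_classifications(
    records: Sequence[tuple[PanelVariant, Classification]],
) -> ClassificationSummary:
    category_counts: Counter = Counter({c: 0 for c in Category})
    gene_counts: dict[str, Counter] = {}
    for variant, cls in records:
        category_counts[cls.category] += 1
        gene_counts.setdefault(variant.gene, Counter())[cls.category] += 1
    return ClassificationSummary(
        category_counts=dict(category_counts),
        gene_counts={g: dict(c) for g, c in gene_counts.items()},
    )


_CARRIER_BY_CATEGORY = {
    Category.PATHOGENIC: CarrierClass.P_LP,
    Category.LIKELY_PATHOGENIC: CarrierClass.P_LP,
    Category.VUS: CarrierClass.VUS,
    Category.LIKELY_BENIGN: CarrierClass.NV_LB,
}

_CARRIER_RANK = {CarrierClass.P_LP: 2, CarrierClass.VUS: 1, CarrierClass.NV_LB: 0}


def carrier_class(categories: Iterable[Category]) -> CarrierClass:
    """Patient-level carrier tier: the maximum classification over the
    patient's retained variants (no variants -> NV_LB)."""
    best = CarrierClass.NV_LB
    for cat in categories:
        tier = _CARRIER_BY_CATEGORY[cat]
        if _CARRIER_RANK[tier] > _CARRIER_RANK[best]:
            best = tier
    return best
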