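"""Readers and writers for the pipeline's tabular formats.

Four tables move through the pipeline: the per-patient variant table (TSV or
VCF dialect), the per-sample depth summary, the cohort phenotype table, and
the classified-variant output table.  TSV is the primary dialect: UTF-8,
tab-separated, one header row, empty cell = absent, frequencies as decimal
fractions.  The VCF dialect carries the same fields in INFO keys (GENE,
CHGVS, PHGVS, CSQ, AF_ALL, AF_EAS, CLNSIG, HGMD, DENOVO, ASSERT) with one
record per patient x variant and a 0/1 genotype for the carrying sample.

Panel configuration is YAML.  All writers are deterministic: identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
import yaml

from .engine import Classification, Category, Provenance, RuleHit, parse_evidence
from .hgvs import parse_protein_hgvs
from .model import (
    CarrierClass,
    ClinvarAssertion,
    CohortRecord,
    CollagenDomain,
    Consequence,
    DepthSummary,
    PROTEIN_CONSEQUENCES,
    PanelConfig,
    PanelVariant,
    Sex,
    StanfordType,
)


class SchemaError(ValueError):
    """A required column or INFO key is missing from an input file."""


VARIANT_COLUMNS = [
    "patient_id",
    "gene",
    "cdna_hgvs",
    "protein_hgvs",
    "consequence",
    "maf_worldwide",
    "maf_east_asian",
    "clinvar",
    "hgmd_dm",
    "de_novo",
    "assertions",
]

PHENOTYPE_COLUMNS = [
    "patient_id",
    "age_at_onset",
    "sex",
    "hypertension",
    "hyperlipidaemia",
    "diabetes",
    "aortic_diameter_z",
    "aneurysm_present",
    "stanford_type",
    "family_history",
]

DEPTH_COLUMNS = ["sample_id", "n_target_bases", "n_bases_depth_gt60"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(cell: str, column: str, row: int) -> bool:
    low = cell.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse {column}={cell!r} as boolean")


def _parse_frequency(cell: str, column: str, row: int) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError:
        raise ValueError(f"row {row}: malformed frequency {column}={cell!r}") from None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"row {row}: frequency {column}={value} outside [0, 1]")
    return value


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return frame


def _variant_from_fields(
    row_no: int,
    config: PanelConfig,
    *,
    patient_id: str,
    gene: str,
    cdna_hgvs: str,
    protein_hgvs: str,
    consequence: str,
    maf_worldwide: Optional[float],
    maf_east_asian: Optional[float],
    clinvar: str,
    hgmd_dm: bool,
    de_novo: bool,
    assertions: frozenset[str],
) -> Optional[PanelVariant]:
    """Build one PanelVariant; returns None for off-panel genes."""
    if gene not in config:
        return None
    try:
        cons = Consequence(consequence)
    except ValueError:
        raise ValueError(f"row {row_no}: unknown consequence {consequence!r}") from None
    clin = ClinvarAssertion(clinvar) if clinvar else ClinvarAssertion.ABSENT
    if protein_hgvs and cons in PROTEIN_CONSEQUENCES:
        change = parse_protein_hgvs(protein_hgvs)
        if change.consequence is not cons:
            raise ValueError(
                f"row {row_no}: consequence {cons.value!r} inconsistent with "
                f"protein change {protein_hgvs!r} ({change.consequence.value})"
            )
    return PanelVariant(
        patient_id=patient_id,
        gene=gene,
        cdna_hgvs=cdna_hgvs,
        protein_hgvs=protein_hgvs,
        consequence=cons,
        maf_worldwide=maf_worldwide,
        maf_east_asian=maf_east_asian,
        clinvar_assertion=clin,
        hgmd_dm=hgmd_dm,
        de_novo=de_novo,
        assertions=assertions,
    )


def read_variant_table(
    path: str | os.PathLike,
    format: str = "tsv",
    config: Optional[PanelConfig] = None,
) -> tuple[list[PanelVariant], int]:
    """Read a variant table in either dialect.

    Returns ``(variants, n_off_panel)`` where ``n_off_panel`` counts rows
    rejected because their gene is not on the configured panel.
    """
    config = config or PanelConfig()
    if format == "tsv":
        return _read_variants_tsv(path, config)
    if format == "vcf":
        return _read_variants_vcf(path, config)
    raise ValueError(f"unknown variant table format {format!r}")


def _read_variants_tsv(
    path: str | os.PathLike, config: PanelConfig
) -> tuple[list[PanelVariant], int]:
    frame = _read_tsv(path, VARIANT_COLUMNS)
    variants: list[PanelVariant] = []
    rejected = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        variant = _variant_from_fields(
            idx,
            config,
            patient_id=row.patient_id,
            gene=row.gene,
            cdna_hgvs=row.cdna_hgvs,
            protein_hgvs=row.protein_hgvs,
            consequence=row.consequence,
            maf_worldwide=_parse_frequency(row.maf_worldwide, "maf_worldwide", idx),
            maf_east_asian=_parse_frequency(row.maf_east_asian, "maf_east_asian", idx),
            clinvar=row.clinvar.strip(),
            hgmd_dm=_parse_bool(row.hgmd_dm, "hgmd_dm", idx),
            de_novo=_parse_bool(row.de_novo, "de_novo", idx),
            assertions=frozenset(t for t in row.assertions.split(";") if t),
        )
        if variant is None:
            rejected += 1
        else:
            variants.append(variant)
    return variants, rejected


def _fmt_freq(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def _variant_row(v: PanelVariant) -> dict[str, str]:
    return {
        "patient_id": v.patient_id,
        "gene": v.gene,
        "cdna_hgvs": v.cdna_hgvs,
        "protein_hgvs": v.protein_hgvs,
        "consequence": v.consequence.value,
        "maf_worldwide": _fmt_freq(v.maf_worldwide),
        "maf_east_asian": _fmt_freq(v.maf_east_asian),
        "clinvar": ""
        if v.clinvar_assertion is ClinvarAssertion.ABSENT
        else v.clinvar_assertion.value,
        "hgmd_dm": "true" if v.hgmd_dm else "false",
        "de_novo": "true" if v.de_novo else "false",
        "assertions": ";".join(sorted(v.assertions)),
    }


def write_variant_table(
    variants: Iterable[PanelVariant], path: str | os.PathLike
) -> None:
    frame = pd.DataFrame([_variant_row(v) for v in variants], columns=VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


# --- VCF dialect -----------------------------------------------------------

_VCF_INFO_LINES = [
    ("GENE", "1", "String", "Panel gene symbol"),
    ("CHGVS", "1", "String", "cDNA HGVS"),
    ("PHGVS", "1", "String", "Protein HGVS"),
    ("CSQ", "1", "String", "Consequence class"),
    # frequencies are carried as strings so the decimal text round-trips
    # (VCF Float is 32-bit and would perturb e.g. 6e-06)
    ("AF_ALL", "1", "String", "Worldwide population allele frequency"),
    ("AF_EAS", "1", "String", "East-Asian population allele frequency"),
    ("CLNSIG", "1", "String", "ClinVar assertion"),
    ("HGMD", "0", "Flag", "HGMD disease-causing (DM)"),
    ("DENOVO", "0", "Flag", "De novo in the patient"),
    ("ASSERT", ".", "String", "External evidence tokens"),
]


def write_variant_vcf(
    variants: Sequence[PanelVariant],
    path: str | os.PathLike,
    config: Optional[PanelConfig] = None,
) -> None:
    """Write variants as an uncompressed multi-sample VCF.

    Coordinates are synthetic (one pseudo-contig per gene, positions in input
    order): the panel workflow keys off gene + HGVS, not genomic position.
    """
    config = config or PanelConfig()
    header = pysam.VariantHeader()
    for gene in config.genes:
        header.contigs.add(gene, length=2_000_000)
    for name, number, typ, desc in _VCF_INFO_LINES:
        header.info.add(name, number, typ, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    samples = list(dict.fromkeys(v.patient_id for v in variants))
    for sample in samples:
        header.add_sample(sample)

    pos_counter: dict[str, int] = {}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            pos_counter[v.gene] = pos_counter.get(v.gene, 0) + 1
            rec = out.new_record(
                contig=v.gene,
                start=pos_counter[v.gene] - 1,
                stop=pos_counter[v.gene],
                alleles=("N", "<VAR>"),
            )
            rec.info["GENE"] = v.gene
            rec.info["CHGVS"] = v.cdna_hgvs or "."
            rec.info["PHGVS"] = v.protein_hgvs or "."
            rec.info["CSQ"] = v.consequence.value
            if v.maf_worldwide is not None:
                rec.info["AF_ALL"] = repr(v.maf_worldwide)
            if v.maf_east_asian is not None:
                rec.info["AF_EAS"] = repr(v.maf_east_asian)
            if v.clinvar_assertion is not ClinvarAssertion.ABSENT:
                rec.info["CLNSIG"] = v.clinvar_assertion.value
            if v.hgmd_dm:
                rec.info["HGMD"] = True
            if v.de_novo:
                rec.info["DENOVO"] = True
            if v.assertions:
                rec.info["ASSERT"] = tuple(sorted(v.assertions))
            for sample in samples:
                rec.samples[sample]["GT"] = (0, 1) if sample == v.patient_id else (0, 0)
            out.write(rec)


def _read_variants_vcf(
    path: str | os.PathLike, config: PanelConfig
) -> tuple[list[PanelVariant], int]:
    variants: list[PanelVariant] = []
    rejected = 0
    with pysam.VariantFile(str(path)) as vcf:
        for key in ("GENE", "CHGVS", "PHGVS", "CSQ"):
            if key not in vcf.header.info:
                raise SchemaError(f"{path}: missing required INFO key {key}")
        for row_no, rec in enumerate(vcf, start=1):
            info = rec.info
            gene = info.get("GENE") or rec.chrom
            assertions = frozenset(info.get("ASSERT") or ())
            for sample in rec.samples.values():
                gt = sample.get("GT") or ()
                if not any(allele for allele in gt if allele):
                    continue
                variant = _variant_from_fields(
                    row_no,
                    config,
                    patient_id=sample.name,
                    gene=gene,
                    cdna_hgvs=_dot(info.get("CHGVS")),
                    protein_hgvs=_dot(info.get("PHGVS")),
                    consequence=info.get("CSQ"),
                    maf_worldwide=_parse_frequency(
                        info.get("AF_ALL") or "", "AF_ALL", row_no
                    ),
                    maf_east_asian=_parse_frequency(
                        info.get("AF_EAS") or "", "AF_EAS", row_no
                    ),
                    clinvar=info.get("CLNSIG") or "",
                    hgmd_dm=bool(info.get("HGMD")),
                    de_novo=bool(info.get("DENOVO")),
                    assertions=assertions,
                )
                if variant is None:
                    rejected += 1
                else:
                    variants.append(variant)
    return variants, rejected


def _dot(value: Optional[str]) -> str:
    return "" if value in (None, ".") else value


# --- classified table ------------------------------------------------------

CLASSIFIED_COLUMNS = VARIANT_COLUMNS + ["category", "via", "evidence", "rule_hits"]


def write_classified_table(
    records: Sequence[tuple[PanelVariant, Classification]],
    path: str | os.PathLike,
) -> None:
    """Write variants with their classifications; the file round-trips."""
    rows = []
    for variant, cls in records:
        row = _variant_row(variant)
        row["category"] = cls.category.value
        row["via"] = cls.via.value
        row["evidence"] = ";".join(sorted(c.value for c in cls.evidence))
        row["rule_hits"] = ";".join(
            f"{hit.rule}:{hit.detail}" if hit.detail else hit.rule
            for hit in cls.rule_hits
        )
        rows.append(row)
    pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_classified_table(
    path: str | os.PathLike, config: Optional[PanelConfig] = None
) -> list[tuple[PanelVariant, Classification]]:
    config = config or PanelConfig()
    frame = _read_tsv(path, CLASSIFIED_COLUMNS)
    records: list[tuple[PanelVariant, Classification]] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        variant = _variant_from_fields(
            idx,
            config,
            patient_id=row.patient_id,
            gene=row.gene,
            cdna_hgvs=row.cdna_hgvs,
            protein_hgvs=row.protein_hgvs,
            consequence=row.consequence,
            maf_worldwide=_parse_frequency(row.maf_worldwide, "maf_worldwide", idx),
            maf_east_asian=_parse_frequency(row.maf_east_asian, "maf_east_asian", idx),
            clinvar=row.clinvar.strip(),
            hgmd_dm=_parse_bool(row.hgmd_dm, "hgmd_dm", idx),
            de_novo=_parse_bool(row.de_novo, "de_novo", idx),
            assertions=frozenset(t for t in row.assertions.split(";") if t),
        )
        if variant is None:
            raise ValueError(f"row {idx}: off-panel gene in classified table")
        hits = []
        for token in (t for t in row.rule_hits.split(";") if t):
            rule, _, detail = token.partition(":")
            hits.append(RuleHit(rule=rule, detail=detail))
        cls = Classification(
            category=Category(row.category),
            via=Provenance(row.via),
            evidence=parse_evidence(t for t in row.evidence.split(";") if t),
            rule_hits=tuple(hits),
        )
        records.append((variant, cls))
    return records


# --- phenotype and depth tables -------------------------------------------


def read_phenotype_table(path: str | os.PathLike) -> list[CohortRecord]:
    frame = _read_tsv(path, PHENOTYPE_COLUMNS)
    records = []
    has_carrier = "carrier_class" in frame.columns
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        records.append(
            CohortRecord(
                patient_id=row.patient_id,
                age_at_onset=float(row.age_at_onset),
                sex=Sex(row.sex),
                hypertension=_parse_bool(row.hypertension, "hypertension", idx),
                hyperlipidaemia=_parse_bool(row.hyperlipidaemia, "hyperlipidaemia", idx),
                diabetes=_parse_bool(row.diabetes, "diabetes", idx),
                aortic_diameter_z=float(row.aortic_diameter_z),
                aneurysm_present=_parse_bool(row.aneurysm_present, "aneurysm_present", idx),
                stanford_type=StanfordType(row.stanford_type),
                family_history=_parse_bool(row.family_history, "family_history", idx),
                carrier_class=CarrierClass(row.carrier_class)
                if has_carrier
                else CarrierClass.NV_LB,
            )
        )
    return records


def write_phenotype_table(
    records: Iterable[CohortRecord],
    path: str | os.PathLike,
    include_carrier_class: bool = False,
) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_at_onset": repr(r.age_at_onset),
            "sex": r.sex.value,
            "hypertension": "true" if r.hypertension else "false",
            "hyperlipidaemia": "true" if r.hyperlipidaemia else "false",
            "diabetes": "true" if r.diabetes else "false",
            "aortic_diameter_z": repr(r.aortic_diameter_z),
            "aneurysm_present": "true" if r.aneurysm_present else "false",
            "stanford_type": r.stanford_type.value,
            "family_history": "true" if r.family_history else "false",
        }
        if include_carrier_class:
            row["carrier_class"] = r.carrier_class.value
        rows.append(row)
    columns = PHENOTYPE_COLUMNS + (["carrier_class"] if include_carrier_class else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_depth_table(path: str | os.PathLike) -> list[DepthSummary]:
    frame = _read_tsv(path, DEPTH_COLUMNS)
    return [
        DepthSummary(
            sample_id=row.sample_id,
            n_target_bases=int(row.n_target_bases),
            n_bases_depth_gt60=int(row.n_bases_depth_gt60),
        )
        for row in frame.itertuples(index=False)
    ]


def write_depth_table(summaries: Iterable[DepthSummary], path: str | os.PathLike) -> None:
    rows = [
        {
            "sample_id": d.sample_id,
            "n_target_bases": str(d.n_target_bases),
            "n_bases_depth_gt60": str(d.n_bases_depth_gt60),
        }
        for d in summaries
    ]
    pd.DataFrame(rows, columns=DEPTH_COLUMNS).to_csv(path, sep="\t", index=False)


# --- panel configuration ----------------------------------------------------


def load_panel_config(path: str | os.PathLike) -> PanelConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    domains = {
        gene: tuple(
            CollagenDomain(start=d["start"], end=d["end"], sequence=d["sequence"])
            for d in doms
        )
        for gene, doms in (data.get("collagen_domains") or {}).items()
    }
    return PanelConfig(
        genes=tuple(data.get("genes") or PanelConfig().genes),
        collagen_domains=domains,
        egf_consensus_positions=frozenset(data.get("egf_consensus_positions") or ()),
        key_residues={
            g: frozenset(v) for g, v in (data.get("key_residues") or {}).items()
        },
        splice_padding_bp=data.get("splice_padding_bp", 15),
    )


def save_panel_config(config: PanelConfig, path: str | os.PathLike) -> None:
    data = {
        "genes": list(config.genes),
        "collagen_domains": {
            gene: [{"start": d.start, "end": d.end, "sequence": d.sequence} for d in doms]
            for gene, doms in config.collagen_domains.items()
        },
        "egf_consensus_positions": sorted(config.egf_consensus_positions),
        "key_residues": {g: sorted(v) for g, v in config.key_residues.items()},
        "splice_padding_bp": config.splice_padding_bp,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)
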