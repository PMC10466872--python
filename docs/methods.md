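# Methods

## Scope and data model

`taadvc` models the downstream analysis of a 23-gene TAAD sequencing panel.
Its unit of observation is a *patient × variant* row (`PanelVariant`):
gene symbol, cDNA and protein HGVS strings, consequence class, worldwide and
East-Asian population allele frequencies, optional clinical-database
assertions (ClinVar category, HGMD DM flag), de novo status, and free
assertion tokens (which may include ACMG evidence codes). HGVS strings are
trusted input: there is no transcript mapping and no cDNA↔protein
consistency proof beyond checking that the declared consequence class
matches the parsed protein change. Protein positions are 1-based; any
genomic intervals follow the 0-based half-open convention.

An absent population frequency is distinct from zero and is recorded as
absent. Absence from the reference population is treated as evidence of
rarity: it can never trigger the frequency filter. A frequency printed as an
exact zero is ingested as 0.0.

The default panel carries 23 genes. The arterial-tortuosity-syndrome gene is
`SLC2A10`; a `SLC1A10` typo circulates in some summaries of this panel and
is deliberately not accepted.

## Filtering

All three filters use strict inequalities, pinned by their verbal
definitions:

| filter | rule | boundary behaviour |
|---|---|---|
| frequency | exclude if MAF > 0.001 in **either** population | MAF = 0.001 is retained |
| consequence | exclude synonymous/intronic unless ClinVar P/LP or HGMD DM | splice-site always retained |
| sample QC | exclude sample if < 80% of target bases have depth > 60 | exactly 80% passes; a base at depth 60 is uncovered |

Sample QC runs first; a failing sample's variants are all excluded with
reason `coverage_fail` and the patient leaves the cohort denominator used by
the association stage. Intronic positions within the assay's 15 bp exon
padding are expected to be annotated `splice_site` upstream and are
retained. The "either population" wording is implemented literally: a
variant present in only one reference population is filtered on that
population alone.

The filter stage satisfies three invariants, enforced by property tests:
every input appears exactly once in the outcome log; decisions are
independent of input order; and raising the frequency threshold can only
move variants from excluded to retained.

## Classification

Classification has two layers. **Gene-aware rules I–VII** fire first and
assign *pathogenic* directly — they take precedence over evidence combining,
which is what lets a variant whose printed evidence only combines to likely
pathogenic still be called pathogenic when, say, it destroys an FBN1
cysteine:

* **I** — asserted pathogenic in ClinVar or disease-causing (DM) in HGMD.
  Only the `pathogenic` ClinVar category fires rule I; `likely_pathogenic`
  is honoured by the consequence-filter rescue but is not, by itself, taken
  as proof of pathogenicity.
* **II** — same amino-acid substitution (gene + ref + position + alt) as an
  entry of an injected known-pathogenic table. The table is a plain TSV, not
  a live database query, for reproducibility.
* **III** — de novo *null-type* variant. The eligible class list is taken
  literally: nonsense, frameshift, in-frame insertion/deletion, splice-site.
  The underlying intent is probably "null variant" generally; the literal
  list is kept and a de novo missense never fires III.
* **IV** — FBN1 missense that removes a cysteine, creates a cysteine, or
  affects a configured conserved EGF-consensus residue. The cysteine clauses
  are always active; the consensus-residue set is configuration with an
  empty default, because no authoritative residue list ships with the
  package and guessing a motif would be worse than abstaining.
* **V** — glycine substitution at an in-register Gly-X-Y position of a
  collagen triple-helical domain. The register is anchored at the configured
  domain start: position *p* is triplet-initial iff `(p − start) % 3 == 0`.
  The configuration carries the domain sequence; a disagreement between the
  configured sequence and the variant's reference residue raises a
  configuration error rather than silently deciding either way.
* **VI** — in-frame insertion inside a collagen triple-helical domain whose
  inserted length is not divisible by 3 residues. Insertions of a multiple
  of 3 residues shift the downstream register by whole triplets and are not
  flagged; whether the inserted segment itself respects Gly-X-Y is not
  modelled.
* **VII** — alteration (missense or in-frame deletion span) of a configured
  key residue with a previously ascribed molecular mechanism. Config-driven,
  default empty.

**ACMG combining** applies when no rule fires. Only pathogenic-side codes
are modelled (PVS1; PS1–PS4; PM1–PM6; PP1–PP5); benign-side codes (BA/BS/BP)
are out of scope and *likely benign* is reachable only through an explicit
input assertion token. The combining table is the standard 2015 one,
implemented over tier counts with ≥ semantics so that adding evidence can
never lower the category (a monotonicity property test guards this). A
brute-force clause-by-clause oracle in the test suite agrees with the
implementation over every evidence set of size ≤ 5.

A patient's **carrier class** is the maximum classification over their
retained variants (P/LP > VUS > NV/LB), so patients with several variants
count once in every denominator.

## Association statistics

For each of eight traits (onset age < 50, female sex, normotension,
normolipidaemia, normoglycaemia, aortic-diameter Z score > 2, aneurysm
presence, Stanford type A) the cohort splits into trait-positive (exposed)
and trait-negative (reference) groups. Trait polarity follows the clinical
convention of reporting the *protective-sounding* level as exposure, so
RR > 1 means carriers are enriched among, e.g., normotensive patients.

* **Relative risk.** RR = (a/n₁)/(b/n₂). When any of the four table cells
  (a, n₁−a, b, n₂−b) is zero, 0.5 is added to all four cells
  (Haldane–Anscombe): a′ = a+0.5, n₁′ = n₁+1, etc.; the corrected cells feed
  both the point estimate and the log-normal CI
  exp(ln RR ± z·SE), SE = √(1/a′ − 1/n₁′ + 1/b′ − 1/n₂′), z = 1.959964.
* **Fisher exact test**, two-sided, in the standard "sum of table
  probabilities not exceeding the observed" definition (scipy's
  implementation, cross-checked in the test suite against an exhaustive
  hypergeometric enumerator on every table with n₁+n₂ ≤ 40, with the
  conventional 1 + 1e−7 relative slack on probability ties). Published risk
  tables computed under other two-sided conventions (e.g. tail doubling)
  will not match these p-values; the rendered report says so explicitly
  rather than adjusting.
* **Rank-sum test** for onset-age comparisons: exact by enumeration of all
  C(n₁+n₂, n₁) group assignments with midrank ties when n₁+n₂ ≤ 12, with
  two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))); the tie-corrected normal
  approximation otherwise. An independent oracle that counts pairwise wins
  instead of summing ranks checks the exact path.
* No multiple-testing adjustment; two-sided α = 0.05 is the reporting
  convention, matching practice for a descriptive eight-trait panel.

The report prints percentages to 1 decimal and RR/CI to 4 decimals, flags
any internal inconsistency between trait-table margins and cohort totals
instead of hiding it, and contains no timestamps, so a re-run under the same
seed is byte-identical (the manifest records a timestamp, but the report
digest covers the report body only).

## Synthetic cohorts

The generator emulates a ~100-patient TAAD case cohort on the 23-gene
panel. Defaults (all overridable in `SimConfig`):

* onset age ~ truncated normal, mean 57 y, SD 14 y, bounds [13, 80] y;
* binary traits by independent Bernoulli draws: female 0.188, hypertension
  0.723, hyperlipidaemia 0.485, diabetes 0.495, Z > 2 0.455, aneurysm 0.653,
  Stanford A/B 0.594/0.287, family history 0.01;
* P/LP carrier status per (age < 50, normotension) stratum, default risks
  0.005 / 0.03 / 0.10 / 0.35 for older-hypertensive / younger-hypertensive /
  older-normotensive / younger-normotensive — chosen to give ~6% overall
  carrier prevalence with strong enrichment among young and normotensive
  patients, the pattern such cohorts show;
* carrier variants are built to be classifiable by construction: two thirds
  are de novo null alleles (rule III), one third FBN1 cysteine missense with
  zero population frequency (rule IV);
* VUS count per patient ~ Poisson(0.65); VUS are missense with no evidence,
  frequencies from a mixture (30% absent, 20% exact zero, 50% uniform on
  [0, 0.005]) so roughly a quarter of raw variants exceed the 0.1% filter,
  as in real panels; gene choice weights FBN1 at 0.25 and spreads the rest
  uniformly; substitutions avoid Cys and Gly so a VUS can never trip rules
  IV–VI;
* depth summaries over 100 000 target bases with covered fractions in
  [0.85, 0.995] (QC failures only when `qc_fail_rate` > 0, drawn in
  [0.50, 0.79]).

Each table (phenotypes, variants, depths) draws from its own child stream of
the master `SeedSequence`, so regenerating one table never perturbs another,
and identical configurations give identical output bytes (ages are rounded
to 0.1 y, Z scores to 0.01, frequencies to 1e−8 before writing).

`inject_known_truth` rewrites the carrier model multiplicatively:
risk(stratum) = base · RR_age^[age<50] · RR_bp^[normotensive]. Because the
two axes are drawn independently, the population RR along each axis equals
its multiplier exactly (`population_rr` verifies the algebra), and targets
forcing any stratum risk above 1 are rejected naming the offending trait.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: relatedness and segregation structure, gene- and
domain-specific mutational spectra beyond the FBN1 weight, covariance among
clinical traits (each is drawn independently), annotation errors, sequencing
artefacts, and real transcript coordinates (cDNA strings are synthesized
consistently but are decorative).

## Problem sizes and verification

The parameter-recovery study runs 200 replicate cohorts of n = 500 with an
injected age-of-onset relative risk of 4 (base stratum risk 0.02, seeds
0–199): the median estimated RR must fall within 15% of truth and the 95%
CI must cover truth in 93–97% of replicates — both a point-estimate and an
interval calibration check of the whole pipeline, not just of the formula.
The Fisher cross-check enumerates every 2×2 table with n₁+n₂ ≤ 40. Both run
inside the ordinary pytest suite on one CPU in a few minutes.

## VCF dialect notes

The VCF reader/writer carries panel fields in INFO keys (GENE, CHGVS, PHGVS,
CSQ, AF_ALL, AF_EAS, CLNSIG, HGMD, DENOVO, ASSERT), one record per
patient × variant with a 0/1 genotype for the carrying sample.
Coordinates are synthetic (one pseudo-contig per gene): the panel workflow
keys off gene + HGVS, not genomic position. Frequencies travel as strings
because VCF's 32-bit Float would perturb values like 6e−06 and break the
lossless round-trip contract.

## Known limitations

* No in-silico effect predictors, no splice-effect modelling from sequence,
  no genome-reference or transcript lookup.
* Benign-side ACMG evidence is not modelled; the engine cannot *demote* a
  variant below VUS on its own.
* Rules IV (EGF consensus), V–VI (collagen domains) and VII (key residues)
  are only as good as the supplied configuration; all default to the
  always-active cysteine clauses plus empty position sets.
* The association stage is purely 2×2: no regression, survival analysis or
  covariate adjustment.
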