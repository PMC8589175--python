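# Methods

`pedvar` implements the analysis pattern used to resolve inherited
retinal dystrophy (IRD) families by whole-genome sequencing: per-sample
quality control, rare-variant filtering, inheritance-model segregation
testing over the pedigree, structural-variant characterization, and
cohort-level reporting. This note records the models, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Pedigrees and kinship

A pedigree is a directed acyclic graph of parent links. Marriage loops
(consanguinity) are allowed; only ancestry cycles are errors, because
consanguineous families are first-class inputs, not degenerate cases.
Kinship is computed exactly, as rationals, with the classical recursion
`phi(a,b) = 1/2 [phi(father_a, b) + phi(mother_a, b)]`, recursing on the
individual further from the founders (longest-path generation index
guarantees the recursed individual is never an ancestor of the other).
Half-founders are treated as children of one known parent and one
unrelated pool founder. A union is consanguineous iff the partners'
kinship is positive; the offspring inbreeding coefficient F equals that
kinship. Branches are maximal nuclear families (one parent couple plus
their sibship); every non-founder belongs to exactly one branch as
offspring, which is what the intrafamilial-heterogeneity search
partitions over.

## Variant model and filtering

Variants carry the annotation fields a SnpEff/PolyPhen2/CADD stack
produces, consumed as fields (the annotators themselves are out of
scope). The filter is two-tier:

* **Rarity** — strict `<` on every available allele-frequency field:
  0.005 against the 1000 Genomes panel, 0.05 against an in-house panel
  and 0.05 within the study cohort. A missing frequency passes: absence
  from a reference panel is evidence of rarity, not grounds for
  exclusion.
* **Deleteriousness** — `highly` iff impact HIGH, or PolyPhen
  possibly/probably damaging, or CADD Phred >= 30; `relatively` iff
  impact HIGH/MODERATE, or PolyPhen damaging, or CADD >= 20 (when not
  already `highly`). The disjunctions are deliberate OR-semantics; the
  `highly` set is a subset of the `relatively` disjunction by
  construction. PolyPhen only speaks to amino-acid substitutions, so its
  prediction is ignored whenever the HGVS-derived class is known to be
  non-missense.

Consequence classification is HGVS-driven, not transcript-aware.
Protein notation takes precedence: `fs` anywhere wins (frameshift), then
a terminating `*`/`Ter` (nonsense) — so an insertion whose protein
effect is an immediate stop is counted as nonsense — then
single-residue substitutions (missense/synonymous), then in-frame
del/dup/ins. Purely intronic cDNA notation is graded by offset
magnitude: |d| <= 2 is a canonical splice site, 3 <= |d| <= 8 splice
region; both count as "splice-altering" in tallies. The window extends
past the canonical +-2 because +5 donor-region substitutions are
established splice mutations in this disease group.

## Segregation models

All models are fully penetrant with no phenocopies; a single unaffected
carrier sinks a dominant candidate. Ungenotyped relatives are ignored,
never imputed. A verdict with no genotyped affected is *indeterminate*,
distinct from a failure.

* **AR hom** — all genotyped affected homozygous for the alternate, no
  unaffected homozygote, every genotyped parent of an affected carries
  the allele.
* **AR compound-het** — two variants in one gene, affected heterozygous
  for both. Phase comes from parents (alleles entering from different
  parents = trans; both from one parent = cis = fail) or, failing that,
  from offspring: a child is phase-informative only when its other
  parent cannot have supplied either allele (genotyped non-carrier, or
  ungenotyped under the rare-allele assumption); informative children
  carrying exactly one allele each prove trans, one carrying both proves
  cis. No informative relatives passes with phase `unknown`, flagged and
  ranked below phase-confirmed calls — families with unavailable
  parental DNA are reportable, just lower-confidence.
* **AD het (strict)** — every genotyped affected *heterozygous*, no
  unaffected carrier. Strict heterozygosity (rather than >= 1 allele) is
  deliberate: it is what separates plain dominant transmission from the
  pseudo-recessive pattern below, and it mirrors how dominant searches
  are actually run (filtering for heterozygous variants shared by all
  affected).
* **X-linked** — non-PAR X only. Affected males hemizygous; affected
  heterozygous females pass and are flagged `manifesting_carrier`;
  apparent father-to-son transmission (carrier father, carrier son,
  mother genotyped non-carrier) fails; a heterozygous diploid call in a
  male on non-PAR X is a data-inconsistency error, not a verdict.
* **De novo** — affected proband heterozygous, both parents genotyped
  homozygous-reference. When QC kinship estimates exist,
  parent-offspring relatedness must be confirmed (|phi - 0.25| <= 0.1);
  a mismatch fails with a `non_paternity` flag. Flanking haplotypes are
  checked over a +-250 kb window (configurable): any trio-impossible
  genotype at a window site rejects the call. The window size is a
  choice — large enough to span informative variation around a gene,
  small enough that independent loci do not enter.
* **Pseudo-recessive dominant** — in consanguineous families a dominant
  allele can run through both sides of a loop: every genotyped affected
  carries it (het or hom), at least one affected is homozygous, and no
  unaffected carries it. The homozygote requirement is what
  distinguishes this from plain AD; without it the verdict routes to the
  dominant model.

`scan_pedigree` evaluates every applicable (model, variant-or-pair)
combination and returns *all* passing verdicts, ordered recessive-first
for recessive-declared or consanguineous families and dominant-first
otherwise. Atypical flags: `multi_gene` when two or more genes pass
pedigree-wide over the same affected individuals;
`intrafamilial_heterogeneity` when nothing passes pedigree-wide but
branch-restricted re-scans resolve different branches with different
genes. Constraint ranking orders dominant-acting verdicts (AD, XL,
de-novo, pseudo-recessive) by descending constraint Z — `z_lof` for
truncating candidates (nonsense/frameshift/canonical splice), `z_mis`
otherwise — within the list positions they already occupy; recessive
verdicts never move, because constraint carries no prioritization signal
for recessive genes. Ties break on (chrom, pos); genes missing from the
panel score a logged neutral 0.

## Structural variants

Deletions are 1-based inclusive on the `g.START_ENDdel` convention, so
length = end - start + 1; internally intervals are half-open 0-based
(BED) with conversion at I/O only. Quality filtering drops events with
caller quality < 1 (likely false positives) or length < 1000 bp (caller
resolution floor); both boundaries are retained. Human-readable sizes
use magnitude-banded precision: >= 1 Mb to 0.1 Mb, 10 kb–1 Mb to 0.1 kb
(integral values printed without the decimal), < 10 kb to 1 kb. One
110,541 bp event in the curated tables rounds to 110.5 Kb under this rule yet is
conventionally quoted as "110 Kb"; that anomaly is documented rather
than special-cased.

CNV segregation recodes copy states as deletion-allele counts (copy 0 =
homozygous deletion, copy 1 = heterozygous) and reuses the small-variant
model tests unchanged; an SNV + heterozygous deletion in one gene on
opposite parental haplotypes is handled by the same compound-het test
with the deletion as a pseudo-allele.

Junction microhomology is the longest suffix of the retained left flank
equal to the prefix of the retained right flank — the exact repeat
shared by both breakpoint sides that non-homologous end-joining leaves
behind. An `N` inside a candidate tract terminates it.

## Cohort QC

Sex is inferred from the heterozygosity rate at non-PAR X sites
(PAR bounds chrX:60,001–2,699,520 and 154,931,044–155,260,560, hg19):
< 0.05 male, > 0.15 female, the gap returns unknown. At least 200 called
sites are required. The thresholds leave a wide margin under a 1%
genotyping-error model (simulated males land near 0.01, females near
0.3).

Observed kinship uses the KING-robust within-family moment estimator,
`phi = (N_het_het - 2 N_opposite_hom) / (N_het_a + N_het_b)`, chosen
because it needs no allele-frequency estimates and therefore tolerates
the strong founder structure of family cohorts; it returns 0.5 for
duplicates and ~0 for unrelated pairs by construction. At 10,000
informative sites the estimate sits within +-0.03 of the analytic value
for first-degree and first-cousin pairs. Declared pairs at second degree
or closer whose estimate strays beyond 0.1 are flagged as mismatches
(blocking de-novo calls for the family); cross-family pairs above 0.1
are flagged as possible sample swaps. Contamination screening flags
autosomal heterozygosity outliers beyond median +- 5 MAD, with at least
10 samples required for cohort statistics. All thresholds live in
`QcThresholds`.

## Synthetic data

The generator emulates the study's family designs: a founder couple,
married-in founder spouses per generation, sibships of configurable
size, and an explicit consanguinity plan realized as first-cousin
marriages at generation 3 (which therefore requires four generations, so
the unions have offspring). Founders draw haplotypes by Hardy–Weinberg
at per-variant allele frequencies (log-uniform over 1e-4–0.5 by
default, so part of the background survives the rarity filter and part
does not); descent is per-variant independent Mendelian transmission —
no recombination model, since the analysis never uses genetic distance —
with an optional linked-block mode that makes de-novo haplotype windows
meaningful. Male X is hemizygous outside the PARs throughout.
Genotyping error is injected post-transmission as symmetric allele flips
(default 0.001; the recovery properties run at 0).

Planted causal configurations write genotypes that satisfy the target
model exactly, with Mendelian-consistent carrier chains seeded up to a
founder; the planting also fixes affection status (carriers affected per
the model). Everything flows from a single integer seed; identical specs
produce byte-identical VCF/PED/FASTA.

What the generator does **not** emulate: realistic site-frequency
spectra, linkage disequilibrium, sequencing reads, caller artifacts, or
phenocopies/incomplete penetrance. Passing recovery tests therefore
demonstrate the correctness of the segregation logic under its stated
assumptions, not robustness to real-data annotation noise or penetrance
violations.

## Reporting

Two entry points are kept deliberately separate. The live pipeline
(`run_pipeline`) derives "solved" from verdicts (QC → filter → scan →
flags → ranking). Fixture replay derives tallies from curated
per-pedigree variant tables, where "solved" is table membership;
detection rates are rounded to the nearest integer percent. The shipped
tables encode 89 known-gene causative variants (84 small variants, 5
deletions); compound-het rows are consistency-checked for a partner
allele in the same pedigree and gene, with a deletion from the CNV table
accepted as the partner.

## Problem sizes used by the test suite

Property suites run at the sizes they are stated at: 6 models x 200
seeded pedigrees for planted recovery (with a 100% recovery bar and a
median passing-set size <= 3 genes), 500 randomized families (<= 8
members, <= 30 variants) for oracle equivalence against naive model
definitions, 50 replicates x 10,000 sites for kinship recovery, and
200 random junctions for the microhomology brute-force comparison.
The whole suite completes in well under a minute on one core.

## Known limitations

* Consequence classification is HGVS-string-driven; it cannot catch
  annotation errors in the strings themselves and does not consult
  transcripts.
* No penetrance modelling: a relaxation flag exists nowhere by design;
  reduced-penetrance families will present as unsolved rather than as
  ranked partial fits.
* Comp-het phase from offspring assumes the unobserved spouse carries
  neither allele (safe for rare alleles, wrong for common ones — but
  common alleles do not survive the rarity filter).
* Digenic interactions are flagged (`multi_gene`) but not modelled.
* Kinship verification compares pairwise moments only; it does not do
  segment-level IBD.
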