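"""Inheritance-model segregation testing over pedigrees.

Each ``test_*`` function evaluates one inheritance model for one variant
(or variant pair) against the genotyped members of a pedigree and returns
a :class:`SegregationVerdict`.  The models are fully penetrant and admit
no phenocopies: a single unaffected carrier sinks a dominant candidate.
Ungenotyped relatives are ignored, never imputed.

Genotypes are passed as a plain mapping ``sample_id -> alt allele count``
covering the *genotyped* members only; a parallel ``ploidy`` mapping marks
haploid calls (male X outside the pseudo-autosomal regions).

``scan_pedigree`` runs the applicable models over every filtered variant,
mirroring the search order used when a family's presumed inheritance fails
to produce a candidate: recessive models first for recessive/consanguineous
families, then dominant, X-linked, de-novo (trios) and finally the
pseudo-recessive pattern that consanguinity can produce for a dominant
allele.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .pedigree import AFFECTED, MALE, FEMALE, UNAFFECTED, Branch, Pedigree
from .variants import AnnotatedVariant, GenotypeMatrix, is_truncating

log = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "SegregationVerdict",
    "GeneConstraint",
    "load_gene_panel",
    "test_ar_hom",
    "test_comphet",
    "test_ad_het",
    "test_xlinked",
    "test_de_novo",
    "test_pseudo_recessive",
    "scan_pedigree",
    "scan_with_atypicals",
    "detect_atypical",
    "rank_by_constraint",
    "verdicts_to_tsv",
    "verdicts_to_json",
]

AR_HOM = "AR_hom"
AR_COMPHET = "AR_comphet"
AD_HET = "AD_het"
XL = "XL"
DE_NOVO = "de_novo"
PSEUDO_RECESSIVE = "pseudo_recessive_dominant"

MODELS = (AR_HOM, AR_COMPHET, AD_HET, XL, DE_NOVO, PSEUDO_RECESSIVE)

ATYPICAL_FLAGS = (
    "multi_gene",
    "intrafamilial_heterogeneity",
    "manifesting_carrier",
    "pseudo_recessive",
    "de_novo",
    "phase_unknown",
    "non_paternity",
)


@dataclass
class SegregationVerdict:
    pedigree_id: str
    gene: str | None
    model: str
    variants: tuple[AnnotatedVariant, ...]
    passes: bool
    indeterminate: bool = False
    affected_carriers: tuple[str, ...] = ()
    unaffected_violations: tuple[str, ...] = ()
    phase: str | None = None  # trans / cis / unknown (comp-het only)
    atypical_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.passes and self.unaffected_violations:
            raise ValueError("a passing verdict cannot carry unaffected violations")
        if self.model == AR_COMPHET and len(self.variants) != 2:
            raise ValueError("comp-het verdict needs exactly 2 variants")
        bad = set(self.atypical_flags) - set(ATYPICAL_FLAGS)
        if bad:
            raise ValueError(f"unknown atypical flags {bad}")

    def with_flags(self, *flags: str) -> "SegregationVerdict":
        return replace(self, atypical_flags=self.atypical_flags | set(flags))


@dataclass(frozen=True)
class GeneConstraint:
    gene: str
    z_mis: float
    z_lof: float
    declared_inheritance: str = "undefined"  # recessive/dominant/x_linked/undefined


def load_gene_panel(stream_or_path) -> dict[str, GeneConstraint]:
    """Gene panel TSV: gene, declared inheritance, z_mis, z_lof."""
    import io

    if hasattr(stream_or_path, "read"):
        text = stream_or_path.read()
    else:
        with open(stream_or_path) as fh:
            text = fh.read()
    panel = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        gene, inh, z_mis, z_lof = line.split("\t")[:4]
        panel[gene] = GeneConstraint(gene, float(z_mis), float(z_lof), inh)
    return panel


# -- helpers -------------------------------------------------------------

Geno = Mapping[str, int]


def _genotyped(ped: Pedigree, geno: Geno, status: str) -> list[str]:
    return [i for i in sorted(geno) if i in ped.members and ped.members[i].affection == status]


def _carries(geno: Geno, ind: str) -> bool:
    return geno.get(ind, 0) > 0


def _hom(geno: Geno, ind: str, ploidy: Mapping[str, int] | None = None) -> bool:
    p = (ploidy or {}).get(ind, 2)
    return geno.get(ind, 0) >= p


def _verdict(ped, gene, model, variants, passes, **kw) -> SegregationVerdict:
    return SegregationVerdict(
        pedigree_id=ped.family_id,
        gene=gene,
        model=model,
        variants=tuple(variants),
        passes=passes,
        **kw,
    )


# -- single-model tests ---------------------------------------------------


def test_ar_hom(
    ped: Pedigree, geno: Geno, variant: AnnotatedVariant | None = None
) -> SegregationVerdict:
    """Autosomal-recessive homozygous model.

    All genotyped affected must be hom-alt; no genotyped unaffected may be
    hom-alt; every genotyped parent of an affected must carry the allele.
    """
    gene = variant.gene if variant else None
    variants = (variant,) if variant else ()
    affected = _genotyped(ped, geno, AFFECTED)
    if not affected:
        return _verdict(ped, gene, AR_HOM, variants, False, indeterminate=True)
    if not all(geno[a] == 2 for a in affected):
        return _verdict(ped, gene, AR_HOM, variants, False)
    violations = [u for u in _genotyped(ped, geno, UNAFFECTED) if geno[u] == 2]
    if violations:
        return _verdict(
            ped, gene, AR_HOM, variants, False, unaffected_violations=tuple(violations)
        )
    for a in affected:
        for parent in ped.parents_of(a):
            if parent is not None and parent in geno and geno[parent] == 0:
                return _verdict(ped, gene, AR_HOM, variants, False)
    return _verdict(
        ped, gene, AR_HOM, variants, True, affected_carriers=tuple(affected)
    )


def _phase_from_parents(
    ped: Pedigree, child: str, g1: Geno, g2: Geno
) -> str | None:
    """trans/cis evidence from the child's genotyped parents, else None."""
    father, mother = ped.parents_of(child)
    if father is None or mother is None:
        return None
    if father not in g1 or father not in g2 or mother not in g1 or mother not in g2:
        return None
    f1, f2 = _carries(g1, father), _carries(g2, father)
    m1, m2 = _carries(g1, mother), _carries(g2, mother)
    if (f1 and not f2 and m2 and not m1) or (f2 and not f1 and m1 and not m2):
        return "trans"
    if (f1 and f2 and not m1 and not m2) or (m1 and m2 and not f1 and not f2):
        return "cis"
    return None


def _phase_from_offspring(ped: Pedigree, proband: str, g1: Geno, g2: Geno) -> str | None:
    """Phase inferred from transmissions.

    A child is informative only if its other parent cannot have supplied
    either allele (genotyped non-carrier, or ungenotyped under the
    rare-allele assumption).  Informative children each carrying exactly
    one allele imply trans in the proband; an informative child carrying
    both implies cis."""
    kids = []
    for k in ped.children_of(proband):
        if k not in g1 or k not in g2:
            continue
        father, mother = ped.parents_of(k)
        other = mother if father == proband else father
        if (
            other is not None
            and other in g1
            and other in g2
            and (_carries(g1, other) or _carries(g2, other))
        ):
            continue
        kids.append(k)
    if any(_carries(g1, k) and _carries(g2, k) for k in kids):
        # both alleles passed through one meiosis: cis in the proband
        return "cis"
    saw_only_1 = any(_carries(g1, k) and not _carries(g2, k) for k in kids)
    saw_only_2 = any(_carries(g2, k) and not _carries(g1, k) for k in kids)
    if saw_only_1 and saw_only_2:
        return "trans"
    return None


def test_comphet(
    ped: Pedigree,
    g1: Geno,
    g2: Geno,
    v1: AnnotatedVariant | None = None,
    v2: AnnotatedVariant | None = None,
) -> SegregationVerdict:
    """Compound-heterozygote model for two variants in one gene.

    Affected must be het for both alleles; phase is read from parental
    genotypes where available, otherwise from offspring transmissions
    (a proband whose children each inherited exactly one of the two
    alleles must hold them in trans).  Cis evidence fails the model;
    no informative relatives passes with phase ``unknown``.
    """
    if v1 is not None and v2 is not None and v1.gene != v2.gene:
        raise ValueError(f"comp-het variants in different genes: {v1.gene} vs {v2.gene}")
    gene = v1.gene if v1 else None
    variants = (v1, v2) if v1 and v2 else (None, None)
    if variants == (None, None):
        variants = (
            AnnotatedVariant("chr0", 1, "N", "N"),
            AnnotatedVariant("chr0", 2, "N", "N"),
        )
    shared = [i for i in g1 if i in g2]
    affected = [i for i in sorted(shared) if ped.members[i].affection == AFFECTED]
    if not affected:
        return _verdict(ped, gene, AR_COMPHET, variants, False, indeterminate=True)
    if not all(g1[a] == 1 and g2[a] == 1 for a in affected):
        return _verdict(ped, gene, AR_COMPHET, variants, False)
    violations = [
        u
        for u in sorted(shared)
        if ped.members[u].affection == UNAFFECTED and _carries(g1, u) and _carries(g2, u)
    ]
    phases = []
    for a in affected:
        for evidence in (
            _phase_from_parents(ped, a, g1, g2),
            _phase_from_offspring(ped, a, g1, g2),
        ):
            if evidence is not None:
                phases.append(evidence)
    if "cis" in phases:
        return _verdict(ped, gene, AR_COMPHET, variants, False, phase="cis")
    # an unaffected double-carrier is only a true violation if the alleles
    # are genuinely biallelic in the affected; report and fail
    if violations:
        return _verdict(
            ped,
            gene,
            AR_COMPHET,
            variants,
            False,
            unaffected_violations=tuple(violations),
        )
    if "trans" in phases:
        return _verdict(
            ped, gene, AR_COMPHET, variants, True,
            affected_carriers=tuple(affected), phase="trans",
        )
    return _verdict(
        ped, gene, AR_COMPHET, variants, True,
        affected_carriers=tuple(affected), phase="unknown",
        atypical_flags=frozenset({"phase_unknown"}),
    )


def test_ad_het(
    ped: Pedigree, geno: Geno, variant: AnnotatedVariant | None = None
) -> SegregationVerdict:
    """Strict autosomal-dominant model: every genotyped affected is
    heterozygous and no genotyped unaffected carries the allele."""
    gene = variant.gene if variant else None
    variants = (variant,) if variant else ()
    affected = _genotyped(ped, geno, AFFECTED)
    if not affected:
        return _verdict(ped, gene, AD_HET, variants, False, indeterminate=True)
    if not all(geno[a] == 1 for a in affected):
        return _verdict(ped, gene, AD_HET, variants, False)
    violations = [u for u in _genotyped(ped, geno, UNAFFECTED) if _carries(geno, u)]
    if violations:
        return _verdict(
            ped, gene, AD_HET, variants, False, unaffected_violations=tuple(violations)
        )
    return _verdict(ped, gene, AD_HET, variants, True, affected_carriers=tuple(affected))


def test_xlinked(
    ped: Pedigree,
    geno: Geno,
    variant: AnnotatedVariant | None = None,
    ploidy: Mapping[str, int] | None = None,
) -> SegregationVerdict:
    """X-linked model for a variant outside the pseudo-autosomal regions.

    Affected males must be hemizygous for the allele; affected
    heterozygous females are tolerated and flagged as manifesting
    carriers.  Apparent father-to-son transmission fails the model, and a
    heterozygous diploid call in a male is a data inconsistency.
    """
    if variant is not None and not variant.is_x_nonpar:
        raise ValueError("X-linked test requires a non-PAR X variant")
    gene = variant.gene if variant else None
    variants = (variant,) if variant else ()
    ploidy = ploidy or {}
    flags: set[str] = set()
    for ind in geno:
        if ped.members[ind].sex == MALE and ploidy.get(ind, 1) == 2 and geno[ind] == 1:
            raise ValueError(f"male {ind!r} has a heterozygous diploid call on non-PAR X")
    affected = _genotyped(ped, geno, AFFECTED)
    if not affected:
        return _verdict(ped, gene, XL, variants, False, indeterminate=True)
    for a in affected:
        ind = ped.members[a]
        if ind.sex == MALE:
            if geno[a] < 1:
                return _verdict(ped, gene, XL, variants, False)
        else:
            if geno[a] < 1:
                return _verdict(ped, gene, XL, variants, False)
            if geno[a] == 1:
                flags.add("manifesting_carrier")
    violations = []
    for u in _genotyped(ped, geno, UNAFFECTED):
        ind = ped.members[u]
        if ind.sex == MALE and _carries(geno, u):
            violations.append(u)
        elif ind.sex != MALE and _hom(geno, u):
            violations.append(u)
    if violations:
        return _verdict(
            ped, gene, XL, variants, False, unaffected_violations=tuple(violations)
        )
    # father-to-son transmission is impossible for X-linked alleles
    for son in geno:
        if ped.members[son].sex != MALE or not _carries(geno, son):
            continue
        father, mother = ped.parents_of(son)
        if father is not None and father in geno and _carries(geno, father):
            mother_could_transmit = mother is None or mother not in geno or _carries(geno, mother)
            if not mother_could_transmit:
                return _verdict(ped, gene, XL, variants, False)
    return _verdict(
        ped, gene, XL, variants, True,
        affected_carriers=tuple(affected), atypical_flags=frozenset(flags),
    )


def _haplotype_window_ok(
    ped: Pedigree,
    proband: str,
    variant: AnnotatedVariant,
    variants: Sequence[AnnotatedVariant],
    gtm: GenotypeMatrix,
    window: int,
) -> bool:
    """Check the de-novo flanking haplotypes: within ``window`` bp of the
    site, every informative variant must be transmissible from the stated
    parents (no Mendelian conflict in the window)."""
    father, mother = ped.parents_of(proband)
    if father is None or mother is None:
        return True
    for i, v in enumerate(variants):
        if v.chrom != variant.chrom or abs(v.pos - variant.pos) > window:
            continue
        if v.key == variant.key:
            continue
        g = gtm.genotypes(i)
        if proband not in g or father not in g or mother not in g:
            continue
        child, f, m = g[proband], g[father], g[mother]
        min_from = (child == 2 and (f == 0 or m == 0)) or (
            child == 0 and (f == 2 or m == 2)
        )
        if min_from:
            return False
    return True


def test_de_novo(
    ped: Pedigree,
    geno: Geno,
    variant: AnnotatedVariant | None = None,
    observed_kinship: Mapping[frozenset, float] | None = None,
    *,
    flanking: tuple[Sequence[AnnotatedVariant], GenotypeMatrix] | None = None,
    window: int = 250_000,
    kinship_tolerance: float = 0.1,
) -> SegregationVerdict:
    """De-novo model: affected proband het, both parents genotyped hom-ref.

    When QC kinship estimates are supplied, parent-offspring relatedness
    must be confirmed (|phi - 0.25| within tolerance); a mismatch fails
    with a non-paternity flag and should suppress the call.  When flanking
    genotypes are supplied, the proband's haplotypes across a window
    around the site must be consistent with inheritance of one haplotype
    from each parent.
    """
    gene = variant.gene if variant else None
    variants = (variant,) if variant else ()
    probands = [
        a
        for a in _genotyped(ped, geno, AFFECTED)
        if all(p is not None and p in geno for p in ped.parents_of(a))
    ]
    if not probands:
        return _verdict(ped, gene, DE_NOVO, variants, False, indeterminate=True)
    for proband in probands:
        father, mother = ped.parents_of(proband)
        if geno[proband] != 1 or geno[father] != 0 or geno[mother] != 0:
            return _verdict(ped, gene, DE_NOVO, variants, False)
        if observed_kinship is not None:
            for parent in (father, mother):
                phi = observed_kinship.get(frozenset((proband, parent)))
                if phi is not None and abs(phi - 0.25) > kinship_tolerance:
                    return _verdict(
                        ped, gene, DE_NOVO, variants, False,
                        atypical_flags=frozenset({"non_paternity"}),
                    )
        if flanking is not None and variant is not None:
            fvars, fgtm = flanking
            if not _haplotype_window_ok(ped, proband, variant, fvars, fgtm, window):
                return _verdict(ped, gene, DE_NOVO, variants, False)
    # carriers other than the probands contradict a de-novo event
    others = [i for i in geno if i not in probands and _carries(geno, i)]
    if others:
        return _verdict(ped, gene, DE_NOVO, variants, False)
    return _verdict(
        ped, gene, DE_NOVO, variants, True,
        affected_carriers=tuple(probands), atypical_flags=frozenset({"de_novo"}),
    )


def test_pseudo_recessive(
    ped: Pedigree,
    geno: Geno,
    variant: AnnotatedVariant | None = None,
    unions: Sequence[tuple] | None = None,
) -> SegregationVerdict:
    """Dominant allele segregating pseudo-recessively under consanguinity:
    every genotyped affected carries it (het or hom), at least one
    affected is homozygous, and no genotyped unaffected carries it."""
    gene = variant.gene if variant else None
    variants = (variant,) if variant else ()
    unions = ped.consanguineous_unions() if unions is None else list(unions)
    if not unions:
        return _verdict(ped, gene, PSEUDO_RECESSIVE, variants, False, indeterminate=True)
    affected = _genotyped(ped, geno, AFFECTED)
    if not affected:
        return _verdict(ped, gene, PSEUDO_RECESSIVE, variants, False, indeterminate=True)
    if not all(_carries(geno, a) for a in affected):
        return _verdict(ped, gene, PSEUDO_RECESSIVE, variants, False)
    if not any(geno[a] == 2 for a in affected):
        # plain AD territory: the pseudo-recessive label needs a homozygote
        return _verdict(ped, gene, PSEUDO_RECESSIVE, variants, False)
    violations = [u for u in _genotyped(ped, geno, UNAFFECTED) if _carries(geno, u)]
    if violations:
        return _verdict(
            ped, gene, PSEUDO_RECESSIVE, variants, False,
            unaffected_violations=tuple(violations),
        )
    return _verdict(
        ped, gene, PSEUDO_RECESSIVE, variants, True,
        affected_carriers=tuple(affected),
        atypical_flags=frozenset({"pseudo_recessive"}),
    )


def verdicts_to_tsv(verdicts: Sequence[SegregationVerdict]) -> str:
    """One row per (pedigree, gene, model)."""
    lines = ["pedigree\tgene\tmodel\tpasses\tphase\tvariants\taffected_carriers\tflags"]
    for v in verdicts:
        sites = ",".join(f"{var.chrom}:{var.pos}" for var in v.variants if var)
        lines.append(
            "\t".join(
                [
                    v.pedigree_id,
                    v.gene or ".",
                    v.model,
                    str(v.passes).lower(),
                    v.phase or ".",
                    sites or ".",
                    ",".join(v.affected_carriers) or ".",
                    ",".join(sorted(v.atypical_flags)) or ".",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def verdicts_to_json(verdicts: Sequence[SegregationVerdict]) -> str:
    import json

    return json.dumps(
        [
            {
                "pedigree": v.pedigree_id,
                "gene": v.gene,
                "model": v.model,
                "passes": v.passes,
                "indeterminate": v.indeterminate,
                "phase": v.phase,
                "variants": [
                    f"{var.chrom}:{var.pos}:{var.ref}>{var.alt}"
                    for var in v.variants
                    if var
                ],
                "affected_carriers": list(v.affected_carriers),
                "unaffected_violations": list(v.unaffected_violations),
                "atypical_flags": sorted(v.atypical_flags),
            }
            for v in verdicts
        ],
        indent=2,
    )


# the model evaluators follow the field's test_<model> naming; keep pytest
# from collecting them when imported into test modules
for _fn in (
    test_ar_hom,
    test_comphet,
    test_ad_het,
    test_xlinked,
    test_de_novo,
    test_pseudo_recessive,
):
    _fn.__test__ = False  # type: ignore[attr-defined]


# -- pedigree scan --------------------------------------------------------


def _model_order(declared: str | None, consanguineous: bool) -> list[str]:
    if declared == "recessive" or consanguineous:
        return [AR_HOM, AR_COMPHET, AD_HET, XL, DE_NOVO, PSEUDO_RECESSIVE]
    return [AD_HET, AR_HOM, AR_COMPHET, XL, DE_NOVO, PSEUDO_RECESSIVE]


def scan_pedigree(
    ped: Pedigree,
    variants: Sequence[AnnotatedVariant],
    gtm: GenotypeMatrix,
    panel: Mapping[str, GeneConstraint] | None = None,
    observed_kinship: Mapping[frozenset, float] | None = None,
) -> list[SegregationVerdict]:
    """Evaluate every applicable (model, variant-or-pair) combination and
    return all passing verdicts.  Variants are assumed pre-filtered."""
    consang = ped.is_consanguineous()
    has_trio = any(
        all(p is not None and p in gtm.samples for p in ped.parents_of(a))
        for a in ped.affected()
    )
    by_gene: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        by_gene.setdefault(v.gene or f"__{v.chrom}:{v.pos}", []).append(i)

    out: list[SegregationVerdict] = []
    for gene in sorted(by_gene):
        idx = by_gene[gene]
        declared = panel[gene].declared_inheritance if panel and gene in panel else None
        order = _model_order(declared, consang)
        for model in order:
            if model == AR_COMPHET:
                for i, j in itertools.combinations(idx, 2):
                    vi, vj = variants[i], variants[j]
                    if vi.is_x_nonpar or vj.is_x_nonpar:
                        continue
                    verdict = test_comphet(
                        ped, gtm.genotypes(i), gtm.genotypes(j), vi, vj
                    )
                    if verdict.passes:
                        out.append(verdict)
                continue
            for i in idx:
                v = variants[i]
                geno = gtm.genotypes(i)
                if model == XL:
                    if not v.is_x_nonpar:
                        continue
                    verdict = test_xlinked(ped, geno, v, gtm.ploidy_of(i))
                elif v.is_x_nonpar:
                    continue
                elif model == AR_HOM:
                    verdict = test_ar_hom(ped, geno, v)
                elif model == AD_HET:
                    verdict = test_ad_het(ped, geno, v)
                elif model == DE_NOVO:
                    if not has_trio:
                        continue
                    verdict = test_de_novo(
                        ped, geno, v, observed_kinship, flanking=(variants, gtm)
                    )
                else:  # PSEUDO_RECESSIVE
                    if not consang:
                        continue
                    verdict = test_pseudo_recessive(ped, geno, v)
                if verdict.passes:
                    out.append(verdict)
    return out


def detect_atypical(
    ped: Pedigree,
    verdicts: Sequence[SegregationVerdict],
    branch_verdicts: Mapping[int, Sequence[SegregationVerdict]] | None = None,
) -> dict[str, frozenset[str]]:
    """Cohort-level atypical flags for one pedigree's verdicts.

    ``multi_gene``: two or more genes each pass a full-pedigree model over
    the same affected individuals.  ``intrafamilial_heterogeneity``:
    no gene passes pedigree-wide, but different branches resolve with
    different genes (``branch_verdicts`` maps branch index -> verdicts of
    the branch-restricted scan).
    """
    flags: set[str] = set()
    genes = {v.gene for v in verdicts if v.passes and v.gene}
    if len(genes) >= 2:
        flags.add("multi_gene")
    if not genes and branch_verdicts:
        branch_genes = {
            b: {v.gene for v in vs if v.passes and v.gene}
            for b, vs in branch_verdicts.items()
        }
        resolved = [gs for gs in branch_genes.values() if gs]
        if len(resolved) >= 2 and len(set().union(*resolved)) >= 2:
            flags.add("intrafamilial_heterogeneity")
    return {"pedigree": frozenset(flags)}


def scan_with_atypicals(
    ped: Pedigree,
    variants: Sequence[AnnotatedVariant],
    gtm: GenotypeMatrix,
    panel: Mapping[str, GeneConstraint] | None = None,
    observed_kinship: Mapping[frozenset, float] | None = None,
) -> tuple[list[SegregationVerdict], frozenset[str]]:
    """Pedigree-wide scan plus branch-restricted rescue and atypical flags.

    When nothing passes pedigree-wide and the affected individuals sit in
    different nuclear branches, each branch is re-scanned as a standalone
    family; branches resolving with different genes mark the family as
    showing intrafamilial genetic heterogeneity.
    """
    verdicts = scan_pedigree(ped, variants, gtm, panel, observed_kinship)
    branch_results: dict[int, list[SegregationVerdict]] = {}
    branch_members_with_affected = [
        b
        for b in ped.branches()
        if any(ped.members[m].affection == AFFECTED for m in b.members)
    ]
    if not verdicts and len(branch_members_with_affected) >= 2:
        for bi, branch in enumerate(branch_members_with_affected):
            sub = ped.branch_subpedigree(branch)
            keep = [s for s in gtm.samples if s in sub.members]
            if len(keep) < 2:
                continue
            sub_gtm = gtm.subset_samples(keep)
            branch_results[bi] = scan_pedigree(
                sub, variants, sub_gtm, panel, observed_kinship
            )
    flags = detect_atypical(ped, verdicts, branch_results)["pedigree"]
    if "multi_gene" in flags:
        verdicts = [v.with_flags("multi_gene") for v in verdicts]
    if "intrafamilial_heterogeneity" in flags:
        verdicts = [
            v.with_flags("intrafamilial_heterogeneity")
            for vs in branch_results.values()
            for v in vs
            if v.passes
        ]
    return verdicts, flags


def rank_by_constraint(
    verdicts: Sequence[SegregationVerdict],
    panel: Mapping[str, GeneConstraint],
) -> list[SegregationVerdict]:
    """Order dominant-acting candidates by gene constraint.

    AD/XL/de-novo verdicts are sorted by descending relevant Z-score
    (z_lof for truncating candidates, z_mis otherwise) within the
    positions they already occupy; recessive-model verdicts keep their
    input order untouched, because constraint carries no ranking signal
    for recessive genes.  Phase-unknown comp-hets stay below confirmed
    ones only insofar as the caller ordered them; ties break on
    (chrom, pos) for determinism.
    """
    dominant_like = {AD_HET, XL, DE_NOVO, PSEUDO_RECESSIVE}

    def z_of(v: SegregationVerdict) -> float:
        gc = panel.get(v.gene or "")
        if gc is None:
            log.warning("gene %s absent from constraint panel; Z=0", v.gene)
            return 0.0
        truncating = any(is_truncating(var.consequence) for var in v.variants if var)
        return gc.z_lof if truncating else gc.z_mis

    def tiebreak(v: SegregationVerdict) -> tuple:
        var = v.variants[0] if v.variants else None
        return (var.chrom, var.pos) if var else ("", 0)

    slots = [i for i, v in enumerate(verdicts) if v.model in dominant_like]
    ordered = sorted(
        (verdicts[i] for i in slots), key=lambda v: (-z_of(v), tiebreak(v))
    )
    out = list(verdicts)
    for slot, v in zip(slots, ordered):
        out[slot] = v
    return out
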