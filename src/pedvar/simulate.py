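"""Synthetic pedigree cohorts: structures, gene-dropped genotypes, planted
causal configurations, CNV junctions — everything the pipeline consumes,
generated from a single seed.

The generator emulates the study designs seen in multi-generation IRD
families: nuclear trios, three/four-generation outbred pedigrees, and
consanguineous pedigrees with planted first-cousin unions.  Founder
genotypes are Hardy-Weinberg draws at stated allele frequencies; descent
is per-variant independent Mendelian sampling (no recombination model —
the analysis never uses genetic distance), with an optional linked-block
mode so that haplotypes around a de-novo site are meaningful.  Planted
causal configurations write genotypes that satisfy the target inheritance
model exactly, with Mendelian-consistent carrier chains up to a founder.

All randomness flows from ``SimulationSpec.seed``; identical specs give
byte-identical PED/VCF/FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
    write_ped,
)
from .segregation import GeneConstraint
from .sv import JunctionAssembly
from .variants import PAR1, AnnotatedVariant, GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "Planting",
    "TruthEntry",
    "SyntheticCohort",
    "generate_pedigree",
    "gene_drop",
    "plant_causal",
    "simulate_pedigree",
    "generate_junction",
    "write_vcf",
    "write_junction_fasta",
    "synthetic_gene_panel",
]

_X_GENE_POS = 5_000_000  # safely outside PAR1 (ends 2,699,520) on the X


@dataclass(frozen=True)
class Planting:
    gene: str
    model: str  # one of segregation.MODELS


@dataclass(frozen=True)
class TruthEntry:
    family_id: str
    gene: str
    model: str
    carriers: tuple[str, ...]
    affected: tuple[str, ...]
    phase: str | None = None


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    family_id: str = "FAM1"
    n_generations: int = 3
    sibship_size: int = 3
    max_couples_per_generation: int = 3
    n_cousin_unions: int = 0
    n_background_variants: int = 30
    background_af_range: tuple[float, float] = (1e-4, 0.5)
    genotyping_error: float = 0.001
    n_genes: int = 10
    include_x: bool = False
    linked_block_bp: int | None = None
    planted: tuple[Planting, ...] = ()

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(f"GENE{i + 1:02d}" for i in range(self.n_genes))


# -- pedigree structure ---------------------------------------------------


def generate_pedigree(spec: SimulationSpec) -> Pedigree:
    """Deterministic family structure for a spec.

    Generation 1 is a founder couple; each later generation pairs blood
    children with married-in founder spouses (or, for the consanguinity
    plan, with a first cousin) and produces a sibship.  Sexes alternate
    within each sibship so every sibship offers both.
    """
    if spec.n_cousin_unions > 0 and spec.n_generations < 4:
        raise ValueError(
            "cousin unions need at least 4 generations (cousins exist from "
            "generation 3 and must have offspring)"
        )
    members: list[Individual] = []
    f1 = Individual("1-1", sex=MALE, affection=UNAFFECTED)
    m1 = Individual("1-2", sex=FEMALE, affection=UNAFFECTED)
    members += [f1, m1]
    # couples that reproduce, per generation
    couples: list[tuple[str, str]] = [(f1.id, m1.id)]
    # sibship id (parent couple index) of each blood member, for cousin logic
    sibship_of: dict[str, int] = {}
    child_no = 0
    for gen in range(2, spec.n_generations + 1):
        children: list[Individual] = []
        for ci, (father, mother) in enumerate(couples):
            for k in range(spec.sibship_size):
                child_no += 1
                sex = MALE if k % 2 == 0 else FEMALE
                child = Individual(
                    f"{gen}-{child_no}", father, mother, sex, UNAFFECTED
                )
                sibship_of[child.id] = ci
                children.append(child)
        members += children
        if gen == spec.n_generations:
            break
        # pair up reproducing couples for the next generation
        new_couples: list[tuple[str, str]] = []
        used: set[str] = set()
        if gen == 3 and spec.n_cousin_unions:
            # realize the consanguinity plan: cousin x cousin marriages
            males = [c for c in children if c.sex == MALE]
            females = [c for c in children if c.sex == FEMALE]
            for male in males:
                if len(new_couples) >= spec.n_cousin_unions:
                    break
                mate = next(
                    (
                        fem
                        for fem in females
                        if fem.id not in used
                        and sibship_of[fem.id] != sibship_of[male.id]
                    ),
                    None,
                )
                if mate is None:
                    continue
                used.update((male.id, mate.id))
                new_couples.append((male.id, mate.id))
            if len(new_couples) < spec.n_cousin_unions:
                raise ValueError(
                    f"infeasible consanguinity plan: only {len(new_couples)} "
                    f"cousin pairs available, {spec.n_cousin_unions} requested"
                )
        if not new_couples:
            for child in children:
                if len(new_couples) >= spec.max_couples_per_generation:
                    break
                spouse_sex = FEMALE if child.sex == MALE else MALE
                spouse = Individual(
                    f"{child.id}S", sex=spouse_sex, affection=UNAFFECTED
                )
                members.append(spouse)
                pair = (
                    (child.id, spouse.id)
                    if child.sex == MALE
                    else (spouse.id, child.id)
                )
                new_couples.append(pair)
        couples = new_couples
    return Pedigree(spec.family_id, members)


# -- gene dropping --------------------------------------------------------


def _variant_position(gene_index: int, offset: int, on_x: bool) -> tuple[str, int]:
    if on_x:
        # 5..105 Mb: clear of both pseudo-autosomal regions
        return "chrX", _X_GENE_POS + (gene_index % 100) * 1_000_000 + offset
    chrom = f"chr{(gene_index % 22) + 1}"
    return chrom, 10_000_000 + gene_index * 2_000_000 + offset


def _gene_index(gene: str) -> int:
    """Stable small index for a gene symbol (process-independent)."""
    digits = "".join(c for c in gene if c.isdigit())
    if digits:
        return int(digits) % 500
    return int.from_bytes(gene.encode(), "big") % 500


class _HaplotypeStore:
    """Phased 0/1 haplotypes per sample; males carry one X haplotype
    outside the PARs (stored twice, read once)."""

    def __init__(self, ped: Pedigree, n_variants: int):
        self.ped = ped
        self.h = {
            s: np.zeros((2, n_variants), dtype=np.int8) for s in ped.members
        }

    def counts(self, variants: Sequence[AnnotatedVariant]) -> GenotypeMatrix:
        samples = sorted(
            self.ped.members, key=lambda s: (self.ped.generation_index[s], s)
        )
        n = len(variants)
        counts = np.zeros((n, len(samples)), dtype=np.int16)
        ploidy = np.full((n, len(samples)), 2, dtype=np.int8)
        x_nonpar = np.array([v.is_x_nonpar for v in variants])
        for j, s in enumerate(samples):
            male = self.ped.members[s].sex == MALE
            hap = self.h[s]
            counts[:, j] = hap[0] + hap[1]
            if male and x_nonpar.any():
                counts[x_nonpar, j] = hap[1][x_nonpar]  # maternal X only
                ploidy[x_nonpar, j] = 1
        return GenotypeMatrix(samples, counts, ploidy)


def gene_drop(
    ped: Pedigree,
    variants: Sequence[AnnotatedVariant],
    afs: Sequence[float],
    rng: np.random.Generator,
    linked_block_bp: int | None = None,
) -> _HaplotypeStore:
    """Drop founder alleles through the pedigree under Mendel's laws.

    Transmission is per-variant independent unless ``linked_block_bp`` is
    set, in which case all variants within a block share one transmitted
    haplotype per meiosis (a crude linkage surrogate for haplotype-window
    checks)."""
    n = len(variants)
    afs = np.asarray(afs, dtype=float)
    x_nonpar = np.array([v.is_x_nonpar for v in variants])
    store = _HaplotypeStore(ped, n)
    # deterministic processing order: founders first, then by generation
    order = sorted(ped.members, key=lambda s: (ped.generation_index[s], s))
    if linked_block_bp:
        chrom_index = {c: k for k, c in enumerate(sorted({v.chrom for v in variants}))}
        block_id = np.array(
            [
                chrom_index[v.chrom] * 10_000_000 + v.pos // linked_block_bp
                for v in variants
            ]
        )
        blocks = {b: np.flatnonzero(block_id == b) for b in np.unique(block_id)}
    for s in order:
        ind = ped.members[s]
        male = ind.sex == MALE
        if ind.is_founder:
            h = (rng.random((2, n)) < afs[None, :]).astype(np.int8)
            if male and x_nonpar.any():
                h[0, x_nonpar] = 0  # no second X
            store.h[s] = h
            continue
        hap = np.zeros((2, n), dtype=np.int8)
        for slot, parent in enumerate(ped.parents_of(s)):
            if parent is None:
                # half-founder: draw the missing contribution from the pool
                hap[slot] = (rng.random(n) < afs).astype(np.int8)
                continue
            ph = store.h[parent]
            if linked_block_bp:
                choice = np.empty(n, dtype=np.int64)
                for b, idxs in blocks.items():
                    choice[idxs] = rng.integers(0, 2)
            else:
                choice = rng.integers(0, 2, size=n)
            parent_male = ped.members[parent].sex == MALE
            if parent_male and x_nonpar.any():
                choice = choice.copy()
                choice[x_nonpar] = 1  # father passes his single X
            hap[slot] = ph[choice, np.arange(n)]
        if male and x_nonpar.any():
            hap[0, x_nonpar] = 0
        store.h[s] = hap
    return store


def make_background_variants(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[list[AnnotatedVariant], np.ndarray]:
    """Background variant panel with log-uniform allele frequencies and
    SnpEff/PolyPhen/CADD-style annotations drawn from benign-leaning
    distributions."""
    genes = spec.genes
    lo, hi = spec.background_af_range
    variants = []
    afs = []
    impacts = ["MODERATE", "LOW", "MODIFIER", "HIGH"]
    impact_p = [0.45, 0.3, 0.2, 0.05]
    pps = ["benign", "possibly_damaging", "probably_damaging"]
    pp_p = [0.7, 0.2, 0.1]
    for i in range(spec.n_background_variants):
        gi = i % len(genes)
        on_x = spec.include_x and gi == len(genes) - 1
        chrom, pos = _variant_position(gi, 1000 + (i // len(genes)) * 250, on_x)
        af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        variants.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref="A",
                alt="G",
                gene=genes[gi],
                impact=str(rng.choice(impacts, p=impact_p)),
                polyphen=str(rng.choice(pps, p=pp_p)),
                cadd_phred=float(rng.uniform(0, 35)),
                af_1kg=af,
                af_inhouse=af,
                af_cohort=af,
            )
        )
        afs.append(af)
    return variants, np.asarray(afs)


# -- planting causal configurations ---------------------------------------


def _seed_het_chain(
    store: _HaplotypeStore,
    ped: Pedigree,
    sample: str,
    vi: int,
    via: str = "father",
) -> list[str]:
    """Make ``sample`` heterozygous with a Mendelian-consistent carrier
    chain walking the ``via`` ("father"/"mother") line up to a founder;
    returns the carriers created, including ``sample``.  X-linked alleles
    must walk the maternal line (via="mother")."""
    slot = 0 if via == "father" else 1
    chain = [sample]
    store.h[sample][slot, vi] = 1
    current = sample
    while True:
        ind = ped.members[current]
        if ind.is_founder:
            break
        parent = ind.father_id if via == "father" else ind.mother_id
        if parent is None:
            break
        if store.h[parent][0, vi] or store.h[parent][1, vi]:
            break  # already a carrier upstream
        store.h[parent][slot, vi] = 1
        chain.append(parent)
        current = parent
    return chain


def _clear_variant(store: _HaplotypeStore, vi: int) -> None:
    for h in store.h.values():
        h[:, vi] = 0


def _sibships_with_children(ped: Pedigree, min_children: int = 1):
    return [
        b
        for b in ped.branches()
        if b.father_id is not None
        and b.mother_id is not None
        and len(b.offspring) >= min_children
    ]


def plant_causal(
    ped: Pedigree,
    store: _HaplotypeStore,
    variants: list[AnnotatedVariant],
    model: str,
    gene: str,
    rng: np.random.Generator,
) -> TruthEntry:
    """Insert a causal configuration for ``model`` into ``gene``.

    Appends the causal variant(s) to ``variants`` and writes phased
    genotypes that satisfy the model exactly.  The returned truth entry
    lists the individuals the model makes affected; the caller applies
    affection statuses (see ``simulate_pedigree``), which keeps multiple
    plantings in one family composable.
    """
    from . import segregation as seg

    gi = _gene_index(gene)
    on_x = model == seg.XL
    chrom, pos = _variant_position(gi, 57, on_x)

    def causal(pos_offset: int = 0, hgvs_p: str | None = "p.Arg100Ter") -> int:
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos + pos_offset,
            ref="C",
            alt="T",
            gene=gene,
            hgvs_p=hgvs_p,
            impact="HIGH",
            cadd_phred=35.0,
        )
        variants.append(v)
        for s in store.h:
            store.h[s] = np.concatenate(
                [store.h[s], np.zeros((2, 1), dtype=np.int8)], axis=1
            )
        return len(variants) - 1

    sibs = _sibships_with_children(ped)
    if model == seg.AR_HOM:
        vi = causal()
        unions = ped.consanguineous_unions()
        if unions:
            father, mother, _ = unions[0]
            kids = [
                k for k in ped.children_of(father) if ped.members[k].mother_id == mother
            ]
        else:
            top = next(b for b in sibs if ped.members[b.father_id].is_founder)
            father, mother, kids = top.father_id, top.mother_id, list(top.offspring)
        _seed_het_chain(store, ped, father, vi, "father")
        _seed_het_chain(store, ped, mother, vi, "father")
        n_aff = max(1, len(kids) // 2)
        for k in kids[:n_aff]:
            store.h[k][:, vi] = 1  # hom: one allele from each het parent
        return TruthEntry(
            ped.family_id, gene, model, tuple(kids[:n_aff]), tuple(kids[:n_aff])
        )
    if model == seg.AR_COMPHET:
        v1 = causal(0)
        v2 = causal(120, hgvs_p="p.Gly200Arg")
        top = next(b for b in sibs if ped.members[b.father_id].is_founder)
        father, mother, kids = top.father_id, top.mother_id, list(top.offspring)
        store.h[father][0, v1] = 1
        store.h[mother][0, v2] = 1
        proband = kids[0]
        store.h[proband][0, v1] = 1  # paternal haplotype
        store.h[proband][1, v2] = 1  # maternal haplotype
        if len(kids) > 1:
            store.h[kids[1]][0, v1] = 1  # unaffected sib carries one allele
        return TruthEntry(
            ped.family_id, gene, model, (proband,), (proband,), phase="trans"
        )
    if model == seg.AD_HET:
        vi = causal()
        carriers = ["1-1"]
        store.h["1-1"][0, vi] = 1
        current = "1-1"
        while True:
            kids = ped.children_of(current)
            if not kids:
                break
            child = sorted(kids)[0]
            slot = 0 if ped.members[child].father_id == current else 1
            store.h[child][slot, vi] = 1
            carriers.append(child)
            current = child
        return TruthEntry(ped.family_id, gene, model, tuple(carriers), tuple(carriers))
    if model == seg.XL:
        vi = causal()
        target = next(
            b
            for b in sibs
            if b.mother_id is not None
            and any(ped.members[k].sex == MALE for k in b.offspring)
        )
        mother = target.mother_id
        _seed_het_chain(store, ped, mother, vi, "mother")  # carrier line
        sons = [k for k in target.offspring if ped.members[k].sex == MALE]
        affected_son = sons[0]
        store.h[affected_son][1, vi] = 1  # maternal X
        return TruthEntry(
            ped.family_id, gene, model, (mother, affected_son), (affected_son,)
        )
    if model == seg.DE_NOVO:
        vi = causal()
        candidates = [
            s
            for s in sorted(ped.members)
            if all(p is not None for p in ped.parents_of(s))
        ]
        proband = candidates[-1]
        store.h[proband][0, vi] = 1  # fresh mutation on one haplotype
        return TruthEntry(ped.family_id, gene, model, (proband,), (proband,))
    if model == seg.PSEUDO_RECESSIVE:
        vi = causal()
        unions = ped.consanguineous_unions()
        if not unions:
            raise ValueError("pseudo-recessive planting needs a consanguineous pedigree")
        carriers: set[str] = set()
        hom: set[str] = set()
        for father, mother, _ in unions:
            for parent in (father, mother):
                if not (store.h[parent][:, vi].any()):
                    carriers.update(_seed_het_chain(store, ped, parent, vi, "father"))
            kids = [
                k
                for k in ped.children_of(father)
                if ped.members[k].mother_id == mother
            ]
            for k in kids:
                store.h[k][:, vi] = 1
                hom.add(k)
        carriers |= hom
        return TruthEntry(
            ped.family_id, gene, model, tuple(sorted(carriers)), tuple(sorted(carriers))
        )
    raise ValueError(f"unknown model {model!r}")


# -- cohort assembly ------------------------------------------------------


@dataclass
class SyntheticCohort:
    spec: SimulationSpec
    pedigree: Pedigree
    variants: list[AnnotatedVariant]
    genotypes: GenotypeMatrix
    truth: list[TruthEntry]

    def write(self, vcf_path, ped_path, truth_path=None) -> None:
        with open(ped_path, "w") as fh:
            fh.write(write_ped(self.pedigree))
        write_vcf(vcf_path, self.variants, self.genotypes, self.pedigree)
        if truth_path:
            with open(truth_path, "w") as fh:
                fh.write("family\tgene\tmodel\tcarriers\taffected\tphase\n")
                for t in self.truth:
                    fh.write(
                        f"{t.family_id}\t{t.gene}\t{t.model}\t"
                        f"{','.join(t.carriers)}\t{','.join(t.affected)}\t"
                        f"{t.phase or 'NA'}\n"
                    )


def simulate_pedigree(spec: SimulationSpec) -> SyntheticCohort:
    """Full single-family simulation: structure, background gene drop,
    planted causal configurations, then genotyping-error injection."""
    rng = np.random.default_rng(spec.seed)
    ped = generate_pedigree(spec)
    variants, afs = make_background_variants(spec, rng)
    store = gene_drop(ped, variants, afs, rng, spec.linked_block_bp)
    truth = []
    used_genes = set()
    for planting in spec.planted:
        if planting.gene in used_genes:
            raise ValueError(f"gene {planting.gene} planted twice")
        used_genes.add(planting.gene)
        # causal sites must not collide with background alleles in the gene
        for i, v in enumerate(variants):
            if v.gene == planting.gene:
                _clear_variant(store, i)
        truth.append(
            plant_causal(ped, store, variants, planting.model, planting.gene, rng)
        )
    if truth:
        affected = {s for t in truth for s in t.affected}
        for s, ind in ped.members.items():
            ind.affection = AFFECTED if s in affected else UNAFFECTED
    if spec.genotyping_error > 0:
        for s, h in store.h.items():
            flips = rng.random(h.shape) < spec.genotyping_error
            store.h[s] = np.where(flips, 1 - h, h).astype(np.int8)
    gtm = store.counts(variants)
    return SyntheticCohort(spec, ped, variants, gtm, truth)


# -- writers --------------------------------------------------------------


def _fmt_info(v: AnnotatedVariant) -> str:
    parts = []
    if v.gene:
        parts.append(f"GENE={v.gene}")
    if v.impact:
        parts.append(f"IMPACT={v.impact}")
    if v.polyphen:
        parts.append(f"PP2={v.polyphen}")
    if v.cadd_phred is not None:
        parts.append(f"CADD={v.cadd_phred:.6g}")
    for key, val in (
        ("AF_1KG", v.af_1kg),
        ("AF_IH", v.af_inhouse),
        ("AF_COH", v.af_cohort),
        ("AF_GNOMAD", v.af_gnomad),
    ):
        if val is not None:
            parts.append(f"{key}={val:.6g}")
    if v.hgvs_c:
        parts.append(f"HGVSC={v.hgvs_c}")
    if v.hgvs_p:
        parts.append(f"HGVSP={v.hgvs_p}")
    return ";".join(parts) or "."


def write_vcf(
    path,
    variants: Sequence[AnnotatedVariant],
    gtm: GenotypeMatrix,
    ped: Pedigree | None = None,
) -> None:
    """Emit a VCF 4.2 file; male non-PAR X genotypes are written haploid."""
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    chroms = []
    for i in order:
        if variants[i].chrom not in chroms:
            chroms.append(variants[i].chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    for key, typ, desc in [
        ("GENE", "String", "Gene symbol"),
        ("IMPACT", "String", "SnpEff-style putative impact"),
        ("PP2", "String", "PolyPhen2-style prediction"),
        ("CADD", "Float", "CADD Phred score"),
        ("AF_1KG", "Float", "1000 Genomes allele frequency"),
        ("AF_IH", "Float", "In-house cohort allele frequency"),
        ("AF_COH", "Float", "Study cohort allele frequency"),
        ("AF_GNOMAD", "Float", "gnomAD allele frequency"),
        ("HGVSC", "String", "cDNA HGVS"),
        ("HGVSP", "String", "protein HGVS"),
    ]:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gtm.samples)
    )
    for i in order:
        v = variants[i]
        row = gtm.counts[i]
        pl = gtm.ploidy[i]
        gts = []
        for j in range(len(gtm.samples)):
            c, p = int(row[j]), int(pl[j])
            if c < 0:
                gts.append("./." if p == 2 else ".")
            elif p == 1:
                gts.append(str(min(c, 1)))
            else:
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[min(c, 2)])
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_fmt_info(v)}\tGT\t"
            + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- junctions ------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def generate_junction(
    flank_length: int,
    homology_length: int,
    seed: int | np.random.Generator = 0,
) -> JunctionAssembly:
    """Deletion junction with an exact planted repeat on both sides.

    The last ``homology_length`` bases of the left flank equal the first
    bases of the right flank; the base preceding the repeat is forced to
    differ from the repeat's first base so the planted length is also the
    maximal one.  Retries (seeded) guard against chance extensions.
    """
    if homology_length > flank_length:
        raise ValueError("homology cannot exceed flank length")
    from .sv import microhomology

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for _ in range(200):
        repeat = _random_seq(rng, homology_length)
        left = _random_seq(rng, flank_length - homology_length) + repeat
        right = repeat + _random_seq(rng, flank_length - homology_length)
        ja = JunctionAssembly(
            left_flank=left, right_flank=right, junction_read=left + right
        )
        if microhomology(ja)[0] == homology_length:
            return ja
    raise RuntimeError("could not realize requested homology length")


def write_junction_fasta(path, ja: JunctionAssembly) -> None:
    with open(path, "w") as fh:
        for name, seq in (
            ("left_flank", ja.left_flank),
            ("right_flank", ja.right_flank),
            ("junction_read", ja.junction_read),
        ):
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


def read_junction_fasta(path) -> JunctionAssembly:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return JunctionAssembly(
        left_flank=str(fa["left_flank"][:]),
        right_flank=str(fa["right_flank"][:]),
        junction_read=str(fa["junction_read"][:]),
    )


# -- gene panel -----------------------------------------------------------


def synthetic_gene_panel(
    genes: Sequence[str], seed: int = 0
) -> dict[str, GeneConstraint]:
    """Synthetic RetNet-style constraint panel: dominant/X-linked genes
    get high Z-scores, recessive genes hover near zero, mirroring the
    constraint contrast the ranking exploits."""
    rng = np.random.default_rng(seed)
    panel = {}
    for i, g in enumerate(genes):
        inh = ("recessive", "dominant", "x_linked", "undefined")[i % 4]
        if inh in ("dominant", "x_linked"):
            z_mis = float(rng.uniform(2.5, 6.0))
            z_lof = float(rng.uniform(2.5, 6.0))
        else:
            z_mis = float(rng.normal(0, 1))
            z_lof = float(rng.normal(0, 1))
        panel[g] = GeneConstraint(g, z_mis, z_lof, inh)
    return panel
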