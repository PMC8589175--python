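"""Naive reference implementations of the six inheritance models, written
as direct transcriptions of the documented model definitions, used to
cross-check ``scan_pedigree`` by exhaustive enumeration on small families.

These deliberately share no code with the package: plain loops over
members, no verdict objects, no shared helpers.
"""

from __future__ import annotations

import itertools

import numpy as np

from pedvar.pedigree import Individual, Pedigree
from pedvar.variants import AnnotatedVariant, GenotypeMatrix


def _status(ped, s):
    return ped.members[s].affection


def _aff(ped, g):
    return [s for s in sorted(g) if _status(ped, s) == "affected"]


def _unaff(ped, g):
    return [s for s in sorted(g) if _status(ped, s) == "unaffected"]


def naive_ar_hom(ped, g):
    aff = _aff(ped, g)
    if not aff:
        return False
    if any(g[a] != 2 for a in aff):
        return False
    if any(g[u] == 2 for u in _unaff(ped, g)):
        return False
    for a in aff:
        for p in ped.parents_of(a):
            if p is not None and p in g and g[p] == 0:
                return False
    return True


def naive_comphet(ped, g1, g2):
    shared = sorted(set(g1) & set(g2))
    aff = [s for s in shared if _status(ped, s) == "affected"]
    if not aff:
        return False
    if any(g1[a] != 1 or g2[a] != 1 for a in aff):
        return False
    # phase: cis evidence anywhere fails
    for a in aff:
        f, m = ped.parents_of(a)
        if f in shared and m in shared:
            if (g1[f] > 0 and g2[f] > 0 and g1[m] == 0 and g2[m] == 0) or (
                g1[m] > 0 and g2[m] > 0 and g1[f] == 0 and g2[f] == 0
            ):
                return False
        for k in ped.children_of(a):
            if k not in shared:
                continue
            kf, km = ped.parents_of(k)
            other = km if kf == a else kf
            if (
                other is not None
                and other in shared
                and (g1[other] > 0 or g2[other] > 0)
            ):
                continue  # other parent could have supplied an allele
            if g1[k] > 0 and g2[k] > 0:
                return False
    for u in shared:
        if _status(ped, u) == "unaffected" and g1[u] > 0 and g2[u] > 0:
            return False
    return True


def naive_ad_het(ped, g):
    aff = _aff(ped, g)
    if not aff:
        return False
    if any(g[a] != 1 for a in aff):
        return False
    if any(g[u] > 0 for u in _unaff(ped, g)):
        return False
    return True


def naive_xl(ped, g):
    aff = _aff(ped, g)
    if not aff:
        return False
    for a in aff:
        if g[a] < 1:
            return False
    for u in _unaff(ped, g):
        if ped.members[u].sex == "male":
            if g[u] > 0:
                return False
        elif g[u] >= 2:
            return False
    for son in g:
        if ped.members[son].sex != "male" or g[son] < 1:
            continue
        f, m = ped.parents_of(son)
        if f is not None and f in g and g[f] > 0:
            if m is not None and m in g and g[m] == 0:
                return False
    return True


def naive_de_novo(ped, g, variant, all_variants, gtm, window=250_000):
    probands = [
        a
        for a in _aff(ped, g)
        if all(p is not None and p in g for p in ped.parents_of(a))
    ]
    if not probands:
        return False
    for a in probands:
        f, m = ped.parents_of(a)
        if g[a] != 1 or g[f] != 0 or g[m] != 0:
            return False
        for i, v in enumerate(all_variants):
            if v.chrom != variant.chrom or v.key == variant.key:
                continue
            if abs(v.pos - variant.pos) > window:
                continue
            gg = gtm.genotypes(i)
            if a in gg and f in gg and m in gg:
                if gg[a] == 2 and (gg[f] == 0 or gg[m] == 0):
                    return False
                if gg[a] == 0 and (gg[f] == 2 or gg[m] == 2):
                    return False
    for s in g:
        if s not in probands and g[s] > 0:
            return False
    return True


def naive_pseudo_recessive(ped, g):
    if not ped.consanguineous_unions():
        return False
    aff = _aff(ped, g)
    if not aff:
        return False
    if any(g[a] == 0 for a in aff):
        return False
    if not any(g[a] == 2 for a in aff):
        return False
    if any(g[u] > 0 for u in _unaff(ped, g)):
        return False
    return True


def enumerate_passing(ped, variants, gtm):
    """Exhaustive (gene, model, variant-keys) passing set."""
    consang = bool(ped.consanguineous_unions())
    has_trio = any(
        all(p is not None and p in gtm.samples for p in ped.parents_of(a))
        for a in ped.affected()
    )
    out = set()
    by_gene = {}
    for i, v in enumerate(variants):
        by_gene.setdefault(v.gene, []).append(i)
    for gene, idx in by_gene.items():
        for i in idx:
            v = variants[i]
            g = gtm.genotypes(i)
            if v.is_x_nonpar:
                if naive_xl(ped, g):
                    out.add((gene, "XL", (v.key,)))
                continue
            if naive_ar_hom(ped, g):
                out.add((gene, "AR_hom", (v.key,)))
            if naive_ad_het(ped, g):
                out.add((gene, "AD_het", (v.key,)))
            if has_trio and naive_de_novo(ped, g, v, variants, gtm):
                out.add((gene, "de_novo", (v.key,)))
            if consang and naive_pseudo_recessive(ped, g):
                out.add((gene, "pseudo_recessive_dominant", (v.key,)))
        for i, j in itertools.combinations(idx, 2):
            vi, vj = variants[i], variants[j]
            if vi.is_x_nonpar or vj.is_x_nonpar:
                continue
            if naive_comphet(ped, gtm.genotypes(i), gtm.genotypes(j)):
                out.add((gene, "AR_comphet", tuple(sorted((vi.key, vj.key)))))
    return out


def verdict_set(verdicts):
    return {
        (v.gene, v.model, tuple(sorted(var.key for var in v.variants)))
        for v in verdicts
        if v.passes
    }


# -- random case generation ----------------------------------------------


def random_case(rng: np.random.Generator):
    """A random small family with random genotypes and affections."""
    kind = rng.integers(0, 4)
    if kind == 0:  # trio
        members = [
            Individual("F", sex="male"),
            Individual("M", sex="female"),
            Individual("C", "F", "M", "male"),
        ]
    elif kind == 1:  # quartet with two kids
        members = [
            Individual("F", sex="male"),
            Individual("M", sex="female"),
            Individual("C1", "F", "M", "male"),
            Individual("C2", "F", "M", "female"),
        ]
    elif kind == 2:  # three generations, 7 members
        members = [
            Individual("G1", sex="male"),
            Individual("G2", sex="female"),
            Individual("P", "G1", "G2", "male"),
            Individual("PS", sex="female"),
            Individual("K1", "P", "PS", "male"),
            Individual("K2", "P", "PS", "female"),
            Individual("U", "G1", "G2", "female"),
        ]
    else:  # consanguineous: sib mating (loop), 6 members
        members = [
            Individual("A", sex="male"),
            Individual("B", sex="female"),
            Individual("C", "A", "B", "male"),
            Individual("D", "A", "B", "female"),
            Individual("E", "C", "D", "male"),
            Individual("F2", "C", "D", "female"),
        ]
    for ind in members:
        ind.affection = (
            "affected" if rng.random() < 0.4 else
            ("unaffected" if rng.random() < 0.9 else "unknown")
        )
    ped = Pedigree(f"R{kind}", members)

    n_var = int(rng.integers(2, 31))
    genes = [f"G{k}" for k in range(int(rng.integers(1, 6)))]
    names = sorted(ped.members)
    counts = np.full((n_var, len(names)), -1, dtype=np.int16)
    ploidy = np.full((n_var, len(names)), 2, dtype=np.int8)
    variants = []
    for i in range(n_var):
        gene = genes[int(rng.integers(0, len(genes)))]
        on_x = rng.random() < 0.15
        if on_x:
            chrom, pos = "chrX", 10_000_000 + i * 1000
        else:
            chrom, pos = f"chr{(i % 4) + 1}", 1_000_000 + i * int(rng.integers(10, 100_000))
        variants.append(
            AnnotatedVariant(chrom=chrom, pos=pos, ref="A", alt="T", gene=gene)
        )
        for j, s in enumerate(names):
            if rng.random() < 0.1:
                continue  # ungenotyped at this site
            male = ped.members[s].sex == "male"
            if on_x and male:
                counts[i, j] = int(rng.integers(0, 2))
                ploidy[i, j] = 1
            else:
                counts[i, j] = int(rng.integers(0, 3))
    gtm = GenotypeMatrix(names, counts, ploidy)
    return ped, variants, gtm
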