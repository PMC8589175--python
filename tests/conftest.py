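"""Shared fixtures: hand-built pedigrees mirroring the study's notable
family structures, plus small genotype helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pedvar.pedigree import Individual, Pedigree
from pedvar.variants import AnnotatedVariant, GenotypeMatrix


def gm(samples: dict[str, int], variant_rows: list[dict[str, int]] | dict[str, int],
       ploidy: dict[str, int] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-variant {sample: count} dicts;
    samples absent from a dict are missing (-1)."""
    if isinstance(variant_rows, dict):
        variant_rows = [variant_rows]
    names = list(samples)
    counts = np.full((len(variant_rows), len(names)), -1, dtype=np.int16)
    pl = np.full((len(variant_rows), len(names)), 2, dtype=np.int8)
    for i, row in enumerate(variant_rows):
        for s, c in row.items():
            counts[i, names.index(s)] = c
    if ploidy:
        for s, p in ploidy.items():
            pl[:, names.index(s)] = p
    return GenotypeMatrix(names, counts, pl)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        "TRIO",
        [
            Individual("F", sex="male", affection="unaffected"),
            Individual("M", sex="female", affection="unaffected"),
            Individual("C", "F", "M", "male", "affected"),
        ],
    )


@pytest.fixture
def quartet() -> Pedigree:
    """Two parents, one affected and one unaffected child."""
    return Pedigree(
        "QUAD",
        [
            Individual("F", sex="male", affection="unaffected"),
            Individual("M", sex="female", affection="unaffected"),
            Individual("A", "F", "M", "female", "affected"),
            Individual("U", "F", "M", "male", "unaffected"),
        ],
    )


@pytest.fixture
def cousin_union_ped() -> Pedigree:
    """First-cousin union with one child (F_child = 1/16)."""
    members = [
        Individual("GF", sex="male"),
        Individual("GM", sex="female"),
        Individual("P1", "GF", "GM", "male"),
        Individual("P2", "GF", "GM", "female"),
        Individual("S1", sex="female"),
        Individual("S2", sex="male"),
        Individual("C1", "P1", "S1", "male"),
        Individual("C2", "S2", "P2", "female"),
        Individual("K", "C1", "C2", "male"),
    ]
    return Pedigree("COUSIN", members)


@pytest.fixture
def pseudo_recessive_ped() -> Pedigree:
    """Consanguineous family in which a dominant allele segregates
    pseudo-recessively: five heterozygous and three homozygous affected
    carriers, no unaffected carrier (cousin parents are double-carrier).
    """
    members = [
        Individual("A", sex="male", affection="affected"),      # founder carrier
        Individual("B", sex="female", affection="unaffected"),
        Individual("C", "A", "B", "male", "affected"),
        Individual("D", "A", "B", "female", "affected"),
        Individual("CS", sex="female", affection="unaffected"),
        Individual("DS", sex="male", affection="unaffected"),
        Individual("E", "C", "CS", "male", "affected"),
        Individual("F", "DS", "D", "female", "affected"),
        # E x F is a first-cousin union; their children are homozygous
        Individual("G", "E", "F", "male", "affected"),
        Individual("H", "E", "F", "female", "affected"),
        Individual("I", "E", "F", "male", "affected"),
    ]
    return Pedigree("RF197LIKE", members)


@pytest.fixture
def pseudo_recessive_geno() -> dict[str, int]:
    return {
        "A": 1, "C": 1, "D": 1, "E": 1, "F": 1,   # five affected het
        "G": 2, "H": 2, "I": 2,                    # three affected hom
        "B": 0, "CS": 0, "DS": 0,                  # unaffected non-carriers
    }


@pytest.fixture
def branch_heterogeneity_ped() -> Pedigree:
    """Four-generation family whose two affected sets sit in different
    nuclear branches and carry homozygous variants in different genes."""
    members = [
        Individual("I1", sex="male"),
        Individual("I2", sex="female"),
        Individual("II3", "I1", "I2", "male", "affected"),
        Individual("II4", "I1", "I2", "female", "affected"),
        Individual("II5", "I1", "I2", "male", "unaffected"),
        Individual("II5S", sex="female"),
        Individual("III1", "II5", "II5S", "male", "unaffected"),
        Individual("III2", sex="female", affection="unaffected"),
        Individual("IV1", "III1", "III2", "male", "affected"),
        Individual("IV2", "III1", "III2", "female", "unaffected"),
    ]
    return Pedigree("VI104LIKE", members)


@pytest.fixture
def twin_multigene_ped() -> Pedigree:
    """Affected twins plus an unaffected sibling; two dominant-acting
    variants in different genes co-segregate in the twins."""
    members = [
        Individual("P1", sex="male"),
        Individual("P2", sex="female"),
        Individual("T1", "P1", "P2", "female", "affected"),
        Individual("T2", "P1", "P2", "female", "affected"),
        Individual("S", "P1", "P2", "male", "unaffected"),
    ]
    return Pedigree("VI111LIKE", members)


def mkvar(chrom="chr2", pos=1000, gene="GENEA", **kw) -> AnnotatedVariant:
    kw.setdefault("ref", "A")
    kw.setdefault("alt", "T")
    return AnnotatedVariant(chrom=chrom, pos=pos, gene=gene, **kw)
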