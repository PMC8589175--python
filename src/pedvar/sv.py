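"""Structural-variant characterization: CNV filtering, interval overlap,
copy-state segregation and breakpoint microhomology.

Coordinates follow the genomic ``g.START_ENDdel`` convention on input and
output: 1-based, both endpoints deleted, so a deletion's length is
``end - start + 1``.  Internally intervals are half-open 0-based (BED
convention); conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pedigree import Pedigree
from .segregation import (
    SegregationVerdict,
    test_ad_het,
    test_ar_hom,
    test_comphet,
    test_pseudo_recessive,
)
from .variants import AnnotatedVariant

__all__ = [
    "CnvEvent",
    "JunctionAssembly",
    "BedExon",
    "read_exon_bed",
    "read_sv_vcf",
    "cnv_quality_filter",
    "deletion_length",
    "format_sv_length",
    "gene_overlap",
    "cnv_segregation",
    "cnv_snv_comphet",
    "microhomology",
    "parse_g_deletion",
]


@dataclass
class CnvEvent:
    """A copy-number event with per-sample copy states.

    ``start``/``end`` are 1-based inclusive (the first and last
    deleted/duplicated base).  ``carriers`` maps sample -> copy number
    (autosomes: 0 = homozygous deletion, 1 = heterozygous deletion,
    2 = reference).
    """

    chrom: str
    start: int
    end: int
    svtype: str = "DEL"
    quality: float = float("inf")
    carriers: dict[str, int] = field(default_factory=dict)
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start: {self.start}..{self.end}")
        if self.svtype == "DEL":
            for s, c in self.carriers.items():
                if c > 2:
                    raise ValueError(f"DEL carrier {s} has copy state {c} > 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval0(self) -> tuple[int, int]:
        """Half-open 0-based internal interval."""
        return (self.start - 1, self.end)

    def as_pseudo_variant(self, gene: str | None = None) -> AnnotatedVariant:
        """Represent the event as a symbolic-allele variant record."""
        return AnnotatedVariant(
            chrom=self.chrom,
            pos=self.start,
            ref="N",
            alt=f"<{self.svtype}>",
            gene=gene or (self.genes[0] if self.genes else None),
            impact="HIGH",
        )

    def genotype_counts(self) -> dict[str, int]:
        """Copy states recoded as deletion-allele counts (DEL only)."""
        if self.svtype != "DEL":
            raise ValueError("allele-count recoding is defined for deletions")
        return {s: 2 - c for s, c in self.carriers.items()}


def read_sv_vcf(path: str) -> list[CnvEvent]:
    """Read symbolic-ALT deletion records (``<DEL>`` with ``END`` INFO).

    Genotypes map to copy states: 0/0 -> 2, 0/1 -> 1, 1/1 -> 0.  QUAL
    carries the caller's quality score.
    """
    import cyvcf2

    events = []
    vcf = cyvcf2.VCF(path)
    samples = list(vcf.samples)
    for rec in vcf:
        alts = rec.ALT or []
        if not alts or not alts[0].startswith("<"):
            continue
        svtype = alts[0].strip("<>").split(":")[0]
        end = rec.INFO.get("END")
        if end is None:
            raise ValueError(f"symbolic record {rec.CHROM}:{rec.POS} lacks END")
        carriers = {}
        for s, g in zip(samples, rec.genotypes):
            alleles = [a for a in g[:-1] if a is not None and a >= 0]
            if alleles:
                carriers[s] = 2 - sum(1 for a in alleles if a > 0)
        events.append(
            CnvEvent(
                chrom=rec.CHROM,
                start=rec.POS + 1,  # VCF POS is the base before the event
                end=int(end),
                svtype=svtype,
                quality=float(rec.QUAL) if rec.QUAL is not None else float("inf"),
                carriers=carriers,
            )
        )
    return events


_G_DEL_RE = re.compile(r"g\.([\d,]+)_([\d,]+)del")


def parse_g_deletion(s: str, chrom: str = "", quality: float = float("inf")) -> CnvEvent:
    """Parse a ``g.65,994,849_67,582,755del``-style coordinate string."""
    m = _G_DEL_RE.search(s)
    if not m:
        raise ValueError(f"not a g.START_ENDdel string: {s!r}")
    start = int(m.group(1).replace(",", ""))
    end = int(m.group(2).replace(",", ""))
    return CnvEvent(chrom=chrom, start=start, end=end, svtype="DEL", quality=quality)


def cnv_quality_filter(
    events: Iterable[CnvEvent], min_quality: float = 1.0, min_length: int = 1000
) -> list[CnvEvent]:
    """Drop likely false positives: quality < 1 or shorter than the
    caller's 1 kb resolution floor (boundary values are retained)."""
    return [e for e in events if e.quality >= min_quality and e.length >= min_length]


def deletion_length(event: CnvEvent) -> int:
    if event.svtype != "DEL":
        raise ValueError("deletion_length requires svtype DEL")
    return event.length


def format_sv_length(bp: int) -> str:
    """Human-readable size with magnitude-banded precision.

    >= 1 Mb: nearest 0.1 Mb; 10 kb to 1 Mb: nearest 0.1 kb; < 10 kb:
    nearest 1 kb.  Integral values drop the decimal, so 32,970 bp prints
    as ``33 Kb`` and 1,587,907 bp as ``1.6 Mb``.
    """
    if bp >= 1_000_000:
        val = round(bp / 1_000_000, 1)
        unit = "Mb"
    elif bp >= 10_000:
        val = round(bp / 1_000, 1)
        unit = "Kb"
    else:
        val = float(round(bp / 1_000))
        unit = "Kb"
    if val == int(val):
        return f"{int(val)} {unit}"
    return f"{val} {unit}"


# -- gene/exon overlap ----------------------------------------------------


@dataclass(frozen=True)
class BedExon:
    chrom: str
    start0: int  # half-open 0-based, standard BED
    end0: int
    gene: str
    exon: int
    strand: str = "+"
    coding: bool = True


def read_exon_bed(stream_or_path) -> list[BedExon]:
    """Read a BED6 exon annotation; the name field is ``GENE|exonN`` with
    an optional ``|utr`` suffix for untranslated blocks."""
    if hasattr(stream_or_path, "read"):
        text = stream_or_path.read()
    else:
        with open(stream_or_path) as fh:
            text = fh.read()
    exons = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
        strand = cols[5] if len(cols) > 5 else "+"
        parts = name.split("|")
        gene = parts[0]
        exon = int(parts[1].removeprefix("exon")) if len(parts) > 1 else 0
        coding = "utr" not in parts[2:]
        exons.append(BedExon(chrom, start, end, gene, exon, strand, coding))
    return exons


def gene_overlap(
    event: CnvEvent, exons: Sequence[BedExon]
) -> list[tuple[str, list[int], dict]]:
    """All genes/exons overlapping the event by >= 1 bp.

    Returns ``(gene, [exon numbers], info)`` with info carrying strand and
    utr/coding flags per exon.
    """
    ev_start, ev_end = event.interval0
    hits: dict[str, dict] = {}
    for ex in exons:
        if ex.chrom != event.chrom:
            continue
        if ex.start0 < ev_end and ev_start < ex.end0:  # half-open overlap
            h = hits.setdefault(
                ex.gene, {"exons": [], "strand": ex.strand, "coding": {}}
            )
            h["exons"].append(ex.exon)
            h["coding"][ex.exon] = ex.coding
    return [
        (gene, sorted(h["exons"]), {"strand": h["strand"], "coding": h["coding"]})
        for gene, h in sorted(hits.items())
    ]


# -- segregation with copy states -----------------------------------------


def cnv_segregation(
    ped: Pedigree, event: CnvEvent, gene: str | None = None
) -> list[SegregationVerdict]:
    """Run the small-variant model tests on a deletion's copy states.

    Copy 0 is treated as homozygous for the deletion allele, copy 1 as
    heterozygous.  Returns the verdicts of every applicable autosomal
    model (AR hom, strict AD, pseudo-recessive where consanguineous).
    """
    geno = event.genotype_counts()
    pseudo = event.as_pseudo_variant(gene)
    verdicts = [
        test_ar_hom(ped, geno, pseudo),
        test_ad_het(ped, geno, pseudo),
    ]
    if ped.is_consanguineous():
        verdicts.append(test_pseudo_recessive(ped, geno, pseudo))
    return verdicts


def cnv_snv_comphet(
    ped: Pedigree,
    event: CnvEvent,
    snv_geno: Mapping[str, int],
    snv: AnnotatedVariant,
) -> SegregationVerdict:
    """SNV + CNV compound heterozygote in one gene.

    A heterozygous small variant and a heterozygous deletion hitting the
    same gene on opposite parental haplotypes behave exactly like a
    biallelic comp-het; the deletion enters the phase logic as a pseudo
    allele.
    """
    pseudo = event.as_pseudo_variant(snv.gene)
    return test_comphet(ped, dict(snv_geno), event.genotype_counts(), snv, pseudo)


# -- junction microhomology -----------------------------------------------


@dataclass
class JunctionAssembly:
    """Breakpoint context of a resolved deletion: the reference sequence
    ending just before the proximal breakpoint (``left_flank``), the
    reference beginning just after the distal breakpoint (``right_flank``)
    and the read crossing the junction."""

    left_flank: str
    right_flank: str
    junction_read: str = ""

    def __post_init__(self) -> None:
        for name in ("left_flank", "right_flank", "junction_read"):
            seq = getattr(self, name).upper()
            if not re.fullmatch(r"[ACGTN]*", seq):
                raise ValueError(f"{name} contains non-ACGTN characters")
            setattr(self, name, seq)


def microhomology(j: JunctionAssembly) -> tuple[int, str]:
    """Longest exact repeat shared by the two breakpoint sides.

    The homology tract is the longest suffix of the retained left flank
    that equals the prefix of the retained right flank — the signature
    that non-homologous end-joining leaves at a deletion junction.  An N
    inside a candidate tract terminates it.
    """
    left, right = j.left_flank, j.right_flank
    best = 0
    limit = min(len(left), len(right))
    for k in range(1, limit + 1):
        cand = left[-k:]
        if "N" in cand:
            break
        if cand == right[:k]:
            best = k
    return best, (left[len(left) - best :] if best else "")
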