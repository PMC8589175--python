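"""Variant data model, HGVS-lite parsing, consequence classes and filters.

The filtering strategy is two-tier.  A variant must first be rare in every
reference panel it appears in (strict ``<`` on each allele-frequency field;
a missing frequency counts as rare — absence from a panel is evidence of
rarity, not grounds for exclusion).  It is then graded by deleteriousness:

* ``highly``    — impact HIGH, or PolyPhen possibly/probably damaging,
                  or CADD Phred >= 30
* ``relatively``— impact HIGH/MODERATE, or PolyPhen damaging,
                  or CADD Phred >= 20 (and not already ``highly``)

Consequence classification is intentionally HGVS-driven rather than
transcript-aware: the protein notation takes precedence (``fs`` beats a
terminating ``*``), and purely intronic cDNA notation is graded by the
magnitude of its offset into the intron (|d| <= 2 canonical splice site,
3 <= |d| <= 8 splice region).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PAR1",
    "PAR2",
    "is_par",
    "AnnotatedVariant",
    "FilterThresholds",
    "HgvsC",
    "parse_hgvs_c",
    "classify_consequence",
    "frequency_pass",
    "deleteriousness_tier",
    "GenotypeMatrix",
    "read_vcf",
    "VcfFieldMap",
    "VcfParseError",
]

# hg19 X-chromosome pseudo-autosomal regions (1-based inclusive); male
# genotypes inside these intervals are diploid, outside haploid.
PAR1 = (60001, 2699520)
PAR2 = (154931044, 155260560)

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_canonical",
    "splice_region",
    "inframe_indel",
    "synonymous",
    "other",
)

SPLICE_CLASSES = ("splice_canonical", "splice_region")


def is_par(chrom: str, pos: int) -> bool:
    """True if an X-chromosome position lies in a pseudo-autosomal region."""
    if chrom.removeprefix("chr").upper() != "X":
        return False
    return PAR1[0] <= pos <= PAR1[1] or PAR2[0] <= pos <= PAR2[1]


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    impact: str | None = None  # HIGH / MODERATE / LOW / MODIFIER
    polyphen: str | None = None  # probably_damaging / possibly_damaging / benign
    cadd_phred: float | None = None
    af_1kg: float | None = None
    af_inhouse: float | None = None
    af_cohort: float | None = None
    af_gnomad: float | None = None
    novelty: str = "reported"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not re.fullmatch(r"[ACGTN*]+|<[A-Z:]+>", allele):
                raise ValueError(f"bad allele string {allele!r}")

    @property
    def is_x(self) -> bool:
        return self.chrom.removeprefix("chr").upper() == "X"

    @property
    def is_x_nonpar(self) -> bool:
        return self.is_x and not is_par(self.chrom, self.pos)

    @property
    def consequence(self) -> str:
        return classify_consequence(self.hgvs_c, self.hgvs_p)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterThresholds:
    max_af_1kg: float = 0.005
    max_af_inhouse: float = 0.05
    max_af_cohort: float = 0.05
    cadd_high: float = 30.0
    cadd_moderate: float = 20.0

    def __post_init__(self) -> None:
        if self.cadd_high < self.cadd_moderate:
            raise ValueError("cadd_high must be >= cadd_moderate")
        for name in ("max_af_1kg", "max_af_inhouse", "max_af_cohort"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


# -- HGVS-lite -----------------------------------------------------------

# c.<pos>[<+/-offset>][_<pos2>[<+/-offset2>]]<edit>
_HGVS_C_RE = re.compile(
    r"""^c\.
        (?P<pos>\d+)(?P<off>[+-]\d+)?
        (?:_(?P<pos2>\d+)(?P<off2>[+-]\d+)?)?
        (?P<edit>
            (?P<from>[ACGTN]+)>(?P<to>[ACGTN]+)
          | delins(?P<delins_seq>[ACGTN]*)
          | del(?P<del_seq>[ACGTN]*)
          | dup(?P<dup_seq>[ACGTN]*)
          | ins(?P<ins_seq>[ACGTN]+)
        )$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class HgvsC:
    """Parsed coding-DNA notation; ``ok`` is False for unparseable input."""

    raw: str
    ok: bool
    pos: int | None = None
    offset: int = 0
    end_pos: int | None = None
    end_offset: int = 0
    edit: str | None = None  # sub / del / dup / ins / delins
    length: int = 0

    @property
    def intronic(self) -> bool:
        return self.ok and (self.offset != 0 or self.end_offset != 0)

    @property
    def min_abs_offset(self) -> int:
        offs = [abs(o) for o in (self.offset, self.end_offset) if o != 0]
        return min(offs) if offs else 0


def _parse_failure(s: str) -> HgvsC:
    return HgvsC(raw=s, ok=False)


def parse_hgvs_c(s: str) -> HgvsC:
    """Parse a cDNA HGVS string into position/offset/edit components.

    Unparseable input returns an explicit failure value (``ok=False``)
    rather than raising: table fixtures carry free-text fields and a bad
    cell must never silently vanish.
    """
    if s is None:
        return _parse_failure("")
    s = s.strip()
    m = _HGVS_C_RE.match(s)
    if not m:
        return _parse_failure(s)
    pos = int(m.group("pos"))
    off = int(m.group("off") or 0)
    pos2 = int(m.group("pos2")) if m.group("pos2") else None
    off2 = int(m.group("off2") or 0)
    if m.group("from") is not None:
        edit = "sub"
        length = len(m.group("to"))
    elif m.group("delins_seq") is not None:
        edit = "delins"
        length = len(m.group("delins_seq")) or _span(pos, pos2)
    elif m.group("del_seq") is not None:
        edit = "del"
        length = len(m.group("del_seq")) or _span(pos, pos2)
    elif m.group("dup_seq") is not None:
        edit = "dup"
        length = len(m.group("dup_seq")) or _span(pos, pos2)
    else:
        edit = "ins"
        length = len(m.group("ins_seq"))
    return HgvsC(
        raw=s,
        ok=True,
        pos=pos,
        offset=off,
        end_pos=pos2,
        end_offset=off2,
        edit=edit,
        length=length,
    )


def _span(pos: int, pos2: int | None) -> int:
    return 1 if pos2 is None else pos2 - pos + 1


# protein notation: p.Xaa123Yaa, p.Xaa123*, p.Xaa123Yaafs*NN, p.Xaa123del ...
_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|"
    "Thr|Trp|Tyr|Val|Sec|Ter"
)
_HGVS_P_SUB_RE = re.compile(
    rf"^[pP]\.\(?(?P<from>{_AA3})(?P<pos>\d+)(?P<to>{_AA3}|\*)\)?$"
)


def _missing(s: str | None) -> bool:
    return s is None or s.strip() in ("", "NA", "N/A", "n/a", ".", "-")


def classify_consequence(hgvs_c: str | None, hgvs_p: str | None) -> str:
    """Single consequence class for a variant, protein notation first.

    ``fs`` anywhere in the protein change wins (frameshift), then a
    terminating ``*``/``Ter`` (nonsense), then single-residue substitution
    (missense or synonymous), then in-frame del/dup/ins.  Variants with no
    protein consequence fall through to intron-offset splice grading.
    """
    if not _missing(hgvs_p):
        p = hgvs_p.strip()
        body = p[2:] if p[:2].lower() == "p." else p
        if "fs" in body:
            return "frameshift"
        if body.endswith("*") or body.endswith("Ter"):
            m = _HGVS_P_SUB_RE.match(p)
            if m and m.group("to") in ("*", "Ter"):
                return "nonsense"
            # e.g. range deletions annotated ...del* — fall through
            if not m:
                return "nonsense"
        m = _HGVS_P_SUB_RE.match(p)
        if m:
            if m.group("to") in ("*", "Ter"):
                return "nonsense"
            return "synonymous" if m.group("from") == m.group("to") else "missense"
        if "delins" in body or "del" in body or "dup" in body or "ins" in body:
            return "inframe_indel"
    if not _missing(hgvs_c):
        c = parse_hgvs_c(hgvs_c)
        if c.ok and c.intronic:
            d = c.min_abs_offset
            if d <= 2:
                return "splice_canonical"
            if d <= 8:
                return "splice_region"
    return "other"


def is_splice_altering(consequence: str) -> bool:
    return consequence in SPLICE_CLASSES


def is_truncating(consequence: str) -> bool:
    """Loss-of-function-like classes, used to pick the z_lof constraint."""
    return consequence in ("nonsense", "frameshift", "splice_canonical")


# -- filters -------------------------------------------------------------


def frequency_pass(v: AnnotatedVariant, t: FilterThresholds | None = None) -> bool:
    """True iff every *available* AF field is strictly below its threshold."""
    t = t or FilterThresholds()
    checks = (
        (v.af_1kg, t.max_af_1kg),
        (v.af_inhouse, t.max_af_inhouse),
        (v.af_cohort, t.max_af_cohort),
    )
    return all(af is None or af < cap for af, cap in checks)


def deleteriousness_tier(v: AnnotatedVariant, t: FilterThresholds | None = None) -> str:
    """Grade a variant ``highly`` / ``relatively`` / ``none``.

    PolyPhen predictions only apply to missense variants; everything else
    is graded on SnpEff-style impact and CADD alone.
    """
    t = t or FilterThresholds()
    if v.impact is None and v.polyphen is None and v.cadd_phred is None:
        log.warning("variant %s:%d has no annotation fields; tier=none", v.chrom, v.pos)
        return "none"
    # PolyPhen speaks to amino-acid substitutions only: ignore it when the
    # HGVS-derived class is known to be something other than missense
    polyphen = v.polyphen if v.consequence in ("missense", "other") else None
    damaging = polyphen in ("possibly_damaging", "probably_damaging")
    if (
        v.impact == "HIGH"
        or damaging
        or (v.cadd_phred is not None and v.cadd_phred >= t.cadd_high)
    ):
        return "highly"
    if (
        v.impact in ("HIGH", "MODERATE")
        or damaging
        or (v.cadd_phred is not None and v.cadd_phred >= t.cadd_moderate)
    ):
        return "relatively"
    return "none"


# -- VCF reading ---------------------------------------------------------


class VcfParseError(ValueError):
    pass


@dataclass(frozen=True)
class VcfFieldMap:
    """INFO-key mapping; annotation field names are site-specific, so the
    reader is configured rather than hard-wired.  ``ann`` enables SnpEff
    ANN fallback for gene/impact when the direct keys are absent."""

    gene: str = "GENE"
    impact: str = "IMPACT"
    polyphen: str = "PP2"
    cadd: str = "CADD"
    af_1kg: str = "AF_1KG"
    af_inhouse: str = "AF_IH"
    af_cohort: str = "AF_COH"
    af_gnomad: str = "AF_GNOMAD"
    ann: str = "ANN"


class GenotypeMatrix:
    """Per-sample allele counts for a list of variants.

    ``counts[i, j]`` is the alt-allele count of sample ``j`` at variant
    ``i`` (-1 for missing); ``ploidy[i, j]`` is 1 for haploid calls (male
    non-PAR X) and 2 otherwise.
    """

    def __init__(self, samples: list[str], counts: np.ndarray, ploidy: np.ndarray):
        self.samples = list(samples)
        self.counts = np.asarray(counts, dtype=np.int16)
        self.ploidy = np.asarray(ploidy, dtype=np.int8)
        if self.counts.shape != self.ploidy.shape:
            raise ValueError("counts/ploidy shape mismatch")
        if self.counts.shape[1] != len(self.samples):
            raise ValueError("sample dimension mismatch")
        self._col = {s: j for j, s in enumerate(self.samples)}

    @property
    def n_variants(self) -> int:
        return self.counts.shape[0]

    def genotypes(self, i: int) -> dict[str, int]:
        """Sample -> alt count at variant row i (missing samples omitted)."""
        row = self.counts[i]
        return {s: int(row[j]) for s, j in self._col.items() if row[j] >= 0}

    def ploidy_of(self, i: int) -> dict[str, int]:
        row = self.ploidy[i]
        return {s: int(row[j]) for s, j in self._col.items()}

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeMatrix":
        idx = [self._col[s] for s in keep]
        return GenotypeMatrix(
            [self.samples[j] for j in idx], self.counts[:, idx], self.ploidy[:, idx]
        )

    def autosomal_het_rate(self, variants: list[AnnotatedVariant]) -> dict[str, float]:
        rows = [i for i, v in enumerate(variants) if not v.is_x]
        out = {}
        for s, j in self._col.items():
            col = self.counts[rows, j]
            called = col >= 0
            out[s] = float(np.mean(col[called] == 1)) if called.any() else float("nan")
        return out


def _info_float(rec, key: str) -> float | None:
    val = rec.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0]
    try:
        return float(val)
    except (TypeError, ValueError):
        return None


def _info_str(rec, key: str) -> str | None:
    val = rec.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0]
    return str(val)


def read_vcf(
    path: str,
    fields: VcfFieldMap | None = None,
) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read a VCF into annotated variants plus a genotype matrix.

    Multi-allelic sites are decomposed into one record per ALT allele;
    each sample's count for a record is the number of copies of that
    specific ALT.  Haploid calls keep ploidy 1.
    """
    import cyvcf2

    fields = fields or VcfFieldMap()
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    count_rows: list[list[int]] = []
    ploidy_rows: list[list[int]] = []
    for rec in vcf:
        alts = rec.ALT or []
        gts = rec.genotypes  # [allele1, allele2, ..., phased]
        for alt_index, alt in enumerate(alts, start=1):
            gene = _info_str(rec, fields.gene)
            impact = _info_str(rec, fields.impact)
            if (gene is None or impact is None) and rec.INFO.get(fields.ann):
                ann = str(rec.INFO.get(fields.ann)).split(",")[0].split("|")
                if len(ann) > 3:
                    impact = impact or ann[2] or None
                    gene = gene or ann[3] or None
            try:
                var = AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=gene,
                    hgvs_c=_info_str(rec, "HGVSC"),
                    hgvs_p=_info_str(rec, "HGVSP"),
                    impact=impact,
                    polyphen=_info_str(rec, fields.polyphen),
                    cadd_phred=_info_float(rec, fields.cadd),
                    af_1kg=_info_float(rec, fields.af_1kg),
                    af_inhouse=_info_float(rec, fields.af_inhouse),
                    af_cohort=_info_float(rec, fields.af_cohort),
                    af_gnomad=_info_float(rec, fields.af_gnomad),
                )
            except ValueError as exc:
                raise VcfParseError(
                    f"malformed record at {rec.CHROM}:{rec.POS}: {exc}"
                ) from exc
            crow, prow = [], []
            for g in gts:
                alleles = [a for a in g[:-1] if a is not None]
                ploidy = max(1, len([a for a in alleles if a >= -1]))
                known = [a for a in alleles if a >= 0]
                if len(known) < len(alleles) or not alleles:
                    crow.append(-1)
                else:
                    crow.append(sum(1 for a in known if a == alt_index))
                prow.append(min(ploidy, 2))
            variants.append(var)
            count_rows.append(crow)
            ploidy_rows.append(prow)
    counts = (
        np.array(count_rows, dtype=np.int16)
        if count_rows
        else np.zeros((0, len(samples)), dtype=np.int16)
    )
    ploidy = (
        np.array(ploidy_rows, dtype=np.int8)
        if ploidy_rows
        else np.full((0, len(samples)), 2, dtype=np.int8)
    )
    return variants, GenotypeMatrix(samples, counts, ploidy)
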