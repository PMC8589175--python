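"""Sample-level quality control: sex inference, relatedness, contamination.

Three screens mirror standard WGS cohort QC:

* sex from the X-chromosome heterozygosity rate (males, hemizygous
  outside the PARs, show near-zero X het; females sit well above),
* pairwise kinship from genotype identity-state counts with the
  KING-robust within-family moment estimator, compared against the
  kinship expected from the declared pedigree,
* an autosomal heterozygosity outlier screen (median +/- k MAD), the
  usual tell for sample contamination.

All thresholds are config-exposed; the defaults are chosen so a 1%
genotyping-error model still separates the classes with a wide margin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pedigree import Pedigree

log = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "QcReport",
    "RelatednessFlag",
    "infer_sex",
    "build_qc_reports",
    "estimate_kinship",
    "verify_family_structure",
    "heterozygosity_screen",
]


@dataclass(frozen=True)
class QcThresholds:
    min_x_sites: int = 200
    male_max_x_het: float = 0.05
    female_min_x_het: float = 0.15
    min_kinship_sites: int = 1000
    kinship_tolerance: float = 0.1
    close_kin_phi: float = 0.125  # 2nd degree and closer
    cross_family_phi: float = 0.1
    het_outlier_k: float = 5.0
    min_cohort_size: int = 10


@dataclass(frozen=True)
class RelatednessFlag:
    pair: tuple[str, str]
    expected_phi: float
    observed_phi: float
    verdict: str  # consistent / mismatch


@dataclass
class QcReport:
    sample_id: str
    inferred_sex: str
    x_het_rate: float
    autosomal_het_rate: float
    relatedness_flags: list[RelatednessFlag] = field(default_factory=list)


def infer_sex(
    x_genotypes: Sequence[int] | np.ndarray,
    thresholds: QcThresholds | None = None,
) -> str:
    """Infer sex from diploid-coded genotype calls at non-PAR X sites.

    ``x_genotypes`` holds alt-allele counts (0/1/2; negative = missing).
    Het rate below the male ceiling calls male, above the female floor
    calls female; the gap between them returns unknown with a warning.
    """
    t = thresholds or QcThresholds()
    g = np.asarray(x_genotypes)
    called = g[g >= 0]
    if called.size < t.min_x_sites:
        log.warning(
            "only %d called non-PAR X sites (< %d); sex unknown",
            called.size,
            t.min_x_sites,
        )
        return "unknown"
    het_rate = float(np.mean(called == 1))
    if het_rate < t.male_max_x_het:
        return "male"
    if het_rate > t.female_min_x_het:
        return "female"
    log.warning("ambiguous X het rate %.3f; sex unknown", het_rate)
    return "unknown"


def estimate_kinship(
    ga: Sequence[int] | np.ndarray,
    gb: Sequence[int] | np.ndarray,
    thresholds: QcThresholds | None = None,
) -> float | None:
    """KING-robust within-pair kinship from shared autosomal genotypes.

    phi_hat = (N_het_het - 2 * N_opposite_hom) / (N_het_a + N_het_b)

    where N_het_het counts sites at which both samples are heterozygous
    and N_opposite_hom counts AA/aa discordances.  The estimator is free
    of allele-frequency estimates, hence robust to the strong founder
    structure of family data.  Returns None (with a warning) when too few
    sites are jointly called.
    """
    t = thresholds or QcThresholds()
    a = np.asarray(ga)
    b = np.asarray(gb)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    shared = (a >= 0) & (b >= 0)
    a, b = a[shared], b[shared]
    if a.size < t.min_kinship_sites:
        log.warning("only %d shared sites (< %d); kinship not estimated", a.size, t.min_kinship_sites)
        return None
    both_het = int(np.sum((a == 1) & (b == 1)))
    opp_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    het_a = int(np.sum(a == 1))
    het_b = int(np.sum(b == 1))
    if het_a + het_b == 0:
        return None
    return (both_het - 2 * opp_hom) / (het_a + het_b)


def verify_family_structure(
    peds: Pedigree | Iterable[Pedigree],
    observed: Mapping[frozenset, float],
    thresholds: QcThresholds | None = None,
) -> list[RelatednessFlag]:
    """Compare observed kinship against pedigree expectation.

    Declared close pairs (expected phi at 2nd degree or nearer) whose
    estimate strays beyond the tolerance are flagged as mismatches —
    these block downstream de-novo calls for the family.  Founder pairs
    from *different* families with unexpectedly high observed kinship are
    flagged too (sample swaps surface exactly this way).
    """
    t = thresholds or QcThresholds()
    if isinstance(peds, Pedigree):
        peds = [peds]
    peds = list(peds)
    flags: list[RelatednessFlag] = []
    sample_family: dict[str, str] = {}
    for ped in peds:
        for ind in ped.members:
            sample_family[ind] = ped.family_id
        ids = sorted(ped.members)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                obs = observed.get(frozenset((a, b)))
                if obs is None:
                    continue
                exp = float(ped.kinship(a, b))
                if exp >= t.close_kin_phi:
                    verdict = (
                        "consistent"
                        if abs(obs - exp) <= t.kinship_tolerance
                        else "mismatch"
                    )
                    if verdict == "mismatch":
                        flags.append(RelatednessFlag((a, b), exp, obs, "mismatch"))
    # cross-family relatedness: any pair spanning two families should be ~0
    for key, obs in observed.items():
        pair = sorted(key)
        if len(pair) != 2:
            continue
        a, b = pair
        fa, fb = sample_family.get(a), sample_family.get(b)
        if fa is None or fb is None or fa == fb:
            continue
        if obs > t.cross_family_phi:
            flags.append(RelatednessFlag((a, b), 0.0, obs, "mismatch"))
    return flags


def build_qc_reports(
    variants,
    gtm,
    thresholds: QcThresholds | None = None,
) -> list[QcReport]:
    """Per-sample QC summary from a variant list plus genotype matrix:
    inferred sex from non-PAR X sites and autosomal/X het rates."""
    t = thresholds or QcThresholds()
    x_rows = [i for i, v in enumerate(variants) if v.is_x_nonpar]
    auto_het = gtm.autosomal_het_rate(variants)
    reports = []
    for j, s in enumerate(gtm.samples):
        xg = gtm.counts[x_rows, j] if x_rows else np.empty(0, dtype=int)
        xp = gtm.ploidy[x_rows, j] if x_rows else np.empty(0, dtype=int)
        # a haploid call is never heterozygous; recode it as a diploid
        # hom so the het-rate convention matches diploid-coded callsets
        diploid_coded = np.where((xg >= 0) & (xp == 1), xg * 2, xg)
        called = diploid_coded[diploid_coded >= 0]
        x_rate = float(np.mean(called == 1)) if called.size else float("nan")
        reports.append(
            QcReport(
                sample_id=s,
                inferred_sex=infer_sex(diploid_coded, t),
                x_het_rate=x_rate,
                autosomal_het_rate=auto_het[s],
            )
        )
    return reports


def heterozygosity_screen(
    het_rates: Mapping[str, float],
    thresholds: QcThresholds | None = None,
) -> list[str]:
    """Samples whose autosomal het rate falls outside median +/- k*MAD."""
    t = thresholds or QcThresholds()
    if len(het_rates) < t.min_cohort_size:
        log.warning(
            "cohort of %d samples is too small for outlier statistics", len(het_rates)
        )
        return []
    samples = sorted(het_rates)
    rates = np.array([het_rates[s] for s in samples], dtype=float)
    med = float(np.median(rates))
    mad = float(np.median(np.abs(rates - med)))
    if mad == 0:
        mad = 1e-9
    lo, hi = med - t.het_outlier_k * mad, med + t.het_outlier_k * mad
    return [s for s, r in zip(samples, rates) if not lo <= r <= hi]
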