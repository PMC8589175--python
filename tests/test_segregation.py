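"""Inheritance-model tests, atypical-genotype detection and ranking.

The randomized oracle suite lives in ``oracle.py``; here each model's
defining behaviours are pinned with hand-built families.
"""

import numpy as np
import pytest

from pedvar.pedigree import Individual, Pedigree
from pedvar.segregation import (
    AD_HET,
    AR_COMPHET,
    AR_HOM,
    DE_NOVO,
    PSEUDO_RECESSIVE,
    XL,
    GeneConstraint,
    rank_by_constraint,
    scan_pedigree,
    scan_with_atypicals,
    test_ad_het,
    test_ar_hom,
    test_comphet,
    test_de_novo,
    test_pseudo_recessive,
    test_xlinked,
)
from pedvar.simulate import Planting, SimulationSpec, simulate_pedigree
from pedvar.pipeline import PipelineConfig, filter_variants

from conftest import gm, mkvar


class TestArHom:
    def test_consanguineous_sibship_passes(self, quartet):
        # both parents het, affected child hom, unaffected sib het
        v = test_ar_hom(quartet, {"F": 1, "M": 1, "A": 2, "U": 1}, mkvar())
        assert v.passes and v.affected_carriers == ("A",)

    def test_het_affected_fails(self, quartet):
        assert not test_ar_hom(quartet, {"F": 1, "M": 1, "A": 1, "U": 0}).passes

    def test_hom_unaffected_is_violation(self, quartet):
        v = test_ar_hom(quartet, {"F": 1, "M": 1, "A": 2, "U": 2})
        assert not v.passes and v.unaffected_violations == ("U",)

    def test_parent_without_allele_fails(self, quartet):
        assert not test_ar_hom(quartet, {"F": 0, "M": 1, "A": 2}).passes

    def test_no_genotyped_affected_is_indeterminate(self, quartet):
        v = test_ar_hom(quartet, {"F": 1, "M": 1, "U": 0})
        assert v.indeterminate and not v.passes


class TestCompHet:
    def test_trans_through_parents(self, quartet):
        v = test_comphet(
            quartet,
            {"F": 1, "M": 0, "A": 1, "U": 0},
            {"F": 0, "M": 1, "A": 1, "U": 1},
        )
        assert v.passes and v.phase == "trans"

    def test_cis_from_one_parent_fails(self, quartet):
        v = test_comphet(
            quartet,
            {"F": 1, "M": 0, "A": 1},
            {"F": 1, "M": 0, "A": 1},
        )
        assert not v.passes and v.phase == "cis"

    def test_phase_from_offspring(self):
        """An adopted proband with no parental data: his two children
        each inherited exactly one allele, proving trans configuration."""
        ped = Pedigree(
            "T811",
            [
                Individual("P", sex="male", affection="affected"),
                Individual("W", sex="female", affection="unaffected"),
                Individual("K1", "P", "W", "male", "unaffected"),
                Individual("K2", "P", "W", "female", "unaffected"),
            ],
        )
        v = test_comphet(
            ped,
            {"P": 1, "K1": 1, "K2": 0, "W": 0},
            {"P": 1, "K1": 0, "K2": 1, "W": 0},
        )
        assert v.passes and v.phase == "trans"

    def test_no_informative_relatives_passes_phase_unknown(self):
        solo = Pedigree("S", [Individual("P", sex="female", affection="affected")])
        v = test_comphet(solo, {"P": 1}, {"P": 1})
        assert v.passes and v.phase == "unknown"
        assert "phase_unknown" in v.atypical_flags

    def test_different_genes_rejected(self, quartet):
        with pytest.raises(ValueError, match="different genes"):
            test_comphet(
                quartet, {"A": 1}, {"A": 1},
                mkvar(gene="G1"), mkvar(gene="G2", pos=2000),
            )


class TestAdHet:
    def test_dominant_transmission_passes(self):
        ped = Pedigree(
            "AD",
            [
                Individual("F", sex="male", affection="affected"),
                Individual("M", sex="female", affection="unaffected"),
                Individual("C1", "F", "M", "male", "affected"),
                Individual("C2", "F", "M", "female", "unaffected"),
            ],
        )
        v = test_ad_het(ped, {"F": 1, "M": 0, "C1": 1, "C2": 0})
        assert v.passes

    def test_unaffected_carrier_fails(self, quartet):
        v = test_ad_het(quartet, {"F": 0, "M": 0, "A": 1, "U": 1})
        assert not v.passes and v.unaffected_violations == ("U",)

    def test_hom_affected_fails_strict_dominant(self, quartet):
        assert not test_ad_het(quartet, {"F": 1, "M": 1, "A": 2, "U": 0}).passes


class TestXLinked:
    @pytest.fixture
    def xl_ped(self):
        return Pedigree(
            "XL",
            [
                Individual("F", sex="male", affection="unaffected"),
                Individual("M", sex="female", affection="unaffected"),
                Individual("S1", "F", "M", "male", "affected"),
                Individual("S2", "F", "M", "male", "unaffected"),
                Individual("D1", "F", "M", "female", "affected"),
            ],
        )

    def xvar(self):
        return mkvar(chrom="chrX", pos=38_182_193, gene="RPGR")

    def test_hemizygous_affected_passes(self, xl_ped):
        v = test_xlinked(
            xl_ped, {"F": 0, "M": 1, "S1": 1, "S2": 0, "D1": 1}, self.xvar(),
            ploidy={"F": 1, "S1": 1, "S2": 1, "M": 2, "D1": 2},
        )
        assert v.passes

    def test_father_to_son_transmission_fails(self):
        ped = Pedigree(
            "XL2",
            [
                Individual("F", sex="male", affection="unaffected"),
                Individual("M", sex="female", affection="unaffected"),
                Individual("S", "F", "M", "male", "affected"),
            ],
        )
        v = test_xlinked(ped, {"F": 1, "M": 0, "S": 1}, self.xvar(),
                         ploidy={"F": 1, "S": 1, "M": 2})
        assert not v.passes

    def test_manifesting_carrier_flagged(self, xl_ped):
        v = test_xlinked(
            xl_ped, {"M": 1, "S1": 1, "D1": 1}, self.xvar(),
            ploidy={"S1": 1, "M": 2, "D1": 2},
        )
        assert v.passes and "manifesting_carrier" in v.atypical_flags

    def test_male_het_diploid_call_is_error(self, xl_ped):
        with pytest.raises(ValueError, match="heterozygous diploid"):
            test_xlinked(xl_ped, {"S1": 1}, self.xvar(), ploidy={"S1": 2})

    def test_par_variant_rejected(self, xl_ped):
        with pytest.raises(ValueError, match="non-PAR"):
            test_xlinked(xl_ped, {"S1": 1}, mkvar(chrom="chrX", pos=60_001))


class TestDeNovo:
    def test_trio_de_novo_passes(self, trio):
        v = test_de_novo(trio, {"F": 0, "M": 0, "C": 1}, mkvar())
        assert v.passes and "de_novo" in v.atypical_flags

    def test_kinship_mismatch_fails_with_flag(self, trio):
        obs = {frozenset(("F", "C")): 0.0, frozenset(("M", "C")): 0.25}
        v = test_de_novo(trio, {"F": 0, "M": 0, "C": 1}, mkvar(), obs)
        assert not v.passes and "non_paternity" in v.atypical_flags

    def test_inherited_allele_fails(self, trio):
        assert not test_de_novo(trio, {"F": 1, "M": 0, "C": 1}).passes

    def test_ungenotyped_parents_indeterminate(self, trio):
        v = test_de_novo(trio, {"M": 0, "C": 1})
        assert v.indeterminate

    def test_planted_site_is_sole_pass_among_background(self):
        """Gene-dropped trio with one planted de-novo: exactly the
        planted site passes the de-novo test across all variants."""
        spec = SimulationSpec(
            seed=42, n_generations=2, sibship_size=1,
            n_background_variants=1000, n_genes=50, genotyping_error=0.0,
            planted=(Planting("GENE09", "de_novo"),),
        )
        cohort = simulate_pedigree(spec)
        ped, gtm = cohort.pedigree, cohort.genotypes
        passing = [
            v.gene
            for i, v in enumerate(cohort.variants)
            if not v.is_x_nonpar
            and test_de_novo(
                ped, gtm.genotypes(i), v, flanking=(cohort.variants, gtm)
            ).passes
        ]
        assert passing == ["GENE09"]


class TestPseudoRecessive:
    def test_mixed_het_hom_affected_passes(
        self, pseudo_recessive_ped, pseudo_recessive_geno
    ):
        v = test_pseudo_recessive(pseudo_recessive_ped, pseudo_recessive_geno)
        assert v.passes and "pseudo_recessive" in v.atypical_flags

    def test_all_het_routes_to_plain_dominant(self, pseudo_recessive_ped):
        geno = {s: 0 for s in pseudo_recessive_ped.members}
        for s in ("A", "C", "D", "E", "F", "G", "H", "I"):
            geno[s] = 1
        assert not test_pseudo_recessive(pseudo_recessive_ped, geno).passes
        assert test_ad_het(pseudo_recessive_ped, geno).passes

    def test_unaffected_carrier_fails(
        self, pseudo_recessive_ped, pseudo_recessive_geno
    ):
        geno = dict(pseudo_recessive_geno, B=1)
        assert not test_pseudo_recessive(pseudo_recessive_ped, geno).passes

    def test_outbred_pedigree_indeterminate(self, quartet):
        v = test_pseudo_recessive(quartet, {"A": 2, "U": 0})
        assert v.indeterminate


class TestScanAndAtypicals:
    def test_single_planted_gene_single_verdict_gene(self):
        spec = SimulationSpec(
            seed=3, genotyping_error=0.0, planted=(Planting("GENE01", "AR_hom"),)
        )
        cohort = simulate_pedigree(spec)
        kept, gtm = filter_variants(cohort.variants, cohort.genotypes, PipelineConfig())
        verdicts = scan_pedigree(cohort.pedigree, kept, gtm)
        assert {v.gene for v in verdicts} == {"GENE01"}

    def test_empty_scan_for_unsolvable(self, quartet):
        variants = [mkvar(gene="G1")]
        gtm = gm({"F": 0, "M": 0, "A": 0, "U": 1}, {"F": 0, "M": 0, "A": 0, "U": 1})
        assert scan_pedigree(quartet, variants, gtm) == []

    def test_multigene_twins(self, twin_multigene_ped):
        ped = twin_multigene_ped
        v_prpf8 = mkvar(chrom="chr17", pos=1_554_155, gene="PRPF8",
                        hgvs_p="p.Phe2317Ile")
        v_prpf31 = mkvar(chrom="chr19", pos=54_629_912, gene="PRPF31",
                         hgvs_p="p.Arg289Profs*30")
        gtm = gm(
            {"T1": 0, "T2": 0, "S": 0},
            [{"T1": 1, "T2": 1, "S": 0}, {"T1": 1, "T2": 1, "S": 0}],
        )
        verdicts, flags = scan_with_atypicals(ped, [v_prpf8, v_prpf31], gtm)
        assert "multi_gene" in flags
        assert {v.gene for v in verdicts if v.passes} == {"PRPF8", "PRPF31"}

    def test_intrafamilial_heterogeneity_across_branches(
        self, branch_heterogeneity_ped
    ):
        ped = branch_heterogeneity_ped
        v_c2orf71 = mkvar(chrom="chr2", pos=29_294_178, gene="C2orf71",
                          hgvs_p="p.Arg984*")
        v_cln3 = mkvar(chrom="chr16", pos=28_502_798, gene="CLN3",
                       hgvs_c="c.125+5G>A")
        gtm = gm(
            {"II3": 0, "II4": 0, "III1": 0, "III2": 0, "IV1": 0, "IV2": 0},
            [
                {"II3": 2, "II4": 2, "III1": 1, "IV1": 1, "IV2": 0, "III2": 0},
                {"II3": 0, "II4": 0, "III1": 1, "III2": 1, "IV1": 2, "IV2": 1},
            ],
        )
        verdicts, flags = scan_with_atypicals(ped, [v_c2orf71, v_cln3], gtm)
        assert "intrafamilial_heterogeneity" in flags
        genes = {v.gene for v in verdicts if v.passes}
        assert genes == {"C2orf71", "CLN3"}

    def test_pseudo_recessive_family_resolves_only_pseudo(
        self, pseudo_recessive_ped, pseudo_recessive_geno
    ):
        """The consanguineous dominant family: recessive and strict
        dominant searches both fail; the combined het-or-hom search
        recovers the allele."""
        ped = pseudo_recessive_ped
        v = mkvar(chrom="chr1", pos=150_316_692, gene="PRPF3", hgvs_p="p.Thr494Met")
        gtm = gm({s: 0 for s in ped.members}, pseudo_recessive_geno)
        assert not test_ar_hom(ped, pseudo_recessive_geno, v).passes
        assert not test_ad_het(ped, pseudo_recessive_geno, v).passes
        verdicts = scan_pedigree(ped, [v], gtm)
        assert [x.model for x in verdicts] == [PSEUDO_RECESSIVE]


class TestRanking:
    def make_verdict(self, gene, model, pos=100, hgvs_p="p.Arg1Gly"):
        from pedvar.segregation import SegregationVerdict

        return SegregationVerdict(
            pedigree_id="P",
            gene=gene,
            model=model,
            variants=(mkvar(gene=gene, pos=pos, hgvs_p=hgvs_p),),
            passes=True,
        )

    def test_high_z_first(self):
        panel = {
            "HIZ": GeneConstraint("HIZ", 4.2, 4.0, "dominant"),
            "LOZ": GeneConstraint("LOZ", 0.3, 0.1, "dominant"),
        }
        vs = [self.make_verdict("LOZ", AD_HET), self.make_verdict("HIZ", AD_HET)]
        ranked = rank_by_constraint(vs, panel)
        assert [v.gene for v in ranked] == ["HIZ", "LOZ"]

    def test_recessive_order_untouched(self):
        panel = {
            "A": GeneConstraint("A", 5.0, 5.0, "recessive"),
            "B": GeneConstraint("B", 0.0, 0.0, "recessive"),
        }
        vs = [self.make_verdict("B", AR_HOM), self.make_verdict("A", AR_HOM)]
        assert [v.gene for v in rank_by_constraint(vs, panel)] == ["B", "A"]

    def test_truncating_uses_lof_z(self):
        panel = {
            "T": GeneConstraint("T", 0.0, 9.0, "dominant"),
            "M": GeneConstraint("M", 5.0, 0.0, "dominant"),
        }
        vs = [
            self.make_verdict("M", AD_HET, pos=1, hgvs_p="p.Arg1Gly"),
            self.make_verdict("T", AD_HET, pos=2, hgvs_p="p.Arg1Ter"),
        ]
        assert [v.gene for v in rank_by_constraint(vs, panel)] == ["T", "M"]

    def test_tie_breaks_on_position(self):
        panel = {"A": GeneConstraint("A", 1.0, 1.0), "B": GeneConstraint("B", 1.0, 1.0)}
        vs = [self.make_verdict("B", AD_HET, pos=200), self.make_verdict("A", AD_HET, pos=100)]
        assert [v.gene for v in rank_by_constraint(vs, panel)] == ["A", "B"]

    def test_absent_gene_gets_neutral_zero(self):
        panel = {"A": GeneConstraint("A", -1.0, -1.0)}
        vs = [self.make_verdict("A", AD_HET), self.make_verdict("NOPE", AD_HET)]
        assert [v.gene for v in rank_by_constraint(vs, panel)] == ["NOPE", "A"]


class TestPermutationInvariance:
    def test_verdicts_invariant_under_sample_order(self, quartet):
        variants = [mkvar(gene="G1")]
        base = {"F": 1, "M": 1, "A": 2, "U": 1}
        orders = [["F", "M", "A", "U"], ["U", "A", "M", "F"], ["A", "U", "F", "M"]]
        results = []
        for order in orders:
            gtm = gm({s: 0 for s in order}, base)
            vs = scan_pedigree(quartet, variants, gtm)
            results.append([(v.gene, v.model, v.passes) for v in vs])
        assert results[0] == results[1] == results[2]
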