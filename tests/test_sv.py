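"""CNV filtering, deletion arithmetic, exon overlap, copy-state
segregation and junction microhomology."""

import numpy as np
import pytest

from pedvar.pedigree import Individual, Pedigree
from pedvar.pipeline import load_cnv_table
from pedvar.simulate import generate_junction
from pedvar.sv import (
    BedExon,
    CnvEvent,
    JunctionAssembly,
    cnv_quality_filter,
    cnv_segregation,
    cnv_snv_comphet,
    deletion_length,
    format_sv_length,
    gene_overlap,
    microhomology,
    parse_g_deletion,
    read_exon_bed,
)

from conftest import mkvar


class TestQualityFilter:
    def test_low_quality_removed(self):
        ev = CnvEvent("chr1", 1000, 5000, quality=0.5)
        assert cnv_quality_filter([ev]) == []

    def test_quality_one_retained(self):
        ev = CnvEvent("chr1", 1000, 5000, quality=1.0)
        assert cnv_quality_filter([ev]) == [ev]

    def test_length_boundary(self):
        short = CnvEvent("chr1", 1000, 1998, quality=5)   # 999 bp
        exact = CnvEvent("chr1", 1000, 1999, quality=5)   # 1000 bp
        assert cnv_quality_filter([short, exact]) == [exact]

    def test_empty_input(self):
        assert cnv_quality_filter([]) == []


class TestDeletionLength:
    @pytest.mark.parametrize(
        "coords,chrom,bp,human",
        [
            ("g.182,456,422_182,479,267del", "chr2", 22_846, "22.8 Kb"),
            ("g.65,994,849_67,582,755del", "chr6", 1_587_907, "1.6 Mb"),
            ("g.42,643,442_42,676,411del", "chr6", 32_970, "33 Kb"),
            ("g.87,616,103_87,623,431del", "chr8", 7_329, "7 Kb"),
        ],
    )
    def test_tabulated_coordinates(self, coords, chrom, bp, human):
        ev = parse_g_deletion(coords, chrom)
        assert deletion_length(ev) == bp
        assert format_sv_length(bp) == human

    def test_single_base(self):
        assert deletion_length(CnvEvent("chr1", 100, 100)) == 1

    def test_end_before_start_errors(self):
        with pytest.raises(ValueError):
            CnvEvent("chr1", 100, 99)


class TestGeneOverlap:
    def test_all_exons_inside_event(self):
        exons = [BedExon("chr1", 1000 * i, 1000 * i + 100, "A", i) for i in range(1, 13)]
        ev = CnvEvent("chr1", 1, 20_000)
        hits = gene_overlap(ev, exons)
        assert hits == [("A", list(range(1, 13)), hits[0][2])]

    def test_two_genes_opposite_strands(self):
        exons = [
            BedExon("chr6", 100, 200, "UBR2", 39, "-"),
            BedExon("chr6", 300, 400, "UBR2", 40, "-"),
            BedExon("chr6", 500, 600, "PRPH2", 2, "+"),
            BedExon("chr6", 700, 800, "PRPH2", 3, "+"),
            BedExon("chr6", 2000, 2100, "PRPH2", 4, "+"),
        ]
        ev = CnvEvent("chr6", 101, 900)
        hits = {g: (ex, info) for g, ex, info in gene_overlap(ev, exons)}
        assert hits["UBR2"][0] == [39, 40]
        assert hits["PRPH2"][0] == [2, 3]
        assert hits["UBR2"][1]["strand"] == "-"
        assert hits["PRPH2"][1]["strand"] == "+"

    def test_one_bp_overlap_counts(self):
        exons = [BedExon("chr1", 100, 200, "G", 1)]
        assert gene_overlap(CnvEvent("chr1", 200, 300), exons)[0][0] == "G"
        assert gene_overlap(CnvEvent("chr1", 201, 300), exons) == []

    def test_coordinate_convention_roundtrip(self):
        """BED half-open <-> 1-based inclusive round trips preserve
        overlap decisions on randomized intervals."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            s0, ln = int(rng.integers(0, 1000)), int(rng.integers(1, 50))
            exon = BedExon("chr1", s0, s0 + ln, "G", 1)
            es, ee = int(rng.integers(1, 1100)), 0
            ee = es + int(rng.integers(0, 60))
            ev = CnvEvent("chr1", es, ee)
            # reference overlap in fully 1-based inclusive space
            want = max(es, s0 + 1) <= min(ee, s0 + ln)
            assert bool(gene_overlap(ev, [exon])) == want

    def test_bed_reader(self, tmp_path):
        p = tmp_path / "panel.bed"
        p.write_text(
            "chr6\t100\t200\tUBR2|exon39\t0\t-\n"
            "chr6\t500\t600\tPRPH2|exon2|utr\t0\t+\n"
        )
        exons = read_exon_bed(str(p))
        assert exons[0].gene == "UBR2" and exons[0].exon == 39
        assert exons[1].coding is False


class TestCnvSegregation:
    def make_sibship(self):
        return Pedigree(
            "CNV",
            [
                Individual("F", sex="male", affection="unaffected"),
                Individual("M", sex="female", affection="unaffected"),
                Individual("A1", "F", "M", "male", "affected"),
                Individual("A2", "F", "M", "female", "affected"),
                Individual("U", "F", "M", "male", "unaffected"),
            ],
        )

    def test_hom_deletion_recessive(self):
        ped = self.make_sibship()
        ev = CnvEvent(
            "chr6", 65_994_849, 67_582_755, quality=5,
            carriers={"F": 1, "M": 1, "A1": 0, "A2": 0, "U": 2},
            genes=("EYS",),
        )
        verdicts = {v.model: v for v in cnv_segregation(ped, ev, "EYS")}
        assert verdicts["AR_hom"].passes
        assert not verdicts["AD_het"].passes

    def test_het_deletion_dominant_cosegregation(self):
        """Dominant 33 Kb deletion: all affected heterozygous carriers,
        no unaffected carrier."""
        members = [
            Individual("F", sex="male", affection="affected"),
            Individual("M", sex="female", affection="unaffected"),
        ]
        carriers = {"F": 1, "M": 2}
        for i in range(7):
            members.append(Individual(f"A{i}", "F", "M", "male", "affected"))
            carriers[f"A{i}"] = 1
        for i in range(14):
            members.append(Individual(f"U{i}", "F", "M", "female", "unaffected"))
            carriers[f"U{i}"] = 2
        ped = Pedigree("C790", members)
        ev = CnvEvent("chr6", 42_643_442, 42_676_411, quality=9, carriers=carriers)
        verdicts = {v.model: v for v in cnv_segregation(ped, ev, "PRPH2")}
        assert verdicts["AD_het"].passes

    def test_het_deletion_in_unaffected_fails_dominant(self):
        ped = self.make_sibship()
        ev = CnvEvent(
            "chr1", 1000, 5000, quality=5,
            carriers={"F": 1, "M": 2, "A1": 1, "A2": 1, "U": 1},
        )
        verdicts = {v.model: v for v in cnv_segregation(ped, ev, "G")}
        assert not verdicts["AD_het"].passes
        assert "U" in verdicts["AD_het"].unaffected_violations

    def test_snv_plus_cnv_comphet_trans(self):
        """Heterozygous frameshift from the father, heterozygous exon
        deletion from the mother: biallelic in the affected child."""
        ped = Pedigree(
            "M0592",
            [
                Individual("F", sex="male", affection="unaffected"),
                Individual("M", sex="female", affection="unaffected"),
                Individual("C", "F", "M", "female", "affected"),
            ],
        )
        ev = CnvEvent(
            "chr8", 87_616_103, 87_623_431, quality=5,
            carriers={"F": 2, "M": 1, "C": 1},
        )
        snv = mkvar(chrom="chr8", pos=87_679_178, gene="CNGB3",
                    hgvs_p="p.Arg274Valfs*13")
        verdict = cnv_snv_comphet(ped, ev, {"F": 1, "M": 0, "C": 1}, snv)
        assert verdict.passes and verdict.phase == "trans"


class TestMicrohomology:
    def test_constructed_shared_tetramer(self):
        ja = JunctionAssembly(left_flank="TTTTACGT", right_flank="ACGTGGGG",
                              junction_read="TTTTACGTGGGG")
        assert microhomology(ja) == (4, "ACGT")

    def test_no_homology(self):
        ja = JunctionAssembly(left_flank="AAAA", right_flank="CCCC")
        assert microhomology(ja)[0] == 0

    def test_n_terminates_homology(self):
        ja = JunctionAssembly(left_flank="GGANCGT", right_flank="NCGTAAA")
        # the N-containing candidate cannot count as homology
        assert microhomology(ja)[0] == 0

    def test_matches_bruteforce_on_random_flanks(self):
        """Greedy scan equals an independent max-k formulation on random
        sequences; typical lengths stay logarithmic in flank size."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        lengths = []
        for _ in range(300):
            left = "".join(rng.choice(bases, 60))
            right = "".join(rng.choice(bases, 60))
            ja = JunctionAssembly(left_flank=left, right_flank=right)
            got = microhomology(ja)[0]
            want = max(
                (k for k in range(1, 61) if left[-k:] == right[:k]), default=0
            )
            assert got == want
            lengths.append(got)
        assert np.mean(lengths) < 4  # ~log4(60) scale, not flank scale

    @pytest.mark.parametrize("hom", [0, 1, 5, 12, 25])
    def test_planted_homology_recovered(self, hom):
        ja = generate_junction(flank_length=120, homology_length=hom, seed=hom + 1)
        assert microhomology(ja)[0] == hom

    def test_bounded_by_flank_length(self):
        ja = generate_junction(flank_length=30, homology_length=30, seed=2)
        ln = microhomology(ja)[0]
        assert ln <= min(len(ja.left_flank), len(ja.right_flank))


class TestCnvFixture:
    def test_five_events_all_pass_quality_filter(self):
        df = load_cnv_table()
        events = [
            CnvEvent(r["chrom"], int(r["start"]), int(r["end"]), quality=10)
            for _, r in df.iterrows()
        ]
        assert len(cnv_quality_filter(events)) == 5
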