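"""Region classification, coding consequences and degron screening."""

import numpy as np
import pytest
from Bio.Seq import Seq

from bulkmap import (
    GeneModel,
    ReferenceMismatchError,
    classify_region,
    coding_consequence,
    degron_check,
    protein_pair,
    revcomp,
    simulate_cross,
)
from bulkmap.annotate import DEGRON_MOTIF
from conftest import small_config


@pytest.fixture(scope="module")
def sim():
    return simulate_cross(small_config(seed=19))


@pytest.fixture(scope="module")
def plus_gene(sim):
    return next(g for g in sim.genes if g.strand == "+")


@pytest.fixture(scope="module")
def minus_gene(sim):
    return next(g for g in sim.genes if g.strand == "-")


class TestClassifyRegion:
    def test_cds_snp_is_exonic(self, sim, plus_gene):
        pos = plus_gene.cds[1][0] + 5  # inside the second CDS exon
        region, gene_id = classify_region(plus_gene.chrom, pos, "A", sim.genes)
        assert region == "exonic" and gene_id == plus_gene.gene_id

    def test_intron_edge_is_splicing(self, sim, plus_gene):
        intron_start = plus_gene.introns()[0][0]
        region, _ = classify_region(plus_gene.chrom, intron_start + 1, "A", sim.genes)
        assert region == "splicing"

    def test_deep_intron_is_intronic(self, sim, plus_gene):
        s, e = plus_gene.introns()[0]
        region, _ = classify_region(plus_gene.chrom, (s + e) // 2, "A", sim.genes)
        assert region == "intronic"

    def test_utrs_and_flanks(self, sim, plus_gene):
        utr5_pos = plus_gene.utr5[0][0] + 2
        assert classify_region(plus_gene.chrom, utr5_pos, "A", sim.genes)[0] == "utr5"
        utr3_pos = plus_gene.utr3[0][0] + 2
        assert classify_region(plus_gene.chrom, utr3_pos, "A", sim.genes)[0] == "utr3"
        gs, ge = plus_gene.span
        assert classify_region(plus_gene.chrom, gs - 100, "A", sim.genes)[0] == "upstream"
        assert classify_region(plus_gene.chrom, ge + 100, "A", sim.genes)[0] == "downstream"

    def test_minus_strand_flips_up_and_downstream(self, sim, minus_gene):
        gs, ge = minus_gene.span
        assert classify_region(minus_gene.chrom, ge + 100, "A", sim.genes)[0] == "upstream"
        assert classify_region(minus_gene.chrom, gs - 100, "A", sim.genes)[0] == "downstream"

    def test_far_from_genes_is_intergenic(self, sim):
        # gene footprints sit well inside each slot; slot boundaries are far
        region, gene_id = classify_region(sim.config.chrom_names[0], 299_000,
                                          "A", sim.genes, flank_bp=2000)
        assert (region, gene_id) == ("intergenic", None)

    def test_unknown_chromosome_warns_and_is_intergenic(self, sim):
        with pytest.warns(UserWarning):
            region, _ = classify_region("Z99", 1000, "A", sim.genes)
        assert region == "intergenic"


class TestCodingConsequence:
    def test_degron_codon_substitution_is_gly_to_glu(self, sim):
        causal = sim.causal
        gene = sim.causal_gene
        effect, codon_change, aa_change = coding_consequence(
            causal.chrom, int(causal.pos), causal.ref, causal.alt, gene, sim.genome
        )
        assert effect == "missense"
        assert codon_change == "GGA>GAA"
        assert aa_change == "G84E"

    def test_synonymous_third_position(self, sim, plus_gene):
        # find a codon whose third-position change is silent (GGN family)
        cds = plus_gene.cds_sequence(sim.genome)
        for ci in range(1, len(cds) // 3 - 1):
            codon = cds[ci * 3 : ci * 3 + 3]
            if codon[:2] == "GG" and codon[2] == "G":
                pos = plus_gene.genomic_of_cds_offset(ci * 3 + 2)
                effect, codon_change, aa_change = coding_consequence(
                    plus_gene.chrom, pos, "G", "A", plus_gene, sim.genome
                )
                assert effect == "synonymous"
                assert codon_change == "GGG>GGA"
                assert aa_change == f"G{ci + 1}G"
                return
        pytest.skip("no GGG codon in this fixture gene")

    def test_two_bp_deletion_is_frameshift(self, sim, plus_gene):
        pos = plus_gene.cds[0][0] + 6
        ref2 = sim.genome[plus_gene.chrom][pos - 1 : pos + 2].tobytes().decode()
        effect, *_ = coding_consequence(
            plus_gene.chrom, pos, ref2, ref2[0], plus_gene, sim.genome
        )
        assert effect == "frameshift"

    def test_three_bp_deletion_is_inframe(self, sim, plus_gene):
        pos = plus_gene.cds[0][0] + 6
        ref4 = sim.genome[plus_gene.chrom][pos - 1 : pos + 3].tobytes().decode()
        effect, *_ = coding_consequence(
            plus_gene.chrom, pos, ref4, ref4[0], plus_gene, sim.genome
        )
        assert effect == "inframe_indel"

    def test_reference_mismatch_is_hard_error(self, sim, plus_gene):
        pos = plus_gene.cds[0][0] + 3
        actual = chr(sim.genome[plus_gene.chrom][pos - 1])
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[actual]
        with pytest.raises(ReferenceMismatchError):
            coding_consequence(plus_gene.chrom, pos, wrong, actual,
                               plus_gene, sim.genome)

    def test_reference_cds_translates_without_internal_stop(self, sim):
        for gene in sim.genes:
            prot = str(Seq(gene.cds_sequence(sim.genome)).translate())
            assert prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_agrees_with_full_protein_diff_oracle(self, sim, rng):
        """Codon-wise consequences match a brute-force whole-protein diff."""
        genes = [g for g in sim.genes]
        for _ in range(300):
            gene = genes[int(rng.integers(0, len(genes)))]
            off = int(rng.integers(0, gene.cds_length))
            pos = gene.genomic_of_cds_offset(off)
            ref = chr(sim.genome[gene.chrom][pos - 1])
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref:
                alt = "ACGT"[int(rng.integers(0, 4))]
            effect, _, _ = coding_consequence(gene.chrom, pos, ref, alt,
                                              gene, sim.genome)
            before, after = protein_pair(gene, sim.genome, pos, ref, alt)
            if before == after:
                oracle = "synonymous"
            else:
                i = next(k for k in range(len(before)) if before[k] != after[k])
                oracle = "nonsense" if after[i] == "*" else "missense"
            assert effect == oracle, f"{gene.gene_id}:{pos} {ref}>{alt}"

    def test_strand_symmetry_of_consequences(self, sim, minus_gene):
        """A minus-strand gene annotates exactly like its plus-strand mirror.

        Reverse-complement the chromosome, flip the gene to the plus strand
        and re-annotate the mirrored variant: effect, codon and amino-acid
        change must be identical.
        """
        gene = minus_gene
        L = len(sim.genome[gene.chrom])
        flipped_seq = np.frombuffer(
            revcomp(sim.genome[gene.chrom].tobytes().decode()).encode(),
            dtype=np.uint8).copy()
        genome2 = {gene.chrom: flipped_seq}

        def mirror_iv(iv):
            s, e = iv
            return (L - e + 1, L - s + 1)

        gene2 = GeneModel(
            gene_id=gene.gene_id, chrom=gene.chrom, strand="+",
            exons=[mirror_iv(iv) for iv in gene.exons],
            cds=[mirror_iv(iv) for iv in gene.cds],
            utr5=[mirror_iv(iv) for iv in gene.utr5],
            utr3=[mirror_iv(iv) for iv in gene.utr3],
        )
        gene2.validate()
        rng = np.random.default_rng(77)
        for _ in range(50):
            off = int(rng.integers(0, gene.cds_length))
            pos = gene.genomic_of_cds_offset(off)
            ref = chr(sim.genome[gene.chrom][pos - 1])
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref:
                alt = "ACGT"[int(rng.integers(0, 4))]
            res1 = coding_consequence(gene.chrom, pos, ref, alt, gene, sim.genome)
            pos2 = L - pos + 1
            res2 = coding_consequence(gene.chrom, pos2, revcomp(ref),
                                      revcomp(alt), gene2, genome2)
            assert res1 == res2


class TestDegron:
    def test_altered_motif_reports_mutant_string(self):
        before = "MSTE" + DEGRON_MOTIF + "KLR"
        after = "MSTE" + "EWPPV" + "KLR"
        status = degron_check(before, after)
        assert status.status == "altered"
        assert status.mutant_motif == "EWPPV"

    def test_absent_and_intact(self):
        assert degron_check("MABCDEF", "MABCDEG").status == "absent"
        s = "MA" + DEGRON_MOTIF + "Z"
        assert degron_check(s, s).status == "intact"

    def test_causal_variant_alters_fixture_degron(self, sim):
        causal = sim.causal
        gene = sim.causal_gene
        before, after = protein_pair(gene, sim.genome, int(causal.pos),
                                     causal.ref, causal.alt)
        assert DEGRON_MOTIF in before
        status = degron_check(before, after)
        assert status.status == "altered" and status.mutant_motif == "EWPPV"
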