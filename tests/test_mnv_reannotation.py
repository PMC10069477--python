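"""Intra-codon MNV detection, codon re-translation and classification."""

from itertools import combinations, product

import pytest

from pgxpanel import (
    default_transcripts,
    find_candidate_mnvs,
    merge_and_classify,
    retranslate_codon,
    scan_and_merge,
)
from pgxpanel.mnv_reannotation import merged_hgvs_p

from conftest import make_missense, single_variant_matrix
import numpy as np
from pgxpanel import GenotypeMatrix

# Independent genetic-code oracle, frozen from the standard table (table 1).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"


def pair_records(cds1=10126, cds2=10127, codon="GAA", alts=("T", "T"),
                 strand="+", chrom="19", base_pos=5000):
    """Two same-codon SNV records (cds positions within codon 3376 by default)."""
    recs = []
    for cds, alt in zip((cds1, cds2), alts):
        pic = (cds - 1) % 3
        ref_t = codon[pic]
        ref = ref_t if strand == "+" else ref_t.translate(str.maketrans("ACGT", "TGCA"))
        a = alt if strand == "+" else alt.translate(str.maketrans("ACGT", "TGCA"))
        alt_codon = codon[:pic] + alt + codon[pic + 1:]
        cons = ("nonsense" if GENETIC_CODE[alt_codon] == "*"
                else "synonymous" if GENETIC_CODE[alt_codon] == GENETIC_CODE[codon]
                else "missense")
        recs.append(make_missense(
            chrom=chrom, pos=base_pos + cds, ref=ref, alt=a, cds_pos=cds,
            ref_codon=codon, consequence=cons, strand=strand,
        ))
    return recs


def matrix_for(records, dosages, phases):
    keys = [r.key for r in records]
    return GenotypeMatrix(
        variant_keys=keys,
        sample_ids=[f"S{i}" for i in range(len(dosages[0]))],
        dosage=np.array(dosages, dtype=np.int8),
        phase=np.array(phases, dtype=np.int8),
    )


class TestRetranslateCodon:
    def test_canonical_glu3376_cases(self):
        """GAA: joint (1,T)+(2,T) -> Leu; (1,T) alone -> stop; (2,T) -> Val."""
        assert retranslate_codon("GAA", [(1, "T"), (2, "T")]) == ("TTA", "E", "L")
        assert retranslate_codon("GAA", [(1, "T")]) == ("TAA", "E", "*")
        assert retranslate_codon("GAA", [(2, "T")]) == ("GTA", "E", "V")

    def test_exhaustive_against_independent_code_table(self):
        """All 64 codons x all single and adjacent double substitutions agree
        with direct lookup in the frozen genetic-code table."""
        for codon in GENETIC_CODE:
            for pos in (1, 2, 3):
                for alt in BASES:
                    expected = codon[:pos - 1] + alt + codon[pos:]
                    got = retranslate_codon(codon, [(pos, alt)])
                    assert got == (expected, GENETIC_CODE[codon],
                                   GENETIC_CODE[expected])
            for p1, p2 in ((1, 2), (2, 3)):
                for a1, a2 in product(BASES, repeat=2):
                    expected = list(codon)
                    expected[p1 - 1] = a1
                    expected[p2 - 1] = a2
                    expected = "".join(expected)
                    got = retranslate_codon(codon, [(p1, a1), (p2, a2)])
                    assert got == (expected, GENETIC_CODE[codon],
                                   GENETIC_CODE[expected])

    def test_substitution_order_invariance(self):
        a = retranslate_codon("GAA", [(1, "T"), (2, "T")])
        b = retranslate_codon("GAA", [(2, "T"), (1, "T")])
        assert a == b

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            retranslate_codon("GAAA", [(1, "T")])
        with pytest.raises(ValueError):
            retranslate_codon("GAA", [(4, "T")])
        with pytest.raises(ValueError):
            retranslate_codon("GAA", [(1, "T"), (1, "C")])


class TestCandidateDetection:
    def test_same_codon_phased_cis_pair_detected(self):
        recs = pair_records()
        gt = matrix_for(recs, [[1, 0], [1, 0]], [[1, -1], [1, -1]])
        scan = find_candidate_mnvs(recs, gt)
        assert len(scan.candidates) == 1
        c = scan.candidates[0]
        assert c.phase_evidence == "phased_gt"
        assert c.carrier_samples == ("S0",)
        assert c.cds_positions == (10126, 10127)

    def test_codon_boundary_is_not_a_candidate(self):
        # cds 10128 (codon 3376 pos 3) and 10129 (codon 3377 pos 1)
        r1 = make_missense(pos=15128, cds_pos=10128, ref_codon="GAA", ref="A",
                           alt="C", consequence="missense")
        r2 = make_missense(pos=15129, cds_pos=10129, ref_codon="CTG", ref="C",
                           alt="A", consequence="missense")
        gt = matrix_for([r1, r2], [[1, 0], [1, 0]], [[1, -1], [1, -1]])
        scan = find_candidate_mnvs([r1, r2], gt)
        assert scan.candidates == [] and scan.in_trans == []

    def test_trans_carriers_reported_separately(self):
        recs = pair_records()
        gt = matrix_for(recs, [[1, 0], [1, 0]], [[1, -1], [2, -1]])
        scan = find_candidate_mnvs(recs, gt)
        assert scan.candidates == []
        assert len(scan.in_trans) == 1

    def test_unphased_shared_carrier_flagged_unknown(self):
        recs = pair_records()
        gt = matrix_for(recs, [[1, 0], [1, 0]], [[0, -1], [0, -1]])
        scan = find_candidate_mnvs(recs, gt)
        assert len(scan.candidates) == 1
        assert scan.candidates[0].phase_evidence == "unknown"

    def test_no_shared_carrier_no_candidate(self):
        recs = pair_records()
        gt = matrix_for(recs, [[1, 0], [0, 1]], [[1, -1], [-1, 1]])
        scan = find_candidate_mnvs(recs, gt)
        assert scan.candidates == [] and scan.in_trans == []


class TestMergeAndClassify:
    def merged(self, **kw):
        recs = pair_records(**kw)
        gt = matrix_for(recs, [[1], [1]], [[1], [1]])
        scan = find_candidate_mnvs(recs, gt)
        assert len(scan.candidates) == 1
        return merge_and_classify(scan.candidates[0])

    def test_rescued_nonsense_with_delins_hgvs(self):
        c = self.merged()
        assert c.hgvs_c_merged == "c.10126_10127delinsTT"
        assert c.category == "rescued_nonsense"
        assert c.per_snv_consequences == ("nonsense", "missense")
        assert c.merged_consequence == "missense"
        assert merged_hgvs_p(c) == "p.Glu3376Leu"

    def test_synonymous_rescue(self):
        # CTT(L): (1,T)->TTT(F) missense, (3,A)->CTA(L) synonymous;
        # joint TTA is Leu again => merged equals ref aa
        c = self.merged(cds1=10126, cds2=10128, codon="CTT", alts=("T", "A"))
        assert c.merged_consequence == "synonymous"
        assert c.category == "synonymous_rescue"

    def test_gained_nonsense_from_two_missense(self):
        # TCA(S): (1,T) kept, (2,G)->TGA... build from missense components:
        # CAC(H): (1,T)->TAC(Y) missense, (2,G)->CGC(R) missense, joint TGC(C)?
        # Use brute force to find a pair where both singles are missense and
        # the double is a stop.
        found = None
        for codon, aa in GENETIC_CODE.items():
            if aa == "*":
                continue
            for (p1, p2) in ((1, 2), (2, 3), (1, 3)):
                for a1, a2 in product(BASES, repeat=2):
                    if a1 == codon[p1 - 1] or a2 == codon[p2 - 1]:
                        continue
                    s1 = codon[:p1 - 1] + a1 + codon[p1:]
                    s2 = codon[:p2 - 1] + a2 + codon[p2:]
                    joint = list(codon)
                    joint[p1 - 1], joint[p2 - 1] = a1, a2
                    joint = "".join(joint)
                    if (GENETIC_CODE[s1] not in ("*", aa)
                            and GENETIC_CODE[s2] not in ("*", aa)
                            and GENETIC_CODE[joint] == "*"):
                        found = (codon, p1, a1, p2, a2)
                        break
                if found:
                    break
            if found:
                break
        assert found, "standard code admits a missense+missense->stop pair"
        codon, p1, a1, p2, a2 = found
        cds = 30001  # codon 10001 starting at cds 30001
        c = self.merged(cds1=cds + p1 - 1, cds2=cds + p2 - 1, codon=codon,
                        alts=(a1, a2))
        assert c.category == "gained_nonsense"

    def test_minus_strand_adjacency_round_trip(self):
        """Genomic adjacency on a minus-strand transcript maps to cDNA
        adjacency through the transcript model, and detection still works."""
        t = default_transcripts()["CYP2D6"]
        assert t.strand == "-"
        cds1, cds2 = 100, 101  # codon 34, positions 1 and 2
        g1, g2 = t.genomic_pos(cds1), t.genomic_pos(cds2)
        assert abs(g1 - g2) == 1
        assert t.cds_pos_from_genomic(g1) == cds1
        recs = pair_records(cds1=cds1, cds2=cds2, codon="GAA", alts=("T", "T"),
                            strand="-", chrom="22", base_pos=0)
        gt = matrix_for(recs, [[1], [1]], [[2], [2]])
        scan = scan_and_merge(recs, gt)
        assert len(scan.candidates) == 1
        c = scan.candidates[0]
        # cDNA-strand substitutions recovered despite genomic revcomp alleles
        assert c.substitutions == ((1, "T"), (2, "T"))
        assert c.category == "rescued_nonsense"
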