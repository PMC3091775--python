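"""Aligner correctness against exhaustive dynamic-programming oracles."""

import numpy as np
import pytest

from retroforge import seqalign
from retroforge.simgenome import SENSE_CODONS

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one representative codon per amino acid, for exact back-translation
AA_TO_CODON = {}
for codon in SENSE_CODONS:
    AA_TO_CODON.setdefault(seqalign.translate(codon), codon)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def random_protein(rng, n):
    return "".join(np.array(list(AA20))[rng.integers(0, 20, n)])


def sw_affine_oracle(query: str, target: str) -> float:
    """Plain-python affine-gap Smith-Waterman, same scoring scheme
    (BLOSUM62, gap of length k costs 11 + k)."""
    open_, ext = 12.0, 1.0
    m, n = len(query), len(target)
    neg = -1e9
    M = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), neg)
    Iy = np.full((m + 1, n + 1), neg)
    qi = seqalign._aa_indices(query)
    ti = seqalign._aa_indices(target)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - ext)
            Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - ext)
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                   Iy[i - 1, j - 1])
                          + seqalign.SUBMAT[qi[i - 1], ti[j - 1]])
            best = max(best, M[i, j])
    return best


def translated_oracle(protein: str, genome_seq: str) -> float:
    best = 0.0
    for strand_seq in (genome_seq, seqalign.revcomp(genome_seq)):
        for f in range(3):
            best = max(best, sw_affine_oracle(
                protein, seqalign.translate(strand_seq[f:])))
    return best


class TestTranslatedSearch:
    def test_exact_planted_orf(self):
        rng = np.random.default_rng(0)
        protein = random_protein(rng, 60)
        planted = "".join(AA_TO_CODON[a] for a in protein)
        genome = random_dna(rng, 1500) + planted + random_dna(rng, 1500)
        hits = seqalign.translated_search(protein, {"chr": genome},
                                          min_score=50)
        top = hits[0]
        assert top.identity == pytest.approx(100.0)
        assert (top.start, top.end) == (1500, 1500 + len(planted))
        assert top.strand == "+"

    def test_reverse_strand_symmetry(self):
        rng = np.random.default_rng(1)
        protein = random_protein(rng, 60)
        planted = "".join(AA_TO_CODON[a] for a in protein)
        genome = random_dna(rng, 1000) + seqalign.revcomp(planted) \
            + random_dna(rng, 1000)
        hits = seqalign.translated_search(protein, {"chr": genome},
                                          min_score=50)
        top = hits[0]
        assert top.strand == "-"
        assert (top.start, top.end) == (1000, 1000 + len(planted))
        assert top.identity == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_top_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        protein = random_protein(rng, 50)
        planted = "".join(AA_TO_CODON[a] for a in protein)
        genome = random_dna(rng, 500) + planted + random_dna(rng, 500)
        hits = seqalign.translated_search(protein, {"chr": genome},
                                          min_score=20)
        assert hits[0].score == pytest.approx(
            translated_oracle(protein, genome), abs=1e-6)

    def test_random_pair_matches_dp_oracle(self):
        # no planted copy: the best local alignment is pure chance, and the
        # search must still find the exhaustive-DP optimum
        rng = np.random.default_rng(11)
        protein = random_protein(rng, 40)
        genome = random_dna(rng, 1200)
        oracle = translated_oracle(protein, genome)
        hits = seqalign.translated_search(protein, {"chr": genome},
                                          min_score=oracle - 0.5)
        assert hits and hits[0].score == pytest.approx(oracle, abs=1e-6)

    def test_score_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        protein = random_protein(rng, 60)
        planted = "".join(AA_TO_CODON[a] for a in protein)
        genome = random_dna(rng, 800) + planted + random_dna(rng, 800)
        index = seqalign.GenomeIndex({"chr": genome})
        lo = seqalign.translated_search(protein, index, min_score=25)
        hi = seqalign.translated_search(protein, index, min_score=80)
        lo_keys = {(h.start, h.end, h.strand) for h in lo}
        hi_keys = {(h.start, h.end, h.strand) for h in hi}
        assert hi_keys <= lo_keys

    def test_strand_antisymmetry(self):
        rng = np.random.default_rng(6)
        protein = random_protein(rng, 55)
        planted = "".join(AA_TO_CODON[a] for a in protein)
        genome = random_dna(rng, 700) + planted + random_dna(rng, 700)
        fwd = seqalign.translated_search(protein, {"chr": genome}, min_score=40)
        rev = seqalign.translated_search(
            protein, {"chr": seqalign.revcomp(genome)}, min_score=40)
        n = len(genome)
        fwd_set = {(n - h.end, n - h.start,
                    "-" if h.strand == "+" else "+", round(h.score, 3))
                   for h in fwd}
        rev_set = {(h.start, h.end, h.strand, round(h.score, 3)) for h in rev}
        assert fwd_set == rev_set

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            seqalign.translated_search("MKV", {"chr": "ACGT" * 100})

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            seqalign.translated_search("M1V" * 10, {"chr": "ACGT" * 100})


def spliced_oracle(protein, genome, min_intron=40, open_pen=30.0, bonus=10.0):
    """Brute force: best gapless codon chain with zero or one intron."""
    m, n = len(protein), len(genome)
    S = seqalign.SUBMAT
    ai = seqalign._aa_indices(protein)
    aa_at = np.full(n + 1, 0, dtype=int)
    for j in range(3, n + 1):
        aa_at[j] = seqalign._AA_INDEX.get(
            seqalign.translate(genome[j - 3:j]) or "X", seqalign._AA_INDEX["X"])
    # cum[a][s][l]: chain score of protein[a:a+l] starting at genome pos s
    cum = np.full((m + 1, n + 1, m + 1), -1e9)
    for a in range(m + 1):
        for s in range(n + 1):
            cum[a][s][0] = 0.0
            sc, length = 0.0, 0
            while a + length < m and s + 3 * (length + 1) <= n:
                sc += S[ai[a + length], aa_at[s + 3 * (length + 1)]]
                length += 1
                cum[a][s][length] = sc
    best = cum.max()
    best_tail = cum.max(axis=2)  # best chain score from (a, s)
    for a in range(m):
        for s in range(n):
            for L1 in range(1, m - a + 1):
                base = cum[a][s][L1]
                if base < -1e8:
                    continue
                d = s + 3 * L1
                for e in range(d + min_intron, n + 1):
                    cost = open_pen
                    if genome[d:d + 2] == "GT":
                        cost -= bonus
                    if genome[e - 2:e] == "AG":
                        cost -= bonus
                    tail = best_tail[a + L1][e]
                    if tail <= 0:
                        continue
                    best = max(best, base - cost + tail)
    return best


class TestSplicedAlign:
    def test_recovers_planted_single_intron(self):
        rng = np.random.default_rng(3)
        protein = random_protein(rng, 20)
        cds = "".join(AA_TO_CODON[a] for a in protein)
        intron = "GT" + random_dna(rng, 46) + "AG"
        genome = random_dna(rng, 40) + cds[:30] + intron + cds[30:] \
            + random_dna(rng, 40)
        st = seqalign.spliced_align(protein, genome, min_intron_bp=40,
                                    filtration_score=10)
        assert isinstance(st, seqalign.SplicedStructure)
        assert st.n_introns == 1
        assert (st.introns[0].genome_start, st.introns[0].genome_end) == (70, 120)
        assert st.introns[0].donor == "GT" and st.introns[0].acceptor == "AG"

    @pytest.mark.parametrize("seed", [3, 8, 13])
    def test_score_matches_single_intron_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        protein = random_protein(rng, 20)
        cds = "".join(AA_TO_CODON[a] for a in protein)
        intron = "GT" + random_dna(rng, 46) + "AG"
        genome = random_dna(rng, 35) + cds[:30] + intron + cds[30:] \
            + random_dna(rng, 35)
        st = seqalign.spliced_align(protein, genome, min_intron_bp=40,
                                    filtration_score=10)
        assert isinstance(st, seqalign.SplicedStructure)
        assert st.score == pytest.approx(spliced_oracle(protein, genome),
                                         abs=1e-4)

    def test_intronless_copy_gives_single_exon(self):
        rng = np.random.default_rng(4)
        protein = random_protein(rng, 40)
        cds = "".join(AA_TO_CODON[a] for a in protein)
        genome = random_dna(rng, 100) + cds + random_dna(rng, 100)
        st = seqalign.spliced_align(protein, genome, filtration_score=35)
        assert isinstance(st, seqalign.SplicedStructure)
        assert st.n_introns == 0
        assert len(st.exons) == 1
        assert st.identity == pytest.approx(100.0)

    def test_filtration_score_rejects(self):
        rng = np.random.default_rng(5)
        st = seqalign.spliced_align(random_protein(rng, 30),
                                    random_dna(rng, 400),
                                    filtration_score=1000.0)
        assert isinstance(st, seqalign.SplicedReject)

    def test_region_too_short_rejects(self):
        rng = np.random.default_rng(6)
        st = seqalign.spliced_align(random_protein(rng, 30), "ACGTACGT")
        assert isinstance(st, seqalign.SplicedReject)


def nw_identity_oracle(a: str, b: str) -> float:
    """Needleman-Wunsch (unit costs) identity over gap-free columns."""
    m, n = len(a), len(b)
    D = np.zeros((m + 1, n + 1), dtype=int)
    D[:, 0] = np.arange(m + 1)
    D[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = min(D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                          D[i - 1, j] + 1, D[i, j - 1] + 1)
    # traceback counting matches and aligned columns
    i, j, matches, columns = m, n, 0, 0
    while i > 0 and j > 0:
        if D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif D[i, j] == D[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
    return 100.0 * matches / columns


class TestNucleotideSearch:
    def test_error_free_est_places_perfectly(self):
        rng = np.random.default_rng(7)
        est = random_dna(rng, 200)
        genome = random_dna(rng, 2000) + est + random_dna(rng, 2000)
        hits = seqalign.nucleotide_search(est, {"chr": genome}, min_len=100)
        assert hits[0].identity == pytest.approx(100.0)
        assert (hits[0].start, hits[0].end) == (2000, 2200)

    def test_duplicated_locus_gives_two_placements(self):
        rng = np.random.default_rng(8)
        est = random_dna(rng, 200)
        genome = (random_dna(rng, 1000) + est + random_dna(rng, 1000)
                  + est + random_dna(rng, 1000))
        hits = seqalign.nucleotide_search(est, {"chr": genome}, min_len=100)
        full = [h for h in hits if h.identity == pytest.approx(100.0)]
        assert len(full) == 2
        assert {h.start for h in full} == {1000, 2200}

    def test_identity_matches_dp_oracle(self):
        rng = np.random.default_rng(9)
        source = random_dna(rng, 150)
        est = list(source)
        for pos in rng.choice(150, size=5, replace=False):
            est[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[est[pos]]
        est = "".join(est)
        genome = random_dna(rng, 1000) + source + random_dna(rng, 1000)
        hits = seqalign.nucleotide_search(est, {"chr": genome}, min_len=100)
        aligned = genome[hits[0].start:hits[0].end]
        assert hits[0].identity == pytest.approx(
            nw_identity_oracle(est, aligned), abs=1e-6)
        assert hits[0].identity == pytest.approx(100.0 * 145 / 150, abs=0.5)

    def test_spliced_read_chains_across_intron(self):
        rng = np.random.default_rng(10)
        exon1, exon2 = random_dna(rng, 120), random_dna(rng, 120)
        intron = random_dna(rng, 500)
        genome = random_dna(rng, 1000) + exon1 + intron + exon2 \
            + random_dna(rng, 1000)
        read = exon1 + exon2
        hits = seqalign.nucleotide_search(read, {"chr": genome}, min_len=100)
        top = hits[0]
        assert len(top.blocks) == 2
        assert top.identity == pytest.approx(100.0, abs=0.5)
        assert top.aligned_length >= 230

    def test_too_short_query_returns_empty(self):
        assert seqalign.nucleotide_search("ACGT", {"chr": "ACGT" * 1000},
                                          min_len=30) == []


class TestAlignCdsPair:
    def test_identical_sequences(self):
        cds = "ATGGCTAAAGGTTAA"
        aln = seqalign.align_cds_pair(cds, cds)
        assert aln.identity == pytest.approx(100.0)
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_codon_deletion(self):
        rng = np.random.default_rng(12)
        codons = [AA_TO_CODON[a] for a in random_protein(rng, 30)]
        a = "ATG" + "".join(codons) + "TAA"
        b = "ATG" + "".join(codons[:10] + codons[11:]) + "TAA"
        aln = seqalign.align_cds_pair(a, b)
        gap_cols = [k for k in range(aln.n_codon_columns)
                    if aln.aligned_b[3 * k:3 * k + 3] == "---"]
        assert len(gap_cols) == 1
        assert aln.aligned_b.count("-") == 3

    def test_gaps_constrained_to_codon_boundaries(self):
        rng = np.random.default_rng(13)
        codons = [AA_TO_CODON[a] for a in random_protein(rng, 25)]
        a = "ATG" + "".join(codons) + "TAA"
        b = "ATG" + "".join(codons[:5] + codons[8:]) + "TAA"
        aln = seqalign.align_cds_pair(a, b)
        for s in (aln.aligned_a, aln.aligned_b):
            pos = 0
            while pos < len(s):
                codon = s[pos:pos + 3]
                assert codon == "---" or "-" not in codon
                pos += 3

    def test_length_not_codon_multiple_is_an_error(self):
        with pytest.raises(ValueError):
            seqalign.align_cds_pair("ATGGC", "ATGGCT")

    def test_flagged_columns_cover_ambiguity(self):
        aln = seqalign.align_cds_pair("ATGGCTNNNTAA", "ATGGCTAAATAA")
        assert any(col in aln.flagged_columns for col in range(4))
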