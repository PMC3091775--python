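"""Sequence search and alignment primitives for retrocopy discovery.

Four aligners, each a functional equivalent of the external tool a
retrocopy screen would normally shell out to:

* :func:`translated_search` — protein vs. genome local search over all six
  reading frames (seed-and-extend over an amino-acid k-mer index, affine-gap
  Smith-Waterman extension with BLOSUM62).
* :func:`spliced_align` — protein-to-genome alignment that may thread
  GT..AG introns between codons, reporting exon/intron structure.
* :func:`nucleotide_search` — EST/mRNA placement on the genome (k-mer
  seeding plus banded edit-distance alignment), reporting every qualifying
  location.
* :func:`align_cds_pair` — codon-aware global alignment of two coding
  sequences, the input to Ka/Ks estimation.

Coordinates are 0-based half-open genome coordinates throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "ProteinHit",
    "SplicedStructure",
    "SplicedExon",
    "SplicedIntron",
    "EstPlacementRaw",
    "CodonAlignment",
    "GenomeIndex",
    "translated_search",
    "spliced_align",
    "nucleotide_search",
    "align_cds_pair",
    "calibrate_min_score",
]

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# dense lookup, unknown characters behave like X
SUBMAT = np.full((len(AA_ALPHABET), len(AA_ALPHABET)), -4.0, dtype=np.float32)
for i, a in enumerate(AA_ALPHABET):
    for j, b in enumerate(AA_ALPHABET):
        try:
            SUBMAT[i, j] = _BLOSUM62[a][b]
        except (KeyError, IndexError):
            pass

# BLAST-style affine gaps: a gap of length k costs GAP_OPEN + k * GAP_EXTEND
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate, stops as '*', trailing partial codon dropped."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def _aa_indices(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, _AA_INDEX["X"]) for ch in seq], dtype=np.int32)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _check_protein(protein: str) -> str:
    protein = protein.upper().rstrip("*")
    bad = set(protein) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"non-amino-acid characters in protein: {sorted(bad)}")
    return protein


# ---------------------------------------------------------------------------
# translated search (six-frame protein vs genome)
# ---------------------------------------------------------------------------


@dataclass
class ProteinHit:
    """One local translated-search alignment on the genome."""

    protein_id: str
    contig: str
    start: int  # genome, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    frame: int  # 0..2 on the strand searched
    score: float
    identity: float  # percent, matches / aligned columns excluding gaps
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    # blocks: (query_aa_start, query_aa_end, genome_start, genome_end)

    @property
    def aligned_aa(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)

    @property
    def query_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


class GenomeIndex:
    """Six-frame translations of a genome plus an amino-acid k-mer index.

    Built once per genome so that repeated :func:`translated_search` calls
    share the translation and seeding work.
    """

    def __init__(self, genome: dict[str, str], word_size: int = 5):
        self.word_size = word_size
        self.frames: list[tuple[str, str, int, str]] = []  # (contig, strand, frame, aa)
        self.contig_lengths = {name: len(seq) for name, seq in genome.items()}
        for name, seq in genome.items():
            seq = seq.upper()
            rc = revcomp(seq)
            for f in range(3):
                self.frames.append((name, "+", f, translate(seq[f:])))
                self.frames.append((name, "-", f, translate(rc[f:])))
        self.kmer_index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for frame_id, (_, _, _, aa) in enumerate(self.frames):
            for pos in range(len(aa) - word_size + 1):
                word = aa[pos:pos + word_size]
                if "*" in word or "X" in word:
                    continue
                self.kmer_index[word].append((frame_id, pos))


def _aa_to_genome(contig_len: int, strand: str, frame: int,
                  aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map an aa interval on a frame translation to genome nt coordinates."""
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return contig_len - nt_end, contig_len - nt_start


def _alignment_stats(alignment) -> tuple[float, list[tuple[int, int, int, int]]]:
    """Percent identity (gap columns excluded) and aligned block pairs."""
    q_blocks, t_blocks = alignment.aligned[1], alignment.aligned[0]
    query, target = alignment.query, alignment.target
    matches = 0
    columns = 0
    pairs = []
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        columns += qe - qs
        for k in range(qe - qs):
            if query[qs + k] == target[ts + k]:
                matches += 1
        pairs.append((int(qs), int(qe), int(ts), int(te)))
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, pairs


def _cluster_seeds(seeds: list[tuple[int, int]], band: int = 12,
                   max_gap: int = 200) -> list[list[tuple[int, int]]]:
    """Group (qpos, tpos) seeds by diagonal band, then by target proximity.

    Two sorted passes: seeds whose diagonals chain within ``band`` of each
    other form a diagonal group; each group is split where consecutive
    target positions jump by more than ``max_gap``.
    """
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    diag_groups: list[list[tuple[int, int]]] = [[by_diag[0]]]
    for prev, cur in zip(by_diag, by_diag[1:]):
        if (cur[1] - cur[0]) - (prev[1] - prev[0]) <= band:
            diag_groups[-1].append(cur)
        else:
            diag_groups.append([cur])
    clusters: list[list[tuple[int, int]]] = []
    for group in diag_groups:
        group.sort(key=lambda s: s[1])
        cluster = [group[0]]
        for prev, cur in zip(group, group[1:]):
            if cur[1] - prev[1] <= max_gap:
                cluster.append(cur)
            else:
                clusters.append(cluster)
                cluster = [cur]
        clusters.append(cluster)
    return clusters


#: below this total six-frame translation length (aa) the search skips
#: seeding and aligns against every frame exhaustively
EXHAUSTIVE_FRAME_AA = 8000


def translated_search(
    protein: str,
    genome: dict[str, str] | GenomeIndex,
    min_score: float = 60.0,
    protein_id: str = "query",
    min_cluster_seeds: int = 2,
) -> list[ProteinHit]:
    """Local search of a protein against all six reading frames of a genome.

    On genomes small enough the protein is aligned against every frame
    translation exhaustively (full Smith-Waterman, so the top score is the
    true optimum); on larger genomes exact ``word_size``-mer amino-acid
    seeds are clustered by diagonal and each cluster is extended with an
    affine-gap local alignment (BLOSUM62, gap open 11, extend 1).  Hits
    scoring below ``min_score`` are suppressed.  Returns hits best-first.
    """
    protein = _check_protein(protein)
    if len(protein) < 20:
        raise ValueError("protein query must be at least 20 aa")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    k = index.word_size
    total_aa = sum(len(aa) for _, _, _, aa in index.frames)
    exhaustive = total_aa <= EXHAUSTIVE_FRAME_AA

    windows_by_frame: dict[int, list[tuple[int, int]]] = defaultdict(list)
    if exhaustive:
        for frame_id, (_, _, _, frame_aa) in enumerate(index.frames):
            windows_by_frame[frame_id].append((0, len(frame_aa)))
    else:
        seeds_by_frame: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for qpos in range(len(protein) - k + 1):
            word = protein[qpos:qpos + k]
            for frame_id, tpos in index.kmer_index.get(word, ()):
                seeds_by_frame[frame_id].append((qpos, tpos))
        for frame_id, seeds in seeds_by_frame.items():
            frame_aa = index.frames[frame_id][3]
            for cluster in _cluster_seeds(seeds):
                if (len(cluster) < min_cluster_seeds
                        and len(cluster) < len(protein) - k + 1):
                    continue
                t_lo = max(0, min(t for _, t in cluster) - len(protein) - 10)
                t_hi = min(len(frame_aa),
                           max(t for _, t in cluster) + len(protein) + 10)
                windows_by_frame[frame_id].append((t_lo, t_hi))

    aligner = _protein_aligner()
    hits: list[ProteinHit] = []
    for frame_id, windows in windows_by_frame.items():
        contig, strand, frame, frame_aa = index.frames[frame_id]
        contig_len = index.contig_lengths[contig]
        seen_windows: set[tuple[int, int]] = set()
        for t_lo, t_hi in windows:
            if (t_lo, t_hi) in seen_windows or t_hi <= t_lo:
                continue
            seen_windows.add((t_lo, t_hi))
            window = frame_aa[t_lo:t_hi]
            alignments = aligner.align(window, protein)
            try:
                if alignments.score < min_score:
                    continue
                best = alignments[0]
            except (ValueError, IndexError, OverflowError):
                continue
            identity, pairs = _alignment_stats(best)
            blocks = []
            for qs, qe, ts, te in pairs:
                gs, ge = _aa_to_genome(contig_len, strand, frame, t_lo + ts, t_lo + te)
                blocks.append((qs, qe, gs, ge))
            g_start = min(b[2] for b in blocks)
            g_end = max(b[3] for b in blocks)
            hits.append(ProteinHit(
                protein_id=protein_id, contig=contig, start=g_start, end=g_end,
                strand=strand, frame=frame, score=float(best.score),
                identity=identity, blocks=sorted(blocks, key=lambda b: b[0]),
            ))

    # overlapping windows can rediscover the same alignment: keep the best
    hits.sort(key=lambda h: -h.score)
    kept: list[ProteinHit] = []
    for hit in hits:
        redundant = any(
            k.contig == hit.contig and k.strand == hit.strand and k.frame == hit.frame
            and min(k.end, hit.end) - max(k.start, hit.start) > 0.5 * (hit.end - hit.start)
            for k in kept
        )
        if not redundant:
            kept.append(hit)
    return kept


def calibrate_min_score(
    genome: dict[str, str],
    protein_lengths: list[int],
    rng: np.random.Generator,
    n_decoys: int = 20,
    target_hits_per_mb: float = 1e-3,
) -> float:
    """Estimate the translated-search score giving few random hits per Mb.

    Shuffled decoy proteins of the given lengths are searched against the
    genome at a permissive threshold; the returned score is the level at
    which the observed decoy hit density drops to ``target_hits_per_mb``
    (the maximum decoy score plus one when no decoy reaches that density).
    """
    index = GenomeIndex(genome)
    genome_mb = sum(index.contig_lengths.values()) / 1e6
    scores: list[float] = []
    aa_pool = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(n_decoys):
        length = int(rng.choice(protein_lengths)) if protein_lengths else 100
        decoy = "".join(rng.choice(list(aa_pool), size=max(length, 20)))
        for hit in translated_search(decoy, index, min_score=20.0,
                                     min_cluster_seeds=1):
            scores.append(hit.score)
    if not scores:
        return 40.0
    scores.sort(reverse=True)
    allowed = target_hits_per_mb * genome_mb * n_decoys
    rank = max(int(allowed), 0)
    if rank >= len(scores):
        return scores[-1]
    return scores[rank] + 1.0


# ---------------------------------------------------------------------------
# spliced protein-to-genome alignment
# ---------------------------------------------------------------------------


@dataclass
class SplicedExon:
    genome_start: int
    genome_end: int
    protein_start: int  # residues covered, 0-based half-open
    protein_end: int


@dataclass
class SplicedIntron:
    genome_start: int
    genome_end: int
    donor: str
    acceptor: str

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start


@dataclass
class SplicedStructure:
    """Exon/intron structure of a protein aligned to a genomic region."""

    protein_id: str
    exons: list[SplicedExon]
    introns: list[SplicedIntron]
    score: float
    identity: float

    @property
    def n_introns(self) -> int:
        return len(self.introns)


@dataclass
class SplicedReject:
    reason: str


DEFAULT_INTRON_OPEN = 30.0
DEFAULT_SPLICE_BONUS = 10.0  # per canonical dinucleotide (GT donor, AG acceptor)
DEFAULT_FRAMESHIFT_PENALTY = 15.0

_NEG = np.float32(-1e30)


def spliced_align(
    protein: str,
    region: str,
    min_intron_bp: int = 40,
    filtration_score: float = 35.0,
    protein_id: str = "query",
    intron_open: float = DEFAULT_INTRON_OPEN,
    splice_bonus: float = DEFAULT_SPLICE_BONUS,
    frameshift_penalty: float = DEFAULT_FRAMESHIFT_PENALTY,
) -> SplicedStructure | SplicedReject:
    """Best local alignment of a protein to a genomic region allowing introns.

    The dynamic program matches protein residues to codons and may open an
    intron between any two consecutive residues; introns shorter than
    ``min_intron_bp`` are forbidden, GT donors and AG acceptors earn a bonus
    (non-canonical boundaries are allowed at full ``intron_open`` cost).
    Single-nucleotide slips (frameshifts) between codons are tolerated at a
    penalty so that disabled copies still produce a structure.  Introns are
    modeled between codons (phase 0).  Structures scoring below
    ``filtration_score`` are rejected.
    """
    protein = _check_protein(protein)
    region = region.upper()
    m, n = len(protein), len(region)
    if n < 3 * min(10, m):
        return SplicedReject(reason=f"region ({n} bp) too short for protein ({m} aa)")
    if m == 0:
        return SplicedReject(reason="empty protein")

    q_idx = _aa_indices(protein)
    # amino acid encoded by the codon ending at j (j >= 3)
    aa_at = np.full(n + 1, _AA_INDEX["X"], dtype=np.int32)
    for j in range(3, n + 1):
        aa_at[j] = _AA_INDEX.get(translate(region[j - 3:j]) or "X", _AA_INDEX["X"])

    donor_bonus = np.zeros(n + 1, dtype=np.float32)
    acc_bonus = np.zeros(n + 1, dtype=np.float32)
    for j in range(n - 1):
        if region[j:j + 2] == "GT":
            donor_bonus[j] = splice_bonus
    for j in range(2, n + 1):
        if region[j - 2:j] == "AG":
            acc_bonus[j] = splice_bonus

    H = np.full((m + 1, n + 1), _NEG, dtype=np.float32)
    Iavail = np.full((m + 1, n + 1), _NEG, dtype=np.float32)
    Iarg = np.zeros((m + 1, n + 1), dtype=np.int32)

    fs = np.float32(frameshift_penalty)
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        base = np.maximum(H[i - 1], Iavail[i - 1] + acc_bonus)
        pred = np.full(n + 1, 0.0, dtype=np.float32)
        shifted3 = np.concatenate([np.full(3, _NEG, dtype=np.float32), base[:-3]])
        shifted2 = np.concatenate([np.full(2, _NEG, dtype=np.float32), base[:-2]])
        shifted4 = np.concatenate([np.full(4, _NEG, dtype=np.float32), base[:-4]])
        pred = np.maximum(pred, shifted3)
        pred = np.maximum(pred, shifted2 - fs)
        pred = np.maximum(pred, shifted4 - fs)
        row = SUBMAT[q_idx[i - 1], aa_at] + pred
        row[:3] = _NEG
        H[i] = row
        # intron opened after residue i at position d, usable from d + min_intron
        S = row - np.float32(intron_open) + donor_bonus
        run_max = np.maximum.accumulate(S)
        new_best = S >= run_max
        arg = np.where(new_best, idx, 0)
        run_arg = np.maximum.accumulate(arg)
        if n + 1 > min_intron_bp:
            Iavail[i, min_intron_bp:] = run_max[:n + 1 - min_intron_bp]
            Iarg[i, min_intron_bp:] = run_arg[:n + 1 - min_intron_bp]

    best_flat = int(np.argmax(H[1:]))
    bi, bj = divmod(best_flat, n + 1)
    bi += 1
    best_score = float(H[bi, bj])
    if best_score < filtration_score:
        return SplicedReject(
            reason=f"best structure score {best_score:.1f} < {filtration_score}")

    # traceback
    matched: list[tuple[int, int]] = []  # (protein residue index 0-based, codon end j)
    introns: list[SplicedIntron] = []
    i, j = bi, bj
    tol = 1e-3
    while i >= 1 and j >= 3:
        matched.append((i - 1, j))
        pred_needed = H[i, j] - SUBMAT[q_idx[i - 1], aa_at[j]]
        jp = None
        for cand_j, pen in ((j - 3, 0.0), (j - 2, fs), (j - 4, fs)):
            if cand_j < 0:
                continue
            val = max(H[i - 1, cand_j], Iavail[i - 1, cand_j] + acc_bonus[cand_j])
            if abs(val - pen - pred_needed) < tol and val > _NEG / 2:
                jp = cand_j
                break
        if jp is None:
            break  # local start
        if H[i - 1, jp] + tol >= Iavail[i - 1, jp] + acc_bonus[jp]:
            i, j = i - 1, jp
        else:
            d = int(Iarg[i - 1, jp])
            introns.append(SplicedIntron(
                genome_start=d, genome_end=jp,
                donor=region[d:d + 2], acceptor=region[jp - 2:jp]))
            i, j = i - 1, d

    matched.reverse()
    introns.reverse()
    if not matched:
        return SplicedReject(reason="empty traceback")

    # group matched codons into exons: split wherever an intron-sized jump
    # separates consecutive codons
    exons: list[list[tuple[int, int]]] = []
    cur = [matched[0]]
    for prev, nxt in zip(matched, matched[1:]):
        gap = nxt[1] - 3 - prev[1]
        if gap >= min_intron_bp - 2:
            exons.append(cur)
            cur = [nxt]
        else:
            cur.append(nxt)
    exons.append(cur)
    exon_objs = [
        SplicedExon(
            genome_start=chunk[0][1] - 3,
            genome_end=chunk[-1][1],
            protein_start=chunk[0][0],
            protein_end=chunk[-1][0] + 1,
        )
        for chunk in exons
    ]
    n_match = sum(1 for res, jend in matched if q_idx[res] == aa_at[jend])
    identity = 100.0 * n_match / len(matched)
    return SplicedStructure(
        protein_id=protein_id, exons=exon_objs, introns=introns,
        score=best_score, identity=identity,
    )


# ---------------------------------------------------------------------------
# nucleotide (EST) placement
# ---------------------------------------------------------------------------


@dataclass
class EstPlacementRaw:
    """One candidate genomic placement of an EST/mRNA read.

    A placement may consist of several aligned blocks (a spliced read
    crossing introns); ``start``/``end`` span all blocks, ``blocks`` holds
    the individual genomic intervals.
    """

    est_id: str
    contig: str
    start: int
    end: int
    strand: str
    aligned_length: int
    identity: float  # percent, matches / aligned columns excluding gaps
    blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


class NucleotideIndex:
    """Exact k-mer index over the forward strand of every contig."""

    def __init__(self, genome: dict[str, str], word_size: int = 14):
        self.word_size = word_size
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.kmer_index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.genome.items():
            for pos in range(0, len(seq) - word_size + 1):
                self.kmer_index[seq[pos:pos + word_size]].append((name, pos))


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions, deletions) from an edlib cigar."""
    matches = mismatches = ins = dels = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        count = int(num)
        num = ""
        if ch == "=":
            matches += count
        elif ch == "X":
            mismatches += count
        elif ch == "I":
            ins += count
        elif ch == "D":
            dels += count
    return matches, mismatches, ins, dels


@dataclass
class _AlignedBlock:
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    columns: int  # gap-free aligned columns
    q_letters: int  # query letters consumed


def _align_block(query: str, target: str, q_lo: int, q_hi: int,
                 t_lo: int, t_hi: int) -> _AlignedBlock | None:
    """Infix-align query[q_lo:q_hi] inside target[t_lo:t_hi]."""
    segment = query[q_lo:q_hi]
    window = target[t_lo:t_hi]
    if not segment or not window:
        return None
    result = edlib.align(segment, window, mode="HW", task="path")
    if result["editDistance"] < 0 or not result["locations"]:
        return None
    t_start, t_end = result["locations"][0]
    matches, mismatches, ins, dels = _cigar_stats(result["cigar"])
    columns = matches + mismatches
    if columns == 0:
        return None
    return _AlignedBlock(
        q_start=q_lo, q_end=q_hi,
        t_start=t_lo + t_start, t_end=t_lo + t_end + 1,
        matches=matches, columns=columns, q_letters=columns + ins)


def _chain_blocks(blocks: list[_AlignedBlock], est_id: str, contig: str,
                  strand: str, max_intron: int,
                  max_q_overlap: int = 40) -> list[EstPlacementRaw]:
    """Chain colinear blocks (spliced alignment) into placements.

    Blocks are colinear when the next block starts (nearly) where the
    previous ends on the query — window padding makes adjacent blocks
    overlap by up to ``max_q_overlap`` letters — and downstream on the
    genome by at most an intron's length.  Each block extends the chain
    whose query end lies closest before it.
    """
    blocks = sorted(blocks, key=lambda b: (b.q_start, b.t_start))
    chains: list[list[_AlignedBlock]] = []
    for block in blocks:
        best_chain = None
        for chain in chains:
            last = chain[-1]
            if (block.q_start >= last.q_end - max_q_overlap
                    and block.q_end > last.q_end
                    and 0 < block.t_start - last.t_end <= max_intron):
                if best_chain is None or chain[-1].q_end > best_chain[-1].q_end:
                    best_chain = chain
        if best_chain is not None:
            best_chain.append(block)
        else:
            chains.append([block])
    out = []
    for chain in chains:
        matches = sum(b.matches for b in chain)
        columns = sum(b.columns for b in chain)
        out.append(EstPlacementRaw(
            est_id=est_id, contig=contig,
            start=min(b.t_start for b in chain),
            end=max(b.t_end for b in chain), strand=strand,
            aligned_length=sum(b.q_letters for b in chain),
            identity=100.0 * matches / columns,
            blocks=[(b.t_start, b.t_end) for b in chain]))
    return out


def nucleotide_search(
    est: str,
    genome: dict[str, str] | NucleotideIndex,
    min_len: int = 30,
    min_identity: float = 80.0,
    est_id: str = "est",
    max_intron: int = 50_000,
) -> list[EstPlacementRaw]:
    """All qualifying genomic placements of a nucleotide query, best first.

    Exact k-mer seeds on both strands are clustered by diagonal; each
    cluster is refined by an infix edit-distance alignment of the covered
    query segment, and colinear blocks separated by up to ``max_intron``
    bp on the genome are chained into one spliced placement (so reads
    sampled from spliced transcripts place correctly across introns).
    Every placement with identity >= ``min_identity`` is returned, sorted
    by identity then aligned length.
    """
    est = est.upper()
    if len(est) < min_len:
        return []
    index = genome if isinstance(genome, NucleotideIndex) else NucleotideIndex(genome)
    k = index.word_size

    placements: list[EstPlacementRaw] = []
    for strand in "+-":
        query = est if strand == "+" else revcomp(est)
        seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        positions = list(range(0, len(query) - k + 1, 4))
        if positions and positions[-1] != len(query) - k:
            positions.append(len(query) - k)
        for qpos in positions:
            for contig, tpos in index.kmer_index.get(query[qpos:qpos + k], ()):
                seeds[contig].append((qpos, tpos))
        for contig, contig_seeds in seeds.items():
            target = index.genome[contig]
            blocks: list[_AlignedBlock] = []
            for cluster in _cluster_seeds(contig_seeds, band=30,
                                          max_gap=max(200, len(query))):
                q_lo = min(q for q, _ in cluster)
                q_hi = min(len(query), max(q for q, _ in cluster) + k)
                # snap to the read ends when the uncovered stub is shorter
                # than a seed word (an error near the edge leaves it unseeded)
                if q_lo < k + 4:
                    q_lo = 0
                if len(query) - q_hi < k + 4:
                    q_hi = len(query)
                t_lo = max(0, min(t for _, t in cluster) - 30)
                t_hi = min(len(target), max(t for _, t in cluster) + k + 30)
                block = _align_block(query, target, q_lo, q_hi, t_lo, t_hi)
                if block is not None:
                    blocks.append(block)
            placements.extend(
                _chain_blocks(blocks, est_id, contig, strand, max_intron))

    placements = [p for p in placements if p.identity >= min_identity]
    placements.sort(key=lambda p: (-p.identity, -p.aligned_length))
    kept: list[EstPlacementRaw] = []
    for p in placements:
        if any(k.contig == p.contig
               and min(k.end, p.end) - max(k.start, p.start) > 0.5 * (p.end - p.start)
               for k in kept):
            continue
        kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# codon-aware CDS pairwise alignment
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Global codon-aware alignment of two coding sequences.

    ``aligned_a``/``aligned_b`` are gapped nucleotide strings of equal
    length (a multiple of 3) with gaps only at codon boundaries.
    ``flagged_columns`` lists codon-column indices containing gaps or
    ambiguity codes, to be excluded from site counting downstream.
    """

    aligned_a: str
    aligned_b: str
    flagged_columns: list[int]
    identity: float
    score: float

    @property
    def n_codon_columns(self) -> int:
        return len(self.aligned_a) // 3


def _trim_cds(cds: str, label: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{label}: length {len(cds)} not a multiple of 3")
    if len(cds) >= 3 and translate(cds[-3:]) == "*":
        cds = cds[:-3]
    return cds


def align_cds_pair(cds_a: str, cds_b: str) -> CodonAlignment:
    """Codon-aware global alignment of two CDSs.

    Both sequences are translated (internal stops tolerated, scored as
    ``*``), globally aligned at the protein level with affine gaps, and the
    protein alignment is mapped back onto codons, which constrains every
    gap to a codon boundary.
    """
    a = _trim_cds(cds_a, "cds_a")
    b = _trim_cds(cds_b, "cds_b")
    prot_a, prot_b = translate(a), translate(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    # cheap end gaps: the two CDSs may differ at their termini
    aligner.end_insertion_score = -1.0
    aligner.end_deletion_score = -1.0
    if not prot_a or not prot_b:
        raise ValueError("empty coding sequence")
    alignment = aligner.align(prot_a.replace("*", "X"), prot_b.replace("*", "X"))[0]
    aligned_a: list[str] = []
    aligned_b: list[str] = []
    ia = ib = 0
    gapped_a, gapped_b = alignment[0], alignment[1]
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-":
            aligned_a.append("---")
        else:
            aligned_a.append(a[3 * ia:3 * ia + 3])
            ia += 1
        if cb == "-":
            aligned_b.append("---")
        else:
            aligned_b.append(b[3 * ib:3 * ib + 3])
            ib += 1
    str_a = "".join(aligned_a)
    str_b = "".join(aligned_b)
    flagged = [
        col for col in range(len(str_a) // 3)
        if any(ch not in "ACGT"
               for ch in str_a[3 * col:3 * col + 3] + str_b[3 * col:3 * col + 3])
    ]
    matches = sum(1 for x, y in zip(str_a, str_b) if x == y and x != "-")
    columns = sum(1 for x, y in zip(str_a, str_b) if x != "-" and y != "-")
    identity = 100.0 * matches / columns if columns else 0.0
    return CodonAlignment(
        aligned_a=str_a, aligned_b=str_b, flagged_columns=flagged,
        identity=identity, score=float(alignment.score),
    )
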