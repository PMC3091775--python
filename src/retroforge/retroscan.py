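"""The retrocopy calling pipeline.

Stages, in order: six-frame translated search of every annotated peptide
against the genome; merging of nearby same-strand hits (gap < 40 bp, i.e.
gaps too small to be introns); identity/coverage filters; parent
assignment (best non-overlapping proteome match, single-coding-exon
parents rejected); intron-loss confirmation by two spliced alignments
(parent protein vs. its own locus, parent protein vs. the candidate locus:
a parental intron > 70 bp spanned by the candidate's alignment must be
absent from the candidate's structure); demotion of retrocopies that look
like copies of other retrocopies rather than of their parent; and finally
intact/pseudogene classification from frameshifts and premature stop
codons in a codon-projected alignment to the parent CDS, with LPB Ka/Ks
attached to every call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
from intervaltree import IntervalTree

from retroforge import molevol, seqalign
from retroforge.models import GeneModel, cds_sequence, extract_proteome
from retroforge.seqalign import (
    GenomeIndex,
    ProteinHit,
    SplicedReject,
    SplicedStructure,
    revcomp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "MergedCandidate",
    "RetrocopyCall",
    "merge_hits",
    "filter_candidates",
    "assign_parent",
    "confirm_intron_loss",
    "exclude_retro_derived",
    "classify_disablements",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Every numeric threshold of the retrocopy screen in one place.

    Defaults encode the screen's standard thresholds: hits merged when separated by
    less than 40 bp, candidates kept at > 50% identity, > 70% query
    coverage and >= 50 aligned amino acids, parents required to have >= 2
    coding exons and >= 50% coverage/identity, and intron loss confirmed
    against parental introns longer than 70 bp (larger than the merge gap,
    so a confirmed loss can never be an artifact of merging).
    """

    merge_gap_bp: int = 40
    min_identity_pct: float = 50.0
    min_overlap_frac: float = 0.70
    min_overlap_aa: int = 50
    min_intron_bp: int = 40
    confirm_span_bp: int = 70
    filtration_score: float = 35.0
    parent_min_coding_exons: int = 2
    parent_min_cov_frac: float = 0.50
    parent_min_identity_pct: float = 50.0
    min_hit_score: float = 60.0
    region_pad: int = 2000

    def validate(self) -> None:
        numbers = (self.merge_gap_bp, self.min_identity_pct, self.min_overlap_frac,
                   self.min_overlap_aa, self.min_intron_bp, self.confirm_span_bp,
                   self.filtration_score, self.parent_min_coding_exons,
                   self.parent_min_cov_frac, self.parent_min_identity_pct)
        if any(x <= 0 for x in numbers):
            raise ValueError("all thresholds must be positive")
        if self.confirm_span_bp <= self.merge_gap_bp:
            raise ValueError(
                "confirm_span_bp must exceed merge_gap_bp: an intron shorter "
                "than the merge gap could be a merging artifact")


@dataclass
class MergedCandidate:
    """Union of nearby translated-search hits from one protein."""

    protein_id: str
    contig: str
    start: int
    end: int
    strand: str
    score: float
    identity: float  # percent, weighted over merged hits
    query_blocks: list[tuple[int, int]]  # merged aa intervals on the query
    n_hits: int = 1

    @property
    def aligned_aa(self) -> int:
        return sum(e - s for s, e in self.query_blocks)

    def coverage_frac(self, protein_length: int) -> float:
        return self.aligned_aa / protein_length if protein_length else 0.0


@dataclass
class RetrocopyCall:
    """One confirmed retrocopy locus."""

    call_id: str
    contig: str
    start: int
    end: int
    strand: str
    parent_id: str
    classification: str  # 'intact' | 'pseudogene'
    disablements: list[dict] = field(default_factory=list)
    primary: bool = True
    intragenic: bool = False
    kaks: molevol.KaKsResult | None = None
    score: float = 0.0
    identity: float = 0.0

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_hits(hits: list[ProteinHit], merge_gap_bp: int = 40) -> list[MergedCandidate]:
    """Union same-strand hits of one protein separated by < ``merge_gap_bp``.

    Merging is transitive and frame-agnostic (a frameshifted copy shows up
    as adjacent hits in different frames).  Gaps of ``merge_gap_bp`` or
    more stay separate — they may be real introns.
    """
    if not hits:
        return []
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"merge_hits expects one protein, got {sorted(ids)}")
    out: list[MergedCandidate] = []
    by_group: dict[tuple[str, str], list[ProteinHit]] = {}
    for h in hits:
        by_group.setdefault((h.contig, h.strand), []).append(h)
    for (contig, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: h.start)
        cluster: list[ProteinHit] = []
        clusters: list[list[ProteinHit]] = []
        for h in group:
            if cluster and h.start - max(x.end for x in cluster) < merge_gap_bp:
                cluster.append(h)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [h]
        clusters.append(cluster)
        for cl in clusters:
            aligned = sum(h.aligned_aa for h in cl)
            identity = sum(h.identity * h.aligned_aa for h in cl) / aligned
            qblocks = _merge_intervals(
                [(qs, qe) for h in cl for qs, qe, _, _ in h.blocks])
            out.append(MergedCandidate(
                protein_id=cl[0].protein_id, contig=contig,
                start=min(h.start for h in cl), end=max(h.end for h in cl),
                strand=strand, score=sum(h.score for h in cl),
                identity=identity, query_blocks=qblocks, n_hits=len(cl),
            ))
    return out


def filter_candidates(
    candidates: list[MergedCandidate],
    config: PipelineConfig,
    protein_lengths: dict[str, int],
) -> list[MergedCandidate]:
    """Identity > 50%, coverage > 70% of the query protein, >= 50 aa aligned."""
    kept = []
    for c in candidates:
        plen = protein_lengths.get(c.protein_id, 0)
        if (c.identity > config.min_identity_pct
                and c.coverage_frac(plen) > config.min_overlap_frac
                and c.aligned_aa >= config.min_overlap_aa):
            kept.append(c)
    return kept


@dataclass
class ParentMatch:
    parent_id: str
    score: float
    identity: float
    coverage: float
    strand: str  # strand of the candidate region carrying the match


def _gene_by_protein(annotation: list[GeneModel]) -> dict[str, GeneModel]:
    mapping = {}
    for gene in annotation:
        for tx in gene.transcripts:
            mapping[tx.transcript_id] = gene
    return mapping


def assign_parent(
    candidate: MergedCandidate,
    genome: dict[str, str],
    proteome: dict[str, str],
    annotation: list[GeneModel],
    config: PipelineConfig,
) -> ParentMatch | None:
    """Best-scoring proteome match whose locus does not overlap the candidate.

    The candidate's genomic sequence is searched with every proteome entry;
    matches from genes overlapping the candidate interval are ignored (a
    locus cannot parent itself).  The winner must satisfy the parent
    coverage/identity thresholds; a winner annotated with fewer than
    ``parent_min_coding_exons`` coding exons (an intronless gene, e.g. an
    olfactory receptor) rejects the candidate.  Ties break by identity,
    then coverage, then protein id.
    """
    pad = 50
    seq = genome[candidate.contig]
    lo = max(0, candidate.start - pad)
    region = seq[lo:candidate.end + pad]
    region_index = GenomeIndex({"cand": region})
    gene_of = _gene_by_protein(annotation)

    matches: list[ParentMatch] = []
    for pid, prot in proteome.items():
        gene = gene_of.get(pid)
        if gene is not None and gene.contig == candidate.contig:
            if min(gene.end, candidate.end) > max(gene.start, candidate.start):
                continue  # overlapping locus: cannot be the parent
        try:
            found = seqalign.translated_search(
                prot, region_index, min_score=config.min_hit_score,
                protein_id=pid)
        except ValueError:
            continue
        if not found:
            continue
        best = found[0]
        coverage = best.aligned_aa / len(prot)
        matches.append(ParentMatch(
            parent_id=pid, score=best.score, identity=best.identity,
            coverage=coverage, strand=best.strand))
    if not matches:
        return None
    matches.sort(key=lambda m: (-m.score, -m.identity, -m.coverage, m.parent_id))
    best = matches[0]
    gene = gene_of.get(best.parent_id)
    if gene is None:
        return None
    n_coding_exons = max(len(tx.cds) for tx in gene.transcripts)
    if n_coding_exons < config.parent_min_coding_exons:
        logger.info("candidate %s:%d-%d: best match %s is a single-coding-exon "
                    "gene; rejected", candidate.contig, candidate.start,
                    candidate.end, best.parent_id)
        return None
    if (best.coverage < config.parent_min_cov_frac
            or best.identity < config.parent_min_identity_pct):
        return None
    return best


def confirm_intron_loss(
    parent_structure: SplicedStructure | SplicedReject,
    retro_structure: SplicedStructure | SplicedReject,
    confirm_span_bp: int = 70,
    boundary_tolerance_aa: int = 3,
) -> bool:
    """Confirm that a parental intron is genuinely lost in the candidate.

    Requires a parental intron strictly longer than ``confirm_span_bp``
    whose flanking exons are both reached by the candidate's alignment,
    with no intron at the corresponding protein position in the
    candidate's structure.  A parent with no introns cannot demonstrate
    loss and the candidate is rejected.
    """
    if isinstance(parent_structure, SplicedReject):
        return False
    if isinstance(retro_structure, SplicedReject):
        return False
    if not parent_structure.introns:
        return False
    retro_lo = min(ex.protein_start for ex in retro_structure.exons)
    retro_hi = max(ex.protein_end for ex in retro_structure.exons)
    retro_boundaries = [ex.protein_end for ex in retro_structure.exons[:-1]]
    for intron, exon in zip(parent_structure.introns, parent_structure.exons):
        if intron.length <= confirm_span_bp:
            continue
        boundary = exon.protein_end  # residue index where the intron sits
        if not (retro_lo < boundary < retro_hi):
            continue  # candidate does not span both flanking exons
        lost = all(abs(boundary - rb) > boundary_tolerance_aa
                   for rb in retro_boundaries)
        if lost:
            return True
    return False


def _pairwise_identity(a: str, b: str) -> float:
    """Global identity as matches over the longer sequence length.

    Normalizing by the longer length (rather than by gap-free columns)
    keeps the measure honest when the two sequences differ in length: a
    short fragment cannot look near-identical to an unrelated long locus
    just because the aligner scatters its letters across it.
    """
    result = edlib.align(a, b, mode="NW", task="path")
    matches, _, _, _ = seqalign._cigar_stats(result["cigar"])
    return 100.0 * matches / max(len(a), len(b))


def exclude_retro_derived(
    calls: list[RetrocopyCall],
    genome: dict[str, str],
    parent_cds: dict[str, str],
) -> list[RetrocopyCall]:
    """Demote calls that resemble another retrocopy more than their parent.

    A retrocopy of a retrocopy has higher nucleotide identity to the older
    retrocopy locus than to the parent's spliced CDS.  Demoted calls stay
    in the output with ``primary=False``; exact ties favor primary.
    """
    seqs = {}
    for call in calls:
        sub = genome[call.contig][call.start:call.end]
        seqs[call.call_id] = sub if call.strand == "+" else revcomp(sub)
    out = []
    for call in calls:
        own = seqs[call.call_id]
        to_parent = _pairwise_identity(own, parent_cds[call.parent_id])
        worst = 0.0
        for other in calls:
            if other.call_id == call.call_id:
                continue
            worst = max(worst, _pairwise_identity(own, seqs[other.call_id]))
        out.append(replace(call, primary=not (worst > to_parent)))
    return out


def _global_nt_aligner():
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def classify_disablements(
    parent_cds_seq: str,
    candidate_region: str,
    end_margin: int = 6,
) -> tuple[str, list[dict], tuple[str, str] | None]:
    """Call frameshifts and premature stops against the parent CDS.

    The copy is first located inside the candidate region by edit-distance
    infix alignment, the region trimmed to the located span, and the
    trimmed pair re-aligned globally with affine gap costs so indels
    appear only where the sequences force them.  Internal indels of length
    not divisible by 3 are frameshifts; the candidate's nucleotides
    projected onto parent codon positions are scanned for in-frame stop
    codons upstream of the final aligned codon.  Returns (classification,
    disablements, aligned (parent, candidate) strings on the parent codon
    frame for Ka/Ks), or classification 'failed' when no usable alignment
    exists.
    """
    located = edlib.align(parent_cds_seq, candidate_region, mode="HW",
                          task="locations")
    if located["editDistance"] < 0 or not located["locations"]:
        return "failed", [], None
    t0, t1 = located["locations"][0]
    trimmed = candidate_region[t0:t1 + 1]
    aligner = _global_nt_aligner()
    try:
        alignment = aligner.align(trimmed, parent_cds_seq)[0]
    except (ValueError, IndexError, OverflowError):
        return "failed", [], None
    target_gapped, query_gapped = str(alignment[0]), str(alignment[1])

    # core = columns between the first and last position where both align
    both = [k for k, (t, q) in enumerate(zip(target_gapped, query_gapped))
            if t != "-" and q != "-"]
    if not both or len(both) < 0.5 * len(parent_cds_seq):
        return "failed", [], None
    n_match = sum(1 for t, q in zip(target_gapped, query_gapped)
                  if t == q and t != "-")
    if n_match < 0.6 * len(both):
        return "failed", [], None  # not a credible copy of this CDS
    core_lo, core_hi = both[0], both[-1]

    projected: list[str] = []  # candidate char per parent CDS position
    disablements: list[dict] = []
    q_pos = 0
    run_op: str | None = None
    run_len = 0
    run_qpos = 0

    def flush_run(next_col: int) -> None:
        # an indel counts as a frameshift only strictly inside the aligned
        # CDS; runs within end_margin (2 codons) of the alignment boundary
        # are end-trimming artifacts, not disablements
        nonlocal run_op, run_len
        if run_op and run_len % 3 != 0 \
                and next_col - run_len >= core_lo + end_margin \
                and next_col - 1 <= core_hi - end_margin:
            kind = "del" if run_op == "query_extra" else "ins"
            disablements.append({"kind": "frameshift", "position": run_qpos,
                                 "detail": f"{kind}{run_len}"})
        run_op, run_len = None, 0

    for col, (t, q) in enumerate(zip(target_gapped, query_gapped)):
        if t != "-" and q != "-":
            flush_run(col)
            projected.append(t)
            q_pos += 1
        elif q != "-":  # parent base missing from candidate (deletion)
            if run_op != "query_extra":
                flush_run(col)
                run_op, run_len, run_qpos = "query_extra", 0, q_pos
            run_len += 1
            projected.append("-")
            q_pos += 1
        else:  # candidate extra base (insertion), only meaningful inside core
            if core_lo < col < core_hi:
                if run_op != "target_extra":
                    flush_run(col)
                    run_op, run_len, run_qpos = "target_extra", 0, q_pos
                run_len += 1
    flush_run(len(target_gapped))

    parent_aligned = parent_cds_seq
    cand_aligned = "".join(projected)
    assert len(parent_aligned) == len(cand_aligned)

    n_codons = len(parent_aligned) // 3
    for ci in range(n_codons - 1):  # the final codon may legitimately stop
        codon = cand_aligned[3 * ci:3 * ci + 3].upper()
        if codon in ("TAA", "TAG", "TGA"):
            disablements.append({"kind": "premature_stop", "position": 3 * ci,
                                 "detail": codon})
    classification = "pseudogene" if disablements else "intact"
    return classification, disablements, (parent_aligned, cand_aligned)


def _kaks_from_projection(pair: tuple[str, str]) -> molevol.KaKsResult | None:
    parent_aligned, cand_aligned = pair
    # mask stop codons (disablements) so site counting stays defined
    usable = len(parent_aligned) - len(parent_aligned) % 3
    pa, ca = [], []
    for k in range(0, usable, 3):
        cc = cand_aligned[k:k + 3]
        pc = parent_aligned[k:k + 3]
        if cc in ("TAA", "TAG", "TGA") or pc in ("TAA", "TAG", "TGA"):
            cc = "NNN"
            pc = "NNN"
        pa.append(pc)
        ca.append(cc)
    try:
        return molevol.kaks_lpb("".join(pa), "".join(ca))
    except (ValueError, molevol.SaturationError):
        return None


@dataclass
class PipelineReport:
    """Per-stage candidate counts of one pipeline run."""

    n_proteins: int = 0
    n_hits: int = 0
    n_merged: int = 0
    n_filtered: int = 0
    n_with_parent: int = 0
    n_confirmed: int = 0
    n_primary: int = 0
    n_intact: int = 0
    n_pseudogene: int = 0
    dropped: list[str] = field(default_factory=list)


def _extract_oriented(genome, contig, start, end, strand, pad=0):
    seq = genome[contig]
    lo, hi = max(0, start - pad), min(len(seq), end + pad)
    sub = seq[lo:hi]
    return (sub if strand == "+" else revcomp(sub)), lo, hi


def run_pipeline(
    genome: dict[str, str],
    annotation: list[GeneModel],
    config: PipelineConfig | None = None,
    proteome: dict[str, str] | None = None,
) -> tuple[list[RetrocopyCall], PipelineReport]:
    """Run the full retrocopy screen on a genome + annotation.

    The proteome defaults to the translation of every protein-coding
    transcript in the annotation.  Any per-candidate stage failure is
    logged and skips that candidate only.
    """
    config = config or PipelineConfig()
    config.validate()
    if proteome is None:
        proteome = extract_proteome(genome, annotation)
    report = PipelineReport(n_proteins=len(proteome))
    index = GenomeIndex(genome)
    gene_of = _gene_by_protein(annotation)

    gene_tree: dict[str, IntervalTree] = {}
    for gene in annotation:
        if gene.biotype != "protein_coding":
            continue
        gene_tree.setdefault(gene.contig, IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id)

    candidates: list[MergedCandidate] = []
    protein_lengths = {pid: len(p) for pid, p in proteome.items()}
    for pid, prot in sorted(proteome.items()):
        try:
            hits = seqalign.translated_search(
                prot, index, min_score=config.min_hit_score, protein_id=pid)
        except ValueError as exc:
            logger.info("query %s skipped: %s", pid, exc)
            continue
        report.n_hits += len(hits)
        candidates.extend(merge_hits(hits, config.merge_gap_bp))
    report.n_merged = len(candidates)

    candidates = filter_candidates(candidates, config, protein_lengths)
    report.n_filtered = len(candidates)

    calls: list[RetrocopyCall] = []
    parent_cds_map: dict[str, str] = {}
    call_n = 0
    for cand in candidates:
        parent = assign_parent(cand, genome, proteome, annotation, config)
        if parent is None:
            report.dropped.append(
                f"{cand.protein_id}@{cand.contig}:{cand.start}-{cand.end}: no parent")
            continue
        report.n_with_parent += 1
        parent_gene = gene_of[parent.parent_id]
        parent_tx = next(t for t in parent_gene.transcripts
                         if t.transcript_id == parent.parent_id)
        parent_prot = proteome[parent.parent_id]
        cds = cds_sequence(genome, parent_tx)
        if cds[-3:].upper() in ("TAA", "TAG", "TGA"):
            cds = cds[:-3]  # terminal stop: irrelevant for, and noisy in, comparisons
        parent_cds_map[parent.parent_id] = cds

        parent_region, _, _ = _extract_oriented(
            genome, parent_gene.contig, parent_gene.start, parent_gene.end,
            parent_gene.strand, pad=config.region_pad)
        parent_structure = seqalign.spliced_align(
            parent_prot, parent_region, min_intron_bp=config.min_intron_bp,
            filtration_score=config.filtration_score,
            protein_id=parent.parent_id)
        cand_region, _, _ = _extract_oriented(
            genome, cand.contig, cand.start, cand.end, cand.strand, pad=200)
        retro_structure = seqalign.spliced_align(
            parent_prot, cand_region, min_intron_bp=config.min_intron_bp,
            filtration_score=config.filtration_score,
            protein_id=parent.parent_id)
        if not confirm_intron_loss(parent_structure, retro_structure,
                                   config.confirm_span_bp):
            report.dropped.append(
                f"{cand.protein_id}@{cand.contig}:{cand.start}-{cand.end}: "
                "intron loss not confirmed")
            continue
        report.n_confirmed += 1

        cand_seq, _, _ = _extract_oriented(
            genome, cand.contig, cand.start, cand.end, cand.strand, pad=100)
        classification, disablements, pair = classify_disablements(
            parent_cds_map[parent.parent_id], cand_seq)
        if classification == "failed":
            report.dropped.append(
                f"{cand.protein_id}@{cand.contig}:{cand.start}-{cand.end}: "
                "CDS alignment failed")
            continue
        kaks = _kaks_from_projection(pair) if pair else None

        tree = gene_tree.get(cand.contig)
        intragenic = False
        if tree is not None:
            for iv in tree.overlap(cand.start, cand.end):
                if iv.begin <= cand.start and cand.end <= iv.end:
                    intragenic = True
                    break

        call_n += 1
        calls.append(RetrocopyCall(
            call_id=f"rc{call_n:04d}", contig=cand.contig,
            start=cand.start, end=cand.end, strand=cand.strand,
            parent_id=parent.parent_id, classification=classification,
            disablements=disablements, intragenic=intragenic, kaks=kaks,
            score=cand.score, identity=cand.identity,
        ))

    calls = exclude_retro_derived(calls, genome, parent_cds_map)
    report.n_primary = sum(1 for c in calls if c.primary)
    report.n_intact = sum(1 for c in calls if c.classification == "intact")
    report.n_pseudogene = sum(1 for c in calls if c.classification == "pseudogene")
    return calls, report


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def calls_to_gff3(calls: list[RetrocopyCall]) -> str:
    lines = ["##gff-version 3"]
    for c in calls:
        attrs = (f"ID={c.call_id};parent_id={c.parent_id};class={c.classification};"
                 f"primary={int(c.primary)};intragenic={int(c.intragenic)}")
        lines.append("\t".join([
            c.contig, "retroforge", "retrocopy", str(c.start + 1), str(c.end),
            f"{c.score:.0f}", c.strand, ".", attrs]))
    return "\n".join(lines) + "\n"


def calls_to_tsv(calls: list[RetrocopyCall]) -> str:
    header = ["call_id", "contig", "start", "end", "strand", "parent_id",
              "class", "primary", "intragenic", "identity", "ka", "ks",
              "ka_ks", "disablements"]
    lines = ["\t".join(header)]
    for c in calls:
        ka = f"{c.kaks.ka:.4f}" if c.kaks else "."
        ks = f"{c.kaks.ks:.4f}" if c.kaks else "."
        ratio = (f"{c.kaks.ratio:.4f}" if c.kaks and c.kaks.ratio is not None
                 else ".")
        dis = ";".join(f"{d['kind']}@{d['position']}" for d in c.disablements) or "."
        lines.append("\t".join(str(x) for x in [
            c.call_id, c.contig, c.start, c.end, c.strand, c.parent_id,
            c.classification, int(c.primary), int(c.intragenic),
            f"{c.identity:.1f}", ka, ks, ratio, dis]))
    return "\n".join(lines) + "\n"
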