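"""Chimeric retrogene identification and structural classification.

A retrocopy becomes part of a chimeric gene when an annotated transcript
overlaps it but derives less than 80% of its spliced length from the
retrocopy — the remaining >= 20% is recruited material: novel coding exons
(new N- or C-terminal peptide, or both), or recruited UTR with part of the
retro-derived N-terminus demoted to 5'UTR.  Chimeras are further split
into fusions (the novel exons belong to a pre-existing neighboring gene)
and de novo genes (recruited UTR forming a single-exon gene, or the
retrocopy spanning the entire new CDS), and flagged when the retro-derived
segment crosses an exon-intron boundary (a newly created splice site).
"""

from __future__ import annotations

from dataclasses import dataclass

from retroforge.models import GeneModel, Transcript
from retroforge.retroscan import RetrocopyCall

__all__ = [
    "ChimeraCall",
    "find_chimeras",
    "classify_chimera",
    "classify_mode",
    "detect_new_splice_site",
    "analyze_chimeras",
]

CATEGORIES = ("N_add", "C_add", "both_add", "UTR_conversion")
MODES = ("fusion", "de_novo")


@dataclass
class ChimeraCall:
    """One chimeric transcript built around a retrocopy."""

    retro_call_id: str
    transcript_id: str
    category: str  # one of CATEGORIES
    mode: str  # 'fusion' | 'de_novo'
    new_splice_site: bool
    retro_fraction_of_transcript: float


@dataclass
class ChimeraCandidate:
    call: RetrocopyCall
    transcript: Transcript
    retro_fraction: float


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _exonic_overlap(tx: Transcript, interval: tuple[int, int]) -> int:
    return sum(_overlap((s, e), interval) for s, e in tx.exons)


def find_chimeras(
    calls: list[RetrocopyCall],
    annotation: list[GeneModel],
    max_retro_frac: float = 0.80,
) -> list[ChimeraCandidate]:
    """Transcripts overlapping a retrocopy by < ``max_retro_frac`` of length.

    A candidate transcript must overlap the retrocopy in its exons, derive
    less than 80% of its spliced length from the retrocopy interval, and
    not arise from the retrocopy's parental locus (transcripts whose gene
    overlaps the parent gene's span are excluded — they are the parent,
    not a new gene).
    """
    gene_by_tx: dict[str, GeneModel] = {}
    gene_by_id: dict[str, GeneModel] = {}
    for gene in annotation:
        gene_by_id[gene.gene_id] = gene
        for tx in gene.transcripts:
            gene_by_tx[tx.transcript_id] = gene

    out: list[ChimeraCandidate] = []
    for call in calls:
        parent_gene = gene_by_tx.get(call.parent_id)
        for gene in annotation:
            if gene.contig != call.contig:
                continue
            if parent_gene is not None and _overlap(
                    gene.span, parent_gene.span) > 0:
                continue  # arises from the parental locus
            for tx in gene.transcripts:
                ov = _exonic_overlap(tx, call.interval)
                if ov == 0:
                    continue
                frac = ov / tx.spliced_length
                if frac < max_retro_frac:
                    out.append(ChimeraCandidate(call=call, transcript=tx,
                                                retro_fraction=frac))
    return out


def _tx_sorted_cds(tx: Transcript) -> list[tuple[int, int]]:
    return sorted(tx.cds)


#: novel coding sequence shorter than this is treated as call-boundary
#: jitter (the local aligner may trim a few diverged terminal codons from
#: the retrocopy interval), not as an added peptide
MIN_NOVEL_NT = 30


def classify_chimera(candidate: ChimeraCandidate,
                     min_novel_nt: int = MIN_NOVEL_NT) -> str | None:
    """Structural category of a chimeric transcript.

    Novel (non-retro) coding sequence on the transcript's 5' side only is
    an N-terminal addition, 3' side only a C-terminal addition, both sides
    both_add.  When the retro-derived segment overlaps the transcript's
    5'UTR the retro N-terminus has been converted to UTR.  Novel stretches
    shorter than ``min_novel_nt`` (10 codons) do not count as a new
    peptide.  Returns None (unclassifiable) when the transcript has no
    annotated CDS.
    """
    tx = candidate.transcript
    call = candidate.call
    if not tx.cds:
        return None
    cds = _tx_sorted_cds(tx)
    exons = sorted(tx.exons)
    cds_lo, cds_hi = cds[0][0], cds[-1][1]

    # UTR regions in genomic coordinates: exonic sequence outside the CDS
    utr_left = [(max(s, 0), min(e, cds_lo)) for s, e in exons if s < cds_lo]
    utr_right = [(max(s, cds_hi), e) for s, e in exons if e > cds_hi]
    five_utr = utr_left if tx.strand == "+" else utr_right
    if sum(_overlap(iv, call.interval) for iv in five_utr) >= min_novel_nt:
        return "UTR_conversion"

    # novel coding material: CDS regions outside the retrocopy interval
    novel_left = sum(max(0, min(e, call.start) - s) for s, e in cds if s < call.start)
    novel_right = sum(max(0, e - max(s, call.end)) for s, e in cds if e > call.end)
    if tx.strand == "-":
        novel_left, novel_right = novel_right, novel_left
    # now left = 5' (N-terminal) side in transcript orientation
    if novel_left >= min_novel_nt and novel_right >= min_novel_nt:
        return "both_add"
    if novel_left >= min_novel_nt:
        return "N_add"
    if novel_right >= min_novel_nt:
        return "C_add"
    return "UTR_conversion" if (utr_left or utr_right) else None


def classify_mode(
    candidate: ChimeraCandidate,
    annotation: list[GeneModel],
) -> str:
    """Fusion with a neighboring gene, or a de novo gene.

    Fusion: novel exonic sequence is shared with a pre-existing gene's
    exons.  De novo: the novel material is only recruited UTR forming a
    single-exon gene, or the retrocopy covers the full new CDS.
    """
    tx = candidate.transcript
    call = candidate.call
    novel_regions: list[tuple[int, int]] = []
    for s, e in tx.exons:
        if e <= call.start or s >= call.end:
            novel_regions.append((s, e))
        else:
            if s < call.start:
                novel_regions.append((s, call.start))
            if e > call.end:
                novel_regions.append((call.end, e))
    for gene in annotation:
        if gene.contig != tx.contig or gene.gene_id == tx.gene_id:
            continue
        for other_tx in gene.transcripts:
            if other_tx.transcript_id == tx.transcript_id:
                continue
            for s, e in other_tx.exons:
                if any(_overlap((s, e), iv) > 0 for iv in novel_regions):
                    return "fusion"
    return "de_novo"


def detect_new_splice_site(candidate: ChimeraCandidate) -> bool:
    """True iff the retro-derived segment crosses an exon-intron boundary.

    Crossing requires at least 1 bp on each side of a boundary internal to
    the transcript (a boundary exactly at the segment's edge does not
    count).
    """
    tx = candidate.transcript
    call = candidate.call
    exons = sorted(tx.exons)
    boundaries = []
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        boundaries.extend([e0, s1])
    return any(call.start < b < call.end for b in boundaries)


def analyze_chimeras(
    calls: list[RetrocopyCall],
    annotation: list[GeneModel],
    max_retro_frac: float = 0.80,
) -> list[ChimeraCall]:
    """Full chimera analysis: find, classify, mode, splice-site flag."""
    out = []
    for cand in find_chimeras(calls, annotation, max_retro_frac):
        category = classify_chimera(cand)
        if category is None:
            continue
        out.append(ChimeraCall(
            retro_call_id=cand.call.call_id,
            transcript_id=cand.transcript.transcript_id,
            category=category,
            mode=classify_mode(cand, annotation),
            new_splice_site=detect_new_splice_site(cand),
            retro_fraction_of_transcript=cand.retro_fraction,
        ))
    for call in out:
        assert call.retro_fraction_of_transcript < max_retro_frac
    return out


def chimeras_to_tsv(chimeras: list[ChimeraCall]) -> str:
    header = ["retro_call_id", "transcript_id", "category", "mode",
              "new_splice_site", "retro_fraction"]
    lines = ["\t".join(header)]
    for c in chimeras:
        lines.append("\t".join([
            c.retro_call_id, c.transcript_id, c.category, c.mode,
            str(int(c.new_splice_site)),
            f"{c.retro_fraction_of_transcript:.3f}"]))
    return "\n".join(lines) + "\n"
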