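"""EST/mRNA placement filtering and transcription evidence for retrocopies.

Placement disambiguation follows a strict recipe designed to keep ESTs of
a parent gene from being credited to its retrocopy (or vice versa): for
each EST only the best genomic placement is kept together with placements
within 0.5 identity points of it (at >= 96% identity); an EST counts as
evidence only when exactly one placement survives, it aligns > 100 bp and
> 97% identity.  Evidence then attaches to a retrocopy when an accepted
placement overlaps its interval, chimeric transcripts are confirmed by
single ESTs spanning retro-derived and novel exons, and the transcriptional
activity of the neighborhood is the count of accepted ESTs in a 40 kb
flanking window with a 2 kb exclusion zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from retroforge import stattests
from retroforge.models import GeneModel, Transcript
from retroforge.retroscan import RetrocopyCall
from retroforge.seqalign import EstPlacementRaw, NucleotideIndex, nucleotide_search

__all__ = [
    "PlacementFilter",
    "EstEvidence",
    "place_ests",
    "attach_evidence",
    "confirm_chimeric_transcript",
    "flanking_activity",
    "distance_to_closest_gene",
    "compare_groups",
    "map_reads",
]


@dataclass
class PlacementFilter:
    """Thresholds of the EST acceptance rules."""

    min_len: int = 100  # accepted alignment must exceed this (strict >)
    genome_min_identity: float = 96.0
    placement_min_identity: float = 97.0
    best_gap_pct: float = 0.5


@dataclass
class EstEvidence:
    """Transcription evidence attached to one retrocopy call."""

    retro_call_id: str
    n_est: int = 0
    n_mrna: int = 0
    chimeric_confirmed: bool = False
    flank_est_count: int = 0
    distance_to_closest_gene: int | None = None
    est_ids: list[str] = field(default_factory=list)


def map_reads(
    reads: dict[str, str],
    genome: dict[str, str] | NucleotideIndex,
    min_identity: float = 90.0,
) -> dict[str, list[EstPlacementRaw]]:
    """Raw candidate placements (best first) for every read."""
    index = genome if isinstance(genome, NucleotideIndex) else NucleotideIndex(genome)
    return {
        read_id: nucleotide_search(seq, index, min_len=30,
                                   min_identity=min_identity, est_id=read_id)
        for read_id, seq in sorted(reads.items())
    }


def place_ests(
    raw: dict[str, list[EstPlacementRaw]],
    filters: PlacementFilter | None = None,
) -> tuple[dict[str, EstPlacementRaw], dict[str, str]]:
    """Apply the uniqueness and identity rules to raw placements.

    Per EST, the best placement is retained together with every placement
    whose identity falls within ``best_gap_pct`` points of it and is at
    least ``genome_min_identity``.  The EST is accepted only if exactly one
    location remains, its aligned length exceeds ``min_len`` and its
    identity exceeds ``placement_min_identity``.  Returns accepted
    placements and a rejection log keyed by EST id.
    """
    filters = filters or PlacementFilter()
    accepted: dict[str, EstPlacementRaw] = {}
    rejected: dict[str, str] = {}
    for est_id, placements in raw.items():
        if not placements:
            rejected[est_id] = "no_placement"
            continue
        best = placements[0]
        retained = [
            p for p in placements
            if p.identity >= best.identity - filters.best_gap_pct
            and p.identity >= filters.genome_min_identity
        ]
        if len(retained) != 1:
            rejected[est_id] = f"non_unique({len(retained)})"
            continue
        only = retained[0]
        if only.aligned_length <= filters.min_len:
            rejected[est_id] = f"short({only.aligned_length})"
            continue
        if only.identity <= filters.placement_min_identity:
            rejected[est_id] = f"low_identity({only.identity:.1f})"
            continue
        accepted[est_id] = only
    return accepted, rejected


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def attach_evidence(
    calls: list[RetrocopyCall],
    est_placements: dict[str, EstPlacementRaw],
    mrna_placements: dict[str, EstPlacementRaw] | None = None,
) -> dict[str, EstEvidence]:
    """Count accepted EST/mRNA placements overlapping each call by >= 1 bp."""
    evidence = {c.call_id: EstEvidence(retro_call_id=c.call_id) for c in calls}
    for call in calls:
        ev = evidence[call.call_id]
        for est_id, p in est_placements.items():
            if p.contig == call.contig and _overlap(p.interval, call.interval) > 0:
                ev.n_est += 1
                ev.est_ids.append(est_id)
        for _, p in (mrna_placements or {}).items():
            if p.contig == call.contig and _overlap(p.interval, call.interval) > 0:
                ev.n_mrna += 1
    return evidence


def confirm_chimeric_transcript(
    est_placements: dict[str, EstPlacementRaw],
    transcript: Transcript,
    call: RetrocopyCall,
) -> bool:
    """True iff one EST overlaps a retro-derived AND a novel exon.

    Exon provenance: an exon is retro-derived when it overlaps the
    retrocopy interval.  A single EST must span both kinds; two ESTs each
    covering one side do not confirm.
    """
    retro_exons = [e for e in transcript.exons if _overlap(e, call.interval) > 0]
    novel_exons = [e for e in transcript.exons if _overlap(e, call.interval) == 0]
    if not retro_exons or not novel_exons:
        return False
    for p in est_placements.values():
        if p.contig != transcript.contig:
            continue
        pieces = p.blocks or [p.interval]
        hits_retro = any(_overlap(piece, e) > 0
                         for piece in pieces for e in retro_exons)
        hits_novel = any(_overlap(piece, e) > 0
                         for piece in pieces for e in novel_exons)
        if hits_retro and hits_novel:
            return True
    return False


def flanking_activity(
    call: RetrocopyCall,
    est_placements: dict[str, EstPlacementRaw],
    exclusion: int = 2_000,
    window: int = 40_000,
    contig_length: int | None = None,
) -> int:
    """Accepted ESTs in the 40 kb flanks, excluding the 2 kb next to the call.

    Counts placements overlapping [start-window, start-exclusion) or
    (end+exclusion, end+window], clipped at contig ends; windows are
    measured from the call's outermost coordinates.
    """
    left = (max(0, call.start - window), max(0, call.start - exclusion))
    right_hi = call.end + window
    if contig_length is not None:
        right_hi = min(right_hi, contig_length)
    right = (call.end + exclusion, right_hi)
    count = 0
    for p in est_placements.values():
        if p.contig != call.contig:
            continue
        if _overlap(p.interval, left) > 0 or _overlap(p.interval, right) > 0:
            count += 1
    return count


def distance_to_closest_gene(
    call: RetrocopyCall,
    annotation: list[GeneModel],
) -> int | None:
    """Minimal gap (bp) to any non-overlapping transcript span, strands ignored.

    Transcripts overlapping the call are removed; None when no other
    transcript exists.
    """
    best: int | None = None
    for gene in annotation:
        if gene.contig != call.contig:
            continue
        for tx in gene.transcripts:
            span = (tx.start, tx.end)
            if _overlap(span, call.interval) > 0:
                continue
            gap = (span[0] - call.end if span[0] >= call.end
                   else call.start - span[1])
            if best is None or gap < best:
                best = gap
    return best


def compare_groups(
    evidence: dict[str, EstEvidence],
    classification: dict[str, str],
) -> dict[str, object]:
    """Group comparisons on attached evidence.

    Mann-Whitney U on flanking EST counts of transcribed vs. silent calls,
    and Fisher's exact test on EST-supported presence/absence between
    intact and pseudogene calls.  Degenerate group sizes are reported as
    not-computable (None).
    """
    transcribed = [ev.flank_est_count for ev in evidence.values() if ev.n_est > 0]
    silent = [ev.flank_est_count for ev in evidence.values() if ev.n_est == 0]
    results: dict[str, object] = {}
    if transcribed and silent:
        u, p = stattests.mann_whitney_u(transcribed, silent)
        results["flank_mwu"] = {"U": u, "p": p,
                                "n_transcribed": len(transcribed),
                                "n_silent": len(silent)}
    else:
        results["flank_mwu"] = None
    intact_yes = sum(1 for cid, ev in evidence.items()
                     if classification.get(cid) == "intact" and ev.n_est > 0)
    intact_no = sum(1 for cid, ev in evidence.items()
                    if classification.get(cid) == "intact" and ev.n_est == 0)
    pseudo_yes = sum(1 for cid, ev in evidence.items()
                     if classification.get(cid) == "pseudogene" and ev.n_est > 0)
    pseudo_no = sum(1 for cid, ev in evidence.items()
                    if classification.get(cid) == "pseudogene" and ev.n_est == 0)
    if intact_yes + intact_no > 0 and pseudo_yes + pseudo_no > 0:
        p = stattests.fisher_exact([[intact_yes, intact_no],
                                    [pseudo_yes, pseudo_no]])
        results["class_fisher"] = {
            "p": p, "table": [[intact_yes, intact_no], [pseudo_yes, pseudo_no]]}
    else:
        results["class_fisher"] = None
    return results


def evidence_to_tsv(evidence: dict[str, EstEvidence]) -> str:
    header = ["retro_call_id", "n_est", "n_mrna", "chimeric_confirmed",
              "flank_est_count", "distance_to_closest_gene"]
    lines = ["\t".join(header)]
    for ev in evidence.values():
        lines.append("\t".join(str(x) for x in [
            ev.retro_call_id, ev.n_est, ev.n_mrna, int(ev.chimeric_confirmed),
            ev.flank_est_count,
            ev.distance_to_closest_gene if ev.distance_to_closest_gene is not None
            else "."]))
    return "\n".join(lines) + "\n"
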