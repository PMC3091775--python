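"""Synthetic genomes with planted retrocopies and machine-readable truth.

The generator emulates the statistical structure the retrocopy screen
assumes: multi-exon parent genes with canonical GT..AG introns and in-frame
ATG..stop CDSs on a random intergenic background, plus planted retrocopies
— intron-less, divergence-mutated copies of parent CDSs flanked by a
poly(A) tract and target-site duplications.  Retrocopies can be left
intact, disabled (frameshift or premature stop), or embedded in a chimeric
gene context (novel N/C-terminal coding exons recruited from a neighboring
gene, or recruited UTRs).  EST/mRNA reads are sampled from spliced
transcripts with a configurable per-base error rate, and ortholog CDS pairs
are simulated at a configurable synonymous divergence for rate calibration.

Every feature is recorded in a :class:`GroundTruth` object so that each
pipeline stage can be scored against what was planted.  Identical
configurations (including the seed) produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from retroforge.models import (
    GeneModel,
    Transcript,
    cds_sequence,
    write_fasta,
    write_gff3,
)

__all__ = [
    "SimConfig",
    "DisablementRecord",
    "RetroTruth",
    "EstTruth",
    "GroundTruth",
    "SimResult",
    "generate_genome",
    "plant_disablement",
    "mutate_sequence",
    "sample_ests",
    "make_ortholog_pairs",
    "write_outputs",
]

SENSE_CODONS = [
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]
STOP_CODONS = ("TAA", "TAG", "TGA")
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

CHIMERA_LABELS = ("chimeric_N", "chimeric_C", "chimeric_both", "chimeric_UTR")


@dataclass
class SimConfig:
    """Parameters of one synthetic genome.

    Lengths are base pairs, ranges inclusive.  ``retro_divergence`` is the
    substitution proportion applied to each planted copy after insertion;
    ``ts_tv_ratio`` the transition/transversion ratio of those mutations.
    """

    genome_length: int = 500_000
    n_parent_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_codons: tuple[int, int] = (30, 80)
    intron_length: tuple[int, int] = (80, 400)
    n_retro_intact: int = 6
    n_retro_pseudo: int = 4
    n_retro_chimeric: int = 4
    retro_divergence: float = 0.05
    ts_tv_ratio: float = 2.0
    polya_length: tuple[int, int] = (15, 30)
    tsd_length: tuple[int, int] = (5, 15)
    est_per_transcript: float = 3.0
    est_error_rate: float = 0.005
    est_length: tuple[int, int] = (150, 450)
    mrna_per_transcript: float = 0.3
    n_single_exon_genes: int = 2
    intragenic_frac: float = 0.25
    retro_transcribed_frac: float = 0.6
    min_spacer: int = 200
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_parent_genes, self.n_retro_intact, self.n_retro_pseudo,
                  self.n_retro_chimeric, self.n_single_exon_genes)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.retro_divergence < 0.75):
            raise ValueError("retro_divergence must be in [0, 0.75)")
        if self.intron_length[0] <= 70:
            raise ValueError("minimum intron length must exceed 70 bp")
        if self.est_error_rate < 0 or self.est_per_transcript < 0:
            raise ValueError("EST parameters must be non-negative")
        if self.exons_per_gene[0] < 2:
            raise ValueError("parent genes need at least 2 exons")


@dataclass
class DisablementRecord:
    kind: str  # 'frameshift' | 'premature_stop'
    position: int  # nucleotide offset within the CDS copy
    detail: str = ""


@dataclass
class RetroTruth:
    """One planted retrocopy: where it is, what it is, where it came from."""

    retro_id: str
    contig: str
    start: int  # CDS copy interval, 0-based half-open
    end: int
    parent_id: str  # parent transcript (= protein) id
    strand: str
    label: str  # intact | frameshift | premature_stop | chimeric_*
    divergence: float
    intragenic: bool
    transcribed: bool
    disablement: DisablementRecord | None = None
    chimera_transcript_id: str | None = None
    new_splice_site: bool = False


@dataclass
class EstTruth:
    est_id: str
    source_id: str
    source_start: int
    source_end: int


@dataclass
class GroundTruth:
    retros: list[RetroTruth] = field(default_factory=list)
    ests: list[EstTruth] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: GroundTruth
    ests: dict[str, str] = field(default_factory=dict)
    mrnas: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; n_codons counts the interior only."""
    body = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS),
                                                         size=n_codons))
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + body + stop


def mutate_sequence(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    ts_tv_ratio: float = 2.0,
    preserve_orf: bool = True,
) -> tuple[str, float]:
    """Apply point substitutions to a requested divergence under K2P.

    ``round(divergence * len)`` positions are mutated; each is a transition
    with probability kappa/(kappa+2), otherwise a random transversion.  With
    ``preserve_orf`` no internal stop codon is created (the offending
    substitution falls back to an alternative or is skipped).  Returns the
    mutated sequence and the realized divergence.
    """
    if not 0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    chars = list(seq)
    n_mut = int(round(divergence * len(seq)))
    if n_mut == 0:
        return seq, 0.0
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    p_ts = ts_tv_ratio / (ts_tv_ratio + 2.0)
    changed = 0
    for pos in sorted(int(p) for p in positions):
        original = chars[pos]
        if original not in "ACGT":
            continue
        if rng.random() < p_ts:
            choices = [TRANSITION[original]] + list(TRANSVERSIONS[original])
        else:
            tv = list(TRANSVERSIONS[original])
            first = tv.pop(rng.integers(0, 2))
            choices = [first] + tv + [TRANSITION[original]]
        for new in choices:
            chars[pos] = new
            if not preserve_orf:
                changed += 1
                break
            codon_start = 3 * (pos // 3)
            codon = "".join(chars[codon_start:codon_start + 3])
            is_last = codon_start >= len(seq) - 3
            if len(codon) < 3 or is_last or codon not in STOP_CODONS:
                changed += 1
                break
            chars[pos] = original
    return "".join(chars), changed / len(seq)


def plant_disablement(
    cds_copy: str,
    kind: str,
    rng: np.random.Generator,
) -> tuple[str, DisablementRecord]:
    """Disable a CDS copy with a frameshift indel or a premature stop codon.

    A frameshift is an indel of length 1 or 2 (never a multiple of 3)
    strictly inside the CDS; a premature stop replaces an in-frame codon
    before 80% of the CDS length.
    """
    if len(cds_copy) < 60:
        raise ValueError("CDS too short to disable (< 60 nt)")
    if kind == "frameshift":
        pos = int(rng.integers(9, len(cds_copy) - 9))
        length = int(rng.integers(1, 3))  # 1 or 2, never 0 mod 3
        if rng.random() < 0.5:
            mutated = cds_copy[:pos] + cds_copy[pos + length:]
            detail = f"del{length}"
        else:
            mutated = cds_copy[:pos] + _random_dna(rng, length) + cds_copy[pos:]
            detail = f"ins{length}"
        return mutated, DisablementRecord(kind="frameshift", position=pos,
                                          detail=detail)
    if kind == "premature_stop":
        n_codons = len(cds_copy) // 3
        hi = max(int(0.8 * n_codons) - 1, 3)
        codon_idx = int(rng.integers(2, hi))
        stop = STOP_CODONS[rng.integers(0, 3)]
        pos = 3 * codon_idx
        mutated = cds_copy[:pos] + stop + cds_copy[pos + 3:]
        return mutated, DisablementRecord(kind="premature_stop", position=pos,
                                          detail=stop)
    raise ValueError(f"unknown disablement kind: {kind}")


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------


@dataclass
class _GeneParts:
    """A gene in sense orientation: alternating exon/intron sequences."""

    gene_id: str
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]

    def sense_length(self) -> int:
        return sum(map(len, self.exon_seqs)) + sum(map(len, self.intron_seqs))

    def genomic_seq(self) -> str:
        parts = []
        for k, ex in enumerate(self.exon_seqs):
            parts.append(ex)
            if k < len(self.intron_seqs):
                parts.append(self.intron_seqs[k])
        sense = "".join(parts)
        return sense if self.strand == "+" else _revcomp(sense)

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Exon intervals relative to the genomic block start, sorted."""
        total = self.sense_length()
        intervals = []
        pos = 0
        for k, ex in enumerate(self.exon_seqs):
            s, e = pos, pos + len(ex)
            if self.strand == "+":
                intervals.append((s, e))
            else:
                intervals.append((total - e, total - s))
            pos = e
            if k < len(self.intron_seqs):
                pos += len(self.intron_seqs[k])
        return sorted(intervals)


def _make_intron(rng: np.random.Generator, length: int) -> str:
    if length < 8:
        raise ValueError("intron too short")
    return "GT" + _random_dna(rng, length - 4) + "AG"


def _design_gene(
    rng: np.random.Generator,
    gene_id: str,
    config: SimConfig,
    n_exons: int | None = None,
    terminal_exon_codons: tuple[str, int] | None = None,
) -> _GeneParts:
    """Random multi-exon gene; introns sit between codons (phase 0).

    ``terminal_exon_codons`` pins the codon count of the first or last exon
    (used to size chimera-neighbor exons).
    """
    lo, hi = config.exons_per_gene
    if n_exons is None:
        n_exons = int(rng.integers(lo, hi + 1))
    codons = [int(rng.integers(*config.exon_codons)) for _ in range(n_exons)]
    if terminal_exon_codons is not None:
        which, count = terminal_exon_codons
        codons[0 if which == "first" else -1] = count
    strand = "+" if rng.random() < 0.5 else "-"
    cds = _random_cds(rng, sum(codons) - 2)  # ATG and stop count as codons
    exon_seqs = []
    pos = 0
    for c in codons:
        exon_seqs.append(cds[pos:pos + 3 * c])
        pos += 3 * c
    intron_seqs = [
        _make_intron(rng, int(rng.integers(config.intron_length[0],
                                           config.intron_length[1] + 1)))
        for _ in range(n_exons - 1)
    ]
    return _GeneParts(gene_id=gene_id, strand=strand, exon_seqs=exon_seqs,
                      intron_seqs=intron_seqs)


def _gene_model_from_parts(parts: _GeneParts, offset: int, contig: str) -> GeneModel:
    exons = [(offset + s, offset + e) for s, e in parts.exon_intervals()]
    tx = Transcript(
        transcript_id=parts.gene_id + ".t1", gene_id=parts.gene_id,
        contig=contig, strand=parts.strand,
        exons=exons, cds=list(exons),
    )
    return GeneModel(
        gene_id=parts.gene_id, contig=contig, strand=parts.strand,
        start=exons[0][0], end=exons[-1][1], transcripts=[tx],
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


@dataclass
class _RetroDesign:
    retro_id: str
    parent_id: str
    cds: str  # mutated CDS copy, sense orientation
    strand: str
    label: str
    divergence: float
    transcribed: bool
    disablement: DisablementRecord | None
    tsd: str
    polya: str

    def insert_seq(self) -> str:
        payload = self.cds + self.polya
        oriented = payload if self.strand == "+" else _revcomp(payload)
        return self.tsd + oriented + self.tsd

    def cds_offset(self) -> tuple[int, int]:
        """CDS interval relative to the insert start (genome coordinates)."""
        if self.strand == "+":
            s = len(self.tsd)
        else:
            s = len(self.tsd) + len(self.polya)
        return s, s + len(self.cds)


def _design_retro(
    rng: np.random.Generator,
    retro_id: str,
    parent_tx: Transcript,
    parent_cds: str,
    config: SimConfig,
    label: str,
    transcribed: bool,
    strand: str | None = None,
) -> _RetroDesign:
    mutated, realized = mutate_sequence(
        parent_cds, config.retro_divergence, rng,
        ts_tv_ratio=config.ts_tv_ratio, preserve_orf=True)
    disablement = None
    if label in ("frameshift", "premature_stop"):
        mutated, disablement = plant_disablement(mutated, label, rng)
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    tsd = _random_dna(rng, int(rng.integers(*config.tsd_length)))
    polya = "A" * int(rng.integers(*config.polya_length))
    return _RetroDesign(
        retro_id=retro_id, parent_id=parent_tx.transcript_id, cds=mutated,
        strand=strand, label=label, divergence=realized,
        transcribed=transcribed, disablement=disablement, tsd=tsd, polya=polya,
    )


def generate_genome(config: SimConfig) -> SimResult:
    """Generate a synthetic genome, annotation and ground truth.

    Parent genes, single-exon decoy genes, retrocopy insertions (intergenic
    or inside host-gene introns) and chimeric gene contexts are laid out on
    one contig separated by random spacers.  Raises a sizing error when
    ``genome_length`` cannot host the requested features.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig = "chr1"

    parents = [
        _design_gene(rng, f"gene{k:04d}", config)
        for k in range(config.n_parent_genes)
    ]
    singles = []
    for k in range(config.n_single_exon_genes):
        g = _design_gene(rng, f"single{k:03d}", config, n_exons=2)
        g.exon_seqs = ["".join(g.exon_seqs)]
        g.intron_seqs = []
        singles.append(g)

    n_total_retro = (config.n_retro_intact + config.n_retro_pseudo
                     + config.n_retro_chimeric)
    if n_total_retro > 0 and not parents:
        raise ValueError("cannot plant retrocopies without parent genes")

    parent_txs = {}
    parent_cds_seqs = {}
    for parts in parents:
        sense_cds = "".join(parts.exon_seqs)
        parent_txs[parts.gene_id] = parts
        parent_cds_seqs[parts.gene_id] = sense_cds

    def pick_parent() -> _GeneParts:
        return parents[int(rng.integers(0, len(parents)))]

    retros: list[_RetroDesign] = []
    ridx = 0

    def next_id() -> str:
        nonlocal ridx
        rid = f"retro{ridx:04d}"
        ridx += 1
        return rid

    labels = (["intact"] * config.n_retro_intact
              + [("frameshift" if k % 2 == 0 else "premature_stop")
                 for k in range(config.n_retro_pseudo)])

    plain_designs: list[_RetroDesign] = []
    for label in labels:
        parts = pick_parent()
        tx_stub = Transcript(transcript_id=parts.gene_id + ".t1",
                             gene_id=parts.gene_id, contig=contig,
                             strand=parts.strand)
        transcribed = bool(rng.random() < config.retro_transcribed_frac)
        plain_designs.append(_design_retro(
            rng, next_id(), tx_stub, parent_cds_seqs[parts.gene_id],
            config, label, transcribed))

    chim_categories = [CHIMERA_LABELS[k % 4] for k in range(config.n_retro_chimeric)]
    chim_designs: list[_RetroDesign] = []
    for label in chim_categories:
        parts = pick_parent()
        tx_stub = Transcript(transcript_id=parts.gene_id + ".t1",
                             gene_id=parts.gene_id, contig=contig,
                             strand=parts.strand)
        chim_designs.append(_design_retro(
            rng, next_id(), tx_stub, parent_cds_seqs[parts.gene_id],
            config, label, transcribed=True, strand="+"))

    # intragenic assignment: at most one planted retro per host gene, never
    # the retro's own parent, and only '+'-strand intragenic work is shared
    # with '-'-strand hosts via explicit coordinate mirroring below
    n_intragenic = int(round(config.intragenic_frac * len(plain_designs)))
    perm = [int(i) for i in rng.permutation(len(plain_designs))]
    intragenic_candidates = [plain_designs[i] for i in perm[:n_intragenic]]

    intragenic_assign: dict[str, _RetroDesign] = {}
    for design in intragenic_candidates:
        own_gene = design.parent_id.rsplit(".t1", 1)[0]
        free = [p for p in parents
                if p.gene_id not in intragenic_assign
                and p.gene_id != own_gene and p.intron_seqs]
        if free:
            host = free[int(rng.integers(0, len(free)))]
            intragenic_assign[host.gene_id] = design
    placed_intragenic = set(d.retro_id for d in intragenic_assign.values())

    # ---- pre-build chimera blocks so block lengths are exact --------------
    chim_blocks: list[dict] = []
    for idx, design in enumerate(chim_designs, start=1):
        lr = len(design.cds)
        block: dict = {"kind": "chimera", "design": design, "index": idx}
        if design.label in ("chimeric_N", "chimeric_C"):
            exon_codons = max(30, int(0.45 * lr / 3))
            which = "last" if design.label == "chimeric_N" else "first"
            nb = _design_gene(rng, f"nbr{idx:03d}", config, n_exons=3,
                              terminal_exon_codons=(which, exon_codons))
            nb.strand = "+"
            block["neighbor"] = nb
            block["gap"] = _random_dna(rng, int(rng.integers(90, 180)))
        elif design.label == "chimeric_both":
            host = _design_gene(rng, f"host{idx:03d}", config, n_exons=3)
            host.strand = "+"
            intron = host.intron_seqs[0]
            mid = len(intron) // 2
            host.intron_seqs[0] = intron[:mid] + design.insert_seq() + intron[mid:]
            block["host"] = host
            block["mid"] = mid
            block["splice_offset"] = int(rng.integers(30, 61))
        else:  # chimeric_UTR
            block["utr3"] = _random_dna(
                rng, int(rng.integers(int(0.3 * lr), int(0.45 * lr))))
        chim_blocks.append(block)

    # ---- assemble block list ----------------------------------------------
    blocks: list[dict] = []
    for design in plain_designs:
        if design.retro_id not in placed_intragenic:
            blocks.append({"kind": "retro", "design": design})
    for parts in parents:
        blocks.append({"kind": "gene", "parts": parts,
                       "embedded": intragenic_assign.get(parts.gene_id)})
    for parts in singles:
        blocks.append({"kind": "gene", "parts": parts, "embedded": None})
    blocks.extend(chim_blocks)

    order = rng.permutation(len(blocks))
    blocks = [blocks[int(i)] for i in order]

    def block_length(block: dict) -> int:
        if block["kind"] == "gene":
            length = block["parts"].sense_length()
            if block["embedded"] is not None:
                length += len(block["embedded"].insert_seq())
            return length
        if block["kind"] == "retro":
            return len(block["design"].insert_seq())
        design = block["design"]
        ln = len(design.insert_seq())
        if design.label in ("chimeric_N", "chimeric_C"):
            return ln + len(block["gap"]) + block["neighbor"].sense_length()
        if design.label == "chimeric_both":
            return block["host"].sense_length()  # insert already embedded
        return ln + len(block["utr3"])

    required = sum(block_length(b) for b in blocks) + \
        (len(blocks) + 1) * config.min_spacer
    if required > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small: features require "
            f"{required} bp (deficit {required - config.genome_length} bp)")

    extra = config.genome_length - required
    spacer_extra = rng.multinomial(extra, np.full(len(blocks) + 1,
                                                  1.0 / (len(blocks) + 1)))

    genome_parts: list[str] = []
    genes: list[GeneModel] = []
    truth = GroundTruth()
    offset = 0

    def add_spacer(k: int) -> None:
        nonlocal offset
        length = config.min_spacer + int(spacer_extra[k])
        genome_parts.append(_random_dna(rng, length))
        offset += length

    def add_seq(seq: str) -> int:
        nonlocal offset
        start = offset
        genome_parts.append(seq)
        offset += len(seq)
        return start

    def record_retro(design: _RetroDesign, start: int, end: int, strand: str,
                     intragenic: bool, chimera_tx: str | None = None,
                     new_splice: bool = False) -> None:
        truth.retros.append(RetroTruth(
            retro_id=design.retro_id, contig=contig, start=start, end=end,
            parent_id=design.parent_id, strand=strand,
            label=design.label, divergence=design.divergence,
            intragenic=intragenic, transcribed=design.transcribed,
            disablement=design.disablement,
            chimera_transcript_id=chimera_tx, new_splice_site=new_splice,
        ))

    for k, block in enumerate(blocks):
        add_spacer(k)
        kind = block["kind"]
        if kind == "gene":
            parts: _GeneParts = block["parts"]
            design = block["embedded"]
            if design is not None:
                intron_ix = int(len(parts.intron_seqs) // 2)
                intron = parts.intron_seqs[intron_ix]
                mid = len(intron) // 2
                ins = design.insert_seq()
                parts.intron_seqs[intron_ix] = intron[:mid] + ins + intron[mid:]
                sense_pos = sum(len(parts.exon_seqs[x])
                                for x in range(intron_ix + 1))
                sense_pos += sum(len(parts.intron_seqs[x])
                                 for x in range(intron_ix))
                sense_pos += mid
                start = add_seq(parts.genomic_seq())
                total = parts.sense_length()
                cs, ce = design.cds_offset()
                if parts.strand == "+":
                    ins_start = start + sense_pos
                    iv = (ins_start + cs, ins_start + ce)
                    strand = design.strand
                else:
                    ins_start = start + total - sense_pos - len(ins)
                    iv = (ins_start + len(ins) - ce, ins_start + len(ins) - cs)
                    strand = "+" if design.strand == "-" else "-"
                record_retro(design, iv[0], iv[1], strand, intragenic=True)
                genes.append(_gene_model_from_parts(parts, start, contig))
            else:
                start = add_seq(parts.genomic_seq())
                genes.append(_gene_model_from_parts(parts, start, contig))
        elif kind == "retro":
            design = block["design"]
            start = add_seq(design.insert_seq())
            cs, ce = design.cds_offset()
            record_retro(design, start + cs, start + ce, design.strand,
                         intragenic=False)
        else:
            _emit_chimera(block, contig, add_seq, genes, record_retro)
    add_spacer(len(blocks))

    genome = {contig: "".join(genome_parts)}
    assert len(genome[contig]) == config.genome_length
    return SimResult(config=config, genome=genome, genes=genes, truth=truth)


def _emit_chimera(block: dict, contig: str, add_seq, genes,
                  record_retro) -> None:
    """Emit a pre-built chimeric context and its transcript annotation."""
    design: _RetroDesign = block["design"]
    idx = block["index"]
    label = design.label
    tx_id = f"chimera{idx:03d}.t1"
    gene_id = f"chimera{idx:03d}"
    cs, ce = design.cds_offset()

    if label in ("chimeric_N", "chimeric_C"):
        nb: _GeneParts = block["neighbor"]
        gap: str = block["gap"]
        if label == "chimeric_N":
            nb_start = add_seq(nb.genomic_seq())
            genes.append(_gene_model_from_parts(nb, nb_start, contig))
            add_seq(gap)
            ins_start = add_seq(design.insert_seq())
            retro_iv = (ins_start + cs, ins_start + ce)
            nb_exon = genes[-1].transcripts[0].exons[-1]
            exons = [nb_exon, retro_iv]
        else:
            ins_start = add_seq(design.insert_seq())
            add_seq(gap)
            nb_start = add_seq(nb.genomic_seq())
            genes.append(_gene_model_from_parts(nb, nb_start, contig))
            retro_iv = (ins_start + cs, ins_start + ce)
            nb_exon = genes[-1].transcripts[0].exons[0]
            exons = [retro_iv, nb_exon]
        record_retro(design, retro_iv[0], retro_iv[1], "+",
                     intragenic=False, chimera_tx=tx_id)
        tx = Transcript(transcript_id=tx_id, gene_id=gene_id, contig=contig,
                        strand="+", exons=sorted(exons), cds=sorted(exons))
        genes.append(GeneModel(
            gene_id=gene_id, contig=contig, strand="+",
            start=tx.start, end=tx.end, transcripts=[tx],
            biotype="chimeric_model"))
        return

    if label == "chimeric_both":
        # host gene already carries the insert in intron 0; the chimeric
        # transcript splices host exon 1 + part of the retro + host exon 2,
        # with the chimeric exon starting inside the retro (new splice site)
        host: _GeneParts = block["host"]
        mid: int = block["mid"]
        start = add_seq(host.genomic_seq())
        genes.append(_gene_model_from_parts(host, start, contig))
        ins_start = start + len(host.exon_seqs[0]) + mid
        retro_iv = (ins_start + cs, ins_start + ce)
        retro_exon = (retro_iv[0] + block["splice_offset"], retro_iv[1])
        host_tx = genes[-1].transcripts[0]
        exons = sorted([host_tx.exons[0], retro_exon, host_tx.exons[1]])
        record_retro(design, retro_iv[0], retro_iv[1], "+",
                     intragenic=True, chimera_tx=tx_id, new_splice=True)
        tx = Transcript(transcript_id=tx_id, gene_id=gene_id, contig=contig,
                        strand="+", exons=exons, cds=list(exons))
        genes.append(GeneModel(
            gene_id=gene_id, contig=contig, strand="+",
            start=tx.start, end=tx.end, transcripts=[tx],
            biotype="chimeric_model"))
        return

    # chimeric_UTR: single-exon transcript; the retro's 5' region is
    # annotated as 5'UTR, recruited downstream sequence as 3'UTR (de novo)
    utr3: str = block["utr3"]
    ins_start = add_seq(design.insert_seq())
    add_seq(utr3)
    retro_iv = (ins_start + cs, ins_start + ce)
    lr = len(design.cds)
    exon = (retro_iv[0], ins_start + len(design.insert_seq()) + len(utr3))
    cds_start = retro_iv[0] + 3 * int(0.3 * lr / 3)
    record_retro(design, retro_iv[0], retro_iv[1], "+",
                 intragenic=False, chimera_tx=tx_id)
    tx = Transcript(transcript_id=tx_id, gene_id=gene_id, contig=contig,
                    strand="+", exons=[exon], cds=[(cds_start, retro_iv[1])])
    genes.append(GeneModel(
        gene_id=gene_id, contig=contig, strand="+",
        start=exon[0], end=exon[1], transcripts=[tx],
        biotype="chimeric_model"))


# ---------------------------------------------------------------------------
# expression reads
# ---------------------------------------------------------------------------


def _est_sources(result: SimResult) -> list[tuple[str, str]]:
    """(source id, spliced sequence) for every transcribable unit."""
    sources = []
    from retroforge.models import spliced_sequence
    for gene in result.genes:
        for tx in gene.transcripts:
            sources.append((tx.transcript_id,
                            spliced_sequence(result.genome, tx)))
    contig = next(iter(result.genome))
    seq = result.genome[contig]
    for retro in result.truth.retros:
        if retro.transcribed and retro.chimera_transcript_id is None:
            sub = seq[retro.start:retro.end]
            sources.append((retro.retro_id,
                            sub if retro.strand == "+" else _revcomp(sub)))
    return sources


def sample_ests(
    result: SimResult,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[EstTruth]]:
    """Sample error-bearing EST reads from every transcribed source.

    Per-source counts are Poisson(``est_per_transcript``); each EST is a
    contiguous subsequence of the spliced source with substitutions applied
    at ``est_error_rate`` per base, emitted on a random strand.
    """
    config = result.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ests: dict[str, str] = {}
    truth: list[EstTruth] = []
    counter = 0
    for source_id, seq in _est_sources(result):
        if len(seq) < 100:
            continue
        n = int(rng.poisson(config.est_per_transcript))
        for _ in range(n):
            lo = min(config.est_length[0], len(seq))
            hi = min(config.est_length[1], len(seq))
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(seq) - length + 1))
            read = list(seq[start:start + length])
            if config.est_error_rate > 0:
                errs = np.flatnonzero(rng.random(length) < config.est_error_rate)
                for pos in errs:
                    old = read[pos]
                    alternatives = [c for c in "ACGT" if c != old]
                    read[pos] = alternatives[int(rng.integers(0, 3))]
            est_seq = "".join(read)
            if rng.random() < 0.5:
                est_seq = _revcomp(est_seq)
            est_id = f"est{counter:05d}"
            counter += 1
            ests[est_id] = est_seq
            truth.append(EstTruth(est_id=est_id, source_id=source_id,
                                  source_start=start, source_end=start + length))
    result.ests = ests
    result.truth.ests.extend(truth)
    return ests, truth


def sample_mrnas(
    result: SimResult,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Full-length, error-free mRNA records for a Poisson-thinned subset."""
    config = result.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    mrnas: dict[str, str] = {}
    counter = 0
    for source_id, seq in _est_sources(result):
        if len(seq) < 100:
            continue
        for _ in range(int(rng.poisson(config.mrna_per_transcript))):
            mrnas[f"mrna{counter:05d}_{source_id}"] = seq
            counter += 1
    result.mrnas = mrnas
    return mrnas


# ---------------------------------------------------------------------------
# ortholog pair simulation
# ---------------------------------------------------------------------------


def make_ortholog_pairs(
    n: int,
    r: float,
    T: float,
    len_codons: int = 300,
    rng: np.random.Generator | None = None,
    ts_tv_ratio: float = 2.0,
    nonsyn_factor: float = 0.1,
    allow_high_divergence: bool = False,
) -> list[tuple[str, str]]:
    """Simulate aligned ortholog CDS pairs with expected Ks = 2*r*T.

    Each pair descends from a random ancestral CDS; the two lineages evolve
    independently for time T.  Synonymous positions change under a Kimura
    two-parameter process whose total rate matches r per silent site per
    year (twofold-degenerate sites accept transitions only, fourfold sites
    the full process); nonsynonymous positions evolve at ``nonsyn_factor``
    times the silent rate, rejecting stops and amino-acid changes at
    twofold sites.
    """
    if n < 1:
        raise ValueError("need at least one pair")
    if r <= 0 or T < 0:
        raise ValueError("rate must be positive, time non-negative")
    d_total = 2.0 * r * T
    if d_total >= 0.75 and not allow_high_divergence:
        raise ValueError(f"2*r*T = {d_total:.3f} is at or beyond saturation (0.75)")
    if d_total >= 1.5:
        raise ValueError(f"2*r*T = {d_total:.3f}: correction fully saturated")
    if rng is None:
        rng = np.random.default_rng(0)
    from retroforge.molevol import _DEGENERACY, GENETIC_CODE

    # ancestral codons are drawn from the "regular" pool: every twofold
    # position exchanges synonymously by transition, so the silent process
    # matches the per-class K2P corrections exactly (AGA/AGG/CGA/CGG/ATA
    # have transversion-synonymous or threefold sites and are excluded)
    irregular = {"AGA", "AGG", "ATA", "CGA", "CGG"}
    regular_codons = [c for c in SENSE_CODONS if c not in irregular]

    kappa = ts_tv_ratio
    d_half = d_total / 2.0  # per lineage
    alpha_t = d_half * kappa / (kappa + 2.0)
    beta_t = d_half / (kappa + 2.0)
    # K2P substitution probabilities at (alpha_t, beta_t)
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = (0.5 - 0.5 * e1) / 2.0
    p_ts_only = 0.5 - 0.5 * np.exp(-2.0 * alpha_t)  # two-state transition chain

    def evolve(cds: str) -> str:
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        out = []
        for codon in codons:
            if codon in ("TAA", "TAG", "TGA") or codon not in _DEGENERACY:
                out.append(codon)
                continue
            new = list(codon)
            deg = _DEGENERACY[codon]
            for k in range(3):
                nt = codon[k]
                if deg[k] == 4:
                    u = rng.random()
                    if u < p_ts:
                        new[k] = TRANSITION[nt]
                    elif u < p_ts + p_tv_each:
                        new[k] = TRANSVERSIONS[nt][0]
                    elif u < p_ts + 2 * p_tv_each:
                        new[k] = TRANSVERSIONS[nt][1]
                elif deg[k] == 2:
                    if rng.random() < p_ts_only:
                        cand = codon[:k] + TRANSITION[nt] + codon[k + 1:]
                        if GENETIC_CODE.get(cand) == GENETIC_CODE[codon]:
                            new[k] = TRANSITION[nt]
                else:
                    if nonsyn_factor > 0 and rng.random() < nonsyn_factor * d_half:
                        u = rng.random()
                        repl = (TRANSITION[nt] if u < kappa / (kappa + 2)
                                else TRANSVERSIONS[nt][int(u * 1e6) % 2])
                        cand = codon[:k] + repl + codon[k + 1:]
                        if GENETIC_CODE.get(cand, "*") != "*":
                            new[k] = repl
            candidate = "".join(new)
            out.append(candidate if GENETIC_CODE.get(candidate, "*") != "*" else codon)
        return "".join(out)

    pairs = []
    for _ in range(n):
        body = "".join(regular_codons[i] for i in
                       rng.integers(0, len(regular_codons),
                                    size=max(len_codons - 2, 1)))
        ancestor = "ATG" + body + STOP_CODONS[rng.integers(0, 3)]
        pairs.append((evolve(ancestor), evolve(ancestor)))
    return pairs


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

TRUTH_HEADER = ["retro_id", "contig", "start", "end", "parent_id", "strand",
                "label", "divergence", "intragenic", "transcribed",
                "disablement_kind", "disablement_pos",
                "chimera_transcript_id", "new_splice_site"]


def write_outputs(result: SimResult, outdir) -> None:
    """Write genome FASTA, annotation GFF3, EST/mRNA FASTA and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    write_gff3(result.genes, outdir / "annotation.gff3")
    if result.ests:
        write_fasta(result.ests, outdir / "ests.fa")
    if result.mrnas:
        write_fasta(result.mrnas, outdir / "mrnas.fa")
    lines = ["\t".join(TRUTH_HEADER)]
    for r in result.truth.retros:
        lines.append("\t".join(str(x) for x in [
            r.retro_id, r.contig, r.start, r.end, r.parent_id, r.strand,
            r.label, f"{r.divergence:.5f}", int(r.intragenic), int(r.transcribed),
            r.disablement.kind if r.disablement else ".",
            r.disablement.position if r.disablement else ".",
            r.chimera_transcript_id or ".", int(r.new_splice_site)]))
    (outdir / "truth_retros.tsv").write_text("\n".join(lines) + "\n")
    est_lines = ["\t".join(["est_id", "source_id", "source_start", "source_end"])]
    for e in result.truth.ests:
        est_lines.append(f"{e.est_id}\t{e.source_id}\t{e.source_start}\t{e.source_end}")
    (outdir / "truth_ests.tsv").write_text("\n".join(est_lines) + "\n")
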