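# Methods

## The problem

Retroposition copies a gene's mRNA back into the genome: the new locus
(a *retrocopy*) lacks the parent's introns and often carries a poly(A)
remnant and short target-site duplications (TSDs). Retrocopies that keep
an open reading frame are candidate *retrogenes*; those disabled by a
frameshift or premature stop codon are *processed pseudogenes*; and
retrocopies that recruit flanking sequence into a new transcript —
novel coding exons, a neighbor's exons, or new UTRs — become *chimeric
retrogenes*. `retroforge` implements the full discovery-and-
characterization workflow for an annotated genome: detection,
classification, transcription evidence, and molecular-evolution dating.

## Detection pipeline

1. **Translated search.** Every annotated peptide is searched against all
   six reading frames of the genome. On small inputs every frame is
   aligned exhaustively (full local Smith–Waterman, BLOSUM62, affine gaps
   costing 11 + k for a gap of length k, so small-instance results equal
   an exhaustive dynamic-programming optimum). On genome-scale inputs the
   search seeds exact 5-mer amino-acid matches against a prebuilt
   six-frame index, clusters seeds by diagonal, and extends each cluster
   with the same local aligner. Frameshifted copies surface as adjacent
   hits in different frames.
2. **Merging.** Same-strand hits of one protein separated by < 40 bp are
   unioned transitively (gaps that small cannot be introns); larger gaps
   stay separate because they may be real introns. Merging is
   frame-agnostic so the two halves of a frameshifted copy rejoin.
3. **Filtering.** A merged candidate survives with amino-acid identity
   > 50%, coverage > 70% of the query protein, and ≥ 50 aligned residues.
4. **Parent assignment.** The candidate's region is re-searched with the
   whole proteome; the best-scoring match whose annotated locus does not
   overlap the candidate becomes the putative parent (a locus cannot
   parent itself). Candidates whose best match has a single coding exon
   are rejected — an intronless "parent" (an olfactory-receptor-like
   gene) cannot demonstrate intron loss. The parent match must cover
   ≥ 50% of the parent protein at ≥ 50% identity. Ties break by score,
   identity, coverage, then protein id, for determinism.
5. **Intron-loss confirmation.** Two spliced alignments of the parent
   protein — against the parent's own locus and against the candidate —
   must show a parental intron longer than 70 bp whose flanking exons the
   candidate's alignment reaches but whose intron is absent from the
   candidate's structure. The 70 bp floor exceeds the 40 bp merge gap, so
   a confirmed loss can never be a merging artifact, and excludes
   micro-gaps mis-annotated as introns.
6. **Retro-derived exclusion.** A call whose nucleotide identity to
   another retrocopy locus exceeds its identity to the parent's spliced
   CDS is likely a copy of a retrocopy, not a primary event; it is kept
   but demoted (`primary=False`). Identity here is matches over the
   longer sequence length: normalizing by gap-free columns would let a
   short fragment look near-identical to an unrelated locus. Exact ties
   favor primary.
7. **Classification.** The parent CDS (terminal stop removed) is located
   in the candidate region by infix edit-distance alignment, then
   re-aligned globally with affine gap costs (match +2, mismatch −3, gap
   open −12, extend −1); the gap-averse scoring prevents the spurious
   compensating indels a unit-cost aligner produces in near-identical
   pairs. Internal indels of length ≢ 0 (mod 3) are frameshifts;
   candidate nucleotides projected onto parent codon positions are
   scanned for in-frame stops upstream of the final codon. Indel runs
   within 6 nt (two codons) of the alignment boundary are treated as
   end-trimming artifacts, not disablements. Any disablement makes the
   call a pseudogene, otherwise intact.

Every call carries LPB Ka/Ks against its parent, computed on the same
codon projection with stop-codon columns masked.

## Spliced alignment

The spliced aligner is a three-state local dynamic program over protein
residues × genome positions: a match state consumes one residue and one
codon; an intron state opens between codons, must run ≥ 40 bp, earns a
bonus for GT donors and AG acceptors (non-canonical boundaries allowed at
full penalty, 30 with a 10 + 10 canonical bonus); and single-nucleotide
slips between codons are tolerated at a penalty of 15 so disabled copies
still produce a structure. Introns are modeled between codons (phase 0
only) — the simulator plants phase-0 introns, and the confirmation logic
needs only intron presence/absence at protein coordinates, so phase-1/2
introns are a known, deliberate limitation. Structures scoring below the
filtration threshold (35 on the BLOSUM62 raw scale; true parent-protein
alignments score in the hundreds) are rejected. On tiny instances the
program's score equals a brute-force enumeration over all single-intron
placements (asserted in the tests).

## EST placement and transcription evidence

Reads are placed by exact 14-mer seeding on both strands, infix
edit-distance refinement of each seed cluster, and chaining of colinear
blocks separated by up to 50 kb on the genome — so reads sampled from
spliced transcripts place correctly across introns, as a spliced aligner
like BLAT would. Acceptance then follows the strict disambiguation
recipe: keep the best placement plus any within 0.5 identity points of it
(at ≥ 96%); accept the EST only if exactly one location remains, aligned
> 100 bp at > 97% identity. This is what keeps a parent's ESTs from being
credited to its retrocopy: the second-best placement at the paralogous
locus sits several identity points below the true one and the EST stays
unique. The uniqueness rule makes acceptance non-monotone in the 96%
retention threshold by construction (raising it can rescue an EST whose
competitor is discarded); the final-acceptance thresholds are monotone.

Evidence attaches to a call on ≥ 1 bp overlap. A chimeric transcript is
confirmed only by a single EST overlapping both a retro-derived and a
novel exon (two one-sided ESTs do not count). Neighborhood activity is
the number of accepted ESTs in the 40 kb flanks excluding the 2 kb
closest to the call, both measured from the call's outermost coordinates;
distance-to-closest-gene is the minimal gap to any non-overlapping
transcript span, strands ignored.

## Chimera taxonomy

A transcript overlapping a retrocopy is chimeric when less than 80% of
its spliced length is retro-derived and it does not arise from the
parental locus. Novel coding sequence 5' of the retro segment only is an
N-terminal addition; 3' only, C-terminal; both sides, both. A retro
segment overlapping the transcript's 5'UTR is a UTR conversion. Novel
stretches shorter than 30 nt (10 codons) do not count as a new peptide —
the local aligner may trim a few diverged terminal codons from the call
interval, and a "peptide" of 1–3 residues is boundary jitter, not
biology. Mode is *fusion* when novel exonic sequence is shared with a
pre-existing gene's exons, *de novo* when the novel material is only
recruited UTR forming a single-exon gene or the retrocopy spans the full
new CDS. A new splice site is flagged when the retro segment crosses an
exon–intron boundary with ≥ 1 bp on each side.

## LPB Ka/Ks and the molecular clock

Each codon position is classified nondegenerate (0-fold), twofold or
fourfold degenerate from the genetic-code table (threefold sites count as
twofold; the arginine/leucine first-position irregularities fall out of
each codon's own row, with site classes averaged over the two sequences
and split half-half when the codons disagree). Transitional (P) and
transversional (Q) difference proportions per class feed Kimura
two-parameter distances A = ½ln(1/(1−2P−Q)) − ¼ln(1/(1−2Q)) and
B = ½ln(1/(1−2Q)), combined as

    Ks = (L2·A2 + L4·A4)/(L2 + L4) + B4
    Ka = A0 + (L0·B0 + L2·B2)/(L0 + L2).

Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises an error rather than
returning NaN. Gapped or ambiguous codon columns are excluded;
stop-codon columns raise an error by default (the pipeline masks them
explicitly when scoring pseudogenes).

The clock is Ks = 2·r·T. The synonymous rate r is calibrated as
mean(ortholog Ks)/(2·T) from ortholog pairs at a known split time (the
median is available as an option); ages are T = Ks/(2·r), and the
origination rate over a window is the count of ages inside it per
million years.

## The synthetic genome

The generator emulates the statistical structure the screen assumes, not
zebrafish sequence composition. Intergenic background is i.i.d. uniform
A/C/G/T. Parent genes have 2–5 exons of 30–80 codons with canonical
GT..AG introns of 80–400 bp placed between codons, and in-frame
ATG..stop CDSs. Retrocopies are copies of a parent's spliced CDS mutated
to the requested divergence under K2P (default ts/tv 2.0), flanked by a
poly(A) tract (15–30 bp) and TSDs (5–15 bp); mutations never create
internal stops, so disablement status is exactly what was planted —
frameshifts are 1–2 nt indels at least 9 nt inside the CDS, premature
stops replace a codon before 80% of the length. A quarter of plain
retrocopies land in the middle of a host gene's intron (never an exon,
one per host, never the retro's own parent), the rest intergenic.
Chimeric contexts plant an intact retrocopy plus an annotated transcript:
N/C additions splice a terminal exon of a dedicated neighbor gene to the
retro CDS (fusion partners, exon sized ≈ 45% of the retro so the retro
fraction stays below 0.8); "both" contexts put the retro in a host
intron and splice host-exon / retro / host-exon, with the chimeric exon
starting 30–60 bp inside the retro so a new splice site exists; UTR
conversions annotate the retro's first 30% as 5'UTR and recruit
downstream sequence as 3'UTR in a single-exon gene (de novo). ESTs are
contiguous 150–450 bp subsequences of spliced transcripts (Poisson count
per source, mean 3) with per-base substitution errors (default 0.5%),
emitted on random strands. Identical configurations produce
byte-identical FASTA/GFF3/TSV outputs.

Ortholog pairs for calibration descend from a common ancestor and evolve
independently for time T: fourfold sites under the full K2P process,
twofold sites by the transition-only two-state chain (both scaled so the
total silent distance is 2·r·T), nonsynonymous sites at 10% of the
silent rate with stops rejected. Ancestral codons come from the
"regular" pool — AGA/AGG/CGA/CGG/ATA are excluded because their twofold
positions exchange synonymously by transversion (or are threefold),
which the per-class K2P correction cannot represent; with them included
the recovered rate is biased about −6%, without them about −1.5%.

What the simulator does **not** emulate: realistic base composition,
repeat landscapes and LINE-1 machinery, gene families and paralogy,
alternative splicing, phase-1/2 introns, EST indel errors, and
chromosome-scale genomes. Passing the recovery suite therefore shows the
pipeline's logic is correct on data satisfying its assumptions, not that
its thresholds are optimal for a real fish genome.

## Validation experiments and problem sizes

The recovery benchmark plants 40 retrocopies (20 intact, 12 disabled, 8
chimeric, one per category pair) among 60 parent genes on a 2 Mb contig
at 8% divergence, and scores sensitivity, false-discovery rate,
disablement-classification accuracy and chimera-label accuracy — all
computed against the machine-readable truth. Rate calibration uses 38
simulated ortholog pairs of 400 codons at r = 4.13×10⁻⁹/site/year and
T = 50 My; Ks parameter recovery uses 50 pairs of 300 codons at each of
Ks ∈ {0.05, 0.2, 0.5, 1.0}. These sizes keep the full validation run in
about a minute while leaving every per-stage count well away from
small-number noise. The unit suites run the same machinery on a 250 kb
genome with 9 planted copies.

## Known limitations

- Introns are modeled at phase 0 only; a phase-1/2 intron in real
  annotation would shift the confirmation boundary by one residue.
- The translated search's seeded mode needs one exact 5-mer amino-acid
  match per hit; copies beyond ~40% amino-acid divergence can escape it
  (irrelevant at the divergences the screen targets, where the identity
  filter is 50%).
- Retrocopies of retrocopies are demoted, not re-parented.
- The EST placer chains blocks greedily; extremely short (< 14 bp) exon
  overhangs of a read are absorbed into the neighboring block as
  mismatches.
- The "significantly lower than 0.5" per-gene Ka/Ks claim is reported as
  a count below 0.5; no significance is attached because the reference
  test is unspecified.
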