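"""Retrocopy pipeline stages: merging, filters, confirmation, classification."""

import numpy as np
import pytest

from retroforge import retroscan, simgenome
from retroforge.retroscan import (
    MergedCandidate,
    PipelineConfig,
    RetrocopyCall,
    classify_disablements,
    confirm_intron_loss,
    exclude_retro_derived,
    filter_candidates,
    merge_hits,
)
from retroforge.seqalign import ProteinHit, SplicedExon, SplicedIntron, \
    SplicedReject, SplicedStructure


def make_hit(start, end, strand="+", frame=0, score=100.0, identity=90.0,
             q=(0, 50), protein_id="p1"):
    return ProteinHit(protein_id=protein_id, contig="chr1", start=start,
                      end=end, strand=strand, frame=frame, score=score,
                      identity=identity, blocks=[(q[0], q[1], start, end)])


class TestMergeHits:
    def test_gap_of_39_merges(self):
        hits = [make_hit(100, 200, q=(0, 33)), make_hit(239, 300, q=(34, 54))]
        merged = merge_hits(hits, merge_gap_bp=40)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 300)

    def test_gap_of_40_stays_separate(self):
        hits = [make_hit(100, 200, q=(0, 33)), make_hit(240, 300, q=(34, 54))]
        assert len(merge_hits(hits, merge_gap_bp=40)) == 2

    def test_single_hit_unchanged_and_idempotent(self):
        hits = [make_hit(100, 200)]
        merged = merge_hits(hits)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 200)

    def test_merging_is_transitive(self):
        hits = [make_hit(100, 200, q=(0, 33)),
                make_hit(230, 330, q=(33, 66)),
                make_hit(360, 460, q=(66, 99))]
        assert len(merge_hits(hits, merge_gap_bp=40)) == 1

    def test_order_invariance(self):
        hits = [make_hit(100, 200, q=(0, 33)), make_hit(239, 300, q=(34, 54)),
                make_hit(5000, 5100, q=(0, 33))]
        a = merge_hits(list(hits))
        b = merge_hits(list(reversed(hits)))
        assert [(m.start, m.end) for m in a] == [(m.start, m.end) for m in b]

    def test_different_strands_never_merge(self):
        hits = [make_hit(100, 200), make_hit(210, 300, strand="-")]
        assert len(merge_hits(hits)) == 2

    def test_frames_merge_on_same_strand(self):
        # a frameshifted copy appears as adjacent hits in different frames
        hits = [make_hit(100, 200, frame=0, q=(0, 33)),
                make_hit(205, 300, frame=1, q=(34, 65))]
        assert len(merge_hits(hits)) == 1

    def test_mixed_protein_ids_are_an_error(self):
        with pytest.raises(ValueError):
            merge_hits([make_hit(0, 10, protein_id="a"),
                        make_hit(20, 30, protein_id="b")])


def make_candidate(identity=90.0, q_blocks=((0, 60),), protein_id="p1"):
    return MergedCandidate(protein_id=protein_id, contig="chr1", start=0,
                           end=300, strand="+", score=100.0,
                           identity=identity, query_blocks=list(q_blocks))


class TestFilterCandidates:
    CONFIG = PipelineConfig()
    LENGTHS = {"p1": 80}

    def test_identity_just_below_threshold_rejected(self):
        cand = make_candidate(identity=49.0)
        assert filter_candidates([cand], self.CONFIG, self.LENGTHS) == []

    def test_coverage_just_below_threshold_rejected(self):
        cand = make_candidate(q_blocks=((0, 55),))  # 55/80 = 0.69
        assert filter_candidates([cand], self.CONFIG, self.LENGTHS) == []

    def test_49_aligned_aa_rejected_even_at_high_identity(self):
        cand = make_candidate(identity=90.0, q_blocks=((0, 49),))
        assert filter_candidates([cand], self.CONFIG, {"p1": 60}) == []

    def test_passing_candidate_kept(self):
        cand = make_candidate(identity=85.0, q_blocks=((0, 60),))
        assert len(filter_candidates([cand], self.CONFIG, self.LENGTHS)) == 1


def parent_structure(intron_len, protein_boundary=30, total=60):
    exon1 = SplicedExon(genome_start=0, genome_end=3 * protein_boundary,
                        protein_start=0, protein_end=protein_boundary)
    exon2 = SplicedExon(genome_start=3 * protein_boundary + intron_len,
                        genome_end=3 * total + intron_len,
                        protein_start=protein_boundary, protein_end=total)
    intron = SplicedIntron(genome_start=3 * protein_boundary,
                           genome_end=3 * protein_boundary + intron_len,
                           donor="GT", acceptor="AG")
    return SplicedStructure(protein_id="p", exons=[exon1, exon2],
                            introns=[intron], score=200.0, identity=100.0)


def intronless_structure(lo=0, hi=60):
    exon = SplicedExon(genome_start=0, genome_end=3 * (hi - lo),
                       protein_start=lo, protein_end=hi)
    return SplicedStructure(protein_id="p", exons=[exon], introns=[],
                            score=200.0, identity=95.0)


class TestConfirmIntronLoss:
    def test_71bp_lost_intron_confirms(self):
        assert confirm_intron_loss(parent_structure(71),
                                   intronless_structure()) is True

    def test_70bp_intron_does_not_confirm(self):
        assert confirm_intron_loss(parent_structure(70),
                                   intronless_structure()) is False

    def test_candidate_spanning_one_exon_does_not_confirm(self):
        # candidate covers only residues 0..28, short of the boundary at 30
        assert confirm_intron_loss(parent_structure(200),
                                   intronless_structure(0, 28)) is False

    def test_intronless_parent_rejects(self):
        assert confirm_intron_loss(intronless_structure(),
                                   intronless_structure()) is False

    def test_retained_intron_does_not_confirm(self):
        assert confirm_intron_loss(parent_structure(200),
                                   parent_structure(150)) is False

    def test_rejected_structures_do_not_confirm(self):
        assert confirm_intron_loss(SplicedReject("x"),
                                   intronless_structure()) is False
        assert confirm_intron_loss(parent_structure(100),
                                   SplicedReject("x")) is False


class TestClassifyDisablements:
    @pytest.fixture
    def parent_cds(self):
        rng = np.random.default_rng(0)
        return simgenome._random_cds(rng, 150)[:-3]

    def test_clean_diverged_copy_is_intact(self, parent_cds):
        rng = np.random.default_rng(1)
        copy, _ = simgenome.mutate_sequence(parent_cds, 0.05, rng)
        region = "ACGT" * 10 + copy + "TGCA" * 10
        classification, disablements, pair = classify_disablements(
            parent_cds, region)
        assert classification == "intact" and disablements == []
        assert pair is not None and len(pair[0]) == len(pair[1])

    def test_planted_deletion_is_frameshift(self, parent_cds):
        pos = 200
        copy = parent_cds[:pos] + parent_cds[pos + 1:]
        classification, disablements, _ = classify_disablements(
            parent_cds, "ACGT" * 10 + copy + "TGCA" * 10)
        assert classification == "pseudogene"
        assert [d["kind"] for d in disablements] == ["frameshift"]

    def test_planted_inframe_stop_is_premature_stop(self, parent_cds):
        pos = 3 * (len(parent_cds) // 6)  # ~50% of the CDS
        copy = parent_cds[:pos] + "TGA" + parent_cds[pos + 3:]
        classification, disablements, _ = classify_disablements(
            parent_cds, "ACGT" * 10 + copy + "TGCA" * 10)
        assert classification == "pseudogene"
        assert disablements == [{"kind": "premature_stop", "position": pos,
                                 "detail": "TGA"}]

    def test_inframe_deletion_is_not_a_frameshift(self, parent_cds):
        pos = 201
        copy = parent_cds[:pos] + parent_cds[pos + 3:]
        classification, disablements, _ = classify_disablements(
            parent_cds, "ACGT" * 10 + copy + "TGCA" * 10)
        assert classification == "intact"

    def test_unrelated_sequence_fails(self, parent_cds):
        rng = np.random.default_rng(5)
        noise = simgenome._random_dna(rng, len(parent_cds))
        classification, _, _ = classify_disablements(parent_cds, noise)
        assert classification == "failed"


def make_call(call_id, start, end, parent="p1", strand="+"):
    return RetrocopyCall(call_id=call_id, contig="chr1", start=start, end=end,
                         strand=strand, parent_id=parent,
                         classification="intact")


class TestExcludeRetroDerived:
    def _setup(self, rng, div_old=0.10):
        parent = simgenome._random_cds(rng, 120)
        old_copy, _ = simgenome.mutate_sequence(parent, div_old, rng)
        return parent, old_copy

    def test_copy_of_retrocopy_demoted(self):
        rng = np.random.default_rng(0)
        parent, old_copy = self._setup(rng)
        genome = {"chr1": "ACGT" * 50 + old_copy + "TGCA" * 50 + old_copy
                  + "GACT" * 50}
        a = make_call("a", 200, 200 + len(old_copy))
        b_start = 200 + len(old_copy) + 200
        b = make_call("b", b_start, b_start + len(old_copy))
        out = exclude_retro_derived([a, b], genome, {"p1": parent})
        # both copies are identical to each other (100%) but only ~90% to
        # the parent: each looks retro-derived; the tie rule keeps neither
        # primary because identity to the other strictly exceeds parent
        assert all(not c.primary for c in out)

    def test_unique_retrocopy_stays_primary(self):
        rng = np.random.default_rng(1)
        parent, copy = self._setup(rng, div_old=0.05)
        genome = {"chr1": "ACGT" * 50 + copy + "TGCA" * 50}
        out = exclude_retro_derived([make_call("a", 200, 200 + len(copy))],
                                    genome, {"p1": parent})
        assert out[0].primary

    def test_exact_tie_favors_primary(self):
        # divergence 0: copies equal each other AND the parent exactly
        rng = np.random.default_rng(2)
        parent = simgenome._random_cds(rng, 120)
        genome = {"chr1": "ACGT" * 50 + parent + "TGCA" * 50 + parent
                  + "GACT" * 50}
        a = make_call("a", 200, 200 + len(parent))
        b_start = 200 + len(parent) + 200
        b = make_call("b", b_start, b_start + len(parent))
        out = exclude_retro_derived([a, b], genome, {"p1": parent})
        assert all(c.primary for c in out)


class TestPipelineConfig:
    def test_confirm_span_must_exceed_merge_gap(self):
        with pytest.raises(ValueError):
            PipelineConfig(confirm_span_bp=40, merge_gap_bp=40).validate()

    def test_default_config_valid(self):
        PipelineConfig().validate()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(min_overlap_aa=0).validate()


class TestPipeline:
    def test_negative_control_no_plantings_no_calls(self):
        config = simgenome.SimConfig(
            genome_length=120_000, n_parent_genes=6, n_retro_intact=0,
            n_retro_pseudo=0, n_retro_chimeric=0, seed=21)
        result = simgenome.generate_genome(config)
        calls, report = retroscan.run_pipeline(result.genome, result.genes)
        assert calls == []

    def test_recovery_on_small_genome(self, small_sim, small_calls,
                                      truth_by_call):
        calls, report = small_calls
        recovered = {t.retro_id for t in truth_by_call.values()}
        planted = {r.retro_id for r in small_sim.truth.retros}
        assert len(calls) == len(truth_by_call)  # no false positives
        assert len(recovered) >= 0.9 * len(planted)

    def test_parent_assignment_matches_truth(self, small_calls, truth_by_call):
        calls, _ = small_calls
        for call in calls:
            assert call.parent_id == truth_by_call[call.call_id].parent_id

    def test_classification_matches_planted_labels(self, small_calls,
                                                   truth_by_call):
        calls, _ = small_calls
        for call in calls:
            truth = truth_by_call[call.call_id]
            if truth.label in ("frameshift", "premature_stop"):
                assert call.classification == "pseudogene"
                assert [d["kind"] for d in call.disablements] == [truth.label]
            else:
                assert call.classification == "intact"

    def test_intragenic_flags_match_truth(self, small_calls, truth_by_call):
        calls, _ = small_calls
        for call in calls:
            assert call.intragenic == truth_by_call[call.call_id].intragenic

    def test_stage_counts_monotone(self, small_calls):
        _, report = small_calls
        assert report.n_merged >= report.n_filtered >= report.n_with_parent \
            >= report.n_confirmed
        assert report.n_intact + report.n_pseudogene == report.n_confirmed

    def test_no_call_overlaps_its_parent_locus(self, small_sim, small_calls):
        calls, _ = small_calls
        gene_span = {t.transcript_id: g.span for g in small_sim.genes
                     for t in g.transcripts}
        for call in calls:
            lo, hi = gene_span[call.parent_id]
            assert min(call.end, hi) - max(call.start, lo) <= 0

    def test_kaks_attached_and_consistent_with_divergence(self, small_calls,
                                                          truth_by_call):
        calls, _ = small_calls
        for call in calls:
            assert call.kaks is not None
            assert call.kaks.ks >= 0 and call.kaks.ka >= 0
            # planted mutations are unconstrained: Ks within a loose band
            # of the planted divergence
            assert call.kaks.ks < 4 * truth_by_call[call.call_id].divergence + 0.05

    def test_output_formats(self, small_calls):
        calls, _ = small_calls
        gff = retroscan.calls_to_gff3(calls)
        assert gff.startswith("##gff-version 3")
        assert gff.count("\tretrocopy\t") == len(calls)
        tsv = retroscan.calls_to_tsv(calls)
        assert len(tsv.strip().split("\n")) == len(calls) + 1
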