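"""The synthetic-data generator: determinism, donor/reference
round-trips, read simulation, and the first-pass mapper emulator."""

import numpy as np
import pytest

from svindel.alignio import AlignmentSet, extract_murs, revcomp
from svindel.features import pileup
from svindel.simdata import (
    SimConfig,
    Variant,
    emulate_first_pass,
    generate_reference,
    implant_variants,
    simulate,
    simulate_reads,
)


class TestGenerateReference:
    def test_deterministic_per_seed(self):
        a, _ = generate_reference(2000, seed=3)
        b, _ = generate_reference(2000, seed=3)
        assert a.sequences == b.sequences

    def test_different_seeds_diverge(self):
        a, _ = generate_reference(5000, seed=1)
        b, _ = generate_reference(5000, seed=2)
        sa, sb = a.sequences["chr1"], b.sequences["chr1"]
        mismatch = sum(1 for x, y in zip(sa, sb) if x != y)
        assert mismatch / len(sa) > 0.6  # expectation 0.75 for uniform bases

    def test_length_and_alphabet(self):
        genome, _ = generate_reference(1000, seed=0)
        seq = genome.sequences["chr1"]
        assert len(seq) == 1000
        assert set(seq) <= set("ACGT")

    def test_duplicated_segment_copies_are_identical(self):
        genome, dup = generate_reference(30_000, seed=4, dup_length=2000)
        (s0, e0), (s1, e1) = dup
        seq = genome.sequences["chr1"]
        assert seq[s0:e0] == seq[s1:e1]
        assert e0 <= s1  # disjoint

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(500, seed=0)


class TestImplantVariants:
    CFG = SimConfig(genome_length=50_000, n_deletions=5,
                    deletion_length=(30, 200), n_insertions=5)

    def test_donor_length_conservation(self):
        genome, _ = generate_reference(50_000, seed=1)
        donor, truth = implant_variants(genome, self.CFG, seed=2)
        delta = sum(
            -v.length if v.kind == "deletion" else v.length for v in truth.variants
        )
        assert len(donor) == 50_000 + delta

    def test_reference_reconstructed_from_donor(self):
        genome, _ = generate_reference(50_000, seed=1)
        donor, truth = implant_variants(genome, self.CFG, seed=2)
        assert truth.reconstruct_reference(donor) == genome.sequences["chr1"]

    def test_insertion_lengths_in_configured_range(self):
        genome, _ = generate_reference(50_000, seed=1)
        _, truth = implant_variants(genome, self.CFG, seed=3)
        ins = [v for v in truth.variants if v.kind == "insertion"]
        assert ins and all(2 <= v.length <= 5 for v in ins)
        assert all(len(v.inserted_sequence) == v.length for v in ins)

    def test_variants_respect_spacing(self):
        genome, _ = generate_reference(50_000, seed=1)
        _, truth = implant_variants(genome, self.CFG, seed=4)
        spans = sorted(
            (v.start, v.start + (v.length if v.kind == "deletion" else 0))
            for v in truth.variants
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= self.CFG.min_spacing

    def test_infeasible_packing_raises(self):
        genome, _ = generate_reference(2000, seed=1)
        config = SimConfig(genome_length=2000, n_deletions=10,
                           deletion_length=(150, 200), n_insertions=0)
        with pytest.raises(ValueError, match="crowded"):
            implant_variants(genome, config, seed=0)


class TestSimulateReads:
    def test_error_free_reads_are_donor_substrings(self):
        genome, _ = generate_reference(20_000, seed=1)
        config = SimConfig(genome_length=20_000, n_deletions=0, n_insertions=0)
        donor, _ = implant_variants(genome, config, seed=1)
        pairs = simulate_reads(donor, config, seed=2)
        for r1, r2 in pairs[:200]:
            assert donor[r1.donor_start : r1.donor_end] == r1.raw_seq
            assert revcomp(donor[r2.donor_start : r2.donor_end]) == r2.raw_seq

    def test_seed_reproducibility(self):
        genome, _ = generate_reference(20_000, seed=1)
        config = SimConfig(genome_length=20_000)
        donor, _ = implant_variants(genome, config, seed=1)
        a = simulate_reads(donor, config, seed=9)
        b = simulate_reads(donor, config, seed=9)
        assert [(r.donor_start, r.raw_seq) for p in a for r in p] == [
            (r.donor_start, r.raw_seq) for p in b for r in p
        ]

    def test_empirical_coverage_near_target(self, small_sim):
        aln = AlignmentSet.from_sam(small_sim.records)
        # away from variant loci the mapped-read depth approximates the
        # configured coverage
        prof = pileup(aln, "chr1", 1000, 3000)
        depth = (prof.umr_depth + prof.numr_depth).mean()
        assert abs(depth - small_sim.config.coverage) / small_sim.config.coverage < 0.1


class TestEmulateFirstPass:
    def _setup(self, **kw):
        config = SimConfig(genome_length=20_000, n_deletions=1,
                           deletion_length=(50, 50), n_insertions=0, **kw)
        genome, dup = generate_reference(20_000, seed=1)
        donor, truth = implant_variants(genome, config, seed=1)
        return config, genome, donor, truth

    def test_clean_read_maps_without_differences(self):
        config, genome, donor, truth = self._setup()
        pairs = simulate_reads(donor, config, seed=1)
        _, records = emulate_first_pass(pairs, truth, genome, config)
        mapped = [r for r in records if not r.is_unmapped and not r.is_secondary]
        assert mapped
        clean = mapped[0]
        ref = genome.sequences["chr1"]
        assert clean.query_sequence == ref[
            clean.reference_start : clean.reference_start + len(clean.query_sequence)
        ] or "D" in clean.cigarstring or "I" in clean.cigarstring

    def test_deletion_spanning_read_becomes_mur(self):
        config, genome, donor, truth = self._setup()
        deletion = truth.variants[0]
        pairs = simulate_reads(donor, config, seed=1)
        _, records = emulate_first_pass(pairs, truth, genome, config)
        murs = extract_murs(records)
        assert murs  # junction reads exceed the 3-gap tolerance
        # every unmapped read's truth interval really straddles the junction
        unmapped_ids = {r.query_name for r in records if r.is_unmapped}
        assert unmapped_ids == {
            r.read_id for pair in pairs for r in pair if r.spans_indel
        }

    def test_read_with_five_errors_is_unmapped(self):
        config, genome, donor, truth = self._setup()
        pairs = simulate_reads(donor, config, seed=1)
        r1, r2 = pairs[0]
        if r1.spans_indel:  # pick a clean pair
            r1, r2 = pairs[1]
        seq = list(r1.raw_seq)
        for k in range(5):
            seq[k * 7] = "A" if seq[k * 7] != "A" else "C"
        r1.raw_seq = "".join(seq)
        _, records = emulate_first_pass([(r1, r2)], truth, genome, config)
        rec1 = [r for r in records if r.is_read1][0]
        assert rec1.is_unmapped

    def test_short_insertion_read_stays_mapped_with_gap_cigar(self):
        config = SimConfig(genome_length=20_000, n_deletions=0,
                           n_insertions=1, insertion_length=(3, 3))
        genome, _ = generate_reference(20_000, seed=2)
        donor, truth = implant_variants(genome, config, seed=2)
        pairs = simulate_reads(donor, config, seed=2)
        _, records = emulate_first_pass(pairs, truth, genome, config)
        with_gap = [
            r for r in records
            if not r.is_unmapped and r.cigarstring and "I" in r.cigarstring
        ]
        assert with_gap  # 3 gap columns within the 4-diff/3-gap tolerance

    def test_four_bp_insertion_reads_are_unmapped(self):
        config = SimConfig(genome_length=20_000, n_deletions=0,
                           n_insertions=1, insertion_length=(4, 4))
        genome, _ = generate_reference(20_000, seed=2)
        donor, truth = implant_variants(genome, config, seed=2)
        pairs = simulate_reads(donor, config, seed=2)
        _, records = emulate_first_pass(pairs, truth, genome, config)
        assert any(r.is_unmapped for r in records)

    def test_duplicated_segment_reads_report_two_placements(self, dup_sim):
        by_name = {}
        for rec in dup_sim.records:
            if not rec.is_unmapped:
                by_name.setdefault((rec.query_name, rec.is_read1), []).append(rec)
        multi = [v for v in by_name.values() if len(v) > 1]
        assert multi
        for placements in multi:
            assert {p.is_secondary for p in placements} == {True, False}
            assert all(p.mapping_quality == 0 for p in placements)


class TestEndToEnd:
    def test_classification_raises_candidate_precision(self, dup_sim):
        """Training a model on truth-labeled candidates and keeping the
        positive calls must not lower — and must actively filter —
        the candidate set's precision."""
        from svindel.alignio import AlignmentSet
        from svindel.candidates import detect_candidates
        from svindel.classifier import TrainingSet, predict, train_svm
        from svindel.features import extract_features
        from svindel.simdata import make_labeled_features

        murs = extract_murs(dup_sim.records)
        candidates = [
            c for c in detect_candidates(murs, dup_sim.reference)
            if c.kind == "deletion"
        ]
        alignments = AlignmentSet.from_sam(dup_sim.records)
        vectors = [
            extract_features(c, alignments, dup_sim.reference) for c in candidates
        ]
        labeled = make_labeled_features(dup_sim.truth, candidates, vectors)
        n_false = sum(1 for v in labeled if v.label == -1)
        assert n_false >= 1  # the duplicated segment must create decoys
        model = train_svm(
            TrainingSet.from_vectors(labeled, kind="deletion"), C=10.0
        )
        calls = predict(model, labeled)
        positives = [v.label for v, (_, cls) in zip(labeled, calls) if cls == 1]
        base = sum(1 for v in labeled if v.label == 1) / len(labeled)
        classified = sum(1 for y in positives if y == 1) / len(positives)
        assert classified >= base
        false_kept = sum(1 for y in positives if y == -1)
        assert false_kept < n_false  # at least one decoy rejected

    def test_single_seed_drives_everything(self):
        config = SimConfig(genome_length=20_000, n_deletions=3,
                           deletion_length=(30, 100), n_insertions=2)
        a = simulate(config, seed=42)
        b = simulate(config, seed=42)
        assert a.reference.sequences == b.reference.sequences
        assert a.donor == b.donor
        assert [r.to_string() for r in a.records] == [r.to_string() for r in b.records]
        c = simulate(config, seed=43)
        assert c.donor != a.donor
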