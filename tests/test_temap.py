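"""TE caller: k-mer index, read placement, multi-map exclusion, SAM
ingestion, breadth of coverage, and the 80%/20% call rules."""

import numpy as np
import pytest

from awnloci import synthio, temap


class TestKmerIndex:
    def test_hand_enumerable_positions(self):
        idx = temap.KmerIndex({"c": "ACGTACGT"}, k=5)
        assert idx.lookup("ACGTA") == [("c", 0)]
        assert idx.lookup("CGTAC") == [("c", 1)]

    def test_absent_kmer_empty(self):
        idx = temap.KmerIndex({"c": "ACGTACGT"}, k=5)
        assert idx.lookup("TTTTT") == []

    def test_no_cross_chromosome_kmers(self):
        # "AAAAA" would appear at the junction if chromosomes were
        # concatenated naively
        idx = temap.KmerIndex({"c1": "GGGAA", "c2": "AAAGG"}, k=5)
        assert idx.lookup("GAAAA") == []
        assert idx.lookup("AAAAA") == []

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            temap.KmerIndex({"c": "ACGTACGT"}, k=4)

    def test_k_larger_than_every_chromosome(self):
        with pytest.raises(ValueError):
            temap.KmerIndex({"c": "ACG"}, k=5)


class TestPlaceRead:
    def test_unique_exact_substring(self, reference, index):
        seq = reference.sequences["chr8"][5000:5100]
        p = temap.place_read(seq, index)
        assert p is not None and not p.excluded
        assert (p.chromosome, p.start, p.end) == ("chr8", 5000, 5100)
        assert p.mismatches == 0

    def test_read_matching_two_loci_excluded(self):
        rng = np.random.default_rng(0)
        from awnloci._seq import random_nucleotides

        repeat = random_nucleotides(100, rng)
        genome = {
            "c": random_nucleotides(500, rng) + repeat
            + random_nucleotides(500, rng) + repeat + random_nucleotides(200, rng)
        }
        idx = temap.KmerIndex(genome, k=31)
        p = temap.place_read(repeat, idx)
        assert p is not None and p.excluded and p.n_best_hits == 2

    def test_read_shorter_than_k_skipped(self, index):
        assert temap.place_read("ACGT", index) is None
        placements, skipped = temap.place_reads([("r1", "ACGT")], index)
        assert placements == [] and skipped == 1

    def test_mismatch_tolerance(self, reference, index):
        seq = list(reference.sequences["chr8"][3000:3100])
        seq[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[50]]
        p = temap.place_read("".join(seq), index)
        assert p is not None and p.start == 3000 and p.mismatches == 1

    def test_simulated_placement_accuracy(self, reference, index):
        """At 20x / 1% error, >=99% of unique placements hit the truth
        position (reads simulated from the reference itself so truth and
        reference coordinates coincide)."""
        params = synthio.ReadSimParams(depth=5, error_rate=0.01, seed=11)
        reads = synthio.simulate_reads(reference.sequences, params)
        correct = total = 0
        for r in reads:
            p = temap.place_read(r.sequence, index, read_id=r.read_id)
            if p is None or p.excluded:
                continue
            total += 1
            correct += (p.chromosome, p.start) == (r.chromosome, r.start)
        assert total > 0.9 * len(reads)
        assert correct / total >= 0.99


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr4\tLN:24400\n"


class TestIngestSam:
    def _write(self, tmp_path, body):
        path = tmp_path / "in.sam"
        path.write_text(SAM_HEADER + body)
        return path

    def test_secondary_flag_marks_multimapped(self, tmp_path):
        body = "r1\t256\tchr4\t101\t60\t100M\t*\t0\t0\t*\t*\n"
        placements = temap.ingest_sam(self._write(tmp_path, body))
        assert len(placements) == 1 and placements[0].excluded

    def test_mapq_zero_primary_excluded(self, tmp_path):
        body = "r1\t0\tchr4\t101\t0\t100M\t*\t0\t0\t*\t*\n"
        placements = temap.ingest_sam(self._write(tmp_path, body))
        assert placements[0].excluded

    def test_unmapped_dropped_and_coordinates(self, tmp_path):
        body = (
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
            "r2\t0\tchr4\t101\t60\t100M\t*\t0\t0\t*\t*\n"
        )
        placements = temap.ingest_sam(self._write(tmp_path, body))
        assert len(placements) == 1
        p = placements[0]
        assert (p.chromosome, p.start, p.end) == ("chr4", 100, 200)
        assert not p.excluded

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text("")
        assert temap.ingest_sam(path) == []

    def test_malformed_line_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(SAM_HEADER + "r1\tnot_a_flag\tchr4\n")
        with pytest.raises(ValueError):
            temap.ingest_sam(path)


def _placement(chrom, start, end, rid="r", multi=False):
    return temap.ReadPlacement(read_id=rid, chromosome=chrom, start=start,
                               end=end, n_best_hits=2 if multi else 1)


class TestBreadth:
    WINDOW = ("c", 1000, 1200)

    def test_no_reads(self):
        assert temap.breadth([], self.WINDOW) == (0, 0.0)

    def test_exact_spanning_read(self):
        assert temap.breadth([_placement("c", 1000, 1200)], self.WINDOW) == (200, 1.0)

    def test_two_reads_with_and_without_gap(self):
        full = [_placement("c", 1000, 1120), _placement("c", 1100, 1220)]
        assert temap.breadth(full, self.WINDOW) == (200, 1.0)
        gapped = [_placement("c", 1000, 1120), _placement("c", 1130, 1250)]
        assert temap.breadth(gapped, self.WINDOW) == (190, 0.95)

    def test_excluded_reads_contribute_nothing(self):
        reads = [_placement("c", 1000, 1200, multi=True)]
        assert temap.breadth(reads, self.WINDOW) == (0, 0.0)

    def test_matches_per_position_oracle(self):
        """Sweep-free oracle: count each window position covered by >=1
        unique read, on randomized small instances."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            w0 = int(rng.integers(0, 500))
            window = ("c", w0, w0 + 200)
            placements = [
                _placement("c", s, s + int(rng.integers(10, 150)),
                           multi=bool(rng.random() < 0.2))
                for s in rng.integers(0, 800, size=int(rng.integers(0, 15)))
            ]
            covered = sum(
                any(p.start <= pos < p.end and not p.excluded for p in placements)
                for pos in range(w0, w0 + 200)
            )
            assert temap.breadth(placements, window) == (covered, covered / 200)

    def test_monotone_under_added_reads(self):
        rng = np.random.default_rng(7)
        placements = []
        prev = 0
        for _ in range(30):
            s = int(rng.integers(900, 1250))
            placements.append(_placement("c", s, s + 50))
            cov, _ = temap.breadth(placements, self.WINDOW)
            assert cov >= prev
            prev = cov

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            temap.breadth([], ("c", 0, 100))


class TestCallTe:
    def _result(self, inside, outside, **kw):
        placements = []
        windows = temap.BoundaryWindows(
            inside_left=("c", 1000, 1200), outside_left=("c", 800, 1000),
            inside_right=("c", 5000, 5200), outside_right=("c", 5200, 5400),
        )
        # synthesize coverage by placing reads across the needed fraction
        for frac, (w0, w1) in zip(
            [inside[0], outside[0], inside[1], outside[1]],
            [(1000, 1200), (800, 1000), (5000, 5200), (5200, 5400)],
        ):
            n = round(frac * 200)
            if n:
                placements.append(_placement("c", w0, w0 + n))
        return temap.call_te("acc", placements, windows, **kw)

    def test_present_rule(self):
        r = self._result(inside=(0.9, 0.95), outside=(0.9, 0.9))
        assert r.status == "present"

    def test_absent_rule(self):
        r = self._result(inside=(0.05, 0.1), outside=(0.9, 0.85))
        assert r.status == "absent"

    def test_between_rules_is_no_call(self):
        r = self._result(inside=(0.5, 0.5), outside=(0.9, 0.9))
        assert r.status == "no_call"

    def test_thresholds_are_strict(self):
        # breadth exactly 0.80 outside fails the > 0.80 requirement
        r = self._result(inside=(0.9, 0.9), outside=(0.8, 0.8))
        assert r.status == "no_call"

    def test_one_bad_edge_with_both_edges_required(self):
        r = self._result(inside=(0.9, 0.1), outside=(0.9, 0.9))
        assert r.status == "no_call"

    def test_either_edge_flag_relaxes(self):
        r = self._result(inside=(0.9, 0.5), outside=(0.9, 0.5), both_edges=False)
        assert r.status == "present"


class TestFlankContinuity:
    def test_te_free_accession_on_own_reference_is_seamless(self, spec):
        """Mapping a TE-free accession on a TE-free reference covers the
        would-be insertion point continuously (the divergent-flank
        fallback path)."""
        reference = synthio.build_reference(spec)
        prof = synthio.AccessionProfile("a", te_present=False)
        genome, _ = synthio.make_accession_genome(reference, prof)
        # the accession's own genome doubles as the alternative reference
        index = temap.KmerIndex(genome, k=31)
        reads = synthio.simulate_reads(
            genome, synthio.ReadSimParams(depth=20, error_rate=0.0, seed=8)
        )
        placements, _ = temap.place_reads(reads, index)
        covered, fraction, seamless = temap.flank_continuity(
            placements, spec.rae1_chrom, spec.te_site
        )
        assert seamless and fraction > 0.9

    def test_gap_in_coverage_is_not_seamless(self):
        placements = [_placement("c", 0, 1000), _placement("c", 1300, 2000)]
        covered, fraction, seamless = temap.flank_continuity(placements, "c", 1001)
        assert not seamless
        assert covered == 200 and fraction == 0.5


class TestEndToEnd:
    def test_te_edge_repeat_does_not_flip_absent_call(self, spec):
        """Planting the TE's edge sequence at a second locus makes edge
        reads multi-mapped; a truth-absent accession must stay absent
        (not drift toward present via mismapped coverage)."""
        reference = synthio.build_reference(spec)
        edge = spec.te_sequence[:400]
        seqs = dict(reference.sequences)
        seqs["chr8"] = seqs["chr8"][:3000] + edge + seqs["chr8"][3400:]
        planted = synthio.Reference(spec=spec, sequences=seqs,
                                    genes=reference.genes)
        index = temap.KmerIndex(planted.sequences, k=31)
        windows = temap.boundary_windows(spec.rae1_chrom, spec.te_site,
                                         spec.te_length)
        prof = synthio.AccessionProfile("a", te_present=False)
        genome, _ = synthio.make_accession_genome(planted, prof)
        reads = synthio.simulate_reads(
            genome, synthio.ReadSimParams(depth=20, error_rate=0.0, seed=13)
        )
        result = temap.call_te_from_reads("a", reads, index, windows)
        assert result.status == "absent"

    def test_removing_te_shrinks_inside_breadth(self, spec, reference, index,
                                                windows):
        """Deterministic zero-error check: deleting the TE drops inside
        breadth from saturated to (near) zero.  Reads whose tail crosses
        the deletion junction by no more than the mismatch budget still
        place, so a few base pairs of junction slop are tolerated."""
        results = {}
        for te_present in (True, False):
            prof = synthio.AccessionProfile("a", te_present=te_present)
            genome, _ = synthio.make_accession_genome(reference, prof)
            reads = synthio.simulate_reads(
                genome, synthio.ReadSimParams(depth=20, error_rate=0.0, seed=3)
            )
            results[te_present] = temap.call_te_from_reads("a", reads, index,
                                                           windows)
        present, absent = results[True], results[False]
        for side in ("inside_left", "inside_right"):
            assert getattr(absent, f"breadth_{side}") <= 0.1
            assert (
                getattr(absent, f"breadth_{side}")
                <= getattr(present, f"breadth_{side}")
            )
        assert absent.status == "absent" and present.status == "present"
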