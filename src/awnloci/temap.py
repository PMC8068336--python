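"""Presence/absence calling of the promoter TE insertion from short-read
breadth of coverage over its boundary windows.

Reads are placed on a TE-containing reference (or ingested from SAM),
multi-mapped reads are excluded, breadth of coverage is computed over the
four 200-bp windows flanking the two TE/flank junctions, and the
insertion is called by the 80%/20% breadth rules:

* ``present``  — breadth > 0.80 inside the TE and > 0.80 outside, at
  both boundaries;
* ``absent``   — breadth < 0.20 inside and > 0.80 outside, at both
  boundaries;
* ``no_call``  — anything in between.

Both thresholds are strict inequalities.  A ``both_edges=False`` flag
relaxes the rule to a single passing edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

WINDOW_LEN = 200


@dataclass(frozen=True)
class ReadPlacement:
    """One read's best placement.  ``n_best_hits > 1`` marks the read
    multi-mapped; such reads contribute to no window."""

    read_id: str
    chromosome: str
    start: int   # 0-based
    end: int     # half-open
    n_best_hits: int = 1
    mismatches: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("placement start must be < end")
        if self.n_best_hits < 1:
            raise ValueError("n_best_hits must be >= 1")

    @property
    def excluded(self) -> bool:
        return self.n_best_hits > 1


@dataclass(frozen=True)
class BoundaryWindows:
    """The four 200-bp breadth windows around the TE insertion, as
    (chromosome, start0, end0) half-open intervals."""

    inside_left: tuple
    outside_left: tuple
    inside_right: tuple
    outside_right: tuple

    def __post_init__(self):
        for name in ("inside_left", "outside_left", "inside_right", "outside_right"):
            chrom, s, e = getattr(self, name)
            if e - s != WINDOW_LEN:
                raise ValueError(f"window {name} is not {WINDOW_LEN} bp")

    def items(self):
        return [
            ("inside_left", self.inside_left),
            ("outside_left", self.outside_left),
            ("inside_right", self.inside_right),
            ("outside_right", self.outside_right),
        ]


def boundary_windows(chromosome: str, te_site: int, te_length: int) -> BoundaryWindows:
    """Windows for a TE whose first base sits at 1-based ``te_site``.

    In 1-based inclusive coordinates: inside-left [s, s+199], outside-left
    [s-200, s-1], inside-right [e-199, e], outside-right [e+1, e+200]
    with e = s + te_length - 1.
    """
    s0 = te_site - 1
    e0 = s0 + te_length
    if s0 - WINDOW_LEN < 0:
        raise ValueError("TE too close to the chromosome start for flank windows")
    if te_length < WINDOW_LEN:
        raise ValueError("TE shorter than one boundary window")
    return BoundaryWindows(
        inside_left=(chromosome, s0, s0 + WINDOW_LEN),
        outside_left=(chromosome, s0 - WINDOW_LEN, s0),
        inside_right=(chromosome, e0 - WINDOW_LEN, e0),
        outside_right=(chromosome, e0, e0 + WINDOW_LEN),
    )


@dataclass(frozen=True)
class TECallResult:
    """Per-accession breadth fractions and the present/absent/no-call
    verdict.  ``covered_bp`` maps window name -> covered positions."""

    accession_id: str
    breadth_inside_left: float
    breadth_outside_left: float
    breadth_inside_right: float
    breadth_outside_right: float
    status: str
    covered_bp: dict


# ---------------------------------------------------------------------------
# k-mer index and read placement


class KmerIndex:
    """Exact k-mer lookup over a set of chromosomes.

    Positions are per-chromosome and 0-based; k-mers never span
    chromosome boundaries.
    """

    def __init__(self, sequences: dict, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        if all(len(s) < k for s in sequences.values()):
            raise ValueError("k larger than every chromosome")
        self.k = k
        self.arrays = {
            c: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for c, s in sequences.items()
        }
        self.lengths = {c: len(s) for c, s in sequences.items()}
        index: dict = {}
        for chrom, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self._index = index

    def lookup(self, kmer: str) -> list:
        """All (chromosome, position) occurrences of a k-mer."""
        return self._index.get(kmer, [])


def place_read(read_seq: str, index: KmerIndex, max_mismatch: int = 5,
               read_id: str = "read") -> ReadPlacement | None:
    """Place one read by k-mer seeding plus full-length verification.

    Candidate loci are seeded from three k-mers (both ends and the
    middle of the read); each candidate is verified by Hamming
    comparison allowing up to ``max_mismatch`` substitutions.  All loci
    tied at the minimal mismatch count are counted in ``n_best_hits``;
    more than one best hit marks the read multi-mapped (excluded).
    Returns ``None`` when the read is unplaceable or shorter than k.
    """
    k = index.k
    rl = len(read_seq)
    if rl < k:
        return None
    offsets = sorted({0, (rl - k) // 2, rl - k})
    candidates = set()
    for off in offsets:
        for chrom, pos in index.lookup(read_seq[off : off + k]):
            start = pos - off
            if 0 <= start and start + rl <= index.lengths[chrom]:
                candidates.add((chrom, start))
    if not candidates:
        return None

    read_arr = np.frombuffer(read_seq.encode("ascii"), dtype=np.uint8)
    best, best_mm = [], max_mismatch + 1
    for chrom, start in candidates:
        mm = int(np.count_nonzero(index.arrays[chrom][start : start + rl] != read_arr))
        if mm < best_mm:
            best, best_mm = [(chrom, start)], mm
        elif mm == best_mm:
            best.append((chrom, start))
    if best_mm > max_mismatch:
        return None
    chrom, start = best[0]
    return ReadPlacement(
        read_id=read_id, chromosome=chrom, start=start, end=start + rl,
        n_best_hits=len(best), mismatches=best_mm,
    )


def place_reads(reads, index: KmerIndex, max_mismatch: int = 5):
    """Place many reads; returns (placements, n_skipped_short).

    ``reads`` yields objects with ``read_id`` and ``sequence`` attributes
    (or ``(read_id, sequence)`` pairs).  Unplaceable reads are dropped;
    reads shorter than k are counted separately.
    """
    placements = []
    skipped = 0
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "sequence") else r
        if len(seq) < index.k:
            skipped += 1
            continue
        p = place_read(seq, index, max_mismatch=max_mismatch, read_id=rid)
        if p is not None:
            placements.append(p)
    return placements, skipped


# ---------------------------------------------------------------------------
# SAM ingestion (alternative entry point)


def ingest_sam(path) -> list:
    """Read placements from a SAM file.

    Secondary/supplementary records and MAPQ-0 records are marked
    multi-mapped (``n_best_hits = 2``); unmapped records are dropped.
    """
    import os

    placements = []
    if os.path.getsize(path) == 0:
        return placements
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for i, rec in enumerate(sam, 1):
                try:
                    if rec.is_unmapped:
                        continue
                    multi = rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0
                    end = rec.reference_end
                    if end is None or end <= rec.reference_start:
                        continue
                    placements.append(
                        ReadPlacement(
                            read_id=rec.query_name,
                            chromosome=rec.reference_name,
                            start=rec.reference_start,
                            end=end,
                            n_best_hits=2 if multi else 1,
                            mismatches=0,
                        )
                    )
                except (ValueError, TypeError) as exc:
                    raise ValueError(f"malformed SAM record {i} in {path}: {exc}") from exc
    except OSError as exc:
        raise ValueError(f"cannot parse SAM file {path}: {exc}") from exc
    return placements


# ---------------------------------------------------------------------------
# Breadth and calling


def breadth(placements, window: tuple) -> tuple:
    """Breadth of coverage of a 200-bp window by uniquely placed reads.

    Returns ``(covered_bp, fraction)`` where ``covered_bp`` is the number
    of window positions overlapped by at least one non-excluded
    placement.
    """
    chrom, w0, w1 = window
    if w1 - w0 != WINDOW_LEN:
        raise ValueError(f"window length must be {WINDOW_LEN}")
    mask = np.zeros(WINDOW_LEN, dtype=bool)
    for p in placements:
        if p.excluded or p.chromosome != chrom:
            continue
        lo = max(p.start, w0)
        hi = min(p.end, w1)
        if lo < hi:
            mask[lo - w0 : hi - w0] = True
    covered = int(mask.sum())
    return covered, covered / WINDOW_LEN


def call_te(accession_id: str, placements, windows: BoundaryWindows,
            present_threshold: float = 0.80, absent_threshold: float = 0.20,
            both_edges: bool = True) -> TECallResult:
    """Apply the breadth rules to the four boundary windows.

    ``present``: inside breadth > present_threshold and outside breadth
    > present_threshold; ``absent``: inside breadth < absent_threshold
    and outside breadth > present_threshold; otherwise ``no_call``.
    With ``both_edges`` (default) the rule must hold at both TE edges;
    otherwise one passing edge suffices.
    """
    covered = {}
    frac = {}
    for name, window in windows.items():
        covered[name], frac[name] = breadth(placements, window)
        if not 0.0 <= frac[name] <= 1.0:
            raise RuntimeError(f"breadth {frac[name]} outside [0, 1]")

    def edge_status(inside, outside):
        if frac[inside] > present_threshold and frac[outside] > present_threshold:
            return "present"
        if frac[inside] < absent_threshold and frac[outside] > present_threshold:
            return "absent"
        return "no_call"

    left = edge_status("inside_left", "outside_left")
    right = edge_status("inside_right", "outside_right")
    if both_edges:
        status = left if left == right else "no_call"
    else:
        status = next((s for s in (left, right) if s != "no_call"), "no_call")

    return TECallResult(
        accession_id=accession_id,
        breadth_inside_left=frac["inside_left"],
        breadth_outside_left=frac["outside_left"],
        breadth_inside_right=frac["inside_right"],
        breadth_outside_right=frac["outside_right"],
        status=status,
        covered_bp=covered,
    )


def flank_continuity(placements, chromosome: str, junction_site: int,
                     threshold: float = 0.80) -> tuple:
    """Seamless-coverage check against a TE-free alternative reference.

    For taxa whose flanking sequence diverges too much to map against
    the TE-containing reference, reads are instead placed on the taxon's
    own (TE-free) genome and the insertion point is interrogated
    directly: if the 400 bp centred on the 1-based ``junction_site`` are
    covered above ``threshold`` the flank is seamless, i.e. there is no
    insertion at that site.  Returns ``(covered_bp, fraction, seamless)``.
    """
    j0 = junction_site - 1
    left = breadth(placements, (chromosome, j0 - WINDOW_LEN, j0))
    right = breadth(placements, (chromosome, j0, j0 + WINDOW_LEN))
    covered = left[0] + right[0]
    fraction = covered / (2 * WINDOW_LEN)
    seamless = left[1] > threshold and right[1] > threshold
    return covered, fraction, seamless


def call_te_from_reads(accession_id: str, reads, index: KmerIndex,
                       windows: BoundaryWindows, max_mismatch: int = 5,
                       present_threshold: float = 0.80,
                       absent_threshold: float = 0.20) -> TECallResult:
    """Convenience pipeline: place reads, then call the TE status."""
    placements, _ = place_reads(reads, index, max_mismatch=max_mismatch)
    return call_te(accession_id, placements, windows,
                   present_threshold=present_threshold,
                   absent_threshold=absent_threshold)
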