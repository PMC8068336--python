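"""Seeded generation of every input the awn-genetics pipeline consumes.

The generator emulates the statistical structure the downstream analysis
assumes: accession genomes that differ from a TE-containing reference by
the presence/absence of a ~4.4-kb promoter transposable element and by
small diagnostic indels in two awn genes (RAE1, a bHLH transcription
factor, and RAE2, an EPFL-family small secreted peptide); short
single-end reads at configurable depth and substitution-error rate; and
chromosome-segment substitution line (CSSL) panels with donor segments,
causal awn loci, and multi-year awn phenotypes.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._config import load_fixture_config
from ._seq import apply_anchored_variants, apply_edit, random_nucleotides, translate

RAE2_EDIT_LABELS = {
    "del6": "hap2",
    "del1": "hap3",
    "del2a": "hap4",
    "del2b": "hap5",
    "ins1": "hap6",
}

#: expected mature-peptide cysteine counts per RAE2 haplotype edit
RAE2_CYS_CLASSES = {None: 6, "hap2": 6, "hap3": 4, "hap4": 7, "hap5": 7, "hap6": 7}


# ---------------------------------------------------------------------------
# CDS fixtures


@dataclass(frozen=True)
class CdsFixture:
    """A coding sequence plus its haplotype-defining edits.

    ``cds_sequence`` starts with ATG, has length divisible by 3, and ends
    with a stop codon.  ``mature_start`` is the 1-based amino-acid index
    where the mature peptide begins (1 for proteins without a cleaved
    signal peptide).  ``hap_edit_positions`` maps a haplotype label to an
    ``(op, pos, arg)`` edit in 1-based CDS coordinates, with ``op`` either
    ``del`` (``arg`` = deleted length) or ``ins`` (``arg`` = inserted
    bases).  ``cys_classes``, when given, asserts the mature cysteine
    count of the unedited CDS (key ``None``) and of each edited allele at
    construction time.
    """

    cds_sequence: str
    mature_start: int = 1
    hap_edit_positions: dict = field(default_factory=dict)
    cys_classes: dict | None = None

    def __post_init__(self):
        cds = self.cds_sequence
        if len(cds) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if cds[-3:] not in ("TAA", "TAG", "TGA"):
            raise ValueError("CDS does not end with a stop codon")
        if self.cys_classes is not None:
            for label, expected in self.cys_classes.items():
                got = self.mature_cys_count(label)
                if got != expected:
                    raise ValueError(
                        f"fixture self-check failed: edit {label!r} yields "
                        f"{got} mature cysteines, expected {expected}"
                    )

    def edited_cds(self, label: str | None) -> str:
        """The CDS with one haplotype edit applied (``None`` = unedited)."""
        if label is None:
            return self.cds_sequence
        op, pos, arg = self.hap_edit_positions[label]
        return apply_edit(self.cds_sequence, op, pos, arg)

    def mature_cys_count(self, label: str | None = None) -> int:
        peptide = translate(self.edited_cds(label))
        return sum(
            1 for i, aa in enumerate(peptide, 1) if aa == "C" and i >= self.mature_start
        )


def _fixture_from_config(section: dict, cys_classes: dict | None) -> CdsFixture:
    edits = {}
    for label, e in section.get("edits", {}).items():
        arg = e["length"] if e["op"] == "del" else e["bases"]
        edits[label] = (e["op"], e["pos"], arg)
    return CdsFixture(
        cds_sequence=section["cds"],
        mature_start=section["mature_start"],
        hap_edit_positions=edits,
        cys_classes=cys_classes,
    )


def rae2_fixture() -> CdsFixture:
    """The packaged RAE2 (EPFL-like) fixture; validates its 6C/4C/7C classes."""
    return _fixture_from_config(load_fixture_config()["rae2"], RAE2_CYS_CLASSES)


def rae1_fixture() -> CdsFixture:
    """The packaged RAE1 (bHLH-like) fixture with the exon-2 1-bp deletion."""
    return _fixture_from_config(load_fixture_config()["rae1"], None)


# ---------------------------------------------------------------------------
# Genome spec


@dataclass
class SyntheticGenomeSpec:
    """Blueprint for a synthetic reference genome and its simulated panels.

    ``chrom_lengths`` are backbone lengths before TE insertion; the
    RAE1-carrying chromosome (``rae1_chrom``) gains ``len(te_sequence)``
    bases in the built reference.  ``te_site`` is the 1-based coordinate
    of the first TE base on the built (TE-containing) reference.
    ``marker_map`` is an ordered list of ``(name, chromosome, 1-based
    position)``; ``causal_loci`` is a list of ``(chromosome, (start, end),
    penetrance)`` with 1-based inclusive intervals.
    """

    chrom_lengths: dict
    te_sequence: str
    te_site: int
    rae1_cds_model: CdsFixture
    rae2_cds_model: CdsFixture
    marker_map: list = field(default_factory=list)
    causal_loci: list = field(default_factory=list)
    seed: int = 0
    rae1_chrom: str = "chr4"
    rae2_chrom: str = "chr8"
    rae1_start: int | None = None  # 1-based CDS start on the built reference
    rae2_start: int | None = None

    def __post_init__(self):
        if self.rae1_chrom not in self.chrom_lengths:
            raise ValueError(f"{self.rae1_chrom} missing from chrom_lengths")
        if not 1 <= self.te_site <= self.chrom_lengths[self.rae1_chrom]:
            raise ValueError(f"te_site {self.te_site} outside {self.rae1_chrom}")
        if self.rae1_start is None:
            # promoter TE sits 500 bp upstream of the gene
            self.rae1_start = self.te_site + len(self.te_sequence) + 500
        if self.rae2_start is None:
            self.rae2_start = self.chrom_lengths[self.rae2_chrom] // 2
        last: dict = {}
        for name, chrom, pos in self.marker_map:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"marker {name} on unknown chromosome {chrom}")
            if chrom in last and pos <= last[chrom]:
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
            last[chrom] = pos
        for chrom, _interval, penetrance in self.causal_loci:
            if not 0.0 <= penetrance <= 1.0:
                raise ValueError(f"penetrance {penetrance} outside [0, 1]")
            if chrom not in self.chrom_lengths:
                raise ValueError(f"causal locus on unknown chromosome {chrom}")

    @property
    def te_length(self) -> int:
        return len(self.te_sequence)


def default_spec(seed: int = 0, chr4_len: int = 20_000, chr8_len: int = 12_000,
                 te_site: int = 8_000, te_length: int = 4_400) -> SyntheticGenomeSpec:
    """A compact two-chromosome spec for read-level simulations.

    The RAE1 chromosome carries the TE in the gene's promoter; the RAE2
    gene sits mid-way along the second chromosome.  Markers are placed
    every 2 kb and the RAE1 gene interval is the single causal awn locus.
    """
    # distinct stream from the backbone generator so the TE is not a
    # copy of chromosome sequence
    rng = np.random.default_rng([seed, 1])
    te_seq = random_nucleotides(te_length, rng)
    markers = []
    i = 1
    for chrom, length in (("chr4", chr4_len + te_length), ("chr8", chr8_len)):
        for pos in range(1_000, length, 2_000):
            markers.append((f"M{i:03d}", chrom, pos))
            i += 1
    rae1_start = te_site + te_length + 500
    causal = [("chr4", (rae1_start, rae1_start + 899), 1.0)]
    return SyntheticGenomeSpec(
        chrom_lengths={"chr4": chr4_len, "chr8": chr8_len},
        te_sequence=te_seq,
        te_site=te_site,
        rae1_cds_model=rae1_fixture(),
        rae2_cds_model=rae2_fixture(),
        marker_map=markers,
        causal_loci=causal,
        seed=seed,
    )


#: approximate rice chromosome lengths (bp), used by the RRESL-like panel
RICE_CHROM_LENGTHS = {
    "chr1": 43_000_000, "chr2": 36_000_000, "chr3": 36_000_000,
    "chr4": 35_000_000, "chr5": 30_000_000, "chr6": 31_000_000,
    "chr7": 30_000_000, "chr8": 28_000_000, "chr9": 23_000_000,
    "chr10": 23_000_000, "chr11": 29_000_000, "chr12": 27_000_000,
}


def rresl_like_spec(seed: int = 0, n_markers: int = 149,
                    causal_penetrance: float = 1.0) -> SyntheticGenomeSpec:
    """A genome-wide spec mimicking a 12-chromosome CSSL marker panel.

    149 SNP markers are spread across 12 rice-sized chromosomes at an
    average spacing of ~3.5 Mb.  The causal awn loci are placed at the
    markers nearest the catalogued RAE1 (chr4 ~16.7 Mb) and RAE2 (chr8
    ~24.0 Mb) positions.  Sequence-level fields use the compact defaults;
    this spec is intended for :func:`make_cssl_panel`, not for building
    multi-megabase FASTA.
    """
    total = sum(RICE_CHROM_LENGTHS.values())
    markers = []
    i = 1
    for chrom, length in RICE_CHROM_LENGTHS.items():
        k = max(2, round(n_markers * length / total))
        step = length // (k + 1)
        for j in range(1, k + 1):
            markers.append((f"S{i:03d}", chrom, j * step))
            i += 1

    def nearest_marker(chrom, pos):
        cands = [m for m in markers if m[1] == chrom]
        return min(cands, key=lambda m: abs(m[2] - pos))

    causal = []
    for chrom, pos in (("chr4", 16_735_371), ("chr8", 23_998_787)):
        _, _, mpos = nearest_marker(chrom, pos)
        causal.append((chrom, (mpos, mpos), causal_penetrance))

    base = default_spec(seed=seed)
    return SyntheticGenomeSpec(
        chrom_lengths=dict(RICE_CHROM_LENGTHS),
        te_sequence=base.te_sequence,
        te_site=16_735_371,
        rae1_cds_model=base.rae1_cds_model,
        rae2_cds_model=base.rae2_cds_model,
        marker_map=markers,
        causal_loci=causal,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reference building


@dataclass
class Reference:
    """A built TE-containing reference: sequences plus annotations."""

    spec: SyntheticGenomeSpec
    sequences: dict          # chromosome -> str
    genes: dict              # gene name -> (chromosome, start0, end0)

    @property
    def te_interval(self) -> tuple:
        """(chromosome, start0, end0) of the TE body."""
        s0 = self.spec.te_site - 1
        return (self.spec.rae1_chrom, s0, s0 + self.spec.te_length)

    def bed_records(self) -> list:
        """BED records (chrom, start0, end0, name) for TE body, the four
        200-bp boundary windows, both CDSs, and markers."""
        chrom, s0, e0 = self.te_interval
        recs = [
            (chrom, s0, e0, "te_body"),
            (chrom, s0, s0 + 200, "te_inside_left"),
            (chrom, s0 - 200, s0, "te_outside_left"),
            (chrom, e0 - 200, e0, "te_inside_right"),
            (chrom, e0, e0 + 200, "te_outside_right"),
        ]
        for name, (gchrom, g0, g1) in self.genes.items():
            recs.append((gchrom, g0, g1, f"{name}_cds"))
        for name, mchrom, pos in self.spec.marker_map:
            recs.append((mchrom, pos - 1, pos, name))
        return recs


# 50-mer repeats copied out of the TE interior exercise multi-map exclusion
_REPEAT_LEN = 50
_N_REPEATS = 3


def build_reference(spec: SyntheticGenomeSpec) -> Reference:
    """Build the TE-containing reference genome for a spec.

    The backbone of every chromosome is seeded uniform random sequence;
    the TE is inserted at ``te_site`` on the RAE1 chromosome, both gene
    CDSs are written in at their configured starts, and a few 50-mers
    from the TE interior are replicated elsewhere in the genome so that
    multi-mapping exclusion has something to chew on.
    """
    rng = np.random.default_rng([spec.seed, 0])
    seqs = {c: random_nucleotides(n, rng) for c, n in spec.chrom_lengths.items()}

    te = spec.te_sequence
    s0 = spec.te_site - 1
    chrom = spec.rae1_chrom
    if s0 > len(seqs[chrom]):
        raise ValueError(f"te_site {spec.te_site} beyond {chrom} backbone")
    seqs[chrom] = seqs[chrom][:s0] + te + seqs[chrom][s0:]

    def write_in(chrom, start1, payload):
        s = start1 - 1
        if s + len(payload) > len(seqs[chrom]):
            raise ValueError(f"feature at {chrom}:{start1} overruns chromosome")
        seqs[chrom] = seqs[chrom][:s] + payload + seqs[chrom][s + len(payload):]

    rae1 = spec.rae1_cds_model.cds_sequence
    rae2 = spec.rae2_cds_model.cds_sequence
    write_in(spec.rae1_chrom, spec.rae1_start, rae1)
    write_in(spec.rae2_chrom, spec.rae2_start, rae2)

    # replicate TE-interior 50-mers well away from the boundary windows
    interior = spec.te_length // 2
    other = [c for c in spec.chrom_lengths if c != chrom] or [chrom]
    for r in range(_N_REPEATS):
        mer = te[interior + r * _REPEAT_LEN : interior + (r + 1) * _REPEAT_LEN]
        dest = other[r % len(other)]
        write_in(dest, 1_000 + r * 500, mer)

    genes = {
        "rae1": (spec.rae1_chrom, spec.rae1_start - 1, spec.rae1_start - 1 + len(rae1)),
        "rae2": (spec.rae2_chrom, spec.rae2_start - 1, spec.rae2_start - 1 + len(rae2)),
    }
    return Reference(spec=spec, sequences=seqs, genes=genes)


# ---------------------------------------------------------------------------
# Accession genomes


@dataclass(frozen=True)
class AccessionProfile:
    """Ground-truth description of one simulated accession.

    ``rae2_edit`` is one of ``none``/``del6``/``del1``/``del2a``/``del2b``
    /``ins1``, mapping one-to-one onto RAE2-hap2..hap6 diagnostics.
    ``extra_snps`` holds neutral substitutions as ``(gene, cds_pos, alt)``.
    """

    accession_id: str
    species_label: str = "synthetic"
    te_present: bool = False
    rae1_exon2_del: bool = False
    rae2_edit: str = "none"
    extra_snps: tuple = ()

    def __post_init__(self):
        if self.rae2_edit != "none" and self.rae2_edit not in RAE2_EDIT_LABELS:
            raise ValueError(f"unknown rae2_edit {self.rae2_edit!r}")


def make_accession_genome(reference: Reference, profile: AccessionProfile):
    """Derive one accession genome from the reference plus its truth VCF.

    Returns ``(sequences, variants)`` where ``variants`` are anchored
    ``(chromosome, pos, ref, alt)`` records in 1-based reference
    coordinates; applying them to the reference reproduces the accession
    genome exactly.
    """
    spec = reference.spec
    per_chrom: dict = {c: [] for c in reference.sequences}

    if not profile.te_present:
        chrom, s0, e0 = reference.te_interval
        if s0 < 1:
            raise ValueError("te_site must be >= 2 for anchored deletion")
        anchor = reference.sequences[chrom][s0 - 1]
        ref = reference.sequences[chrom][s0 - 1 : e0]
        per_chrom[chrom].append((s0, ref, anchor))

    def gene_edit(gene: str, op: str, cds_pos: int, arg):
        chrom, g0, _ = reference.genes[gene]
        seq = reference.sequences[chrom]
        g = g0 + cds_pos  # 1-based genomic position of cds_pos
        if op == "del":
            length = int(arg)
            pos = g - 1
            per_chrom[chrom].append((pos, seq[pos - 1 : pos + length], seq[pos - 1]))
        elif op == "ins":
            pos = g - 1
            per_chrom[chrom].append((pos, seq[pos - 1], seq[pos - 1] + str(arg)))
        else:  # substitution
            per_chrom[chrom].append((g, seq[g - 1], str(arg)))

    if profile.rae1_exon2_del:
        op, pos, arg = spec.rae1_cds_model.hap_edit_positions["exon2_del"]
        gene_edit("rae1", op, pos, arg)
    if profile.rae2_edit != "none":
        hap = RAE2_EDIT_LABELS[profile.rae2_edit]
        op, pos, arg = spec.rae2_cds_model.hap_edit_positions[hap]
        gene_edit("rae2", op, pos, arg)
    for gene, cds_pos, alt in profile.extra_snps:
        gene_edit(gene, "snp", cds_pos, alt)

    seqs = {}
    variants = []
    for chrom, chrom_vars in per_chrom.items():
        seqs[chrom] = apply_anchored_variants(reference.sequences[chrom], chrom_vars)
        variants.extend((chrom, p, r, a) for p, r, a in sorted(chrom_vars))
    return seqs, variants


def apply_truth_vcf(reference: Reference, variants) -> dict:
    """Apply truth variants back onto the reference (round-trip check)."""
    per_chrom: dict = {c: [] for c in reference.sequences}
    for chrom, pos, ref, alt in variants:
        per_chrom[chrom].append((pos, ref, alt))
    return {
        c: apply_anchored_variants(reference.sequences[c], vs)
        for c, vs in per_chrom.items()
    }


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadSimParams:
    """Single-end read-simulation knobs: length, mean fold-coverage,
    per-base substitution error rate, and RNG seed."""

    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 0.2:
            raise ValueError("error_rate must be in [0, 0.2)")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    chromosome: str
    start: int  # 0-based truth start on the source genome
    sequence: str


_BASES = "ACGT"


def simulate_reads(genome: dict, params: ReadSimParams) -> list:
    """Uniform single-end reads over a genome (dict chromosome -> str).

    Read count is ``round(depth * genome_length / read_length)``; start
    positions are uniform over valid windows, chromosomes weighted by
    length; substitution errors are introduced at ``error_rate`` per base.
    """
    rl = params.read_length
    chroms = [c for c in genome if len(genome[c]) >= rl]
    if not chroms:
        raise ValueError("read_length exceeds every chromosome length")
    total = sum(len(genome[c]) for c in genome)
    n_reads = round(params.depth * total / rl)
    rng = np.random.default_rng(params.seed)

    weights = np.array([len(genome[c]) - rl + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=weights)

    reads = []
    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        start = int(rng.integers(0, len(genome[chrom]) - rl + 1))
        seq = genome[chrom][start : start + rl]
        n_err = rng.binomial(rl, params.error_rate)
        if n_err:
            seq_l = list(seq)
            for p in rng.choice(rl, size=n_err, replace=False):
                cur = seq_l[p]
                seq_l[p] = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4]
            seq = "".join(seq_l)
        reads.append(SimRead(f"r{i:06d}", chrom, start, seq))
    return reads


# ---------------------------------------------------------------------------
# CSSL panel simulation


@dataclass
class CsslPanel:
    """A simulated CSSL panel: marker genotypes, phenotypes, and truth."""

    genotypes: pd.DataFrame      # line, marker, chromosome, position, call
    phenotypes: pd.DataFrame     # line, year, awned_spikelets, total_spikelets,
                                 # mean_awn_length_mm
    truth_segments: pd.DataFrame  # line, chromosome, start, end, carries_causal


def make_cssl_panel(spec: SyntheticGenomeSpec, n_lines: int, seed: int,
                    n_years: int = 3, false_positive_rate: float = 0.0) -> CsslPanel:
    """Simulate a CSSL panel whose donor segments tile the marker map.

    Each line carries one contiguous block of donor-type markers (split
    into at most two segments where the block straddles a chromosome
    boundary); consecutive lines overlap so that most positions are
    covered by at least two lines.  A line is awned in a given year with
    probability equal to the causal locus penetrance if any of its donor
    segments overlaps a causal locus, else ``false_positive_rate``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    markers = list(spec.marker_map)
    if not markers:
        raise ValueError("spec has an empty marker map")
    rng = np.random.default_rng(seed)
    m = len(markers)

    w = max(2, math.ceil(1.5 * m / n_lines))
    if n_lines == 1:
        starts = [0]
    else:
        step = (m - w) / (n_lines - 1)
        starts = [round(i * step) for i in range(n_lines)]

    geno_rows, seg_rows, pheno_rows = [], [], []
    for li, s in enumerate(starts):
        line = f"L{li + 1:03d}"
        window = set(range(s, min(s + w, m)))
        for mi, (name, chrom, pos) in enumerate(markers):
            call = "D" if mi in window else "R"
            geno_rows.append((line, name, chrom, pos, call))

        # donor segments = runs of donor markers per chromosome
        segs = []
        donor = sorted(window)
        run = [donor[0]]
        for a, b in zip(donor, donor[1:]):
            if b == a + 1 and markers[b][1] == markers[a][1]:
                run.append(b)
            else:
                segs.append(run)
                run = [b]
        segs.append(run)
        carries = False
        line_ivals = []
        for run in segs:
            chrom = markers[run[0]][1]
            start, end = markers[run[0]][2], markers[run[-1]][2]
            line_ivals.append((chrom, start, end))
            for c_chrom, (c_lo, c_hi), _pen in spec.causal_loci:
                if chrom == c_chrom and start <= c_hi and end >= c_lo:
                    carries = True
        penetrances = [
            pen
            for c_chrom, (c_lo, c_hi), pen in spec.causal_loci
            for chrom, start, end in line_ivals
            if chrom == c_chrom and start <= c_hi and end >= c_lo
        ]
        p_awned = max(penetrances) if carries else false_positive_rate
        for chrom, start, end in line_ivals:
            seg_rows.append((line, chrom, start, end, carries))

        for year in range(1, n_years + 1):
            total = int(rng.integers(80, 151))
            if rng.random() < p_awned:
                ratio = rng.uniform(0.07, 1.0)
                awned = max(1, round(ratio * total))
                length = float(rng.uniform(5.0, 60.0))
            else:
                awned = 0
                length = float(rng.uniform(0.0, 1.5))
            pheno_rows.append((line, year, awned, total, round(length, 1)))

    return CsslPanel(
        genotypes=pd.DataFrame(
            geno_rows, columns=["line", "marker", "chromosome", "position", "call"]
        ),
        phenotypes=pd.DataFrame(
            pheno_rows,
            columns=["line", "year", "awned_spikelets", "total_spikelets",
                     "mean_awn_length_mm"],
        ),
        truth_segments=pd.DataFrame(
            seg_rows, columns=["line", "chromosome", "start", "end", "carries_causal"]
        ),
    )


# ---------------------------------------------------------------------------
# File writers (plain-text formats)


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} {r.chromosome}:{r.start}\n{r.sequence}\n+\n")
            fh.write("I" * len(r.sequence) + "\n")


def write_truth_vcf(variants, path, contigs: dict) -> None:
    """Write anchored truth variants as minimal VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=awnloci-synthio\n')
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in variants:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for chrom, start0, end0, name in records:
            fh.write(f"{chrom}\t{start0}\t{end0}\t{name}\n")
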