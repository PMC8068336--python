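# Methods

## The TE presence/absence model

The promoter insertion is a ~4.4-kb transposable element whose internal
sequence occurs at multiple genomic locations, so its presence at the
RAE1 promoter cannot be read from depth alone. The caller instead
scores *breadth* of coverage — the fraction of positions covered by at
least one uniquely placed read — in four 200-bp windows anchored at the
two TE/flank junctions of a TE-containing reference: inside-left
`[s, s+199]`, outside-left `[s−200, s−1]`, inside-right `[e−199, e]`,
outside-right `[e+1, e+200]` (1-based inclusive; `s` and `e` the first
and last TE base). A TE-carrying accession covers all four windows; a
TE-free accession covers the outside windows but leaves the inside
windows empty, because junction-spanning reads cannot align
contiguously.

Call rules, with strict inequalities: *present* when all four breadths
exceed 0.80; *absent* when both inside breadths are below 0.20 and both
outside breadths exceed 0.80; otherwise *no call*. The 0.80/0.20
thresholds are the documented operating points of this assay and both
boundaries must agree by default (`both_edges=False` relaxes to a
single passing edge, for truncated or partially assembled references).
Breadth values strictly between the two rules deliberately fall through
to *no call* rather than being forced into a class.

For taxa whose flanking sequence has diverged too far to map against
the TE-containing reference at all, `flank_continuity()` implements the
fallback: map reads to the taxon's own (TE-free) genome and test
whether the 400 bp centred on the insertion point are covered
seamlessly, which rules out an insertion at that site.

### Read placement

Placement is substitution-only seed-and-verify: three k-mers (both read
ends and the middle, default k = 31) propose candidate loci from an
exact-match index; each candidate is verified by full-length Hamming
comparison with a mismatch budget (default 5 per 100-bp read). All loci
tied at the minimal mismatch count accrue to `n_best_hits`; any tie
(`n_best_hits > 1`) excludes the read from every window, which is what
protects the inside windows from reads originating at other copies of
the TE sequence. Reads may also arrive as SAM, where
secondary/supplementary flags or MAPQ 0 mark multi-mapping. Gapped
alignment and indel realignment are out of scope: the decision variable
is breadth, which is insensitive to small indels at 200-bp scale.

One consequence of the mismatch budget is *junction slop*: in a TE-free
accession, a read whose last ≤5 bases cross the deletion junction still
places on the reference and covers a few inside-window positions.
Inside breadth for a true absence is therefore near zero but not
exactly zero (≲5% in practice), comfortably below the 20% absence
threshold; tests assert the bound rather than exact zero.

## Haplotype and group classification

RAE1 haplotypes are the 2×2 of promoter-TE status and the exon-2 1-bp
deletion: hap1 (neither; the functional allele), hap2 (deletion only),
hap3 (TE only), hap4 (both). A *no call* TE status propagates to an
unresolved haplotype and group rather than guessing.

RAE2 haplotypes are keyed on five diagnostic second-exon indels: hap2 a
6-bp (in-frame) deletion, hap3 a 1-bp deletion, hap4 and hap5 two
distinct 2-bp deletions, hap6 a 1-bp insertion; hap1 has none of them.
Variants are normalized from anchored VCF-style representation to
(kind, first-affected-position, length) before matching. An indel that
frameshifts but matches no configured diagnostic yields *unresolved*; a
heterozygous diagnostic site warns and yields *unresolved* (the panel
species are inbred, so heterozygosity indicates a data problem rather
than a genotype).

Functionality is decided mechanistically, not by lookup: the allele's
CDS is reconstructed (variants applied right-to-left so coordinates
stay valid), translated with the standard code halting at the first
stop, and the cysteines at or after the mature-peptide start counted.
RAE2 is functional iff the count is exactly 6 — equivalent to
hap1/hap2, and the code asserts that equivalence on every call. Groups
are the four combinations of the two functional flags (I both, II RAE1
only, III RAE2 only, IV neither). Percentages are rounded half-up to
one decimal; exact counts are always emitted alongside, since rounded
percentages alone are not recoverable.

Diagnostic indel coordinates are configuration
(`data/fixtures.yaml`), packaged to match the synthetic fixtures and
overridable for real data, because the analysis depends only on which
indel is which, not on its absolute position.

## The synthetic fixtures

The packaged RAE2 fixture is a 228-nt synthetic EPFL-like CDS (75
residues + stop, mature peptide from residue 6) engineered so each
haplotype edit reproduces its documented cysteine class: 6C unedited
and under the hap2 in-frame deletion; 4C under hap3, whose frameshift's
premature stop falls between the 4th and 5th cysteine codons,
destroying cysteines 5 and 6; 7C under hap4/hap5/hap6, whose
frameshifts start after the 6th cysteine and read exactly one
frame-shifted cysteine before the new stop. These invariants are
asserted at fixture construction, so a corrupted fixture cannot load.
The RAE1 fixture is a 900-nt synthetic bHLH-like CDS carrying the
reference G at CDS position 780; deleting it frameshifts the tail into
a premature stop.

## What the generator emulates — and what it does not

`synthio` generates uniform-random chromosome backbones with the TE
inserted at the promoter site, both CDS fixtures written in at fixed
coordinates, and three TE-interior 50-mers replicated elsewhere so that
multi-map exclusion is exercised. Accession genomes apply the profile's
edits; their truth VCFs round-trip exactly onto the reference. Reads
are single-end, uniformly positioned, with i.i.d. substitution errors
(default 100 bp, 20× depth, 1% error — the read-level study
conditions). CSSL panels tile the marker map with overlapping donor
blocks (one block per line, split in two where it straddles a
chromosome boundary); a carrier line is awned each year with
probability equal to the causal locus penetrance (default 1.0), with
awned-spikelet ratios drawn from the observed 7–100% range and awn
lengths 5–60 mm versus 0–1.5 mm for awnless years.

Deliberately not modeled: quality-score profiles, indel sequencing
errors, paired ends, GC/coverage bias, real repeat families beyond the
planted copies, linkage disequilibrium, and population structure.
Passing tests therefore demonstrate the correctness of the decision
rules and their robustness to substitution noise and planted repeats —
not performance on real library artifacts, which is governed upstream
by the aligner and QC.

Default problem sizes are deliberately compact — a 20-kb TE chromosome
and a 12-kb second chromosome (~36 kb of genome, ~7,000 reads per
accession at 20×) — because every decision in the caller is local to
200-bp windows, so nothing is learned from longer chromosomes. The
CSSL spec mirrors a real panel's shape instead: 12 rice-sized
chromosomes, 149 markers at ~3.5-Mb spacing, 35 lines, causal loci
snapped to the markers nearest the catalogued RAE1 (chr4 ~16.7 Mb) and
RAE2 (chr8 ~24.0 Mb) positions.

## CSSL mapping choices

Segment boundaries use a conservative core/uncertainty representation:
the core ends at the outermost same-call marker and the recombination
breakpoint is only known to lie in the flanking inter-marker gap, which
is carried explicitly rather than collapsed to a midpoint. Missing
marker calls are bridged and counted; a chromosome with no usable call
is reported untyped.

"Awned" requires at least two qualifying years (length > 3 mm, awned
spikelets present) because the phenotype is labile year to year and
several panels were scored in only two seasons; the threshold is
configurable. Candidate loci are built by interval intersection with a
support threshold: maximal regions covered by ≥ `min_support` donor
cores of awned lines (default 2; heterozygous segments excluded by
default). Non-awned lines whose donor segments overlap a locus are
reported as conflicts, never subtracted — a non-penetrant carrier, or a
line whose segment misses the gene within the shared interval, must
not erase a true locus. The union-of-supporting-segments alternative
to intersection is available by dropping `min_support` to 1.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive in user-facing text and VCF, 0-based
half-open internally and in BED. Indels use anchored VCF
representation. Translation rejects non-ATG starts and ambiguity codes
and ignores a trailing partial codon. An awned-spikelet ratio with zero
total spikelets is reported missing (NaN), not an error. Percentage
rounding is half-up (not banker's) to one decimal. All generators
accept explicit seeds and are deterministic given them; derived seeds
stay below 2^31.

## Known limitations

- The placer verifies substitutions only; a real divergent-flank taxon
  needs the alternative-reference path, not a bigger mismatch budget.
- Heterozygous material is out of scope beyond detection-and-warn.
- Locus intervals are bounded by marker cores, so a causal gene lying
  between a core end and the next marker is localized only to the
  adjacent uncertainty gap.
- The group-frequency pipeline assumes one haplotype per accession
  (inbred panels); population-level phasing is not attempted.
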