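# awnloci

Tools for the genetics of awn development in rice and its wild AA-genome
relatives. The awn — the needle-like extension of the lemma tip — was
lost during Asian rice domestication largely through two genes:
**RAE1** (*REGULATOR OF AWN ELONGATION 1*, a bHLH transcription factor,
silenced by a ~4.4-kb transposable-element insertion in its promoter or
truncated by a 1-bp exon-2 deletion) and **RAE2** (an EPFL-family small
secreted peptide whose function requires exactly six cysteines in the
mature peptide; frameshifting indels yield dysfunctional 4C or 7C
forms). `awnloci` implements the three analyses that together
characterize these loci across accession panels, plus a seeded
synthetic-data generator that can exercise every step end to end.

## What it computes

**TE presence/absence from read coverage** (`awnloci.temap`). The
promoter TE also occurs elsewhere in the genome, so naive mapping is
uninformative. Reads are placed on a TE-containing reference with a
k-mer seed-and-verify placer (or ingested from SAM); multi-mapped reads
are excluded; breadth of coverage is computed over four 200-bp windows
flanking the two TE/flank junctions. The call is

- *present* if breadth > 80% both inside and outside the TE at both
  boundaries (>160/200 bp),
- *absent* if breadth < 20% inside (<40/200 bp) and > 80% outside,
- *no call* otherwise.

**Haplotype and functional-group classification**
(`awnloci.haplotyper`). RAE1 haplotypes 1–4 follow from the TE status ×
exon-2 deletion; RAE2 haplotypes 1–6 from five diagnostic second-exon
indels. Each RAE2 allele is reconstructed, translated through any
frameshift to its premature stop, and its mature-peptide cysteines
counted: 6C ⇔ functional. Accessions then fall into group I (RAE1 and
RAE2 functional), II (RAE1 only), III (RAE2 only), or IV (neither), and
group frequencies are summarized per species.

**CSSL locus mapping** (`awnloci.csslmap`). Chromosome-segment
substitution lines (CSSLs) carry one or two donor-species segments in a
recurrent background. Graphical genotypes are inferred from ordered
marker calls (runs of identical calls become segments; recombination is
placed in the inter-marker gap as explicit boundary uncertainty). A
line is awned when its mean awn length exceeded 3 mm, with awned
spikelets present, in at least two years. Awn loci are the maximal
intervals where donor segments of awned lines stack to a minimum
support, annotated against the catalogued awn genes (RAE1, LABA1, RAE2,
An7, An9, An10, qAWL2, RAE3).

**Synthetic data** (`awnloci.synthio`). Deterministic, seeded
generation of everything above: a reference with the 4.4-kb TE inserted
at a fixed promoter site (with TE-interior 50-mers replicated elsewhere
so multi-map exclusion is exercised), accession genomes realizing any
haplotype combination with truth VCFs that round-trip exactly,
uniform-coverage single-end reads with substitution errors, and tiling
CSSL panels with causal loci, configurable penetrance, and multi-year
phenotypes.

## Worked example

The packaged demo simulates six accessions (two *japonica*-like, two
*indica*-like, two *O. rufipogon*-like) at 20× depth with 1% read
error, calls the TE from coverage, classifies haplotypes and groups,
and maps awn loci on a simulated 35-line CSSL panel:

```sh
awnloci run-all --out-dir demo_out
```

`demo_out/haplotype_calls.tsv`:

```text
accession  species    rae1_hap  rae2_hap  cys_count  group
jap1       japonica   hap3      hap3      4          IV
jap2       japonica   hap3      hap1      6          III
ind1       indica     hap2      hap5      7          IV
ind2       indica     hap1      hap1      6          I
ruf1       rufipogon  hap1      hap1      6          I
ruf2       rufipogon  hap1      hap5      7          II
```

`jap1` carries the promoter TE (called *present* from breadth, hence
hap3) plus the 1-bp RAE2 deletion whose frameshift truncates the
peptide to 4 cysteines — both genes dysfunctional, group IV. `ind2` and
`ruf1` retain both functional alleles (6C), group I.
`demo_out/awn_loci.tsv` localizes the two simulated causal loci; the
chr8 interval overlaps the catalogued RAE2 position:

```text
chromosome  start     end       support  supporting_lines  known_overlaps  novel
chr4        11666665  16333331  2        L012,L013                         True
chr8        20999997  25666663  2        L025,L026         RAE2            False
```

Identical seeds give byte-identical outputs; `demo_out/manifest.json`
records the digests.

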