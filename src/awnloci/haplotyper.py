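"""RAE1/RAE2 haplotype assignment, frameshift-aware allele translation,
functional classification, and group I-IV frequency summaries.

RAE1 haplotypes are defined by two mutations: the ~4.4-kb promoter TE
insertion and a 1-bp deletion in the second exon.

================  ===========  ============
haplotype         promoter TE  exon-2 del
================  ===========  ============
RAE1-hap1         absent       no   (functional)
RAE1-hap2         absent       yes
RAE1-hap3         present      no
RAE1-hap4         present      yes
================  ===========  ============

RAE2 haplotypes are defined by five diagnostic indels in the second
exon; the functional test is the mature-peptide cysteine count after
reconstructing and translating the allele (functional iff exactly six
cysteines, i.e. hap1 or hap2).  Groups combine the two functional flags:
I = both functional, II = RAE1 only, III = RAE2 only, IV = neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from ._config import load_fixture_config
from ._seq import translate
from .synthio import CdsFixture, rae2_fixture

UNRESOLVED = "unresolved"

GROUP_BY_FLAGS = {
    (True, True): "I",
    (True, False): "II",
    (False, True): "III",
    (False, False): "IV",
}

FUNCTIONAL_RAE2_HAPS = {"hap1", "hap2"}


@dataclass(frozen=True)
class Variant:
    """A CDS-space variant: gene, 1-based CDS position, anchored ref/alt."""

    gene: str       # "RAE1" or "RAE2"
    cds_pos: int
    ref: str
    alt: str
    het: bool = False  # heterozygous call; accessions are modeled inbred

    def normalized(self) -> tuple:
        """(kind, pos, length) with ``pos`` the first affected CDS base.

        Anchored indels (ref and alt sharing a leading base) normalize to
        ``del``/``ins`` at the base after the anchor; equal-length
        substitutions normalize to ``snp``.
        """
        r, a = self.ref, self.alt
        if len(r) > len(a) and r.startswith(a):
            return ("del", self.cds_pos + len(a), len(r) - len(a))
        if len(a) > len(r) and a.startswith(r):
            return ("ins", self.cds_pos + len(r), len(a) - len(r))
        if len(r) == len(a):
            return ("snp", self.cds_pos, len(r))
        # non-left-anchored complex allele; treat as replacement
        return ("complex", self.cds_pos, len(a) - len(r))


@dataclass(frozen=True)
class AccessionGenotype:
    """One accession's TE status plus its variant set over RAE1/RAE2."""

    accession_id: str
    species_label: str
    te_status: str  # present / absent / no_call
    variants: tuple = ()

    def gene_variants(self, gene: str) -> list:
        return [v for v in self.variants if v.gene == gene]


@dataclass(frozen=True)
class HaplotypeCall:
    accession_id: str
    species_label: str
    rae1_hap: str
    rae2_hap: str
    rae1_functional: bool | None
    rae2_functional: bool | None
    cys_count: int | None
    group: str


# ---------------------------------------------------------------------------
# Diagnostic configuration


@dataclass(frozen=True)
class DiagnosticConfig:
    """Positions of the haplotype-defining indels, in CDS coordinates.

    The packaged defaults match the synthetic fixtures; for real data
    load a table with the observed coordinates instead.
    """

    rae1_exon2_del: tuple                 # (kind, pos, length)
    rae2_haps: dict                       # hap label -> (kind, pos, length)
    rae2_fixture: CdsFixture = field(default_factory=rae2_fixture)

    @classmethod
    def packaged(cls) -> "DiagnosticConfig":
        cfg = load_fixture_config()
        r1 = cfg["rae1_diagnostics"]["exon2_del"]
        return cls(
            rae1_exon2_del=(r1["kind"], r1["pos"], r1["length"]),
            rae2_haps={
                hap: (d["kind"], d["pos"], d["length"])
                for hap, d in cfg["rae2_diagnostics"].items()
            },
        )


# ---------------------------------------------------------------------------
# Haplotype assignment


def assign_rae1_hap(te_status: str, exon2_del: bool) -> str:
    """RAE1 haplotype from TE status and the exon-2 1-bp deletion."""
    if te_status == "no_call":
        return UNRESOLVED
    if te_status not in ("present", "absent"):
        raise ValueError(f"unknown te_status {te_status!r}")
    table = {
        ("absent", False): "hap1",
        ("absent", True): "hap2",
        ("present", False): "hap3",
        ("present", True): "hap4",
    }
    return table[(te_status, exon2_del)]


def assign_rae2_hap(variants, config: DiagnosticConfig) -> str:
    """RAE2 haplotype from the diagnostic indels among a variant list.

    No diagnostic indel -> hap1.  Exactly one diagnostic indel -> its
    haplotype.  Two conflicting diagnostics raise; an unconfigured
    frameshifting indel or a heterozygous diagnostic site yields
    ``unresolved`` (accessions are modeled as inbred/haploid).
    """
    hits = []
    unknown_frameshift = False
    for v in variants:
        kind, pos, length = v.normalized()
        if kind in ("snp",):
            continue
        matched = None
        for hap, (dk, dp, dl) in config.rae2_haps.items():
            if (kind, pos, length) == (dk, dp, dl):
                matched = hap
                break
        if matched:
            if v.het:
                warnings.warn(
                    f"heterozygous RAE2 diagnostic at CDS {pos}; call unresolved"
                )
                return UNRESOLVED
            hits.append((matched, v))
        elif kind in ("del", "ins", "complex") and abs(length) % 3 != 0:
            unknown_frameshift = True
    if len(hits) > 1:
        names = ", ".join(h for h, _ in hits)
        raise ValueError(f"conflicting RAE2 diagnostic indels: {names}")
    if unknown_frameshift:
        return UNRESOLVED
    return hits[0][0] if hits else "hap1"


def has_rae1_exon2_del(variants, config: DiagnosticConfig) -> bool:
    target = config.rae1_exon2_del
    return any(v.normalized() == target for v in variants)


# ---------------------------------------------------------------------------
# Allele reconstruction and translation


def reconstruct_cds(ref_cds: str, variants) -> str:
    """Apply CDS-space variants to a reference CDS.

    Variants are applied right-to-left so that positions remain valid;
    overlapping variants raise a conflict error.
    """
    ordered = sorted(variants, key=lambda v: v.cds_pos)
    for v1, v2 in zip(ordered, ordered[1:]):
        if v1.cds_pos + len(v1.ref) > v2.cds_pos:
            raise ValueError(
                f"overlapping variants at CDS positions {v1.cds_pos} and {v2.cds_pos}"
            )
    out = ref_cds
    for v in reversed(ordered):
        p = v.cds_pos
        if out[p - 1 : p - 1 + len(v.ref)] != v.ref:
            raise ValueError(f"reference mismatch at CDS position {p}")
        out = out[: p - 1] + v.alt + out[p - 1 + len(v.ref) :]
    return out


def count_cysteines(peptide: str, mature_start: int) -> int:
    """Cysteines at or after the 1-based mature-peptide start."""
    if not 1 <= mature_start <= len(peptide) + 1:
        raise ValueError("mature_start outside the peptide")
    return sum(1 for i, aa in enumerate(peptide, 1) if aa == "C" and i >= mature_start)


# ---------------------------------------------------------------------------
# Function and group calls


def call_function(rae1_hap: str, rae2_hap: str, cys_count: int | None):
    """(rae1_functional, rae2_functional); ``None`` when unresolved.

    RAE1 is functional only as hap1 (no promoter TE, intact exon 2);
    RAE2 is functional iff the mature peptide retains exactly six
    cysteines, which is equivalent to hap1/hap2.
    """
    rae1 = None if rae1_hap == UNRESOLVED else rae1_hap == "hap1"
    if rae2_hap == UNRESOLVED or cys_count is None:
        rae2 = None
    else:
        rae2 = cys_count == 6
        if rae2 != (rae2_hap in FUNCTIONAL_RAE2_HAPS):
            warnings.warn(
                f"cysteine count {cys_count} inconsistent with {rae2_hap}; "
                "the cysteine count decides functionality"
            )
    return rae1, rae2


def assign_group(rae1_functional, rae2_functional) -> str:
    """Group I-IV from the two functional flags (unresolved propagates)."""
    if rae1_functional is None or rae2_functional is None:
        return UNRESOLVED
    return GROUP_BY_FLAGS[(bool(rae1_functional), bool(rae2_functional))]


def classify_accession(genotype: AccessionGenotype,
                       config: DiagnosticConfig | None = None) -> HaplotypeCall:
    """Full per-accession classification: haplotypes, cysteine count,
    functional flags, and group."""
    config = config or DiagnosticConfig.packaged()
    rae1_vars = genotype.gene_variants("RAE1")
    if any(v.het and v.normalized() == config.rae1_exon2_del for v in rae1_vars):
        warnings.warn("heterozygous RAE1 exon-2 deletion; haplotype unresolved")
        rae1_hap = UNRESOLVED
    else:
        rae1_hap = assign_rae1_hap(
            genotype.te_status, has_rae1_exon2_del(rae1_vars, config)
        )
    rae2_vars = genotype.gene_variants("RAE2")
    rae2_hap = assign_rae2_hap(rae2_vars, config)

    cys = None
    if rae2_hap != UNRESOLVED:
        fixture = config.rae2_fixture
        alt_cds = reconstruct_cds(fixture.cds_sequence, rae2_vars)
        cys = count_cysteines(translate(alt_cds), fixture.mature_start)

    rae1_fn, rae2_fn = call_function(rae1_hap, rae2_hap, cys)
    return HaplotypeCall(
        accession_id=genotype.accession_id,
        species_label=genotype.species_label,
        rae1_hap=rae1_hap,
        rae2_hap=rae2_hap,
        rae1_functional=rae1_fn,
        rae2_functional=rae2_fn,
        cys_count=cys,
        group=assign_group(rae1_fn, rae2_fn),
    )


# ---------------------------------------------------------------------------
# Frequency summaries


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0." + "0" * ndigits),
                                          rounding=ROUND_HALF_UP))


def summarize_groups(calls, by: str = "species_label") -> pd.DataFrame:
    """Per-species group counts and percentages (round-half-up, 1 dp).

    Returns one row per species with columns ``n_I``..``n_IV``,
    ``n_unresolved``, ``n_total``, and ``pct_I``..``pct_IV`` computed
    over resolved accessions.  Exact counts are always emitted alongside
    percentages because rounded percentages alone are not recoverable.
    """
    rows = []
    df = pd.DataFrame(
        [{"species": getattr(c, by), "group": c.group} for c in calls]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["species", "n_I", "n_II", "n_III", "n_IV",
                     "n_unresolved", "n_total",
                     "pct_I", "pct_II", "pct_III", "pct_IV"]
        )
    for species, sub in df.groupby("species", sort=True):
        counts = {g: int((sub["group"] == g).sum()) for g in ("I", "II", "III", "IV")}
        n_unres = int((sub["group"] == UNRESOLVED).sum())
        n_total = len(sub)
        n_resolved = n_total - n_unres
        row = {"species": species,
               **{f"n_{g}": counts[g] for g in ("I", "II", "III", "IV")},
               "n_unresolved": n_unres, "n_total": n_total}
        for g in ("I", "II", "III", "IV"):
            row[f"pct_{g}"] = (
                _round_half_up(100.0 * counts[g] / n_resolved) if n_resolved else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Input adapters


def genotype_from_profile(profile, te_status: str | None = None,
                          config: DiagnosticConfig | None = None,
                          rae1_fixture_model: CdsFixture | None = None) -> AccessionGenotype:
    """Build an :class:`AccessionGenotype` from a synthio profile.

    ``te_status`` defaults to the profile's truth (``present``/``absent``);
    pass an observed TE call to couple with the coverage caller instead.
    """
    from .synthio import RAE2_EDIT_LABELS, rae1_fixture

    config = config or DiagnosticConfig.packaged()
    rae1_model = rae1_fixture_model or rae1_fixture()
    variants = []
    if profile.rae1_exon2_del:
        _, pos, length = config.rae1_exon2_del
        cds = rae1_model.cds_sequence
        variants.append(
            Variant("RAE1", pos - 1, cds[pos - 2 : pos - 1 + length], cds[pos - 2])
        )
    if profile.rae2_edit != "none":
        hap = RAE2_EDIT_LABELS[profile.rae2_edit]
        kind, pos, length = config.rae2_haps[hap]
        cds = config.rae2_fixture.cds_sequence
        if kind == "del":
            variants.append(
                Variant("RAE2", pos - 1, cds[pos - 2 : pos - 1 + length], cds[pos - 2])
            )
        else:  # 1-bp insertion fixture inserts "A"
            op, fpos, bases = config.rae2_fixture.hap_edit_positions[hap]
            variants.append(
                Variant("RAE2", fpos - 1, cds[fpos - 2], cds[fpos - 2] + str(bases))
            )
    for gene, cds_pos, alt in profile.extra_snps:
        model = rae1_model if gene.lower() == "rae1" else config.rae2_fixture
        variants.append(
            Variant(gene.upper(), cds_pos, model.cds_sequence[cds_pos - 1], alt)
        )
    return AccessionGenotype(
        accession_id=profile.accession_id,
        species_label=profile.species_label,
        te_status=te_status or ("present" if profile.te_present else "absent"),
        variants=tuple(variants),
    )


def genotypes_from_vcf(path, species_map: dict, te_status_map: dict,
                       gene_intervals: dict) -> list:
    """Read per-accession genomic VCFs is out of scope here; this adapter
    converts a simple genomic VCF (single unphased sample column absent)
    into CDS-space genotypes for the configured gene intervals.

    ``gene_intervals`` maps gene name -> (chromosome, cds_start0, cds_end0)
    on the same reference the VCF coordinates use.  Variants outside the
    intervals are ignored.  All records in one file are attributed to one
    accession named by the file's stem.
    """
    import pathlib

    import pysam

    path = pathlib.Path(path)
    acc = path.stem
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for gene, (chrom, g0, g1) in gene_intervals.items():
                if rec.chrom == chrom and g0 < rec.pos <= g1:
                    alt = rec.alts[0] if rec.alts else rec.ref
                    variants.append(
                        Variant(gene.upper(), rec.pos - g0, rec.ref, alt)
                    )
    return [
        AccessionGenotype(
            accession_id=acc,
            species_label=species_map.get(acc, "unknown"),
            te_status=te_status_map.get(acc, "no_call"),
            variants=tuple(variants),
        )
    ]


def calls_to_frame(calls) -> pd.DataFrame:
    """Flatten haplotype calls into the per-accession output table."""
    return pd.DataFrame(
        [
            {
                "accession": c.accession_id,
                "species": c.species_label,
                "rae1_hap": c.rae1_hap,
                "rae2_hap": c.rae2_hap,
                "cys_count": c.cys_count,
                "group": c.group,
            }
            for c in calls
        ]
    )
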