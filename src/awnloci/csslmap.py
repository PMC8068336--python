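"""CSSL graphical genotypes and awn-locus mapping.

A chromosome-segment substitution line (CSSL) carries one or a few
donor-species chromosome segments in a recurrent-parent background.
This module reconstructs each line's graphical genotype from ordered
marker calls (runs of identical calls become segments; a state change
between two markers is a recombination somewhere in the inter-marker
gap, recorded as boundary uncertainty), scores the awn phenotype from
multi-year spikelet observations, localizes awn loci as maximal regions
where donor segments of awned lines stack to a minimum support, and
annotates the result against a catalogue of known awn genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._config import load_gene_catalogue

STATE_BY_CALL = {"D": "donor", "R": "recurrent", "H": "het"}


@dataclass
class Segment:
    """A maximal run of identical marker calls on one chromosome.

    ``core_start``/``core_end`` are the outermost same-call marker
    positions (1-based, inclusive).  The true recombination breakpoints
    lie in the flanking inter-marker gaps, recorded as
    ``uncertainty_left``/``uncertainty_right`` (open intervals; for
    terminal segments they extend to the chromosome ends when known).
    """

    line_id: str
    chromosome: str
    state: str               # donor / recurrent / het
    core_start: int
    core_end: int
    uncertainty_left: tuple
    uncertainty_right: tuple
    markers: tuple = ()


@dataclass
class LocusCall:
    """A candidate awn locus: a maximal interval supported by donor
    segments of at least ``min_support`` awned lines."""

    chromosome: str
    start: int
    end: int
    support: int
    supporting_lines: tuple
    panels: tuple = ()
    conflicting_lines: tuple = ()   # non-awned donor carriers overlapping
    known_overlaps: tuple = ()
    novel: bool = True


# ---------------------------------------------------------------------------
# Graphical genotypes


def infer_segments(line_id: str, calls: pd.DataFrame,
                   chrom_lengths: dict | None = None) -> tuple:
    """Segments for one line from its marker calls.

    ``calls`` needs columns ``chromosome``, ``position``, ``call`` (D/R/H
    or missing).  Missing calls are bridged (skipped) and counted.
    Returns ``(segments, n_missing, untyped_chromosomes)``.
    """
    chrom_lengths = chrom_lengths or {}
    segments = []
    n_missing = 0
    untyped = []
    for chrom, sub in calls.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        typed = []
        for _, row in sub.iterrows():
            call = row["call"]
            if pd.isna(call) or call not in STATE_BY_CALL:
                n_missing += 1
                continue
            typed.append((int(row["position"]), call))
        if not typed:
            untyped.append(chrom)
            continue
        chrom_end = chrom_lengths.get(chrom)
        runs = []
        run = [typed[0]]
        for item in typed[1:]:
            if item[1] == run[-1][1]:
                run.append(item)
            else:
                runs.append(run)
                run = [item]
        runs.append(run)
        for i, run in enumerate(runs):
            core_start, core_end = run[0][0], run[-1][0]
            left = (1, core_start) if i == 0 else (runs[i - 1][-1][0], core_start)
            right = (
                (core_end, chrom_end if chrom_end else core_end)
                if i == len(runs) - 1
                else (core_end, runs[i + 1][0][0])
            )
            segments.append(
                Segment(
                    line_id=line_id,
                    chromosome=chrom,
                    state=STATE_BY_CALL[run[0][1]],
                    core_start=core_start,
                    core_end=core_end,
                    uncertainty_left=left,
                    uncertainty_right=right,
                    markers=tuple(p for p, _ in run),
                )
            )
    return tuple(segments), n_missing, untyped


def infer_all_segments(genotypes: pd.DataFrame,
                       chrom_lengths: dict | None = None) -> dict:
    """Segments per line for a whole marker-genotype table."""
    out = {}
    for line, sub in genotypes.groupby("line", sort=True):
        segs, _, _ = infer_segments(line, sub, chrom_lengths)
        out[line] = segs
    return out


# ---------------------------------------------------------------------------
# Phenotype scoring


def awned_spikelet_ratio(awned_spikelets: int, total_spikelets: int) -> float:
    """Percent of spikelets on the panicle bearing an awn (NaN if no
    spikelets were scored)."""
    if awned_spikelets < 0 or awned_spikelets > total_spikelets:
        raise ValueError("awned_spikelets must be within [0, total_spikelets]")
    if total_spikelets == 0:
        return math.nan
    return 100.0 * awned_spikelets / total_spikelets


def classify_awned(observations: pd.DataFrame, min_years: int = 2,
                   min_length_mm: float = 3.0) -> bool:
    """Whether a line is awned across its multi-year observations.

    A year counts as awned when the mean awn length strictly exceeds
    ``min_length_mm`` (awns > 3 mm on mature grains) and at least one
    spikelet was awned; the line is awned when that held in at least
    ``min_years`` years.
    """
    if observations.empty:
        raise ValueError("no observations for line")
    awned_years = (
        (observations["mean_awn_length_mm"] > min_length_mm)
        & (observations["awned_spikelets"] > 0)
    ).sum()
    return bool(awned_years >= min_years)


def classify_all_awned(phenotypes: pd.DataFrame, min_years: int = 2,
                       min_length_mm: float = 3.0) -> dict:
    return {
        line: classify_awned(sub, min_years=min_years, min_length_mm=min_length_mm)
        for line, sub in phenotypes.groupby("line", sort=True)
    }


# ---------------------------------------------------------------------------
# Locus localization


def candidate_loci(segments_by_line: dict, awned: dict,
                   panels: dict | None = None, min_support: int = 1,
                   include_het: bool = False) -> list:
    """Awn loci as maximal regions covered by >= ``min_support`` donor
    segments of awned lines.

    Within each panel every donor core segment of an awned line is a
    candidate; overlapping candidates are intersected by a coverage
    sweep, and maximal intervals reaching the support threshold are
    emitted with their supporting lines.  Non-awned donor carriers
    overlapping an emitted locus are reported as conflicts rather than
    subtracted (a non-penetrant carrier must not erase a locus).
    """
    panels = panels or {}
    states = {"donor"} | ({"het"} if include_het else set())
    cands = []
    for line, segs in segments_by_line.items():
        if not awned.get(line, False):
            continue
        for s in segs:
            if s.state in states:
                cands.append((s.chromosome, s.core_start, s.core_end, line))
    noncarriers = [
        (s.chromosome, s.core_start, s.core_end, line)
        for line, segs in segments_by_line.items()
        if not awned.get(line, False)
        for s in segs
        if s.state in states
    ]

    loci = []
    for chrom in sorted({c[0] for c in cands}):
        ivals = [c for c in cands if c[0] == chrom]
        events: dict = {}
        for _, lo, hi, _ in ivals:
            events[lo] = events.get(lo, 0) + 1
            events[hi + 1] = events.get(hi + 1, 0) - 1
        positions = sorted(events)
        count = 0
        open_start = None
        for i, x in enumerate(positions):
            count += events[x]
            nxt = positions[i + 1] if i + 1 < len(positions) else x
            if count >= min_support and open_start is None:
                open_start = x
            if count < min_support and open_start is not None:
                loci.append((chrom, open_start, x - 1))
                open_start = None
        if open_start is not None:
            loci.append((chrom, open_start, positions[-1] - 1))

    out = []
    for chrom, lo, hi in loci:
        supp = sorted(
            {line for c, s, e, line in cands if c == chrom and s <= hi and e >= lo}
        )
        confl = sorted(
            {line for c, s, e, line in noncarriers if c == chrom and s <= hi and e >= lo}
        )
        out.append(
            LocusCall(
                chromosome=chrom,
                start=lo,
                end=hi,
                support=len(supp),
                supporting_lines=tuple(supp),
                panels=tuple(sorted({panels[l] for l in supp if l in panels})),
                conflicting_lines=tuple(confl),
            )
        )
    return out


def annotate_known(loci, gene_table: pd.DataFrame | None = None) -> list:
    """Label each locus with overlapping catalogued awn genes/loci.

    Catalogue rows with ``scope == 'gene'`` overlap by coordinates; rows
    with ``scope == 'chromosome'`` tag any locus on that chromosome.
    Loci overlapping nothing keep ``novel=True``.
    """
    table = gene_table if gene_table is not None else load_gene_catalogue()
    required = {"name", "chromosome", "start", "end", "scope"}
    if not required <= set(table.columns):
        raise ValueError(f"gene table missing columns {required - set(table.columns)}")
    annotated = []
    for locus in loci:
        hits = []
        for _, g in table.iterrows():
            if g["chromosome"] != locus.chromosome:
                continue
            if g["scope"] == "chromosome":
                hits.append(g["name"])
            elif locus.start <= int(g["end"]) and locus.end >= int(g["start"]):
                hits.append(g["name"])
        annotated.append(
            LocusCall(
                chromosome=locus.chromosome,
                start=locus.start,
                end=locus.end,
                support=locus.support,
                supporting_lines=locus.supporting_lines,
                panels=locus.panels,
                conflicting_lines=locus.conflicting_lines,
                known_overlaps=tuple(hits),
                novel=not hits,
            )
        )
    return annotated


# ---------------------------------------------------------------------------
# Convenience pipeline


def map_loci(genotypes: pd.DataFrame, phenotypes: pd.DataFrame,
             min_support: int = 2, min_years: int = 2,
             min_length_mm: float = 3.0, chrom_lengths: dict | None = None,
             panels: dict | None = None,
             gene_table: pd.DataFrame | None = None) -> tuple:
    """Genotypes + phenotypes -> (segments_by_line, annotated loci)."""
    segments = infer_all_segments(genotypes, chrom_lengths)
    awned = classify_all_awned(phenotypes, min_years=min_years,
                               min_length_mm=min_length_mm)
    loci = candidate_loci(segments, awned, panels=panels, min_support=min_support)
    return segments, annotate_known(loci, gene_table)


def loci_to_frame(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": l.chromosome,
                "start": l.start,
                "end": l.end,
                "support": l.support,
                "supporting_lines": ",".join(l.supporting_lines),
                "panels": ",".join(l.panels),
                "conflicting_lines": ",".join(l.conflicting_lines),
                "known_overlaps": ",".join(l.known_overlaps),
                "novel": l.novel,
            }
            for l in loci
        ]
    )


def segments_to_bed(segments_by_line: dict) -> list:
    """Segments as BED records (chrom, start0, end0, name=line:state)."""
    recs = []
    for line, segs in segments_by_line.items():
        for s in segs:
            recs.append((s.chromosome, s.core_start - 1, s.core_end,
                         f"{line}:{s.state}"))
    return recs
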