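"""Candidate regulatory-region prioritization.

Orchestrates the full in silico nomination: the anchor bin is the bin
containing the gene midpoint; partner bins are the consensus of each
enzyme map's top-k interaction partners (plus, by default, the anchor bin
itself, since the gene's own bin can harbour a proximal element); within
each selected bin the highest-enrichment region of the enhancer-mark
track is called; candidates are ranked by peak height and can be exported
as a BED file of sequencing targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .contact_map import ContactMap, consensus_top_partners, rank_partners
from .errors import IncompatibleResolutionError, InvalidArgumentError, ParseError
from .genome import (
    GeneAnnotation,
    GenomeBin,
    GenomicInterval,
    bin_of_position,
    interval_from_bed,
    interval_to_bed,
    upstream_distance,
)
from .signal_track import (
    DEFAULT_FRAC,
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_WIDTH,
    EnrichmentRegion,
    SignalTrack,
    highest_enrichment_region,
)

log = logging.getLogger(__name__)

LOCALITY_DISTAL = "distal"
LOCALITY_PROXIMAL = "proximal"
LOCALITY_TRANS = "trans"


@dataclass(frozen=True)
class SelectionParams:
    scope: str = "intra"
    top_k: int = 1
    include_anchor_bin: bool = True
    frac: float = DEFAULT_FRAC
    max_gap: int = DEFAULT_MAX_GAP
    min_width: int = DEFAULT_MIN_WIDTH


@dataclass(frozen=True)
class CandidateRegion:
    """A nominated regulatory region with its provenance.

    distance_to_gene is the signed strand-aware distance from the region to
    the gene's 5' end (None for trans candidates); locality classifies the
    source bin relative to the gene: proximal = the gene-containing bin,
    distal = another bin on the gene's chromosome, trans = another
    chromosome.
    """

    region: EnrichmentRegion
    source_bin: GenomeBin
    supporting_counts: dict = field(hash=False)
    distance_to_gene: Optional[int]
    locality: str
    label: str


def _locality(source_bin: GenomeBin, anchor: GenomeBin) -> str:
    if source_bin.chrom != anchor.chrom:
        return LOCALITY_TRANS
    return LOCALITY_PROXIMAL if source_bin == anchor else LOCALITY_DISTAL


def anchor_bin_of(gene: GeneAnnotation, bin_size: int) -> GenomeBin:
    """The bin containing the gene midpoint (unambiguous for straddlers)."""
    return bin_of_position(gene.interval.chrom, gene.interval.midpoint, bin_size)


def select_candidates(
    maps: list[ContactMap],
    gene: GeneAnnotation,
    track: SignalTrack,
    params: SelectionParams = SelectionParams(),
) -> list[CandidateRegion]:
    """Nominate candidate regulatory regions for ``gene``.

    Returns candidates sorted by descending peak height; selected bins with
    no positive signal are silently dropped.
    """
    if not maps:
        return []
    bin_size = maps[0].bin_size
    for m in maps[1:]:
        if m.bin_size != bin_size:
            raise IncompatibleResolutionError(
                f"maps disagree on bin size: {m.bin_size} vs {bin_size}"
            )
    anchor = anchor_bin_of(gene, bin_size)
    log.info("anchor bin for %s: %s index %d", gene.name, anchor.chrom, anchor.index)

    rankings = [rank_partners(m, anchor, scope=params.scope) for m in maps]
    for r in rankings:
        log.debug(
            "%s ranking (top 5): %s",
            r.enzyme_label,
            [(b.chrom, b.index, c) for b, c in r.top(5)],
        )
    selected = consensus_top_partners(rankings, params.top_k) if params.top_k > 0 else []
    if params.include_anchor_bin and anchor not in selected:
        selected.append(anchor)
    log.info("selected bins: %s", [(b.chrom, b.index) for b in selected])

    candidates: list[CandidateRegion] = []
    for b in selected:
        region = highest_enrichment_region(
            track,
            b.interval,
            frac=params.frac,
            max_gap=params.max_gap,
            min_width=params.min_width,
        )
        if region is None:
            log.info("bin %s:%d has no enrichment region; dropped", b.chrom, b.index)
            continue
        locality = _locality(b, anchor)
        distance = (
            None
            if locality == LOCALITY_TRANS
            else upstream_distance(gene, region.interval)
        )
        counts = {m.enzyme_label: m.count(b, anchor) for m in maps}
        label = f"{gene.name}_{b.chrom}_bin{b.index}"
        log.info(
            "candidate %s: %s:%d-%d peak=%.3g distance=%s (%s)",
            label,
            region.interval.chrom,
            region.interval.start,
            region.interval.end,
            region.peak_height,
            distance,
            locality,
        )
        candidates.append(
            CandidateRegion(
                region=region,
                source_bin=b,
                supporting_counts=counts,
                distance_to_gene=distance,
                locality=locality,
                label=label,
            )
        )
    candidates.sort(key=lambda c: (-c.region.peak_height, c.label))
    return candidates


def export_targets(candidates: list[CandidateRegion], path) -> None:
    """Write candidates as a BED6 file of sequencing targets.

    Score is the peak height clamped to the BED 0–1000 range.
    """
    if not candidates:
        raise InvalidArgumentError("no candidates to export")
    with Path(path).open("w") as fh:
        for c in candidates:
            chrom, s0, e0 = interval_to_bed(c.region.interval)
            score = int(round(min(max(c.region.peak_height, 0.0), 1000.0)))
            fh.write(f"{chrom}\t{s0}\t{e0}\t{c.label}\t{score}\t.\n")


def import_targets(path) -> list[CandidateRegion]:
    """Re-read an exported targets BED as bare candidates (for screening).

    Interaction counts and distances are not stored in BED and come back
    empty/None; the region interval, label, and score survive the
    round-trip exactly.
    """
    path = Path(path)
    out: list[CandidateRegion] = []
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, line_no, "expected at least 4 BED columns")
            try:
                iv = interval_from_bed(fields[0], int(fields[1]), int(fields[2]))
                score = float(fields[4]) if len(fields) >= 5 else 0.0
            except (ValueError, InvalidArgumentError) as exc:
                raise ParseError(path, line_no, f"bad BED record: {exc}") from exc
            region = EnrichmentRegion(interval=iv, peak_height=score, area=0.0)
            out.append(
                CandidateRegion(
                    region=region,
                    source_bin=bin_of_position(iv.chrom, iv.start),
                    supporting_counts={},
                    distance_to_gene=None,
                    locality=LOCALITY_DISTAL,
                    label=fields[3],
                )
            )
    return out
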