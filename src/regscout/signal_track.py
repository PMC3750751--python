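"""Enhancer-mark signal tracks and highest-enrichment region calling.

The signal (e.g. H3K27ac ChIP-seq enrichment) is piecewise constant per
bedGraph semantics: a sorted, non-overlapping set of valued intervals with
implicit value 0 everywhere else. No smoothing or interpolation is applied.

:func:`highest_enrichment_region` operationalizes "the relatively short
region with the highest enrichment inside a query window": threshold at a
fraction of the in-window maximum, merge above-threshold runs across short
gaps, drop slivers, and return the run containing the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import InvalidArgumentError, ParseError
from .genome import GenomicInterval, interval_from_bed, interval_to_bed

DEFAULT_FRAC = 0.5
DEFAULT_MAX_GAP = 200
DEFAULT_MIN_WIDTH = 100


@dataclass(frozen=True)
class SignalTrack:
    """Sorted, non-overlapping valued intervals; value 0 off-track."""

    intervals: tuple[tuple[GenomicInterval, float], ...]
    track_label: str = ""

    def __post_init__(self):
        prev: Optional[GenomicInterval] = None
        for iv, value in self.intervals:
            if value < 0:
                raise InvalidArgumentError(f"negative signal value {value} at {iv}")
            if prev is not None and (prev.chrom, prev.start) > (iv.chrom, iv.start):
                raise InvalidArgumentError("track intervals not sorted")
            if prev is not None and prev.chrom == iv.chrom and iv.start <= prev.end:
                raise InvalidArgumentError(f"track intervals overlap at {iv}")
            prev = iv

    def segments_in(self, query: GenomicInterval) -> list[tuple[int, int, float]]:
        """Covered (start, end, value) pieces clipped to ``query``."""
        out = []
        for iv, value in self.intervals:
            if iv.chrom != query.chrom or iv.end < query.start:
                continue
            if iv.start > query.end:
                break
            out.append((max(iv.start, query.start), min(iv.end, query.end), value))
        return out


@dataclass(frozen=True)
class EnrichmentRegion:
    """A called high-enrichment region within some query window."""

    interval: GenomicInterval
    peak_height: float
    area: float


def read_bedgraph(path, track_label: str = "") -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open on disk)."""
    path = Path(path)
    records: list[tuple[GenomicInterval, float]] = []
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, line_no, f"expected 4 columns, got {len(fields)}")
            try:
                iv = interval_from_bed(fields[0], int(fields[1]), int(fields[2]))
                value = float(fields[3])
            except (ValueError, InvalidArgumentError) as exc:
                raise ParseError(path, line_no, f"bad bedGraph record: {exc}") from exc
            if value < 0:
                raise ParseError(path, line_no, f"negative signal value {value}")
            records.append((iv, value))
    records.sort(key=lambda r: (r[0].chrom, r[0].start))
    try:
        return SignalTrack(intervals=tuple(records), track_label=track_label or path.stem)
    except InvalidArgumentError as exc:
        raise ParseError(path, 0, str(exc)) from exc


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(v)


def write_bedgraph(track: SignalTrack, path) -> None:
    with Path(path).open("w") as fh:
        for iv, value in track.intervals:
            chrom, s0, e0 = interval_to_bed(iv)
            fh.write(f"{chrom}\t{s0}\t{e0}\t{_fmt_value(value)}\n")


def _merge_runs(
    above: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for s, e in above:
        if runs and s - runs[-1][1] - 1 <= max_gap:
            runs[-1] = (runs[-1][0], max(runs[-1][1], e))
        else:
            runs.append((s, e))
    return runs


def highest_enrichment_region(
    track: SignalTrack,
    query: GenomicInterval,
    frac: float = DEFAULT_FRAC,
    max_gap: int = DEFAULT_MAX_GAP,
    min_width: int = DEFAULT_MIN_WIDTH,
    return_all: bool = False,
):
    """Call the highest-enrichment region inside ``query``.

    Let M be the maximum signal within the query; positions with signal >=
    frac*M form runs, runs separated by <= max_gap uncovered-or-below bp
    are merged, merged runs shorter than min_width are discarded, and the
    run containing the (leftmost) maximal position is returned as an
    :class:`EnrichmentRegion` with peak_height M. Returns None when the
    query has no positive signal (or the max's run was discarded).

    With ``return_all`` every surviving run is returned (descending peak
    height, leftmost first on ties), mirroring a multi-region scan.
    """
    if not (0 < frac <= 1):
        raise InvalidArgumentError(f"frac must be in (0, 1], got {frac}")
    if max_gap < 0:
        raise InvalidArgumentError(f"max_gap must be >= 0, got {max_gap}")
    if min_width < 1:
        raise InvalidArgumentError(f"min_width must be >= 1, got {min_width}")

    segments = track.segments_in(query)
    if not segments:
        return [] if return_all else None
    peak = max(v for _s, _e, v in segments)
    if peak <= 0:
        return [] if return_all else None
    threshold = frac * peak
    above = [(s, e) for s, e, v in segments if v >= threshold]
    runs = _merge_runs(above, max_gap)
    runs = [(s, e) for s, e in runs if e - s + 1 >= min_width]
    argmax = min(s for s, _e, v in segments if v == peak)

    def region_of(run: tuple[int, int]) -> EnrichmentRegion:
        s, e = run
        iv = GenomicInterval(query.chrom, s, e)
        inside = [
            (max(ss, s), min(ee, e), v) for ss, ee, v in segments if ss <= e and ee >= s
        ]
        height = max(v for _a, _b, v in inside)
        area = sum(v * (b - a + 1) for a, b, v in inside)
        return EnrichmentRegion(interval=iv, peak_height=height, area=area)

    if return_all:
        regions = [region_of(r) for r in runs]
        regions.sort(key=lambda r: (-r.peak_height, r.interval.start))
        return regions
    for run in runs:
        if run[0] <= argmax <= run[1]:
            return region_of(run)
    return None  # the max's run was shorter than min_width


def compare_peak_heights(regions: list[EnrichmentRegion]) -> list[EnrichmentRegion]:
    """Stable descending sort by peak height; ties keep input order."""
    if not regions:
        raise InvalidArgumentError("cannot compare an empty region list")
    return sorted(regions, key=lambda r: -r.peak_height)
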