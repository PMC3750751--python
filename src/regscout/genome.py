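"""Genomic coordinates, fixed-size binning, and gene-relative distances.

All in-memory coordinates are 1-based and inclusive at both ends, the
convention used for printed genomic positions. On-disk BED and bedGraph
records are 0-based half-open; conversion happens exactly once, at I/O
boundaries (:func:`interval_from_bed`, :func:`interval_to_bed`).

A genome bin of size ``B`` and index ``i`` covers positions
``[i*B, (i+1)*B - 1]`` (clipped to 1 at the left edge for bin 0), so with
1-Mb bins the bin of index 29 on chr17 covers exactly
29,000,000–29,999,999 and contains the entire NF1 gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import IncompatibleCoordinatesError, InvalidArgumentError, ParseError

DEFAULT_BIN_SIZE = 1_000_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise InvalidArgumentError(
                f"interval start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise InvalidArgumentError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def encloses(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class GenomeBin:
    """One fixed-size bin of the genome partition used by a contact map."""

    chrom: str
    index: int
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        if self.index < 0:
            raise InvalidArgumentError(f"bin index must be >= 0, got {self.index}")
        if self.bin_size < 1:
            raise InvalidArgumentError(
                f"bin size must be >= 1, got {self.bin_size}"
            )

    @property
    def interval(self) -> GenomicInterval:
        # bin 0 starts at coordinate 1 because positions are 1-based
        start = max(1, self.index * self.bin_size)
        end = (self.index + 1) * self.bin_size - 1
        return GenomicInterval(self.chrom, start, end)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: symbol, span, and strand (+ or -)."""

    name: str
    interval: GenomicInterval
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InvalidArgumentError(f"strand must be + or -, got {self.strand!r}")


def bin_of_position(chrom: str, pos: int, bin_size: int = DEFAULT_BIN_SIZE) -> GenomeBin:
    """Return the bin containing ``pos``; index = floor(pos / bin_size)."""
    if pos < 1:
        raise InvalidArgumentError(f"position must be >= 1, got {pos}")
    if bin_size < 1:
        raise InvalidArgumentError(f"bin size must be >= 1, got {bin_size}")
    return GenomeBin(chrom, pos // bin_size, bin_size)


def bins_overlapping_interval(
    iv: GenomicInterval, bin_size: int = DEFAULT_BIN_SIZE
) -> list[GenomeBin]:
    """All bins overlapping ``iv``, consecutive and sorted by index."""
    first = bin_of_position(iv.chrom, iv.start, bin_size).index
    last = bin_of_position(iv.chrom, iv.end, bin_size).index
    return [GenomeBin(iv.chrom, i, bin_size) for i in range(first, last + 1)]


def upstream_distance(gene: GeneAnnotation, region: GenomicInterval) -> int:
    """Signed distance from ``region`` to the 5' end of ``gene``, in bp.

    Positive when the region lies entirely upstream (5', strand-aware) of
    the gene, negative when entirely downstream, and 0 when the region
    overlaps the gene body. For a plus-strand gene with an upstream region
    this is ``gene.start - region.end``.
    """
    giv = gene.interval
    if region.chrom != giv.chrom:
        raise IncompatibleCoordinatesError(
            f"region on {region.chrom} but gene {gene.name} on {giv.chrom}"
        )
    if region.overlaps(giv):
        return 0
    if region.end < giv.start:  # region on the lower-coordinate side
        d = giv.start - region.end
        return d if gene.strand == "+" else -d
    d = region.start - giv.end  # region on the higher-coordinate side
    return d if gene.strand == "-" else -d


def round_kb(distance_bp: int) -> int:
    """Nearest-kb display rounding used for reported distances."""
    sign = -1 if distance_bp < 0 else 1
    return sign * ((abs(distance_bp) + 500) // 1000)


# --- BED boundary conversion (bit-exact both ways) -----------------------

def interval_from_bed(chrom: str, start0: int, end0: int) -> GenomicInterval:
    """0-based half-open BED coordinates -> internal 1-based inclusive."""
    return GenomicInterval(chrom, start0 + 1, end0)


def interval_to_bed(iv: GenomicInterval) -> tuple[str, int, int]:
    """Internal 1-based inclusive -> 0-based half-open BED coordinates."""
    return iv.chrom, iv.start - 1, iv.end


def read_gene_bed(path) -> GeneAnnotation:
    """Read a single gene annotation from a BED6 (or BED4+) file."""
    path = Path(path)
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
            except (ValueError, InvalidArgumentError) as exc:
                raise ParseError(path, line_no, f"bad BED record: {exc}") from exc
            strand = fields[5] if len(fields) >= 6 else "+"
            return GeneAnnotation(name=fields[3], interval=iv, strand=strand)
    raise ParseError(path, 0, "no gene record found")


def write_gene_bed(gene: GeneAnnotation, path) -> None:
    chrom, s0, e0 = interval_to_bed(gene.interval)
    with Path(path).open("w") as fh:
        fh.write(f"{chrom}\t{s0}\t{e0}\t{gene.name}\t0\t{gene.strand}\n")
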