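"""Binned, pre-normalized chromatin-contact maps and partner-bin ranking.

A :class:`ContactMap` holds symmetric interaction counts between fixed-size
genome bins for one restriction-enzyme Hi-C experiment (e.g. a HindIII map
and an NcoI map are two separate ContactMaps). Maps are consumed already
bias-normalized, so counts are non-negative reals; missing bin pairs mean
count 0.

On disk a map is a tab-separated file::

    # enzyme_label=HindIII
    # bin_size=1000000
    chromA	binA	chromB	binB	count
    chr17	28	chr17	29	703

one unordered bin pair per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import (
    ConsistencyError,
    IncompatibleResolutionError,
    InvalidArgumentError,
    ParseError,
)
from .genome import DEFAULT_BIN_SIZE, GenomeBin

Scope = str  # "intra" | "inter" | "all"
_SCOPES = ("intra", "inter", "all")

HEADER = "chromA\tbinA\tchromB\tbinB\tcount"


def _canonical(a: GenomeBin, b: GenomeBin) -> tuple[GenomeBin, GenomeBin]:
    return (a, b) if (a.chrom, a.index) <= (b.chrom, b.index) else (b, a)


@dataclass
class ContactMap:
    enzyme_label: str
    bin_size: int = DEFAULT_BIN_SIZE
    _entries: dict[tuple[GenomeBin, GenomeBin], float] = field(default_factory=dict)

    def set_count(self, a: GenomeBin, b: GenomeBin, count: float) -> None:
        if a.bin_size != self.bin_size or b.bin_size != self.bin_size:
            raise IncompatibleResolutionError(
                f"bin size {a.bin_size}/{b.bin_size} does not match map "
                f"bin size {self.bin_size}"
            )
        if count < 0:
            raise InvalidArgumentError(f"negative interaction count {count}")
        self._entries[_canonical(a, b)] = float(count)

    def count(self, a: GenomeBin, b: GenomeBin) -> float:
        """Symmetric lookup; unrecorded pairs have count 0."""
        return self._entries.get(_canonical(a, b), 0.0)

    def pairs(self) -> Iterable[tuple[GenomeBin, GenomeBin, float]]:
        for (a, b), c in self._entries.items():
            yield a, b, c

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactMap)
            and self.enzyme_label == other.enzyme_label
            and self.bin_size == other.bin_size
            and self._entries == other._entries
        )


@dataclass(frozen=True)
class PartnerRanking:
    """Bins ranked by interaction count with a fixed anchor bin.

    The anchor never appears as its own partner and counts are
    non-increasing down the list; ties are broken by chromosome name then
    bin index so rankings are deterministic.
    """

    anchor: GenomeBin
    scope: Scope
    ranked: tuple[tuple[GenomeBin, float], ...]
    enzyme_label: str = ""

    def top(self, k: Optional[int]) -> tuple[tuple[GenomeBin, float], ...]:
        return self.ranked if k is None else self.ranked[:k]


def rank_partners(
    cmap: ContactMap,
    anchor: GenomeBin,
    scope: Scope = "all",
    top_k: Optional[int] = None,
) -> PartnerRanking:
    """Rank all partner bins of ``anchor`` by descending interaction count.

    ``scope`` restricts partners to the anchor's chromosome ("intra"),
    other chromosomes ("inter"), or no restriction ("all").
    """
    if scope not in _SCOPES:
        raise InvalidArgumentError(f"scope must be one of {_SCOPES}, got {scope!r}")
    if anchor.bin_size != cmap.bin_size:
        raise IncompatibleResolutionError(
            f"anchor bin size {anchor.bin_size} != map bin size {cmap.bin_size}"
        )
    hits: list[tuple[GenomeBin, float]] = []
    for a, b, c in cmap.pairs():
        if anchor not in (a, b):
            continue
        partner = b if a == anchor else a
        if partner == anchor:  # self-interaction excluded
            continue
        if scope == "intra" and partner.chrom != anchor.chrom:
            continue
        if scope == "inter" and partner.chrom == anchor.chrom:
            continue
        hits.append((partner, c))
    hits.sort(key=lambda pc: (-pc[1], pc[0].chrom, pc[0].index))
    if top_k is not None:
        hits = hits[:top_k]
    return PartnerRanking(
        anchor=anchor,
        scope=scope,
        ranked=tuple(hits),
        enzyme_label=cmap.enzyme_label,
    )


def consensus_top_partners(
    rankings: list[PartnerRanking], k: int
) -> list[GenomeBin]:
    """Combine per-enzyme-map rankings into one ordered partner-bin list.

    A bin is considered by each map in which it appears among that map's
    top-``k`` partners. Bins are ordered by (number of supporting maps
    descending, best rank across maps ascending, chromosome, index), so a
    partner supported by every enzyme map precedes one seen in only one.
    """
    if not rankings:
        return []
    anchor, scope = rankings[0].anchor, rankings[0].scope
    for r in rankings[1:]:
        if r.anchor != anchor or r.scope != scope:
            raise InvalidArgumentError(
                "consensus requires rankings with a common anchor and scope"
            )
    support: dict[GenomeBin, int] = {}
    best_rank: dict[GenomeBin, int] = {}
    for r in rankings:
        for rank, (b, _c) in enumerate(r.top(k), start=1):
            support[b] = support.get(b, 0) + 1
            best_rank[b] = min(best_rank.get(b, rank), rank)
    return sorted(
        support,
        key=lambda b: (-support[b], best_rank[b], b.chrom, b.index),
    )


# --- I/O -----------------------------------------------------------------

def read_contact_map(path, enzyme_label: Optional[str] = None) -> ContactMap:
    """Read the contact TSV dialect; a single row populates both orientations.

    The same unordered pair appearing twice with different counts is a
    consistency error (the map would be asymmetric).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    entries: dict[tuple, float] = {}
    saw_header = False
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not saw_header:
                if line != HEADER:
                    raise ParseError(path, line_no, f"expected header {HEADER!r}")
                saw_header = True
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(path, line_no, f"expected 5 columns, got {len(fields)}")
            try:
                bin_size = int(meta.get("bin_size", DEFAULT_BIN_SIZE))
                a = GenomeBin(fields[0], int(fields[1]), bin_size)
                b = GenomeBin(fields[2], int(fields[3]), bin_size)
                c = float(fields[4])
            except (ValueError, InvalidArgumentError) as exc:
                raise ParseError(path, line_no, f"bad contact row: {exc}") from exc
            if c < 0:
                raise ParseError(path, line_no, f"negative count {c}")
            key = _canonical(a, b)
            if key in entries and entries[key] != c:
                raise ConsistencyError(
                    f"{path}:{line_no}: pair {a.chrom}:{a.index} ~ "
                    f"{b.chrom}:{b.index} recorded with conflicting counts "
                    f"{entries[key]} and {c}"
                )
            entries[key] = c
    if not saw_header:
        raise ParseError(path, 0, "missing contact-map header line")
    label = enzyme_label or meta.get("enzyme_label", path.stem)
    cmap = ContactMap(
        enzyme_label=label,
        bin_size=int(meta.get("bin_size", DEFAULT_BIN_SIZE)),
    )
    cmap._entries = entries
    return cmap


def _fmt_count(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(c)


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write canonical, deterministic contact TSV (re-read is an identity)."""
    rows = sorted(
        cmap.pairs(), key=lambda abc: (abc[0].chrom, abc[0].index, abc[1].chrom, abc[1].index)
    )
    with Path(path).open("w") as fh:
        fh.write(f"# enzyme_label={cmap.enzyme_label}\n")
        fh.write(f"# bin_size={cmap.bin_size}\n")
        fh.write(HEADER + "\n")
        for a, b, c in rows:
            fh.write(f"{a.chrom}\t{a.index}\t{b.chrom}\t{b.index}\t{_fmt_count(c)}\n")
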