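"""Independent brute-force oracles and random-instance builders for tests.

Everything here is deliberately naive (per-position scans, exhaustive
sorts) so it stays independent of the library code paths it checks.
"""

from itertools import combinations

import numpy as np

from regscout import ContactMap, GenomeBin, GenomicInterval, SignalTrack


def random_contact_map(rng: np.random.Generator, bin_size: int = 1000) -> ContactMap:
    cmap = ContactMap(enzyme_label="random", bin_size=bin_size)
    chroms = {f"chr{i + 1}": int(rng.integers(2, 7)) for i in range(int(rng.integers(1, 4)))}
    bins = [GenomeBin(c, i, bin_size) for c, n in chroms.items() for i in range(n)]
    for a, b in combinations(bins, 2):
        if rng.random() < 0.6:
            cmap.set_count(a, b, float(rng.integers(0, 50)))
    return cmap


def brute_force_ranking(cmap: ContactMap, anchor: GenomeBin, scope: str):
    """Exhaustive sort of every anchor-touching pair."""
    partners = {}
    for a, b, c in cmap.pairs():
        if anchor not in (a, b):
            continue
        partner = b if a == anchor else a
        if partner == anchor:
            continue
        if scope == "intra" and partner.chrom != anchor.chrom:
            continue
        if scope == "inter" and partner.chrom == anchor.chrom:
            continue
        partners[partner] = c
    return sorted(partners.items(), key=lambda kv: (-kv[1], kv[0].chrom, kv[0].index))


def brute_force_consensus(rankings, k):
    """Enumerate the union of top-k sets and sort by the documented key."""
    tops = [r.ranked[:k] for r in rankings]
    union = {b for top in tops for b, _c in top}
    def key(bin_):
        support = sum(any(b == bin_ for b, _ in top) for top in tops)
        ranks = [
            i + 1
            for top in tops
            for i, (b, _) in enumerate(top)
            if b == bin_
        ]
        return (-support, min(ranks), bin_.chrom, bin_.index)
    return sorted(union, key=key)


def random_track(
    rng: np.random.Generator, chrom: str = "chrR", span: int = 3000, max_intervals: int = 20
) -> SignalTrack:
    n = int(rng.integers(0, max_intervals + 1))
    cuts = sorted(rng.choice(np.arange(1, span), size=min(2 * n, span - 1), replace=False))
    intervals = []
    for s, e in zip(cuts[0::2], cuts[1::2]):
        intervals.append((GenomicInterval(chrom, int(s), int(e)), float(rng.integers(0, 10))))
    return SignalTrack(intervals=tuple(intervals), track_label="random")


def per_base_values(track: SignalTrack, query: GenomicInterval) -> np.ndarray:
    vals = np.zeros(query.length)
    for iv, v in track.intervals:
        if iv.chrom != query.chrom:
            continue
        lo, hi = max(iv.start, query.start), min(iv.end, query.end)
        if lo <= hi:
            vals[lo - query.start : hi - query.start + 1] = v
    return vals


def peak_region_oracle(track, query, frac, max_gap, min_width):
    """Position-by-position rebuild of the highest-enrichment-region rule.

    Returns the (start, end) of the run containing the leftmost maximum,
    or None.
    """
    vals = per_base_values(track, query)
    peak = vals.max() if len(vals) else 0.0
    if peak <= 0:
        return None
    above = vals >= frac * peak
    runs = []
    current = None
    for offset, flag in enumerate(above):
        if flag:
            if current is None:
                current = [offset, offset]
            elif offset - current[1] - 1 <= max_gap:
                current[1] = offset
            else:
                runs.append(tuple(current))
                current = [offset, offset]
    if current is not None:
        runs.append(tuple(current))
    runs = [(s, e) for s, e in runs if e - s + 1 >= min_width]
    argmax = int(np.argmax(vals))
    for s, e in runs:
        if s <= argmax <= e:
            return (query.start + s, query.start + e)
    return None


def screen_assignment_oracle(variants, candidates):
    """Per-variant, per-region membership by explicit bound checks."""
    assignment = {c.label: [] for c in candidates}
    for v in variants:
        for c in candidates:
            iv = c.region.interval
            if v.chrom == iv.chrom and iv.start <= v.pos <= iv.end:
                assignment[c.label].append(v)
    return assignment
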