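"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the statistical shape of the pipeline's three
inputs so every stage can be exercised and validated without downloads:

* contact maps — intra-chromosomal expected counts follow a power-law
  decay ``base_count * d**(-decay_exponent)`` in bin distance ``d`` (the
  canonical ~1/d scaling of contact frequency), a small constant
  background for inter-chromosomal pairs, Poisson noise on every expected
  count, and optional planted high-contact bin pairs (expected count
  multiplied);
* signal tracks — fixed-width background tiles with exponential heights
  plus planted rectangular plateaus (the ground-truth enhancers);
* cohorts — exactly the planted (site, carriers) structure plus optional
  uniform background variants.

Everything is a pure function of the :class:`SimulationConfig` (seed
included), so identical configs give bitwise-identical outputs.

:func:`build_fixture` writes the worked-example data set: two enzyme
maps whose counts around the NF1-containing bin match the published
values, an enhancer-mark track with plateaus at regions A and B, the NF1
annotation, the three TF-binding sites, the two catalogued rare variants,
and a 47-patient cohort carrying the three reported variants.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .contact_map import ContactMap, write_contact_map
from .errors import InvalidArgumentError
from .genome import (
    GeneAnnotation,
    GenomeBin,
    GenomicInterval,
    write_gene_bed,
)
from .signal_track import SignalTrack, write_bedgraph
from .variant_screen import (
    KnownVariantRecord,
    PatientVariant,
    TFBindingSite,
    write_cohort_vcf,
    write_known_variants,
    write_tf_sites,
)


@dataclass(frozen=True)
class PlantedContact:
    chrom_a: str
    index_a: int
    chrom_b: str
    index_b: int
    multiplier: float


@dataclass(frozen=True)
class PlantedPeak:
    interval: GenomicInterval
    height: float


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: tuple[str, ...]
    zygosity: str = "het"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic data set.

    ``chromosomes`` maps chromosome name to its bin count; all synthetic
    coordinates live on the implied spans. ``base_count`` is the expected
    intra-chromosomal count at bin distance 1 and ``inter_count`` the flat
    inter-chromosomal expectation. ``signal_background`` is the mean of the
    exponential tile heights (0 disables background); ``signal_tile`` the
    tile width in bp.
    """

    seed: int = 0
    bin_size: int = 10_000
    chromosomes: Mapping[str, int] = field(default_factory=lambda: {"chrS1": 20})
    decay_exponent: float = 1.0
    base_count: float = 50.0
    inter_count: float = 1.0
    planted_contacts: tuple[PlantedContact, ...] = ()
    signal_background: float = 1.0
    signal_tile: int = 100
    planted_peaks: tuple[PlantedPeak, ...] = ()
    cohort_size: int = 47
    planted_variants: tuple[PlantedVariant, ...] = ()
    background_variant_rate: float = 0.0
    background_variant_span: Optional[GenomicInterval] = None

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise InvalidArgumentError(
                f"decay exponent must be > 0, got {self.decay_exponent}"
            )
        if self.base_count <= 0:
            raise InvalidArgumentError(f"base count must be > 0, got {self.base_count}")
        if self.bin_size < 1 or self.signal_tile < 1:
            raise InvalidArgumentError("bin size and signal tile must be >= 1")
        peaks = sorted(
            self.planted_peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )
        for a, b in zip(peaks, peaks[1:]):
            if a.interval.overlaps(b.interval):
                raise InvalidArgumentError(
                    f"planted peaks overlap: {a.interval} and {b.interval}"
                )
        seen = set()
        for pv in self.planted_variants:
            for patient in pv.carriers:
                key = (patient, pv.chrom, pv.pos, pv.alt)
                if key in seen:
                    raise InvalidArgumentError(
                        f"duplicate planted (patient, site): {key}"
                    )
                seen.add(key)

    def patient_ids(self) -> list[str]:
        width = len(str(self.cohort_size))
        return [f"P{i:0{width}d}" for i in range(1, self.cohort_size + 1)]


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    # crc32 keys the sub-stream stably across processes (str hash is not)
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def simulate_contact_map(cfg: SimulationConfig, enzyme_label: str) -> ContactMap:
    """Draw one symmetric Poisson contact map under ``cfg``."""
    rng = _rng(cfg, f"contacts/{enzyme_label}")
    planted = {
        tuple(sorted([(p.chrom_a, p.index_a), (p.chrom_b, p.index_b)])): p.multiplier
        for p in cfg.planted_contacts
    }
    cmap = ContactMap(enzyme_label=enzyme_label, bin_size=cfg.bin_size)
    chroms = sorted(cfg.chromosomes)
    for ci, chrom_a in enumerate(chroms):
        n_a = cfg.chromosomes[chrom_a]
        for i in range(n_a):
            # intra-chromosomal, i < j
            for j in range(i + 1, n_a):
                mu = cfg.base_count * (j - i) ** (-cfg.decay_exponent)
                mu *= planted.get(((chrom_a, i), (chrom_a, j)), 1.0)
                cmap.set_count(
                    GenomeBin(chrom_a, i, cfg.bin_size),
                    GenomeBin(chrom_a, j, cfg.bin_size),
                    float(rng.poisson(mu)),
                )
            # inter-chromosomal against later chromosomes
            for chrom_b in chroms[ci + 1:]:
                for j in range(cfg.chromosomes[chrom_b]):
                    mu = cfg.inter_count
                    mu *= planted.get(((chrom_a, i), (chrom_b, j)), 1.0)
                    if mu <= 0:
                        continue
                    cmap.set_count(
                        GenomeBin(chrom_a, i, cfg.bin_size),
                        GenomeBin(chrom_b, j, cfg.bin_size),
                        float(rng.poisson(mu)),
                    )
    return cmap


def simulate_signal_track(cfg: SimulationConfig, track_label: str = "synthetic") -> SignalTrack:
    """Exponential background tiles with planted plateaus overlaid."""
    rng = _rng(cfg, "signal")
    tiles: list[tuple[GenomicInterval, float]] = []
    if cfg.signal_background > 0:
        for chrom in sorted(cfg.chromosomes):
            span_end = cfg.chromosomes[chrom] * cfg.bin_size - 1
            starts = np.arange(1, span_end + 1, cfg.signal_tile)
            heights = rng.exponential(cfg.signal_background, size=len(starts))
            for s, h in zip(starts, heights):
                tiles.append(
                    (
                        GenomicInterval(chrom, int(s), min(int(s) + cfg.signal_tile - 1, span_end)),
                        float(h),
                    )
                )
    # carve out room for each plateau, then insert it
    for peak in cfg.planted_peaks:
        piv = peak.interval
        carved: list[tuple[GenomicInterval, float]] = []
        for iv, h in tiles:
            if not iv.overlaps(piv):
                carved.append((iv, h))
                continue
            if iv.start < piv.start:
                carved.append((GenomicInterval(iv.chrom, iv.start, piv.start - 1), h))
            if iv.end > piv.end:
                carved.append((GenomicInterval(iv.chrom, piv.end + 1, iv.end), h))
        carved.append((piv, peak.height))
        tiles = carved
    tiles.sort(key=lambda t: (t[0].chrom, t[0].start))
    return SignalTrack(intervals=tuple(tiles), track_label=track_label)


def simulate_cohort(cfg: SimulationConfig) -> list[PatientVariant]:
    """Exactly the planted carriers, plus optional background variants."""
    ids = set(cfg.patient_ids())
    out: list[PatientVariant] = []
    for pv in cfg.planted_variants:
        for patient in pv.carriers:
            if patient not in ids:
                raise InvalidArgumentError(
                    f"planted carrier {patient} exceeds cohort size {cfg.cohort_size}"
                )
            out.append(
                PatientVariant(
                    patient_id=patient,
                    chrom=pv.chrom,
                    pos=pv.pos,
                    ref=pv.ref,
                    alt=pv.alt,
                    zygosity=pv.zygosity,
                )
            )
    if cfg.background_variant_rate > 0:
        if cfg.background_variant_span is None:
            raise InvalidArgumentError(
                "background_variant_rate needs background_variant_span"
            )
        rng = _rng(cfg, "cohort")
        span = cfg.background_variant_span
        planted_positions = {(pv.chrom, pv.pos) for pv in cfg.planted_variants}
        taken = set()
        for patient in cfg.patient_ids():
            for _ in range(rng.poisson(cfg.background_variant_rate)):
                pos = int(rng.integers(span.start, span.end + 1))
                if (span.chrom, pos) in planted_positions or (patient, pos) in taken:
                    continue
                taken.add((patient, pos))
                ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
                out.append(
                    PatientVariant(
                        patient_id=patient,
                        chrom=span.chrom,
                        pos=pos,
                        ref=str(ref),
                        alt=str(alt),
                    )
                )
    return out


# --- the worked-example fixture ------------------------------------------

REGION_A = GenomicInterval("chr17", 28_846_790, 28_847_790)
REGION_B = GenomicInterval("chr17", 29_378_421, 29_379_750)
NF1_GENE = GeneAnnotation(
    name="NF1",
    interval=GenomicInterval("chr17", 29_421_945, 29_709_134),
    strand="+",
)
TF_SITES = (
    TFBindingSite("p300", GenomicInterval("chr17", 28_846_840, 28_847_158)),
    TFBindingSite("c-Fos", GenomicInterval("chr17", 28_846_815, 28_847_158)),
    TFBindingSite("c-Jun", GenomicInterval("chr17", 28_846_819, 28_847_094)),
)
# alleles for the two catalogued SNPs are a synthetic convention (only the
# rs ids, positions and frequencies are published); carrier overlap is the
# minimal arrangement giving 5 distinct carriers
KNOWN_VARIANTS = (
    KnownVariantRecord(
        id="rs78190160", chrom="chr17", pos=28_847_605, ref="G", alt="A",
        clinical_significance="uncertain", maf=0.007, mac=16,
    ),
    KnownVariantRecord(
        id="rs71372224", chrom="chr17", pos=28_846_883, ref="C", alt="A",
        clinical_significance="uncertain", maf=0.007, mac=16,
    ),
)
COHORT_SIZE = 47
FIXTURE_VARIANTS = (
    PlantedVariant("chr17", 28_846_793, "C", "T", carriers=("P01", "P02")),
    PlantedVariant("chr17", 28_847_605, "G", "A", carriers=("P01", "P03", "P04")),
    PlantedVariant("chr17", 28_846_883, "C", "A", carriers=("P02", "P03", "P05")),
)
# peak heights encode only the published ordering (A higher than B)
FIXTURE_PEAK_A = 10.0
FIXTURE_PEAK_B = 4.0

HINDIII_COUNTS = {(28, 29): 703.0, (29, 31): 222.0, (29, 32): 59.0}
NCOI_COUNTS = {(28, 29): 255.0, (29, 31): 699.0, (29, 32): 150.0}
NCOI_INTER = (("chr1", 0), ("chr17", 29), 21.0)


def fixture_maps() -> list[ContactMap]:
    hindiii = ContactMap(enzyme_label="HindIII", bin_size=1_000_000)
    for (i, j), c in HINDIII_COUNTS.items():
        hindiii.set_count(GenomeBin("chr17", i), GenomeBin("chr17", j), c)
    ncoi = ContactMap(enzyme_label="NcoI", bin_size=1_000_000)
    for (i, j), c in NCOI_COUNTS.items():
        ncoi.set_count(GenomeBin("chr17", i), GenomeBin("chr17", j), c)
    (ca, ia), (cb, ib), count = NCOI_INTER
    ncoi.set_count(GenomeBin(ca, ia), GenomeBin(cb, ib), count)
    return [hindiii, ncoi]


def fixture_track() -> SignalTrack:
    # low background blocks sit far (> any merge gap) from the plateaus so
    # called regions coincide exactly with the plateaus
    intervals = (
        (GenomicInterval("chr17", 28_500_000, 28_500_500), 1.0),
        (REGION_A, FIXTURE_PEAK_A),
        (GenomicInterval("chr17", 29_100_000, 29_100_400), 1.2),
        (REGION_B, FIXTURE_PEAK_B),
    )
    return SignalTrack(intervals=intervals, track_label="H3K27ac")


def fixture_cohort() -> list[PatientVariant]:
    cfg = SimulationConfig(
        cohort_size=COHORT_SIZE, planted_variants=FIXTURE_VARIANTS
    )
    return simulate_cohort(cfg)


def fixture_patient_ids() -> list[str]:
    return SimulationConfig(cohort_size=COHORT_SIZE).patient_ids()


def build_fixture(outdir) -> dict[str, Path]:
    """Write the complete worked-example data set; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hindiii_map": outdir / "hindiii_map.tsv",
        "ncoi_map": outdir / "ncoi_map.tsv",
        "signal": outdir / "h3k27ac.bedgraph",
        "gene": outdir / "nf1.bed",
        "tf_sites": outdir / "tf_sites.bed",
        "catalog": outdir / "known_variants.tsv",
        "cohort": outdir / "cohort.vcf",
    }
    hindiii, ncoi = fixture_maps()
    write_contact_map(hindiii, paths["hindiii_map"])
    write_contact_map(ncoi, paths["ncoi_map"])
    write_bedgraph(fixture_track(), paths["signal"])
    write_gene_bed(NF1_GENE, paths["gene"])
    write_tf_sites(TF_SITES, paths["tf_sites"])
    write_known_variants(KNOWN_VARIANTS, paths["catalog"])
    write_cohort_vcf(fixture_cohort(), fixture_patient_ids(), paths["cohort"])
    return paths
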