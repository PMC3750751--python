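"""Cohort variant screening against candidate regulatory regions.

Variants carried by cohort patients are assigned to candidate regions by
inclusive interval membership, annotated for novelty against a
known-variant catalog (allele-aware: same chromosome, position, ref and
alt), and checked for overlap with transcription-factor binding sites.
The per-region summary gives the count of distinct variant sites and of
distinct carrier patients — the numbers a mutation-screening study
reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ConsistencyError, InvalidArgumentError, ParseError
from .genome import GenomicInterval, interval_from_bed
from .selection import CandidateRegion

NOVEL = "novel"


@dataclass(frozen=True)
class PatientVariant:
    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str = "het"  # het | hom

    def __post_init__(self):
        if self.pos < 1:
            raise InvalidArgumentError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InvalidArgumentError(f"ref and alt alleles are identical: {self.ref}")
        if self.zygosity not in ("het", "hom"):
            raise InvalidArgumentError(f"zygosity must be het or hom, got {self.zygosity!r}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class KnownVariantRecord:
    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    clinical_significance: str = ""
    maf: Optional[float] = None
    mac: Optional[int] = None

    def __post_init__(self):
        if self.maf is not None and not (0 <= self.maf <= 0.5):
            raise InvalidArgumentError(f"minor-allele frequency out of range: {self.maf}")


@dataclass(frozen=True)
class TFBindingSite:
    factor: str
    interval: GenomicInterval
    evidence: str = ""


@dataclass(frozen=True)
class SiteSummary:
    chrom: str
    pos: int
    ref: str
    alt: str
    region_label: str
    novelty: str  # "novel" or "known:<id>"
    carriers: tuple[str, ...]
    tf_hits: tuple[str, ...]

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class RegionSummary:
    label: str
    interval: GenomicInterval
    distinct_sites: int
    carrier_patients: int
    zero_variants: bool


@dataclass(frozen=True)
class ScreenReport:
    regions: tuple[RegionSummary, ...]
    sites: tuple[SiteSummary, ...]
    cohort_size: Optional[int] = None

    def region(self, label: str) -> RegionSummary:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    def sites_in(self, label: str) -> list[SiteSummary]:
        return [s for s in self.sites if s.region_label == label]

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "region": s.region_label,
                    "novelty": s.novelty,
                    "carrier_count": s.carrier_count,
                    "carriers": ",".join(s.carriers),
                    "tf_sites": ",".join(s.tf_hits),
                }
                for s in self.sites
            ],
            columns=[
                "chrom", "pos", "ref", "alt", "region", "novelty",
                "carrier_count", "carriers", "tf_sites",
            ],
        )

    def region_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": r.label,
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "distinct_sites": r.distinct_sites,
                    "carrier_patients": r.carrier_patients,
                    "zero_variants": r.zero_variants,
                }
                for r in self.regions
            ],
            columns=[
                "region", "chrom", "start", "end",
                "distinct_sites", "carrier_patients", "zero_variants",
            ],
        )

    def summary_text(self) -> str:
        lines = []
        for r in self.regions:
            lines.append(
                f"{r.label} ({r.interval.chrom}:{r.interval.start}-{r.interval.end}): "
                f"{r.distinct_sites} distinct variant site(s), "
                f"{r.carrier_patients} carrier patient(s)"
                + (" [no variants]" if r.zero_variants else "")
            )
            for s in self.sites_in(r.label):
                tf = f"; TF sites: {', '.join(s.tf_hits)}" if s.tf_hits else ""
                lines.append(
                    f"  {s.chrom}:{s.pos} {s.ref}>{s.alt} {s.novelty} "
                    f"in {s.carrier_count} patient(s){tf}"
                )
        total = len({p for s in self.sites for p in s.carriers})
        denom = f"/{self.cohort_size}" if self.cohort_size else ""
        lines.append(f"total carrier patients across regions: {total}{denom}")
        return "\n".join(lines)


def sites_overlapping(chrom: str, pos: int, sites: Sequence[TFBindingSite]) -> list[TFBindingSite]:
    return [s for s in sites if s.interval.contains(chrom, pos)]


def site_overlap_count(chrom: str, pos: int, sites: Sequence[TFBindingSite]) -> int:
    """Number of TF-binding-site intervals containing ``pos`` (inclusive)."""
    if pos < 1:
        raise InvalidArgumentError(f"position must be >= 1, got {pos}")
    return len(sites_overlapping(chrom, pos, sites))


def screen(
    variants: Sequence[PatientVariant],
    candidates: Sequence[CandidateRegion],
    catalog: Sequence[KnownVariantRecord] = (),
    sites: Sequence[TFBindingSite] = (),
    cohort_size: Optional[int] = None,
) -> ScreenReport:
    """Screen a cohort's variants against candidate regions.

    A variant belongs to a candidate iff its position lies within the
    candidate's region interval (both bounds inclusive). Novelty depends
    only on (chrom, pos, ref, alt) and the catalog, never on carriers.
    """
    known = {(k.chrom, k.pos, k.ref, k.alt): k.id for k in catalog}

    seen: set[tuple[str, tuple]] = set()
    for v in variants:
        key = (v.patient_id, v.site)
        if key in seen:
            raise ConsistencyError(
                f"duplicate record for patient {v.patient_id} at "
                f"{v.chrom}:{v.pos} {v.ref}>{v.alt}"
            )
        seen.add(key)

    site_summaries: list[SiteSummary] = []
    region_summaries: list[RegionSummary] = []
    for cand in candidates:
        iv = cand.region.interval
        assigned = [v for v in variants if iv.contains(v.chrom, v.pos)]
        by_site: dict[tuple, list[PatientVariant]] = {}
        for v in assigned:
            by_site.setdefault(v.site, []).append(v)
        for (chrom, pos, ref, alt), carriers in sorted(by_site.items()):
            rsid = known.get((chrom, pos, ref, alt))
            site_summaries.append(
                SiteSummary(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    region_label=cand.label,
                    novelty=NOVEL if rsid is None else f"known:{rsid}",
                    carriers=tuple(sorted({v.patient_id for v in carriers})),
                    tf_hits=tuple(
                        s.factor for s in sites_overlapping(chrom, pos, sites)
                    ),
                )
            )
        carrier_ids = {v.patient_id for v in assigned}
        if cohort_size is not None and len(carrier_ids) > cohort_size:
            raise ConsistencyError(
                f"region {cand.label} has {len(carrier_ids)} carriers but the "
                f"cohort holds {cohort_size} patients"
            )
        region_summaries.append(
            RegionSummary(
                label=cand.label,
                interval=iv,
                distinct_sites=len(by_site),
                carrier_patients=len(carrier_ids),
                zero_variants=not by_site,
            )
        )
    return ScreenReport(
        regions=tuple(region_summaries),
        sites=tuple(site_summaries),
        cohort_size=cohort_size,
    )


# --- cohort I/O ----------------------------------------------------------

COHORT_TSV_COLUMNS = ["patient_id", "chrom", "pos", "ref", "alt", "zygosity"]


def read_cohort_variants(path, format: Optional[str] = None) -> list[PatientVariant]:
    """Read per-patient variant calls from VCF or TSV.

    One record per (patient, carried site); reference-only genotypes
    produce no record. Multi-allelic VCF rows are split into biallelic
    records. ``format`` defaults from the file extension.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        records = _read_cohort_vcf(path)
    elif format == "tsv":
        records = _read_cohort_tsv(path)
    else:
        raise InvalidArgumentError(f"unknown cohort format {format!r}")
    seen = set()
    for v in records:
        key = (v.patient_id, v.site)
        if key in seen:
            raise ConsistencyError(
                f"{path}: duplicate record for patient {v.patient_id} at "
                f"{v.chrom}:{v.pos}"
            )
        seen.add(key)
    return records


def _read_cohort_vcf(path: Path) -> list[PatientVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[PatientVariant] = []
    for record in vcf:
        for alt_index, alt in enumerate(record.ALT, start=1):
            for sample_index, genotype in enumerate(record.genotypes):
                alleles = [a for a in genotype[:-1] if a >= 0]
                if not alleles:
                    continue
                copies = alleles.count(alt_index)
                if copies == 0:
                    continue
                zygosity = "hom" if copies == len(alleles) and len(alleles) > 1 else "het"
                out.append(
                    PatientVariant(
                        patient_id=samples[sample_index],
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        zygosity=zygosity,
                    )
                )
    return out


def _read_cohort_tsv(path: Path) -> list[PatientVariant]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(path, 0, f"unreadable cohort TSV: {exc}") from exc
    missing = [c for c in COHORT_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(path, 1, f"cohort TSV missing columns {missing}")
    out = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                PatientVariant(
                    patient_id=str(row.patient_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    zygosity=str(row.zygosity),
                )
            )
        except (ValueError, InvalidArgumentError) as exc:
            raise ParseError(path, row_number, f"bad cohort row: {exc}") from exc
    return out


def write_cohort_tsv(variants: Sequence[PatientVariant], path) -> None:
    rows = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt, v.patient_id))
    with Path(path).open("w") as fh:
        fh.write("\t".join(COHORT_TSV_COLUMNS) + "\n")
        for v in rows:
            fh.write(
                f"{v.patient_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.zygosity}\n"
            )


def write_cohort_vcf(
    variants: Sequence[PatientVariant],
    patient_ids: Sequence[str],
    path,
) -> None:
    """Write a minimal VCF v4.2 with one sample column per cohort patient."""
    by_site: dict[tuple, dict[str, str]] = {}
    for v in variants:
        if v.patient_id not in patient_ids:
            raise InvalidArgumentError(
                f"variant carrier {v.patient_id} is not in the cohort"
            )
        by_site.setdefault(v.site, {})[v.patient_id] = (
            "1/1" if v.zygosity == "hom" else "0/1"
        )
    chroms = sorted({site[0] for site in by_site})
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(patient_ids)
            + "\n"
        )
        for (chrom, pos, ref, alt), carriers in sorted(by_site.items()):
            gts = "\t".join(carriers.get(p, "0/0") for p in patient_ids)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# --- catalog and TF-site I/O --------------------------------------------

CATALOG_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "clinical_significance", "maf", "mac"]


def read_known_variants(path) -> list[KnownVariantRecord]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(path, 1, f"catalog TSV missing columns {missing}")
    out = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                KnownVariantRecord(
                    id=str(row.id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    clinical_significance=str(row.clinical_significance),
                    maf=None if pd.isna(row.maf) else float(row.maf),
                    mac=None if pd.isna(row.mac) else int(row.mac),
                )
            )
        except (ValueError, InvalidArgumentError) as exc:
            raise ParseError(path, row_number, f"bad catalog row: {exc}") from exc
    return out


def write_known_variants(records: Sequence[KnownVariantRecord], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for k in sorted(records, key=lambda k: (k.chrom, k.pos, k.alt)):
            maf = "" if k.maf is None else f"{k.maf:g}"
            mac = "" if k.mac is None else str(k.mac)
            fh.write(
                f"{k.id}\t{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t"
                f"{k.clinical_significance}\t{maf}\t{mac}\n"
            )


def read_tf_sites(path) -> list[TFBindingSite]:
    """Read TF-binding sites from BED4 (name column = factor)."""
    path = Path(path)
    out = []
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
            out.append(TFBindingSite(factor=fields[3], interval=iv))
    return out


def write_tf_sites(sites: Sequence[TFBindingSite], path) -> None:
    with Path(path).open("w") as fh:
        for s in sites:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start - 1}\t{s.interval.end}\t{s.factor}\n"
            )
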