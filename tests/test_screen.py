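import numpy as np
import pytest

from regscout import (
    GenomicInterval,
    PatientVariant,
    bin_of_position,
    screen,
    site_overlap_count,
)
from regscout.errors import ConsistencyError, InvalidArgumentError
from regscout.selection import CandidateRegion
from regscout.signal_track import EnrichmentRegion
from regscout.simulate import (
    COHORT_SIZE,
    KNOWN_VARIANTS,
    TF_SITES,
    fixture_cohort,
    fixture_patient_ids,
)
from regscout.variant_screen import (
    read_cohort_variants,
    write_cohort_tsv,
    write_cohort_vcf,
)

from _oracles import screen_assignment_oracle


def make_candidate(label, chrom, start, end):
    return CandidateRegion(
        region=EnrichmentRegion(GenomicInterval(chrom, start, end), 1.0, 0.0),
        source_bin=bin_of_position(chrom, start),
        supporting_counts={},
        distance_to_gene=None,
        locality="distal",
        label=label,
    )


REGION_A_CAND = make_candidate("A", "chr17", 28_846_790, 28_847_790)
REGION_B_CAND = make_candidate("B", "chr17", 29_378_421, 29_379_750)


class TestCohortIO:
    def test_vcf_fixture_contains_two_novel_variant_carriers(self, fixture_paths):
        variants = read_cohort_variants(fixture_paths["cohort"])
        at_793 = [v for v in variants if v.pos == 28_846_793]
        assert sorted(v.patient_id for v in at_793) == ["P01", "P02"]
        assert all(v.zygosity == "het" for v in at_793)
        assert all((v.ref, v.alt) == ("C", "T") for v in at_793)

    def test_all_reference_vcf_yields_no_records(self, tmp_path):
        path = tmp_path / "ref.vcf"
        write_cohort_vcf([], ["P1", "P2"], path)
        # a site with no carriers would not even be written; add one hom-ref row
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\n"
        )
        assert read_cohort_variants(path) == []

    def test_tsv_and_vcf_of_same_cohort_agree(self, tmp_path):
        cohort = fixture_cohort()
        vcf_path, tsv_path = tmp_path / "c.vcf", tmp_path / "c.tsv"
        write_cohort_vcf(cohort, fixture_patient_ids(), vcf_path)
        write_cohort_tsv(cohort, tsv_path)
        from_vcf = set(read_cohort_variants(vcf_path))
        from_tsv = set(read_cohort_variants(tsv_path))
        assert from_vcf == from_tsv

    def test_multiallelic_vcf_rows_are_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n"
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/2\n"
        )
        variants = sorted(read_cohort_variants(path), key=lambda v: (v.patient_id, v.alt))
        assert [(v.patient_id, v.alt, v.zygosity) for v in variants] == [
            ("P1", "G", "het"),
            ("P1", "T", "het"),
            ("P2", "T", "het"),
        ]

    def test_duplicate_patient_site_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "patient_id\tchrom\tpos\tref\talt\tzygosity\n"
            "P1\tchr1\t100\tA\tG\thet\n"
            "P1\tchr1\t100\tA\tG\thet\n"
        )
        with pytest.raises(ConsistencyError):
            read_cohort_variants(path)


class TestScreen:
    def test_fixture_screen_reproduces_reported_counts(self, fixture_paths):
        report = screen(
            read_cohort_variants(fixture_paths["cohort"]),
            [REGION_A_CAND, REGION_B_CAND],
            KNOWN_VARIANTS,
            TF_SITES,
            cohort_size=COHORT_SIZE,
        )
        region_a = report.region("A")
        assert region_a.distinct_sites == 3
        assert region_a.carrier_patients == 5
        region_b = report.region("B")
        assert region_b.distinct_sites == 0
        assert region_b.zero_variants

        by_pos = {s.pos: s for s in report.sites}
        assert by_pos[28_846_793].novelty == "novel"
        assert by_pos[28_846_793].carrier_count == 2
        assert by_pos[28_847_605].novelty == "known:rs78190160"
        assert by_pos[28_847_605].carrier_count == 3
        assert by_pos[28_846_883].novelty == "known:rs71372224"
        assert set(by_pos[28_846_883].tf_hits) == {"p300", "c-Fos", "c-Jun"}

    def test_empty_cohort_gives_zero_flags(self):
        report = screen([], [REGION_A_CAND, REGION_B_CAND])
        assert all(r.zero_variants for r in report.regions)
        assert report.sites == ()

    def test_novelty_is_allele_aware(self):
        # same position as rs71372224, different alt allele
        variant = PatientVariant("P1", "chr17", 28_846_883, "C", "G")
        report = screen([variant], [REGION_A_CAND], KNOWN_VARIANTS)
        assert report.sites[0].novelty == "novel"

    def test_duplicate_patient_site_rejected(self):
        v = PatientVariant("P1", "chr17", 28_846_793, "C", "T")
        with pytest.raises(ConsistencyError):
            screen([v, v], [REGION_A_CAND])

    def test_matches_membership_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(19)
        regions = [
            make_candidate("R1", "chr9", 1_000, 2_000),
            make_candidate("R2", "chr9", 5_000, 5_500),
            make_candidate("R3", "chr10", 100, 900),
        ]
        for _ in range(25):
            variants = []
            seen = set()
            for _ in range(30):
                patient = f"P{rng.integers(1, 9)}"
                chrom = str(rng.choice(["chr9", "chr10"]))
                pos = int(rng.integers(1, 7_000))
                if (patient, chrom, pos) in seen:
                    continue
                seen.add((patient, chrom, pos))
                variants.append(PatientVariant(patient, chrom, pos, "A", "T"))
            report = screen(variants, regions)
            expected = screen_assignment_oracle(variants, regions)
            for region in report.regions:
                exp = expected[region.label]
                assert region.distinct_sites == len({v.site for v in exp})
                assert region.carrier_patients == len({v.patient_id for v in exp})
            # conservation across disjoint regions
            assert sum(r.distinct_sites for r in report.regions) == len(
                {v.site for vs in expected.values() for v in vs}
            )

    def test_screen_is_additive_over_cohort_partition(self):
        cohort = fixture_cohort()
        half1 = [v for v in cohort if v.patient_id in ("P01", "P02")]
        half2 = [v for v in cohort if v.patient_id not in ("P01", "P02")]
        whole = screen(cohort, [REGION_A_CAND])
        part1 = screen(half1, [REGION_A_CAND])
        part2 = screen(half2, [REGION_A_CAND])
        merged_carriers = {
            p for rep in (part1, part2) for s in rep.sites for p in s.carriers
        }
        assert merged_carriers == {p for s in whole.sites for p in s.carriers}
        merged_sites = {(s.chrom, s.pos, s.ref, s.alt) for rep in (part1, part2) for s in rep.sites}
        assert merged_sites == {(s.chrom, s.pos, s.ref, s.alt) for s in whole.sites}


class TestTFSiteOverlap:
    @pytest.mark.parametrize(
        "pos,count",
        [
            (28_846_883, 3),   # rs71372224 inside all three sites
            (1, 0),
            (28_847_100, 2),   # inside p300 and c-Fos, past the c-Jun end
            (28_847_158, 2),   # inclusive right bound of p300/c-Fos
            (28_846_815, 1),   # inclusive left bound of c-Fos only
        ],
    )
    def test_inclusive_bounds_against_published_sites(self, pos, count):
        assert site_overlap_count("chr17", pos, TF_SITES) == count

    def test_wrong_chromosome_never_counts(self):
        assert site_overlap_count("chr1", 28_846_883, TF_SITES) == 0

    def test_nonpositive_position_rejected(self):
        with pytest.raises(InvalidArgumentError):
            site_overlap_count("chr17", 0, TF_SITES)
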