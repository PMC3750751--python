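import numpy as np
import pytest

from regscout import (
    GenomeBin,
    GenomicInterval,
    highest_enrichment_region,
    rank_partners,
    select_candidates,
    simulate_cohort,
    simulate_contact_map,
    simulate_signal_track,
)
from regscout.errors import InvalidArgumentError
from regscout.selection import SelectionParams
from regscout.simulate import (
    PlantedContact,
    PlantedPeak,
    PlantedVariant,
    SimulationConfig,
)

TWO_CHROMS = {"chrS1": 20, "chrS2": 20}


def planted_cfg(seed, decay=1.0, multiplier=20.0):
    """One planted partner bin (distance 5 from the anchor at bin 10) with
    a plateau enhancer inside it, over exponential signal background."""
    peak = PlantedPeak(GenomicInterval("chrS1", 54_000, 55_000), height=10.0)
    return SimulationConfig(
        seed=seed,
        bin_size=10_000,
        chromosomes=TWO_CHROMS,
        decay_exponent=decay,
        base_count=50.0,
        inter_count=1.0,
        planted_contacts=(PlantedContact("chrS1", 5, "chrS1", 10, multiplier),),
        signal_background=1.0,
        signal_tile=100,
        planted_peaks=(peak,),
    )


class TestContactSimulation:
    def test_same_seed_gives_identical_maps(self):
        cfg = planted_cfg(seed=4)
        assert simulate_contact_map(cfg, "E") == simulate_contact_map(cfg, "E")

    def test_different_enzyme_labels_give_independent_draws(self):
        cfg = planted_cfg(seed=4)
        assert simulate_contact_map(cfg, "E1") != simulate_contact_map(cfg, "E2")

    def test_map_is_symmetric_by_construction(self):
        cmap = simulate_contact_map(planted_cfg(seed=2), "E")
        for a, b, c in cmap.pairs():
            assert cmap.count(b, a) == c >= 0

    def test_mean_count_follows_distance_decay(self):
        # replicate draws of two fixed-distance pairs vs their expectations
        base, decay = 50.0, 1.0
        for d in (1, 4):
            draws = []
            for seed in range(300):
                cfg = SimulationConfig(
                    seed=seed, chromosomes={"chrS1": d + 1}, base_count=base,
                    decay_exponent=decay, inter_count=0.0, signal_background=0.0,
                )
                cmap = simulate_contact_map(cfg, "E")
                draws.append(cmap.count(GenomeBin("chrS1", 0, cfg.bin_size),
                                        GenomeBin("chrS1", d, cfg.bin_size)))
            mu = base * d ** -decay
            se = np.sqrt(mu / len(draws))
            assert abs(np.mean(draws) - mu) < 3 * se

    def test_planted_pair_dominates_partner_ranking(self):
        hits = 0
        for seed in range(20):
            cfg = planted_cfg(seed)
            cmap = simulate_contact_map(cfg, "E")
            anchor = GenomeBin("chrS1", 10, cfg.bin_size)
            top = rank_partners(cmap, anchor, "intra").ranked[0][0]
            hits += top == GenomeBin("chrS1", 5, cfg.bin_size)
        assert hits >= 19

    def test_invalid_decay_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(decay_exponent=0.0)


class TestSignalSimulation:
    def test_same_seed_gives_identical_tracks(self):
        cfg = planted_cfg(seed=8)
        assert simulate_signal_track(cfg) == simulate_signal_track(cfg)

    def test_zero_background_no_peaks_gives_empty_track(self):
        cfg = SimulationConfig(signal_background=0.0)
        assert simulate_signal_track(cfg).intervals == ()

    def test_planted_plateau_is_recovered(self):
        cfg = planted_cfg(seed=3)
        track = simulate_signal_track(cfg)
        region = highest_enrichment_region(
            track, GenomeBin("chrS1", 5, cfg.bin_size).interval
        )
        plateau = cfg.planted_peaks[0].interval
        assert region is not None
        assert region.interval.overlaps(plateau)
        assert region.peak_height == cfg.planted_peaks[0].height

    def test_overlapping_planted_peaks_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(
                planted_peaks=(
                    PlantedPeak(GenomicInterval("c", 100, 200), 5.0),
                    PlantedPeak(GenomicInterval("c", 150, 250), 5.0),
                )
            )


class TestCohortSimulation:
    def test_planted_structure_is_exact(self):
        cfg = SimulationConfig(
            cohort_size=10,
            planted_variants=(
                PlantedVariant("chr1", 100, "A", "G", ("P01", "P03")),
            ),
        )
        cohort = simulate_cohort(cfg)
        assert sorted(v.patient_id for v in cohort) == ["P01", "P03"]
        assert all((v.chrom, v.pos) == ("chr1", 100) for v in cohort)

    def test_empty_plant_zero_background_gives_empty_cohort(self):
        assert simulate_cohort(SimulationConfig(cohort_size=5)) == []

    def test_carrier_outside_cohort_rejected(self):
        cfg = SimulationConfig(
            cohort_size=3,
            planted_variants=(PlantedVariant("chr1", 100, "A", "G", ("P9",)),),
        )
        with pytest.raises(InvalidArgumentError):
            simulate_cohort(cfg)

    def test_duplicate_planted_patient_site_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(
                planted_variants=(
                    PlantedVariant("chr1", 100, "A", "G", ("P01", "P01")),
                )
            )

    def test_background_variants_stay_outside_given_span(self):
        span = GenomicInterval("chrB", 1, 10_000)
        cfg = SimulationConfig(
            seed=6, cohort_size=10, background_variant_rate=1.0,
            background_variant_span=span,
        )
        cohort = simulate_cohort(cfg)
        assert cohort, "expected some background variants at rate 1.0"
        assert all(span.contains(v.chrom, v.pos) for v in cohort)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("decay", [0.8, 1.0, 1.5])
    def test_pipeline_recovers_planted_enhancer_across_decay_grid(self, decay):
        from regscout import GeneAnnotation

        gene = GeneAnnotation("SYN", GenomicInterval("chrS1", 104_000, 106_000))
        hits = 0
        n = 15
        for seed in range(n):
            cfg = planted_cfg(seed=1000 + seed, decay=decay, multiplier=20.0)
            cmap = simulate_contact_map(cfg, "E")
            track = simulate_signal_track(cfg)
            candidates = select_candidates([cmap], gene, track, SelectionParams())
            if candidates and candidates[0].region.interval.overlaps(
                cfg.planted_peaks[0].interval
            ):
                hits += 1
        assert hits >= int(0.9 * n)
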