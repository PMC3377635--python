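import numpy as np
import pytest

from deepcoral.biogeo import (
    SpeciesDepthRange,
    curate_records,
    diversity_profile,
    genus_depth_summary,
    species_depth_ranges,
    species_shallower_than,
    tukey_five_numbers,
)
from deepcoral.datamodel import SpecimenRecord
from deepcoral.synthetic import RecordSimConfig, simulate_records


def rec(rid, dmin, dmax, genus="G", species="sp1", n_colonies=1):
    return SpecimenRecord(record_id=rid, genus=genus, species=species,
                          depth_min_m=dmin, depth_max_m=dmax,
                          n_colonies=n_colonies)


def fivenum_oracle(values):
    """Brute-force sort-and-hinge computation, independent of the library."""
    xs = sorted(values)
    n = len(xs)

    def med(seq):
        m = len(seq)
        return seq[m // 2] if m % 2 else (seq[m // 2 - 1] + seq[m // 2]) / 2

    k = (n + 1) // 2
    return xs[0], med(xs[:k]), med(xs), med(xs[-k:]), xs[-1]


class TestCuration:
    def test_point_record_never_excluded_by_range_rule(self):
        curated, _ = curate_records([rec("r1", 500, 500)])
        assert not curated[0].excluded_range_rule and curated[0].retained

    def test_wide_trawl_excluded_by_hand_arithmetic(self):
        # mean 250 m, range 300 m > 125 m: excluded
        curated, report = curate_records([rec("r1", 100, 400)])
        assert curated[0].excluded_range_rule
        assert report.n_excluded_range == 1 and report.n_retained == 0

    def test_range_exactly_half_of_mean_is_retained(self):
        # strict inequality: range 200 m == 0.5 * mean 400 m passes
        curated, _ = curate_records([rec("r1", 300, 500)])
        assert curated[0].retained

    def test_manual_exclusion_takes_precedence(self):
        curated, report = curate_records([rec("bad", 100, 400)], ["bad"])
        assert curated[0].excluded_manual
        assert report.n_excluded_manual == 1 and report.n_excluded_range == 0

    def test_depth_point_is_interval_mean(self):
        curated, _ = curate_records([rec("r1", 570, 2262)])
        assert curated[0].depth_point_m == pytest.approx((570 + 2262) / 2)

    def test_accounting_identity_and_colony_conservation(self):
        records = [rec(f"r{i}", 100 + i, 100 + i, n_colonies=i + 1)
                   for i in range(10)]
        records.append(rec("wide", 100, 400, n_colonies=5))
        curated, report = curate_records(records, ["r3"])
        assert report.n_input == report.n_retained + \
            report.n_excluded_range + report.n_excluded_manual
        assert report.n_colonies_retained == sum(
            c.record.n_colonies for c in curated if c.retained
        )


class TestTukeySummary:
    def test_single_record_all_five_equal(self):
        curated, _ = curate_records([rec("r1", 500, 500)])
        s = genus_depth_summary(curated)[0]
        assert s.minimum == s.lower_hinge == s.median == s.upper_hinge \
            == s.maximum == 500

    def test_extreme_depth_flagged_as_outlier(self):
        records = [rec(f"r{i}", d, d) for i, d in
                   enumerate([100, 200, 300, 400, 10000])]
        s = genus_depth_summary(curate_records(records)[0])[0]
        assert s.outliers == (10000,)
        assert s.median == 300

    @pytest.mark.parametrize("seed", range(100))
    def test_hinges_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(10, 4000, size=rng.integers(1, 40)).tolist()
        assert tukey_five_numbers(values) == pytest.approx(
            fivenum_oracle(values)
        )

    def test_summary_omits_genus_with_no_retained_records(self):
        records = [rec("keep", 500, 500, genus="A"),
                   rec("wide", 100, 400, genus="B")]
        summaries = genus_depth_summary(curate_records(records)[0])
        assert [s.genus for s in summaries] == ["A"]


class TestSpeciesRanges:
    def test_single_record_zero_width_range(self):
        ranges = species_depth_ranges(curate_records([rec("r1", 600, 600)])[0])
        assert ranges[0].depth_lo == ranges[0].depth_hi == 600

    def test_hand_built_three_record_species(self):
        records = [rec("a", 200, 200), rec("b", 900, 900), rec("c", 400, 600)]
        r = species_depth_ranges(curate_records(records)[0])[0]
        assert (r.depth_lo, r.depth_hi, r.n_records) == (200, 900, 3)

    def test_raw_extremes_mode_uses_station_bounds(self):
        records = [rec("a", 400, 600)]
        avg = species_depth_ranges(curate_records(records)[0])[0]
        raw = species_depth_ranges(curate_records(records)[0],
                                   use_raw_extremes=True)[0]
        assert (avg.depth_lo, avg.depth_hi) == (500, 500)
        assert (raw.depth_lo, raw.depth_hi) == (400, 600)

    def test_species_ranges_nest_within_genus_extent(self):
        records = [rec(f"r{i}", 100 * i, 100 * i, species=f"sp{i % 3 + 1}")
                   for i in range(1, 10)]
        curated, _ = curate_records(records)
        ranges = species_depth_ranges(curated)
        depths = [c.depth_point_m for c in curated]
        for r in ranges:
            assert min(depths) <= r.depth_lo <= r.depth_hi <= max(depths)


class TestShallowerThan:
    def test_all_deep_gives_zero(self):
        ranges = [SpeciesDepthRange("a", 500, 900, 2)]
        assert species_shallower_than(ranges, 200)[0] == 0

    def test_boundary_is_strict(self):
        ranges = [SpeciesDepthRange("a", 200, 900, 2)]
        assert species_shallower_than(ranges, 200)[0] == 0
        assert species_shallower_than(ranges, 200.1)[0] == 1

    def test_hand_built_mixed_set(self):
        ranges = [
            SpeciesDepthRange("shallow1", 50, 300, 2),
            SpeciesDepthRange("shallow2", 150, 2000, 3),
            SpeciesDepthRange("deep", 600, 1200, 4),
        ]
        count, names = species_shallower_than(ranges, 200)
        assert count == 2 and names == ["shallow1", "shallow2"]


class TestDiversityProfile:
    def test_single_species_overlap_bins(self):
        profile = diversity_profile([SpeciesDepthRange("a", 150, 450, 3)])
        hits = {b: c for b, c in zip(profile.bins(), profile.counts) if c}
        assert hits == {(100, 200): 1, (200, 300): 1, (300, 400): 1,
                        (400, 500): 1}

    def test_two_species_share_a_bin(self):
        ranges = [SpeciesDepthRange("a", 50, 120, 1),
                  SpeciesDepthRange("b", 150, 450, 1)]
        profile = diversity_profile(ranges)
        assert dict(zip(profile.bins(), profile.counts))[(100, 200)] == 2

    def test_double_counting_identity_and_order_invariance(self, rng):
        ranges = [
            SpeciesDepthRange(f"s{i}", lo, lo + span, 1)
            for i, (lo, span) in enumerate(
                zip(rng.uniform(10, 4000, 30), rng.uniform(0, 800, 30))
            )
        ]
        profile = diversity_profile(ranges)
        per_species = [
            sum(1 for lo, hi in profile.bins()
                if r.depth_lo < hi and r.depth_hi >= lo)
            for r in ranges
        ]
        assert sum(profile.counts) == sum(per_species)
        shuffled = list(ranges)
        rng.shuffle(shuffled)
        assert diversity_profile(shuffled).counts == profile.counts

    def test_widening_a_range_never_decreases_counts(self, rng):
        ranges = [SpeciesDepthRange(f"s{i}", lo, lo + 50, 1)
                  for i, lo in enumerate(rng.uniform(100, 4000, 10))]
        before = diversity_profile(ranges).counts
        widened = [SpeciesDepthRange(r.species, r.depth_lo - 60,
                                     r.depth_hi + 60, r.n_records)
                   for r in ranges]
        after = diversity_profile(widened).counts
        assert all(a >= b for a, b in zip(after, before))

    def test_range_beyond_max_depth_lands_in_terminal_bin(self):
        profile = diversity_profile([SpeciesDepthRange("deep", 4600, 4800, 1)],
                                    max_depth=4500)
        assert profile.counts[-1] == 1 and sum(profile.counts) == 1

    def test_point_mode_counts_levels_inside_interval(self):
        profile = diversity_profile([SpeciesDepthRange("a", 150, 450, 1)],
                                    mode="point")
        hits = {lo for (lo, _), c in zip(profile.bins(), profile.counts) if c}
        assert hits == {200, 300, 400}


class TestCurationAgainstSimulatorTruth:
    @pytest.mark.parametrize("seed", range(100))
    def test_flags_equal_truth_flags(self, seed):
        cfg = RecordSimConfig(n_records=60, n_forced_range_violations=4,
                              n_forced_manual_exclusions=2, seed=seed)
        records, truth = simulate_records(cfg)
        manual = [r for r, v in truth.record_excluded_manual.items() if v]
        curated, report = curate_records(records, manual)
        for c in curated:
            rid = c.record.record_id
            assert c.excluded_range_rule == truth.record_excluded_range[rid]
            assert c.excluded_manual == truth.record_excluded_manual[rid]
        assert report.n_retained == 60 - 6
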