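"""Pseudo-marker construction and permutation association."""

import math

import numpy as np
import pytest

from coacnv.association import (
    associate,
    build_pseudomarkers,
    carrier_odds_ratio,
    filter_for_association,
    marker_seed,
    permutation_test,
)
from coacnv.burden import BurdenTable, Stratum, fisher_exact_p
from coacnv.model import CnvSegment, Direction
from coacnv.report import fmt_p, round_half_away


def labels_for(n_cases, n_controls):
    out = {f"CA{i}": "case" for i in range(n_cases)}
    out.update({f"CO{i}": "control" for i in range(n_controls)})
    return out


class TestFilter:
    def test_marker_and_span_bounds(self, seg_factory):
        few_markers = seg_factory("A", "chr1", 0, 50_000, 1, nm=4)
        short = seg_factory("A", "chr1", 0, 9_999, 1, nm=9)
        boundary = seg_factory("A", "chr1", 0, 10_000, 1, nm=5)  # both bounds inclusive
        kept = filter_for_association([few_markers, short, boundary])
        assert kept == [boundary]

    def test_empty_input(self):
        assert filter_for_association([]) == []

    def test_missing_marker_count_is_an_error(self):
        seg = CnvSegment("A", "chr1", 0, 50_000, 1, None)
        with pytest.raises(ValueError, match="n_markers"):
            filter_for_association([seg])


class TestPseudoMarkers:
    def test_two_overlapping_segments_hand_sweep(self, genome, sample_factory, seg_factory):
        """Losses [100,200) and [150,250) in two samples: 4 positions, and
        both samples carry the markers at 150 and 200."""
        samples = [sample_factory("A"), sample_factory("B", status="control")]
        segs = [
            seg_factory("A", "chr1", 100, 200, 1),
            seg_factory("B", "chr1", 150, 250, 1),
        ]
        markers = build_pseudomarkers(segs, samples, genome)
        positions = [m.position for m in markers]
        assert positions == [100, 150, 200, 250]
        by_pos = {m.position: m.carriers for m in markers}
        assert by_pos[100] == {"A"}
        assert by_pos[150] == {"A", "B"}
        assert by_pos[200] == {"A", "B"}  # A's own endpoint still carried
        assert by_pos[250] == {"B"}

    def test_single_segment_two_markers(self, genome, sample_factory, seg_factory):
        samples = [sample_factory("A")]
        markers = build_pseudomarkers([seg_factory("A", "chr1", 5, 50, 3)], samples, genome)
        assert len(markers) == 2
        assert all(m.carriers == {"A"} for m in markers)
        assert all(m.direction is Direction.gain for m in markers)

    def test_marker_count_bound(self, genome, sample_factory, seg_factory):
        samples = [sample_factory("A")]
        segs = [seg_factory("A", "chr1", 100 * i, 100 * i + 50, 1) for i in range(20)]
        markers = build_pseudomarkers(segs, samples, genome)
        assert len(markers) <= 2 * len(segs)

    def test_directions_kept_separate(self, genome, sample_factory, seg_factory):
        samples = [sample_factory("A"), sample_factory("B")]
        segs = [
            seg_factory("A", "chr1", 100, 200, 1),  # loss
            seg_factory("B", "chr1", 100, 200, 3),  # gain at same breakpoints
        ]
        markers = build_pseudomarkers(segs, samples, genome)
        assert len(markers) == 4
        for m in markers:
            assert m.carriers == ({"A"} if m.direction is Direction.loss else {"B"})


class TestPermutationTest:
    def test_exhaustive_two_by_two(self):
        """2 cases + 2 controls, carriers exactly the cases: only 1 of the
        C(4,2)=6 assignments reaches T=2, so p = 1/6."""
        labels = labels_for(2, 2)
        p, t_obs = permutation_test({"CA0", "CA1"}, labels, mode="exhaustive")
        assert t_obs == 2
        assert p == pytest.approx(1 / 6)

    def test_all_carriers_ties_everywhere(self):
        labels = labels_for(3, 5)
        p, _ = permutation_test(set(labels), labels, n_perm=500, seed=1)
        assert p == 1.0

    def test_monte_carlo_floor(self):
        """A carrier set reachable by essentially no permutation bottoms out
        at (0+1)/(100000+1), printing as 1.0E-5."""
        labels = labels_for(40, 400)
        carriers = {f"CA{i}" for i in range(40)}  # all 40 cases, no controls
        p, t_obs = permutation_test(carriers, labels, n_perm=100_000, seed=3)
        assert t_obs == 40
        assert p == pytest.approx(1 / 100_001)
        assert fmt_p(p) == "1.0E-5"

    def test_exhaustive_guard(self):
        labels = labels_for(15, 15)
        with pytest.raises(ValueError, match="monte_carlo"):
            permutation_test({"CA0"}, labels, mode="exhaustive")

    def test_monte_carlo_matches_exhaustive_on_small_cohorts(self):
        """Spot-check beyond the acceptance sweep: MC at 1e5 within 0.01."""
        labels = labels_for(3, 4)
        carriers = {"CA0", "CA1", "CO0"}
        p_ex, _ = permutation_test(carriers, labels, mode="exhaustive")
        p_mc, _ = permutation_test(carriers, labels, n_perm=100_000, seed=9)
        assert abs(p_mc - p_ex) < 0.01

    def test_exhaustive_equals_one_sided_fisher(self):
        """The exhaustive permutation p of the carrier-count statistic equals
        the one-sided Fisher p of the carrier 2x2 table."""
        labels = labels_for(4, 6)
        for carriers in [{"CA0", "CA1", "CO3"}, {"CA0"}, {"CO0", "CO1"}, set(labels)]:
            p_ex, t_obs = permutation_test(carriers, labels, mode="exhaustive")
            a = t_obs            # case carriers
            b = 4 - a            # case non-carriers
            c = len(carriers) - a  # control carriers
            d = 6 - c            # control non-carriers
            t = BurdenTable(Stratum.autosomes, "all", a, b, c, d)
            assert p_ex == pytest.approx(fisher_exact_p(t, "greater"), abs=1e-12)

    def test_determinism_and_order_invariance(self):
        labels = labels_for(10, 30)
        carriers = {"CA0", "CA3", "CO5", "CO7"}
        p1, _ = permutation_test(carriers, labels, n_perm=5_000, seed=42)
        shuffled = dict(sorted(labels.items(), reverse=True))
        p2, _ = permutation_test(frozenset(carriers), shuffled, n_perm=5_000, seed=42)
        assert p1 == p2

    def test_unknown_carrier_rejected(self):
        with pytest.raises(ValueError, match="carriers"):
            permutation_test({"GHOST"}, labels_for(2, 2), n_perm=10, seed=0)


class TestCarrierOddsRatio:
    @pytest.mark.parametrize(
        "cc, nc, kc, nk, expected",
        [
            (43, 70, 103, 605, 7.76),
            (37, 70, 119, 605, 4.58),
            (6, 70, 1, 605, 56.63),  # 56.625 rounds half away from zero
        ],
    )
    def test_published_loci(self, cc, nc, kc, nk, expected):
        assert round_half_away(carrier_odds_ratio(cc, nc, kc, nk), 2) == expected

    def test_zero_cell_flagged(self):
        assert carrier_odds_ratio(5, 10, 0, 20) is None

    def test_overflow_counts_rejected(self):
        with pytest.raises(ValueError):
            carrier_odds_ratio(11, 10, 0, 20)


class TestAssociate:
    def _planted_cohort(self, sample_factory, seg_factory, n_cases=70, n_controls=605,
                        f_case=0.6, f_control=0.02, seed=7):
        rng = np.random.default_rng(seed)
        samples = [sample_factory(f"CA{i}", sex="female") for i in range(n_cases)]
        samples += [sample_factory(f"CO{i}", sex="female", status="control")
                    for i in range(n_controls)]
        segs = []
        for s in samples:
            f = f_case if s.status.value == "case" else f_control
            if rng.uniform() < f:
                segs.append(seg_factory(s.sample_id, "chr5", 1_000_000, 1_020_000, 1, nm=12))
        return samples, segs

    def test_planted_locus_recovered(self, genome, sample_factory, seg_factory):
        """A strongly case-enriched planted deletion is recovered as one
        merged locus at the floor p = 1/(n_perm+1); 100,000 permutations are
        needed because the +1-corrected floor at fewer draws sits above the
        5e-5 genome-wide threshold."""
        samples, segs = self._planted_cohort(sample_factory, seg_factory)
        results = associate(segs, samples, genome, n_perm=100_000, seed=7)
        assert len(results) == 1
        (r,) = results
        assert (r.chrom, r.start, r.end) == ("chr5", 1_000_000, 1_020_000)
        assert r.direction is Direction.loss
        # no permutation ties the observed statistic at this separation
        assert r.empirical_p == pytest.approx(1 / 100_001)

    def test_no_carriers_empty_result(self, genome, sample_factory):
        samples = [sample_factory("CA0"), sample_factory("CO0", status="control")]
        assert associate([], samples, genome, n_perm=100, seed=0) == []

    def test_distinct_carrier_sets_not_merged(self, genome, sample_factory, seg_factory):
        """Adjacent significant markers with different carrier sets stay
        separate loci."""
        samples = [sample_factory(f"CA{i}", sex="female") for i in range(30)]
        samples += [sample_factory(f"CO{i}", sex="female", status="control")
                    for i in range(300)]
        segs = []
        # locus 1: cases 0..19 carry [1e6, 1.02e6); locus 2 starts 1 kb
        # downstream and is carried by cases 5..24
        for i in range(20):
            segs.append(seg_factory(f"CA{i}", "chr3", 1_000_000, 1_020_000, 1, nm=12))
        for i in range(5, 25):
            segs.append(seg_factory(f"CA{i}", "chr3", 1_021_000, 1_041_000, 1, nm=12))
        results = associate(segs, samples, genome, n_perm=20_000, seed=11, threshold=1e-3)
        assert len(results) == 2
        assert {(r.start, r.end) for r in results} == {
            (1_000_000, 1_020_000),
            (1_021_000, 1_041_000),
        }

    def test_identical_carrier_sets_merged(self, genome, sample_factory, seg_factory):
        samples = [sample_factory(f"CA{i}", sex="female") for i in range(20)]
        samples += [sample_factory(f"CO{i}", sex="female", status="control")
                    for i in range(200)]
        segs = [seg_factory(f"CA{i}", "chr3", 1_000_000, 1_040_000, 1, nm=20)
                for i in range(15)]
        results = associate(segs, samples, genome, n_perm=20_000, seed=2, threshold=1e-3)
        assert len(results) == 1
        assert (results[0].start, results[0].end) == (1_000_000, 1_040_000)

    def test_x_analysis_is_sex_stratified(self, genome, sample_factory, seg_factory):
        """An X locus carried only by male cases is tested among males."""
        samples = [sample_factory(f"CA{i}", sex="male") for i in range(30)]
        samples += [sample_factory(f"CO{i}", sex="male", status="control")
                    for i in range(300)]
        samples += [sample_factory(f"CAF{i}", sex="female") for i in range(5)]
        segs = [seg_factory(f"CA{i}", "chrX", 30_000_000, 30_020_000, 2, nm=12)
                for i in range(20)]
        results = associate(segs, samples, genome, n_perm=20_000, seed=4, threshold=1e-3)
        assert len(results) == 1
        (r,) = results
        assert r.stratum == "male"
        assert r.n_cases == 30 and r.n_controls == 300

    def test_determinism_bit_identical(self, genome, sample_factory, seg_factory):
        samples, segs = self._planted_cohort(sample_factory, seg_factory, 30, 100, 0.5, 0.05)
        r1 = associate(segs, samples, genome, n_perm=2_000, seed=13, threshold=0.01)
        r2 = associate(segs, samples, genome, n_perm=2_000, seed=13, threshold=0.01)
        assert r1 == r2

    def test_marker_seed_stability(self):
        s = marker_seed(123, "chr1", 1_000, "loss")
        assert s == marker_seed(123, "chr1", 1_000, "loss")
        assert s != marker_seed(123, "chr1", 1_001, "loss")
        assert 0 <= s < 2**31 - 1
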