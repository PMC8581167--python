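"""Ring binning, normalisation cascade and percent-positive quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import micropattern as mp
from micropattern.profiling import BinGeometry, DEFAULT_BINS, RadialProfile, assign_bins


def brute_force_bin(d: float, bin_width: float = 25.0, n_bins: int = 20) -> int:
    """Independent oracle: linear search over half-open ring intervals."""
    for b in range(1, n_bins + 1):
        if (b - 1) * bin_width <= d < b * bin_width:
            return b
    return n_bins  # beyond the outer edge: clipped


class TestBinGeometry:
    def test_twenty_bins_tile_colony_radius(self):
        geom = BinGeometry()
        assert geom.n_bins == 20
        assert geom.bin_width_um == 25.0
        assert geom.max_radius_um == 500.0
        np.testing.assert_allclose(geom.edges_um, np.arange(0, 501, 25))

    def test_examples(self):
        assert mp.assign_bin(0.0) == 1
        assert mp.assign_bin(25.0) == 2      # half-open convention
        assert mp.assign_bin(24.999) == 1
        assert mp.assign_bin(499.9) == 20
        assert mp.assign_bin(600.0) == 20    # clipped

    def test_negative_distance_errors(self):
        with pytest.raises(ValueError):
            mp.assign_bin(-1.0)
        with pytest.raises(ValueError):
            assign_bins(np.array([1.0, -0.5]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 600, size=10_000)
        bins, n_clipped = assign_bins(d)
        expected = np.array([brute_force_bin(x) for x in d])
        np.testing.assert_array_equal(bins, expected)
        assert n_clipped == int(np.sum(d >= 500.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1000, allow_nan=False))
    def test_property_matches_oracle(self, d):
        assert mp.assign_bin(d) == brute_force_bin(d)


def test_nucleus_distance():
    assert mp.nucleus_distance((3, 4), (0, 0)) == pytest.approx(5.0)
    assert mp.nucleus_distance((1.5, -2.0), (1.5, -2.0)) == 0.0
    assert mp.nucleus_distance((10 + 25, 4), (10, 4)) == pytest.approx(25.0)


def test_normalize_nucleus():
    assert mp.normalize_nucleus(200.0, 100.0) == pytest.approx(2.0)
    assert mp.normalize_nucleus(0.0, 50.0) == 0.0
    assert mp.normalize_nucleus(400.0, 200.0) == mp.normalize_nucleus(200.0, 100.0)
    with pytest.raises(ValueError):
        mp.normalize_nucleus(1.0, 0.0)


class TestBackgroundEstimation:
    def test_mixture_recovery(self):
        """Background 0.1 / positive mode 1.0 mixture: background within 0.05."""
        rng = np.random.default_rng(21)
        neg = rng.normal(0.1, 0.03, size=600)
        pos = rng.normal(1.0, 0.12, size=400)
        model = mp.estimate_background(np.concatenate([neg, pos]), marker="M")
        assert model.method == "gmm"
        assert abs(model.background - 0.1) <= 0.05
        assert model.threshold > model.background

    def test_all_negative_well_near_zero_positive(self):
        rng = np.random.default_rng(22)
        ratios = np.abs(rng.normal(0.1, 0.03, size=800))
        model = mp.estimate_background(ratios, marker="M")
        rate = np.mean(model.is_positive(ratios))
        assert rate < 0.02

    def test_subtraction_floor(self):
        model = mp.PositivityModel(marker="M", background=0.2, threshold=0.3)
        out = model.subtract(np.array([0.05, 0.2, 0.5]))
        assert np.all(out >= 0)
        np.testing.assert_allclose(out, [0.0, 0.0, 0.3])

    def test_degenerate_distribution_falls_back_to_percentiles(self):
        ratios = np.full(100, 0.4)
        model = mp.estimate_background(ratios, marker="M")
        assert model.method == "percentile"

    def test_too_few_nuclei_errors(self):
        with pytest.raises(ValueError, match=">= 50"):
            mp.estimate_background(np.ones(10))


class TestColonyProfile:
    def test_flat_profile(self):
        bins = np.array([1, 1, 2, 5, 20])
        prof = mp.colony_profile(np.ones(5), bins, "M")
        occupied = ~np.isnan(prof.values)
        np.testing.assert_allclose(prof.values[occupied], 1.0)
        assert list(np.flatnonzero(occupied) + 1) == [1, 2, 5, 20]

    def test_empty_bins_are_missing_not_zero(self):
        prof = mp.colony_profile(np.array([2.0]), np.array([3]), "M")
        assert np.isnan(prof.values[0])
        assert prof.n[0] == 0
        assert prof.values[2] == 2.0

    def test_ring_simulation_peak_bin(self):
        """Ring at 425 um / width 40: colony profile argmax in bin 17 or 18."""
        rng = np.random.default_rng(3)
        model = mp.RadialExpressionModel(kind="ring", center_um=425, width_um=40,
                                         amplitude=1.2, baseline=0.0)
        d = 494 * np.sqrt(rng.random(2000))
        positive = rng.random(2000) < model.positive_fraction(d)
        ratios = model.expression_ratio(d, positive)
        bins, _ = assign_bins(d)
        prof = mp.colony_profile(ratios, bins, "M")
        assert prof.peak_bin() in (17, 18)

    def test_zero_nuclei_errors(self):
        with pytest.raises(ValueError):
            mp.colony_profile(np.array([]), np.array([]), "M")


class TestWellNormalize:
    def _profile(self, values):
        v = np.full(20, np.nan)
        v[:len(values)] = values
        return RadialProfile(marker="M", level="colony", values=v,
                             n=np.ones(20, dtype=int))

    def test_divides_by_well_max(self):
        profs = mp.well_normalize([self._profile([1.0, 4.0]), self._profile([2.0, 0.5])])
        assert np.nanmax([np.nanmax(p.values) for p in profs]) == pytest.approx(1.0)
        np.testing.assert_allclose(profs[0].values[:2], [0.25, 1.0])

    def test_single_colony_max_becomes_one(self):
        profs = mp.well_normalize([self._profile([0.5, 2.0])])
        assert np.nanmax(profs[0].values) == pytest.approx(1.0)

    def test_identical_colonies_stay_identical(self):
        a, b = mp.well_normalize([self._profile([1.0, 3.0]), self._profile([1.0, 3.0])])
        np.testing.assert_allclose(a.values, b.values)

    def test_idempotent(self):
        once = mp.well_normalize([self._profile([1.0, 4.0])])
        twice = mp.well_normalize(once)
        np.testing.assert_allclose(twice[0].values, once[0].values)

    def test_all_zero_well_left_alone(self):
        profs = mp.well_normalize([self._profile([0.0, 0.0])])
        np.testing.assert_allclose(profs[0].values[:2], 0.0)


class TestAggregate:
    def _profile(self, values):
        v = np.asarray(values, dtype=float)
        return RadialProfile(marker="M", level="colony", values=v,
                             n=np.ones(v.size, dtype=int),
                             geometry=BinGeometry(bin_width_um=25.0, n_bins=v.size))

    def test_identical_profiles_mean_same_sd_zero(self):
        p = self._profile([1.0, 2.0])
        agg = mp.aggregate([p, p], "well")
        np.testing.assert_allclose(agg.values, [1.0, 2.0])
        np.testing.assert_allclose(agg.sd, 0.0)

    def test_closed_form_sd(self):
        agg = mp.aggregate([self._profile([0.0, 1.0]), self._profile([1.0, 0.0])], "well")
        np.testing.assert_allclose(agg.values, [0.5, 0.5])
        np.testing.assert_allclose(agg.sd, np.sqrt(0.5), rtol=1e-12)

    def test_hierarchical_differs_from_pooling(self):
        """3-well toy, hand-computed: wells average colonies first."""
        w1 = mp.aggregate([self._profile([1.0]), self._profile([1.0]),
                           self._profile([1.0]), self._profile([1.0])], "well")
        w2 = mp.aggregate([self._profile([4.0])], "well")
        w3 = mp.aggregate([self._profile([7.0])], "well")
        exp = mp.aggregate([w1, w2, w3], "experiment")
        assert exp.values[0] == pytest.approx((1.0 + 4.0 + 7.0) / 3)  # = 4, not pooled 2.67
        pooled = np.mean([1, 1, 1, 1, 4, 7])
        assert exp.values[0] != pytest.approx(pooled)

    def test_missing_bins_propagate(self):
        a = self._profile([1.0, np.nan])
        b = self._profile([3.0, np.nan])
        agg = mp.aggregate([a, b], "well")
        assert np.isnan(agg.values[1])
        assert agg.n[1] == 0

    def test_mixed_geometry_errors(self):
        a = self._profile([1.0, 2.0])
        b = RadialProfile(marker="M", level="colony", values=np.ones(3),
                          n=np.ones(3), geometry=BinGeometry(10.0, 3))
        with pytest.raises(ValueError, match="geometr"):
            mp.aggregate([a, b], "well")


class TestPercentPositive:
    def test_exact_fraction(self):
        model = mp.PositivityModel(marker="M", background=0.0, threshold=0.5)
        ratios = np.concatenate([np.ones(30), np.zeros(70)])
        assert mp.percent_positive(ratios, model) == pytest.approx(30.0)

    def test_zero_positive(self):
        model = mp.PositivityModel(marker="M", background=0.0, threshold=0.5)
        assert mp.percent_positive(np.zeros(50), model) == 0.0

    def test_binomial_recovery_at_n800(self):
        """Configured positive fraction 0.4 recovered within 3 points at n=800."""
        rng = np.random.default_rng(17)
        positive = rng.random(800) < 0.4
        ratios = np.where(positive, rng.normal(1.0, 0.1, 800),
                          np.abs(rng.normal(0.1, 0.03, 800)))
        model = mp.estimate_background(ratios, marker="M")
        pct = mp.percent_positive(ratios, model)
        assert abs(pct - 40.0) <= 3.0
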