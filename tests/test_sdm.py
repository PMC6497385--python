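"""NDVI harmonics, pseudo-absences, network training, AUC, thresholding."""

import itertools

import numpy as np
import pytest

from herpatlas.geoio import RasterGrid
from herpatlas.sdm import (
    BinaryRange,
    NetConfig,
    PseudoAbsenceConfig,
    auc,
    contiguity_filter,
    eligible_for_sdm,
    fit_ensemble,
    ndvi_harmonics,
    presence_pixels,
    sample_pseudo_absences,
    threshold_binary,
    train_net,
)


class TestNdviHarmonics:
    def test_constant_series_has_zero_amplitude(self):
        c1, c2 = ndvi_harmonics(np.full(46, 0.4), period=23)
        assert c1 == pytest.approx(0.4)
        assert c2 == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_noiseless_cosine(self):
        t = np.arange(46)
        y = 0.5 + 0.2 * np.cos(2 * np.pi * t / 23)
        c1, c2 = ndvi_harmonics(y, period=23)
        assert c1 == pytest.approx(0.5)
        assert c2 == pytest.approx(0.2)

    @pytest.mark.parametrize("phase", [0.0, 0.7, 1.9, np.pi])
    def test_amplitude_invariant_to_phase(self, phase):
        t = np.arange(46)
        y = 0.3 + 0.15 * np.cos(2 * np.pi * t / 23 - phase)
        _, c2 = ndvi_harmonics(y, period=23)
        assert c2 == pytest.approx(0.15)

    def test_all_missing_pixel_is_nodata(self):
        series = np.column_stack([np.full(24, np.nan), np.full(24, 0.2)])
        c1, c2 = ndvi_harmonics(series, period=24)
        assert np.isnan(c1[0]) and np.isnan(c2[0])
        assert c1[1] == pytest.approx(0.2)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError):
            ndvi_harmonics(np.ones(10), period=23)


class TestEligibility:
    def test_pixel_unique_counting(self):
        grid = RasterGrid(0, 10, 1.0, np.zeros((10, 10)))
        # 7 records on 5 unique pixels
        lon = [0.5, 0.55, 1.5, 2.5, 3.5, 4.5, 4.6]
        lat = [9.5] * 7
        pres = presence_pixels(lon, lat, grid)
        assert len(pres) == 5
        assert eligible_for_sdm(pres)

    def test_below_minimum_routes_to_fallback(self):
        assert not eligible_for_sdm({(0, 0), (0, 1), (1, 0), (1, 1)})
        assert not eligible_for_sdm(set())


class TestPseudoAbsences:
    def world(self, n=30):
        dem = RasterGrid(0, n, 1.0, np.where(
            np.arange(n * n).reshape(n, n) % 2 == 0, 100.0, 900.0))
        return dem, np.ones((n, n), dtype=bool)

    def test_ratio_and_altitude_balance(self):
        dem, valid = self.world()
        pres = {(0, 0), (0, 1), (0, 2), (0, 3)}
        pa = sample_pseudo_absences(pres, dem, valid.copy(),
                                    PseudoAbsenceConfig(seed=1))
        assert len(pa) == 20
        elev = np.array([dem.values[r, c] for r, c in pa])
        assert (elev < 500).sum() == 10
        assert (elev >= 500).sum() == 10
        assert not (pa & pres)

    def test_world_below_split_reallocates_with_warning(self):
        n = 20
        dem = RasterGrid(0, n, 1.0, np.full((n, n), 50.0))
        pres = {(0, 0), (1, 1)}
        with pytest.warns(UserWarning, match="reallocated"):
            pa = sample_pseudo_absences(pres, dem, np.ones((n, n), bool),
                                        PseudoAbsenceConfig(seed=2))
        assert len(pa) == 10

    def test_same_seed_reproduces(self):
        dem, valid = self.world()
        pres = {(5, 5), (6, 6), (7, 7)}
        cfg = PseudoAbsenceConfig(seed=42)
        a = sample_pseudo_absences(pres, dem, valid.copy(), cfg)
        b = sample_pseudo_absences(pres, dem, valid.copy(), cfg)
        assert a == b


class TestTrainNet:
    def separable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal([2, 2], 0.3, (10, 2)),
                       rng.normal([-2, -2], 0.3, (10, 2))])
        y = np.array([1] * 10 + [0] * 10)
        return X, y

    def test_separable_toy_reaches_perfect_training_auc(self):
        X, y = self.separable()
        net = train_net(X, y, NetConfig(seed=0))
        s = net.predict(X)
        assert auc(s[y == 1], s[y == 0]) == 1.0

    def test_same_seed_gives_bit_identical_weights(self):
        X, y = self.separable()
        n1 = train_net(X, y, NetConfig(seed=3))
        n2 = train_net(X, y, NetConfig(seed=3))
        assert np.array_equal(n1.W1, n2.W1) and np.array_equal(n1.W2, n2.W2)

    def test_untrained_net_is_uninformative_on_random_labels(self):
        """With zero training, predictions come from random initial weights
        and should not separate randomly shuffled labels on average."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        cfg = NetConfig(iterations=1, learning_rate=1e-12, seed=0)
        aucs = []
        for i in range(300):
            y = rng.permutation([1] * 20 + [0] * 20)
            net = train_net(X, y, cfg, seed=i)
            s = net.predict(X)
            aucs.append(auc(s[y == 1], s[y == 0]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_labels_error(self):
        X, _ = self.separable()
        with pytest.raises(ValueError):
            train_net(X, np.ones(len(X)), NetConfig())

    def test_burn_in_discards_trace_only(self):
        X, y = self.separable()
        short = train_net(X, y, NetConfig(seed=1, burn_in=5))
        full = train_net(X, y, NetConfig(seed=1, burn_in=0))
        assert np.array_equal(short.W1, full.W1)
        assert len(full.loss_trace) == len(short.loss_trace) + 5


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_enumerated_pairs(self):
        # pairs: (.7>.5),(.7>.3),(.4<.5),(.4>.3) -> 3/4
        assert auc([0.7, 0.4], [0.5, 0.3]) == pytest.approx(0.75)

    def test_tie_counts_half(self):
        assert auc([0.5], [0.5]) == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos = rng.integers(0, 10, size=rng.integers(1, 20)) / 10
            neg = rng.integers(0, 10, size=rng.integers(1, 20)) / 10
            brute = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0
                for p, q in itertools.product(pos, neg)
            ])
            assert auc(pos, neg) == pytest.approx(brute, rel=1e-12)


def little_world(seed=0, n=40):
    """Small raster world with a sharp environmental gradient niche."""
    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n))
    bio1 = 20 + 10 * xx + 0.1 * rng.standard_normal((n, n))
    bio12 = 300 * yy + 5 * rng.standard_normal((n, n))
    grid = RasterGrid(0.0, float(n), 1.0, bio1)
    preds = {
        "ndvi_c1": grid.like(0.2 + 0.001 * bio12),
        "ndvi_c2": grid.like(0.1 + 0.0005 * bio12),
        "BIO1": grid.like(bio1),
        "BIO12": grid.like(bio12),
    }
    suit = np.exp(-(((bio1 - 21) / 1.0) ** 2 + ((bio12 - 250) / 40.0) ** 2))
    return grid, preds, suit


class TestEnsemble:
    def test_sharp_niche_scores_high_auc(self):
        grid, preds, suit = little_world()
        rng = np.random.default_rng(1)
        order = np.argsort(suit.ravel())[::-1]
        pres = {(int(i // 40), int(i % 40)) for i in order[:30]}
        pool = [(int(i // 40), int(i % 40)) for i in order[200:]]
        absn = {pool[j] for j in rng.choice(len(pool), 150, replace=False)}
        ens = fit_ensemble(preds, pres, absn,
                           NetConfig(replicates=5, iterations=500, seed=2))
        assert ens.auc_mean > 0.9

    def test_single_replicate_mean_is_that_replicate(self):
        grid, preds, suit = little_world()
        pres = {(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5)}
        absn = {(30 + i, 30 + j) for i in range(5) for j in range(6)}
        ens = fit_ensemble(preds, pres, absn,
                           NetConfig(replicates=1, iterations=100, seed=0),
                           keep_replicates=True)
        np.testing.assert_array_equal(ens.mean_raster.values,
                                      ens.replicate_rasters[0].values)
        assert ens.auc_sd == 0.0

    def test_shuffled_labels_give_chance_auc(self):
        grid, preds, suit = little_world()
        rng = np.random.default_rng(3)
        cells = [(int(r), int(c)) for r, c in rng.integers(0, 40, (300, 2))]
        cells = list(dict.fromkeys(cells))
        pres = set(cells[:40])
        absn = set(cells[40:240])
        ens = fit_ensemble(preds, pres, absn,
                           NetConfig(replicates=10, iterations=200, seed=4))
        assert ens.auc_mean == pytest.approx(0.5, abs=0.12)


class TestBinaryRange:
    def raster(self, vals):
        a = np.asarray(vals, dtype=float)
        return RasterGrid(0.0, float(a.shape[0]), 1.0, a)

    def test_threshold_is_minimum_presence_value(self):
        vals = np.array([[0.62, 0.35], [0.71, 0.10]])
        br = threshold_binary(self.raster(vals), {(0, 0), (0, 1), (1, 0)})
        assert br.threshold == pytest.approx(0.35)
        assert br.mask.tolist() == [[True, True], [True, False]]

    def test_uniform_raster_all_true(self):
        br = threshold_binary(self.raster(np.full((3, 3), 0.4)), {(1, 1)})
        assert br.mask.all()

    def test_monotone_in_raised_pixels(self):
        vals = np.array([[0.6, 0.2], [0.5, 0.1]])
        pres = {(0, 0)}
        before = threshold_binary(self.raster(vals), pres)
        vals2 = vals.copy()
        vals2[1, 1] = 0.9
        after = threshold_binary(self.raster(vals2), pres)
        assert not before.mask[1, 1] and after.mask[1, 1]
        assert (after.mask >= before.mask).all()

    def test_presences_always_inside(self):
        rng = np.random.default_rng(0)
        vals = rng.random((10, 10))
        pres = {(int(r), int(c)) for r, c in rng.integers(0, 10, (8, 2))}
        br = threshold_binary(self.raster(vals), pres)
        for r, c in pres:
            assert br.mask[r, c]


class TestContiguityFilter:
    def test_hand_labelled_components(self):
        mask = np.array([
            [1, 1, 0, 1],
            [0, 0, 0, 1],
            [1, 0, 0, 0],
        ], dtype=bool)
        grid = RasterGrid(0.0, 3.0, 1.0, mask.astype(float))
        br = BinaryRange(mask, 0.5, grid)
        out = contiguity_filter(br, {(0, 0)})
        assert out.mask.tolist() == [
            [True, True, False, False],
            [False, False, False, False],
            [False, False, False, False],
        ]
        assert out.n_components_retained == 1

    def test_diagonal_touch_counts_as_contiguous(self):
        mask = np.array([[1, 0], [0, 1]], dtype=bool)
        grid = RasterGrid(0.0, 2.0, 1.0, mask.astype(float))
        out = contiguity_filter(BinaryRange(mask, 0.5, grid), {(0, 0)})
        assert out.mask[1, 1]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        mask = rng.random((20, 20)) > 0.6
        pres = {tuple(p) for p in np.argwhere(mask)[:3]}
        grid = RasterGrid(0.0, 20.0, 1.0, mask.astype(float))
        once = contiguity_filter(BinaryRange(mask, 0.5, grid), pres)
        twice = contiguity_filter(once, pres)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_output_nested_in_input_and_valid_mask(self):
        rng = np.random.default_rng(6)
        vals = rng.random((15, 15))
        grid = RasterGrid(0.0, 15.0, 1.0, vals)
        pres = {(int(r), int(c)) for r, c in rng.integers(0, 15, (5, 2))}
        thresh = threshold_binary(grid, pres)
        filt = contiguity_filter(thresh, pres)
        assert (filt.mask <= thresh.mask).all()
        assert (thresh.mask <= grid.valid_mask).all()
        for r, c in pres:
            assert filt.mask[r, c]
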