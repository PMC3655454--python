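import numpy as np
import pytest

from caar.fractal import (
    BoxCountResult,
    EmbeddingConfig,
    GridLadder,
    box_count_curve,
    box_count_points,
    custom_grid_ladder,
    default_grid_ladder,
    embed_delay,
    fit_dimension,
    select_order,
)
from caar.fractal import _curve_count, _point_count
from caar.signal_io import TimeSeries
from caar.synthetic import gen_sine, gen_weierstrass

from oracles import brute_curve_cells, brute_point_cells


class TestGridLadder:
    def test_default_ladder_doubles_from_point_one(self):
        sizes = default_grid_ladder().sizes
        assert len(sizes) == 17
        assert sizes[0] == 0.1
        assert sizes[-1] == pytest.approx(6553.6)
        np.testing.assert_allclose(sizes[1:] / sizes[:-1], 2.0, rtol=0)
        assert np.all(sizes <= 10000)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            GridLadder(np.array([1.0, 2.0, 4.0]))

    def test_custom_ladder_respects_bound(self):
        lad = custom_grid_ladder(0.5, 100.0, 3.0)
        assert lad.sizes[0] == 0.5 and lad.sizes[-1] <= 100.0


class TestEmbedDelay:
    def test_definition_small_example(self):
        ps = embed_delay(
            TimeSeries(np.array([1.0, 2, 3, 4])), EmbeddingConfig(tau=1, L=1)
        )
        assert ps.vectors.tolist() == [[2, 1], [3, 2], [4, 3]]

    def test_zero_lags_returns_samples(self):
        v = np.array([5.0, 6, 7])
        ps = embed_delay(TimeSeries(v), EmbeddingConfig(tau=3, L=0))
        np.testing.assert_array_equal(ps.vectors.ravel(), v)

    def test_vector_count_formula(self):
        ps = embed_delay(
            TimeSeries(np.arange(10.0)), EmbeddingConfig(tau=2, L=2)
        )
        assert ps.vectors.shape == (6, 3)

    def test_span_must_fit(self):
        with pytest.raises(ValueError):
            embed_delay(TimeSeries(np.arange(10.0)), EmbeddingConfig(tau=5, L=2))


class TestFitDimension:
    def test_exact_line_recovered(self):
        sizes = 0.5 * 2.0 ** np.arange(8)
        counts = np.exp(8.0) / sizes  # log N = 1*log(1/eps) + 8
        slope, intercept, rng_, r2 = fit_dimension(sizes, counts, "full")
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert intercept == pytest.approx(8.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_auto_range_excludes_plateau(self):
        # clean slope-1.5 region then a flat plateau at the 4 largest sizes
        sizes = 2.0 ** np.arange(12)
        counts = np.exp(1.5 * np.log(1.0 / sizes) + 20)
        counts[-4:] = counts[-5]
        slope, _, rng_, _ = fit_dimension(sizes, counts, "auto")
        assert slope == pytest.approx(1.5, abs=0.01)
        assert rng_[1] <= 7  # plateau indices 8..11 excluded

    def test_auto_matches_exhaustive_window_scan(self, rng):
        sizes = 2.0 ** np.arange(10)
        counts = np.ceil(
            np.exp(1.2 * np.log(1.0 / sizes) + 12 + rng.normal(0, 0.05, 10))
        )
        slope, _, win, r2 = fit_dimension(sizes, counts, "auto")
        # brute force every contiguous window of >= 5 points
        best = None
        for i in range(10):
            for j in range(i + 4, 10):
                lx = np.log(1.0 / sizes[i : j + 1])
                ly = np.log(counts[i : j + 1])
                b, a = np.polyfit(lx, ly, 1)
                ssr = float(np.sum((ly - (b * lx + a)) ** 2))
                sst = float(np.sum((ly - ly.mean()) ** 2))
                key = (round(1 - ssr / sst, 12), j - i + 1, -i)
                if best is None or key > best[0]:
                    best = (key, (i, j))
        assert win == best[1]

    def test_explicit_range_restricts_points(self):
        sizes = 2.0 ** np.arange(8)
        counts = 1000.0 / sizes
        counts[0] = 5000  # corrupt a point outside the explicit range
        slope, _, win, _ = fit_dimension(sizes, counts, (2, 6))
        assert win == (2, 6)
        assert slope == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dimension([1, 2, 4], [8, 4, 2], "full")

    def test_zero_count_in_range_rejected(self):
        sizes = 2.0 ** np.arange(6)
        counts = np.array([32, 16, 8, 4, 2, 0])
        with pytest.raises(ValueError, match="count"):
            fit_dimension(sizes, counts, "full")


class TestCurveCounting:
    def test_horizontal_segment_count(self):
        # flat polyline spanning T=63 index units: ceil(T/eps) cells (+-1)
        ts = TimeSeries(np.full(64, 2.5))
        for eps in (1.7, 5.0, 12.3):
            n = _curve_count(
                np.arange(1.0, 65.0), ts.values, eps
            )
            assert abs(n - np.ceil(63.0 / eps)) <= 1

    def test_diagonal_line_dimension_one(self):
        line = TimeSeries(np.arange(1.0, 4097.0))
        res = box_count_curve(line)
        assert 0.9 <= res.slope <= 1.1

    def test_smooth_sine_dimension_near_one(self):
        ts = gen_sine(512, amplitude=2048, noise_sd=0.0, length=4096)
        res = box_count_curve(ts)
        assert 0.9 <= res.slope <= 1.2

    def test_weierstrass_recovers_closed_form_dimension(self):
        w = gen_weierstrass(0.7, 3.0, length=4096)
        v = w.values
        v = 1 + (v - v.min()) * (4095 / (v.max() - v.min()))
        res = box_count_curve(TimeSeries(v))
        expected = 2 + np.log(0.7) / np.log(3.0)  # ~1.675
        assert res.slope == pytest.approx(expected, abs=0.2)

    def test_normalize_rescales_to_standard_box(self):
        ts = gen_sine(512, amplitude=1e-3, noise_sd=0.0, length=2048)
        res = box_count_curve(ts, normalize=True)
        assert 0.9 <= res.slope <= 1.2

    def test_counts_monotone_in_eps(self, rng):
        ts = TimeSeries(rng.normal(0, 40, 800))
        res = box_count_curve(ts)
        assert np.all(np.diff(res.counts) <= 0)

    def test_scaling_invariance_of_slope(self, rng):
        y = rng.normal(0, 10, 300)
        lad = custom_grid_ladder(0.5, 200.0)
        c1 = np.array([_curve_count(np.arange(1.0, 301.0), y, e) for e in lad.sizes])
        s = 7.3  # rescale both axes and the ladder together
        c2 = np.array(
            [_curve_count(s * np.arange(1.0, 301.0), s * y, s * e) for e in lad.sizes]
        )
        f1 = fit_dimension(lad.sizes, c1, "full")[0]
        f2 = fit_dimension(s * lad.sizes, c2, "full")[0]
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(4):
            n = int(rng.integers(20, 200))
            y = rng.normal(0, rng.uniform(1, 25), n)
            t = np.arange(1.0, n + 1.0)
            for eps in (float(rng.uniform(0.9, 3)), float(rng.uniform(3, 12))):
                assert _curve_count(t, y, eps) == len(
                    brute_curve_cells(t, y, eps)
                )


class TestPointCounting:
    def test_identical_vectors_occupy_one_cell(self):
        ps = embed_delay(
            TimeSeries(np.full(30, 4.2)), EmbeddingConfig(tau=1, L=2)
        )
        counts = [_point_count(ps.vectors, e) for e in (0.5, 2.0, 8.0)]
        assert counts == [1, 1, 1]

    def test_uniform_interval_dimension_one(self, rng):
        ps = embed_delay(
            TimeSeries(rng.uniform(0, 100, 20000)), EmbeddingConfig(tau=1, L=0)
        )
        res = box_count_points(ps)
        assert res.slope == pytest.approx(1.0, abs=0.2)

    def test_uniform_square_dimension_two(self, rng):
        ps = embed_delay(
            TimeSeries(rng.uniform(0, 100, 20000)), EmbeddingConfig(tau=1, L=1)
        )
        res = box_count_points(ps)
        assert res.slope == pytest.approx(2.0, abs=0.2)

    def test_matches_brute_force_occupancy(self, rng):
        pts = rng.uniform(0, 50, size=(150, 3))
        for eps in (1.3, 4.9, 17.0):
            assert _point_count(pts, eps) == len(brute_point_cells(pts, eps))

    def test_counts_monotone_in_eps(self, rng):
        ps = embed_delay(
            TimeSeries(rng.normal(0, 30, 2000)), EmbeddingConfig(tau=1, L=4)
        )
        res = box_count_points(ps)
        assert np.all(np.diff(res.counts) <= 0)


class TestSelectOrder:
    def test_ceiling_of_mean_slope(self, monkeypatch):
        import caar.fractal as fr

        slopes = iter([4.2, 4.6])
        monkeypatch.setattr(
            fr,
            "box_count_points",
            lambda ps, ladder=None: BoxCountResult(
                sizes=np.ones(5), counts=np.ones(5), log_inv_eps=np.zeros(5),
                log_counts=np.zeros(5), slope=next(slopes), intercept=0.0,
                linear_range=(0, 4), r_squared=1.0,
            ),
        )
        sigs = [TimeSeries(np.arange(100.0)), TimeSeries(np.arange(100.0))]
        assert fr.select_order(sigs, EmbeddingConfig(tau=1, L=2)) == 5

    @pytest.mark.parametrize(
        "slopes,expected", [([2.0, 2.0], 2), ([2.5], 3), ([0.2], 1)]
    )
    def test_integer_and_rounding_conventions(self, monkeypatch, slopes, expected):
        import caar.fractal as fr

        it = iter(slopes)
        monkeypatch.setattr(
            fr,
            "box_count_points",
            lambda ps, ladder=None: BoxCountResult(
                sizes=np.ones(5), counts=np.ones(5), log_inv_eps=np.zeros(5),
                log_counts=np.zeros(5), slope=next(it), intercept=0.0,
                linear_range=(0, 4), r_squared=1.0,
            ),
        )
        sigs = [TimeSeries(np.arange(50.0)) for _ in slopes]
        assert fr.select_order(sigs, EmbeddingConfig(tau=1, L=1)) == expected

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            select_order([], EmbeddingConfig())

    def test_end_to_end_on_noise_signals(self, rng):
        """Structural run: order from real phase-space slopes is a small
        positive integer."""
        sigs = [TimeSeries(rng.normal(0, 50, 600)) for _ in range(2)]
        p = select_order(sigs, EmbeddingConfig(tau=1, L=4))
        assert 1 <= p <= 6
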