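"""Correlation integral against brute force; dimension recovery; z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eureka_eeg import fracdim
from eureka_eeg.synthdata import SynthSpec, Oscillation, generate_epochs, generate_manifold
from tests.conftest import make_epochs


def brute_force_correlation_integral(points, delta):
    """Double-loop transcription of the ordered-pair definition."""
    n = len(points)
    count = 0
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(points[i] - points[j]) < delta:
                count += 1
    return count / n**2


class TestCorrelationIntegral:
    def test_two_points_hand_counts(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert fracdim.correlation_integral(pts, [2.0])[0] == 0.5
        assert fracdim.correlation_integral(pts, [0.5])[0] == 0.0
        # boundary: the inequality is strict
        assert fracdim.correlation_integral(pts, [1.0])[0] == 0.0

    def test_matches_brute_force_on_random_clouds(self, rng):
        pts = rng.standard_normal((200, 3))
        deltas = rng.uniform(0.1, 4.0, size=10)
        fast = fracdim.correlation_integral(pts, deltas)
        slow = [brute_force_correlation_integral(pts, d) for d in deltas]
        assert np.array_equal(fast, slow)

    def test_saturation_value_under_ordered_pair_normalization(self, rng):
        n = 37
        pts = rng.uniform(size=(n, 2))
        c = fracdim.correlation_integral(pts, [10.0])[0]
        assert c == pytest.approx((n**2 - n) / n**2)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_monotone_nondecreasing_in_delta(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((60, 2))
        c = fracdim.correlation_integral(pts, np.linspace(0.05, 5, 25))
        assert np.all(np.diff(c) >= 0)
        assert np.all((0 <= c) & (c <= 1))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fracdim.correlation_integral(np.zeros((1, 2)), [1.0])


class TestDimensionCurve:
    def test_line_mid_scale_plateau(self):
        cloud = generate_manifold("line", 1500, 3, seed=4)
        curve = fracdim.dimension_curve(cloud.points)
        assert 0.9 <= fracdim.plateau(curve) <= 1.1

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            fracdim.dimension_curve(np.zeros((100, 2)))

    def test_tiny_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            fracdim.dimension_curve(rng.standard_normal((100, 2)), np.array([0.0, 1.0]))

    def test_zero_count_bins_are_nan(self, rng):
        pts = rng.standard_normal((100, 2))
        grid = np.linspace(np.log(1e-8), np.log(10), 20)  # includes empty scales
        curve = fracdim.dimension_curve(pts, grid)
        assert np.isnan(curve.d_local[curve.c_delta == 0]).all()


class TestZscore:
    def test_output_moments(self, rng):
        ep = make_epochs(rng.standard_normal((5, 3, 100)) * 7 + 3)
        z = fracdim.zscore(ep)
        assert np.allclose(z.data.mean(axis=(0, 2)), 0, atol=1e-9)
        assert np.allclose(z.data.std(axis=(0, 2)), 1, atol=1e-9)

    def test_affine_invariance(self, rng):
        data = rng.standard_normal((4, 2, 80))
        a = fracdim.zscore(make_epochs(data))
        b = fracdim.zscore(make_epochs(3.5 * data - 11.0))
        assert np.allclose(a.data, b.data, atol=1e-9)

    def test_standardized_input_unchanged(self, rng):
        data = rng.standard_normal((4, 2, 500))
        data = (data - data.mean(axis=(0, 2), keepdims=True)) / data.std(
            axis=(0, 2), keepdims=True
        )
        z = fracdim.zscore(make_epochs(data))
        assert np.allclose(z.data, data, atol=1e-9)

    def test_constant_channel_rejected(self, rng):
        data = rng.standard_normal((3, 2, 50))
        data[:, 1] = 4.2
        with pytest.raises(ValueError):
            fracdim.zscore(make_epochs(data))


@pytest.fixture(scope="module")
def dimension_study(dense_montage):
    """Small dense-montage study with a right-temporal low-dim regime in Aha."""
    ch = tuple(dense_montage.ch_names)
    spec = SynthSpec(
        n_trials_per_cell=10,
        channels=ch,
        fs=200.0,
        bands=(Oscillation(channels=ch, f_lo=8, f_hi=12, amplitude=2.0),),
        coupling=(
            Oscillation(channels=dense_montage.clusters["RT"], f_lo=8, f_hi=12,
                        amplitude=10.0, kappa=30.0, window=(0.0, 0.5),
                        condition="Aha", stage="third"),
        ),
        noise_amplitude=5.0,
        seed=21,
    )
    return generate_epochs(spec)


class TestClusterDimension:
    def test_ten_labeled_clusters_per_condition(self, dimension_study, dense_montage):
        raw, corrected = fracdim.cluster_dimension(
            dimension_study, dense_montage, max_points=600
        )
        labels = {k[0] for k in raw}
        assert labels == {"LF", "RF", "LC", "RC", "LT", "RT", "LP", "RP", "LO", "RO"}
        assert all(cond in ("Aha", "Ctrl") for _, cond in raw)
        assert len(raw) == 20 and len(corrected) == 20

    def test_injected_low_dim_regime_reduces_rt_cluster_only(
        self, dimension_study, dense_montage
    ):
        raw, corrected = fracdim.cluster_dimension(
            dimension_study, dense_montage, max_points=600
        )
        drop_rt = np.nanmedian(corrected["RT", "Aha"].d_local)
        drop_lt = np.nanmedian(corrected["LT", "Aha"].d_local)
        drop_rt_ctrl = np.nanmedian(corrected["RT", "Ctrl"].d_local)
        assert drop_rt < drop_lt - 0.5
        assert drop_rt < drop_rt_ctrl - 0.5

    def test_missing_cluster_channel_rejected(self, dimension_study, dense_montage):
        slim = dimension_study.pick(dimension_study.ch_names[:10])
        with pytest.raises(ValueError):
            fracdim.cluster_dimension(slim, dense_montage)


class TestDimensionLI:
    def _arrays(self, rng, n_sub=6, n_bins=30):
        return rng.uniform(2.0, 3.0, size=(n_sub, n_bins))

    def test_symmetric_hemispheres_give_zero_li(self, rng):
        d = self._arrays(rng)
        res = fracdim.dimension_li(d, d, d, d, np.linspace(0, 2, 30), n_perm=150)
        assert np.allclose(res.li_aha, 0.0)
        assert not res.mask.any()

    def test_right_reduction_flagged_and_sign_flips_on_swap(self, rng):
        d_r_aha = self._arrays(rng) - 0.8
        d_l_aha = self._arrays(rng)
        d_r_ctrl = self._arrays(rng)
        d_l_ctrl = self._arrays(rng)
        grid = np.linspace(0, 2, 30)
        res = fracdim.dimension_li(d_r_aha, d_l_aha, d_r_ctrl, d_l_ctrl, grid,
                                   n_perm=300, seed=3)
        assert res.mask.any()
        swapped = fracdim.dimension_li(d_l_aha, d_r_aha, d_l_ctrl, d_r_ctrl, grid,
                                       n_perm=300, seed=3)
        assert np.allclose(swapped.difference, -res.difference, equal_nan=True)
        assert np.array_equal(swapped.mask, res.mask)
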