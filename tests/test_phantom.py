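from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy import stats as sps
from scipy.ndimage import label as cc_label

from topotest.moran import MoranConfig
from topotest.phantom import (
    Parcellation,
    PhantomConfig,
    SmoothingSpec,
    box_smooth,
    match_kernel,
    match_kernel_from_curve,
    parcellation_from_labels,
    probe_kernel_curve,
    pseudorandom_volume,
    simulate_null_pairs,
    synth_parcellation,
)
from topotest.volume_io import MaskedVolume

from _oracles import region_correlation_oracle
from conftest import full_mask_volume


class TestSynthParcellation:
    def test_region_count_and_background(self, medium_parc):
        labels = np.unique(medium_parc.labels)
        np.testing.assert_array_equal(labels, np.arange(117))
        assert not medium_parc.mask.all()  # ellipsoid leaves background

    def test_single_region_covers_whole_mask(self):
        parc = synth_parcellation((10, 12, 10), K=1, seed=0)
        assert (parc.labels[parc.mask] == 1).all()

    def test_seed_determinism(self):
        a = synth_parcellation((15, 15, 15), K=20, seed=42)
        b = synth_parcellation((15, 15, 15), K=20, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_regions_are_contiguous(self, small_parc):
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        for r in range(1, small_parc.K + 1):
            _, n_comp = cc_label(small_parc.labels == r, structure=structure)
            assert n_comp == 1, f"region {r} split into {n_comp} components"

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            synth_parcellation((4, 4, 4), K=1000, seed=0)

    def test_from_labels_recodes_to_consecutive(self):
        raw = np.zeros((4, 4, 4), dtype=np.int32)
        raw[0, 0, 0] = 5
        raw[1:, :, :] = 90
        parc = parcellation_from_labels(raw)
        assert parc.K == 2
        assert set(np.unique(parc.labels)) == {0, 1, 2}


class TestPseudorandomVolume:
    def test_noiseless_volume_is_region_constant(self, small_parc):
        vol = pseudorandom_volume(small_parc, PhantomConfig(noise_sd=0.0, seed=4))
        in_mask = vol.data[small_parc.mask]
        assert len(np.unique(in_mask)) == small_parc.K
        for r in (1, small_parc.K):
            region_vals = vol.data[small_parc.labels == r]
            assert np.ptp(region_vals) == 0.0

    def test_determinism(self, small_parc):
        cfg = PhantomConfig(seed=11)
        a = pseudorandom_volume(small_parc, cfg)
        b = pseudorandom_volume(small_parc, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_region_draws_have_stated_moments(self, small_parc):
        # grand mean over many volumes' region draws ~ N(0, 1/(K*n))
        n_vols = 400
        draws = []
        for s in range(n_vols):
            vol = pseudorandom_volume(small_parc, PhantomConfig(noise_sd=0.0, seed=s))
            for r in range(1, small_parc.K + 1):
                draws.append(vol.data[small_parc.labels == r][0])
        draws = np.asarray(draws)
        assert abs(draws.mean()) < 3.0 / np.sqrt(len(draws))
        assert draws.std() == pytest.approx(1.0, rel=0.05)

    def test_background_stays_zero(self, small_parc):
        vol = pseudorandom_volume(small_parc, PhantomConfig(seed=1))
        assert (vol.data[~small_parc.mask] == 0.0).all()


class TestBoxSmooth:
    def test_kernel_one_is_identity(self, small_pattern):
        out = box_smooth(small_pattern, 1)
        np.testing.assert_array_equal(out.data, small_pattern.data)

    def test_constant_volume_unchanged(self):
        vol = full_mask_volume(np.full((6, 6, 6), 3.5))
        out = box_smooth(vol, 5)
        np.testing.assert_allclose(out.data, 3.5, rtol=1e-12)

    def test_impulse_response_is_truncated_cube_mean(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        out = box_smooth(full_mask_volume(data), 3)
        assert out.data[2, 2, 2] == pytest.approx(1 / 27)
        assert out.data[1, 2, 2] == pytest.approx(1 / 27)
        # at a face the window is truncated to 18 voxels
        edge = np.zeros((5, 5, 5))
        edge[0, 2, 2] = 1.0
        out_edge = box_smooth(full_mask_volume(edge), 3)
        assert out_edge.data[0, 2, 2] == pytest.approx(1 / 18)

    def test_even_kernel_rejected(self, small_pattern):
        with pytest.raises(ValueError, match="odd"):
            box_smooth(small_pattern, 4)

    def test_smoothing_spec_validation(self):
        with pytest.raises(ValueError, match="odd"):
            SmoothingSpec(kernel=2)


@pytest.fixture(scope="module")
def curve(small_parc):
    return probe_kernel_curve(
        small_parc, PhantomConfig(), MoranConfig(window=9),
        candidates=(1, 3, 7, 11), n_probe=6, seed=3,
    )


class TestMatchKernel:
    def test_curve_is_monotone_in_kernel(self, curve):
        vals = [curve[k] for k in sorted(curve)]
        assert np.all(np.diff(vals) > 0)

    def test_self_matching_returns_smallest_candidate(self, small_parc, curve):
        assert match_kernel_from_curve(curve, curve[1]) == 1

    def test_unattainable_target_returns_largest_with_warning(self, curve, caplog):
        with caplog.at_level(logging.WARNING):
            k = match_kernel_from_curve(curve, 10.0)
        assert k == 11
        assert any("exceeds" in r.message for r in caplog.records)

    def test_non_decreasing_in_target(self, curve):
        targets = np.linspace(0.0, 1.0, 9)
        kernels = [match_kernel_from_curve(curve, t) for t in targets]
        assert all(k2 >= k1 for k1, k2 in zip(kernels, kernels[1:]))

    def test_end_to_end_wrapper(self, small_parc):
        k = match_kernel(
            small_parc, PhantomConfig(), target_I=0.0, moran_cfg=MoranConfig(window=9),
            n_probe=4, seed=0, candidates=(1, 3, 7),
        )
        assert k == 1


class TestSimulateNullPairs:
    def test_seed_determinism(self, small_parc):
        a = simulate_null_pairs(small_parc, PhantomConfig(), 3, 7, n_pairs=20, seed=5)
        b = simulate_null_pairs(small_parc, PhantomConfig(), 3, 7, n_pairs=20, seed=5)
        np.testing.assert_array_equal(a.r2_values, b.r2_values)

    def test_kernel_swap_symmetry(self, small_parc):
        mcfg = MoranConfig(window=9)
        a = simulate_null_pairs(small_parc, PhantomConfig(), 3, 7, n_pairs=10, seed=5, moran_cfg=mcfg)
        b = simulate_null_pairs(small_parc, PhantomConfig(), 7, 3, n_pairs=10, seed=5, moran_cfg=mcfg)
        np.testing.assert_array_equal(a.r2_values, b.r2_values)
        assert a.achieved_I_a == b.achieved_I_b
        assert a.achieved_I_b == b.achieved_I_a

    def test_unsmoothed_null_matches_region_level_oracle(self, small_parc):
        """At kernel 1 the null's dof are the K regions, not the voxel count."""
        null = simulate_null_pairs(small_parc, PhantomConfig(), 1, 1, n_pairs=300, seed=2)
        sizes = np.bincount(small_parc.labels[small_parc.mask])[1:]
        oracle = region_correlation_oracle(sizes.astype(float), 3000, np.random.default_rng(0))
        # means agree within combined Monte-Carlo error
        se = np.sqrt(null.r2_values.var() / 300 + oracle.var() / 3000)
        assert abs(null.r2_values.mean() - oracle.mean()) < 4 * se
        # and both are far above the naive voxel-count null moment 1/(m-1)
        assert null.r2_values.mean() > 20 / (small_parc.mask.sum() - 1)

    def test_smoothing_inflates_null_correlations(self, small_parc):
        small = simulate_null_pairs(small_parc, PhantomConfig(), 1, 1, n_pairs=120, seed=3)
        big = simulate_null_pairs(small_parc, PhantomConfig(), 11, 11, n_pairs=120, seed=4)
        stat = sps.mannwhitneyu(big.r2_values, small.r2_values, alternative="greater")
        assert stat.pvalue < 0.01

    def test_achieved_moran_recorded_when_requested(self, small_parc):
        null = simulate_null_pairs(
            small_parc, PhantomConfig(), 3, 3, n_pairs=5, seed=1, moran_cfg=MoranConfig(window=9)
        )
        assert np.isfinite(null.achieved_I_a)
        assert null.achieved_I_a == null.achieved_I_b
        fast = simulate_null_pairs(small_parc, PhantomConfig(), 3, 3, n_pairs=5, seed=1)
        assert np.isnan(fast.achieved_I_a)
        np.testing.assert_array_equal(fast.r2_values, null.r2_values)


class TestParcellationInvariants:
    def test_label_contract_enforced(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 2  # label 1 missing
        with pytest.raises(ValueError, match="labels exactly"):
            Parcellation(labels=labels, K=2)
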