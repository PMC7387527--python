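"""Threshold segmentation and metric extraction against brute-force oracles."""

import numpy as np
import pytest

from tmtvkit import (
    LesionSet,
    SuvVolume,
    ThresholdSpec,
    Voi,
    apply_threshold,
    compute_metrics,
    delineate,
    delineate_multiple,
    generate_phantom,
    suv_peak,
)
from .conftest import full_voi, random_volume, sphere_spec

THRESHOLDS = (
    ThresholdSpec("absolute", 2.5),
    ThresholdSpec("relative", 0.41),
    ThresholdSpec("relative", 0.50),
)


def brute_force_threshold(vol: SuvVolume, voi: Voi, t: ThresholdSpec):
    """Independent triple-loop voxel scan implementing the same contract."""
    if t.kind == "absolute":
        cut = t.value
    else:
        suv_max = -np.inf
        for i in range(vol.shape[0]):
            for j in range(vol.shape[1]):
                for k in range(vol.shape[2]):
                    if voi.mask[i, j, k] and vol.values[i, j, k] > suv_max:
                        suv_max = vol.values[i, j, k]
        cut = t.value * suv_max
    mask = np.zeros(vol.shape, dtype=bool)
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                if voi.mask[i, j, k] and vol.values[i, j, k] > cut:
                    mask[i, j, k] = True
    return mask, cut


def brute_force_suv_peak(vol: SuvVolume, scope: Voi, volume_cm3: float = 1.0) -> float:
    """Exhaustive center scan: mean SUV in the sphere around every candidate."""
    radius = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    best = -np.inf
    centers = np.argwhere(scope.mask)
    for ci, cj, ck in centers:
        acc, cnt = 0.0, 0
        for i in range(vol.shape[0]):
            for j in range(vol.shape[1]):
                for k in range(vol.shape[2]):
                    d2 = sum(
                        ((a - b) * s) ** 2
                        for a, b, s in zip((i, j, k), (ci, cj, ck), vol.spacing_mm)
                    )
                    if d2 <= radius**2:
                        acc += vol.values[i, j, k]
                        cnt += 1
        best = max(best, acc / cnt)
    return best


class TestApplyThreshold:
    @pytest.mark.parametrize("t", THRESHOLDS, ids=lambda t: t.label)
    def test_matches_brute_force_scan(self, t):
        """Exact oracle equivalence on seeded random volumes."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            vol = random_volume(rng)
            voi = Voi(mask=rng.random(vol.shape) > 0.3)
            mask, cut = apply_threshold(vol, voi, t)
            ref_mask, ref_cut = brute_force_threshold(vol, voi, t)
            assert cut == pytest.approx(ref_cut, abs=0)
            assert np.array_equal(mask.mask, ref_mask)

    def test_uniform_voi_fully_selected(self):
        vol = SuvVolume(values=np.full((8, 8, 4), 3.0), spacing_mm=(2, 2, 2))
        voi = full_voi(vol)
        mask, cut = apply_threshold(vol, voi, ThresholdSpec("absolute", 2.5))
        assert mask.voxel_count == voi.voxel_count
        assert cut == 2.5

    def test_relative_half_of_suvmax5_equals_absolute_2p5(self, rng):
        vol = random_volume(rng)
        values = vol.values * (5.0 / vol.values.max())
        vol = SuvVolume(values=values, spacing_mm=vol.spacing_mm)
        voi = full_voi(vol)
        m_rel, cut_rel = apply_threshold(vol, voi, ThresholdSpec("relative", 0.50))
        m_abs, _ = apply_threshold(vol, voi, ThresholdSpec("absolute", 2.5))
        assert cut_rel == pytest.approx(2.5)
        assert np.array_equal(m_rel.mask, m_abs.mask)

    def test_empty_voi_rejected(self, rng):
        vol = random_volume(rng)
        with pytest.raises(ValueError, match="empty"):
            apply_threshold(vol, Voi(np.zeros(vol.shape, bool)), THRESHOLDS[0])

    def test_all_zero_voi_relative_rejected(self):
        vol = SuvVolume(values=np.zeros((8, 8, 4)), spacing_mm=(2, 2, 2))
        with pytest.raises(ValueError, match="SUVmax is 0"):
            apply_threshold(vol, full_voi(vol), ThresholdSpec("relative", 0.41))

    def test_threshold_spec_validation(self):
        with pytest.raises(ValueError):
            ThresholdSpec("absolute", 0.0)
        with pytest.raises(ValueError):
            ThresholdSpec("relative", 1.2)
        assert ThresholdSpec.parse("abs:2.5") == ThresholdSpec("absolute", 2.5)
        assert ThresholdSpec.parse("rel:0.41") == ThresholdSpec("relative", 0.41)


class TestComputeMetrics:
    def test_uniform_region(self):
        values = np.zeros((10, 10, 4))
        mask = np.zeros((10, 10, 4), dtype=bool)
        mask.flat[:100] = True
        values[mask] = 4.0
        vol = SuvVolume(values=values, spacing_mm=(2, 2, 2))
        res = compute_metrics(vol, Voi(mask), Voi(mask), threshold_used_suv=2.5)
        assert res.tmtv_cm3 == pytest.approx(0.8)
        assert res.suv_mean == pytest.approx(4.0)
        assert res.tlg_cm3 == pytest.approx(3.2)

    def test_single_voxel(self, rng):
        vol = random_volume(rng)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[5, 5, 3] = True
        res = compute_metrics(vol, Voi(mask), Voi(mask), 1.0)
        assert res.suv_mean == res.suv_max == vol.values[5, 5, 3]

    def test_empty_mask_error_names_threshold(self, rng):
        vol = random_volume(rng)
        with pytest.raises(ValueError, match="99"):
            compute_metrics(vol, Voi(np.zeros(vol.shape, bool)), full_voi(vol), 99.0)

    def test_suv_peak_matches_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        vol = SuvVolume(values=rng.uniform(0, 10, (8, 8, 6)), spacing_mm=(4, 4, 4))
        scope = Voi(mask=rng.random(vol.shape) > 0.5)
        assert suv_peak(vol, scope) == pytest.approx(
            brute_force_suv_peak(vol, scope), rel=1e-12
        )

    def test_suv_peak_clipped_at_grid_edge(self):
        # peak centered at a corner still averages only in-grid voxels
        values = np.zeros((8, 8, 6))
        values[0, 0, 0] = 10.0
        vol = SuvVolume(values=values, spacing_mm=(4, 4, 4))
        scope = np.zeros(vol.shape, dtype=bool)
        scope[0, 0, 0] = True
        got = suv_peak(vol, Voi(scope))
        assert got == pytest.approx(brute_force_suv_peak(vol, Voi(scope)), rel=1e-12)
        assert got > 0


@pytest.fixture(scope="module")
def blurred():
    vol, masks, _ = generate_phantom(sphere_spec(psf_fwhm_mm=6.0))
    return vol, masks[0]


class TestDelineate:
    def test_mask50_nested_in_mask41(self, blurred):
        vol, gt = blurred
        voi = Voi(np.ones(vol.shape, bool))
        m41, _ = apply_threshold(vol, voi, ThresholdSpec("relative", 0.41))
        m50, _ = apply_threshold(vol, voi, ThresholdSpec("relative", 0.50))
        assert np.all(m41.mask[m50.mask])

    def test_suvmax_invariant_across_thresholds(self, blurred):
        vol, gt = blurred
        voi = Voi(np.ones(vol.shape, bool))
        maxes = {delineate(vol, voi, t).suv_max for t in THRESHOLDS}
        assert len(maxes) == 1

    def test_suv_peak_invariant_with_voi_scope(self, blurred):
        vol, gt = blurred
        voi = Voi(np.ones(vol.shape, bool))
        peaks = {delineate(vol, voi, t, peak_scope="voi").suv_peak for t in THRESHOLDS}
        assert len(peaks) == 1

    def test_mask_scope_peak_non_decreasing_as_threshold_drops(self):
        # two hot spots: the lower threshold admits the second, cooler one
        rng = np.random.default_rng(0)
        vol = SuvVolume(values=rng.uniform(0, 1, (20, 12, 8)), spacing_mm=(4, 4, 4))
        values = vol.values.copy()
        values[3:6, 4:7, 3:5] = 10.0
        values[14:17, 4:7, 3:5] = 6.0
        vol = SuvVolume(values=values, spacing_mm=(4, 4, 4))
        voi = Voi(np.ones(vol.shape, bool))
        peaks = [
            delineate(vol, voi, ThresholdSpec("relative", v), peak_scope="mask").suv_peak
            for v in (0.8, 0.5, 0.3)
        ]
        assert peaks[0] <= peaks[1] <= peaks[2]

    def test_tmtv_non_increasing_in_threshold(self, blurred):
        vol, gt = blurred
        voi = Voi(np.ones(vol.shape, bool))
        tmtvs = [
            delineate(vol, voi, ThresholdSpec("absolute", v)).tmtv_cm3
            for v in (1.0, 2.5, 4.0, 6.0)
        ]
        assert all(a >= b for a, b in zip(tmtvs, tmtvs[1:]))

    def test_tlg_identity(self, blurred):
        vol, gt = blurred
        voi = Voi(np.ones(vol.shape, bool))
        for t in THRESHOLDS:
            res = delineate(vol, voi, t)
            assert res.tlg_cm3 == pytest.approx(res.suv_mean * res.tmtv_cm3, rel=1e-9)

    def test_noiseless_sharp_phantom_recovers_ground_truth(self, sphere_phantom):
        """With no blur/noise, all three cutoffs reproduce the true mask."""
        vol, gt, _ = sphere_phantom
        voi = Voi(np.ones(vol.shape, bool))
        for t in THRESHOLDS:
            mask, _ = apply_threshold(vol, voi, t)
            assert np.array_equal(mask.mask, gt.mask)

    def test_partial_volume_crossover_of_absolute_cutoff(self):
        """Blur pulls the 2.5-SUV isocontour inside faint lesions and outside
        avid ones; the crossover sits near uptake = 2×2.5 − background."""
        from tmtvkit import LesionSpec, PhantomSpec

        def ratio(uptake):
            spec = PhantomSpec(
                grid_shape=(50, 50, 50), spacing_mm=(2, 2, 2), background_suv=0.3,
                lesions=(LesionSpec((49, 49, 49), (10, 10, 10), uptake),),
                psf_fwhm_mm=6.0,
            )
            vol, masks, _ = generate_phantom(spec)
            true = masks[0].voxel_count * vol.voxel_volume_cm3
            res = delineate(vol, Voi(np.ones(vol.shape, bool)), ThresholdSpec("absolute", 2.5))
            return res.tmtv_cm3 / true

        assert ratio(4.0) < 1.0  # faint lesion: underestimation
        assert ratio(8.0) >= 1.0  # avid lesion: overestimation


class TestDelineateMultiple:
    def _two_lesion_volume(self):
        values = np.full((24, 12, 8), 0.5)
        a = np.zeros_like(values, dtype=bool)
        b = np.zeros_like(values, dtype=bool)
        a[2:6, 4:8, 2:6] = True
        b[16:20, 4:8, 2:6] = True
        values[a] = 10.0
        values[b] = 4.0
        vol = SuvVolume(values=values, spacing_mm=(2, 2, 2))
        return vol, Voi(a), Voi(b)

    def test_single_lesion_consistent_with_delineate(self, rng):
        vol = random_volume(rng)
        voi = Voi(mask=rng.random(vol.shape) > 0.4)
        t = ThresholdSpec("relative", 0.41)
        single = delineate(vol, voi, t)
        multi = delineate_multiple(vol, LesionSet([voi]), t)
        assert multi.tmtv_cm3 == pytest.approx(single.tmtv_cm3)
        assert multi.suv_mean == pytest.approx(single.suv_mean)
        assert np.array_equal(multi.mask.mask, single.mask.mask)

    def test_two_identical_lesions_double_tmtv(self):
        vol, a, b = self._two_lesion_volume()
        values = vol.values.copy()
        values[b.mask] = 10.0  # make both lesions identical
        vol = SuvVolume(values=values, spacing_mm=vol.spacing_mm)
        t = ThresholdSpec("absolute", 2.5)
        one = delineate(vol, a, t)
        both = delineate_multiple(vol, LesionSet([a, b]), t)
        assert both.tmtv_cm3 == pytest.approx(2 * one.tmtv_cm3)

    def test_per_lesion_scope_contains_global_for_cool_lesion(self):
        """SUVmax 10 vs 4 under rel 0.41: the cooler lesion's per-lesion
        cutoff (1.64) admits more voxels than the global one (4.1)."""
        vol, a, b = self._two_lesion_volume()
        t = ThresholdSpec("relative", 0.41)
        per = delineate_multiple(vol, LesionSet([a, b]), t, suvmax_scope="per_lesion")
        glo = delineate_multiple(vol, LesionSet([a, b]), t, suvmax_scope="global")
        per_cool = per.mask.mask & b.mask
        glo_cool = glo.mask.mask & b.mask
        assert np.all(per_cool[glo_cool])
        assert per_cool.sum() > glo_cool.sum()
        # oracle check on the cool lesion with each cutoff
        ref_per, _ = brute_force_threshold(vol, b, ThresholdSpec("absolute", 0.41 * 4.0))
        ref_glo, _ = brute_force_threshold(vol, b, ThresholdSpec("absolute", 0.41 * 10.0))
        assert np.array_equal(per_cool, ref_per)
        assert np.array_equal(glo_cool, ref_glo)

    def test_cold_lesion_warns_and_contributes_zero(self):
        vol, a, b = self._two_lesion_volume()
        t = ThresholdSpec("absolute", 6.0)  # cool lesion (SUV 4) is empty
        with pytest.warns(UserWarning, match="contributes 0"):
            res = delineate_multiple(vol, LesionSet([a, b]), t)
        hot_only = delineate(vol, a, t)
        assert res.tmtv_cm3 == pytest.approx(hot_only.tmtv_cm3)
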