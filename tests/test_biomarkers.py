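import numpy as np
import pytest

from conftest import random_mask
from petmip.biomarkers import (
    biomarker_table,
    compute_dmax,
    compute_record,
    compute_sdmax,
    compute_stmtv,
    compute_tmtv,
    label_lesions,
    mask_profiles,
    percentile_span,
)
from petmip.projection import MipImage, MipMask, MipPair, make_mip_pair
from petmip.volume_io import LesionMask3D, PetVolume


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def flood_fill_count(mask: np.ndarray) -> int:
    """Count 26-connected components by explicit BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(p, mask.shape)) and mask[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return count


def span_by_cumulative_scan(profile, spacing, lo=0.02, hi=0.98) -> float:
    """Percentile span by explicit cumulative scan (independent oracle)."""
    total = sum(profile)
    if total == 0:
        return 0.0

    def q(p):
        acc = 0.0
        for k, v in enumerate(profile):
            acc += v
            if acc / total >= p:
                return k
        return len(profile) - 1

    return (q(hi) - q(lo)) * spacing


def mask_from(data, spacing):
    return LesionMask3D(np.asarray(data, dtype=np.uint8), spacing)


def pair_from_masks(cor, sag, spacing_cor=(4.0, 4.0), spacing_sag=(4.0, 4.0)):
    def v(arr, spacing, view):
        m = MipMask(np.asarray(arr, dtype=np.uint8), spacing, view)
        img = MipImage(np.asarray(arr, dtype=float), spacing, view)
        return img, m

    return MipPair(coronal=v(cor, spacing_cor, "coronal"), sagittal=v(sag, spacing_sag, "sagittal"))


# ---------------------------------------------------------------------------
# TMTV
# ---------------------------------------------------------------------------


class TestTmtv:
    def test_100_voxels_at_4mm_is_6_4_cm3(self):
        data = np.zeros((10, 10, 10))
        data.flat[:100] = 1
        assert compute_tmtv(mask_from(data, (4.0, 4.0, 4.0))) == pytest.approx(6.4)

    def test_empty_mask_is_zero(self):
        assert compute_tmtv(mask_from(np.zeros((4, 4, 4)), (4.0, 4.0, 4.0))) == 0.0

    def test_voxelized_sphere_close_to_analytic(self):
        from conftest import sphere_phantom

        _, mask, truth = sphere_phantom(radius_mm=10.0, spacing=(2.0, 2.0, 2.0))
        tmtv = compute_tmtv(mask)
        assert tmtv == pytest.approx(truth.lesion_volumes_mm3[0] / 1000.0, rel=0.10)


class TestLabeling:
    def test_corner_touching_voxels_are_one_component(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = data[1, 1, 1] = 1
        labels, centroids = label_lesions(mask_from(data, (1.0, 1.0, 1.0)))
        assert labels.max() == 1 and len(centroids) == 1

    def test_separated_voxels_are_two_components(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, 0] = data[0, 0, 2] = 1
        labels, centroids = label_lesions(mask_from(data, (1.0, 1.0, 1.0)))
        assert labels.max() == 2 and len(centroids) == 2

    def test_component_count_matches_flood_fill(self, rng):
        for _ in range(10):
            mask = random_mask(rng, shape=(12, 12, 12), p=0.15)
            labels, _ = label_lesions(mask)
            assert labels.max() == flood_fill_count(mask.data)

    def test_centroids_in_physical_mm(self):
        data = np.zeros((10, 10, 10))
        data[2, 3, 4] = 1
        _, centroids = label_lesions(mask_from(data, (2.0, 3.0, 4.0)))
        np.testing.assert_allclose(centroids[0], [(2 + 0.5) * 2, (3 + 0.5) * 3, (4 + 0.5) * 4])


class TestDmax:
    def test_3_4_5_triangle_is_5_cm(self):
        data = np.zeros((21, 21, 21))
        data[0, 0, 0] = 1
        data[15, 20, 0] = 1  # centroids 30 mm and 40 mm apart at 2 mm spacing
        dmax, n, flags = compute_dmax(mask_from(data, (2.0, 2.0, 2.0)))
        assert dmax == pytest.approx(5.0)
        assert n == 2 and flags == []

    def test_single_lesion_flagged_zero(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 1
        dmax, n, flags = compute_dmax(mask_from(data, (4.0, 4.0, 4.0)))
        assert dmax == 0.0 and n == 1 and "n_lesions<2" in flags

    def test_matches_exhaustive_pair_enumeration(self, rng):
        for _ in range(10):
            mask = random_mask(rng, shape=(14, 14, 14), p=0.05)
            _, centroids = label_lesions(mask)
            if len(centroids) < 2:
                continue
            best = max(
                np.linalg.norm(a - b) for i, a in enumerate(centroids) for b in centroids[i + 1 :]
            )
            dmax, _, _ = compute_dmax(mask)
            assert dmax == pytest.approx(best / 10.0, abs=1e-12)

    def test_bounded_by_bounding_box_diagonal(self, small_cohort):
        for case in small_cohort:
            dmax, n, _ = compute_dmax(case.mask)
            if n < 2:
                continue
            nz = np.nonzero(case.mask.data)
            ext = [(idx.max() - idx.min()) * s for idx, s in zip(nz, case.mask.spacing)]
            assert dmax <= np.linalg.norm(ext) / 10.0 + 1e-9


# ---------------------------------------------------------------------------
# surrogate biomarkers
# ---------------------------------------------------------------------------


class TestStmtv:
    def test_pixel_count_times_area(self):
        cor = np.zeros((8, 8))
        cor.flat[:10] = 1
        sag = np.zeros((8, 8))
        sag.flat[:6] = 1
        total, comp = compute_stmtv(pair_from_masks(cor, sag))
        assert total == pytest.approx(16 * 0.16)
        assert comp["coronal"] == pytest.approx(10 * 0.16)
        assert comp["sagittal"] == pytest.approx(6 * 0.16)

    def test_empty_masks_zero(self):
        total, _ = compute_stmtv(pair_from_masks(np.zeros((4, 4)), np.zeros((4, 4))))
        assert total == 0.0


class TestProfiles:
    def test_full_row_profiles(self):
        m = np.zeros((3, 3))
        m[:, 1] = 1  # one full image row (constant vertical index)
        prof = mask_profiles(MipMask(m.astype(np.uint8), (4.0, 4.0), "coronal"))
        assert prof.x_profile.tolist() == [1, 1, 1]
        assert prof.y_profile.tolist() == [0, 3, 0]

    def test_profiles_sum_to_pixel_count(self, rng):
        for _ in range(10):
            m = (rng.uniform(size=(9, 13)) < 0.3).astype(np.uint8)
            prof = mask_profiles(MipMask(m, (4.0, 2.8), "sagittal"))
            assert prof.x_profile.sum() == m.sum() == prof.y_profile.sum()
            assert np.array_equal(prof.x_profile, [m[i, :].sum() for i in range(9)])
            assert np.array_equal(prof.y_profile, [m[:, j].sum() for j in range(13)])


class TestPercentileSpan:
    def test_single_bin_is_zero(self):
        assert percentile_span(np.array([0, 5, 0]), 4.0) == 0.0

    def test_uniform_100_bins(self):
        span = percentile_span(np.ones(100), 4.0)
        assert span == pytest.approx(96 * 4.0)

    def test_two_unit_bins_distance_10(self):
        profile = np.zeros(11)
        profile[0] = profile[10] = 1
        assert percentile_span(profile, 1.0) == pytest.approx(10.0)

    def test_empty_profile_is_zero(self):
        assert percentile_span(np.zeros(5), 4.0) == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            percentile_span(np.array([1, -1, 1]), 4.0)

    def test_matches_cumulative_scan_oracle(self, rng):
        for _ in range(200):
            profile = rng.integers(0, 5, size=rng.integers(1, 40))
            spacing = float(rng.uniform(0.5, 5))
            assert percentile_span(profile, spacing) == pytest.approx(
                span_by_cumulative_scan(profile.tolist(), spacing), abs=1e-12
            )


class TestSdmax:
    def test_single_pixel_views_give_zero(self):
        cor = np.zeros((6, 6))
        cor[2, 2] = 1
        sag = np.zeros((6, 6))
        sag[4, 1] = 1
        total, per_view = compute_sdmax(pair_from_masks(cor, sag))
        assert total == 0.0

    def test_two_pixels_100mm_apart_in_each_view(self):
        cor = np.zeros((30, 6))
        cor[2, 3] = cor[27, 3] = 1  # 25 px * 4 mm = 100 mm horizontally
        sag = np.zeros((30, 6))
        sag[1, 2] = sag[26, 2] = 1
        total, per_view = compute_sdmax(pair_from_masks(cor, sag))
        assert per_view["coronal"].sdmax_component_cm == pytest.approx(10.0)
        assert per_view["sagittal"].sdmax_component_cm == pytest.approx(10.0)
        assert total == pytest.approx(20.0)

    def test_translation_invariance(self, rng):
        m = np.zeros((20, 20))
        m[3:6, 4:9] = 1
        shifted = np.roll(np.roll(m, 5, axis=0), 3, axis=1)
        t1, _ = compute_sdmax(pair_from_masks(m, m))
        t2, _ = compute_sdmax(pair_from_masks(shifted, shifted))
        assert t1 == pytest.approx(t2)

    def test_span_bound(self, rng):
        for _ in range(10):
            m = (rng.uniform(size=(15, 22)) < 0.2).astype(np.uint8)
            u, v = 4.0, 2.8
            total, per_view = compute_sdmax(pair_from_masks(m, m, (u, v), (u, v)))
            bound = ((15 - 1) * u + (22 - 1) * v) / 10.0
            for vb in per_view.values():
                assert vb.sdmax_component_cm <= bound + 1e-9


class TestIdentitiesAndScaling:
    def test_totals_are_sum_of_view_components(self, small_cohort):
        for case in small_cohort:
            pair = make_mip_pair(case.volume, case.mask)
            rec = compute_record(case.patient_id, case.mask, pair)
            assert rec.stmtv_cm2 == pytest.approx(
                rec.per_view["coronal"].stmtv_component_cm2 + rec.per_view["sagittal"].stmtv_component_cm2
            )
            assert rec.sdmax_cm == pytest.approx(
                rec.per_view["coronal"].sdmax_component_cm + rec.per_view["sagittal"].sdmax_component_cm
            )

    def test_doubling_spacing_scales_biomarkers_exactly(self, small_cohort):
        case = small_cohort[0]
        sp2 = tuple(2 * s for s in case.mask.spacing)
        mask2 = LesionMask3D(case.mask.data.copy(), sp2)
        vol2 = PetVolume(case.volume.data.copy(), sp2)
        r1 = compute_record("a", case.mask, make_mip_pair(case.volume, case.mask))
        r2 = compute_record("a", mask2, make_mip_pair(vol2, mask2))
        assert r2.tmtv_cm3 == pytest.approx(8 * r1.tmtv_cm3)
        assert r2.stmtv_cm2 == pytest.approx(4 * r1.stmtv_cm2)
        assert r2.dmax_cm == pytest.approx(2 * r1.dmax_cm)
        assert r2.sdmax_cm == pytest.approx(2 * r1.sdmax_cm)

    def test_adding_voxels_never_decreases_burden(self, rng, small_cohort):
        case = small_cohort[0]
        grown_data = case.mask.data.copy()
        extra = (rng.uniform(size=grown_data.shape) < 0.01).astype(np.uint8)
        grown_data |= extra
        grown = LesionMask3D(grown_data, case.mask.spacing)
        r1 = compute_record("a", case.mask, make_mip_pair(case.volume, case.mask))
        r2 = compute_record("a", grown, make_mip_pair(case.volume, grown))
        assert r2.tmtv_cm3 >= r1.tmtv_cm3
        assert r2.stmtv_cm2 >= r1.stmtv_cm2


class TestBiomarkerTable:
    def test_one_row_per_patient_all_finite(self, small_cohort):
        records = [
            compute_record(c.patient_id, c.mask, make_mip_pair(c.volume, c.mask)) for c in small_cohort[:3]
        ]
        table = biomarker_table(records)
        assert len(table) == 3
        num = table.drop(columns=["patient_id", "flags"])
        assert np.isfinite(num.to_numpy(dtype=float)).all()

    def test_quartiles_match_sorted_oracle(self, rng):
        from petmip.biomarkers import describe_biomarkers
        import pandas as pd

        vals = rng.uniform(0, 100, size=11)
        table = pd.DataFrame({"patient_id": range(11), "TMTV_cm3": vals, "flags": "", "n_lesions": 2})
        desc = describe_biomarkers(table)
        s = np.sort(vals)
        assert desc.loc["TMTV_cm3", "median"] == pytest.approx(s[5])
        assert desc.loc["TMTV_cm3", "Q1"] == pytest.approx(np.percentile(vals, 25))
        assert desc.loc["TMTV_cm3", "Q3"] == pytest.approx(np.percentile(vals, 75))
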