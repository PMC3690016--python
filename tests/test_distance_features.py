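"""Distance transform, data mappings, RSFS resampling and the Legendre fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapefeat import distance_features as df
from shapefeat import synthetic
from shapefeat.errors import (
    EmptyMaskError,
    MultiComponentError,
    ParameterError,
    TooFewPixelsError,
)


def _mapped(values, kind="sort"):
    return df.MappedDistribution(np.asarray(values, dtype=float), kind)


class TestDistanceTransform:
    def test_single_pixel_has_distance_one(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        dmap = df.distance_transform(mask)
        assert dmap[2, 2] == 1.0
        assert (dmap[~mask] == -1.0).all()

    def test_one_pixel_row_all_ones(self):
        mask = np.zeros((3, 5), bool)
        mask[1, 1:4] = True
        dmap = df.distance_transform(mask)
        assert np.allclose(dmap[1, 1:4], 1.0)

    def test_border_object_still_finite(self):
        mask = np.ones((3, 3), bool)
        dmap = df.distance_transform(mask)
        assert dmap.max() == 2.0 and dmap.min() == 1.0

    def test_disk_against_brute_force_nearest_background(self):
        mask = synthetic.make_disk(20, (50, 50))
        dmap = df.distance_transform(mask)
        # oracle: all-pairs scan on the padded grid
        padded = np.pad(mask, 1)
        bg = np.argwhere(~padded)
        obj = np.argwhere(padded)
        for r, c in obj[:: max(1, len(obj) // 40)]:
            d = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1)).min()
            assert np.isclose(dmap[r - 1, c - 1], d)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            df.distance_transform(np.zeros((4, 4), bool))


class TestExtractSorted:
    def test_sorted_ascending(self):
        mask = synthetic.make_disk(10, (30, 30))
        series = df.extract_sorted(df.distance_transform(mask))
        assert (np.diff(series.y) >= 0).all()
        assert series.n == mask.sum()

    def test_translation_and_rotation_leave_series_unchanged(self):
        mask = synthetic.generate_samples(
            synthetic.ELONGATED_SPEC, synthetic.ROUNDED_SPEC, 1, seed=9
        )[0].mask
        base = df.extract_sorted(df.distance_transform(mask)).y
        moved = np.roll(mask, (6, -3), axis=(0, 1))
        rotated = np.rot90(mask)
        assert np.array_equal(base, df.extract_sorted(df.distance_transform(moved)).y)
        assert np.array_equal(base, df.extract_sorted(df.distance_transform(rotated)).y)


class TestApplyMapping:
    def test_scaled(self):
        out = df.apply_mapping(_mapped([1, 2, 4]), "scaled")
        assert np.allclose(out.y, [0.25, 0.5, 1.0])

    def test_accu(self):
        out = df.apply_mapping(_mapped([1, 2, 4]), "accu")
        assert np.allclose(out.y, [1, 3, 7])

    def test_accu_scaled(self):
        out = df.apply_mapping(_mapped([1, 2, 4]), "accuScaled")
        assert np.allclose(out.y, [1 / 7, 3 / 7, 1.0])

    def test_sort_is_identity(self):
        m = _mapped([1, 2, 4])
        assert df.apply_mapping(m, "sort") is m

    @given(
        st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=60)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mappings_are_nondecreasing_and_normalized(self, values):
        series = _mapped(np.sort(values))
        for kind in df.MAPPING_KINDS:
            out = df.apply_mapping(series, kind)
            assert (np.diff(out.y) >= -1e-12).all()
            if kind in ("scaled", "accuScaled"):
                assert np.isclose(out.y[-1], 1.0)
                assert (out.y > 0).all() and (out.y <= 1.0 + 1e-12).all()


class TestRsfs:
    def test_identity_ramp_hits_index_formula(self):
        # oracle: idx_j = j*10 on the ramp 1..101 gives values 11, 21, ..., 101
        fv = df.rsfs(_mapped(np.arange(1.0, 102.0)))
        assert np.allclose(fv.values, np.arange(11.0, 102.0, 10.0))

    def test_last_feature_is_one_for_scaled_mappings(self, disk80):
        series = df.extract_sorted(df.distance_transform(disk80))
        for kind in ("scaled", "accuScaled"):
            fv = df.rsfs(df.apply_mapping(series, kind))
            assert fv.values[-1] == 1.0

    def test_constant_series_gives_constant_features(self):
        fv = df.rsfs(_mapped(np.full(37, 2.5)))
        assert np.allclose(fv.values, 2.5)

    def test_values_nondecreasing(self, disk80):
        series = df.extract_sorted(df.distance_transform(disk80))
        fv = df.rsfs(series)
        assert (np.diff(fv.values) >= 0).all()

    def test_too_few_pixels_raises(self):
        with pytest.raises(TooFewPixelsError):
            df.rsfs(_mapped(np.arange(1.0, 11.0)))


class TestRescaleAbscissae:
    def test_small_cases(self):
        assert np.allclose(df.rescale_abscissae(3), [-1, 0, 1])
        assert np.allclose(df.rescale_abscissae(2), [-1, 1])

    def test_equidistant_spacing(self):
        x = df.rescale_abscissae(1000)
        assert np.allclose(np.diff(x), 2 / 999)

    def test_too_short_raises(self):
        with pytest.raises(ParameterError):
            df.rescale_abscissae(1)


class TestLegendreBasis:
    def test_printed_closed_forms(self):
        x = np.array([0.5, 1.0, -1.0, 0.0])
        basis = df.legendre_basis(4, x).basis
        assert np.isclose(basis[2, 0], 0.5 * (3 * 0.25 - 1))  # p_3(0.5) = -0.125
        assert np.isclose(basis[3, 1], 1.0)  # p_4(1) = 1
        assert np.allclose(basis[0], 1.0)
        assert np.allclose(basis[1], x)

    def test_recursion_matches_degree4_closed_form(self):
        x = np.linspace(-1, 1, 200)
        basis = df.legendre_basis(5, x).basis
        closed = (35 * x**4 - 30 * x**2 + 3) / 8
        assert np.abs(basis[4] - closed).max() <= 1e-12

    @pytest.mark.parametrize("order", [3, 7, 10])
    def test_rows_match_numpy_legendre(self, order):
        # independent oracle: numpy's Legendre module
        x = np.linspace(-1, 1, 101)
        basis = df.legendre_basis(order, x).basis
        for n in range(order):
            ref = np.polynomial.legendre.Legendre.basis(n)(x)
            assert np.allclose(basis[n], ref, atol=1e-12)

    def test_out_of_domain_raises(self):
        with pytest.raises(ParameterError):
            df.legendre_basis(3, np.array([0.0, 1.1]))


class TestFitLegendre:
    def test_constant_projects_on_first_basis_function(self):
        fv = df.fit_legendre(_mapped(np.full(200, 3.25)))
        assert np.isclose(fv.values[0], 3.25)
        assert np.abs(fv.values[1:]).max() <= 1e-12

    def test_linear_series_is_p2(self):
        x = df.rescale_abscissae(300)
        fv = df.fit_legendre(df.MappedDistribution(x, "sort"))
        assert np.isclose(fv.values[1], 1.0)
        assert np.abs(np.delete(fv.values, 1)).max() <= 1e-10

    def test_roundtrip_recovers_random_coefficients(self, rng):
        x = df.rescale_abscissae(1000)
        basis = df.legendre_basis(10, x).basis
        for _ in range(10):
            a_true = rng.normal(size=10)
            y = a_true @ basis
            fv = df.fit_legendre(df.MappedDistribution(y, "sort"))
            assert np.abs(fv.values - a_true).max() <= 1e-10

    def test_projection_method_agrees_to_order_one_over_n(self, rng):
        x = df.rescale_abscissae(5000)
        basis = df.legendre_basis(10, x).basis
        y = rng.normal(size=10) @ basis
        series = df.MappedDistribution(y, "sort")
        lstsq = df.fit_legendre(series).values
        proj = df.fit_legendre(series, method="projection").values
        assert 0 < np.abs(lstsq - proj).max() < 0.05

    def test_disk_scaled_mean_is_one_third(self, disk80):
        # closed form: D_scaled quantile function is 1 - sqrt(1-u); mean 1/3
        series = df.apply_mapping(df.extract_sorted(df.distance_transform(disk80)), "scaled")
        fv = df.fit_legendre(series)
        assert abs(fv.values[0] - 1 / 3) < 0.02

    def test_underdetermined_raises(self):
        with pytest.raises(TooFewPixelsError):
            df.fit_legendre(_mapped(np.arange(1.0, 6.0)), order=10)


class TestReconstruct:
    def test_constant_coefficients(self):
        x = df.rescale_abscissae(50)
        out = df.reconstruct(np.array([2.5] + [0.0] * 9), x)
        assert np.allclose(out, 2.5)

    def test_fit_then_reconstruct_is_idempotent_on_low_degree(self, rng):
        x = df.rescale_abscissae(400)
        basis = df.legendre_basis(10, x).basis
        y = rng.normal(size=10) @ basis
        fv = df.fit_legendre(df.MappedDistribution(y, "sort"))
        assert np.abs(df.reconstruct(fv, x) - y).max() <= 1e-10

    def test_degree9_beats_degree3_on_disk(self, disk80):
        series = df.apply_mapping(
            df.extract_sorted(df.distance_transform(disk80)), "scaled"
        )
        x = df.rescale_abscissae(series.n)
        rms = {}
        for order in (4, 10):
            fv = df.fit_legendre(series, order=order)
            resid = df.reconstruct(fv, x) - series.y
            rms[order] = np.sqrt(np.mean(resid**2))
        assert rms[10] < rms[4]


@pytest.fixture(scope="module")
def leaflet():
    return synthetic.generate_samples(
        synthetic.ELONGATED_SPEC, synthetic.ROUNDED_SPEC, 1, seed=21
    )[0].mask


class TestFeaturize:

    @pytest.mark.parametrize("set_kind", ["RSFS", "LPFS"])
    @pytest.mark.parametrize("mapping", df.MAPPING_KINDS)
    def test_translation_and_rot90_exactly_invariant(self, leaflet, set_kind, mapping):
        base = df.featurize(leaflet, set_kind, mapping)
        moved = df.featurize(np.roll(leaflet, (4, -7), axis=(0, 1)), set_kind, mapping)
        rotated = df.featurize(np.rot90(leaflet), set_kind, mapping)
        assert np.array_equal(base.values, moved.values)
        assert np.array_equal(base.values, rotated.values)

    def test_disk_radii_share_scaled_features(self):
        # both disks approximate the same closed-form distribution
        f40 = df.featurize(synthetic.make_disk(40, (100, 100)), "LPFS", "scaled")
        f80 = df.featurize(synthetic.make_disk(80, (200, 200)), "LPFS", "scaled")
        assert np.abs(f40.values - f80.values).max() < 0.02
        r40 = df.featurize(synthetic.make_disk(40, (100, 100)), "RSFS", "scaled")
        r80 = df.featurize(synthetic.make_disk(80, (200, 200)), "RSFS", "scaled")
        assert np.abs(r40.values - r80.values).max() < 0.02

    def test_multi_component_mask_raises(self):
        mask = np.zeros((9, 9), bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        with pytest.raises(MultiComponentError):
            df.featurize(mask, "RSFS")

    def test_rsfs_and_lpfs_describe_the_same_distribution(self, leaflet):
        series = df.apply_mapping(
            df.extract_sorted(df.distance_transform(leaflet)), "scaled"
        )
        x = df.rescale_abscissae(series.n)
        lpfs = df.fit_legendre(series)
        resid = df.reconstruct(lpfs, x) - series.y
        rms = np.sqrt(np.mean(resid**2))
        idx = np.floor(np.arange(1, 11) * (series.n - 1) / 10 + 0.5).astype(int)
        rsfs_values = df.rsfs(series).values
        assert np.abs(df.reconstruct(lpfs, x[idx]) - rsfs_values).max() <= 3 * rms + 1e-9
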