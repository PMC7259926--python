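"""Bray-Curtis metric, province statistics and nutrient summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ecoprov as ep
from ecoprov.dissimilarity import REDFIELD_SCALE


assemblages = hnp.arrays(
    float, st.integers(2, 51),
    elements=st.floats(0.0, 1e6, allow_nan=False, allow_infinity=False),
).filter(lambda a: a.sum() > 0)


class TestBrayCurtis:
    def test_identical_assemblages_zero(self):
        a = np.arange(1.0, 52.0)
        assert ep.bray_curtis(a, a) == 0.0

    def test_disjoint_supports_one(self):
        a = np.r_[np.ones(25), np.zeros(26)]
        b = np.r_[np.zeros(25), np.ones(26)]
        assert ep.bray_curtis(a, b) == 1.0

    def test_hand_evaluated_example(self):
        assert ep.bray_curtis(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == \
            pytest.approx(1.0 / 3.0)

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import braycurtis

        for _ in range(20):
            a = rng.uniform(0, 10, size=51)
            b = rng.uniform(0, 10, size=51)
            assert ep.bray_curtis(a, b) == pytest.approx(braycurtis(a, b), abs=1e-12)

    @settings(max_examples=150, derandomize=True)
    @given(assemblages.flatmap(
        lambda a: st.tuples(st.just(a),
                            hnp.arrays(float, len(a),
                                       elements=st.floats(0.0, 1e6)).filter(
                                           lambda b: b.sum() > 0))))
    def test_metric_properties(self, pair):
        a, b = pair
        bc = ep.bray_curtis(a, b)
        assert 0.0 <= bc <= 1.0
        assert bc == ep.bray_curtis(b, a)
        assert ep.bray_curtis(a, a) == 0.0
        # scale invariance
        assert ep.bray_curtis(3.5 * a, 3.5 * b) == pytest.approx(bc, abs=1e-12)

    def test_rejections(self):
        z = np.zeros(5)
        with pytest.raises(ep.ValidationError):
            ep.bray_curtis(z, z)
        with pytest.raises(ep.ValidationError):
            ep.bray_curtis(np.array([1.0, -1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ep.ValidationError):
            ep.bray_curtis(np.ones(3), np.ones(4))


class TestProvinceMeanAssemblage:
    def test_single_and_two_cell_means(self, tiny_labeled_field):
        field, lab = tiny_labeled_field
        vecs = field.type_biomass.reshape(51, -1).T[lab.cell_ids]
        means = ep.province_mean_assemblage(lab, field, area_weighted=False)
        for pid, mean in means.items():
            members = vecs[lab.labels == pid]
            np.testing.assert_allclose(mean, members.mean(axis=0), rtol=1e-12)

    def test_cos_latitude_weighting_matches_direct_sum(self, small_field,
                                                       small_labeling):
        means = ep.province_mean_assemblage(small_labeling, small_field)
        lat, _ = small_field.cell_latlon(small_labeling.cell_ids)
        w = np.cos(np.deg2rad(lat))
        vecs = small_field.type_biomass.reshape(51, -1).T[small_labeling.cell_ids]
        pid = small_labeling.province_ids()[0]
        sel = small_labeling.labels == pid
        expected = (vecs[sel] * w[sel, None]).sum(axis=0) / w[sel].sum()
        np.testing.assert_allclose(means[int(pid)], expected, rtol=1e-12)


class TestIntraprovinceBC:
    def test_zero_noise_province_is_zero(self, tiny_labeled_field):
        field, lab = tiny_labeled_field
        table, summary = ep.intraprovince_bc(lab, field)
        assert np.allclose(table["mean_bc"], 0.0, atol=1e-12)
        assert summary["cell_weighted_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_three_cell_toy_matches_hand_loop(self):
        spec = ep.SyntheticSpec(n_lat=1, n_lon=3, n_provinces=1, noise_sd=0.4,
                                low_biomass_frac=0.0, ice_band_lat=90.0, seed=2)
        field = ep.generate_field(spec)
        labels = np.zeros(3, dtype=int)
        cells = np.arange(3)
        table, _ = ep.intraprovince_bc(labels, field, cells, area_weighted=False)
        vecs = field.type_biomass.reshape(51, -1).T
        mean = vecs.mean(axis=0)
        expected = np.mean([ep.bray_curtis(v, mean) for v in vecs])
        assert table["mean_bc"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_merging_distinct_provinces_increases_dissimilarity(self,
                                                                tiny_labeled_field):
        field, lab = tiny_labeled_field
        table, _ = ep.intraprovince_bc(lab, field)
        merged = np.where(lab.labels <= 1, 0, lab.labels)
        mtable, _ = ep.intraprovince_bc(merged, field, lab.cell_ids)
        assert mtable.loc[0, "mean_bc"] >= max(table.loc[0, "mean_bc"],
                                               table.loc[1, "mean_bc"])


class TestInterprovinceBC:
    def test_matrix_matches_pairwise_calls(self, small_field, small_labeling):
        bc = ep.interprovince_bc(small_labeling, small_field)
        means = ep.province_mean_assemblage(small_labeling, small_field)
        ids = list(bc.province_ids)
        for i, pi in enumerate(ids):
            for j, pj in enumerate(ids):
                expected = 0.0 if i == j else ep.bray_curtis(means[pi], means[pj])
                assert bc.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_zero_diagonal_range(self, small_field, small_labeling):
        bc = ep.interprovince_bc(small_labeling, small_field)
        bc.validate()  # symmetry, [0,1], zero diagonal
        assert np.array_equal(bc.values, bc.values.T)

    def test_groups_and_types_levels_both_valid(self, small_field, small_labeling):
        a = ep.interprovince_bc(small_labeling, small_field, level="types")
        b = ep.interprovince_bc(small_labeling, small_field, level="groups")
        assert not np.allclose(a.values, b.values)
        for m in (a, b):
            assert np.all(m.values >= 0) and np.all(m.values <= 1)

    def test_single_province_rejected(self, tiny_labeled_field):
        field, lab = tiny_labeled_field
        with pytest.raises(ep.ValidationError):
            ep.interprovince_bc(np.zeros(len(lab.labels), dtype=int), field,
                                lab.cell_ids)


class TestBenchmarkBC:
    def test_self_benchmark_identical(self, small_field, small_labeling):
        _, own = ep.intraprovince_bc(small_labeling, small_field)
        _, ref = ep.benchmark_bc(small_labeling, small_field)
        assert ref == own

    def test_single_global_province_on_uniform_field(self):
        spec = ep.SyntheticSpec(n_lat=6, n_lon=8, n_provinces=1, noise_sd=0.0,
                                low_biomass_frac=0.0, ice_band_lat=90.0, seed=3)
        field = ep.generate_field(spec)
        cells = np.arange(field.n_cells)
        _, summary = ep.benchmark_bc(np.zeros(field.n_cells, dtype=int), field, cells)
        assert summary["cell_weighted_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_random_partition_is_worse_than_pipeline(self, small_field,
                                                     small_labeling):
        _, own = ep.intraprovince_bc(small_labeling, small_field)
        _, null = ep.shuffled_benchmark(small_labeling, small_field, seed=0)
        assert null["cell_weighted_mean"] >= own["cell_weighted_mean"]

    def test_unlabeled_cells_excluded_with_warning(self, small_field,
                                                   small_labeling):
        ref = np.array(small_labeling.labels)
        ref[:10] = -1
        with pytest.warns(UserWarning, match="unlabeled"):
            _, summary = ep.benchmark_bc(ref, small_field, small_labeling.cell_ids)
        assert summary["n_cells"] <= len(ref) - 10


class TestNutrientSummary:
    def test_redfield_scaling(self):
        spec = ep.SyntheticSpec(n_lat=2, n_lon=2, n_provinces=1, noise_sd=0.0,
                                low_biomass_frac=0.0, ice_band_lat=90.0, seed=1,
                                flux_profiles=np.array([[2.0, 1e-4, 0.5, 3.0]]))
        field = ep.generate_field(spec)
        labels = np.zeros(4, dtype=int)
        out = ep.province_nutrient_summary(labels, field, np.arange(4))
        assert out.loc[0, "flux_Fe_scaled"] == pytest.approx(1.6)   # 1e-4 * 16e3
        assert out.loc[0, "flux_P_scaled"] == pytest.approx(8.0)    # 0.5 * 16
        assert out.loc[0, "flux_N_scaled"] == pytest.approx(2.0)
        assert out.loc[0, "flux_Si_scaled"] == pytest.approx(3.0)
        assert REDFIELD_SCALE == {"N": 1.0, "Fe": 16.0e3, "P": 16.0, "Si": 1.0}

    def test_contains_group_biomasses(self, small_field, small_labeling):
        out = ep.province_nutrient_summary(small_labeling, small_field)
        from ecoprov.preprocess import GROUP_NAMES

        assert all(g in out.columns for g in GROUP_NAMES)
        assert len(out) == small_labeling.n_clusters
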