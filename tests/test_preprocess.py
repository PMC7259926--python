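"""Functional-group summation, masking rules, and feature-transform contracts."""

import numpy as np
import pytest

import ecoprov as ep
from ecoprov.preprocess import (
    FEATURE_COLUMNS,
    GROUP_SIZES,
    GriddedEcosystemField,
    N_FEATURES,
    N_GROUPS,
    N_TYPES,
    default_type_groups,
)


def _field_from_cells(groups, fluxes, ice):
    """1 x n grid built from per-cell 7-vectors / 4-vectors."""
    groups = np.asarray(groups, dtype=float)
    fluxes = np.asarray(fluxes, dtype=float)
    n = groups.shape[0]
    return GriddedEcosystemField(
        lat=np.array([0.0]),
        lon=np.linspace(-180, 180, n, endpoint=False),
        nutrient_flux=fluxes.T.reshape(4, 1, n),
        ice_fraction=np.asarray(ice, dtype=float).reshape(1, n),
        group_biomass=groups.T.reshape(N_GROUPS, 1, n),
    )


class TestSumFunctionalGroups:
    def test_all_zero_types_give_all_zero_groups(self):
        field = GriddedEcosystemField(
            lat=np.array([0.0]), lon=np.array([0.0]),
            nutrient_flux=np.zeros((4, 1, 1)), ice_fraction=np.zeros((1, 1)),
            type_biomass=np.zeros((N_TYPES, 1, 1)),
        )
        out = ep.sum_functional_groups(field)
        assert np.array_equal(out.group_biomass, np.zeros((N_GROUPS, 1, 1)))

    def test_random_vector_matches_per_group_accumulation(self, rng):
        types = rng.uniform(0, 10, size=(N_TYPES, 2, 3))
        field = GriddedEcosystemField(
            lat=np.array([0.0, 1.0]), lon=np.array([0.0, 1.0, 2.0]),
            nutrient_flux=np.zeros((4, 2, 3)), ice_fraction=np.zeros((2, 3)),
            type_biomass=types,
        )
        out = ep.sum_functional_groups(field)
        # brute-force accumulation oracle
        expected = np.zeros((N_GROUPS, 2, 3))
        tg = default_type_groups()
        for t in range(N_TYPES):
            expected[tg[t]] += types[t]
        np.testing.assert_allclose(out.group_biomass, expected, rtol=1e-12)

    def test_dimension_contract_55_to_11(self, small_field):
        assert small_field.type_biomass.shape[0] + 4 == 55
        fm = ep.apply_masks(small_field)
        assert fm.values.shape[1] == N_FEATURES == 11
        assert sum(GROUP_SIZES) == 51

    def test_non_partitioning_membership_rejected(self, small_field):
        bad = default_type_groups()
        bad[0] = 99
        with pytest.raises(ep.ValidationError):
            ep.sum_functional_groups(small_field, bad)


class TestApplyMasks:
    def test_threshold_edges(self):
        groups = np.array([
            [1.0e-3 / N_GROUPS] * N_GROUPS,   # total 1.0e-3: below threshold
            [1.0 / N_GROUPS] * N_GROUPS,      # high biomass, high ice -> excluded
            [1.0 / N_GROUPS] * N_GROUPS,      # retained
            [1.2e-3 / N_GROUPS] * N_GROUPS,   # exactly at threshold -> retained
        ])
        field = _field_from_cells(groups, np.ones((4, 4)), [0.0, 0.75, 0.0, 0.0])
        fm = ep.apply_masks(field)
        assert fm.cell_ids.tolist() == [2, 3]

    def test_idempotent_survivor_set(self, small_field):
        a = ep.apply_masks(small_field)
        b = ep.apply_masks(small_field)
        assert np.array_equal(a.cell_ids, b.cell_ids)
        assert np.array_equal(a.values, b.values)

    def test_survivor_bookkeeping_matches_generator(self):
        spec = ep.SyntheticSpec(n_lat=20, n_lon=30, n_provinces=3,
                                low_biomass_frac=0.1, seed=8)
        field = ep.generate_field(spec)
        fm = ep.apply_masks(field)
        n_surv = (field.n_cells - fm.meta["n_below_biomass"] - fm.meta["n_iced"]
                  + fm.meta["n_iced_and_below"])
        assert fm.n == n_surv
        assert fm.n == field.n_cells - field.attrs["n_iced"] - field.attrs["n_low_biomass"]

    def test_empty_survivor_set_rejected_with_counts(self):
        groups = np.full((3, N_GROUPS), 1e-6)
        field = _field_from_cells(groups, np.ones((4, 3)), [0.0, 0.0, 0.0])
        with pytest.raises(ep.ValidationError, match="below biomass threshold"):
            ep.apply_masks(field)


class TestTransformFeatures:
    def test_minmax_column_forced(self):
        groups = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, N_GROUPS))
        field = _field_from_cells(groups, np.tile([[1.0], [2.0], [3.0]], (1, 4)),
                                  [0.0] * 3)
        fm = ep.transform_features(ep.apply_masks(field))
        minmax = fm.intermediates["minmax"]
        # log then min-max of [1,2,3] -> [0, log2/log3, 1]; fluxes un-logged -> [0,.5,1]
        np.testing.assert_allclose(minmax[:, 0], [0.0, np.log(2) / np.log(3), 1.0])
        np.testing.assert_allclose(minmax[:, N_GROUPS], [0.0, 0.5, 1.0])

    def test_minmax_and_standardized_invariants(self, small_features):
        minmax = small_features.intermediates["minmax"]
        assert np.all(np.abs(minmax.min(axis=0)) < 1e-12)
        assert np.all(np.abs(minmax.max(axis=0) - 1.0) < 1e-12)
        z = small_features.values
        assert np.all(np.abs(z.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(z.var(axis=0) - 1.0) < 1e-9)

    def test_commutes_with_row_permutation(self, small_field, rng):
        fm = ep.apply_masks(small_field)
        perm = rng.permutation(fm.n)
        permuted = ep.FeatureMatrix(values=fm.values[perm],
                                    index_map=fm.index_map.iloc[perm].reset_index(drop=True))
        a = ep.transform_features(fm).values
        b = ep.transform_features(permuted).values
        np.testing.assert_allclose(a[perm], b, rtol=1e-12, atol=1e-12)

    def test_zero_biomass_group_stays_finite(self):
        groups = np.ones((5, N_GROUPS))
        groups[:, 3] = 0.0  # one group absent everywhere it matters
        groups[0, 3] = 2.0
        field = _field_from_cells(groups, np.ones((4, 5)), [0.0] * 5)
        fm = ep.transform_features(ep.apply_masks(field))
        assert np.all(np.isfinite(fm.values))
        for stage in fm.intermediates.values():
            assert np.all(np.isfinite(stage))

    def test_constant_column_zeroed_with_warning(self):
        groups = np.ones((4, N_GROUPS))
        groups[:, 0] = [1, 2, 3, 4]
        field = _field_from_cells(groups, np.ones((4, 4)) * [[1], [2], [3], [4]],
                                  [0.0] * 4)
        with pytest.warns(UserWarning, match="constant feature column"):
            fm = ep.transform_features(ep.apply_masks(field))
        constant_cols = [i for i, c in enumerate(FEATURE_COLUMNS)
                         if 1 <= i < N_GROUPS]
        assert np.all(fm.values[:, constant_cols] == 0.0)

    def test_wrong_stage_rejected(self, small_features):
        with pytest.raises(ep.ValidationError):
            ep.transform_features(small_features)
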