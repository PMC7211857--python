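"""Dataset validation, design matrices, packing and linear predictors."""

import numpy as np
import pandas as pd
import pytest

from fishgrowth import (
    GrowthDataset,
    ModelSpec,
    ParameterLayout,
    ParameterSet,
    build_design_matrices,
    linear_predictors,
)
from conftest import toy_frame


class TestGrowthDataset:
    def test_ordering_and_registries(self, toy_data):
        assert toy_data.fish_ids == ["a", "b", "c"]
        assert toy_data.levels["species"] == ["MT", "BT"]
        assert toy_data.levels["population"] == ["p1", "p2"]
        assert toy_data.n_obs == 6

    def test_rejects_duplicate_fish_age(self):
        df = toy_frame()
        df.loc[1, "age"] = 1.0
        with pytest.raises(ValueError, match="duplicate"):
            GrowthDataset(df)

    def test_rejects_inconsistent_group(self):
        df = toy_frame()
        df.loc[1, "population"] = "p2"
        with pytest.raises(ValueError, match="inconsistent"):
            GrowthDataset(df)

    def test_rejects_bad_values(self):
        df = toy_frame()
        df.loc[0, "length"] = -5.0
        with pytest.raises(ValueError, match="length"):
            GrowthDataset(df)
        df = toy_frame()
        df.loc[0, "age"] = -1.0
        with pytest.raises(ValueError, match="age"):
            GrowthDataset(df)

    def test_missing_column(self):
        with pytest.raises(ValueError, match="missing mandatory"):
            GrowthDataset(toy_frame().drop(columns="length"))


class TestDesignMatrices:
    def test_constant_is_intercept_only(self, toy_data):
        d = build_design_matrices(toy_data, ModelSpec())
        for p in ("asymptote", "rate", "location"):
            assert d.X[p].shape == (3, 1)
            np.testing.assert_array_equal(d.X[p], np.ones((3, 1)))

    def test_categorical_levels_and_reference(self, multi_pop_data):
        data, _, _ = multi_pop_data
        spec = ModelSpec(asymptote="population", rate="species")
        d = build_design_matrices(data, spec)
        # 4-level population -> intercept + 3 indicators
        assert d.X["asymptote"].shape[1] == 4
        # 3-level species -> intercept + 2 indicators
        assert d.X["rate"].shape[1] == 3
        assert d.X["location"].shape[1] == 1
        # reference level (first appearance) has all-zero indicators
        ref_rows = data.fish_table["population"] == data.levels["population"][0]
        np.testing.assert_array_equal(
            d.X["asymptote"][ref_rows.to_numpy(), 1:], 0.0
        )
        # full column rank with all levels populated
        for p in ("asymptote", "rate", "location"):
            assert np.linalg.matrix_rank(d.X[p]) == d.X[p].shape[1]

    def test_names_stable_snapshot(self, multi_pop_data):
        data, _, _ = multi_pop_data
        spec = ModelSpec(asymptote="population", rate="species")
        d = build_design_matrices(data, spec)
        assert d.names["asymptote"] == [
            "asymptote.intercept",
            "asymptote.population[UIdri_MT]",
            "asymptote.population[LIdri_RT]",
            "asymptote.population[UVol_BT]",
        ]
        assert d.names["rate"] == [
            "rate.intercept",
            "rate.species[RT]",
            "rate.species[BT]",
        ]

    def test_interaction_and_unknown_term(self, multi_pop_data):
        data, _, _ = multi_pop_data
        d = build_design_matrices(data, ModelSpec(asymptote="species:population"))
        # 2 x 3 products of non-reference indicators
        assert d.X["asymptote"].shape[1] == 1 + 2 * 3
        with pytest.raises(ValueError, match="unknown predictor term"):
            build_design_matrices(data, ModelSpec(asymptote="weight"))


class TestPacking:
    def _layout(self, data, spec):
        return ParameterLayout(build_design_matrices(data, spec), spec.random_effects)

    def test_roundtrip_and_length(self, multi_pop_data):
        data, _, _ = multi_pop_data
        spec = ModelSpec(asymptote="population", rate="population", location="population")
        layout = self._layout(data, spec)
        assert layout.size == 12 + 4
        rng = np.random.default_rng(0)
        x = rng.normal(size=layout.size)
        theta = layout.unpack(x)
        np.testing.assert_array_equal(layout.pack(theta), x)

    def test_switched_off_effect_shortens_vector(self, toy_data):
        spec = ModelSpec(random_effects=(True, True, False))
        layout = self._layout(toy_data, spec)
        assert layout.size == 3 + 3
        theta = layout.unpack(np.zeros(layout.size))
        assert theta.log_sigma["location"] is None
        assert theta.sigma("location") == 0.0

    def test_constant_spec_count(self, toy_data):
        assert self._layout(toy_data, ModelSpec()).size == 3 + 4

    def test_length_mismatch(self, toy_data):
        layout = self._layout(toy_data, ModelSpec())
        with pytest.raises(ValueError):
            layout.unpack(np.zeros(layout.size + 1))


class TestLinearPredictors:
    def test_link_identities(self, toy_data):
        spec = ModelSpec()
        design = build_design_matrices(toy_data, spec)
        layout = ParameterLayout(design, spec.random_effects)
        theta = layout.unpack(np.zeros(layout.size))
        asym, rate, loc = linear_predictors(theta, np.zeros((3, 3)), design)
        np.testing.assert_allclose(asym, 1.0)
        np.testing.assert_allclose(rate, 1.0)
        np.testing.assert_allclose(loc, 0.0)

    def test_random_effect_scaling(self, toy_data):
        spec = ModelSpec()
        design = build_design_matrices(toy_data, spec)
        theta = ParameterSet(
            beta={"asymptote": np.array([np.log(300.0)]), "rate": np.zeros(1),
                  "location": np.zeros(1)},
            log_sigma={"asymptote": np.log(0.1), "rate": np.log(0.1), "location": np.log(0.1)},
            log_sigma_eps=0.0,
        )
        eff = np.zeros((3, 3))
        eff[0, 0] = 1.0  # one unit of asymptote effect
        asym, _, _ = linear_predictors(theta, eff, design)
        assert asym[0] == pytest.approx(300.0 * np.exp(0.1), rel=1e-12)
        assert asym[1] == pytest.approx(300.0, rel=1e-12)

    def test_switched_off_effect_ignored(self, toy_data):
        spec = ModelSpec(random_effects=(False, True, True))
        design = build_design_matrices(toy_data, spec)
        layout = ParameterLayout(design, spec.random_effects)
        theta = layout.unpack(np.zeros(layout.size))
        eff = np.ones((3, 3)) * 5.0  # stored asymptote effects must not leak
        asym, _, _ = linear_predictors(theta, eff, design)
        np.testing.assert_allclose(asym, 1.0)


class TestModelSpec:
    def test_serialization_roundtrip(self):
        spec = ModelSpec(
            function="gompertz", asymptote="species", rate=("population",),
            location="constant", random_effects=(True, False, True),
        )
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_label(self):
        spec = ModelSpec(asymptote="population", rate="population", location="population")
        assert spec.label == "vbgf: Linf(Population), k(Population), t0(Population)"

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(function="richards")
        with pytest.raises(ValueError):
            ModelSpec(random_effects=(True, True))
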