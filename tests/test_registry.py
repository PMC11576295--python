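"""Registry, response validation, scoring and reliability."""

import numpy as np
import pandas as pd
import pytest

from ipvkit.registry import (
    correlation_matrix,
    cronbach_alpha,
    default_registry,
    load_registry,
    score_subscales,
    validate_responses,
)


def _uniform_responses(registry, n=10, seed=0):
    rng = np.random.default_rng(seed)
    cols = {}
    for iid in registry.item_ids:
        sc = registry.scale_of(iid)
        cols[iid] = rng.integers(sc.min_code, sc.max_code + 1, n)
    return pd.DataFrame(cols)


class TestDefaultRegistry:
    def test_structure(self, registry):
        assert registry.n_items == 47
        assert len(registry.instruments) == 4
        assert len(registry.facet_ids) == 11
        counts = {i.name: i.n_items for i in registry.instruments}
        assert counts == {"MHC-SF": 14, "PERMA": 15, "FS": 8, "WBCF": 10}
        facet_counts = [len(v) for v in registry.items_by_facet().values()]
        assert facet_counts == [3, 5, 6, 3, 3, 3, 3, 3, 8, 6, 4]

    def test_wbcf_reverse_item_is_the_only_one(self, registry):
        assert registry.reverse_coded_items() == {"WBCF-PC-2"}

    def test_item_id_convention(self, registry):
        assert "MHC-SF-SWB-4" in registry.item_ids
        assert "FS-1" in registry.item_ids  # unidimensional: no facet segment

    def test_duplicate_item_rejected(self):
        cfg = {"FS": {"FS": {"items": ["FS-1", "FS-1"], "range": [1, 7]}}}
        with pytest.raises(ValueError, match="duplicate"):
            load_registry(cfg)

    def test_item_without_range_rejected(self):
        cfg = {"FS": {"FS": {"items": 8}}}
        with pytest.raises(ValueError, match="range"):
            load_registry(cfg)

    def test_unknown_instrument_rejected(self):
        cfg = {"NOPE": {"X": {"items": 3, "range": [0, 4]}}}
        with pytest.raises(ValueError, match="unknown instrument"):
            load_registry(cfg)


class TestValidation:
    def test_boundary_codes_accepted_and_rejected(self, registry):
        data = _uniform_responses(registry)
        data.loc[0, "MHC-SF-EWB-1"] = 5  # max of the 0-5 scale
        validate_responses(data, registry)
        data.loc[0, "MHC-SF-EWB-1"] = 6
        with pytest.raises(ValueError, match="outside"):
            validate_responses(data, registry)

    def test_missing_cell_rejected(self, registry):
        data = _uniform_responses(registry).astype(float)
        data.loc[3, "FS-2"] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            validate_responses(data, registry)

    def test_unknown_column_rejected(self, registry):
        data = _uniform_responses(registry)
        data["bogus"] = 1
        with pytest.raises(ValueError, match="unknown"):
            validate_responses(data, registry)

    def test_reverse_coding_value(self, registry):
        data = _uniform_responses(registry)
        data["WBCF-PC-2"] = 0
        out = validate_responses(data, registry)
        assert (out["WBCF-PC-2"] == 4).all()  # 0 on a 0-4 scale -> 4

    def test_reverse_coding_is_involution(self, registry):
        data = _uniform_responses(registry, seed=5)
        twice = validate_responses(validate_responses(data, registry), registry)
        pd.testing.assert_frame_equal(twice, data[registry.item_ids])


class TestScoring:
    def test_constant_max_fs(self, registry):
        data = _uniform_responses(registry, n=6)
        for iid in registry.items_by_instrument()["FS"]:
            data[iid] = 7
        scores = score_subscales(data, registry)
        assert scores.composites["FS"].eq(7.0).all()
        assert scores.summary.loc["FS", "SD"] == 0.0

    def test_composites_are_row_means(self, registry):
        # 3-respondent toy check on the EWB subscale, by hand:
        # rows (0,1,2), (3,4,5), (5,5,5) -> means 1, 4, 5
        data = _uniform_responses(registry, n=3)
        ewb = ["MHC-SF-EWB-1", "MHC-SF-EWB-2", "MHC-SF-EWB-3"]
        data.loc[:, ewb] = [[0, 1, 2], [3, 4, 5], [5, 5, 5]]
        scores = score_subscales(data, registry)
        assert scores.composites["EWB"].tolist() == [1.0, 4.0, 5.0]

    def test_wbcf_standardized_composite_centered(self, registry):
        data = _uniform_responses(registry, n=200, seed=1)
        scores = score_subscales(data, registry)
        assert scores.standardized["PC"] and scores.standardized["PF"]
        assert abs(scores.summary.loc["PC", "M"]) < 1e-12
        assert not scores.standardized["EWB"]

    def test_zero_variance_item_with_standardize(self, registry):
        data = _uniform_responses(registry, n=20)
        data["WBCF-PC-1"] = 2
        with pytest.raises(ValueError, match="zero-variance"):
            score_subscales(data, registry, standardize_items=True)


class TestCronbachAlpha:
    def test_spearman_brown_two_items(self):
        # exact sample correlation 0.5 between two equal-variance items
        items = pd.DataFrame({"a": [1, -1, 0, 0], "b": [1, 0, -1, 0]})
        assert np.corrcoef(items.a, items.b)[0, 1] == pytest.approx(0.5)
        res = cronbach_alpha(items)
        assert res.alpha == pytest.approx(2 * 0.5 / 1.5, abs=1e-12)

    def test_identical_columns_alpha_one(self):
        x = pd.Series([1, 2, 3, 4, 2])
        items = pd.DataFrame({"a": x, "b": x, "c": x})
        assert cronbach_alpha(items).alpha == pytest.approx(1.0)

    def test_uncorrelated_items_alpha_zero(self):
        # orthogonal equal-variance contrasts: alpha = 0 exactly
        items = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        assert cronbach_alpha(items).alpha == pytest.approx(0.0, abs=1e-12)

    def test_invariance_shift_and_reorder(self):
        rng = np.random.default_rng(2)
        items = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        a0 = cronbach_alpha(items).alpha
        shifted = items + 7
        assert cronbach_alpha(shifted).alpha == pytest.approx(a0, abs=1e-12)
        assert cronbach_alpha(items[list("dbca")]).alpha == pytest.approx(a0, abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [1, 2, 3]}))
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(pd.DataFrame({"a": [1, 1, 1], "b": [2, 2, 2]}))


class TestCorrelationMatrix:
    def test_identity_and_sign(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        df = pd.DataFrame({"x": x, "mx": -x, "y": rng.normal(size=40)})
        C = correlation_matrix(df)
        assert C.loc["x", "x"] == pytest.approx(1.0)
        assert C.loc["x", "mx"] == pytest.approx(-1.0)
        assert np.allclose(C, C.T)

    def test_hand_computed_toy(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]})
        # hand Pearson r: cov=2, sds=sqrt(2.5) -> r = 0.8
        assert correlation_matrix(df).loc["a", "b"] == pytest.approx(0.8)

    def test_positive_semidefinite(self, registry):
        data = _uniform_responses(registry, n=100, seed=9)
        scores = score_subscales(data, registry)
        C = correlation_matrix(scores)
        assert np.linalg.eigvalsh(C.to_numpy()).min() > -1e-10

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [1, 1, 1]})
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(df)
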