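"""Wrapper feature selection: binary codec, penalized fitness, recovery."""

import numpy as np
import pytest

from woaboost import model as _model
from woaboost.cohort import one_hot_encode
from woaboost.core import WOAConfig
from woaboost.selection import (
    FeatureMask,
    SelectionFitnessConfig,
    binarize_position,
    mask_columns,
    mask_to_feature_indices,
    select_features,
    selection_fitness,
)


class TestBinaryCodec:
    def test_worked_example_mask(self):
        X = np.array([0.9, 0.1, 0.6, 0.7, 0.2, 0.3, 0.8, 0.4, 0.51, 0.0])
        mask = binarize_position(X)
        assert list(mask.bits) == [1, 0, 1, 1, 0, 0, 1, 0, 1, 0]

    def test_worked_example_one_based_indices(self):
        mask = FeatureMask(bits=(1, 0, 1, 1, 0, 0, 1, 0, 1, 0))
        assert mask_to_feature_indices(mask, one_based=True) == (1, 3, 4, 7, 9)

    def test_all_ones_and_zero_based(self):
        mask = FeatureMask(bits=(1, 1, 1))
        assert mask_to_feature_indices(mask) == (1, 2, 3)
        last = FeatureMask(bits=tuple([0] * 15 + [1]))
        assert mask_to_feature_indices(last, one_based=False) == (15,)

    def test_empty_mask_repaired_at_argmax(self):
        mask = binarize_position(np.array([0.2, 0.4, 0.1]))
        assert list(mask.bits) == [0, 1, 0]
        allzero = binarize_position(np.zeros(4))
        assert list(allzero.bits) == [1, 0, 0, 0]

    def test_all_above_threshold_selects_everything(self):
        assert binarize_position(np.ones(5)).n_selected == 5

    def test_invalid_masks_rejected(self):
        with pytest.raises(ValueError):
            FeatureMask(bits=(0, 0, 0))
        with pytest.raises(ValueError):
            FeatureMask(bits=(0, 2, 0))


class TestFitnessArithmetic:
    @pytest.fixture()
    def stub_cv(self, monkeypatch):
        """Pin the CV F1 so the penalty arithmetic is isolated."""

        def patch(value):
            monkeypatch.setattr(_model, "cv_f1", lambda *a, **k: (value, 0.0))

        return patch

    def test_perfect_f1_leaves_only_penalty(self, cohort, stub_cv):
        stub_cv(1.0)
        enc = one_hot_encode(cohort)
        mask = FeatureMask(bits=tuple([1, 1] + [0] * 14))
        fit = selection_fitness(
            mask, enc, cohort.target, cohort.schema.feature_names,
            SelectionFitnessConfig(),
        )
        assert fit == pytest.approx(0.99 * 0.0 + 0.01 * (2 / 16))

    def test_zero_f1_full_mask_is_worst_case(self, cohort, stub_cv):
        stub_cv(0.0)
        enc = one_hot_encode(cohort)
        mask = FeatureMask(bits=tuple([1] * 16))
        fit = selection_fitness(
            mask, enc, cohort.target, cohort.schema.feature_names,
            SelectionFitnessConfig(),
        )
        assert fit == pytest.approx(1.0)

    def test_penalty_off_depends_only_on_f1(self, cohort, stub_cv):
        stub_cv(0.8)
        enc = one_hot_encode(cohort)
        cfg = SelectionFitnessConfig(alpha=1.0, beta_penalty=0.0)
        for bits in ([1] + [0] * 15, [1] * 16):
            fit = selection_fitness(
                FeatureMask(bits=tuple(bits)), enc, cohort.target,
                cohort.schema.feature_names, cfg,
            )
            assert fit == pytest.approx(1.0 * 0.2)

    def test_monotone_in_f1_and_feature_count(self):
        cfg = SelectionFitnessConfig()
        fit = lambda f1, k: cfg.alpha * (1 - f1) + cfg.beta_penalty * (k / 16)
        assert fit(0.9, 2) < fit(0.8, 2)
        assert fit(0.9, 2) < fit(0.9, 5)

    def test_weights_must_be_convex(self):
        with pytest.raises(ValueError):
            SelectionFitnessConfig(alpha=0.9, beta_penalty=0.2)


class TestMaskingConsistency:
    def test_mask_then_encode_equals_encode_then_subset(self, cohort):
        """The classifier sees identical matrices either way."""
        mask = FeatureMask(bits=tuple([1, 0] * 8))
        enc = one_hot_encode(cohort)
        names = cohort.schema.feature_names
        cols = mask_columns(mask, enc, names)
        direct = enc.matrix[:, cols]
        # re-encode a cohort restricted to the selected features
        kept = [names[i] for i in mask.selected_indices]
        sub_cols = [c for f in kept for c in enc.feature_column_indices(f)]
        assert np.array_equal(direct, enc.matrix[:, sub_cols])


class TestSelectFeatures:
    SMALL = dict(n_agents=6, n_iters=6)

    def test_penalty_only_objective_returns_single_feature(self, cohort):
        res = select_features(
            cohort,
            variant="woa",
            opt_cfg=WOAConfig(seed=0, **self.SMALL),
            sel_cfg=SelectionFitnessConfig(alpha=0.0, beta_penalty=1.0),
        )
        assert res.mask.n_selected == 1

    def test_same_seed_reproduces_result(self, planted_cohort):
        kw = dict(
            variant="mwoa",
            opt_cfg=WOAConfig(seed=4, **self.SMALL),
        )
        r1 = select_features(planted_cohort, **kw)
        r2 = select_features(planted_cohort, **kw)
        assert r1.mask == r2.mask
        assert np.array_equal(r1.history, r2.history)
        assert r1.fitness == r2.fitness

    def test_planted_features_recovered_single_seed(self, planted_cohort):
        res = select_features(
            planted_cohort,
            variant="mwoa",
            opt_cfg=WOAConfig(n_agents=10, n_iters=20, seed=0),
        )
        assert {"Response", "Pathology"} <= set(res.selected_names)

    def test_result_json_contains_decomposition(self, planted_cohort):
        import json

        res = select_features(
            planted_cohort, variant="woa", opt_cfg=WOAConfig(seed=1, **self.SMALL)
        )
        payload = json.loads(res.to_json())
        assert set(payload) >= {
            "bits", "selected_indices_1based", "selected_features",
            "fitness", "fitness_decomposition", "history",
        }
        assert payload["selected_indices_1based"] == [
            i + 1 for i in res.mask.selected_indices
        ]

    def test_unknown_variant_rejected(self, cohort):
        with pytest.raises(ValueError):
            select_features(cohort, variant="pso")
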