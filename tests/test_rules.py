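"""Interval-rule classification and greedy configuration training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoecho import (FeatureMap, RuleConfig, TrainingConstraints,
                      TrainingError, WindowSpec, classify,
                      control_correction, train_config)


def make_map(values, frame_index=0):
    values = np.asarray(values, dtype=np.float32)
    n_lat, n_ax = values.shape[:2]
    return FeatureMap(values, np.arange(n_lat), np.arange(n_ax),
                      WindowSpec(1, 16), frame_index)


def gaussian_maps(rng, n_maps, shape, shift_feature=None, shift=0.0,
                  mask=None):
    """Synthetic 25-feature maps of unit Gaussians; optionally one
    feature is shifted inside the mask region."""
    maps = []
    for k in range(n_maps):
        v = rng.standard_normal(shape + (25,))
        if shift_feature is not None:
            v[mask, shift_feature] += shift
        maps.append(make_map(v, k))
    return maps


class TestClassify:
    def test_unbounded_interval_colors_everything(self, rng):
        fmap = make_map(rng.standard_normal((4, 5, 25)))
        cfg = RuleConfig((3,), ((-np.inf, np.inf),))
        assert classify(fmap, cfg).all()

    def test_disjoint_interval_colors_nothing(self, rng):
        v = rng.uniform(0, 1, (4, 5, 25))
        cfg = RuleConfig((2,), ((5.0, 9.0),))
        assert not classify(make_map(v), cfg).any()

    def test_hand_enumerated_three_pixels(self):
        v = np.zeros((1, 3, 25))
        v[0, :, 1] = [0.5, 2.0, 0.7]   # feature 1
        v[0, :, 4] = [3.0, 3.0, 9.0]   # feature 4
        cfg = RuleConfig((1, 4), ((0.0, 1.0), (2.0, 4.0)))
        det = classify(make_map(v), cfg)
        assert det.tolist() == [[True, False, False]]

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig((), ())

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(deadline=None, max_examples=30)
    def test_widening_is_monotone(self, a, b):
        """Widening any interval never turns a colored pixel off."""
        rng = np.random.default_rng(3)
        fmap = make_map(rng.standard_normal((6, 6, 25)))
        narrow = RuleConfig((0, 7), ((-a, a), (-1.0, 1.0)))
        wide = RuleConfig((0, 7), ((-a - b, a + b), (-1.0, 1.0)))
        d_narrow = classify(fmap, narrow)
        d_wide = classify(fmap, wide)
        assert (d_wide | ~d_narrow).all()


class TestControlCorrection:
    def test_subtraction(self):
        assert control_correction(100, 10) == 90

    def test_zero_control_is_identity(self):
        assert control_correction(55, 0) == 55

    def test_floored_at_zero(self):
        assert control_correction(5, 12) == 0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            control_correction(-1, 0)


class TestTrainConfig:
    shape = (12, 40)

    def _mask(self):
        mask = np.zeros(self.shape, dtype=bool)
        mask[:, 10:25] = True
        return mask

    def test_separable_feature_gives_near_perfect_single_rule(self, rng):
        mask = self._mask()
        targets = gaussian_maps(rng, 4, self.shape, shift_feature=4,
                                shift=10.0, mask=mask)
        controls = gaussian_maps(rng, 2, self.shape)
        cfg = train_config(targets, controls, mask)
        assert cfg.feature_indices == (4,)
        assert cfg.metadata["train_sensitivity"] > 85.0
        assert cfg.metadata["train_specificity"] > 99.0

    def test_target_identical_to_control_fails(self):
        # large maps so the greedy search cannot overfit its way past
        # the minimum-sensitivity floor on pure noise
        local = np.random.default_rng(0)
        shape = (30, 100)
        mask = np.zeros(shape, dtype=bool)
        mask[:, 30:60] = True
        targets = gaussian_maps(local, 3, shape)
        controls = gaussian_maps(local, 3, shape)
        with pytest.raises(TrainingError):
            train_config(targets, controls, mask)

    def test_unconstrained_returns_max_sensitivity_config(self, rng):
        mask = self._mask()
        targets = gaussian_maps(rng, 3, self.shape, shift_feature=9,
                                shift=1.0, mask=mask)
        cfg = train_config(targets, [], mask,
                           constraints=TrainingConstraints(
                               min_specificity=0.0,
                               max_control_fraction=1.0))
        # with no constraints a single widest-coverage interval survives
        assert len(cfg.feature_indices) == 1
        assert cfg.metadata["train_sensitivity"] >= 90.0

    def test_constraints_hold_on_training_data(self, rng):
        mask = self._mask()
        targets = gaussian_maps(rng, 4, self.shape, shift_feature=4,
                                shift=3.0, mask=mask)
        controls = gaussian_maps(rng, 2, self.shape)
        constraints = TrainingConstraints(min_specificity=90.0,
                                          max_control_fraction=0.1)
        cfg = train_config(targets, controls, mask, constraints=constraints)
        assert cfg.metadata["train_specificity"] >= 90.0
        assert cfg.metadata["train_control_fraction"] <= 0.1

    def test_deterministic(self, rng):
        mask = self._mask()
        targets = gaussian_maps(rng, 3, self.shape, shift_feature=4,
                                shift=3.0, mask=mask)
        controls = gaussian_maps(rng, 2, self.shape)
        a = train_config(targets, controls, mask)
        b = train_config(targets, controls, mask)
        assert a.feature_indices == b.feature_indices
        assert a.intervals == b.intervals

    def test_json_round_trip(self, rng):
        mask = self._mask()
        targets = gaussian_maps(rng, 3, self.shape, shift_feature=4,
                                shift=5.0, mask=mask)
        cfg = train_config(targets, [], mask, target_label="33e10")
        back = RuleConfig.from_json(cfg.to_json())
        assert back.feature_indices == cfg.feature_indices
        assert back.intervals == cfg.intervals
        assert back.target_label == "33e10"
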