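"""Subnetworks, aggregator, masking, and batch forward."""

import numpy as np
import pytest

from neuroscreen import protocols as P
from neuroscreen.data_model import PipelineConfig
from neuroscreen.fusion import (
    Aggregator,
    AggregatorSpec,
    ScreeningModel,
    SessionFeatures,
    Subnetwork,
    SubnetworkSpec,
    aggregate,
    protocol_input,
    subnetwork_input_dim,
)


@pytest.fixture
def paper_config():
    return PipelineConfig()


class TestProtocolInput:
    def test_body_only_two_cameras(self, rng, paper_config):
        feats = {
            ("body", cam): rng.normal(size=128)
            for cam in paper_config.cameras_for_landmarks
        }
        vec = protocol_input(feats, 14, paper_config)
        assert vec.shape == (256,)
        assert subnetwork_input_dim(14, paper_config) == 256

    def test_face_hand_two_cameras(self, rng, paper_config):
        feats = {
            (part, cam): rng.normal(size=128)
            for part in ("face", "hand")
            for cam in paper_config.cameras_for_landmarks
        }
        vec = protocol_input(feats, 12, paper_config)
        assert vec.shape == (512,)

    def test_voice_protocol(self, rng, paper_config):
        vec = protocol_input({("voice",): rng.normal(size=512)}, 9, paper_config)
        assert vec.shape == (512,)
        assert subnetwork_input_dim(9, paper_config) == 512

    def test_fixed_concatenation_order(self, paper_config):
        # center camera features come first, then left
        feats = {
            ("body", paper_config.cameras_for_landmarks[0]): np.zeros(128),
            ("body", paper_config.cameras_for_landmarks[1]): np.ones(128),
        }
        vec = protocol_input(feats, 14, paper_config)
        assert (vec[:128] == 0).all() and (vec[128:] == 1).all()

    def test_missing_feature_raises(self, paper_config):
        with pytest.raises(KeyError, match="missing feature"):
            protocol_input({}, 14, paper_config)


class TestSubnetwork:
    def test_output_dims(self, rng):
        sub = Subnetwork(SubnetworkSpec(input_dim=40), rng)
        sub.eval()
        feat, logits = sub.forward_with_normality(
            nnet_tensor(rng.normal(size=(5, 40)))
        )
        assert feat.shape == (5, 8)
        assert logits.shape == (5, 2)

    def test_eval_deterministic(self, rng):
        sub = Subnetwork(SubnetworkSpec(input_dim=12), rng)
        sub.eval()
        x = nnet_tensor(rng.normal(size=(3, 12)))
        np.testing.assert_array_equal(sub(x).data, sub(x).data)

    def test_wrong_dim_raises(self, rng):
        sub = Subnetwork(SubnetworkSpec(input_dim=12), rng)
        with pytest.raises(ValueError, match="input dim"):
            sub(nnet_tensor(np.zeros((2, 13))))


def nnet_tensor(x):
    from neuroscreen.nnet import Tensor

    return Tensor(x)


class TestAggregator:
    def test_full_protocol_set_input_dim(self, rng):
        spec = AggregatorSpec(n_protocols=15)
        assert spec.input_dim == 120
        agg = Aggregator(spec, rng)
        agg.eval()
        stroke, pd = agg(nnet_tensor(rng.normal(size=(4, 120))))
        assert stroke.shape == (4, 2) and pd.shape == (4, 2)

    def test_single_protocol_ablation_input_dim(self, rng):
        assert AggregatorSpec(n_protocols=1).input_dim == 8

    def test_all_masked_input_finite(self, rng):
        agg = Aggregator(AggregatorSpec(n_protocols=15), rng)
        stroke, pd = aggregate(np.zeros((15, 8)), np.zeros(15, dtype=bool), agg)
        assert np.isfinite(stroke).all() and np.isfinite(pd).all()

    def test_masking_equals_zero_imputation(self, rng):
        agg = Aggregator(AggregatorSpec(n_protocols=15), rng)
        feats = rng.normal(size=(15, 8))
        mask = np.ones(15, dtype=bool)
        mask[[2, 7]] = False
        zeroed = feats.copy()
        zeroed[[2, 7]] = 0.0
        a = aggregate(feats, mask, agg)
        b = aggregate(zeroed, np.ones(15, dtype=bool), agg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestScreeningModelForward:
    def _features(self, model, rng, missing=()):
        inputs = {}
        for pid in model.active_protocols:
            if pid in missing:
                inputs[pid] = None
            else:
                inputs[pid] = rng.normal(size=subnetwork_input_dim(pid, model.config))
        return SessionFeatures("x", inputs)

    def test_shapes_and_determinism(self, rng, tiny_config):
        model = ScreeningModel(tiny_config, rng)
        model.train(False)
        batch = [self._features(model, rng) for _ in range(3)]
        s1, p1, norm, mask = model.forward_batch(batch)
        s2, p2, _, _ = model.forward_batch(batch)
        assert s1.shape == (3, 2) and p1.shape == (3, 2)
        assert mask.shape == (3, 15) and mask.all()
        np.testing.assert_array_equal(s1.data, s2.data)
        assert set(norm) == set(model.active_protocols)

    @pytest.mark.parametrize("subset_seed", [0, 1, 2, 3])
    def test_random_protocol_subsets(self, rng, tiny_config, subset_seed):
        srng = np.random.default_rng(subset_seed)
        size = int(srng.integers(1, 16))
        subset = tuple(sorted(srng.choice(P.PROTOCOL_IDS, size=size, replace=False)))
        model = ScreeningModel(tiny_config, rng, active_protocols=subset)
        model.train(False)
        batch = [self._features(model, rng)]
        stroke, pd, _, mask = model.forward_batch(batch)
        assert np.isfinite(stroke.data).all() and np.isfinite(pd.data).all()
        assert mask.shape == (1, len(subset))
        assert model.aggregator.spec.input_dim == 8 * len(subset)

    def test_masked_protocols_are_finite_and_zero_imputed(self, rng, tiny_config):
        model = ScreeningModel(tiny_config, rng)
        model.train(False)
        batch = [self._features(model, rng, missing=(1, 5, 9))]
        stroke, pd, norm, mask = model.forward_batch(batch)
        assert np.isfinite(stroke.data).all()
        assert not mask[0, [0, 4, 8]].any()
        assert all(pid not in norm for pid in (1, 5, 9))

    def test_all_masked_batch(self, rng, tiny_config):
        model = ScreeningModel(tiny_config, rng)
        model.train(False)
        batch = [self._features(model, rng, missing=tuple(P.PROTOCOL_IDS))]
        stroke, pd, norm, mask = model.forward_batch(batch)
        assert np.isfinite(stroke.data).all() and np.isfinite(pd.data).all()
        assert not mask.any() and not norm
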