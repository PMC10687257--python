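"""Loss routing, label smoothing, weighted sampling, and the training loop."""

import numpy as np
import pytest

from neuroscreen import protocols as P
from neuroscreen.data_model import (
    Disease,
    PipelineConfig,
    ProtocolLabel,
    Site,
    SubjectSession,
)
from neuroscreen.encoders import parameter_digest
from neuroscreen.fusion import ScreeningModel, SessionFeatures, subnetwork_input_dim
from neuroscreen.nnet import Tensor
from neuroscreen.training import (
    batch_loss,
    sampling_weights,
    session_loss,
    smooth_targets,
    smoothed_bce,
    train,
)


def make_session(subject_id, disease, labels=None, site=Site.KUAH):
    labels = labels or (ProtocolLabel.NORMAL,) * 15
    return SubjectSession(subject_id, disease, tuple(labels), (), site=site)


def make_features(model, rng, subject_id="x", missing=()):
    inputs = {
        pid: (None if pid in missing
              else rng.normal(size=subnetwork_input_dim(pid, model.config)))
        for pid in model.active_protocols
    }
    return SessionFeatures(subject_id, inputs)


class TestSmoothedBce:
    def test_confident_correct_prediction_near_zero_at_eps0(self):
        loss = smoothed_bce(np.array([-20.0, 20.0]), 1, 0.0)
        assert float(loss.data) < 1e-6

    def test_symmetric_logits_give_log2_for_any_eps(self):
        for eps in (0.0, 0.1, 0.3):
            loss = smoothed_bce(np.array([0.0, 0.0]), 0, eps)
            np.testing.assert_allclose(float(loss.data), np.log(2.0), rtol=1e-12)

    def test_minimized_at_smoothed_target(self):
        # with eps=0.1 the optimum is softmax == (0.1, 0.9) for label 1
        opt_logits = np.array([np.log(0.1), np.log(0.9)])
        base = float(smoothed_bce(opt_logits, 1, 0.1).data)
        for delta in (0.05, -0.05):
            perturbed = opt_logits + np.array([delta, -delta])
            assert float(smoothed_bce(perturbed, 1, 0.1).data) > base

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            smoothed_bce(np.zeros(2), 0, 0.6)

    def test_smooth_targets_rows(self):
        t = smooth_targets(np.array([0, 1]), 0.1)
        np.testing.assert_allclose(t, [[0.9, 0.1], [0.1, 0.9]])


class TestLossRouting:
    @pytest.fixture
    def model(self, tiny_config):
        return ScreeningModel(tiny_config, np.random.default_rng(0))

    def test_hc_contributes_to_both_heads(self, model, tiny_config, rng):
        session = make_session("a", Disease.HC)
        b = session_loss(model, make_features(model, rng), session, tiny_config)
        assert b.stroke is not None and b.pd is not None

    def test_stroke_routes_to_stroke_head_only(self, model, tiny_config, rng):
        session = make_session("a", Disease.STROKE)
        b = session_loss(model, make_features(model, rng), session, tiny_config)
        assert b.stroke is not None and b.pd is None

    def test_pd_routes_to_pd_head_only(self, model, tiny_config, rng):
        session = make_session("a", Disease.PD)
        b = session_loss(model, make_features(model, rng), session, tiny_config)
        assert b.pd is not None and b.stroke is None

    def test_all_uncertain_masks_every_protocol_loss(self, model, tiny_config, rng):
        session = make_session("a", Disease.STROKE,
                               (ProtocolLabel.UNCERTAIN,) * 15)
        b = session_loss(model, make_features(model, rng), session, tiny_config)
        assert b.protocol == {}
        np.testing.assert_allclose(float(b.total.data), float(b.stroke.data))

    def test_missing_payload_masks_protocol_loss(self, model, tiny_config, rng):
        session = make_session("a", Disease.HC)
        feats = make_features(model, rng, missing=(3, 4))
        b = session_loss(model, feats, session, tiny_config)
        assert 3 not in b.protocol and 4 not in b.protocol
        assert len(b.protocol) == 13

    def test_decomposition_identity_on_random_batches(self, model, tiny_config, rng):
        """The ledger reconstructs the total within 1e-6 relative."""
        diseases = [Disease.HC, Disease.STROKE, Disease.PD]
        label_pool = list(ProtocolLabel)
        for trial in range(5):
            batch_sessions, batch_feats = [], []
            for i in range(6):
                labels = tuple(label_pool[rng.integers(3)] for _ in range(15))
                batch_sessions.append(
                    make_session(f"s{i}", diseases[rng.integers(3)], labels)
                )
                batch_feats.append(
                    make_features(model, rng, missing=tuple(
                        rng.choice(P.PROTOCOL_IDS, size=2, replace=False)
                    ))
                )
            b = batch_loss(model, batch_feats, batch_sessions, tiny_config)
            expected = sum(
                float(t.data) for t in (b.stroke, b.pd) if t is not None
            ) + b.lambda_v * sum(float(t.data) for t in b.protocol.values())
            np.testing.assert_allclose(float(b.total.data), expected, rtol=1e-6)
            assert all(float(t.data) >= 0 for t in b.protocol.values())


class TestSamplingWeights:
    def test_weight_values(self, tiny_config):
        abnormal = (ProtocolLabel.ABNORMAL,) + (ProtocolLabel.NORMAL,) * 14
        sessions = [
            make_session("a", Disease.HC, site=Site.KUAH),
            make_session("b", Disease.HC, abnormal, site=Site.KUAH),
            make_session("c", Disease.HC, abnormal, site=Site.SUSH),
            make_session("d", Disease.HC, site=Site.SUSH),
        ]
        np.testing.assert_array_equal(
            sampling_weights(sessions, tiny_config), [1.0, 4.0, 6.0, 1.0]
        )

    def test_empirical_oversampling_ratio(self, tiny_config):
        """4x draw frequency for abnormal-label subjects, within 3 sigma."""
        abnormal = (ProtocolLabel.ABNORMAL,) + (ProtocolLabel.NORMAL,) * 14
        sessions = [make_session(f"a{i}", Disease.HC, site=Site.KUAH)
                    for i in range(50)]
        sessions += [make_session(f"b{i}", Disease.HC, abnormal, site=Site.KUAH)
                     for i in range(50)]
        w = sampling_weights(sessions, tiny_config)
        p = w / w.sum()
        rng = np.random.default_rng(0)
        draws = rng.choice(len(sessions), size=100_000, p=p)
        frac_abnormal = (draws >= 50).mean()
        expected = 4.0 / 5.0
        sigma = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(frac_abnormal - expected) < 3 * sigma


class TestTrainLoop:
    @pytest.fixture
    def setup(self, tiny_config):
        rng = np.random.default_rng(3)
        model = ScreeningModel(tiny_config, np.random.default_rng(1))
        sessions, feats = [], {}
        # planted separable structure directly in feature space
        for i in range(40):
            disease = [Disease.HC, Disease.STROKE, Disease.PD][i % 3]
            f = make_features(model, rng, subject_id=f"s{i}")
            shift = {Disease.HC: 0.0, Disease.STROKE: 3.0, Disease.PD: -3.0}[disease]
            f.inputs = {pid: v + shift for pid, v in f.inputs.items()}
            labels = (ProtocolLabel.ABNORMAL if disease is not Disease.HC
                      else ProtocolLabel.NORMAL,) * 15
            sessions.append(make_session(f"s{i}", disease, labels))
            feats[f"s{i}"] = f
        return model, sessions, feats

    def test_loss_decreases_and_history_recorded(self, setup, tiny_config):
        model, sessions, feats = setup
        result = train(model, sessions[:30], sessions[30:], tiny_config,
                       features=feats, seed=0)
        assert len(result.history) == tiny_config.epochs
        assert result.history[-1]["train_loss"] < result.history[0]["train_loss"]
        assert np.isfinite(result.history[-1]["train_loss"])

    def test_same_seed_reproduces_history(self, tiny_config):
        def run():
            model = ScreeningModel(tiny_config, np.random.default_rng(1))
            rng = np.random.default_rng(3)
            sessions, feats = [], {}
            for i in range(24):
                disease = [Disease.HC, Disease.STROKE, Disease.PD][i % 3]
                f = make_features(model, rng, subject_id=f"s{i}")
                sessions.append(make_session(f"s{i}", disease))
                feats[f"s{i}"] = f
            return train(model, sessions[:18], sessions[18:], tiny_config,
                         features=feats, seed=5).history

        h1, h2 = run(), run()
        assert h1 == h2

    def test_encoders_frozen_through_training(self, setup, tiny_config):
        model, sessions, feats = setup
        digests = [parameter_digest(m) for m in model.encoder_modules()]
        train(model, sessions[:30], sessions[30:], tiny_config,
              features=feats, seed=0)
        assert digests == [parameter_digest(m) for m in model.encoder_modules()]

    def test_gradient_flow_trainable_only(self, setup, tiny_config):
        model, sessions, feats = setup
        model.train(True)
        b = batch_loss(model, [feats["s0"], feats["s1"]],
                       sessions[:2], tiny_config)
        b.total.backward()
        trainable_grads = [p.grad is not None for p in model.trainable_parameters()]
        assert any(trainable_grads)
        for enc in model.encoder_modules():
            for mod in enc.modules():
                for v in vars(mod).values():
                    if isinstance(v, Tensor):
                        assert v.grad is None

    def test_lambda_zero_silences_normality_heads(self, tiny_config):
        config = PipelineConfig.tiny(seed=0, epochs=3, lambda_v=0.0)
        model = ScreeningModel(config, np.random.default_rng(1))
        rng = np.random.default_rng(3)
        feats = [make_features(model, rng, subject_id=f"s{i}") for i in range(4)]
        sessions = [make_session(f"s{i}", Disease.HC) for i in range(4)]
        model.train(True)
        b = batch_loss(model, feats, sessions, config)
        b.total.backward()
        for sub in model.subnetworks.values():
            assert sub.normality_head.weight.grad is None
            assert sub.normality_head.bias.grad is None

    def test_empty_split_rejected(self, setup, tiny_config):
        model, sessions, feats = setup
        with pytest.raises(ValueError, match="non-empty"):
            train(model, [], sessions[:5], tiny_config, features=feats)
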