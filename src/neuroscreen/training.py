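"""Multitask training: smoothed binary cross-entropy, loss routing, sampling.

The total loss is

    L_total = L_f^s + L_f^p + sum_v lambda_v * L_v,        lambda_v = 0.1,

where L_f^s / L_f^p are the stroke / Parkinson's disease-head losses and L_v
the per-protocol normality losses.  Routing: a healthy control contributes to
both disease losses (target healthy on each), a stroke subject only to L_f^s,
a Parkinsonian subject only to L_f^p.  Protocol losses are included only
where the clinician's label is normal or abnormal — uncertain labels are
excluded — and only where the protocol's payload is actually present.  All
targets are label-smoothed; classes are imbalanced, so subjects with at
least one abnormal protocol label are oversampled (4x KUAH, 6x SUSH).
Encoders are frozen: only subnetworks, normality heads and the aggregator
receive gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnet
from . import protocols as P
from .data_model import Disease, PipelineConfig, ProtocolLabel, Site, SubjectSession
from .fusion import ScreeningModel, SessionFeatures
from .nnet import Tensor
from .nnet.layers import softmax


def smooth_targets(labels: np.ndarray, epsilon: float) -> np.ndarray:
    """(m,) binary labels -> (m, 2) smoothed target rows (true class 1 - eps)."""
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("label smoothing must lie in [0, 0.5)")
    labels = np.asarray(labels, dtype=int)
    targets = np.full((labels.size, 2), epsilon)
    targets[np.arange(labels.size), labels] = 1.0 - epsilon
    return targets


def smoothed_bce(logits, label: int, epsilon: float) -> Tensor:
    """Cross-entropy of softmax(logits) against the smoothed binary target."""
    logits = Tensor.as_tensor(logits)
    if logits.ndim == 1:
        logits = logits.reshape(1, 2)
    labels = np.full(logits.shape[0], int(label))
    return nnet.softmax_cross_entropy(logits, smooth_targets(labels, epsilon))


def _gather_rows(x: Tensor, rows: np.ndarray) -> Tensor:
    def backward(g):
        if x.requires_grad:
            buf = np.zeros_like(x.data)
            buf[rows] = g
            x._accumulate(buf)

    return Tensor._result(x.data[rows], (x,), backward)


@dataclass
class LossBreakdown:
    """Eq.-style ledger: the total is reconstructable from its terms."""

    total: Tensor
    stroke: Tensor | None
    pd: Tensor | None
    protocol: dict[int, Tensor] = field(default_factory=dict)
    lambda_v: float = 0.1

    def as_floats(self) -> dict:
        return {
            "total": float(self.total.data),
            "stroke": None if self.stroke is None else float(self.stroke.data),
            "pd": None if self.pd is None else float(self.pd.data),
            "protocol": {pid: float(t.data) for pid, t in self.protocol.items()},
            "lambda_v": self.lambda_v,
        }


_DISEASE_CODE = {Disease.HC: 0, Disease.STROKE: 1, Disease.PD: 2}


def batch_loss(
    model: ScreeningModel,
    batch_feats: list[SessionFeatures],
    batch_sessions: list[SubjectSession],
    config: PipelineConfig,
) -> LossBreakdown:
    """Forward a batch and assemble the routed, masked multitask loss.

    Each included head/protocol term is the mean cross-entropy over the
    samples it applies to; the total combines them with weight 1.0 for the
    disease terms and lambda_v per protocol term.
    """
    eps = config.label_smoothing
    stroke_logits, pd_logits, normality, mask = model.forward_batch(batch_feats)
    codes = np.array([_DISEASE_CODE[s.disease_label] for s in batch_sessions])

    def head_loss(logits: Tensor, positive_code: int) -> Tensor | None:
        include = np.flatnonzero((codes == 0) | (codes == positive_code))
        if include.size == 0:
            return None
        labels = (codes[include] == positive_code).astype(int)
        return nnet.softmax_cross_entropy(
            _gather_rows(logits, include), smooth_targets(labels, eps)
        )

    l_stroke = head_loss(stroke_logits, _DISEASE_CODE[Disease.STROKE])
    l_pd = head_loss(pd_logits, _DISEASE_CODE[Disease.PD])

    protocol_terms: dict[int, Tensor] = {}
    for pid in model.active_protocols:
        if config.lambda_v == 0.0 or pid not in normality:
            continue  # lambda_v = 0 disables the auxiliary heads entirely
        rows, logits = normality[pid]
        labels, keep = [], []
        for k, i in enumerate(rows):
            lab = batch_sessions[i].label_of(pid)
            if lab is ProtocolLabel.UNCERTAIN:
                continue
            keep.append(k)
            labels.append(1 if lab is ProtocolLabel.ABNORMAL else 0)
        if not keep:
            continue
        term = nnet.softmax_cross_entropy(
            _gather_rows(logits, np.array(keep)),
            smooth_targets(np.array(labels), eps),
        )
        protocol_terms[pid] = term

    total = Tensor(np.zeros(()))
    if l_stroke is not None:
        total = total + l_stroke
    if l_pd is not None:
        total = total + l_pd
    for term in protocol_terms.values():
        total = total + config.lambda_v * term
    return LossBreakdown(total, l_stroke, l_pd, protocol_terms, config.lambda_v)


def session_loss(
    model: ScreeningModel,
    feats: SessionFeatures,
    session: SubjectSession,
    config: PipelineConfig,
) -> LossBreakdown:
    """Single-session loss (batch of one)."""
    return batch_loss(model, [feats], [session], config)


def sampling_weights(sessions: list[SubjectSession],
                     config: PipelineConfig | None = None) -> np.ndarray:
    """Relative draw weights: the site's oversampling factor for subjects with
    any abnormal protocol label, 1 otherwise."""
    factors = (config or PipelineConfig()).oversampling
    return np.array(
        [factors[s.site] if s.any_abnormal else 1.0 for s in sessions]
    )


# ---------------------------------------------------------------------------
# Optimization loop
# ---------------------------------------------------------------------------


def predict_scores(
    model: ScreeningModel, feats: list[SessionFeatures]
) -> dict[str, np.ndarray]:
    """Eval-mode disease probabilities (positive-class softmax) per session."""
    model.train(False)
    with nnet.no_grad():
        stroke_logits, pd_logits, _, _ = model.forward_batch(feats)
    return {
        "stroke": softmax(stroke_logits.data)[:, 1],
        "pd": softmax(pd_logits.data)[:, 1],
    }


def _disease_auc(scores: np.ndarray, sessions: list[SubjectSession],
                 positive: Disease) -> float:
    """AUC of one head's scores: its disease vs healthy controls."""
    from .evaluation import auc

    keep = [i for i, s in enumerate(sessions)
            if s.disease_label in (positive, Disease.HC)]
    labels = [int(sessions[i].disease_label is positive) for i in keep]
    return auc(scores[keep], labels)


@dataclass
class TrainResult:
    history: list[dict]
    best_epoch: int
    best_val_auc: dict[str, float]
    model: ScreeningModel


def train(
    model: ScreeningModel,
    train_sessions: list[SubjectSession],
    val_sessions: list[SubjectSession],
    config: PipelineConfig,
    *,
    features: dict[str, SessionFeatures] | None = None,
    seed: int | None = None,
) -> TrainResult:
    """Adam loop with weighted sampling and validation-AUC early stopping.

    Per epoch, len(train) samples are drawn with replacement proportionally
    to the sampling weights and consumed in batches.  Validation AUC is
    computed per disease each epoch; the returned model carries the weights
    of the epoch maximizing the mean of the two AUCs.  Encoders never
    receive gradients (their parameter digest is unchanged by training).
    """
    if not train_sessions or not val_sessions:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    def feats_of(sessions):
        if features is None:
            return [model.session_features(s) for s in sessions]
        return [features[s.subject_id] for s in sessions]

    train_feats = feats_of(train_sessions)
    val_feats = feats_of(val_sessions)
    if config.n_augment > 0:
        aug_rng = np.random.default_rng(rng.integers(2**31))
        variants = [
            [model.session_features(s, augment_rng=aug_rng) for s in train_sessions]
            for _ in range(config.n_augment)
        ]
    else:
        variants = None

    weights = sampling_weights(train_sessions, config)
    probs = weights / weights.sum()
    opt = nnet.Adam(
        model.trainable_parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )

    history: list[dict] = []
    best_mean, best_epoch, best_state = -np.inf, -1, None
    n = len(train_sessions)
    for epoch in range(config.epochs):
        model.train(True)
        draws = rng.choice(n, size=n, replace=True, p=probs)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = draws[start:start + config.batch_size]
            if variants is not None:
                pool = rng.integers(config.n_augment, size=idx.size)
                bfeats = [variants[v][i] for v, i in zip(pool, idx)]
            else:
                bfeats = [train_feats[i] for i in idx]
            bsessions = [train_sessions[i] for i in idx]
            breakdown = batch_loss(model, bfeats, bsessions, config)
            opt.zero_grad()
            breakdown.total.backward()
            opt.step()
            epoch_losses.append(breakdown.as_floats())

        scores = predict_scores(model, val_feats)
        val_auc = {
            "stroke": _disease_auc(scores["stroke"], val_sessions, Disease.STROKE),
            "pd": _disease_auc(scores["pd"], val_sessions, Disease.PD),
        }
        mean_auc = 0.5 * (val_auc["stroke"] + val_auc["pd"])
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean([l["total"] for l in epoch_losses])),
            "val_auc_stroke": val_auc["stroke"],
            "val_auc_pd": val_auc["pd"],
            "best": False,
        }
        if mean_auc > best_mean:
            best_mean, best_epoch = mean_auc, epoch
            best_state = {k: v.copy() for k, v in model.named_state().items()}
            record["best"] = True
        history.append(record)

    if best_state is not None:
        model.load_state(best_state)
    model.train(False)
    best = history[best_epoch]
    return TrainResult(
        history=history,
        best_epoch=best_epoch,
        best_val_auc={"stroke": best["val_auc_stroke"], "pd": best["val_auc_pd"]},
        model=model,
    )
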