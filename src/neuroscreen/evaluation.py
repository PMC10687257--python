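"""ROC/AUC evaluation and stratified 3-fold cross-validation with a test set.

AUC follows the Mann-Whitney convention (ties half-credited).  Splits are
stratified on a composite of the disease label and whether the subject has
any abnormal protocol label, so both the disease and protocol-label class
ratios stay even across folds and the held-out test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data_model import Disease, PipelineConfig, SubjectSession
from .fusion import ScreeningModel
from .training import TrainResult, predict_scores, train


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("need both classes present to compute ROC/AUC")
    return labels


def auc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> np.ndarray:
    """Ordered (FPR, TPR) points; trapezoidal area equals :func:`auc`."""
    labels = _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    folds: tuple[tuple[str, ...], ...]
    test: tuple[str, ...]


def _strata(sessions: list[SubjectSession]) -> np.ndarray:
    return np.array(
        [f"{s.disease_label.value}|{int(s.any_abnormal)}" for s in sessions]
    )


def make_splits(
    sessions: list[SubjectSession],
    k: int = 3,
    test_fraction: float = 0.235,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic stratified partition into k folds plus a held-out test set.

    Stratification key: (disease label, any-abnormal-protocol).  If some
    stratum is too small to split, it falls back to the disease label alone;
    a disease class smaller than k + 1 subjects is a hard error.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    ids = np.array([s.subject_id for s in sessions])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    diseases = np.array([s.disease_label.value for s in sessions])
    counts = {d: int((diseases == d).sum()) for d in set(diseases)}
    too_small = [d for d, c in counts.items() if c < k + 1]
    if len(counts) < 3 or too_small:
        raise ValueError(
            f"cohort cannot be stratified: needs all three disease classes with "
            f">= {k + 1} subjects each (got {counts}); enlarge the cohort or "
            f"reduce k/test_fraction"
        )
    strata = _strata(sessions)
    # merge strata too thin to appear in every split
    min_needed = k + 1
    for label in np.unique(strata):
        if (strata == label).sum() < min_needed:
            strata[strata == label] = label.split("|")[0]

    idx = np.arange(len(sessions))
    dev_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=strata
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        tuple(ids[dev_idx[fold]]) for _, fold in skf.split(dev_idx, strata[dev_idx])
    )
    return SplitPlan(folds=folds, test=tuple(ids[test_idx]))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Per-fold and aggregate test performance of the screening model."""

    fold_auc: list[dict[str, float]]
    mean_auc: dict[str, float]
    chosen_epochs: list[int]
    roc: dict[str, np.ndarray] = field(default_factory=dict)
    history: list[list[dict]] = field(default_factory=list)


def _score_split(model, feats, sessions, positive: Disease, scores: np.ndarray):
    keep = [i for i, s in enumerate(sessions)
            if s.disease_label in (positive, Disease.HC)]
    labels = [int(sessions[i].disease_label is positive) for i in keep]
    return scores[keep], labels


def cross_validate(
    sessions: list[SubjectSession],
    config: PipelineConfig,
    *,
    k: int = 3,
    test_fraction: float = 0.235,
    active_protocols: tuple[int, ...] | None = None,
) -> EvalResult:
    """k-fold cross-validation with a common held-out test set.

    Per fold: train on k-1 folds, early-stop on the remaining fold, then
    score the shared test set with the selected epoch's weights.  Encoder
    weights are created once (from the config seed) and shared across folds;
    frozen encoding is therefore computed once per session.  Reported AUC is
    disease-vs-HC for each head, per fold and averaged.
    """
    from . import protocols as P

    plan = make_splits(sessions, k=k, test_fraction=test_fraction, seed=config.seed)
    by_id = {s.subject_id: s for s in sessions}
    active = tuple(active_protocols) if active_protocols else P.PROTOCOL_IDS

    model = ScreeningModel(config, np.random.default_rng(config.seed),
                           active_protocols=active)
    features = {s.subject_id: model.session_features(s) for s in sessions}
    test_sessions = [by_id[i] for i in plan.test]
    test_feats = [features[i] for i in plan.test]

    fold_auc, chosen, histories = [], [], []
    roc: dict[str, np.ndarray] = {}
    for fold_i in range(k):
        val_ids = plan.folds[fold_i]
        train_ids = [i for j, fold in enumerate(plan.folds) if j != fold_i for i in fold]
        fold_seed = (config.seed + 1) * 1000 + fold_i
        fold_model = ScreeningModel(config, np.random.default_rng(fold_seed),
                                    active_protocols=active)
        # share the frozen encoders (and the features computed through them)
        fold_model.landmark_encoders = model.landmark_encoders
        fold_model.voice_encoder = model.voice_encoder
        result: TrainResult = train(
            fold_model,
            [by_id[i] for i in train_ids],
            [by_id[i] for i in val_ids],
            config,
            features=features,
            seed=fold_seed,
        )
        scores = predict_scores(fold_model, test_feats)
        entry = {}
        for disease, key in ((Disease.STROKE, "stroke"), (Disease.PD, "pd")):
            s, labels = _score_split(fold_model, test_feats, test_sessions,
                                     disease, scores[key])
            entry[key] = auc(s, labels)
            if fold_i == 0:
                roc[key] = roc_points(s, labels)
        fold_auc.append(entry)
        chosen.append(result.best_epoch)
        histories.append(result.history)

    mean_auc = {
        key: float(np.mean([f[key] for f in fold_auc])) for key in ("stroke", "pd")
    }
    return EvalResult(
        fold_auc=fold_auc,
        mean_auc=mean_auc,
        chosen_epochs=chosen,
        roc=roc,
        history=histories,
    )
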