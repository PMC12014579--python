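"""Cross-validation schemes, ROC/AUC, and candidate ranking.

Three evaluation protocols are provided, all retraining the model from
scratch on the reduced association matrix so no information leaks from the
held-out cells:

* K-fold CV: known associations are split into K near-equal random folds;
  each fold in turn is hidden from the training matrix and scored against
  all never-known cells.
* Leave-one-disease-out CV (LODOCV): every known lncRNA of one disease is
  hidden at once and all lncRNAs are re-ranked for that disease — the
  protocol that probes diseases without any training association.
* LOOCV: one association at a time is hidden; ranks are pooled into a
  single AUC.

The ROC sweep iterates over distinct score thresholds and integrates by the
trapezoid rule, which equals tie-corrected Mann-Whitney pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import AssociationDataset, normalize_name
from .model import Hyperparameters, predict_scores
from .sampling import build_mask
from .similarity import SimilarityMatrices
from .training import train

__all__ = [
    "ROCResult",
    "CVReport",
    "UndefinedAUCError",
    "roc_auc",
    "kfold_cv",
    "lodocv",
    "loocv",
    "rank_candidates",
]


class UndefinedAUCError(ValueError):
    """AUC requires at least one positive and one negative label."""


@dataclass
class ROCResult:
    """ROC sweep: descending thresholds with their TPR/FPR, plus the AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CVReport:
    """Per-fold (or per-disease) AUCs with summary statistics.

    ``variance`` is the population variance of the per-unit AUCs.
    ``assignments`` maps each key to the cells it held out.
    """

    keys: list
    aucs: np.ndarray
    mean: float
    variance: float
    assignments: dict
    seed: int


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC by threshold sweep over distinct score values.

    A cell counts as predicted-positive when its score is >= the threshold;
    sweeping thresholds from high to low traces the curve from (0,0) to
    (1,1) and the trapezoid rule handles tied scores with half credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    P = labels.sum()
    N = len(labels) - P
    if P == 0 or N == 0:
        raise UndefinedAUCError(
            "AUC undefined: need at least one positive and one negative"
        )
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    # last index of each run of equal scores
    boundary = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(l)[boundary]
    fps = (boundary + 1) - tps
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    thresholds = np.r_[np.inf, s[boundary]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def _train_and_score_sub(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    hyper: Hyperparameters,
    ld_train: np.ndarray,
    seed: int,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrain on a reduced LD and return scores over the LD sub-space."""
    ds = dataset.with_training_ld(ld_train)
    mask = build_mask(ds, similarities, seed, epsilon=epsilon, allow_topup=allow_topup)
    params, _ = train(ds, similarities, mask, replace(hyper, seed=seed))
    scores = predict_scores(params)
    return scores, scores[np.ix_(dataset.lncrna_sub_index, dataset.disease_sub_index)]


def kfold_cv(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    K: int,
    seed: int,
    hyper: Hyperparameters,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> CVReport:
    """K-fold cross-validation over the known associations.

    The positives are sorted, shuffled with ``seed`` and split into K folds
    whose sizes differ by at most one.  Per fold the test positives are
    zeroed in the training matrix, negatives are re-sampled from the fold's
    own propagation matrix (seed = ``seed`` + fold index), the model is
    retrained and the fold AUC is computed over the candidate set: test
    positives (label 1) against all never-known cells (label 0); training
    positives are excluded.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    positives = np.argwhere(dataset.LD == 1)  # row-major == sorted
    if len(positives) < K:
        raise ValueError(f"need at least K={K} positives, have {len(positives)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(positives))
    folds = np.array_split(perm, K)
    unknown = dataset.LD == 0
    aucs = []
    assignments: dict[int, np.ndarray] = {}
    for f, fold_idx in enumerate(folds):
        test_pos = positives[fold_idx]
        if len(test_pos) == 0:
            raise ValueError(f"fold {f} has zero test positives")
        assignments[f] = test_pos
        ld_train = dataset.LD.copy()
        ld_train[test_pos[:, 0], test_pos[:, 1]] = 0.0
        _, sub = _train_and_score_sub(
            dataset, similarities, hyper, ld_train, seed + f,
            epsilon=epsilon, allow_topup=allow_topup,
        )
        cand_scores = np.r_[
            sub[test_pos[:, 0], test_pos[:, 1]], sub[unknown]
        ]
        cand_labels = np.r_[np.ones(len(test_pos)), np.zeros(int(unknown.sum()))]
        aucs.append(roc_auc(cand_scores, cand_labels).auc)
    aucs = np.asarray(aucs)
    return CVReport(
        keys=list(range(K)),
        aucs=aucs,
        mean=float(aucs.mean()),
        variance=float(aucs.var()),
        assignments=assignments,
        seed=seed,
    )


def lodocv(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    hyper: Hyperparameters,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> CVReport:
    """Leave-one-disease-out cross-validation.

    For every disease with at least one known lncRNA, its whole LD column
    is zeroed in the training matrix, the model is retrained, and all nl
    lncRNAs are ranked for that disease (held-out knowns labelled 1).
    Reported per disease name, with mean and population variance.
    """
    keys: list[str] = []
    aucs = []
    assignments: dict[str, np.ndarray] = {}
    for j in range(dataset.nd_ld):
        known_rows = np.flatnonzero(dataset.LD[:, j] == 1)
        if known_rows.size == 0:
            continue
        full_j = int(dataset.disease_sub_index[j])
        name = dataset.disease_names[full_j]
        ld_train = dataset.LD.copy()
        ld_train[:, j] = 0.0
        scores, _ = _train_and_score_sub(
            dataset, similarities, hyper, ld_train, hyper.seed + j,
            epsilon=epsilon, allow_topup=allow_topup,
        )
        col = scores[:, full_j]
        labels = np.zeros(dataset.nl)
        labels[dataset.lncrna_sub_index[known_rows]] = 1.0
        keys.append(name)
        assignments[name] = known_rows
        aucs.append(roc_auc(col, labels).auc)
    aucs = np.asarray(aucs)
    return CVReport(
        keys=keys,
        aucs=aucs,
        mean=float(aucs.mean()),
        variance=float(aucs.var()),
        assignments=assignments,
        seed=hyper.seed,
    )


def loocv(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    hyper: Hyperparameters,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> float:
    """Leave-one-out cross-validation pooled into a single AUC.

    Each known association in turn is hidden and the model retrained; the
    held-out cell's score (label 1) and the scores of all never-known cells
    from that round (label 0) are pooled across rounds before the final
    ROC sweep.
    """
    positives = np.argwhere(dataset.LD == 1)
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least 2 positives")
    unknown = dataset.LD == 0
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for r, (i, j) in enumerate(positives):
        ld_train = dataset.LD.copy()
        ld_train[i, j] = 0.0
        _, sub = _train_and_score_sub(
            dataset, similarities, hyper, ld_train, hyper.seed + r,
            epsilon=epsilon, allow_topup=allow_topup,
        )
        pooled_scores.append(np.r_[sub[i, j], sub[unknown]])
        pooled_labels.append(np.r_[1.0, np.zeros(int(unknown.sum()))])
    return roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels)).auc


def rank_candidates(
    scores: np.ndarray,
    dataset: AssociationDataset,
    disease_name: str,
    k: int,
) -> list[tuple[str, float]]:
    """Top-k candidate lncRNAs for a disease by descending predicted score.

    Candidates are all lncRNAs without a known association to the disease;
    ties are broken by lncRNA name.  If fewer than k candidates exist the
    full list is returned.
    """
    key = normalize_name(disease_name)
    try:
        full_j = next(
            i
            for i, n in enumerate(dataset.disease_names)
            if normalize_name(n) == key
        )
    except StopIteration:
        raise KeyError(f"unknown disease {disease_name!r}") from None
    known_full: set[int] = set()
    sub_cols = np.flatnonzero(dataset.disease_sub_index == full_j)
    if sub_cols.size:
        j = int(sub_cols[0])
        known_full = {
            int(dataset.lncrna_sub_index[i])
            for i in np.flatnonzero(dataset.LD[:, j] == 1)
        }
    candidates = [
        (dataset.lncrna_names[i], float(scores[i, full_j]))
        for i in range(dataset.nl)
        if i not in known_full
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[: max(k, 0)]
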