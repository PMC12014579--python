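"""Full-batch Adam optimisation of the composite loss.

The whole objective is a single matrix expression over small dense
matrices, so optimisation is full-batch: every iteration evaluates the
loss and its analytic gradient once and applies one Adam update to all
sixteen parameter arrays.  The loop stops the first time the total loss
drops below the tolerance, or at the iteration cap (which in practice is
the binding rule: the tolerance is rarely reachable at realistic mask
sizes).  With a fixed seed and single-threaded numerics the trace is
reproducible bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationDataset
from .model import (
    Hyperparameters,
    LossBreakdown,
    ModelParameters,
    init_parameters,
    loss_and_gradients,
    compute_losses,
    predict_scores,
)
from .sampling import SampleMask, build_mask
from .similarity import SimilarityMatrices

__all__ = ["TrainingTrace", "DivergenceError", "train", "fit_predict", "FitResult"]

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8


class DivergenceError(RuntimeError):
    """The loss became non-finite during optimisation."""


@dataclass
class TrainingTrace:
    """Per-iteration loss breakdowns plus why and when training stopped."""

    losses: list[LossBreakdown]
    stop_reason: str  # "tolerance_reached" or "max_iterations"

    @property
    def iterations(self) -> int:
        return len(self.losses)

    @property
    def final(self) -> LossBreakdown:
        return self.losses[-1]

    def running_min(self) -> np.ndarray:
        """Non-increasing running minimum of the total loss."""
        return np.minimum.accumulate([lb.loss_total for lb in self.losses])


def train(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    mask: SampleMask,
    hyper: Hyperparameters,
) -> tuple[ModelParameters, TrainingTrace]:
    """Optimise all parameters with full-batch Adam.

    Each iteration evaluates the loss at the current parameters, records
    it, stops if it is below ``hyper.tolerance``, and otherwise applies one
    Adam step.  Raises :class:`DivergenceError` if the loss turns
    non-finite.
    """
    params = init_parameters(
        dataset.nm, dataset.nd, dataset.nl, hyper.seed, hyper.init_std
    )
    m = params.zeros_like()
    v = params.zeros_like()
    lr = hyper.learning_rate
    losses: list[LossBreakdown] = []
    stop_reason = "max_iterations"
    t = 0
    for it in range(1, hyper.max_iterations + 1):
        breakdown, grads = loss_and_gradients(
            dataset, similarities, mask, params, hyper
        )
        losses.append(breakdown)
        if not np.isfinite(breakdown.loss_total):
            raise DivergenceError(
                f"non-finite loss at iteration {it} (learning rate {lr})"
            )
        if breakdown.loss_total < hyper.tolerance:
            stop_reason = "tolerance_reached"
            break
        t += 1
        c1 = 1.0 - ADAM_BETA1**t
        c2 = 1.0 - ADAM_BETA2**t
        for name, g in grads.items():
            mn = getattr(m, name)
            vn = getattr(v, name)
            mn *= ADAM_BETA1
            mn += (1.0 - ADAM_BETA1) * g
            vn *= ADAM_BETA2
            vn += (1.0 - ADAM_BETA2) * (g * g)
            getattr(params, name)[...] -= lr * (mn / c1) / (
                np.sqrt(vn / c2) + ADAM_EPS
            )
    if not losses:  # max_iterations == 0: record the initial loss only
        losses.append(compute_losses(dataset, similarities, mask, params, hyper))
        stop_reason = "max_iterations"
    return params, TrainingTrace(losses=losses, stop_reason=stop_reason)


@dataclass
class FitResult:
    """Completed score matrix plus the artifacts that produced it."""

    scores: np.ndarray  # nl x nd, entries in (0, 1)
    params: ModelParameters
    mask: SampleMask
    trace: TrainingTrace

    def scores_in_ld_subspace(self, dataset: AssociationDataset) -> np.ndarray:
        """Restrict the completed matrix to LD's nl_ld x nd_ld sub-space."""
        return self.scores[
            np.ix_(dataset.lncrna_sub_index, dataset.disease_sub_index)
        ]


def fit_predict(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    hyper: Hyperparameters,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> FitResult:
    """End-to-end fit: propagate, sample negatives, train, predict.

    The sampling seed is ``hyper.seed``; the returned score matrix spans
    the full nl x nd space.
    """
    mask = build_mask(
        dataset, similarities, hyper.seed, epsilon=epsilon, allow_topup=allow_topup
    )
    params, trace = train(dataset, similarities, mask, hyper)
    scores = predict_scores(params)
    return FitResult(scores=scores, params=params, mask=mask, trace=trace)
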