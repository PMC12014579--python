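"""Balanced negative sampling licensed by a KATZ-style propagation matrix.

Known associations are a tiny fraction of the lncRNA-disease matrix, so
treating every zero cell as a negative would swamp the supervised loss.
Instead, a propagation matrix FLD accumulates 1-, 2- and 3-step support for
each cell through the association matrix itself and the two similarity
matrices:

    FLD = LD·LDᵀ·LD + LD·S_D·S_D + S_L·S_L·LD + S_L·LD·S_D

A cell with FLD exactly 0 has no walk-based evidence at all; negatives are
drawn uniformly without replacement from those cells, as many as there are
positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationDataset
from .similarity import SimilarityMatrices, similarity_sub_blocks

__all__ = [
    "SampleMask",
    "InsufficientNegativesError",
    "compute_fld",
    "sample_negatives",
    "build_mask",
]


class InsufficientNegativesError(RuntimeError):
    """Fewer zero-support cells than positives; cannot balance the sample."""


@dataclass
class SampleMask:
    """Balanced positive/negative (lncRNA-row, disease-col) pairs into LD.

    ``positives``/``negatives`` are (k, 2) integer arrays of index pairs in
    row-major order; the sets are disjoint and equally sized, every negative
    has both LD and FLD equal to zero, and ``positives`` covers all 1-cells
    of the LD the mask was drawn from.
    """

    positives: np.ndarray
    negatives: np.ndarray
    FLD: np.ndarray
    seed: int

    @property
    def set_l(self) -> np.ndarray:
        """Sub-space lncRNA rows incident to the sampled cells."""
        return np.unique(np.concatenate([self.positives[:, 0], self.negatives[:, 0]]))

    @property
    def set_d(self) -> np.ndarray:
        """Sub-space disease columns incident to the sampled cells."""
        return np.unique(np.concatenate([self.positives[:, 1], self.negatives[:, 1]]))


def compute_fld(
    LD: np.ndarray, S_D_sub: np.ndarray, S_L_sub: np.ndarray
) -> np.ndarray:
    """Evaluate the four-term propagation matrix exactly as written."""
    LD = np.asarray(LD, dtype=float)
    nl_ld, nd_ld = LD.shape
    if S_D_sub.shape != (nd_ld, nd_ld):
        raise ValueError(
            f"S_D sub-block shape {S_D_sub.shape} incompatible with LD {LD.shape}"
        )
    if S_L_sub.shape != (nl_ld, nl_ld):
        raise ValueError(
            f"S_L sub-block shape {S_L_sub.shape} incompatible with LD {LD.shape}"
        )
    return (
        LD @ LD.T @ LD
        + LD @ S_D_sub @ S_D_sub
        + S_L_sub @ S_L_sub @ LD
        + S_L_sub @ LD @ S_D_sub
    )


def sample_negatives(
    LD: np.ndarray,
    FLD: np.ndarray,
    seed: int,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> SampleMask:
    """Draw as many negatives as there are positives from zero-support cells.

    Eligible cells satisfy ``LD == 0`` and ``FLD <= epsilon`` (default:
    exactly zero).  If they are fewer than the positives, an error is raised
    unless ``allow_topup`` is set, in which case the shortfall is filled
    deterministically from the lowest-FLD zero cells (an extension beyond
    the basic rule, off by default).
    """
    LD = np.asarray(LD, dtype=float)
    if FLD.shape != LD.shape:
        raise ValueError(f"FLD shape {FLD.shape} != LD shape {LD.shape}")
    positives = np.argwhere(LD == 1)
    n_pos = len(positives)
    eligible = np.argwhere((LD == 0) & (FLD <= epsilon))
    rng = np.random.default_rng(seed)
    if len(eligible) >= n_pos:
        pick = rng.choice(len(eligible), size=n_pos, replace=False)
        negatives = eligible[np.sort(pick)]
    elif allow_topup:
        chosen = {tuple(c) for c in eligible}
        zero_cells = np.argwhere(LD == 0)
        vals = FLD[zero_cells[:, 0], zero_cells[:, 1]]
        # stable sort keeps row-major order among equal FLD values
        order = np.argsort(vals, kind="stable")
        extra = [
            tuple(zero_cells[k])
            for k in order
            if tuple(zero_cells[k]) not in chosen
        ][: n_pos - len(eligible)]
        negatives = np.array(sorted(chosen | set(extra)), dtype=np.intp)
        if len(negatives) < n_pos:
            raise InsufficientNegativesError(
                f"only {len(negatives)} zero cells for {n_pos} positives"
            )
    else:
        raise InsufficientNegativesError(
            f"{len(eligible)} cells with zero propagation support are not "
            f"enough to balance {n_pos} positives; pass allow_topup=True to "
            f"fill from the lowest-support cells"
        )
    return SampleMask(
        positives=positives.astype(np.intp),
        negatives=np.asarray(negatives, dtype=np.intp),
        FLD=FLD,
        seed=seed,
    )


def build_mask(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    seed: int,
    epsilon: float = 0.0,
    allow_topup: bool = False,
) -> SampleMask:
    """Restrict the similarity matrices, propagate, and sample negatives."""
    S_D_sub, S_L_sub = similarity_sub_blocks(similarities, dataset)
    FLD = compute_fld(dataset.LD, S_D_sub, S_L_sub)
    return sample_negatives(
        dataset.LD, FLD, seed, epsilon=epsilon, allow_topup=allow_topup
    )
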