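import numpy as np
import pytest

from cnmclda import (
    AssociationDataset,
    Hyperparameters,
    SimilarityMatrices,
    SyntheticConfig,
    generate,
)
from cnmclda.model import ModelParameters, compute_losses
from cnmclda.sampling import build_mask


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study conditions used by the recovery checks."""
    cfg = SyntheticConfig()
    dataset, similarities, truth = generate(cfg)
    return cfg, dataset, similarities, truth


@pytest.fixture(scope="session")
def small_fixture():
    """A scaled-down instance for fast training-behaviour tests."""
    cfg = SyntheticConfig(
        nm=24, nd=18, nl=24, nl_ld=14, nd_ld=10,
        latent_rank=3, density_md=0.12, density_ml=0.12, density_ld=0.12,
        seed=5,
    )
    dataset, similarities, truth = generate(cfg)
    return cfg, dataset, similarities, truth


@pytest.fixture()
def toy_problem():
    """Tiny instance (nm=4, nd=3, nl=5) for gradient and shape checks."""
    cfg = SyntheticConfig(
        nm=4, nd=3, nl=5, nl_ld=3, nd_ld=2,
        latent_rank=2, density_md=0.3, density_ml=0.3, density_ld=0.4,
        seed=3,
    )
    dataset, similarities, _ = generate(cfg)
    mask = build_mask(dataset, similarities, seed=0, allow_topup=True)
    return dataset, similarities, mask


@pytest.fixture()
def identity_2x2():
    """Hand-built 2x2 problem: LD = I, identity similarities.

    The propagation matrix is 4I, so exactly the two off-diagonal cells are
    eligible negatives — a fully controlled sampling/stopping test bed.
    """
    rng = np.random.default_rng(9)
    dataset = AssociationDataset(
        mirna_names=["m1", "m2", "m3"],
        disease_names=["d1", "d2"],
        lncrna_names=["l1", "l2"],
        MD=rng.integers(0, 2, size=(3, 2)).astype(float),
        ML=rng.integers(0, 2, size=(3, 2)).astype(float),
        LD=np.eye(2),
        lncrna_sub_index=np.array([0, 1]),
        disease_sub_index=np.array([0, 1]),
    )
    similarities = SimilarityMatrices(S_D=np.eye(2), S_L=np.eye(2))
    return dataset, similarities


def numerical_gradient(dataset, similarities, mask, params, hyper, h=1e-6):
    """Central finite differences of the total loss for every parameter."""
    grads = params.zeros_like()
    for name, arr in params.items():
        g = getattr(grads, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            lp = compute_losses(dataset, similarities, mask, params, hyper).loss_total
            arr[idx] = orig - h
            lm = compute_losses(dataset, similarities, mask, params, hyper).loss_total
            arr[idx] = orig
            g[idx] = (lp - lm) / (2.0 * h)
    return grads


def max_relative_gradient_error(analytic: ModelParameters, numeric: ModelParameters):
    worst = 0.0
    for name, ga in analytic.items():
        gn = getattr(numeric, name)
        denom = np.maximum(1e-6, np.maximum(np.abs(ga), np.abs(gn)))
        worst = max(worst, float(np.max(np.abs(ga - gn) / denom)))
    return worst


def mann_whitney_auc(scores, labels):
    """Exhaustive tie-corrected pair-counting AUC (independent oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
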