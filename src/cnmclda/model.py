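"""The two convolutional sub-models, the score predictor, and the composite loss.

Each entity (disease or lncRNA) is represented by its miRNA interaction
profile, i.e. a binary vector of length nm.  A sub-model is a convolutional
layer whose kernels span the full profile (so each kernel emits one scalar)
followed by three fully-connected layers, all ReLU-activated:

    disease side:  h1 = ReLU(W1 x + b1)          h1 in R^nd
                   h2 = ReLU(W2ᵀ h1 + b2)        h2 in R^nd
                   h3 = ReLU(W3ᵀ h2 + b3)        h3 in R^nm
                   h4 = ReLU(W4ᵀ h3 + b4)        h4 in R^1

with W2 (nd x nd), W3 (nd x nm), W4 (nm x 1); the lncRNA side is identical
with nl in place of nd and ML columns as inputs.  The completed score
matrix couples the middle weight matrices of the two sides directly:

    LD' = sigmoid(Wl2 · Wl3 · Wd3ᵀ · Wd2ᵀ)       (nl x nd)

Training minimises  loss1 + λ1·loss2 + λ2·loss3 + λ3·loss4 + λ4·loss5:

    loss1  squared error of LD' against the balanced positive/negative mask
    loss2  squared reconstruction error of the layer-3 output against the
           entity's own miRNA profile, over entities incident to the mask
    loss3  similarity anchoring of the middle weight matrices,
           mean((Wl2 - S_L)²) + mean((Wd2 - S_D)²)
    loss4  mean-square penalty on the four matrices entering the predictor
    loss5  mean-square penalty on every weight and bias of both sub-models

The two data terms (loss1, loss2) are raw sums over the sampled cells and
entities; the three parameter terms (loss3-loss5) are normalised per matrix
entry.  The normalisation keeps the published λ weights meaningful
independently of problem size: with unnormalised Frobenius penalties and
λ3 = 10, the penalty incurred by any weight configuration carrying signal
exceeds the entire attainable loss1 stake of 0.25·(p+q), so the optimum
pins the predictor at zero and the loss_total < 1e-3 stopping rule can
never fire (loss3 -> 0 forces loss4 ≈ ||S||²_F).  Per-entry normalisation
is the standard mean-reduction convention of deep-learning frameworks and
restores both properties.

Gradients are computed analytically (closed-form backpropagation through
the small, fixed computation graph); their correctness is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .data_io import AssociationDataset
from .sampling import SampleMask
from .similarity import SimilarityMatrices

__all__ = [
    "Hyperparameters",
    "ModelParameters",
    "LossBreakdown",
    "save_checkpoint",
    "load_checkpoint",
    "init_parameters",
    "relu",
    "sigmoid",
    "conv_forward",
    "forward_disease",
    "forward_lncrna",
    "predict_scores",
    "compute_losses",
    "loss_and_gradients",
]

PARAM_NAMES = (
    "Wd1", "Bd1", "Wd2", "Bd2", "Wd3", "Bd3", "Wd4", "Bd4",
    "Wl1", "Bl1", "Wl2", "Bl2", "Wl3", "Bl3", "Wl4", "Bl4",
)


@dataclass
class Hyperparameters:
    """Loss weights and optimisation settings.

    The λ defaults are the values selected by grid search over
    {1e-3, 1e-2, 0.1, 1, 10} per weight; the stopping tolerance applies to
    the total loss.
    """

    lambda1: float = 1e-3
    lambda2: float = 1e-1
    lambda3: float = 10.0
    lambda4: float = 1.0
    learning_rate: float = 1e-3
    max_iterations: int = 5000
    tolerance: float = 1e-3
    seed: int = 0
    init_std: float = 0.01

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ModelParameters:
    """All weights and biases of both sub-models.

    Shapes (disease side; lncRNA side replaces nd by nl):
    W1 (nd, nm) conv kernels, B1 (nd,); W2 (nd, nd), B2 (nd,);
    W3 (nd, nm), B3 (nm,); W4 (nm, 1), B4 (1,).
    """

    Wd1: np.ndarray
    Bd1: np.ndarray
    Wd2: np.ndarray
    Bd2: np.ndarray
    Wd3: np.ndarray
    Bd3: np.ndarray
    Wd4: np.ndarray
    Bd4: np.ndarray
    Wl1: np.ndarray
    Bl1: np.ndarray
    Wl2: np.ndarray
    Bl2: np.ndarray
    Wl3: np.ndarray
    Bl3: np.ndarray
    Wl4: np.ndarray
    Bl4: np.ndarray

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in PARAM_NAMES:
            yield name, getattr(self, name)

    def copy(self) -> "ModelParameters":
        return ModelParameters(**{k: v.copy() for k, v in self.items()})

    def zeros_like(self) -> "ModelParameters":
        return ModelParameters(**{k: np.zeros_like(v) for k, v in self.items()})

    @property
    def nm(self) -> int:
        return self.Wd1.shape[1]

    @property
    def nd(self) -> int:
        return self.Wd1.shape[0]

    @property
    def nl(self) -> int:
        return self.Wl1.shape[0]

    def validate_shapes(self) -> None:
        nm, nd, nl = self.nm, self.nd, self.nl
        expected = {
            "Wd1": (nd, nm), "Bd1": (nd,), "Wd2": (nd, nd), "Bd2": (nd,),
            "Wd3": (nd, nm), "Bd3": (nm,), "Wd4": (nm, 1), "Bd4": (1,),
            "Wl1": (nl, nm), "Bl1": (nl,), "Wl2": (nl, nl), "Bl2": (nl,),
            "Wl3": (nl, nm), "Bl3": (nm,), "Wl4": (nm, 1), "Bl4": (1,),
        }
        for name, shape in expected.items():
            actual = getattr(self, name).shape
            if actual != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {actual}")
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class LossBreakdown:
    """The five loss components and their λ-weighted total."""

    loss1: float
    loss2: float
    loss3: float
    loss4: float
    loss5: float
    loss_total: float


def init_parameters(
    nm: int, nd: int, nl: int, seed: int, init_std: float = 0.01
) -> ModelParameters:
    """Seeded initialisation: i.i.d. N(0, init_std²) weights, zero biases.

    Draw order is fixed so a seed pins down the parameters exactly.
    """
    rng = np.random.default_rng(seed)
    def w(*shape: int) -> np.ndarray:
        return rng.normal(0.0, init_std, size=shape)
    return ModelParameters(
        Wd1=w(nd, nm), Bd1=np.zeros(nd),
        Wd2=w(nd, nd), Bd2=np.zeros(nd),
        Wd3=w(nd, nm), Bd3=np.zeros(nm),
        Wd4=w(nm, 1), Bd4=np.zeros(1),
        Wl1=w(nl, nm), Bl1=np.zeros(nl),
        Wl2=w(nl, nl), Bl2=np.zeros(nl),
        Wl3=w(nl, nm), Bl3=np.zeros(nm),
        Wl4=w(nm, 1), Bl4=np.zeros(1),
    )


def save_checkpoint(
    params: ModelParameters, path, metadata: dict | None = None
) -> None:
    """Serialise parameters (plus scalar metadata) to an ``.npz``-compatible
    archive with fixed zip timestamps, so identical parameters always
    produce byte-identical files."""
    import io
    import zipfile

    entries: list[tuple[str, np.ndarray]] = list(params.items())
    for key, value in (metadata or {}).items():
        entries.append((f"meta_{key}", np.asarray(value)))
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name, arr in entries:
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_checkpoint(path) -> tuple[ModelParameters, dict]:
    """Read back a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        params = ModelParameters(**{k: data[k] for k in PARAM_NAMES})
        meta = {
            k[5:]: data[k] for k in data.files if k.startswith("meta_")
        }
    params.validate_shapes()
    return params, meta


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # split by sign for overflow-free evaluation
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def conv_forward(
    x: np.ndarray, kernels: np.ndarray, biases: np.ndarray
) -> np.ndarray:
    """Full-width convolution: kernel j spans the whole profile, so feature
    map j collapses to ReLU(<kernel_j, x> + bias_j)."""
    x = np.asarray(x, dtype=float)
    if kernels.ndim != 2 or kernels.shape[1] != x.shape[0]:
        raise ValueError(
            f"kernels {kernels.shape} incompatible with input of length {x.shape[0]}"
        )
    if biases.shape != (kernels.shape[0],):
        raise ValueError(
            f"biases {biases.shape} incompatible with {kernels.shape[0]} kernels"
        )
    return relu(kernels @ x + biases)


def _forward_profile(
    x: np.ndarray,
    W1: np.ndarray, B1: np.ndarray,
    W2: np.ndarray, B2: np.ndarray,
    W3: np.ndarray, B3: np.ndarray,
    W4: np.ndarray, B4: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    h1 = conv_forward(x, W1, B1)
    h2 = relu(W2.T @ h1 + B2)
    h3 = relu(W3.T @ h2 + B3)
    h4 = relu(W4.T @ h3 + B4)
    return h1, h2, h3, h4


def forward_disease(
    col_index: int, MD: np.ndarray, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the disease sub-model on disease ``col_index``'s miRNA profile;
    returns all four layer outputs (lengths nd, nd, nm, 1)."""
    if not 0 <= col_index < MD.shape[1]:
        raise IndexError(f"disease column {col_index} out of range")
    return _forward_profile(
        MD[:, col_index],
        params.Wd1, params.Bd1, params.Wd2, params.Bd2,
        params.Wd3, params.Bd3, params.Wd4, params.Bd4,
    )


def forward_lncrna(
    col_index: int, ML: np.ndarray, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the lncRNA sub-model on lncRNA ``col_index``'s miRNA profile;
    returns all four layer outputs (lengths nl, nl, nm, 1)."""
    if not 0 <= col_index < ML.shape[1]:
        raise IndexError(f"lncRNA column {col_index} out of range")
    return _forward_profile(
        ML[:, col_index],
        params.Wl1, params.Bl1, params.Wl2, params.Bl2,
        params.Wl3, params.Bl3, params.Wl4, params.Bl4,
    )


def predict_scores(params: ModelParameters) -> np.ndarray:
    """Completed score matrix LD' = sigmoid(Wl2 · Wl3 · Wd3ᵀ · Wd2ᵀ), nl x nd,
    every entry strictly inside (0, 1)."""
    A = params.Wl2 @ params.Wl3          # nl x nm
    B = params.Wd2 @ params.Wd3          # nd x nm
    return sigmoid(A @ B.T)


def _mask_full_indices(
    dataset: AssociationDataset, mask: SampleMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cells = np.vstack([mask.positives, mask.negatives])
    if cells.size and (
        cells[:, 0].max() >= dataset.nl_ld or cells[:, 1].max() >= dataset.nd_ld
    ):
        raise IndexError("mask references cells outside the LD sub-space")
    rows = dataset.lncrna_sub_index[cells[:, 0]]
    cols = dataset.disease_sub_index[cells[:, 1]]
    labels = np.concatenate(
        [np.ones(len(mask.positives)), np.zeros(len(mask.negatives))]
    )
    return rows, cols, labels


def _reconstruction_side(
    X: np.ndarray,
    W1: np.ndarray, B1: np.ndarray,
    W2: np.ndarray, B2: np.ndarray,
    W3: np.ndarray, B3: np.ndarray,
):
    """Vectorised forward pass to layer 3 for a batch of profiles (columns
    of X); returns the per-layer pre-activations/activations needed for the
    backward pass and the squared reconstruction error against X itself."""
    Z1 = W1 @ X + B1[:, None]
    H1 = relu(Z1)
    Z2 = W2.T @ H1 + B2[:, None]
    H2 = relu(Z2)
    Z3 = W3.T @ H2 + B3[:, None]
    H3 = relu(Z3)
    err = H3 - X
    return Z1, H1, Z2, H2, Z3, H3, err, float((err * err).sum())


def _losses(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    mask: SampleMask,
    params: ModelParameters,
    hyper: Hyperparameters,
    want_grads: bool,
) -> tuple[LossBreakdown, ModelParameters | None]:
    params.validate_shapes()
    p = params
    grads = p.zeros_like() if want_grads else None

    # ---- loss1: masked squared error of the completed matrix -------------
    A = p.Wl2 @ p.Wl3                    # nl x nm
    B = p.Wd2 @ p.Wd3                    # nd x nm
    rows, cols, labels = _mask_full_indices(dataset, mask)
    z = np.einsum("ij,ij->i", A[rows], B[cols])
    s = sigmoid(z)
    resid = s - labels
    loss1 = float(resid @ resid)
    if want_grads:
        g = 2.0 * resid * s * (1.0 - s)
        G = np.zeros((p.nl, p.nd))
        np.add.at(G, (rows, cols), g)
        dA = G @ B                       # nl x nm
        dB = G.T @ A                     # nd x nm
        grads.Wl2 += dA @ p.Wl3.T
        grads.Wl3 += p.Wl2.T @ dA
        grads.Wd2 += dB @ p.Wd3.T
        grads.Wd3 += p.Wd2.T @ dB

    # ---- loss2: profile reconstruction over mask-incident entities -------
    set_d_full = np.unique(dataset.disease_sub_index[
        np.concatenate([mask.positives[:, 1], mask.negatives[:, 1]])
    ])
    set_l_full = np.unique(dataset.lncrna_sub_index[
        np.concatenate([mask.positives[:, 0], mask.negatives[:, 0]])
    ])
    loss2 = 0.0
    lam1 = hyper.lambda1
    for side, cols_full in (("d", set_d_full), ("l", set_l_full)):
        if cols_full.size == 0:
            continue
        if side == "d":
            X = dataset.MD[:, cols_full]
            W1, B1, W2, B2, W3, B3 = p.Wd1, p.Bd1, p.Wd2, p.Bd2, p.Wd3, p.Bd3
        else:
            X = dataset.ML[:, cols_full]
            W1, B1, W2, B2, W3, B3 = p.Wl1, p.Bl1, p.Wl2, p.Bl2, p.Wl3, p.Bl3
        Z1, H1, Z2, H2, Z3, H3, err, sq = _reconstruction_side(
            X, W1, B1, W2, B2, W3, B3
        )
        loss2 += sq
        if want_grads and lam1 != 0.0:
            G3 = 2.0 * err * (Z3 > 0)
            dW3 = H2 @ G3.T
            dB3 = G3.sum(axis=1)
            G2 = (W3 @ G3) * (Z2 > 0)
            dW2 = H1 @ G2.T
            dB2 = G2.sum(axis=1)
            G1 = (W2 @ G2) * (Z1 > 0)
            dW1 = G1 @ X.T
            dB1 = G1.sum(axis=1)
            if side == "d":
                grads.Wd1 += lam1 * dW1; grads.Bd1 += lam1 * dB1
                grads.Wd2 += lam1 * dW2; grads.Bd2 += lam1 * dB2
                grads.Wd3 += lam1 * dW3; grads.Bd3 += lam1 * dB3
            else:
                grads.Wl1 += lam1 * dW1; grads.Bl1 += lam1 * dB1
                grads.Wl2 += lam1 * dW2; grads.Bl2 += lam1 * dB2
                grads.Wl3 += lam1 * dW3; grads.Bl3 += lam1 * dB3

    # ---- loss3: similarity anchoring of the middle weight matrices -------
    if similarities.S_L.shape != (p.nl, p.nl):
        raise ValueError("S_L shape incompatible with lncRNA-side parameters")
    if similarities.S_D.shape != (p.nd, p.nd):
        raise ValueError("S_D shape incompatible with disease-side parameters")
    Dl = p.Wl2 - similarities.S_L
    Dd = p.Wd2 - similarities.S_D
    loss3 = float((Dl * Dl).sum() / Dl.size + (Dd * Dd).sum() / Dd.size)
    if want_grads:
        grads.Wl2 += hyper.lambda2 * (2.0 / Dl.size) * Dl
        grads.Wd2 += hyper.lambda2 * (2.0 / Dd.size) * Dd

    # ---- loss4: penalty on the predictor matrices ------------------------
    loss4 = 0.0
    for name in ("Wl2", "Wl3", "Wd2", "Wd3"):
        W = getattr(p, name)
        loss4 += float((W * W).sum() / W.size)
        if want_grads:
            g = getattr(grads, name)
            g += hyper.lambda3 * (2.0 / W.size) * W

    # ---- loss5: penalty on every weight and bias -------------------------
    loss5 = 0.0
    for name, arr in p.items():
        loss5 += float((arr * arr).sum() / arr.size)
        if want_grads:
            g = getattr(grads, name)
            g += hyper.lambda4 * (2.0 / arr.size) * arr
    loss_total = (
        loss1
        + hyper.lambda1 * loss2
        + hyper.lambda2 * loss3
        + hyper.lambda3 * loss4
        + hyper.lambda4 * loss5
    )
    return (
        LossBreakdown(loss1, loss2, loss3, loss4, loss5, loss_total),
        grads,
    )


def compute_losses(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    mask: SampleMask,
    params: ModelParameters,
    hyper: Hyperparameters,
) -> LossBreakdown:
    """Evaluate the five loss components and their weighted total."""
    breakdown, _ = _losses(dataset, similarities, mask, params, hyper, False)
    return breakdown


def loss_and_gradients(
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    mask: SampleMask,
    params: ModelParameters,
    hyper: Hyperparameters,
) -> tuple[LossBreakdown, ModelParameters]:
    """Loss breakdown plus the analytic gradient of the weighted total with
    respect to every weight and bias (a ``ModelParameters`` of gradients)."""
    breakdown, grads = _losses(dataset, similarities, mask, params, hyper, True)
    assert grads is not None
    return breakdown, grads
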