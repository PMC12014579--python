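"""Self-contained synthetic datasets with planted low-rank structure.

The generator emulates the shape of the real corpus: three binary
association matrices (miRNA-disease, miRNA-lncRNA, lncRNA-disease) that
share a latent miRNA feature space, similarity matrices consistent with the
planted signal, and an optional MeSH-style annotation table.

Every entity (miRNA, disease, lncRNA) is assigned to one of ``latent_rank``
communities and receives a non-negative latent vector supported on that
community's private pair of coordinates, with gamma-distributed magnitudes.
Cross-community inner products and cosine similarities are therefore
exactly zero — mirroring how diseases in disjoint MeSH branches share no
ancestors — while within-community similarity varies continuously.  The
exact zeros matter: the negative sampler only accepts cells with zero
propagation support, which do not exist when every similarity is positive.

Associations are obtained by thresholding latent inner products at the
quantile that achieves the requested density; optional label noise moves a
fraction of the 1-entries to uniformly chosen 0-cells (density-preserving),
degrading the planted signal without inflating the association count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import AssociationDataset
from .similarity import SimilarityMatrices

__all__ = ["SyntheticConfig", "generate", "write_synthetic_files", "permute_labels"]

_SUBDIMS = 2  # latent coordinates private to each community


@dataclass
class SyntheticConfig:
    """Problem sizes and signal parameters for the generator.

    Defaults are the study conditions used throughout the test suite: a
    scaled-down corpus (60 miRNAs, 50 diseases, 80 lncRNAs, with a 40 x 30
    curated lncRNA-disease block), four planted communities, association
    densities around the ~5% seen in curated association databases, and no
    label noise.
    """

    nm: int = 60
    nd: int = 50
    nl: int = 80
    nl_ld: int = 40
    nd_ld: int = 30
    latent_rank: int = 4
    density_md: float = 0.05
    density_ml: float = 0.05
    density_ld: float = 0.05
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nl_ld > self.nl or self.nd_ld > self.nd:
            raise ValueError("LD sub-space cannot exceed the full spaces")
        for name in ("density_md", "density_ml", "density_ld"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0,1)")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0,1)")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be positive")


def _latent_vectors(
    rng: np.random.Generator, n: int, rank: int
) -> np.ndarray:
    """Community-structured non-negative latents: entity i sits in one of
    ``rank`` communities and is supported on that community's private pair
    of coordinates with Gamma(2, 1) magnitudes."""
    comm = rng.integers(0, rank, size=n)
    mags = rng.gamma(shape=2.0, scale=1.0, size=(n, _SUBDIMS))
    vecs = np.zeros((n, rank * _SUBDIMS))
    for i in range(n):
        base = comm[i] * _SUBDIMS
        vecs[i, base : base + _SUBDIMS] = mags[i]
    return vecs


def _threshold_by_density(
    products: np.ndarray, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Binarise by the (1 - density)-quantile of the product distribution."""
    flat = products.ravel()
    if np.ptp(flat) == 0:
        raise ValueError(
            "degenerate product distribution (all entries equal); "
            "increase latent_rank or the problem size"
        )
    cutoff = np.quantile(flat, 1.0 - density)
    binary = (products > cutoff).astype(float)
    return binary


def _apply_label_noise(
    binary: np.ndarray, noise_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Move a ``noise_rate`` fraction of the 1-entries to random 0-cells."""
    if noise_rate == 0.0:
        return binary
    out = binary.copy()
    ones = np.argwhere(out == 1)
    n_flip = int(round(noise_rate * len(ones)))
    if n_flip == 0:
        return out
    drop = ones[rng.choice(len(ones), size=n_flip, replace=False)]
    out[drop[:, 0], drop[:, 1]] = 0.0
    zeros = np.argwhere(out == 0)
    add = zeros[rng.choice(len(zeros), size=n_flip, replace=False)]
    out[add[:, 0], add[:, 1]] = 1.0
    return out


def _cosine(vecs: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    S = (vecs @ vecs.T) / np.outer(norms, norms)
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(
    config: SyntheticConfig,
) -> tuple[AssociationDataset, SimilarityMatrices, np.ndarray]:
    """Generate a dataset, similarity matrices, and the ground-truth scores.

    Returns ``(dataset, similarities, truth)`` where ``truth`` is the
    pre-threshold latent inner-product matrix over the LD sub-space
    (nl_ld x nd_ld) — the planted signal the pipeline is meant to recover.
    Similarities are cosine similarities of the latent vectors.

    So the three pair files written from the result stay mutually
    resolvable, every LD-active lncRNA/disease is guaranteed at least one
    miRNA association (the strongest latent product is switched on when
    thresholding left the profile empty).
    """
    rng = np.random.default_rng(config.seed)
    m_vec = _latent_vectors(rng, config.nm, config.latent_rank)
    d_vec = _latent_vectors(rng, config.nd, config.latent_rank)
    l_vec = _latent_vectors(rng, config.nl, config.latent_rank)

    MD = _threshold_by_density(m_vec @ d_vec.T, config.density_md, rng)
    ML = _threshold_by_density(m_vec @ l_vec.T, config.density_ml, rng)
    truth_full = l_vec[: config.nl_ld] @ d_vec[: config.nd_ld].T
    LD = _threshold_by_density(truth_full, config.density_ld, rng)

    MD = _apply_label_noise(MD, config.noise_rate, rng)
    ML = _apply_label_noise(ML, config.noise_rate, rng)
    LD = _apply_label_noise(LD, config.noise_rate, rng)

    # keep LD-active entities resolvable through the miRNA-bearing tables
    d_active = LD.sum(axis=0) > 0
    for j in np.flatnonzero(d_active & (MD[:, : config.nd_ld].sum(axis=0) == 0)):
        MD[int(np.argmax(m_vec @ d_vec[j])), j] = 1.0
    l_active = LD.sum(axis=1) > 0
    for i in np.flatnonzero(l_active & (ML[:, : config.nl_ld].sum(axis=0) == 0)):
        ML[int(np.argmax(m_vec @ l_vec[i])), i] = 1.0

    dataset = AssociationDataset(
        mirna_names=[f"mir-{i+1:04d}" for i in range(config.nm)],
        disease_names=[f"disease-{i+1:04d}" for i in range(config.nd)],
        lncrna_names=[f"lnc-{i+1:04d}" for i in range(config.nl)],
        MD=MD,
        ML=ML,
        LD=LD,
        lncrna_sub_index=np.arange(config.nl_ld, dtype=np.intp),
        disease_sub_index=np.arange(config.nd_ld, dtype=np.intp),
    )
    dataset.validate()
    similarities = SimilarityMatrices(S_D=_cosine(d_vec), S_L=_cosine(l_vec))
    return dataset, similarities, truth_full


def _community_of(vec: np.ndarray) -> int:
    return int(np.flatnonzero(vec)[0] // _SUBDIMS) if vec.any() else 0


def synthetic_annotations_table(
    dataset: AssociationDataset, similarities: SimilarityMatrices
) -> list[tuple[str, str]]:
    """A synthetic MeSH-style annotation per disease whose DAG similarities
    correlate with the planted structure: diseases in the same community
    share a branch root, and within a community they split into two
    sub-branches by their dominant latent coordinate."""
    rows: list[tuple[str, str]] = []
    S = similarities.S_D
    nd = len(dataset.disease_names)
    # recover community labels from the exact-zero structure of S_D
    comm = -np.ones(nd, dtype=int)
    next_comm = 0
    for i in range(nd):
        if comm[i] >= 0:
            continue
        members = np.flatnonzero(S[i] > 0)
        comm[members] = next_comm
        next_comm += 1
    for i, name in enumerate(dataset.disease_names):
        # split each community by affinity to its first member
        anchor = int(np.flatnonzero(comm == comm[i])[0])
        sub = 1 if S[i, anchor] >= 0.5 else 2
        code = f"C{comm[i]+1:02d}.S{sub}.D{i+1:03d}"
        rows.append((name, code))
    return rows


def write_synthetic_files(
    outdir: str | Path,
    dataset: AssociationDataset,
    similarities: SimilarityMatrices,
    truth: np.ndarray,
) -> dict[str, Path]:
    """Write pair TSVs, a synthetic annotation TSV, labeled similarity TSVs
    and the ground-truth matrix into ``outdir``; returns the path map.

    Entities without any association do not appear in the pair files, so a
    dataset rebuilt from the files covers the degree->=1 sub-universe.
    """
    from .data_io import write_score_matrix  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_pairs(fname: str, mat: np.ndarray, rows, cols) -> None:
        p = outdir / fname
        with open(p, "w", encoding="utf-8") as fh:
            for i, j in np.argwhere(mat == 1):
                fh.write(f"{rows[i]}\t{cols[j]}\n")
        paths[fname] = p

    write_pairs("md_pairs.tsv", dataset.MD, dataset.mirna_names, dataset.disease_names)
    write_pairs("ml_pairs.tsv", dataset.ML, dataset.mirna_names, dataset.lncrna_names)
    write_pairs(
        "ld_pairs.tsv",
        dataset.LD,
        [dataset.lncrna_names[i] for i in dataset.lncrna_sub_index],
        [dataset.disease_names[j] for j in dataset.disease_sub_index],
    )
    p = outdir / "annotations.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for name, code in synthetic_annotations_table(dataset, similarities):
            fh.write(f"{name}\t{code}\n")
    paths["annotations.tsv"] = p
    write_score_matrix(
        similarities.S_D,
        dataset.disease_names,
        dataset.disease_names,
        outdir / "S_D.tsv",
    )
    paths["S_D.tsv"] = outdir / "S_D.tsv"
    write_score_matrix(
        similarities.S_L,
        dataset.lncrna_names,
        dataset.lncrna_names,
        outdir / "S_L.tsv",
    )
    paths["S_L.tsv"] = outdir / "S_L.tsv"
    write_score_matrix(
        truth,
        [dataset.lncrna_names[i] for i in dataset.lncrna_sub_index],
        [dataset.disease_names[j] for j in dataset.disease_sub_index],
        outdir / "ground_truth.tsv",
    )
    paths["ground_truth.tsv"] = outdir / "ground_truth.tsv"
    return paths


def permute_labels(dataset: AssociationDataset, seed: int) -> AssociationDataset:
    """Negative control: scatter LD's 1-entries uniformly over the matrix,
    destroying any relation between the labels and the planted structure
    while preserving the association count."""
    rng = np.random.default_rng(seed)
    n_ones = int(dataset.LD.sum())
    flat = np.zeros(dataset.LD.size)
    flat[rng.choice(dataset.LD.size, size=n_ones, replace=False)] = 1.0
    return dataset.with_training_ld(flat.reshape(dataset.LD.shape))
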