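"""Disease semantic similarity from MeSH DAGs and lncRNA functional similarity.

Disease similarity follows the classical DAG-contribution scheme: a disease's
own MeSH node(s) contribute 1, and each ancestor contributes ``decay`` times
the best contribution among its children inside the disease's DAG.  Two
diseases are similar in proportion to the contributions of the DAG nodes
they share, normalised by their total semantic values.

lncRNA functional similarity is the best-match average (BMA) over the
disease sets the two lncRNAs are associated with: each disease on one side
is matched to its most similar disease on the other side, and the matches
are averaged over both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_io import AssociationDataset, DiseaseAnnotation, normalize_name

__all__ = [
    "SimilarityMatrices",
    "semantic_contributions",
    "disease_semantic_similarity",
    "lncrna_functional_similarity",
    "build_similarities",
    "similarity_sub_blocks",
]

DEFAULT_DECAY = 0.5


@dataclass
class SimilarityMatrices:
    """Disease semantic similarity S_D (nd x nd) and lncRNA functional
    similarity S_L (nl x nl); symmetric, unit diagonal, entries in [0, 1]."""

    S_D: np.ndarray
    S_L: np.ndarray


def semantic_contributions(
    annotation: DiseaseAnnotation, decay: float = DEFAULT_DECAY
) -> dict[str, float]:
    """Contribution of every DAG node of a disease's MeSH annotation.

    The disease's own tree-number nodes get 1; an ancestor ``t`` gets
    ``decay * max(contribution of children of t within the DAG)``.  A node
    reachable through several tree numbers takes the maximum contribution.
    Empty annotations yield an empty map.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must lie in (0,1), got {decay}")
    nodes = annotation.dag_nodes()
    if not nodes:
        return {}
    children: dict[str, list[str]] = {n: [] for n in nodes}
    for n in nodes:
        if "." in n:
            parent = n.rsplit(".", 1)[0]
            if parent in children:
                children[parent].append(n)
    contrib: dict[str, float] = {}
    # children are strictly deeper, so deepest-first order is a valid
    # topological order for the max-propagation recurrence
    for node in sorted(nodes, key=lambda n: -n.count(".")):
        if node in annotation.tree_numbers:
            contrib[node] = 1.0
        else:
            contrib[node] = decay * max(contrib[c] for c in children[node])
    return contrib


def disease_semantic_similarity(
    disease_names: Sequence[str],
    annotations: Mapping[str, DiseaseAnnotation],
    decay: float = DEFAULT_DECAY,
) -> np.ndarray:
    """Pairwise semantic similarity over ``disease_names``.

    S_D(A, B) = sum over shared DAG nodes t of (c_A(t) + c_B(t)), divided by
    the sum of all contributions of A plus all contributions of B.  Pairs in
    which either disease is unannotated get 0 off-diagonal; the diagonal is
    forced to 1.  ``annotations`` is keyed by normalized disease name (as
    returned by :func:`cnmclda.data_io.read_mesh_annotations`).
    """
    nd = len(disease_names)
    contribs: list[dict[str, float]] = []
    totals = np.zeros(nd)
    for name in disease_names:
        ann = annotations.get(normalize_name(name))
        c = semantic_contributions(ann, decay) if ann is not None else {}
        contribs.append(c)
        totals[len(contribs) - 1] = sum(c.values())
    S = np.zeros((nd, nd))
    for i in range(nd):
        ci = contribs[i]
        if not ci:
            continue
        for j in range(i + 1, nd):
            cj = contribs[j]
            if not cj:
                continue
            shared = ci.keys() & cj.keys()
            if not shared:
                continue
            num = sum(ci[t] + cj[t] for t in shared)
            S[i, j] = S[j, i] = num / (totals[i] + totals[j])
    np.fill_diagonal(S, 1.0)
    return S


def lncrna_functional_similarity(
    S_D: np.ndarray,
    LD: np.ndarray,
    lncrna_sub_index: np.ndarray,
    disease_sub_index: np.ndarray,
    nl: int,
) -> np.ndarray:
    """Best-match-average functional similarity over the full lncRNA space.

    For lncRNAs u, v with associated disease sets D_u, D_v (read off LD and
    mapped to full disease indices):

        S_L(u, v) = [ sum_{d in D_u} max_{d' in D_v} S_D(d, d')
                    + sum_{d in D_v} max_{d' in D_u} S_D(d, d') ]
                    / (|D_u| + |D_v|)

    lncRNAs without disease associations (including all lncRNAs outside the
    LD sub-space) get 0 off-diagonal and 1 on the diagonal.
    """
    disease_sets: dict[int, np.ndarray] = {}
    for row, full in enumerate(lncrna_sub_index):
        cols = np.flatnonzero(LD[row] == 1)
        if cols.size:
            disease_sets[int(full)] = disease_sub_index[cols]
    S = np.zeros((nl, nl))
    keys = sorted(disease_sets)
    for a_pos, u in enumerate(keys):
        Du = disease_sets[u]
        for v in keys[a_pos + 1 :]:
            Dv = disease_sets[v]
            block = S_D[np.ix_(Du, Dv)]
            val = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                len(Du) + len(Dv)
            )
            S[u, v] = S[v, u] = val
    np.fill_diagonal(S, 1.0)
    return S


def build_similarities(
    dataset: AssociationDataset,
    annotations: Mapping[str, DiseaseAnnotation],
    decay: float = DEFAULT_DECAY,
) -> SimilarityMatrices:
    """Compute both similarity matrices for a dataset from MeSH annotations."""
    S_D = disease_semantic_similarity(dataset.disease_names, annotations, decay)
    S_L = lncrna_functional_similarity(
        S_D,
        dataset.LD,
        dataset.lncrna_sub_index,
        dataset.disease_sub_index,
        dataset.nl,
    )
    return SimilarityMatrices(S_D=S_D, S_L=S_L)


def similarity_sub_blocks(
    similarities: SimilarityMatrices, dataset: AssociationDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict S_D / S_L to the LD sub-spaces (the only conformable blocks
    for the propagation matrix of the negative sampler)."""
    S_D_sub = similarities.S_D[
        np.ix_(dataset.disease_sub_index, dataset.disease_sub_index)
    ]
    S_L_sub = similarities.S_L[
        np.ix_(dataset.lncrna_sub_index, dataset.lncrna_sub_index)
    ]
    return S_D_sub, S_L_sub
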