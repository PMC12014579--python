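"""Parsing of association-pair files and MeSH annotations into matrices.

The pipeline consumes three bipartite association tables — miRNA–disease
(MD), miRNA–lncRNA (ML) and lncRNA–disease (LD) — supplied as two-column
TSV files with one entity pair per line.  Entity identity is resolved
case-insensitively after whitespace trimming, so the same RNA or disease
spelled differently across source databases joins to a single index; the
first-seen spelling is kept for output.  The lncRNA–disease table usually
covers only a subset of the lncRNA/disease universes (in the reference
corpus 77 of 1089 lncRNAs and 95 of 373 diseases), so ``AssociationDataset``
carries injective index maps from LD's rows/columns into the full spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "DiseaseAnnotation",
    "PairFileError",
    "UnresolvableEntityError",
    "read_association_pairs",
    "build_dataset",
    "read_mesh_annotations",
    "write_score_matrix",
    "read_score_matrix",
    "normalize_name",
]


class PairFileError(ValueError):
    """A pair file line could not be parsed."""


class UnresolvableEntityError(ValueError):
    """An entity in the LD pair file is absent from its universe."""


def normalize_name(name: str) -> str:
    """Canonical key for entity identity: trimmed, case-folded."""
    return name.strip().casefold()


@dataclass(frozen=True)
class DiseaseAnnotation:
    """A disease together with its MeSH tree numbers (dot-separated codes)."""

    disease_name: str
    tree_numbers: frozenset[str] = frozenset()

    def dag_nodes(self) -> frozenset[str]:
        """All DAG nodes: every prefix of every tree number truncated at dots."""
        nodes: set[str] = set()
        for tn in self.tree_numbers:
            parts = tn.split(".")
            for k in range(1, len(parts) + 1):
                nodes.add(".".join(parts[:k]))
        return frozenset(nodes)


@dataclass
class AssociationDataset:
    """The three binary association matrices plus entity universes.

    ``MD`` is nm x nd (miRNA x disease), ``ML`` is nm x nl (miRNA x lncRNA)
    and ``LD`` is nl_ld x nd_ld over the subset of entities with curated
    lncRNA-disease links.  ``lncrna_sub_index[i]`` maps row i of LD to a row
    of the full lncRNA space; ``disease_sub_index[j]`` maps column j of LD
    to a full disease index.
    """

    mirna_names: list[str]
    disease_names: list[str]
    lncrna_names: list[str]
    MD: np.ndarray
    ML: np.ndarray
    LD: np.ndarray
    lncrna_sub_index: np.ndarray
    disease_sub_index: np.ndarray

    @property
    def nm(self) -> int:
        return len(self.mirna_names)

    @property
    def nd(self) -> int:
        return len(self.disease_names)

    @property
    def nl(self) -> int:
        return len(self.lncrna_names)

    @property
    def nl_ld(self) -> int:
        return self.LD.shape[0]

    @property
    def nd_ld(self) -> int:
        return self.LD.shape[1]

    def with_training_ld(self, LD: np.ndarray) -> "AssociationDataset":
        """A copy sharing everything but carrying a modified LD (e.g. with
        held-out positives zeroed for cross-validation)."""
        if LD.shape != self.LD.shape:
            raise ValueError(f"LD shape {LD.shape} != {self.LD.shape}")
        return replace(self, LD=LD)

    def validate(self) -> None:
        for name, mat in (("MD", self.MD), ("ML", self.ML), ("LD", self.LD)):
            if not np.isin(mat, (0.0, 1.0)).all():
                raise ValueError(f"{name} contains non-binary entries")
        if self.MD.shape != (self.nm, self.nd):
            raise ValueError("MD shape inconsistent with name lists")
        if self.ML.shape != (self.nm, self.nl):
            raise ValueError("ML shape inconsistent with name lists")
        for idx, bound, label in (
            (self.lncrna_sub_index, self.nl, "lncrna_sub_index"),
            (self.disease_sub_index, self.nd, "disease_sub_index"),
        ):
            if len(np.unique(idx)) != len(idx):
                raise ValueError(f"{label} is not injective")
            if idx.size and (idx.min() < 0 or idx.max() >= bound):
                raise ValueError(f"{label} out of range")


def read_association_pairs(
    path: str | Path, expected_roles: tuple[str, str] = ("entity", "entity")
) -> list[tuple[str, str]]:
    """Read a two-column TSV of association pairs, deduplicated in
    first-seen order.

    Blank lines and ``#`` comment lines are skipped.  Deduplication compares
    trimmed, case-folded names; the first spelling encountered is retained.
    A non-comment line with fewer than two tab-separated fields raises
    :class:`PairFileError` naming the offending line number.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PairFileError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields "
                    f"({expected_roles[0]}, {expected_roles[1]}), got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            key = (normalize_name(a), normalize_name(b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((a, b))
    return pairs


def _universe(names: Iterable[str]) -> tuple[list[str], dict[str, int]]:
    """First-seen-ordered unique names plus a normalized-name index map."""
    ordered: list[str] = []
    index: dict[str, int] = {}
    for name in names:
        key = normalize_name(name)
        if key not in index:
            index[key] = len(ordered)
            ordered.append(name.strip())
    return ordered, index


def build_dataset(
    md_pairs: Sequence[tuple[str, str]],
    ml_pairs: Sequence[tuple[str, str]],
    ld_pairs: Sequence[tuple[str, str]],
) -> AssociationDataset:
    """Assemble the binary matrices and index maps from deduplicated pairs.

    Universes: miRNAs are the union of the first columns of the MD and ML
    tables; diseases come from the MD table; lncRNAs from the ML table.
    Every lncRNA (disease) mentioned in ``ld_pairs`` must resolve into the
    lncRNA (disease) universe, otherwise :class:`UnresolvableEntityError`
    lists the offenders.
    """
    mirna_names, m_idx = _universe(
        [p[0] for p in md_pairs] + [p[0] for p in ml_pairs]
    )
    disease_names, d_idx = _universe([p[1] for p in md_pairs])
    lncrna_names, l_idx = _universe([p[1] for p in ml_pairs])

    MD = np.zeros((len(mirna_names), len(disease_names)))
    for m, d in md_pairs:
        MD[m_idx[normalize_name(m)], d_idx[normalize_name(d)]] = 1.0
    ML = np.zeros((len(mirna_names), len(lncrna_names)))
    for m, l in ml_pairs:
        ML[m_idx[normalize_name(m)], l_idx[normalize_name(l)]] = 1.0

    missing: list[str] = []
    for l, d in ld_pairs:
        if normalize_name(l) not in l_idx:
            missing.append(f"lncRNA {l!r}")
        if normalize_name(d) not in d_idx:
            missing.append(f"disease {d!r}")
    if missing:
        raise UnresolvableEntityError(
            "entities in lncRNA-disease pairs absent from their universe: "
            + ", ".join(sorted(set(missing)))
        )

    sub_l: list[int] = []
    sub_d: list[int] = []
    row_of: dict[int, int] = {}
    col_of: dict[int, int] = {}
    for l, d in ld_pairs:
        li = l_idx[normalize_name(l)]
        di = d_idx[normalize_name(d)]
        if li not in row_of:
            row_of[li] = len(sub_l)
            sub_l.append(li)
        if di not in col_of:
            col_of[di] = len(sub_d)
            sub_d.append(di)
    LD = np.zeros((len(sub_l), len(sub_d)))
    for l, d in ld_pairs:
        LD[row_of[l_idx[normalize_name(l)]], col_of[d_idx[normalize_name(d)]]] = 1.0

    ds = AssociationDataset(
        mirna_names=mirna_names,
        disease_names=disease_names,
        lncrna_names=lncrna_names,
        MD=MD,
        ML=ML,
        LD=LD,
        lncrna_sub_index=np.asarray(sub_l, dtype=np.intp),
        disease_sub_index=np.asarray(sub_d, dtype=np.intp),
    )
    ds.validate()
    return ds


def read_mesh_annotations(path: str | Path) -> dict[str, DiseaseAnnotation]:
    """Read a disease -> MeSH-tree-number table.

    Two-column TSV: disease name, then ``;``-separated tree numbers.  The
    returned mapping is keyed by normalized disease name.  A disease listed
    twice with identical code sets is merged silently; conflicting code sets
    raise an error.
    """
    out: dict[str, DiseaseAnnotation] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PairFileError(
                    f"{path}: line {lineno}: expected disease<TAB>tree-numbers"
                )
            name = fields[0].strip()
            codes = frozenset(
                c.strip() for c in fields[1].split(";") if c.strip()
            )
            key = normalize_name(name)
            if key in out:
                if out[key].tree_numbers != codes:
                    raise ValueError(
                        f"{path}: line {lineno}: duplicate annotation for "
                        f"{name!r} with conflicting tree numbers"
                    )
                continue
            out[key] = DiseaseAnnotation(disease_name=name, tree_numbers=codes)
    return out


def write_score_matrix(
    matrix: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
    path: str | Path,
) -> None:
    """Write a labeled score matrix as TSV (one header row, one label column).

    Values are printed with 17 significant digits so a read-back round-trip
    is bit-identical for doubles.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(row_names), len(col_names)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(row_names)} row names x {len(col_names)} column names"
        )
    df = pd.DataFrame(matrix, index=list(row_names), columns=list(col_names))
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="name")


def read_score_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read back a TSV written by :func:`write_score_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (
        df.to_numpy(dtype=float),
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
    )
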