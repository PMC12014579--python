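"""One-command orchestration: configuration, mode dispatch, artifact manifest.

An :class:`ExperimentConfig` (YAML on disk) is the single source of truth;
``run_experiment`` resolves defaults, executes the requested mode
end-to-end, writes every artifact under the output directory, echoes the
resolved configuration next to the outputs, and records a JSON manifest of
output files with SHA-256 content hashes so identical configurations can be
verified to reproduce identical results.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_io import (
    build_dataset,
    read_association_pairs,
    read_mesh_annotations,
    read_score_matrix,
    write_score_matrix,
    normalize_name,
    AssociationDataset,
)
from .evaluation import CVReport, kfold_cv, lodocv, loocv, rank_candidates
from .model import Hyperparameters, save_checkpoint
from .sampling import build_mask
from .similarity import SimilarityMatrices, build_similarities
from .synthetic import SyntheticConfig, generate, write_synthetic_files
from .training import fit_predict

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment"]

MODES = (
    "simulate",
    "similarity",
    "sample",
    "train",
    "cv5",
    "cv10",
    "lodocv",
    "loocv",
    "rank",
)


class ConfigError(ValueError):
    """The experiment configuration is invalid for the requested mode."""


@dataclass
class ExperimentConfig:
    """Everything needed to run one experiment end-to-end."""

    mode: str = "train"
    outdir: str = "results"
    seed: int = 0
    # input tables (unused by mode=simulate)
    md_pairs: str | None = None
    ml_pairs: str | None = None
    ld_pairs: str | None = None
    annotations: str | None = None
    sd_matrix: str | None = None
    sl_matrix: str | None = None
    # similarity
    decay: float = 0.5
    # sampling
    epsilon: float = 0.0
    allow_topup: bool = False
    # model / training
    lambda1: float = 1e-3
    lambda2: float = 1e-1
    lambda3: float = 10.0
    lambda4: float = 1.0
    learning_rate: float = 1e-3
    max_iterations: int = 5000
    tolerance: float = 1e-3
    init_std: float = 0.01
    # evaluation
    disease: str | None = None
    top_k: int = 20
    # synthetic generation (mode=simulate)
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(
                f"invalid mode {self.mode!r}; expected one of {MODES}"
            )
        if self.mode != "simulate":
            for key in ("md_pairs", "ml_pairs", "ld_pairs"):
                if getattr(self, key) is None:
                    raise ConfigError(f"mode {self.mode!r} requires {key}")
            if self.annotations is None and (
                self.sd_matrix is None or self.sl_matrix is None
            ):
                raise ConfigError(
                    "need either an annotations table or both similarity matrices"
                )
        if self.mode == "rank" and self.disease is None:
            raise ConfigError("mode 'rank' requires a disease name")

    def hyper(self) -> Hyperparameters:
        return Hyperparameters(
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            lambda3=self.lambda3,
            lambda4=self.lambda4,
            learning_rate=self.learning_rate,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            seed=self.seed,
            init_std=self.init_std,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_dataset(config: ExperimentConfig) -> AssociationDataset:
    md = read_association_pairs(config.md_pairs, ("miRNA", "disease"))
    ml = read_association_pairs(config.ml_pairs, ("miRNA", "lncRNA"))
    ld = read_association_pairs(config.ld_pairs, ("lncRNA", "disease"))
    return build_dataset(md, ml, ld)


def _aligned_matrix(path: str, names: list[str], label: str) -> np.ndarray:
    mat, rows, cols = read_score_matrix(path)
    index = {normalize_name(n): i for i, n in enumerate(rows)}
    if {normalize_name(n) for n in cols} != set(index):
        raise ConfigError(f"{label}: row and column labels differ")
    try:
        order = [index[normalize_name(n)] for n in names]
    except KeyError as exc:
        raise ConfigError(f"{label}: missing entity {exc.args[0]!r}") from None
    order = np.asarray(order)
    return mat[np.ix_(order, order)]


def _load_similarities(
    config: ExperimentConfig, dataset: AssociationDataset
) -> SimilarityMatrices:
    if config.sd_matrix is not None and config.sl_matrix is not None:
        return SimilarityMatrices(
            S_D=_aligned_matrix(config.sd_matrix, dataset.disease_names, "S_D"),
            S_L=_aligned_matrix(config.sl_matrix, dataset.lncrna_names, "S_L"),
        )
    annotations = read_mesh_annotations(config.annotations)
    return build_similarities(dataset, annotations, config.decay)


def _write_mask_tsv(path: Path, dataset: AssociationDataset, mask) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncRNA\tdisease\tlabel\n")
        for (i, j), label in [
            *((tuple(c), 1) for c in mask.positives),
            *((tuple(c), 0) for c in mask.negatives),
        ]:
            lname = dataset.lncrna_names[dataset.lncrna_sub_index[i]]
            dname = dataset.disease_names[dataset.disease_sub_index[j]]
            fh.write(f"{lname}\t{dname}\t{label}\n")


def _write_trace_csv(path: Path, trace) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["iteration", "loss1", "loss2", "loss3", "loss4", "loss5", "loss_total"]
        )
        for it, lb in enumerate(trace.losses, start=1):
            w.writerow(
                [it, lb.loss1, lb.loss2, lb.loss3, lb.loss4, lb.loss5, lb.loss_total]
            )
        w.writerow(["stop_reason", trace.stop_reason, "", "", "", "", ""])


def _write_cv_report(outdir: Path, stem: str, report: CVReport) -> list[Path]:
    csv_path = outdir / f"{stem}.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["unit", "auc"])
        for key, auc in zip(report.keys, report.aucs):
            w.writerow([key, auc])
    summary_path = outdir / f"{stem}_summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "mean_auc": report.mean,
                "variance": report.variance,
                "n_units": len(report.keys),
                "seed": report.seed,
            },
            fh,
            indent=2,
        )
    return [csv_path, summary_path]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured mode end-to-end and return the manifest.

    On failure a ``FAILED`` marker naming the stage is left in the output
    directory and the exception propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    produced: list[Path] = [outdir / "resolved_config.yaml"]
    stage = "setup"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
            dataset, similarities, truth = generate(syn)
            paths = write_synthetic_files(outdir, dataset, similarities, truth)
            produced.extend(paths.values())
        else:
            stage = "load"
            dataset = _load_dataset(config)
            similarities = _load_similarities(config, dataset)
            hyper = config.hyper()
            if config.mode == "similarity":
                stage = "similarity"
                write_score_matrix(
                    similarities.S_D,
                    dataset.disease_names,
                    dataset.disease_names,
                    outdir / "S_D.tsv",
                )
                write_score_matrix(
                    similarities.S_L,
                    dataset.lncrna_names,
                    dataset.lncrna_names,
                    outdir / "S_L.tsv",
                )
                produced += [outdir / "S_D.tsv", outdir / "S_L.tsv"]
            elif config.mode == "sample":
                stage = "sample"
                mask = build_mask(
                    dataset,
                    similarities,
                    config.seed,
                    epsilon=config.epsilon,
                    allow_topup=config.allow_topup,
                )
                _write_mask_tsv(outdir / "mask.tsv", dataset, mask)
                produced.append(outdir / "mask.tsv")
            elif config.mode == "train":
                stage = "train"
                result = fit_predict(
                    dataset,
                    similarities,
                    hyper,
                    epsilon=config.epsilon,
                    allow_topup=config.allow_topup,
                )
                save_checkpoint(
                    result.params,
                    outdir / "checkpoint.npz",
                    metadata={"seed": config.seed},
                )
                write_score_matrix(
                    result.scores,
                    dataset.lncrna_names,
                    dataset.disease_names,
                    outdir / "scores.tsv",
                )
                _write_mask_tsv(outdir / "mask.tsv", dataset, result.mask)
                _write_trace_csv(outdir / "trace.csv", result.trace)
                produced += [
                    outdir / "checkpoint.npz",
                    outdir / "scores.tsv",
                    outdir / "mask.tsv",
                    outdir / "trace.csv",
                ]
            elif config.mode in ("cv5", "cv10"):
                stage = config.mode
                K = 5 if config.mode == "cv5" else 10
                report = kfold_cv(
                    dataset, similarities, K, config.seed, hyper,
                    epsilon=config.epsilon, allow_topup=config.allow_topup,
                )
                produced += _write_cv_report(outdir, config.mode, report)
            elif config.mode == "lodocv":
                stage = "lodocv"
                report = lodocv(
                    dataset, similarities, hyper,
                    epsilon=config.epsilon, allow_topup=config.allow_topup,
                )
                produced += _write_cv_report(outdir, "lodocv", report)
            elif config.mode == "loocv":
                stage = "loocv"
                auc = loocv(
                    dataset, similarities, hyper,
                    epsilon=config.epsilon, allow_topup=config.allow_topup,
                )
                path = outdir / "loocv_summary.json"
                with open(path, "w", encoding="utf-8") as fh:
                    json.dump({"auc": auc, "seed": config.seed}, fh, indent=2)
                produced.append(path)
            elif config.mode == "rank":
                stage = "rank"
                result = fit_predict(
                    dataset,
                    similarities,
                    hyper,
                    epsilon=config.epsilon,
                    allow_topup=config.allow_topup,
                )
                top = rank_candidates(
                    result.scores, dataset, config.disease, config.top_k
                )
                path = outdir / "ranking.tsv"
                with open(path, "w", encoding="utf-8") as fh:
                    fh.write("rank\tlncRNA\tscore\n")
                    for r, (name, score) in enumerate(top, start=1):
                        fh.write(f"{r}\t{name}\t{score:.17g}\n")
                produced.append(path)
        stage = "manifest"
        manifest = {
            "mode": config.mode,
            "seed": config.seed,
            "files": {p.name: _sha256(p) for p in produced},
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        with open(outdir / "FAILED", "w", encoding="utf-8") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise
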