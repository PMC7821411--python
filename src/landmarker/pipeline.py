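"""End-to-end orchestration: preprocess → train → attribute → select →
benchmark, driven by one seeded configuration.

``run_discovery`` executes the landmark-mining workflow on an expression
matrix; ``run_benchmark`` scores one or more landmark sets by training the
landmark→target regressor on the training split and evaluating predictions
on the held-out split, with pairwise paired-t comparisons over common
target genes (the D1000-vs-L1000 experimental design, generalized).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict, field

import numpy as np
import yaml

from . import attribution, autoencoder, evaluation, inference, io, preprocess
from .attribution import LandmarkSet
from .matrix import ExpressionMatrix

__all__ = [
    "RunConfig",
    "PipelineError",
    "DiscoveryResult",
    "BenchmarkResult",
    "run_discovery",
    "run_benchmark",
    "random_landmark_set",
]

logger = logging.getLogger("landmarker")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Every tunable of the workflow, with defaults at the published values
    where one exists: 100 epochs, 10% dropout, L2 alpha 1e-6, hidden widths
    500/100/500, k = 943 landmarks, significance alpha 0.01, normalization
    range [4, 15], 90/10 split."""

    low: float = 4.0
    high: float = 15.0
    split_fraction: float = 0.9
    dedup: bool = True
    dedup_clusters: int | None = None
    dedup_threshold: float = 0.99
    hidden_widths: tuple = (500, 100, 500)
    epochs: int = 100
    dropout_rate: float = 0.10
    l2_alpha: float = 1e-6
    batch_size: int = 256
    learning_rate: float = 1e-3
    reference: str = "train_mean"  # or "zeros"
    attribution_samples: int | None = None
    signed_importance: bool = False
    k: int = 943
    regressor_hidden: tuple = (200,)
    regressor_epochs: int = 200
    alpha: float = 0.01
    seed: int = 17

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        self.regressor_hidden = tuple(int(w) for w in self.regressor_hidden)
        if self.reference not in ("train_mean", "zeros"):
            raise ValueError("reference must be train_mean or zeros")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_widths"] = list(self.hidden_widths)
        d["regressor_hidden"] = list(self.regressor_hidden)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    """Everything the discovery workflow produces."""

    normalized: ExpressionMatrix
    split: preprocess.SplitResult
    model: autoencoder.AutoencoderModel
    training_history: list
    reference: attribution.ReferenceInput
    ranking: attribution.ImportanceRanking
    landmarks: LandmarkSet
    manifest: dict = field(default_factory=dict)


@dataclass
class BenchmarkResult:
    """Per-set evaluation reports and pairwise comparisons."""

    reports: dict  # set name -> EvaluationReport
    comparisons: dict  # (name_a, name_b) -> SetComparison
    manifest: dict = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    logger.info("=== stage: %s ===", name)
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise PipelineError(name, exc) from exc


def run_discovery(
    X: ExpressionMatrix, config: RunConfig | None = None, outdir: str | None = None
) -> DiscoveryResult:
    """Normalize, split, train the autoencoder, attribute, select landmarks.

    ``k`` is capped at the size of the gene universe. With ``outdir`` set,
    the trained model, ranked gene list, score table and a manifest (config
    hash + seed) are written there.
    """
    if config is None:
        config = RunConfig()

    norm = _stage(
        "quantile_normalize", preprocess.quantile_normalize, X, config.low, config.high
    )
    if config.dedup:
        norm = _stage(
            "deduplicate",
            preprocess.deduplicate_profiles,
            norm,
            config.dedup_clusters,
            config.dedup_threshold,
            config.seed,
        )
    split = _stage(
        "split", preprocess.train_test_split, norm, config.split_fraction, config.seed
    )
    train_unit = _stage(
        "scale", preprocess.minmax_to_unit, split.train, config.low, config.high
    )

    ae_config = autoencoder.TrainConfig(
        epochs=config.epochs,
        l2_alpha=config.l2_alpha,
        dropout_rate=config.dropout_rate,
        batch_size=config.batch_size,
        seed=config.seed,
        learning_rate=config.learning_rate,
    )

    def _train():
        params, history = autoencoder.train(
            train_unit, config.hidden_widths, ae_config
        )
        return autoencoder.AutoencoderModel(
            params=params, low=config.low, high=config.high, config=ae_config
        ), history

    model, history = _stage("train_autoencoder", _train)

    def _attribute():
        if config.reference == "train_mean":
            ref = attribution.reference_from_training(train_unit)
        else:
            ref = attribution.ReferenceInput(
                np.zeros(train_unit.n_genes), source="zeros"
            )
        tensor = attribution.compute_contribution_tensor(
            model.params,
            train_unit,
            ref,
            n_samples=config.attribution_samples,
            seed=config.seed,
        )
        ranking = attribution.aggregate_importance(
            tensor, signed=config.signed_importance
        )
        return ref, ranking

    ref, ranking = _stage("attribution", _attribute)
    k_eff = min(config.k, len(ranking))
    landmarks = _stage("select", attribution.select_landmarks, ranking, k_eff)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": X.n_genes,
        "n_samples": X.n_samples,
        "n_train": split.train.n_samples,
        "n_test": split.test.n_samples,
        "k": k_eff,
        "final_train_loss": history[-1],
    }
    result = DiscoveryResult(
        normalized=norm,
        split=split,
        model=model,
        training_history=history,
        reference=ref,
        ranking=ranking,
        landmarks=landmarks,
        manifest=manifest,
    )
    if outdir is not None:
        _write_discovery(result, outdir)
    return result


def _write_discovery(result: DiscoveryResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.model.save(os.path.join(outdir, "model.ae.npz"))
    io.write_gene_list(
        result.landmarks.gene_ids, os.path.join(outdir, "landmarks.txt")
    )
    io.write_scores(
        result.ranking.gene_ids,
        result.ranking.scores,
        os.path.join(outdir, "scores.tsv"),
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1)


def random_landmark_set(
    gene_ids, k: int, seed: int = 0
) -> LandmarkSet:
    """A size-k uniform random landmark set — the null baseline."""
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_ids), size=k, replace=False)
    return LandmarkSet(gene_ids=[gene_ids[i] for i in chosen], k=k)


def run_benchmark(
    split: preprocess.SplitResult,
    landmark_sets: dict,
    config: RunConfig | None = None,
) -> BenchmarkResult:
    """Score each landmark set with the landmark→target regressor.

    For each named set: partition genes, train the regressor on the training
    split, predict the held-out split, evaluate per target gene. Every pair
    of sets is then compared over their common target genes.
    """
    if config is None:
        config = RunConfig()
    if not landmark_sets:
        raise ValueError("need at least one landmark set")

    reports: dict = {}
    for name, landmarks in landmark_sets.items():
        def _bench(name=name, landmarks=landmarks):
            lm_train, tg_train = inference.split_landmark_target(
                split.train, landmarks
            )
            lm_test, tg_test = inference.split_landmark_target(split.test, landmarks)
            spec = inference.RegressorSpec(
                hidden_widths=config.regressor_hidden,
                epochs=config.regressor_epochs,
                batch_size=config.batch_size,
                seed=config.seed,
                learning_rate=config.learning_rate,
            )
            model, _ = inference.train_regressor(lm_train, tg_train, spec)
            predicted = inference.predict_targets(model, lm_test)
            report = evaluation.evaluate(tg_test, predicted, alpha=config.alpha)
            logger.info(
                "set %s: mean MAE %.4f, mean PCC %.4f, significant %d/%d",
                name,
                report.mean_mae,
                report.mean_pcc,
                report.n_significant,
                report.n_genes,
            )
            return report

        reports[name] = _stage(f"benchmark:{name}", _bench)

    comparisons: dict = {}
    names = list(reports)
    for i, name_a in enumerate(names):
        for name_b in names[i + 1 :]:
            comparisons[(name_a, name_b)] = _stage(
                f"compare:{name_a}-vs-{name_b}",
                evaluation.compare_landmark_sets,
                reports[name_a],
                reports[name_b],
            )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sets": {name: lm.k for name, lm in landmark_sets.items()},
    }
    return BenchmarkResult(reports=reports, comparisons=comparisons, manifest=manifest)
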