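"""End-to-end orchestration: featurize -> enumerate pairs -> balance ->
select -> train -> evaluate, with per-stage artifacts and a run manifest.

Balancing is applied to the TRAINING split only; the held-out split
keeps its natural class imbalance so the reported metrics reflect the
deployment distribution rather than the resampled one.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ddapre import io_formats
from ddapre.disease_features import WalkConfig, embed_diseases
from ddapre.drug_features import embed_drugs, fuse_drug_features
from ddapre.ensemble import StackingModel, fit_stacking, predict_stacking
from ddapre.evaluation import score_report
from ddapre.feature_selection import select_top_k
from ddapre.fixtures import FeatureMatrix
from ddapre.io_formats import (
    AssociationTable,
    EmbeddingTable,
    enumerate_pair_space,
)
from ddapre.resampling import (
    DistanceMetric,
    ResampleConfig,
    adaptive_metric_select,
    candidate_metrics,
    fit_median_quantizer,
    grouped_undersample,
    ksu_pairs_undersample,
)


@dataclass
class PipelineConfig:
    """Every stage's settings in one place; defaults follow the framework's
    reference values where stated (drug dim 300, window 10, radius 1,
    disease dim 64, k_selected 140, Hamming metric)."""

    drugs_csv: str = ""
    diseases_csv: str = ""
    positives_csv: str = ""
    external_embeddings_tsv: str | None = None
    out_dir: str = "run"
    # drug featurization
    drug_dim: int = 300
    drug_window: int = 10
    radius: int = 1
    embed_epochs: int = 5
    # disease featurization
    disease_dim: int = 64
    walks_per_node: int = 10
    walk_length: int = 40
    walk_window: int = 5
    # balancing
    do_balance: bool = True
    metric: str = "hamming"  # or auto|euclidean|chebyshev|manhattan|minkowski
    minkowski_p: float = 3.0
    n_clusters: int | None = None
    group_by_drug: bool = True
    # selection
    do_select: bool = True
    k_selected: int = 140
    # model / evaluation
    n_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 42

    @staticmethod
    def from_toml(path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return PipelineConfig(**data)


@dataclass
class RunManifest:
    config: dict
    stage_seconds: dict = field(default_factory=dict)
    artifact_checksums: dict = field(default_factory=dict)
    library_versions: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self, default=_json_default, indent=2))


def _json_default(obj):
    if isinstance(obj, (RunManifest,)):
        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_pair_features(
    pairs: AssociationTable,
    drug_table: EmbeddingTable,
    disease_table: EmbeddingTable,
) -> FeatureMatrix:
    """Per-pair concatenation [drug vector || disease vector]."""
    drug_mat = np.stack([drug_table[d] for d in pairs.drug_ids])
    dis_mat = np.stack([disease_table[d] for d in pairs.disease_ids])
    names = [f"drug_{i}" for i in range(drug_table.dimension)] + [
        f"disease_{i}" for i in range(disease_table.dimension)
    ]
    return FeatureMatrix(
        np.hstack([drug_mat, dis_mat]),
        pairs.labels,
        list(pairs.drug_ids),
        list(pairs.disease_ids),
        names,
    )


def _resolve_metric(cfg: PipelineConfig, X: np.ndarray, y: np.ndarray):
    if cfg.metric == "auto":
        metric, table = adaptive_metric_select(X, y, seed=cfg.seed)
        return metric, table.to_dict(orient="records")
    if cfg.metric == "hamming":
        return (
            DistanceMetric("hamming", hamming_thresholds=fit_median_quantizer(X)),
            None,
        )
    if cfg.metric == "minkowski":
        return DistanceMetric("minkowski", p=cfg.minkowski_p), None
    return DistanceMetric(cfg.metric), None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, persisting each stage's output."""
    import sklearn
    import xgboost

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        library_versions={
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    )

    def stage(name):
        def deco(fn):
            start = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # structured stage failure
                raise StageError(name, exc) from exc
            manifest.stage_seconds[name] = round(time.perf_counter() - start, 3)
            return result

        return deco

    @stage("read_inputs")
    def inputs():
        drugs = io_formats.read_drug_table(config.drugs_csv)
        diseases = io_formats.read_disease_table(config.diseases_csv)
        positives = io_formats.read_association_table(config.positives_csv)
        return drugs, diseases, positives

    drugs, diseases, positives = inputs

    @stage("drug_features")
    def drug_emb():
        table = embed_drugs(
            drugs,
            dimension=config.drug_dim,
            window=config.drug_window,
            radius=config.radius,
            epochs=config.embed_epochs,
            seed=config.seed,
        )
        if config.external_embeddings_tsv:
            external = io_formats.read_embedding_table(config.external_embeddings_tsv)
            table = fuse_drug_features(table, external)
        io_formats.write_embedding_table(table, out / "drug_embeddings.tsv")
        return table

    @stage("disease_features")
    def disease_emb():
        cfg = WalkConfig(
            walks_per_node=config.walks_per_node,
            walk_length=config.walk_length,
            window=config.walk_window,
            dimension=config.disease_dim,
            epochs=config.embed_epochs,
            seed=config.seed,
        )
        table = embed_diseases(diseases, cfg)
        io_formats.write_embedding_table(table, out / "disease_embeddings.tsv")
        return table

    @stage("enumerate_pairs")
    def pairs():
        table = enumerate_pair_space(drugs, diseases, positives)
        io_formats.write_association_table(table, out / "pair_space.csv")
        return table

    matrix = build_pair_features(pairs, drug_emb, disease_emb)

    @stage("split")
    def split():
        idx = np.arange(matrix.n_samples)
        train_idx, test_idx = train_test_split(
            idx,
            test_size=config.test_fraction,
            stratify=matrix.y,
            random_state=config.seed % (2**31),
        )
        return np.sort(train_idx), np.sort(test_idx)

    train_idx, test_idx = split

    @stage("balance")
    def balance():
        X_train, y_train = matrix.X[train_idx], matrix.y[train_idx]
        if not config.do_balance:
            return train_idx, None
        metric, score_table = _resolve_metric(config, X_train, y_train)
        rcfg = ResampleConfig(
            n_clusters=config.n_clusters, metric=metric, seed=config.seed
        )
        if config.group_by_drug:
            group_ids = [matrix.drug_ids[i] for i in train_idx]
            result = grouped_undersample(X_train, y_train, group_ids, rcfg)
        else:
            result = ksu_pairs_undersample(X_train, y_train, rcfg)
        kept = train_idx[result.retained_indices]
        (out / "resample.json").write_text(
            json.dumps(
                {
                    "retained": kept.tolist(),
                    "removed": train_idx[result.removed_indices].tolist(),
                    "metric": metric.kind,
                    "metric_scores": score_table,
                    "diagnostics": result.diagnostics,
                },
                default=_json_default,
            )
        )
        return kept, result

    balanced_idx, _resample = balance

    @stage("select")
    def select():
        X_bal, y_bal = matrix.X[balanced_idx], matrix.y[balanced_idx]
        if not config.do_select:
            return np.arange(matrix.n_features), None
        k = min(config.k_selected, matrix.n_features)
        result = select_top_k(X_bal, y_bal, k)
        (out / "selected_features.json").write_text(
            json.dumps(
                {
                    "indices": result.selected_indices.tolist(),
                    "mean_f_all": result.mean_f_all,
                    "mean_f_selected": result.mean_f_selected,
                },
                default=_json_default,
            )
        )
        return result.selected_indices, result

    feature_idx, _ftest = select

    @stage("train")
    def train():
        return fit_stacking(
            matrix.X[np.ix_(balanced_idx, feature_idx)],
            matrix.y[balanced_idx],
            n_folds=config.n_folds,
            seed=config.seed,
        )

    model: StackingModel = train

    @stage("evaluate")
    def evaluate():
        scores = model.predict_scores(matrix.X[np.ix_(test_idx, feature_idx)])
        report = score_report(scores, matrix.y[test_idx])
        (out / "report.json").write_text(
            json.dumps(report.as_dict(), default=_json_default, indent=2)
        )
        return report

    report = evaluate

    @stage("predict_all")
    def predict_all():
        scores, hard = predict_stacking(model, matrix.X[:, feature_idx])
        frame = pd.DataFrame(
            {
                "drug_id": matrix.drug_ids,
                "disease_id": matrix.disease_ids,
                "score": scores,
                "label_pred": hard,
            }
        )
        frame.to_csv(out / "predictions.csv", index=False)
        return frame

    predictions = predict_all

    manifest.report = report.as_dict()
    for artifact in sorted(out.glob("*")):
        if artifact.name != "MANIFEST.json" and artifact.is_file():
            manifest.artifact_checksums[artifact.name] = _checksum(artifact)
    manifest.save(out / "MANIFEST.json")
    return manifest


def rank_candidates(
    predictions: pd.DataFrame, disease_id: str, top_k: int = 10
) -> pd.DataFrame:
    """Top-k candidate drugs for one disease, by descending score.

    Ties are broken by drug id so the ranking is reproducible.
    """
    block = predictions[predictions["disease_id"] == disease_id]
    if block.empty:
        raise ValueError(f"no predictions for disease {disease_id!r}")
    ranked = block.sort_values(
        ["score", "drug_id"], ascending=[False, True]
    ).head(top_k)
    ranked = ranked.reset_index(drop=True)
    ranked.index += 1
    ranked.index.name = "rank"
    return ranked
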