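"""Multi-context fusion, the SVM seizure detector, and the experiment driver.

Per fragment the three context features — global (PCA scores), channel-wise
(concatenated SDAE codes), temporal (EEG-word embedding) — are concatenated
in that fixed order into one fused vector

    x_Fusion = [x_global (+) x_channelwise (+) x_temporal],

standardized (train-fold statistics only) and classified by an SVM (RBF by
default, hyperparameters from a small cross-validated grid).  Evaluation
reports the confusion-matrix metrics (precision, recall, F1, accuracy),
the ROC and PR curves, and their trapezoidal AUCs.

``run_experiment`` orchestrates the whole pipeline on a set of annotated
records: segment, label, balance and 4:1 split, scalograms, the three
extractors fit on the *training fold only*, fusion, detector training, and
test-fold evaluation.  Any subset of the three contexts can be enabled for
ablation runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import channel_sdae, eeg_embeddings, global_pca, scalogram
from .channel_sdae import CorruptionConfig, SDAEModel, TrainConfig
from .eeg_embeddings import ContextConfig, EEGSentence
from .io_segmentation import (
    ICTAL,
    EEGRecord,
    Fragment,
    SplitDataset,
    balance_and_split,
    label_fragments,
    segment_record,
)
from .scalogram import WaveletConfig

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("global", "channelwise", "temporal")


@dataclass
class FusedFeature:
    values: np.ndarray
    block_spans: dict[str, tuple[int, int]]  # name -> (start, stop)


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc_roc: float
    auc_pr: float
    confusion: ConfusionMatrix
    roc_curve: np.ndarray  # (n, 2): FPR, TPR
    pr_curve: np.ndarray   # (n, 2): recall, precision

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "confusion": asdict(self.confusion),
        }


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    C: float | None = None          # None -> small grid search
    gamma: float | str | None = None
    cv_folds: int = 3
    seed: int = 0


@dataclass
class DetectorModel:
    pipeline: Pipeline
    block_spans: dict[str, tuple[int, int]]
    config: SVMConfig
    seed: int = 0

    def _check_spans(self, block_spans: dict | None) -> None:
        if block_spans is not None and block_spans != self.block_spans:
            raise ValueError(
                f"feature layout mismatch: detector was trained on "
                f"{self.block_spans}, got {block_spans}"
            )

    def predict(self, X: np.ndarray, block_spans: dict | None = None) -> np.ndarray:
        self._check_spans(block_spans)
        return self.pipeline.predict(np.asarray(X))

    def decision_scores(self, X: np.ndarray, block_spans: dict | None = None) -> np.ndarray:
        self._check_spans(block_spans)
        return self.pipeline.decision_function(np.asarray(X))


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse(
    global_feature: np.ndarray,
    channelwise: np.ndarray,
    temporal: np.ndarray,
) -> FusedFeature:
    """Concatenate the three context blocks in fixed order with recorded spans.

    All three blocks must be present and non-empty; reduced (ablation)
    models go through ``run_experiment``'s ``contexts`` setting instead.
    """
    blocks = {
        "global": np.ravel(getattr(global_feature, "scores", global_feature)),
        "channelwise": np.ravel(channelwise),
        "temporal": np.ravel(temporal),
    }
    spans: dict[str, tuple[int, int]] = {}
    start = 0
    for name in BLOCK_ORDER:
        b = blocks[name]
        if b.size == 0:
            raise ValueError(
                f"{name} feature block is empty; request a reduced model "
                "explicitly via the pipeline contexts configuration"
            )
        if not np.all(np.isfinite(b)):
            raise ValueError(f"{name} feature block contains non-finite values")
        spans[name] = (start, start + b.size)
        start += b.size
    return FusedFeature(np.concatenate([blocks[n] for n in BLOCK_ORDER]), spans)


def _stack(features: Sequence[FusedFeature]) -> tuple[np.ndarray, dict]:
    spans = features[0].block_spans
    for f in features:
        if f.block_spans != spans:
            raise ValueError("inconsistent block spans across fused features")
    return np.stack([f.values for f in features]), spans


# ---------------------------------------------------------------------------
# Detector
# ---------------------------------------------------------------------------

def train_detector(
    X: Sequence[FusedFeature] | np.ndarray,
    y: Sequence,
    cfg: SVMConfig | None = None,
    block_spans: dict | None = None,
) -> DetectorModel:
    """Standardize (train statistics) and fit the SVM seizure detector.

    With ``cfg.C``/``cfg.gamma`` unset, a small grid is searched by
    stratified cross-validation inside the training fold.
    """
    cfg = cfg or SVMConfig()
    if len(X) and isinstance(X[0], FusedFeature):
        M, block_spans = _stack(X)
    else:
        M = np.asarray(X, dtype=np.float64)
        block_spans = block_spans or {"all": (0, M.shape[1])}
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training data contains a single class: {classes}")

    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=cfg.kernel, random_state=cfg.seed)),
    ])
    if cfg.C is not None and (cfg.gamma is not None or cfg.kernel == "linear"):
        pipe.set_params(svm__C=cfg.C)
        if cfg.kernel != "linear":
            pipe.set_params(svm__gamma=cfg.gamma)
        pipe.fit(M, y)
        fitted = pipe
    else:
        grid: dict[str, list] = {"svm__C": [1.0, 10.0, 100.0]}
        if cfg.kernel != "linear":
            grid["svm__gamma"] = ["scale", 1e-2, 1e-3]
        search = GridSearchCV(
            pipe,
            grid,
            cv=StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed),
            scoring="f1" if set(classes) == {0, 1} else "accuracy",
            n_jobs=1,
        )
        search.fit(M, y)
        fitted = search.best_estimator_
    return DetectorModel(fitted, block_spans, cfg, seed=cfg.seed)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                      stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Precision, recall, F1 and accuracy from hard-prediction counts.

    Zero-denominator metrics are reported as 0 with a warning.
    """
    precision = _safe_ratio(cm.TP, cm.TP + cm.FP, "precision")
    recall = _safe_ratio(cm.TP, cm.TP + cm.FN, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
    accuracy = _safe_ratio(cm.TP + cm.TN, cm.total, "accuracy")
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy}


def score_curves(
    y: np.ndarray, scores: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """ROC and PR curves from continuous scores; AUCs by the trapezoidal rule.

    Returns (auc_roc, auc_pr, roc_points, pr_points) with roc_points rows
    (FPR, TPR) and pr_points rows (recall, precision).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=np.float64)
    fpr, tpr, _ = roc_curve(y, scores)
    auc_roc = float(np.trapezoid(tpr, fpr))
    prec_c, rec_c, _ = precision_recall_curve(y, scores)
    # reverse to threshold-traversal order (recall ascending); duplicate
    # recall values then contribute zero width to the trapezoidal sum
    prec_c, rec_c = prec_c[::-1], rec_c[::-1]
    auc_pr = float(np.trapezoid(prec_c, rec_c))
    return (auc_roc, auc_pr,
            np.column_stack([fpr, tpr]),
            np.column_stack([rec_c, prec_c]))


def evaluate(
    model: DetectorModel,
    X_test: Sequence[FusedFeature] | np.ndarray,
    y_test: Sequence,
) -> MetricsReport:
    """Confusion-matrix metrics plus ROC/PR curves and trapezoidal AUCs.

    The positive class is label 1 (ictal); hard labels use the SVM's
    default decision boundary, curves use the continuous decision scores.
    """
    if len(X_test) and isinstance(X_test[0], FusedFeature):
        M, spans = _stack(X_test)
        model._check_spans(spans)
    else:
        M = np.asarray(X_test, dtype=np.float64)
    y = np.asarray(y_test)
    if y.size == 0 or np.unique(y).size < 2:
        raise ValueError("test set must be nonempty and contain both classes")

    pred = model.predict(M)
    scores = model.decision_scores(M)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    cm = ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)
    hard = metrics_from_confusion(cm)
    auc_roc, auc_pr, roc_pts, pr_pts = score_curves(y, scores)
    return MetricsReport(
        **hard, auc_roc=auc_roc, auc_pr=auc_pr, confusion=cm,
        roc_curve=roc_pts, pr_curve=pr_pts,
    )


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every knob of the end-to-end experiment, with the study defaults."""

    window_s: float = 3.0
    step_s: float = 1.0
    min_overlap_fraction: float = 0.0
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    grid: tuple[int, int] = (16, 16)
    pca_k: int = 10
    pca_candidates: tuple[int, ...] = ()   # non-empty -> select k by probe CV
    sdae_sizes: tuple[int, ...] = (80, 60)
    corruption_fraction: float = 0.3
    sdae_train: TrainConfig = field(default_factory=TrainConfig)
    embedding: ContextConfig = field(default_factory=ContextConfig)
    embedding_dim: int = 20
    contexts: tuple[str, ...] = BLOCK_ORDER
    svm: SVMConfig = field(default_factory=SVMConfig)
    train_ratio: float = 0.8
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.contexts) - set(BLOCK_ORDER)
        if unknown or not self.contexts:
            raise ValueError(
                f"contexts must be a nonempty subset of {BLOCK_ORDER}"
            )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    report: MetricsReport
    detector: DetectorModel
    split: SplitDataset
    block_spans: dict[str, tuple[int, int]]
    sdae_models: list[SDAEModel] | None = None
    gpca_model: global_pca.PCAModel | None = None
    embedding: eeg_embeddings.EmbeddingMatrix | None = None


def _fragment_vectors(
    fragments: Sequence[Fragment], fs: float, cfg: PipelineConfig
) -> np.ndarray:
    """Scalogram vectors of every fragment: shape (N, C, rows*cols)."""
    return np.stack([
        scalogram.fragment_to_vectors(f.samples, fs, cfg.wavelet, cfg.grid)
        for f in fragments
    ])


def _train_sentences(
    fragments: Sequence[Fragment],
    word_ids: np.ndarray,  # (N, C) global ids aligned with `fragments`
) -> list[EEGSentence]:
    """Per-(record, channel) word sequences in temporal order."""
    by_record: dict[str, list[int]] = {}
    for i, f in enumerate(fragments):
        by_record.setdefault(f.record_id, []).append(i)
    sentences = []
    for rid, idx in sorted(by_record.items()):
        idx.sort(key=lambda i: fragments[i].index_in_record)
        for c in range(word_ids.shape[1]):
            sentences.append(EEGSentence(
                words=[int(word_ids[i, c]) for i in idx],
                record_id=rid, channel_id=c,
            ))
    return sentences


def run_experiment(
    config: PipelineConfig, records: Sequence[EEGRecord]
) -> ExperimentResult:
    """Run the full multi-context pipeline on annotated records.

    Stages: segment and label each record; balance classes and split 4:1
    (stratified, seeded); compute per-channel scalogram vectors; fit the
    enabled extractors on the training fold only; fuse the enabled blocks;
    train the SVM; evaluate on the held-out fold.  With ``out_dir`` set,
    fitted models, metrics, curves and a run log are persisted.
    """
    if not records:
        raise ValueError("no records given")
    fs = records[0].fs

    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("pipeline stage: %s", name)

    try:
        stage("segmentation")
        fragments: list[Fragment] = []
        for rec in records:
            seq = segment_record(rec, config.window_s, config.step_s)
            seq = label_fragments(seq, rec.annotations,
                                  config.min_overlap_fraction)
            fragments.extend(seq.fragments)

        stage("balance/split")
        split = balance_and_split(fragments, config.train_ratio, config.seed)
        train, test = split.train, split.test

        stage("scalogram")
        V_train = _fragment_vectors(train, fs, config)
        V_test = _fragment_vectors(test, fs, config)
        n_ch = V_train.shape[1]

        blocks_train: dict[str, np.ndarray] = {}
        blocks_test: dict[str, np.ndarray] = {}
        gpca_model = None
        sdae_models: list[SDAEModel] | None = None
        emb = None

        if "global" in config.contexts:
            stage("global PCA")
            flat_train = V_train.reshape(len(train), -1)
            flat_test = V_test.reshape(len(test), -1)
            y_train_lbl = [f.label for f in train]
            k = config.pca_k
            if config.pca_candidates:
                k = global_pca.select_k(flat_train, y_train_lbl,
                                        config.pca_candidates,
                                        seed=config.seed)
            gpca_model = global_pca.fit_gpca(flat_train, k)
            blocks_train["global"] = global_pca.transform_gpca_batch(
                gpca_model, flat_train)
            blocks_test["global"] = global_pca.transform_gpca_batch(
                gpca_model, flat_test)

        need_sdae = {"channelwise", "temporal"} & set(config.contexts)
        if need_sdae:
            stage("channel-wise SDAEs")
            corr = CorruptionConfig(fraction=config.corruption_fraction,
                                    seed=config.seed)
            sdae_models = [
                channel_sdae.train_sdae(
                    V_train[:, c, :], config.sdae_sizes, corr,
                    config.sdae_train, channel_id=c,
                )
                for c in range(n_ch)
            ]

        if "channelwise" in config.contexts:
            blocks_train["channelwise"] = np.stack([
                channel_sdae.encode_channelwise(sdae_models, V_train[i])
                for i in range(len(train))
            ])
            blocks_test["channelwise"] = np.stack([
                channel_sdae.encode_channelwise(sdae_models, V_test[i])
                for i in range(len(test))
            ])

        if "temporal" in config.contexts:
            stage("EEG embeddings")
            dict_size = sdae_models[0].dictionary_size

            def to_words(V):
                return np.array([
                    [
                        c * dict_size + channel_sdae.translate_to_word(
                            sdae_models[c], V[i, c]).word_id
                        for c in range(n_ch)
                    ]
                    for i in range(V.shape[0])
                ])

            words_train = to_words(V_train)
            words_test = to_words(V_test)
            sentences = _train_sentences(train, words_train)
            emb, _tree = eeg_embeddings.train_embeddings(
                sentences, config.embedding, q=config.embedding_dim,
                n_words=n_ch * dict_size,
            )
            blocks_train["temporal"] = np.stack([
                emb.vectors[row].mean(axis=0) for row in words_train])
            blocks_test["temporal"] = np.stack([
                emb.vectors[row].mean(axis=0) for row in words_test])

        stage("fusion")
        enabled = [b for b in BLOCK_ORDER if b in config.contexts]
        spans: dict[str, tuple[int, int]] = {}
        start = 0
        for name in enabled:
            width = blocks_train[name].shape[1]
            spans[name] = (start, start + width)
            start += width
        X_train = np.concatenate([blocks_train[n] for n in enabled], axis=1)
        X_test = np.concatenate([blocks_test[n] for n in enabled], axis=1)
        y_train = np.array([1 if f.label == ICTAL else 0 for f in train])
        y_test = np.array([1 if f.label == ICTAL else 0 for f in test])

        stage("detector training")
        svm_cfg = SVMConfig(**{**asdict(config.svm), "seed": config.seed})
        detector = train_detector(X_train, y_train, svm_cfg, block_spans=spans)

        stage("evaluation")
        report = evaluate(detector, X_test, y_test)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{current_stage}': {exc}"
        ) from exc

    result = ExperimentResult(
        report=report, detector=detector, split=split, block_spans=spans,
        sdae_models=sdae_models, gpca_model=gpca_model, embedding=emb,
    )
    if config.out_dir:
        _persist(config, result)
    return result


def _persist(config: PipelineConfig, result: ExperimentResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(result.report.as_dict(), fh, indent=2)
    np.savetxt(out / "roc_curve.csv", result.report.roc_curve,
               delimiter=",", header="fpr,tpr", comments="")
    np.savetxt(out / "pr_curve.csv", result.report.pr_curve,
               delimiter=",", header="recall,precision", comments="")
    if result.gpca_model is not None:
        global_pca.save_gpca(result.gpca_model, out / "gpca.npz")
    if result.sdae_models:
        for m in result.sdae_models:
            channel_sdae.save_sdae(m, out / f"sdae_ch{m.channel_id}.npz")
    if result.embedding is not None:
        dict_size = (result.sdae_models[0].dictionary_size
                     if result.sdae_models else None)
        eeg_embeddings.save_embeddings(result.embedding,
                                       out / "embeddings.txt", dict_size)
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_train": len(result.split.train),
                "n_test": len(result.split.test),
                "block_spans": result.block_spans,
            },
            fh, indent=2, default=str,
        )
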