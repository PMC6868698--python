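"""Cross-validation protocol, metric suite and case-study ranking.

Evaluation follows the standard link-prediction recipe: the known
associations are the positives, an equal number of unknown pairs is drawn
uniformly as negatives (once per experiment), and stratified tenfold
cross-validation is run.  In every fold the association matrix is re-made
into a training view with the fold's positive entries zeroed, and kernels,
cluster enhancement, fusion, encoder and classifier are all recomputed from
that view only, so no information about test pairs leaks into training.
``paper_mode`` disables the per-fold recomputation and derives similarities
once from the full matrix (the optimistic variant some published protocols
use).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierConfig
from .dataio import AssociationMatrix, SimilarityMatrix
from .features import EncoderConfig
from .model import ClusterParams, DrugDiseaseModel
from .similarity import KernelParams, LogisticParams

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "EvalReport",
    "sample_negatives",
    "compute_metrics",
    "roc_auc",
    "make_folds",
    "run_cross_validation",
    "rank_candidates_for_disease",
]

Pair = tuple[str, str, int]


@dataclass
class FoldSplit:
    """Training and test pairs of one cross-validation fold."""

    fold_id: int
    train_pairs: list[Pair]
    test_pairs: list[Pair]


def sample_negatives(A: AssociationMatrix, n: int, seed: int) -> list[Pair]:
    """Uniform sample without replacement of n unknown (zero) cells of A."""
    zero = np.argwhere(A.values == 0)
    if n > len(zero):
        raise ValueError(f"requested {n} negatives but only {len(zero)} zero cells exist")
    rng = np.random.default_rng(seed)
    chosen = zero[rng.choice(len(zero), size=n, replace=False)]
    return [(A.drug_ids[j], A.disease_ids[i], 0) for i, j in chosen]


def compute_metrics(labels, predictions) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall and F1 from hard 0/1 predictions.

    Precision is 0 (with a warning) when nothing is predicted positive, and
    F1 is 0 when precision + recall is 0.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("labels and predictions must be equal-length and non-empty")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    acc = (tp + tn) / y.size
    if tp + fp == 0:
        logger.warning("no predicted positives; precision set to 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return acc, prec, rec, f1


def roc_auc(labels, scores) -> tuple[np.ndarray, float]:
    """ROC points and AUC by the midrank Mann-Whitney formulation.

    AUC is the probability a random positive outscores a random negative,
    with ties counted half; the ROC polyline is returned as (fpr, tpr) rows.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC needs both classes present")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(y[order] == 1)
    fps = np.cumsum(y[order] == 0)
    # collapse threshold ties to the last point of each distinct score
    distinct = np.r_[np.nonzero(np.diff(s[order]))[0], len(s) - 1]
    roc = np.column_stack([fps[distinct] / n_neg, tps[distinct] / n_pos])
    roc = np.vstack([[0.0, 0.0], roc])
    return roc, float(auc)


def make_folds(samples: list[Pair], k: int, seed: int) -> list[FoldSplit]:
    """Stratified k-fold split: positives spread evenly (counts differ <= 1)."""
    labels = np.array([lab for _, _, lab in samples])
    if int((labels == 1).sum()) < k:
        raise ValueError(f"need at least {k} positives for {k}-fold cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(samples)), labels), start=1):
        folds.append(
            FoldSplit(fold_id, [samples[i] for i in tr], [samples[i] for i in te])
        )
    return folds


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics (percent scale)."""

    fold_metrics: pd.DataFrame  # columns: fold, acc, prec, recall, f1 (percent), auc
    roc_points: list[np.ndarray]
    seed: int
    split_manifest: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.fold_metrics[["acc", "prec", "recall", "f1", "auc"]].mean()

    @property
    def std(self) -> pd.Series:
        return self.fold_metrics[["acc", "prec", "recall", "f1", "auc"]].std(ddof=1)

    def summary(self) -> str:
        lines = ["fold\tAcc.(%)\tPrec.(%)\tRecall(%)\tF1(%)\tAUC"]
        for _, r in self.fold_metrics.iterrows():
            lines.append(
                f"{int(r['fold'])}\t{r['acc']:.2f}\t{r['prec']:.2f}"
                f"\t{r['recall']:.2f}\t{r['f1']:.2f}\t{r['auc']:.4f}"
            )
        m, s = self.mean, self.std
        lines.append(
            f"Average\t{m['acc']:.2f} ± {s['acc']:.2f}\t{m['prec']:.2f} ± {s['prec']:.2f}"
            f"\t{m['recall']:.2f} ± {s['recall']:.2f}\t{m['f1']:.2f} ± {s['f1']:.2f}"
            f"\t{m['auc']:.4f} ± {s['auc']:.4f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "folds": self.fold_metrics.to_dict(orient="records"),
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            "split_manifest": self.split_manifest,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _training_view(A: AssociationMatrix, test_pairs: list[Pair]) -> AssociationMatrix:
    """Copy of A with the test positives zeroed out."""
    view = A.copy()
    for drug_id, disease_id, label in test_pairs:
        if label == 1:
            view.values[view.disease_index(disease_id), view.drug_index(drug_id)] = 0
    return view


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


def run_cross_validation(
    A: AssociationMatrix,
    drug_similarity: SimilarityMatrix,
    disease_similarity: SimilarityMatrix,
    *,
    k: int = 10,
    seed: int = 0,
    negative_ratio: float = 1.0,
    paper_mode: bool = False,
    shuffle_labels: bool = False,
    threshold: float = 0.5,
    kernel_params: KernelParams = KernelParams(),
    logistic_params: LogisticParams = LogisticParams(),
    cluster_params: ClusterParams = ClusterParams(),
    encoder_config: EncoderConfig | None = None,
    classifier_config: ClassifierConfig = ClassifierConfig(),
) -> EvalReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Negatives are sampled once per experiment at ``negative_ratio`` times
    the positive count.  Unless ``paper_mode`` is set, every similarity is
    recomputed per fold from the training view.  ``shuffle_labels`` runs
    the permutation null: sample labels are permuted over the same pairs,
    which should drive AUC to chance for any leakage-free pipeline.
    """
    positives = [
        (A.drug_ids[j], A.disease_ids[i], 1) for i, j in np.argwhere(A.values == 1)
    ]
    n_neg = int(round(negative_ratio * len(positives)))
    negatives = sample_negatives(A, n_neg, _stage_seed(seed, "negatives"))
    samples = positives + negatives
    if shuffle_labels:
        rng = np.random.default_rng(_stage_seed(seed, "shuffle"))
        perm = rng.permutation([lab for _, _, lab in samples])
        samples = [(d, e, int(lab)) for (d, e, _), lab in zip(samples, perm)]
    folds = make_folds(samples, k, _stage_seed(seed, "folds"))

    shared = None
    if paper_mode:
        shared = DrugDiseaseModel(
            A, drug_similarity, disease_similarity,
            kernel_params=kernel_params, logistic_params=logistic_params,
            cluster_params=cluster_params,
        ).fused_similarities()

    rows = []
    rocs = []
    manifest = []
    for fold in folds:
        view = A if paper_mode else _training_view(A, fold.test_pairs)
        fold_seed = _stage_seed(seed, f"fold{fold.fold_id}")
        model = DrugDiseaseModel(
            view, drug_similarity, disease_similarity,
            kernel_params=kernel_params,
            logistic_params=logistic_params,
            cluster_params=cluster_params,
            encoder_config=encoder_config,
            classifier_config=classifier_config,
            precomputed=shared,
        )
        res = model.fit(
            [(d, e) for d, e, _ in fold.train_pairs],
            [lab for _, _, lab in fold.train_pairs],
            seed=fold_seed,
        )
        test_xy = [(d, e) for d, e, _ in fold.test_pairs]
        test_y = [lab for _, _, lab in fold.test_pairs]
        scores = res.score_pairs(test_xy)
        preds = (scores >= threshold).astype(int)
        acc, prec, rec, f1 = compute_metrics(test_y, preds)
        roc, auc = roc_auc(test_y, scores)
        rows.append(
            {"fold": fold.fold_id, "acc": 100 * acc, "prec": 100 * prec,
             "recall": 100 * rec, "f1": 100 * f1, "auc": auc}
        )
        rocs.append(roc)
        manifest.append(
            {"fold": fold.fold_id,
             "test_pairs": [[d, e, int(lab)] for d, e, lab in fold.test_pairs]}
        )
        logger.info("fold %d: acc %.2f%%, auc %.4f", fold.fold_id, rows[-1]["acc"], auc)
    return EvalReport(pd.DataFrame(rows), rocs, seed, manifest)


def rank_candidates_for_disease(
    A: AssociationMatrix,
    drug_similarity: SimilarityMatrix,
    disease_similarity: SimilarityMatrix,
    disease_id: str,
    *,
    seed: int = 0,
    negative_ratio: float = 1.0,
    kernel_params: KernelParams = KernelParams(),
    logistic_params: LogisticParams = LogisticParams(),
    cluster_params: ClusterParams = ClusterParams(),
    encoder_config: EncoderConfig | None = None,
    classifier_config: ClassifierConfig = ClassifierConfig(),
) -> list[tuple[str, str, float]]:
    """Leave-one-disease-out candidate ranking.

    All associations of the target disease are removed from the training
    view; the model trains on the remaining positives plus balanced sampled
    negatives (never touching the target disease's cells) and every drug is
    then scored against the target and returned in descending order.
    """
    di = A.disease_index(disease_id)
    view = A.copy()
    view.values[di, :] = 0

    positives = [
        (view.drug_ids[j], view.disease_ids[i], 1)
        for i, j in np.argwhere(view.values == 1)
    ]
    # candidate negatives exclude the target disease's row entirely
    masked = view.copy()
    masked.values[di, :] = 1  # mark as non-sampleable
    n_neg = int(round(negative_ratio * len(positives)))
    negatives = sample_negatives(masked, n_neg, _stage_seed(seed, "negatives"))

    samples = positives + negatives
    model = DrugDiseaseModel(
        view, drug_similarity, disease_similarity,
        kernel_params=kernel_params,
        logistic_params=logistic_params,
        cluster_params=cluster_params,
        encoder_config=encoder_config,
        classifier_config=classifier_config,
    )
    res = model.fit(
        [(d, e) for d, e, _ in samples],
        [lab for _, _, lab in samples],
        seed=_stage_seed(seed, "casestudy"),
    )
    return res.rank_drugs(disease_id)
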