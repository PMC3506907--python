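"""Supervised per-TF inference (SIRENE-style).

One binary classifier is trained per transcription factor: genes are the
instances (feature vector = the gene's expression profile across samples),
the TF's known targets are the positives and all remaining genes are
treated as negatives. Scores come from k-fold cross-validation over genes,
so each gene is scored by a classifier that never saw its label. Positive
decision values indicate predicted interactions; the magnitude reflects
confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .simulator import ExpressionDataset
from .unsupervised import ScoreMatrix

logger = logging.getLogger("grnbench.supervised")


@dataclass
class TrainingSet:
    """Known (TF, target) interactions used to train per-TF classifiers."""

    positives: set[tuple[str, str]]
    tfs: list[str]
    negatives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        tf_set = set(self.tfs)
        for tf, tgt in self.positives | self.negatives:
            if tf not in tf_set:
                raise ValueError(f"pair ({tf}, {tgt}) uses unlisted TF")
            if tf == tgt:
                raise ValueError(f"self-pair ({tf}, {tgt}) not allowed")
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")

    def targets_of(self, tf: str) -> set[str]:
        return {t for (r, t) in self.positives if r == tf}


def _standardize_profiles(x: np.ndarray) -> np.ndarray:
    """Z-score each instance (gene profile) so distances reflect shape.

    After per-gene standardization, squared Euclidean distance between two
    profiles is an affine function of their Pearson correlation, which is
    the similarity the regulon structure lives in; absolute expression
    levels carry no regulatory information here.
    """
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _feature_matrix(values: np.ndarray, features: str) -> np.ndarray:
    """Instance features per gene: raw profile shape or |correlation| map.

    ``abscorr`` embeds each gene as its vector of absolute Pearson
    correlations to every gene. A regulon usually mixes activated and
    repressed targets, whose profiles are anti-correlated; taking the
    magnitude folds both onto the same side so a single classifier can
    learn regulon membership regardless of regulation sign. ``profile``
    uses the z-scored expression profile directly.
    """
    if features == "profile":
        return _standardize_profiles(values)
    if features == "abscorr":
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(values)
        return np.abs(np.nan_to_num(c, nan=0.0))
    raise ValueError(f"unknown feature representation {features!r}")


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise Euclidean distance."""
    d = pdist(x)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    med = float(np.median(d))
    return 1.0 / (2.0 * med ** 2)


def train_and_score(data: ExpressionDataset,
                    training: TrainingSet,
                    folds: int = 3,
                    min_positives: int = 2,
                    C: float = 1.0,
                    gamma: float | str = "median",
                    cv_repeats: int = 3,
                    features: str = "abscorr",
                    seed: int = 0) -> ScoreMatrix:
    """Cross-validated per-TF SVM scoring of all candidate targets.

    For every TF with at least ``min_positives`` known targets present in
    the data, an RBF-kernel SVM with balanced class weights is trained under
    stratified k-fold cross-validation over genes; the edge weight
    TF -> gene is the decision value assigned to that gene by folds that
    held it out, averaged over ``cv_repeats`` independent random splits
    (repeat-averaging reduces the variance of the decision values). TFs
    below ``min_positives`` are skipped (logged); only trained TFs
    contribute score rows.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    gene_index = {g: i for i, g in enumerate(data.gene_ids)}
    missing = [tf for tf in training.tfs if tf not in gene_index]
    if missing:
        raise ValueError(f"TFs without expression data: {missing}")

    x_all = _feature_matrix(data.values, features)  # rows are instances
    g = data.n_genes
    scores = np.zeros((g, g))
    trained: list[str] = []
    skipped: list[str] = []
    rng = np.random.default_rng(seed)

    for tf in training.tfs:
        targets = {t for t in training.targets_of(tf) if t in gene_index}
        if len(targets) < min_positives:
            skipped.append(tf)
            continue
        inst = [gi for gi in data.gene_ids if gi != tf]
        x = x_all[[gene_index[gi] for gi in inst]]
        y = np.array([1 if gi in targets else 0 for gi in inst])
        n_pos = int(y.sum())
        n_splits = min(folds, n_pos, int((y == 0).sum()))
        if n_splits < 2:
            logger.warning("sirene: TF %s cannot be stratified into >= 2 "
                           "folds; skipped", tf)
            skipped.append(tf)
            continue
        if n_splits < folds:
            logger.info("sirene: TF %s re-stratified from %d to %d folds",
                        tf, folds, n_splits)
        gam = _median_heuristic_gamma(x) if gamma == "median" else gamma
        decision = np.zeros(len(inst))
        for _ in range(cv_repeats):
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=int(rng.integers(2 ** 31 - 1)))
            for train_idx, test_idx in cv.split(x, y):
                clf = SVC(kernel="rbf", C=C, gamma=gam,
                          class_weight="balanced")
                clf.fit(x[train_idx], y[train_idx])
                decision[test_idx] += clf.decision_function(x[test_idx])
        decision /= cv_repeats
        row = gene_index[tf]
        for gi, d in zip(inst, decision):
            scores[row, gene_index[gi]] = d
        trained.append(tf)

    if skipped:
        logger.info("sirene: skipped TFs (below min_positives or "
                    "unstratifiable): %s", skipped)
    return ScoreMatrix(values=scores, gene_ids=list(data.gene_ids),
                       directed=True, method="sirene",
                       params={"folds": folds, "min_positives": min_positives,
                               "C": C, "gamma": gamma, "seed": seed,
                               "cv_repeats": cv_repeats, "features": features,
                               "skipped_tfs": skipped},
                       regulators=trained)


def high_confidence(scores: ScoreMatrix,
                    threshold: float = 0.5
                    ) -> list[tuple[str, str, float]]:
    """Edges with weight >= threshold, sorted by descending weight."""
    rows = scores.regulators if scores.regulators is not None \
        else scores.gene_ids
    index = {g: i for i, g in enumerate(scores.gene_ids)}
    out = []
    for tf in rows:
        i = index[tf]
        for j, tgt in enumerate(scores.gene_ids):
            if i == j:
                continue
            w = scores.values[i, j]
            if w >= threshold:
                out.append((tf, tgt, float(w)))
    out.sort(key=lambda e: (-e[2], e[0], e[1]))
    return out
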