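"""Classification metrics, ROC/AUC statistics and map visualizations.

Covers the evaluation battery for the patch classifiers: confusion matrices
with row-normalized percentage views; per-class prediction percentage
(recall), mean correct-class probability and one-vs-rest sensitivity and
specificity with micro/macro averages; one-vs-rest ROC curves with the
pairwise (Mann-Whitney) AUC; DeLong's structural-components test for paired
AUC differences; the 2x2 Pearson chi-square for accuracy comparisons; the
nerve/parotid-style two-class restriction of a multiclass classifier; and
tile-level prediction label maps and probability heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .classifier import PredictionBatch
from .patchwork import PATCH

logger = logging.getLogger(__name__)

ALPHA = 0.001  # critical alpha level for significance statements


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percentages(self) -> np.ndarray:
        """Row-normalized percentages; zero-support rows are NaN (flagged)."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, 100.0 * self.counts / row, np.nan)

    def micro_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.percentages() if percent else self.counts
        return pd.DataFrame(data, index=list(self.class_names),
                            columns=list(self.class_names))

    def to_csv(self, path: str | Path, percent: bool = True) -> None:
        self.to_frame(percent=percent).to_csv(path, na_rep="NA")


@dataclass
class ClassMetrics:
    """Per-class and averaged accuracy/probability metrics."""

    per_class: pd.DataFrame  # class, n, prediction_pct, probability_pct, sensitivity, specificity
    micro_accuracy: float
    macro_accuracy: float
    micro_probability: float
    macro_probability: float

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        avg = pd.DataFrame([
            {"class": "macroaverage", "prediction_pct": self.macro_accuracy * 100,
             "probability_pct": self.macro_probability * 100},
            {"class": "microaverage", "prediction_pct": self.micro_accuracy * 100,
             "probability_pct": self.micro_probability * 100},
        ])
        return pd.concat([df, avg], ignore_index=True)


def confusion_and_metrics(preds: PredictionBatch) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Confusion matrix plus the full per-class metric battery.

    Micro accuracy is total correct / total patches; macro accuracy is the
    unweighted mean of per-class recalls over classes with support.
    """
    labels = preds.labels
    K = preds.n_classes
    if labels.size == 0:
        raise ValueError("empty prediction batch")
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError("true label outside [0, K)")
    predicted = preds.predicted
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (labels, predicted), 1)
    cm = ConfusionMatrix(counts=counts, class_names=preds.class_names)

    correct_p = preds.correct_probs()
    rows = []
    recalls, probs = [], []
    for k in range(K):
        mask = labels == k
        n_k = int(mask.sum())
        pos_pred = predicted == k
        tp = int((mask & pos_pred).sum())
        fn = int(mask.sum()) - tp
        fp = int((~mask & pos_pred).sum())
        tn = labels.size - tp - fn - fp
        recall = tp / n_k if n_k else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        mean_p = float(correct_p[mask].mean()) if n_k else np.nan
        rows.append({"class": preds.class_names[k], "n": n_k,
                     "prediction_pct": 100.0 * recall if n_k else np.nan,
                     "probability_pct": 100.0 * mean_p if n_k else np.nan,
                     "sensitivity": recall, "specificity": spec})
        if n_k:
            recalls.append(recall)
            probs.append(mean_p)
    metrics = ClassMetrics(
        per_class=pd.DataFrame(rows),
        micro_accuracy=float(np.mean(predicted == labels)),
        macro_accuracy=float(np.mean(recalls)),
        micro_probability=float(correct_p.mean()),
        macro_probability=float(np.mean(probs)),
    )
    assert abs(metrics.micro_accuracy - cm.micro_accuracy()) < 1e-12
    return cm, metrics


def pairwise_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUC by the pairwise definition: (concordant + 0.5 ties) / (n+ n-).

    Computed via average ranks, which is algebraically identical and O(n log n).
    """
    pos = np.asarray(positives, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_one_vs_rest(preds: PredictionBatch, k: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC for class k: (fpr, tpr, thresholds, auc).

    Curve points are taken at every distinct score threshold (no
    interpolation); the AUC is the pairwise statistic, so ties contribute
    one half.  Returns NaN AUC when the batch contains a single class.
    """
    scores = preds.probs[:, k]
    pos = preds.labels == k
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    auc = pairwise_auc(scores, pos)
    if n_pos == 0 or n_neg == 0:
        logger.warning("roc_one_vs_rest: class %d has no %s examples", k,
                       "positive" if n_pos == 0 else "negative")
        return (np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.array([np.inf, -np.inf]),
                auc)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    pos_sorted = pos[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(pos_sorted)[cut]
    fp = np.cumsum(~pos_sorted)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    return fpr, tpr, thresholds, auc


@dataclass
class DeLongResult:
    """Paired comparison of two correlated AUCs by DeLong's method."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    x = scores[pos]
    y = scores[~pos]
    # rank-based midrank placements
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    m, n = x.size, y.size
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    return v10, v01


def delong_auc_test(scores_a: np.ndarray, scores_b: np.ndarray,
                    labels: np.ndarray) -> DeLongResult:
    """Two-sided DeLong test for the AUC difference of paired scores.

    ``labels`` marks positives (nonzero) on the same instances for both
    score vectors.  AUCs come from placement values; the variance of the
    difference uses the structural-components covariance estimator.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    pos = np.asarray(labels).astype(bool)
    m, n = int(pos.sum()), int((~pos).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    v10a, v01a = _placements(scores_a, pos)
    v10b, v01b = _placements(scores_b, pos)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    cov_ab = s10[0, 1] / m + s01[0, 1] / n
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 0:
        z = 0.0 if np.isclose(auc_a, auc_b) else np.inf * np.sign(auc_a - auc_b)
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_a=float(var_a),
                        var_b=float(var_b), cov_ab=float(cov_ab), z=float(z),
                        p_value=p)


def chi_square_2x2(correct_a: int, wrong_a: int, correct_b: int, wrong_b: int
                   ) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    o = np.array([[correct_a, wrong_a], [correct_b, wrong_b]], dtype=float)
    if np.any(o < 0):
        raise ValueError("counts must be >= 0")
    row = o.sum(axis=1, keepdims=True)
    col = o.sum(axis=0, keepdims=True)
    total = o.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("both margins must be positive")
    e = row @ col / total
    statistic = float(((o - e) ** 2 / e).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


@dataclass
class BinaryTaskResult:
    """Two-class restriction of a multiclass classifier.

    Probabilities of the two chosen classes are renormalized to sum to 1;
    patches whose two probabilities are both zero are excluded (counted).
    """

    preds: PredictionBatch  # binary batch: probs (N, 2), labels in {0, 1}
    class_pair: tuple[str, str]
    n_excluded: int
    per_class: pd.DataFrame  # prediction_pct, probability_pct per class


def binarize_two_class(preds: PredictionBatch, i: int, j: int) -> BinaryTaskResult:
    """Restrict evaluation to classes i and j and renormalize their probabilities.

    Only patches whose true label is i or j are evaluated.  For each such
    patch, p'_i = p_i / (p_i + p_j); prediction is the larger probability
    (tie -> lower class index).
    """
    if i == j:
        raise ValueError("class pair must be distinct")
    mask = (preds.labels == i) | (preds.labels == j)
    if not mask.any():
        raise ValueError("no patches of the requested class pair")
    pi = preds.probs[mask, i]
    pj = preds.probs[mask, j]
    denom = pi + pj
    valid = denom > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("binarize_two_class: %d patches excluded (p_i + p_j = 0)",
                       n_excluded)
    pi, pj = pi[valid], pj[valid]
    labels01 = (preds.labels[mask][valid] == j).astype(np.int64)
    probs = np.column_stack([pi / (pi + pj), pj / (pi + pj)])
    pair_names = (preds.class_names[i], preds.class_names[j])
    batch = PredictionBatch(probs=probs, labels=labels01, class_names=pair_names)
    rows = []
    for b, name in enumerate(pair_names):
        m = labels01 == b
        rows.append({
            "class": name,
            "n": int(m.sum()),
            "prediction_pct": 100.0 * float((batch.predicted[m] == b).mean()) if m.any() else np.nan,
            "probability_pct": 100.0 * float(probs[m, b].mean()) if m.any() else np.nan,
        })
    return BinaryTaskResult(preds=batch, class_pair=pair_names,
                            n_excluded=n_excluded, per_class=pd.DataFrame(rows))


@dataclass
class RenderedMap:
    """A tile-colored canvas aligned with the 32 x 32 patch grid."""

    canvas: np.ndarray  # (H, W, 3) float RGB in [0, 1]
    kind: str  # "label_map" | "probability_heatmap"
    legend: dict

    def save(self, path: str | Path) -> None:
        from PIL import Image  # noqa: PLC0415

        img = (np.clip(self.canvas, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img).save(path)


BACKGROUND_GRAY = (0.5, 0.5, 0.5)


def _class_colors(n: int) -> np.ndarray:
    from matplotlib import colormaps  # noqa: PLC0415

    cmap = colormaps["tab20"] if n > 10 else colormaps["tab10"]
    return np.array([cmap(i % cmap.N)[:3] for i in range(n)])


def render_maps(shape_hw: tuple[int, int], preds: PredictionBatch,
                mode: str = "label_map") -> RenderedMap:
    """Color each predicted tile on an image-sized canvas.

    ``preds.coords`` must carry the tile-grid origins produced by the tiler.
    ``label_map`` colors tiles by predicted class; ``probability_heatmap``
    colors by correct-class probability on a fixed [0, 1] sequential scale.
    Background / dropped tiles are gray.
    """
    from matplotlib import colormaps  # noqa: PLC0415

    if preds.coords is None:
        raise ValueError("predictions carry no tile coordinates")
    H, W = shape_hw
    nrow, ncol = H // PATCH, W // PATCH
    canvas = np.empty((H, W, 3), dtype=float)
    canvas[:] = BACKGROUND_GRAY
    if mode == "label_map":
        colors = _class_colors(preds.n_classes)
        legend = {name: tuple(float(v) for v in colors[k])
                  for k, name in enumerate(preds.class_names)}
        values = colors[preds.predicted]
    elif mode == "probability_heatmap":
        cmap = colormaps["viridis"]
        legend = {"scale": "correct-class probability, 0 -> 1", "cmap": "viridis"}
        values = np.array([cmap(p)[:3] for p in preds.correct_probs()])
    else:
        raise ValueError(f"unknown map mode {mode!r}")
    for (r, c), color in zip(preds.coords, values):
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError(f"tile coordinate ({r}, {c}) outside scene grid")
        canvas[r * PATCH:(r + 1) * PATCH, c * PATCH:(c + 1) * PATCH] = color
    return RenderedMap(canvas=canvas, kind=mode, legend=legend)
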