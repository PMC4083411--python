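"""Unseen-protein cross-validation and the binary-classification metric suite.

Metrics follow the standard confusion-matrix definitions with the
stabilising class (ddGu >= 0) as positive:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    Q2  = (TP+TN)/total * 100
    Se  = TP/(TP+FN) * 100        Sp  = TN/(TN+FP) * 100
    PPV = TP/(TP+FP) * 100        NPV = TN/(TN+FN) * 100

AUC is the area under the ROC curve (equivalently the Mann-Whitney
probability that a random positive outscores a random negative, ties 1/2).
Cross-validation is homology-aware: all mutations of a cluster of homologous
proteins stay within one fold, and the fold generator balances both fold
sizes and class ratios.  Experiments are replicated with fresh random folds
and summarised with paired t-tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

#: Acceptable |fold positive-rate - global positive-rate| for generated folds.
RATIO_TOLERANCE = 0.15


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    mcc: float
    q2: float
    se: float
    sp: float
    ppv: float
    npv: float
    auc: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {"MCC": self.mcc, "Q2": self.q2, "Se": self.se, "Sp": self.sp,
                "PPV": self.ppv, "NPV": self.npv, "AUC": self.auc}


def confusion(labels: Sequence, predictions: Sequence) -> ConfusionCounts:
    """Tally a confusion matrix; truthy = stabilising = positive."""
    y = np.asarray([bool(v) for v in labels])
    p = np.asarray([bool(v) for v in predictions])
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum(y & p)), tn=int(np.sum(~y & ~p)),
        fp=int(np.sum(~y & p)), fn=int(np.sum(y & ~p)),
    )


def _rate(num: int, den: int) -> float:
    # zero-denominator rates are undefined, reported as NaN, never raised
    return 100.0 * num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts) -> MetricSet:
    """The metric suite (without AUC) from a confusion matrix.

    MCC with any zero marginal is defined as 0; percentage rates with a zero
    denominator are NaN (undefined-marked).
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = ((c.tp * c.tn - c.fp * c.fn) / denom) if denom > 0 else 0.0
    return MetricSet(
        mcc=mcc,
        q2=100.0 * (c.tp + c.tn) / c.total,
        se=_rate(c.tp, c.tp + c.fn),
        sp=_rate(c.tn, c.tn + c.fp),
        ppv=_rate(c.tp, c.tp + c.fp),
        npv=_rate(c.tn, c.tn + c.fn),
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR step points over all thresholds) and its area."""
    y = np.asarray([bool(v) for v in labels])
    s = np.asarray(scores, float)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(roc_auc_score(y, s))


def optimize_threshold(scores: Sequence[float], labels: Sequence) -> float:
    """Threshold (predict positive iff score >= t) maximising MCC.

    Candidates are the midpoints between consecutive sorted unique scores
    plus one candidate below the minimum and one above the maximum; ties in
    MCC keep the lowest threshold.
    """
    y = np.asarray([bool(v) for v in labels])
    s = np.asarray(scores, float)
    if y.all() or not y.any():
        raise ValueError("threshold optimisation needs both classes")
    u = np.unique(s)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    best_t, best_mcc = candidates[0], -np.inf
    for t in candidates:
        m = metrics(confusion(y, s >= t)).mcc
        if m > best_mcc:
            best_t, best_mcc = t, m
    return float(best_t)


@dataclass
class FoldAssignment:
    """cluster_id -> fold index (1..k); never splits a cluster."""

    assignment: Dict[str, int]
    k: int

    def fold_of(self, cluster_id: str) -> int:
        return self.assignment[cluster_id]

    def folds(self) -> List[List[str]]:
        out: List[List[str]] = [[] for _ in range(self.k)]
        for cid, f in self.assignment.items():
            out[f - 1].append(cid)
        return out


def make_unseen_protein_folds(
    cluster_sizes: Dict[str, int],
    cluster_positives: Dict[str, int],
    k: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Greedy balanced assignment of homology clusters to k folds.

    Clusters are placed largest-first into the fold minimising a cost that
    weighs mutation-count imbalance and positive-rate deviation equally;
    equal-cost choices are broken by a seeded shuffle.  No cluster is ever
    split across folds.
    """
    clusters = list(cluster_sizes)
    if len(clusters) < k:
        raise ValueError(f"{len(clusters)} clusters cannot fill {k} folds")
    if k < 2:
        raise ValueError("k must be >= 2")
    total_n = sum(cluster_sizes.values())
    total_pos = sum(cluster_positives.get(c, 0) for c in clusters)
    global_rate = total_pos / total_n if total_n else 0.0
    target = total_n / k

    rng = np.random.default_rng(seed)
    rng.shuffle(clusters)
    clusters.sort(key=lambda c: -cluster_sizes[c])  # stable: ties keep shuffle order

    fold_n = np.zeros(k)
    fold_pos = np.zeros(k)
    assignment: Dict[str, int] = {}
    for cid in clusters:
        n_c = cluster_sizes[cid]
        p_c = cluster_positives.get(cid, 0)
        costs = np.empty(k)
        for f in range(k):
            n_after = fold_n[f] + n_c
            rate_after = (fold_pos[f] + p_c) / n_after
            # load fraction, so lighter folds always look cheaper
            size_cost = n_after / max(target, 1.0)
            ratio_cost = abs(rate_after - global_rate)
            costs[f] = size_cost + ratio_cost
        best = np.flatnonzero(costs <= costs.min() + 1e-12)
        f = int(rng.choice(best))
        assignment[cid] = f + 1
        fold_n[f] += n_c
        fold_pos[f] += p_c
    # guarantee no empty fold (possible when a few giant clusters dominate)
    for f in range(k):
        if fold_n[f] == 0:
            donor = int(np.argmax(fold_n))
            movable = [c for c, g in assignment.items() if g == donor + 1]
            c = min(movable, key=lambda c: cluster_sizes[c])
            assignment[c] = f + 1
            fold_n[f] += cluster_sizes[c]
            fold_n[donor] -= cluster_sizes[c]
    return FoldAssignment(assignment, k)


@dataclass
class ReplicationReport:
    """Per-replicate metrics and their aggregate summary."""

    replicates: List[MetricSet]
    method: str = ""

    def series(self, name: str) -> np.ndarray:
        return np.array([m.as_dict()[name] for m in self.replicates])

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.series(name)))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self.series(name), ddof=1)) if len(self.replicates) > 1 else 0.0

    def summary(self) -> Dict[str, Tuple[float, float]]:
        return {k: (self.mean(k), self.sd(k)) for k in
                ("AUC", "MCC", "Q2", "Se", "Sp", "PPV", "NPV")}

    def write(self, path) -> None:
        names = ("AUC", "MCC", "Q2", "Se", "Sp", "PPV", "NPV")
        with open(path, "w") as fh:
            fh.write("replicate\t" + "\t".join(names) + "\n")
            for i, m in enumerate(self.replicates, 1):
                d = m.as_dict()
                fh.write(f"{i}\t" + "\t".join(f"{d[n]:.6f}" for n in names) + "\n")
            fh.write("mean\t" + "\t".join(f"{self.mean(n):.6f}" for n in names) + "\n")
            fh.write("sd\t" + "\t".join(f"{self.sd(n):.6f}" for n in names) + "\n")


FitScore = Callable[[np.ndarray], Callable[[np.ndarray], np.ndarray]]


def cross_validate(
    y: Sequence,
    record_clusters: Sequence[str],
    fit: FitScore,
    k: int = 10,
    reps: int = 100,
    seed: int = 0,
    max_redraws: int = 10,
) -> ReplicationReport:
    """Replicated unseen-protein k-fold cross-validation.

    ``fit(train_idx)`` must return a ``score(idx) -> stabilising scores``
    closure.  Per replicate: fresh seeded folds; per fold, the method is
    fitted on the out-of-fold records, a decision threshold is optimised for
    maximum MCC on the *training* scores, and the held-out fold is scored;
    pooled held-out scores and thresholded labels give the replicate's
    MetricSet (AUC from the pooled scores).  A replicate whose folds leave a
    single-class training set is redrawn with a fresh seed (logged).
    """
    y = np.asarray([bool(v) for v in y])
    record_clusters = np.asarray(record_clusters)
    n = len(y)
    cluster_ids = sorted(set(record_clusters))
    sizes = {c: int(np.sum(record_clusters == c)) for c in cluster_ids}
    positives = {c: int(np.sum(y[record_clusters == c])) for c in cluster_ids}

    replicates: List[MetricSet] = []
    rep_seed = seed
    for rep in range(reps):
        for attempt in range(max_redraws):
            folds = make_unseen_protein_folds(sizes, positives, k=k, seed=rep_seed)
            rep_seed += 1
            fold_of_record = np.array(
                [folds.fold_of(c) for c in record_clusters]
            )
            try:
                scores = np.empty(n)
                preds = np.empty(n, bool)
                for f in range(1, k + 1):
                    te = fold_of_record == f
                    tr = ~te
                    if not te.any():
                        continue
                    if len(np.unique(y[tr])) < 2:
                        raise ValueError("single-class training fold")
                    scorer = fit(np.flatnonzero(tr))
                    train_scores = scorer(np.flatnonzero(tr))
                    t = optimize_threshold(train_scores, y[tr])
                    s = scorer(np.flatnonzero(te))
                    scores[te] = s
                    preds[te] = s >= t
                break
            except ValueError as exc:
                logger.info("replicate %d redrawn: %s", rep, exc)
        else:
            raise ValueError(f"replicate {rep}: no valid fold assignment found")
        m = metrics(confusion(y, preds))
        m.auc = roc_auc(scores, y)[2]
        replicates.append(m)
    return ReplicationReport(replicates)


# ---------------------------------------------------------------------------
# Per-category breakdowns
# ---------------------------------------------------------------------------

ASA_TWO_BINS = ("<=25%", ">25%")
ASA_FOUR_BINS = ("0-20%", "20-40%", "40-60%", ">60%")
DDG_BINS = ("small", "large")


def asa_two_bin(rasa: float) -> str:
    return ASA_TWO_BINS[0] if rasa <= 0.25 else ASA_TWO_BINS[1]


def asa_four_bin(rasa: float) -> str:
    """Bins [0,20), [20,40), [40,60), [60,100] of relative ASA."""
    if rasa < 0.20:
        return ASA_FOUR_BINS[0]
    if rasa < 0.40:
        return ASA_FOUR_BINS[1]
    if rasa < 0.60:
        return ASA_FOUR_BINS[2]
    return ASA_FOUR_BINS[3]


def ddg_bin(ddg: float) -> str:
    """'small' stability changes are ddGu in the closed interval [-1, 1]."""
    return DDG_BINS[0] if -1.0 <= ddg <= 1.0 else DDG_BINS[1]


def category_breakdown(
    labels: Sequence,
    predictions: Sequence,
    scores: Sequence[float],
    bins: Dict[str, Sequence[str]],
) -> Dict[Tuple[str, str], Optional[MetricSet]]:
    """Metric suite within true-structure / ddG-magnitude bins.

    ``bins`` maps a table name (e.g. ``"ss"``, ``"asa2"``, ``"ddg"``) to a
    per-record bin label array, normally derived from experimentally
    determined structure, never from the routing predictions.  An empty bin
    yields None (undefined-marked, not dropped).
    """
    y = np.asarray([bool(v) for v in labels])
    p = np.asarray([bool(v) for v in predictions])
    s = np.asarray(scores, float)
    out: Dict[Tuple[str, str], Optional[MetricSet]] = {}
    for name, labels_arr in bins.items():
        arr = np.asarray(labels_arr)
        if arr.shape != y.shape:
            raise ValueError(f"bin table {name!r} does not cover all records")
        for b in dict.fromkeys(arr.tolist()):
            mask = arr == b
            if not mask.any():
                out[(name, b)] = None
                continue
            m = metrics(confusion(y[mask], p[mask]))
            if 0 < y[mask].sum() < mask.sum():
                m.auc = roc_auc(s[mask], y[mask])[2]
            out[(name, b)] = m
    return out


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test on per-replicate differences.

    Zero-variance differences are reported as the exact limit (t = 0, p = 1
    for identical series; t = +/-inf, p = 0 for a constant non-zero shift)
    with a warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired series must have equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance paired differences; p is a limit case")
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
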