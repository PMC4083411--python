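"""Greedy feature-set search: SFS, floating SFS, and stability selection.

All search routines are generic over an ``evaluate(frozenset) -> float``
callback and a pool sequence whose order defines the canonical tie-break.
SFFS adds features greedily and, after every addition, floats back down by
removing any feature whose removal strictly improves the score; every
visited combination is registered, and the best-scoring visited combination
is the result.  Stability selection estimates per-feature significance as
the probability of being selected by plain SFS over repeated random
half-subsamples of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Hashable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

Evaluate = Callable[[FrozenSet], float]


@dataclass
class SelectionTrace:
    """Log of one SFFS/SFS run: actions, the visited-set registry, and the
    best visited combination."""

    steps: List[Tuple[str, Hashable, float]] = field(default_factory=list)
    registry: Dict[FrozenSet, float] = field(default_factory=dict)
    _order: List[FrozenSet] = field(default_factory=list)
    best_set: FrozenSet = frozenset()
    best_score: float = float("-inf")
    additions: int = 0

    def visit(self, subset: FrozenSet, score: float) -> None:
        if subset not in self.registry:
            self.registry[subset] = score
            self._order.append(subset)
            if score > self.best_score:
                self.best_score, self.best_set = score, subset

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\taction\tdescriptor\tscore\n")
            for i, (action, item, score) in enumerate(self.steps, 1):
                fh.write(f"{i}\t{action}\t{item}\t{score:.6f}\n")
            names = sorted(str(d) for d in self.best_set)
            fh.write(f"# best\t{self.best_score:.6f}\t{','.join(names)}\n")


class _Cache:
    """Memoised evaluate so re-visited combinations cost nothing."""

    def __init__(self, evaluate: Evaluate):
        self._fn = evaluate
        self._seen: Dict[FrozenSet, float] = {}
        self.calls = 0

    def __call__(self, subset: FrozenSet) -> float:
        if subset not in self._seen:
            self.calls += 1
            self._seen[subset] = float(self._fn(subset))
        return self._seen[subset]


def sfs_step(
    current: FrozenSet, pool: Sequence[Hashable], evaluate: Evaluate
) -> Tuple[Hashable, float]:
    """Best single addition: argmax over f not in current of
    evaluate(current | {f}); ties keep the earliest pool entry."""
    candidates = [f for f in pool if f not in current]
    if not candidates:
        raise ValueError("no candidate features to add")
    best_f, best_score = None, float("-inf")
    for f in candidates:
        score = evaluate(current | {f})
        if score > best_score:
            best_f, best_score = f, score
    return best_f, best_score


def sfs(
    pool: Sequence[Hashable],
    evaluate: Evaluate,
    budget: int = 10,
    stop_on_no_improvement: bool = False,
) -> SelectionTrace:
    """Plain sequential forward selection up to ``budget`` additions.

    With ``stop_on_no_improvement`` the search stops early once no candidate
    strictly improves the current score (the inner rule used by stability
    selection).
    """
    cached = _Cache(evaluate)
    trace = SelectionTrace()
    current: FrozenSet = frozenset()
    current_score = float("-inf")
    while trace.additions < budget and len(current) < len(pool):
        f, score = sfs_step(current, pool, cached)
        if stop_on_no_improvement and score <= current_score:
            break
        current = current | {f}
        current_score = score
        trace.additions += 1
        trace.steps.append(("add", f, score))
        trace.visit(current, score)
    return trace


def sffs(
    pool: Sequence[Hashable], evaluate: Evaluate, budget: int = 10
) -> SelectionTrace:
    """Sequential forward floating selection.

    Forward additions via :func:`sfs_step`; after each addition, features are
    iteratively removed while a removal *strictly* improves the score.  The
    search terminates once ``budget`` cumulative additions have been made;
    the result is the best-scoring combination in the visited registry.
    """
    if not pool:
        raise ValueError("empty feature pool")
    cached = _Cache(evaluate)
    trace = SelectionTrace()
    current: FrozenSet = frozenset()
    current_score = float("-inf")
    while trace.additions < budget:
        if len(current) == len(pool):
            break
        f, score = sfs_step(current, pool, cached)
        current = current | {f}
        current_score = score
        trace.additions += 1
        trace.steps.append(("add", f, score))
        trace.visit(current, score)
        # backward float: remove while strictly improving
        improved = True
        while improved and len(current) > 1:
            improved = False
            best_r, best_r_score = None, current_score
            for r in [f for f in pool if f in current]:
                s = cached(current - {r})
                if s > best_r_score:
                    best_r, best_r_score = r, s
            if best_r is not None:
                current = current - {best_r}
                current_score = best_r_score
                trace.steps.append(("remove", best_r, best_r_score))
                trace.visit(current, best_r_score)
                improved = True
    return trace


@dataclass
class StabilityProfile:
    """Per-feature selection probabilities from stability selection."""

    probabilities: Dict[Hashable, float]
    k: int
    subsample_fraction: float

    def ranked(self) -> List[Tuple[Hashable, float]]:
        return sorted(self.probabilities.items(), key=lambda kv: (-kv[1], str(kv[0])))

    def top(self) -> Hashable:
        return self.ranked()[0][0]


def stability_selection(
    y: np.ndarray,
    pool: Sequence[Hashable],
    evaluate_factory: Callable[[np.ndarray], Evaluate],
    k: int = 100,
    seed: int = 0,
    budget: int = 10,
    subsample_fraction: float = 0.5,
    max_retries: int = 20,
) -> StabilityProfile:
    """Selection probability of each feature over ``k`` SFS replicates.

    Each replicate draws a uniform random subsample of size ``floor(n/2)``
    without replacement, builds an evaluate callback for that subsample via
    ``evaluate_factory(indices)``, and runs plain SFS (early stop when no
    addition improves, hard cap ``budget``).  A single-class subsample is
    redrawn (logged), up to ``max_retries`` per replicate.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 4:
        raise ValueError("stability selection needs n >= 4")
    if k < 1:
        raise ValueError("k must be >= 1")
    m = int(n * subsample_fraction)
    rng = np.random.default_rng(seed)
    counts: Dict[Hashable, int] = {f: 0 for f in pool}
    for rep in range(k):
        for attempt in range(max_retries):
            idx = rng.choice(n, size=m, replace=False)
            if len(np.unique(y[idx])) > 1:
                break
            logger.info("stability selection replicate %d: single-class subsample, redrawn", rep)
        else:
            raise ValueError("could not draw a two-class subsample")
        evaluate = evaluate_factory(np.sort(idx))
        trace = sfs(pool, evaluate, budget=budget, stop_on_no_improvement=True)
        # the final SFS set is the last visited (the path is monotone)
        final = trace._order[-1] if trace._order else frozenset()
        for f in final:
            counts[f] += 1
    probs = {f: counts[f] / k for f in pool}
    return StabilityProfile(probs, k, subsample_fraction)


# ---------------------------------------------------------------------------
# Evaluate-callback factories
# ---------------------------------------------------------------------------

def cv_auc_evaluator(
    X: np.ndarray,
    y: np.ndarray,
    columns: Dict[Hashable, Sequence[int]],
    make_estimator: Callable,
    folds: int = 3,
    seed: int = 0,
) -> Evaluate:
    """Evaluate a feature set as mean stratified-CV AUC of an estimator.

    ``columns`` maps each selectable feature to its column indices in X;
    ``make_estimator()`` returns an unfitted sklearn-style classifier with a
    ``decision_function`` or ``predict_proba``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n_splits = max(2, min(folds, int(np.bincount(y).min())))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    def evaluate(subset: FrozenSet) -> float:
        if not subset:
            return 0.5
        cols = sorted(c for f in subset for c in columns[f])
        aucs = []
        for tr, te in splits:
            est = make_estimator()
            est.fit(X[np.ix_(tr, cols)], y[tr])
            if hasattr(est, "decision_function"):
                s = est.decision_function(X[np.ix_(te, cols)])
            else:
                s = est.predict_proba(X[np.ix_(te, cols)])[:, 1]
            aucs.append(roc_auc_score(y[te], s))
        return float(np.mean(aucs))

    return evaluate


def linear_cv_auc_evaluator(
    X: np.ndarray,
    y: np.ndarray,
    columns: Dict[Hashable, Sequence[int]],
    folds: int = 3,
    seed: int = 0,
) -> Evaluate:
    """Fast least-squares linear scorer: mean CV AUC of an OLS discriminant.

    A linear regression of the +/-1 class indicator on the selected columns
    is a monotone proxy for Fisher's discriminant, so its AUC matches an LDA
    at a fraction of the cost.  Used for selection-heavy simulations.
    """
    X = np.asarray(X, float)
    yy = np.where(np.asarray(y, int) > 0, 1.0, -1.0)
    y = np.asarray(y, int)

    def fast_auc(yb, s):
        # Mann-Whitney AUC with average ranks (ties count 1/2)
        from scipy.stats import rankdata
        r = rankdata(s)
        n_pos = int(yb.sum())
        n_neg = len(yb) - n_pos
        return (r[yb.astype(bool)].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_splits = max(2, min(folds, int(np.bincount(y).min())))
    fold_of = np.empty(n, int)
    fold_of[order] = np.arange(n) % n_splits

    def evaluate(subset: FrozenSet) -> float:
        if not subset:
            return 0.5
        cols = sorted(c for f in subset for c in columns[f])
        aucs = []
        for f in range(n_splits):
            te = fold_of == f
            tr = ~te
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            A = np.column_stack([np.ones(tr.sum()), X[np.ix_(tr, cols)]])
            beta, *_ = np.linalg.lstsq(A, yy[tr], rcond=None)
            s = np.column_stack([np.ones(te.sum()), X[np.ix_(te, cols)]]) @ beta
            aucs.append(fast_auc(y[te], s))
        return float(np.mean(aucs)) if aucs else 0.5

    return evaluate
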