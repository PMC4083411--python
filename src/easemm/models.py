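"""Per-category SVM models, structure-based routing, and the consensus.

Five radial-basis-kernel SVMs are trained on partitions of the data: two by
predicted solvent exposure (exposed/buried at a 25% relative-ASA threshold)
and three by predicted secondary structure (helix/sheet/coil).  A mutation
is scored by the one exposure-routed model (method EASE-ASA) and the one
SS-routed model (EASE-SS); the consensus probability is their plain mean:

    P_MM = (P_ASA + P_SS) / 2

The stabilising class (ddGu >= 0) is the positive class throughout; the SVM
error weight ``w`` applies to it, since it is the minority class in the
experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureDescriptor, FeatureVector, canonical_order
from .io import ProviderTable, StabilityRecord

BUNDLE_FORMAT_VERSION = 1

#: Printed parameter grids: 7 x 5 x 5 = 175 combinations.
C_GRID = tuple(2.0 ** e for e in (-5, -3, -1, 1, 3, 5, 7))
GAMMA_GRID = tuple(2.0 ** e for e in (-7, -5, -3, -1, 1))
W_GRID = (1.0, 1.5, 2.0, 2.5, 3.0)

EXPOSURE_THRESHOLD = 0.25  # exposed iff rASA strictly > 25%

ASA_CATEGORIES = ("exposed", "buried")
SS_CATEGORIES = ("helix", "sheet", "coil")
SS_ORDER = ("H", "E", "C")  # tie-break priority helix > sheet > coil


@dataclass(frozen=True, order=True)
class ModelCategory:
    axis: str  # "ASA" | "SS"
    value: str

    def __post_init__(self):
        valid = {"ASA": ASA_CATEGORIES, "SS": SS_CATEGORIES}.get(self.axis)
        if valid is None:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.value not in valid:
            raise ValueError(f"{self.value!r} not a {self.axis} category")

    @property
    def name(self) -> str:
        return f"{self.axis}:{self.value}"


ALL_CATEGORIES = tuple(
    [ModelCategory("ASA", v) for v in ASA_CATEGORIES]
    + [ModelCategory("SS", v) for v in SS_CATEGORIES]
)


@dataclass(frozen=True)
class SVMParams:
    C: float
    gamma: float
    w: float

    def __post_init__(self):
        if self.C not in C_GRID or self.gamma not in GAMMA_GRID or self.w not in W_GRID:
            raise ValueError(f"{self} not drawn from the printed grids")


def param_grid() -> List[SVMParams]:
    """All 175 grid combinations, in tie-break order (C, then gamma, then w)."""
    return [SVMParams(C, g, w) for C in C_GRID for g in GAMMA_GRID for w in W_GRID]


DEFAULT_PARAMS = SVMParams(C=2.0, gamma=2.0 ** -3, w=2.0)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def route_asa(providers: ProviderTable, protein_id: str, position: int) -> str:
    """Exposure category of a site: the provider category if present, else
    derived from rASA with the strict >25% rule (25% exactly is buried)."""
    if (protein_id, position) in providers.exposure:
        return providers.exposure[(protein_id, position)]
    rasa = providers.get_rasa(protein_id, position)
    return "exposed" if rasa > EXPOSURE_THRESHOLD else "buried"


def route_ss(providers: ProviderTable, protein_id: str, position: int) -> str:
    """SS category by argmax of the (H, E, C) probabilities; ties resolve in
    helix > sheet > coil priority (first maximal index)."""
    probs = providers.get_ss_probs(protein_id, position)
    return SS_CATEGORIES[int(np.argmax(probs))]


def route(providers: ProviderTable, record: StabilityRecord, axis: str) -> ModelCategory:
    if axis == "ASA":
        return ModelCategory("ASA", route_asa(providers, record.protein_id, record.position))
    if axis == "SS":
        return ModelCategory("SS", route_ss(providers, record.protein_id, record.position))
    raise ValueError(f"unknown axis {axis!r}")


def partition_by_category(
    records: Sequence[StabilityRecord], providers: ProviderTable, axis: str
) -> Dict[ModelCategory, List[int]]:
    """Disjoint, exhaustive partition of record indices along one axis."""
    values = ASA_CATEGORIES if axis == "ASA" else SS_CATEGORIES
    out: Dict[ModelCategory, List[int]] = {ModelCategory(axis, v): [] for v in values}
    for i, rec in enumerate(records):
        out[route(providers, rec, axis)].append(i)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _make_svc(params: SVMParams, seed: int) -> SVC:
    return SVC(
        kernel="rbf", C=params.C, gamma=params.gamma,
        class_weight={1: params.w}, random_state=seed,
    )


def _fit_classifier(X, y, params: SVMParams, seed: int, calibrate: bool):
    """Fit the RBF SVM, optionally with a Platt-style sigmoid on the
    decision value (cross-fitted within the training data)."""
    if calibrate:
        cv = max(2, min(5, int(np.bincount(np.asarray(y, int)).min())))
        clf = CalibratedClassifierCV(_make_svc(params, seed), method="sigmoid",
                                     cv=cv, ensemble=False)
    else:
        clf = _make_svc(params, seed)
    clf.fit(X, y)
    return clf


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Optional[Sequence[SVMParams]] = None,
    folds: int = 10,
    seed: int = 0,
) -> SVMParams:
    """Pick the grid point maximising mean inner-CV AUC.

    The same seeded stratified folds are reused for every grid point; ties
    resolve to the smaller C, then smaller gamma, then smaller w (the grid
    iteration order).
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search needs both classes in the training set")
    grid = list(grid) if grid is not None else param_grid()
    n_splits = max(2, min(folds, counts.min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best: Optional[SVMParams] = None
    best_auc = -np.inf
    for params in grid:
        aucs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            clf = _make_svc(params, seed)
            clf.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best_auc, best = mean_auc, params
    if best is None:
        raise ValueError("no valid inner-CV split found")
    return best


@dataclass
class CategoryModel:
    """One trained per-category classifier with its selected features."""

    category: ModelCategory
    descriptors: Tuple[FeatureDescriptor, ...]
    params: SVMParams
    clf: object  # SVC or CalibratedClassifierCV
    calibrated: bool
    train_fingerprint: str = ""

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Probability of the stabilising class for rows of X (the model's
        own feature columns)."""
        X = np.atleast_2d(np.asarray(X, float))
        if self.calibrated:
            idx = list(self.clf.classes_).index(1)
            return self.clf.predict_proba(X)[:, idx]
        # logistic link on the decision value: monotone, in (0, 1)
        return 1.0 / (1.0 + np.exp(-self.clf.decision_function(X)))


def train_category_model(
    X: np.ndarray,
    y: np.ndarray,
    category: ModelCategory,
    descriptors: Sequence[FeatureDescriptor],
    params: SVMParams = DEFAULT_PARAMS,
    seed: int = 0,
    calibrate: bool = True,
) -> CategoryModel:
    """Fit one RBF SVM on a category partition.

    ``calibrate=True`` (default) fits a Platt-style sigmoid on the decision
    value within the training data; ``calibrate=False`` substitutes a plain
    logistic link (still monotone — ranking metrics are unaffected).
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    if len(X) == 0:
        raise ValueError(f"{category.name}: empty training partition")
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"{category.name}: single-class partition; merge categories or add data"
        )
    if not descriptors:
        raise ValueError(f"{category.name}: empty descriptor list")
    clf = _fit_classifier(X, y, params, seed, calibrate)
    fp = f"n={len(y)},pos={int(y.sum())}"
    return CategoryModel(category, tuple(canonical_order(descriptors)), params,
                         clf, calibrate, fp)


# ---------------------------------------------------------------------------
# The bank and the consensus
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    protein_id: str
    mutation: str
    route_asa: str
    route_ss: str
    p_asa: float
    p_ss: float
    p_mm: float
    label: str


@dataclass
class CategoryModelBank:
    """All five per-category models plus per-method decision thresholds."""

    models: Dict[ModelCategory, CategoryModel]
    thresholds: Dict[str, float] = field(
        default_factory=lambda: {"ease-asa": 0.5, "ease-ss": 0.5, "ease-mm": 0.5}
    )
    version: int = BUNDLE_FORMAT_VERSION

    def validate(self) -> None:
        missing = [c.name for c in ALL_CATEGORIES if c not in self.models]
        if missing:
            raise ValueError(f"bank missing categories: {missing}")
        for cat, model in self.models.items():
            if not model.descriptors:
                raise ValueError(f"{cat.name}: empty descriptor list")

    def predict_one(
        self, fv: FeatureVector, providers: ProviderTable, record: StabilityRecord
    ) -> PredictionResult:
        self.validate()
        cat_asa = route(providers, record, "ASA")
        cat_ss = route(providers, record, "SS")
        m_asa, m_ss = self.models[cat_asa], self.models[cat_ss]
        p_asa = float(m_asa.probabilities(fv.subset(m_asa.descriptors))[0])
        p_ss = float(m_ss.probabilities(fv.subset(m_ss.descriptors))[0])
        p_mm = consensus(p_asa, p_ss)
        label = "stabilising" if p_mm >= self.thresholds["ease-mm"] else "destabilising"
        return PredictionResult(
            record.protein_id, record.mutation, cat_asa.value, cat_ss.value,
            p_asa, p_ss, p_mm, label,
        )


def consensus(p_asa: float, p_ss: float) -> float:
    """The consensus probability: exact arithmetic mean of the two methods."""
    return (p_asa + p_ss) / 2.0


def save_bank(bank: CategoryModelBank, path) -> None:
    bank.validate()
    payload = {
        "format_version": bank.version,
        "thresholds": dict(bank.thresholds),
        "models": {
            cat.name: {
                "axis": cat.axis,
                "value": cat.value,
                "descriptors": [d.name for d in model.descriptors],
                "params": (model.params.C, model.params.gamma, model.params.w),
                "clf": model.clf,
                "calibrated": model.calibrated,
                "fingerprint": model.train_fingerprint,
            }
            for cat, model in bank.models.items()
        },
    }
    joblib.dump(payload, path)


def load_bank(path) -> CategoryModelBank:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot load model bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not a model bundle")
    if payload["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"{path}: bundle format {payload['format_version']} != "
            f"supported {BUNDLE_FORMAT_VERSION}"
        )
    models = {}
    for name, m in payload["models"].items():
        cat = ModelCategory(m["axis"], m["value"])
        models[cat] = CategoryModel(
            category=cat,
            descriptors=tuple(FeatureDescriptor.parse(d) for d in m["descriptors"]),
            params=SVMParams(*m["params"]),
            clf=m["clf"],
            calibrated=m["calibrated"],
            train_fingerprint=m.get("fingerprint", ""),
        )
    bank = CategoryModelBank(models=models, thresholds=payload["thresholds"],
                             version=payload["format_version"])
    bank.validate()
    return bank


def write_prediction_table(results: Iterable[PredictionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\twt\tposition\tmut\troute_asa\troute_ss\t"
                 "p_asa\tp_ss\tp_mm\tlabel\n")
        for r in results:
            wt, mut = r.mutation[0], r.mutation[-1]
            pos = r.mutation[1:-1]
            fh.write(f"{r.protein_id}\t{wt}\t{pos}\t{mut}\t{r.route_asa}\t"
                     f"{r.route_ss}\t{r.p_asa:.6f}\t{r.p_ss:.6f}\t"
                     f"{r.p_mm:.6f}\t{r.label}\n")


# ---------------------------------------------------------------------------
# Array-level method fitters (used by cross-validation and simulations)
# ---------------------------------------------------------------------------

MethodFitter = Callable[[np.ndarray], Callable[[np.ndarray], np.ndarray]]


def make_method_fitter(
    X: np.ndarray,
    y: np.ndarray,
    asa_cats: Sequence[str],
    ss_cats: Sequence[str],
    method: str,
    descriptors_by_category: Dict[ModelCategory, Sequence[int]],
    params: SVMParams = DEFAULT_PARAMS,
    seed: int = 0,
    calibrate: bool = False,
) -> MethodFitter:
    """Build a fit(train_idx) -> score(idx) closure for one method.

    ``method`` is one of ``ease-asa``, ``ease-ss``, ``ease-mm``, ``single``.
    ``descriptors_by_category`` maps each category (plus the pooled
    pseudo-category key ``None`` for ``single``) to feature-column indices of
    X.  Scores are stabilising-class probabilities.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    asa_cats = np.asarray(asa_cats)
    ss_cats = np.asarray(ss_cats)

    def fit_axis(train_idx, axis, cats, values):
        fitted = {}
        for v in values:
            cat = ModelCategory(axis, v)
            cols = list(descriptors_by_category[cat])
            idx = train_idx[cats[train_idx] == v]
            if len(idx) == 0 or len(np.unique(y[idx])) < 2:
                raise ValueError(f"{cat.name}: degenerate training partition")
            clf = _fit_classifier(X[np.ix_(idx, cols)], y[idx], params, seed, calibrate)
            fitted[v] = (clf, cols)
        def score(idx):
            idx = np.asarray(idx)
            out = np.empty(len(idx))
            for v, (clf, cols) in fitted.items():
                mask = cats[idx] == v
                if not mask.any():
                    continue
                sub = X[np.ix_(idx[mask], cols)]
                if calibrate:
                    pi = list(clf.classes_).index(1)
                    out[mask] = clf.predict_proba(sub)[:, pi]
                else:
                    out[mask] = 1.0 / (1.0 + np.exp(-clf.decision_function(sub)))
            return out
        return score

    def fit(train_idx):
        train_idx = np.asarray(train_idx)
        if method == "single":
            cols = list(descriptors_by_category[None])
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("single: degenerate training set")
            clf = _fit_classifier(X[np.ix_(train_idx, cols)], y[train_idx],
                                  params, seed, calibrate)
            def score(idx):
                sub = X[np.ix_(np.asarray(idx), cols)]
                if calibrate:
                    pi = list(clf.classes_).index(1)
                    return clf.predict_proba(sub)[:, pi]
                return 1.0 / (1.0 + np.exp(-clf.decision_function(sub)))
            return score
        if method == "ease-asa":
            return fit_axis(train_idx, "ASA", asa_cats, ASA_CATEGORIES)
        if method == "ease-ss":
            return fit_axis(train_idx, "SS", ss_cats, SS_CATEGORIES)
        if method == "ease-mm":
            s_asa = fit_axis(train_idx, "ASA", asa_cats, ASA_CATEGORIES)
            s_ss = fit_axis(train_idx, "SS", ss_cats, SS_CATEGORIES)
            return lambda idx: (s_asa(idx) + s_ss(idx)) / 2.0
        raise ValueError(f"unknown method {method!r}")

    return fit
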