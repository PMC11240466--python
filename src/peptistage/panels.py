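"""Multi-marker panel construction by a forward-selection AUC threshold ladder.

Single markers must reach a cross-validated AUC above 0.65 to survive; all
pairs of survivors are screened at 0.70; panels of size 3-6 must clear 0.75,
0.85, 0.90 and 0.95 respectively *and* beat their best parent panel —
combinations with reduced predictive power are abandoned.  Performance is
estimated with repeated stratified 2-fold cross-validation, pooling
out-of-fold scores; the positive class is late-stage (stage III), so
sensitivity is the recall of stage III and specificity the recall of stage I.

Classifiers are standard library implementations (random forest by default,
plus SVM, k-nearest neighbors, naive Bayes and logistic regression for
comparison); the bespoke machinery here is the ladder search and its
leakage-free bookkeeping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import MarkerTable

__all__ = [
    "LadderConfig",
    "MarkerPerformance",
    "PanelModel",
    "make_classifier",
    "cv_performance",
    "forward_select",
    "compare_classifiers",
    "validate_panel",
    "auc_concordance",
]

DEFAULT_THRESHOLDS = {1: 0.65, 2: 0.70, 3: 0.75, 4: 0.85, 5: 0.90, 6: 0.95}
CLASSIFIERS = ("rf", "svm", "knn", "nb", "logreg")


@dataclass(frozen=True)
class LadderConfig:
    """Forward-selection ladder settings: size-specific AUC thresholds,
    2-fold CV with seeded repeats, and the classifier to score panels with."""

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    folds: int = 2
    repeats: int = 10
    seed: int = 0
    classifier: str = "rf"
    max_size: int = 6
    # extensions must beat the parent panel's AUC ("combinations with reduced
    # predictive power were abandoned"); disable for exhaustive enumeration
    require_improvement: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need >= 2 folds")
        sizes = sorted(self.thresholds)
        vals = [self.thresholds[s] for s in sizes]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("ladder thresholds must be non-decreasing in panel size")


@dataclass(frozen=True)
class MarkerPerformance:
    marker_ids: tuple
    classifier: str
    sensitivity: float
    specificity: float
    auc: float

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.auc):
            if not 0 <= v <= 1:
                raise ValueError("performance metrics must lie in [0, 1]")


@dataclass
class PanelModel:
    """An ordered marker combination surviving the ladder."""

    marker_ids: tuple
    classifier: str
    cv_auc: float
    cv_sensitivity: float
    cv_specificity: float
    model: object | None = None
    validation: dict | None = None


def make_classifier(name: str, seed: int = 0):
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "nb":
        return GaussianNB()
    if name == "logreg":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _xy(table: MarkerTable, serials) -> tuple[np.ndarray, np.ndarray]:
    X = table.matrix[list(serials)].to_numpy(dtype=float)
    y = (table.labels == "late").to_numpy().astype(int)
    return X, y


def make_folds(y: np.ndarray, config: LadderConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified fold assignments, shared across classifiers."""
    cv = RepeatedStratifiedKFold(
        n_splits=config.folds, n_repeats=config.repeats, random_state=config.seed
    )
    return list(cv.split(np.zeros((y.size, 1)), y))


def fold_hash(folds) -> str:
    h = hashlib.sha256()
    for tr, te in folds:
        h.update(np.asarray(tr).tobytes())
        h.update(np.asarray(te).tobytes())
    return h.hexdigest()


def auc_concordance(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney concordance count (ties count 1/2)."""
    pos = np.asarray(scores)[np.asarray(y) == 1]
    neg = np.asarray(scores)[np.asarray(y) == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def _youden_point(y: np.ndarray, scores: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) at the Youden-optimal ROC point."""
    fpr, tpr, thr = roc_curve(y, scores)
    j = int(np.argmax(tpr - fpr))
    return float(tpr[j]), float(1.0 - fpr[j]), float(thr[j])


def cv_performance(
    table: MarkerTable,
    serials,
    config: LadderConfig,
    classifier: str | None = None,
    folds=None,
) -> MarkerPerformance:
    """Cross-validated performance of one marker subset.

    Out-of-fold scores are pooled over all repeats; AUC is the area under the
    pooled ROC, and sensitivity/specificity are read off at the score
    threshold maximizing Youden's J.  Deterministic given the config seed.
    """
    name = classifier or config.classifier
    X, y = _xy(table, serials)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    if folds is None:
        folds = make_folds(y, config)
    pooled_scores = np.empty(0)
    pooled_y = np.empty(0, dtype=int)
    for k, (tr, te) in enumerate(folds):
        model = make_classifier(name, seed=config.seed + k)
        model.fit(X[tr], y[tr])
        pooled_scores = np.append(pooled_scores, _scores(model, X[te]))
        pooled_y = np.append(pooled_y, y[te])
    auc = float(roc_auc_score(pooled_y, pooled_scores))
    sens, spec, _ = _youden_point(pooled_y, pooled_scores)
    return MarkerPerformance(tuple(serials), name, sens, spec, auc)


def forward_select(
    table: MarkerTable, candidates, config: LadderConfig | None = None
) -> list[PanelModel]:
    """Grow marker panels through the AUC threshold ladder.

    Stage 1 keeps single markers with AUC above the size-1 threshold; stage 2
    keeps pairs of stage-1 survivors above the size-2 threshold; stages 3+
    extend every surviving panel by each remaining candidate, keeping
    extensions that clear the size threshold *and* improve on the parent's
    AUC.  Duplicate marker sets are evaluated once.  Returns surviving panels
    of every size, sorted by cv_auc descending.
    """
    config = config or LadderConfig()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate markers")
    _, y = _xy(table, candidates[:1])
    folds = make_folds(y, config)
    cache: dict[frozenset, MarkerPerformance] = {}

    def perf(subset: frozenset) -> MarkerPerformance:
        if subset not in cache:
            cache[subset] = cv_performance(table, sorted(subset), config, folds=folds)
        return cache[subset]

    survivors: dict[int, dict[frozenset, MarkerPerformance]] = {}
    singles = {}
    for c in candidates:
        p = perf(frozenset([c]))
        if p.auc > config.thresholds.get(1, 0.65):
            singles[frozenset([c])] = p
    survivors[1] = singles
    if not singles:
        return []

    single_ids = sorted({c for s in singles for c in s})
    pairs = {}
    thr2 = config.thresholds.get(2, 0.70)
    for i, a in enumerate(single_ids):
        for b in single_ids[i + 1:]:
            s = frozenset([a, b])
            p = perf(s)
            if p.auc > thr2:
                pairs[s] = p
    survivors[2] = pairs

    for size in range(3, config.max_size + 1):
        prev = survivors.get(size - 1, {})
        if not prev:
            break
        thr = config.thresholds.get(size)
        if thr is None:
            break
        level: dict[frozenset, MarkerPerformance] = {}
        for parent, parent_perf in prev.items():
            for c in candidates:
                if c in parent:
                    continue
                s = parent | {c}
                if s in level:
                    continue
                p = perf(s)
                improves = p.auc > parent_perf.auc or not config.require_improvement
                if p.auc > thr and improves:
                    level[s] = p
        survivors[size] = level

    panels = []
    for size, level in survivors.items():
        for subset, p in level.items():
            assert p.auc > config.thresholds.get(size, 0.0)
            panels.append(
                PanelModel(
                    marker_ids=tuple(sorted(subset)),
                    classifier=p.classifier,
                    cv_auc=p.auc,
                    cv_sensitivity=p.sensitivity,
                    cv_specificity=p.specificity,
                )
            )
    panels.sort(key=lambda pm: (-pm.cv_auc, pm.marker_ids))
    return panels


def compare_classifiers(
    table: MarkerTable, serials, config: LadderConfig | None = None,
    classifiers=CLASSIFIERS,
) -> list[dict]:
    """Rank classifiers by CV AUC on identical folds (ties by sensitivity).

    A classifier that fails to fit is recorded with ``failed=True`` rather
    than silently dropped.
    """
    config = config or LadderConfig()
    if len(classifiers) < 2:
        raise ValueError("need >= 2 classifiers to compare")
    _, y = _xy(table, list(serials))
    folds = make_folds(y, config)
    fhash = fold_hash(folds)
    results = []
    for name in classifiers:
        try:
            p = cv_performance(table, serials, config, classifier=name, folds=folds)
            results.append(
                {"classifier": name, "auc": p.auc, "sensitivity": p.sensitivity,
                 "specificity": p.specificity, "failed": False, "fold_hash": fhash}
            )
        except Exception as exc:  # noqa: BLE001 - report, don't hide
            results.append(
                {"classifier": name, "auc": np.nan, "sensitivity": np.nan,
                 "specificity": np.nan, "failed": True, "error": str(exc),
                 "fold_hash": fhash}
            )
    results.sort(
        key=lambda r: (-(r["auc"] if np.isfinite(r["auc"]) else -1),
                       -(r["sensitivity"] if np.isfinite(r["sensitivity"]) else -1))
    )
    return results


def validate_panel(
    panel: PanelModel,
    train: MarkerTable,
    test: MarkerTable,
    thresholds=(0.7, 0.9),
    seed: int = 0,
) -> dict:
    """Refit a panel on the full training split and score the masked test set.

    Reports test sensitivity (recall of stage III), specificity (recall of
    stage I) and AUC at the Youden point, plus sensitivity/specificity at
    each requested fixed score threshold (a score above the threshold calls
    stage III).
    """
    overlap = set(train.matrix.index) & set(test.matrix.index)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)}")
    serials = list(panel.marker_ids)
    X_tr, y_tr = _xy(train, serials)
    X_te, y_te = _xy(test, serials)
    model = make_classifier(panel.classifier, seed=seed)
    model.fit(X_tr, y_tr)
    scores = _scores(model, X_te)
    auc = float(roc_auc_score(y_te, scores)) if len(set(y_te)) == 2 else np.nan
    sens, spec, youden_thr = _youden_point(y_te, scores)
    by_threshold = {}
    for t in thresholds:
        pred = (scores > t).astype(int)
        tp = int(((pred == 1) & (y_te == 1)).sum())
        tn = int(((pred == 0) & (y_te == 0)).sum())
        fn = int(((pred == 0) & (y_te == 1)).sum())
        fp = int(((pred == 1) & (y_te == 0)).sum())
        by_threshold[t] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    panel.model = model
    panel.validation = {
        "auc": auc, "sensitivity": sens, "specificity": spec,
        "youden_threshold": youden_thr, "by_threshold": by_threshold,
        "scores": scores, "y_true": y_te,
    }
    return panel.validation


def performance_frame(panels: list[PanelModel]) -> pd.DataFrame:
    rows = []
    for pm in panels:
        row = {
            "components": "+".join(str(m) for m in pm.marker_ids),
            "size": len(pm.marker_ids),
            "classifier": pm.classifier,
            "cv_auc": pm.cv_auc,
            "cv_sensitivity": pm.cv_sensitivity,
            "cv_specificity": pm.cv_specificity,
        }
        if pm.validation:
            row.update(
                test_auc=pm.validation["auc"],
                test_sensitivity=pm.validation["sensitivity"],
                test_specificity=pm.validation["specificity"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
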