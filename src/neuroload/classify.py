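"""Grid-searched SVM / decision-tree / random-forest evaluation of the
three feature sets with a per-subject 80/20 split + fivefold CV protocol.

For each subject and feature set, the data is split 80/20 stratified by
difficulty level, a grid search with fivefold cross-validation runs on the
80% partition, the best parameters are refit on the full 80%, and train and
test accuracies are recorded. Standardization is fit inside the training
folds only (no test-partition leakage). Summaries (min/mean/max/std across
subjects) mirror the study's reporting layout.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import ConfigurationError, GridSearchSpec, ParameterError
from .features import feature_columns
from .types import EvaluationResult

logger = logging.getLogger(__name__)

CLASSIFIERS: Tuple[str, ...] = ("svm", "dt", "rf")
FEATURE_SETS: Tuple[str, ...] = ("only_eeg", "only_fnirs", "fused")


def _make_estimator(classifier: str, seed: int) -> Pipeline:
    if classifier == "svm":
        clf = SVC(kernel="rbf")
    elif classifier == "dt":
        clf = DecisionTreeClassifier(random_state=seed)
    elif classifier == "rf":
        clf = RandomForestClassifier(random_state=seed)
    else:
        raise ParameterError(f"unknown classifier {classifier!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def split_and_tune(table: pd.DataFrame, spec: GridSearchSpec,
                   classifier: str, seed: int
                   ) -> Tuple[Pipeline, dict, float, float]:
    """Stratified 80/20 split + fivefold-CV grid search on the 80%.

    Returns (fitted model, chosen params, test accuracy %, train accuracy %).
    The winning parameter combination is refit on the full 80% partition;
    feature standardization is part of the estimator pipeline, so its
    statistics come from training data only.
    """
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["level"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("need at least two classes")
    if (counts * 0.8).min() < 5:
        logger.warning("fewer than 5 training samples in some class; "
                       "fivefold CV may fail")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed)
    min_class = int(np.unique(y_tr, return_counts=True)[1].min())
    if min_class < 2:
        raise ParameterError("a class has fewer than 2 training samples")
    n_splits = min(5, min_class)
    if n_splits < 5:
        logger.warning("reducing CV folds to %d (smallest class has %d "
                       "training samples)", n_splits, min_class)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(classifier, seed), spec.param_grid(classifier),
        cv=cv, scoring="accuracy", n_jobs=1, refit=True)
    search.fit(X_tr, y_tr)
    model = search.best_estimator_
    test_acc = 100.0 * float(model.score(X_te, y_te))
    train_acc = 100.0 * float(model.score(X_tr, y_tr))
    return model, dict(search.best_params_), test_acc, train_acc


def evaluate_all(per_subject_tables: Sequence[Dict[str, pd.DataFrame]],
                 spec: Optional[GridSearchSpec] = None, seed: int = 0,
                 classifiers: Sequence[str] = CLASSIFIERS,
                 feature_sets: Sequence[str] = FEATURE_SETS,
                 ) -> List[EvaluationResult]:
    """Per-subject evaluation of every (feature set, classifier) pair.

    ``per_subject_tables`` holds one dict per subject mapping feature-set
    name -> feature table. Returns one EvaluationResult per pair (9 with the
    default three sets x three classifiers).
    """
    spec = spec or GridSearchSpec()
    for tables in per_subject_tables:
        missing = [s for s in feature_sets if s not in tables]
        if missing:
            raise ConfigurationError(f"missing feature sets {missing}")
    results = []
    for fset in feature_sets:
        for clf in classifiers:
            test_accs, train_accs, params = [], [], []
            for tables in per_subject_tables:
                _, p, te, tr = split_and_tune(tables[fset], spec, clf, seed)
                test_accs.append(te)
                train_accs.append(tr)
                params.append(p)
            results.append(EvaluationResult(
                feature_set=fset, classifier=clf,
                per_subject_test_accuracy=test_accs,
                per_subject_train_accuracy=train_accs,
                chosen_params=params))
    return results


def results_table(results: Sequence[EvaluationResult],
                  which: str = "test") -> pd.DataFrame:
    """Min/mean/max/std summary per (feature set, classifier), in %."""
    rows = []
    for r in results:
        row = {"feature_set": r.feature_set, "classifier": r.classifier}
        row.update(r.summary(which))
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_long_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Per-subject accuracies in long form for the two-way ANOVA."""
    rows = []
    for r in results:
        for i, acc in enumerate(r.per_subject_test_accuracy):
            rows.append({"subject": i, "feature_set": r.feature_set,
                         "classifier": r.classifier, "accuracy": acc})
    return pd.DataFrame(rows)


def accuracy_anova(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Two-way ANOVA of accuracy on feature set and classifier.

    Returns the ANOVA table with main effects of feature set and classifier
    and their interaction (F and p per effect).
    """
    frame = accuracy_long_frame(results)
    if frame["subject"].nunique() < 2:
        raise ParameterError("two-way ANOVA needs at least 2 subjects")
    model = smf.ols("accuracy ~ C(feature_set) * C(classifier)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table
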