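"""Fall-risk grouping, group-difference testing and classification.

Three layers, mirroring clinical usage:

* a duration threshold (default 13.5 s on the subject's best trial)
  splitting low- from high-fall-risk individuals;
* per-parameter two-group tests — Student t when both groups look
  normal (Shapiro–Wilk) with homogeneous variances (median-centred
  Levene), Wilcoxon rank-sum otherwise — plus a one-way MANOVA across
  all parameters (Pillai's trace F approximation);
* an exhaustive search over all 1–3-feature subsets × ten standard
  classifiers, scored by leave-one-subject-out cross-validation, with
  per-class sensitivity/specificity from the pooled held-out
  predictions.

Scale-sensitive classifiers (nearest neighbours, SVMs, Gaussian
process, neural net) get a z-score standardizer fit on training folds
only; all classifiers run with library defaults and a fixed seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.multivariate.manova import MANOVA

from .gait import PARAMETER_NAMES

logger = logging.getLogger(__name__)

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"

#: Classifier roster of the subset search; True = standardize features.
CLASSIFIER_ROSTER = (
    ("nearest_neighbors", True),
    ("linear_svm", True),
    ("rbf_svm", True),
    ("gaussian_process", True),
    ("decision_tree", False),
    ("random_forest", False),
    ("neural_net", True),
    ("adaboost", False),
    ("naive_bayes", False),
    ("qda", False),
)


def threshold_classify(best_duration: float, cutoff: float = 13.5) -> str:
    """Low risk iff the best-trial duration is strictly below the cutoff."""
    if best_duration <= 0:
        raise ValueError("invalid duration")
    if cutoff <= 0:
        raise ValueError("invalid cutoff")
    return LOW_RISK if best_duration < cutoff else HIGH_RISK


def best_trials(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: the trial with minimum total duration."""
    idx = cohort.groupby("subject")["total_duration"].idxmin()
    return cohort.loc[idx].reset_index(drop=True)


@dataclass(frozen=True)
class GroupTestResult:
    parameter: str
    test_used: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float
    mean_sd_group1: tuple[float, float]
    mean_sd_group2: tuple[float, float]


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) == 0:
        return False  # degenerate; Shapiro–Wilk undefined
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    cohort: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    parameters: tuple[str, ...] = PARAMETER_NAMES,
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Two-group test per parameter: t-test when both groups pass
    Shapiro–Wilk and Levene (median-centred) at ``alpha``, Wilcoxon
    rank-sum otherwise."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    out = []
    for name in parameters:
        g1 = cohort.loc[groups == labels[0], name].to_numpy(float)
        g2 = cohort.loc[groups == labels[1], name].to_numpy(float)
        if min(g1.size, g2.size) < 3:
            raise ValueError("group too small")
        normal = _is_normal(g1, alpha) and _is_normal(g2, alpha)
        if normal and (np.ptp(g1) > 0 or np.ptp(g2) > 0):
            homo = stats.levene(g1, g2, center="median").pvalue > alpha
        else:
            homo = False
        if normal and homo:
            res = stats.ttest_ind(g1, g2, equal_var=True)
            used = "t"
        else:
            res = stats.ranksums(g1, g2)
            used = "wilcoxon"
        out.append(
            GroupTestResult(
                parameter=name,
                test_used=used,
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                mean_sd_group1=(float(g1.mean()), float(g1.std(ddof=1))),
                mean_sd_group2=(float(g2.mean()), float(g2.std(ddof=1))),
            )
        )
    return out


def manova_groups(
    cohort: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    parameters: tuple[str, ...] = PARAMETER_NAMES,
) -> tuple[float, float, float, float]:
    """One-way MANOVA over the parameters: (F, df1, df2, p) for the
    group effect, Pillai's trace F approximation."""
    groups = np.asarray(groups)
    endog = cohort[list(parameters)].to_numpy(float)
    codes = pd.factorize(groups)[0].astype(float)
    if endog.shape[1] == 1:  # 1-D case: MANOVA degenerates to ANOVA
        res = stats.f_oneway(*(endog[codes == c, 0] for c in np.unique(codes)))
        df1 = len(np.unique(codes)) - 1
        df2 = endog.shape[0] - len(np.unique(codes))
        return float(res.statistic), float(df1), float(df2), float(res.pvalue)
    exog = np.column_stack([np.ones_like(codes), codes])
    try:
        mv = MANOVA(endog, exog)
        table = mv.mv_test(
            hypotheses=[("group", np.array([[0.0, 1.0]]), None)]
        ).results["group"]["stat"]
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular covariance: drop collinear parameters"
        ) from err
    row = table.loc["Pillai's trace"]
    return (
        float(row["F Value"]),
        float(row["Num DF"]),
        float(row["Den DF"]),
        float(row["Pr > F"]),
    )


def make_classifiers(seed: int = 0) -> dict[str, Pipeline]:
    """The ten standard classifiers, seeded, scaled where appropriate."""
    base = {
        "nearest_neighbors": KNeighborsClassifier(),
        "linear_svm": SVC(kernel="linear", random_state=seed),
        "rbf_svm": SVC(kernel="rbf", random_state=seed),
        "gaussian_process": GaussianProcessClassifier(random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "neural_net": MLPClassifier(random_state=seed, max_iter=2000),
        "adaboost": AdaBoostClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
        # tiny ridge keeps QDA usable when a class has barely more
        # members than features (it hard-errors on singular covariance)
        "qda": QuadraticDiscriminantAnalysis(reg_param=1e-3),
    }
    out = {}
    for name, scale in CLASSIFIER_ROSTER:
        steps = ([("scale", StandardScaler())] if scale else []) + [
            ("clf", base[name])
        ]
        out[name] = Pipeline(steps)
    return out


def class_sensitivity_specificity(
    confusion: np.ndarray, target_class: int
) -> tuple[float, float]:
    """One-vs-rest (sensitivity, specificity) from a confusion matrix
    with rows = true classes, columns = predicted classes."""
    confusion = np.asarray(confusion, float)
    if confusion.sum() < 1 or (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative, >=1 total")
    tp = confusion[target_class, target_class]
    fn = confusion[target_class].sum() - tp
    fp = confusion[:, target_class].sum() - tp
    tn = confusion.sum() - tp - fn - fp
    if tp + fn == 0:
        raise ValueError("empty target class: sensitivity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return float(sens), float(spec)


def loso_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    model: Pipeline,
    classes: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Leave-one-subject-out accuracy and pooled confusion matrix."""
    splitter = LeaveOneGroupOut()
    k = classes.size
    confusion = np.zeros((k, k), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    for train, test in splitter.split(X, y, groups=subjects):
        assert not set(subjects[train]) & set(subjects[test])
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        for yt, yp in zip(y[test], pred):
            confusion[class_index[yt], class_index[yp]] += 1
    score = float(np.trace(confusion) / confusion.sum())
    return score, confusion


def feature_subset_search(
    cohort: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    features: tuple[str, ...] = PARAMETER_NAMES,
    max_subset: int = 3,
    classifiers: tuple[str, ...] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive 1..max_subset feature subsets × classifiers, LOSO-scored.

    ``cohort`` must hold one row per subject (best trial).  Results are
    ranked by score (descending), then subset size (smaller first),
    then feature names.  Sensitivity/specificity per class come from
    the pooled held-out confusion matrix.
    """
    if max_subset not in (1, 2, 3):
        raise ValueError("max_subset must be 1, 2 or 3")
    labels = np.asarray(labels)
    if cohort["subject"].duplicated().any():
        raise ValueError("one row per subject required (use best_trials)")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 1).any():
        logger.warning(
            "a class has a single member; it can never be predicted in LOSO"
        )
    subjects = cohort["subject"].to_numpy()
    models = make_classifiers(seed)
    names = classifiers or tuple(models)

    rows = []
    for size in range(1, max_subset + 1):
        for subset in itertools.combinations(sorted(features), size):
            X = cohort[list(subset)].to_numpy(float)
            for cname in names:
                score, confusion = loso_evaluate(
                    X, labels, subjects, models[cname], classes
                )
                row = {
                    "features": "+".join(subset),
                    "n_features": size,
                    "classifier": cname,
                    "cv_score": score,
                }
                for i, c in enumerate(classes):
                    sens, spec = class_sensitivity_specificity(confusion, i)
                    row[f"sens_{c}"] = sens
                    row[f"spec_{c}"] = spec
                rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["cv_score", "n_features", "features", "classifier"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
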