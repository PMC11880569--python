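"""Classification pipeline: PCL-M labelling, per-fold t-test feature
screening, z-scoring, classifier families, and leakage-free leave-one-out
evaluation.

Every data-dependent step — feature selection, train-mean imputation,
standardisation, model fitting, hyperparameter search — is performed
strictly inside each leave-one-out fold on the training rows only; the
held-out participant influences nothing but their own prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier, VotingClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import CohortMatrix

log = logging.getLogger(__name__)

PCLM_MIN, PCLM_MAX = 17, 85
DEFAULT_LABEL_THRESHOLD = 36
DEFAULT_ALPHA = 0.05

MODEL_IDS = ("gp", "knn", "random_forest", "decision_tree", "logistic", "mlp",
             "voting_soft", "voting_hard")


def label_from_pclm(score: int, threshold: int = DEFAULT_LABEL_THRESHOLD) -> bool:
    """PTSD-positive iff the PCL-M total score exceeds the threshold (36).

    The PCL-M sums 17 items each scored 1-5, so totals span [17, 85];
    out-of-range scores are rejected.
    """
    if not PCLM_MIN <= score <= PCLM_MAX:
        raise ValueError(f"PCL-M score {score} outside [{PCLM_MIN}, {PCLM_MAX}]")
    return score > threshold


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
) -> list[str]:
    """Keep features whose two-sided two-sample t-test p-value is < alpha.

    Welch's unequal-variance variant by default (``equal_var=True`` for the
    Student variant).  Missing cells are excluded pairwise; a feature with
    fewer than two observed values in either class, or with zero variance
    and equal means (p undefined), is dropped.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present in the training rows")
    kept = []
    for col in X.columns:
        a = X.loc[y, col].dropna().to_numpy()
        b = X.loc[~y, col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # near-constant columns trip a precision warning; they resolve to
            # p = nan and are dropped below
            warnings.simplefilter("ignore", RuntimeWarning)
            p = scipy.stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        if np.isfinite(p) and p < alpha:
            kept.append(col)
    return kept


@dataclass
class ScalerParams:
    """Per-column train mean/SD; also used for train-mean imputation."""

    mean: pd.Series
    sd: pd.Series  # population SD (ddof=0); 0 where the column is constant


def fit_scaler(X_train: pd.DataFrame) -> ScalerParams:
    return ScalerParams(mean=X_train.mean(), sd=X_train.std(ddof=0))


def apply_scaler(params: ScalerParams, X: pd.DataFrame) -> pd.DataFrame:
    """Impute missing cells with the train mean, then z-score with train
    parameters; constant columns map to 0."""
    Xi = X.fillna(params.mean)
    sd = params.sd.replace(0.0, np.nan)
    return (Xi - params.mean).div(sd).fillna(0.0)


def _build_model(model_id: str, n_train: int, seed: int, search_budget: int):
    if model_id == "gp":
        kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(1.0, (1e-2, 1e3))
        return GaussianProcessClassifier(
            kernel=kernel,
            n_restarts_optimizer=max(0, search_budget - 1),
            random_state=seed,
        )
    if model_id == "knn":
        return KNeighborsClassifier(n_neighbors=min(5, max(1, n_train - 1)))
    if model_id == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if model_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if model_id == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if model_id == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=3000, random_state=seed)
    if model_id in ("voting_soft", "voting_hard"):
        members = [
            ("gp", _build_model("gp", n_train, seed, search_budget)),
            ("random_forest", _build_model("random_forest", n_train, seed, search_budget)),
            ("logistic", _build_model("logistic", n_train, seed, search_budget)),
        ]
        voting = "soft" if model_id == "voting_soft" else "hard"
        return VotingClassifier(members, voting=voting)
    raise ValueError(f"unknown model_id {model_id!r}; choose from {MODEL_IDS}")


class _HardVoteProba:
    """Wrap a hard-voting ensemble so it exposes vote-share probabilities."""

    def __init__(self, ensemble):
        self.ensemble = ensemble

    def predict_proba(self, X):
        votes = np.stack([est.predict(X) for est in self.ensemble.estimators_], axis=1)
        p1 = votes.astype(float).mean(axis=1)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.ensemble.predict(X)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    model_id: str = "gp",
    search_budget: int = 8,
    seed: int = 0,
):
    """Fit one of the classifier families and return a probability-emitting
    predictor.

    The default Gaussian-process classifier uses an RBF kernel whose length
    scale and signal variance are tuned by seeded multistart maximisation
    of the (Laplace-approximate) marginal likelihood; ``search_budget`` is
    the number of optimizer starts.
    """
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data contain a single class")
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need at least 2 training rows per class")
    model = _build_model(model_id, len(y), seed, search_budget)
    with warnings.catch_warnings():
        # on strongly separable folds the GP amplitude saturates its bound;
        # the fitted classifier is fine, the retuning advice is not actionable
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X, dtype=float), y)
    if model_id == "voting_hard":
        return _HardVoteProba(model)
    return model


@dataclass
class FoldResult:
    held_out_id: str
    selected_keys: list[str]
    scaler_params: ScalerParams
    model_id: str
    predicted_prob: float
    predicted_label: bool
    true_label: bool
    # retained for the explanation stage (all leakage-free by construction)
    model: object = field(repr=False, default=None)
    X_train_scaled: pd.DataFrame | None = field(repr=False, default=None)
    x_test_scaled: pd.Series | None = field(repr=False, default=None)
    x_test_raw_imputed: pd.Series | None = field(repr=False, default=None)


@dataclass
class EvaluationSummary:
    accuracy: float
    tpr: float
    tnr: float
    confusion: dict[str, int]  # tp / fp / tn / fn
    roc: list[tuple[float, float]]  # (fpr, tpr) points
    auc: float
    majority_baseline: float
    n_selected_per_fold: list[int]

    @property
    def n_selected_mean(self) -> float:
        return float(np.mean(self.n_selected_per_fold))

    @property
    def n_selected_sd(self) -> float:
        return float(np.std(self.n_selected_per_fold, ddof=1))


def majority_baseline(labels: np.ndarray) -> float:
    """Accuracy of constantly predicting the most frequent class."""
    labels = np.asarray(labels, dtype=bool)
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    n_pos = labels.sum()
    return max(n_pos, len(labels) - n_pos) / len(labels)


def run_fold(
    cohort: CohortMatrix,
    held_out_id: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
    model_id: str = "gp",
    search_budget: int = 8,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> FoldResult:
    """One leave-one-out fold: select, impute+scale, fit, predict."""
    train_idx = cohort.X.index != held_out_id
    X_train = cohort.X.loc[train_idx]
    y_train = cohort.labels.loc[train_idx].to_numpy()

    selected = select_features(X_train, y_train, alpha=alpha, equal_var=equal_var)
    if not selected:
        # degenerate fold: keep the single most discriminative feature so a
        # prediction can still be issued (logged; does not occur under
        # realistic effect sizes)
        pvals = {}
        for col in X_train.columns:
            a = X_train.loc[y_train, col].dropna()
            b = X_train.loc[~y_train, col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                pvals[col] = scipy.stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        finite = {c: p for c, p in pvals.items() if np.isfinite(p)}
        if not finite:
            raise ValueError(f"fold {held_out_id}: no testable feature")
        selected = [min(finite, key=finite.get)]
        log.warning("fold %s: no feature passed screening; fell back to %s",
                    held_out_id, selected[0])

    scaler = fit_scaler(X_train[selected])
    Xs_train = apply_scaler(scaler, X_train[selected])
    model = train_classifier(
        Xs_train.to_numpy(), y_train, model_id=model_id,
        search_budget=search_budget, seed=seed,
    )

    x_raw = cohort.X.loc[[held_out_id], selected]
    xs = apply_scaler(scaler, x_raw)
    prob = float(model.predict_proba(xs.to_numpy())[0, 1])
    return FoldResult(
        held_out_id=held_out_id,
        selected_keys=list(selected),
        scaler_params=scaler,
        model_id=model_id,
        predicted_prob=prob,
        predicted_label=prob > decision_threshold,
        true_label=bool(cohort.labels.loc[held_out_id]),
        model=model,
        X_train_scaled=Xs_train,
        x_test_scaled=xs.iloc[0],
        x_test_raw_imputed=x_raw.fillna(scaler.mean).iloc[0],
    )


def summarize_folds(folds: list[FoldResult]) -> EvaluationSummary:
    y_true = np.array([f.true_label for f in folds])
    y_pred = np.array([f.predicted_label for f in folds])
    probs = np.array([f.predicted_prob for f in folds])
    tp = int((y_pred & y_true).sum())
    tn = int((~y_pred & ~y_true).sum())
    fp = int((y_pred & ~y_true).sum())
    fn = int((~y_pred & y_true).sum())
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    fpr, tpr, _ = roc_curve(y_true, probs)
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationSummary(
        accuracy=(tp + tn) / len(folds),
        tpr=tp / n_pos if n_pos else float("nan"),
        tnr=tn / n_neg if n_neg else float("nan"),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        majority_baseline=majority_baseline(y_true),
        n_selected_per_fold=[len(f.selected_keys) for f in folds],
    )


def loo_evaluate(
    cohort: CohortMatrix,
    *,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
    model_id: str = "gp",
    search_budget: int = 8,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> tuple[EvaluationSummary, list[FoldResult]]:
    """Leave-one-out evaluation over all participants.

    The reported accuracy is the average held-out accuracy across folds;
    TPR/TNR, the confusion matrix and a probability-sweep ROC come with it.
    """
    if cohort.n < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 participants")
    if cohort.labels.all() or not cohort.labels.any():
        raise ValueError("both classes must be present in the cohort")
    folds = []
    for pid in cohort.X.index:
        try:
            folds.append(
                run_fold(
                    cohort, pid, alpha=alpha, equal_var=equal_var, model_id=model_id,
                    search_budget=search_budget, seed=seed,
                    decision_threshold=decision_threshold,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"fold for participant {pid} failed: {exc}") from exc
    return summarize_folds(folds), folds
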