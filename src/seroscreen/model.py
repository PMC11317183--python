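"""RBF-kernel SVM diagnostic classifier with kernel-space RFE.

Training follows a fixed recipe: a stratified split into training and test
sets, a powers-of-two grid search for ``(C, gamma)`` by mean out-of-fold
AUROC, recursive feature elimination ranking features by the change in the
margin criterion

    J = 1/2 * sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)

when a feature's column is removed from the kernel with the dual
coefficients held fixed, a data-driven choice of the feature count by
cross-validated AUROC along the elimination path, and a decision threshold
anchored at a target specificity (default 90%) on the training-set scores of
the final model (out-of-fold scores supply the cross-validated sensitivity
at the same target).  Standardisation parameters, grid search, RFE and the
threshold all
depend on training data only; the test set is touched exactly once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .diagnostics import auc_score
from .errors import ConfigurationError, InsufficientDataError, ValidationError


def _pow2(lo: int, hi: int, step: int = 2) -> tuple[float, ...]:
    return tuple(float(2.0**e) for e in range(lo, hi + 1, step))


@dataclass
class ModelConfig:
    """Classifier hyper-parameters and search settings.

    The grid is the standard coarse powers-of-two lattice,
    C in 2^-5..2^15 and gamma in 2^-15..2^3 (step 2 in the exponent).
    """

    c_grid: tuple[float, ...] = field(default_factory=lambda: _pow2(-5, 15))
    gamma_grid: tuple[float, ...] = field(default_factory=lambda: _pow2(-15, 3))
    cv_folds: int = 4
    target_specificity: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not (0.0 < self.target_specificity < 1.0):
            raise ConfigurationError("target_specificity must lie in (0, 1)")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ConfigurationError("C and gamma must be positive")


@dataclass
class CohortSplit:
    train_cases: list[str]
    train_controls: list[str]
    test_cases: list[str]
    test_controls: list[str]

    @property
    def train_ids(self) -> list[str]:
        return self.train_cases + self.train_controls

    @property
    def test_ids(self) -> list[str]:
        return self.test_cases + self.test_controls


def split_cohort(
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    n_case_train: int,
    n_control_train: int,
    seed: int = 0,
) -> CohortSplit:
    """Seeded uniform split without replacement; the remainder is the test set."""
    cases = sorted(case_ids)
    controls = sorted(control_ids)
    if n_case_train > len(cases) or n_control_train > len(controls):
        raise ConfigurationError(
            f"requested training sizes ({n_case_train}/{n_control_train}) exceed "
            f"available samples ({len(cases)}/{len(controls)})"
        )
    rng = np.random.default_rng(seed)
    case_perm = rng.permutation(len(cases))
    ctrl_perm = rng.permutation(len(controls))
    split = CohortSplit(
        train_cases=sorted(cases[i] for i in case_perm[:n_case_train]),
        train_controls=sorted(controls[i] for i in ctrl_perm[:n_control_train]),
        test_cases=sorted(cases[i] for i in case_perm[n_case_train:]),
        test_controls=sorted(controls[i] for i in ctrl_perm[n_control_train:]),
    )
    if not split.test_cases and not split.test_controls:
        warnings.warn("training sizes equal cohort totals: test set is empty")
    return split


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """Per-feature z-scoring with training statistics (population SD)."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, x: pd.DataFrame) -> "Scaler":
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return cls(mean=mean, sd=sd)

    def transform(self, x: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.mean.index if c not in x.columns]
        if missing:
            raise ValidationError(f"features absent from data: {missing[:5]}")
        x = x[self.mean.index]
        return (x - self.mean) / self.sd


# ---------------------------------------------------------------------------
# cross-validated AUROC
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _cv_fold_scores(
    x: pd.DataFrame, y: np.ndarray, c: float, gamma: float, folds
) -> tuple[np.ndarray, list[float]]:
    """Out-of-fold decision scores plus per-fold AUROCs.

    Standardisation is refit inside every fold so no validation information
    leaks into the per-fold models.
    """
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for tr, va in folds:
        scaler = Scaler.fit(x.iloc[tr])
        svc = SVC(C=c, gamma=gamma, kernel="rbf")
        svc.fit(scaler.transform(x.iloc[tr]).to_numpy(), y[tr])
        scores = svc.decision_function(scaler.transform(x.iloc[va]).to_numpy())
        oof[va] = scores
        fold_aucs.append(auc_score(scores[y[va] == 1], scores[y[va] == 0]))
    return oof, fold_aucs


def grid_search(
    x: pd.DataFrame, y: np.ndarray, config: ModelConfig
) -> tuple[float, float, pd.DataFrame]:
    """Pick ``(C, gamma)`` maximising mean out-of-fold AUROC.

    Ties break toward smaller C, then smaller gamma.  Returns the winning
    pair plus the full search table.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("grid search requires both classes in training data")
    counts = np.bincount(y)
    if counts.min() < config.cv_folds:
        raise InsufficientDataError(
            f"need >= {config.cv_folds} samples per class for {config.cv_folds}-fold CV"
        )
    folds = _stratified_folds(y, config.cv_folds, config.seed)
    records = []
    best = (-np.inf, None, None)
    for c in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            _, fold_aucs = _cv_fold_scores(x, y, c, gamma, folds)
            mean_auc = float(np.mean(fold_aucs))
            records.append((c, gamma, mean_auc))
            if mean_auc > best[0]:
                best = (mean_auc, c, gamma)
    table = pd.DataFrame(records, columns=["C", "gamma", "cv_auroc"])
    return best[1], best[2], table


# ---------------------------------------------------------------------------
# recursive feature elimination (kernel Delta-J criterion)
# ---------------------------------------------------------------------------


def _margin_criterion(ay: np.ndarray, kernel: np.ndarray) -> float:
    return 0.5 * float(ay @ kernel @ ay)


def rfe_rank(
    x: pd.DataFrame, y: np.ndarray, c: float, gamma: float
) -> list[str]:
    """Rank features by iterative elimination of the smallest ``|Delta J|``.

    ``x`` must already be standardised with training statistics.  At each
    round the SVM is fit on the surviving features; for every feature the
    kernel is re-evaluated with that feature's column removed (dual
    coefficients held fixed) and the feature whose removal changes the margin
    criterion least is eliminated (ties to the lowest feature index).
    Returns feature names in elimination order: first eliminated (least
    important) to last survivor (most important).
    """
    y = np.asarray(y, dtype=int)
    features = list(x.columns)
    data = x.to_numpy(dtype=float)
    order: list[str] = []
    current = list(range(data.shape[1]))
    round_no = 0
    while len(current) > 1:
        round_no += 1
        try:
            svc = SVC(C=c, gamma=gamma, kernel="rbf")
            svc.fit(data[:, current], y)
        except Exception as exc:  # pragma: no cover - solver failure surface
            raise ValidationError(f"SVM solver failed in RFE round {round_no}: {exc}") from exc
        sv = data[np.ix_(svc.support_, current)]
        ay = svc.dual_coef_[0]
        kernel = rbf_kernel(sv, sv, gamma=gamma)
        j_full = _margin_criterion(ay, kernel)
        deltas = np.empty(len(current))
        for pos in range(len(current)):
            col = sv[:, pos]
            sq = (col[:, None] - col[None, :]) ** 2
            # removing feature f multiplies the RBF kernel by exp(+gamma d_f^2)
            j_minus = _margin_criterion(ay, kernel * np.exp(gamma * sq))
            deltas[pos] = abs(j_full - j_minus)
        drop = int(np.argmin(deltas))  # argmin takes the first, i.e. lowest index
        order.append(features[current[drop]])
        current.pop(drop)
    order.append(features[current[0]])
    return order


def rfe_delta_j(
    x: pd.DataFrame, y: np.ndarray, c: float, gamma: float
) -> pd.Series:
    """One-round ``|Delta J|`` per feature for the SVM fit on all features."""
    y = np.asarray(y, dtype=int)
    data = x.to_numpy(dtype=float)
    svc = SVC(C=c, gamma=gamma, kernel="rbf")
    svc.fit(data, y)
    sv = data[svc.support_]
    ay = svc.dual_coef_[0]
    kernel = rbf_kernel(sv, sv, gamma=gamma)
    j_full = _margin_criterion(ay, kernel)
    out = {}
    for pos, name in enumerate(x.columns):
        col = sv[:, pos]
        sq = (col[:, None] - col[None, :]) ** 2
        out[name] = abs(j_full - _margin_criterion(ay, kernel * np.exp(gamma * sq)))
    return pd.Series(out)


def select_feature_count(
    x: pd.DataFrame,
    y: np.ndarray,
    elimination_order: Sequence[str],
    c: float,
    gamma: float,
    config: ModelConfig,
) -> tuple[int, list[str], pd.DataFrame]:
    """Choose the feature count maximising mean out-of-fold AUROC.

    For each k along the elimination path the survivors are the k features
    eliminated last; ties in AUROC break toward the smallest k.  Returns
    ``(k, selected_features, path_table)`` with the selected features in
    original column order.
    """
    y = np.asarray(y, dtype=int)
    order = list(elimination_order)
    folds = _stratified_folds(y, config.cv_folds, config.seed)
    records = []
    best_k, best_auc = None, -np.inf
    for k in range(1, len(order) + 1):
        survivors = order[len(order) - k:]
        cols = [f for f in x.columns if f in survivors]
        _, fold_aucs = _cv_fold_scores(x[cols], y, c, gamma, folds)
        mean_auc = float(np.mean(fold_aucs))
        records.append((k, mean_auc))
        if mean_auc > best_auc:
            best_auc, best_k = mean_auc, k
    survivors = order[len(order) - best_k:]
    selected = [f for f in x.columns if f in survivors]
    return best_k, selected, pd.DataFrame(records, columns=["k", "cv_auroc"])


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------


def calibrate_threshold(
    scores: np.ndarray, y: np.ndarray, target_specificity: float = 0.90
) -> float:
    """Smallest observed score achieving the target specificity on controls.

    A sample is called positive when its score is >= the threshold, so the
    specificity at threshold t is the fraction of control scores strictly
    below t.  If even the largest score cannot reach the target, the
    threshold is placed just above the maximum score with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    controls = scores[y == 0]
    if controls.size == 0:
        raise InsufficientDataError("threshold calibration requires control scores")
    for t in np.unique(scores):
        if np.mean(controls < t) >= target_specificity:
            return float(t)
    warnings.warn("target specificity unreachable; threshold set above all scores")
    eps = 1e-9 * max(1.0, abs(float(scores.max())))
    return float(scores.max()) + eps


# ---------------------------------------------------------------------------
# trained model artifact
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted RBF-SVM with its preprocessing and calibrated threshold.

    Stores everything needed to score new samples: selected features, the
    training standardisation, the support-vector expansion (dual
    coefficients ``alpha_i y_i``, support vectors, bias) and the decision
    threshold.
    """

    feature_ids: list[str]
    scaler: Scaler
    c: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i over support vectors
    intercept: float
    threshold: float
    cv_auroc_pooled: float = float("nan")
    cv_auroc_mean: float = float("nan")
    cv_sensitivity: float = float("nan")
    cv_specificity: float = float("nan")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValidationError("a trained model must keep at least one feature")
        if np.any(np.abs(self.dual_coef) > self.c * (1 + 1e-8)):
            raise ValidationError("dual coefficients violate the box constraint")

    @property
    def kkt_residual(self) -> float:
        """|sum alpha_i y_i|, zero at optimality up to solver tolerance."""
        return float(abs(self.dual_coef.sum()))

    def decision_scores(self, x: pd.DataFrame) -> np.ndarray:
        xs = self.scaler.transform(x[self.feature_ids]).to_numpy(dtype=float)
        kernel = rbf_kernel(xs, self.support_vectors, gamma=self.gamma)
        return kernel @ self.dual_coef + self.intercept

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return (self.decision_scores(x) >= self.threshold).astype(int)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "seroscreen-model-v1",
            "feature_ids": self.feature_ids,
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_sd": self.scaler.sd.tolist(),
            "C": self.c,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "cv_auroc_pooled": self.cv_auroc_pooled,
            "cv_auroc_mean": self.cv_auroc_mean,
            "cv_sensitivity": self.cv_sensitivity,
            "cv_specificity": self.cv_specificity,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        if d.get("format") != "seroscreen-model-v1":
            raise ValidationError(f"unknown model format {d.get('format')!r}")
        features = list(d["feature_ids"])
        return cls(
            feature_ids=features,
            scaler=Scaler(
                mean=pd.Series(d["scaler_mean"], index=features),
                sd=pd.Series(d["scaler_sd"], index=features),
            ),
            c=float(d["C"]),
            gamma=float(d["gamma"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            cv_auroc_pooled=float(d["cv_auroc_pooled"]),
            cv_auroc_mean=float(d["cv_auroc_mean"]),
            cv_sensitivity=float(d["cv_sensitivity"]),
            cv_specificity=float(d["cv_specificity"]),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _calibration_optimism(
    x: pd.DataFrame,
    y: np.ndarray,
    c: float,
    gamma: float,
    folds,
    target: float,
) -> float:
    """Mean specificity shortfall of resubstitution-calibrated thresholds.

    For every fold, a model fit on the fold's training part is thresholded at
    the target specificity on its *own* training scores; the shortfall of the
    specificity actually reached on the held-out controls estimates the
    optimism of that calibration.  Clipped at zero.
    """
    shortfalls = []
    for tr, va in folds:
        scaler = Scaler.fit(x.iloc[tr])
        svc = SVC(C=c, gamma=gamma, kernel="rbf")
        svc.fit(scaler.transform(x.iloc[tr]).to_numpy(), y[tr])
        thr = calibrate_threshold(
            svc.decision_function(scaler.transform(x.iloc[tr]).to_numpy()), y[tr], target
        )
        va_scores = svc.decision_function(scaler.transform(x.iloc[va]).to_numpy())
        va_controls = va_scores[y[va] == 0]
        if va_controls.size:
            shortfalls.append(target - float(np.mean(va_controls < thr)))
    return max(0.0, float(np.mean(shortfalls))) if shortfalls else 0.0


@dataclass
class TrainingReport:
    model: TrainedModel
    best_c: float
    best_gamma: float
    grid_table: pd.DataFrame
    elimination_order: list[str]
    feature_path: pd.DataFrame
    oof_scores: pd.Series  # out-of-fold decision scores per training sample


def train_classifier(
    x_train: pd.DataFrame, y_train: np.ndarray, config: ModelConfig | None = None
) -> TrainingReport:
    """End-to-end training: grid search, RFE, k selection, threshold, final fit."""
    config = config or ModelConfig()
    y = np.asarray(y_train, dtype=int)
    best_c, best_gamma, grid_table = grid_search(x_train, y, config)

    scaler_full = Scaler.fit(x_train)
    order = rfe_rank(scaler_full.transform(x_train), y, best_c, best_gamma)
    _, selected, path = select_feature_count(x_train, y, order, best_c, best_gamma, config)

    folds = _stratified_folds(y, config.cv_folds, config.seed)
    oof, fold_aucs = _cv_fold_scores(x_train[selected], y, best_c, best_gamma, folds)
    # CV operating point: out-of-fold threshold applied to out-of-fold scores,
    # so both sides live on the fold models' score scale
    oof_threshold = calibrate_threshold(oof, y, config.target_specificity)
    cv_sens = float(np.mean(oof[y == 1] >= oof_threshold))
    cv_spec = float(np.mean(oof[y == 0] < oof_threshold))

    # a threshold calibrated on a model's own training scores overstates
    # specificity on unseen controls; estimate that optimism fold-wise and
    # raise the calibration target to compensate (training data only)
    optimism = _calibration_optimism(
        x_train[selected], y, best_c, best_gamma, folds, config.target_specificity
    )
    n_controls = int((y == 0).sum())
    adjusted_target = min(
        config.target_specificity + optimism, 1.0 - 0.5 / max(n_controls, 1)
    )

    scaler = Scaler.fit(x_train[selected])
    svc = SVC(C=best_c, gamma=best_gamma, kernel="rbf")
    svc.fit(scaler.transform(x_train[selected]).to_numpy(), y)
    # decision threshold: the training-set score reaching the (optimism
    # corrected) target specificity under the final model, so threshold and
    # test scores share one scoring function (fold models score on a
    # different scale)
    train_scores = svc.decision_function(scaler.transform(x_train[selected]).to_numpy())
    threshold = calibrate_threshold(train_scores, y, adjusted_target)
    model = TrainedModel(
        feature_ids=selected,
        scaler=scaler,
        c=best_c,
        gamma=best_gamma,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        threshold=threshold,
        cv_auroc_pooled=auc_score(oof[y == 1], oof[y == 0]),
        cv_auroc_mean=float(np.mean(fold_aucs)),
        cv_sensitivity=cv_sens,
        cv_specificity=cv_spec,
        seed=config.seed,
    )
    return TrainingReport(
        model=model,
        best_c=best_c,
        best_gamma=best_gamma,
        grid_table=grid_table,
        elimination_order=order,
        feature_path=path,
        oof_scores=pd.Series(oof, index=x_train.index),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    auroc: float
    sensitivity: float
    specificity: float
    n_case: int
    n_control: int
    sensitivity_acpa_positive: float
    sensitivity_acpa_negative: float
    n_acpa_positive: int
    n_acpa_negative: int
    threshold: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate(
    model: TrainedModel,
    x_test: pd.DataFrame,
    y_test: np.ndarray,
    acpa_status: Sequence[str] | None = None,
) -> EvalReport:
    """Score a held-out set: AUROC plus operating-point and ACPA-stratified rates."""
    y = np.asarray(y_test, dtype=int)
    scores = model.decision_scores(x_test)
    cases = scores[y == 1]
    controls = scores[y == 0]
    auroc = auc_score(cases, controls)
    sens = float(np.mean(cases >= model.threshold)) if cases.size else float("nan")
    spec = float(np.mean(controls < model.threshold)) if controls.size else float("nan")
    sens_pos = sens_neg = float("nan")
    n_pos = n_neg = 0
    if acpa_status is not None:
        status = np.asarray(list(acpa_status))
        pos_mask = (y == 1) & (status == "positive")
        neg_mask = (y == 1) & (status == "negative")
        n_pos, n_neg = int(pos_mask.sum()), int(neg_mask.sum())
        if n_pos:
            sens_pos = float(np.mean(scores[pos_mask] >= model.threshold))
        if n_neg:
            sens_neg = float(np.mean(scores[neg_mask] >= model.threshold))
    return EvalReport(
        auroc=auroc,
        sensitivity=sens,
        specificity=spec,
        n_case=int(cases.size),
        n_control=int(controls.size),
        sensitivity_acpa_positive=sens_pos,
        sensitivity_acpa_negative=sens_neg,
        n_acpa_positive=n_pos,
        n_acpa_negative=n_neg,
        threshold=model.threshold,
    )


def compare_single_markers(
    train_markers: pd.DataFrame,
    y_train: np.ndarray,
    test_markers: pd.DataFrame,
    y_test: np.ndarray,
    target_specificity: float = 0.90,
    combinations: Sequence[tuple[str, ...]] = (),
    model_sensitivity: float | None = None,
) -> pd.DataFrame:
    """Sensitivity of single markers (and OR-combinations) at matched specificity.

    Each marker is dichotomised at the smallest training value whose
    specificity on training controls reaches the target; a combination is
    positive when any member is positive.  Samples with a missing marker
    value are excluded and counted.
    """
    y_tr = np.asarray(y_train, dtype=int)
    y_te = np.asarray(y_test, dtype=int)
    cutoffs: dict[str, float] = {}
    for marker in train_markers.columns:
        vals = train_markers[marker].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        cutoffs[marker] = calibrate_threshold(vals[ok], y_tr[ok], target_specificity)

    def _rates(name: str, members: tuple[str, ...]) -> dict:
        sub = test_markers[list(members)].to_numpy(dtype=float)
        ok = ~np.isnan(sub).any(axis=1)
        pos = np.zeros(len(test_markers), dtype=bool)
        for j, m in enumerate(members):
            pos |= np.nan_to_num(sub[:, j], nan=-np.inf) >= cutoffs[m]
        case = ok & (y_te == 1)
        ctrl = ok & (y_te == 0)
        return {
            "marker": name,
            "sensitivity": float(pos[case].mean()) if case.any() else float("nan"),
            "specificity": float((~pos[ctrl]).mean()) if ctrl.any() else float("nan"),
            "n_excluded": int((~ok).sum()),
        }

    rows = [_rates(m, (m,)) for m in test_markers.columns]
    rows += [_rates("+".join(combo), tuple(combo)) for combo in combinations]
    if model_sensitivity is not None:
        rows.insert(0, {
            "marker": "model",
            "sensitivity": float(model_sensitivity),
            "specificity": float("nan"),
            "n_excluded": 0,
        })
    return pd.DataFrame(rows)
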