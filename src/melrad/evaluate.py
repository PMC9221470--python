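"""Model training and evaluation: repeated cross-validation of the baseline
(clinical-only) and extended (clinical + selected radiomic) extremely
randomized forests, with bootstrap confidence intervals for the mean AUC and
bootstrap mean ROC curves.

Evaluation design
-----------------
Patients are randomly assigned to K folds, repeated R times (default 10 x
5-fold).  Within each fold, preprocessing and FCBF selection are fitted on
the training split only; the two models are trained and applied on identical
splits.  Out-of-fold scores are pooled per repetition into one AUC; the
point estimate is the mean over repetitions.  For the 95% CI, B patient-level
bootstrap resamples are drawn once and reused across repetitions and across
the models being compared; per resample, the pooled AUC is computed per
repetition and averaged, and the CI is the 2.5th/97.5th percentile of the B
means.  Two models differ significantly when their CIs do not overlap; a
model is predictive when its CI lower bound exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .endpoints import (
    CLINICAL_FEATURE_KINDS,
    PreprocessorState,
    apply_preprocessor,
    fit_preprocessor,
)
from .fcbf import SelectionResult, discretize, fcbf

# ---------------------------------------------------------------------------
# CV scheme
# ---------------------------------------------------------------------------


@dataclass
class CVScheme:
    """Repeated K-fold assignment: R repetitions of a random, unstratified
    partition of the patients into K validation folds."""

    repetitions: int = 10
    folds: int = 5
    seed: int = 0

    def assignments(self, n: int) -> np.ndarray:
        """(R, n) array of fold indices in 0..K-1."""
        rng = np.random.default_rng(self.seed)
        out = np.empty((self.repetitions, n), dtype=int)
        for r in range(self.repetitions):
            perm = rng.permutation(n)
            folds = np.array_split(perm, self.folds)
            for k, idx in enumerate(folds):
                out[r, idx] = k
        return out


@dataclass
class PredictionSet:
    """Out-of-fold probability scores: one score per patient per repetition."""

    endpoint: str
    model: str
    patient_ids: np.ndarray  # (n,)
    labels: np.ndarray  # (n,) in {0,1}
    scores: np.ndarray  # (R, n) in [0,1]

    @property
    def n_repetitions(self) -> int:
        return self.scores.shape[0]


@dataclass
class AUCSummary:
    """Mean pooled AUC over repetitions with a percentile-bootstrap 95% CI."""

    endpoint: str
    model: str
    point: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_patients: int

    @property
    def predictive(self) -> bool:
        return self.ci_low > 0.5

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "model": self.model,
            "auc": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "n_patients": self.n_patients,
            "predictive": self.predictive,
        }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr_mean: np.ndarray
    tpr_low: np.ndarray
    tpr_high: np.ndarray


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def train_model(X: np.ndarray, y: np.ndarray, seed: int) -> ExtraTreesClassifier:
    """Fit an extremely randomized forest (default hyperparameters, row
    bootstrapping enabled, seeded)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class; cannot fit")
    clf = ExtraTreesClassifier(n_estimators=100, bootstrap=True, random_state=seed)
    clf.fit(X, y)
    return clf


def predict_scores(clf: ExtraTreesClassifier, X: np.ndarray) -> np.ndarray:
    return clf.predict_proba(X)[:, 1]


def pooled_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic ROC AUC with half-credit for score ties."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def _fast_auc(scores: np.ndarray, labels01: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (positive labels == 1)."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n1 = labels01.sum()
    n0 = labels01.size - n1
    return (r[labels01 == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ---------------------------------------------------------------------------
# repeated CV
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    baseline: PredictionSet
    extended: PredictionSet | None
    fold_assignments: np.ndarray  # (R, n)
    selection_logs: list[dict] = field(default_factory=list)
    redraws: list[int] = field(default_factory=list)


def run_repeated_cv(
    clinical: pd.DataFrame,
    radiomic: pd.DataFrame | None,
    labels: pd.Series,
    scheme: CVScheme | None = None,
    fcbf_delta: float = 0.0,
    model_seed: int = 0,
) -> CVResult:
    """Evaluate the baseline (and, when radiomic features are given, the
    extended) model in repeated K-fold CV on one endpoint.

    clinical / radiomic are feature tables indexed by patient_id; labels is
    the endpoint series (its index defines the included patients).  Both
    models see identical fold assignments.  A repetition whose training
    folds do not contain both classes is redrawn with a shifted seed (and
    logged).
    """
    scheme = scheme or CVScheme()
    pids = labels.index.to_numpy()
    n = len(pids)
    if n < 5 * scheme.folds:
        raise ValueError(f"only {n} included patients; need >= {5 * scheme.folds}")
    y = labels.to_numpy()
    clin = clinical.loc[pids]
    rad = radiomic.loc[pids] if radiomic is not None else None

    assignments = scheme.assignments(n)
    redraws: list[int] = []
    for r in range(scheme.repetitions):
        bump = 0
        while _bad_assignment(assignments[r], y, scheme.folds):
            bump += 1
            rng = np.random.default_rng(scheme.seed + 100_000 + 1000 * r + bump)
            perm = rng.permutation(n)
            folds = np.array_split(perm, scheme.folds)
            for k, idx in enumerate(folds):
                assignments[r, idx] = k
            redraws.append(r)

    base_scores = np.full((scheme.repetitions, n), np.nan)
    ext_scores = np.full((scheme.repetitions, n), np.nan) if rad is not None else None
    logs: list[dict] = []

    for r in range(scheme.repetitions):
        for k in range(scheme.folds):
            val = assignments[r] == k
            tr = ~val
            seed = model_seed + 7919 * r + k
            state = fit_preprocessor(clin.iloc[tr], CLINICAL_FEATURE_KINDS)
            Xtr_c = apply_preprocessor(state, clin.iloc[tr])
            Xva_c = apply_preprocessor(state, clin.iloc[val])

            clf = train_model(Xtr_c, y[tr], seed)
            base_scores[r, val] = predict_scores(clf, Xva_c)

            if rad is None:
                continue
            rad_kinds = {c: "continuous" for c in rad.columns}
            rstate = fit_preprocessor(rad.iloc[tr], rad_kinds)
            Xtr_r = apply_preprocessor(rstate, rad.iloc[tr])
            Xva_r = apply_preprocessor(rstate, rad.iloc[val])
            sel = fcbf(discretize(Xtr_r), y[tr], list(rad.columns), delta=fcbf_delta)
            cols = [rad.columns.get_loc(c) for c in sel.selected]
            logs.append({
                "repetition": r,
                "fold": k,
                "n_selected": len(sel.selected),
                "selected": sel.selected,
                "su_to_class": [sel.su_to_class[c] for c in sel.selected],
            })
            Xtr_e = np.hstack([Xtr_c, Xtr_r[:, cols]])
            Xva_e = np.hstack([Xva_c, Xva_r[:, cols]])
            eclf = train_model(Xtr_e, y[tr], seed)
            ext_scores[r, val] = predict_scores(eclf, Xva_e)

    baseline = PredictionSet("", "baseline", pids, y, base_scores)
    extended = (
        PredictionSet("", "extended", pids, y, ext_scores) if ext_scores is not None else None
    )
    if isinstance(labels.name, str):
        baseline.endpoint = labels.name
        if extended is not None:
            extended.endpoint = labels.name
    return CVResult(baseline, extended, assignments, logs, redraws)


def _bad_assignment(assign: np.ndarray, y: np.ndarray, k: int) -> bool:
    for fold in range(k):
        tr = y[assign != fold]
        if len(np.unique(tr)) < 2:
            return True
    return False


# ---------------------------------------------------------------------------
# bootstrap summaries
# ---------------------------------------------------------------------------


def bootstrap_indices(n: int, B: int, seed: int) -> np.ndarray:
    """(B, n) patient-level resample indices, to be shared across the
    repetitions and across the models under comparison."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


def bootstrap_auc_ci(
    ps: PredictionSet,
    B: int = 1000,
    seed: int = 0,
    indices: np.ndarray | None = None,
    max_redraws: int = 1000,
) -> AUCSummary:
    """Percentile-bootstrap 95% CI for the mean AUC over repetitions.

    A resample leaving a single class is redrawn (logged via counter,
    capped).  The point estimate is the plain mean of the pooled AUC over
    repetitions on the full sample.
    """
    n = ps.labels.size
    if indices is None:
        indices = bootstrap_indices(n, B, seed)
    y = ps.labels
    point = float(np.mean([pooled_auc(ps.scores[r], y) for r in range(ps.n_repetitions)]))
    rng = np.random.default_rng(seed + 1)
    means = np.empty(indices.shape[0])
    redraws = 0
    for b in range(indices.shape[0]):
        idx = indices[b]
        while len(np.unique(y[idx])) < 2:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            idx = rng.integers(0, n, size=n)
        yb = y[idx]
        means[b] = np.mean([_fast_auc(ps.scores[r][idx], yb) for r in range(ps.n_repetitions)])
    lo, hi = np.percentile(means, [2.5, 97.5])
    return AUCSummary(
        endpoint=ps.endpoint,
        model=ps.model,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_bootstrap=indices.shape[0],
        n_patients=n,
    )


def mean_roc(
    ps: PredictionSet,
    B: int = 1000,
    seed: int = 0,
    n_grid: int = 101,
    indices: np.ndarray | None = None,
) -> ROCCurve:
    """Bootstrap mean ROC curve: at each FPR grid point, the TPR (linearly
    interpolated per repetition, averaged over repetitions) is bootstrapped
    on patient level; the band is the 2.5th/97.5th percentile."""
    n = ps.labels.size
    grid = np.linspace(0.0, 1.0, n_grid)
    if indices is None:
        indices = bootstrap_indices(n, B, seed)
    y = ps.labels
    rng = np.random.default_rng(seed + 1)
    curves = np.empty((indices.shape[0], n_grid))
    for b in range(indices.shape[0]):
        idx = indices[b]
        while len(np.unique(y[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        curves[b] = np.mean(
            [_interp_roc(ps.scores[r][idx], y[idx], grid) for r in range(ps.n_repetitions)],
            axis=0,
        )
    tpr_mean = np.maximum.accumulate(curves.mean(axis=0))
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return ROCCurve(grid, tpr_mean, np.maximum.accumulate(lo), np.maximum.accumulate(hi))


def _interp_roc(scores: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    fpr, tpr, _ = roc_curve(y, scores)
    return np.interp(grid, fpr, tpr)


def compare_models(a: AUCSummary, b: AUCSummary) -> dict:
    """CI-overlap comparison plus per-model predictivity."""
    if a.endpoint != b.endpoint:
        raise ValueError(f"cannot compare different endpoints: {a.endpoint} vs {b.endpoint}")
    overlap = (a.ci_low <= b.ci_high) and (b.ci_low <= a.ci_high)
    return {
        "endpoint": a.endpoint,
        "significantly_different": not overlap,
        f"{a.model}_predictive": a.predictive,
        f"{b.model}_predictive": b.predictive,
        "delta_auc": b.point - a.point,
    }
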