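"""Five-member consensus habitat-suitability model with AUC/TSS evaluation.

The member families follow standard species-distribution-modelling practice:

``linear_logistic``
    logistic regression on linear + quadratic terms per variable (GLM);
``spline_logistic``
    logistic regression on a cubic spline basis per variable (GAM stand-in);
``boosted_trees``
    gradient-boosted classification trees (depth <= 3, 500 trees);
``random_forest``
    random forest (500 trees);
``maxent_like``
    L1-penalized logistic regression on linear + quadratic + pairwise
    product features, using the background sample as the contrast class —
    the established equivalence between MaxEnt and penalized logistic
    regression on background points.

The consensus prediction is the unweighted mean of member suitabilities (a
TSS-weighted mean is available).  Because background samples vastly
outnumber presences (10,000 vs a few hundred), absence rows are
down-weighted so the total class weights are equal.

Evaluation is authored here rather than delegated: AUC as the rank
(Mann-Whitney) statistic with ties counted half, and TSS as
``max_t (sensitivity(t) + specificity(t) - 1)`` swept over the observed
prediction values as thresholds (classification rule: predicted >= t means
presence; the largest maximizing threshold is reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .raster import EnvStack, RasterGrid

__all__ = [
    "MEMBER_KINDS",
    "MemberModel",
    "FittedEnsemble",
    "EvaluationResult",
    "fit_member",
    "fit_ensemble",
    "predict_ensemble",
    "evaluate",
    "auc_score",
    "tss_score",
    "binarize",
]

MEMBER_KINDS = (
    "linear_logistic",
    "spline_logistic",
    "boosted_trees",
    "random_forest",
    "maxent_like",
)


# ---------------------------------------------------------------------------
# feature recipes


def _poly_features(X: np.ndarray, pairwise: bool) -> np.ndarray:
    cols = [X, X**2]
    if pairwise:
        n = X.shape[1]
        prods = [X[:, i] * X[:, j] for i in range(n) for j in range(i + 1, n)]
        if prods:
            cols.append(np.column_stack(prods))
    return np.hstack(cols)


@dataclass
class MemberModel:
    """One fitted suitability model; ``predict`` maps raw layer rows to [0,1]."""

    kind: str
    estimator: object
    feature_names: list[str]
    kept_columns: np.ndarray  # indices into the raw layer table

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        if self.kind in ("linear_logistic", "maxent_like"):
            X = _poly_features(X, pairwise=self.kind == "maxent_like")
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


def _drop_constant(X_p: np.ndarray, X_a: np.ndarray, names):
    X = np.vstack([X_p, X_a])
    keep = np.flatnonzero(X.std(axis=0) > 0)
    if keep.size < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep.tolist())]
        warnings.warn(f"dropping constant layer(s) for linear model: {dropped}")
    if keep.size == 0:
        raise ValueError("all layers constant; cannot fit")
    return keep


def fit_member(
    kind: str,
    train_presence_rows: np.ndarray,
    train_absence_rows: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> MemberModel:
    """Fit one ensemble member on raw extracted layer rows.

    Requires at least 10 presence and 10 absence rows with no missing
    values.  Absences are down-weighted so total class weights balance.
    Stochastic members (trees, forests) are seeded.
    """
    if kind not in MEMBER_KINDS:
        raise ValueError(f"unknown member kind {kind!r}; expected one of {MEMBER_KINDS}")
    X_p = np.asarray(train_presence_rows, dtype=float)
    X_a = np.asarray(train_absence_rows, dtype=float)
    if len(X_p) < 10 or len(X_a) < 10:
        raise ValueError("need >= 10 presence and >= 10 absence training rows")
    if np.isnan(X_p).any() or np.isnan(X_a).any():
        raise ValueError("training rows contain missing values; drop flagged rows first")
    n_layers = X_p.shape[1]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(n_layers)]

    if kind in ("linear_logistic", "spline_logistic", "maxent_like"):
        kept = _drop_constant(X_p, X_a, feature_names)
    else:
        kept = np.arange(n_layers)
    X_p, X_a = X_p[:, kept], X_a[:, kept]

    y = np.concatenate([np.ones(len(X_p)), np.zeros(len(X_a))])
    w = np.concatenate(
        [np.ones(len(X_p)), np.full(len(X_a), len(X_p) / len(X_a))]
    )
    X = np.vstack([X_p, X_a])

    if kind == "linear_logistic":
        X = _poly_features(X, pairwise=False)
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, C=10.0)),
            ]
        )
    elif kind == "spline_logistic":
        est = Pipeline(
            [
                (
                    "spline",
                    SplineTransformer(
                        n_knots=5, degree=3, knots="quantile", include_bias=False
                    ),
                ),
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, C=10.0)),
            ]
        )
    elif kind == "maxent_like":
        X = _poly_features(X, pairwise=True)
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegression(
                        l1_ratio=1.0, C=1.0, solver="liblinear",
                        max_iter=2000, random_state=seed,
                    ),
                ),
            ]
        )
    elif kind == "boosted_trees":
        est = GradientBoostingClassifier(
            n_estimators=500, max_depth=3, learning_rate=0.05, random_state=seed
        )
    else:  # random_forest
        est = RandomForestClassifier(
            n_estimators=500, random_state=seed, n_jobs=1, min_samples_leaf=2
        )

    fit_kwargs = {}
    if isinstance(est, Pipeline):
        fit_kwargs["clf__sample_weight"] = w
    else:
        fit_kwargs["sample_weight"] = w
    est.fit(X, y, **fit_kwargs)
    return MemberModel(
        kind=kind,
        estimator=est,
        feature_names=[feature_names[i] for i in kept],
        kept_columns=kept,
    )


# ---------------------------------------------------------------------------
# evaluation statistics


def auc_score(presence_scores, absence_scores) -> float:
    """Rank-based AUC (Mann-Whitney statistic); ties counted half."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if len(p) == 0 or len(a) == 0:
        raise ValueError("need at least one presence and one absence score")
    ranks = rankdata(np.concatenate([p, a]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(a)))


def tss_score(presence_scores, absence_scores) -> tuple[float, float]:
    """Max of sensitivity + specificity - 1 over observed thresholds.

    The rule "predicted >= t is presence" is swept over the sorted unique
    predicted values; returns ``(tss, threshold)`` with the largest
    threshold attaining the maximum.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    thresholds = np.unique(np.concatenate([p, a]))[::-1]  # descending
    best_tss, best_t = -np.inf, thresholds[0]
    for t in thresholds:
        sens = np.mean(p >= t)
        spec = np.mean(a < t)
        tss = sens + spec - 1
        if tss > best_tss:  # ties keep the earlier (larger) threshold
            best_tss, best_t = tss, t
    return float(best_tss), float(best_t)


@dataclass
class EvaluationResult:
    auc: float
    tss: float
    tss_threshold: float
    n_test_presence: int
    n_test_absence: int


def evaluate(model, test_presence_rows, test_absence_rows) -> EvaluationResult:
    """Score a member or ensemble on held-out presence/absence rows.

    *model* is anything with a ``predict(rows) -> [0,1]`` method.  If all
    predictions are identical the result is AUC 0.5, TSS 0, with a warning.
    """
    X_p = np.asarray(test_presence_rows, dtype=float)
    X_a = np.asarray(test_absence_rows, dtype=float)
    if len(X_p) < 1 or len(X_a) < 1:
        raise ValueError("need >= 1 test presence and absence row")
    sp = model.predict(X_p)
    sa = model.predict(X_a)
    if np.ptp(np.concatenate([sp, sa])) == 0:
        warnings.warn("all predictions identical; AUC=0.5, TSS=0")
        return EvaluationResult(0.5, 0.0, float(sp[0]), len(X_p), len(X_a))
    auc = auc_score(sp, sa)
    tss, thr = tss_score(sp, sa)
    return EvaluationResult(auc, tss, thr, len(X_p), len(X_a))


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class FittedEnsemble:
    """Five member models plus the consensus rule and their evaluations."""

    members: list[MemberModel]
    consensus_rule: str = "mean"
    evaluations: dict[str, EvaluationResult] = field(default_factory=dict)
    feature_names: list[str] | None = None  # raw-layer order used in training

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.members])

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self.member_predictions(X)
        if self.consensus_rule == "mean":
            return P.mean(axis=1)
        if self.consensus_rule == "tss_weighted_mean":
            w = np.array(
                [max(self.evaluations[m.kind].tss, 0.0) for m in self.members]
            )
            if w.sum() == 0:
                return P.mean(axis=1)
            return P @ (w / w.sum())
        raise ValueError(f"unknown consensus rule {self.consensus_rule!r}")


def fit_ensemble(
    train_presence_rows,
    train_absence_rows,
    seed: int = 0,
    kinds=MEMBER_KINDS,
    consensus_rule: str = "mean",
    feature_names: list[str] | None = None,
) -> FittedEnsemble:
    """Fit all member kinds on the same training rows."""
    members = [
        fit_member(k, train_presence_rows, train_absence_rows,
                   seed=seed + i, feature_names=feature_names)
        for i, k in enumerate(kinds)
    ]
    return FittedEnsemble(
        members=members, consensus_rule=consensus_rule, feature_names=feature_names
    )


def predict_ensemble(ens: FittedEnsemble, stack: EnvStack) -> RasterGrid:
    """Consensus suitability over every valid cell of *stack*.

    Layers are matched to the training features by name where names were
    given; any cell with nodata in any layer is nodata in the output.
    """
    if ens.feature_names is not None:
        missing = [n for n in ens.feature_names if n not in stack.names]
        if missing:
            raise ValueError(f"stack missing layer(s) {missing}")
        ordered = EnvStack([stack[n] for n in ens.feature_names])
    else:
        ordered = stack
    rows, valid = ordered.table()
    out = np.full(rows.shape[0], -9999.0)
    if valid.any():
        out[valid] = ens.predict(rows[valid])
    tmpl = stack.template
    grid = tmpl.with_values(out.reshape(tmpl.shape), name="suitability")
    grid.nodata = -9999.0
    return grid


def binarize(suitability: RasterGrid, threshold: float) -> RasterGrid:
    """Threshold a suitability grid to {0, 1}; nodata propagates."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    vals = suitability.values
    out = (vals >= threshold).astype(np.int64)
    out[suitability.nodata_mask] = -9999
    grid = suitability.with_values(out, name="suitability_binary")
    grid.nodata = -9999
    return grid
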