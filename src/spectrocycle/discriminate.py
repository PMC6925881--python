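"""Feature gating, canonical 2-D projection, linear classification, CV.

The classification scheme: one-way ANOVA gates features (P < alpha, at most
``cap`` kept, ranked by F); the retained features are z-scored and projected
to two canonical variables -- axis 1 the Fisher discriminant direction
(within-class-scatter-whitened between-means direction), axis 2 the leading
within-class residual direction orthogonal to axis 1 in the whitened metric
(Fisher analysis of a two-class problem yields a single axis; the second
axis is added so the projection plane shows within-class structure and the
classifier may use both) -- and a pooled-covariance linear discriminant with
an equal-priors midpoint bias assigns the label.  Stratified k-fold
cross-validation performs selection, standardisation and fitting inside
each training split only.

Cell-cycle phase is decided by a two-stage decision tree: stage 1 separates
G1 from S/G2/M (replicating vs not), stage 2 separates S from G2+M (M is
merged with G2 throughout, M-phase cells being too rare to model alone).
The same machinery classifies cell origin (pancreatic vs cervical lines).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionResult",
    "CanonicalSpace",
    "LinearClassifier",
    "StageModel",
    "TwoStageModel",
    "ClassificationReport",
    "anova_f",
    "select_features",
    "fit_canonical_space",
    "project",
    "fit_linear_classifier",
    "roc_auc",
    "cross_validate",
    "fit_stage",
    "fit_two_stage",
    "predict_two_stage",
    "G2M",
    "merge_g2m",
]

G2M = "G2M"

_RIDGE = 1e-6


def merge_g2m(phases: np.ndarray | pd.Series) -> np.ndarray:
    """Merge the rare M phase into G2: {G1, S, G2, M} -> {G1, S, G2M}."""
    arr = np.asarray(phases, dtype=object)
    return np.where(np.isin(arr, ("G2", "M")), G2M, arr)


# ---------------------------------------------------------------------------
# ANOVA feature gate
# ---------------------------------------------------------------------------

def _anova_f_matrix(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over the columns of X."""
    classes = np.unique(labels)
    k = len(classes)
    n = X.shape[0]
    if k < 2:
        raise ValueError("ANOVA needs at least two classes")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for cls in classes:
        sub = X[labels == cls]
        if sub.shape[0] < 2:
            raise ValueError("ANOVA needs >= 2 members per class")
        mu = sub.mean(axis=0)
        ssb += sub.shape[0] * (mu - grand) ** 2
        ssw += ((sub - mu) ** 2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    msb = ssb / df_b
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    # degenerate conventions: no variance anywhere -> F = 0, p = 1;
    # between-class variance with zero within-class variance -> p = 0.
    both_zero = (msw < 1e-300) & (msb < 1e-300)
    sep = (msw < 1e-300) & (msb >= 1e-300)
    f[both_zero] = 0.0
    f[sep] = np.inf
    p = np.empty_like(f)
    finite = np.isfinite(f)
    p[finite] = stats.f.sf(f[finite], df_b, df_w)
    p[~finite] = 0.0
    p[both_zero] = 1.0
    return f, p


def anova_f(values, labels) -> tuple[float, float]:
    """One-way ANOVA F = MSB/MSW with df (k-1, n-k) and its upper-tail p."""
    x = np.asarray(values, dtype=float)[:, None]
    f, p = _anova_f_matrix(x, np.asarray(labels))
    return float(f[0]), float(p[0])


@dataclass(frozen=True)
class SelectionResult:
    """ANOVA-gated feature subset, ranked by F descending."""

    features: tuple[str, ...]
    f_stats: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    cap: int


def select_features(
    table: pd.DataFrame,
    labels,
    alpha: float = 0.005,
    cap: int = 13,
    feature_cols: list[str] | None = None,
) -> SelectionResult:
    """Keep features with ANOVA p < alpha, best-F first, at most ``cap``.

    Ties in F are broken by feature-name lexicographic order.  Raises when
    nothing passes the gate.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ("line", "phase")]
    if not feature_cols or table.empty:
        raise ValueError("empty feature table")
    X = table[feature_cols].to_numpy(dtype=float)
    f, p = _anova_f_matrix(X, np.asarray(labels))
    passing = [i for i in range(len(feature_cols)) if p[i] < alpha]
    if not passing:
        raise ValueError("insufficient discriminative signal: "
                         "no feature passes the ANOVA gate")
    passing.sort(key=lambda i: (-f[i], feature_cols[i]))
    kept = passing[:cap]
    return SelectionResult(
        features=tuple(feature_cols[i] for i in kept),
        f_stats={feature_cols[i]: float(f[i]) for i in kept},
        p_values={feature_cols[i]: float(p[i]) for i in kept},
        alpha=alpha,
        cap=cap,
    )


# ---------------------------------------------------------------------------
# Canonical 2-D projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalSpace:
    """Two unit-norm weight vectors over the selected features.

    Axis 2 is orthogonal to axis 1 in the within-class-scatter-whitened
    metric (w2' Sw w1 = 0).
    """

    weights: np.ndarray  # (2, d)
    feature_names: tuple[str, ...]
    class_labels: tuple
    class_means: np.ndarray  # (2, 2): class x canonical variable


def fit_canonical_space(
    X: np.ndarray, labels, feature_names: tuple[str, ...] | None = None
) -> CanonicalSpace:
    """Fisher discriminant axis plus the orthogonalised residual axis.

    Expects standardised features.  Works in within-class-scatter-whitened
    coordinates: axis 1 is the whitened between-means direction, axis 2 the
    leading principal component of whitened within-class residuals after
    projecting axis 1 out.  A ridge of 1e-6 on the scatter diagonal guards
    near-singular scatter.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("canonical space is fitted on exactly two classes")
    n0, n1 = (int((labels == c).sum()) for c in classes)
    if min(n0, n1) < 3:
        raise ValueError("need at least 3 cells per class")
    d = X.shape[1]
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(d))

    mus = np.stack([X[labels == c].mean(axis=0) for c in classes])
    resid = X.copy()
    for c, mu in zip(classes, mus):
        resid[labels == c] -= mu
    sw = resid.T @ resid / X.shape[0] + _RIDGE * np.eye(d)

    evals, evecs = np.linalg.eigh(sw)
    if np.any(evals <= 0):
        raise ValueError("singular within-class scatter")
    w_half_inv = evecs @ np.diag(evals**-0.5) @ evecs.T

    delta = w_half_inv @ (mus[1] - mus[0])
    norm = np.linalg.norm(delta)
    if norm < 1e-12:
        raise ValueError("coincident class means")
    a1 = delta / norm

    resid_w = resid @ w_half_inv
    resid_w -= np.outer(resid_w @ a1, a1)
    _, _, vt = np.linalg.svd(resid_w, full_matrices=False)
    a2 = vt[0]
    # deterministic sign
    lead = np.argmax(np.abs(a2))
    if a2[lead] < 0:
        a2 = -a2

    w1 = w_half_inv @ a1
    w2 = w_half_inv @ a2
    w1 /= np.linalg.norm(w1)
    w2 /= np.linalg.norm(w2)
    weights = np.stack([w1, w2])
    class_means = mus @ weights.T
    return CanonicalSpace(weights, tuple(feature_names), classes, class_means)


def project(X, space: CanonicalSpace) -> np.ndarray:
    """Project cells onto the two canonical variables."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in space.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        X = X[list(space.feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != space.weights.shape[1]:
        raise ValueError("column count does not match canonical space")
    return X @ space.weights.T


# ---------------------------------------------------------------------------
# Linear classifier in the canonical plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearClassifier:
    """sign(w . z + b) decision in the 2-D canonical space."""

    weights: np.ndarray  # (2,)
    bias: float
    positive_label: object
    negative_label: object

    def scores(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) @ self.weights + self.bias

    def predict(self, Z: np.ndarray) -> np.ndarray:
        s = self.scores(Z)
        return np.where(s > 0, self.positive_label, self.negative_label)


def fit_linear_classifier(
    Z: np.ndarray, labels, positive_label=None
) -> LinearClassifier:
    """Pooled-covariance Fisher discriminant with equal-priors midpoint bias."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    classes = list(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if positive_label is None:
        positive_label = classes[1]
    negative_label = [c for c in classes if c != positive_label][0]
    mu_p = Z[labels == positive_label].mean(axis=0)
    mu_n = Z[labels == negative_label].mean(axis=0)
    resid = Z.copy()
    resid[labels == positive_label] -= mu_p
    resid[labels == negative_label] -= mu_n
    cov = resid.T @ resid / len(Z)
    for ridge in (0.0, _RIDGE):
        try:
            w = np.linalg.solve(cov + ridge * np.eye(Z.shape[1]), mu_p - mu_n)
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("singular pooled covariance")
    b = -float(w @ (mu_p + mu_n) / 2.0)
    return LinearClassifier(w, b, positive_label, negative_label)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, positive_label=None) -> tuple[list[tuple[float, float]], float]:
    """Threshold-sweep ROC points and trapezoidal AUC.

    Sweeping thresholds over the unique scores traces the ROC; trapezoidal
    integration gives ties half credit, making the AUC identical to the
    rank (Mann-Whitney) statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if positive_label is None:
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        positive_label = classes[1]
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep only the last index of each tied score block
    distinct = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# Stage fit and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class StageModel:
    """Standardisation + selection + canonical space + classifier for one stage."""

    selection: SelectionResult
    space: CanonicalSpace
    classifier: LinearClassifier
    feature_means: dict[str, float]
    feature_stds: dict[str, float]

    def _standardise(self, table: pd.DataFrame) -> np.ndarray:
        names = list(self.space.feature_names)
        missing = [f for f in names if f not in table.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        X = table[names].to_numpy(dtype=float)
        mu = np.array([self.feature_means[f] for f in names])
        sd = np.array([self.feature_stds[f] for f in names])
        return (X - mu) / sd

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Project cells into the stage's canonical plane."""
        return self._standardise(table) @ self.space.weights.T

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        return self.classifier.scores(self.transform(table))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict(self.transform(table))

    def to_dict(self) -> dict:
        return {
            "features": list(self.space.feature_names),
            "feature_means": self.feature_means,
            "feature_stds": self.feature_stds,
            "canonical_weights": self.space.weights.tolist(),
            "class_labels": list(self.space.class_labels),
            "class_means": self.space.class_means.tolist(),
            "classifier": {
                "weights": self.classifier.weights.tolist(),
                "bias": self.classifier.bias,
                "positive_label": self.classifier.positive_label,
                "negative_label": self.classifier.negative_label,
            },
            "selection": {
                "features": list(self.selection.features),
                "f_stats": self.selection.f_stats,
                "p_values": self.selection.p_values,
                "alpha": self.selection.alpha,
                "cap": self.selection.cap,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageModel":
        sel = SelectionResult(
            features=tuple(d["selection"]["features"]),
            f_stats=d["selection"]["f_stats"],
            p_values=d["selection"]["p_values"],
            alpha=d["selection"]["alpha"],
            cap=d["selection"]["cap"],
        )
        space = CanonicalSpace(
            weights=np.asarray(d["canonical_weights"], dtype=float),
            feature_names=tuple(d["features"]),
            class_labels=tuple(d["class_labels"]),
            class_means=np.asarray(d["class_means"], dtype=float),
        )
        clf = LinearClassifier(
            weights=np.asarray(d["classifier"]["weights"], dtype=float),
            bias=float(d["classifier"]["bias"]),
            positive_label=d["classifier"]["positive_label"],
            negative_label=d["classifier"]["negative_label"],
        )
        return cls(sel, space, clf, d["feature_means"], d["feature_stds"])


def _zscore_params(table: pd.DataFrame, feature_cols: list[str]):
    X = table[feature_cols].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return mu, sd


def fit_stage(
    table: pd.DataFrame,
    labels,
    alpha: float = 0.005,
    cap: int = 13,
    positive_label=None,
    feature_cols: list[str] | None = None,
) -> StageModel:
    """Fit one binary stage: z-score, select, project, classify."""
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ("line", "phase")]
    labels = np.asarray(labels)
    sel = select_features(table, labels, alpha, cap, feature_cols)
    names = list(sel.features)
    mu, sd = _zscore_params(table, names)
    X = (table[names].to_numpy(dtype=float) - mu) / sd
    space = fit_canonical_space(X, labels, tuple(names))
    Z = X @ space.weights.T
    clf = fit_linear_classifier(Z, labels, positive_label)
    return StageModel(
        sel, space, clf,
        feature_means=dict(zip(names, mu.tolist())),
        feature_stds=dict(zip(names, sd.tolist())),
    )


@dataclass
class ClassificationReport:
    """Pooled held-out performance of one cross-validated binary task."""

    accuracy: float  # percent
    auc: float
    roc: list[tuple[float, float]]
    confusion: dict
    fold_assignment: np.ndarray
    seed: int
    n: int
    positive_label: object

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc": self.roc,
            "confusion": self.confusion,
            "fold_assignment": self.fold_assignment.tolist(),
            "seed": self.seed,
            "n": self.n,
            "positive_label": self.positive_label,
        }


def cross_validate(
    table: pd.DataFrame,
    labels,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.005,
    cap: int = 13,
    positive_label=None,
    feature_cols: list[str] | None = None,
) -> ClassificationReport:
    """Stratified k-fold CV with selection and fitting inside training folds.

    Every cell is tested exactly once; fold sizes differ by at most one.
    Classes with fewer than k members trigger leave-one-out with a warning.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError("need at least k samples")
    classes = np.unique(labels)
    if positive_label is None:
        positive_label = classes[1]
    min_class = min(int((labels == c).sum()) for c in classes)
    if min_class < k:
        warnings.warn("a class has fewer members than k; "
                      "falling back to leave-one-out")
        splits = [(np.delete(np.arange(n), i), np.array([i]))
                  for i in range(n)]
        fold_of = np.arange(n)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), labels))
        fold_of = np.empty(n, dtype=int)
        for f, (_, test_idx) in enumerate(splits):
            fold_of[test_idx] = f

    scores = np.empty(n)
    predictions = np.empty(n, dtype=object)
    for train_idx, test_idx in splits:
        model = fit_stage(
            table.iloc[train_idx], labels[train_idx],
            alpha=alpha, cap=cap, positive_label=positive_label,
            feature_cols=feature_cols,
        )
        scores[test_idx] = model.scores(table.iloc[test_idx])
        predictions[test_idx] = model.predict(table.iloc[test_idx])

    accuracy = 100.0 * float((predictions == labels).mean())
    roc, auc = roc_auc(scores, labels, positive_label)
    confusion = {
        f"{true}->{pred}": int(((labels == true) & (predictions == pred)).sum())
        for true in classes for pred in classes
    }
    return ClassificationReport(
        accuracy, auc, roc, confusion, fold_of, seed, n, positive_label)


# ---------------------------------------------------------------------------
# Two-stage cell-cycle decision tree
# ---------------------------------------------------------------------------

@dataclass
class TwoStageModel:
    """Stage 1: G1 vs S/G2/M; stage 2 (replicating cells only): S vs G2+M."""

    stage1: StageModel
    stage2: StageModel

    def to_dict(self) -> dict:
        return {"stage1": self.stage1.to_dict(), "stage2": self.stage2.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStageModel":
        return cls(StageModel.from_dict(d["stage1"]),
                   StageModel.from_dict(d["stage2"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "TwoStageModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_two_stage(
    table: pd.DataFrame,
    phases,
    alpha: float = 0.005,
    cap: int = 13,
    feature_cols: list[str] | None = None,
) -> TwoStageModel:
    """Fit the two-stage decision tree on true phase labels.

    Stage 1 is trained on all cells (G1 vs the rest); stage 2 on the true
    S/G2/M cells only (S vs G2+M), with independent feature selection per
    stage.
    """
    phases = np.asarray(phases, dtype=object)
    merged = merge_g2m(phases)
    present = set(np.unique(merged))
    if not {"G1", "S", G2M} <= present:
        raise ValueError(f"need G1, S and G2/M cells, got {sorted(present)}")
    stage1_labels = np.where(merged == "G1", "G1", "rest")
    stage1 = fit_stage(table, stage1_labels, alpha, cap,
                       positive_label="rest", feature_cols=feature_cols)
    sub = merged != "G1"
    stage2 = fit_stage(table.loc[sub], merged[sub], alpha, cap,
                       positive_label="S", feature_cols=feature_cols)
    return TwoStageModel(stage1, stage2)


def predict_two_stage(model: TwoStageModel, table: pd.DataFrame) -> np.ndarray:
    """Phase prediction per cell in {G1, S, G2M}.

    A stage-1 G1 verdict is final; stage 2 is consulted only for cells the
    first stage calls replicating.
    """
    stage1_pred = model.stage1.predict(table)
    out = np.empty(len(table), dtype=object)
    is_g1 = stage1_pred == "G1"
    out[is_g1] = "G1"
    rest = ~is_g1
    if rest.any():
        out[rest] = model.stage2.predict(table.loc[rest])
    return out
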