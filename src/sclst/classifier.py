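"""CNA-based classifier of LST status.

SMOTE rebalancing of the minority class, a bagged decision-tree (random
forest) classifier with out-of-bag (OOB) error, permutation variable
importance on the error-rate scale, and bootstrap ROC/AUC.

Bagging and the OOB bookkeeping are managed here (per-tree bootstrap masks
are needed for OOB permutation importance); the trees are scikit-learn
CART trees (Gini impurity, sqrt(p) feature subsampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

LABEL_LOW = "low"
LABEL_HIGH = "high"
ORDINAL_LEVELS = np.array([-1, 0, 1])


@dataclass(frozen=True)
class SMOTEParams:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority after oversampling
    rounding: str = "nearest"  # "nearest" | "vote"
    seed: int = 0


@dataclass(frozen=True)
class RFParams:
    n_trees: int = 500
    features_per_split: int | None = None  # default floor(sqrt(p))
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class FeatureTable:
    """Cells x gene-CNA covariates (-1/0/+1) with a binary LST label.

    ``synthetic_parents`` maps a synthetic (SMOTE) row's index to the two
    observed rows it interpolates — used to keep out-of-bag evaluation
    honest in the presence of oversampling.
    """

    X: pd.DataFrame
    y: pd.Series  # values in {"low", "high"}
    synthetic_parents: dict[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing entries")
        if set(self.y.unique()) - {LABEL_LOW, LABEL_HIGH}:
            raise ValueError("labels must be 'low'/'high'")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(table: FeatureTable, params: SMOTEParams | None = None,
          return_raw: bool = False):
    """Synthetic minority oversampling.

    New minority samples are x_i + lambda * (x_nn - x_i) with lambda ~
    Uniform(0,1) and x_nn one of the k nearest minority neighbors
    (Euclidean). Because the covariates are ordinal {-1,0,+1}, each
    synthetic coordinate is rounded back to the nearest level ("nearest",
    default) or takes the closer parent's value ("vote"). An already
    balanced table is returned unchanged.

    With ``return_raw`` the pre-rounding synthetic coordinates and their two
    parents are also returned, for verification of the interpolation.
    """
    if params is None:
        params = SMOTEParams()
    counts = table.y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    minority = counts.idxmin()
    majority = counts.idxmax()
    n_min, n_maj = int(counts[minority]), int(counts[majority])
    n_target = int(round(params.target_ratio * n_maj))
    if n_min >= n_target:
        if return_raw:
            empty = np.empty((0, table.X.shape[1]))
            return table, (empty, empty, empty)
        return table
    if n_min <= params.k_neighbors:
        raise ValueError(
            f"minority class size {n_min} must exceed k_neighbors "
            f"{params.k_neighbors}")
    rng = np.random.default_rng(params.seed)
    minority_index = table.X.index[table.y == minority]
    Xm = table.X[table.y == minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]
    n_new = n_target - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = neigh[base, rng.integers(0, params.k_neighbors, size=n_new)]
    lam = rng.uniform(0.0, 1.0, size=(n_new, 1))
    synth = Xm[base] + lam * (Xm[pick] - Xm[base])
    if params.rounding == "nearest":
        rounded = ORDINAL_LEVELS[
            np.argmin(np.abs(synth[..., None] - ORDINAL_LEVELS), axis=-1)]
    elif params.rounding == "vote":
        rounded = np.where(lam < 0.5, Xm[base], Xm[pick]).astype(int)
    else:
        raise ValueError(f"unknown rounding mode {params.rounding!r}")
    new_index = [f"smote{i + 1:04d}" for i in range(n_new)]
    X_new = pd.DataFrame(rounded, columns=table.X.columns, index=new_index)
    y_new = pd.Series(minority, index=new_index)
    parents = {s: (str(minority_index[i]), str(minority_index[j]))
               for s, i, j in zip(new_index, base, pick)}
    out = FeatureTable(X=pd.concat([table.X, X_new]),
                       y=pd.concat([table.y, y_new]),
                       synthetic_parents=parents)
    if return_raw:
        return out, (synth, Xm[base], Xm[pick])
    return out


def smote_interpolate(x_i: np.ndarray, x_nn: np.ndarray,
                      lam: float) -> np.ndarray:
    """The pre-rounding interpolation step, exposed for verification."""
    return x_i + lam * (x_nn - x_i)


# ---------------------------------------------------------------------------
# Random forest with explicit OOB bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class RandomForestModel:
    trees: list[DecisionTreeClassifier]
    oob_masks: list[np.ndarray]  # per tree: True where the sample is OOB
    feature_names: list[str]
    classes_: np.ndarray  # sorted label strings; index 1 = positive (high)
    X_train: np.ndarray = field(repr=False)
    y_train: np.ndarray = field(repr=False)
    oob_error: float = float("nan")

    def oob_votes(self, X: np.ndarray | None = None) -> np.ndarray:
        """n x n_classes OOB vote counts; each sample is predicted only by
        trees whose bootstrap excluded it. ``X`` overrides the feature
        matrix (same shape) for permutation importance."""
        if X is None:
            X = self.X_train
        votes = np.zeros((len(X), len(self.classes_)), dtype=np.int64)
        for tree, mask in zip(self.trees, self.oob_masks):
            if not mask.any():
                continue
            pred = tree.predict(X[mask])
            for ci, cls in enumerate(self.classes_):
                votes[np.flatnonzero(mask)[pred == cls], ci] += 1
        return votes

    def oob_proba(self) -> np.ndarray:
        """OOB vote fraction for the positive ('high') class per sample."""
        votes = self.oob_votes()
        tot = votes.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = votes[:, 1] / tot
        return np.where(tot > 0, p, 0.5)

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((len(X), len(self.classes_)), dtype=np.int64)
        for tree in self.trees:
            pred = tree.predict(X)
            for ci, cls in enumerate(self.classes_):
                votes[pred == cls, ci] += 1
        return self.classes_[votes.argmax(axis=1)]


def _oob_error_from_votes(votes: np.ndarray, y: np.ndarray,
                          classes: np.ndarray) -> float:
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        return float("nan")
    pred = classes[votes[covered].argmax(axis=1)]
    return float((pred != y[covered]).mean())


def train_rf(table: FeatureTable, params: RFParams | None = None
             ) -> RandomForestModel:
    """Fit a bagged ensemble of CART trees.

    Each tree is grown on a bootstrap resample (n draws with replacement)
    with ``features_per_split`` (default floor(sqrt(p))) random candidate
    features per node and Gini impurity splitting. Out-of-bag error is the
    majority-vote error over each sample's OOB trees.
    """
    if params is None:
        params = RFParams()
    if table.y.nunique() < 2:
        raise ValueError("training requires both classes")
    rng = np.random.default_rng(params.seed)
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=object)
    n, p = X.shape
    max_features = params.features_per_split or max(1, int(np.sqrt(p)))
    trees, masks = [], []
    for _ in range(params.n_trees):
        idx = rng.integers(0, n, size=n)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=max_features,
            min_samples_leaf=params.min_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        masks.append(mask)
    model = RandomForestModel(
        trees=trees, oob_masks=masks, feature_names=list(table.X.columns),
        # fixed order so the positive class ("high") sits at column 1
        classes_=np.array([LABEL_LOW, LABEL_HIGH], dtype=object),
        X_train=X, y_train=y)
    model.oob_error = _oob_error_from_votes(model.oob_votes(), y,
                                            model.classes_)
    return model


def vimp(model: RandomForestModel, n_permutations: int = 5,
         seed: int = 0) -> pd.Series:
    """Permutation variable importance on the error-rate scale (Breiman).

    For every tree, the feature's values are permuted and the tree's
    out-of-bag misclassification rate recomputed; importance_j is the mean
    increase over trees and permutation rounds. 0.30 means permuting the
    feature raises a tree's error by 30 percentage points on average. A
    feature no tree splits on has importance exactly 0.
    """
    rng = np.random.default_rng(seed)
    n = len(model.X_train)
    # baseline per-tree OOB errors; trees not using feature j are
    # unaffected by its permutation and contribute exactly 0
    tree_err = np.full(len(model.trees), np.nan)
    tree_preds: list[np.ndarray] = []
    for ti, (tree, mask) in enumerate(zip(model.trees, model.oob_masks)):
        if not mask.any():
            tree_preds.append(np.empty(0, dtype=object))
            continue
        pred = tree.predict(model.X_train[mask])
        tree_preds.append(pred)
        tree_err[ti] = float((pred != model.y_train[mask]).mean())
    uses_feature = [set(t.tree_.feature[t.tree_.feature >= 0])
                    for t in model.trees]
    out = np.zeros(len(model.feature_names))
    for j in range(len(model.feature_names)):
        affected = [ti for ti, used in enumerate(uses_feature)
                    if j in used and not np.isnan(tree_err[ti])]
        if not affected:
            continue
        n_valid = int(np.sum(~np.isnan(tree_err)))
        deltas = []
        for _ in range(n_permutations):
            Xp = model.X_train.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            total = 0.0
            for ti in affected:
                mask = model.oob_masks[ti]
                pred = model.trees[ti].predict(Xp[mask])
                err = float((pred != model.y_train[mask]).mean())
                total += err - tree_err[ti]
            deltas.append(total / n_valid)
        out[j] = float(np.mean(deltas))
    return pd.Series(out, index=model.feature_names)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(proba: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
            seed: int = 0) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """ROC by threshold sweep, AUC by trapezoid (equal to the normalised
    Mann-Whitney U statistic), and a percentile bootstrap CI over cells."""
    y = np.asarray([1 if l == LABEL_HIGH else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes in the evaluation set")
    proba = np.asarray(proba, dtype=float)
    fpr, tpr, _ = sk_roc_curve(y, proba)
    a = float(sk_auc(fpr, tpr))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        f, t, _ = sk_roc_curve(y[idx], proba[idx])
        boots.append(sk_auc(f, t))
    if boots:
        ci = (float(np.percentile(boots, 2.5)),
              float(np.percentile(boots, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return curve, a, ci


# ---------------------------------------------------------------------------
# Planted-signal cohort simulator and end-to-end chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Feature-level synthetic cohort for classifier evaluation.

    ``n_causal`` genes carry the signal through a logistic link: with no
    causal loss P(high) = ``p_high_base``; each causal gene lost adds
    logit(``p_high_causal``) - logit(``p_high_base``) to the log-odds, so a
    single loss raises P(high) from 0.2 to 0.8 and further losses raise it
    beyond. Background alteration rates are loss-biased like real
    single-cell CNA data.
    """

    n_cells: int = 120
    n_genes: int = 39
    n_causal: int = 3
    p_loss: float = 0.25
    p_gain: float = 0.15
    #: causal-gene loss rate 0.3 makes the expected class balance ~63% high
    #: under the logistic link — the LST-high:low ratio seen in CTC cohorts
    causal_p_loss: float = 0.3
    p_high_base: float = 0.2
    p_high_causal: float = 0.8
    seed: int = 0


def simulate_feature_cohort(config: CohortConfig) -> tuple[FeatureTable, list[str]]:
    """Generate (feature table, causal gene names). With ``n_causal = 0``
    the labels are independent of every feature (null cohort)."""
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i + 1:03d}" for i in range(config.n_genes)]
    causal = genes[:config.n_causal]
    X = np.zeros((config.n_cells, config.n_genes), dtype=int)
    for j in range(config.n_genes):
        pl = config.causal_p_loss if j < config.n_causal else config.p_loss
        u = rng.uniform(size=config.n_cells)
        X[:, j] = np.where(u < pl, -1, np.where(u < pl + config.p_gain, 1, 0))
    if config.n_causal > 0:
        k = (X[:, :config.n_causal] == -1).sum(axis=1)
        logit = lambda p: np.log(p / (1 - p))
        eta = logit(config.p_high_base) + k * (
            logit(config.p_high_causal) - logit(config.p_high_base))
        p_high = 1.0 / (1.0 + np.exp(-eta))
        y = np.where(rng.uniform(size=config.n_cells) < p_high,
                     LABEL_HIGH, LABEL_LOW)
    else:
        # null cohort: labels independent of every feature, exactly
        # balanced so no oversampling is involved
        half = config.n_cells // 2
        y = np.array([LABEL_HIGH] * half
                     + [LABEL_LOW] * (config.n_cells - half), dtype=object)
        rng.shuffle(y)
    idx = [f"cell{i + 1:03d}" for i in range(config.n_cells)]
    table = FeatureTable(X=pd.DataFrame(X, columns=genes, index=idx),
                         y=pd.Series(y, index=idx))
    return table, causal


@dataclass
class ClassifierReport:
    oob_error: float
    vimp: pd.Series
    roc: pd.DataFrame
    auc: float
    auc_ci: tuple[float, float]

    def to_json(self) -> str:
        return json.dumps({
            "oob_error": self.oob_error,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "vimp": {k: float(v) for k, v in
                     self.vimp.sort_values(ascending=False).items()},
        }, indent=2)


def end_to_end_classifier(table: FeatureTable,
                          smote_params: SMOTEParams | None = None,
                          rf_params: RFParams | None = None,
                          vimp_permutations: int = 5,
                          n_boot: int = 1000,
                          seed: int = 0) -> ClassifierReport:
    """Full chain: SMOTE -> random forest -> permutation VIMP -> OOB
    ROC/AUC with bootstrap CI. Evaluation uses out-of-bag probabilities on
    the (rebalanced) training cohort; there is no external test set."""
    if smote_params is None:
        smote_params = SMOTEParams(seed=seed)
    if rf_params is None:
        rf_params = RFParams(seed=seed)
    balanced = smote(table, smote_params)
    model = train_rf(balanced, rf_params)
    importances = vimp(model, n_permutations=vimp_permutations, seed=seed)
    # ROC/AUC over the observed cells only. Synthetic minority interpolants
    # are excluded from the evaluation set (they sit between real cells and
    # are trivially classified); the forest itself was still trained on
    # them, so the out-of-bag AUC remains a training-cohort quantity and
    # carries the optimism any SMOTE-then-evaluate design has.
    observed = balanced.X.index.isin(table.X.index)
    curve, a, ci = roc_auc(model.oob_proba()[observed],
                           model.y_train[observed], n_boot=n_boot, seed=seed)
    return ClassifierReport(oob_error=model.oob_error, vimp=importances,
                            roc=curve, auc=a, auc_ci=ci)
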