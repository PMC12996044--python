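"""Stability selection, nested cross-validated classification, permutation
testing and biomarker ranking.

The four-step engine behind response prediction:

1. keep the top-N features by mean relative abundance, then score each by how
   often a LASSO (squared-error, L1 penalty 0.1 on standardized features)
   gives it a nonzero coefficient across stratified shuffle splits, keeping
   the top-k stability-selected features;
2. estimate performance of an extremely-randomized-trees classifier with an
   outer stratified 75/25 shuffle split repeated, hyperparameters tuned per
   outer split by inner stratified k-fold grid search on AUC;
3. compare the observed mean AUC with a null distribution from re-running
   the whole pipeline (selection included, to avoid leakage) on label
   permutations; p = fraction of null AUCs >= observed;
4. rank selected features by mean impurity importance, normalized to the
   maximum, with an enrichment direction from group mean abundances.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import preprocess

DEFAULT_GRID: tuple[dict, ...] = tuple(
    {"n_estimators": n, "max_features": mf, "min_samples_leaf": msl}
    for n in (100, 300) for mf in ("sqrt", "log2") for msl in (1, 3)
)


@dataclasses.dataclass
class StabilitySelectionResult:
    selection_counts: pd.Series      # per feature, in [0, n_splits]
    n_splits: int
    penalty: float
    selected_features: list[str]     # top_k by count (desc), ties by id (asc)


@dataclasses.dataclass
class NestedCvResult:
    outer_split_aucs: list[float]
    mean_auc: float
    best_hyperparameters: list[dict]
    mean_feature_importance: pd.Series


@dataclasses.dataclass
class PermutationTestResult:
    observed_auc: float
    null_aucs: np.ndarray
    p: float
    n_permutations: int


@dataclasses.dataclass
class PipelineConfig:
    """Knobs of the full per-cohort pipeline (defaults = study settings)."""

    top_n: int = 250
    n_splits: int = 50
    train_fraction: float = 0.75
    penalty: float = 0.1
    top_k: int = 50
    n_outer: int = 10
    test_fraction: float = 0.25
    inner_folds: int = 5
    grid: tuple[dict, ...] = DEFAULT_GRID
    n_permutations: int = 200


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores; returns (z, keep-mask) dropping constant columns."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s)",
                      stacklevel=2)
    z = (x[:, keep] - mu[keep]) / sd[keep]
    return z, keep


def lasso_fit(x: np.ndarray, y: np.ndarray, penalty: float,
              logistic: bool = False) -> np.ndarray:
    """L1-penalised fit on standardized features; returns coefficients.

    Default is squared-error LASSO on the 0/1 response — minimizing
    (1/2n)||y - Xb - b0||^2 + penalty * ||b||_1 with an unpenalised
    intercept, by coordinate descent. ``logistic=True`` swaps in an
    L1-logistic model with C = 1/(n * penalty) as the nearest equivalent.
    Columns constant in *x* are dropped (coefficient 0 in the output).
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z, keep = _standardize(x)
    coefs = np.zeros(x.shape[1])
    if keep.any():
        if logistic:
            est = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                     C=1.0 / (len(y) * penalty))
            est.fit(z, y.astype(int))
            coefs[keep] = est.coef_[0]
        else:
            est = Lasso(alpha=penalty, tol=1e-6, max_iter=50_000)
            est.fit(z, y)
            coefs[keep] = est.coef_
    return coefs


def stability_select(x: pd.DataFrame, y, n_splits: int = 50,
                     train_fraction: float = 0.75, penalty: float = 0.1,
                     top_k: int = 50, seed: int | None = None,
                     logistic: bool = False) -> StabilitySelectionResult:
    """Score features by LASSO selection frequency over stratified splits."""
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                      train_size=train_fraction,
                                      random_state=_rs(seed))
    xm = x.to_numpy(dtype=float)
    counts = np.zeros(x.shape[1], dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-column drops inside splits
        for train_idx, _ in splitter.split(xm, y):
            coefs = lasso_fit(xm[train_idx], (y[train_idx] == y.max()).astype(float),
                              penalty, logistic=logistic)
            counts[np.abs(coefs) > 1e-10] += 1
    series = pd.Series(counts, index=x.columns, name="selection_count")
    nonzero = series[series > 0]
    ranked = sorted(nonzero.index, key=lambda f: (-nonzero[f], f))
    return StabilitySelectionResult(selection_counts=series, n_splits=n_splits,
                                    penalty=penalty,
                                    selected_features=ranked[:top_k])


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    pos = labels == classes.max()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _rs(seed: int | None) -> int | None:
    """Clamp derived random states into sklearn's accepted range."""
    return None if seed is None else int(seed) % (2**31)


def _grid_search(x: np.ndarray, y: np.ndarray, grid, inner_folds: int,
                 seed: int | None) -> dict:
    """Inner stratified k-fold grid search maximizing mean AUC."""
    if len(grid) == 1:
        return dict(grid[0])
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                         random_state=_rs(seed))
    folds = list(cv.split(x, y))
    best, best_score = None, -np.inf
    for params in grid:
        scores = []
        for tr, te in folds:
            est = ExtraTreesClassifier(random_state=_rs(seed), **params)
            est.fit(x[tr], y[tr])
            prob = est.predict_proba(x[te])[:, 1]
            if len(np.unique(y[te])) < 2:  # pragma: no cover - stratified
                continue
            scores.append(auc(prob, y[te]))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score:  # first-best wins ties: grid order is fixed
            best, best_score = dict(params), mean
    return best


def nested_cv_evaluate(x: pd.DataFrame, y, grid=DEFAULT_GRID,
                       n_outer: int = 10, test_fraction: float = 0.25,
                       inner_folds: int = 5,
                       seed: int | None = None) -> NestedCvResult:
    """Outer repeated stratified shuffle split around an inner grid search.

    Per outer repetition: split 75/25 stratified; tune on the training part
    only; refit extremely-randomized trees with the winning configuration on
    the full training part; record AUC on the held-out quarter and the
    fitted model's impurity importances. AUCs and importances are averaged
    over repetitions.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    xm = x.to_numpy(dtype=float)
    counts = np.bincount((y == classes.max()).astype(int))
    if counts.min() * (1 - test_fraction) < inner_folds:
        raise ValueError("minority class too small for the inner folds")
    ss = np.random.SeedSequence(_rs(seed))
    outer = StratifiedShuffleSplit(n_splits=n_outer, test_size=test_fraction,
                                   random_state=_rs(seed))
    yb = (y == classes.max()).astype(int)
    aucs, bests, importances = [], [], []
    for rep, (tr, te) in enumerate(outer.split(xm, yb)):
        rep_seed = int(ss.generate_state(rep + 2)[-1] % (2**31))
        best = _grid_search(xm[tr], yb[tr], grid, inner_folds, rep_seed)
        est = ExtraTreesClassifier(random_state=rep_seed, **best)
        est.fit(xm[tr], yb[tr])
        prob = est.predict_proba(xm[te])[:, 1]
        aucs.append(auc(prob, yb[te]))
        bests.append(best)
        importances.append(est.feature_importances_)
    mean_imp = pd.Series(np.mean(importances, axis=0), index=x.columns,
                         name="importance")
    return NestedCvResult(outer_split_aucs=[float(a) for a in aucs],
                          mean_auc=float(np.mean(aucs)),
                          best_hyperparameters=bests,
                          mean_feature_importance=mean_imp)


def run_pipeline(relabund: pd.DataFrame, y, config: PipelineConfig,
                 seed: int | None = None
                 ) -> tuple[StabilitySelectionResult, NestedCvResult]:
    """Top-N filter -> stability selection -> nested CV, with derived seeds."""
    ss = np.random.SeedSequence(_rs(seed))
    s_sel, s_cv = (int(v % (2**31)) for v in ss.generate_state(2))
    top = preprocess.top_n_by_mean_abundance(relabund, config.top_n)
    selection = stability_select(top, y, n_splits=config.n_splits,
                                 train_fraction=config.train_fraction,
                                 penalty=config.penalty, top_k=config.top_k,
                                 seed=s_sel)
    features = selection.selected_features
    if not features:  # LASSO found nothing: fall back to the top-k abundant
        features = list(top.columns[:config.top_k])
    cv = nested_cv_evaluate(top[features], y, grid=config.grid,
                            n_outer=config.n_outer,
                            test_fraction=config.test_fraction,
                            inner_folds=config.inner_folds, seed=s_cv)
    return selection, cv


def permutation_test(relabund: pd.DataFrame, y, config: PipelineConfig,
                     seed: int | None = None, add_one: bool = False,
                     observed: NestedCvResult | None = None
                     ) -> PermutationTestResult:
    """Whole-pipeline label-permutation null for the mean AUC.

    Every permutation re-runs stability selection *and* nested CV on the
    shuffled labels, so selection optimism is part of the null. p is the
    plain fraction of null AUCs >= observed (``add_one`` switches to the
    (r+1)/(n+1) convention).
    """
    if config.n_permutations < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(y)
    ss = np.random.SeedSequence(_rs(seed))
    if observed is None:
        _, observed = run_pipeline(relabund, y, config, seed=seed)
    rng = np.random.default_rng(int(ss.generate_state(3)[-1] % (2**31)))
    null = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        perm_seed = int(ss.generate_state(i + 4)[-1] % (2**31))
        _, cv = run_pipeline(relabund, rng.permutation(y), config,
                             seed=perm_seed)
        null[i] = cv.mean_auc
    hits = int((null >= observed.mean_auc).sum())
    p = ((hits + 1) / (config.n_permutations + 1) if add_one
         else hits / config.n_permutations)
    return PermutationTestResult(observed_auc=observed.mean_auc,
                                 null_aucs=null, p=float(p),
                                 n_permutations=config.n_permutations)


def rank_biomarkers(cv: NestedCvResult, relabund: pd.DataFrame, y,
                    taxonomy: pd.DataFrame | None = None,
                    top_n: int = 15) -> pd.DataFrame:
    """Top features by mean importance, normalized to the maximum.

    Direction is "non_response" when the feature's mean relative abundance is
    higher in the non-responder group, "response" when higher in responders,
    "indeterminate" on an exact tie. Taxonomy (best available rank label) is
    attached when provided.
    """
    imp = cv.mean_feature_importance
    ranked = sorted(imp.index, key=lambda f: (-imp[f], f))[:top_n]
    y = pd.Series(np.asarray(y), index=relabund.index)
    labels = sorted(y.unique(), key=str)
    # responder group = the label that sorts as "responder"-like; callers pass
    # strings "responder"/"non_responder" or 1/0 (1 = responder)
    resp_label = labels[-1]
    rows = []
    max_imp = float(imp[ranked[0]]) if ranked else 1.0
    for feat in ranked:
        mean_resp = float(relabund.loc[y == resp_label, feat].mean())
        mean_non = float(relabund.loc[y != resp_label, feat].mean())
        if mean_non > mean_resp:
            direction = "non_response"
        elif mean_resp > mean_non:
            direction = "response"
        else:
            direction = "indeterminate"
        label = ""
        if taxonomy is not None and feat in taxonomy.index:
            ranks = taxonomy.loc[feat]
            named = [str(v) for v in ranks if str(v)]
            label = " ".join(named[-2:]) if named else ""
        rows.append({
            "asv_id": feat,
            "raw_importance": float(imp[feat]),
            "normalized_importance": float(imp[feat]) / max_imp if max_imp else 0.0,
            "direction": direction,
            "taxonomy": label,
            "mean_abundance_responder": mean_resp,
            "mean_abundance_nonresponder": mean_non,
        })
    return pd.DataFrame(rows)
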