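"""Boosted-tree species distribution models and their evaluation suite.

Presence/pseudo-absence tables are fitted with gradient-boosted
classification trees (bernoulli loss) at the fixed ecology-standard
settings: learning rate 0.005, tree complexity (interaction depth) 5,
2000 trees, bag fraction 0.75.  Skill is reported as training AUC, 10-fold
stratified cross-validated AUC/TSS, spatially blocked 5-fold AUC (to
counter spatial autocorrelation), deviance-explained R^2, and an
overfitting check on the train-CV AUC gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier

from ._geo import AzimuthalEquidistant
from .env_covariates import ScalingParams

#: fixed boosted-regression-tree settings
DEFAULT_HYPERPARAMS = {
    "learning_rate": 0.005,
    "tree_complexity": 5,
    "n_trees": 2000,
    "bag_fraction": 0.75,
}


class DegenerateLabelsError(ValueError):
    """Table contains a single class; a binomial model cannot be fitted."""


@dataclass
class SDMModel:
    """A fitted boosted-tree habitat model."""

    species: str
    covariates: list[str]
    hyperparams: dict
    scaling: ScalingParams | None
    estimator: GradientBoostingClassifier
    seed: int

    @property
    def relative_influence(self) -> pd.Series:
        """Per-covariate split-improvement share, scaled to sum to 100."""
        imp = self.estimator.feature_importances_
        total = imp.sum()
        vals = imp / total * 100.0 if total > 0 else np.full_like(imp, 100.0 / len(imp))
        return pd.Series(vals, index=self.covariates).sort_values(ascending=False)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.covariates].values
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class EvalReport:
    """The metric suite for one model."""

    auc_train: float = np.nan
    r2_deviance: float = np.nan
    tss_train: float = np.nan
    auc_cv_mean: float = np.nan
    auc_cv_sd: float = np.nan
    tss_cv_mean: float = np.nan
    auc_block_mean: float = np.nan
    auc_block_sd: float = np.nan
    block_size_km2: float = np.nan
    extras: dict = field(default_factory=dict)

    @property
    def overfit_delta_cv(self) -> float:
        return self.auc_train - self.auc_cv_mean

    @property
    def overfit_delta_block(self) -> float:
        return self.auc_train - self.auc_block_mean

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("auc_train", "r2_deviance", "tss_train", "auc_cv_mean",
              "auc_cv_sd", "tss_cv_mean", "auc_block_mean", "auc_block_sd",
              "block_size_km2")}
        d["overfit_delta_cv"] = self.overfit_delta_cv
        d["overfit_delta_block"] = self.overfit_delta_block
        return d


def _make_estimator(hp: dict, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        loss="log_loss",
        learning_rate=hp["learning_rate"],
        n_estimators=hp["n_trees"],
        max_depth=hp["tree_complexity"],
        subsample=hp["bag_fraction"],
        random_state=seed,
    )


def fit_brt(table: pd.DataFrame, covariates: list[str],
            hyperparams: dict | None = None, seed: int = 0,
            species: str = "", scaling: ScalingParams | None = None) -> SDMModel:
    """Fit the boosted-tree binomial model on a labeled table.

    ``table`` must hold a 0/1 ``label`` column and the covariate columns
    (already standardized).  Needs both classes and >= 20 rows.
    """
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    y = table["label"].values.astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("table contains a single label class")
    if len(table) < 20:
        raise ValueError(f"need >= 20 rows to fit, got {len(table)}")
    X = table[covariates].values.astype(float)
    est = _make_estimator(hp, seed).fit(X, y)
    return SDMModel(species, list(covariates), hp, scaling, est, seed)


# ---------------------------------------------------------------------------
# metrics

def auc(labels, scores) -> float:
    """Rank-formulation AUC: probability a random presence outscores a
    random absence, ties counted 1/2."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def tss(labels, scores) -> float:
    """True skill statistic: max over thresholds of
    sensitivity + specificity - 1 (Youden's J at the best cut)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("TSS undefined with a single class")
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    # evaluate only at distinct-score boundaries, plus the trivial all-negative cut
    distinct = np.r_[ss[1:] != ss[:-1], True]
    sens = tp[distinct] / n1
    spec = 1 - fp[distinct] / n0
    j = np.r_[0.0, sens + spec - 1.0]
    return float(j.max())


def r2_deviance(labels, scores) -> float:
    """Deviance explained: 1 - residual/null binomial deviance."""
    y = np.asarray(labels).astype(float)
    p = np.clip(np.asarray(scores, dtype=float), 1e-12, 1 - 1e-12)
    resid = -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    null = -2 * np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar))
    return float(1 - resid / null) if null > 0 else np.nan


# ---------------------------------------------------------------------------
# cross-validation

def cv_kfold(table: pd.DataFrame, covariates: list[str], k: int = 10,
             hyperparams: dict | None = None, seed: int = 0) -> dict:
    """Stratified k-fold CV; per-fold AUC/TSS, aggregated mean ± SD.

    A fold that would lack both classes triggers a reshuffle with a new
    derived seed (warned).  ``k == n`` degenerates to leave-one-out, where
    per-fold AUC is undefined; metrics are then computed on the pooled
    out-of-fold predictions.
    """
    y = table["label"].values.astype(int)
    n = len(table)
    if k > n:
        raise ValueError("k cannot exceed the number of rows")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        folds = _stratified_folds(y, k, rng)
        ok = all(len(np.unique(y[f])) == 2 for f in folds) or k == n
        if ok:
            break
        warnings.warn("fold without both classes; refolding with a new seed")
    aucs, tsss = [], []
    pooled_pred = np.full(n, np.nan)
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        m = fit_brt(table.iloc[train], covariates, hyperparams, seed=seed)
        p = m.predict(table.iloc[f])
        pooled_pred[f] = p
        if len(np.unique(y[f])) == 2:
            aucs.append(auc(y[f], p))
            tsss.append(tss(y[f], p))
    if aucs:
        out = {"auc_cv_mean": float(np.mean(aucs)),
               "auc_cv_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
               "tss_cv_mean": float(np.mean(tsss))}
    else:  # leave-one-out fallback: pooled predictions
        out = {"auc_cv_mean": auc(y, pooled_pred),
               "auc_cv_sd": np.nan,
               "tss_cv_mean": tss(y, pooled_pred)}
    out["per_fold_auc"] = aucs
    return out


def _stratified_folds(y: np.ndarray, k: int, rng) -> list[np.ndarray]:
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def assign_spatial_blocks(lon, lat, block_size_km2: float,
                          n_folds: int = 5, seed: int = 0,
                          center: tuple[float, float] | None = None):
    """Fold labels from square spatial blocks of area ``block_size_km2``.

    Blocks of side sqrt(block_size_km2) tile the points' planar
    (azimuthal-equidistant) extent; non-empty blocks are shuffled and dealt
    round-robin to folds, so co-located points always share a fold.
    """
    if block_size_km2 <= 0:
        raise ValueError("block_size_km2 must be positive")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if center is None:
        center = (float(lon.mean()), float(lat.mean()))
    x, y = AzimuthalEquidistant(*center).forward(lon, lat)
    side = np.sqrt(block_size_km2)
    bx = np.floor(x / side).astype(int)
    by = np.floor(y / side).astype(int)
    blocks = pd.factorize(pd.Series(list(zip(bx, by))))[0]
    uniq = np.unique(blocks)
    if len(uniq) < n_folds:
        raise ValueError(
            f"only {len(uniq)} non-empty blocks for {n_folds} folds; "
            "use a smaller block size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    block_fold = {b: i % n_folds for i, b in enumerate(order)}
    return np.array([block_fold[b] for b in blocks])


def cv_spatial_block(table: pd.DataFrame, covariates: list[str],
                     block_size_km2: float, n_folds: int = 5,
                     hyperparams: dict | None = None, seed: int = 0) -> dict:
    """Spatial block CV: all rows in a block share a fold."""
    y = table["label"].values.astype(int)
    fold = assign_spatial_blocks(table["lon"].values, table["lat"].values,
                                 block_size_km2, n_folds, seed)
    aucs, tsss = [], []
    for f in range(n_folds):
        test = np.flatnonzero(fold == f)
        train = np.flatnonzero(fold != f)
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            warnings.warn(f"spatial fold {f} lacks both classes; skipped")
            continue
        m = fit_brt(table.iloc[train], covariates, hyperparams, seed=seed)
        p = m.predict(table.iloc[test])
        aucs.append(auc(y[test], p))
        tsss.append(tss(y[test], p))
    if not aucs:
        raise ValueError("no evaluable spatial fold")
    return {"auc_block_mean": float(np.mean(aucs)),
            "auc_block_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            "tss_block_mean": float(np.mean(tsss)),
            "block_size_km2": float(block_size_km2),
            "per_fold_auc": aucs}


def evaluate(model: SDMModel, table: pd.DataFrame,
             block_size_km2: float | None = None, k: int = 10,
             n_block_folds: int = 5, seed: int = 0) -> EvalReport:
    """Full metric suite for a fitted model on its fitting table."""
    y = table["label"].values.astype(int)
    p = model.predict(table)
    rep = EvalReport(auc_train=auc(y, p), r2_deviance=r2_deviance(y, p),
                     tss_train=tss(y, p))
    cv = cv_kfold(table, model.covariates, k=k,
                  hyperparams=model.hyperparams, seed=seed)
    rep.auc_cv_mean = cv["auc_cv_mean"]
    rep.auc_cv_sd = cv["auc_cv_sd"]
    rep.tss_cv_mean = cv["tss_cv_mean"]
    if block_size_km2 is not None:
        try:
            bl = cv_spatial_block(table, model.covariates, block_size_km2,
                                  n_folds=n_block_folds,
                                  hyperparams=model.hyperparams, seed=seed)
            rep.auc_block_mean = bl["auc_block_mean"]
            rep.auc_block_sd = bl["auc_block_sd"]
            rep.block_size_km2 = bl["block_size_km2"]
        except ValueError as e:
            rep.extras["block_cv_error"] = str(e)
    return rep


def overfit_check(report: EvalReport, tol: float = 0.1) -> bool:
    """Pass iff both train-CV AUC gaps are strictly below ``tol``.

    A gap of exactly ``tol`` fails (strict <).  A missing block-CV mean is
    ignored (insufficient spatial spread to block).
    """
    gaps = [report.overfit_delta_cv]
    if np.isfinite(report.auc_block_mean):
        gaps.append(report.overfit_delta_block)
    return all(np.isfinite(g) and g < tol for g in gaps)
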