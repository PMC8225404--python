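"""Event-by-event regression of band power on behavioral features.

For each electrode and band, band-averaged log power is modelled as a linear
function of the 10 behavioral features: continuous features standardized
(duration and magnitude log-transformed first), day and time-of-day one-hot
encoded with one reference level dropped.  Fitting minimises the Huber loss
(IRLS); features are pruned per split by forward selection on OLS adjusted
R²; importance is the drop in withheld-data R² after permuting one feature's
training values.  Everything is averaged over repeated day-balanced 90/10
train/test splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

HUBER_DELTA = 1.345  # 95% Gaussian efficiency
CONTINUOUS_FEATURES = [
    "duration", "magnitude", "angle", "onset_speed",
    "speech_ratio", "bimanual_ratio", "bimanual_overlap", "bimanual_class",
]
LOG_FEATURES = ("duration", "magnitude")
CATEGORICAL_FEATURES = ["day", "time_of_day"]


class DesignBuilder:
    """Feature encoding fitted on training rows only (no test-set leakage).

    Continuous features are standardized using training mean/SD (duration and
    magnitude after a log transform); categorical features become one-hot
    blocks with the first observed level dropped.  Single-level categorical
    blocks are dropped with a warning; a zero-variance continuous feature is
    an error.
    """

    def __init__(self) -> None:
        self.means: dict[str, float] = {}
        self.sds: dict[str, float] = {}
        self.levels: dict[str, list] = {}
        self.columns: list[str] = []
        self.blocks: dict[str, list[int]] = {}

    def fit(self, table: pd.DataFrame) -> "DesignBuilder":
        self.columns, self.blocks = [], {}
        for feat in CONTINUOUS_FEATURES:
            x = table[feat].to_numpy(dtype=float)
            if feat in LOG_FEATURES:
                x = np.log(x)
            m, s = float(x.mean()), float(x.std())
            if s < 1e-12:
                raise ValueError(f"feature {feat!r} has zero variance on training rows")
            self.means[feat], self.sds[feat] = m, s
            self.blocks[feat] = [len(self.columns)]
            self.columns.append(feat)
        for feat in CATEGORICAL_FEATURES:
            levels = sorted(pd.unique(table[feat]).tolist())
            if len(levels) < 2:
                warnings.warn(f"categorical {feat!r} has a single level; block dropped", stacklevel=2)
                continue
            self.levels[feat] = levels
            idx = []
            for lv in levels[1:]:  # drop-one encoding, first level is the reference
                idx.append(len(self.columns))
                self.columns.append(f"{feat}={lv}")
            self.blocks[feat] = idx
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        n = len(table)
        X = np.zeros((n, len(self.columns)))
        for feat in CONTINUOUS_FEATURES:
            x = table[feat].to_numpy(dtype=float)
            if feat in LOG_FEATURES:
                x = np.log(x)
            X[:, self.blocks[feat][0]] = (x - self.means[feat]) / self.sds[feat]
        for feat, levels in self.levels.items():
            vals = table[feat].to_numpy()
            for j, lv in zip(self.blocks[feat], levels[1:]):
                X[:, j] = (vals == lv).astype(float)
        return X

    def stats_checksum(self) -> float:
        """Scalar fingerprint of the fitted standardization statistics."""
        return float(sum(self.means.values()) + sum(self.sds.values()))


@dataclass
class RegressionResult:
    band: str
    electrode: str
    n_splits: int
    mean_full_r2: float
    mean_coefs: dict[str, np.ndarray]  # feature -> mean coefficient(s), over retaining splits
    mean_intercept: float
    delta_r2: dict[str, float]  # feature -> mean ΔR² over retaining splits
    retention: dict[str, float]  # feature -> fraction of splits retained
    split_indices: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    train_stats_checksums: list[float] = field(default_factory=list)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return 0.0 if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    n = len(y)
    r2 = _r2(y, yhat)
    if n - n_params - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def huber_fit(
    X: np.ndarray,
    y: np.ndarray,
    delta: float = HUBER_DELTA,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Huber-loss linear fit by iteratively reweighted least squares.

    ``X`` excludes the intercept; the returned vector is (intercept, coefs).
    Residuals are scaled by a MAD estimate each iteration; a (near-)perfect
    fit short-circuits to the least-squares solution.  Raises on
    rank-deficient designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(y) <= X.shape[1]:
        raise ValueError("need more rows than columns")
    A = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    for _ in range(max_iter):
        r = y - A @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale < 1e-10 * max(1.0, float(np.abs(y).max())):
            return beta  # perfect (or near-perfect) fit
        z = np.abs(r) / scale
        w = np.where(z <= delta, 1.0, delta / z)
        Aw = A * w[:, None]
        new = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            return new
        beta = new
    return beta


def forward_select(
    X: np.ndarray, y: np.ndarray, blocks: dict[str, list[int]]
) -> list[str]:
    """Greedy forward selection on OLS adjusted R²; blocks enter atomically.

    Starts intercept-only and repeatedly adds the block with the largest
    positive adjusted-R² gain; ties are broken by block (column) order.
    Returns the retained feature names, possibly empty.
    """
    if len(blocks) < 2:
        raise ValueError("need at least 2 candidate features")
    remaining = list(blocks)
    selected: list[str] = []
    cols: list[int] = []
    current = _adjusted_r2(y, np.full(len(y), y.mean()), 0)
    while remaining:
        best_gain, best_feat = 0.0, None
        for feat in remaining:
            trial = cols + blocks[feat]
            beta = _ols(X[:, trial], y)
            yhat = np.column_stack([np.ones(len(X)), X[:, trial]]) @ beta
            adj = _adjusted_r2(y, yhat, len(trial))
            gain = adj - current
            if gain > best_gain + 1e-12:
                best_gain, best_feat = gain, feat
        if best_feat is None:
            break
        selected.append(best_feat)
        cols += blocks[best_feat]
        beta = _ols(X[:, cols], y)
        yhat = np.column_stack([np.ones(len(X)), X[:, cols]]) @ beta
        current = _adjusted_r2(y, yhat, len(cols))
        remaining.remove(best_feat)
    return selected


def delta_r2(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cols: list[int],
    feature_cols: list[int],
    full_r2: float,
    rng: np.random.Generator,
    delta: float = HUBER_DELTA,
) -> float:
    """Importance of one feature: full R² minus R² after permuting its training values.

    All columns of the feature's block are permuted with the same row
    permutation; the model is refit and evaluated on the unshuffled test set.
    """
    perm = rng.permutation(len(X_train))
    Xs = X_train.copy()
    Xs[:, feature_cols] = Xs[perm][:, feature_cols]
    beta = huber_fit(Xs[:, cols], y_train, delta=delta)
    yhat = np.column_stack([np.ones(len(X_test)), X_test[:, cols]]) @ beta
    return full_r2 - _r2(y_test, yhat)


def day_balanced_split(
    days: np.ndarray, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test indices: each day contributes ~test_frac of its events.

    Per-day test count is max(1, round(test_frac * n_day)) for days with at
    least 2 events; a day with fewer events goes entirely to training (with a
    warning).
    """
    train, test = [], []
    for day in np.unique(days):
        idx = np.flatnonzero(days == day)
        if len(idx) < 2:
            warnings.warn(f"day {day} has < 2 events; all assigned to training", stacklevel=2)
            train.extend(idx)
            continue
        n_test = min(len(idx) - 1, max(1, int(round(test_frac * len(idx)))))
        perm = rng.permutation(idx)
        test.extend(perm[:n_test])
        train.extend(perm[n_test:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def run_splits(
    y: np.ndarray,
    feature_table: pd.DataFrame,
    n_splits: int = 200,
    test_frac: float = 0.1,
    seed: int = 0,
    band: str = "",
    electrode: str = "",
    delta: float = HUBER_DELTA,
    keep_split_indices: bool = False,
) -> RegressionResult:
    """Full per-electrode-band procedure over repeated day-balanced splits.

    Per split: stratify 90/10 within day, standardize on training rows,
    forward-select, Huber-fit, evaluate withheld R², then one permutation
    ΔR² per retained feature.  Coefficients and ΔR² are averaged over the
    splits in which the feature was retained; retention frequencies are
    recorded.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(feature_table):
        raise ValueError("y and feature table must have equal length")
    if len(y) < 20:
        raise ValueError("need at least 20 events")
    days = feature_table["day"].to_numpy()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_splits)

    full_r2s = np.empty(n_splits)
    coef_acc: dict[str, list[np.ndarray]] = {}
    int_acc: list[float] = []
    dr2_acc: dict[str, list[float]] = {}
    retained_count: dict[str, int] = {}
    checksums: list[float] = []
    splits_kept: list[tuple[np.ndarray, np.ndarray]] = []

    for k in range(n_splits):
        rng = np.random.default_rng(child_seeds[k])
        tr, te = day_balanced_split(days, test_frac, rng)
        builder = DesignBuilder().fit(feature_table.iloc[tr])
        X_tr = builder.transform(feature_table.iloc[tr])
        X_te = builder.transform(feature_table.iloc[te])
        y_tr, y_te = y[tr], y[te]
        selected = forward_select(X_tr, y_tr, builder.blocks)
        cols = [c for f in selected for c in builder.blocks[f]]
        if cols:
            beta = huber_fit(X_tr[:, cols], y_tr, delta=delta)
            yhat = np.column_stack([np.ones(len(X_te)), X_te[:, cols]]) @ beta
        else:
            beta = np.array([float(np.mean(y_tr))])
            yhat = np.full(len(te), beta[0])
        r2 = _r2(y_te, yhat)
        full_r2s[k] = r2
        int_acc.append(float(beta[0]))
        offset = 1
        for f in selected:
            ncol = len(builder.blocks[f])
            coef_acc.setdefault(f, []).append(beta[offset : offset + ncol])
            offset += ncol
            retained_count[f] = retained_count.get(f, 0) + 1
        for f in selected:
            dr2 = delta_r2(X_tr, y_tr, X_te, y_te, cols, builder.blocks[f], r2, rng, delta=delta)
            dr2_acc.setdefault(f, []).append(dr2)
        checksums.append(builder.stats_checksum())
        if keep_split_indices:
            splits_kept.append((tr, te))

    all_feats = list(coef_acc)
    return RegressionResult(
        band=band,
        electrode=electrode,
        n_splits=n_splits,
        mean_full_r2=float(full_r2s.mean()),
        mean_coefs={f: np.mean(np.stack(coef_acc[f]), axis=0) for f in all_feats},
        mean_intercept=float(np.mean(int_acc)),
        delta_r2={f: float(np.mean(dr2_acc[f])) for f in dr2_acc},
        retention={f: retained_count.get(f, 0) / n_splits for f in retained_count},
        split_indices=splits_kept,
        train_stats_checksums=checksums,
    )


def regress_all(
    band_powers: pd.DataFrame,
    feature_table: pd.DataFrame,
    n_splits: int = 200,
    test_frac: float = 0.1,
    seed: int = 0,
) -> list[RegressionResult]:
    """Run ``run_splits`` for every (electrode, band) in a tidy band-power table.

    ``band_powers`` columns: event, channel, band, value; rows are matched to
    ``feature_table`` by the event id.
    """
    results = []
    feats = feature_table.set_index("event")
    for (channel, band), grp in band_powers.groupby(["channel", "band"], sort=True):
        grp = grp[grp["event"].isin(feats.index)]
        sub = feats.loc[grp["event"]].reset_index()
        res = run_splits(
            grp["value"].to_numpy(), sub, n_splits=n_splits, test_frac=test_frac,
            seed=seed, band=str(band), electrode=str(channel),
        )
        results.append(res)
    return results
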