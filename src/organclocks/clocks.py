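"""Bagged LASSO chronological-age models.

Each organ clock is an ensemble of B (default 500) LASSO regressions, one
per bootstrap resample of the training cohort (each resample the size of
the cohort). Features are z-scored log10 protein abundances plus an
unstandardized sex indicator (F=1, M=0); standardization parameters are
estimated once on the full training cohort and reused at prediction time.
Per bootstrap, the L1 penalty is tuned by 5-fold cross-validation over a
log-spaced grid, choosing the *largest* penalty whose mean CV score
retains 95% of the best score — a deliberate bias toward sparser models.
The ensemble prediction is the arithmetic mean over instances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

logger = logging.getLogger(__name__)


@dataclass
class CohortData:
    """Subject-level plasma proteomics plus metadata.

    ``proteins``: subjects x probes DataFrame of log10-transformed
    abundances (no missing values). ``meta``: DataFrame aligned on the same
    index with at least ``age`` (years, > 0), ``sex`` (F=1/M=0) and
    ``cohort`` columns; optional ``healthy`` flag, trait and
    time/event columns.
    """

    proteins: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.proteins.index.equals(self.meta.index):
            raise ValueError("proteins and meta must share the same subject index")
        if self.proteins.isna().any().any():
            bad = self.proteins.columns[self.proteins.isna().any()]
            raise ValueError(f"missing protein values in columns {list(bad)[:5]}")
        if (self.meta["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if not self.meta["sex"].isin([0, 1]).all():
            raise ValueError("sex must be coded F=1 / M=0")

    @property
    def subject_ids(self) -> list:
        return list(self.proteins.index)

    @property
    def age(self) -> np.ndarray:
        return self.meta["age"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.meta["sex"].to_numpy(dtype=float)

    def subset(self, mask) -> "CohortData":
        return CohortData(self.proteins.loc[mask], self.meta.loc[mask])


@dataclass
class ClockConfig:
    """Training configuration for a bagged clock."""

    n_bootstraps: int = 500
    cv_folds: int = 5
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    retention: float = 0.95
    scoring: str = "r2"  # or "neg_mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")


@dataclass
class ClockModel:
    """A trained bagged LASSO ensemble.

    ``coefs`` is B x (p+1): one row per bootstrap instance, columns indexed
    like ``probes`` plus a final sex term. ``feature_means``/``feature_sds``
    are the training-cohort standardization parameters for the p probes.
    """

    model_name: str
    probes: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coefs: np.ndarray
    intercepts: np.ndarray
    lambdas: np.ndarray
    bootstrap_indices: np.ndarray  # B x n_train
    config: ClockConfig
    n_train: int = 0

    @property
    def n_instances(self) -> int:
        return self.coefs.shape[0]

    def nonzero_instance_counts(self) -> pd.Series:
        """Per probe, number of instances with a nonzero coefficient."""
        counts = (self.coefs[:, : len(self.probes)] != 0).sum(axis=0)
        return pd.Series(counts, index=self.probes)

    def to_json(self) -> str:
        d = {
            "schema": "organclocks.clock/1",
            "model_name": self.model_name,
            "probes": self.probes,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "coefs": self.coefs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "lambdas": self.lambdas.tolist(),
            "bootstrap_indices": self.bootstrap_indices.tolist(),
            "n_train": self.n_train,
            "config": vars(self.config),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        if d.get("schema") != "organclocks.clock/1":
            raise ValueError(f"unrecognized model schema: {d.get('schema')!r}")
        return cls(
            model_name=d["model_name"],
            probes=list(d["probes"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            coefs=np.asarray(d["coefs"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            bootstrap_indices=np.asarray(d["bootstrap_indices"], dtype=np.int64),
            n_train=int(d["n_train"]),
            config=ClockConfig(**d["config"]),
        )


@dataclass
class AgePrediction:
    """Per-subject instance-level and ensemble-mean predicted ages."""

    subject_ids: list
    instance_predictions: np.ndarray  # n_subjects x B
    model_name: str

    @property
    def mean_prediction(self) -> np.ndarray:
        return self.instance_predictions.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.model_name, "predicted_age": self.mean_prediction},
            index=pd.Index(self.subject_ids, name="subject"),
        )


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """LASSO fit minimizing (1/2n)||y - Xb - b0||^2 + lam*||b||_1.

    The intercept is unpenalized. ``lam = 0`` falls back to ordinary least
    squares via the normal equations (minimum-norm solution).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if lam == 0:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        intercept = y.mean() - X.mean(axis=0) @ beta
        return beta, float(intercept)
    est = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
    est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_)


def lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max|X'(y-ybar)|/n."""
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    if lam_max <= 0:
        raise ValueError("response is orthogonal to all features; no lambda grid")
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambdas)


def select_lambda(lambdas: np.ndarray, scores: np.ndarray, retention: float = 0.95) -> float:
    """Largest lambda whose mean CV score retains ``retention`` x best score.

    Expects a descending grid. If the best score is nonpositive the
    retention rule is meaningless (scores may all be negative); the
    arg-max lambda is returned with a warning, ties resolved to the largest
    (sparsest) lambda.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    best = scores.max()
    if best <= 0:
        logger.warning("best CV score <= 0; returning arg-max lambda")
        return float(lambdas[np.flatnonzero(scores == best)[0]])
    ok = np.flatnonzero(scores >= retention * best)
    return float(lambdas[ok[0]])  # grid descending: first qualifying = largest


def _cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    scoring: str,
) -> np.ndarray:
    """Mean CV score per alpha via the full coordinate-descent path."""
    n = len(y)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    scores = np.zeros((n_folds, len(alphas)))
    for k, test in enumerate(folds):
        train = np.setdiff1d(perm, test, assume_unique=True)
        Xtr, ytr = X[train], y[train]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = lasso_path(
            Xtr - xm, ytr - ym, alphas=alphas, precompute=True
        )
        pred = (X[test] - xm) @ coefs + ym  # n_test x n_alphas
        resid = pred - y[test][:, None]
        mse = (resid ** 2).mean(axis=0)
        if scoring == "r2":
            denom = ((y[test] - y[test].mean()) ** 2).mean()
            scores[k] = 1 - mse / denom
        elif scoring == "neg_mse":
            scores[k] = -mse
        else:
            raise ValueError(f"unknown scoring {scoring!r}")
    return scores.mean(axis=0)


def standardize_features(
    cohort: CohortData,
    probes: list[str],
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-score probe columns (given or freshly estimated) and append sex."""
    P = cohort.proteins[probes].to_numpy(dtype=float)
    if means is None:
        means = P.mean(axis=0)
        sds = P.std(axis=0, ddof=0)
        zero = sds == 0
        if zero.any():
            bad = [probes[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"zero-variance probes: {bad}")
    Z = (P - means) / sds
    X = np.column_stack([Z, cohort.sex])
    return X, means, sds


def train_bagged_clock(
    train: CohortData,
    probes,
    config: ClockConfig,
    model_name: str = "clock",
) -> ClockModel:
    """Train a bagged LASSO age model on the given probe set.

    The caller is responsible for restricting ``train`` to healthy
    subjects. Fully reproducible from ``config.seed``: bootstrap draws and
    CV fold shuffles are sub-seeded per instance via SeedSequence, so
    instances are independent of evaluation order.
    """
    probes = sorted(probes)
    missing = [p for p in probes if p not in train.proteins.columns]
    if missing:
        raise ValueError(f"probes absent from cohort: {missing[:5]}")
    n = len(train.proteins)
    if n < config.cv_folds:
        raise ValueError(f"n={n} smaller than cv_folds={config.cv_folds}")
    if "healthy" in train.meta.columns and not train.meta["healthy"].all():
        logger.info("training cohort includes non-healthy subjects (caller's choice)")

    X, means, sds = standardize_features(train, probes)
    y = train.age
    B, p = config.n_bootstraps, X.shape[1]
    coefs = np.zeros((B, p))
    intercepts = np.zeros(B)
    lambdas = np.zeros(B)
    indices = np.zeros((B, n), dtype=np.int64)

    for b in range(B):
        boot_rng = np.random.default_rng(np.random.SeedSequence([config.seed, b, 0]))
        cv_rng = np.random.default_rng(np.random.SeedSequence([config.seed, b, 1]))
        idx = boot_rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        grid = lambda_grid(Xb, yb, config.n_lambdas, config.lambda_min_ratio)
        scores = _cv_scores(Xb, yb, grid, config.cv_folds, cv_rng, config.scoring)
        lam = select_lambda(grid, scores, config.retention)
        beta, b0 = fit_lasso(Xb, yb, lam)
        coefs[b], intercepts[b], lambdas[b], indices[b] = beta, b0, lam, idx

    return ClockModel(
        model_name=model_name,
        probes=probes,
        feature_means=means,
        feature_sds=sds,
        coefs=coefs,
        intercepts=intercepts,
        lambdas=lambdas,
        bootstrap_indices=indices,
        config=config,
        n_train=n,
    )


def predict_age(
    model: ClockModel, cohort: CohortData, restandardize: bool = False
) -> AgePrediction:
    """Evaluate every ensemble instance; the ensemble age is their mean.

    By default the training-cohort standardization is applied; with
    ``restandardize`` the probe means/SDs are re-estimated on ``cohort``.
    """
    missing = [p for p in model.probes if p not in cohort.proteins.columns]
    if missing:
        raise ValueError(f"cohort is missing model probes: {missing[:5]}")
    if restandardize:
        X, _, _ = standardize_features(cohort, model.probes)
    else:
        X, _, _ = standardize_features(
            cohort, model.probes, model.feature_means, model.feature_sds
        )
    preds = X @ model.coefs.T + model.intercepts  # n x B
    return AgePrediction(cohort.subject_ids, preds, model.model_name)
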