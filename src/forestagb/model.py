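"""Bayesian linear AGB model on truncated-SVD orthogonal predictors.

Area-based LiDAR predictors are many and strongly collinear while
calibration sets are small (a few dozen plots), so ordinary least squares
is unstable.  The model used here regresses the centered response on the
orthogonal components of the standardized predictor matrix:

1.  standardize the n x p predictor matrix ``X`` column-wise to ``Z``;
2.  take the SVD ``Z = U S V^T`` and keep the smallest ``k`` components
    whose squared singular values account for at least the configured
    *explanation ratio* of total predictor variance;
3.  give each component coefficient an independent zero-mean Gaussian
    prior whose SD scales with its singular value,
    ``sd(alpha_j) = tau * s_j / s_1``: components that explain more of
    the predictor variability are allowed to deviate further from zero;
4.  with Gaussian noise of variance ``sigma^2`` the posterior mean is the
    generalized-ridge closed form

        alpha_j = (d_j^T y_c) / (d_j^T d_j + sigma^2 s_1^2 / (tau^2 s_j^2))

    where ``d_j = Z v_j`` is the j-th component score vector and ``y_c``
    the centered response; the intercept is the training response mean.

As ``tau -> inf`` with explanation ratio 1 this reduces to OLS; small
``tau`` shrinks every coefficient toward zero and predictions toward the
training mean.  The exact prior/posterior algebra is this package's own
closed-form realization of the scheme (the construction is stated only in
outline in the literature it follows); ``tau`` and the explanation ratio
are exposed as knobs.

When the response carries no signal the posterior coefficients shrink
and predictions collapse to the training mean -- the mechanism behind
cross-design prediction bias in weak-correlation regimes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class ModelConfig:
    """Tuning knobs of the truncated-SVD Bayesian linear model."""

    explanation_ratio: float = 0.95   # fraction of predictor variance retained
    tau: float = 10.0                 # prior scale of the leading component
    noise_variance_mode: str = "estimate"  # "estimate" | "fixed"
    fixed_noise_sd: float | None = None    # Mg/ha, used when mode == "fixed"

    def __post_init__(self) -> None:
        if not 0.0 < self.explanation_ratio <= 1.0:
            raise ConfigError("explanation_ratio must be in (0, 1]")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.noise_variance_mode not in ("estimate", "fixed"):
            raise ConfigError("noise_variance_mode must be 'estimate' or 'fixed'")
        if self.noise_variance_mode == "fixed" and (
                self.fixed_noise_sd is None or self.fixed_noise_sd <= 0):
            raise ConfigError("fixed mode needs a positive fixed_noise_sd")


def standardize(X: np.ndarray | pd.DataFrame
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Column-standardize a predictor matrix (population-SD convention).

    Returns ``(Z, means, sds, kept)`` where ``kept`` indexes the retained
    columns; constant columns are dropped with a warning.  Raises if every
    column is constant.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ConfigError("X must be two-dimensional")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0)  # ddof=0
    kept = [j for j in range(arr.shape[1]) if sds[j] > 0]
    if not kept:
        raise ConfigError("all predictor columns are constant")
    if len(kept) < arr.shape[1]:
        dropped = sorted(set(range(arr.shape[1])) - set(kept))
        warnings.warn(f"dropping constant predictor columns {dropped}",
                      stacklevel=2)
    Z = (arr[:, kept] - means[kept]) / sds[kept]
    return Z, means[kept], sds[kept], kept


@dataclass
class ModelFit:
    """A fitted model: standardization constants, retained SVD factors and
    posterior component-coefficient means."""

    feature_names: list[str]
    predictor_means: np.ndarray
    predictor_sds: np.ndarray
    response_mean: float
    V: np.ndarray                 # p x k right singular vectors (retained)
    singular_values: np.ndarray   # length k, descending
    k_retained: int
    alpha: np.ndarray             # posterior component-coefficient means
    noise_variance: float
    config: ModelConfig
    dropped_columns: list[str] = field(default_factory=list)

    def coefficients(self) -> np.ndarray:
        """Coefficients mapped back to the standardized-predictor basis."""
        return self.V @ self.alpha

    def raw_coefficients(self) -> np.ndarray:
        """Coefficients on the raw predictor scale (no intercept)."""
        return self.coefficients() / self.predictor_sds

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "predictor_means": self.predictor_means.tolist(),
            "predictor_sds": self.predictor_sds.tolist(),
            "response_mean": self.response_mean,
            "V": self.V.tolist(),
            "singular_values": self.singular_values.tolist(),
            "k_retained": self.k_retained,
            "alpha": self.alpha.tolist(),
            "noise_variance": self.noise_variance,
            "dropped_columns": self.dropped_columns,
            "config": {
                "explanation_ratio": self.config.explanation_ratio,
                "tau": self.config.tau,
                "noise_variance_mode": self.config.noise_variance_mode,
                "fixed_noise_sd": self.config.fixed_noise_sd,
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ModelFit":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            predictor_means=np.asarray(d["predictor_means"]),
            predictor_sds=np.asarray(d["predictor_sds"]),
            response_mean=d["response_mean"],
            V=np.asarray(d["V"]),
            singular_values=np.asarray(d["singular_values"]),
            k_retained=d["k_retained"],
            alpha=np.asarray(d["alpha"]),
            noise_variance=d["noise_variance"],
            config=ModelConfig(**d["config"]),
            dropped_columns=d["dropped_columns"],
        )


def _as_matrix(X, feature_cols: list[str] | None
               ) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = feature_cols if feature_cols is not None else list(X.columns)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise SchemaError(f"predictor table is missing columns {missing}")
        return X[cols].to_numpy(float), list(cols)
    arr = np.asarray(X, dtype=float)
    names = [f"x{j}" for j in range(arr.shape[1])]
    return arr, names


def fit(X, y, config: ModelConfig | None = None,
        feature_cols: list[str] | None = None) -> ModelFit:
    """Fit the truncated-SVD Bayesian linear model.

    ``X`` is an n x p array or DataFrame of predictors, ``y`` the AGB
    response in Mg/ha.  Requires n >= 3.  If the truncation rule would
    retain zero components the leading one is kept with a warning.
    """
    if config is None:
        config = ModelConfig()
    arr, names = _as_matrix(X, feature_cols)
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n < 3:
        raise ConfigError(f"need at least 3 training plots, got {n}")
    if y.shape != (n,):
        raise ConfigError("y length must match the number of rows of X")

    Z, means, sds, kept = standardize(arr)
    kept_names = [names[j] for j in kept]
    dropped = [names[j] for j in range(p) if j not in kept]

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_TOL)) if s.size else 0
    if rank == 0:
        raise ConfigError("predictor matrix has rank zero after standardization")
    s = s[:rank]
    U = U[:, :rank]
    Vt = Vt[:rank]

    energy = np.cumsum(s ** 2) / np.sum(s ** 2)
    k = int(np.searchsorted(energy, config.explanation_ratio - 1e-12) + 1)
    k = min(k, rank)
    if k == 0:  # defensive; searchsorted can't yield 0 here
        warnings.warn("truncation retained no component; keeping the first")
        k = 1

    ybar = float(y.mean())
    yc = y - ybar
    D = U[:, :k] * s[:k]            # component scores, d_j = Z v_j
    dty = D.T @ yc
    dtd = s[:k] ** 2                # d_j^T d_j for orthonormal U

    alpha_ols = dty / dtd
    if config.noise_variance_mode == "fixed":
        sigma2 = float(config.fixed_noise_sd) ** 2
    else:
        resid = yc - D @ alpha_ols
        dof = n - k - 1
        if dof > 0:
            sigma2 = float(resid @ resid) / dof
        else:  # saturated fit: fall back to response variance
            sigma2 = float(yc @ yc) / max(n - 1, 1)
        sigma2 = max(sigma2, 1e-12)

    penalty = sigma2 * s[0] ** 2 / (config.tau ** 2 * s[:k] ** 2)
    alpha = dty / (dtd + penalty)

    return ModelFit(
        feature_names=kept_names,
        predictor_means=means,
        predictor_sds=sds,
        response_mean=ybar,
        V=Vt[:k].T,
        singular_values=s[:k],
        k_retained=k,
        alpha=alpha,
        noise_variance=sigma2,
        config=config,
        dropped_columns=dropped,
    )


def predict(fit_: ModelFit, X_new, clamp_non_negative: bool = False
            ) -> np.ndarray:
    """Predict AGB (Mg/ha) for new plots with a fitted model.

    Predictors are standardized with the stored training means/SDs and
    projected onto the retained components.  Raw model output can be
    negative; error statistics must see it unclamped, so clamping at zero
    is opt-in for reporting only.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in fit_.feature_names if c not in X_new.columns]
        if missing:
            raise SchemaError(f"prediction table is missing columns {missing}")
        arr = X_new[fit_.feature_names].to_numpy(float)
    else:
        arr = np.asarray(X_new, dtype=float)
        if arr.shape[1] != len(fit_.feature_names):
            raise SchemaError(
                f"expected {len(fit_.feature_names)} predictor columns, "
                f"got {arr.shape[1]}")
    Z = (arr - fit_.predictor_means) / fit_.predictor_sds
    yhat = fit_.response_mean + Z @ fit_.V @ fit_.alpha
    if clamp_non_negative:
        yhat = np.maximum(yhat, 0.0)
    return yhat
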