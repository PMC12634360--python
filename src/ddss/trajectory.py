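"""Lasso regularization paths and surgeon preference sequences.

The central object is the *preference sequence*: for one surgeon (or one pooled group
of records), fit the Lasso of per-surgeon-normalized operative time on the 14
standardized ordinal indicator codes over a decreasing geometric grid of penalties
``lambda``, and record the order in which coefficients first leave zero.  Surgeons who
are sensitive to many indicators activate many features early; proficient surgeons
activate only a small stable core.  The sequence is the surgeon's signature used by
the decoupler, and the coefficient vector truncated at ``lambda0`` with the
``|beta| >= tau`` retention rule gives the interpretable per-group difficulty factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path as _sklearn_lasso_path
from sklearn.utils import check_array

from .exceptions import ValidationError
from .records import normalize_durations
from .schema import Dataset

__all__ = [
    "LassoPath",
    "PreferenceSequence",
    "RetainedFeatureSet",
    "LearningCurveTable",
    "LassoActivationPath",
    "fit_lasso_path",
    "activation_sequence",
    "retained_features",
    "surgeon_sequences",
    "monthly_trajectories",
]

#: A coefficient is "active" once its magnitude exceeds this tolerance.
ACTIVATION_TOL = 1e-8


@dataclass(frozen=True)
class LassoPath:
    """Coefficients along a strictly decreasing penalty grid.

    ``coefs`` has shape (grid points, n features) on the standardized-predictor
    scale; at the head of the grid (``lambda >= lambda_max``) every coefficient
    is exactly zero.
    """

    lambdas: np.ndarray
    coefs: np.ndarray
    intercepts: np.ndarray
    n_obs: int
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or np.any(np.diff(lam) >= 0) or np.any(lam <= 0):
            raise ValidationError("lambdas must be a strictly decreasing positive grid")
        if self.coefs.shape != (lam.size, len(self.feature_names)):
            raise ValidationError("coefs shape must be (grid, n_features)")
        if not np.all(np.isfinite(self.coefs)):
            raise ValidationError("coefficients must be finite")

    def coefficients_at(self, lam0: float, clip_above: bool = False) -> np.ndarray:
        """Coefficient vector at ``lam0``, linearly interpolated in log-lambda.

        ``lam0`` must lie within the grid; with ``clip_above`` a penalty above the
        top of the grid returns the (exactly zero) head of the path instead of
        raising, which is the mathematically correct solution for
        ``lam0 >= lambda_max``.
        """
        lam = self.lambdas
        if lam0 > lam[0]:
            if clip_above:
                return np.zeros(self.coefs.shape[1])
            raise ValidationError(
                f"lambda0={lam0} above the top of the grid ({lam[0]:.6g})"
            )
        if lam0 < lam[-1]:
            raise ValidationError(
                f"lambda0={lam0} below the bottom of the grid ({lam[-1]:.6g})"
            )
        xs = np.log(lam[::-1])  # increasing for np.interp
        return np.array(
            [
                np.interp(np.log(lam0), xs, self.coefs[::-1, j])
                for j in range(self.coefs.shape[1])
            ]
        )


@dataclass(frozen=True)
class PreferenceSequence:
    """Ordered indicator tokens: a surgeon's feature-activation order."""

    surgeon_id: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValidationError("preference sequence must not repeat tokens")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class RetainedFeatureSet:
    """Indicators whose |coefficient| at ``lambda0`` meets the ``tau`` threshold."""

    entries: dict[str, float]
    lambda0: float = 0.01
    tau: float = 0.05

    def __post_init__(self) -> None:
        for name, value in self.entries.items():
            if abs(value) < self.tau:
                raise ValidationError(
                    f"retained entry {name!r} has |coef| {abs(value):.4g} < tau"
                )

    @property
    def names(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass(frozen=True)
class LearningCurveTable:
    """Per-month pooled Lasso results over contiguous months 1..M.

    ``coefficients[m]`` is the full coefficient vector at ``lambda0`` (or None for a
    month without enough records); ``retained[m]`` the corresponding retained set.
    """

    months: tuple[int, ...]
    coefficients: dict[int, np.ndarray | None]
    retained: dict[int, RetainedFeatureSet | None]
    n_records: dict[int, int]
    feature_names: tuple[str, ...]
    lambda0: float = 0.01
    tau: float = 0.05


class LassoActivationPath(BaseEstimator):
    """Lasso path fitter exposing activation order and the retention rule.

    Solves ``(1/2n)||y - b0 - X beta||^2 + lambda ||beta||_1`` on a geometric grid
    of ``grid_size`` penalties from ``lambda_max`` (where every coefficient is zero
    by the KKT conditions) down to ``lambda_min_ratio * lambda_max``.

    Parameters
    ----------
    grid_size : number of penalty grid points.
    lambda_min_ratio : ratio of the smallest to the largest grid penalty.
    standardize : center predictors and scale them to population SD 1 before
        fitting; constant columns are pinned to coefficient zero.
    solver_tol, max_iter : forwarded to the coordinate-descent backend; the tight
        default tolerance keeps grid coefficients accurate to well below 1e-6.
    """

    def __init__(
        self,
        grid_size: int = 200,
        lambda_min_ratio: float = 1e-4,
        standardize: bool = True,
        activation_tol: float = ACTIVATION_TOL,
        solver_tol: float = 1e-12,
        max_iter: int = 100_000,
    ):
        self.grid_size = grid_size
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.activation_tol = activation_tol
        self.solver_tol = solver_tol
        self.max_iter = max_iter

    def fit(self, X, y, feature_names: tuple[str, ...] | None = None):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 2:
            raise ValidationError(f"need >= 2 observations to fit a path, got {n}")
        if y.size != n:
            raise ValidationError("X and y length mismatch")

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)  # population SD
            Xs = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        else:
            Xs = X
        y_mean = float(y.mean())
        yc = y - y_mean

        lam_max = float(np.max(np.abs(Xs.T @ yc)) / n) if p else 0.0
        if lam_max <= self.activation_tol:
            # Response orthogonal to every predictor (e.g. y identically 0):
            # the whole path is zero on a nominal grid.
            lambdas = np.geomspace(1.0, self.lambda_min_ratio, self.grid_size)
            coefs = np.zeros((self.grid_size, p))
        else:
            lambdas = np.geomspace(
                lam_max, lam_max * self.lambda_min_ratio, self.grid_size
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # benign convergence chatter
                alphas, path_coefs, _ = _sklearn_lasso_path(
                    Xs,
                    yc,
                    alphas=lambdas,
                    tol=self.solver_tol,
                    max_iter=self.max_iter,
                )
            order = np.argsort(alphas)[::-1]
            lambdas = alphas[order]
            coefs = path_coefs[:, order].T

        names = tuple(feature_names) if feature_names else tuple(
            f"x{j}" for j in range(p)
        )
        self.path_ = LassoPath(
            lambdas=lambdas,
            coefs=coefs,
            intercepts=np.full(lambdas.size, y_mean),
            n_obs=n,
            feature_names=names,
        )
        self.lambdas_ = self.path_.lambdas
        self.coefs_ = self.path_.coefs
        self.intercepts_ = self.path_.intercepts
        return self

    def activation_order(self) -> list[int]:
        """Feature indices ordered by first activation along the path."""
        path = self.path_
        active = np.abs(path.coefs) > self.activation_tol
        keys = []
        for j in range(path.coefs.shape[1]):
            idx = np.flatnonzero(active[:, j])
            if idx.size == 0:
                continue
            first = int(idx[0])
            # ties at a grid point: larger |coef| there first, then schema order
            keys.append((first, -abs(float(path.coefs[first, j])), j))
        return [j for _, _, j in sorted(keys)]

    def activation_counts(self) -> np.ndarray:
        """Diagnostic: number of zero -> non-zero transitions per feature."""
        active = np.abs(self.path_.coefs) > self.activation_tol
        starts = active & ~np.vstack([np.zeros(active.shape[1], bool), active[:-1]])
        return starts.sum(axis=0)


# -- module-level operations (thin wrappers) ---------------------------------------


def fit_lasso_path(
    ds: Dataset,
    grid_size: int = 200,
    lambda_min_ratio: float = 1e-4,
    response: dict[str, float] | None = None,
) -> LassoPath:
    """Fit the Lasso path on a Dataset subset.

    Response: per-surgeon z-scored operative time computed within ``ds`` (or passed
    pre-computed via ``response`` keyed by record id).  Predictors: ordinal codes
    standardized to mean 0, population SD 1 over this subset.
    """
    if len(ds) < 2:
        raise ValidationError(f"need >= 2 records, got {len(ds)}")
    X = ds.codes
    if np.isnan(X).any():
        raise ValidationError("dataset contains missing values; impute first")
    if response is None:
        response = normalize_durations(ds)
    y = np.array([response[rid] for rid in ds.record_ids])
    est = LassoActivationPath(grid_size=grid_size, lambda_min_ratio=lambda_min_ratio)
    est.fit(X, y, feature_names=ds.schema.abbreviations)
    return est.path_


def activation_sequence(
    path: LassoPath, surgeon_id: str = "", activation_tol: float = ACTIVATION_TOL
) -> PreferenceSequence:
    """Order indicators by first activation; never-activated ones are omitted."""
    est = LassoActivationPath(activation_tol=activation_tol)
    est.path_ = path
    tokens = tuple(path.feature_names[j] for j in est.activation_order())
    return PreferenceSequence(surgeon_id=surgeon_id, tokens=tokens)


def retained_features(
    path: LassoPath, lambda0: float = 0.01, tau: float = 0.05
) -> RetainedFeatureSet:
    """Apply the truncation-retention rule: keep |coef(lambda0)| >= tau."""
    beta = path.coefficients_at(lambda0)
    entries = {
        name: float(b)
        for name, b in zip(path.feature_names, beta)
        if abs(b) >= tau
    }
    return RetainedFeatureSet(entries=entries, lambda0=lambda0, tau=tau)


def surgeon_sequences(
    ds: Dataset, grid_size: int = 200, lambda_min_ratio: float = 1e-4
) -> list[PreferenceSequence]:
    """One preference sequence per surgeon, fitted on that surgeon's records only."""
    out = []
    for sid, sub in ds.by_surgeon().items():
        path = fit_lasso_path(sub, grid_size=grid_size, lambda_min_ratio=lambda_min_ratio)
        out.append(activation_sequence(path, surgeon_id=sid))
    return out


def monthly_trajectories(
    ds: Dataset,
    months: int = 10,
    lambda0: float = 0.01,
    tau: float = 0.05,
    grid_size: int = 200,
) -> LearningCurveTable:
    """Pool records by month-since-joining and fit one path per month.

    The response is the per-surgeon operative-time z-score computed once over each
    surgeon's full record history (normalization is a dataset-level preprocessing
    step), then subset by month.  A month with fewer than two records is reported
    as empty rather than raising.
    """
    response = normalize_durations(ds)
    coefficients: dict[int, np.ndarray | None] = {}
    retained: dict[int, RetainedFeatureSet | None] = {}
    n_records: dict[int, int] = {}
    names = ds.schema.abbreviations
    for m in range(1, months + 1):
        sub = ds.subset(lambda r, m=m: r.month_index == m)
        n_records[m] = len(sub)
        if len(sub) < 2:
            coefficients[m] = None
            retained[m] = None
            continue
        path = fit_lasso_path(sub, grid_size=grid_size, response=response)
        beta = path.coefficients_at(lambda0, clip_above=True)
        coefficients[m] = beta
        entries = {
            name: float(b) for name, b in zip(names, beta) if abs(b) >= tau
        }
        retained[m] = RetainedFeatureSet(entries=entries, lambda0=lambda0, tau=tau)
    return LearningCurveTable(
        months=tuple(range(1, months + 1)),
        coefficients=coefficients,
        retained=retained,
        n_records=n_records,
        feature_names=names,
        lambda0=lambda0,
        tau=tau,
    )
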