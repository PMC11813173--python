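"""Age-conditional D-score references: LMS interpolation, DAZ and centiles.

The reference distribution at age *t* is a Box-Cox normal with median
``M_t`` (D units), coefficient-of-variation-like spread ``S_t`` and
Box-Cox skewness power ``L_t``. A measurement ``D`` converts to its
age-standardized normal equivalent deviate (the DAZ) by

    Z = ((D / M)^L - 1) / (L * S)          (|L| > 1e-4)
    Z = ln(D / M) / S                      (L ~ 0)

and the 100*alpha centile is the inverse map evaluated at the standard
normal quantile ``Z_alpha``. The packaged ``dutch_references`` fixture is
the normative table; :func:`fit_lms` is an explicitly simplified
re-estimation tool (binned Box-Cox-normal ML plus polynomial smoothing on
log-age), not a reimplementation of the penalized-spline fit behind the
shipped table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .data import load_fixture
from .errors import (
    ConfigurationError,
    DomainError,
    ExtrapolationWarning,
    InsufficientDataError,
)

_L_ZERO = 1e-4  # |L| below this uses the logarithmic branch


@dataclass
class ReferenceRow:
    age_years: float
    M: float
    S: float
    L: float


class ReferenceTable:
    """Ordered age-indexed L/M/S rows; ages strictly increasing, decimal years."""

    def __init__(self, df: pd.DataFrame):
        df = df[["age_years", "M", "S", "L"]].astype(float).reset_index(drop=True)
        if len(df) == 0:
            raise ConfigurationError("empty reference table")
        if not df["age_years"].is_monotonic_increasing or df["age_years"].duplicated().any():
            raise ConfigurationError("reference ages must be strictly increasing")
        if (df["S"] <= 0).any() or (df["M"] <= 0).any():
            raise ConfigurationError("reference M and S must be positive")
        self.df = df

    @classmethod
    def dutch(cls) -> "ReferenceTable":
        """The packaged Dutch D-score reference (2 weeks – 2.8 years)."""
        return cls(load_fixture("dutch_references"))

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    @property
    def age_min(self) -> float:
        return float(self.df["age_years"].iloc[0])

    @property
    def age_max(self) -> float:
        return float(self.df["age_years"].iloc[-1])

    def interpolate(self, age_years, clamp: bool = False):
        """Piecewise-linear (L, M, S) at ``age_years`` (scalar or array)."""
        age = np.asarray(age_years, dtype=float)
        out_of_range = (age < self.age_min) | (age > self.age_max)
        if np.any(out_of_range):
            if not clamp:
                raise DomainError(
                    f"age {np.atleast_1d(age)[np.atleast_1d(out_of_range)][0]:.4f} y outside "
                    f"reference range [{self.age_min:.4f}, {self.age_max:.4f}]"
                )
            warnings.warn(
                "age outside reference range; clamped to nearest knot",
                ExtrapolationWarning,
                stacklevel=2,
            )
            age = np.clip(age, self.age_min, self.age_max)
        x = self.df["age_years"].to_numpy()
        L = np.interp(age, x, self.df["L"].to_numpy())
        M = np.interp(age, x, self.df["M"].to_numpy())
        S = np.interp(age, x, self.df["S"].to_numpy())
        if np.isscalar(age_years):
            return float(L), float(M), float(S)
        return L, M, S


def interpolate_lms(age_years, table: ReferenceTable, clamp: bool = False):
    """(L, M, S) at ``age_years`` by linear interpolation on the table mesh."""
    return table.interpolate(age_years, clamp=clamp)


def _z_from_lms(d, L, M, S):
    d, L, M, S = np.broadcast_arrays(
        np.asarray(d, float), np.asarray(L, float), np.asarray(M, float), np.asarray(S, float)
    )
    use_power = np.abs(L) > _L_ZERO
    L_safe = np.where(use_power, L, 1.0)  # avoid 0/0 in the unused branch
    z = np.where(
        use_power,
        (np.power(d / M, L_safe) - 1.0) / (L_safe * S),
        np.log(d / M) / S,
    )
    return z


def daz(d, age_years, table: ReferenceTable, clamp: bool = False):
    """D-score-for-age Z-score."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise DomainError("D-score must be positive for the Box-Cox transform")
    L, M, S = table.interpolate(age_years, clamp=clamp)
    z = _z_from_lms(d_arr, L, M, S)
    return float(z) if np.isscalar(d) and np.isscalar(age_years) else z


def centile(alpha, age_years, table: ReferenceTable, clamp: bool = False):
    """The 100*alpha reference centile in D units (inverse of :func:`daz`)."""
    alpha_arr = np.asarray(alpha, dtype=float)
    if np.any((alpha_arr <= 0) | (alpha_arr >= 1)):
        raise DomainError("alpha must lie strictly between 0 and 1")
    z = stats.norm.ppf(alpha_arr)
    L, M, S = table.interpolate(age_years, clamp=clamp)
    L, M, S, z = np.broadcast_arrays(
        np.asarray(L, float), np.asarray(M, float), np.asarray(S, float), z
    )
    base = 1.0 + L * S * z
    if np.any((np.abs(L) > _L_ZERO) & (base <= 0)):
        raise DomainError("requested centile outside the Box-Cox support (1 + L*S*z <= 0)")
    out = np.where(
        np.abs(L) > _L_ZERO,
        M * np.power(np.where(base > 0, base, 1.0), 1.0 / np.where(np.abs(L) > _L_ZERO, L, 1.0)),
        M * np.exp(S * z),
    )
    return float(out) if np.isscalar(alpha) and np.isscalar(age_years) else out


def _fit_bccg_bin(y: np.ndarray) -> tuple[float, float, float]:
    """ML fit of the Box-Cox-normal (mu, sigma, nu) to one age bin."""
    y = np.asarray(y, dtype=float)
    mu0 = float(np.median(y))
    s0 = float(np.std(np.log(y))) or 0.05

    def nll(theta):
        mu, log_sigma, nu = theta
        sigma = np.exp(log_sigma)
        if mu <= 0:
            return 1e10
        r = y / mu
        if abs(nu) > _L_ZERO:
            z = (np.power(r, nu) - 1.0) / (nu * sigma)
        else:
            z = np.log(r) / sigma
        # log f(y) = (nu-1) log r - log(mu sigma) - z^2/2 + const
        return -float(np.sum((nu - 1.0) * np.log(r) - np.log(mu * sigma) - 0.5 * z**2))

    res = optimize.minimize(
        nll,
        x0=np.array([mu0, np.log(s0), 1.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    mu, log_sigma, nu = res.x
    return float(mu), float(np.exp(log_sigma)), float(nu)


def fit_lms(
    ages,
    d,
    df_M: int = 2,
    df_S: int = 2,
    df_L: int = 1,
    n_bins: int = 12,
    min_bin: int = 20,
    mesh: np.ndarray | None = None,
) -> ReferenceTable:
    """Fit a simplified LMS reference from (age, D) pairs.

    Ages are sliced into ``n_bins`` quantile bins (bins under ``min_bin``
    observations merge into their neighbour), each bin is fitted by
    Box-Cox-normal maximum likelihood, and the three parameter tracks are
    smoothed across log-age by count-weighted polynomials of degree
    ``df_M``/``df_S``/``df_L``. Requires >= 200 observations spanning
    >= 5 distinct age bins.
    """
    ages = np.asarray(ages, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(d) & (d > 0) & (ages > 0)
    ages, d = ages[ok], d[ok]
    if len(d) < 200:
        raise InsufficientDataError(f"need >= 200 observations, got {len(d)}")
    edges = np.unique(np.quantile(ages, np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < 5:
        raise InsufficientDataError("ages span fewer than 5 distinct bins")
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)

    # merge undersized bins to the left
    counts = np.bincount(idx, minlength=len(edges) - 1)
    if (counts < min_bin).any():
        warnings.warn("merging age bins with fewer than min_bin observations", stacklevel=2)
        labels = np.arange(len(counts))
        for b in range(len(counts)):
            if counts[b] < min_bin and b > 0:
                labels[labels == b] = labels[b - 1]
        idx = labels[idx]

    rows = []
    for b in np.unique(idx):
        sel = idx == b
        mu, sigma, nu = _fit_bccg_bin(d[sel])
        rows.append((float(np.median(ages[sel])), mu, sigma, nu, int(sel.sum())))
    binfit = pd.DataFrame(rows, columns=["age_years", "M", "S", "L", "n"])
    if len(binfit) < 5:
        raise InsufficientDataError("fewer than 5 usable age bins after merging")

    x = np.log(binfit["age_years"].to_numpy())
    w = binfit["n"].to_numpy().astype(float)
    coef_M = np.polyfit(x, binfit["M"], min(df_M, len(binfit) - 1), w=np.sqrt(w))
    coef_S = np.polyfit(x, binfit["S"], min(df_S, len(binfit) - 1), w=np.sqrt(w))
    coef_L = np.polyfit(x, binfit["L"], min(df_L, len(binfit) - 1), w=np.sqrt(w))

    if mesh is None:
        mesh = np.linspace(ages.min(), ages.max(), 60)
    mesh = np.asarray(mesh, dtype=float)
    lx = np.log(mesh)
    out = pd.DataFrame(
        {
            "age_years": mesh,
            "M": np.polyval(coef_M, lx),
            "S": np.maximum(np.polyval(coef_S, lx), 1e-4),
            "L": np.polyval(coef_L, lx),
        }
    )
    return ReferenceTable(out)


class LMSReferenceFitter(BaseEstimator):
    """sklearn-style wrapper around :func:`fit_lms`.

    ``fit(X)`` expects a DataFrame with ``age_years`` and ``d`` columns;
    the fitted reference is available as ``reference_table_``.
    """

    def __init__(self, df_M=2, df_S=2, df_L=1, n_bins=12, min_bin=20, mesh=None):
        self.df_M = df_M
        self.df_S = df_S
        self.df_L = df_L
        self.n_bins = n_bins
        self.min_bin = min_bin
        self.mesh = mesh

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.reference_table_ = fit_lms(
            X["age_years"],
            X["d"],
            df_M=self.df_M,
            df_S=self.df_S,
            df_L=self.df_L,
            n_bins=self.n_bins,
            min_bin=self.min_bin,
            mesh=self.mesh,
        )
        return self

    def transform(self, X):
        """DAZ for (age_years, d) rows under the fitted reference."""
        X = pd.DataFrame(X)
        return daz(
            X["d"].to_numpy(), X["age_years"].to_numpy(), self.reference_table_, clamp=True
        )
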