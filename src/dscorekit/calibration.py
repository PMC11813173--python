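"""Pairwise conditional (pseudo-likelihood) Rasch item calibration.

Item difficulties are estimated from discordant response pairs within a
measurement occasion: conditional on a child passing exactly one of two
co-administered items, the probability that the *easier* one is the passed
one depends only on the two difficulties, not on the child's ability. This
conditioning removes the ability distribution from the likelihood, so
perfect scores (all-PASS or all-FAIL occasions) need not be discarded —
they simply contribute no discordant pairs.

Convention: larger delta = harder item. The probability that the child
passes item i and fails item j, given a discordant pair, is
``exp(delta_j) / (exp(delta_i) + exp(delta_j))``.

Difficulties are identified up to a constant; the raw logit solution is
normalized to mean zero and then mapped to the D metric by an affine
transform that sends two designated anchor items exactly to their fixed
D values (20 and 40 D for the DDI anchors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .data import Item, ItemBank, ResponseSet
from .errors import ConnectivityWarning, DegenerateTransformError, InsufficientDataError


@dataclass
class PairwiseCounts:
    """Discordant-pair counts: ``n[i, j]`` = occasions passing item i and
    failing item j (both administered at the same occasion)."""

    items: list[str]
    n: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        assert self.n.shape == (len(self.items), len(self.items))
        assert np.all(np.diag(self.n) == 0)

    def n_components(self) -> int:
        adj = (self.n + self.n.T) > 0
        k, _ = connected_components(adj, directed=False)
        return k


@dataclass
class CalibrationResult:
    difficulties_logit: pd.Series
    converged: bool
    iterations: int
    transform: tuple[float, float] | None = None  # (intercept a, slope b), D = a + b*logit

    @property
    def difficulties_d(self) -> pd.Series | None:
        if self.transform is None:
            return None
        a, b = self.transform
        return (a + b * self.difficulties_logit).rename("delta_d")


def tabulate_pairs(responses: ResponseSet, pool_waves: bool = False) -> PairwiseCounts:
    """Count discordant item pairs within measurement occasions.

    With ``pool_waves=True`` all of a child's visits are pooled into a
    single pseudo-occasion (treats longitudinal repeats as one test).
    """
    df = responses.df
    if responses.L < 2:
        raise InsufficientDataError("need at least 2 distinct items to form pairs")
    index = ["child_id"] if pool_waves else ["child_id", "wave"]
    wide = df.pivot_table(index=index, columns="item", values="score", aggfunc="max")
    items = list(wide.columns)
    x = wide.to_numpy(dtype=float)
    p = (x == 1).astype(float)  # NaN compares False: unobserved cells drop out
    f = (x == 0).astype(float)
    n = p.T @ f
    np.fill_diagonal(n, 0.0)
    counts = PairwiseCounts(items, n)
    if counts.n_components() > 1:
        warnings.warn(
            f"discordant item-pair graph has {counts.n_components()} components; "
            "difficulties are only relatively identified within components",
            ConnectivityWarning,
            stacklevel=2,
        )
    return counts


def _neg_pseudo_loglik(delta: np.ndarray, n: np.ndarray) -> tuple[float, np.ndarray]:
    # sum over ordered pairs: n_ij * log(exp(d_j) / (exp(d_i)+exp(d_j)))
    d_i = delta[:, None]
    d_j = delta[None, :]
    logp = d_j - np.logaddexp(d_i, d_j)
    mask = (n + n.T) > 0
    np.fill_diagonal(mask, False)
    value = -float(np.sum(n[mask] * logp[mask]))
    tot = n + n.T
    eps = np.exp(delta)
    denom = np.where(tot > 0, tot / (eps[:, None] + eps[None, :]), 0.0).sum(axis=1)
    grad = eps * denom - n.sum(axis=0)
    return value, grad


def estimate_difficulties(
    counts: PairwiseCounts, tol: float = 1e-6, max_iter: int = 1000
) -> CalibrationResult:
    """Maximise the pairwise conditional pseudo-likelihood.

    Uses the classical fixed-point update on ``eps_i = exp(delta_i)``::

        eps_i <- sum_j n_ji / sum_j (n_ij + n_ji) / (eps_i + eps_j)

    (``n_ji`` counts failures of item i in discordant pairs, so items that
    are failed more often end up with larger difficulty) with geometric-mean
    normalization each sweep, falling back to quasi-Newton minimisation of
    the negative pseudo-log-likelihood if the iteration stalls.
    Pairs never observed discordant contribute nothing.
    """
    n = counts.n
    k = len(counts.items)
    if k < 2:
        raise InsufficientDataError("need at least 2 items")
    tot = n + n.T  # symmetric discordant totals
    fails = n.sum(axis=0)  # n_ji summed over j: discordant failures of i
    active = tot.sum(axis=1) > 0

    eps = np.ones(k)
    converged = False
    it = 0
    omega = 1.6  # log-scale over-relaxation of the linearly convergent map
    for it in range(1, max_iter + 1):
        denom_mat = np.where(tot > 0, tot / (eps[:, None] + eps[None, :]), 0.0)
        denom = denom_mat.sum(axis=1)
        new = np.where((denom > 0) & (fails > 0), fails / np.where(denom > 0, denom, 1.0), eps)
        # items with no discordant fails sit at the boundary; damp them to
        # a large-but-finite value relative to the rest
        new = np.clip(new, 1e-8, 1e8)
        logs = np.log(eps) + omega * (np.log(new) - np.log(eps))
        logs -= logs[active].mean() if active.any() else logs.mean()
        new = np.exp(logs)
        delta_change = np.max(np.abs(np.log(new) - np.log(eps))) / omega
        eps = new
        if delta_change < tol:
            converged = True
            break

    delta = np.log(eps)
    if not converged:
        res = optimize.minimize(
            _neg_pseudo_loglik,
            delta,
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-8},
        )
        delta = res.x - res.x.mean()
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                "pairwise calibration did not converge; returning last iterate",
                stacklevel=2,
            )
    delta = delta - delta[active].mean() if active.any() else delta - delta.mean()
    return CalibrationResult(
        difficulties_logit=pd.Series(delta, index=counts.items, name="delta_logit"),
        converged=converged,
        iterations=it,
    )


def anchor(
    difficulties_logit: pd.Series, anchors: dict[str, float] | list[tuple[str, float]]
) -> tuple[pd.Series, tuple[float, float]]:
    """Affinely rescale logit difficulties so two anchor items take fixed
    D values. Returns the D-metric difficulties and the transform (a, b)
    with ``D = a + b * logit``."""
    pairs = list(anchors.items()) if isinstance(anchors, dict) else list(anchors)
    if len(pairs) != 2:
        raise ValueError("exactly two anchor items are required")
    (c1, v1), (c2, v2) = pairs
    for c in (c1, c2):
        if c not in difficulties_logit.index or pd.isna(difficulties_logit[c]):
            raise KeyError(f"anchor item {c!r} has no calibrated logit difficulty")
    l1, l2 = float(difficulties_logit[c1]), float(difficulties_logit[c2])
    if l1 == l2:
        raise DegenerateTransformError(
            f"anchor items {c1!r}, {c2!r} have identical logit difficulty {l1}"
        )
    b = (v2 - v1) / (l2 - l1)
    a = v1 - b * l1
    if b <= 0:
        warnings.warn(
            "anchoring slope b <= 0: calibrated ordering of the anchor items "
            "contradicts their target D values",
            stacklevel=2,
        )
    return (a + b * difficulties_logit).rename("delta_d"), (a, b)


class RaschCalibrator(BaseEstimator):
    """Pairwise-likelihood Rasch calibration as an sklearn-style estimator.

    Parameters
    ----------
    anchors : dict[str, float] | None
        Two ``{item_code: D value}`` pairs fixing the D metric, e.g.
        ``{"ddigmd057": 20, "ddigmd063": 40}``. If None, only logit
        difficulties are produced.
    tol, max_iter : convergence control for the fixed-point iteration.
    pool_waves : bool
        Pool a child's visits into one pseudo-occasion when pairing.

    Attributes (after :meth:`fit`)
    ------------------------------
    difficulties_logit_ : pd.Series, mean-zero logit difficulties.
    difficulties_d_ : pd.Series | None, anchored D-metric difficulties.
    transform_ : (a, b) | None with ``D = a + b * logit``.
    counts_ : PairwiseCounts; converged_ : bool; n_iter_ : int.
    """

    def __init__(self, anchors=None, tol=1e-6, max_iter=1000, pool_waves=False):
        self.anchors = anchors
        self.tol = tol
        self.max_iter = max_iter
        self.pool_waves = pool_waves

    def fit(self, X, y=None):
        responses = X if isinstance(X, ResponseSet) else ResponseSet(pd.DataFrame(X))
        self.counts_ = tabulate_pairs(responses, pool_waves=self.pool_waves)
        result = estimate_difficulties(self.counts_, tol=self.tol, max_iter=self.max_iter)
        self.difficulties_logit_ = result.difficulties_logit
        self.converged_ = result.converged
        self.n_iter_ = result.iterations
        if self.anchors is not None:
            self.difficulties_d_, self.transform_ = anchor(
                self.difficulties_logit_, self.anchors
            )
        else:
            self.difficulties_d_ = None
            self.transform_ = None
        return self

    def to_itembank(self, codebook: ItemBank | None = None) -> ItemBank:
        """Export calibrated difficulties as an :class:`ItemBank`, merging
        metadata from ``codebook`` when given."""
        items = []
        for code in self.difficulties_logit_.index:
            base = codebook[code] if codebook is not None and code in codebook else Item(code)
            items.append(
                Item(
                    code=code,
                    domain=base.domain,
                    label=base.label,
                    debut_age=base.debut_age,
                    difficulty_logit=float(self.difficulties_logit_[code]),
                    difficulty_d=(
                        float(self.difficulties_d_[code])
                        if self.difficulties_d_ is not None
                        else None
                    ),
                )
            )
        return ItemBank(items, anchor_spec=self.anchors)


def calibrate(responses: ResponseSet, anchors=None, **kwargs) -> RaschCalibrator:
    """Functional wrapper: fit a :class:`RaschCalibrator` on ``responses``."""
    return RaschCalibrator(anchors=anchors, **kwargs).fit(responses)
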