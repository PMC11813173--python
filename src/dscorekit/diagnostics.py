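"""Model-evaluation suite: residual fit statistics, DIF, information,
reliability.

All diagnostics start from the standardized residual of an observed 0/1
response against its fitted Rasch probability,

    z_ni = (x_ni - P_ni) / sqrt(W_ni),   W_ni = P_ni (1 - P_ni),

and aggregate it per item (infit = sum of squared raw residuals over sum
of variances; outfit = mean squared standardized residual) or per
measurement occasion. Both statistics have expectation 1 under the model;
values above 1 signal underfit (noise), below 1 overfit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import ItemBank, ResponseSet
from .errors import InsufficientDataError
from .references import ReferenceTable
from .scoring import DScorer, response_probability

ITEM_UNDERFIT_THRESHOLD = 1.3
PERSON_FIT_THRESHOLD = 3.0


def residuals(
    responses: ResponseSet, abilities: pd.DataFrame, itembank: ItemBank
) -> pd.DataFrame:
    """Per-response residual table over observed cells only.

    ``abilities`` must have one row per measurement occasion with columns
    ``child_id, wave, d`` (the output of :meth:`DScorer.transform` works).
    """
    df = responses.df[["child_id", "wave", "item", "score"]].copy()
    ab = abilities[["child_id", "wave", "d"]]
    merged = df.merge(ab, on=["child_id", "wave"], how="left", validate="many_to_one")
    if merged["d"].isna().any():
        miss = merged.loc[merged["d"].isna(), ["child_id", "wave"]].iloc[0]
        raise KeyError(
            f"no ability for occasion (child {miss['child_id']!r}, wave {miss['wave']!r})"
        )
    delta = itembank.difficulties_d()
    merged["delta"] = merged["item"].map(delta)
    if merged["delta"].isna().any():
        code = merged.loc[merged["delta"].isna(), "item"].iloc[0]
        raise KeyError(f"item {code!r} has no anchored difficulty")
    merged["P"] = response_probability(merged["d"].to_numpy(), merged["delta"].to_numpy())
    merged["W"] = merged["P"] * (1.0 - merged["P"])
    merged["z"] = (merged["score"] - merged["P"]) / np.sqrt(merged["W"])
    return merged.rename(columns={"score": "x"})[
        ["child_id", "wave", "item", "x", "d", "delta", "P", "W", "z"]
    ]


def item_fit(resid: pd.DataFrame, threshold: float = ITEM_UNDERFIT_THRESHOLD) -> pd.DataFrame:
    """Per-item infit and outfit with the underfit flag."""
    g = resid.assign(sq=(resid["x"] - resid["P"]) ** 2, zsq=resid["z"] ** 2).groupby("item")
    out = pd.DataFrame(
        {
            "n": g.size(),
            "infit": g["sq"].sum() / g["W"].sum(),
            "outfit": g["zsq"].mean(),
        }
    )
    out["underfit"] = (out["infit"] > threshold) | (out["outfit"] > threshold)
    return out


def person_fit(resid: pd.DataFrame, threshold: float = PERSON_FIT_THRESHOLD) -> pd.DataFrame:
    """Per-occasion infit and outfit; flagged above the customary 3.0."""
    g = resid.assign(sq=(resid["x"] - resid["P"]) ** 2, zsq=resid["z"] ** 2).groupby(
        ["child_id", "wave"]
    )
    out = pd.DataFrame(
        {
            "n": g.size(),
            "infit": g["sq"].sum() / g["W"].sum(),
            "outfit": g["zsq"].mean(),
        }
    )
    out["flag"] = (out["infit"] > threshold) | (out["outfit"] > threshold)
    return out


def item_information(beta, delta):
    """Fisher information I = P (1 - P); maximal 0.25 at beta = delta."""
    p = response_probability(beta, delta)
    return p * (1.0 - p)


def information_by_age(
    delta_d: float,
    reference: ReferenceTable,
    ages_years: np.ndarray,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Item information along the reference median path M(age).

    Returns per-age information plus an ``in_window`` flag marking ages
    where the item yields at least ``threshold`` information for the
    median child.
    """
    ages_years = np.asarray(ages_years, dtype=float)
    _, m, _ = reference.interpolate(ages_years, clamp=True)
    info = item_information(np.asarray(m, dtype=float), delta_d)
    return pd.DataFrame(
        {"age_years": ages_years, "median_d": m, "information": info, "in_window": info >= threshold}
    )


@dataclass
class DifReport:
    uniform_effect: float  # group main effect, logits
    uniform_p: float  # LR test p-value for the group main effect
    nonuniform_effect: float  # ability x group interaction slope
    nonuniform_p: float  # LR test p-value for the interaction
    n: int
    separation: bool = False


def dif_test(x, ability, group) -> DifReport:
    """Logistic-regression DIF test for one item.

    Fits three nested logistic models of the response on (1) ability,
    (2) ability + group, (3) ability + group + ability:group. Uniform DIF
    is the likelihood-ratio test of model 2 vs 1 (effect size = the group
    coefficient in logits); non-uniform DIF is model 3 vs 2.
    """
    x = np.asarray(x, dtype=float)
    ability = np.asarray(ability, dtype=float)
    group = np.asarray(group)
    codes = pd.Categorical(group).codes.astype(float)
    if len(np.unique(codes)) != 2:
        raise InsufficientDataError("DIF test needs exactly two groups")
    for g in (0, 1):
        sel = codes == g
        if sel.sum() < 30 or len(np.unique(x[sel])) < 2:
            raise InsufficientDataError(
                "each group needs >= 30 observations with response variation"
            )
    a = (ability - ability.mean()) / ability.std()  # scaling aids convergence

    def _fit(cols):
        X = sm.add_constant(np.column_stack(cols))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(x, X)
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception:  # noqa: BLE001 - perfect separation and kin
                return None
        return res

    m1 = _fit([a])
    m2 = _fit([a, codes])
    m3 = _fit([a, codes, a * codes])
    separation = any(
        r is None or not np.all(np.isfinite(r.params)) or np.any(np.abs(r.params) > 30)
        for r in (m1, m2, m3)
    )
    if m1 is None or m2 is None or m3 is None:
        warnings.warn("separation detected; DIF effect unbounded", stacklevel=2)
        return DifReport(np.inf, np.nan, np.inf, np.nan, len(x), separation=True)
    lr_u = 2.0 * (m2.llf - m1.llf)
    lr_n = 2.0 * (m3.llf - m2.llf)
    report = DifReport(
        uniform_effect=float(m2.params[2]),
        uniform_p=float(stats.chi2.sf(max(lr_u, 0.0), df=1)),
        nonuniform_effect=float(m3.params[3]),
        nonuniform_p=float(stats.chi2.sf(max(lr_n, 0.0), df=1)),
        n=len(x),
        separation=separation,
    )
    if separation:
        warnings.warn("separation detected; DIF effect unbounded", stacklevel=2)
    return report


def dif_scan(
    responses: ResponseSet,
    abilities: pd.DataFrame,
    group_col: str,
    alpha: float = 0.05,
    fdr: bool = False,
    min_per_group: int = 30,
) -> pd.DataFrame:
    """Run :func:`dif_test` for every eligible item in a response set.

    ``group_col`` names a column of ``responses.df``. With ``fdr=True``
    p-values are Benjamini-Hochberg adjusted across items.
    """
    df = responses.df.merge(
        abilities[["child_id", "wave", "d"]], on=["child_id", "wave"], how="inner"
    )
    rows = []
    for item, sub in df.groupby("item"):
        try:
            rep = dif_test(sub["score"], sub["d"], sub[group_col])
        except InsufficientDataError:
            continue
        rows.append(
            {
                "item": item,
                "uniform_effect": rep.uniform_effect,
                "uniform_p": rep.uniform_p,
                "nonuniform_effect": rep.nonuniform_effect,
                "nonuniform_p": rep.nonuniform_p,
                "n": rep.n,
                "separation": rep.separation,
            }
        )
    out = pd.DataFrame(rows).set_index("item") if rows else pd.DataFrame()
    if fdr and len(out):
        out["uniform_p_adj"] = _bh(out["uniform_p"].to_numpy())
        out["nonuniform_p_adj"] = _bh(out["nonuniform_p"].to_numpy())
        out["uniform_dif"] = out["uniform_p_adj"] < alpha
    elif len(out):
        out["uniform_dif"] = out["uniform_p"] < alpha
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class ReliabilityReport:
    var_ability: float
    var_error: float
    sem: float
    R: float


def reliability_from_variances(var_ability: float, var_error: float) -> ReliabilityReport:
    """R = (var_ability - var_error) / var_ability."""
    R = (var_ability - var_error) / var_ability
    return ReliabilityReport(var_ability, var_error, float(np.sqrt(var_error)), float(R))


def reliability(
    itembank: ItemBank,
    responses: ResponseSet,
    reference: ReferenceTable | None,
    seed: int,
    replicates: int = 1,
    scorer: DScorer | None = None,
) -> ReliabilityReport:
    """Simulation-based reliability of the D-score on a given design.

    Scores the observed data, then generates ``replicates`` hypothetical
    datasets from the fitted abilities/difficulties preserving the exact
    missing-data pattern, re-scores each, and estimates the error variance
    as the variance of (re-estimated - modelled) ability. Reported in the
    metric of the supplied difficulties/abilities (D units here).
    """
    rng = np.random.default_rng(seed)
    if scorer is None:
        scorer = DScorer(itembank=itembank, reference=reference).fit()
    scored = scorer.transform(responses)
    var_ability = float(np.var(scored["d"].to_numpy(), ddof=1))

    df = responses.df.copy()
    occ_d = scored.set_index(["child_id", "wave"])["d"]
    beta = df.set_index(["child_id", "wave"]).index.map(occ_d).to_numpy(dtype=float)
    delta = df["item"].map(itembank.difficulties_d()).to_numpy(dtype=float)
    p = response_probability(beta, delta)

    err_vars = []
    for _ in range(replicates):
        sim = df.copy()
        sim["score"] = (rng.random(len(p)) < p).astype(int)
        rescored = scorer.transform(ResponseSet(sim))
        diff = rescored["d"].to_numpy() - scored["d"].to_numpy()
        err_vars.append(float(np.var(diff, ddof=1)))
    var_error = float(np.mean(err_vars))
    return reliability_from_variances(var_ability, var_error)
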