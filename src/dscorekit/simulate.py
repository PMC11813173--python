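"""Synthetic longitudinal milestone cohorts with known truth.

The default design emulates the structure of the Dutch SMOCC-style
surveillance study: ~2000 children seen at nine scheduled visits between
1 and 24 months, each visit administering an age-targeted *standard* set
of easy milestones (~90% pass at the scheduled age) plus an *additional*
set borrowed from the next visit (~50% pass). Child ability follows the
reference median curve plus a child-level random intercept; responses are
Bernoulli draws from the logistic Rasch model. Everything is reproducible
from a single seed, and the generating abilities/difficulties are returned
as truth tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    AgeCorrectionSpec,
    Item,
    ItemBank,
    ResponseSet,
    days_to_years,
    ddi_itembank,
    months_to_days,
)
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .references import ReferenceTable

#: scheduled SMOCC-style visit ages (months) and standard-set sizes
WAVE_MONTHS = (1, 2, 3, 6, 9, 12, 15, 18, 24)


@dataclass
class Wave:
    label: str
    age_months: float
    jitter_sd_days: float = 7.0  # truncated at +/- 3 sd


@dataclass
class CohortDesign:
    """Visit schedule and per-wave item sets."""

    n_children: int
    waves: Sequence[Wave]
    item_assignment: Mapping[str, tuple[Sequence[str], Sequence[str]]]
    dropout: Mapping[str, float] | None = None  # per-wave retention probability

    def __post_init__(self):
        ages = [w.age_months for w in self.waves]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ConfigurationError("wave ages must be strictly increasing")

    @classmethod
    def smocc_like(cls, itembank: ItemBank | None = None, n_children: int = 2000) -> "CohortDesign":
        """The default nine-visit design.

        The standard set at each visit consists of the milestones whose
        debut age equals the visit age; the additional set is the next
        visit's standard set (none after the last scheduled visit, where
        the 30-month debut items serve as the additional set when
        available).
        """
        bank = itembank if itembank is not None else ddi_itembank()
        by_debut: dict[float, list[str]] = {}
        for code in bank.codes:
            debut = bank[code].debut_age
            if debut is not None:
                by_debut.setdefault(float(debut), []).append(code)
        schedule = [float(m) for m in WAVE_MONTHS]
        assignment = {}
        waves = []
        for k, m in enumerate(schedule):
            label = f"{int(m)}m"
            standard = by_debut.get(m, [])
            nxt = schedule[k + 1] if k + 1 < len(schedule) else 30.0
            additional = by_debut.get(nxt, [])
            assignment[label] = (standard, additional)
            waves.append(Wave(label=label, age_months=m))
        return cls(n_children=n_children, waves=waves, item_assignment=assignment)


@dataclass
class GrowthModel:
    """Latent development model: ability = median_curve(age) + b_n + e_nt.

    ``median_curve`` maps age in days to D units (default: the packaged
    Dutch reference median). For preterm children (fraction drawn with the
    given gestational-age distribution) the curve is evaluated at the
    fully corrected age, i.e. their development follows corrected age by
    construction.
    """

    median_curve: Callable | None = None
    between_child_sd: float = 3.0
    within_visit_noise_sd: float = 0.0
    preterm_fraction: float = 0.0
    ga_mean_days: float = 210.0
    ga_sd_days: float = 14.0
    term_ga_days: int = 280

    def curve(self) -> Callable:
        if self.median_curve is not None:
            return self.median_curve
        ref = ReferenceTable.dutch()

        def c(age_days):
            _, m, _ = ref.interpolate(days_to_years(np.asarray(age_days, float)), clamp=True)
            return np.asarray(m, dtype=float)

        return c


def simulate_responses(beta, delta, rng) -> np.ndarray:
    """Bernoulli PASS/FAIL draws from the logistic Rasch model."""
    p = expit(np.asarray(beta, float) - np.asarray(delta, float))
    return (rng.random(p.shape) < p).astype(int)


def simulate_cohort(
    design: CohortDesign,
    growth: GrowthModel,
    itembank: ItemBank,
    seed: int,
) -> tuple[ResponseSet, dict[str, pd.DataFrame]]:
    """Generate a longitudinal cohort; returns (responses, truth tables).

    Truth tables: ``abilities`` (one row per realized occasion with the
    true ability and its components), ``items`` (generating difficulties),
    ``children`` (random intercepts, gestational ages).
    """
    rng = np.random.default_rng(seed)
    delta = itembank.difficulties_d()
    for label, (std, add) in design.item_assignment.items():
        for code in list(std) + list(add):
            if code not in itembank or pd.isna(delta.get(code, np.nan)):
                raise ConfigurationError(
                    f"item {code!r} in wave {label!r} missing from bank or uncalibrated"
                )
    curve = growth.curve()

    n = design.n_children
    child_ids = np.array([f"c{idx:05d}" for idx in range(n)])
    b = rng.normal(0.0, growth.between_child_sd, size=n)
    preterm = rng.random(n) < growth.preterm_fraction
    ga = np.full(n, float(growth.term_ga_days))
    if preterm.any():
        ga[preterm] = np.clip(
            rng.normal(growth.ga_mean_days, growth.ga_sd_days, size=preterm.sum()), 140, 279
        )

    resp_frames = []
    truth_frames = []
    for w in design.waves:
        retain_p = 1.0 if design.dropout is None else float(design.dropout.get(w.label, 1.0))
        retained = rng.random(n) < retain_p
        jitter = np.clip(
            rng.normal(0.0, w.jitter_sd_days, size=n),
            -3 * w.jitter_sd_days,
            3 * w.jitter_sd_days,
        )
        age = np.maximum(np.round(months_to_days(w.age_months) + jitter), 1.0)
        # development follows fully corrected age for preterms
        dev_age = age - (growth.term_ga_days - ga)
        e = (
            rng.normal(0.0, growth.within_visit_noise_sd, size=n)
            if growth.within_visit_noise_sd > 0
            else np.zeros(n)
        )
        beta = curve(np.maximum(dev_age, 1.0)) + b + e
        std, add = design.item_assignment[w.label]
        items = list(std) + list(add)
        if not items:
            continue
        d_items = delta[items].to_numpy(dtype=float)
        x = simulate_responses(beta[:, None], d_items[None, :], rng)
        keep = np.nonzero(retained)[0]
        k = len(items)
        resp_frames.append(
            pd.DataFrame(
                {
                    "child_id": np.repeat(child_ids[keep], k),
                    "wave": w.label,
                    "age_days": np.repeat(age[keep], k),
                    "item": np.tile(np.array(items, dtype=object), len(keep)),
                    "score": x[keep].ravel(),
                    "ga_days": np.repeat(ga[keep], k),
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "child_id": child_ids[keep],
                    "wave": w.label,
                    "age_days": age[keep],
                    "beta": beta[keep],
                    "b": b[keep],
                    "e": e[keep],
                    "ga_days": ga[keep],
                }
            )
        )

    resp = pd.concat(resp_frames, ignore_index=True)
    truth = {
        "abilities": pd.concat(truth_frames, ignore_index=True),
        "items": delta.rename("delta_d").reset_index().rename(columns={"index": "item"}),
        "children": pd.DataFrame(
            {"child_id": child_ids, "b": b, "ga_days": ga, "preterm": preterm}
        ),
    }
    return ResponseSet(resp), truth


def synthetic_itembank(
    reference: ReferenceTable | None = None, codebook: ItemBank | None = None
) -> ItemBank:
    """DDI-shaped item bank with synthetic D difficulties.

    Difficulties are placed so that the study design's intent holds under
    the growth model: an item debuting at visit k sits at the median
    ability of visit k-1 (it passes ~50% when administered there as an
    additional item, and is easy at its own visit); first-visit items sit
    ln(9) below the 1-month median (~90% pass for the median child). These
    are synthetic stand-ins: the realized difficulties of the underlying
    instrument are not public.
    """
    ref = reference if reference is not None else ReferenceTable.dutch()
    bank = codebook if codebook is not None else ddi_itembank()
    schedule = [float(m) for m in WAVE_MONTHS] + [30.0]

    def median_at(months):
        _, m, _ = ref.interpolate(days_to_years(months_to_days(months)), clamp=True)
        return float(m)

    items = []
    for code in bank.codes:
        it = bank[code]
        debut = float(it.debut_age)
        k = schedule.index(debut) if debut in schedule else None
        if k is None:
            raise ConfigurationError(f"item {code!r} debut {debut} not on the visit schedule")
        if k == 0:
            d = median_at(debut) - np.log(9.0)
        else:
            d = median_at(schedule[k - 1])
        items.append(
            Item(
                code=code,
                domain=it.domain,
                label=it.label,
                debut_age=debut,
                difficulty_d=round(d, 2),
            )
        )
    return ItemBank(items, anchor_spec=bank.anchor_spec)


def corrected_age(postnatal_days, ga_days, spec: AgeCorrectionSpec) -> float:
    """corrected = postnatal - f * (term GA - GA), all in days.

    May be negative at very early postnatal ages; callers decide handling
    (downstream prior lookups clamp to the reference floor).
    """
    if not 140 <= ga_days <= 320:
        raise DomainError(f"gestational age {ga_days} d outside plausible range [140, 320]")
    if postnatal_days < 0:
        raise DomainError("postnatal age must be nonnegative")
    corrected = float(postnatal_days) - spec.f * (spec.term_ga_days - float(ga_days))
    if corrected < 0:
        warnings.warn("corrected age is negative; passing through unclamped", stacklevel=2)
    return corrected


def age_equivalent(attainment_ages, stage: str | None = None) -> float:
    """Mean first-attainment age for a milestone, at 1 decimal.

    ``attainment_ages`` is a Series/array of per-child first-attainment
    ages (or a DataFrame with ``stage`` naming the column); missing entries
    are excluded, never imputed.
    """
    if isinstance(attainment_ages, pd.DataFrame):
        if stage is None or stage not in attainment_ages.columns:
            raise KeyError(f"stage {stage!r} not found")
        values = attainment_ages[stage]
    else:
        values = pd.Series(attainment_ages)
    values = pd.to_numeric(values, errors="coerce").dropna()
    if len(values) == 0:
        raise InsufficientDataError(f"no non-missing attainment ages for stage {stage!r}")
    return round(float(values.mean()), 1)


def empirical_pass_curve(
    responses: ResponseSet, item: str, bins: np.ndarray | int = 10
) -> tuple[pd.DataFrame, float | None]:
    """Per-age-bin pass proportion and the linearly interpolated 50%-pass age.

    The 50% crossing (the classical probability-based difficulty of a
    milestone) is located between the first pair of adjacent bins whose
    proportions straddle 0.5; None (flagged undefined) when the curve
    never crosses.
    """
    df = responses.df[responses.df["item"] == item]
    if len(df) == 0:
        raise InsufficientDataError(f"item {item!r} not observed")
    ages = df["age_days"].to_numpy(dtype=float)
    if np.isscalar(bins):
        edges = np.unique(np.quantile(ages, np.linspace(0, 1, int(bins) + 1)))
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        rows.append(
            (float(np.mean(ages[sel])), float(df["score"].to_numpy()[sel].mean()), int(sel.sum()))
        )
    curve = pd.DataFrame(rows, columns=["age_days", "pass_rate", "n"]).sort_values("age_days")
    if len(curve) < 2:
        raise InsufficientDataError(f"item {item!r} observed in fewer than 2 age bins")
    age50 = None
    a = curve["age_days"].to_numpy()
    p = curve["pass_rate"].to_numpy()
    for i in range(len(p) - 1):
        lo, hi = p[i], p[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            age50 = float(a[i] + (0.5 - lo) / (hi - lo) * (a[i + 1] - a[i]))
            break
        if lo == 0.5:
            age50 = float(a[i])
            break
    return curve, age50
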