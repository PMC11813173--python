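"""Domain types, file readers/writers and packaged fixtures.

The canonical internal age unit is days (integer). Helpers convert to the
two units used in reporting: months (``age_days / 30.4375``) and decimal
years (``age_days / 365.25``). Milestone response data are kept in long
(tidy) format: one row per observed PASS/FAIL, missing observations are
absent rows and are never coerced to 0.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, FixtureLookupError, ParseError

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: canonical response columns
RESPONSE_COLUMNS = ["child_id", "wave", "age_days", "item", "score"]


def days_to_months(age_days):
    return np.asarray(age_days, dtype=float) / DAYS_PER_MONTH


def months_to_days(age_months):
    return np.asarray(age_months, dtype=float) * DAYS_PER_MONTH


def days_to_years(age_days):
    return np.asarray(age_days, dtype=float) / DAYS_PER_YEAR


def years_to_days(age_years):
    return np.asarray(age_years, dtype=float) * DAYS_PER_YEAR


@dataclass
class Item:
    """A single milestone.

    ``difficulty_logit`` (logits) and ``difficulty_d`` (D units) stay None
    until the item is calibrated/anchored; when both are present they are
    related by the bank-wide affine anchoring transform.
    """

    code: str
    domain: str = ""
    label: str = ""
    debut_age: float | None = None  # months
    difficulty_logit: float | None = None
    difficulty_d: float | None = None


@dataclass
class AgeCorrectionSpec:
    """Preterm age-correction: corrected = postnatal − f·(term − GA)."""

    f: float = 1.0
    term_ga_days: int = 280

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise DomainError(f"correction factor f={self.f} outside [0, 1]")


class ItemBank:
    """Ordered collection of :class:`Item` with optional anchor specification."""

    def __init__(self, items: Iterable[Item], anchor_spec: Mapping[str, float] | None = None):
        self.items: dict[str, Item] = {}
        for it in items:
            if it.code in self.items:
                raise ParseError(f"duplicate item code {it.code!r} in item bank")
            self.items[it.code] = it
        self.anchor_spec = dict(anchor_spec) if anchor_spec else None
        if self.anchor_spec:
            missing = [c for c in self.anchor_spec if c not in self.items]
            if missing:
                raise ConfigurationError(f"anchor codes not in bank: {missing}")

    def __len__(self):
        return len(self.items)

    def __contains__(self, code):
        return code in self.items

    def __getitem__(self, code) -> Item:
        return self.items[code]

    @property
    def codes(self) -> list[str]:
        return list(self.items)

    def difficulties_d(self) -> pd.Series:
        return pd.Series(
            {c: it.difficulty_d for c, it in self.items.items()}, name="delta_d", dtype=float
        )

    def difficulties_logit(self) -> pd.Series:
        return pd.Series(
            {c: it.difficulty_logit for c, it in self.items.items()},
            name="delta_logit",
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.codes,
                "domain": [it.domain for it in self.items.values()],
                "debut": [it.debut_age for it in self.items.values()],
                "label": [it.label for it in self.items.values()],
                "delta_logit": [it.difficulty_logit for it in self.items.values()],
                "delta_d": [it.difficulty_d for it in self.items.values()],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, anchor_spec=None) -> "ItemBank":
        items = []
        for _, r in df.iterrows():
            items.append(
                Item(
                    code=str(r["item"]),
                    domain=str(r.get("domain", "") or ""),
                    label=str(r.get("label", "") or ""),
                    debut_age=None if pd.isna(r.get("debut", np.nan)) else float(r["debut"]),
                    difficulty_logit=(
                        None if pd.isna(r.get("delta_logit", np.nan)) else float(r["delta_logit"])
                    ),
                    difficulty_d=(
                        None if pd.isna(r.get("delta_d", np.nan)) else float(r["delta_d"])
                    ),
                )
            )
        return cls(items, anchor_spec)

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class ResponseSet:
    """Long-format PASS/FAIL observations.

    Columns: ``child_id, wave, age_days, item, score``. A measurement
    *occasion* is one (child, wave) visit (falling back to (child, age)
    when no wave labels exist).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESPONSE_COLUMNS))

    def __post_init__(self):
        df = self.df.copy()
        for col in RESPONSE_COLUMNS:
            if col not in df.columns:
                if col == "wave":
                    df["wave"] = ""
                else:
                    raise ParseError(f"response table missing required column {col!r}")
        df = df[RESPONSE_COLUMNS + [c for c in df.columns if c not in RESPONSE_COLUMNS]]
        df = df.dropna(subset=["score"])
        if len(df):
            bad = df[~df["score"].isin([0, 1, 0.0, 1.0, "0", "1"])]
            if len(bad):
                i = bad.index[0]
                raise ParseError(
                    f"non-binary score {bad.loc[i, 'score']!r} at row {i} "
                    f"(child {bad.loc[i, 'child_id']!r}, item {bad.loc[i, 'item']!r})"
                )
            df["score"] = df["score"].astype(int)
            df["age_days"] = df["age_days"].astype(float)
            if (df["age_days"] < 0).any():
                i = df.index[df["age_days"] < 0][0]
                raise ParseError(f"negative age_days at row {i}")
            dup = df.duplicated(subset=["child_id", "wave", "item"])
            if dup.any():
                i = df.index[dup][0]
                raise ParseError(
                    f"duplicate response for (child {df.loc[i, 'child_id']!r}, "
                    f"wave {df.loc[i, 'wave']!r}, item {df.loc[i, 'item']!r}) at row {i}"
                )
        df = df.reset_index(drop=True)
        self.df = df

    @property
    def N(self) -> int:
        """Number of stored responses."""
        return len(self.df)

    @property
    def L(self) -> int:
        """Number of distinct items."""
        return self.df["item"].nunique()

    def occasion_keys(self) -> pd.DataFrame:
        """Distinct measurement occasions with their ages."""
        return (
            self.df.groupby(["child_id", "wave"], sort=False)["age_days"]
            .first()
            .reset_index()
        )

    def wide(self) -> pd.DataFrame:
        """Derived occasion × item matrix view (NaN where unobserved)."""
        return self.df.pivot_table(
            index=["child_id", "wave"], columns="item", values="score", aggfunc="first"
        )

    def write_csv(self, path):
        self.df[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_responses(path, dialect: Mapping[str, str] | None = None) -> ResponseSet:
    """Read a long-format response file (CSV or TSV by extension).

    ``dialect`` maps canonical names to file column names, e.g.
    ``{"child_id": "id", "age": "agedays", "age_unit": "days"}``.
    Recognised ``age_unit`` values: days (default), months, years.
    Empty score cells are dropped (a blank is *not* a FAIL).
    """
    dialect = dict(dialect or {})
    age_unit = dialect.pop("age_unit", "days")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - wrap with file context
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    colmap = {}
    for canon, aliases in {
        "child_id": ["child_id", "id", "child", "subjid"],
        "wave": ["wave", "visit", "occasion"],
        "age": ["age_days", "age", "agedays"],
        "item": ["item", "item_code", "lex"],
        "score": ["score", "value", "response"],
    }.items():
        name = dialect.get(canon)
        if name is None:
            name = next((a for a in aliases if a in raw.columns), None)
        if name is None and canon != "wave":
            raise ParseError(f"cannot resolve a column for {canon!r} in {path}")
        if name is not None and name not in raw.columns:
            raise ParseError(f"configured column {name!r} for {canon!r} not in {path}")
        colmap[canon] = name

    df = pd.DataFrame({"child_id": raw[colmap["child_id"]].astype(str)})
    df["wave"] = raw[colmap["wave"]].astype(str) if colmap["wave"] else ""
    age = pd.to_numeric(raw[colmap["age"]], errors="coerce")
    if age_unit == "days":
        pass
    elif age_unit == "months":
        age = months_to_days(age)
    elif age_unit == "years":
        age = years_to_days(age)
    else:
        raise ConfigurationError(f"unknown age unit {age_unit!r}")
    df["age_days"] = age
    df["item"] = raw[colmap["item"]].astype(str)
    df["score"] = pd.to_numeric(raw[colmap["score"]], errors="coerce")
    # blanks that were never scores stay NaN and are dropped by ResponseSet;
    # non-numeric garbage must be reported, not silently dropped
    raw_scores = raw[colmap["score"]]
    garbage = raw_scores.notna() & df["score"].isna()
    if garbage.any():
        i = df.index[garbage][0]
        raise ParseError(f"unreadable score {raw_scores[i]!r} at row {i} of {path}")
    return ResponseSet(df)


SCORE_COLUMNS = ["child_id", "wave", "age_days", "d", "sem", "daz"]


def write_scores(records, path) -> None:
    """Write per-occasion D-score records to CSV.

    D is serialized at 2 decimals, DAZ at 3; a missing DAZ becomes an
    empty field, never the text "NaN".
    """
    df = pd.DataFrame(records)
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in ("daz", "sem") else ""
    out = df[SCORE_COLUMNS + [c for c in df.columns if c not in SCORE_COLUMNS]].copy()
    out["d"] = out["d"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out["sem"] = out["sem"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out["daz"] = out["daz"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)


_FIXTURES = {
    "shirley_motor": ("shirley_motor.csv", ","),
    "ddi_codebook": ("ddi_codebook.tsv", "\t"),
    "anchors": ("anchors.csv", ","),
    "worked_example": ("worked_example.csv", ","),
    "dutch_references": ("dutch_references.csv", ","),
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged tables.

    Available: ``shirley_motor`` (first-attainment ages in weeks for 21
    babies), ``ddi_codebook`` (the 57 DDI milestones with debut ages),
    ``anchors`` (the two D-metric anchor milestones at 20 and 40 D),
    ``worked_example`` (five 15-month milestones with difficulties and two
    children's responses), ``dutch_references`` (age-conditional L/M/S
    reference values for the D-score).
    """
    try:
        fname, sep = _FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    with _resources.files("dscorekit.fixtures").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep=sep)


def ddi_itembank() -> ItemBank:
    """The 57-milestone DDI inventory (uncalibrated), with the anchor spec."""
    cb = load_fixture("ddi_codebook")
    anchors = load_fixture("anchors")
    bank = ItemBank.from_frame(cb, anchor_spec=dict(zip(anchors["item"], anchors["value"])))
    return bank
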