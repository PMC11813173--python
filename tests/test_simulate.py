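"""Cohort simulator: design realization, response law, corrected age,
age equivalents and empirical pass curves."""

import warnings

import numpy as np
import pandas as pd
import pytest

import dscorekit as dk
from dscorekit.data import DAYS_PER_MONTH, days_to_months
from dscorekit.errors import ConfigurationError, DomainError, InsufficientDataError


@pytest.fixture(scope="module")
def design(synthetic_bank):
    return dk.CohortDesign.smocc_like(synthetic_bank, n_children=300)


class TestDesign:
    def test_wave_item_counts_match_schedule(self, design):
        standard = {lab: len(std) for lab, (std, _) in design.item_assignment.items()}
        assert standard == {
            "1m": 5, "2m": 2, "3m": 5, "6m": 6, "9m": 7,
            "12m": 6, "15m": 6, "18m": 6, "24m": 7,
        }
        # additional set is the next wave's standard set
        labels = list(design.item_assignment)
        for cur, nxt in zip(labels, labels[1:]):
            assert design.item_assignment[cur][1] == design.item_assignment[nxt][0]

    def test_nonincreasing_wave_ages_rejected(self):
        with pytest.raises(ConfigurationError):
            dk.CohortDesign(
                n_children=10,
                waves=[dk.Wave("a", 3.0), dk.Wave("b", 2.0)],
                item_assignment={"a": ([], []), "b": ([], [])},
            )

    def test_unknown_item_rejected(self, synthetic_bank):
        design = dk.CohortDesign(
            n_children=5,
            waves=[dk.Wave("w", 6.0)],
            item_assignment={"w": (["nonexistent"], [])},
        )
        with pytest.raises(ConfigurationError, match="nonexistent"):
            dk.simulate_cohort(design, dk.GrowthModel(), synthetic_bank, seed=1)


class TestSimulateCohort:
    def test_same_seed_identical(self, design, synthetic_bank):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, ta = dk.simulate_cohort(design, dk.GrowthModel(), synthetic_bank, seed=42)
            b, tb = dk.simulate_cohort(design, dk.GrowthModel(), synthetic_bank, seed=42)
            c, _ = dk.simulate_cohort(design, dk.GrowthModel(), synthetic_bank, seed=43)
        pd.testing.assert_frame_equal(a.df, b.df)
        pd.testing.assert_frame_equal(ta["abilities"], tb["abilities"])
        assert not a.df.equals(c.df)

    def test_median_placed_item_passes_half(self, synthetic_bank, dutch_reference):
        # an item at the median ability of its wave passes ~50%
        growth = dk.GrowthModel()
        curve = growth.curve()
        age = 12 * DAYS_PER_MONTH
        bank = dk.ItemBank([dk.Item(code="probe", difficulty_d=float(curve(age)))])
        design = dk.CohortDesign(
            n_children=2000,
            waves=[dk.Wave("12m", 12.0, jitter_sd_days=0.0)],
            item_assignment={"12m": (["probe"], [])},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs, _ = dk.simulate_cohort(design, growth, bank, seed=13)
        rate = rs.df["score"].mean()
        # oracle: E[logistic(X)] with X ~ N(0, sd^2), by quadrature
        from scipy.special import expit
        from numpy.polynomial.hermite_e import hermegauss

        nodes, wts = hermegauss(81)
        expect = float(np.sum(wts * expit(nodes * growth.between_child_sd)) / np.sum(wts))
        se = np.sqrt(expect * (1 - expect) / 2000)
        assert rate == pytest.approx(expect, abs=3 * se)
        assert abs(rate - 0.5) < 0.05

    def test_standard_item_at_tenth_percentile_passes_ninety(self, dutch_reference):
        # the screening design intent: standard items sit at the 10th
        # ability percentile, so ~90% of children pass
        growth = dk.GrowthModel()
        curve = growth.curve()
        age = 12 * DAYS_PER_MONTH
        delta = float(curve(age)) - 1.2816 * growth.between_child_sd
        bank = dk.ItemBank([dk.Item(code="std", difficulty_d=delta)])
        design = dk.CohortDesign(
            n_children=2000,
            waves=[dk.Wave("12m", 12.0, jitter_sd_days=0.0)],
            item_assignment={"12m": (["std"], [])},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs, _ = dk.simulate_cohort(design, growth, bank, seed=14)
        rate = rs.df["score"].mean()
        from scipy.special import expit
        from numpy.polynomial.hermite_e import hermegauss

        nodes, wts = hermegauss(81)
        expect = float(
            np.sum(wts * expit(nodes * growth.between_child_sd + 1.2816 * growth.between_child_sd))
            / np.sum(wts)
        )
        se = np.sqrt(expect * (1 - expect) / 2000)
        assert rate == pytest.approx(expect, abs=3 * se)
        assert rate > 0.85

    def test_pass_rates_nondecreasing_with_age(self, small_cohort, synthetic_bank):
        responses, _ = small_cohort
        # per item administered at >= 2 waves, the empirical pass rate rises
        df = responses.df
        rates = df.groupby(["item", "wave"])["score"].agg(["mean", "count"])
        wave_order = {f"{m}m": i for i, m in enumerate((1, 2, 3, 6, 9, 12, 15, 18, 24))}
        violations = 0
        checked = 0
        for item, sub in rates.groupby(level="item"):
            sub = sub[sub["count"] >= 50]
            ordered = sub.reset_index().sort_values(by="wave", key=lambda s: s.map(wave_order))
            if len(ordered) >= 2:
                checked += 1
                if np.any(np.diff(ordered["mean"]) < -0.05):
                    violations += 1
        assert checked > 20
        assert violations == 0

    def test_dropout_reduces_rows(self, design, synthetic_bank):
        lossy = dk.CohortDesign(
            n_children=300,
            waves=design.waves,
            item_assignment=design.item_assignment,
            dropout={"24m": 0.5},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full, _ = dk.simulate_cohort(design, dk.GrowthModel(), synthetic_bank, seed=3)
            drop, _ = dk.simulate_cohort(lossy, dk.GrowthModel(), synthetic_bank, seed=3)
        n_full = (full.df["wave"] == "24m").sum()
        n_drop = (drop.df["wave"] == "24m").sum()
        assert 0.3 * n_full < n_drop < 0.7 * n_full

    def test_preterm_daz_centred_after_full_correction(self, synthetic_bank, dutch_reference):
        growth = dk.GrowthModel(preterm_fraction=1.0)
        design = dk.CohortDesign.smocc_like(synthetic_bank, n_children=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs, truth = dk.simulate_cohort(design, growth, synthetic_bank, seed=19)
            scorer = dk.DScorer(
                itembank=synthetic_bank,
                reference=dutch_reference,
                age_correction=dk.AgeCorrectionSpec(f=1.0),
            ).fit()
            scored = scorer.transform(rs)
            from dscorekit.data import days_to_years

            ok = scored["d"].to_numpy() > 0  # Box-Cox needs positive D
            z = dk.daz(
                scored["d"].to_numpy()[ok],
                days_to_years(np.maximum(scored["age_used_days"].to_numpy()[ok], 14.0)),
                dutch_reference,
                clamp=True,
            )
        # development follows corrected age by construction, so corrected-age
        # DAZ is centred near zero (between-child sd ~ 1 DAZ unit)
        assert abs(np.nanmean(z)) < 0.25


class TestCorrectedAge:
    def test_full_correction_ten_weeks(self):
        assert dk.corrected_age(100, 210, dk.AgeCorrectionSpec(f=1.0)) == 30.0

    def test_half_correction_five_weeks(self):
        assert dk.corrected_age(100, 210, dk.AgeCorrectionSpec(f=0.5)) == 65.0

    def test_no_correction(self):
        assert dk.corrected_age(100, 210, dk.AgeCorrectionSpec(f=0.0)) == 100.0

    def test_negative_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            out = dk.corrected_age(10, 210, dk.AgeCorrectionSpec(f=1.0))
        assert out == -60.0

    def test_out_of_range_ga(self):
        with pytest.raises(DomainError):
            dk.corrected_age(100, 100, dk.AgeCorrectionSpec())
        with pytest.raises(ValueError):
            dk.AgeCorrectionSpec(f=1.5)


class TestAgeEquivalent:
    def test_walking_stage_means(self):
        sh = dk.load_fixture("shirley_motor")
        assert dk.age_equivalent(sh, "stepping") == 16.1
        assert dk.age_equivalent(sh, "standing") == 27.2
        assert dk.age_equivalent(sh, "walking_with_help") == 43.3
        assert dk.age_equivalent(sh, "walking_alone") == 63.3

    def test_single_child(self):
        assert dk.age_equivalent([10.0]) == 10.0

    def test_all_missing_rejected(self):
        with pytest.raises(InsufficientDataError):
            dk.age_equivalent([np.nan, np.nan], stage="s")


class TestEmpiricalPassCurve:
    def test_all_pass_has_undefined_crossing(self):
        df = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(40)],
                "wave": "w",
                "age_days": np.linspace(100, 700, 40),
                "item": "easy",
                "score": 1,
            }
        )
        curve, age50 = dk.empirical_pass_curve(dk.ResponseSet(df), "easy", bins=4)
        assert age50 is None
        assert (curve["pass_rate"] == 1.0).all()

    def test_crossing_recovers_median_placed_difficulty(self, synthetic_bank, dutch_reference):
        growth = dk.GrowthModel()
        curve_fn = growth.curve()
        target_age = 9 * DAYS_PER_MONTH
        bank = dk.ItemBank([dk.Item(code="probe", difficulty_d=float(curve_fn(target_age)))])
        waves = [dk.Wave(f"w{m}", float(m)) for m in (3, 6, 9, 12, 15)]
        design = dk.CohortDesign(
            n_children=2000,
            waves=waves,
            item_assignment={w.label: (["probe"], []) for w in waves},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs, _ = dk.simulate_cohort(design, growth, bank, seed=29)
        _, age50 = dk.empirical_pass_curve(rs, "probe", bins=10)
        assert age50 is not None
        assert abs(days_to_months(age50) - 9.0) < 1.0

    def test_unobserved_item_rejected(self, small_cohort):
        responses, _ = small_cohort
        with pytest.raises(InsufficientDataError):
            dk.empirical_pass_curve(responses, "nope")


def test_end_to_end_recovery(dutch_reference):
    """simulate -> calibrate -> anchor -> score closes the loop.

    1000 children seen at four visits answer the same 20 milestones whose
    difficulties track the reference median curve; the longitudinal design
    supplies the wide ability variation the instrument is built for.
    """
    k = 20
    delta_d = np.linspace(35.0, 57.0, k)
    bank = dk.ItemBank(
        [dk.Item(code=f"i{j:02d}", difficulty_d=float(delta_d[j])) for j in range(k)]
    )
    waves = [dk.Wave(f"{m}m", float(m)) for m in (6, 9, 12, 15)]
    design = dk.CohortDesign(
        n_children=1000,
        waves=waves,
        item_assignment={w.label: ([f"i{j:02d}" for j in range(k)], []) for w in waves},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rs, truth = dk.simulate_cohort(design, dk.GrowthModel(), bank, seed=101)
        cal = dk.RaschCalibrator(anchors={"i00": 35.0, "i19": 57.0}).fit(rs)
    logit_est = cal.difficulties_logit_[[f"i{j:02d}" for j in range(k)]].to_numpy()
    centred = delta_d - delta_d.mean()  # generating metric is D-as-logit
    assert np.sqrt(np.mean((logit_est - centred) ** 2)) < 0.15
    assert cal.difficulties_d_["i00"] == pytest.approx(35.0)
    assert cal.difficulties_d_["i19"] == pytest.approx(57.0)

    scored = (
        dk.DScorer(itembank=cal.to_itembank(), reference=dutch_reference)
        .fit()
        .transform(rs)
    )
    merged = scored.merge(truth["abilities"], on=["child_id", "wave"])
    assert np.corrcoef(merged["d"], merged["beta"])[0, 1] > 0.95
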