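"""Component probabilities, product-rule synthesis and jackknife."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demosae.ages import SEGMENT_LABELS
from demosae.birth_history import (
    ChildRecord,
    WomanRecord,
    records_to_frames,
    tabulate_mortality,
)
from demosae.mortality import (
    MortalitySegmentEstimate,
    component_probabilities,
    floor_variance,
    jackknife_variance,
    rates_from_tabulation,
    synthesize_rates,
)

INTERVIEW = 1446


def _tab(deaths, cohorts):
    return pd.DataFrame(
        {
            "segment": list(SEGMENT_LABELS),
            "deaths": np.asarray(deaths, dtype=float),
            "cohort": np.asarray(cohorts, dtype=float),
        }
    )


def _segments(qs):
    return [
        MortalitySegmentEstimate(lbl, q, q * 1000, 1000.0)
        for lbl, q in zip(SEGMENT_LABELS, qs)
    ]


class TestComponentProbabilities:
    def test_simple_quotient(self):
        segs = component_probabilities(
            _tab([30, 0, 0, 0, 0, 0, 0, 0], [1000] * 8)
        )
        assert segs[0].q == pytest.approx(0.03)
        assert all(s.q == 0 for s in segs[1:])

    def test_empty_cohort_flagged_zero(self):
        segs = component_probabilities(_tab([0] * 8, [0] * 8))
        assert all(s.q == 0 and s.empty for s in segs)

    def test_deaths_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            component_probabilities(_tab([10] + [0] * 7, [5] + [100] * 7))

    def test_matches_survival_enumeration_on_toy_cohort(self):
        # 50 children, fully observed 60 months, deaths at known ages:
        # q_j must match the per-child Kaplan-Meier-style enumeration
        rng = np.random.default_rng(4)
        death_months = rng.choice(
            [-1, 0, 1, 4, 8, 15, 30, 40, 50], size=50,
            p=[0.5, 0.1, 0.06, 0.06, 0.07, 0.07, 0.05, 0.05, 0.04],
        )
        records = []
        for i, dm in enumerate(death_months):
            dead = dm >= 0
            child = ChildRecord(
                child_birth_cmc=INTERVIEW - 60,
                is_dead=dead,
                age_at_death_days=int(dm) * 30 + 1 if dead else None,
                age_at_death_months=int(dm) if dead else None,
            )
            records.append(
                WomanRecord(f"w{i}", "D1", "P1", 1.0, INTERVIEW,
                            INTERVIEW - 300, [child])
            )
        w, c = records_to_frames(records)
        segs = component_probabilities(
            tabulate_mortality(w, c).drop(columns="district_id")
        )
        bounds = [(0, 1), (1, 3), (3, 6), (6, 12), (12, 24), (24, 36),
                  (36, 48), (48, 60)]
        for s, (lo, hi) in zip(segs, bounds):
            at_risk = ((death_months < 0) | (death_months >= lo)).sum()
            died = ((death_months >= lo) & (death_months < hi)).sum()
            assert s.q == pytest.approx(died / at_risk)


class TestSynthesizeRates:
    def test_product_rule_example(self):
        r = synthesize_rates(
            _segments([0.03, 0.01, 0.005, 0.005, 0, 0, 0, 0])
        )
        assert r.nmr == pytest.approx(30.0)
        assert r.imr == pytest.approx(
            1000 * (1 - 0.97 * 0.99 * 0.995 * 0.995)
        )
        assert round(r.imr, 2) == 49.28
        assert r.u5mr == pytest.approx(r.imr)

    def test_zero_hazard_zero_rates(self):
        r = synthesize_rates(_segments([0.0] * 8))
        assert r.nmr == r.imr == r.u5mr == 0.0

    def test_certain_neonatal_death_saturates(self):
        r = synthesize_rates(_segments([1.0, 0, 0, 0, 0, 0, 0, 0]))
        assert r.nmr == r.imr == r.u5mr == 1000.0

    def test_out_of_range_probability_rejected(self):
        segs = _segments([0.0] * 8)
        segs[0].q = 1.5
        with pytest.raises(ValueError):
            synthesize_rates(segs)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=8, max_size=8)
    )
    @settings(max_examples=200, deadline=None)
    def test_rates_always_nested(self, qs):
        r = synthesize_rates(_segments(qs))
        assert 0 <= r.nmr <= r.imr <= r.u5mr <= 1000 + 1e-9


class TestJackknife:
    @staticmethod
    def _binomial_frames(rng, G=200, p=0.2):
        records = []
        for g in range(G):
            dead = rng.random() < p
            child = ChildRecord(
                child_birth_cmc=INTERVIEW - 30,
                is_dead=bool(dead),
                age_at_death_days=40 if dead else None,
                age_at_death_months=1 if dead else None,
            )
            records.append(
                WomanRecord(f"w{g}", "D1", f"P{g}", 1.0, INTERVIEW,
                            INTERVIEW - 300, [child])
            )
        return records_to_frames(records)

    def test_constant_estimator_has_zero_variance(self, small_dataset):
        _, women, children, _ = small_dataset
        d = women["district_id"].iloc[0]
        w = women[women["district_id"] == d]
        c = children[children["district_id"] == d]
        assert jackknife_variance(w, c, lambda *_: 1.23) == pytest.approx(0.0)

    def test_single_psu_flagged_missing(self):
        w = pd.DataFrame({"psu_id": ["P1"] * 5, "weight": 1.0})
        assert np.isnan(jackknife_variance(w, pd.DataFrame(), lambda *_: 0.0))

    def test_binomial_toy_matches_closed_form(self):
        # one child per PSU: the delete-one jackknife of a proportion
        # should average to p(1-p)/G over replications
        rng = np.random.default_rng(11)
        G, p, reps = 200, 0.2, 200
        variances = []
        for _ in range(reps):
            w, c = self._binomial_frames(rng, G, p)
            est = lambda women, children: children["is_dead"].mean()
            variances.append(jackknife_variance(w, c, est))
        mean_var = np.mean(variances)
        assert mean_var == pytest.approx(p * (1 - p) / G, rel=0.25)

    def test_weight_scaling_leaves_rate_variance_unchanged(self, small_dataset):
        _, women, children, _ = small_dataset
        d = women["district_id"].iloc[0]
        w = women[women["district_id"] == d]
        c = children[children["district_id"] == d]

        def u5mr(ww, cc):
            return rates_from_tabulation(tabulate_mortality(ww, cc)).iloc[0]["u5mr"]

        v1 = jackknife_variance(w, c, u5mr)
        v2 = jackknife_variance(
            w.assign(weight=w["weight"] * 2),
            c.assign(weight=c["weight"] * 2),
            u5mr,
        )
        assert v2 == pytest.approx(v1, rel=1e-10)


class TestClosedCohortIdentity:
    def test_uncensored_imr_equals_death_share(self):
        rng = np.random.default_rng(8)
        records = []
        deaths_under_12 = 0
        n = 400
        for i in range(n):
            dm = int(rng.integers(0, 70))
            dead = dm < 60 and rng.random() < 0.15
            if dead and dm < 12:
                deaths_under_12 += 1
            child = ChildRecord(
                child_birth_cmc=INTERVIEW - 60,
                is_dead=dead,
                age_at_death_days=dm * 30 + 1 if dead else None,
                age_at_death_months=dm if dead else None,
            )
            records.append(
                WomanRecord(f"w{i}", "D1", "P1", 1.0, INTERVIEW,
                            INTERVIEW - 300, [child])
            )
        w, c = records_to_frames(records)
        r = rates_from_tabulation(tabulate_mortality(w, c)).iloc[0]
        assert r["imr"] == pytest.approx(1000 * deaths_under_12 / n)


def test_variance_floor_positive_for_zero_deaths():
    v = floor_variance(0.0, 500)
    assert v == pytest.approx((0.5 / 500) * (1 - 0.5 / 500) / 500)
    with pytest.raises(ValueError):
        floor_variance(10.0, 0)
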