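"""TTB computation, Kaplan-Meier, log-rank, and baseline chi-squared."""

import math

import numpy as np
import pytest

from conftest import make_cohort, make_patient
from dnarna.io_model import Cohort, RnaAlterationCall
from dnarna.survival_ttb import (
    baseline_chi2,
    compute_ttb,
    km_estimate,
    logrank_test,
    stratum_labels,
    ttb_by_pdl1_test,
    ttb_survival_analysis,
)
from dnarna.synthetic import SimulationConfig, generate_cohort


class TestTtb:
    def test_labels(self):
        assert stratum_labels([2, 5]) == ["0-2", "3-5", ">=6"]
        with pytest.raises(ValueError):
            stratum_labels([5, 2])

    @pytest.mark.parametrize(
        "ttb,stratum",
        [(0, "0-2"), (2, "0-2"), (3, "3-5"), (5, "3-5"), (6, ">=6"), (9, ">=6")],
    )
    def test_stratum_boundaries(self, ttb, stratum):
        cohort = make_cohort(dna={}, rna={"P1": [f"G{i}" for i in range(ttb)]}, patients=["P1"])
        (rec,) = compute_ttb(cohort)
        assert rec.ttb == ttb
        assert rec.stratum == stratum

    def test_zero_rna_calls_gets_zero(self):
        cohort = make_cohort(dna={"P1": ["TP53"]}, rna={}, patients=["P1"])
        (rec,) = compute_ttb(cohort)
        assert rec.ttb == 0

    def test_sum_equals_distinct_rna_records(self):
        cohort = generate_cohort(SimulationConfig(seed=9, n_patients=60))
        records = compute_ttb(cohort)
        assert sum(r.ttb for r in records) == len(
            {(c.patient_id, c.gene) for c in cohort.rna_calls}
        )


class TestKm:
    def test_uncensored_closed_form(self):
        curve = km_estimate([1, 2, 3, 4], [True] * 4)
        assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert curve.at_risk.tolist() == [4, 3, 2, 1]

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([1, 2, 3], [False] * 3)
        assert curve.event_times.size == 0
        assert math.isnan(curve.median)

    def test_matches_manual_product_limit_table(self):
        times = [1, 2, 2, 3, 4, 4, 5, 6, 7, 8]
        events = [True, True, False, True, False, True, True, False, True, False]
        curve = km_estimate(times, events)
        # hand computation: risk sets after deaths-before-censorings tie rule
        # t=1: 10 at risk, 1 death -> 9/10
        # t=2: 9 at risk, 1 death (1 censored after) -> 9/10 * 8/9 = 0.8
        # t=3: 7 at risk, 1 death -> 0.8 * 6/7
        # t=4: 6 at risk, 1 death -> * 5/6
        # t=5: 4 at risk, 1 death -> * 3/4
        # t=7: 2 at risk, 1 death -> * 1/2
        expected = [0.9, 0.8, 0.8 * 6 / 7, 0.8 * 6 / 7 * 5 / 6,
                    0.8 * 6 / 7 * 5 / 6 * 3 / 4, 0.8 * 6 / 7 * 5 / 6 * 3 / 4 * 1 / 2]
        assert curve.survival == pytest.approx(expected)
        assert curve.at_risk.tolist() == [10, 9, 7, 6, 4, 2]

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, size=50)
        curve = km_estimate(times, [True] * 50)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3, 4, 5], [True, True, False, True, True])
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [True, True]), ([], [])])

    def test_hand_computed_two_group_example(self):
        """n=6, no censoring: statistic equals the O-E / hypergeometric-V sums."""
        g1 = ([1.0, 3.0, 5.0], [True, True, True])
        g2 = ([2.0, 4.0, 6.0], [True, True, True])
        # risk tables at event times 1..6 (deaths all distinct):
        # t: n1, n2, d in group1?
        # 1: 3,3 d1  E1 += 3/6;  V += (3*3*1*5)/(6^2*5)=9/36... use closed form below
        o_minus_e = 0.0
        v = 0.0
        n1, n2 = 3, 3
        for t, grp in [(1, 1), (2, 2), (3, 1), (4, 2), (5, 1), (6, 2)]:
            n = n1 + n2
            e1 = n1 / n
            o1 = 1.0 if grp == 1 else 0.0
            o_minus_e += o1 - e1
            v += n1 * n2 / n**2  # d=1, no ties: V = n1*n2*d*(n-d)/(n^2*(n-1))
            if grp == 1:
                n1 -= 1
            else:
                n2 -= 1
        expected = o_minus_e**2 / v
        res = logrank_test([g1, g2])
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_permutation_calibration(self):
        """Under random relabeling the log-rank p is approximately uniform."""
        rng = np.random.default_rng(7)
        times = rng.exponential(10, size=60)
        events = rng.random(60) < 0.8
        pvals = []
        for _ in range(200):
            labels = rng.permutation(np.repeat([0, 1, 2], 20))
            groups = [
                (times[labels == k], events[labels == k]) for k in range(3)
            ]
            pvals.append(logrank_test(groups).p_value)
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSurvivalAnalysis:
    def test_restricted_to_treated(self):
        cohort = generate_cohort(SimulationConfig(seed=12))
        res = ttb_survival_analysis(cohort, treated_only=True)
        n_treated = sum(p.treated for p in cohort.patients)
        assert sum(c.n for c in res["curves"].values()) == n_treated
        assert res["logrank"] is not None

    def test_pdl1_exact_small_sample(self):
        patients = [
            make_patient(f"N{i}", pdl1_status="negative") for i in range(3)
        ] + [make_patient(f"P{i}", pdl1_status="positive") for i in range(3)]
        rna = []
        for i, t in enumerate([4, 5, 6]):
            rna += [RnaAlterationCall(f"N{i}", f"G{j}", "over") for j in range(t)]
        for i, t in enumerate([1, 2, 3]):
            rna += [RnaAlterationCall(f"P{i}", f"G{j}", "over") for j in range(t)]
        cohort = Cohort(patients=patients, dna_calls=[], rna_calls=rna)
        res = ttb_by_pdl1_test(cohort, compute_ttb(cohort))
        assert res.p_value == pytest.approx(0.1)

    def test_pdl1_unknown_excluded(self):
        patients = [
            make_patient("A", pdl1_status="negative"),
            make_patient("B", pdl1_status="positive"),
            make_patient("C", pdl1_status="unknown"),
        ]
        cohort = Cohort(patients=patients, dna_calls=[], rna_calls=[])
        res = ttb_by_pdl1_test(cohort, compute_ttb(cohort))
        assert res.n1 == 1 and res.n2 == 1

    def test_pdl1_power_under_planted_shift(self):
        """TTB shifted +2 in negatives, n=60/60: p<0.05 in >=90% of seeds."""
        rejections = 0
        n_seeds = 200
        from dnarna.concordance import mann_whitney_two_sided

        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            neg = rng.poisson(4, size=60)
            pos = rng.poisson(2, size=60)
            if mann_whitney_two_sided(list(neg), list(pos)).p_value < 0.05:
                rejections += 1
        assert rejections >= 0.9 * n_seeds


class TestBaselineChi2:
    # 2x2 cohort-comparison rows: patients with both assays vs DNA only
    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ([[126, 127], [80, 105]], 0.207),   # age >= 60
            ([[122, 131], [90, 95]], 1.0),      # male/female
            ([[128, 125], [86, 99]], 0.452),    # >3 prior therapies
            ([[30, 223], [27, 158]], 0.486),    # ECOG 0 vs 1
            ([[86, 167], [49, 136]], 0.115),    # >2 metastatic sites
            ([[27, 226], [26, 159]], 0.356),    # low albumin
            ([[127, 108], [71, 69]], 0.605),    # high LDH (known subset)
        ],
    )
    def test_yates_reproduces_published_style_pvalues(self, table, expected_p):
        _, p = baseline_chi2(table, yates=True)
        assert p == pytest.approx(expected_p, abs=5e-4)

    def test_yates_floor_keeps_sex_row_at_one(self):
        # without the floored correction this near-balanced row has p < 1
        _, p_uncorr = baseline_chi2([[122, 131], [90, 95]], yates=False)
        assert p_uncorr < 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            baseline_chi2([[0, 0], [5, 3]])
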