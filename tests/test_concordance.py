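"""Concordant-event detection and event-level statistics."""

import numpy as np
import pytest
from scipy import stats

from conftest import concordant_events_bruteforce, make_cohort, make_patient
from dnarna.concordance import (
    ConcordantEvent,
    cn_expression_correlation,
    detect_concordant_events,
    event_class_breakdown,
    events_from_distribution,
    mann_whitney_two_sided,
    purity_concordance_test,
)
from dnarna.io_model import Cohort, DnaAlterationCall, RnaAlterationCall
from dnarna.synthetic import SimulationConfig, generate_cohort


def _event(gene="KRAS", classes=("copy_number_gain",), cn=None, score=None, pid="P1"):
    return ConcordantEvent(
        patient_id=pid,
        gene=gene,
        dna_classes=frozenset(classes),
        rna_direction="over",
        copy_number=cn,
        expression_score=score,
    )


class TestDetect:
    def test_same_gene_only(self):
        cohort = make_cohort(
            dna={"P1": ["TP53", "KRAS"]},
            rna={"P1": ["KRAS", "VEGFA"]},
        )
        summary = detect_concordant_events(cohort)
        assert [(e.patient_id, e.gene) for e in summary.events] == [("P1", "KRAS")]

    def test_disjoint_gene_sets_yield_nothing(self):
        cohort = make_cohort(dna={"P1": ["TP53"]}, rna={"P1": ["VEGFA"]})
        assert detect_concordant_events(cohort).events == []

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_bruteforce_oracle(self, seed):
        cohort = generate_cohort(SimulationConfig(seed=seed, n_patients=60))
        summary = detect_concordant_events(cohort)
        got = {(e.patient_id, e.gene) for e in summary.events}
        assert got == concordant_events_bruteforce(cohort)

    def test_per_patient_counts_bounded_by_assay_gene_counts(self):
        cohort = generate_cohort(SimulationConfig(seed=5, n_patients=80))
        summary = detect_concordant_events(cohort)
        dna_by = cohort.dna_genes_by_patient()
        rna_by = cohort.rna_genes_by_patient()
        for pid, n in summary.per_patient_event_counts.items():
            assert n <= min(len(dna_by[pid]), len(rna_by[pid]))

    def test_histogram_self_consistency(self):
        cohort = generate_cohort(SimulationConfig(seed=3, n_patients=100))
        summary = detect_concordant_events(cohort)
        hist = {}
        for n in summary.per_patient_event_counts.values():
            hist[n] = hist.get(n, 0) + 1
        n_patients, n_events = events_from_distribution(hist)
        assert n_patients == len(summary.per_patient_event_counts)
        assert n_events == len(summary.events)


class TestEventsFromDistribution:
    @pytest.mark.parametrize(
        "dist,expected",
        [({1: 44, 2: 4, 3: 2}, (50, 58)), ({}, (0, 0)), ({2: 3}, (3, 6))],
    )
    def test_totals(self, dist, expected):
        assert events_from_distribution(dist) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            events_from_distribution({-1: 2})
        with pytest.raises(ValueError):
            events_from_distribution({1: -2})


class TestClassBreakdown:
    def test_percentages(self):
        events = [
            _event(pid="P1", classes=("copy_number_gain",)),
            _event(pid="P2", classes=("copy_number_loss",)),
            _event(pid="P3", classes=("missense_snv",)),
            _event(pid="P4", classes=("fusion_or_rearrangement",)),
        ]
        from dnarna.concordance import ConcordanceSummary

        bd = event_class_breakdown(ConcordanceSummary(events=events))
        assert bd["copy_number_gain"]["count"] == 1
        assert sum(v["count"] for v in bd.values()) == 4
        assert sum(v["percent"] for v in bd.values()) == pytest.approx(100.0)

    def test_copy_number_takes_priority_over_point_mutations(self):
        ev = _event(classes=("missense_snv", "copy_number_gain"))
        assert ev.primary_class() == "copy_number_gain"

    def test_counts_match_recount(self):
        cohort = generate_cohort(SimulationConfig(seed=7))
        summary = detect_concordant_events(cohort)
        bd = event_class_breakdown(summary)
        recount = {}
        for ev in summary.events:
            recount[ev.primary_class()] = recount.get(ev.primary_class(), 0) + 1
        assert {k: v["count"] for k, v in bd.items()} == recount


class TestCnExpressionCorrelation:
    def _summary(self, pairs):
        from dnarna.concordance import ConcordanceSummary

        events = [
            _event(pid=f"P{i}", cn=c, score=s) for i, (c, s) in enumerate(pairs)
        ]
        return ConcordanceSummary(events=events)

    def test_perfect_monotone(self):
        res = cn_expression_correlation(self._summary([(1, 10), (2, 20), (3, 30)]))
        assert res.statistic == pytest.approx(1.0)

    def test_reversed(self):
        res = cn_expression_correlation(self._summary([(1, 30), (2, 20), (3, 10)]))
        assert res.statistic == pytest.approx(-1.0)

    def test_insufficient_data_flagged_not_raised(self):
        res = cn_expression_correlation(self._summary([(1, 10), (2, 20)]))
        assert not res.ok
        assert "insufficient" in res.reason

    def test_matches_manual_midrank_computation(self):
        rng = np.random.default_rng(42)
        cn = rng.integers(0, 8, size=20).astype(float)  # ties guaranteed
        score = cn + rng.normal(0, 2, size=20)
        res = cn_expression_correlation(self._summary(list(zip(cn, score))))

        def midranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            sx = np.asarray(x)[order]
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        r1, r2 = midranks(cn), midranks(score)
        rho = np.corrcoef(r1, r2)[0, 1]
        assert res.statistic == pytest.approx(rho, abs=1e-12)


class TestPurityTest:
    def _cohort_with_purities(self, event_purities, none_purities):
        patients = []
        dna, rna = [], []
        for i, pu in enumerate(event_purities):
            pid = f"E{i}"
            patients.append(make_patient(pid, tumor_purity=pu))
            dna.append(DnaAlterationCall(pid, "KRAS", "missense_snv"))
            rna.append(RnaAlterationCall(pid, "KRAS", "over"))
        for i, pu in enumerate(none_purities):
            patients.append(make_patient(f"N{i}", tumor_purity=pu))
        return Cohort(patients=patients, dna_calls=dna, rna_calls=rna)

    def test_exact_small_sample_p(self):
        """Fully separated purities, 3 vs 3: exact two-sided p = 2/C(6,3)*... = 0.1."""
        cohort = self._cohort_with_purities([0.7, 0.8, 0.9], [0.1, 0.2, 0.3])
        summary = detect_concordant_events(cohort)
        res = purity_concordance_test(cohort, summary)
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == pytest.approx(9.0)  # U of the event group

    def test_identical_distributions_give_p_one(self):
        res = mann_whitney_two_sided(
            [0.2, 0.4, 0.6, 0.8] * 5, [0.2, 0.4, 0.6, 0.8] * 5
        )
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_missing_purity_excluded(self):
        cohort = self._cohort_with_purities([0.7, 0.8, 0.9], [0.1, 0.2, None])
        summary = detect_concordant_events(cohort)
        res = purity_concordance_test(cohort, summary)
        assert res.n2 == 2

    def test_power_under_planted_shift(self):
        """A +0.3 purity shift at n=40/40 is detected (p<0.05) in >=90% of seeds."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            base = rng.beta(4, 4, size=40) * 0.6  # mean ~0.3
            shifted = base + 0.3
            res = mann_whitney_two_sided(list(shifted), list(rng.beta(4, 4, size=40) * 0.6))
            if res.p_value < 0.05:
                rejections += 1
        assert rejections >= 0.9 * n_seeds
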