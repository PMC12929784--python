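"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exact rational enumeration,
nested loops) so they stay independent of the library code paths they
check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from dnarna.io_model import (
    Cohort,
    DnaAlterationCall,
    PatientRecord,
    RnaAlterationCall,
)


def make_patient(pid: str, **kw) -> PatientRecord:
    """A valid PatientRecord with overridable defaults."""
    defaults = dict(
        patient_id=pid,
        tumor_type="colorectal",
        age_years=60.0,
        sex="female",
        n_prior_therapies=3,
        ecog=1,
        n_metastatic_sites=2,
        albumin_low=False,
        ldh_high=False,
        tumor_purity=0.6,
        pdl1_status="negative",
        treated=True,
        os_months=10.0,
        os_event=True,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


def make_cohort(dna: dict[str, list], rna: dict[str, list], patients=None) -> Cohort:
    """Cohort from {patient: [genes]} maps; classes/directions defaulted."""
    pids = sorted(set(dna) | set(rna) | set(patients or []))
    patient_records = [make_patient(p) for p in pids]
    dna_calls = [
        DnaAlterationCall(patient_id=p, gene=g, alteration_class="missense_snv")
        for p, genes in sorted(dna.items())
        for g in genes
    ]
    rna_calls = [
        RnaAlterationCall(patient_id=p, gene=g, direction="over")
        for p, genes in sorted(rna.items())
        for g in genes
    ]
    return Cohort(patients=patient_records, dna_calls=dna_calls, rna_calls=rna_calls)


@pytest.fixture(scope="session")
def toy_cohort() -> Cohort:
    return make_cohort(
        dna={"P1": ["TP53", "KRAS"], "P2": ["KRAS", "APC"], "P3": []},
        rna={"P1": ["KRAS", "VEGFA"], "P2": ["VEGFA"], "P3": []},
    )


# ---------------------------------------------------------------------------
# Independent oracles


def hypergeom_pmf_exact(a: int, k_row: int, k_col: int, n: int) -> Fraction:
    """Exact probability of cell a in a 2x2 table with fixed margins."""
    return Fraction(comb(k_row, a) * comb(n - k_row, k_col - a), comb(n, k_col))


def fisher_two_sided_exact(n00: int, n10: int, n01: int, n11: int) -> Fraction:
    """Minimum-likelihood two-sided Fisher p by full exact enumeration."""
    n = n00 + n10 + n01 + n11
    k_row = n11 + n10
    k_col = n11 + n01
    p_obs = hypergeom_pmf_exact(n11, k_row, k_col, n)
    lo = max(0, k_row + k_col - n)
    hi = min(k_row, k_col)
    total = Fraction(0)
    for a in range(lo, hi + 1):
        p = hypergeom_pmf_exact(a, k_row, k_col, n)
        if p <= p_obs:
            total += p
    return total


def hypergeom_upper_tail_exact(overlap: int, n_universe: int, k_set: int, n_query: int) -> Fraction:
    """P(X >= overlap) for X ~ Hypergeom(N, K, n), exact."""
    total = Fraction(0)
    for x in range(overlap, min(k_set, n_query) + 1):
        total += Fraction(
            comb(k_set, x) * comb(n_universe - k_set, n_query - x),
            comb(n_universe, n_query),
        )
    return total


def bh_stepup_oracle(p_values):
    """BH adjusted p-values straight from the step-up definition:
    q_i = min over p_(j) >= p_i of m * p_(j) / rank_j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = {}
    running = 1.0
    for rank, i in reversed(list(enumerate(order, start=1))):
        running = min(running, m * p_values[i] / rank)
        adj[i] = min(1.0, running)
    return [adj[i] for i in range(m)]


def concordant_events_bruteforce(cohort: Cohort) -> set[tuple[str, str]]:
    """All (patient, gene) pairs altered in both assays, by nested loops."""
    out = set()
    for p in cohort.patients:
        for d in cohort.dna_calls:
            if d.patient_id != p.patient_id:
                continue
            for r in cohort.rna_calls:
                if r.patient_id == p.patient_id and r.gene == d.gene:
                    out.add((p.patient_id, d.gene))
    return out


def contingency_bruteforce(cohort: Cohort, dna_gene: str, rna_gene: str):
    """(n00, n10, n01, n11) by a per-patient membership scan."""
    n00 = n10 = n01 = n11 = 0
    for p in cohort.patients:
        has_d = any(
            c.patient_id == p.patient_id and c.gene == dna_gene
            for c in cohort.dna_calls
        )
        has_r = any(
            c.patient_id == p.patient_id and c.gene == rna_gene
            for c in cohort.rna_calls
        )
        if has_d and has_r:
            n11 += 1
        elif has_d:
            n10 += 1
        elif has_r:
            n01 += 1
        else:
            n00 += 1
    return n00, n10, n01, n11
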