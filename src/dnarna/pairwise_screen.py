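"""Exhaustive DNA-gene x RNA-gene association screen.

Every gene reported altered by DNA profiling is paired with every gene
reported altered by RNA profiling.  For each pair a patient-level 2x2
contingency table is built (presence/absence of an alteration in each gene,
counting distinct genes per patient), tested with the two-sided Fisher
exact test, and Benjamini-Hochberg correction is applied across the full
family of pairs.  Pairs where the two genes are the same symbol are flagged
as *concordant pairs*; all others are *discordant pairs*.

The screen is vectorized: indicator matrices give every table's n11 by a
single matrix product, and Fisher p-values are memoized over the distinct
(n11, DNA margin, RNA margin, N) tuples, which are few compared with the
number of pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Patient counts for one (DNA gene g, RNA gene h) pair.

    n00: no DNA alteration in g, no expression alteration in h
    n10: DNA alteration in g only;  n01: expression alteration in h only
    n11: both.
    """

    n00: int
    n10: int
    n01: int
    n11: int

    @property
    def total(self) -> int:
        return self.n00 + self.n10 + self.n01 + self.n11

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]])


@dataclass(frozen=True)
class GenePairResult:
    dna_gene: str
    rna_gene: str
    table: ContingencyTable2x2
    odds_ratio: float  # may be inf; nan flags an undefined (zero-margin) OR
    p_value: float
    adjusted_p: float
    is_concordant_pair: bool


def build_contingency(
    cohort: Cohort, dna_gene: str, rna_gene: str
) -> ContingencyTable2x2:
    """Count patients by presence of a DNA alteration in ``dna_gene`` and an
    expression alteration in ``rna_gene``.  A gene absent from all calls
    simply yields a zero margin."""
    dna_by_pt = cohort.dna_genes_by_patient()
    rna_by_pt = cohort.rna_genes_by_patient()
    n00 = n10 = n01 = n11 = 0
    for pid in cohort.patient_ids:
        d = dna_gene in dna_by_pt[pid]
        r = rna_gene in rna_by_pt[pid]
        if d and r:
            n11 += 1
        elif d:
            n10 += 1
        elif r:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable2x2(n00=n00, n10=n10, n01=n01, n11=n11)


@lru_cache(maxsize=1_000_000)
def _fisher_cached(n11: int, k_dna: int, k_rna: int, n: int) -> float:
    table = [[n11, k_dna - n11], [k_rna - n11, n - k_dna - (k_rna - n11)]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test with the minimum-likelihood rule.

    Returns (odds_ratio, p_value).  The p-value sums the hypergeometric
    probabilities, at the observed margins, of all tables no more probable
    than the observed one.  The sample odds ratio is (n11*n00)/(n10*n01),
    +inf when only the denominator is zero, and nan (undefined) when a row
    or column margin is zero — in which case p is exactly 1.
    """
    t = table
    if min(t.n00, t.n10, t.n01, t.n11) < 0:
        raise ValueError(f"negative cell in contingency table: {t}")
    k_dna = t.n11 + t.n10
    k_rna = t.n11 + t.n01
    n = t.total
    if k_dna in (0, n) or k_rna in (0, n):
        return math.nan, 1.0
    num = t.n11 * t.n00
    den = t.n10 * t.n01
    odds = math.inf if den == 0 else num / den
    p = _fisher_cached(t.n11, k_dna, k_rna, n)
    return odds, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_screen(cohort: Cohort) -> list[GenePairResult]:
    """Test every (DNA gene, RNA gene) pair and BH-adjust across all pairs.

    Returns exactly |unique DNA genes| x |unique RNA genes| results, sorted
    by (adjusted p, raw p, dna_gene, rna_gene).
    """
    dna_genes = sorted(cohort.unique_dna_genes())
    rna_genes = sorted(cohort.unique_rna_genes())
    if not dna_genes or not rna_genes:
        logger.warning(
            "empty gene universe (DNA %d, RNA %d genes); screen is empty",
            len(dna_genes),
            len(rna_genes),
        )
        return []

    pids = cohort.patient_ids
    pid_idx = {pid: i for i, pid in enumerate(pids)}
    n = len(pids)
    dmat = np.zeros((n, len(dna_genes)), dtype=np.int64)
    rmat = np.zeros((n, len(rna_genes)), dtype=np.int64)
    dg_idx = {g: j for j, g in enumerate(dna_genes)}
    rg_idx = {g: j for j, g in enumerate(rna_genes)}
    for c in cohort.dna_calls:
        dmat[pid_idx[c.patient_id], dg_idx[c.gene]] = 1
    for c in cohort.rna_calls:
        rmat[pid_idx[c.patient_id], rg_idx[c.gene]] = 1

    n11 = dmat.T @ rmat  # |dna| x |rna|
    k_dna = dmat.sum(axis=0)
    k_rna = rmat.sum(axis=0)

    results_raw = []
    p_values = []
    for i, g in enumerate(dna_genes):
        for j, h in enumerate(rna_genes):
            a = int(n11[i, j])
            table = ContingencyTable2x2(
                n00=n - int(k_dna[i]) - int(k_rna[j]) + a,
                n10=int(k_dna[i]) - a,
                n01=int(k_rna[j]) - a,
                n11=a,
            )
            odds, p = fisher_exact_two_sided(table)
            results_raw.append((g, h, table, odds, p))
            p_values.append(p)

    adjusted = bh_adjust(p_values)
    results = [
        GenePairResult(
            dna_gene=g,
            rna_gene=h,
            table=table,
            odds_ratio=odds,
            p_value=p,
            adjusted_p=float(q),
            is_concordant_pair=(g == h),
        )
        for (g, h, table, odds, p), q in zip(results_raw, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.dna_gene, r.rna_gene))
    return results


def partition_significant(
    results: Sequence[GenePairResult], alpha: float = 0.05
) -> tuple[list[GenePairResult], list[GenePairResult], dict[str, int]]:
    """Split results into significant concordant / significant discordant.

    Significance is adjusted p < ``alpha``.  Returns (concordant pairs,
    discordant pairs, counts) where counts reports the totals.
    """
    sig = [r for r in results if r.adjusted_p < alpha]
    concordant = [r for r in sig if r.is_concordant_pair]
    discordant = [r for r in sig if not r.is_concordant_pair]
    counts = {
        "total_pairs": len(results),
        "significant": len(sig),
        "significant_concordant": len(concordant),
        "significant_discordant": len(discordant),
    }
    return concordant, discordant, counts


def write_pairs(results: Sequence[GenePairResult], path) -> None:
    """Write pairs.tsv: one row per tested gene pair."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "dna_gene\trna_gene\tn00\tn10\tn01\tn11\todds_ratio\tp_value\t"
            "adjusted_p\tis_concordant_pair\n"
        )
        for r in results:
            t = r.table
            odds = "NA" if math.isnan(r.odds_ratio) else repr(r.odds_ratio)
            fh.write(
                f"{r.dna_gene}\t{r.rna_gene}\t{t.n00}\t{t.n10}\t{t.n01}\t"
                f"{t.n11}\t{odds}\t{r.p_value!r}\t{r.adjusted_p!r}\t"
                f"{'true' if r.is_concordant_pair else 'false'}\n"
            )
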