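"""Same-gene DNA/RNA concordant-event detection and event-level summaries.

A *concordant event* is a (patient, gene) pair reported as altered by both
DNA profiling and RNA profiling in the same patient, regardless of the
alteration class on the DNA side or the direction of the expression change.
Directional consistency is deliberately not required: a deletion paired with
overexpression still counts as a concordant event, and the class breakdown
is tabulated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .io_model import Cohort, COPY_NUMBER_CLASSES

# When one (patient, gene) carries several DNA alteration classes, the event
# is assigned a single primary class by this priority (highest first).
DEFAULT_CLASS_PRIORITY: tuple[str, ...] = (
    "copy_number_gain",
    "copy_number_loss",
    "fusion_or_rearrangement",
    "splice_site",
    "frameshift_or_stopgain",
    "missense_snv",
)


@dataclass(frozen=True)
class ConcordantEvent:
    patient_id: str
    gene: str
    dna_classes: frozenset[str]
    rna_direction: str
    copy_number: Optional[float] = None
    expression_score: Optional[float] = None

    def primary_class(
        self, priority: Sequence[str] = DEFAULT_CLASS_PRIORITY
    ) -> str:
        for cls in priority:
            if cls in self.dna_classes:
                return cls
        # unknown classes fall back to lexicographic minimum
        return min(self.dna_classes)


@dataclass
class ConcordanceSummary:
    events: list[ConcordantEvent]
    per_patient_event_counts: dict[str, int] = field(default_factory=dict)
    genes_involved: set[str] = field(default_factory=set)
    class_breakdown: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RankTestResult:
    """A two-sample rank test outcome, or an insufficient-data marker."""

    statistic: Optional[float]
    p_value: Optional[float]
    n1: int
    n2: int
    reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.p_value is not None


def detect_concordant_events(
    cohort: Cohort, priority: Sequence[str] = DEFAULT_CLASS_PRIORITY
) -> ConcordanceSummary:
    """Detect one event per (patient, gene) altered in both assays.

    The event carries the full set of DNA classes for that (patient, gene),
    the RNA direction, and—when present—the copy number of the highest-
    priority copy-number call and the RNA expression score.
    """
    rna_by_pt: dict[str, dict[str, object]] = {}
    for c in cohort.rna_calls:
        rna_by_pt.setdefault(c.patient_id, {})[c.gene] = c
    dna_by_pt_gene: dict[tuple[str, str], list] = {}
    for c in cohort.dna_calls:
        dna_by_pt_gene.setdefault((c.patient_id, c.gene), []).append(c)

    events: list[ConcordantEvent] = []
    for (pid, gene), dcalls in sorted(dna_by_pt_gene.items()):
        rcall = rna_by_pt.get(pid, {}).get(gene)
        if rcall is None:
            continue
        classes = frozenset(d.alteration_class for d in dcalls)
        cn = None
        for cls in DEFAULT_CLASS_PRIORITY:
            if cls in COPY_NUMBER_CLASSES and cls in classes:
                cn = next(
                    (
                        d.copy_number
                        for d in dcalls
                        if d.alteration_class == cls and d.copy_number is not None
                    ),
                    None,
                )
                if cn is not None:
                    break
        events.append(
            ConcordantEvent(
                patient_id=pid,
                gene=gene,
                dna_classes=classes,
                rna_direction=rcall.direction,
                copy_number=cn,
                expression_score=rcall.expression_score,
            )
        )

    per_patient: dict[str, int] = {}
    for ev in events:
        per_patient[ev.patient_id] = per_patient.get(ev.patient_id, 0) + 1
    breakdown: dict[str, int] = {}
    for ev in events:
        cls = ev.primary_class(priority)
        breakdown[cls] = breakdown.get(cls, 0) + 1
    return ConcordanceSummary(
        events=events,
        per_patient_event_counts=per_patient,
        genes_involved={ev.gene for ev in events},
        class_breakdown=breakdown,
    )


def events_from_distribution(distribution: dict[int, int]) -> tuple[int, int]:
    """Totals implied by an events-per-patient histogram.

    ``distribution`` maps events-per-patient -> number of patients; returns
    (total patients, total events).
    """
    for k, v in distribution.items():
        if k < 0 or v < 0:
            raise ValueError(
                f"events-per-patient histogram must be non-negative, got {k}: {v}"
            )
    n_patients = sum(distribution.values())
    n_events = sum(k * v for k, v in distribution.items())
    return n_patients, n_events


def event_class_breakdown(
    summary: ConcordanceSummary, priority: Sequence[str] = DEFAULT_CLASS_PRIORITY
) -> dict[str, dict[str, float]]:
    """Counts and percentages of concordant events by primary class."""
    counts: dict[str, int] = {}
    for ev in summary.events:
        cls = ev.primary_class(priority)
        counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    return {
        cls: {"count": n, "percent": 100.0 * n / total if total else 0.0}
        for cls, n in sorted(counts.items(), key=lambda kv: -kv[1])
    }


def cn_expression_correlation(summary: ConcordanceSummary) -> RankTestResult:
    """Spearman rank correlation of copy number vs expression score.

    Computed over concordant events carrying both numeric fields (in
    practice, copy-number events).  Ties are handled by midranks.  Fewer
    than three usable events yields an insufficient-data result rather
    than an exception.
    """
    pairs = [
        (ev.copy_number, ev.expression_score)
        for ev in summary.events
        if ev.copy_number is not None and ev.expression_score is not None
    ]
    if len(pairs) < 3:
        return RankTestResult(
            statistic=None,
            p_value=None,
            n1=len(pairs),
            n2=0,
            reason=f"insufficient data: {len(pairs)} events with both fields",
        )
    cn, expr = zip(*pairs)
    rho, p = stats.spearmanr(cn, expr)
    return RankTestResult(statistic=float(rho), p_value=float(p), n1=len(pairs), n2=0)


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> RankTestResult:
    """Two-sided Mann-Whitney U test of x vs y.

    Uses exact enumeration when both samples have at most ``exact_max_n``
    observations and no cross-group ties; otherwise the normal approximation
    with tie and continuity corrections.  Reports the U statistic of the
    first sample.
    """
    x, y = list(x), list(y)
    if not x or not y:
        return RankTestResult(
            statistic=None,
            p_value=None,
            n1=len(x),
            n2=len(y),
            reason="insufficient data: one group is empty",
        )
    use_exact = (
        len(x) <= exact_max_n
        and len(y) <= exact_max_n
        and len(set(x) | set(y)) == len(x) + len(y)
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return RankTestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n1=len(x),
        n2=len(y),
    )


def purity_concordance_test(
    cohort: Cohort, summary: ConcordanceSummary
) -> RankTestResult:
    """Mann-Whitney comparison of tumor purity: patients with >=1 concordant
    event vs patients with none.  Patients with missing purity are excluded.
    The U statistic reported is for the concordant group."""
    with_event = set(summary.per_patient_event_counts)
    grp_event, grp_none = [], []
    for p in cohort.patients:
        if p.tumor_purity is None:
            continue
        (grp_event if p.patient_id in with_event else grp_none).append(
            p.tumor_purity
        )
    return mann_whitney_two_sided(grp_event, grp_none)


def write_events(summary: ConcordanceSummary, path) -> None:
    """Write events.tsv: one row per concordant event."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "patient_id\tgene\tprimary_class\trna_direction\tcopy_number\t"
            "expression_score\n"
        )
        for ev in summary.events:
            cn = "NA" if ev.copy_number is None else ev.copy_number
            es = "NA" if ev.expression_score is None else ev.expression_score
            fh.write(
                f"{ev.patient_id}\t{ev.gene}\t{ev.primary_class()}\t"
                f"{ev.rna_direction}\t{cn}\t{es}\n"
            )
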