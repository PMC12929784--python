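"""Seeded generator of paired DNA/RNA profiling cohorts.

The generator emulates the statistical structure of a pan-cancer
precision-oncology cohort in which tumor DNA and RNA were profiled on the
same gene-panel platform:

* 253 patients; a 242-gene DNA alteration universe and a 52-gene
  expression-alteration universe (a subset of the DNA universe, so
  same-gene concordance is observable);
* per-patient counts of distinct DNA-altered genes with median 4 on
  support [0, 21], and distinct expression-altered genes with median 2 on
  support [0, 9];
* DNA alteration classes mixed 42.9% frameshift/stop-gain, 30.4% copy
  number, 23.8% missense SNV, 2.9% fusion/rearrangement; RNA directions
  mixed 87.7% over- / 12.3% under-expression;
* copy-number/expression coupling: a copy-number call in a panel gene
  induces a matching expression call (gain -> over, loss -> under) with a
  probability proportional to tumor purity, and the induced expression
  score is rank-correlated with copy number (target Spearman ~ 0.72 among
  concordant copy-number events);
* overall survival drawn per tumor-transcriptional-burden stratum
  (default median OS 9.8 / 11.9 / 6.7 months for TTB 0-2 / 3-5 / >=6)
  with independent exponential censoring;
* PD-L1 negativity weakly increasing in TTB; a treated-patient fraction
  of 217/253.

Gene frequencies follow a Zipf-like law so that a minority of genes (TP53,
KRAS, ...) are common, as in real panels.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .concordance import cn_expression_correlation, detect_concordant_events
from .io_model import (
    Cohort,
    DnaAlterationCall,
    PatientRecord,
    RnaAlterationCall,
)
from .survival_ttb import DEFAULT_TTB_BREAKS, stratum_labels

# Recurrently altered cancer genes occupy the top Zipf ranks of the DNA
# universe; the remainder of the 242-gene panel is synthetic filler.
NAMED_GENES: tuple[str, ...] = (
    "TP53", "KRAS", "CDKN2A", "PIK3CA", "APC", "CDKN2B", "AR", "ESR1",
    "CCND1", "CDK4", "AKT2", "EGFR", "ERBB2", "MYC", "VEGFA", "PTEN",
    "RB1", "BRAF", "FGFR1", "MDM2", "CCNE1", "MET", "STK11", "SMAD4",
    "ARID1A", "KMT2D", "NF1", "ATM", "BRCA2", "NOTCH1",
)

TUMOR_TYPES: tuple[tuple[str, float], ...] = (
    ("colorectal", 0.21),
    ("head_and_neck", 0.12),
    ("sarcoma", 0.12),
    ("breast", 0.09),
    ("pancreas", 0.07),
    ("lung", 0.05),
    ("gynecologic", 0.04),
    ("ovarian", 0.04),
    ("prostate", 0.03),
    ("melanoma", 0.02),
    ("other", 0.21),
)


@dataclass(frozen=True)
class PlantedPair:
    """A cross-gene association planted into the cohort.

    Among carriers of a DNA alteration in ``dna_gene``, the odds of an
    expression alteration in ``rna_gene`` are multiplied by
    ``odds_multiplier`` relative to the baseline odds."""

    dna_gene: str
    rna_gene: str
    odds_multiplier: float


@dataclass
class SimulationConfig:
    """Generator parameters with cohort-calibrated defaults."""

    n_patients: int = 253
    n_dna_genes: int = 242
    n_rna_genes: int = 52

    # per-patient distinct DNA-altered genes: negative binomial truncated
    # to [0, dna_count_max]; calibrated so the cohort median is 4
    dna_count_r: float = 6.0
    dna_count_mean: float = 4.45
    dna_count_max: int = 21

    # baseline per-patient distinct expression-altered genes: explicit
    # probabilities on 0..9, calibrated so the cohort median is 2 after
    # coupling-induced calls are added, with enough mass in the upper TTB
    # strata to make per-stratum survival medians estimable
    rna_count_probs: tuple[float, ...] = (
        0.11, 0.16, 0.36, 0.065, 0.055, 0.05, 0.08, 0.07, 0.035, 0.015,
    )
    rna_count_max: int = 9

    # DNA alteration-class mixture over call records
    class_mixture: dict = field(
        default_factory=lambda: {
            "frameshift_or_stopgain": 0.429,
            "copy_number": 0.304,
            "missense_snv": 0.238,
            "fusion_or_rearrangement": 0.029,
        }
    )
    copy_number_gain_fraction: float = 0.75
    rna_direction_mixture: dict = field(
        default_factory=lambda: {"over": 0.877, "under": 0.123}
    )

    # Zipf exponents for gene frequencies
    dna_zipf_s: float = 1.0
    rna_zipf_s: float = 0.8

    # copy-number -> expression coupling: probability that a copy-number
    # call in a panel gene induces the matching expression call is
    # concordance_coupling * tumor_purity
    concordance_coupling: float = 0.26
    # coupling for non-copy-number classes (off by default)
    non_cnv_coupling: float = 0.0
    # latent Gaussian correlation between copy number and expression score
    # within coupled events; calibrated so pooled concordant-event Spearman
    # is ~0.72 once accidental (uncoupled) overlaps are included
    cn_expr_latent_rho: float = 0.88

    planted_pairs: tuple[PlantedPair, ...] = ()

    # tumor purity ~ Beta(a, b)
    purity_alpha: float = 4.0
    purity_beta: float = 2.2

    ttb_breaks: tuple[int, ...] = DEFAULT_TTB_BREAKS
    stratum_median_os: dict = field(
        default_factory=lambda: {"0-2": 9.8, "3-5": 11.9, ">=6": 6.7}
    )
    censoring_rate: float = 0.20

    # P(PD-L1 negative | known) = sigmoid(intercept + slope * ttb)
    pdl1_intercept: float = -0.30
    pdl1_logit_slope: float = 0.15
    pdl1_unknown_fraction: float = 0.06

    treated_fraction: float = 217 / 253
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.n_rna_genes > self.n_dna_genes:
            raise ValueError("RNA gene universe must fit inside the DNA universe")
        if self.rna_count_max >= self.n_rna_genes:
            raise ValueError(
                "rna count support must not exceed the RNA gene universe"
            )
        if self.dna_count_max >= self.n_dna_genes:
            raise ValueError(
                "dna count support must not exceed the DNA gene universe"
            )
        for name, mix in (
            ("class_mixture", self.class_mixture),
            ("rna_direction_mixture", self.rna_direction_mixture),
        ):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has negative probability")
        if not math.isclose(sum(self.rna_count_probs), 1.0, abs_tol=1e-6):
            raise ValueError("rna_count_probs must sum to 1")
        if len(self.rna_count_probs) != self.rna_count_max + 1:
            raise ValueError("rna_count_probs must cover 0..rna_count_max")
        for p in (
            self.concordance_coupling,
            self.non_cnv_coupling,
            self.censoring_rate,
            self.treated_fraction,
            self.pdl1_unknown_fraction,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability parameter out of [0, 1]: {p}")
        labels = stratum_labels(self.ttb_breaks)
        missing = [l for l in labels if l not in self.stratum_median_os]
        if missing:
            raise ValueError(f"stratum_median_os missing strata {missing}")


def dna_gene_universe(config: SimulationConfig) -> list[str]:
    """DNA universe: named driver genes first, synthetic filler after."""
    n = config.n_dna_genes
    genes = list(NAMED_GENES[:n])
    genes += [f"GENE{i:03d}" for i in range(len(genes) + 1, n + 1)]
    return genes[:n]


def rna_gene_universe(config: SimulationConfig) -> list[str]:
    """RNA universe, ordered by decreasing baseline expression-alteration
    frequency.

    Mid-rank filler genes head the list so that baseline expression calls
    are mostly independent of the DNA hotspots; the named driver genes
    (through which copy-number coupling acts) sit in the tail, keeping
    accidental same-gene overlap low.
    """
    dna_genes = dna_gene_universe(config)
    n = config.n_rna_genes
    named = [g for g in NAMED_GENES if g in dna_genes]
    n_filler = max(0, n - len(named))
    # deterministic spread of filler picks across the mid-frequency range
    filler_pool = [g for g in dna_genes if g not in NAMED_GENES]
    step = max(1, len(filler_pool) // max(1, n_filler + 1))
    filler = [filler_pool[(i + 1) * step % len(filler_pool)] for i in range(n_filler)]
    # dedupe while preserving order
    seen: set[str] = set()
    ordered = []
    for g in filler + named:
        if g not in seen:
            seen.add(g)
            ordered.append(g)
    i = 0
    while len(ordered) < n:  # top up if modular picks collided
        g = filler_pool[i]
        if g not in seen:
            seen.add(g)
            ordered.append(g)
        i += 1
    ordered = ordered[:n]
    # VEGFA-like highly expressed genes are commonly dysregulated; keep one
    # named gene at a moderate baseline rank so cross-gene structure between
    # hotspot DNA genes and a recurrent RNA gene is representable
    if "VEGFA" in ordered:
        ordered.remove("VEGFA")
        ordered.insert(4, "VEGFA")
    return ordered


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** s
    return w / w.sum()


def _truncated_nbinom_counts(
    rng: np.random.Generator, n: int, r: float, mean: float, upper: int
) -> np.ndarray:
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p, size=n)
    while True:  # resample the few draws above the support
        over = counts > upper
        if not over.any():
            return counts
        counts[over] = rng.negative_binomial(r, p, size=int(over.sum()))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a full synthetic cohort. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    dna_genes = dna_gene_universe(config)
    rna_genes = rna_gene_universe(config)
    rna_set = set(rna_genes)
    dna_w = _zipf_weights(len(dna_genes), config.dna_zipf_s)
    rna_w = _zipf_weights(len(rna_genes), config.rna_zipf_s)

    pids = [f"PT{i + 1:04d}" for i in range(n)]
    purity = rng.beta(config.purity_alpha, config.purity_beta, size=n)

    dna_counts = _truncated_nbinom_counts(
        rng, n, config.dna_count_r, config.dna_count_mean, config.dna_count_max
    )
    rna_counts = rng.choice(
        np.arange(config.rna_count_max + 1),
        size=n,
        p=np.asarray(config.rna_count_probs),
    )

    class_names = list(config.class_mixture)
    class_probs = np.array([config.class_mixture[c] for c in class_names])

    dna_calls: list[DnaAlterationCall] = []
    rna_calls_by_pt: list[dict[str, RnaAlterationCall]] = []
    dna_cnv_calls_by_pt: list[list[DnaAlterationCall]] = []

    for i, pid in enumerate(pids):
        genes = rng.choice(
            len(dna_genes), size=int(dna_counts[i]), replace=False, p=dna_w
        )
        cnv_calls = []
        for gi in genes:
            gene = dna_genes[int(gi)]
            cls = class_names[int(rng.choice(len(class_names), p=class_probs))]
            if cls == "copy_number":
                gain = rng.random() < config.copy_number_gain_fraction
                cls = "copy_number_gain" if gain else "copy_number_loss"
                z1 = rng.standard_normal()
                if gain:
                    cn = max(2.5, 4.0 + 2.0 * z1)
                else:
                    cn = min(1.5, max(0.0, 0.8 + 0.4 * z1))
                call = DnaAlterationCall(
                    patient_id=pid, gene=gene, alteration_class=cls, copy_number=round(cn, 2)
                )
                cnv_calls.append((call, z1))
            else:
                call = DnaAlterationCall(
                    patient_id=pid, gene=gene, alteration_class=cls
                )
            dna_calls.append(call)
        dna_cnv_calls_by_pt.append(cnv_calls)

        # baseline expression calls, independent of the DNA profile
        r_genes = rng.choice(
            len(rna_genes), size=int(rna_counts[i]), replace=False, p=rna_w
        )
        calls: dict[str, RnaAlterationCall] = {}
        for gi in r_genes:
            gene = rna_genes[int(gi)]
            over = rng.random() < config.rna_direction_mixture["over"]
            score = (
                round(float(np.clip(rng.normal(85, 9), 55, 100)), 1)
                if over
                else round(float(np.clip(rng.normal(12, 7), 0, 45)), 1)
            )
            calls[gene] = RnaAlterationCall(
                patient_id=pid,
                gene=gene,
                direction="over" if over else "under",
                expression_score=score,
            )
        rna_calls_by_pt.append(calls)

    # copy-number -> expression coupling, modulated by tumor purity
    rho = config.cn_expr_latent_rho
    for i, pid in enumerate(pids):
        calls = rna_calls_by_pt[i]
        for call, z1 in dna_cnv_calls_by_pt[i]:
            if call.gene not in rna_set or call.gene in calls:
                continue
            if len(calls) >= config.rna_count_max:
                break
            if rng.random() >= config.concordance_coupling * purity[i]:
                continue
            gain = call.alteration_class == "copy_number_gain"
            z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
            if gain:
                score = float(np.clip(82 + 9 * z2, 55, 100))
            else:
                score = float(np.clip(14 + 8 * z2, 0, 45))
            calls[call.gene] = RnaAlterationCall(
                patient_id=pid,
                gene=call.gene,
                direction="over" if gain else "under",
                expression_score=round(score, 1),
            )
    if config.non_cnv_coupling > 0:
        by_pid = {pid: i for i, pid in enumerate(pids)}
        for call in dna_calls:
            if call.alteration_class in (
                "copy_number_gain",
                "copy_number_loss",
            ):
                continue
            i = by_pid[call.patient_id]
            calls = rna_calls_by_pt[i]
            if call.gene not in rna_set or call.gene in calls:
                continue
            if len(calls) >= config.rna_count_max:
                continue
            if rng.random() >= config.non_cnv_coupling * purity[i]:
                continue
            over = rng.random() < config.rna_direction_mixture["over"]
            calls[call.gene] = RnaAlterationCall(
                patient_id=call.patient_id,
                gene=call.gene,
                direction="over" if over else "under",
                expression_score=round(
                    float(np.clip(rng.normal(85, 9) if over else rng.normal(12, 7), 0, 100)), 1
                ),
            )

    # planted cross-gene associations
    dna_carrier: dict[str, set[int]] = {}
    pid_index = {pid: i for i, pid in enumerate(pids)}
    for c in dna_calls:
        dna_carrier.setdefault(c.gene, set()).add(pid_index[c.patient_id])
    for planted in config.planted_pairs:
        carriers = sorted(dna_carrier.get(planted.dna_gene, set()))
        if not carriers:
            continue
        n_with_h = sum(
            1 for calls in rna_calls_by_pt if planted.rna_gene in calls
        )
        p_h = max(n_with_h / n, 1.0 / (2 * n))
        odds = p_h / (1.0 - p_h) * planted.odds_multiplier
        q = odds / (1.0 + odds)
        add_p = max(0.0, (q - p_h) / (1.0 - p_h))
        for i in carriers:
            calls = rna_calls_by_pt[i]
            if planted.rna_gene in calls or len(calls) >= config.rna_count_max:
                continue
            if rng.random() >= add_p:
                continue
            over = rng.random() < config.rna_direction_mixture["over"]
            calls[planted.rna_gene] = RnaAlterationCall(
                patient_id=pids[i],
                gene=planted.rna_gene,
                direction="over" if over else "under",
                expression_score=round(
                    float(np.clip(rng.normal(85, 9) if over else rng.normal(12, 7), 0, 100)), 1
                ),
            )

    # clinical covariates and survival
    labels = stratum_labels(config.ttb_breaks)
    breaks = list(config.ttb_breaks)
    tumor_names = [t for t, _ in TUMOR_TYPES]
    tumor_probs = np.array([p for _, p in TUMOR_TYPES])
    tumor_probs = tumor_probs / tumor_probs.sum()
    patients: list[PatientRecord] = []
    for i, pid in enumerate(pids):
        ttb = len(rna_calls_by_pt[i])
        stratum = labels[int(np.searchsorted(breaks, ttb, side="left"))]
        median_os = config.stratum_median_os[stratum]
        scale = median_os / math.log(2.0)
        t_event = rng.exponential(scale)
        c = config.censoring_rate
        if c > 0:
            t_cens = rng.exponential(scale * (1.0 - c) / c)
        else:
            t_cens = math.inf
        os_months = min(t_event, t_cens)
        os_event = t_event <= t_cens

        if rng.random() < config.pdl1_unknown_fraction:
            pdl1 = "unknown"
        else:
            p_neg = _sigmoid(config.pdl1_intercept + config.pdl1_logit_slope * ttb)
            pdl1 = "negative" if rng.random() < p_neg else "positive"

        patients.append(
            PatientRecord(
                patient_id=pid,
                tumor_type=tumor_names[int(rng.choice(len(tumor_names), p=tumor_probs))],
                age_years=float(np.clip(round(rng.normal(58, 12)), 20, 84)),
                sex="female" if rng.random() < 0.52 else "male",
                n_prior_therapies=int(rng.poisson(4)),
                ecog=int(rng.random() < 0.88),
                n_metastatic_sites=int(rng.poisson(2)),
                albumin_low=bool(rng.random() < 0.11),
                ldh_high=bool(rng.random() < 0.54) if rng.random() >= 0.07 else None,
                tumor_purity=round(float(purity[i]), 3),
                pdl1_status=pdl1,
                treated=bool(rng.random() < config.treated_fraction),
                os_months=round(os_months, 2),
                os_event=os_event,
            )
        )

    rna_calls = [
        call
        for calls in rna_calls_by_pt
        for _, call in sorted(calls.items())
    ]
    return Cohort(patients=patients, dna_calls=dna_calls, rna_calls=rna_calls)


def calibration_report(cohort: Cohort, config: SimulationConfig) -> dict:
    """Realized vs configured summaries, with pass/fail flags.

    Tolerances: per-patient medians exact; class/direction mixtures within
    3 percentage points; copy-number/expression Spearman within 0.1 of the
    configured target; treated per-stratum KM medians within 2.5 months.
    """
    report: dict[str, dict] = {}
    if not cohort.patients:
        return report

    from .io_model import cohort_summary

    summ = cohort_summary(cohort)

    def entry(name, configured, realized, ok):
        report[name] = {
            "configured": configured,
            "realized": realized,
            "ok": bool(ok),
        }

    med_dna = summ["dna_genes_per_patient"]["median"]
    med_rna = summ["rna_genes_per_patient"]["median"]
    entry("median_dna_genes_per_patient", 4, med_dna, med_dna == 4)
    entry("median_rna_genes_per_patient", 2, med_rna, med_rna == 2)
    entry(
        "unique_dna_genes",
        config.n_dna_genes,
        summ["unique_dna_genes"],
        summ["unique_dna_genes"] <= config.n_dna_genes,
    )
    entry(
        "unique_rna_genes",
        config.n_rna_genes,
        summ["unique_rna_genes"],
        summ["unique_rna_genes"] <= config.n_rna_genes,
    )

    cls_pct = summ["dna_class_percent"]
    realized_cnv = cls_pct.get("copy_number_gain", 0.0) + cls_pct.get(
        "copy_number_loss", 0.0
    )
    targets = {
        "frameshift_or_stopgain": 100 * config.class_mixture["frameshift_or_stopgain"],
        "copy_number": 100 * config.class_mixture["copy_number"],
        "missense_snv": 100 * config.class_mixture["missense_snv"],
        "fusion_or_rearrangement": 100
        * config.class_mixture["fusion_or_rearrangement"],
    }
    realized_cls = {
        "frameshift_or_stopgain": cls_pct.get("frameshift_or_stopgain", 0.0),
        "copy_number": realized_cnv,
        "missense_snv": cls_pct.get("missense_snv", 0.0),
        "fusion_or_rearrangement": cls_pct.get("fusion_or_rearrangement", 0.0),
    }
    for k, tgt in targets.items():
        entry(f"class_percent_{k}", tgt, realized_cls[k], abs(realized_cls[k] - tgt) <= 3.0)
    dir_pct = summ["rna_direction_percent"]
    for k, frac in config.rna_direction_mixture.items():
        realized = dir_pct.get(k, 0.0)
        entry(f"direction_percent_{k}", 100 * frac, realized, abs(realized - 100 * frac) <= 3.0)

    concordance = detect_concordant_events(cohort)
    rho = cn_expression_correlation(concordance)
    entry(
        "concordant_cn_expression_spearman",
        0.72,
        rho.statistic,
        rho.ok and abs(rho.statistic - 0.72) <= 0.1,
    )
    entry(
        "concordant_events",
        58,
        len(concordance.events),
        True,  # informational; the printed study value is not a generator target
    )

    from .survival_ttb import ttb_survival_analysis

    surv = ttb_survival_analysis(cohort, breaks=config.ttb_breaks, treated_only=True)
    for lab, target in config.stratum_median_os.items():
        curve = surv["curves"].get(lab)
        realized = curve.median if curve is not None else float("nan")
        entry(
            f"km_median_os_{lab}",
            target,
            realized,
            math.isfinite(realized) and abs(realized - target) <= 2.5,
        )
    return report
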