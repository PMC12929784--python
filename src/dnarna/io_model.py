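"""Cohort data model, TSV readers/writers, and validation.

The pipeline's single input object is a :class:`Cohort`: a clinical table of
patients, a table of DNA alteration calls, and a table of RNA (expression)
alteration calls, joined on ``patient_id``.  All files are tab-separated
UTF-8 text with a mandatory header row; missing values are an empty field
or ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DNA_CLASSES = frozenset(
    {
        "frameshift_or_stopgain",
        "copy_number_gain",
        "copy_number_loss",
        "missense_snv",
        "fusion_or_rearrangement",
        "splice_site",
    }
)
COPY_NUMBER_CLASSES = frozenset({"copy_number_gain", "copy_number_loss"})
RNA_DIRECTIONS = frozenset({"over", "under"})
PDL1_STATUSES = frozenset({"positive", "negative", "unknown"})
SEXES = frozenset({"male", "female"})

PATIENT_COLUMNS = [
    "patient_id",
    "tumor_type",
    "age_years",
    "sex",
    "n_prior_therapies",
    "ecog",
    "n_metastatic_sites",
    "albumin_low",
    "ldh_high",
    "tumor_purity",
    "pdl1_status",
    "treated",
    "os_months",
    "os_event",
]
DNA_COLUMNS = ["patient_id", "gene", "alteration_class", "copy_number"]
RNA_COLUMNS = ["patient_id", "gene", "direction", "expression_score"]


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort contract."""


def normalize_gene_symbol(raw: str, alias_map: Optional[Mapping[str, str]] = None) -> str:
    """Normalize a gene symbol: strip whitespace and uppercase.

    Gene identity throughout the package is exact match on the normalized
    symbol.  An optional ``alias_map`` (normalized alias -> canonical symbol)
    can be supplied for panels that report non-canonical names.
    """
    if raw is None:
        raise CohortValidationError("gene symbol is missing (None)")
    sym = str(raw).strip().upper()
    if not sym:
        raise CohortValidationError(f"gene symbol is empty or blank: {raw!r}")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    tumor_type: str
    age_years: float
    sex: str
    n_prior_therapies: int
    ecog: int
    n_metastatic_sites: int
    albumin_low: bool
    ldh_high: Optional[bool]
    tumor_purity: Optional[float]
    pdl1_status: str
    treated: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: os_months must be >= 0, got {self.os_months}"
            )
        if self.age_years < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: age_years must be >= 0"
            )
        if self.tumor_purity is not None and not (0.0 <= self.tumor_purity <= 1.0):
            raise CohortValidationError(
                f"patient {self.patient_id}: tumor_purity must lie in [0, 1], "
                f"got {self.tumor_purity}"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"patient {self.patient_id}: sex must be one of {sorted(SEXES)}"
            )
        if self.pdl1_status not in PDL1_STATUSES:
            raise CohortValidationError(
                f"patient {self.patient_id}: pdl1_status must be one of "
                f"{sorted(PDL1_STATUSES)}"
            )
        if self.ecog not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id}: ecog must be 0 or 1"
            )


@dataclass(frozen=True)
class DnaAlterationCall:
    patient_id: str
    gene: str
    alteration_class: str
    copy_number: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alteration_class not in DNA_CLASSES:
            raise CohortValidationError(
                f"DNA call ({self.patient_id}, {self.gene}): unknown "
                f"alteration_class {self.alteration_class!r}"
            )
        if self.copy_number is not None:
            if self.alteration_class not in COPY_NUMBER_CLASSES:
                raise CohortValidationError(
                    f"DNA call ({self.patient_id}, {self.gene}): copy_number given "
                    f"for non-copy-number class {self.alteration_class!r}"
                )
            if self.copy_number < 0:
                raise CohortValidationError(
                    f"DNA call ({self.patient_id}, {self.gene}): negative copy_number"
                )


@dataclass(frozen=True)
class RnaAlterationCall:
    patient_id: str
    gene: str
    direction: str
    expression_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in RNA_DIRECTIONS:
            raise CohortValidationError(
                f"RNA call ({self.patient_id}, {self.gene}): direction must be "
                f"'over' or 'under', got {self.direction!r}"
            )


@dataclass
class Cohort:
    """A joined patient/DNA-call/RNA-call dataset.

    Invariants enforced at construction: patient ids are unique, every call
    resolves to a patient, gene symbols are normalized, DNA calls are
    deduplicated on (patient, gene, class), and RNA calls are unique per
    (patient, gene).
    """

    patients: list[PatientRecord] = field(default_factory=list)
    dna_calls: list[DnaAlterationCall] = field(default_factory=list)
    rna_calls: list[RnaAlterationCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")
        known = set(ids)
        for call in list(self.dna_calls) + list(self.rna_calls):
            if call.patient_id not in known:
                raise CohortValidationError(
                    f"call references unknown patient_id {call.patient_id!r} "
                    f"(gene {call.gene})"
                )
        seen_dna = set()
        deduped_dna = []
        for c in self.dna_calls:
            key = (c.patient_id, c.gene, c.alteration_class)
            if key not in seen_dna:
                seen_dna.add(key)
                deduped_dna.append(c)
        self.dna_calls = deduped_dna
        seen_rna = set()
        deduped_rna = []
        for c in self.rna_calls:
            key = (c.patient_id, c.gene)
            if key in seen_rna:
                logger.warning(
                    "duplicate RNA call for (%s, %s); keeping first", *key
                )
                continue
            seen_rna.add(key)
            deduped_rna.append(c)
        self.rna_calls = deduped_rna

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def dna_genes_by_patient(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {p.patient_id: set() for p in self.patients}
        for c in self.dna_calls:
            out[c.patient_id].add(c.gene)
        return out

    def rna_genes_by_patient(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {p.patient_id: set() for p in self.patients}
        for c in self.rna_calls:
            out[c.patient_id].add(c.gene)
        return out

    def unique_dna_genes(self) -> set[str]:
        return {c.gene for c in self.dna_calls}

    def unique_rna_genes(self) -> set[str]:
        return {c.gene for c in self.rna_calls}


# ---------------------------------------------------------------------------
# Parsing helpers


_MISSING = {"", "na", "nan", "none"}


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).strip().lower() in _MISSING


def _parse_bool(v, where: str) -> bool:
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise CohortValidationError(f"{where}: cannot parse boolean from {v!r}")


def _parse_float(v, where: str) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        raise CohortValidationError(f"{where}: cannot parse number from {v!r}") from None


def _parse_int(v, where: str) -> int:
    f = _parse_float(v, where)
    if f != int(f):
        raise CohortValidationError(f"{where}: expected integer, got {v!r}")
    return int(f)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{list(required)}"
        )
    return df


def read_cohort(
    patients_path: str | Path,
    dna_path: str | Path,
    rna_path: str | Path,
    alias_map: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read and validate a cohort from three TSV files.

    Rows are validated with file/row-addressed diagnostics; duplicate
    (patient, gene) RNA rows are collapsed with a logged warning.
    """
    pdf = _read_tsv(patients_path, PATIENT_COLUMNS)
    ddf = _read_tsv(dna_path, DNA_COLUMNS)
    rdf = _read_tsv(rna_path, RNA_COLUMNS)

    patients = []
    for i, row in pdf.iterrows():
        where = f"{patients_path} row {i + 2}"
        patients.append(
            PatientRecord(
                patient_id=str(row["patient_id"]).strip(),
                tumor_type=str(row["tumor_type"]).strip(),
                age_years=_parse_float(row["age_years"], where),
                sex=str(row["sex"]).strip().lower(),
                n_prior_therapies=_parse_int(row["n_prior_therapies"], where),
                ecog=_parse_int(row["ecog"], where),
                n_metastatic_sites=_parse_int(row["n_metastatic_sites"], where),
                albumin_low=_parse_bool(row["albumin_low"], where),
                ldh_high=None
                if _is_missing(row["ldh_high"])
                else _parse_bool(row["ldh_high"], where),
                tumor_purity=None
                if _is_missing(row["tumor_purity"])
                else _parse_float(row["tumor_purity"], where),
                pdl1_status=str(row["pdl1_status"]).strip().lower(),
                treated=_parse_bool(row["treated"], where),
                os_months=_parse_float(row["os_months"], where),
                os_event=_parse_bool(row["os_event"], where),
            )
        )

    dna_calls = []
    for i, row in ddf.iterrows():
        where = f"{dna_path} row {i + 2}"
        try:
            gene = normalize_gene_symbol(row["gene"], alias_map)
        except CohortValidationError as e:
            raise CohortValidationError(f"{where}: {e}") from None
        dna_calls.append(
            DnaAlterationCall(
                patient_id=str(row["patient_id"]).strip(),
                gene=gene,
                alteration_class=str(row["alteration_class"]).strip(),
                copy_number=None
                if _is_missing(row["copy_number"])
                else _parse_float(row["copy_number"], where),
            )
        )

    rna_calls = []
    for i, row in rdf.iterrows():
        where = f"{rna_path} row {i + 2}"
        try:
            gene = normalize_gene_symbol(row["gene"], alias_map)
        except CohortValidationError as e:
            raise CohortValidationError(f"{where}: {e}") from None
        rna_calls.append(
            RnaAlterationCall(
                patient_id=str(row["patient_id"]).strip(),
                gene=gene,
                direction=str(row["direction"]).strip().lower(),
                expression_score=None
                if _is_missing(row["expression_score"])
                else _parse_float(row["expression_score"], where),
            )
        )

    return Cohort(patients=patients, dna_calls=dna_calls, rna_calls=rna_calls)


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and float(v).is_integer():
        return str(int(v))
    return str(v)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write patients.tsv / dna_calls.tsv / rna_calls.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.tsv",
        "dna_calls": out / "dna_calls.tsv",
        "rna_calls": out / "rna_calls.tsv",
    }
    with open(paths["patients"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(PATIENT_COLUMNS) + "\n")
        for p in cohort.patients:
            fh.write(
                "\t".join(
                    _fmt(getattr(p, col)) for col in PATIENT_COLUMNS
                )
                + "\n"
            )
    with open(paths["dna_calls"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(DNA_COLUMNS) + "\n")
        for c in cohort.dna_calls:
            fh.write(
                f"{c.patient_id}\t{c.gene}\t{c.alteration_class}\t"
                f"{_fmt(c.copy_number)}\n"
            )
    with open(paths["rna_calls"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(RNA_COLUMNS) + "\n")
        for c in cohort.rna_calls:
            fh.write(
                f"{c.patient_id}\t{c.gene}\t{c.direction}\t"
                f"{_fmt(c.expression_score)}\n"
            )
    return paths


def cohort_summary(cohort: Cohort) -> dict:
    """Summaries of a cohort's alteration landscape.

    Per-patient alteration counts count *distinct genes* per assay (a gene
    with both an amplification and a missense call in one patient counts
    once); class/direction mixtures are over call records.
    """
    dna_by_pt = cohort.dna_genes_by_patient()
    rna_by_pt = cohort.rna_genes_by_patient()
    dna_counts = pd.Series(
        {pid: len(g) for pid, g in dna_by_pt.items()}, dtype=float
    )
    rna_counts = pd.Series(
        {pid: len(g) for pid, g in rna_by_pt.items()}, dtype=float
    )

    def _dist(s: pd.Series) -> dict:
        if s.empty:
            return {"median": 0.0, "min": 0, "max": 0, "mean": 0.0}
        return {
            "median": float(s.median()),
            "min": int(s.min()),
            "max": int(s.max()),
            "mean": float(s.mean()),
        }

    class_counts = pd.Series(
        [c.alteration_class for c in cohort.dna_calls], dtype=object
    ).value_counts()
    direction_counts = pd.Series(
        [c.direction for c in cohort.rna_calls], dtype=object
    ).value_counts()
    n_dna = int(class_counts.sum()) if len(class_counts) else 0
    n_rna = int(direction_counts.sum()) if len(direction_counts) else 0
    return {
        "n_patients": len(cohort.patients),
        "n_dna_calls": len(cohort.dna_calls),
        "n_rna_calls": len(cohort.rna_calls),
        "unique_dna_genes": len(cohort.unique_dna_genes()),
        "unique_rna_genes": len(cohort.unique_rna_genes()),
        "dna_genes_per_patient": _dist(dna_counts),
        "rna_genes_per_patient": _dist(rna_counts),
        "dna_class_percent": {
            k: 100.0 * v / n_dna for k, v in class_counts.items()
        },
        "rna_direction_percent": {
            k: 100.0 * v / n_rna for k, v in direction_counts.items()
        },
    }
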