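"""Reading, validating and filtering somatic-mutation and clinical tables.

The package consumes annotated variant calls in a MAF-like tab-separated
layout (one row per variant per sample) plus a clinical table with follow-up
time in months and an event indicator.  Upstream steps — alignment, variant
calling, functional annotation — are out of scope: rows arriving here are
assumed to be annotated calls.

Variant-level filtering reproduces the standard clean-up applied to targeted
panel calls before burden or signature analysis: intronic calls, common
population polymorphisms (1000 Genomes AF and dbSNP-common), synonymous
variants, and calls with weak read support are removed.  Copy-number and
fusion events are excluded at the cohort level because a presence/absence
gene-mutation model is only defined over small variants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Canonical variant-classification vocabulary.  Anything a dialect cannot map
# lands in "other" (kept by default: it is not demonstrably synonymous).
CLASSIFICATIONS = (
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice",
    "silent",
    "intron",
    "cnv",
    "fusion",
    "other",
)

NONSYNONYMOUS = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice"}
)

VARIANT_TYPES = ("SNV", "insertion", "deletion", "other")

# Single built-in symbol alias: "BRAC2" circulates in some DDR gene lists as a
# typo for BRCA2; resolving it keeps the DDR comparator rule consistent.
GENE_ALIASES = {"BRAC2": "BRCA2"}

#: Classification mapping for standard MAF Variant_Classification values.
MAF_CLASSIFICATION_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Silent": "silent",
    "Intron": "intron",
    "CNV": "cnv",
    "Fusion": "fusion",
}

MAF_VARIANT_TYPE_MAP = {
    "SNP": "SNV",
    "SNV": "SNV",
    "INS": "insertion",
    "DEL": "deletion",
}


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One annotated somatic variant call in one sample."""

    sample_id: str
    gene: str
    variant_classification: str = "other"
    variant_type: str = "other"
    supporting_reads: int | None = None
    population_af: float | None = None
    dbsnp_common_flag: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_id", self.sample_id.strip())
        gene = self.gene.strip().upper()
        object.__setattr__(self, "gene", GENE_ALIASES.get(gene, gene))
        if not self.sample_id:
            raise ValueError("sample_id is empty after trimming")
        if not self.gene:
            raise ValueError("gene symbol is empty after trimming")
        if self.variant_classification not in CLASSIFICATIONS:
            object.__setattr__(self, "variant_classification", "other")
        if self.variant_type not in VARIANT_TYPES:
            object.__setattr__(self, "variant_type", "other")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population_af {self.population_af} outside [0, 1]")
        if self.supporting_reads is not None and self.supporting_reads < 0:
            raise ValueError("supporting_reads must be nonnegative")


@dataclass(frozen=True, slots=True)
class ClinicalRecord:
    """Follow-up for one sample: time in months, event indicator, covariates."""

    sample_id: str
    time_months: float
    event: int
    endpoint: str = "OS"
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_id", self.sample_id.strip())
        if not self.sample_id:
            raise ValueError("sample_id is empty after trimming")
        if self.time_months < 0:
            raise ValueError(f"time_months {self.time_months} is negative")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")
        if self.endpoint not in ("OS", "PFS"):
            raise ValueError(f"endpoint must be OS or PFS, got {self.endpoint!r}")


@dataclass
class Cohort:
    """Mutation and clinical records for one patient cohort.

    ``sample_ids`` is the ordered sample universe; every clinical record must
    reference a known sample.  Mutation records for unknown samples are
    rejected (``strict=True``) or dropped with a log line.
    """

    mutations: list[MutationRecord]
    clinical: list[ClinicalRecord]
    sample_ids: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sample_ids:
            seen: dict[str, None] = {}
            for rec in self.clinical:
                seen.setdefault(rec.sample_id, None)
            for rec in self.mutations:
                seen.setdefault(rec.sample_id, None)
            self.sample_ids = list(seen)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids in cohort")
        known = set(self.sample_ids)
        missing = {r.sample_id for r in self.clinical} - known
        if missing:
            raise ValueError(f"clinical records for unknown samples: {sorted(missing)}")
        orphans = {r.sample_id for r in self.mutations} - known
        if orphans:
            raise ValueError(f"mutation records for unknown samples: {sorted(orphans)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical records as a DataFrame indexed by sample_id."""
        rows = []
        for rec in self.clinical:
            row = {
                "sample_id": rec.sample_id,
                "time_months": rec.time_months,
                "event": rec.event,
                "endpoint": rec.endpoint,
            }
            row.update(rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class FilterConfig:
    """Switches and thresholds for the variant-level filter rules."""

    drop_cnv_fusion: bool = True
    drop_intronic: bool = True
    max_population_af: float = 0.01
    drop_dbsnp_common: bool = True
    drop_silent: bool = True
    min_supporting_reads: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_population_af <= 1.0:
            raise ValueError("max_population_af must be in [0, 1]")
        if self.min_supporting_reads < 0:
            raise ValueError("min_supporting_reads must be nonnegative")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "FilterConfig":
        return cls(**dict(d))


@dataclass
class FilterReport:
    """Accounting of a filter pass: every input record is attributed to the
    first rule that removed it, or retained."""

    input_count: int
    retained_count: int
    removals: dict[str, int]
    skipped_rules: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        total = self.retained_count + sum(self.removals.values())
        if total != self.input_count:
            raise AssertionError(
                f"filter report does not conserve records: "
                f"{self.retained_count} + {sum(self.removals.values())} != {self.input_count}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Dialects


@dataclass(frozen=True)
class TableDialect:
    """Column mapping from an on-disk table to MutationRecord fields.

    ``classification_map`` translates the file's variant-classification
    vocabulary to the canonical one; unmapped values become "other".
    """

    sample_col: str
    gene_col: str
    classification_col: str
    variant_type_col: str | None = None
    supporting_reads_col: str | None = None
    population_af_col: str | None = None
    dbsnp_common_col: str | None = None
    classification_map: Mapping[str, str] = field(default_factory=dict)
    variant_type_map: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def maf(cls) -> "TableDialect":
        """Dialect for standard MAF headers (cBioPortal-style exports)."""
        return cls(
            sample_col="Tumor_Sample_Barcode",
            gene_col="Hugo_Symbol",
            classification_col="Variant_Classification",
            variant_type_col="Variant_Type",
            supporting_reads_col="t_alt_count",
            population_af_col="AF",
            dbsnp_common_col="dbSNP_Common",
            classification_map=MAF_CLASSIFICATION_MAP,
            variant_type_map=MAF_VARIANT_TYPE_MAP,
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "TableDialect":
        return cls(**dict(d))


def _parse_bool(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "."):
        return None
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ValueError(f"cannot parse boolean flag {value!r}")


def read_mutation_table(
    path: str | Path, dialect: TableDialect | None = None, sep: str = "\t"
) -> list[MutationRecord]:
    """Read a MAF-like table into MutationRecords, one per row.

    Mandatory columns (sample, gene, classification) missing from the header
    raise a ValueError naming the column.  An empty file yields an empty list
    with a warning.
    """
    dialect = dialect or TableDialect.maf()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("mutation table %s is empty", path)
        return []
    if df.empty:
        logger.warning("mutation table %s is empty", path)
        return []
    for col in (dialect.sample_col, dialect.gene_col, dialect.classification_col):
        if col not in df.columns:
            raise ValueError(f"mutation table {path} is missing mandatory column {col!r}")

    records: list[MutationRecord] = []
    for _, row in df.iterrows():
        raw_cls = str(row[dialect.classification_col]).strip()
        cls = dialect.classification_map.get(raw_cls, raw_cls if raw_cls in CLASSIFICATIONS else "other")
        vt = "other"
        if dialect.variant_type_col and dialect.variant_type_col in df.columns:
            raw_vt = str(row[dialect.variant_type_col]).strip()
            vt = dialect.variant_type_map.get(raw_vt, raw_vt if raw_vt in VARIANT_TYPES else "other")
        reads = None
        if dialect.supporting_reads_col and dialect.supporting_reads_col in df.columns:
            v = row[dialect.supporting_reads_col]
            if pd.notna(v) and str(v).strip() not in ("", "NA", "."):
                reads = int(float(v))
        af = None
        if dialect.population_af_col and dialect.population_af_col in df.columns:
            v = row[dialect.population_af_col]
            if pd.notna(v) and str(v).strip() not in ("", "NA", "."):
                af = float(v)
        flag = None
        if dialect.dbsnp_common_col and dialect.dbsnp_common_col in df.columns:
            flag = _parse_bool(row[dialect.dbsnp_common_col])
        records.append(
            MutationRecord(
                sample_id=str(row[dialect.sample_col]),
                gene=str(row[dialect.gene_col]),
                variant_classification=cls,
                variant_type=vt,
                supporting_reads=reads,
                population_af=af,
                dbsnp_common_flag=flag,
            )
        )
    return records


def write_mutation_table(
    records: Iterable[MutationRecord], path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write records in the dialect's column layout (inverse of the reader)."""
    dialect = dialect or TableDialect.maf()
    inv_cls = {v: k for k, v in dialect.classification_map.items()}
    inv_vt = {v: k for k, v in dialect.variant_type_map.items()}
    rows = []
    for rec in records:
        row = {
            dialect.sample_col: rec.sample_id,
            dialect.gene_col: rec.gene,
            dialect.classification_col: inv_cls.get(
                rec.variant_classification, rec.variant_classification
            ),
        }
        if dialect.variant_type_col:
            row[dialect.variant_type_col] = inv_vt.get(rec.variant_type, rec.variant_type)
        if dialect.supporting_reads_col:
            row[dialect.supporting_reads_col] = rec.supporting_reads
        if dialect.population_af_col:
            row[dialect.population_af_col] = rec.population_af
        if dialect.dbsnp_common_col:
            row[dialect.dbsnp_common_col] = rec.dbsnp_common_flag
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table


_EVENT_TOKENS = {
    "1": 1, "0": 0, "dead": 1, "deceased": 1, "alive": 0,
    "true": 1, "false": 0, "yes": 1, "no": 0, "event": 1, "censored": 0,
}


def read_clinical_table(
    path: str | Path,
    sample_col: str = "sample_id",
    time_col: str = "time_months",
    event_col: str = "event",
    endpoint: str = "OS",
    covariate_cols: Sequence[str] | None = None,
    sep: str = "\t",
) -> list[ClinicalRecord]:
    """Read a clinical table; time must parse as a nonnegative number and the
    event column as one of {0/1, dead/alive, TRUE/FALSE}.  Unparseable rows
    produce a hard error listing their (0-based) row indices.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} is missing mandatory column {col!r}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (sample_col, time_col, event_col)]

    records, bad_rows = [], []
    for i, row in df.iterrows():
        try:
            time = float(row[time_col])
            if not np.isfinite(time):
                raise ValueError("non-finite time")
            ev = _EVENT_TOKENS[str(row[event_col]).strip().lower()]
            covs = {c: row[c] for c in covariate_cols if pd.notna(row[c])}
            records.append(
                ClinicalRecord(
                    sample_id=str(row[sample_col]),
                    time_months=time,
                    event=ev,
                    endpoint=endpoint,
                    covariates=covs,
                )
            )
        except (ValueError, KeyError):
            bad_rows.append(int(i))
    if bad_rows:
        raise ValueError(
            f"clinical table {path}: unparseable time/event in rows {bad_rows}"
        )
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "sample_id": rec.sample_id,
            "time_months": rec.time_months,
            "event": rec.event,
            "endpoint": rec.endpoint,
        }
        row.update(rec.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant filtering

#: Rule order is fixed so that report attribution is deterministic: each
#: removed record is counted under the first rule that rejects it.
FILTER_RULE_ORDER = (
    "cnv_fusion",
    "intron",
    "population_af",
    "dbsnp_common",
    "silent",
    "read_support",
)


def apply_variant_filters(
    records: Sequence[MutationRecord], cfg: FilterConfig | None = None
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the variant-level filter rules in fixed order.

    Rules relying on an optional field (population_af, dbsnp_common_flag,
    supporting_reads) pass records where the field is missing (fail-open);
    each such skip is logged once per field.
    """
    cfg = cfg or FilterConfig()
    removals = {rule: 0 for rule in FILTER_RULE_ORDER}
    skipped: set[str] = set()
    retained: list[MutationRecord] = []

    for rec in records:
        if cfg.drop_cnv_fusion and rec.variant_classification in ("cnv", "fusion"):
            removals["cnv_fusion"] += 1
            continue
        if cfg.drop_intronic and rec.variant_classification == "intron":
            removals["intron"] += 1
            continue
        if rec.population_af is None:
            skipped.add("population_af")
        elif rec.population_af > cfg.max_population_af:
            removals["population_af"] += 1
            continue
        if rec.dbsnp_common_flag is None:
            skipped.add("dbsnp_common")
        elif cfg.drop_dbsnp_common and rec.dbsnp_common_flag:
            removals["dbsnp_common"] += 1
            continue
        if cfg.drop_silent and rec.variant_classification == "silent":
            removals["silent"] += 1
            continue
        if rec.supporting_reads is None:
            skipped.add("read_support")
        elif rec.supporting_reads < cfg.min_supporting_reads:
            removals["read_support"] += 1
            continue
        retained.append(rec)

    for rule in sorted(skipped):
        logger.info("filter rule %s skipped for records lacking the field", rule)
    report = FilterReport(
        input_count=len(records),
        retained_count=len(retained),
        removals={k: v for k, v in removals.items() if v},
        skipped_rules=sorted(skipped),
    )
    report.check_conservation()
    return retained, report


def assemble_cohort(
    mutations: Sequence[MutationRecord],
    clinical: Sequence[ClinicalRecord],
    filter_cfg: FilterConfig | None = None,
    provenance: str = "",
) -> tuple[Cohort, FilterReport]:
    """Filter variants and assemble a validated Cohort.

    The sample universe is taken from the clinical table; mutation records for
    samples without clinical follow-up are dropped with a log line (they
    cannot enter survival analysis).
    """
    retained, report = apply_variant_filters(mutations, filter_cfg)
    known = {rec.sample_id for rec in clinical}
    kept = [r for r in retained if r.sample_id in known]
    n_orphan = len(retained) - len(kept)
    if n_orphan:
        logger.info("dropped %d mutation records without clinical follow-up", n_orphan)
    cohort = Cohort(
        mutations=kept,
        clinical=list(clinical),
        sample_ids=[rec.sample_id for rec in clinical],
        provenance=provenance or f"assembled; filter report: {report.removals}",
    )
    return cohort, report
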