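"""Binary mutation matrix construction, gene-prevalence filtering and TMB.

The count-threshold model operates on gene mutation *status*, so the variant
table is collapsed to a samples x genes 0/1 matrix: entry 1 iff the sample
carries at least one retained nonsynonymous variant in that gene.  Tumor
mutational burden (TMB) keeps multiplicity: it is the count of retained
nonsynonymous SNVs and indels per megabase of sequenced territory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import Cohort

logger = logging.getLogger(__name__)


@dataclass
class BinaryMutationMatrix:
    """Samples x genes presence/absence matrix backed by a pandas DataFrame.

    ``df`` has sample IDs as index, gene symbols as columns, int8 {0,1}
    entries.  Labels are unique in both dimensions.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample labels in mutation matrix")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate gene labels in mutation matrix")
        vals = self.df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0 or 1")
        self.df = self.df.astype(np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genes(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "BinaryMutationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


def build_binary_matrix(cohort: Cohort) -> BinaryMutationMatrix:
    """Collapse retained variant records to per-sample gene mutation status.

    Samples with zero retained mutations keep an all-zero row; they remain
    part of the cohort and of every downstream group.
    """
    if not cohort.sample_ids:
        raise ValueError("cannot build a mutation matrix from an empty cohort")
    genes = sorted({rec.gene for rec in cohort.mutations})
    df = pd.DataFrame(
        np.zeros((len(cohort.sample_ids), len(genes)), dtype=np.int8),
        index=pd.Index(cohort.sample_ids, name="sample_id"),
        columns=genes,
    )
    if cohort.mutations:
        sample_pos = {s: i for i, s in enumerate(cohort.sample_ids)}
        gene_pos = {g: j for j, g in enumerate(genes)}
        arr = df.to_numpy()
        for rec in cohort.mutations:
            arr[sample_pos[rec.sample_id], gene_pos[rec.gene]] = 1
        df.iloc[:, :] = arr
    return BinaryMutationMatrix(df)


def prevalence_filter(
    matrix: BinaryMutationMatrix, min_samples: int = 3
) -> BinaryMutationMatrix:
    """Keep genes mutated in at least ``min_samples`` samples (inclusive).

    Rarely recurrent genes carry no usable signal for a cohort-level model
    and inflate the feature space; the default requires recurrence in three
    samples.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts = matrix.df.sum(axis=0)
    keep = counts[counts >= min_samples].index
    if len(keep) == 0:
        raise ValueError(
            f"prevalence filter at min_samples={min_samples} removed every gene; "
            "lower min_samples"
        )
    dropped = matrix.shape[1] - len(keep)
    if dropped:
        logger.info("prevalence filter dropped %d/%d genes", dropped, matrix.shape[1])
    return BinaryMutationMatrix(matrix.df[list(keep)])


@dataclass(frozen=True)
class TmbResult:
    """Per-sample tumor mutational burden and the high/low grouping."""

    sample_id: str
    mutation_count: int
    panel_size_mb: float
    tmb: float
    group: str  # "TMB_H" | "TMB_L"


#: Variant types entering the TMB numerator (nonsynonymous SNVs + indels).
_TMB_TYPES = frozenset({"SNV", "insertion", "deletion"})


def compute_tmb(
    cohort: Cohort, panel_size_mb: float, cutoff: float = 10.0
) -> list[TmbResult]:
    """TMB = retained nonsynonymous SNV+indel count / megabases sequenced.

    ``panel_size_mb`` is the sequenced territory of the assay (around 1.14 Mb
    for large targeted panels, 30-38 Mb for exomes) and must be supplied by
    the caller.  TMB-high is the inclusive ``tmb >= cutoff`` (default 10
    mutations/Mb).  Assumes synonymous variants were already filtered out.
    """
    if panel_size_mb <= 0:
        raise ValueError("panel_size_mb must be positive")
    counts = {s: 0 for s in cohort.sample_ids}
    for rec in cohort.mutations:
        if rec.variant_type in _TMB_TYPES:
            counts[rec.sample_id] += 1
    results = []
    for sample_id in cohort.sample_ids:
        tmb = counts[sample_id] / panel_size_mb
        results.append(
            TmbResult(
                sample_id=sample_id,
                mutation_count=counts[sample_id],
                panel_size_mb=panel_size_mb,
                tmb=tmb,
                group="TMB_H" if tmb >= cutoff else "TMB_L",
            )
        )
    return results


def tmb_frame(results: list[TmbResult]) -> pd.DataFrame:
    """TMB results as a DataFrame indexed by sample_id."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "mutation_count": r.mutation_count,
                "tmb": r.tmb,
                "group": r.group,
            }
            for r in results
        ]
    ).set_index("sample_id")
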