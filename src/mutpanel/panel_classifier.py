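"""Count-threshold MT/WT calling and rule-based comparator biomarkers.

The panel model is deliberately simple: count how many of the panel's genes
carry a somatic mutation in a sample; at or above the threshold ``k`` the
sample is MT (mutant, predicted to benefit from checkpoint blockade), below
it WT.  Comparator biomarkers from the literature have the same shape —
"at least m mutated genes among a fixed set" — and are expressed as
:class:`GeneSetRule` so the panel rule and the comparators share one code
path for evaluation.

Bundled default: an 18-gene NSCLC panel with k = 2 (see
``_assets/panel_18gene.json``), plus the KEAP1-driven co-mutation rule
(>=2 of KEAP1/STK11/PBRM1/SMARCA4) and the 5-gene DDR rule
(>=1 of MSH2/MSH6/PMS2/POLE/BRCA2).  An APOBEC gene-status rule has no
agreed gene list and therefore no default: callers must supply the genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .mutation_features import BinaryMutationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelModel:
    """A gene panel plus the mutant-count threshold ``k``."""

    genes: tuple[str, ...]
    threshold_k: int = 2
    name: str = "panel"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if not self.genes:
            raise ValueError("panel must contain at least one gene")
        if self.threshold_k < 1:
            raise ValueError("threshold_k must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "genes": list(self.genes), "threshold_k": self.threshold_k},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PanelModel":
        d = json.loads(text)
        return cls(
            genes=tuple(d["genes"]),
            threshold_k=int(d.get("threshold_k", 2)),
            name=d.get("name", "panel"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelModel":
        return cls.from_json(Path(path).read_text())


def default_panel() -> PanelModel:
    """The bundled 18-gene NSCLC immunotherapy panel with k = 2."""
    text = resources.files("mutpanel._assets").joinpath("panel_18gene.json").read_text()
    return PanelModel.from_json(text)


@dataclass(frozen=True)
class GeneSetRule:
    """Binary biomarker: positive iff >= ``min_mutated`` genes of a fixed set
    are mutated."""

    name: str
    genes: frozenset[str]
    min_mutated: int = 1
    positive_label: str = "+"
    negative_label: str = "-"

    def __post_init__(self) -> None:
        if self.min_mutated < 1 or self.min_mutated > len(self.genes):
            raise ValueError("min_mutated must be in [1, |genes|]")


def keap1_comutation_rule() -> GeneSetRule:
    """KEAP1-driven co-mutation: >=2 mutated among KEAP1, STK11, PBRM1, SMARCA4."""
    return GeneSetRule(
        name="KEAP1_comutation",
        genes=frozenset({"KEAP1", "STK11", "PBRM1", "SMARCA4"}),
        min_mutated=2,
        positive_label="CO+",
        negative_label="CO-",
    )


def ddr_rule() -> GeneSetRule:
    """DDR pathway signature: >=1 mutated among MSH2, MSH6, PMS2, POLE, BRCA2."""
    return GeneSetRule(
        name="DDR",
        genes=frozenset({"MSH2", "MSH6", "PMS2", "POLE", "BRCA2"}),
        min_mutated=1,
        positive_label="DDR+",
        negative_label="DDR-",
    )


def apobec_rule(genes: frozenset[str] | set[str] | None = None) -> GeneSetRule:
    """APOBEC gene-mutation-status rule: >=1 mutated among a user-supplied set.

    There is no consensus gene list for "APOBEC-related gene mutation", so no
    default is shipped; calling this without genes is an error.
    """
    if not genes:
        raise ValueError(
            "the APOBEC gene-status rule requires an explicit gene list; "
            "no default is defined"
        )
    return GeneSetRule(
        name="APOBEC",
        genes=frozenset(genes),
        min_mutated=1,
        positive_label="APOBEC+",
        negative_label="APOBEC-",
    )


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    panel_count: int
    group: str  # "MT" | "WT"
    comparator_calls: tuple[tuple[str, str], ...] = ()


# ---------------------------------------------------------------------------


def _missing_panel_genes(matrix: BinaryMutationMatrix, genes) -> list[str]:
    return [g for g in genes if g not in matrix.df.columns]


def count_panel_mutations(
    matrix: BinaryMutationMatrix, panel: PanelModel, sample_id: str
) -> int:
    """Number of panel genes mutated in the sample.

    Panel genes absent from the matrix count as unmutated: from
    presence/absence input alone, "not assayed" is indistinguishable from
    wild-type.  Missing genes are logged once per call site.
    """
    if sample_id not in matrix.df.index:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    missing = _missing_panel_genes(matrix, panel.genes)
    if missing:
        logger.warning("panel genes absent from matrix, treated as unmutated: %s", missing)
    present = [g for g in panel.genes if g not in missing]
    return int(matrix.df.loc[sample_id, present].sum()) if present else 0


def classify_mt_wt(count: int, panel: PanelModel) -> str:
    """MT iff the panel mutant-gene count reaches the threshold ``k``."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    return "MT" if count >= panel.threshold_k else "WT"


def evaluate_gene_set_rule(
    matrix: BinaryMutationMatrix, rule: GeneSetRule, sample_id: str
) -> str:
    """Positive label iff >= min_mutated of the rule's genes are mutated."""
    if sample_id not in matrix.df.index:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    present = [g for g in sorted(rule.genes) if g in matrix.df.columns]
    count = int(matrix.df.loc[sample_id, present].sum()) if present else 0
    return rule.positive_label if count >= rule.min_mutated else rule.negative_label


def classify_cohort(
    matrix: BinaryMutationMatrix,
    panel: PanelModel,
    rules: list[GeneSetRule] | None = None,
) -> pd.DataFrame:
    """Vectorized MT/WT + comparator calls for every sample in the matrix.

    Returns a DataFrame indexed by sample_id with columns ``panel_count``,
    ``group`` and one column per comparator rule.
    """
    rules = rules or []
    missing = _missing_panel_genes(matrix, panel.genes)
    if missing:
        logger.warning("panel genes absent from matrix, treated as unmutated: %s", missing)
    present = [g for g in panel.genes if g not in missing]
    counts = (
        matrix.df[present].sum(axis=1).astype(int)
        if present
        else pd.Series(0, index=matrix.df.index)
    )
    out = pd.DataFrame(
        {
            "panel_count": counts,
            "group": (counts >= panel.threshold_k).map({True: "MT", False: "WT"}),
        }
    )
    for rule in rules:
        rp = [g for g in sorted(rule.genes) if g in matrix.df.columns]
        rc = matrix.df[rp].sum(axis=1) if rp else pd.Series(0, index=matrix.df.index)
        out[rule.name] = (rc >= rule.min_mutated).map(
            {True: rule.positive_label, False: rule.negative_label}
        )
    out.index.name = "sample_id"
    return out


def stratify_by_count(
    matrix: BinaryMutationMatrix, panel: PanelModel
) -> dict[int, list[str]]:
    """Partition samples into mutant-count strata 0, 1, 2, ... max observed."""
    calls = classify_cohort(matrix, panel)
    max_count = int(calls["panel_count"].max()) if len(calls) else 0
    strata: dict[int, list[str]] = {c: [] for c in range(max_count + 1)}
    for sample_id, count in calls["panel_count"].items():
        strata[int(count)].append(sample_id)
    return strata
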