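"""Per-gene feature construction from per-sample omics cohorts.

For each cancer type the cohort carries three channels per gene: a
mutation indicator (or frequency) per tumor sample, paired tumor/normal
methylation beta values, and paired tumor/normal expression. Each channel
collapses to one per-gene summary per cancer type:

* mutation rate — mean indicator/frequency over samples,
* differential methylation — mean of (beta_tumor − beta_normal) over
  matched pairs,
* differential expression — mean log2(tumor/normal) over matched pairs.

With C cancer types this yields a 3·C-column biological block (48 columns
for the 16-type pan-cancer setting); an optional 10-column block of
system-level (SYS) gene properties is appended, giving the 58-column
pre-enhancement matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureMatrix, GeneGraph

logger = logging.getLogger("mdignn")

__all__ = [
    "OmicsCohort",
    "SYS_COLUMNS",
    "mutation_rate",
    "diff_methylation",
    "diff_expression",
    "build_biological_block",
    "attach_sys_block",
    "standardize_features",
]

# Ten system-level gene properties: duplication, essentiality (2),
# expression breadth, network topology (4), complex membership, miRNA load.
SYS_COLUMNS = (
    "ohnolog",
    "essentiality_pct",
    "essential_flag",
    "n_expressing_tissues",
    "degree",
    "hub_flag",
    "betweenness",
    "clustering_coeff",
    "n_complexes",
    "n_mirnas",
)


@dataclass
class OmicsCohort:
    """Paired tumor/normal omics matrices per cancer type.

    Per cancer type ``c`` and gene ``g``:

    * ``mutation[c]`` — DataFrame genes × samples, binary indicators or
      per-sample frequencies in [0, 1];
    * ``methylation_tumor[c]`` / ``methylation_normal[c]`` — genes ×
      matched samples, beta values in [0, 1], identical column order;
    * ``expression_tumor[c]`` / ``expression_normal[c]`` — genes ×
      matched samples, strictly positive (pre-pseudocount is the caller's
      job), identical column order.
    """

    mutation: dict[str, pd.DataFrame] = field(default_factory=dict)
    methylation_tumor: dict[str, pd.DataFrame] = field(default_factory=dict)
    methylation_normal: dict[str, pd.DataFrame] = field(default_factory=dict)
    expression_tumor: dict[str, pd.DataFrame] = field(default_factory=dict)
    expression_normal: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def cancer_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.mutation))

    def validate(self) -> None:
        for c in self.cancer_types:
            for tumor, normal, name in (
                (self.methylation_tumor[c], self.methylation_normal[c], "methylation"),
                (self.expression_tumor[c], self.expression_normal[c], "expression"),
            ):
                if list(tumor.columns) != list(normal.columns):
                    unpaired = set(tumor.columns) ^ set(normal.columns)
                    raise ValueError(
                        f"{name} samples not 1:1 paired in {c}: "
                        f"{sorted(map(str, unpaired))[:5]}"
                    )
            for beta in (self.methylation_tumor[c], self.methylation_normal[c]):
                vals = beta.to_numpy()
                if vals.size and (vals.min() < 0 or vals.max() > 1):
                    raise ValueError(f"methylation betas outside [0,1] in {c}")
            for expr in (self.expression_tumor[c], self.expression_normal[c]):
                if expr.size and expr.to_numpy().min() <= 0:
                    raise ValueError(
                        f"nonpositive expression in {c}; add a pseudocount first"
                    )


def _gene_row(df: pd.DataFrame, gene: str) -> np.ndarray | None:
    if gene in df.index:
        return df.loc[gene].to_numpy(dtype=np.float64)
    return None


def mutation_rate(cohort: OmicsCohort, gene: str, cancer_type: str) -> float:
    """Mean mutation indicator/frequency over the cancer type's samples.

    A gene absent from the cohort scores 0 (zero-fill convention).
    """
    df = cohort.mutation[cancer_type]
    if df.shape[1] < 1:
        raise ValueError(f"no samples for cancer type {cancer_type}")
    row = _gene_row(df, gene)
    if row is None:
        logger.warning("gene %s absent from %s mutation data; rate=0", gene, cancer_type)
        return 0.0
    return float(row.mean())


def diff_methylation(cohort: OmicsCohort, gene: str, cancer_type: str) -> float:
    """Mean tumor−normal beta difference over matched sample pairs."""
    tumor = cohort.methylation_tumor[cancer_type]
    normal = cohort.methylation_normal[cancer_type]
    if list(tumor.columns) != list(normal.columns):
        unpaired = sorted(map(str, set(tumor.columns) ^ set(normal.columns)))
        raise ValueError(f"unpaired methylation sample(s): {unpaired[:5]}")
    t, n = _gene_row(tumor, gene), _gene_row(normal, gene)
    if t is None or n is None:
        logger.warning("gene %s absent from %s methylation; dm=0", gene, cancer_type)
        return 0.0
    return float(np.mean(t - n))


def diff_expression(cohort: OmicsCohort, gene: str, cancer_type: str) -> float:
    """Mean per-pair log2 fold change, tumor over matched normal."""
    tumor = cohort.expression_tumor[cancer_type]
    normal = cohort.expression_normal[cancer_type]
    if list(tumor.columns) != list(normal.columns):
        unpaired = sorted(map(str, set(tumor.columns) ^ set(normal.columns)))
        raise ValueError(f"unpaired expression sample(s): {unpaired[:5]}")
    t, n = _gene_row(tumor, gene), _gene_row(normal, gene)
    if t is None or n is None:
        logger.warning("gene %s absent from %s expression; logFC=0", gene, cancer_type)
        return 0.0
    if (t <= 0).any() or (n <= 0).any():
        raise ValueError(
            f"nonpositive expression for {gene} in {cancer_type}; "
            "add a pseudocount before featurization"
        )
    return float(np.mean(np.log2(t / n)))


def build_biological_block(cohort: OmicsCohort, graph: GeneGraph) -> FeatureMatrix:
    """Assemble the 3·C-column biological block aligned to the graph.

    Column order is deterministic: cancer types sorted, then channels
    (mutation, methylation, expression) within each type. Genes absent
    from the cohort are zero-filled.
    """
    types = cohort.cancer_types
    if not types:
        raise ValueError("cohort has zero cancer types")
    cohort.validate()
    n = graph.n_nodes
    values = np.zeros((n, 3 * len(types)), dtype=np.float64)
    names: list[str] = []
    order = list(graph.nodes)
    for j, c in enumerate(types):
        names += [f"{c}:mutation", f"{c}:methylation", f"{c}:expression"]
        mut = cohort.mutation[c].reindex(order).to_numpy(dtype=np.float64)
        values[:, 3 * j] = np.nan_to_num(mut.mean(axis=1))
        mt = cohort.methylation_tumor[c].reindex(order).to_numpy(dtype=np.float64)
        mn = cohort.methylation_normal[c].reindex(order).to_numpy(dtype=np.float64)
        values[:, 3 * j + 1] = np.nan_to_num((mt - mn).mean(axis=1))
        et = cohort.expression_tumor[c].reindex(order).to_numpy(dtype=np.float64)
        en = cohort.expression_normal[c].reindex(order).to_numpy(dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            values[:, 3 * j + 2] = np.nan_to_num(np.log2(et / en).mean(axis=1))
    return FeatureMatrix(
        values=values,
        gene_order=graph.nodes,
        column_blocks={"biological": (0, 3 * len(types))},
        column_names=tuple(names),
    )


def attach_sys_block(
    features: FeatureMatrix,
    sys_table: pd.DataFrame,
    enabled: bool = True,
) -> FeatureMatrix:
    """Append the 10-column SYS block; with ``enabled=False`` (ablation)
    the biological block passes through unchanged.

    ``sys_table`` is indexed by gene symbol with the :data:`SYS_COLUMNS`
    columns; genes missing from it are zero-filled (count logged), extra
    genes are ignored.
    """
    if not enabled:
        return features
    missing_cols = [c for c in SYS_COLUMNS if c not in sys_table.columns]
    if missing_cols:
        raise ValueError(f"SYS table missing columns: {missing_cols}")
    n = len(features.gene_order)
    sys_values = np.zeros((n, len(SYS_COLUMNS)), dtype=np.float64)
    n_missing = 0
    for i, g in enumerate(features.gene_order):
        if g in sys_table.index:
            sys_values[i] = sys_table.loc[g, list(SYS_COLUMNS)].to_numpy(
                dtype=np.float64
            )
        else:
            n_missing += 1
    if n_missing:
        logger.info("zero-filled SYS rows for %d genes", n_missing)
    f0 = features.n_features
    blocks = dict(features.column_blocks)
    blocks["sys"] = (f0, f0 + len(SYS_COLUMNS))
    names = None
    if features.column_names is not None:
        names = features.column_names + SYS_COLUMNS
    return FeatureMatrix(
        values=np.hstack([features.values, sys_values]),
        gene_order=features.gene_order,
        column_blocks=blocks,
        column_names=names,
    )


def standardize_features(features: FeatureMatrix) -> FeatureMatrix:
    """Z-score every column over all graph nodes (label-free, transductive).

    Constant columns are centred and left at zero variance scale 1 to
    avoid division by zero.
    """
    mu = features.values.mean(axis=0)
    sd = features.values.std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureMatrix(
        values=(features.values - mu) / sd,
        gene_order=features.gene_order,
        column_blocks=dict(features.column_blocks),
        column_names=features.column_names,
    )
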