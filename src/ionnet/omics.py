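"""Human-relevance filtering of the interactor network.

Maps mouse gene symbols to human orthologs, asks which interactors were
detected in a deep human heart proteome, which are expressed in human
cardiomyocyte subpopulations, and summarizes expression correlations across
cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import InteractionNetwork

__all__ = [
    "OrthologMap",
    "map_orthologs",
    "fraction_detected",
    "fraction_expressed",
    "celltype_correlations",
    "summed_expression_per_celltype",
    "cross_species_abundance_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Source-to-target gene symbol mapping with an uppercase fallback.

    Mouse symbols absent from the table fall back to their all-capitals form,
    the convention for mouse-to-human symbol conversion when no curated
    ortholog is available.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    uppercase_fallback: bool = True

    def __post_init__(self) -> None:
        for k, v in self.mapping.items():
            if not k or not v:
                raise ValueError("ortholog map contains empty symbols")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).iloc[:, :2]
        df.columns = ["source", "target"]
        df = df.dropna()
        return cls(dict(zip(df["source"], df["target"])), **kwargs)


def map_orthologs(
    symbols: Sequence[str], ortholog_map: OrthologMap
) -> pd.DataFrame:
    """Map symbols to human orthologs; table lookup, then uppercase fallback.

    Returns a frame indexed by the input symbols with columns ``human`` and
    ``provenance`` ("mapped" or "uppercased").  Idempotent on its own output.
    """
    rows = []
    for s in symbols:
        if s in ortholog_map.mapping:
            rows.append({"symbol": s, "human": ortholog_map.mapping[s], "provenance": "mapped"})
        elif ortholog_map.uppercase_fallback:
            rows.append({"symbol": s, "human": s.upper(), "provenance": "uppercased"})
        else:
            rows.append({"symbol": s, "human": s, "provenance": "unmapped"})
    return pd.DataFrame(rows).set_index("symbol")


def _interactor_nodes(
    network: InteractionNetwork, include_baits: bool
) -> set[str]:
    nodes = set(network.interactors)
    if include_baits:
        nodes |= network.baits
    return nodes


def fraction_detected(
    network: InteractionNetwork,
    human_protein_list: Iterable[str],
    include_baits: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Percent of interactor nodes present in a human proteome list.

    Baits are excluded from numerator and denominator by default.  Returns
    (percent, per-gene decision table).
    """
    nodes = sorted(_interactor_nodes(network, include_baits))
    if not nodes:
        raise ValueError("network has no interactor nodes")
    present = set(human_protein_list)
    table = pd.DataFrame(
        {"detected": [n in present for n in nodes]}, index=nodes
    )
    return 100.0 * table["detected"].mean(), table


def fraction_expressed(
    network: InteractionNetwork,
    expression: pd.DataFrame,
    cm_columns: Sequence[str],
    include_baits: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Percent of interactors with non-zero mean expression in >=1 CM column.

    The test is strictly non-zero ("relative expression value > 0").  Genes
    absent from the matrix count as not expressed and are logged.
    """
    missing_cols = [c for c in cm_columns if c not in expression.columns]
    if missing_cols:
        raise ValueError(f"cardiomyocyte columns absent from matrix: {missing_cols}")
    nodes = sorted(_interactor_nodes(network, include_baits))
    if not nodes:
        raise ValueError("network has no interactor nodes")
    rows = []
    for n in nodes:
        if n not in expression.index:
            log.info("gene %s absent from expression matrix; counted not expressed", n)
            rows.append({"gene": n, "in_matrix": False, "expressed": False})
        else:
            expressed = bool((expression.loc[n, list(cm_columns)] > 0).any())
            rows.append({"gene": n, "in_matrix": True, "expressed": expressed})
    table = pd.DataFrame(rows).set_index("gene")
    return 100.0 * table["expressed"].mean(), table


def celltype_correlations(
    expression: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations of cell-type profiles over a gene subset.

    Zero-variance columns yield NaN for their pairs (logged), diagonal is 1.
    """
    sub = expression if genes is None else expression.loc[list(genes)]
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 genes for correlations")
    corr = sub.corr(method="pearson")
    degenerate = sub.std(ddof=0) == 0
    for c in corr.columns[degenerate]:
        log.info("cell type %s has zero variance over the gene subset", c)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def summed_expression_per_celltype(
    expression: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.Series:
    """Summed mean expression of the gene subset per cell type, descending."""
    sub = expression if genes is None else expression.loc[list(genes)]
    return sub.sum(axis=0).sort_values(ascending=False)


def cross_species_abundance_correlation(
    abund_a: Mapping[str, float] | pd.Series,
    abund_b: Mapping[str, float] | pd.Series,
) -> tuple[float, int]:
    """Pearson r of log-scale protein abundances over the shared genes.

    Returns (r, n shared genes).  Values are used as provided and are
    expected to be on a log scale already.
    """
    a = pd.Series(abund_a, dtype=float)
    b = pd.Series(abund_b, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes (< 3)")
    r = float(np.corrcoef(a[shared], b[shared])[0, 1])
    return r, len(shared)
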