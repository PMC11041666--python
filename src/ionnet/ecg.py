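"""ECG-GWAS annotation of network genes.

Each gene is scored by the single most significant variant x timepoint
association within its linkage-disequilibrium block, against a Bonferroni
cutoff of alpha divided by the number of effectively independent ECG
timepoints (80 for the 500-point averaged ECG cycle) and the number of
proteins tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .network import InteractionNetwork

__all__ = [
    "CorrectionScheme",
    "EcgAssociation",
    "bonferroni_cutoff",
    "min_p_in_block",
    "annotate_network_ecg",
]


@dataclass
class CorrectionScheme:
    """Multiple-testing scheme: alpha / n_independent_ecg_tests / n_proteins."""

    alpha: float = 0.05
    n_independent_ecg_tests: int = 80
    n_proteins: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_independent_ecg_tests <= 0 or self.n_proteins <= 0:
            raise ValueError("test counts must be positive")


@dataclass
class EcgAssociation:
    """Strongest ECG association of one gene within its LD block."""

    gene: str
    best_variant: str
    best_timepoint: int  # 1-based index into the ECG cycle
    min_p: float
    cutoff: float
    significant: bool


def bonferroni_cutoff(scheme: CorrectionScheme) -> float:
    """alpha / (n_independent_ecg_tests * n_proteins), e.g.
    0.05/80/10 = 6.25e-5 for a 10-protein follow-up set."""
    return scheme.alpha / (scheme.n_independent_ecg_tests * scheme.n_proteins)


def min_p_in_block(
    gene: str, table: pd.DataFrame
) -> tuple[str, int, float]:
    """Global minimum p over a gene's variant x timepoint table.

    Ties break deterministically: first by variant (row) order, then by
    timepoint (column) order.  Returns (variant, 1-based timepoint, p).
    """
    if table is None:
        raise ValueError(f"gene {gene!r} has no LD block table")
    if table.size == 0:
        raise ValueError(f"LD block of gene {gene!r} has no variants")
    arr = table.to_numpy(dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError(f"p-values of gene {gene!r} must lie in (0, 1]")
    flat = int(np.argmin(arr))  # argmin takes the first occurrence row-major
    vi, ti = divmod(flat, arr.shape[1])
    return str(table.index[vi]), ti + 1, float(arr[vi, ti])


def annotate_network_ecg(
    network: InteractionNetwork,
    tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    n_independent_ecg_tests: int = 80,
    include_baits: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Annotate every network gene with its strongest ECG association.

    The Bonferroni denominator uses the number of genes actually tested
    (genes with a non-empty LD-block table); genes without tables are
    reported untested and excluded from the summary denominator.  Returns
    (per-gene table, percent significant among tested).
    """
    nodes = set(network.interactors)
    if include_baits:
        nodes |= network.baits
    if not nodes:
        raise ValueError("network has no genes to annotate")
    tested = sorted(n for n in nodes if n in tables and tables[n].size > 0)
    untested = sorted(nodes - set(tested))
    if not tested:
        raise ValueError("no network gene has an LD-block table")
    scheme = CorrectionScheme(alpha, n_independent_ecg_tests, len(tested))
    cutoff = bonferroni_cutoff(scheme)
    rows = []
    for gene in tested:
        variant, timepoint, p = min_p_in_block(gene, tables[gene])
        rows.append(
            {
                "gene": gene,
                "best_variant": variant,
                "best_timepoint": timepoint,
                "min_p": p,
                "cutoff": cutoff,
                "significant": p < cutoff,
                "tested": True,
            }
        )
    for gene in untested:
        rows.append(
            {
                "gene": gene,
                "best_variant": "",
                "best_timepoint": 0,
                "min_p": np.nan,
                "cutoff": cutoff,
                "significant": False,
                "tested": False,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    frac = 100.0 * table.loc[table["tested"], "significant"].mean()
    return table, float(frac)
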