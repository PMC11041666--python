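"""Interaction-network assembly, shared-interactor analysis and ranking.

Baits and their significant interactors form a bipartite-ish graph: every
edge runs from a bait to one of its called interactors, but a channel protein
can itself appear in another channel's pulldown, producing channel-channel
edges whose endpoints both carry the bait role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "InteractorRecord",
    "InteractionNetwork",
    "rank_interactors",
    "shared_interactors",
    "build_combined_network",
    "annotate_known",
    "write_network",
    "read_known_pairs",
]


@dataclass(frozen=True)
class InteractorRecord:
    """Prioritization record for one (bait, interactor) call.

    ``peptide_specificity`` is the peptide count in the bait's own IP minus
    the maximum count observed for the protein in any other IP.
    """

    bait: str
    protein: str
    n_replicates_identified: int
    sequence_coverage: float
    peptide_specificity: int


def rank_interactors(records: Sequence[InteractorRecord]) -> list[InteractorRecord]:
    """Order candidates for follow-up.

    Lexicographic descending on (replicates identified, sequence coverage,
    peptide specificity), with a stable ascending tie-break on protein id so
    the order is deterministic and invariant to input order.
    """
    return sorted(
        records,
        key=lambda r: (
            -r.n_replicates_identified,
            -r.sequence_coverage,
            -r.peptide_specificity,
            r.protein,
        ),
    )


def peptide_specificity(
    peptide_counts: pd.DataFrame, protein: str, bait: str
) -> int:
    """Bait-IP peptide count minus the max count in any other bait's IP."""
    if peptide_counts.shape[1] < 2:
        raise ValueError("peptide specificity needs counts for >=2 baits")
    row = peptide_counts.loc[protein]
    others = row.drop(bait)
    return int(row[bait] - others.max())


@dataclass
class InteractionNetwork:
    """Graph of baits and interactors with per-edge provenance."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def baits(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("role") == "bait"}

    @property
    def interactors(self) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True) if d.get("role") == "interactor"
        }

    def per_bait_sets(self) -> dict[str, set[str]]:
        """Recompute each bait's partner set from the edges."""
        out: dict[str, set[str]] = {b: set() for b in self.baits}
        for u, v, d in self.graph.edges(data=True):
            for b in d.get("baits", []):
                other = v if u == b else u
                out.setdefault(b, set()).add(other)
        return out

    def shared_subsets(self, queries: Iterable[frozenset[str]]) -> dict[frozenset[str], set[str]]:
        sets = self.per_bait_sets()
        return {q: shared_interactors(sets, q) for q in map(frozenset, queries)}


def shared_interactors(
    per_bait_sets: Mapping[str, set[str]], query: Iterable[str]
) -> set[str]:
    """Proteins interacting with every bait in ``query`` (set intersection).

    Bait proteins appearing in another bait's set are retained, so
    channel-channel links survive the intersection.
    """
    query = list(query)
    unknown = [b for b in query if b not in per_bait_sets]
    if unknown:
        raise KeyError(f"unknown baits: {unknown}")
    if not query:
        return set()
    result = set(per_bait_sets[query[0]])
    for b in query[1:]:
        result &= per_bait_sets[b]
    return result


def build_combined_network(
    per_bait_sets: Mapping[str, set[str]]
) -> InteractionNetwork:
    """Union of all bait-interactor edges across pulldowns.

    A node is a bait if it is a key of ``per_bait_sets``; any bait found in
    another bait's significant set yields a channel-channel edge with both
    endpoints in the bait role.
    """
    g = nx.Graph()
    for bait in per_bait_sets:
        g.add_node(bait, role="bait")
    for bait, prots in per_bait_sets.items():
        for p in prots:
            if p == bait:
                continue
            if p not in g:
                g.add_node(p, role="interactor")
            if g.has_edge(bait, p):
                g.edges[bait, p]["baits"] = sorted(
                    set(g.edges[bait, p]["baits"]) | {bait}
                )
            else:
                g.add_edge(bait, p, baits=[bait], known=False)
    return InteractionNetwork(g)


def read_known_pairs(path: str | Path) -> pd.DataFrame:
    """Read a known-interaction table: columns protein_a, protein_b, score."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("known-pair table needs columns protein_a, protein_b, score")
    df = df.iloc[:, :3]
    df.columns = ["protein_a", "protein_b", "score"]
    try:
        df["score"] = df["score"].astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed score column in {path}: {exc}") from exc
    return df


def annotate_known(
    network: InteractionNetwork,
    known_pairs: pd.DataFrame | Sequence[pd.DataFrame],
    min_score: float = 0.4,
) -> InteractionNetwork:
    """Flag edges whose pair appears with score >= min_score in any table.

    Pairs are treated as undirected.  Scores below the cutoff exclude
    low-confidence prior evidence (the conventional 0.4 threshold).
    """
    if isinstance(known_pairs, pd.DataFrame):
        known_pairs = [known_pairs]
    known: set[frozenset[str]] = set()
    for table in known_pairs:
        scores = pd.to_numeric(table["score"], errors="raise")
        keep = table[scores >= min_score]
        known |= {
            frozenset((a, b))
            for a, b in zip(keep["protein_a"], keep["protein_b"])
        }
    for u, v in network.graph.edges:
        network.graph.edges[u, v]["known"] = frozenset((u, v)) in known
    return network


def write_network(
    network: InteractionNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Serialize to GraphML, SIF or a plain edge TSV.

    Node attributes record the role (bait vs interactor); edge attributes
    record the originating bait(s) and the known-interaction flag.
    """
    path = Path(path)
    g = network.graph
    if format == "graphml":
        out = g.copy()
        for u, v, d in out.edges(data=True):
            d["baits"] = ",".join(d.get("baits", []))
        nx.write_graphml(out, path)
    elif format == "sif":
        with path.open("w") as fh:
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\tinteracts\t{v}\n")
            for n in sorted(nx.isolates(g)):
                fh.write(f"{n}\n")
    elif format == "edge_tsv":
        rows = [
            {
                "bait": ",".join(d.get("baits", [])),
                "node_a": u,
                "node_b": v,
                "role_a": g.nodes[u].get("role", ""),
                "role_b": g.nodes[v].get("role", ""),
                "known": d.get("known", False),
            }
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(
            rows, columns=["bait", "node_a", "node_b", "role_a", "role_b", "known"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    for u, v, d in g.edges(data=True):
        if isinstance(d.get("baits"), str):
            d["baits"] = [b for b in d["baits"].split(",") if b]
    return InteractionNetwork(g)
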