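"""Gene-ontology facet tallies and interaction-network summaries.

Descriptive summaries of the identified carbonylated-protein list: the
percentage of proteins carrying each term of an annotation facet (cellular
component, molecular function, protein class, biological process), and
structural summaries of a protein–protein interaction network (node/edge
counts after confidence filtering, degrees, connected components).

Annotations and edges are read from packaged TSV fixtures rather than live
database queries: PANTHER/STRING contents drift between releases, so live
results are not reproducible.  The shipped fixtures are synthetic —
constructed to the published aggregate proportions, not retrieved
per-protein assignments — and say so in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import pandas as pd

__all__ = [
    "FACETS",
    "ProteinAnnotation",
    "load_annotations",
    "load_network",
    "facet_proportions",
    "network_summary",
    "NetworkSummary",
]

FACETS = (
    "cellular_component",
    "molecular_function",
    "protein_class",
    "biological_process",
)


@dataclass(frozen=True)
class ProteinAnnotation:
    """One protein's identifiers and per-facet term lists."""

    gene: str
    uniprot: str
    terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def facet(self, facet: str) -> tuple[str, ...]:
        if facet not in FACETS:
            raise KeyError(f"unknown facet {facet!r}")
        return self.terms.get(facet, ())


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("oxidiet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_annotations(path: str | None = None) -> list[ProteinAnnotation]:
    """Load an annotation TSV (default: the packaged synthetic fixture).

    Expected columns: ``gene, uniprot`` plus one column per facet holding
    ``;``-separated term lists (empty = unannotated for that facet).
    Gene names must be unique.
    """
    df = (
        pd.read_csv(path, sep="\t", comment="#")
        if path is not None
        else _read_packaged_tsv("synthetic_annotations.tsv")
    )
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene names in annotation table: {dup}")
    out = []
    for _, row in df.iterrows():
        terms = {}
        for facet in FACETS:
            raw = row.get(facet)
            if isinstance(raw, str) and raw.strip():
                terms[facet] = tuple(t.strip() for t in raw.split(";") if t.strip())
        out.append(
            ProteinAnnotation(
                gene=str(row["gene"]), uniprot=str(row.get("uniprot", "")), terms=terms
            )
        )
    return out


def facet_proportions(
    annotations: list[ProteinAnnotation],
    facet: str,
    *,
    within: str | None = None,
) -> pd.Series:
    """Percentage of proteins carrying each term of a facet.

    The denominator is the number of proteins with at least one term in the
    facet (unclassified proteins do not dilute the percentages).  A protein
    with several terms counts once per term, so multi-label facets may sum
    above 100%.

    ``within`` restricts both numerator and denominator to proteins that
    carry the given term, e.g. the share of *metabolic-process* proteins
    that are lipid-metabolic.

    Returns an empty Series when no protein is annotated in the facet.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    if facet not in FACETS:
        raise KeyError(f"unknown facet {facet!r}")
    pool = [a for a in annotations if a.facet(facet)]
    if within is not None:
        pool = [a for a in pool if within in a.facet(facet)]
    if not pool:
        return pd.Series(dtype=float, name=facet)
    counts: dict[str, int] = {}
    for a in pool:
        for term in a.facet(facet):
            counts[term] = counts.get(term, 0) + 1
    ser = pd.Series(counts, name=facet).sort_values(ascending=False)
    return 100.0 * ser / len(pool)


def load_network(path: str | None = None) -> nx.Graph:
    """Load an interaction edge list (default: packaged synthetic fixture).

    Expected columns ``protein_a, protein_b, evidence, score`` with
    evidence in {physical, functional} and score in [0, 1].  Self-loops and
    duplicate edges are rejected.
    """
    df = (
        pd.read_csv(path, sep="\t", comment="#")
        if path is not None
        else _read_packaged_tsv("synthetic_network.tsv")
    )
    g = nx.Graph()
    for _, row in df.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        score = float(row["score"])
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"confidence score {score} outside [0, 1]")
        evidence = str(row["evidence"])
        if evidence not in ("physical", "functional"):
            raise ValueError(f"unknown evidence type {evidence!r}")
        if g.has_edge(a, b):
            raise ValueError(f"duplicate edge {a!r}–{b!r}")
        g.add_edge(a, b, evidence=evidence, score=score)
    return g


@dataclass(frozen=True)
class NetworkSummary:
    """Structural summary of a confidence-filtered interaction network."""

    n_nodes: int
    n_edges: int
    degrees: dict[str, int]
    components: tuple[frozenset[str], ...]

    @property
    def n_components(self) -> int:
        return len(self.components)


def network_summary(graph: nx.Graph, min_confidence: float = 0.4) -> NetworkSummary:
    """Summarize a network after dropping low-confidence edges.

    Edges with ``score < min_confidence`` are removed, then nodes left
    isolated are dropped; degrees and connected components are computed on
    the filtered graph.  With ``min_confidence = 0`` the edge count is the
    identity.
    """
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes)
    for a, b, attrs in graph.edges(data=True):
        if attrs.get("score", 1.0) >= min_confidence:
            kept.add_edge(a, b, **attrs)
    kept.remove_nodes_from([n for n in list(kept.nodes) if kept.degree(n) == 0])
    return NetworkSummary(
        n_nodes=kept.number_of_nodes(),
        n_edges=kept.number_of_edges(),
        degrees={n: int(d) for n, d in kept.degree()},
        components=tuple(frozenset(c) for c in nx.connected_components(kept)),
    )
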