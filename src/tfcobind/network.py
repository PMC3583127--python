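"""Interaction calling, evidence annotation, hubs, and PPI enrichment.

Scan results are thresholded into interaction networks (default log10 p
thresholds: -20 for the global rank-overlap scan, -6 for tissue contexts,
-11 for homogeneous cell-line contexts whose larger specific-gene sets
inflate significance).  Calls can be annotated against a known
protein-protein interaction (PPI) edge list: direct hits and "trios" --
pairs whose two members share a known interaction partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact

DEFAULT_THRESHOLDS = {"global": -20.0, "tissue": -6.0, "cell_line": -11.0}


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class InteractionCall:
    """One called factor pair with its context and evidence annotations."""

    tf_a: str
    tf_b: str
    context: str
    log10_p: float
    similar_flag: Optional[bool] = None
    evidence: set[str] = field(default_factory=set)
    shared_cofactors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tf_a >= self.tf_b:
            raise ValueError("tf_a must sort before tf_b")
        if not self.evidence <= {"known_ppi", "trio"}:
            raise ValueError("evidence must be a subset of {known_ppi, trio}")
        if "trio" in self.evidence and not self.shared_cofactors:
            raise ValueError("trio evidence requires shared cofactors")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf_a, self.tf_b)


def call_interactions(
    results: Sequence, threshold_log10_p: float, context: str = "global"
) -> list[InteractionCall]:
    """Keep results at or below the log10 p threshold.

    Accepts rank-overlap scan results (``min_log10_p``) or tissue test results
    (``log10_p``); tissue results must additionally be enriched in the
    triple-positive cell to be called.
    """
    calls = []
    for r in results:
        if hasattr(r, "min_log10_p"):
            logp, enriched = r.min_log10_p, True
        else:
            logp, enriched = r.log10_p, r.enriched
        if logp <= threshold_log10_p and enriched:
            a, b = canonical_pair(r.tf_a, r.tf_b)
            calls.append(
                InteractionCall(
                    tf_a=a,
                    tf_b=b,
                    context=getattr(r, "tissue", context),
                    log10_p=logp,
                    similar_flag=getattr(r, "similar_flag", None),
                )
            )
    return calls


def read_ppi_edges(path) -> set[tuple[str, str]]:
    """Two-column TSV of known interacting pairs, canonically ordered."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str, comment="#")
    return {canonical_pair(a, b) for a, b in zip(df["a"], df["b"]) if a != b}


def annotate_evidence(
    calls: Sequence[InteractionCall], ppi_edges: Iterable[tuple[str, str]]
) -> list[InteractionCall]:
    """Mark direct PPI hits and trios (shared known co-factor) on each call."""
    edges = {canonical_pair(*e) for e in ppi_edges}
    neighbors: dict[str, set[str]] = {}
    for a, b in edges:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    out = []
    for c in calls:
        evidence = set()
        cofactors = sorted(
            (neighbors.get(c.tf_a, set()) & neighbors.get(c.tf_b, set()))
            - {c.tf_a, c.tf_b}
        )
        if c.pair in edges:
            evidence.add("known_ppi")
        if cofactors:
            evidence.add("trio")
        out.append(
            InteractionCall(
                tf_a=c.tf_a,
                tf_b=c.tf_b,
                context=c.context,
                log10_p=c.log10_p,
                similar_flag=c.similar_flag,
                evidence=evidence,
                shared_cofactors=cofactors,
            )
        )
    return out


def ppi_enrichment(
    calls: Sequence[InteractionCall],
    all_tested_pairs: Iterable[tuple[str, str]],
    ppi_edges: Iterable[tuple[str, str]],
):
    """Fold enrichment and one-sided Fisher p of known PPIs among calls.

    The 2x2 table crosses called/not-called with PPI/not-PPI over all tested
    pairs.  Returns ``(fold, fisher_p, table)``; fold is None when the tested
    universe holds no PPI pair at all.
    """
    tested = {canonical_pair(*p) for p in all_tested_pairs}
    called = {c.pair for c in calls}
    if not called <= tested:
        raise ValueError("calls must be a subset of the tested pairs")
    edges = {canonical_pair(*e) for e in ppi_edges} & tested
    a = len(called & edges)
    b = len(called) - a
    c = len(edges) - a
    d = len(tested) - a - b - c
    table = [[a, b], [c, d]]
    if not edges:
        return None, 1.0, table
    _, p = fisher_exact(table, alternative="greater")
    frac_called = a / len(called) if called else 0.0
    frac_all = len(edges) / len(tested)
    fold = frac_called / frac_all
    return fold, float(p), table


@dataclass
class InteractionNetwork:
    """Called interactions as an undirected graph with node degrees."""

    nodes: dict[str, int]
    edges: list[InteractionCall]
    context: str

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.tf_a not in self.nodes or e.tf_b not in self.nodes:
                raise ValueError(f"edge endpoint missing from nodes: {e.pair}")
        degrees = {n: 0 for n in self.nodes}
        for e in self.edges:
            degrees[e.tf_a] += 1
            degrees[e.tf_b] += 1
        if degrees != self.nodes:
            raise ValueError("node degrees inconsistent with incident edges")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(context=self.context)
        for node, degree in self.nodes.items():
            g.add_node(node, degree=degree)
        for e in self.edges:
            g.add_edge(
                e.tf_a,
                e.tf_b,
                log10_p=e.log10_p,
                similar_flag=str(e.similar_flag),
                evidence=",".join(sorted(e.evidence)),
                cofactors=",".join(e.shared_cofactors),
            )
        return g

    def to_graphml(self, path, min_degree_fraction: float = 0.5) -> None:
        g = self.to_networkx()
        hubs = set(find_hubs(self, min_degree_fraction))
        for node in g.nodes:
            g.nodes[node]["hub"] = node in hubs
        nx.write_graphml(g, path)


def build_network(calls: Sequence[InteractionCall], context: str = "global") -> InteractionNetwork:
    degrees: dict[str, int] = {}
    for c in calls:
        degrees[c.tf_a] = degrees.get(c.tf_a, 0) + 1
        degrees[c.tf_b] = degrees.get(c.tf_b, 0) + 1
    return InteractionNetwork(nodes=degrees, edges=list(calls), context=context)


def find_hubs(net: InteractionNetwork, min_degree_fraction: float = 0.5) -> list[str]:
    """Nodes with degree >= fraction * max degree, by decreasing degree then id.

    Operationalizes "one or two central regulators with many interactions";
    the fraction is configurable.
    """
    if not net.nodes:
        raise ValueError("network has no nodes")
    max_deg = max(net.nodes.values())
    cut = min_degree_fraction * max_deg
    hubs = [n for n, d in net.nodes.items() if d >= cut]
    return sorted(hubs, key=lambda n: (-net.nodes[n], n))


def calls_to_tsv(calls: Sequence[InteractionCall], path) -> None:
    df = pd.DataFrame(
        [
            {
                "tf_a": c.tf_a,
                "tf_b": c.tf_b,
                "context": c.context,
                "log10_p": c.log10_p,
                "similar_flag": c.similar_flag,
                "evidence": ",".join(sorted(c.evidence)),
                "cofactors": ",".join(c.shared_cofactors),
            }
            for c in sorted(calls, key=lambda c: (c.context, c.log10_p, c.tf_a, c.tf_b))
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def enrichment_to_tsv(fold, fisher_p, table, path) -> None:
    df = pd.DataFrame(
        [
            {
                "fold": math.nan if fold is None else fold,
                "fisher_p": fisher_p,
                "called_ppi": table[0][0],
                "called_nonppi": table[0][1],
                "uncalled_ppi": table[1][0],
                "uncalled_nonppi": table[1][1],
            }
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
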