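"""GO over-representation analysis of paralog groups.

Eight groups are built from representative pairs: WGD-derived,
tandem-derived, and six Ks ranges A-F.  Annotations are closed upward
over the ontology (is_a and part_of), terms with fewer than ``min_set``
annotated background genes are skipped, the hypergeometric tail gives the
raw p per term and direction, and Benjamini-Hochberg controls the FDR
within each group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pairing import RepresentativePair
from .mechanism import TANDEM, WGD

__all__ = [
    "Ontology",
    "ParalogGroup",
    "EnrichmentResult",
    "parse_obo",
    "propagate_annotations",
    "ora_test",
    "build_groups",
    "KS_RANGES",
]

# (low, high] Ks bounds for the range groups
KS_RANGES: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.5),
    "B": (0.5, 1.0),
    "C": (1.0, 1.5),
    "D": (1.5, 2.0),
    "E": (0.0, 1.0),
    "F": (1.0, 2.0),
}


@dataclass(frozen=True)
class Ontology:
    """GO DAG: edges point child -> parent (is_a / part_of)."""

    graph: nx.DiGraph
    names: Mapping[str, str]

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            return set()
        return nx.descendants(self.graph, term)

    def roots(self) -> set[str]:
        return {t for t in self.graph if self.graph.out_degree(t) == 0}


@dataclass(frozen=True)
class ParalogGroup:
    name: str  # WGD | tandem | A..F
    genes: frozenset
    ks_bounds: tuple[float, float] | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    group: str
    k: int  # annotated genes in group
    n: int  # group size
    K: int  # annotated genes in background
    N: int  # background size
    raw_p: float
    corrected_p: float
    direction: str  # "over" | "under"


def parse_obo(stream: Iterable[str]) -> Ontology:
    """Minimal OBO parser: [Term] stanzas with id, name, is_a and
    relationship: part_of; obsolete terms are skipped."""
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    term_id = None
    in_term = False
    pending: list[tuple[str, str]] = []
    stanza: dict[str, list[str]] = {}

    def flush():
        nonlocal term_id, stanza
        if term_id and "true" not in stanza.get("is_obsolete", []):
            graph.add_node(term_id)
            names[term_id] = stanza.get("name", [""])[0]
            for parent in stanza.get("parents", []):
                pending.append((term_id, parent))
        term_id = None
        stanza = {}

    for raw in stream:
        line = raw.strip()
        if line == "[Term]":
            flush()
            in_term = True
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            in_term = False
            continue
        if not in_term or not line or ":" not in line:
            continue
        key, _, value = line.partition(":")
        value = value.split("!")[0].strip()
        if key == "id":
            term_id = value
        elif key == "name":
            stanza.setdefault("name", []).append(value)
        elif key == "is_obsolete":
            stanza.setdefault("is_obsolete", []).append(value)
        elif key == "is_a":
            stanza.setdefault("parents", []).append(value)
        elif key == "relationship" and value.startswith("part_of"):
            stanza.setdefault("parents", []).append(value.split()[1])
    flush()
    for child, parent in pending:
        if parent in graph:
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return Ontology(graph=graph, names=names)


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], ontology: Ontology
) -> dict[str, frozenset]:
    """Close each gene's term set upward over the DAG (idempotent).  Terms
    absent from the ontology are kept as-is."""
    closure_cache: dict[str, set[str]] = {}
    out: dict[str, frozenset] = {}
    for gene, terms in annotations.items():
        closed: set[str] = set()
        for t in terms:
            if t not in closure_cache:
                closure_cache[t] = {t} | ontology.ancestors(t)
            closed |= closure_cache[t]
        out[gene] = frozenset(closed)
    return out


def ora_test(
    group: ParalogGroup,
    background: frozenset | set,
    annotations: Mapping[str, Iterable[str]],
    min_set: int = 10,
    alpha: float = 0.05,
    min_set_on: str = "background",
    exclude_terms: Iterable[str] = (),
) -> list[EnrichmentResult]:
    """Per-term hypergeometric over/under-representation with BH correction.

    ``min_set`` binds on the background annotation count K by default
    (``min_set_on="group"`` applies it to k instead).  Genes are counted
    once each (sets throughout).
    """
    group_genes = frozenset(group.genes) & frozenset(background)
    bg = frozenset(background)
    if not group_genes:
        return []
    if not group_genes <= bg:
        raise ValueError("group must be a subset of the background")
    excluded = frozenset(exclude_terms)
    term_bg: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in bg:
        for t in frozenset(annotations.get(gene, ())):
            if t in excluded:
                continue
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in group_genes:
                term_k[t] = term_k.get(t, 0) + 1
    n = len(group_genes)
    N = len(bg)
    rows = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_k.get(term, 0)
        if min_set_on == "background":
            if K < min_set:
                continue
        elif k < min_set:
            continue
        p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_under = float(stats.hypergeom.cdf(k, N, K, n))
        if p_over <= p_under:
            rows.append((term, k, K, min(p_over, 1.0), "over"))
        else:
            rows.append((term, k, K, min(p_under, 1.0), "under"))
    if not rows:
        return []
    raw = [r[3] for r in rows]
    _, corrected, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term,
            group=group.name,
            k=k,
            n=n,
            K=K,
            N=N,
            raw_p=p,
            corrected_p=float(max(cp, p)),
            direction=direction,
        )
        for (term, k, K, p, direction), cp in zip(rows, corrected)
    ]
    return results


def build_groups(pairs: Iterable[RepresentativePair]) -> list[ParalogGroup]:
    """WGD and tandem groups from mechanism labels plus the six Ks-range
    groups (A-F, mechanism-agnostic); gene sets are unions of pair members."""
    pairs = list(pairs)
    groups = []
    for label, name in ((WGD, "WGD"), (TANDEM, "tandem")):
        genes = frozenset(
            g for p in pairs if p.label == label for g in (p.gene_a, p.gene_b)
        )
        groups.append(ParalogGroup(name=name, genes=genes))
    for name, (lo, hi) in KS_RANGES.items():
        genes = frozenset(
            g for p in pairs if lo < p.ks <= hi for g in (p.gene_a, p.gene_b)
        )
        groups.append(ParalogGroup(name=name, genes=genes, ks_bounds=(lo, hi)))
    return groups
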