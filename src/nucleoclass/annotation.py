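"""Downstream characterisation of predicted classes.

Two analyses: a GO biological-process census that counts, per class, the
high-reliability proteins annotated with a query term or any of its
descendants; and orthologue-conservation fractions per class and organism
with a bootstrap standard deviation.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .classifier import Prediction
from .types import NucleolarClass

__all__ = [
    "OntologyGraph",
    "descendant_closure",
    "term_census",
    "conservation_fractions",
]


class OntologyGraph:
    """A DAG of ontology terms with child -> parent edges (is_a by
    default; part_of optionally included when loading OBO)."""

    def __init__(self, edges: Iterable[Tuple[str, str]], nodes: Iterable[str] = ()) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        self.graph = g

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @classmethod
    def from_obo(cls, path, relations: Tuple[str, ...] = ("is_a",)) -> "OntologyGraph":
        """Load from OBO.  obonet emits child -> parent edges keyed by
        relation; only the requested relations are kept."""
        import obonet

        raw = obonet.read_obo(path)
        edges = [
            (child, parent)
            for child, parent, key in raw.edges(keys=True)
            if key in relations
        ]
        return cls(edges, nodes=raw.nodes())

    @classmethod
    def from_tsv(cls, path) -> "OntologyGraph":
        """Load from a two-column child<TAB>parent file ('#' comments)."""
        edges = []
        with open(path) as fh:
            header_skipped = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 2:
                    raise ValueError(f"{path}: expected 2 columns, got {line!r}")
                if not header_skipped and cols[0].lower() in ("child", "term", "child_id"):
                    header_skipped = True
                    continue
                edges.append((cols[0], cols[1]))
        return cls(edges)


def descendant_closure(graph: OntologyGraph, term: str) -> FrozenSet[str]:
    """The term plus every term below it (all terms whose child->parent
    paths reach it)."""
    if term not in graph:
        raise KeyError(f"unknown ontology term: {term!r}")
    return frozenset({term} | nx.ancestors(graph.graph, term))


def term_census(
    predictions: Sequence[Prediction],
    annotations: Mapping[str, Iterable[str]],
    graph: OntologyGraph,
    query_terms: Sequence[str],
    min_ri: float = 10.0,
    inclusive: bool = False,
) -> Dict[Tuple[NucleolarClass, str], int]:
    """Count, per (class, query term), the high-reliability proteins
    annotated with the term or any of its descendants.

    A protein counts toward a term when its reliability index exceeds
    ``min_ri`` (strictly by default; set ``inclusive`` to count boundary
    proteins) and at least one of its annotations lies in the term's
    descendant closure.  A protein counts at most once per term, however
    many closure annotations it carries.
    """
    closures = {t: descendant_closure(graph, t) for t in query_terms}
    counts: Dict[Tuple[NucleolarClass, str], int] = {}
    for pred in predictions:
        ok = (
            pred.reliability_index >= min_ri
            if inclusive
            else pred.reliability_index > min_ri
        )
        if not ok:
            continue
        terms = set(annotations.get(pred.id, ()))
        for q, closure in closures.items():
            if terms & closure:
                key = (pred.label, q)
                counts[key] = counts.get(key, 0) + 1
    return counts


def conservation_fractions(
    groups: Mapping[NucleolarClass, Iterable[str]],
    table: Mapping[str, Iterable[str]],
    organisms: Sequence[str],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> Dict[Tuple[NucleolarClass, str], Tuple[float, float]]:
    """Per (class, organism): fraction of the group's proteins with an
    orthologue in the organism, plus a bootstrap SD.

    The bootstrap resamples each group's proteins with replacement
    (group size preserved) ``n_boot`` times; the same resampled datasets
    are used across organisms within a group.
    """
    rng = np.random.default_rng(seed)
    out: Dict[Tuple[NucleolarClass, str], Tuple[float, float]] = {}
    for cls, members_iter in groups.items():
        members = sorted(set(members_iter))
        n = len(members)
        if n == 0:
            raise ValueError(f"empty group: {cls}")
        ortho = {pid: frozenset(table.get(pid, ())) for pid in members}
        idx = rng.integers(0, n, size=(n_boot, n))
        for org in organisms:
            has = np.array([org in ortho[pid] for pid in members], dtype=float)
            fraction = float(has.mean())
            boot_means = has[idx].mean(axis=1)
            sd = float(boot_means.std(ddof=1)) if n_boot > 1 else 0.0
            out[(cls, org)] = (fraction, sd)
    return out
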