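"""Ontology graphs, equivalence mappings, and subsumption queries.

Two directed acyclic graphs drive the benchmark: a Mondo-like disease
ontology, used for grounding free-text diagnoses and for the subsumption
roll-up scoring rule, and an HPO-like phenotype ontology used for organ
stratification. Both are held as labeled is-a DAGs (child → parent edges);
all other relation types are ignored, because disease grouping in Mondo is
is-a based.

Cross-nomenclature equivalence mappings (OMIM/Orphanet → Mondo) are loaded
from SSSOM TSV restricted to ``skos:exactMatch`` rows; a source identifier
mapping to more than one Mondo term under exact-match semantics is a load
error, never silently resolved.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .pheno_io import DiseaseRef

__all__ = [
    "Term",
    "OntologyGraph",
    "MappingTable",
    "OntologyLoadError",
    "MappingError",
    "load_ontology",
    "load_mappings_sssom",
    "align_to_mondo",
    "write_ontology_obograph",
    "write_mappings_sssom",
]


class OntologyLoadError(ValueError):
    """The ontology document is structurally invalid (e.g. a cyclic is-a graph)."""


class MappingError(ValueError):
    """The mapping table violates exact-match semantics."""


@dataclass(frozen=True)
class Term:
    label: str
    synonyms: tuple[str, ...] = ()


class OntologyGraph:
    """A labeled is-a DAG over CURIE-identified terms.

    Edges run child → parent. Obsolete terms remain resolvable by id (a
    deposited response may cite a merged term) but are excluded from the
    lexical index used for grounding.
    """

    def __init__(
        self,
        nodes: Mapping[str, Term],
        edges: Iterable[tuple[str, str]],
        obsolete: Iterable[str] = (),
    ):
        self.nodes: dict[str, Term] = dict(nodes)
        self.obsolete: frozenset[str] = frozenset(obsolete)
        for curie, term in self.nodes.items():
            if not term.label:
                raise OntologyLoadError(f"term {curie} has an empty label")
            if any(not s for s in term.synonyms):
                raise OntologyLoadError(f"term {curie} has an empty synonym")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, parent in edges:
            if child not in self.nodes or parent not in self.nodes:
                raise OntologyLoadError(
                    f"edge ({child}, {parent}) references an unknown term"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyLoadError(f"is-a structure is cyclic: {cycle}")
        self._g = g
        # populated lazily by the grounding module
        self._lexical_index: dict | None = None

    # -- basic queries ----------------------------------------------------

    def __contains__(self, curie: str) -> bool:
        return curie in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def terms(self) -> list[str]:
        return sorted(self.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    def label(self, curie: str) -> str:
        return self.nodes[curie].label

    def synonyms(self, curie: str) -> tuple[str, ...]:
        return self.nodes[curie].synonyms

    def parents(self, curie: str) -> set[str]:
        if curie not in self.nodes:
            raise KeyError(curie)
        return set(self._g.successors(curie))

    def children(self, curie: str) -> set[str]:
        if curie not in self.nodes:
            raise KeyError(curie)
        return set(self._g.predecessors(curie))

    # -- subsumption ------------------------------------------------------

    def descendants(self, term: str, max_distance: int | None = None) -> set[str]:
        """Terms from which ``term`` is reachable along is-a edges.

        Includes ``term`` itself at distance 0. ``max_distance=None`` means
        unbounded; otherwise only terms within that many edges are returned.
        """
        if term not in self.nodes:
            raise KeyError(term)
        if max_distance is not None and max_distance < 0:
            raise ValueError("max_distance must be non-negative")
        # walking child-ward == following reversed is-a edges
        dists = nx.single_source_shortest_path_length(
            self._g.reverse(copy=False), term, cutoff=max_distance
        )
        return set(dists)

    def edge_distance(self, ancestor: str, descendant: str) -> int | None:
        """Shortest is-a path length descendant → ancestor, or None."""
        if ancestor not in self.nodes or descendant not in self.nodes:
            raise KeyError(ancestor if ancestor not in self.nodes else descendant)
        try:
            return nx.shortest_path_length(self._g, descendant, ancestor)
        except nx.NetworkXNoPath:
            return None


# ---------------------------------------------------------------------------
# OBO Graph JSON loading

_OBO_IRI = re.compile(r"^https?://purl\.obolibrary\.org/obo/([A-Za-z0-9]+)_(\S+)$")


def _compact(ident: str) -> str:
    m = _OBO_IRI.match(ident)
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    return ident


def load_ontology(document: str) -> OntologyGraph:
    """Load an OBO Graph JSON document, retaining only is-a edges.

    Deprecated nodes are flagged obsolete. Edges whose endpoints were not
    loaded as labeled classes are dropped. A cyclic is-a structure is a load
    error naming one cycle.
    """
    doc = json.loads(document)
    graphs = doc.get("graphs", [doc])
    nodes: dict[str, Term] = {}
    obsolete: set[str] = set()
    edges: list[tuple[str, str]] = []
    for graph in graphs:
        for node in graph.get("nodes", []):
            if node.get("type", "CLASS") not in ("CLASS", None):
                continue
            curie = _compact(node["id"])
            label = node.get("lbl") or curie
            meta = node.get("meta") or {}
            syns = tuple(
                s["val"] for s in meta.get("synonyms", []) if s.get("val")
            )
            nodes[curie] = Term(label=label, synonyms=syns)
            if meta.get("deprecated"):
                obsolete.add(curie)
        for edge in graph.get("edges", []):
            if edge.get("pred") not in ("is_a", "rdfs:subClassOf", "subClassOf"):
                continue
            sub, obj = _compact(edge["sub"]), _compact(edge["obj"])
            if sub in nodes and obj in nodes:
                edges.append((sub, obj))
    return OntologyGraph(nodes, edges, obsolete)


def write_ontology_obograph(graph: OntologyGraph, path: str | Path) -> None:
    doc = {
        "graphs": [
            {
                "nodes": [
                    {
                        "id": curie,
                        "lbl": term.label,
                        "type": "CLASS",
                        "meta": {
                            "synonyms": [{"pred": "hasExactSynonym", "val": s} for s in term.synonyms],
                            **({"deprecated": True} if curie in graph.obsolete else {}),
                        },
                    }
                    for curie, term in sorted(graph.nodes.items())
                ],
                "edges": [
                    {"sub": c, "pred": "is_a", "obj": p}
                    for c, p in sorted(graph.edges)
                ],
            }
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# equivalence mappings

EXACT_MATCH = "skos:exactMatch"
_MONDO_PREFIXES = ("MONDO", "MONDOX")


@dataclass(frozen=True)
class MappingTable:
    """Exact-match equivalences from OMIM/Orphanet identifiers to Mondo."""

    pairs: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MappingTable":
        table: dict[str, str] = {}
        for source, target in pairs:
            if source in table and table[source] != target:
                raise MappingError(
                    f"{source} maps to both {table[source]} and {target} "
                    "under exact-match semantics"
                )
            if not target.startswith(_MONDO_PREFIXES):
                raise MappingError(f"mapping target {target} is not a Mondo CURIE")
            table[source] = target
        return cls(pairs=table)

    def get(self, source: str) -> str | None:
        return self.pairs.get(source)

    def __len__(self) -> int:
        return len(self.pairs)


def load_mappings_sssom(text: str) -> MappingTable:
    """Load an SSSOM TSV, keeping only ``skos:exactMatch`` rows.

    Broad/narrow matches are ignored: the scoring rule relies on genuine
    equivalence. One-to-many exact matches are rejected at load.
    """
    import io

    import pandas as pd

    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    for col in ("subject_id", "predicate_id", "object_id"):
        if col not in df.columns:
            raise MappingError(f"SSSOM table missing column {col!r}")
    exact = df[df["predicate_id"] == EXACT_MATCH]
    return MappingTable.from_pairs(
        zip(exact["subject_id"], exact["object_id"])
    )


def write_mappings_sssom(table: MappingTable, path: str | Path) -> None:
    lines = ["subject_id\tpredicate_id\tobject_id"]
    for source, target in sorted(table.pairs.items()):
        lines.append(f"{source}\t{EXACT_MATCH}\t{target}")
    Path(path).write_text("\n".join(lines) + "\n")


def align_to_mondo(ref: DiseaseRef, mappings: MappingTable) -> str | None:
    """Resolve a disease reference to its Mondo identifier.

    Mondo identifiers pass through unchanged; OMIM/Orphanet identifiers
    resolve through the exact-match table. An absent mapping returns
    ``None`` (unmapped) — never a silent default.
    """
    if ref.prefix in _MONDO_PREFIXES:
        return ref.id
    return mappings.get(ref.id)
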