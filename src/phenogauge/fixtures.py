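"""Packaged toy fixture ontology and mapping table.

A hand-written miniature disease ontology built around geleophysic
dysplasia — a genetically heterogeneous disease whose clinical grouping
term subsumes three genetic subtypes — plus a few distractor diseases and
one obsolete term. Mondo identifiers are real only where the worked
example pins them (the grouping term and subtype 2, with its OMIM
equivalence); sibling subtype and distractor identifiers are synthetic
placeholders in a reserved MONDO:00990xx range. The companion SSSOM table
carries the matching OMIM/Orphanet exact-match rows.
"""

from __future__ import annotations

from importlib import resources

from .ontology import MappingTable, OntologyGraph, load_mappings_sssom, load_ontology

__all__ = ["toy_disease_ontology", "toy_disease_mappings"]


def _read(name: str) -> str:
    return (resources.files("phenogauge") / "data" / name).read_text()


def toy_disease_ontology() -> OntologyGraph:
    """The packaged geleophysic-dysplasia toy ontology."""
    return load_ontology(_read("toy_mondo.json"))


def toy_disease_mappings() -> MappingTable:
    """Exact-match OMIM/Orphanet → Mondo rows for the toy ontology."""
    return load_mappings_sssom(_read("toy_mappings.sssom.tsv"))
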