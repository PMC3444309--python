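"""Phenotype ontology: loading, validation and is-a traversal.

The ontology is a directed acyclic graph (DAG) of phenotype classes related
by ``is_a`` (subsumption). Queries on a broad class (e.g. *Abnormality of
the Cerebellum*) must also return evidence recorded on narrower classes
(*Ataxia*, *Arnold-Chiari type I malformation*), so the transitive closure
of the is-a relation is the workhorse of the whole package.

Two serialisations are supported: a subset of the OBO 1.2 flat-file format
(stanza ``[Term]`` with ``id:``, ``name:``, ``is_a:``, ``synonym:`` and an
optional ``subset:`` provenance tag) read through :mod:`obonet`, and an
equivalent four-column tabular form. Multiple parents are permitted (DAG,
not tree). Synonyms are stored for display only; all matching is by exact
term id.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "Term",
    "Ontology",
    "OntologyError",
    "UnknownTermError",
    "parse_ontology",
    "load_ctx_ontology",
    "to_obo",
    "to_tabular",
]

SOURCE_TAGS = ("HPO-derived", "SNOMED-derived", "new")


class OntologyError(ValueError):
    """Raised when an ontology file is structurally invalid."""


class UnknownTermError(KeyError):
    """Raised when a term id is not part of the ontology."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"unknown term id: {self.term_id!r}"


@dataclass(frozen=True)
class Term:
    """One ontology class.

    ``source_tag`` records provenance only (whether the concept was reused
    from HPO, from SNOMED CT, or newly created); it has no semantics.
    """

    term_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    source_tag: str = "new"


@dataclass
class Ontology:
    """A validated is-a DAG of :class:`Term` objects.

    ``graph`` holds one edge child -> parent per ``is_a`` statement, so
    graph-reachability *from* a term yields its ancestors.
    """

    terms: dict[str, Term]
    root_ids: list[str]
    graph: nx.DiGraph = field(repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable via one or more parent links; excludes self."""
        self._require(term_id)
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms whose ancestors include ``term_id``; excludes self."""
        self._require(term_id)
        return nx.ancestors(self.graph, term_id)

    def subsumes(self, general_id: str, specific_id: str) -> bool:
        """True iff ``general_id`` equals or is an ancestor of ``specific_id``.

        Reflexive by definition: every class subsumes itself, matching the
        query semantics in which a class denotes itself plus its strict
        descendants.
        """
        self._require(general_id)
        self._require(specific_id)
        return general_id == specific_id or general_id in self.ancestors(specific_id)

    def roots_of(self, term_id: str) -> set[str]:
        """The hierarchy roots a term belongs to."""
        self._require(term_id)
        if term_id in self.root_ids:
            return {term_id}
        return self.ancestors(term_id) & set(self.root_ids)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'"([^"]*)"')


def _as_stream(source: str | TextIO) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _duplicate_ids_in_obo(text: str) -> list[str]:
    """obonet silently merges duplicate stanzas; pre-scan for them."""
    ids: list[str] = []
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            ids.append(line[3:].strip())
            in_term = False  # only the first id line of the stanza
    seen: set[str] = set()
    dups = []
    for tid in ids:
        if tid in seen and tid not in dups:
            dups.append(tid)
        seen.add(tid)
    return dups


def _parse_obo(stream: TextIO) -> dict[str, Term]:
    text = stream.read()
    dups = _duplicate_ids_in_obo(text)
    if dups:
        raise OntologyError(f"duplicate term id(s): {', '.join(dups)}")
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # node created only because something referenced it
            continue
        synonyms = tuple(
            m.group(1)
            for raw in data.get("synonym", ())
            if (m := _SYNONYM_RE.search(raw))
        )
        tags = data.get("subset", ())
        source_tag = tags[0] if tags else "new"
        terms[node] = Term(
            term_id=node,
            label=data["name"],
            synonyms=synonyms,
            parent_ids=tuple(data.get("is_a", ())),
            source_tag=source_tag,
        )
    return terms


def _parse_tabular(stream: TextIO) -> dict[str, Term]:
    frame = pd.read_csv(stream, dtype=str).fillna("")
    required = {"term_id", "label", "parent_ids", "synonyms"}
    missing = required - set(frame.columns)
    if missing:
        raise OntologyError(f"tabular ontology missing column(s): {sorted(missing)}")
    terms: dict[str, Term] = {}
    for row in frame.itertuples(index=False):
        tid = row.term_id.strip()
        if not tid:
            raise OntologyError("empty term_id in tabular ontology")
        if tid in terms:
            raise OntologyError(f"duplicate term id(s): {tid}")
        parents = tuple(p for p in row.parent_ids.split(";") if p)
        synonyms = tuple(s for s in row.synonyms.split(";") if s)
        tag = getattr(row, "source_tag", "") or "new"
        terms[tid] = Term(tid, row.label, synonyms, parents, tag)
    return terms


def _validate(terms: dict[str, Term]) -> Ontology:
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for term in terms.values():
        for parent in term.parent_ids:
            if parent not in terms:
                raise OntologyError(
                    f"term {term.term_id!r} references unknown parent {parent!r}"
                )
            graph.add_edge(term.term_id, parent)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"is-a cycle detected: {path}")
    roots = sorted(tid for tid, t in terms.items() if not t.parent_ids)
    return Ontology(terms=terms, root_ids=roots, graph=graph)


def parse_ontology(source: str | TextIO, format: str = "obo-subset") -> Ontology:
    """Parse and validate an ontology.

    Parameters
    ----------
    source:
        A character stream or a string holding the whole file.
    format:
        ``"obo-subset"`` (OBO 1.2 flat file) or ``"tabular"`` (CSV with
        columns ``term_id,label,parent_ids,synonyms`` and optional
        ``source_tag``; multi-valued cells semicolon-joined).

    Raises
    ------
    OntologyError
        On duplicate ids, dangling parent references, or an is-a cycle
        (the message names one cycle).
    """
    stream = _as_stream(source)
    if format == "obo-subset":
        terms = _parse_obo(stream)
    elif format == "tabular":
        terms = _parse_tabular(stream)
    else:
        raise ValueError(f"unknown ontology format: {format!r}")
    return _validate(terms)


def load_ctx_ontology() -> Ontology:
    """Load the CTX phenotype ontology subset shipped with the package."""
    from importlib import resources

    ref = resources.files("ctxquery.data").joinpath("ctx_ontology.obo")
    return parse_ontology(ref.read_text(encoding="utf-8"), format="obo-subset")


# ---------------------------------------------------------------------------
# Serialisation (round-trip support)
# ---------------------------------------------------------------------------

def to_obo(ontology: Ontology) -> str:
    """Serialise to the OBO 1.2 subset; parse(to_obo(o)) == o term/edge-wise."""
    chunks = ["format-version: 1.2", "ontology: ctxquery-export", ""]
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        lines = [f"[Term]", f"id: {term.term_id}", f"name: {term.label}"]
        lines += [f"is_a: {p}" for p in term.parent_ids]
        lines += [f'synonym: "{s}" EXACT []' for s in term.synonyms]
        if term.source_tag != "new":
            lines.append(f"subset: {term.source_tag}")
        chunks.append("\n".join(lines))
        chunks.append("")
    return "\n".join(chunks)


def to_tabular(ontology: Ontology) -> str:
    """Serialise to the four-column CSV form."""
    rows = [
        {
            "term_id": t.term_id,
            "label": t.label,
            "parent_ids": ";".join(t.parent_ids),
            "synonyms": ";".join(t.synonyms),
            "source_tag": t.source_tag,
        }
        for t in (ontology.terms[tid] for tid in sorted(ontology.terms))
    ]
    return pd.DataFrame(rows).to_csv(index=False)
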