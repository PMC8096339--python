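"""Variation Ontology (VariO) RNA term registry and hierarchy.

VariO names variation types, effects and mechanisms with accessions of the
form ``VariO:NNNN``; a systematic annotation renders an accession together
with its full name, e.g. ``VariO:0319 RNA deletion``.  This module holds the
RNA subtree of that vocabulary: a bundled plain-text registry transcribed
from the published RNA systematics (with its accession collisions resolved
in a documented conflict table), plus a loader for official OBO releases.

The hierarchy is a rooted DAG over ``is_a`` links.  Queries (ancestors,
depth, rendering, name lookup) behave identically whether the terms came
from the bundled table or from an OBO file.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

import networkx as nx
import obonet

ACCESSION_RE = re.compile(r"^VariO:\d{4}$")

CATEGORIES = frozenset(
    {"variation_type", "function", "property", "structure", "typing"}
)


class OntologyError(ValueError):
    """Raised for malformed ontology input or internal inconsistency."""


class UnknownAccessionError(KeyError):
    """Raised when an accession is not present in the hierarchy."""


@dataclass(frozen=True)
class Term:
    """One VariO term: accession, name, is_a parents and bookkeeping."""

    accession: str
    name: str
    parent_accessions: tuple[str, ...] = ()
    category: str = "variation_type"
    source: str = "bundled"
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not ACCESSION_RE.match(self.accession):
            raise OntologyError(
                f"accession {self.accession!r} does not match VariO:NNNN"
            )
        if not self.name:
            raise OntologyError(f"term {self.accession} has an empty name")


@dataclass(frozen=True)
class Conflict:
    """A registry integrity problem found by :func:`validate_registry`."""

    kind: str  # duplicate_accession | duplicate_name | orphan | cycle
    accession: str
    detail: str


class Hierarchy:
    """Rooted, acyclic is_a hierarchy over VariO terms.

    ``terms`` maps accession to :class:`Term`; ``roots`` are the terms with
    no parents.  Depth is counted in edges from the nearest root, so every
    root has depth 0 and ``depth(child) = 1 + min(depth(parent))``.
    """

    def __init__(self, terms: Iterable[Term], *, validate: bool = True):
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.accession in self.terms:
                raise OntologyError(f"duplicate accession {t.accession}")
            self.terms[t.accession] = t
        self.roots: list[str] = [
            a for a, t in self.terms.items() if not t.parent_accessions
        ]
        self._graph = nx.DiGraph()  # edges: child -> parent
        self._graph.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parent_accessions:
                self._graph.add_edge(t.accession, p)
        self._by_name: dict[str, str] = {}
        for t in self.terms.values():
            self._by_name.setdefault(t.name, t.accession)
        if validate:
            conflicts = validate_registry(self)
            if conflicts:
                c = conflicts[0]
                raise OntologyError(
                    f"inconsistent registry: {c.kind} at {c.accession}: {c.detail}"
                )

    # -- basic queries ---------------------------------------------------

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def get(self, accession: str) -> Term:
        try:
            return self.terms[accession]
        except KeyError:
            raise UnknownAccessionError(accession) from None

    def by_name(self, name: str) -> Term:
        """Look a term up by its exact (lowercase) name."""
        try:
            return self.terms[self._by_name[name]]
        except KeyError:
            raise UnknownAccessionError(name) from None

    def depth(self, accession: str) -> int:
        """Edges from the nearest root (roots have depth 0)."""
        term = self.get(accession)
        if not term.parent_accessions:
            return 0
        return 1 + min(self.depth(p) for p in term.parent_accessions)

    def max_depth(self) -> int:
        return max(self.depth(a) for a in self.terms)


def ancestors(h: Hierarchy, accession: str) -> list[str]:
    """Transitive is_a closure of *accession*, nearest ancestor first.

    Deduplicated breadth-first order, so a term's root comes last.
    """
    h.get(accession)
    seen: list[str] = []
    frontier = list(h.get(accession).parent_accessions)
    while frontier:
        nxt: list[str] = []
        for a in frontier:
            if a not in seen:
                seen.append(a)
                nxt.extend(h.get(a).parent_accessions)
        frontier = nxt
    return seen


def render(h: Hierarchy, accession: str) -> str:
    """Render the systematic annotation string ``<accession> <name>``."""
    t = h.get(accession)
    return f"{t.accession} {t.name}"


def parse_rendered(s: str) -> str:
    """Inverse of :func:`render`: extract the accession from a rendered term."""
    acc = s.split(" ", 1)[0]
    if not ACCESSION_RE.match(acc):
        raise OntologyError(f"not a rendered VariO term: {s!r}")
    return acc


def validate_registry(h: Hierarchy) -> list[Conflict]:
    """Report duplicate names, orphan parents and is_a cycles.

    Duplicate *accessions* cannot survive Hierarchy construction, so naive
    (conflicting) registries are validated via :func:`scan_table_conflicts`
    on the raw table instead.
    """
    conflicts: list[Conflict] = []
    names: dict[str, str] = {}
    for t in h.terms.values():
        if t.name in names:
            conflicts.append(
                Conflict("duplicate_name", t.accession,
                         f"name {t.name!r} also used by {names[t.name]}")
            )
        else:
            names[t.name] = t.accession
        for p in t.parent_accessions:
            if p not in h.terms:
                conflicts.append(
                    Conflict("orphan", t.accession, f"parent {p} not in registry")
                )
    try:
        cycle = nx.find_cycle(h._graph)
    except nx.NetworkXNoCycle:
        pass
    else:
        conflicts.append(
            Conflict("cycle", cycle[0][0],
                     " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}")
        )
    return conflicts


def scan_table_conflicts(rows: Iterable[tuple[str, str]]) -> list[Conflict]:
    """Find duplicate-accession assignments in raw (accession, name) rows.

    This is the check that flags the accession collisions present in the
    published text before conflict resolution (e.g. VariO:0468 assigned to
    both 'translation-related non-coding RNA' and 'transfer RNA').
    """
    seen: dict[str, str] = {}
    conflicts: list[Conflict] = []
    for acc, name in rows:
        if acc in seen and seen[acc] != name:
            conflicts.append(
                Conflict("duplicate_accession", acc,
                         f"assigned to both {seen[acc]!r} and {name!r}")
            )
        seen.setdefault(acc, name)
    return conflicts


def _read_registry_rows(text: str) -> list[Term]:
    reader = csv.DictReader(
        (ln for ln in io.StringIO(text) if not ln.startswith("#")),
        delimiter="\t",
    )
    terms = []
    for row in reader:
        parents = tuple(p for p in (row["parents"] or "").split("|") if p)
        syns = tuple(s for s in (row.get("synonyms") or "").split("|") if s)
        terms.append(
            Term(
                accession=row["accession"],
                name=row["name"],
                parent_accessions=parents,
                category=row["category"],
                source=row["source"],
                synonyms=syns,
            )
        )
    return terms


def load_registry() -> Hierarchy:
    """Load and validate the bundled RNA term registry.

    The registry is a version-controlled TSV containing every accession
    quoted in the RNA systematics text, with collisions resolved per the
    conflict table embedded in the file header (``source`` column).
    """
    text = (
        resources.files("vario_rna.data").joinpath("rna_terms.tsv").read_text()
    )
    return Hierarchy(_read_registry_rows(text))


_OBO_LINE_RE = re.compile(r"^[A-Za-z_-]+:\s*\S")


def _prescan_obo(text: str) -> None:
    """Line-numbered well-formedness check over [Term] stanzas.

    obonet is deliberately lenient; this pre-scan supplies hard errors with
    line numbers for content that is not ``tag: value`` shaped.
    """
    in_term = False
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            in_term = stripped == "[Term]"
            continue
        if in_term and not _OBO_LINE_RE.match(stripped):
            raise OntologyError(f"malformed stanza line {i}: {line!r}")


def load_obo(stream) -> Hierarchy:
    """Build a Hierarchy from OBO 1.2/1.4 text.

    *stream* may be a path or an open text handle.  Only ``id``, ``name``,
    ``is_a`` and ``is_obsolete`` are consumed; obsolete terms are excluded.
    Terms whose accessions fall outside the ``VariO:NNNN`` pattern (e.g.
    imports from other ontologies) are skipped.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        with open(stream) as fh:
            text = fh.read()
    if not text.strip():
        raise OntologyError("empty OBO input")
    _prescan_obo(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    terms = []
    for node, data in graph.nodes(data=True):
        if not ACCESSION_RE.match(node):
            continue
        if "name" not in data:
            raise OntologyError(f"stanza {node} is missing a name")
        parents = tuple(p for p in data.get("is_a", ()) if p in graph)
        terms.append(
            Term(accession=node, name=data["name"],
                 parent_accessions=parents, source="obo")
        )
    if not terms:
        raise OntologyError("OBO input contains no VariO [Term] stanzas")
    return Hierarchy(terms)
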