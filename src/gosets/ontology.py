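"""Gene Ontology term hierarchy: OBO parsing, synonym/obsolete resolution,
term depths, and a versioned on-disk cache.

The ontology is a directed acyclic graph with one root per namespace
(biological_process, molecular_function, cellular_component).  Edges point
from the more specific term (child) to the more general term (parent);
by default both ``is_a`` and ``part_of`` relationships count as parent
edges, because gene annotations propagate over both under the true-path
rule.  ``regulates``-type relationships are not followed.

Because the ontology evolves, an OBO release also documents retired
accessions: *obsolete* terms (annotations citing them must be dropped) and
*alternate ids* (synonymous accessions that must be rewritten to the
preferred accession).  Both maps are first-class outputs of the parser.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .errors import CacheError, OboParseError, OntologyValidationError

GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")

#: Relationship types that constitute parent edges for annotation
#: propagation.  ``is_a`` is always followed and need not be listed.
DEFAULT_RELATIONSHIPS: tuple[str, ...] = ("part_of",)

CACHE_FORMAT_VERSION = 1


@dataclass
class GOTerm:
    """One current or obsolete ontology term."""

    term_id: str
    name: str = ""
    namespace: str = ""
    parent_ids: set[str] = field(default_factory=set)
    is_obsolete: bool = False
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        if not GO_ACCESSION_RE.match(self.term_id):
            raise ValueError(f"not a GO accession: {self.term_id!r}")


@dataclass
class OntologyDAG:
    """The parsed term hierarchy.

    ``terms`` holds current terms only; ``alt_id_map`` rewrites synonymous
    accessions to the preferred accession; ``obsolete_ids`` lists retired
    accessions (with ``replaced_by`` hints where the file supplied exactly
    one replacement).  ``root_ids`` maps namespace -> root accession.
    """

    terms: dict[str, GOTerm] = field(default_factory=dict)
    alt_id_map: dict[str, str] = field(default_factory=dict)
    obsolete_ids: set[str] = field(default_factory=set)
    replaced_by: dict[str, str] = field(default_factory=dict)
    root_ids: dict[str, str] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        """Directed graph with edges child -> parent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parent_ids:
                g.add_edge(term.term_id, parent)
        return g

    def children_of(self) -> dict[str, list[str]]:
        """Adjacency parent -> sorted list of children."""
        children: dict[str, list[str]] = {tid: [] for tid in self.terms}
        for term in self.terms.values():
            for parent in term.parent_ids:
                children[parent].append(term.term_id)
        for kids in children.values():
            kids.sort()
        return children


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving an accession against the DAG.

    ``status`` is one of ``"current"``, ``"obsolete"``, ``"unknown"``;
    ``accession`` is the preferred accession when current, else None.
    ``was_synonym`` marks accessions rewritten through the alt_id map.
    """

    status: str
    accession: str | None = None
    was_synonym: bool = False


@dataclass
class TermDepthMap:
    """Shortest edge-distance from each term to its namespace root."""

    depth: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, term_id: str) -> int:
        return self.depth[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.depth


def _iter_stanzas(stream: Iterable[str]):
    """Yield (stanza_type, start_line, [(line_no, key, value), ...]).

    The OBO header (everything before the first stanza) is skipped.
    Trailing ``! comment`` text is stripped from values.
    """
    stanza_type = None
    start_line = 0
    fields: list[tuple[int, str, str]] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            if stanza_type is not None:
                yield stanza_type, start_line, fields
            stanza_type = stripped[1:-1]
            start_line = line_no
            fields = []
            continue
        if not stripped or stripped.startswith("!"):
            continue
        if stanza_type is None:
            continue  # header lines (format-version, date, ...)
        if ":" not in stripped:
            raise OboParseError(f"malformed tag line: {stripped!r}", line=line_no)
        key, _, value = stripped.partition(":")
        # strip trailing OBO comments but keep "!" inside quoted defs
        if "!" in value and '"' not in value:
            value = value.split("!", 1)[0]
        fields.append((line_no, key.strip(), value.strip()))
    if stanza_type is not None:
        yield stanza_type, start_line, fields


def parse_obo(
    stream: IO[str] | Iterable[str],
    relationships: Iterable[str] = DEFAULT_RELATIONSHIPS,
) -> OntologyDAG:
    """Parse OBO 1.2 ``[Term]`` stanzas into an :class:`OntologyDAG`.

    ``relationships`` is the allow-list of ``relationship:`` types treated
    as parent edges in addition to ``is_a``.  Raises
    :class:`OboParseError` for malformed stanzas (with the line number) and
    :class:`OntologyValidationError` for cyclic structure, dangling parent
    references, cross-namespace ``part_of`` edges, or a namespace with
    more than one root.
    """
    allowed_rel = frozenset(relationships)
    dag = OntologyDAG()
    for stanza_type, start_line, fields in _iter_stanzas(stream):
        if stanza_type != "Term":
            continue
        term_id: str | None = None
        name = ""
        namespace = ""
        parents: set[str] = set()
        alt_ids: list[str] = []
        is_obsolete = False
        replaced: list[str] = []
        for line_no, key, value in fields:
            if key == "id":
                if not GO_ACCESSION_RE.match(value.strip()):
                    raise OboParseError(
                        f"invalid term id {value!r}", line=line_no
                    )
                term_id = value.strip()
            elif key == "name":
                name = value
            elif key == "namespace":
                namespace = value
            elif key == "is_a":
                parents.add(value.split("!", 1)[0].strip())
            elif key == "relationship":
                parts = value.split()
                if len(parts) >= 2 and parts[0] in allowed_rel:
                    parents.add(parts[1].strip())
            elif key == "alt_id":
                alt_ids.append(value.strip())
            elif key == "is_obsolete":
                is_obsolete = value.strip().lower() == "true"
            elif key == "replaced_by":
                replaced.append(value.strip())
        if term_id is None:
            raise OboParseError("[Term] stanza missing id", line=start_line)
        if is_obsolete:
            dag.obsolete_ids.add(term_id)
            # >1 replacement (or consider-only) is treated as no replacement
            if len(replaced) == 1:
                dag.replaced_by[term_id] = replaced[0]
        else:
            dag.terms[term_id] = GOTerm(
                term_id=term_id,
                name=name,
                namespace=namespace,
                parent_ids=parents,
            )
        for alt in alt_ids:
            dag.alt_id_map[alt] = term_id

    _validate(dag)
    return dag


def _validate(dag: OntologyDAG) -> None:
    for term in dag.terms.values():
        for parent in term.parent_ids:
            if parent not in dag.terms:
                raise OntologyValidationError(
                    f"term {term.term_id} has parent {parent} "
                    "that is not a current term"
                )
            pns = dag.terms[parent].namespace
            if pns != term.namespace:
                raise OntologyValidationError(
                    f"edge {term.term_id} -> {parent} crosses namespaces "
                    f"({term.namespace!r} -> {pns!r})"
                )
    g = dag.graph()
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        pass
    else:
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyValidationError(f"cyclic is_a structure: {path}")
    # exactly one root per namespace among current terms
    roots: dict[str, list[str]] = {}
    for term in dag.terms.values():
        if not term.parent_ids:
            roots.setdefault(term.namespace, []).append(term.term_id)
    for namespace, ids in roots.items():
        if len(ids) > 1:
            raise OntologyValidationError(
                f"namespace {namespace!r} has multiple roots: {sorted(ids)}"
            )
        dag.root_ids[namespace] = ids[0]


def resolve_term(dag: OntologyDAG, accession: str) -> Resolution:
    """Resolve an accession to its preferred current accession.

    Accessions are compared case-sensitively after trimming surrounding
    whitespace.  A synonymous accession whose preferred term is itself
    obsolete resolves as obsolete.
    """
    accession = accession.strip()
    if accession in dag.terms:
        return Resolution("current", accession)
    if accession in dag.alt_id_map:
        target = dag.alt_id_map[accession]
        if target in dag.obsolete_ids:
            return Resolution("obsolete")
        return Resolution("current", target, was_synonym=True)
    if accession in dag.obsolete_ids:
        return Resolution("obsolete")
    return Resolution("unknown")


def compute_depths(dag: OntologyDAG) -> TermDepthMap:
    """Breadth-first depths from each namespace root.

    depth[root] = 0 and depth[t] = 1 + min over parents of depth[parent].
    Raises :class:`OntologyValidationError` naming any term unreachable
    from its namespace root.
    """
    children = dag.children_of()
    depth: dict[str, int] = {}
    for root in dag.root_ids.values():
        depth[root] = 0
        frontier = [root]
        while frontier:
            nxt: list[str] = []
            for tid in frontier:
                for child in children[tid]:
                    if child not in depth:
                        depth[child] = depth[tid] + 1
                        nxt.append(child)
            frontier = nxt
    missing = [tid for tid in dag.terms if tid not in depth]
    if missing:
        raise OntologyValidationError(
            f"term {missing[0]} has no path to its namespace root"
        )
    return TermDepthMap(depth)


def cache_dag(dag: OntologyDAG, path: str) -> None:
    """Serialize the DAG to ``path`` as versioned JSON."""
    payload = {
        "format_version": CACHE_FORMAT_VERSION,
        "terms": {
            t.term_id: {
                "name": t.name,
                "namespace": t.namespace,
                "parent_ids": sorted(t.parent_ids),
            }
            for t in dag.terms.values()
        },
        "alt_id_map": dag.alt_id_map,
        "obsolete_ids": sorted(dag.obsolete_ids),
        "replaced_by": dag.replaced_by,
        "root_ids": dag.root_ids,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_cached(path: str) -> OntologyDAG:
    """Load a DAG previously written by :func:`cache_dag`.

    Raises :class:`CacheError` on corrupt content or a format-version
    mismatch; the caller should re-parse the OBO source in that case.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise CacheError(
            f"cannot read ontology cache {path!r} ({exc}); re-parse the OBO file"
        ) from exc
    if not isinstance(payload, Mapping) or "format_version" not in payload:
        raise CacheError(
            f"ontology cache {path!r} has no format version; re-parse the OBO file"
        )
    version = payload["format_version"]
    if version != CACHE_FORMAT_VERSION:
        raise CacheError(
            f"ontology cache {path!r} has format version {version}, "
            f"expected {CACHE_FORMAT_VERSION}; re-parse the OBO file"
        )
    dag = OntologyDAG(
        terms={
            tid: GOTerm(
                term_id=tid,
                name=rec["name"],
                namespace=rec["namespace"],
                parent_ids=set(rec["parent_ids"]),
            )
            for tid, rec in payload["terms"].items()
        },
        alt_id_map=dict(payload["alt_id_map"]),
        obsolete_ids=set(payload["obsolete_ids"]),
        replaced_by=dict(payload["replaced_by"]),
        root_ids=dict(payload["root_ids"]),
    )
    return dag
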