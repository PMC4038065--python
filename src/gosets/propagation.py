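"""True-path-rule propagation of gene annotations up the ontology.

A gene annotated to a term is implicitly annotated to every ancestor of
that term.  Annotation databases mostly record only the specific terms, so
a set built from direct annotations alone misses most of its biologically
relevant members; making the implicit annotations explicit — propagating
each gene up the DAG towards the namespace root — is what turns per-term
annotation lists into usable gene sets.

The propagation here is a single memoized sweep in topological order:
each term's member set is computed once by unioning its own direct members
with its children's (already complete) sets, rather than walking upward
from every association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .associations import Association
from .errors import ContractViolation
from .ontology import OntologyDAG

__all__ = ["TermGeneIndex", "build_index", "propagate", "propagated_fraction"]


@dataclass
class TermGeneIndex:
    """Per-term gene membership.

    ``members`` maps term accession -> set of gene identifiers.
    ``provenance`` records each term's count of *direct* (pre-propagation)
    memberships, so the fraction of memberships created by propagation
    stays computable after the sweep.
    """

    members: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)

    def total_memberships(self) -> int:
        return sum(len(genes) for genes in self.members.values())

    def direct_memberships(self) -> int:
        return sum(self.provenance.get(t, 0) for t in self.members)


def build_index(assocs: Sequence[Association]) -> TermGeneIndex:
    """Group resolved associations into direct per-term gene sets.

    Duplicate (gene, term) pairs — e.g. the same annotation under two
    evidence codes — collapse to a single membership.
    """
    members: dict[str, set[str]] = {}
    for a in assocs:
        members.setdefault(a.term_id, set()).add(a.gene_id)
    provenance = {t: len(genes) for t, genes in members.items()}
    return TermGeneIndex(members=members, provenance=provenance)


def propagate(index: TermGeneIndex, dag: OntologyDAG) -> TermGeneIndex:
    """Propagate direct memberships to every ancestor term.

    Returns a new index where ``members[t]`` is the union of the direct
    members of ``t`` and of all its descendants through parent edges.
    Terms that end up with no members are omitted.  Terms in the index
    that are absent from the DAG are a contract violation: accessions must
    be resolved against the ontology before propagation.
    """
    stray = [t for t in index.members if t not in dag.terms]
    if stray:
        raise ContractViolation(
            f"term {stray[0]} in the index is not a current ontology term; "
            "run association resolution before propagation"
        )
    acc: dict[str, set[str]] = {
        t: set(genes) for t, genes in index.members.items()
    }
    # edges child -> parent; topological order yields children first,
    # so one union sweep makes every parent's set transitively complete
    for term_id in nx.topological_sort(dag.graph()):
        genes = acc.get(term_id)
        if not genes:
            continue
        for parent in dag.terms[term_id].parent_ids:
            acc.setdefault(parent, set()).update(genes)
    members = {t: genes for t, genes in acc.items() if genes}
    provenance = {
        t: index.provenance.get(t, 0) for t in members
    }
    return TermGeneIndex(members=members, provenance=provenance)


def propagated_fraction(index: TermGeneIndex) -> float | None:
    """Fraction of term memberships created by propagation.

    (total memberships - direct memberships) / total memberships over all
    terms in the index.  Returns None for an empty index (no data).
    """
    total = index.total_memberships()
    if total == 0:
        return None
    return (total - index.direct_memberships()) / total
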