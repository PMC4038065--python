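"""Post-processing and output: size filtering, duplicate collapsing,
level-annotated descriptions, and .gmt / .gmx serialization.

GO-derived collections routinely contain several terms with exactly the
same gene membership (typically a parent whose genes all arrive from one
child).  Identical sets distort the GSEA false-discovery-rate estimate, so
each distinct gene content is emitted once — but, unlike collections that
silently discard the duplicates, the description field of each output set
lists *every* term sharing that content, each with its distance from the
namespace root ("level") as a specificity guide.  The set's name and URL
come from the most general of those terms (minimum depth).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Sequence

from .errors import ConfigError, ContractViolation
from .ontology import OntologyDAG, TermDepthMap
from .propagation import TermGeneIndex

#: Default AmiGO term-detail URL pattern; ``{accession}`` is substituted.
DEFAULT_URL_TEMPLATE = "http://amigo.geneontology.org/amigo/term/{accession}"

#: Default size bounds: below 10 genes a set rarely reaches significance,
#: above 700 the term is too general to interpret.
DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 700


@dataclass(frozen=True)
class TermInfo:
    """One contributing term of a gene set: accession, label, depth."""

    term_id: str
    name: str
    depth: int


@dataclass
class GeneSet:
    """A unique gene content with all GO terms that share it.

    ``representative`` is the member of ``all_terms`` with minimum depth
    (the most general term); ties break on lexicographically smallest
    accession.  ``genes`` is sorted for deterministic output.
    """

    set_name: str
    genes: list[str]
    all_terms: list[TermInfo]
    representative: TermInfo
    url: str


@dataclass
class Collection:
    """An ordered list of gene sets plus run provenance."""

    sets: list[GeneSet] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)


def size_filter(index: TermGeneIndex, min_size: int, max_size: int) -> TermGeneIndex:
    """Retain terms whose member count lies in [min_size, max_size]
    (inclusive on both bounds)."""
    if min_size > max_size:
        raise ConfigError(f"min_size {min_size} exceeds max_size {max_size}")
    members = {
        t: genes
        for t, genes in index.members.items()
        if min_size <= len(genes) <= max_size
    }
    provenance = {t: index.provenance.get(t, 0) for t in members}
    return TermGeneIndex(members=members, provenance=provenance)


def sanitize_set_name(name: str) -> str:
    """MSigDB-style set name: uppercase, runs of non-alphanumerics
    collapsed to single underscores."""
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").upper()


def collapse_duplicates(
    index: TermGeneIndex,
    depths: TermDepthMap,
    dag: OntologyDAG,
    url_template: str = DEFAULT_URL_TEMPLATE,
) -> list[GeneSet]:
    """Group terms with identical gene content into single gene sets.

    Each distinct gene content yields one :class:`GeneSet` whose
    ``all_terms`` lists every contributing term ordered by (depth,
    accession); the first entry — minimum depth, smallest accession on
    ties — is the representative.  Name collisions gain "_2", "_3", ...
    suffixes in representative-accession order.
    """
    for t in index.members:
        if t not in depths:
            raise ContractViolation(f"term {t} missing from the depth map")
    by_content: dict[frozenset[str], list[str]] = {}
    for t, genes in index.members.items():
        by_content.setdefault(frozenset(genes), []).append(t)

    sets: list[GeneSet] = []
    for content, term_ids in by_content.items():
        infos = sorted(
            (
                TermInfo(t, dag.terms[t].name if t in dag.terms else "", depths[t])
                for t in term_ids
            ),
            key=lambda info: (info.depth, info.term_id),
        )
        rep = infos[0]
        sets.append(
            GeneSet(
                set_name=sanitize_set_name(rep.name) or rep.term_id.replace(":", "_"),
                genes=sorted(content),
                all_terms=infos,
                representative=rep,
                url=url_template.format(accession=rep.term_id),
            )
        )
    sets.sort(key=lambda s: s.representative.term_id)
    _disambiguate_names(sets)
    return sets


def _disambiguate_names(sets: Sequence[GeneSet]) -> None:
    seen: dict[str, int] = {}
    for s in sets:
        n = seen.get(s.set_name, 0) + 1
        seen[s.set_name] = n
        if n > 1:
            s.set_name = f"{s.set_name}_{n}"


def format_description(gene_set: GeneSet) -> str:
    """Enumerate all contributing terms with their levels.

    Grammar: entries joined by ``|``; each entry
    ``GO:NNNNNNN <term name> [level D]``.
    """
    return "|".join(
        f"{info.term_id} {info.name} [level {info.depth}]"
        for info in gene_set.all_terms
    )


def _second_field(gene_set: GeneSet, url_only: bool) -> str:
    if url_only:
        return gene_set.url
    return f"{gene_set.url} {format_description(gene_set)}"


def write_gmt(collection: Collection, stream: IO[str], url_only: bool = False) -> None:
    """Write the MSigDB .gmt layout: one set per line,
    name TAB url+description TAB gene TAB gene ...

    ``url_only`` restricts the second field to the URL for strict MSigDB
    mimicry; by default it carries "URL<space>description" so both the
    link and the full term list survive inside the format's single
    free-text field.
    """
    for s in collection.sets:
        fields = [s.set_name, _second_field(s, url_only), *s.genes]
        stream.write("\t".join(fields) + "\n")


def write_gmx(collection: Collection, stream: IO[str], url_only: bool = False) -> None:
    """Write the MSigDB .gmx layout — the transpose of .gmt: one set per
    column; row 1 names, row 2 descriptions, then genes, short columns
    padded with empty fields."""
    columns = [
        [s.set_name, _second_field(s, url_only), *s.genes]
        for s in collection.sets
    ]
    if not columns:
        return
    height = max(len(col) for col in columns)
    for row_idx in range(height):
        row = [col[row_idx] if row_idx < len(col) else "" for col in columns]
        stream.write("\t".join(row) + "\n")


def build_collection(
    index: TermGeneIndex,
    depths: TermDepthMap,
    dag: OntologyDAG,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    url_template: str = DEFAULT_URL_TEMPLATE,
    params: dict | None = None,
    warnings: dict | None = None,
) -> Collection:
    """Size-filter a propagated index and collapse it into a collection."""
    filtered = size_filter(index, min_size, max_size)
    sets = collapse_duplicates(filtered, depths, dag, url_template)
    return Collection(sets=sets, params=params or {}, warnings=warnings or {})
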