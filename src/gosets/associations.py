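"""Gene-GO association acquisition, filtering and resolution.

Three source dialects are supported:

* NCBI ``gene2go`` — tab-separated, one row per (taxon, Entrez Gene ID,
  GO term, evidence code); ``#`` comment/header lines.
* GAF 2.x — the GO association file format: 17 tab-separated columns,
  ``!`` comment lines.  The gene identifier is either the DB object ID
  (column 2) or the symbol (column 3), at the user's choice.
* Array annotation files (Affymetrix NetAffx CSV, or a tab-separated
  Agilent-style layout) — probe-keyed, typically without evidence codes.

Rows whose qualifier contains ``NOT`` assert *non*-membership and are
excluded by every reader.  After reading, associations can be filtered by
evidence code, have their gene identifiers remapped through a two-column
map file, and are resolved against the ontology: synonymous accessions are
rewritten to the preferred accession, obsolete and unknown accessions are
dropped, and the three kinds of anomaly are counted for reporting.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

from .errors import DialectError, GosetsError
from .ontology import GO_ACCESSION_RE, OntologyDAG, resolve_term

logger = logging.getLogger("gosets")

#: Standard GO evidence codes (experimental, curated, computational and
#: electronic classes).
ALL_EVIDENCE_CODES: frozenset[str] = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA",
    }
)

#: Named evidence profiles.  ``high_quality`` drops electronically inferred
#: (IEA), no-data (ND) and non-traceable (NAS) annotations; ``all``
#: disables evidence filtering entirely.
EVIDENCE_PROFILES: dict[str, frozenset[str] | None] = {
    "all": None,
    "high_quality": ALL_EVIDENCE_CODES - {"IEA", "ND", "NAS"},
}


@dataclass(frozen=True)
class Association:
    """One gene-to-term annotation.  ``evidence`` is None for sources
    that carry no evidence codes (array annotation files)."""

    gene_id: str
    term_id: str
    evidence: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not GO_ACCESSION_RE.match(self.term_id):
            raise ValueError(f"not a GO accession: {self.term_id!r}")


@dataclass
class ResolutionCounters:
    """Warning counters from :func:`resolve_associations`."""

    synonyms_remapped: int = 0
    obsoletes_dropped: int = 0
    unknown_dropped: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "synonyms_remapped": self.synonyms_remapped,
            "obsoletes_dropped": self.obsoletes_dropped,
            "unknown_dropped": self.unknown_dropped,
        }


@dataclass
class IdMap:
    """Gene-identifier translation loaded from a two-column file.

    ``keep_unmapped`` leaves identifiers absent from the map unchanged
    (useful for partial remaps); ``drop_unmapped`` removes them (useful to
    restrict a multi-species annotation file to one species).
    """

    mapping: dict[str, str] = field(default_factory=dict)
    mode: str = "keep_unmapped"

    def __post_init__(self) -> None:
        if self.mode not in ("keep_unmapped", "drop_unmapped"):
            raise ValueError(f"unknown IdMap mode {self.mode!r}")


def load_id_map(stream: IO[str] | Iterable[str], mode: str = "keep_unmapped") -> IdMap:
    """Read a two-column tab-separated source -> target map; ``#`` comments
    allowed.  Duplicate source keys are a load error."""
    mapping: dict[str, str] = {}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise GosetsError(
                f"id map line {line_no}: expected two tab-separated columns"
            )
        src, dst = parts[0].strip(), parts[1].strip()
        if src in mapping:
            raise GosetsError(f"id map line {line_no}: duplicate source key {src!r}")
        mapping[src] = dst
    return IdMap(mapping=mapping, mode=mode)


def _dedupe(assocs: Iterable[Association]) -> list[Association]:
    """Drop exact duplicates, preserving first-seen order."""
    seen: set[Association] = set()
    out: list[Association] = []
    for a in assocs:
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def read_gene2go(
    stream: IO[str] | Iterable[str],
    taxon: int,
    id_choice: str = "entrez_id",
) -> list[Association]:
    """Read an NCBI gene2go table, keeping only rows for ``taxon``.

    gene2go carries no gene symbols; ``id_choice`` other than
    ``entrez_id`` is rejected — remap Entrez IDs to symbols through an
    :class:`IdMap` instead.  Rows qualified ``NOT`` are excluded.
    """
    if id_choice != "entrez_id":
        raise GosetsError(
            "gene2go provides Entrez Gene IDs only; use an id map file "
            "to translate to symbols"
        )
    out: list[Association] = []
    n_rows = 0
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            logger.warning("gene2go line %d: expected >=4 columns, skipped", line_no)
            continue
        n_rows += 1
        try:
            row_taxon = int(cols[0])
        except ValueError:
            logger.warning("gene2go line %d: bad tax_id %r, skipped", line_no, cols[0])
            continue
        if row_taxon != taxon:
            continue
        qualifier = cols[4].strip() if len(cols) > 4 else ""
        if "NOT" in qualifier.split("|"):
            continue
        out.append(Association(cols[1].strip(), cols[2].strip(), cols[3].strip()))
    if not out:
        logger.warning("gene2go: no associations found for taxon %d", taxon)
    return _dedupe(out)


def read_gaf(
    stream: IO[str] | Iterable[str],
    taxon: int | None = None,
    id_choice: str = "symbol",
) -> list[Association]:
    """Read a GAF 2.x file.

    ``id_choice``: ``symbol`` keys associations by column 3 (DB object
    symbol), ``object_id`` by column 2 (DB object ID).  A qualifier field
    containing ``NOT`` excludes the row.  When ``taxon`` is given, the
    column-13 taxon field is matched against ``taxon:<id>``.
    """
    if id_choice not in ("symbol", "object_id"):
        raise GosetsError(f"unknown id_choice {id_choice!r}")
    out: list[Association] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            logger.warning("GAF line %d: expected >=15 columns, skipped", line_no)
            continue
        qualifier = cols[3].strip()
        if "NOT" in qualifier.split("|"):
            continue
        if taxon is not None:
            taxa = _parse_gaf_taxa(cols[12])
            if taxa is None:
                logger.warning(
                    "GAF line %d: unparseable taxon field %r, skipped under "
                    "active taxon filter", line_no, cols[12],
                )
                continue
            if taxon not in taxa:
                continue
        gene = cols[2].strip() if id_choice == "symbol" else cols[1].strip()
        evidence = cols[6].strip()
        out.append(Association(gene, cols[4].strip(), evidence))
    if not out:
        logger.warning("GAF: no associations read")
    return _dedupe(out)


def _parse_gaf_taxa(fieldval: str) -> set[int] | None:
    taxa: set[int] = set()
    for part in fieldval.strip().split("|"):
        m = re.match(r"^taxon:(\d+)$", part.strip())
        if not m:
            return None
        taxa.add(int(m.group(1)))
    return taxa or None


_AFFY_GO_COLUMNS = (
    "Gene Ontology Biological Process",
    "Gene Ontology Cellular Component",
    "Gene Ontology Molecular Function",
)
_AFFY_PROBE_COLUMN = "Probe Set ID"
#: NetAffx GO cell entry: "<numeric id> // <term name> // <evidence>"
_AFFY_ENTRY_RE = re.compile(r"^\s*(\d{1,7})\s*//\s*[^/]*?\s*//\s*(\S*)\s*$")

#: Agilent-style GO cell entry: "GO:NNNNNNN" with optional "(EVIDENCE)".
_AGILENT_ENTRY_RE = re.compile(r"^\s*(GO:\d{7})(?:\((\w+)\))?\s*$")


def read_array_annotation(
    stream: IO[str] | Iterable[str],
    dialect: str,
    probe_column: str | None = None,
    go_columns: Sequence[str] | None = None,
) -> list[Association]:
    """Read probe-to-GO associations from an array annotation file.

    ``affymetrix``: quoted CSV with ``#`` comment header; GO cells hold
    ``///``-separated entries ``<id> // <name> // <evidence>`` (``---``
    marks an empty cell).  ``agilent``: tab-separated; the GO column holds
    ``|``-separated ``GO:NNNNNNN(EVIDENCE)`` entries, evidence optional.
    Column names can be overridden for non-standard exports.
    """
    if dialect == "affymetrix":
        return _read_affymetrix(stream, probe_column, go_columns)
    if dialect == "agilent":
        return _read_agilent(stream, probe_column, go_columns)
    raise DialectError(f"unknown array dialect {dialect!r}")


def _read_affymetrix(stream, probe_column, go_columns) -> list[Association]:
    probe_column = probe_column or _AFFY_PROBE_COLUMN
    go_columns = tuple(go_columns) if go_columns else _AFFY_GO_COLUMNS
    rows = csv.reader(line for line in stream if not line.startswith("#"))
    try:
        header = next(rows)
    except StopIteration:
        raise DialectError("affymetrix annotation file is empty") from None
    index = {name: i for i, name in enumerate(header)}
    if probe_column not in index:
        raise DialectError(f"missing probe column {probe_column!r}")
    present = [c for c in go_columns if c in index]
    if not present:
        raise DialectError(f"no GO columns found (looked for {list(go_columns)})")
    out: list[Association] = []
    for row_no, row in enumerate(rows, start=2):
        if len(row) <= index[probe_column]:
            logger.warning("affymetrix row %d: too few columns, skipped", row_no)
            continue
        probe = row[index[probe_column]].strip()
        for col in present:
            if len(row) <= index[col]:
                continue
            cell = row[index[col]].strip()
            if not cell or cell == "---":
                continue
            for entry in cell.split("///"):
                if not entry.strip():
                    continue
                m = _AFFY_ENTRY_RE.match(entry)
                if not m:
                    logger.warning(
                        "affymetrix row %d: malformed GO entry %r, skipped",
                        row_no, entry.strip(),
                    )
                    continue
                accession = "GO:" + m.group(1).zfill(7)
                evidence = m.group(2) or None
                out.append(Association(probe, accession, evidence))
    return _dedupe(out)


_AGILENT_PROBE_COLUMN = "ProbeID"
_AGILENT_GO_COLUMN = "GO"


def _read_agilent(stream, probe_column, go_columns) -> list[Association]:
    probe_column = probe_column or _AGILENT_PROBE_COLUMN
    go_column = (list(go_columns) or [_AGILENT_GO_COLUMN])[0] if go_columns else _AGILENT_GO_COLUMN
    lines = (line.rstrip("\n") for line in stream if not line.startswith("#"))
    try:
        header = next(lines).split("\t")
    except StopIteration:
        raise DialectError("agilent annotation file is empty") from None
    index = {name: i for i, name in enumerate(header)}
    if probe_column not in index:
        raise DialectError(f"missing probe column {probe_column!r}")
    if go_column not in index:
        raise DialectError(f"missing GO column {go_column!r}")
    out: list[Association] = []
    for row_no, line in enumerate(lines, start=2):
        cols = line.split("\t")
        if len(cols) <= max(index[probe_column], index[go_column]):
            logger.warning("agilent row %d: too few columns, skipped", row_no)
            continue
        probe = cols[index[probe_column]].strip()
        cell = cols[index[go_column]].strip()
        if not cell:
            continue
        for entry in cell.split("|"):
            if not entry.strip():
                continue
            m = _AGILENT_ENTRY_RE.match(entry)
            if not m:
                logger.warning(
                    "agilent row %d: malformed GO entry %r, skipped",
                    row_no, entry.strip(),
                )
                continue
            out.append(Association(probe, m.group(1), m.group(2)))
    return _dedupe(out)


def filter_by_evidence(
    assocs: Sequence[Association],
    allowed: Iterable[str] | None,
) -> list[Association]:
    """Keep associations whose evidence code is in ``allowed``.

    ``allowed=None`` disables filtering (everything passes, including
    evidence-free associations from array sources).  With an active
    filter, evidence-free associations are excluded with a warning that
    the source carried no codes.
    """
    if allowed is None:
        return list(assocs)
    allowed_set = frozenset(allowed)
    if not allowed_set:
        raise GosetsError("evidence allow-list is empty; use None to disable filtering")
    unknown = allowed_set - ALL_EVIDENCE_CODES
    if unknown:
        logger.warning("unrecognised evidence codes in allow-list: %s", sorted(unknown))
    n_no_code = sum(1 for a in assocs if a.evidence is None)
    if n_no_code:
        logger.warning(
            "%d associations carry no evidence code (source provides none) "
            "and were excluded by the evidence filter", n_no_code,
        )
    return [a for a in assocs if a.evidence is not None and a.evidence in allowed_set]


def apply_id_map(assocs: Sequence[Association], id_map: IdMap) -> list[Association]:
    """Substitute gene identifiers through ``id_map``.

    Unmapped identifiers are kept verbatim (``keep_unmapped``) or removed
    with a reported count (``drop_unmapped``).
    """
    out: list[Association] = []
    n_dropped = 0
    for a in assocs:
        if a.gene_id in id_map.mapping:
            out.append(replace(a, gene_id=id_map.mapping[a.gene_id]))
        elif id_map.mode == "keep_unmapped":
            out.append(a)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("id map: dropped %d associations with unmapped identifiers", n_dropped)
    return _dedupe(out)


def resolve_associations(
    assocs: Sequence[Association],
    dag: OntologyDAG,
) -> tuple[list[Association], ResolutionCounters]:
    """Resolve every accession against the ontology.

    Synonymous accessions are rewritten to the preferred accession;
    associations citing obsolete terms or terms absent from the ontology
    are dropped.  All three anomaly kinds are counted, never fatal.
    """
    counters = ResolutionCounters()
    out: list[Association] = []
    for a in assocs:
        res = resolve_term(dag, a.term_id)
        if res.status == "current":
            if res.was_synonym:
                counters.synonyms_remapped += 1
                out.append(replace(a, term_id=res.accession))
            else:
                out.append(a)
        elif res.status == "obsolete":
            counters.obsoletes_dropped += 1
        else:
            counters.unknown_dropped += 1
    if counters.synonyms_remapped:
        logger.warning(
            "%d associations cited synonymous GO terms and were remapped "
            "to the preferred accession", counters.synonyms_remapped,
        )
    if counters.obsoletes_dropped:
        logger.warning(
            "%d associations cited obsolete GO terms and were discarded",
            counters.obsoletes_dropped,
        )
    if counters.unknown_dropped:
        logger.warning(
            "%d associations cited GO terms absent from the ontology and "
            "were discarded", counters.unknown_dropped,
        )
    return _dedupe(out), counters
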