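"""Synthetic ontology and association generators with ground truth.

Every stage of the pipeline — OBO parsing, the three association reader
dialects, resolution, propagation, output — can be exercised without
downloading real GO releases: the generators here emit syntactically
valid files (actual text, so comment handling, quoting and padding are
parsed for real) alongside the ground truth an oracle test needs (the
exact edge list, the alternate-id and obsolete accession maps, the
post-resolution association list and the expected warning counters).

The generators target code-path coverage, not statistical realism of GO
term-size distributions.  Output is a deterministic function of the spec
(identical spec + seed => identical bytes).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .associations import Association, ResolutionCounters
from .errors import GosetsError

__all__ = [
    "FixtureSpec",
    "OntologyTruth",
    "AssociationTruth",
    "make_ontology",
    "make_associations",
    "make_id_map",
    "sarcomere_like_fixture",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_terms: int = 50
    max_parents: int = 3
    n_genes: int = 100
    n_assocs: int = 200
    obsolete_fraction: float = 0.1
    synonym_fraction: float = 0.1
    evidence_mix: tuple[tuple[str, float], ...] = (
        ("IEA", 0.5),
        ("TAS", 0.3),
        ("IDA", 0.2),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 3:
            raise GosetsError("n_terms must be >= 3 (a root plus two levels)")
        for frac in (self.obsolete_fraction, self.synonym_fraction):
            if not 0.0 <= frac <= 1.0:
                raise GosetsError("fractions must lie in [0, 1]")


@dataclass
class OntologyTruth:
    """Ground truth accompanying a generated OBO file."""

    root_id: str
    namespace: str
    edges: list[tuple[str, str]]  # (child, parent)
    names: dict[str, str]
    alt_id_map: dict[str, str]
    obsolete_ids: list[str]
    replaced_by: dict[str, str]

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.names)


def _acc(n: int) -> str:
    return f"GO:{n:07d}"


def make_ontology(spec: FixtureSpec) -> tuple[str, OntologyTruth]:
    """Emit an OBO 1.2 file plus its ground truth.

    The DAG is acyclic by construction: term i draws its parents only
    from terms generated before it.  Roughly 30% of parent edges are
    written as ``relationship: part_of`` rather than ``is_a``.  Alternate
    ids and obsolete stanzas (half with a ``replaced_by`` target) are
    appended in accession ranges disjoint from the current terms.
    """
    rng = random.Random(spec.seed)
    namespace = "biological_process"
    term_ids = [_acc(i) for i in range(1, spec.n_terms + 1)]
    names = {tid: f"synthetic process {tid[3:]}" for tid in term_ids}
    edges: list[tuple[str, str]] = []
    edge_kind: dict[tuple[str, str], str] = {}
    for i in range(2, spec.n_terms + 1):
        child = _acc(i)
        n_parents = rng.randint(1, min(spec.max_parents, i - 1))
        parents = rng.sample(term_ids[: i - 1], n_parents)
        for parent in parents:
            edges.append((child, parent))
            edge_kind[(child, parent)] = (
                "part_of" if rng.random() < 0.3 else "is_a"
            )

    n_syn = round(spec.synonym_fraction * spec.n_terms)
    alt_id_map = {
        _acc(spec.n_terms + k): rng.choice(term_ids) for k in range(1, n_syn + 1)
    }
    n_obs = round(spec.obsolete_fraction * spec.n_terms)
    obsolete_ids = [
        _acc(spec.n_terms + n_syn + k) for k in range(1, n_obs + 1)
    ]
    replaced_by = {
        obs: rng.choice(term_ids) for j, obs in enumerate(obsolete_ids) if j % 2 == 0
    }

    alts_by_term: dict[str, list[str]] = {}
    for alt, tid in alt_id_map.items():
        alts_by_term.setdefault(tid, []).append(alt)

    lines = ["format-version: 1.2", ""]
    for tid in term_ids:
        lines += ["[Term]", f"id: {tid}", f"name: {names[tid]}",
                  f"namespace: {namespace}"]
        for alt in sorted(alts_by_term.get(tid, [])):
            lines.append(f"alt_id: {alt}")
        for child, parent in edges:
            if child != tid:
                continue
            if edge_kind[(child, parent)] == "is_a":
                lines.append(f"is_a: {parent} ! {names[parent]}")
            else:
                lines.append(f"relationship: part_of {parent} ! {names[parent]}")
        lines.append("")
    for obs in obsolete_ids:
        lines += ["[Term]", f"id: {obs}", f"name: obsolete synthetic {obs[3:]}",
                  f"namespace: {namespace}", "is_obsolete: true"]
        if obs in replaced_by:
            lines.append(f"replaced_by: {replaced_by[obs]}")
        lines.append("")
    truth = OntologyTruth(
        root_id=term_ids[0],
        namespace=namespace,
        edges=edges,
        names=names,
        alt_id_map=alt_id_map,
        obsolete_ids=obsolete_ids,
        replaced_by=replaced_by,
    )
    return "\n".join(lines), truth


@dataclass
class AssociationTruth:
    """Expected reader + resolver behaviour for a generated file.

    ``associations`` is the expected *post-resolution* list (synonyms
    already rewritten to the preferred accession; obsolete/unknown rows
    absent; exact duplicates removed) for the dialect's default identifier
    choice and, for gene2go, the target taxon.
    """

    associations: list[Association]
    counters: ResolutionCounters
    n_not_rows: int = 0
    n_decoy_taxon_rows: int = 0


#: Injection rates for anomalous rows, as fractions of n_assocs.
_NOT_FRACTION = 0.1
_SYNONYM_FRACTION = 0.1
_OBSOLETE_FRACTION = 0.1
_UNKNOWN_FRACTION = 0.1

_TARGET_TAXON = 10090
_DECOY_TAXON = 9606


def _sample_evidence(rng: random.Random, mix) -> str:
    codes = [c for c, _ in mix]
    weights = [w for _, w in mix]
    return rng.choices(codes, weights=weights, k=1)[0]


def make_associations(
    spec: FixtureSpec,
    truth: OntologyTruth,
    dialect: str,
    taxon: int = _TARGET_TAXON,
) -> tuple[str, AssociationTruth]:
    """Emit an association file in one dialect plus its ground truth.

    Beyond ``n_assocs`` clean rows, the file carries controlled numbers of
    NOT-qualified rows, rows citing synonymous / obsolete / unknown
    accessions (to exercise the resolution counters) and, for gene2go,
    rows for a decoy taxon.  The ground truth excludes every row the
    pipeline must drop and counts what it must warn about.
    """
    if dialect not in ("gene2go", "gaf", "affymetrix"):
        raise GosetsError(f"unknown fixture dialect {dialect!r}")
    dialect_offset = {"gene2go": 1, "gaf": 2, "affymetrix": 3}[dialect]
    rng = random.Random(spec.seed * 7919 + dialect_offset)
    term_ids = truth.term_ids
    genes = [_gene_name(dialect, i) for i in range(1, spec.n_genes + 1)]

    rows: list[dict] = []  # row dicts in file order
    seen: set[tuple[str, str, str]] = set()
    for _ in range(spec.n_assocs):
        rows.append({
            "gene": rng.choice(genes),
            "term": rng.choice(term_ids),
            "evidence": _sample_evidence(rng, spec.evidence_mix),
            "kind": "clean",
        })

    def inject(kind: str, n: int, term_pool: list[str]) -> None:
        # dedicated gene range so injected rows never collide with clean
        # rows after resolution (keeps the expected counters exact)
        for k in range(1, n + 1):
            rows.append({
                "gene": _gene_name(dialect, 900000 + len(rows)),
                "term": term_pool[(spec.seed + k) % len(term_pool)]
                if term_pool else term_ids[0],
                "evidence": _sample_evidence(rng, spec.evidence_mix),
                "kind": kind,
            })

    n_not = round(_NOT_FRACTION * spec.n_assocs)
    n_syn = round(_SYNONYM_FRACTION * spec.n_assocs) if truth.alt_id_map else 0
    n_obs = round(_OBSOLETE_FRACTION * spec.n_assocs) if truth.obsolete_ids else 0
    n_unk = round(_UNKNOWN_FRACTION * spec.n_assocs)
    inject("not", n_not, term_ids)
    inject("synonym", n_syn, sorted(truth.alt_id_map))
    inject("obsolete", n_obs, sorted(truth.obsolete_ids))
    inject("unknown", n_unk, [_acc(9900000 + j) for j in range(1, 50)])
    if dialect == "gene2go":
        n_decoy = max(1, spec.n_assocs // 10)
        for _ in range(n_decoy):
            rows.append({
                "gene": rng.choice(genes),
                "term": rng.choice(term_ids),
                "evidence": _sample_evidence(rng, spec.evidence_mix),
                "kind": "decoy_taxon",
            })
    else:
        n_decoy = 0
    rng.shuffle(rows)

    counters = ResolutionCounters()
    expected: list[Association] = []
    for row in rows:
        if row["kind"] in ("not", "decoy_taxon"):
            continue
        if row["kind"] == "obsolete":
            counters.obsoletes_dropped += 1
            continue
        if row["kind"] == "unknown":
            counters.unknown_dropped += 1
            continue
        term = row["term"]
        if row["kind"] == "synonym":
            counters.synonyms_remapped += 1
            term = truth.alt_id_map[term]
        evidence = row["evidence"]
        key = (row["gene"], term, evidence)
        if key in seen:
            continue
        seen.add(key)
        expected.append(Association(row["gene"], term, evidence))

    if dialect == "gene2go":
        text = _emit_gene2go(rows, truth, taxon)
    elif dialect == "gaf":
        text = _emit_gaf(rows, truth, taxon)
    else:
        text = _emit_affymetrix(rows, truth)
    return text, AssociationTruth(
        associations=expected,
        counters=counters,
        n_not_rows=n_not,
        n_decoy_taxon_rows=n_decoy,
    )


def _gene_name(dialect: str, i: int) -> str:
    if dialect == "gene2go":
        return str(1000 + i)
    if dialect == "gaf":
        return f"GENE{i}"
    return f"{i}_at"


def _term_label(truth: OntologyTruth, term: str) -> str:
    return truth.names.get(term, "retired synthetic term")


def _emit_gene2go(rows, truth: OntologyTruth, taxon: int) -> str:
    lines = ["#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory"]
    for row in rows:
        tax = _DECOY_TAXON if row["kind"] == "decoy_taxon" else taxon
        qualifier = "NOT" if row["kind"] == "not" else "-"
        lines.append("\t".join([
            str(tax), row["gene"], row["term"], row["evidence"],
            qualifier, _term_label(truth, row["term"]), "-", "Process",
        ]))
    return "\n".join(lines) + "\n"


def _emit_gaf(rows, truth: OntologyTruth, taxon: int) -> str:
    lines = ["!gaf-version: 2.2"]
    for row in rows:
        qualifier = "NOT|involved_in" if row["kind"] == "not" else "involved_in"
        symbol = row["gene"]
        lines.append("\t".join([
            "SynDB", f"DB:{symbol}", symbol, qualifier, row["term"],
            "PMID:0000001", row["evidence"], "", "P",
            _term_label(truth, row["term"]), "", "protein",
            f"taxon:{taxon}", "20130901", "SynDB", "", "",
        ]))
    return "\n".join(lines) + "\n"


def _emit_affymetrix(rows, truth: OntologyTruth) -> str:
    by_probe: dict[str, list[dict]] = {}
    for row in rows:
        if row["kind"] == "not":  # NetAffx rows carry no qualifier
            continue
        by_probe.setdefault(row["gene"], []).append(row)
    lines = [
        "#%netaffx-annotation-tabular-format-version=1.0",
        "#%synthetic annotation fixture",
        '"Probe Set ID","Gene Symbol","Gene Ontology Biological Process",'
        '"Gene Ontology Cellular Component","Gene Ontology Molecular Function"',
    ]
    for probe in sorted(by_probe):
        entries = " /// ".join(
            f"{int(row['term'][3:])} // {_term_label(truth, row['term'])} "
            f"// {row['evidence']}"
            for row in by_probe[probe]
        )
        lines.append(
            f'"{probe}","SYM_{probe}","{entries}","---","---"'
        )
    return "\n".join(lines) + "\n"


def make_id_map(spec: FixtureSpec, dialect: str = "gene2go") -> tuple[str, dict[str, str]]:
    """Emit a two-column id map covering half of the fixture's genes."""
    mapping = {
        _gene_name(dialect, i): f"M_{_gene_name(dialect, i)}"
        for i in range(1, spec.n_genes + 1, 2)
    }
    lines = ["# source\ttarget"]
    lines += [f"{src}\t{dst}" for src, dst in sorted(mapping.items())]
    return "\n".join(lines) + "\n", mapping


# -- canned structural analogue of a sparsely annotated parent term --------

SARCOMERE_DIRECT = 16
SARCOMERE_DESCENDANT = 81


def sarcomere_like_fixture() -> tuple[str, str, dict]:
    """A canned DAG mirroring the motivating structure for propagation:
    a parent cellular-component-style term with 16 directly annotated
    genes whose child terms contribute 81 further distinct genes, so the
    parent's set grows from 16 to 97 after propagation.

    Synthetic stand-in: the term and gene identifiers are invented; only
    the 16/81/97 arithmetic mirrors real annotation sparsity.
    Returns (obo text, gene2go text, expectations dict).
    """
    root, parent = _acc(1), _acc(2)
    children = [_acc(3), _acc(4), _acc(5)]
    child_names = ["a band-like region", "i band-like region", "z disc-like region"]
    lines = ["format-version: 1.2", "",
             "[Term]", f"id: {root}", "name: cellular component root",
             "namespace: cellular_component", "",
             "[Term]", f"id: {parent}", "name: sarcomere-like assembly",
             "namespace: cellular_component", f"is_a: {root}", ""]
    for cid, cname in zip(children, child_names):
        lines += ["[Term]", f"id: {cid}", f"name: {cname}",
                  "namespace: cellular_component", f"is_a: {parent}", ""]
    obo_text = "\n".join(lines)

    g2g = ["#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory"]
    gene = 0
    for _ in range(SARCOMERE_DIRECT):
        gene += 1
        g2g.append(f"{_TARGET_TAXON}\t{gene}\t{parent}\tIDA\t-\tsarcomere-like assembly\t-\tComponent")
    for k in range(SARCOMERE_DESCENDANT):
        gene += 1
        child = children[k % len(children)]
        g2g.append(f"{_TARGET_TAXON}\t{gene}\t{child}\tIDA\t-\tchild term\t-\tComponent")
    expectations = {
        "parent_term": parent,
        "direct": SARCOMERE_DIRECT,
        "descendant_only": SARCOMERE_DESCENDANT,
        "after_propagation": SARCOMERE_DIRECT + SARCOMERE_DESCENDANT,
        "taxon": _TARGET_TAXON,
    }
    return obo_text, "\n".join(g2g) + "\n", expectations


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write ontology.obo, gene2go.tsv, assoc.gaf, array.csv, idmap.tsv
    and truth.json into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obo_text, onto_truth = make_ontology(spec)
    paths = {"ontology.obo": out / "ontology.obo"}
    paths["ontology.obo"].write_text(obo_text, encoding="utf-8")

    truth_doc: dict = {
        "spec": {
            "n_terms": spec.n_terms, "max_parents": spec.max_parents,
            "n_genes": spec.n_genes, "n_assocs": spec.n_assocs,
            "obsolete_fraction": spec.obsolete_fraction,
            "synonym_fraction": spec.synonym_fraction, "seed": spec.seed,
        },
        "ontology": {
            "root_id": onto_truth.root_id,
            "edges": sorted(onto_truth.edges),
            "alt_id_map": onto_truth.alt_id_map,
            "obsolete_ids": onto_truth.obsolete_ids,
        },
        "dialects": {},
    }
    for dialect, filename in (
        ("gene2go", "gene2go.tsv"), ("gaf", "assoc.gaf"),
        ("affymetrix", "array.csv"),
    ):
        text, assoc_truth = make_associations(spec, onto_truth, dialect)
        paths[filename] = out / filename
        paths[filename].write_text(text, encoding="utf-8")
        truth_doc["dialects"][dialect] = {
            "associations": [
                [a.gene_id, a.term_id, a.evidence]
                for a in assoc_truth.associations
            ],
            "counters": assoc_truth.counters.as_dict(),
            "n_not_rows": assoc_truth.n_not_rows,
            "n_decoy_taxon_rows": assoc_truth.n_decoy_taxon_rows,
        }
    idmap_text, mapping = make_id_map(spec)
    paths["idmap.tsv"] = out / "idmap.tsv"
    paths["idmap.tsv"].write_text(idmap_text, encoding="utf-8")
    truth_doc["id_map"] = mapping
    paths["truth.json"] = out / "truth.json"
    paths["truth.json"].write_text(
        json.dumps(truth_doc, indent=1, sort_keys=True), encoding="utf-8"
    )
    return paths
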