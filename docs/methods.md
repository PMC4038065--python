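# Methods

## Model

A Gene Ontology release is a set of three rooted directed acyclic graphs
(biological process, molecular function, cellular component); nodes are
terms, edges point from the more specific term to the more general one.
A gene–GO association assigns a gene to a term with an evidence code.
Under the true-path rule an annotation to a term entails annotation to
every ancestor, so the gene set of a term t is

    members(t) = direct(t) ∪ ⋃_{c : c →* t} direct(c)

where →* is reachability over propagating edges.  `gosets` computes this
closure for all terms, then size-filters, collapses duplicate contents,
and serializes.

### Propagating edge set

`is_a` is always a propagating edge.  `part_of` is included by default:
membership of a part implies involvement of the whole for the purpose of
set enrichment, and this matches the convention of the established
GO-based enrichment tools.  `regulates`, `negatively_regulates` and
`positively_regulates` are excluded — a regulator of a process is not a
member of it.  The allow-list is a parameter of `parse_obo` for users
who want `is_a`-only semantics.

### Propagation algorithm

A single sweep over terms in topological order (children before
parents): each term's accumulated gene set is unioned into each of its
parents.  Because every term is processed after all of its descendants,
one sweep yields the full transitive closure; each term's set is touched
once per incoming edge, so the cost is O(total set sizes × edges) in the
worst case and in practice seconds for ontology-scale inputs.  Terms
whose sets are empty after the sweep are dropped — they could never pass
any minimum size filter ≥ 1.  Direct (pre-propagation) membership counts
are kept alongside, so the fraction of memberships created by
propagation — the headline diagnostic of why propagation matters — is
computable at any later stage:

    propagated_fraction = (total memberships − direct memberships) / total memberships

An empty index yields an explicit no-data signal (`None`), not 0.

### Term depth ("level")

depth(root) = 0; depth(t) = 1 + min over parents of depth(parent),
computed by breadth-first search from each namespace root.  Depth is a
rough specificity guide appended to every term in the output
descriptions.  Shortest (not longest) path is used so that a term
reachable both directly and through a deep branch is labelled by its
most general placement.

## Input handling

* **Resolution order.** Evidence filtering precedes identifier mapping,
  which precedes accession resolution; resolution precedes propagation
  (propagation refuses unresolved accessions as a contract violation).
  Synonymous accessions are rewritten to the preferred accession;
  obsolete and unknown accessions are dropped.  All three anomalies are
  counted and reported, never fatal: they are expected whenever the
  ontology and the association source date from different releases.  A
  synonymous accession whose preferred target is itself obsolete is
  treated as obsolete.  An obsolete stanza with zero or multiple
  `replaced_by` targets is treated as obsolete with no replacement.
* **NOT qualifiers.** Rows whose qualifier contains `NOT` assert
  non-membership and are excluded by every reader; including them would
  poison every ancestor set during propagation.
* **Evidence profiles.** `all` disables filtering; `high_quality` is
  all standard codes minus IEA (electronic, uncurated), ND (no data) and
  NAS (non-traceable statement).  The exact code set behind the
  historical MSigDB GO build is not published, so `high_quality` is a
  documented convention, not a reproduction; any custom list is
  accepted, with unknown codes warned about rather than rejected
  (evidence codes evolve).  Associations without evidence codes (array
  annotation sources) pass only when filtering is disabled, with a
  warning otherwise.
* **gene2go** carries Entrez Gene IDs only; requesting symbols from it
  is an error pointing at the id-map mechanism (an Entrez→symbol map
  file).  GAF sources offer symbol (column 3) or DB object ID (column 2).
* **Array dialects.** The Affymetrix NetAffx grammar is
  `'///'`-separated cell entries `<id> // <name> // <evidence>` with
  `---` as the null marker.  The Agilent layout is less standardized;
  the implemented grammar is `|`-separated `GO:NNNNNNN(EVIDENCE)`
  entries (evidence optional) in a tab-separated file, with probe/GO
  column-name overrides for other exports.
* **Identifier hygiene.** Accessions are compared case-sensitively
  after whitespace trimming; gene identifiers are preserved as-is.
  Duplicate associations differing only in evidence code collapse to a
  single membership at index construction — evidence matters only at
  filter time.

## Output choices

* **Size bounds** are inclusive; defaults 10 and 700 (below 10 a set
  rarely reaches significance; above 700 the term is too general to
  interpret).
* **Duplicate collapsing** groups terms by exact gene content.  One set
  is emitted per content; its description lists every contributing term
  as `GO:NNNNNNN name [level D]` joined by `|`, so an analyst can see
  that, e.g., a parent's signal is indistinguishable from one child's.
  The representative (naming the set and its URL) is the minimum-depth
  term — the most general — with ties broken by smallest accession for
  determinism.  The exact description grammar is this package's own; the
  requirement it satisfies is that all terms and their levels survive in
  the output.
* **gmt second field.** The format offers a single free-text field but
  both a URL and the term list must survive; the default emits
  `URL<space>description` in that field, and a `url_only` switch exists
  for strict MSigDB mimicry.  Set names are uppercase with
  non-alphanumeric runs collapsed to `_` (MSigDB c5 style), with `_2`,
  `_3`, ... suffixes on collisions.  Output is UTF-8 with UNIX newlines;
  sets are ordered by representative accession and genes sorted, so
  identical inputs give byte-identical files.
* **Cache.** The parsed DAG is cached as versioned JSON; a corrupt or
  version-mismatched cache is an explicit error instructing re-parse
  (the driver then re-parses with a logged warning) — never a silent
  fallback to partial data.

## Synthetic fixtures

The generator emits real files (OBO, gene2go, GAF, NetAffx CSV, id map)
so the parsers' comment/quoting/padding paths are exercised, plus the
exact ground truth (edge list, synonym/obsolete maps, post-resolution
association list, expected warning counters).  DAGs are acyclic by
construction (parents drawn only from earlier terms); ~30% of edges are
written as `part_of`.  Default injection rates — 10% of terms obsolete,
10% synonymous, and NOT/synonym/obsolete/unknown rows each at 10% of the
clean association count — are chosen to exercise every counter with
non-trivial numbers while leaving the clean path dominant; injected rows
use a dedicated gene-id range so expected counters stay exact under
deduplication.  A canned fixture reproduces the structure that motivates
propagation: a parent term with 16 directly annotated genes whose
children carry 81 further distinct genes, giving exactly 97 after
propagation.  Its identifiers are synthetic; only the arithmetic mirrors
real annotation sparsity.

What the fixtures do *not* emulate: real GO term-size distributions,
multi-namespace ontologies (the random generator emits one namespace;
multi-namespace behaviour is covered by hand-written cases),
inter-ontology links, or realistic gene id vocabularies.  Passing tests
therefore demonstrate correctness of the graph algorithms, parsers and
formats — not biological realism of any particular collection.

## Problem sizes used in checks

The oracle-equivalence check runs 100 random DAGs of up to 1000 terms
and 5000 associations against a brute-force ancestor-closure oracle; the
end-to-end check builds a collection from a 1000-term / 5000-association
fixture.  These sizes are large enough that an accidentally quadratic
traversal or per-association upward walk would be conspicuous, while
keeping the whole suite fast to iterate on.

## Known limitations

* Flat-file inputs only (OBO, gene2go, GAF, annotation CSV/TSV): no
  database or web-service backends.
* No cross-species ortholog mapping; the id map is a plain string
  translation.
* No downward propagation or probabilistic annotation inference.
* The `.grp` single-set format and GSEA statistics themselves are out of
  scope — this package builds the collections GSEA consumes.
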