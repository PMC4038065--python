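"""Independent oracles and test-only format readers.

Everything here is deliberately implemented without the package's own
graph machinery so that oracle comparisons stay independent of the code
paths they check.
"""

from __future__ import annotations

import re


def parents_map_from_edges(edges):
    """edges: iterable of (child, parent) -> {child: set(parents)}."""
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    return parents


def ancestors_oracle(term, parents):
    """All ancestors of ``term`` by exhaustive upward traversal."""
    out: set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(parents.get(t, ()))
    return out


def closure_oracle(assocs, edges):
    """Brute-force propagation: each (gene, term) pair adds the gene to
    the term and every ancestor of the term.  Returns {term: set(genes)}
    with empty sets omitted."""
    parents = parents_map_from_edges(edges)
    members: dict[str, set[str]] = {}
    for a in assocs:
        for t in {a.term_id} | ancestors_oracle(a.term_id, parents):
            members.setdefault(t, set()).add(a.gene_id)
    return members


def bfs_depth_oracle(edges, roots):
    """Breadth-first depths over child->parent edges, per root."""
    children: dict[str, list[str]] = {}
    nodes = set(roots)
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
        nodes.update((child, parent))
    depth: dict[str, int] = {}
    for root in roots:
        depth[root] = 0
        frontier = [root]
        while frontier:
            nxt = []
            for t in frontier:
                for c in children.get(t, ()):
                    if c not in depth:
                        depth[c] = depth[t] + 1
                        nxt.append(c)
            frontier = nxt
    return depth


def read_gmt(text):
    """Test-only .gmt reader: list of (name, second_field, [genes])."""
    out = []
    for line in text.splitlines():
        if not line:
            continue
        fields = line.split("\t")
        out.append((fields[0], fields[1], fields[2:]))
    return out


def read_gmx(text):
    """Test-only .gmx reader: transposes columns back into gmt triples,
    dropping padding fields."""
    rows = [line.split("\t") for line in text.splitlines() if line != ""]
    if not rows:
        return []
    n_cols = len(rows[0])
    out = []
    for c in range(n_cols):
        column = [row[c] for row in rows if c < len(row)]
        while column and column[-1] == "":
            column.pop()
        out.append((column[0], column[1], column[2:]))
    return out


_DESC_ENTRY_RE = re.compile(r"^(GO:\d{7}) (.*) \[level (\d+)\]$")


def parse_description(desc):
    """Inverse of the description grammar: list of (term_id, name, depth)."""
    out = []
    for entry in desc.split("|"):
        m = _DESC_ENTRY_RE.match(entry)
        if not m:
            raise ValueError(f"unparseable description entry: {entry!r}")
        out.append((m.group(1), m.group(2), int(m.group(3))))
    return out


def split_second_field(field_value):
    """Split the gmt second field into (url, description-or-None)."""
    if " " in field_value:
        url, desc = field_value.split(" ", 1)
        return url, desc
    return field_value, None
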