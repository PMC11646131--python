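"""Rooted taxonomy trees with rank labels, LCA and clade-membership queries.

The classifier stores a taxon id per k-mer and resolves multi-taxon k-mers
to their lowest common ancestor (LCA); the filtering rules ("retain reads
classified at the order of the species of interest or lower") are pure
clade-membership tests on this tree.

Two on-disk dialects are supported: the NCBI ``nodes.dmp``/``names.dmp``
pipe-delimited format, and a minimal TSV with header
``taxon_id<TAB>parent_id<TAB>rank[<TAB>name]``. The root is the unique node
whose parent is itself (NCBI convention, taxid 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (cycle, orphan, no root)."""


class UnknownTaxonError(KeyError):
    """A taxon id was queried that is not present in the tree."""


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Validated rooted taxonomy.

    ``depth`` is precomputed per node (root depth 0) so LCA queries are
    simple two-pointer walks.
    """

    nodes: dict[int, TaxonNode]
    root_id: int
    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._depth:
            self._depth = _compute_depths(self.nodes, self.root_id)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise UnknownTaxonError(f"taxon {taxon_id} not in taxonomy") from None

    def depth(self, taxon_id: int) -> int:
        self.node(taxon_id)
        return self._depth[taxon_id]

    def parent(self, taxon_id: int) -> int:
        return self.node(taxon_id).parent_id

    def lineage(self, taxon_id: int) -> list[int]:
        """Path from ``taxon_id`` up to and including the root."""
        self.node(taxon_id)
        path = [taxon_id]
        while path[-1] != self.root_id:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def children(self, taxon_id: int) -> list[int]:
        self.node(taxon_id)
        return [
            n.taxon_id
            for n in self.nodes.values()
            if n.parent_id == taxon_id and n.taxon_id != taxon_id
        ]

    def subtree(self, clade_root: int) -> set[int]:
        """All taxon ids at or below ``clade_root``."""
        self.node(clade_root)
        return {t for t in self.nodes if is_in_clade(self, t, clade_root)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tparent_id\trank\tname\n")
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")


def _compute_depths(nodes: Mapping[int, TaxonNode], root_id: int) -> dict[int, int]:
    depth: dict[int, int] = {root_id: 0}
    for tid in nodes:
        if tid in depth:
            continue
        chain = []
        cur = tid
        seen_local = set()
        while cur not in depth:
            if cur in seen_local:
                raise TaxonomyError(f"cycle detected at taxon {cur}")
            seen_local.add(cur)
            chain.append(cur)
            cur = nodes[cur].parent_id
        base = depth[cur]
        for i, c in enumerate(reversed(chain), start=1):
            depth[c] = base + i
    return depth


def _validate(nodes: dict[int, TaxonNode]) -> TaxonomyTree:
    if not nodes:
        raise TaxonomyError("empty taxonomy")
    roots = [t for t, n in nodes.items() if n.parent_id == n.taxon_id]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root (parent_id == taxon_id), found {roots}")
    root_id = roots[0]
    for tid, n in nodes.items():
        if n.parent_id not in nodes:
            raise TaxonomyError(f"taxon {tid} has orphan parent id {n.parent_id}")
    # _compute_depths raises on cycles
    depths = _compute_depths(nodes, root_id)
    return TaxonomyTree(nodes=nodes, root_id=root_id, _depth=depths)


def _parse_dmp_row(line: str) -> list[str]:
    # NCBI dmp rows end with "\t|\n" and use "\t|\t" as the field separator.
    return [f.strip() for f in line.rstrip("\n").rstrip("|\t").split("\t|\t")]


def load_taxonomy(
    nodes_source: str | Path,
    names_source: str | Path | None = None,
) -> TaxonomyTree:
    """Load and validate a taxonomy from TSV or NCBI dmp files.

    Parameters
    ----------
    nodes_source
        Either a TSV (header line starting with ``taxon_id``, columns
        taxon_id, parent_id, rank and optionally name) or an NCBI-style
        ``nodes.dmp`` (pipe-delimited; first three fields taxid, parent
        taxid, rank).
    names_source
        Optional ``names.dmp`` (taxid, name, unique name, name class;
        scientific names win) or two-column TSV (taxon_id, name). When no
        name is available the taxon id string is used.
    """
    nodes_source = Path(nodes_source)
    text = nodes_source.read_text()
    raw: dict[int, tuple[int, str, str | None]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TaxonomyError(f"{nodes_source}: no rows")
    is_dmp = "\t|" in lines[0]
    start = 0
    if not is_dmp and lines[0].lower().startswith("taxon_id"):
        start = 1
    for ln in lines[start:]:
        fields = _parse_dmp_row(ln) if is_dmp else ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise TaxonomyError(f"{nodes_source}: need at least 3 columns, got {ln!r}")
        tid, pid, rank = int(fields[0]), int(fields[1]), fields[2]
        name = fields[3] if (not is_dmp and len(fields) > 3 and fields[3]) else None
        if tid in raw:
            raise TaxonomyError(f"duplicate taxon id {tid}")
        raw[tid] = (pid, rank, name)

    names: dict[int, str] = {}
    if names_source is not None:
        for ln in Path(names_source).read_text().splitlines():
            if not ln.strip():
                continue
            if "\t|" in ln:
                fields = _parse_dmp_row(ln)
                tid, name = int(fields[0]), fields[1]
                name_class = fields[3] if len(fields) > 3 else "scientific name"
                if name_class == "scientific name" or tid not in names:
                    names[tid] = name
            else:
                fields = ln.split("\t")
                if fields[0].lower() == "taxon_id":
                    continue
                names[int(fields[0])] = fields[1]

    nodes = {
        tid: TaxonNode(
            taxon_id=tid,
            parent_id=pid,
            rank=rank,
            name=names.get(tid) or inline_name or str(tid),
        )
        for tid, (pid, rank, inline_name) in raw.items()
    }
    return _validate(nodes)


def taxonomy_from_records(
    records: Iterable[tuple[int, int, str] | tuple[int, int, str, str]],
) -> TaxonomyTree:
    """Build a validated tree from in-memory (taxon_id, parent_id, rank[, name]) rows."""
    nodes: dict[int, TaxonNode] = {}
    for rec in records:
        tid, pid, rank = rec[0], rec[1], rec[2]
        name = rec[3] if len(rec) > 3 else str(tid)  # type: ignore[misc]
        if tid in nodes:
            raise TaxonomyError(f"duplicate taxon id {tid}")
        nodes[tid] = TaxonNode(int(tid), int(pid), rank, name)
    return _validate(nodes)


def lca(tree: TaxonomyTree, a: int, b: int) -> int:
    """Lowest common ancestor of two taxa (``lca(x, x) == x``)."""
    da, db = tree.depth(a), tree.depth(b)
    while da > db:
        a = tree.nodes[a].parent_id
        da -= 1
    while db > da:
        b = tree.nodes[b].parent_id
        db -= 1
    while a != b:
        a = tree.nodes[a].parent_id
        b = tree.nodes[b].parent_id
    return a


def lca_of_set(tree: TaxonomyTree, ids: Iterable[int]) -> int:
    """Fold of :func:`lca` over a non-empty collection; order-independent."""
    it = iter(ids)
    try:
        acc = next(it)
    except StopIteration:
        raise ValueError("lca_of_set requires a non-empty collection") from None
    tree.node(acc)
    for t in it:
        acc = lca(tree, acc, t)
    return acc


def is_in_clade(tree: TaxonomyTree, node: int, clade_root: int) -> bool:
    """True iff ``node`` equals ``clade_root`` or lies below it.

    This is the "at rank X or lower" retention rule expressed as subtree
    membership: an ancestor of the clade root is *not* in the clade.
    """
    tree.node(clade_root)
    cur = node
    tree.node(cur)
    d_target = tree.depth(clade_root)
    while tree.depth(cur) > d_target:
        cur = tree.nodes[cur].parent_id
    return cur == clade_root
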