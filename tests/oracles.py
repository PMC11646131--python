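"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, lineage lists, exhaustive scans) and shares no code with the
package modules it checks.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def canon(kmer: str) -> str:
    r = rc(kmer)
    return kmer if kmer <= r else r


def lineage(parents: dict[int, int], node: int) -> list[int]:
    """node → root path from a raw parent map (root: parent == self)."""
    path = [node]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return path


def lca_by_lineage(parents: dict[int, int], a: int, b: int) -> int:
    """Deepest common element of the two full lineage lists."""
    lb = set(lineage(parents, b))
    for anc in lineage(parents, a):
        if anc in lb:
            return anc
    raise AssertionError("disconnected tree")


def fold_lca(parents: dict[int, int], ids: list[int]) -> int:
    acc = ids[0]
    for t in ids[1:]:
        acc = lca_by_lineage(parents, acc, t)
    return acc


def count_hits(entries: dict[str, int], seq: str, k: int) -> dict[int, int]:
    hits: dict[int, int] = defaultdict(int)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b not in "ACGT" for b in window):
            continue
        taxon = entries.get(canon(window))
        if taxon is not None:
            hits[taxon] += 1
    return dict(hits)


def classify_by_path_enumeration(
    parents: dict[int, int], entries: dict[str, int], seq: str, k: int
) -> int | None:
    """Exhaustive root-to-leaf path scoring; None = unclassified.

    Each leaf's path score is the sum of hits over its lineage; the winner
    is the deepest hit-bearing node on a maximal-score path, with ties
    across paths resolved to the LCA of the tied winners.
    """
    hits = count_hits(entries, seq, k)
    if not hits:
        return None
    children = defaultdict(list)
    for n, p in parents.items():
        if n != p:
            children[p].append(n)
    leaves = [n for n in parents if not children[n]]
    best_score = None
    winners: set[int] = set()
    for leaf in leaves:
        path = lineage(parents, leaf)  # leaf → root
        score = sum(hits.get(t, 0) for t in path)
        deepest_hit = next((t for t in path if hits.get(t, 0) > 0), None)
        if deepest_hit is None:
            continue
        if best_score is None or score > best_score:
            best_score, winners = score, {deepest_hit}
        elif score == best_score:
            winners.add(deepest_hit)
    return fold_lca(parents, sorted(winners))


def exhaustive_best_alignment(
    ref: str, read: str, max_mismatch_rate: float
) -> tuple[int, list[tuple[int, str]]] | None:
    """Scan every position on both strands; ungapped +1/−3 scoring.

    Returns (best score, [(0-based position, strand), ...] of all loci at
    that score) or None if nothing passes the mismatch ceiling.
    """
    L = len(read)
    max_mm = int(np.ceil(max_mismatch_rate * L))
    ref_a = np.frombuffer(ref.encode(), dtype="S1")
    best: int | None = None
    loci: list[tuple[int, str]] = []
    for strand, q in (("+", read), ("-", rc(read))):
        qa = np.frombuffer(q.encode(), dtype="S1")
        for start in range(len(ref) - L + 1):
            mm = int((ref_a[start : start + L] != qa).sum())
            if mm > max_mm:
                continue
            score = L - 4 * mm
            if best is None or score > best:
                best, loci = score, [(start, strand)]
            elif score == best:
                loci.append((start, strand))
    if best is None:
        return None
    return best, loci


def naive_block_jackknife_se(per_site: np.ndarray, block_size: int) -> float:
    """Delete-one-block jackknife SE via the textbook loop (equal blocks)."""
    n = len(per_site)
    blocks = [per_site[s : s + block_size] for s in range(0, n, block_size)]
    m = len(blocks)
    theta_del = []
    for j in range(m):
        rest = np.concatenate([b for i, b in enumerate(blocks) if i != j])
        theta_del.append(rest.mean())
    theta_del = np.array(theta_del)
    return float(np.sqrt((m - 1) / m * ((theta_del - theta_del.mean()) ** 2).sum()))


def random_tree(rng: np.random.Generator, n_nodes: int) -> dict[int, int]:
    """Random rooted parent map on ids 1..n (1 is root, parent of itself)."""
    parents = {1: 1}
    for i in range(2, n_nodes + 1):
        parents[i] = int(rng.integers(1, i))
    return parents
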