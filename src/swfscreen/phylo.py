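"""Distance-based phylogeny: p-distances, neighbour joining, bootstrap
support, outgroup rooting and support-cutoff condensation.

The distance model is the uncorrected p-distance with pairwise deletion of
gap columns (a Poisson correction is available by flag); tree construction is
Saitou-Nei neighbour joining on the rate-corrected criterion
Q(i,j) = (m-2) d(i,j) - r(i) - r(j), with ties broken by the
lexicographically smallest pair of cluster labels (a cluster's label is the
smallest leaf label it contains), so the output is deterministic.  Negative
branch lengths are clamped to zero and the deficit logged.

Bootstrap support of an internal edge is the percentage of
column-resampled replicate trees containing the same leaf bipartition.
Condensing at a cutoff collapses every internal edge with support strictly
below the cutoff into a polytomy (support >= cutoff is retained).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .seq import ProteinSequence

logger = logging.getLogger("swfscreen")

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite distances")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("non-zero diagonal")


class Clade:
    """Tree node: leaves carry ``name``; internal nodes may carry percent
    ``support``; ``length`` is the length of the edge above the node."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None, children: list["Clade"] | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf():
            return [self]
        out: list[Clade] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def walk(self) -> Iterable["Clade"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def __repr__(self) -> str:
        return f"Clade({to_newick(self)})"


@dataclass
class PhyloTree:
    root: Clade
    rooted: bool = False
    meta: dict = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()


# --- distances ---------------------------------------------------------------

def p_distance(
    alignment: Sequence[ProteinSequence],
    poisson_correction: bool = False,
) -> DistanceMatrix:
    """Pairwise proportion of differing sites over gap-free column pairs.

    With ``poisson_correction`` distances become -ln(1 - p).  Raises if two
    rows share no comparable (mutually ungapped) column.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 taxa")
    lengths = {len(s.residues) for s in alignment}
    if len(lengths) != 1:
        raise ValueError("rows have unequal lengths; input must be aligned")
    taxa = [s.id for s in alignment]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    arr = np.array([list(s.residues) for s in alignment])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~is_gap[i] & ~is_gap[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable columns for {taxa[i]!r} vs {taxa[j]!r}")
            p = float((arr[i, ok] != arr[j, ok]).mean())
            if poisson_correction:
                if p >= 1.0:
                    raise ValueError(f"saturated pair {taxa[i]!r} vs {taxa[j]!r}")
                p = -math.log(1.0 - p)
            D[i, j] = D[j, i] = p
    return DistanceMatrix(taxa, D)


# --- neighbour joining -------------------------------------------------------

def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("clamped negative branch length %.6g to 0 (%s)", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining; returns an unrooted tree (trifurcating
    root).  Deterministic under ties (lexicographic cluster labels)."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes: dict[int, Clade] = {i: Clade(name=t) for i, t in enumerate(dm.taxa)}
    labels: dict[int, str] = {i: t for i, t in enumerate(dm.taxa)}
    active = list(range(n))
    nxt = n
    Dd: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            Dd[(i, j)] = D[i, j]

    def d(i: int, j: int) -> float:
        return Dd[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key)
                    best_pair = (i, j)
        i, j = best_pair
        li = d(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        ci, cj = nodes[i], nodes[j]
        ci.length = _clamp(li, f"join {labels[i]}")
        cj.length = _clamp(lj, f"join {labels[j]}")
        u = Clade(children=[ci, cj])
        nodes[nxt] = u
        labels[nxt] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (d(i, k) + d(j, k) - d(i, j)) / 2
            Dd[(min(k, nxt), max(k, nxt))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    # closing star: v_a = (d_ab + d_ac - d_bc) / 2
    a, b, c = sorted(active, key=lambda k: labels[k])
    va = (d(a, b) + d(a, c) - d(b, c)) / 2
    vb = (d(a, b) + d(b, c) - d(a, c)) / 2
    vc = (d(a, c) + d(b, c) - d(a, b)) / 2
    nodes[a].length = _clamp(va, f"star {labels[a]}")
    nodes[b].length = _clamp(vb, f"star {labels[b]}")
    nodes[c].length = _clamp(vc, f"star {labels[c]}")
    root = Clade(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, rooted=False, meta={"method": "nj"})


# --- bipartitions and bootstrap ----------------------------------------------

def bipartitions(tree: PhyloTree) -> dict[frozenset[str], Clade]:
    """Non-trivial leaf bipartitions, each normalized to the side NOT
    containing the lexicographically smallest taxon, mapped to the child node
    of the defining edge."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: dict[frozenset[str], Clade] = {}
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if len(side) >= 2 and len(all_leaves - side) >= 2:  # non-trivial only
            out[side] = node
    return out


def bootstrap_support(
    alignment: Sequence[ProteinSequence],
    n_replicates: int = 100,
    seed: int = 0,
    poisson_correction: bool = False,
) -> PhyloTree:
    """NJ tree of the full alignment with per-edge bootstrap support.

    Columns are resampled with replacement per replicate; each internal edge's
    support is the percentage of replicate trees containing its bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ncol = len(alignment[0].residues)
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(p_distance(alignment, poisson_correction))
    bips = bipartitions(tree)
    counts = {bip: 0 for bip in bips}
    rng = np.random.default_rng(seed)
    rows = [s.residues for s in alignment]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [
            ProteinSequence(id=s.id, residues="".join(row[c] for c in cols))
            for s, row in zip(alignment, rows)
        ]
        rep_tree = nj_tree(p_distance(resampled, poisson_correction))
        rep_bips = set(bipartitions(rep_tree))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in bips.items():
        node.support = 100.0 * counts[bip] / n_replicates
    tree.meta.update(bootstrap_replicates=n_replicates, bootstrap_seed=seed)
    return tree


# --- rooting and condensation ------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the midpoint of the outgroup leaf's pendant edge.

    Leaf set and all leaf-to-leaf path lengths are preserved; edge supports
    stay attached to the same bipartition.
    """
    if outgroup not in tree.leaf_names():
        raise ValueError(f"outgroup label {outgroup!r} not found among leaves")
    # build undirected adjacency; edge attributes live on the child node
    src = copy.deepcopy(tree.root)
    adj: dict[int, list[tuple[int, float, float | None]]] = {}
    info: dict[int, Clade] = {}

    def collect(node: Clade) -> int:
        nid = id(node)
        info[nid] = node
        adj.setdefault(nid, [])
        for child in node.children:
            cid = collect(child)
            adj[nid].append((cid, child.length, child.support))
            adj[cid].append((nid, child.length, child.support))
        return nid

    collect(src)
    leaf = next(l for l in src.leaves() if l.name == outgroup)
    lid = id(leaf)
    (pid, plen, psup) = adj[lid][0]
    half = plen / 2.0

    def build(nid: int, parent: int, length: float, support: float | None) -> Clade:
        node = info[nid]
        out = Clade(name=node.name, length=length, support=support)
        for (cid, clen, csup) in adj[nid]:
            if cid == parent:
                continue
            out.children.append(build(cid, nid, clen, csup))
        return out

    # new root has two children: the outgroup leaf and the rest of the tree
    out_leaf = Clade(name=outgroup, length=half)
    rest = build(pid, lid, half, psup)
    root = Clade(children=[out_leaf, rest])
    return PhyloTree(root=root, rooted=True, meta=dict(tree.meta, outgroup=outgroup))


def condense(tree: PhyloTree, cutoff_percent: float) -> PhyloTree:
    """Collapse internal edges with support < cutoff into polytomies.

    A collapsed edge's length is added to the promoted children so that
    root-to-leaf depths are preserved.  Edges with support >= cutoff, leaf
    edges, and edges without a support value are retained.
    """
    new_root = copy.deepcopy(tree.root)

    def visit(node: Clade) -> None:
        changed = True
        while changed:
            changed = False
            new_children: list[Clade] = []
            for child in node.children:
                if (not child.is_leaf() and child.support is not None
                        and child.support < cutoff_percent):
                    for gc in child.children:
                        gc.length += child.length
                        new_children.append(gc)
                    changed = True
                else:
                    new_children.append(child)
            node.children = new_children
        for child in node.children:
            visit(child)

    visit(new_root)
    return PhyloTree(root=new_root, rooted=tree.rooted,
                     meta=dict(tree.meta, condense_cutoff=cutoff_percent))


# --- path lengths and Newick -------------------------------------------------

def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Sum of branch lengths between every unordered leaf pair."""
    # for each leaf, record its distance to every ancestor node; the leaf-leaf
    # distance is the minimum over shared ancestors
    node_dist: dict[str, dict[int, float]] = {}

    def down(node: Clade, dist_from: dict[int, float]) -> None:
        here = dict(dist_from)
        here[id(node)] = 0.0
        if node.is_leaf():
            node_dist[node.name] = here
            return
        for child in node.children:
            down(child, {k: v + child.length for k, v in here.items()})

    down(tree.root, {})
    names = sorted(node_dist)
    out: dict[tuple[str, str], float] = {}
    ids_per_leaf = {n: set(node_dist[n]) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = ids_per_leaf[a] & ids_per_leaf[b]
            out[(a, b)] = min(node_dist[a][s] + node_dist[b][s] for s in shared)
    return out


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def to_newick(node: Clade, with_support: bool = True, _root: bool = True) -> str:
    if node.is_leaf():
        s = f"{node.name}:{_fmt_len(node.length)}"
    else:
        inner = ",".join(to_newick(c, with_support, _root=False) for c in node.children)
        label = ""
        if with_support and node.support is not None:
            label = _fmt_len(node.support)
        s = f"({inner}){label}"
        if not _root:
            s += f":{_fmt_len(node.length)}"
    return s + ";" if _root else s


def write_newick(tree: PhyloTree, path, with_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree.root, with_support=with_support) + "\n")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (supports support values as internal labels)."""
    from io import StringIO

    from Bio import Phylo

    bio_tree = Phylo.read(StringIO(text), "newick")

    def convert(cl) -> Clade:
        node = Clade(
            name=cl.name,
            length=cl.branch_length if cl.branch_length is not None else 0.0,
            support=cl.confidence,
        )
        for ch in cl.clades:
            node.children.append(convert(ch))
        return node

    return PhyloTree(root=convert(bio_tree.root), rooted=bio_tree.rooted)


def write_distance_tsv(dm: DistanceMatrix, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
        for i, t in enumerate(dm.taxa):
            fh.write(t + "\t" + "\t".join(f"{x:.6f}" for x in dm.matrix[i]) + "\n")
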