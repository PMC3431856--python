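"""Distance and parsimony phylogenetics for concatenated mitochondrial proteins.

The pipeline mirrors the classic workflow for mitogenome papers: per-gene
amino-acid alignment blocks are concatenated, pairwise distances are taken
under a p or Poisson-corrected model, trees are built by neighbor joining
(Saitou-Nei) and by Fitch parsimony with nearest-neighbor-interchange hill
climbing, and node confidence comes from the nonparametric bootstrap with a
50% majority-rule consensus.

Trees are unrooted; internally they are stored rooted at a trifurcating hub
node, the standard representation of an unrooted binary tree.  Outgroup
rooting is a presentation step (:func:`root_with_outgroup`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-?X.")


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Aligned matrices
# ---------------------------------------------------------------------------

@dataclass
class AlignedMatrix:
    """Equal-length aligned amino-acid rows keyed by unique taxon names."""

    names: list[str]
    rows: list[str]
    block_ranges: Optional[dict[str, tuple[int, int]]] = None  # gene -> [start, end)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise PhyloError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            raise PhyloError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloError("aligned rows have unequal lengths")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def subsample_columns(self, idx: Sequence[int]) -> "AlignedMatrix":
        return AlignedMatrix(
            names=list(self.names),
            rows=["".join(r[i] for i in idx) for r in self.rows])

    @classmethod
    def from_fasta(cls, handle: TextIO) -> "AlignedMatrix":
        names, rows, cur = [], [], []
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                names.append(line[1:].split()[0])
            else:
                cur.append(line.upper())
        if cur:
            rows.append("".join(cur))
        return cls(names=names, rows=rows)

    @classmethod
    def from_phylip(cls, handle: TextIO) -> "AlignedMatrix":
        """Relaxed sequential PHYLIP (name, whitespace, sequence)."""
        header = handle.readline().split()
        n, m = int(header[0]), int(header[1])
        names, rows = [], []
        for line in handle:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            names.append(name)
            rows.append(re.sub(r"\s", "", seq).upper())
            if len(names) == n:
                break
        mat = cls(names=names, rows=rows)
        if mat.n_columns != m:
            raise PhyloError("PHYLIP header does not match row length")
        return mat

    def to_fasta(self, handle: TextIO) -> None:
        for name, row in zip(self.names, self.rows):
            handle.write(f">{name}\n{row}\n")


def concatenate_pcgs(blocks: Sequence[tuple[str, AlignedMatrix]]) -> AlignedMatrix:
    """Row-wise concatenation of per-gene blocks with shared taxon sets.

    ``blocks`` is an ordered sequence of (gene name, alignment).  Column
    provenance is kept in ``block_ranges``.
    """
    if not blocks:
        raise PhyloError("no blocks to concatenate")
    base = sorted(blocks[0][1].names)
    for gene, m in blocks:
        if sorted(m.names) != base:
            raise PhyloError(f"block {gene!r} has a different taxon set")
    names = blocks[0][1].names
    rows = ["" for _ in names]
    ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene, m in blocks:
        ranges[gene] = (offset, offset + m.n_columns)
        for i, name in enumerate(names):
            rows[i] += m.row(name)
        offset += m.n_columns
    return AlignedMatrix(names=names, rows=rows, block_ranges=ranges)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def aa_distance(m: AlignedMatrix, model: str = "poisson") -> np.ndarray:
    """Pairwise distance matrix under the p or Poisson model.

    Columns where either sequence of a pair carries a gap character are
    deleted for that pair.  p is the mismatch fraction; the Poisson
    correction is -ln(1 - p).  p = 1 (or no comparable columns) yields NaN,
    which downstream tree building refuses.
    """
    if model not in ("p", "poisson"):
        raise PhyloError(f"unknown distance model {model!r}")
    if m.n_taxa < 2:
        raise PhyloError("need at least two taxa")
    enc = np.array([list(r) for r in m.rows])
    ok = ~np.isin(enc, list(GAP_CHARS))
    n = m.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            total = int(both.sum())
            if total == 0:
                raise PhyloError(
                    f"no comparable columns between {m.names[i]} and {m.names[j]}")
            p = float((enc[i][both] != enc[j][both]).sum()) / total
            if model == "p":
                d = p
            else:
                d = -math.log(1.0 - p) if p < 1.0 else float("nan")
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "TreeNode":
        return TreeNode(self.name, self.length, self.support,
                        [c.copy() for c in self.children])

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at a hub node (trifurcating when binary)."""

    root: TreeNode

    def taxa(self) -> list[str]:
        return sorted(leaf.name for leaf in self.root.leaves())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each given as the side excluding the
        lexicographically smallest taxon."""
        all_taxa = frozenset(self.taxa())
        ref = min(all_taxa)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_taxa) - 1:
                side = all_taxa - below if ref in below else below
                out.add(side)
            return below

        walk(self.root)
        return out

    def split_supports(self) -> dict[frozenset, Optional[float]]:
        all_taxa = frozenset(self.taxa())
        ref = min(all_taxa)
        out: dict[frozenset, Optional[float]] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_taxa) - 1:
                side = all_taxa - below if ref in below else below
                out[side] = node.support
            return below

        walk(self.root)
        return out


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    return a.taxa() == b.taxa() and a.splits() == b.splits()


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def _fmt_len(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".") or "0"


def write_newick(t: PhyloTree) -> str:
    def fmt(node: TreeNode, top: bool = False) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                body += _fmt_len(node.support)
        if not top:
            body += f":{_fmt_len(node.length)}"
        return body

    return fmt(t.root, top=True) + ";"


def read_newick(text: str) -> PhyloTree:
    text = text.strip()
    if not text.endswith(";"):
        raise PhyloError("Newick string must end with ';'")
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise PhyloError(f"malformed Newick near offset {pos}")
            m = re.match(r"[^,():;]*", text[pos:])
            label = m.group()
            pos += len(label)
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            m = re.match(r"[^,():;]+", text[pos:])
            if m is None:
                raise PhyloError(f"malformed Newick near offset {pos}")
            node.name = m.group()
            pos += len(node.name)
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", text[pos:])
            if m is None:
                raise PhyloError(f"malformed branch length at offset {pos}")
            node.length = float(m.group())
            pos += len(m.group())
        return node

    root = parse()
    if text[pos:] != ";":
        raise PhyloError("trailing characters after Newick tree")
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, names: Sequence[str]) -> PhyloTree:
    """Saitou-Nei agglomeration.

    Ties on the Q criterion resolve to the lowest (i, j) index pair.
    Negative branch lengths are clamped to zero.  NaN distances are refused.
    """
    D = np.asarray(D, dtype=float)
    n = len(names)
    if D.shape != (n, n):
        raise PhyloError("distance matrix shape does not match names")
    if np.isnan(D).any():
        raise PhyloError("distance matrix contains missing values")
    if not np.allclose(D, D.T):
        raise PhyloError("distance matrix is not symmetric")
    if n < 2:
        raise PhyloError("need at least two taxa")

    nodes = [TreeNode(name=nm) for nm in names]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))          # row-major: lowest (i, j) on ties
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = np.zeros(D.shape[0] + 1)
        for am in active:
            if am in (i, j):
                continue
            new_row[am] = 0.5 * (D[i, am] + D[j, am] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for idx, ln in zip((a, b, c), (la, lb, lc)):
            nodes[idx].length = max(ln, 0.0)
        root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    else:  # exactly two taxa
        a, b = active
        nodes[a].length = nodes[b].length = D[a, b] / 2
        root = TreeNode(children=[nodes[a], nodes[b]])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Fitch parsimony and NNI search
# ---------------------------------------------------------------------------

def _column_masks(m: AlignedMatrix) -> dict[str, np.ndarray]:
    """Per-taxon bitmask arrays over columns; gaps and X are wildcards."""
    bit = {aa: 1 << i for i, aa in enumerate(AA_ALPHABET)}
    full = (1 << len(AA_ALPHABET)) - 1
    out = {}
    for name, row in zip(m.names, m.rows):
        out[name] = np.array(
            [bit.get(ch, full) for ch in row], dtype=np.int64)
    return out


def fitch_score(t: PhyloTree, m: AlignedMatrix,
                weights: Optional[np.ndarray] = None) -> int:
    """Minimum number of state changes the tree requires, summed over columns.

    Gap characters act as wildcards (missing data).  The tree must contain
    exactly the alignment's taxa; multifurcations beyond the hub root are
    not supported.
    """
    if t.taxa() != sorted(m.names):
        raise PhyloError("tree taxa do not match alignment")
    masks = _column_masks(m)
    ncols = m.n_columns
    if weights is None:
        weights = np.ones(ncols, dtype=np.int64)
    changes = np.zeros(ncols, dtype=np.int64)

    def down(node: TreeNode) -> np.ndarray:
        if node.is_leaf:
            return masks[node.name]
        acc = None
        for child in node.children:
            cm = down(child)
            if acc is None:
                acc = cm
                continue
            inter = acc & cm
            empty = inter == 0
            changes[empty] += 1
            acc = np.where(empty, acc | cm, inter)
        return acc

    # fold the hub's subtrees pairwise; with a binary unrooted tree this is
    # exactly Fitch's bottom-up pass rooted along one of the hub's edges
    down(t.root)
    return int((changes * weights).sum())


def _internal_edges(root: TreeNode) -> list[tuple[TreeNode, TreeNode]]:
    """(parent, internal child) pairs, in deterministic preorder."""
    out = []

    def walk(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                out.append((node, c))
                walk(c)

    walk(root)
    return out


def nni_neighbors(t: PhyloTree) -> list[PhyloTree]:
    """The trees one nearest-neighbor interchange away, in move order."""
    out = []
    edges = _internal_edges(t.root)
    for e_idx, (parent, child) in enumerate(edges):
        sib_idx = next(i for i, c in enumerate(parent.children) if c is not child)
        for g_idx in range(len(child.children)):
            tc = t.copy()
            p2, c2 = _internal_edges(tc.root)[e_idx]
            s2 = p2.children[sib_idx]
            g2 = c2.children[g_idx]
            p2.children[sib_idx] = g2
            c2.children[g_idx] = s2
            out.append(tc)
    return out


def nni_search(start: PhyloTree, m: AlignedMatrix,
               weights: Optional[np.ndarray] = None) -> PhyloTree:
    """Steepest-descent NNI hill climbing on the Fitch score.

    Deterministic: all moves are scored each round, the best improvement is
    applied (first in move order on ties), and the search stops when no
    move lowers the score.
    """
    current = start.copy()
    cur_score = fitch_score(current, m, weights)
    while True:
        best = None
        for cand in nni_neighbors(current):
            sc = fitch_score(cand, m, weights)
            if sc < cur_score and (best is None or sc < best[0]):
                best = (sc, cand)
        if best is None:
            return current
        cur_score, current = best


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------

def mp_search(m: AlignedMatrix,
              weights: Optional[np.ndarray] = None) -> PhyloTree:
    """Maximum-parsimony tree: NNI hill climbing with a depth-2 escape.

    The climb starts from the neighbor-joining tree on p-distances; when it
    stalls, a new climb is launched from each NNI neighbor of the current
    optimum and the search continues whenever one of them lands lower.
    Deterministic given the alignment.
    """
    cur = nni_search(neighbor_joining(aa_distance(m, "p"), m.names), m, weights)
    cur_score = fitch_score(cur, m, weights)
    improved = True
    while improved:
        improved = False
        for nb in nni_neighbors(cur):
            cand = nni_search(nb, m, weights)
            sc = fitch_score(cand, m, weights)
            if sc < cur_score:
                cur, cur_score = cand, sc
                improved = True
                break
    return cur


def _build_tree(m: AlignedMatrix, builder: str, model: str = "poisson") -> PhyloTree:
    if builder == "nj":
        return neighbor_joining(aa_distance(m, model), m.names)
    if builder == "mp":
        return mp_search(m)
    raise PhyloError(f"unknown tree builder {builder!r}")


def majority_consensus(split_freqs: dict[frozenset, float],
                       taxa: Sequence[str]) -> PhyloTree:
    """50% majority-rule consensus tree from split frequencies in [0, 1]."""
    taxa = sorted(taxa)
    majority = {s: f for s, f in split_freqs.items() if f > 0.5}
    root = TreeNode(children=[TreeNode(name=t) for t in taxa])
    leafset = {id(c): frozenset([c.name]) for c in root.children}

    def node_leafset(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        return frozenset().union(*(node_leafset(c) for c in node.children))

    for split, freq in sorted(majority.items(),
                              key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        # find the node whose child set covers the split, group those children
        def insert(node: TreeNode) -> bool:
            inside = [c for c in node.children if node_leafset(c) <= split]
            covered = frozenset().union(*(node_leafset(c) for c in inside)) \
                if inside else frozenset()
            if covered == split and len(inside) < len(node.children):
                if len(inside) == len(node.children):
                    return True
                new = TreeNode(children=inside, support=round(freq * 100, 1))
                node.children = [c for c in node.children if c not in inside]
                node.children.append(new)
                return True
            for c in node.children:
                if not c.is_leaf and split < node_leafset(c):
                    return insert(c)
            return False

        insert(root)
    return PhyloTree(root)


def bootstrap_support(m: AlignedMatrix, builder: str = "nj",
                      replicates: int = 1000, seed: int = 0,
                      model: str = "poisson") -> PhyloTree:
    """Nonparametric bootstrap with 50% majority-rule consensus.

    Alignment columns are resampled with replacement ``replicates`` times,
    a tree is built per replicate, and each split's support is the percent
    of replicate trees containing it.  The returned tree is the majority
    consensus with supports attached; it is reproducible given ``seed``.
    """
    if replicates < 1:
        raise PhyloError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        idx = rng.integers(0, m.n_columns, m.n_columns)
        rep = m.subsample_columns(list(idx))
        tree = _build_tree(rep, builder, model)
        for s in tree.splits():
            counts[s] = counts.get(s, 0) + 1
    freqs = {s: c / replicates for s, c in counts.items()}
    return majority_consensus(freqs, m.names)


def bootstrap_split_table(tree: PhyloTree) -> list[tuple[str, float]]:
    """(split, support) rows for TSV export, sorted by support."""
    rows = [("|".join(sorted(s)), sup if sup is not None else 100.0)
            for s, sup in tree.split_supports().items()]
    return sorted(rows, key=lambda r: (-r[1], r[0]))


def root_with_outgroup(t: PhyloTree, outgroup: Union[str, Iterable[str]]) -> PhyloTree:
    """Rooted presentation of an unrooted tree on the outgroup edge.

    The returned tree has a binary root on the edge above the smallest
    clade containing all outgroup taxa, with the edge length split evenly.
    """
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    want = frozenset(outgroup)
    if not want <= frozenset(t.taxa()):
        raise PhyloError("outgroup taxa missing from the tree")

    # flatten to adjacency so the tree can be rebuilt from any edge
    adj: dict[int, list[tuple[int, float, Optional[float]]]] = {}
    names: dict[int, Optional[str]] = {}
    counter = [0]

    def flatten(node: TreeNode) -> int:
        uid = counter[0]
        counter[0] += 1
        names[uid] = node.name
        adj.setdefault(uid, [])
        for c in node.children:
            cid = flatten(c)
            adj[uid].append((cid, c.length, c.support))
            adj[cid].append((uid, c.length, c.support))
        return uid

    flatten(t.root)

    def leafset_from(cur: int, parent: int) -> frozenset:
        nbrs = [nb for nb, _, _ in adj[cur] if nb != parent]
        if not nbrs:
            return frozenset([names[cur]])
        return frozenset().union(*(leafset_from(nb, cur) for nb in nbrs))

    # the rooting edge: smallest subtree (over all directed edges) with
    # all outgroup taxa below it
    best = None
    for u in adj:
        for v, length, support in adj[u]:
            below = leafset_from(v, u)
            if want <= below and (best is None or len(below) < best[0]):
                best = (len(below), u, v, length, support)
    if best is None:
        raise PhyloError("outgroup not found on a rootable edge")
    _, u, v, length, support = best

    def build(cur: int, parent: int) -> TreeNode:
        node = TreeNode(name=names[cur])
        for nb, ln, sup in adj[cur]:
            if nb == parent:
                continue
            child = build(nb, cur)
            child.length = ln
            child.support = sup
            node.children.append(child)
        return node

    out_side = build(v, u)
    in_side = build(u, v)
    out_side.length = in_side.length = length / 2
    out_side.support = in_side.support = support
    return PhyloTree(TreeNode(children=[out_side, in_side]))
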