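import numpy as np
import pytest

from mitodesc import genome_model, phylo, synthetic_data


@pytest.fixture(scope="session")
def reference():
    """The packaged Sesamia inferens annotation table."""
    return genome_model.load_reference_annotation()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default-condition synthetic genome with its plant ledger."""
    return synthetic_data.simulate_mitogenome(synthetic_data.GenomeSpec(seed=7))


def random_unrooted_tree(names, rng, min_len=0.05, max_len=1.0):
    """Random binary unrooted tree with uniform branch lengths."""
    nodes = [phylo.TreeNode(name=n, length=float(rng.uniform(min_len, max_len)))
             for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(phylo.TreeNode(
            children=[a, b], length=float(rng.uniform(min_len, max_len))))
    return phylo.PhyloTree(phylo.TreeNode(children=nodes))


def tree_path_distances(tree, names):
    """Leaf-to-leaf path-length matrix (the additive metric of the tree)."""
    import collections
    adj = collections.defaultdict(list)

    def walk(n):
        for c in n.children:
            adj[id(n)].append((id(c), c.length))
            adj[id(c)].append((id(n), c.length))
            walk(c)

    walk(tree.root)
    leafid = {l.name: id(l) for l in tree.root.leaves()}
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        dist = {leafid[a]: 0.0}
        stack = [leafid[a]]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for j, b in enumerate(names):
            D[i, j] = dist[leafid[b]]
    return D


def all_unrooted_topologies(names):
    """Every unrooted binary topology over the taxa (15 for five taxa)."""
    trees = [phylo.PhyloTree(phylo.TreeNode(
        children=[phylo.TreeNode(name=n) for n in names[:3]]))]
    for nm in names[3:]:
        grown = []
        for t in trees:
            def edges(node, acc):
                for c in node.children:
                    acc.append((node, c))
                    edges(c, acc)
                return acc
            n_edges = len(edges(t.root, []))
            for ei in range(n_edges):
                t2 = t.copy()
                p, c = edges(t2.root, [])[ei]
                mid = phylo.TreeNode(children=[c, phylo.TreeNode(name=nm)])
                p.children[p.children.index(c)] = mid
                grown.append(t2)
        trees = grown
    return trees


# keep the working tree clean: derandomized property tests need no example DB
from hypothesis import settings as _settings
_settings.register_profile("mitodesc", database=None, derandomize=True)
_settings.load_profile("mitodesc")
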