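"""Synthetic medical-concept ontology.

A random tree over concept codes with a sprinkling of cross-links, standing
in for the parent-child/related-concept structure of a clinical terminology
such as SNOMED-CT. Codes are strings ``C0000, C0001, ...``; node 0 is the
root, and the children of the root define the top-level "classes" whose
subtrees the population generator uses as latent-factor territories.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

CROSS_LINK_FRACTION = 0.05  # cross-links added on top of the spanning tree


def code_name(i: int) -> str:
    return f"C{i:04d}"


def generate_ontology(n_codes: int, branching: int = 3, seed: int = 0) -> nx.Graph:
    """Build a connected concept graph: random tree plus ~5% cross-links.

    Parameters
    ----------
    n_codes:
        Number of concept codes (graph nodes); at least 50 so that the
        vocabulary is large enough to express a multi-factor latent state.
    branching:
        Maximum number of children per node in the tree skeleton (>= 2).
    seed:
        Fully determines the graph.

    Returns
    -------
    networkx.Graph with string nodes; ``G.graph["root"]`` is the root code
    and ``G.graph["tree_edges"]`` the number of spanning-tree edges.
    """
    if n_codes < 50:
        raise ValueError(
            f"n_codes={n_codes} is too small: the synthetic ontology needs at "
            "least 50 concepts to carve out latent-factor subtrees"
        )
    if branching < 2:
        raise ValueError("branching must be >= 2")

    rng = np.random.default_rng(seed)
    G = nx.Graph()
    G.add_nodes_from(code_name(i) for i in range(n_codes))

    # Random tree: attach each new node to a uniformly chosen earlier node
    # that still has spare child slots (bounded by `branching`).
    child_count = np.zeros(n_codes, dtype=int)
    for i in range(1, n_codes):
        open_parents = np.flatnonzero(child_count[:i] < branching)
        parent = int(rng.choice(open_parents))
        child_count[parent] += 1
        G.add_edge(code_name(parent), code_name(i))

    n_tree_edges = n_codes - 1
    n_cross = int(round(CROSS_LINK_FRACTION * n_tree_edges))
    added = 0
    while added < n_cross:
        u, v = rng.integers(0, n_codes, size=2)
        if u == v:
            continue
        cu, cv = code_name(int(u)), code_name(int(v))
        if G.has_edge(cu, cv):
            continue
        G.add_edge(cu, cv)
        added += 1

    G.graph["root"] = code_name(0)
    G.graph["tree_edges"] = n_tree_edges
    return G


def top_level_ancestor_index(G: nx.Graph, n_codes: int) -> dict[str, int]:
    """Map each code to the index of its top-level subtree (child of root).

    The root itself maps to subtree 0. Uses the tree skeleton implicitly via
    BFS from the root on the full graph; cross-links can only merge subtree
    assignment where BFS reaches a node first, which is fine for the
    generator's purpose (a stable partition of codes into class territories).
    """
    root = G.graph["root"]
    first_level = sorted(G.neighbors(root))
    assignment: dict[str, int] = {root: 0}
    for idx, child in enumerate(first_level):
        assignment[child] = idx
    # BFS layer by layer, inheriting the ancestor index
    frontier = list(first_level)
    while frontier:
        nxt = []
        for node in frontier:
            for nb in G.neighbors(node):
                if nb not in assignment:
                    assignment[nb] = assignment[node]
                    nxt.append(nb)
        frontier = nxt
    return assignment


def latent_factor_assignment(G: nx.Graph, codes: list[str], n_latent: int) -> dict[str, int]:
    """Partition codes into ``n_latent`` contiguous blocks of subtree order.

    Codes are sorted by (top-level subtree, code) and chunked, so codes from
    the same subtree load on the same latent factor wherever possible while
    every factor is guaranteed a nonempty territory even when the root has
    fewer children than there are factors.
    """
    sub = top_level_ancestor_index(G, len(codes))
    ordered = sorted(codes, key=lambda c: (sub.get(c, 0), c))
    chunk = int(np.ceil(len(ordered) / n_latent))
    return {c: min(i // chunk, n_latent - 1) for i, c in enumerate(ordered)}


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source,target\n")
        for u, v in sorted(G.edges()):
            fh.write(f"{u},{v}\n")


def read_edge_list(path) -> nx.Graph:
    G = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        assert header.strip() == "source,target"
        for line in fh:
            u, v = line.strip().split(",")
            G.add_edge(u, v)
    G.graph["root"] = min(G.nodes())
    return G
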