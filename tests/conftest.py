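"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths: column
classification is re-derived with plain Python sets, and tree bipartitions
are recovered by deleting one edge at a time from a generic adjacency graph
and flood-filling the two components.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from gbsphylo.loci import Assembly, LocusAlignment

# independent IUPAC table (kept separate from gbsphylo.iupac on purpose)
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "M": {"A", "C"}, "R": {"A", "G"}, "W": {"A", "T"},
    "S": {"C", "G"}, "Y": {"C", "T"}, "K": {"G", "T"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
}
AMBIG_CHARS = "MRWSYK"


def brute_column_classes(chars: list[str]) -> tuple[bool, bool, bool]:
    """(snp, pis, singleton) for one alignment column, by plain enumeration."""
    present = [c for c in chars if c not in ("N", "-")]
    sets = [IUPAC_SETS[c] for c in present]
    union = set().union(*sets) if sets else set()
    snp = len(union) > 1
    carriers = {a: sum(1 for s in sets if a in s) for a in union}
    pis = snp and sum(1 for v in carriers.values() if v >= 2) >= 2
    singleton = False
    if snp and len(present) >= 2:
        for pattern in set(present):
            if present.count(pattern) == len(present) - 1:
                singleton = True
    return snp, pis, singleton


def brute_assembly_counts(assembly: Assembly) -> tuple[int, int, int]:
    """(n_snps, n_pis, n_singletons) by looping every column."""
    n_snp = n_pis = n_sing = 0
    for locus in assembly.loci:
        seqs = list(locus.samples.values())
        for col in range(locus.length):
            snp, pis, sing = brute_column_classes([s[col] for s in seqs])
            n_snp += snp
            n_pis += pis
            n_sing += sing
    return n_snp, n_pis, n_sing


# ---------------------------------------------------------------------------
# graph-based tree oracles


def _tree_graph(tree):
    """dendropy tree -> (adjacency {id: set(id)}, edge list with lengths, leaves)."""
    adj: dict[int, set[int]] = {}
    edges: list[tuple[int, int, float]] = []
    leaf_of: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(id(node), set())
        if node.is_leaf():
            leaf_of[id(node)] = node.taxon.label
        if node.parent_node is not None:
            a, b = id(node.parent_node), id(node)
            adj[a].add(b)
            adj.setdefault(b, set()).add(a)
            edges.append((a, b, node.edge.length or 0.0))
    return adj, edges, leaf_of


def brute_splits(tree, include_trivial: bool = False) -> dict[frozenset, float]:
    """Splits (normalized away from the reference tip) by edge deletion + BFS."""
    adj, edges, leaf_of = _tree_graph(tree)
    tips = sorted(leaf_of.values())
    ref = tips[0]
    n = len(tips)
    out: dict[frozenset, float] = {}
    for a, b, length in edges:
        # flood fill from b with edge (a, b) removed
        seen = {b}
        stack = [b]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((a, b), (b, a)) or y in seen:
                    continue
                seen.add(y)
                stack.append(y)
        side = frozenset(leaf_of[x] for x in seen if x in leaf_of)
        if ref in side:
            side = frozenset(tips) - side
        if len(side) in (0, n):
            continue
        if not include_trivial and not (2 <= len(side) <= n - 2):
            continue
        out[side] = out.get(side, 0.0) + length
    return out


def brute_rf(tree1, tree2) -> int:
    return len(set(brute_splits(tree1)) ^ set(brute_splits(tree2)))


def brute_kf(tree1, tree2) -> float:
    m1 = brute_splits(tree1, include_trivial=True)
    m2 = brute_splits(tree2, include_trivial=True)
    total = 0.0
    for s in set(m1) | set(m2):
        total += (m1.get(s, 0.0) - m2.get(s, 0.0)) ** 2
    return math.sqrt(total)


# ---------------------------------------------------------------------------
# random fixtures


def random_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random binary unrooted-shape newick with random branch lengths."""
    nodes = [f"{l}:{rng.uniform(0.1, 2.0):.4f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.4f}")
    return "(" + ",".join(nodes) + ");"


def random_assembly(rng: np.random.Generator, n_samples: int = 6,
                    n_loci: int = 8, max_len: int = 12) -> Assembly:
    """Random small assembly with ambiguity codes and missing data."""
    roster = [f"s{i}" for i in range(1, n_samples + 1)]
    alphabet = list("ACGT") + list(AMBIG_CHARS) + ["N", "-"]
    probs = np.array([0.18] * 4 + [0.03] * 6 + [0.05, 0.05])
    probs = probs / probs.sum()
    loci = []
    for li in range(n_loci):
        length = int(rng.integers(4, max_len + 1))
        k = int(rng.integers(1, n_samples + 1))
        chosen = [roster[i] for i in sorted(rng.choice(n_samples, size=k, replace=False))]
        samples = {
            s: "".join(rng.choice(alphabet, size=length, p=probs)) for s in chosen
        }
        loci.append(LocusAlignment(str(li + 1), samples))
    return Assembly(loci, roster)


@pytest.fixture
def rng():
    return np.random.default_rng(20190111)
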