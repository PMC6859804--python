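"""Support-annotated trees and the evaluation metrics of the workflow.

Covers: Newick I/O with per-branch support values (bootstrap 0-100 or
posterior probability 0-1 scales), the resolution quotient (supported
internal branches over the n-3 branches of a fully resolved unrooted tree),
Robinson-Foulds and Kuhner-Felsenstein branch-score distances computed from
bipartition sets, relative branch-length summaries, one-tip-per-species
pruning, and a neighbor-joining bootstrap surrogate used for end-to-end runs
on synthetic supermatrices.

Trees are compared unrooted; rooting is honored only for branch-length
summaries.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .replication import UndefinedRateError

SUPPORT_SCALES = {"BS": (0.0, 100.0), "PP": (0.0, 1.0)}


@dataclass
class SupportedTree:
    """A dendropy tree plus the scale its branch supports are expressed on."""

    tree: dendropy.Tree
    support_scale: str = "BS"

    def __post_init__(self) -> None:
        if self.support_scale not in SUPPORT_SCALES:
            raise ValueError(f"unknown support scale {self.support_scale!r}")
        lo, hi = SUPPORT_SCALES[self.support_scale]
        for node in self.tree.preorder_node_iter():
            s = _node_support(node)
            if s is not None and not lo <= s <= hi:
                raise ValueError(
                    f"support {s} outside {self.support_scale} scale [{lo}, {hi}]"
                )

    @property
    def tip_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


def _node_support(node: dendropy.Node) -> float | None:
    if node.is_leaf() or node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        raise ValueError(f"non-numeric internal node label {node.label!r}")


def read_newick(source: str, support_scale: str = "BS") -> SupportedTree:
    """Parse Newick text or a file path; internal node labels are supports."""
    import os

    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    from dendropy.dataio.newickreader import NewickReader

    try:
        if "(" not in source and os.path.exists(source):
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dup}")
    return SupportedTree(tree, support_scale)


def write_newick(tree: SupportedTree | dendropy.Tree) -> str:
    t = tree.tree if isinstance(tree, SupportedTree) else tree
    return t.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip() + "\n"


# ---------------------------------------------------------------------------
# bipartitions


def _as_tree(t) -> dendropy.Tree:
    return t.tree if isinstance(t, SupportedTree) else t


def bipartition_map(
    tree, include_trivial: bool = False
) -> dict[frozenset, dict]:
    """Unrooted bipartitions -> {'length', 'support', 'nodes'}.

    Each split is keyed by the tip-label set on the side *not* containing a
    fixed reference taxon.  A root bifurcation contributes one split whose
    length is the sum of the two root-child edges (standard unrooted
    treatment).
    """
    t = _as_tree(tree)
    tips = sorted(l.taxon.label for l in t.leaf_node_iter())
    n = len(tips)
    ref = tips[0]
    out: dict[frozenset, dict] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        under = frozenset(l.taxon.label for l in node.leaf_iter())
        side = frozenset(tips) - under if ref in under else under
        if not include_trivial and not (2 <= len(side) <= n - 2):
            continue
        if len(side) == 0 or len(side) == n:
            continue
        entry = out.setdefault(side, {"length": 0.0, "support": None, "nodes": []})
        if node.edge.length is not None:
            entry["length"] += node.edge.length
        s = _node_support(node)
        if s is not None:
            entry["support"] = s if entry["support"] is None else max(entry["support"], s)
        entry["nodes"].append(node)
    return out


def _check_tip_sets(t1, t2) -> int:
    s1 = set(l.taxon.label for l in _as_tree(t1).leaf_node_iter())
    s2 = set(l.taxon.label for l in _as_tree(t2).leaf_node_iter())
    if s1 != s2:
        raise ValueError(
            f"tip sets differ: only-first={sorted(s1 - s2)}, only-second={sorted(s2 - s1)}"
        )
    return len(s1)


def rf_distance(t1, t2) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalization by 2(n-3)."""
    n = _check_tip_sets(t1, t2)
    b1 = set(bipartition_map(t1))
    b2 = set(bipartition_map(t2))
    rf = len(b1 ^ b2)
    norm = rf / (2.0 * (n - 3)) if n > 3 else 0.0
    return rf, norm


def kf_branch_score(t1, t2) -> float:
    """Kuhner-Felsenstein branch-score distance.

    sqrt of the summed squared branch-length differences over the union of
    bipartitions, terminal branches included; a split absent from one tree
    contributes its full length.
    """
    _check_tip_sets(t1, t2)
    m1 = bipartition_map(t1, include_trivial=True)
    m2 = bipartition_map(t2, include_trivial=True)
    total = 0.0
    for split in set(m1) | set(m2):
        l1 = m1.get(split, {}).get("length", 0.0)
        l2 = m2.get(split, {}).get("length", 0.0)
        total += (l1 - l2) ** 2
    return math.sqrt(total)


def resolution_quotient(tree, threshold: float, strict: bool = True) -> float:
    """Supported internal branches / internal branches of a resolved tree.

    The denominator is n - 3 (the internal-branch count of a fully resolved
    unrooted tree on n tips), so polytomies depress the quotient and a star
    tree scores 0.  Support must be strictly above ``threshold`` (or >= when
    ``strict`` is False); branches without a support value never count.
    """
    st = tree if isinstance(tree, SupportedTree) else SupportedTree(tree)
    n = st.n_tips
    if n < 4:
        raise ValueError(f"resolution quotient needs >= 4 tips, got {n}")
    _, hi = SUPPORT_SCALES[st.support_scale]
    if threshold > hi:
        raise ValueError(
            f"threshold {threshold} exceeds {st.support_scale} scale maximum {hi}"
        )
    supported = 0
    for entry in bipartition_map(st).values():
        s = entry["support"]
        if s is None:
            continue
        if (s > threshold) if strict else (s >= threshold):
            supported += 1
    return supported / (n - 3)


# ---------------------------------------------------------------------------
# branch lengths


@dataclass(frozen=True)
class BranchLengthSummary:
    total: float
    mean: float
    median_rel_terminal: float
    median_rel_internal: float


def branch_length_summary(tree) -> BranchLengthSummary:
    """Totals and relative medians of terminal vs internal branch lengths.

    Terminal branches are tip-adjacent; all remaining branches (excluding the
    root edge) are internal.  Medians are divided by the total tree length.
    A tree without internal branches yields NaN for the internal median.
    """
    t = _as_tree(tree)
    terminal, internal = [], []
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.edge.length is None:
            continue
        (terminal if node.is_leaf() else internal).append(node.edge.length)
    if len(terminal) + len(internal) < 2:
        raise ValueError("branch length summary needs >= 2 branches")
    total = sum(terminal) + sum(internal)
    if total == 0:
        raise UndefinedRateError("total branch length is 0")
    mean = total / (len(terminal) + len(internal))
    med_t = float(np.median(terminal)) / total if terminal else float("nan")
    med_i = float(np.median(internal)) / total if internal else float("nan")
    return BranchLengthSummary(total, mean, med_t, med_i)


def prune_to_one_per_species(tree, species_of: dict[str, str]) -> SupportedTree:
    """Keep the first-listed accession per species; collapse removed paths.

    ``species_of`` maps every tip label to a species name (insertion order
    decides which accession is kept); suppressed degree-2 nodes merge branch
    lengths additively.
    """
    st = tree if isinstance(tree, SupportedTree) else SupportedTree(tree)
    tips = set(st.tip_labels)
    missing = tips - set(species_of)
    if missing:
        raise ValueError(f"tips absent from species table: {sorted(missing)}")
    keep: dict[str, str] = {}
    for tip, sp in species_of.items():
        if tip in tips and sp not in keep:
            keep[sp] = tip
    clone = st.tree.clone(depth=1)
    clone.retain_taxa_with_labels(list(keep.values()))
    return SupportedTree(clone, st.support_scale)


# ---------------------------------------------------------------------------
# neighbor-joining bootstrap surrogate


def _p_distance_matrix(mat: np.ndarray, names: list[str]) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of missing cells."""
    n = len(names)
    present = mat != 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            overlap = int(both.sum())
            if overlap == 0:
                raise ValueError(
                    f"samples ({names[i]}, {names[j]}) share no overlapping sites"
                )
            d[i, j] = d[j, i] = (mat[i, both] != mat[j, both]).sum() / overlap
    return d


def nj_tree(supermatrix: dict[str, str]) -> SupportedTree:
    """Neighbor-joining tree on p-distances (no supports)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    from .loci import encode

    names = list(supermatrix)
    if len(names) < 4:
        raise ValueError("neighbor joining needs >= 4 samples")
    mat = np.vstack([encode(supermatrix[s]) for s in names])
    d = _p_distance_matrix(mat, names)
    tn = nj(DistanceMatrix(d, ids=names))
    buf = io.StringIO()
    tn.write(buf)
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    for node in tree.preorder_node_iter():
        node.label = None
        if node.edge.length is not None and node.edge.length < 0:
            node.edge.length = 0.0  # NJ can emit small negatives
    return SupportedTree(tree, "BS")


def nj_bootstrap_tree(
    supermatrix: dict[str, str], n_bootstrap: int = 100, seed: int = 0
) -> SupportedTree:
    """NJ tree with bootstrap supports (bipartition frequencies x 100).

    Columns are resampled with replacement; bootstrap replicates in which a
    sample pair loses all overlap are skipped (and excluded from the support
    denominator).  Deterministic for a fixed seed.
    """
    main = nj_tree(supermatrix)
    from .loci import encode

    names = list(supermatrix)
    mat = np.vstack([encode(supermatrix[s]) for s in names])
    L = mat.shape[1]
    rng = np.random.default_rng(seed)
    split_counts: dict[frozenset, int] = {}
    n_ok = 0
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        bm = mat[:, cols]
        try:
            d = _p_distance_matrix(bm, names)
        except ValueError:
            continue
        from skbio import DistanceMatrix
        from skbio.tree import nj as _nj

        tn = _nj(DistanceMatrix(d, ids=names))
        buf = io.StringIO()
        tn.write(buf)
        bt = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
        n_ok += 1
        for split in bipartition_map(bt):
            split_counts[split] = split_counts.get(split, 0) + 1
    for split, entry in bipartition_map(main).items():
        support = 100.0 * split_counts.get(split, 0) / n_ok if n_ok else 0.0
        for node in entry["nodes"]:
            node.label = f"{support:g}"
    return SupportedTree(main.tree, "BS")
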