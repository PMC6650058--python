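"""Distance-based tree building: neighbor-joining, UPGMA, bootstrap, rooting.

These are the pipeline's native tree engines. NJ follows Saitou & Nei's
Q-criterion with the standard branch-length formulas; UPGMA is unweighted
average linkage, producing an ultrametric tree with node heights equal to
half the merge distance. Both use a fixed deterministic tie-break (lowest
index pair in the current ordering). Negative NJ branch-length estimates are
clamped to zero and the total clamped deficit recorded on the tree.

Externally built trees (ML/BI/chronograms) enter the pipeline as Newick via
:mod:`barcodelim.seqio` and are treated identically downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix, _k2p_matrix_from_codes, distance_matrix
from .seqio import Alignment


@dataclass
class TreeInferenceConfig:
    """How to build trees: method, bootstrap replicates, seed, deletion mode."""

    method: str = "nj"
    n_bootstrap: int = 1000
    seed: int = 0
    deletion_mode: str = "complete"

    def __post_init__(self) -> None:
        if self.method not in ("nj", "upgma"):
            raise ValueError(f"unknown tree method {self.method!r}")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")


def _require_defined(dm: DistanceMatrix) -> None:
    if not dm.defined.all():
        pairs = dm.undefined_pairs()
        raise ValueError(
            f"distance matrix has {len(pairs)} undefined (saturated) entries: "
            f"{pairs[:10]}"
        )


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted tree, exact on additive input.

    Tie-break: the minimum Q entry with the lowest (i, j) pair in the current
    node ordering (merged nodes are appended at the end). Negative branch
    lengths are clamped to 0; the summed deficit is stored in
    ``tree.annotations`` under ``nj_clamped_deficit``.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs >= 3 sequences")
    _require_defined(dm)
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(s)) for s in dm.ids]
    D = dm.d.astype(float).copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0.0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)  # row-major => lowest (i, j), i < j
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x != i and x != j]
        Dn = np.empty((m - 1, m - 1))
        Dn[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        Dn[m - 2, : m - 2] = dnew[keep]
        Dn[: m - 2, m - 2] = dnew[keep]
        Dn[m - 2, m - 2] = 0.0
        D = Dn
        nodes = [nodes[x] for x in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = dendropy.Node()
    for child, length in (
        (a, (dab + dac - dbc) / 2.0),
        (b, (dab + dbc - dac) / 2.0),
        (c, (dac + dbc - dab) / 2.0),
    ):
        root.add_child(child)
        child.edge.length = clamp(length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    tree.annotations.add_new("nj_clamped_deficit", deficit)
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Unweighted average-linkage clustering; rooted ultrametric tree.

    Node heights equal half the merge distance; tie-break as in NJ.
    """
    if dm.n < 2:
        raise ValueError("UPGMA needs >= 2 sequences")
    _require_defined(dm)
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(s)) for s in dm.ids]
    heights = [0.0] * dm.n
    sizes = [1] * dm.n
    D = dm.d.astype(float).copy()
    while len(nodes) > 1:
        m = len(nodes)
        M = D.copy()
        np.fill_diagonal(M, np.inf)
        i, j = divmod(int(np.argmin(M)), m)
        h = D[i, j] / 2.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(h - heights[i], 0.0)
        nodes[j].edge.length = max(h - heights[j], 0.0)
        ni, nj = sizes[i], sizes[j]
        dnew = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        keep = [x for x in range(m) if x != i and x != j]
        Dn = np.empty((m - 1, m - 1))
        Dn[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        Dn[m - 2, : m - 2] = dnew[keep]
        Dn[: m - 2, m - 2] = dnew[keep]
        Dn[m - 2, m - 2] = 0.0
        D = Dn
        nodes = [nodes[x] for x in keep] + [parent]
        heights = [heights[x] for x in keep] + [h]
        sizes = [sizes[x] for x in keep] + [ni + nj]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


# -- ultrametric helpers ---------------------------------------------------

def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path lengths (edge lengths; missing lengths count as 0)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Heights (time before present), with the deepest tip at height 0."""
    depths = node_depths(tree)
    max_depth = max(depths[leaf] for leaf in tree.leaf_node_iter())
    return {node: max_depth - depth for node, depth in depths.items()}


def is_ultrametric(tree: dendropy.Tree, tol: float | None = None) -> bool:
    """True when all tip heights agree within tol (default 1e-6 x root height)."""
    heights = node_heights(tree)
    root_h = heights[tree.seed_node]
    if tol is None:
        tol = 1e-6 * max(root_h, 1e-300)
    return all(abs(heights[leaf]) <= tol for leaf in tree.leaf_node_iter())


# -- bootstrap -------------------------------------------------------------

def _split_key(labels_below: frozenset, all_labels: frozenset, ref: str) -> frozenset:
    """Canonical unrooted-split key: the side not containing ``ref``."""
    if ref in labels_below:
        return all_labels - labels_below
    return labels_below


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset]:
    out: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset({node.taxon.label})
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= out[ch]
            out[node] = frozenset(s)
    return out


def internal_split_keys(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset]:
    """Non-trivial unrooted splits keyed by the internal node below each edge."""
    leafsets = _leafsets(tree)
    all_labels = leafsets[tree.seed_node]
    ref = min(all_labels)
    keys: dict[dendropy.Node, frozenset] = {}
    for node, below in leafsets.items():
        if node.parent_node is None:
            continue
        key = _split_key(below, all_labels, ref)
        if 2 <= len(key) <= len(all_labels) - 2:
            keys[node] = key
    return keys


def bootstrap_supports(
    alignment: Alignment,
    config: TreeInferenceConfig | None = None,
    outgroup_ids: list[str] | None = None,
    allow_superset_root: bool = False,
) -> dendropy.Tree:
    """Point tree from the full alignment with % bootstrap split supports.

    Columns are resampled with replacement (replicate r seeded with
    ``config.seed + r``); each internal split's support is the percentage of
    replicate trees containing that split (unrooted comparison). With
    ``outgroup_ids`` the point tree is rooted on the outgroup stem *before*
    supports are attached, so clade labels stay consistent. An alignment with
    no variation yields a tree without supports.
    """
    cfg = config or TreeInferenceConfig()
    build = neighbor_joining if cfg.method == "nj" else upgma
    # canonical row order: the NJ/UPGMA tie-break is index-based, so sorting
    # by id here makes the point tree and all supports independent of the
    # order sequences appear in the input alignment
    alignment = alignment.subset(sorted(alignment.ids))
    dm = distance_matrix(alignment, cfg.deletion_mode)
    tree = build(dm)
    if outgroup_ids:
        tree = root_with_outgroup(
            tree, outgroup_ids, allow_superset=allow_superset_root
        )

    codes = alignment.to_codes()
    clean = codes[:, (codes < 4).all(axis=0)]
    no_variation = bool((dm.d == 0).all())
    if cfg.n_bootstrap == 0 or no_variation or clean.shape[1] == 0:
        return tree

    counts: Counter[frozenset] = Counter()
    n_cols = clean.shape[1]
    for r in range(cfg.n_bootstrap):
        rng = np.random.default_rng(cfg.seed + r)
        cols = rng.integers(0, n_cols, size=n_cols)
        d_b, ok_b = _k2p_matrix_from_codes(clean[:, cols])
        d_b[~ok_b] = np.nanmax(np.where(ok_b, d_b, np.nan))  # saturate, keep finite
        dm_b = DistanceMatrix(
            ids=list(alignment.ids), d=d_b, defined=np.ones_like(ok_b), deletion_mode=cfg.deletion_mode
        )
        rep = build(dm_b)
        counts.update(set(internal_split_keys(rep).values()))

    for node, key in internal_split_keys(tree).items():
        support = 100.0 * counts[key] / cfg.n_bootstrap
        node.label = f"{support:.0f}"
        node.annotations.add_new("support", support)
    return tree


def get_support(node: dendropy.Node) -> float | None:
    ann = node.annotations.get_value("support", None)
    if ann is not None:
        return float(ann)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


# -- rooting ---------------------------------------------------------------

def root_with_outgroup(
    tree: dendropy.Tree,
    outgroup_ids: list[str],
    fallback_midpoint: bool = False,
    allow_superset: bool = False,
) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The outgroup must be monophyletic in the unrooted tree; otherwise an
    error names the conflict (or, if ``fallback_midpoint``, the tree is
    midpoint-rooted instead). With ``allow_superset`` the root goes on the
    longest edge having every outgroup id on one side (the outgroup stem) —
    useful when unidentified specimens cluster inside the outgroup clade.
    """
    tree = tree.clone(depth=1)
    leafsets = _leafsets(tree)
    all_labels = leafsets[tree.seed_node]
    og = frozenset(outgroup_ids)
    missing = og - all_labels
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    target_edge = None
    best_key = None
    for node, below in leafsets.items():
        if node.parent_node is None:
            continue
        if below == og or (all_labels - below) == og:
            target_edge = node.edge
            break
        if allow_superset:
            for side in (below, all_labels - below):
                if og <= side and side != all_labels:
                    key = (node.edge.length or 0.0, len(og) - len(side))
                    if best_key is None or key > best_key:
                        best_key = key
                        target_edge = node.edge
    if target_edge is None:
        if fallback_midpoint:
            tree.reroot_at_midpoint(update_bipartitions=False)
            tree.is_rooted = True
            return tree
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic in the tree; "
            "no edge separates it from the ingroup"
        )
    length = target_edge.length or 0.0
    tree.reroot_at_edge(
        target_edge, length1=length / 2.0, length2=length / 2.0,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return tree
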