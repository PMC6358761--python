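"""Distance-based phylogeny and subfamily classification.

Protein distances are Poisson-corrected (d = -ln(1 - p)) with pairwise
deletion (only mutually ungapped columns count).  Trees are built with
Saitou-Nei neighbor joining, which recovers additive distance matrices
exactly; clade confidence comes from bootstrap resampling of alignment
columns.  Genes are assigned to the five trihelix subfamilies (SIP1, GTγ,
GT, SH4, GTδ) by the smallest clade that contains them together with marker
taxa of a single subfamily, falling back to the nearest marker by patristic
distance when clades mix subfamilies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from trihelix.errors import ValidationError

SUBFAMILIES = ("SIP1", "GTγ", "GT", "SH4", "GTδ")

SATURATION_CAP = 10.0  # distance assigned when p -> 1 (documented cap)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    distances: np.ndarray  # symmetric, zero diagonal
    shared_sites: np.ndarray  # per-pair ungapped column counts
    saturated: np.ndarray  # boolean mask where p == 1 hit the cap

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValidationError("distances must be symmetric, nonnegative, zero-diagonal")


@dataclass
class SubfamilyAssignment:
    """gene -> subfamily label (None when unassignable) with the marker taxa
    supporting each call; ambiguous genes were labelled by the nearest-marker
    fallback."""

    labels: dict[str, str | None]
    supporting_markers: dict[str, tuple[str, ...]]
    ambiguous: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def poisson_distance(
    alignment: Mapping[str, str],
    pairwise_deletion: bool = True,
    saturation_cap: float = SATURATION_CAP,
) -> DistanceMatrix:
    """Poisson-corrected pairwise protein distances with pairwise deletion.

    For each pair, p = mismatches / mutually ungapped columns and
    d = -ln(1 - p).  p = 1 saturates and is capped at ``saturation_cap``.
    Without pairwise deletion, columns gapped in any sequence are dropped
    globally (complete deletion).
    """
    ids = tuple(alignment)
    if len(ids) < 2:
        raise ValidationError("need at least 2 aligned sequences")
    seqs = [alignment[i].upper() for i in ids]
    if len({len(s) for s in seqs}) != 1:
        raise ValidationError("aligned sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    gap = (arr == "-") | (arr == ".")
    if not pairwise_deletion:
        keep = ~gap.any(axis=0)
        arr, gap = arr[:, keep], gap[:, keep]

    n = len(ids)
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValidationError(
                    f"no shared ungapped columns between {ids[i]} and {ids[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / m
            if p >= 1.0:
                dist, sat = saturation_cap, True
            else:
                dist, sat = -np.log1p(-p), False
            d[i, j] = d[j, i] = dist
            shared[i, j] = shared[j, i] = m
            saturated[i, j] = saturated[j, i] = sat
    return DistanceMatrix(ids, d, shared, saturated)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Ties in the Q criterion break on the lexicographically smallest cluster
    pair (clusters are named by their smallest leaf).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister edge.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    namespace = dendropy.TaxonNamespace(list(dm.ids))
    nodes: dict[str, dendropy.Node] = {}
    for name in dm.ids:
        node = dendropy.Node(taxon=namespace.get_taxon(name))
        nodes[name] = node
    dist: dict[str, dict[str, float]] = {
        a: {b: float(dm.distances[i, j]) for j, b in enumerate(dm.ids) if a != b}
        for i, a in enumerate(dm.ids)
    }
    active = sorted(nodes)

    def clamp(v_i: float, v_j: float) -> tuple[float, float]:
        if v_i < 0:
            v_j += v_i
            v_i = 0.0
        if v_j < 0:
            v_i += v_j
            v_j = 0.0
        return v_i, max(v_j, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best, best_pair = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                a, b = active[ai], active[aj]
                q = (m - 2) * dist[a][b] - r[a] - r[b]
                if best is None or q < best - 1e-12:
                    best, best_pair = q, (a, b)
        a, b = best_pair
        d_ab = dist[a][b]
        v_a = d_ab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        v_b = d_ab - v_a
        v_a, v_b = clamp(v_a, v_b)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = v_a
        parent.add_child(nodes[b])
        nodes[b].edge.length = v_b
        label = min(a, b)
        for other in active:
            if other in (a, b):
                continue
            d_new = (dist[a][other] + dist[b][other] - d_ab) / 2.0
            dist.setdefault(label, {})[other] = d_new
            dist[other][label] = d_new
        nodes[label] = parent
        active = sorted(set(active) - {a, b} | {label})

    root = dendropy.Node()
    a, b, c = active
    d_ab, d_ac, d_bc = dist[a][b], dist[a][c], dist[b][c]
    lengths = {
        a: (d_ab + d_ac - d_bc) / 2.0,
        b: (d_ab + d_bc - d_ac) / 2.0,
        c: (d_ac + d_bc - d_ab) / 2.0,
    }
    for name in (a, b, c):
        root.add_child(nodes[name])
        nodes[name].edge.length = max(lengths[name], 0.0)
    tree = dendropy.Tree(seed_node=root, taxon_namespace=namespace)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree, taxa: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf sets on the side not containing the
    reference (smallest) taxon, so rooting is irrelevant."""
    ref = min(taxa)
    full = set(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(frozenset(side))
    return out


def bootstrap_support(
    alignment: Mapping[str, str],
    replicates: int = 1000,
    rng_seed: int = 0,
    pairwise_deletion: bool = True,
) -> dendropy.Tree:
    """NJ tree from the full alignment with internal-node labels giving the
    percentage of bootstrap replicates (column resampling) that contain each
    original bipartition.  ``replicates=0`` returns the unadorned tree."""
    width = len(next(iter(alignment.values())))
    if width < 2:
        raise ValidationError("alignment needs at least 2 columns")
    tree = neighbor_joining(poisson_distance(alignment, pairwise_deletion))
    if replicates == 0:
        return tree
    taxa = list(alignment)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(rng_seed)
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        resampled = {name: "".join(seq[c] for c in cols) for name, seq in alignment.items()}
        try:
            rep_tree = neighbor_joining(poisson_distance(resampled, pairwise_deletion))
        except ValidationError:
            continue  # replicate with no shared columns for some pair
        for bp in _bipartitions(rep_tree, taxa):
            counts[bp] = counts.get(bp, 0) + 1
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        ref = min(taxa)
        if ref in side:
            side = set(taxa) - side
        if 2 <= len(side) <= len(taxa) - 2:
            support = 100.0 * counts.get(frozenset(side), 0) / replicates
            node.label = str(int(round(support)))
    return tree


# ---------------------------------------------------------------------------
# subfamily assignment
# ---------------------------------------------------------------------------


def assign_subfamilies(
    tree: dendropy.Tree, marker_map: Mapping[str, str]
) -> SubfamilyAssignment:
    """Label each non-marker leaf with the subfamily of the smallest clade
    containing it and markers of exactly one subfamily; mixed clades fall back
    to the nearest marker by patristic distance and are flagged ambiguous.

    Clades are taken in the unrooted sense: every edge splits the taxa in
    two, and both sides count as candidate clades.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    markers = {t: s for t, s in marker_map.items() if t in leaf_labels}
    if not markers:
        raise ValidationError("tree contains no marker taxa")

    sides: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        under = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.append(under)
        sides.append(frozenset(leaf_labels - under))

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels: dict[str, str | None] = {}
    supporting: dict[str, tuple[str, ...]] = {}
    ambiguous: set[str] = set()

    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in markers:
            labels[name] = markers[name]
            supporting[name] = (name,)
            continue
        candidates = [
            s for s in sides if name in s and any(m in s for m in markers)
        ]
        candidates.sort(key=lambda s: (len(s), tuple(sorted(s))))
        smallest = candidates[0]
        clade_markers = sorted(m for m in markers if m in smallest)
        subfams = {markers[m] for m in clade_markers}
        if len(subfams) == 1:
            labels[name] = subfams.pop()
            supporting[name] = tuple(clade_markers)
        else:
            nearest = min(
                markers,
                key=lambda m: (pdm.patristic_distance(taxa[name], taxa[m]), m),
            )
            labels[name] = markers[nearest]
            supporting[name] = (nearest,)
            ambiguous.add(name)
    return SubfamilyAssignment(labels=labels, supporting_markers=supporting, ambiguous=ambiguous)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
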