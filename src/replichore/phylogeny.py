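"""Distance-based 16S phylogeny: p-distance, neighbor-joining, bootstrap.

Distances are uncorrected p-distances with pairwise deletion (sites where
either sequence has a gap, N or another ambiguity are discarded for that
pair); a Jukes-Cantor correction is available but off by default, since
published similarity matrices rarely state a model. Trees are built with
classical neighbor-joining (Q-criterion joins, canonical branch-length and
distance-update formulas), which recovers any additive matrix exactly.
Bootstrap supports are percentages of column-resampled replicates
containing each internal bipartition.

Determinism: join ties are broken by the lexicographically smallest
taxon-pair label, and all bootstrap randomness flows from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "PairwiseDeletionError",
    "read_alignment",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

VALID_BASES = frozenset(b"ACGT")


class PairwiseDeletionError(ValueError):
    """A pair of sequences retains zero comparable sites."""


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("aligned rows must have equal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.rows), self.n_sites)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_sites, self.n_sites)
        m = self.matrix()[:, cols]
        return Alignment(
            list(self.taxa), [bytes(r).decode("ascii") for r in m]
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    return Alignment([r.id for r in aln], [str(r.seq) for r in aln])


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray                 # symmetric, zero diagonal
    units: str = "substitutions per site"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def p_distance_matrix(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of ambiguous sites.

    ``model="jc"`` applies the Jukes-Cantor correction
    d = -3/4 ln(1 - 4p/3) to each pairwise p-distance.
    """
    m = aln.matrix()
    valid = np.isin(m, list(VALID_BASES))
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            retained = int(both.sum())
            if retained == 0:
                raise PairwiseDeletionError(
                    f"no comparable sites between {aln.taxa[i]!r} and "
                    f"{aln.taxa[j]!r}"
                )
            p = float((m[i][both] != m[j][both]).sum()) / retained
            if model == "jc":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {aln.taxa[i]!r} and "
                        f"{aln.taxa[j]!r} is beyond the Jukes-Cantor range"
                    )
                p = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(aln.taxa), d)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0            # edge length to the parent
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def _quote(name: str) -> str:
    if any(ch in name for ch in " (),:;[]'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass
class PhyloTree:
    """Unrooted tree held with a trifurcating (or bifurcating) root node."""

    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def newick(
        self, support_threshold: Optional[float] = None, decimals: int = 10
    ) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = _quote(node.name or "")
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if node.support is not None and (
                    support_threshold is None or node.support > support_threshold
                ):
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.{decimals}f}"

        return fmt(self.root, True) + ";"

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length (patristic) distances between all leaf pairs."""
        taxa = self.taxa
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        d = np.zeros((n, n))

        def below(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.name]: 0.0}
            acc: dict[int, float] = {}
            child_maps = []
            for c in node.children:
                cm = {k: v + c.length for k, v in below(c).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            d[i, j] = d[j, i] = di + dj
                for k, v in child_maps[a].items():
                    acc[k] = v
            return acc

        below(self.root)
        return DistanceMatrix(taxa, d)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions, canonicalized as the leaf-name set on
        the side NOT containing the alphabetically first taxon."""
        taxa = set(self.taxa)
        anchor = min(taxa)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            under = set()
            for c in node.children:
                under |= walk(c)
            if node is not self.root and len(under) > 1 and len(taxa - under) > 1:
                side = under if anchor not in under else taxa - under
                out[frozenset(side)] = node
            return under

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# Neighbor-joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical neighbor-joining.

    Join selection minimizes Q(i,j) = (n-2) d(i,j) - r_i - r_j; ties are
    broken by the lexicographically smallest sorted pair of cluster labels
    (a cluster's label is the smallest leaf name under it). Negative branch
    lengths are clamped to 0 with the deficit moved to the sister edge.
    On an additive matrix the output reproduces the generating tree and
    branch lengths exactly.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    labels: list[str] = list(D.taxa)
    d = D.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_label = tuple(sorted((labels[i], labels[j])))
                key = (q, pair_label)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distance from the new node to every other active cluster
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(ln, 0.0)
    # order children deterministically by their smallest leaf label
    def canonical(node: TreeNode) -> str:
        return min(l.name for l in node.leaves())

    def sort_rec(node: TreeNode) -> None:
        node.children.sort(key=canonical)
        for ch in node.children:
            sort_rec(ch)

    sort_rec(root)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapResult:
    tree: PhyloTree
    replicates: int
    completed: int
    skipped: int


def bootstrap_support(
    aln: Alignment,
    replicates: int = 100,
    seed: int = 0,
    model: str = "p",
) -> BootstrapResult:
    """Bootstrap supports for the NJ tree of an alignment.

    Columns are resampled with replacement ``replicates`` times; the
    support of each internal bipartition of the full-data tree is the
    percentage of completed replicates whose tree contains it. Replicates
    with an undefined pairwise distance are skipped and counted. Supports
    are attached to the tree; thresholding (e.g. show only >50%) is a
    display-time choice of :meth:`PhyloTree.newick`.
    """
    import warnings

    rng = np.random.default_rng(seed)
    main = neighbor_joining(p_distance_matrix(aln, model=model))
    target = main.bipartitions()
    counts = {bp: 0 for bp in target}
    skipped = 0
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        try:
            t = neighbor_joining(p_distance_matrix(rep, model=model))
        except PairwiseDeletionError as err:
            skipped += 1
            warnings.warn(f"bootstrap replicate skipped: {err}")
            continue
        found = t.bipartitions()
        for bp in counts:
            if bp in found:
                counts[bp] += 1
    completed = replicates - skipped
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / completed if completed else None
    return BootstrapResult(
        tree=main, replicates=replicates, completed=completed, skipped=skipped
    )


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(
    tree: PhyloTree,
    path: str | Path,
    support_threshold: Optional[float] = None,
) -> Path:
    path = Path(path)
    path.write_text(tree.newick(support_threshold=support_threshold) + "\n")
    return path


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick file (via dendropy) into a :class:`PhyloTree`;
    internal node labels are interpreted as bootstrap supports."""
    import dendropy

    dt = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(nd) -> TreeNode:
        if nd.is_leaf():
            return TreeNode(
                name=nd.taxon.label if nd.taxon else nd.label,
                length=nd.edge.length or 0.0,
            )
        support = None
        if nd.label is not None:
            try:
                support = float(nd.label)
            except ValueError:
                pass
        return TreeNode(
            name=None,
            length=nd.edge.length or 0.0,
            support=support,
            children=[convert(c) for c in nd.child_nodes()],
        )

    return PhyloTree(convert(dt.seed_node))
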