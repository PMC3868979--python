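"""Distance estimation, tree building, branch support and patristic distances.

The built-in tree method is neighbor-joining on Jukes-Cantor distances.
Branch lengths are therefore in substitutions/site, which is what the
nearest-neighbor switch statistic minimizes over. Branch supports come from
a nonparametric bootstrap over alignment columns; they are reported for
inspection but never enter switch calling, which depends only on distances.
An external-tool adapter (FASTA in, newick out) allows substituting e.g. a
maximum-likelihood program while keeping the same downstream contract.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .mask_align import Alignment

log = logging.getLogger(__name__)

JC_CAP = 5.0  # substitutions/site assigned to saturated pairs (p >= 0.74)
_P_SATURATION = 0.74


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances over gene ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_skbio(self) -> SkbioDM:
        return SkbioDM(self.values, ids=list(self.ids))


PatristicTable = DistanceMatrix  # leaf-to-leaf path-length sums along a tree


_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _base_matrix(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    n, L = len(alignment.rows), alignment.length
    codes = np.full((n, L), -1, dtype=np.int8)
    for i, row in enumerate(alignment.rows):
        for j, ch in enumerate(row):
            codes[i, j] = _BASES.get(ch, -1)
    return codes, codes >= 0


def pairwise_distances(
    alignment: Alignment,
    model: str = "jc",
    on_empty: str = "error",
) -> DistanceMatrix:
    """Pairwise-deletion p or Jukes-Cantor distances from a masked alignment.

    Columns where either row holds ``N`` or a gap are excluded from both the
    mismatch count and the comparable-column count for that pair. Under the
    JC model, ``d = -(3/4) ln(1 - (4/3) p)``; saturated pairs
    (p >= 0.74) are capped at :data:`JC_CAP` with a warning.

    ``on_empty`` controls pairs with zero comparable columns: ``"error"``
    raises naming both ids; ``"cap"`` assigns the cap (used inside the
    bootstrap, where a column resample may drop all shared columns).
    """
    if model not in ("p", "jc"):
        raise ValueError(f"unknown distance model {model!r}")
    codes, valid = _base_matrix(alignment)
    n = len(alignment.rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                if on_empty == "error":
                    raise ValueError(
                        f"no comparable columns between "
                        f"{alignment.row_ids[i]!r} and {alignment.row_ids[j]!r}"
                    )
                out[i, j] = out[j, i] = JC_CAP
                continue
            mism = int((codes[i][both] != codes[j][both]).sum())
            p = mism / comparable
            if model == "p":
                d = p
            elif p >= _P_SATURATION:
                log.warning(
                    "saturated pair %s/%s (p=%.3f); distance capped at %.1f",
                    alignment.row_ids[i],
                    alignment.row_ids[j],
                    p,
                    JC_CAP,
                )
                d = JC_CAP
            else:
                d = -0.75 * np.log1p(-4.0 * p / 3.0)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(alignment.row_ids, out)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with nonnegative branch lengths.

    Ids are sorted lexicographically before agglomeration so ties resolve
    deterministically regardless of input order. Negative estimated branch
    lengths are clamped to zero. Two taxa yield the degenerate single-edge
    tree (each tip at half the pairwise distance).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    order = sorted(range(n), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    vals = dm.values[np.ix_(order, order)]
    if n == 2:
        half = float(vals[0, 1]) / 2.0
        a = TreeNode(name=ids[0], length=half)
        b = TreeNode(name=ids[1], length=half)
        return TreeNode(children=[a, b])
    tree = nj(SkbioDM(vals, ids=ids), neg_as_zero=True)
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            node.length = 0.0
    return tree


def patristic_distances(tree: TreeNode) -> PatristicTable:
    """Leaf-to-leaf path-length sums along tree branches, sorted by leaf id."""
    dm = tree.tip_tip_distances()
    ids = sorted(dm.ids)
    idx = [dm.ids.index(i) for i in ids]
    return DistanceMatrix(tuple(ids), dm.data[np.ix_(idx, idx)])


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each canonicalized to the side NOT containing
    the lexicographically smallest tip (rooting-invariant)."""
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    full = frozenset(tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = full - clade if anchor in clade else clade
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


def bootstrap_support(
    alignment: Alignment,
    tree: TreeNode,
    n_reps: int,
    seed: int,
    model: str = "jc",
) -> TreeNode:
    """Attach column-resampling bootstrap supports to a tree's internal nodes.

    Each replicate resamples alignment columns with replacement, recomputes
    distances (saturation-capped, empty pairs capped) and a neighbor-joining
    tree, and records its bipartitions. Support of an internal branch is the
    fraction of replicates containing its bipartition, stored as
    ``node.support`` in [0, 1]. Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    L = alignment.length
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(r[c] for c in cols) for r in alignment.rows)
        rep_aln = Alignment(alignment.row_ids, rows)
        dm = pairwise_distances(rep_aln, model=model, on_empty="cap")
        rep_tree = build_nj_tree(dm)
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    tips = sorted(t.name for t in tree.tips())
    anchor, full = tips[0], frozenset(tips)
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = full - clade if anchor in clade else clade
        if 2 <= len(side) <= len(full) - 2:
            node.support = counts.get(side, 0) / n_reps
    return out


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    mean_branch: float = 0.1,
) -> TreeNode:
    """Random binary tree with exponential branch lengths.

    Leaves ``L0..L{n-1}`` are joined pairwise in random order; every branch
    gets an independent Exponential(``mean_branch``) length. A verification
    utility: its patristic table is additive by construction, so it serves
    as ground truth for distance and tree-building code.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    nodes = [
        TreeNode(name=f"L{i}", length=float(rng.exponential(mean_branch)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(
            TreeNode(children=[a, b], length=float(rng.exponential(mean_branch)))
        )
    root = nodes[0]
    root.length = None
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write newick; bootstrap supports become internal node labels."""
    t = tree.copy()
    for node in t.non_tips(include_self=True):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.name = f"{sup:.3f}"
    t.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


class ExternalTreeBuilder:
    """Subprocess adapter: gapped FASTA alignment in, newick on stdout.

    Suits maximum-likelihood programs; the returned tree must carry the
    alignment's ids as leaf labels and nonnegative branch lengths (negative
    lengths are clamped).
    """

    def __init__(self, argv: Sequence[str]):
        if not argv:
            raise ValueError("empty tree-builder command")
        self.argv = list(argv)
        if shutil.which(self.argv[0]) is None:
            raise FileNotFoundError(f"executable not found: {self.argv[0]}")

    def __call__(self, alignment: Alignment) -> TreeNode:
        with tempfile.TemporaryDirectory() as tmp:
            in_path = Path(tmp) / "alignment.fasta"
            alignment.to_fasta(in_path)
            argv = [a.replace("{in}", str(in_path)) for a in self.argv]
            if "{in}" not in " ".join(self.argv):
                argv.append(str(in_path))
            proc = subprocess.run(argv, capture_output=True, text=True, check=True)
        tree = TreeNode.read([proc.stdout])
        leaf_ids = {t.name for t in tree.tips()}
        if leaf_ids != set(alignment.row_ids):
            raise ValueError("external tree builder changed the leaf set")
        for node in tree.traverse(include_self=False):
            if node.length is None or node.length < 0:
                node.length = 0.0
        return tree
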