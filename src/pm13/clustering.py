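"""Distance matrices, neighbour-joining cladograms and score histograms.

Similarity scores are turned into distances d = 1 − PM13Score, clustered
with the Saitou–Nei neighbour-joining algorithm into an unrooted binary
tree, and serialized as Newick (readable by any tree viewer). Ties in the
NJ join criterion are broken deterministically towards the lowest label
index pair, and negative branch lengths are clamped to zero with the
deficit logged; exact tree-shape replication of runs that used other
tie-break conventions is therefore not promised.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .descriptor import ScoreMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

_NEWICK_META = set("()[]{}:;,'\" \t\n")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]


@dataclass
class TreeNode:
    """A node of an (un)rooted cladogram; leaves carry labels, edges lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        return [leaf for child, _ in self.children for leaf in child.leaves()]


@dataclass
class Cladogram:
    root: TreeNode  # unrooted tree, stored rooted at the last internal node

    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-lexical side."""
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if not node.children:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return out


def to_distance_matrix(scores: ScoreMatrix) -> DistanceMatrix:
    """Elementwise 1 − PM13Score (PMSMin), zero diagonal."""
    m = np.asarray(scores.pms_min, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("score matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise InputError("score matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise InputError("score matrix must have a unit diagonal")
    if m.min() < -1e-12 or m.max() > 1 + 1e-12:
        raise InputError("scores must lie in [0, 1]")
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(scores.labels), np.clip(d, 0.0, 1.0))


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("NJ: clamped negative branch length %.3g at %s", length, context)
        return 0.0
    return length


def neighbor_join(dm: DistanceMatrix) -> Cladogram:
    """Saitou–Nei neighbour joining with deterministic tie-breaks.

    The pair minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j is joined; ties go
    to the lowest (i, j) label index pair. Negative branch lengths are
    clamped to zero (deficit logged).
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbour joining needs at least 3 labels")
    d = np.array(dm.values, dtype=float)
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], _clamp(li, "join")),
                                    (nodes[j], _clamp(lj, "join"))])
        nodes.append(parent)
        new = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=0.0)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            duk = (sub[ai, ak] + sub[aj, ak] - dij) / 2
            d[new, k] = d[k, new] = duk
        active = [k for k in active if k not in (i, j)] + [new]

    # terminal three-star: closed-form branch lengths
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    root = TreeNode(children=[(nodes[a], _clamp(la, "star")),
                              (nodes[b], _clamp(lb, "star")),
                              (nodes[c], _clamp(lc, "star"))])
    return Cladogram(root)


def _quote(label: str) -> str:
    if any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: TreeNode) -> str:
    if not node.children:
        return _quote(node.label)
    inner = ",".join(f"{_newick(child)}:{length:.10g}"
                     for child, length in node.children)
    return f"({inner})"


def serialize_newick(t: Cladogram) -> str:
    if not t.root.children and t.root.label is None:
        raise InputError("cannot serialize an empty tree")
    return _newick(t.root) + ";"


def to_newick(t: Cladogram, path: str | Path) -> Path:
    """Write the tree as Newick; labels with metacharacters are quoted.

    The written text is checked to re-read losslessly (same leaf set).
    """
    text = serialize_newick(t)
    reread = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True)
    leaves = sorted(lf.taxon.label for lf in reread.leaf_node_iter())
    if leaves != sorted(t.leaf_labels()):
        raise InputError("Newick round-trip lost leaf labels")
    path = Path(path)
    path.write_text(text + "\n")
    return path


def score_histogram(scores) -> np.ndarray:
    """Counts of scores over the 10 bins [0,0.1), …, [0.8,0.9), [0.9,1.0].

    Bin 5 covers [0.5, 0.6), bin 7 covers [0.7, 0.8); the top bin is closed
    so a perfect score of 1.0 lands in bin 9.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise InputError("scores must lie in [0, 1]")
    counts = np.zeros(10, dtype=int)
    if scores.size:
        idx = np.minimum((scores * 10).astype(int), 9)
        np.add.at(counts, idx, 1)
    return counts


# ---------------------------------------------------------------------------
# matrix TSV I/O (CLI surface)

def write_matrix_tsv(scores: ScoreMatrix, path: str | Path) -> Path:
    path = Path(path)
    with io.StringIO() as buf:
        buf.write("label\t" + "\t".join(scores.labels) + "\n")
        for lab, row in zip(scores.labels, scores.pms_min):
            buf.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        path.write_text(buf.getvalue())
    return path


def read_matrix_tsv(path: str | Path, threshold: float = 0.5) -> ScoreMatrix:
    lines = Path(path).read_text().splitlines()
    labels = lines[0].split("\t")[1:]
    rows = [[float(v) for v in line.split("\t")[1:]] for line in lines[1:]]
    m = np.array(rows)
    return ScoreMatrix(labels, m, m.copy(), threshold)
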