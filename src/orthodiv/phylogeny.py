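"""Three-way ortholog concatenation, pairwise distances, and NJ tree.

Distances are closed-form: p-distance, Kimura two-parameter, or Tamura–Nei
1993 (the default, accommodating unequal base frequencies and distinct
purine/pyrimidine transition rates).  The tree is Saitou–Nei neighbor
joining; with exactly three taxa the branch lengths solve the star linear
system exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import TreeNode, log


@dataclass
class ConcatenatedAlignment:
    """Gap- and N-free concatenated columns for the three species."""

    labels: tuple[str, str, str]
    rows: tuple[str, str, str]
    gene_of_column: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def threeway_orthologs(
    pairs_ab: list[tuple[str, str]], pairs_ac: list[tuple[str, str]],
) -> list[tuple[str, str, str]]:
    """Gene triples where the same A-gene anchors a pair in both lists.

    A-genes paired with more than one partner in either list are ambiguous
    and dropped.
    """
    def unique_map(pairs):
        m: dict[str, str | None] = {}
        for a, x in pairs:
            m[a] = x if a not in m else None
        return m

    map_b = unique_map(pairs_ab)
    map_c = unique_map(pairs_ac)
    triples = []
    for a in sorted(map_b):
        b, c = map_b[a], map_c.get(a)
        if b is None or c is None:
            continue
        triples.append((a, b, c))
    return triples


def build_concatenation(
    triples: list[tuple[str, str, str]],
    columns_ab: dict[str, list[tuple[int, int]]],
    columns_ac: dict[str, list[tuple[int, int]]],
    seqs: dict[str, str],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> ConcatenatedAlignment:
    """Anchor each triple on the A member: a three-way column exists where
    an A position is aligned in both pairwise CDS alignments.

    ``columns_ab[a_gene]`` are gapless (a_pos, b_pos) columns from the A-B
    alignment, likewise ``columns_ac``.  Columns containing N are removed;
    genes are concatenated in stable A-gene id order.
    """
    rows: list[list[str]] = [[], [], []]
    gene_of_column: list[str] = []
    skipped = 0
    for a, b, c in sorted(triples):
        ab = columns_ab.get(a)
        ac = columns_ac.get(a)
        if not ab or not ac:
            skipped += 1
            continue
        b_at = dict(ab)
        c_at = dict(ac)
        common = [p for p in b_at if p in c_at]
        wrote = False
        for pa in sorted(common):
            ba = seqs[a][pa]
            bb = seqs[b][b_at[pa]]
            bc = seqs[c][c_at[pa]]
            if "N" in (ba, bb, bc):
                continue
            rows[0].append(ba)
            rows[1].append(bb)
            rows[2].append(bc)
            gene_of_column.append(a)
            wrote = True
        if not wrote:
            skipped += 1
    if skipped:
        log.info("build_concatenation: %d triples without common columns", skipped)
    return ConcatenatedAlignment(
        labels=labels,
        rows=("".join(rows[0]), "".join(rows[1]), "".join(rows[2])),
        gene_of_column=gene_of_column,
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class SaturationError(ValueError):
    """A distance formula hit the logarithm of a non-positive argument."""


def _pair_distance(s1: str, s2: str, model: str) -> float:
    n = len(s1)
    if n == 0:
        raise ValueError("empty alignment")
    if model == "p":
        diff = sum(a != b for a, b in zip(s1, s2))
        return diff / n

    p1 = p2 = q = 0  # A<->G, C<->T transitions, transversions
    counts = {b: 0 for b in "ACGT"}
    for a, b in zip(s1, s2):
        counts[a] += 1
        counts[b] += 1
        if a == b:
            continue
        pair = {a, b}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    P1, P2, Q = p1 / n, p2 / n, q / n

    if model == "K2P":
        P = P1 + P2
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError("K2P distance undefined (saturated)")
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)

    if model == "TN93":
        tot = 2 * n
        gA, gC, gG, gT = (counts[b] / tot for b in "ACGT")
        gR, gY = gA + gG, gC + gT
        k1 = 2.0 * gA * gG / gR
        k2 = 2.0 * gC * gT / gY
        k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
        w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
        w3 = 1.0 - Q / (2.0 * gR * gY)
        if w1 <= 0 or w2 <= 0 or w3 <= 0:
            raise SaturationError("TN93 distance undefined (saturated)")
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)

    raise ValueError(f"unknown distance model {model!r}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def pairwise_distance(alignment: ConcatenatedAlignment, model: str = "TN93") -> DistanceMatrix:
    """All pairwise distances of the concatenated rows, substitutions/site."""
    labels = list(alignment.labels)
    k = len(labels)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d = _pair_distance(alignment.rows[i], alignment.rows[j], model)
            except SaturationError as exc:
                raise SaturationError(
                    f"{exc} for pair ({labels[i]}, {labels[j]})") from None
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, matrix=m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Agglomerates the pair minimizing the Q criterion until three clusters
    remain, then resolves the final star exactly from the linear system.
    Negative branch lengths are clamped to zero with a warning.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in labels]

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("nj_tree: negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = d.sum(axis=1)
        q = (n - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([
            np.hstack([d[np.ix_(keep, keep)], d_new[keep, None]]),
            np.hstack([d_new[None, keep], [[0.0]]]),
        ])
        nodes = [nodes[k] for k in keep] + [new]

    # exact 3-star resolution: a+b=d(AB), a+c=d(AC), b+c=d(BC)
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    nodes[0].length = clamp(0.5 * (dab + dac - dbc))
    nodes[1].length = clamp(0.5 * (dab + dbc - dac))
    nodes[2].length = clamp(0.5 * (dac + dbc - dab))
    return TreeNode(children=nodes)


def tree_path_lengths(tree: TreeNode) -> dict[frozenset[str], float]:
    """Leaf-to-leaf path-length metric of a tree (for additivity checks)."""
    paths: dict[frozenset[str], float] = {}

    def walk(node: TreeNode) -> list[tuple[str, float]]:
        if node.is_leaf():
            return [(node.label, node.length)]
        below: list[list[tuple[str, float]]] = [walk(c) for c in node.children]
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for la, da in below[x]:
                    for lb, db in below[y]:
                        paths[frozenset((la, lb))] = da + db
        return [(lab, dist + node.length) for sub in below for lab, dist in sub]

    walk(tree)
    return paths
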