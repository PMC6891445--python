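"""Distance phylogenetics: nucleotide distances, UPGMA/NJ, bootstrap.

Distances are computed with pairwise deletion (columns with a gap or an
ambiguity code in either sequence are dropped for that pair) under the
p-distance, Jukes-Cantor (JC69), Kimura two-parameter (K2P), or
Tamura-Nei (TN93) corrections.  Saturated pairs (a logarithm argument
falling to zero or below) raise an error naming the pair rather than
returning infinity.

Trees are built with average-linkage agglomeration (UPGMA, ultrametric)
or Saitou-Nei neighbor joining; ties break on the lowest index pair and
negative NJ branch lengths are clamped to zero with the excess moved to
the sister branch, so construction is fully deterministic.  Bootstrap
support is the percentage of column-resampled replicates whose tree
contains each internal bipartition of the tree from the full alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SaturationError
from .seq_core import LocusAlignment

_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_PURINE = (0, 2)  # A, G


def encode_alignment(aln: LocusAlignment) -> np.ndarray:
    """(n_records, n_columns) uint8 matrix; A/C/G/T -> 0..3, other -> 255."""
    raw = np.frombuffer("".join(r.seq for r in aln.records).encode(),
                        dtype=np.uint8)
    return _CODE[raw].reshape(len(aln.records), aln.length)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    model: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise DataError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise DataError("distance matrix entries must be finite and >= 0")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def pairwise_distance(codes_a: np.ndarray, codes_b: np.ndarray,
                      model: str) -> float:
    """Distance between two encoded rows under the chosen model."""
    valid = (codes_a < 4) & (codes_b < 4)
    n = int(valid.sum())
    if n == 0:
        raise DataError("pair has no comparable columns")
    a, b = codes_a[valid], codes_b[valid]
    diff = a != b
    p = float(diff.sum()) / n
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError("JC69 saturated")
        return -0.75 * math.log(arg)

    a_pur = (a == 0) | (a == 2)
    b_pur = (b == 0) | (b == 2)
    transition = diff & (a_pur == b_pur)
    transversion = diff & (a_pur != b_pur)
    P = float(transition.sum()) / n
    Q = float(transversion.sum()) / n
    if model == "k2p":
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError("K2P saturated")
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    if model == "tn93":
        return _tn93(a, b, n, Q)
    raise DataError(f"unknown distance model {model!r}")


def _tn93(a: np.ndarray, b: np.ndarray, n: int, Q: float) -> float:
    # Base frequencies averaged over the pair.
    counts = np.bincount(np.concatenate([a, b]), minlength=4).astype(float)
    freqs = counts / counts.sum()
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) == 0:
        raise SaturationError("TN93 undefined: a base is absent in the pair")
    P1 = float(((a == 0) & (b == 2)).sum() + ((a == 2) & (b == 0)).sum()) / n
    P2 = float(((a == 1) & (b == 3)).sum() + ((a == 3) & (b == 1)).sum()) / n
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("TN93 saturated")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def distance_matrix(aln: LocusAlignment, model: str = "p") -> DistanceMatrix:
    """All-vs-all distances for one alignment (pairwise deletion)."""
    codes = encode_alignment(aln)
    return distance_matrix_from_codes(codes, aln.ids(), model)


def distance_matrix_from_codes(codes: np.ndarray, ids: list[str],
                               model: str) -> DistanceMatrix:
    n = codes.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pairwise_distance(codes[i], codes[j], model)
            except (SaturationError, DataError) as exc:
                raise type(exc)(f"pair {ids[i]}/{ids[j]}: {exc}") from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values, model=model)


# --- Trees -----------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted tree node; NJ trees carry a trifurcating root."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def min_leaf(self) -> str:
        return min(leaf.name for leaf in self.leaves())

    def sort(self) -> None:
        """Canonical child ordering: by lexicographic smallest leaf."""
        for child in self.children:
            child.sort()
        self.children.sort(key=lambda c: c.min_leaf())

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def _walk(node: TreeNode, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths[node.name] = acc
            for child in node.children:
                _walk(child, acc)

        for child in self.children:
            _walk(child, 0.0)
        return depths


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative clustering; heights are half the
    merge distance, so the result is ultrametric by construction."""
    n = len(dm.ids)
    if n < 2:
        raise DataError("UPGMA needs >= 2 taxa")
    d = dm.values.astype(float).copy()
    active = list(range(n))
    nodes = {i: TreeNode(name=dm.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    next_id = n
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = dist[frozenset((i, j))]
                if best is None or key < best[0] - 1e-15:
                    best = (key, i, j)
        merge_d, i, j = best
        height = merge_d / 2.0
        left, right = nodes[i], nodes[j]
        left.length = height - heights[i]
        right.length = height - heights[j]
        parent = TreeNode(children=[left, right])
        nodes[next_id] = parent
        heights[next_id] = height
        sizes[next_id] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j]))
        dist.pop(frozenset((i, j)))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    root = nodes[active[0]]
    root.sort()
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to zero and the excess moved to
    the sister branch (total cherry length preserved).  The returned tree
    has a trifurcating root and is to be read as unrooted.
    """
    n = len(dm.ids)
    if n < 3:
        raise DataError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(name=name) for name in dm.ids]
    d = dm.values.astype(float).copy()
    active = list(range(n))
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[frozenset((i, k))] for k in active if k != i)
             for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[frozenset((i, j))] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dist[frozenset((i, j))]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = node_of[i], node_of[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = 0.5 * (dik + djk - dij)
        dist.pop(frozenset((i, j)))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij = dist[frozenset((i, j))]
    dik = dist[frozenset((i, k))]
    djk = dist[frozenset((j, k))]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = TreeNode(children=[node_of[i], node_of[j], node_of[k]])
    for node, length in zip(root.children, (li, lj, lk)):
        node.length = max(length, 0.0)
    root.sort()
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# --- Bipartitions, support, monophyly -------------------------------------

def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial leaf-set splits induced by internal edges.

    Each split is a frozenset of the two leaf-name sides, which makes the
    representation independent of rooting.
    """
    all_leaves = tree.leaf_names()
    splits = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        below = node.leaf_names()
        above = all_leaves - below
        if len(below) >= 2 and len(above) >= 2:
            splits.add(frozenset((below, above)))
    return splits


def is_monophyletic(tree: TreeNode, taxa: set[str], outgroup: str) -> bool:
    """True iff ``taxa`` form a clade when the tree is rooted on ``outgroup``.

    Equivalent, rooting-free formulation: some edge of the tree separates
    exactly ``taxa`` from the rest (which contains the outgroup).
    """
    taxa = set(taxa)
    all_leaves = tree.leaf_names()
    missing = (taxa | {outgroup}) - all_leaves
    if missing:
        raise DataError(f"taxa not in tree: {sorted(missing)}")
    if outgroup in taxa:
        return False  # a set containing its own outgroup is never a clade
    if len(taxa) == 1:
        return True
    target = frozenset(taxa)
    rest = frozenset(all_leaves - taxa)
    if len(rest) < 2:  # taxa = everything but the outgroup: trivially a clade
        return True
    return frozenset((target, rest)) in bipartitions(tree)


def bootstrap(aln: LocusAlignment, n_reps: int, method: str = "upgma",
              model: str = "p", seed: int = 0) -> TreeNode:
    """Tree from the full alignment with bootstrap supports attached.

    Columns are resampled with replacement per replicate; support for each
    internal edge is the percentage of successful replicates containing
    its bipartition.  Replicates with a saturated pair are skipped with a
    warning and removed from the denominator.
    """
    if n_reps < 1:
        raise DataError("bootstrap needs n_reps >= 1")
    build = {"upgma": upgma, "nj": neighbor_joining}.get(method)
    if build is None:
        raise DataError(f"unknown tree method {method!r}")
    ids = aln.ids()
    codes = encode_alignment(aln)
    tree = build(distance_matrix_from_codes(codes, ids, model))

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {split: 0 for split in bipartitions(tree)}
    successes = 0
    for _ in range(n_reps):
        cols = rng.integers(0, codes.shape[1], size=codes.shape[1])
        try:
            dm = distance_matrix_from_codes(codes[:, cols], ids, model)
        except SaturationError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        successes += 1
        rep_splits = bipartitions(build(dm))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if successes == 0:
        raise SaturationError("all bootstrap replicates saturated")

    all_leaves = tree.leaf_names()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        below = node.leaf_names()
        split = frozenset((below, all_leaves - below))
        if split in counts:
            node.support = round(100.0 * counts[split] / successes)
    return tree


# --- Newick ----------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    """Newick text with 6-decimal branch lengths and integer supports."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = "" if node.support is None else str(node.support)
            body = f"({inner}){label}"
        if top:
            return body
        length = 0.0 if abs(node.length) < 5e-13 else node.length
        return f"{body}:{length:.6f}"

    tree.sort()
    return fmt(tree, top=True) + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse the Newick dialect emitted by :func:`write_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise DataError("newick text must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise DataError("unbalanced parentheses in newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        label = []
        while pos < len(s) and s[pos] not in ",():;":
            label.append(s[pos])
            pos += 1
        if label:
            token = "".join(label)
            if node.is_leaf:
                node.name = token
            else:
                node.support = int(token)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            num = []
            while pos < len(s) and s[pos] not in ",()":
                num.append(s[pos])
                pos += 1
            node.length = float("".join(num))
        return node

    root = parse_node()
    if pos != len(s):
        raise DataError("trailing characters in newick text")
    return root
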