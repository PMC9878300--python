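"""Distance-based phylogeny: pairwise distances, neighbor-joining and
bootstrap supports.

This is a deliberately lightweight stand-in for likelihood tree searches:
p / JC69 / K2P distances, Saitou-Nei neighbor-joining with deterministic
tie-breaking, column-bootstrap supports, and an alignment-free k-mer cosine
distance for whole genomes where no alignment exists.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "kmer_distance_matrix",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = set("ACGT")


class SaturationError(ValueError):
    """Distance undefined: correction logarithm argument non-positive."""


def _pair_counts(a: str, b: str) -> tuple[int, int, int]:
    """(valid columns, transitions, transversions) ignoring gap/ambiguous
    columns pairwise."""
    n = ts = tv = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca not in VALID or cb not in VALID:
            continue
        n += 1
        if ca == cb:
            continue
        same_class = (ca in PURINES) == (cb in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def pairwise_distance(a: str, b: str, model: str = "K2P") -> float:
    """Evolutionary distance between two equal-length aligned sequences.

    model 'p' is the raw mismatch proportion, 'JC69' the Jukes-Cantor
    correction -3/4 ln(1 - 4p/3), 'K2P' the Kimura two-parameter distance
    -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).  Raises :class:`SaturationError` when
    the correction is undefined.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n, ts, tv = _pair_counts(a, b)
    if n == 0:
        raise ValueError("no valid columns shared by the two sequences")
    p = (ts + tv) / n
    if model == "p":
        return p
    if model == "JC69":
        arg = 1 - 4 * p / 3
        if arg <= 0:
            raise SaturationError(f"JC69 undefined at p={p:.3f}")
        return -0.75 * math.log(arg)
    if model == "K2P":
        P, Q = ts / n, tv / n
        x, y = 1 - 2 * P - Q, 1 - 2 * Q
        if x <= 0 or y <= 0:
            raise SaturationError(f"K2P undefined at P={P:.3f}, Q={Q:.3f}")
        return -0.5 * math.log(x) - 0.25 * math.log(y)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

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

    def to_phylip(self) -> str:
        lines = [str(len(self.taxa))]
        for name, row in zip(self.taxa, self.d):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def distance_matrix(alignment: dict[str, str], model: str = "K2P") -> DistanceMatrix:
    """All-pairs distances over a taxon -> aligned-sequence mapping."""
    taxa = sorted(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_distance(alignment[taxa[i]], alignment[taxa[j]], model)
    return DistanceMatrix(taxa=taxa, d=d)


def kmer_distance_matrix(genomes: dict[str, str], k: int = 8) -> DistanceMatrix:
    """Alignment-free cosine distances between k-mer count vectors."""
    taxa = sorted(genomes)
    vecs = []
    for t in taxa:
        counts: dict[str, int] = {}
        s = genomes[t].upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= VALID:
                counts[w] = counts.get(w, 0) + 1
        vecs.append(counts)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = vecs[i], vecs[j]
        dot = sum(v * b.get(w, 0) for w, v in a.items())
        na = math.sqrt(sum(v * v for v in a.values()))
        nb = math.sqrt(sum(v * v for v in b.values()))
        cos = dot / (na * nb) if na and nb else 0.0
        d[i, j] = d[j, i] = max(0.0, 1.0 - cos)
    return DistanceMatrix(taxa=taxa, d=d)


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_lengths: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name
            else:
                inner = ",".join(render(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += str(node.support)
                elif node.name:
                    label += node.name
            if with_lengths:
                label += f":{node.length:.6f}"
            return label

        inner = ",".join(render(c) for c in self.children)
        return f"({inner});" if self.children else f"{self.name};"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set of one side canonicalized
        to exclude the lexicographically smallest taxon overall."""
        all_leaves = set(self.leaves())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                splits.add(frozenset(side))
            return below

        walk(self)
        return splits


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining over a symmetric distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    taxon pair (on current cluster labels) for determinism; negative branch
    lengths are clamped to zero with the deficit shifted to the sibling.
    """
    n0 = len(matrix.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    labels = list(matrix.taxa)
    d = matrix.d.astype(float).copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent = TreeNode(children=[ni, nj])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [min(ni.leaves() + nj.leaves())]
        d = d2

    # final three-way join: solve the star branch lengths exactly
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "K2P",
) -> TreeNode:
    """NJ tree from the full alignment with column-bootstrap edge supports.

    Columns are resampled with replacement per replicate; supports are the
    percentage of replicate trees containing each internal split of the
    point-estimate tree.  A replicate pair that saturates under ``model``
    falls back to the p-distance for that pair.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    taxa = sorted(alignment)
    length = len(alignment[taxa[0]])
    if any(len(alignment[t]) != length for t in taxa):
        raise ValueError("alignment sequences differ in length")

    def matrix_from(seqs: dict[str, str]) -> DistanceMatrix:
        n = len(taxa)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            try:
                dist = pairwise_distance(seqs[taxa[i]], seqs[taxa[j]], model)
            except SaturationError:
                dist = pairwise_distance(seqs[taxa[i]], seqs[taxa[j]], "p")
            d[i, j] = d[j, i] = dist
        return DistanceMatrix(taxa=list(taxa), d=d)

    point = neighbor_joining(matrix_from(alignment))
    target = point.bipartitions()
    hits = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    arrays = {t: np.frombuffer(alignment[t].encode(), dtype="S1") for t in taxa}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        seqs = {t: arrays[t][cols].tobytes().decode() for t in taxa}
        rep = neighbor_joining(matrix_from(seqs))
        for split in rep.bipartitions() & target:
            hits[split] += 1

    def annotate(node: TreeNode, all_leaves: set[str], anchor: str) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for child in node.children:
            below |= annotate(child, all_leaves, anchor)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = round(100 * hits[frozenset(side)] / n_replicates)
        return below

    leaves = set(point.leaves())
    annotate(point, leaves, min(leaves))
    return point
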