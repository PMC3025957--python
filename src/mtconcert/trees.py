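"""Distance trees per tract and the paralogue/orthologue clustering contrast.

Neighbor-joining on p-distances stands in for likelihood trees: at the
near-identity divergences involved, the informative signal is simply which
leaves are (nearly) identical, which distances capture fully. The
interesting readout is the topology class: in converted (homogenized)
tracts each individual's two copies pair up (``paralog_clustered``); in the
non-converted central tract the copy-I leaves and copy-II leaves form two
clades (``ortholog_clustered``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from .align import JointAlignment
from .conversion_scan import NoComparableSites, p_distance

ZERO_EPS = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix over (individual, copy) labels."""

    labels: list[str]
    matrix: np.ndarray
    triangle_violations: int = 0

    def __post_init__(self) -> None:
        assert self.matrix.shape == (len(self.labels), len(self.labels))
        assert np.allclose(self.matrix, self.matrix.T)
        assert np.allclose(np.diag(self.matrix), 0)
        n = len(self.labels)
        viol = 0
        for i, j, k in combinations(range(n), 3):
            d = self.matrix
            if (
                d[i, j] > d[i, k] + d[k, j] + ZERO_EPS
                or d[i, k] > d[i, j] + d[j, k] + ZERO_EPS
                or d[j, k] > d[j, i] + d[i, k] + ZERO_EPS
            ):
                viol += 1
        self.triangle_violations = viol


class TopologyClass(str, Enum):
    paralog_clustered = "paralog_clustered"
    ortholog_clustered = "ortholog_clustered"
    mixed = "mixed"


@dataclass
class Tree:
    """Unrooted tree with nonnegative branch lengths.

    ``negative_clamped`` flags NJ branch estimates below zero that were
    clamped; ``star`` flags the degenerate all-zero-distance case.
    """

    tree: "skbio.TreeNode"
    star: bool = False
    negative_clamped: bool = False

    @property
    def leaf_names(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def newick(self) -> str:
        return str(self.tree).strip()


@dataclass
class TopologyCall:
    kind: TopologyClass
    paralog_pairs: dict[str, bool] = field(default_factory=dict)  # individual -> cherry?
    copy_clades: dict[str, bool] = field(default_factory=dict)  # copy -> forms clade?


def distance_matrix(aln: JointAlignment, interval: tuple[int, int]) -> DistanceMatrix:
    """All-pairs p-distance over an alignment interval (pairwise deletion)."""
    labels = aln.labels
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            d[i, j] = d[j, i] = p_distance(aln.matrix[i], aln.matrix[j], interval)
        except NoComparableSites:
            raise NoComparableSites(
                f"pair ({labels[i]}, {labels[j]}) has no comparable columns in {interval}"
            ) from None
    return DistanceMatrix(labels=labels, matrix=d)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Neighbor-joining (Saitou-Nei) tree; labels sorted for determinism.

    An all-zero matrix yields a flagged star tree. Negative branch length
    estimates are clamped to zero and flagged.
    """
    if len(d.labels) < 4:
        raise ValueError("nj_tree needs >= 4 labels")
    order = sorted(range(len(d.labels)), key=lambda i: d.labels[i])
    labels = [d.labels[i] for i in order]
    mat = d.matrix[np.ix_(order, order)]
    if np.allclose(mat, 0):
        star = skbio.TreeNode(children=[skbio.TreeNode(name=l, length=0.0) for l in labels])
        return Tree(tree=star, star=True)
    dm = skbio.DistanceMatrix(mat, labels)
    raw = _skbio_nj(dm, neg_as_zero=False)
    clamped = any(n.length is not None and n.length < 0 for n in raw.traverse())
    t = _skbio_nj(dm, neg_as_zero=True)
    return Tree(tree=t, negative_clamped=clamped)


def _split_label(name: str) -> tuple[str, str]:
    ind, cp = name.rsplit("-", 1)
    return ind, cp


def classify_topology(t: Tree) -> TopologyCall:
    """Classify whether copies cluster within individuals or across them.

    ``paralog_clustered``: every individual's pair {X-I, X-II} is a cherry or
    at zero patristic distance. ``ortholog_clustered``: the copy-I leaves and
    copy-II leaves each form one side of a bipartition of the unrooted tree.
    Otherwise ``mixed``.
    """
    tips = {tip.name: tip for tip in t.tree.tips()}
    by_ind: dict[str, dict[str, str]] = {}
    for name in tips:
        ind, cp = _split_label(name)
        by_ind.setdefault(ind, {})[cp] = name

    paralog_pairs: dict[str, bool] = {}
    for ind, copies in by_ind.items():
        if set(copies) != {"I", "II"}:
            paralog_pairs[ind] = False
            continue
        a, b = tips[copies["I"]], tips[copies["II"]]
        cherry = a.parent is b.parent
        zero = a.distance(b) <= ZERO_EPS
        paralog_pairs[ind] = bool(cherry or zero)

    all_names = set(tips)
    copy_clades: dict[str, bool] = {}
    subsets = {frozenset(s) for s in t.tree.subsets()}
    for cp in ("I", "II"):
        members = frozenset(n for n in all_names if _split_label(n)[1] == cp)
        complement = frozenset(all_names - members)
        copy_clades[cp] = bool(members) and (
            members in subsets
            or complement in subsets
            or len(members) == 1
            or len(complement) == 1
        )

    if paralog_pairs and all(paralog_pairs.values()):
        kind = TopologyClass.paralog_clustered
    elif all(copy_clades.get(cp, False) for cp in ("I", "II")):
        kind = TopologyClass.ortholog_clustered
    else:
        kind = TopologyClass.mixed
    return TopologyCall(kind=kind, paralog_pairs=paralog_pairs, copy_clades=copy_clades)
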