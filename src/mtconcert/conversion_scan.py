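"""Paralogue/orthologue diversity contrast and delimitation of the
non-converted central tract (putative Replication Fork Barrier, RFB).

The gene-conversion signal is a contrast between two mean p-distances over a
region of the joint alignment:

* ``pi_dupl`` — mean p-distance between the two duplicate copies (I vs II)
  *within* each individual (paralogue diversity);
* ``pi_ind`` — mean p-distance between individuals *within* the same copy
  (orthologue diversity), pooled over copies I and II (per-copy means are
  also reported).

Conversion homogenizes paralogues, driving ``pi_dupl`` to ~0 while
``pi_ind`` accumulates normally. A tract exempt from conversion shows the
reverse pattern (``pi_dupl >> pi_ind``); the outermost paralogue-variable
sites delimit it.

p-distances use pairwise deletion: columns where either row has a gap are
excluded from that pair's comparison. Indel columns are excluded from
p-distances but included in the polymorphic-site tally; a contiguous run of
gap columns counts as one indel position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import numpy as np

from .align import JointAlignment

GAP = ord("-")


class NoComparableSites(ValueError):
    """A pairwise comparison had zero gap-free columns."""


class SiteKind(str, Enum):
    invariant = "invariant"
    paralog_variable = "paralog_variable"
    ortholog_variable = "ortholog_variable"
    both = "both"
    indel = "indel"


@dataclass
class SiteClass:
    column: int
    kind: SiteKind
    alleles: dict[str, str]  # row label -> symbol at this column


@dataclass
class RegionStats:
    interval: tuple[int, int]  # alignment columns, half-open
    pi_dupl: float
    pi_ind: float
    pi_ind_by_copy: dict[str, float]
    pi_dupl_by_individual: dict[str, float]
    n_sites_compared: int  # columns with no gap in any row
    n_polymorphic: int  # columns with >= 2 distinct symbols (gaps count)
    n_indel_positions: int  # maximal runs of gap-containing columns


@dataclass
class RfbCall:
    interval_cols: tuple[int, int]
    interval_ref: tuple[int, int]  # reference coordinates, half-open
    length_bases: int
    n_paralog_sites: int
    inside: RegionStats
    upstream: RegionStats | None
    downstream: RegionStats | None
    secondary: list[tuple[tuple[int, int], int]] = field(default_factory=list)


def _to_array(row: str) -> np.ndarray:
    return np.frombuffer(row.encode("ascii"), dtype=np.uint8)


def p_distance(row_a: str, row_b: str, columns: tuple[int, int] | None = None) -> float:
    """Proportion of differing sites among gap-free columns (pairwise deletion).

    Raises :class:`NoComparableSites` when no comparable columns exist —
    an undefined distance is an error, not 0.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a, b = _to_array(row_a), _to_array(row_b)
    if columns is not None:
        s, e = columns
        if s < 0 or e > a.size or s > e:
            raise ValueError(f"interval ({s}, {e}) out of bounds")
        a, b = a[s:e], b[s:e]
    ok = (a != GAP) & (b != GAP)
    n = int(ok.sum())
    if n == 0:
        raise NoComparableSites("no comparable sites (all columns gapped)")
    return float((a[ok] != b[ok]).sum()) / n


def _rows_by_copy(aln: JointAlignment) -> tuple[list[str], dict[str, dict[str, str]]]:
    """Individuals (with both copies) and rows keyed [copy][individual]."""
    rows: dict[str, dict[str, str]] = {"I": {}, "II": {}}
    for (ind, cp), row in zip(aln.row_labels, aln.matrix):
        rows.setdefault(cp, {})[ind] = row
    complete = [i for i in aln.individuals if i in rows["I"] and i in rows["II"]]
    return complete, rows


def region_stats(aln: JointAlignment, interval: tuple[int, int]) -> RegionStats:
    """Paralogue/orthologue diversity and polymorphism counts over an interval."""
    s, e = interval
    if s < 0 or e > aln.n_cols or s >= e:
        raise ValueError(f"interval ({s}, {e}) outside alignment of {aln.n_cols} columns")
    individuals, rows = _rows_by_copy(aln)
    if len(individuals) < 2:
        raise ValueError("region_stats needs >= 2 individuals with both copies")

    dupl: dict[str, float] = {
        ind: p_distance(rows["I"][ind], rows["II"][ind], interval) for ind in individuals
    }
    pooled: list[float] = []
    by_copy: dict[str, float] = {}
    for cp in ("I", "II"):
        vals = [
            p_distance(rows[cp][i1], rows[cp][i2], interval)
            for i1, i2 in combinations(individuals, 2)
        ]
        by_copy[cp] = float(np.mean(vals))
        pooled.extend(vals)

    mat = np.vstack([_to_array(r)[s:e] for r in aln.matrix])
    has_gap = (mat == GAP).any(axis=0)
    poly = np.array([np.unique(mat[:, c]).size > 1 for c in range(mat.shape[1])])
    # count maximal runs of gap-containing columns
    n_indel = int(((has_gap) & ~np.concatenate([[False], has_gap[:-1]])).sum())

    return RegionStats(
        interval=interval,
        pi_dupl=float(np.mean(list(dupl.values()))),
        pi_ind=float(np.mean(pooled)),
        pi_ind_by_copy=by_copy,
        pi_dupl_by_individual=dupl,
        n_sites_compared=int((~has_gap).sum()),
        n_polymorphic=int(poly.sum()),
        n_indel_positions=n_indel,
    )


def classify_sites(aln: JointAlignment) -> list[SiteClass]:
    """Classify every alignment column by where its variation lies.

    Gap-containing columns are ``indel``. Otherwise a column is
    ``paralog_variable`` if any individual's two copies differ there,
    ``ortholog_variable`` if any two individuals differ within the same copy,
    ``both`` when both hold, else ``invariant``.
    """
    individuals, rows = _rows_by_copy(aln)
    if len(individuals) < 2:
        raise ValueError("classify_sites needs >= 2 individuals with both copies")
    mat = np.vstack([_to_array(r) for r in aln.matrix])
    labels = aln.labels
    idx = {lab: i for i, lab in enumerate(labels)}

    has_gap = (mat == GAP).any(axis=0)
    para = np.zeros(aln.n_cols, dtype=bool)
    for ind in individuals:
        ri, rii = mat[idx[f"{ind}-I"]], mat[idx[f"{ind}-II"]]
        para |= ri != rii
    ortho = np.zeros(aln.n_cols, dtype=bool)
    for cp in ("I", "II"):
        have = [i for i in individuals if f"{i}-{cp}" in idx]
        for i1, i2 in combinations(have, 2):
            ortho |= mat[idx[f"{i1}-{cp}"]] != mat[idx[f"{i2}-{cp}"]]

    out: list[SiteClass] = []
    for c in range(aln.n_cols):
        if has_gap[c]:
            kind = SiteKind.indel
        elif para[c] and ortho[c]:
            kind = SiteKind.both
        elif para[c]:
            kind = SiteKind.paralog_variable
        elif ortho[c]:
            kind = SiteKind.ortholog_variable
        else:
            kind = SiteKind.invariant
        out.append(
            SiteClass(column=c, kind=kind, alleles={lab: chr(mat[i, c]) for lab, i in idx.items()})
        )
    return out


def _safe_region_stats(aln: JointAlignment, interval: tuple[int, int]) -> RegionStats | None:
    s, e = interval
    if e - s <= 0:
        return None
    try:
        return region_stats(aln, interval)
    except NoComparableSites:
        return None


def call_rfb(
    sites: list[SiteClass],
    aln: JointAlignment,
    min_paralog_sites: int = 3,
    merge_gap: int = 30,
) -> RfbCall | None:
    """Delimit the central non-converted tract from paralogue-variable sites.

    Candidate tracts are runs of paralogue-variable (or ``both``) sites,
    merging runs separated by at most ``merge_gap`` intervening columns. The
    tract with the most paralogue-variable sites is returned (others become
    secondary calls) provided it has at least ``min_paralog_sites`` such
    sites and shows the RFB diversity pattern: ``pi_dupl > pi_ind`` inside,
    not outside. Boundaries are the outermost paralogue-variable sites.
    """
    para_cols = [
        s.column for s in sites if s.kind in (SiteKind.paralog_variable, SiteKind.both)
    ]
    if not para_cols:
        return None

    clusters: list[list[int]] = [[para_cols[0]]]
    for c in para_cols[1:]:
        if c - clusters[-1][-1] - 1 <= merge_gap:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    ranked = sorted(clusters, key=lambda cl: (-len(cl), cl[0]))
    best = ranked[0]
    if len(best) < min_paralog_sites:
        return None
    start, end = best[0], best[-1] + 1

    inside = _safe_region_stats(aln, (start, end))
    upstream = _safe_region_stats(aln, (0, start))
    downstream = _safe_region_stats(aln, (end, aln.n_cols))
    if inside is None or not inside.pi_dupl > inside.pi_ind:
        return None
    for flank in (upstream, downstream):
        if flank is not None and flank.pi_dupl > flank.pi_ind and flank.pi_dupl > 1e-9:
            return None

    ref_iv = aln.ref_interval_of_columns(start, end)
    return RfbCall(
        interval_cols=(start, end),
        interval_ref=ref_iv,
        length_bases=ref_iv[1] - ref_iv[0],
        n_paralog_sites=len(best),
        inside=inside,
        upstream=upstream,
        downstream=downstream,
        secondary=[((cl[0], cl[-1] + 1), len(cl)) for cl in ranked[1:]],
    )


def conversion_contrast_test(
    aln: JointAlignment,
    interval: tuple[int, int],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the homogenization contrast (pi_ind - pi_dupl).

    The null re-pairs copies across individuals (copy-II rows shuffled among
    individuals) and recomputes the contrast; ``p = (1 + #{null >= obs}) /
    (n_perm + 1)``. A large observed contrast (paralogues far more similar
    than orthologues) is evidence of within-individual homogenization, i.e.,
    gene conversion. Degenerate intervals (all rows identical) return 1.0.
    """
    individuals, rows = _rows_by_copy(aln)
    if len(individuals) < 3:
        raise ValueError("need >= 3 individuals for a meaningful null")
    s, e = interval
    sub = {cp: {i: rows[cp][i][s:e] for i in individuals} for cp in ("I", "II")}
    if len({r for cp in sub.values() for r in cp.values()}) == 1:
        return 1.0

    stats = region_stats(aln, interval)
    obs = stats.pi_ind - stats.pi_dupl

    n = len(individuals)
    cross = np.zeros((n, n))
    for a, ia in enumerate(individuals):
        for b, ib in enumerate(individuals):
            cross[a, b] = p_distance(sub["I"][ia], sub["II"][ib])

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null_dupl = float(cross[np.arange(n), perm].mean())
        if stats.pi_ind - null_dupl >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)
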