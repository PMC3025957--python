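"""Self-comparison detection of a large tandem duplication in one mt genome.

Strategy: exact k-mer seed matches of the genome against itself (tandem
orientation only, offset >= ``min_len``) are clustered by diagonal; the best
cluster's anchor pairs give the local homology offsets at the left and right
ends of the duplicated region, and boundaries are extended base-by-base from
the anchors while a 30-base running-identity window stays above
``min_identity``, then trimmed to matching columns. Anchoring the left and
right ends separately tolerates copies of unequal length (e.g. indels or
repeat-count differences between the copies).

The short tandem-repeat arrays inside the control region also self-match,
but at offsets far below ``min_len``, so the offset filter ranks them out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import LabeledSeq, align_global
from .genome_io import GenomeRecord


class OverlappingRepeatError(ValueError):
    """Best self-match is overlapping/inverted, not a tandem duplication."""


@dataclass
class DuplicatePair:
    genome_id: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    identity: float
    spacer_len: int

    def __post_init__(self) -> None:
        if self.copy1[1] > self.copy2[0]:
            raise OverlappingRepeatError(
                f"{self.genome_id}: copies {self.copy1}/{self.copy2} overlap"
            )
        assert self.spacer_len >= 0


def _seed_pairs(seq: str, k: int, min_offset: int, max_kmer_hits: int = 50):
    """Tandem-oriented exact k-mer match pairs (p1, p2), p2 - p1 >= min_offset."""
    occ: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        occ.setdefault(seq[i : i + k], []).append(i)
    pairs: list[tuple[int, int]] = []
    for positions in occ.values():
        if len(positions) < 2 or len(positions) > max_kmer_hits:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                if positions[b] - positions[a] >= min_offset:
                    pairs.append((positions[a], positions[b]))
    return pairs


def _cluster_by_offset(pairs: list[tuple[int, int]], band: int) -> list[list[tuple[int, int]]]:
    pairs = sorted(pairs, key=lambda p: (p[1] - p[0], p[0]))
    clusters: list[list[tuple[int, int]]] = []
    for p in pairs:
        d = p[1] - p[0]
        if clusters and d - (clusters[-1][0][1] - clusters[-1][0][0]) <= band:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


_RUN = 4  # clean-match run length anchoring a trimmed boundary


def _extend_left(match: np.ndarray, i0: int, lo: int, window: int, thr: float) -> int:
    """Outermost (smallest) position whose rightward 30-base window keeps
    >= thr identity, tolerating local dips; scanning stops after a full
    window-length of consecutive failing windows (homology truly over).
    The boundary is then trimmed to the start of a clean match run so chance
    matches in flanking sequence cannot extend it."""
    best, fails, t = i0, 0, i0
    while t - 1 >= lo and fails < window:
        t -= 1
        w = match[t : min(t + window, match.size)]
        if w.size and w.mean() >= thr:
            best, fails = t, 0
        else:
            fails += 1
    for s in range(best, min(i0, match.size - _RUN) + 1):
        if match[s : s + _RUN].all():
            return s
    return i0


def _extend_right(match: np.ndarray, i0: int, hi: int, window: int, thr: float) -> int:
    """Rightmost matching position, symmetric to :func:`_extend_left`."""
    best, fails, e = i0, 0, i0
    while e + 1 <= hi and fails < window:
        e += 1
        w = match[max(e + 1 - window, 0) : e + 1]
        if w.size and w.mean() >= thr:
            best, fails = e, 0
        else:
            fails += 1
    for t in range(best, max(i0, _RUN - 1) - 1, -1):
        if match[t - _RUN + 1 : t + 1].all():
            return t
    return i0


def detect_duplication(
    genome: GenomeRecord,
    min_len: int = 1000,
    min_identity: float = 0.9,
    seed_len: int = 20,
    band: int = 50,
    window: int = 30,
) -> DuplicatePair | None:
    """Find the highest-scoring tandem duplication; ``None`` if none qualifies.

    Ties between equal-scoring seed clusters go to the smaller copy1 start.
    Raises :class:`OverlappingRepeatError` when the best self-match is not in
    tandem order.
    """
    seq = genome.seq
    if len(seq) <= 2 * min_len:
        raise ValueError(f"sequence shorter than 2*min_len ({len(seq)} <= {2 * min_len})")
    pairs = _seed_pairs(seq, seed_len, min_len)
    if not pairs:
        return None
    clusters = _cluster_by_offset(pairs, band)
    # rank: most distinct seed start positions, then smaller copy1 start
    clusters.sort(key=lambda cl: (-len({p[0] for p in cl}), min(p[0] for p in cl)))
    cl = clusters[0]

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    left = min(cl, key=lambda p: p[0])
    right = max(cl, key=lambda p: p[0])
    d_a = left[1] - left[0]
    d_b = right[1] - right[0]

    def match_at(d: int) -> np.ndarray:
        return arr[: len(seq) - d] == arr[d:]

    m_a = match_at(d_a)
    m_b = match_at(d_b)
    # The left-anchor offset run [S1, ...) starts at the duplication start;
    # the right-anchor run ends at the copy1/copy2 junction. Copy2's
    # boundaries are the same positions shifted by the respective offsets.
    s1 = _extend_left(m_a, left[0], 0, window, min_identity)
    js2 = s1 + d_a
    je1 = _extend_right(m_b, right[0] + seed_len - 1, m_b.size - 1, window, min_identity) + 1
    e2 = je1 + d_b

    if je1 > js2:
        if je1 - js2 > window:
            raise OverlappingRepeatError(
                f"{genome.id}: best self-match overlaps itself ([{s1},{je1}) vs [{js2},{e2}))"
            )
        # independent junction estimates crossed by a few bases: reconcile
        j = (je1 + js2) // 2
        je1, js2 = j, j
    if je1 - s1 < min_len or e2 - js2 < min_len:
        return None
    aln = align_global(seq[s1:je1], seq[js2:e2])
    ra, rb = aln.rows
    identity = sum(x == y for x, y in zip(ra, rb)) / len(ra)
    if identity < min_identity:
        return None
    return DuplicatePair(
        genome_id=genome.id,
        copy1=(s1, je1),
        copy2=(js2, e2),
        identity=identity,
        spacer_len=js2 - je1,
    )


def extract_copies(genome: GenomeRecord, pair: DuplicatePair) -> tuple[LabeledSeq, LabeledSeq]:
    """Extract the two paralogous copies as labelled sequences (<id>-I, <id>-II)."""
    if pair.genome_id != genome.id:
        raise ValueError(f"pair refers to {pair.genome_id!r}, not {genome.id!r}")
    for name, (s, e) in (("copy1", pair.copy1), ("copy2", pair.copy2)):
        if e - s <= 0:
            raise ValueError(f"{name} interval ({s}, {e}) is empty")
        if s < 0 or e > len(genome.seq):
            raise ValueError(f"{name} interval ({s}, {e}) outside genome")
    return (
        LabeledSeq(genome.id, "I", genome.seq[pair.copy1[0] : pair.copy1[1]]),
        LabeledSeq(genome.id, "II", genome.seq[pair.copy2[0] : pair.copy2[1]]),
    )
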