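"""Global pairwise alignment and the joint alignment of all duplicate copies.

The aligner is a Gotoh affine-gap global aligner with default DNA scores
(match +1, mismatch -2, gap open -5, gap extend -1); a gap of length L costs
``gap_open + L * gap_extend``. Traceback ties are broken deterministically:
prefer the diagonal move, then the vertical (gap in the second sequence),
then the horizontal.

The joint alignment of the 2N duplicate copies (N individuals x copies I/II)
is built by aligning every copy to a designated reference and projecting onto
reference columns: a gap in the reference opens new columns for all rows.
Copies within a species differ by a few percent at most, so projection loses
nothing material relative to a full multiple alignment and is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

NEG = -1e30


@dataclass(frozen=True)
class LabeledSeq:
    """A duplicate copy with provenance: individual id and copy (I or II)."""

    individual: str
    copy: str  # "I" or "II"
    seq: str

    @property
    def label(self) -> str:
        return f"{self.individual}-{self.copy}"


@dataclass
class PairwiseAlignment:
    rows: tuple[str, str]
    score: float
    params: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        a, b = self.rows
        assert len(a) == len(b)
        assert not any(x == "-" and y == "-" for x, y in zip(a, b))


@njit(cache=False)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b: consumes a ("up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in a: consumes b ("left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(
                M[i - 1, j] + gap_open + gap_extend,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open + gap_extend,
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open + gap_extend,
                Y[i, j - 1] + gap_extend,
                X[i, j - 1] + gap_open + gap_extend,
            )
    return M, X, Y


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()


def align_global(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two DNA strings.

    Raises ``ValueError`` on empty input. Tie-breaking during traceback is
    deterministic: diagonal, then up (gap in ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("align_global requires non-empty sequences")
    ea, eb = _encode(a), _encode(b)
    M, X, Y = _gotoh_fill(ea, eb, match, mismatch, gap_open, gap_extend)
    n, m = len(a), len(b)
    eps = 1e-9

    # choose final state with preference M > X > Y
    finals = (M[n, m], X[n, m], Y[n, m])
    score = max(finals)
    state = int(np.argmax(np.array(finals) >= score - eps))

    ra: list[str] = []
    rb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # M: diagonal
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            opts = (M[i, j], X[i, j], Y[i, j])
            state = next(k for k in range(3) if abs(opts[k] - target) < eps)
        elif state == 1:  # X: up, gap in b
            ra.append(a[i - 1])
            rb.append("-")
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + gap_open + gap_extend - val) < eps:
                state = 0
            elif abs(X[i, j] + gap_extend - val) < eps:
                state = 1
            else:
                state = 2
            if i == 0 and j == 0:
                break
        else:  # Y: left, gap in a
            ra.append("-")
            rb.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + gap_open + gap_extend - val) < eps:
                state = 0
            elif abs(Y[i, j] + gap_extend - val) < eps:
                state = 2
            else:
                state = 1
            if i == 0 and j == 0:
                break
    ra.reverse()
    rb.reverse()
    return PairwiseAlignment(
        rows=("".join(ra), "".join(rb)),
        score=float(score),
        params=(match, mismatch, gap_open, gap_extend),
    )


@dataclass
class JointAlignment:
    """Aligned matrix of 2N duplicate copies in reference-column space.

    ``ref_map[c]`` is the coordinate of column ``c`` in the (unmasked)
    reference sequence, or -1 for columns the reference does not cover
    (insertions relative to the reference).
    """

    row_labels: list[tuple[str, str]]  # (individual, copy)
    matrix: list[str]
    reference_label: str
    ref_map: np.ndarray
    region_marks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.matrix}
        assert len(lengths) == 1, "ragged joint alignment"
        if len(self.matrix) < 4:
            raise ValueError("joint alignment needs >= 4 rows (>= 2 individuals x 2 copies)")

    @property
    def n_cols(self) -> int:
        return len(self.matrix[0])

    @property
    def labels(self) -> list[str]:
        return [f"{ind}-{cp}" for ind, cp in self.row_labels]

    @property
    def individuals(self) -> list[str]:
        seen: list[str] = []
        for ind, _ in self.row_labels:
            if ind not in seen:
                seen.append(ind)
        return seen

    def row(self, individual: str, copy: str) -> str:
        for (ind, cp), r in zip(self.row_labels, self.matrix):
            if ind == individual and cp == copy:
                return r
        raise KeyError(f"no row {individual}-{copy}")

    def column_of_ref(self, ref_pos: int) -> int:
        hits = np.nonzero(self.ref_map == ref_pos)[0]
        if hits.size == 0:
            raise KeyError(f"reference position {ref_pos} not in alignment")
        return int(hits[0])

    def ref_interval_of_columns(self, start_col: int, end_col: int) -> tuple[int, int]:
        """Map a column interval to the smallest covering reference interval."""
        covered = self.ref_map[start_col:end_col]
        covered = covered[covered >= 0]
        if covered.size == 0:
            raise ValueError("column interval covers no reference positions")
        return int(covered.min()), int(covered.max()) + 1


def _apply_mask(seq: str, intervals: list[tuple[int, int]]) -> str:
    """Excise intervals (0-based half-open, in the sequence's own coordinates)."""
    if not intervals:
        return seq
    keep = np.ones(len(seq), dtype=bool)
    for s, e in intervals:
        if s < 0 or e > len(seq) or s > e:
            raise ValueError(f"mask interval ({s}, {e}) out of bounds")
        keep[s:e] = False
    return "".join(ch for ch, k in zip(seq, keep) if k)


def build_joint_alignment(
    copies: list[LabeledSeq],
    reference_label: str,
    mask: dict[str, list[tuple[int, int]]] | None = None,
    **scores: float,
) -> JointAlignment:
    """Align every copy to the reference and merge by reference-column projection.

    ``mask`` maps a copy label to intervals (in that copy's own coordinates)
    excised before alignment — used to drop variable-copy-number repeat
    arrays whose columnwise homology is meaningless.
    """
    if len(copies) < 4:
        raise ValueError("need >= 4 labeled copies")
    labels = [c.label for c in copies]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    per_ind: dict[str, int] = {}
    for c in copies:
        per_ind[c.individual] = per_ind.get(c.individual, 0) + 1
    for ind, cnt in per_ind.items():
        if cnt != 2:
            warnings.warn(f"individual {ind!r} has {cnt} copies (expected 2); rows kept")

    mask = mask or {}
    seqs = {c.label: _apply_mask(c.seq, mask.get(c.label, [])) for c in copies}
    try:
        ref_seq = seqs[reference_label]
    except KeyError:
        raise ValueError(f"reference label {reference_label!r} not among copies") from None
    R = len(ref_seq)

    # per row: character aligned to each reference position, and the
    # insertion string preceding each reference position (index 0..R)
    aligned: dict[str, np.ndarray] = {}
    inserts: dict[str, list[str]] = {}
    for c in copies:
        lab = c.label
        if lab == reference_label:
            continue
        aln = align_global(ref_seq, seqs[lab], **scores)
        ref_row, other_row = aln.rows
        chars = np.full(R, "-", dtype="<U1")
        ins: list[str] = [""] * (R + 1)
        k = 0
        for rc, oc in zip(ref_row, other_row):
            if rc == "-":
                ins[k] += oc
            else:
                chars[k] = oc
                k += 1
        aligned[lab] = chars
        inserts[lab] = ins

    ins_len = [0] * (R + 1)
    for lab in inserts:
        for k in range(R + 1):
            ins_len[k] = max(ins_len[k], len(inserts[lab][k]))

    out_rows: dict[str, list[str]] = {lab: [] for lab in labels}
    ref_map: list[int] = []
    for k in range(R + 1):
        if ins_len[k]:
            for lab in labels:
                if lab == reference_label:
                    out_rows[lab].append("-" * ins_len[k])
                else:
                    s = inserts[lab][k]
                    out_rows[lab].append(s + "-" * (ins_len[k] - len(s)))
            ref_map.extend([-1] * ins_len[k])
        if k < R:
            for lab in labels:
                if lab == reference_label:
                    out_rows[lab].append(ref_seq[k])
                else:
                    out_rows[lab].append(str(aligned[lab][k]))
            ref_map.append(k)

    matrix = ["".join(out_rows[lab]) for lab in labels]
    return JointAlignment(
        row_labels=[(c.individual, c.copy) for c in copies],
        matrix=matrix,
        reference_label=reference_label,
        ref_map=np.array(ref_map, dtype=np.int64),
    )


def write_joint_fasta(aln: JointAlignment, path) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(aln.labels, aln.matrix):
            fh.write(f">{lab}\n{row}\n")
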