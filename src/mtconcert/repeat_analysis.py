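"""Decomposition of control-region tandem-repeat arrays.

Covers: repeat-period estimation by shift autocorrelation, cutting an array
into units (with per-unit boundary refinement, since unit variants may
differ in length), cataloguing unit types with positional classes, and
copy-number heteroplasmy spectra across cloned amplicons.

Positional classes follow the array-position rule: a type found only as the
first unit is B, only as the last unit E, only as the sole unit of
single-unit arrays BE, never first or last M; types violating the
partition are U.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import align_global

COMPLETE_TOL = 0.15  # units within +/-15% of the period count as complete


class NotRepetitiveError(ValueError):
    """No candidate period reaches the minimum autocorrelation identity."""


@dataclass
class RepeatUnit:
    seq: str
    start: int
    end: int
    complete: bool = True


@dataclass
class RepeatArray:
    source: tuple[str, str]  # (sequence id, region label: CRI/CRII/second_repeat)
    span: tuple[int, int]
    period: int
    units: list[RepeatUnit]
    leading_partial: str = ""
    trailing_partial: str = ""

    def __post_init__(self) -> None:
        total = len(self.leading_partial) + len(self.trailing_partial) + sum(
            len(u.seq) for u in self.units
        )
        assert total == self.span[1] - self.span[0], "units + partials must tile the span"
        pos = self.span[0] + len(self.leading_partial)
        for u in self.units:
            assert u.start == pos and u.end - u.start == len(u.seq)
            pos = u.end

    @property
    def n_complete(self) -> int:
        return sum(1 for u in self.units if u.complete)


@dataclass
class UnitType:
    label: str
    consensus: str
    member_count: int
    positional_class: str  # B, M, E, BE or U


@dataclass
class UnitTypeCatalog:
    types: dict[str, UnitType]

    def class_of(self, seq: str) -> str:
        for t in self.types.values():
            if t.consensus == seq:
                return t.positional_class
        raise KeyError("unknown unit sequence")


@dataclass
class HeteroplasmySpectrum:
    region: str
    histogram: dict[int, int]
    dominant: int
    dominant_tied: bool = False


def estimate_period(seq: str, min_period: int = 10, max_period: int = 200) -> int:
    """Repeat period maximizing mean base identity between seq[i] and seq[i+p].

    Searched over [min_period, max_period]; exact score ties go to the
    smallest period. Raises :class:`NotRepetitiveError` if no period reaches
    identity 0.6.
    """
    if len(seq) < 2 * min_period:
        raise ValueError("sequence shorter than 2*min_period")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    scores: dict[int, float] = {}
    for p in range(min_period, max_period + 1):
        if len(seq) - p < min_period:
            break
        scores[p] = float((arr[:-p] == arr[p:]).mean())
    best = max(scores.values(), default=-1.0)
    if best < 0.6:
        raise NotRepetitiveError(f"no period in [{min_period}, {max_period}] with identity >= 0.6")
    # the true period and its multiples score alike up to sampling noise;
    # prefer the smallest period within a small tolerance of the maximum
    return min(p for p, s in scores.items() if s >= best - 0.03)


def _slice_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


_PHASE_TOL = 0.03  # near-ties go to the smallest phase: for a pure tandem
# array every phase scores alike and the canonical cut starts at position 0


def _best_phase(seq: str, period: int) -> int:
    scores: dict[int, float] = {}
    for phase in range(min(period, max(len(seq) - 2 * period + 1, 1))):
        slices = [
            seq[phase + k * period : phase + (k + 1) * period]
            for k in range((len(seq) - phase) // period)
        ]
        if len(slices) < 2:
            continue
        scores[phase] = float(np.mean([_slice_identity(a, b) for a, b in zip(slices, slices[1:])]))
    if not scores:
        return 0
    best = max(scores.values())
    return min(p for p, s in scores.items() if s >= best - _PHASE_TOL)


def decompose_array(
    seq: str,
    period: int,
    anchor: str | None = None,
    source: tuple[str, str] = ("", ""),
    offset: int = 0,
) -> RepeatArray:
    """Cut a repeat array into units of roughly ``period`` bases.

    The phase (start of the first unit) is the anchor motif's position when
    ``anchor`` is given, otherwise the phase maximizing identity between
    consecutive unit slices. Each subsequent unit boundary is refined by
    globally aligning candidate cuts (period +/-15%) against the first
    unit, so unit variants of slightly different length are cut correctly.
    Leading/trailing incomplete copies are stored as partials.
    """
    if period > len(seq):
        raise ValueError(f"period {period} exceeds sequence length {len(seq)}")
    if anchor is not None:
        phase = seq.find(anchor)
        if phase < 0:
            raise ValueError("anchor motif not found in sequence")
    else:
        phase = _best_phase(seq, period)

    lo = math.ceil(period * (1 - COMPLETE_TOL))
    hi = math.floor(period * (1 + COMPLETE_TOL))
    units: list[RepeatUnit] = []
    cur = phase
    template: str | None = None
    while len(seq) - cur >= lo:
        if template is None:
            L = min(period, len(seq) - cur)
        else:
            best_L, best_score = None, -np.inf
            for L_cand in range(lo, min(hi, len(seq) - cur) + 1):
                score = align_global(template, seq[cur : cur + L_cand]).score
                if score > best_score + 1e-9 or (
                    score > best_score - 1e-9
                    and best_L is not None
                    and abs(L_cand - period) < abs(best_L - period)
                ):
                    best_L, best_score = L_cand, score
            L = best_L
        unit_seq = seq[cur : cur + L]
        units.append(
            RepeatUnit(seq=unit_seq, start=offset + cur, end=offset + cur + L, complete=lo <= L <= hi)
        )
        if template is None:
            template = unit_seq
        cur += L
    return RepeatArray(
        source=source,
        span=(offset, offset + len(seq)),
        period=period,
        units=units,
        leading_partial=seq[:phase],
        trailing_partial=seq[cur:],
    )


def catalog_unit_types(arrays: list[RepeatArray], max_mismatch: int = 0) -> UnitTypeCatalog:
    """Group complete units into types and assign positional classes.

    Default grouping is exact sequence identity (each distinct unit sequence
    is its own type); ``max_mismatch > 0`` greedily merges equal-length
    units within that Hamming distance of a type's representative.
    """
    if not arrays:
        raise ValueError("need >= 1 array")
    reps: list[str] = []
    members: dict[int, list[tuple[int, int, int]]] = {}  # type idx -> (array, pos, n_complete)

    def type_of(u: str) -> int:
        for t, rep in enumerate(reps):
            if u == rep:
                return t
            if (
                max_mismatch > 0
                and len(u) == len(rep)
                and sum(x != y for x, y in zip(u, rep)) <= max_mismatch
            ):
                return t
        reps.append(u)
        return len(reps) - 1

    for ai, arr in enumerate(arrays):
        complete = [u for u in arr.units if u.complete]
        for pos, u in enumerate(complete):
            t = type_of(u.seq)
            members.setdefault(t, []).append((ai, pos, len(complete)))

    types: dict[str, UnitType] = {}
    for t, rep in enumerate(reps):
        occ = members[t]
        firsts = [pos == 0 for _, pos, _ in occ]
        lasts = [pos == n - 1 for _, pos, n in occ]
        soles = [n == 1 for _, _, n in occ]
        if all(soles):
            cls = "BE"
        elif all(firsts) and not any(lasts):
            cls = "B"
        elif all(lasts) and not any(firsts):
            cls = "E"
        elif not any(firsts) and not any(lasts):
            cls = "M"
        else:
            cls = "U"
        label = f"T{t + 1}"
        types[label] = UnitType(
            label=label, consensus=rep, member_count=len(occ), positional_class=cls
        )
    return UnitTypeCatalog(types=types)


def copy_number_spectrum(arrays: list[RepeatArray]) -> dict[str, HeteroplasmySpectrum]:
    """Complete-unit copy-number histograms per region across clones."""
    if not arrays:
        raise ValueError("need >= 1 array")
    by_region: dict[str, Counter] = {}
    for arr in arrays:
        by_region.setdefault(arr.source[1], Counter())[arr.n_complete] += 1
    out: dict[str, HeteroplasmySpectrum] = {}
    for region, hist in by_region.items():
        top = max(hist.values())
        winners = sorted(k for k, v in hist.items() if v == top)
        out[region] = HeteroplasmySpectrum(
            region=region,
            histogram=dict(sorted(hist.items())),
            dominant=winners[0],
            dominant_tied=len(winners) > 1,
        )
    return out


def base_composition(seq: str) -> dict[str, float]:
    """A/C/G/T fractions; ambiguity codes excluded from both numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return {b: c / total for b, c in counts.items()}
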