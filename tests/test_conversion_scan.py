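"""p-distance, region statistics, site classification and RFB delimitation.

Region statistics are checked against an independent nested-loop oracle that
recomputes every quantity directly from the raw rows.
"""

from itertools import combinations

import numpy as np
import pytest

import mtconcert as m
from mtconcert.conversion_scan import NoComparableSites, SiteKind

from conftest import make_alignment


# ---------------------------------------------------------------- oracle


def oracle_p_distance(a, b, s, e):
    diffs = comp = 0
    for x, y in zip(a[s:e], b[s:e]):
        if x != "-" and y != "-":
            comp += 1
            diffs += x != y
    if comp == 0:
        raise ZeroDivisionError
    return diffs / comp


def oracle_region_stats(rows: dict[str, str], s, e):
    """Brute-force pi_dupl / pi_ind / counts from label -> row mapping."""
    inds = sorted({lab.rsplit("-", 1)[0] for lab in rows})
    dupl = [oracle_p_distance(rows[f"{i}-I"], rows[f"{i}-II"], s, e) for i in inds]
    pooled = []
    for cp in ("I", "II"):
        for a, b in combinations(inds, 2):
            pooled.append(oracle_p_distance(rows[f"{a}-{cp}"], rows[f"{b}-{cp}"], s, e))
    n_poly = 0
    gap_cols = []
    for c in range(s, e):
        col = [rows[lab][c] for lab in rows]
        n_poly += len(set(col)) > 1
        gap_cols.append("-" in col)
    n_indel = sum(
        1 for i, g in enumerate(gap_cols) if g and (i == 0 or not gap_cols[i - 1])
    )
    return sum(dupl) / len(dupl), sum(pooled) / len(pooled), n_poly, n_indel


def random_gapped_alignment(rng, n_ind, n_cols, gap_frac=0.01):
    rows = {}
    for i in range(n_ind):
        for cp in ("I", "II"):
            chars = rng.choice(list("ACGT"), size=n_cols)
            gaps = rng.random(n_cols) < gap_frac
            chars[gaps] = "-"
            rows[f"i{i}-{cp}"] = "".join(chars)
    # ensure the reference row has no gaps so ref_map is well defined
    rows["i0-I"] = rows["i0-I"].replace("-", "A")
    return rows


# ---------------------------------------------------------------- p_distance


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("AC-T", "ACGT", 0.0),  # pairwise deletion: 3 comparable, 0 differing
    ],
)
def test_p_distance_cases(a, b, expected):
    assert m.p_distance(a, b) == expected


def test_p_distance_no_comparable_sites_is_error():
    with pytest.raises(NoComparableSites):
        m.p_distance("--AA", "AA--")


def test_p_distance_ambiguity_codes_mismatch():
    # conservative: an ambiguity code differs from any other symbol
    assert m.p_distance("ACGR", "ACGA") == 0.25


# ---------------------------------------------------------------- region_stats


def test_region_stats_trivial_cases():
    rows = {lab: "ACGTACGTAC" for lab in ("a-I", "a-II", "b-I", "b-II")}
    st = m.region_stats(make_alignment(rows), (0, 10))
    assert st.pi_dupl == 0.0 and st.pi_ind == 0.0
    assert st.n_polymorphic == 0 and st.n_indel_positions == 0


def test_region_stats_two_individuals_forced():
    base = "A" * 100
    other = "C" + "A" * 48 + "C" + "A" * 50
    rows = {"a-I": base, "a-II": base, "b-I": other, "b-II": other}
    st = m.region_stats(make_alignment(rows), (0, 100))
    assert st.pi_dupl == 0.0
    assert st.pi_ind == pytest.approx(0.02)
    assert st.n_polymorphic == 2


def test_region_stats_needs_two_individuals():
    rows = {"a-I": "ACGT", "a-II": "ACGT", "a2-I": "ACGT"}
    aln = make_alignment({**rows, "a2-II": "ACGT"})
    aln.row_labels = [("a", "I"), ("a", "II"), ("a", "x1"), ("a", "x2")]
    with pytest.raises(ValueError, match="2 individuals"):
        m.region_stats(aln, (0, 4))


def test_region_stats_matches_bruteforce_oracle(rng):
    for _ in range(10):
        n_ind = int(rng.integers(2, 7))
        n_cols = int(rng.integers(20, 300))
        rows = random_gapped_alignment(rng, n_ind, n_cols, gap_frac=0.02)
        aln = make_alignment(rows)
        s = int(rng.integers(0, n_cols // 2))
        e = int(rng.integers(s + 5, n_cols + 1))
        st = m.region_stats(aln, (s, e))
        pd_, pi, poly, indel = oracle_region_stats(rows, s, e)
        assert st.pi_dupl == pytest.approx(pd_, abs=1e-12)
        assert st.pi_ind == pytest.approx(pi, abs=1e-12)
        assert st.n_polymorphic == poly
        assert st.n_indel_positions == indel


def test_pi_dupl_monotone_under_planted_paralog_difference(rng):
    rows = random_gapped_alignment(rng, 4, 150, gap_frac=0.0)
    aln = make_alignment(rows)
    before = m.region_stats(aln, (40, 90)).pi_dupl
    r = rows["i2-II"]
    col = 60
    new = "A" if r[col] != "A" else "C"
    rows2 = dict(rows, **{"i2-II": r[:col] + new + r[col + 1 :]})
    after = m.region_stats(make_alignment(rows2), (40, 90)).pi_dupl
    if rows["i2-I"][col] == r[col]:  # planted a new paralogue difference
        assert after > before
    else:
        assert after >= before - 1 / 50


# ---------------------------------------------------------------- classify_sites


def test_classify_invariant_alignment():
    rows = {lab: "ACGTACGT" for lab in ("a-I", "a-II", "b-I", "b-II")}
    assert all(s.kind == SiteKind.invariant for s in m.classify_sites(make_alignment(rows)))


def test_classify_shared_copy_ii_substitution_is_paralog_only():
    base = "AAAAAAAAAA"
    cii = "AAAAGAAAAA"  # all individuals carry it on copy II only
    rows = {"a-I": base, "a-II": cii, "b-I": base, "b-II": cii}
    sites = m.classify_sites(make_alignment(rows))
    assert sites[4].kind == SiteKind.paralog_variable
    assert all(s.kind == SiteKind.invariant for i, s in enumerate(sites) if i != 4)


def test_classify_ortholog_and_both_and_indel():
    rows = {
        "a-I": "AAGA-A",
        "a-II": "AACAAA",
        "b-I": "ATGAAA",
        "b-II": "ATGAAA",
    }
    kinds = [s.kind for s in m.classify_sites(make_alignment(rows))]
    assert kinds[1] == SiteKind.ortholog_variable  # a vs b within both copies
    assert kinds[2] == SiteKind.both  # a-I vs a-II, and a-II vs b-II
    assert kinds[4] == SiteKind.indel
    assert kinds[0] == SiteKind.invariant


def test_classify_matches_simulated_event_log(default_sim, scenario_alignment):
    """Columns the generator mutated are exactly the non-invariant ones."""
    aln = scenario_alignment
    sites = m.classify_sites(aln)
    para_cols = {s.column for s in sites if s.kind in (SiteKind.paralog_variable, SiteKind.both)}
    ts, te = default_sim.truth.rfb_by_copy["sim-1"]["I"]
    # paralogue-variable sites live inside (or at the edge of) the true RFB
    lo = aln.column_of_ref(ts)
    hi = aln.column_of_ref(te - 1)
    assert all(lo - 2 <= c <= hi + 2 for c in para_cols)
    assert len(para_cols) >= 20


# ---------------------------------------------------------------- call_rfb


def test_call_rfb_no_paralog_sites_is_no_call():
    rows = {lab: "ACGTACGT" * 10 for lab in ("a-I", "a-II", "b-I", "b-II")}
    aln = make_alignment(rows)
    assert m.call_rfb(m.classify_sites(aln), aln) is None


def test_call_rfb_planted_tract():
    rng = np.random.default_rng(7)
    n = 400
    base = "".join(rng.choice(list("ACGT"), size=n))
    tract = (150, 210)
    cii = list(base)
    for pos in range(*tract):
        if rng.random() < 0.3:
            cii[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cii[pos]]
    cii = "".join(cii)
    rows = {"a-I": base, "a-II": cii, "b-I": base, "b-II": cii, "c-I": base, "c-II": cii}
    aln = make_alignment(rows)
    call = m.call_rfb(m.classify_sites(aln), aln)
    assert call is not None
    s, e = call.interval_cols
    assert tract[0] <= s <= tract[0] + 15 and tract[1] - 15 <= e <= tract[1]
    assert call.inside.pi_dupl > call.inside.pi_ind
    assert call.upstream.pi_dupl == 0.0
    assert call.n_paralog_sites >= 3


def test_call_rfb_recovers_simulated_tract(default_sim, scenario_result):
    call = scenario_result.rfb
    assert call is not None
    ts, te = default_sim.truth.rfb_by_copy["sim-1"]["I"]
    s, e = call.interval_ref
    inter = max(0, min(e, te) - max(s, ts))
    union = max(e, te) - min(s, ts)
    assert inter / union >= 0.8
    assert call.inside.pi_dupl > call.inside.pi_ind
    assert call.upstream.pi_dupl <= call.upstream.pi_ind
    assert call.downstream.pi_dupl <= call.downstream.pi_ind


def test_scenario_reproduces_diversity_contrast(scenario_result):
    """Orthologues similar / paralogues divergent inside the tract, reversed outside."""
    inside = scenario_result.stats["rfb"]
    up = scenario_result.stats["upstream"]
    down = scenario_result.stats["downstream"]
    assert inside.pi_dupl > 0.1 > inside.pi_ind
    for flank in (up, down):
        assert flank.pi_dupl < 0.005
        assert flank.pi_ind > flank.pi_dupl


# ------------------------------------------------- conversion_contrast_test


def test_permutation_p_degenerate_is_one():
    rows = {lab: "ACGT" * 10 for lab in ("a-I", "a-II", "b-I", "b-II", "c-I", "c-II")}
    aln = make_alignment(rows)
    assert m.conversion_contrast_test(aln, (0, 40), n_perm=99, seed=0) == 1.0


def test_permutation_p_bounds(rng):
    rows = random_gapped_alignment(rng, 4, 100, gap_frac=0.0)
    aln = make_alignment(rows)
    p = m.conversion_contrast_test(aln, (0, 100), n_perm=99, seed=3)
    assert 1 / 100 <= p <= 1.0


def test_permutation_p_small_for_simulated_conversion(scenario_alignment, scenario_result):
    s, _ = scenario_result.rfb.interval_cols
    p = m.conversion_contrast_test(scenario_alignment, (0, s), n_perm=999, seed=7)
    assert p <= 0.05


def test_permutation_needs_three_individuals():
    rows = {lab: "ACGT" * 5 for lab in ("a-I", "a-II", "b-I", "b-II")}
    with pytest.raises(ValueError):
        m.conversion_contrast_test(make_alignment(rows), (0, 20), n_perm=9, seed=0)
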