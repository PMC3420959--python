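"""Target-site scanning, RVD cipher and off-target mismatch scanning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from talenkit.design import (
    DEFAULT_CIPHER,
    DesignParams,
    HalfSiteMatch,
    RvdModule,
    TalenSite,
    classify_risk,
    count_half_mismatches,
    decode_rvd_array,
    design_rvd_arrays,
    rvd_array_from_codes,
    scan_off_targets,
    scan_target_sites,
)
from talenkit.fixtures import make_design_gene, make_homolog, random_dna
from talenkit.sequences import DnaSequence, revcomp

BASE_TO_RVD = {b: c for c, b in DEFAULT_CIPHER.items()}


# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_force_sites(seq: str, params: DesignParams) -> set[tuple]:
    """Naive enumeration over all anchor index pairs, keeping the canonical
    (balanced, then shortest-spacer, then longest-left) decomposition."""
    best: dict[tuple[int, int], tuple] = {}
    L = len(seq)
    for a in range(L):
        if seq[a] != "T":
            continue
        for nl in range(params.rvd_min, params.rvd_max + 1):
            for sp in range(params.spacer_min, params.spacer_max + 1):
                for nr in range(params.rvd_min, params.rvd_max + 1):
                    b = a + 1 + nl + sp + nr
                    if b >= L or seq[b] != "A" or "N" in seq[a : b + 1]:
                        continue
                    key = (abs(nl - nr), sp, -nl)
                    if (a, b) not in best or key < best[(a, b)][0]:
                        best[(a, b)] = (key, (a, b, nl, sp, nr))
    return {v[1] for v in best.values()}


def site_tuple(s: TalenSite) -> tuple:
    return (
        s.span[0],
        s.span[1] - 1,
        len(s.left.bases),
        s.spacer_len,
        len(s.right.bases),
    )


def brute_force_offtargets(records, left_bases, right_plus, max_mm, params):
    hits = set()
    for rec in records:
        for strand, s in (("+", rec.seq), ("-", revcomp(rec.seq))):
            L = len(s)
            for sp in range(params.spacer_min, params.spacer_max + 1):
                for la in range(L):
                    ra = la + len(left_bases) + sp
                    if ra + len(right_plus) > L:
                        break
                    lm = sum(x != y for x, y in zip(s[la : la + len(left_bases)], left_bases))
                    rm = sum(x != y for x, y in zip(s[ra : ra + len(right_plus)], right_plus))
                    if lm <= max_mm and rm <= max_mm:
                        start, end = la - 1, ra + len(right_plus) + 1
                        if start < 0 or end > L:
                            continue
                        if strand == "-":
                            start, end = L - end, L - start
                        hits.add((rec.id, start, end, strand, lm, rm, sp))
    return hits


# ---------------------------------------------------------------------------
# site scanning


def test_poly_a_has_no_sites():
    seq = DnaSequence("polyA", "A" * 100)
    assert scan_target_sites(seq) == []


def test_too_short_sequence_warns_and_returns_empty():
    seq = DnaSequence("tiny", "TACG" * 5)
    with pytest.warns(UserWarning, match="shorter than the minimal"):
        assert scan_target_sites(seq) == []


def _planted_construct(rng, n_left=16, spacer=15, n_right=16) -> tuple[str, int]:
    """T + left bases + spacer + revcomp(T + right bases) in CG filler.

    CG-only filler guarantees the planted anchors are the only T/A pair,
    so the expected site count is knowable in advance.
    """
    seg = lambda n: "".join(rng.choice(list("CG"), size=n))
    core = "T" + seg(n_left) + seg(spacer) + revcomp("T" + seg(n_right))
    return seg(10) + core + seg(40), 10


def test_planted_construct_yields_exactly_one_site_matching_brute_force(rng):
    seq_str, start = _planted_construct(rng)
    seq = DnaSequence("construct", seq_str)
    params = DesignParams()
    sites = scan_target_sites(seq, params)
    assert len(sites) == 1
    (site,) = sites
    assert site.spacer_len == 15
    assert site.span[0] == start
    assert {site_tuple(s) for s in sites} == {
        (a, b, nl, sp, nr) for a, b, nl, sp, nr in brute_force_sites(seq_str, params)
    }


@pytest.mark.parametrize("spacer,expected", [(13, 0), (14, 1), (17, 1)])
def test_spacer_range_is_enforced(rng, spacer, expected):
    seq_str, _ = _planted_construct(rng, spacer=spacer)
    sites = scan_target_sites(DnaSequence("c", seq_str))
    assert len(sites) == expected


def test_overlong_spacer_rejected_even_with_maximal_half_sites(rng):
    # anchors 61 bp apart cannot be decomposed with spacer <= 17
    seq_str, _ = _planted_construct(rng, n_left=21, spacer=18, n_right=21)
    assert scan_target_sites(DnaSequence("c", seq_str)) == []


def test_scan_agrees_with_brute_force_on_random_sequence(rng):
    seq_str = random_dna(rng, 1500, gc=0.5)
    params = DesignParams()
    sites = scan_target_sites(DnaSequence("rand", seq_str), params)
    expected = brute_force_sites(seq_str, params)
    assert {site_tuple(s) for s in sites} == expected
    assert len(sites) == len(expected)


def test_site_invariants_on_random_sequence(rng):
    seq_str = random_dna(rng, 3000, gc=0.45)
    params = DesignParams()
    for s in scan_target_sites(DnaSequence("rand", seq_str), params):
        assert params.spacer_min <= s.spacer_len <= params.spacer_max
        assert params.rvd_min <= len(s.left.bases) <= params.rvd_max
        assert params.rvd_min <= len(s.right.bases) <= params.rvd_max
        assert seq_str[s.left.anchor_T_pos] == "T"
        assert seq_str[s.right.anchor_T_pos] == "A"  # T on the - strand
        assert s.left.end + s.spacer_len == s.right.start
        assert s.left.bases == seq_str[s.left.start + 1 : s.left.end]
        assert s.right.bases == revcomp(seq_str[s.right.start : s.right.end - 1])


def test_strand_symmetry(rng):
    seq_str = random_dna(rng, 800, gc=0.5)
    fwd = scan_target_sites(DnaSequence("f", seq_str))
    rev = scan_target_sites(DnaSequence("r", revcomp(seq_str)))
    L = len(seq_str)
    fwd_spans = {s.span for s in fwd}
    mirrored = {(L - e, L - a) for a, e in (s.span for s in rev)}
    assert fwd_spans == mirrored
    # anchor pairs mirror too: Left/Right roles swap under reverse complement
    fwd_anchors = {(s.left.anchor_T_pos, s.right.anchor_T_pos) for s in fwd}
    rev_anchors = {
        (L - 1 - s.right.anchor_T_pos, L - 1 - s.left.anchor_T_pos) for s in rev
    }
    assert fwd_anchors == rev_anchors


def test_widening_ranges_never_removes_sites(rng):
    seq_str = random_dna(rng, 600, gc=0.5)
    seq = DnaSequence("m", seq_str)
    narrow = DesignParams(spacer_min=15, spacer_max=16, rvd_min=17, rvd_max=19)
    wide = DesignParams(spacer_min=14, spacer_max=17, rvd_min=16, rvd_max=21)
    anchors = lambda sites: {
        (s.left.anchor_T_pos, s.right.anchor_T_pos) for s in sites
    }
    assert anchors(scan_target_sites(seq, narrow)) <= anchors(
        scan_target_sites(seq, wide)
    )


# ---------------------------------------------------------------------------
# RVD cipher


def test_design_arrays_match_cipher(design_fixture):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    assert left.bases == site.left.bases
    assert right.bases == site.right.bases
    assert [m.code for m in left.modules] == [BASE_TO_RVD[b] for b in site.left.bases]
    assert left.n == len(site.left.bases)


def test_anchor_thymine_gets_no_module(design_fixture):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    # half-target = anchor + recognized bases: one module fewer than the footprint
    assert left.n == (site.left.end - site.left.start) - 1
    assert right.n == (site.right.end - site.right.start) - 1


def test_design_arrays_rejects_ambiguous_base(design_fixture):
    site = design_fixture.sites[0]
    bad_left = HalfSiteMatch(
        "+", site.left.start, site.left.end, site.left.anchor_T_pos,
        site.left.bases[:5] + "N" + site.left.bases[6:],
    )
    bad_site = TalenSite(bad_left, site.right, site.spacer_len, site.span, 0.0)
    with pytest.raises(ValueError, match="position 5"):
        design_rvd_arrays(bad_site)


def test_design_arrays_rejects_empty_half():
    left = HalfSiteMatch("+", 0, 1, 0, "")
    right = HalfSiteMatch("-", 20, 38, 37, "A" * 17)
    site = TalenSite(left, right, 15, (0, 38), 0.0)
    with pytest.raises(ValueError, match="no recognized bases"):
        design_rvd_arrays(site)


@pytest.mark.parametrize(
    "codes,expected",
    [(["NG"], "T"), (["NI", "HD", "NN", "NG"], "ACGT"), (["NN"] * 20, "G" * 20)],
)
def test_decode_rvd_array(codes, expected):
    arr = rvd_array_from_codes(codes, "Left")
    assert decode_rvd_array(arr) == expected


def test_decode_rejects_unknown_module():
    arr = rvd_array_from_codes(["NI", "HD"], "Left")
    bad = arr.__class__("Left", arr.modules + (RvdModule("XX", "A"),))
    with pytest.raises(ValueError, match="XX"):
        decode_rvd_array(bad)


@given(st.text(alphabet="ACGT", min_size=16, max_size=21))
def test_cipher_round_trip(bases):
    codes = [BASE_TO_RVD[b] for b in bases]
    assert decode_rvd_array(rvd_array_from_codes(codes, "Left")) == bases


# ---------------------------------------------------------------------------
# mismatch counting and risk


def test_count_half_mismatches_identity_and_substitutions(rng):
    s = random_dna(rng, 19)
    assert count_half_mismatches(s, s) == 0
    mutated = list(s)
    pos = rng.choice(19, size=3, replace=False)
    for i in pos:
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    mutated = "".join(mutated)
    brute = sum(a != b for a, b in zip(s, mutated))
    assert count_half_mismatches(s, mutated) == brute == 3
    assert count_half_mismatches(mutated, s) == 3  # symmetric
    with pytest.raises(ValueError):
        count_half_mismatches(s, s[:-1])


@pytest.mark.parametrize(
    "lm,rm,risk",
    [(0, 0, "high"), (2, 0, "high"), (0, 2, "high"), (1, 2, "low"),
     (2, 2, "low"), (3, 4, "none"), (3, 3, "none")],
)
def test_risk_classification(lm, rm, risk):
    assert classify_risk(lm, rm) == risk


# ---------------------------------------------------------------------------
# off-target scanning


def test_self_hit_in_design_gene(design_fixture):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    hits = scan_off_targets([design_fixture.gene], left, right, max_mm_per_half=0)
    assert len(hits) == 1
    (h,) = hits
    assert (h.left_mismatches, h.right_mismatches) == (0, 0)
    assert h.risk == "high"
    assert (h.start, h.end) == site.span


def test_planted_homolog_mismatch_pattern(design_fixture):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    hom = make_homolog(5, design_fixture, 3, 4)
    hits = scan_off_targets([hom], left, right, max_mm_per_half=4)
    assert [(h.left_mismatches, h.right_mismatches, h.risk) for h in hits] == [
        (3, 4, "none")
    ]
    # below the per-half budget the homolog disappears
    assert scan_off_targets([hom], left, right, max_mm_per_half=3) == []


def test_offtarget_agrees_with_brute_force(rng, design_fixture):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    genome = [
        DnaSequence("rand", random_dna(rng, 2000, gc=0.5)),
        design_fixture.gene,
    ]
    params = DesignParams()
    hits = scan_off_targets(genome, left, right, max_mm_per_half=1, params=params)
    got = {
        (h.seq_id, h.start, h.end, h.strand, h.left_mismatches,
         h.right_mismatches, h.spacer_len)
        for h in hits
    }
    expected = brute_force_offtargets(
        genome, left.bases, revcomp(right.bases), 1, params
    )
    assert got == expected


def test_raising_mm_budget_never_removes_hits(design_fixture, rng):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    genome = [make_homolog(6, design_fixture, 2, 1)]
    key = lambda hits: {
        (h.seq_id, h.start, h.end, h.strand, h.spacer_len) for h in hits
    }
    prev: set = set()
    for mm in range(0, 5):
        cur = key(scan_off_targets(genome, left, right, mm))
        assert prev <= cur
        prev = cur


def test_empty_genome_gives_empty_result(design_fixture):
    site = design_fixture.sites[0]
    left, right = design_rvd_arrays(site)
    assert scan_off_targets([], left, right, 2) == []
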