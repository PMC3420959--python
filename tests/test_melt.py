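"""Duplex thermodynamics, pairing combinatorics and melt-curve model."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given
from hypothesis import strategies as st

from talenkit.fixtures import make_deletion_allele, random_dna
from talenkit.melt import (
    AllelePool,
    enumerate_duplexes,
    helicity,
    melt_curve,
    pool_melt_curve,
    temperature_grid,
)
from talenkit.thermo import ThermoParams, duplex_thermo

# frozen oracle: explicit hand walk over the unified stack table for this
# 20-mer (init + two terminal corrections + 19 dinucleotide stacks),
# Tm = 1000*dH / (dS + R ln(C_T/4)) at C_T = 0.25 uM
ORACLE_SEQ = "ACGTGCTTAGGCATCGAATC"
ORACLE_DH = -157.8  # kcal/mol
ORACLE_DS = -427.1  # cal/(mol*K)
ORACLE_TM = 69.84832680388678  # Celsius


def test_perfect_duplex_matches_hand_summed_oracle():
    t = duplex_thermo(ORACLE_SEQ, ORACLE_SEQ)
    assert t.dh == pytest.approx(ORACLE_DH, abs=1e-9)
    assert t.ds == pytest.approx(ORACLE_DS, abs=1e-9)
    assert t.tm == pytest.approx(ORACLE_TM, abs=0.01)
    assert t.n_mismatches == 0 and t.n_loop_bases == 0


def test_perfect_duplex_matches_biopython_with_salt(rng):
    # independent route: Biopython's own Tm_NN on the same tables
    for _ in range(5):
        seq = random_dna(rng, 30)
        mine = duplex_thermo(seq, seq, ThermoParams(na_mM=50.0)).tm
        ref = mt.Tm_NN(
            seq, nn_table=mt.DNA_NN3, dnac1=125, dnac2=125, Na=50, saltcorr=5
        )
        assert mine == pytest.approx(ref, abs=1e-6)


def test_gc_rich_melts_above_at_rich():
    gc = duplex_thermo("GCGGCCGCGGCCGCGGGCCG", "GCGGCCGCGGCCGCGGGCCG")
    at = duplex_thermo("ATAATTATAATTATAATTAT", "ATAATTATAATTATAATTAT")
    assert gc.tm > at.tm


def test_mismatches_monotonically_destabilize(rng):
    wt = random_dna(rng, 60, gc=0.5)
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    tms = []
    mutant = list(wt)
    for n_mm, pos in enumerate([None, 15, 30, 45]):
        if pos is not None:
            mutant[pos] = swap[mutant[pos]]
        t = duplex_thermo(wt, "".join(mutant))
        assert t.n_mismatches == n_mm
        tms.append(t.tm)
    assert all(a > b for a, b in zip(tms, tms[1:]))


def test_deletion_heteroduplex_melts_below_homoduplex(het_pool_setup):
    wt, _, allele = het_pool_setup
    mut = allele.apply(wt)
    hom = duplex_thermo(wt, wt)
    het = duplex_thermo(wt, mut)
    assert het.n_loop_bases == 18
    assert het.tm < hom.tm
    # symmetry: orientation does not matter
    assert duplex_thermo(mut, wt).tm == pytest.approx(het.tm, abs=1e-9)


def test_larger_bulge_melts_earlier(het_pool_setup):
    wt, site, _ = het_pool_setup
    small = make_deletion_allele(site, del_len=4).apply(wt)
    large = make_deletion_allele(site, del_len=12).apply(wt)
    assert duplex_thermo(wt, large).tm < duplex_thermo(wt, small).tm


def test_unalignable_sequences_rejected():
    with pytest.raises(ValueError, match="alignable"):
        duplex_thermo("A" * 80, "C" * 80)
    with pytest.raises(ValueError, match="non-empty"):
        duplex_thermo("", "ACGT")


# ---------------------------------------------------------------------------
# pairing combinatorics


def test_pure_pool_single_species():
    pool = AllelePool((("WT", "ACGTACGTACGTACGTACGT"),), (1.0,))
    species = enumerate_duplexes(pool)
    assert len(species) == 1
    assert species[0].fraction == pytest.approx(1.0)


def test_heterozygote_pool_two_hom_two_het(het_pool_setup):
    wt, _, allele = het_pool_setup
    pool = AllelePool((("WT", wt), ("mut", allele.apply(wt))), (0.5, 0.5))
    species = enumerate_duplexes(pool, ThermoParams())
    assert len(species) == 4
    hom = [s for s in species if s.top_allele == s.bottom_allele]
    het = [s for s in species if s.top_allele != s.bottom_allele]
    assert len(hom) == 2 and len(het) == 2
    for s in species:
        assert s.fraction == pytest.approx(0.25)
    # the two heteroduplex orientations share identical thermodynamics
    assert het[0].thermo.tm == pytest.approx(het[1].thermo.tm, abs=1e-12)
    assert sum(s.fraction for s in species) == pytest.approx(1.0)


def test_rare_mutant_heteroduplex_fraction():
    f = 1 / 70
    pool = AllelePool(
        (("WT", "ACGT" * 25), ("mut", "ACGT" * 24 + "ACG")), (1 - f, f)
    )
    species = enumerate_duplexes(pool)
    het = sum(s.fraction for s in species if s.top_allele != s.bottom_allele)
    assert het == pytest.approx(2 * f * (1 - f), abs=1e-12)


@given(
    st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=5)
)
def test_fraction_conservation(weights):
    freqs = tuple(w / sum(weights) for w in weights)
    pool = AllelePool(
        tuple((f"a{i}", "ACGT" * 10) for i in range(len(freqs))), freqs
    )
    species = enumerate_duplexes(pool)
    assert len(species) == len(freqs) ** 2
    assert sum(s.fraction for s in species) == pytest.approx(1.0, abs=1e-9)


def test_zero_frequency_allele_changes_nothing(het_pool_setup):
    wt, _, allele = het_pool_setup
    base = AllelePool((("WT", wt),), (1.0,))
    extended = AllelePool((("WT", wt), ("mut", allele.apply(wt))), (1.0, 0.0))
    c1 = pool_melt_curve(base)
    c2 = pool_melt_curve(extended)
    np.testing.assert_allclose(c1.fluor, c2.fluor, atol=1e-12)


def test_pool_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        AllelePool((("a", "ACGT"), ("b", "ACGT")), (0.6, 0.6))
    with pytest.raises(ValueError, match="non-negative"):
        AllelePool((("a", "ACGT"), ("b", "ACGT")), (1.5, -0.5))
    with pytest.raises(ValueError, match="at least one"):
        AllelePool((), ())


# ---------------------------------------------------------------------------
# melt curves


def test_single_species_curve_sigmoidal_midpoint(het_pool_setup):
    wt, _, _ = het_pool_setup
    pool = AllelePool((("WT", wt),), (1.0,))
    curve = pool_melt_curve(pool)
    assert np.all(np.diff(curve.fluor) <= 1e-12)  # non-increasing
    tm = duplex_thermo(wt, wt).tm
    crossing = curve.temps[np.argmin(np.abs(curve.fluor - 0.5))]
    assert abs(crossing - tm) <= 0.1 + 1e-9  # within one grid step


def test_heterozygote_melts_earlier_than_wt(het_pool_setup):
    wt, _, allele = het_pool_setup
    het_pool = AllelePool((("WT", wt), ("m", allele.apply(wt))), (0.5, 0.5))
    wt_curve = pool_melt_curve(AllelePool((("WT", wt),), (1.0,)))
    het_curve = pool_melt_curve(het_pool)
    het_tm = duplex_thermo(wt, allele.apply(wt)).tm
    hom_tm = duplex_thermo(wt, wt).tm
    between = (wt_curve.temps > het_tm) & (wt_curve.temps < hom_tm)
    assert np.max(wt_curve.fluor[between] - het_curve.fluor[between]) > 0.2


def test_mixture_curve_is_weighted_sum_of_species(het_pool_setup):
    wt, _, allele = het_pool_setup
    pool = AllelePool((("WT", wt), ("m", allele.apply(wt))), (0.7, 0.3))
    species = enumerate_duplexes(pool, ThermoParams())
    curve = melt_curve(species)
    manual = sum(s.fraction * helicity(s.thermo, curve.temps) for s in species)
    np.testing.assert_allclose(curve.fluor, manual, atol=1e-9)


def test_dilution_continuity(het_pool_setup):
    wt, _, allele = het_pool_setup
    mut = allele.apply(wt)
    wt_curve = pool_melt_curve(AllelePool((("WT", wt),), (1.0,)))
    sup = []
    for f in (0.1, 0.01, 0.001):
        c = pool_melt_curve(AllelePool((("WT", wt), ("m", mut)), (1 - f, f)))
        sup.append(np.max(np.abs(c.fluor - wt_curve.fluor)))
    assert sup[0] > sup[1] > sup[2]
    assert sup[2] < 0.01


def test_noise_is_deterministic_for_fixed_seed(het_pool_setup):
    wt, _, _ = het_pool_setup
    pool = AllelePool((("WT", wt),), (1.0,))
    c1 = pool_melt_curve(pool, noise_sd=0.004, rng=42)
    c2 = pool_melt_curve(pool, noise_sd=0.004, rng=42)
    c3 = pool_melt_curve(pool, noise_sd=0.004, rng=43)
    np.testing.assert_array_equal(c1.fluor, c2.fluor)
    assert not np.array_equal(c1.fluor, c3.fluor)


def test_melt_curve_input_validation(het_pool_setup):
    wt, _, _ = het_pool_setup
    species = enumerate_duplexes(AllelePool((("WT", wt),), (1.0,)), ThermoParams())
    with pytest.raises(ValueError, match="empty"):
        melt_curve([])
    with pytest.raises(ValueError, match="ascending"):
        melt_curve(species, temps=np.array([90.0, 80.0, 70.0]))
    with pytest.raises(ValueError, match="thermodynamics"):
        melt_curve(enumerate_duplexes(AllelePool((("WT", wt),), (1.0,))))
    grid = temperature_grid()
    assert grid[0] == 65.0 and grid[-1] == pytest.approx(95.0)


def test_truncated_pool_keeps_major_alleles(het_pool_setup):
    wt, _, allele = het_pool_setup
    mut = allele.apply(wt)
    pool = AllelePool(
        (("WT", wt), ("m", mut), ("rare", mut[:-1])), (0.9, 0.095, 0.005)
    )
    small = pool.truncated(min_freq=0.01)
    assert small.labels == ("WT", "m")
    assert sum(small.freqs) == pytest.approx(1.0)
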