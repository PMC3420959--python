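"""Nearest-neighbor duplex thermodynamics for homo- and heteroduplexes.

A duplex formed between the + strands of two alleles of one amplicon is
summarized by van't Hoff parameters (dH, dS) accumulated over aligned
dinucleotide steps:

* Watson-Crick steps use the unified DNA stack parameters,
* internal single mismatches use the published mismatch stack corrections
  (both tables shipped with Biopython's MeltingTemp module),
* bases looped out of the duplex by an indel contribute no stacking and
  incur a configurable destabilization penalty, applied as a dS
  adjustment equivalent to +0.3 kcal/mol free energy per base at 37 C.

Tm follows Tm = dH / (dS + R ln(C_T/4)) for non-self-complementary
strands at total strand concentration C_T. Absolute accuracy is not the
goal — the model exists to produce realistic relative melt-curve shapes;
the monovalent-salt entropy correction is therefore off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio.SeqUtils import MeltingTemp as mt

R_GAS = 1.987  # cal/(mol*K)
T_REF = 310.15  # K, reference temperature for the loop penalty
_COMP = str.maketrans("ACGT", "TGCA")

#: alignments with normalized edit distance above this are rejected —
#: the two sequences are not variants of one amplicon
MAX_NORMALIZED_DISTANCE = 0.8


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic model configuration.

    ct_molar : total strand concentration C_T (M); default 0.25 uM.
    loop_dg_per_base : free-energy penalty per looped-out base (kcal/mol).
    na_mM : monovalent salt for the entropic correction; 0 disables it.
    """

    ct_molar: float = 0.25e-6
    loop_dg_per_base: float = 0.3
    na_mM: float = 0.0


@dataclass(frozen=True)
class DuplexThermo:
    dh: float  # kcal/mol
    ds: float  # cal/(mol*K)
    tm: float  # Celsius
    n_mismatches: int
    n_loop_bases: int

    @property
    def defects(self) -> int:
        return self.n_mismatches + self.n_loop_bases


def _aligned_columns(top: str, bottom: str) -> list[tuple[str, str]]:
    """Global alignment of two + strand sequences as (top, bottom) columns.

    '-' marks a base absent from one strand (looped out of the duplex).
    """
    if top == bottom:
        return list(zip(top, bottom))
    res = edlib.align(top, bottom, mode="NW", task="path")
    if res["editDistance"] / max(len(top), len(bottom)) > MAX_NORMALIZED_DISTANCE:
        raise ValueError(
            "sequences share no alignable core; they are not variants of one amplicon"
        )
    nice = edlib.getNiceAlignment(res, top, bottom)
    return list(zip(nice["query_aligned"], nice["target_aligned"]))


def _stack_lookup(key: str) -> tuple[float, float] | None:
    """(dH, dS) for a dinucleotide step 5'-XY-3'/3'-WZ-5' written 'XY/WZ'.

    Tables store one orientation; the flipped reading of the same step is
    tried before giving up.
    """
    for table in (mt.DNA_NN3, mt.DNA_IMM1):
        if key in table:
            return tuple(table[key])
    top, bottom = key.split("/")
    rkey = bottom[::-1] + "/" + top[::-1]
    for table in (mt.DNA_NN3, mt.DNA_IMM1):
        if rkey in table:
            return tuple(table[rkey])
    return None


@lru_cache(maxsize=65536)
def duplex_thermo(
    top: str, bottom_source: str, params: ThermoParams = ThermoParams()
) -> DuplexThermo:
    """van't Hoff parameters and Tm of the duplex of two allele strands.

    ``top`` and ``bottom_source`` are both given 5'->3' on the + strand;
    the physical duplex pairs ``top`` with the reverse complement of
    ``bottom_source``, so an aligned column (x, y) is a Watson-Crick pair
    iff x == y.
    """
    if not top or not bottom_source:
        raise ValueError("both strands must be non-empty")
    cols = _aligned_columns(top, bottom_source)

    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol*K)
    n_mm = 0
    n_loop = 0

    # helix initiation + terminal penalties over the first/last paired column
    paired = [(x, y) for x, y in cols if x != "-" and y != "-"]
    if not paired:
        raise ValueError("alignment contains no paired bases")
    init_h, init_s = mt.DNA_NN3["init"]
    dh += init_h
    ds += init_s
    for x, y in (paired[0], paired[-1]):
        term = "init_A/T" if (x == y and x in "AT") else "init_G/C"
        if x != y:  # terminal mismatch: use the weaker A/T-like initiation
            term = "init_A/T"
        th, ts = mt.DNA_NN3[term]
        dh += th
        ds += ts

    for (x1, y1), (x2, y2) in zip(cols, cols[1:]):
        if "-" in (x1, y1) or "-" in (x2, y2):
            continue  # stacking interrupted by a loop
        key = (
            f"{x1}{x2}/"
            f"{y1.translate(_COMP)}{y2.translate(_COMP)}"
        )
        stack = _stack_lookup(key)
        if stack is not None:
            dh += stack[0]
            ds += stack[1]
        # adjacent mismatches outside the tabulated set contribute no stack

    for x, y in cols:
        if x == "-" or y == "-":
            n_loop += 1
        elif x != y:
            n_mm += 1

    # looped-out bases: +loop_dg_per_base kcal/mol each, as a dS adjustment
    ds -= n_loop * params.loop_dg_per_base * 1000.0 / T_REF

    if params.na_mM > 0:
        # SantaLucia (1998) entropic monovalent-salt correction
        ds += 0.368 * (len(paired) - 1) * math.log(params.na_mM / 1000.0)

    tm_k = dh * 1000.0 / (ds + R_GAS * math.log(params.ct_molar / 4.0))
    return DuplexThermo(
        dh=dh, ds=ds, tm=tm_k - 273.15, n_mismatches=n_mm, n_loop_bases=n_loop
    )
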