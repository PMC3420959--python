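"""TALEN target-site design and off-target scanning.

A TALEN pair binds a site laid out on the + strand as::

    [T] L1..Ln_left  --spacer (14-17 bp)--  R'1..R'n_right [A]
     ^ Left anchor                                          ^ Right anchor

The Left monomer binds the + strand: a 5' thymine (contacted by the TALE
N-terminus, not by an RVD module) followed by one recognized base per RVD
repeat. The Right monomer binds the - strand the same way, so on the
+ strand its half-site reads as the reverse complement: n_right bases
followed by an A (the - strand anchor T). FokI dimerises and cleaves in
the spacer, so the full configuration is
``>=17 bp - N_14-17 - >=17 bp`` counting each half-target as anchor + RVD
bases with 16-21 repeats per monomer.

Each RVD (repeat-variable di-residue) module recognizes one nucleotide via
the standard Golden Gate kit cipher NI=A, HD=C, NN=G, NG=T (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequences import DnaSequence, revcomp

#: default RVD module -> cognate base cipher
DEFAULT_CIPHER: dict[str, str] = {"NI": "A", "HD": "C", "NN": "G", "NG": "T"}

#: cleavage-risk thresholds calibrated to observed homolog cleavage:
#: a site differing at only 2 of ~36 recognized positions is cleaved
#: effectively, while ~6-7 total mismatches abolish cleavage.
DEFAULT_RISK_THRESHOLDS: dict[str, int] = {"high_total": 2, "low_total": 4}


@dataclass(frozen=True)
class DesignParams:
    """Target-site search parameters.

    Defaults follow the routine zebrafish design rules: spacer 14-17 bp,
    16-21 RVD repeats per monomer, obligatory 5' T anchor on each binding
    strand, and a soft preference for a terminal T in each half-site.
    """

    spacer_min: int = 14
    spacer_max: int = 17
    rvd_min: int = 16
    rvd_max: int = 21
    require_5prime_T: bool = True
    restrict_options: bool = True
    cipher: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CIPHER))

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if not (1 <= self.rvd_min <= self.rvd_max <= 31):
            raise ValueError("rvd range must satisfy 1 <= min <= max <= 31")
        bases = sorted(self.cipher.values())
        if bases != ["A", "C", "G", "T"]:
            raise ValueError("cipher must be a bijection onto {A,C,G,T}")

    @property
    def base_to_rvd(self) -> dict[str, str]:
        return {base: code for code, base in self.cipher.items()}


@dataclass(frozen=True)
class RvdModule:
    """One repeat module and the nucleotide it recognizes."""

    code: str
    cognate_base: str


@dataclass(frozen=True)
class RvdArray:
    """Ordered RVD modules for one TALEN monomer (5'->3' on its strand)."""

    side: str  # "Left" | "Right"
    modules: tuple[RvdModule, ...]

    def __post_init__(self) -> None:
        if self.side not in ("Left", "Right"):
            raise ValueError("side must be 'Left' or 'Right'")

    @property
    def n(self) -> int:
        return len(self.modules)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(m.code for m in self.modules)

    @property
    def bases(self) -> str:
        return "".join(m.cognate_base for m in self.modules)


@dataclass(frozen=True)
class HalfSiteMatch:
    """One monomer's binding footprint, in + strand coordinates.

    ``bases`` is read 5'->3' on the binding strand (for the Right monomer
    this is the reverse complement of the + strand slice). The interval
    [start, end) includes the anchor position.
    """

    strand: str  # "+" | "-"
    start: int
    end: int
    anchor_T_pos: int
    bases: str


@dataclass(frozen=True)
class TalenSite:
    """A paired Left/Right half-site match with its spacer."""

    left: HalfSiteMatch
    right: HalfSiteMatch
    spacer_len: int
    span: tuple[int, int]
    rank_score: float

    @property
    def spacer_interval(self) -> tuple[int, int]:
        return (self.left.end, self.left.end + self.spacer_len)

    def shifted(self, offset: int) -> "TalenSite":
        """The same site translated by ``offset`` (e.g. into amplicon coords)."""

        def mv(h: HalfSiteMatch) -> HalfSiteMatch:
            return replace(
                h,
                start=h.start + offset,
                end=h.end + offset,
                anchor_T_pos=h.anchor_T_pos + offset,
            )

        return replace(
            self,
            left=mv(self.left),
            right=mv(self.right),
            span=(self.span[0] + offset, self.span[1] + offset),
        )


@dataclass(frozen=True)
class OffTargetHit:
    """A candidate cleavage locus found by mismatch scanning."""

    seq_id: str
    start: int
    end: int
    strand: str
    left_mismatches: int
    right_mismatches: int
    spacer_len: int
    risk: str  # "high" | "low" | "none"


# ---------------------------------------------------------------------------
# site scanning


def _composition_penalty(left_bases: str, right_bases: str) -> int:
    """Soft guideline: the last recognized base of each half-site is
    preferably T (the downstream assembly kit's terminal-repeat convention)."""
    penalty = 0
    if left_bases[-1] != "T":
        penalty += 1
    if right_bases[-1] != "T":
        penalty += 1
    return penalty


def _canonical_key(n_left: int, spacer: int, n_right: int) -> tuple[int, int, int]:
    """Preference order among decompositions of one anchor pair: balanced
    half-sites first, then shorter spacer, then longer left half."""
    return (abs(n_left - n_right), spacer, -n_left)


def scan_target_sites(
    seq: DnaSequence, params: DesignParams | None = None
) -> list[TalenSite]:
    """Exhaustively enumerate TALEN target sites in ``seq``.

    All combinations of left length, spacer length and right length within
    the configured ranges are tried at every anchor position. A pair of
    anchors admits several (left, spacer, right) decompositions — one
    site per anchor pair is reported, under the canonical decomposition
    (balanced half-sites, then shortest spacer). Sites are returned
    sorted by ``rank_score`` (composition penalty first, then 5'
    proximity, then shorter span). Sites containing N are skipped.
    """
    params = params or DesignParams()
    s = seq.seq
    L = len(s)
    min_span = 2 * (params.rvd_min + 1) + params.spacer_min
    if L < min_span:
        warnings.warn(
            f"sequence {seq.id!r} ({L} nt) shorter than the minimal site span "
            f"({min_span} nt); no sites possible",
            stacklevel=2,
        )
        return []

    # best decomposition per (left anchor, right anchor) pair
    best: dict[tuple[int, int], tuple[tuple[int, int, int], TalenSite]] = {}
    # weight so composition outranks position, per the ranking convention
    weight = float(L)
    for a in range(L):
        if s[a] != "T" and params.require_5prime_T:
            continue
        for n_left in range(params.rvd_min, params.rvd_max + 1):
            left_end = a + 1 + n_left
            if left_end + params.spacer_min + params.rvd_min + 1 > L:
                break
            for spacer in range(params.spacer_min, params.spacer_max + 1):
                r0 = left_end + spacer
                for n_right in range(params.rvd_min, params.rvd_max + 1):
                    b = r0 + n_right  # + strand position of the Right anchor
                    if b >= L:
                        break
                    if s[b] != "A" and params.require_5prime_T:
                        continue
                    key = _canonical_key(n_left, spacer, n_right)
                    anchor_pair = (a, b)
                    if anchor_pair in best and best[anchor_pair][0] <= key:
                        continue
                    window = s[a : b + 1]
                    if "N" in window:
                        continue
                    left_bases = s[a + 1 : left_end]
                    right_bases = revcomp(s[r0:b])
                    penalty = (
                        _composition_penalty(left_bases, right_bases)
                        if params.restrict_options
                        else 0
                    )
                    site = TalenSite(
                        left=HalfSiteMatch("+", a, left_end, a, left_bases),
                        right=HalfSiteMatch("-", r0, b + 1, b, right_bases),
                        spacer_len=spacer,
                        span=(a, b + 1),
                        rank_score=penalty * weight + a,
                    )
                    best[anchor_pair] = (key, site)
    sites = [site for _, site in best.values()]
    sites.sort(key=lambda t: (t.rank_score, t.span[0], t.span[1] - t.span[0]))
    return sites


# ---------------------------------------------------------------------------
# RVD arrays


def design_rvd_arrays(
    site: TalenSite, params: DesignParams | None = None
) -> tuple[RvdArray, RvdArray]:
    """Emit the Left and Right RVD arrays for a site.

    One module per recognized base, 5'->3' on each monomer's binding
    strand; the anchor T gets no module (it is contacted by the TALE
    N-terminal backbone).
    """
    params = params or DesignParams()
    b2r = params.base_to_rvd

    def encode(bases: str, side: str) -> RvdArray:
        if not bases:
            raise ValueError(f"{side} half-site has no recognized bases")
        modules = []
        for i, base in enumerate(bases):
            if base not in b2r:
                raise ValueError(
                    f"{side} half-site position {i}: cannot assign an RVD "
                    f"module to base {base!r}"
                )
            modules.append(RvdModule(b2r[base], base))
        return RvdArray(side, tuple(modules))

    return encode(site.left.bases, "Left"), encode(site.right.bases, "Right")


def rvd_array_from_codes(
    codes: Sequence[str] | str, side: str, params: DesignParams | None = None
) -> RvdArray:
    """Build an RvdArray from module codes (e.g. ``"NI,HD,NN,NG"``)."""
    params = params or DesignParams()
    if isinstance(codes, str):
        codes = [c.strip() for c in codes.split(",") if c.strip()]
    modules = []
    for c in codes:
        if c not in params.cipher:
            raise ValueError(f"unknown RVD module code {c!r}")
        modules.append(RvdModule(c, params.cipher[c]))
    return RvdArray(side, tuple(modules))


def decode_rvd_array(
    arr: RvdArray, cipher: Mapping[str, str] | None = None
) -> str:
    """Inverse of the cipher: the DNA the array recognizes (binding strand)."""
    cipher = cipher or DEFAULT_CIPHER
    out = []
    for i, mod in enumerate(arr.modules):
        if mod.code not in cipher:
            raise ValueError(f"module {i}: unknown RVD code {mod.code!r}")
        out.append(cipher[mod.code])
    return "".join(out)


# ---------------------------------------------------------------------------
# off-target scanning


def count_half_mismatches(half_bases: str, locus_bases: str) -> int:
    """Hamming distance between a half-site and a locus over RVD positions."""
    if len(half_bases) != len(locus_bases):
        raise ValueError(
            f"length mismatch: {len(half_bases)} vs {len(locus_bases)}"
        )
    return sum(a != b for a, b in zip(half_bases, locus_bases))


def classify_risk(
    left_mm: int, right_mm: int, thresholds: Mapping[str, int] | None = None
) -> str:
    """Cleavage-risk class from per-half mismatch counts.

    high: total mismatches <= 2 (observed to be effectively cleaved);
    low: total <= 4; none otherwise (~6 mismatches abolish cleavage).
    """
    t = thresholds or DEFAULT_RISK_THRESHOLDS
    total = left_mm + right_mm
    if total <= t["high_total"] and min(left_mm, right_mm) <= t["high_total"]:
        return "high"
    if total <= t["low_total"]:
        return "low"
    return "none"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_mismatches(enc: np.ndarray, pattern: str) -> np.ndarray:
    """mm[i] = Hamming distance of pattern vs enc[i:i+len(pattern)]."""
    p = _encode(pattern)
    m = len(p)
    n = len(enc) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for k in range(m):
        mm += enc[k : k + n] != p[k]
    return mm


def scan_off_targets(
    genome: Iterable[DnaSequence],
    left_arr: RvdArray,
    right_arr: RvdArray,
    max_mm_per_half: int,
    params: DesignParams | None = None,
    include_anchor: bool = False,
    thresholds: Mapping[str, int] | None = None,
) -> list[OffTargetHit]:
    """Exhaustive mismatch scan for loci a TALEN pair could cleave.

    Every locus where both half-sites match within ``max_mm_per_half``
    mismatches, on opposing strands, with spacer in the configured range,
    is reported — in both orientations of each record. The intended design
    site appears as a (0, 0) hit. With ``include_anchor`` the two anchor
    positions (5' T of each monomer) are added to the mismatch counts;
    by default mismatches are counted over RVD-recognized bases only.
    """
    if max_mm_per_half < 0:
        raise ValueError("max_mm_per_half must be >= 0")
    params = params or DesignParams()
    left_bases = left_arr.bases
    right_plus = revcomp(right_arr.bases)  # Right half-site as seen on + strand
    n_left, n_right = len(left_bases), len(right_plus)

    hits: list[OffTargetHit] = []
    for rec in genome:
        L = len(rec.seq)
        for strand, s in (("+", rec.seq), ("-", revcomp(rec.seq))):
            enc = _encode(s)
            mm_left = _window_mismatches(enc, left_bases)
            mm_right = _window_mismatches(enc, right_plus)
            if include_anchor:
                not_t = (enc != ord("T")).astype(np.int32)
                not_a = (enc != ord("A")).astype(np.int32)
            for spacer in range(params.spacer_min, params.spacer_max + 1):
                # left recognized bases start at la; geometry:
                # anchor(la-1) [left: la..la+n_left) spacer [right) anchor(A)
                offset = n_left + spacer
                n_pos = len(mm_left) - offset - n_right
                if n_pos <= 0:
                    continue
                lm = mm_left[:n_pos]
                rm = mm_right[offset : offset + n_pos]
                if include_anchor:
                    # left anchor at la-1 (T), right anchor at la+offset+n_right (A);
                    # pad so out-of-range anchors count as mismatched
                    pad_t = np.concatenate(([1], not_t))
                    pad_a = np.concatenate((not_a, [1]))
                    lm = lm + pad_t[:n_pos]
                    rm = rm + pad_a[offset + n_right : offset + n_right + n_pos]
                cand = np.nonzero((lm <= max_mm_per_half) & (rm <= max_mm_per_half))[0]
                for la in cand:
                    la = int(la)
                    start = la - 1  # include anchor positions in the interval
                    end = la + offset + n_right + 1
                    if start < 0 or end > L:
                        continue
                    if strand == "-":
                        start, end = L - end, L - start
                    l_mm, r_mm = int(lm[la]), int(rm[la])
                    hits.append(
                        OffTargetHit(
                            seq_id=rec.id,
                            start=start,
                            end=end,
                            strand=strand,
                            left_mismatches=l_mm,
                            right_mismatches=r_mm,
                            spacer_len=spacer,
                            risk=classify_risk(l_mm, r_mm, thresholds),
                        )
                    )
    hits.sort(
        key=lambda h: (h.seq_id, h.start, h.strand, h.spacer_len)
    )
    return hits
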