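"""Synthetic-data generators: genes with planted TALEN sites, homolog
families with controlled mismatch patterns, dilution-series pools and
amplicon-feasible target regions.

These generators define the study conditions the rest of the package is
exercised under: target regions whose amplicons fall in the 90-120 bp
HRMA window, homolog families reproducing asymmetric cleavage specificity
(a 2-mismatch homolog is cleavable, a 7-mismatch one is not), and mixed
WT/mutant pools down to a 1/70 mutant haploid fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import DesignParams, TalenSite, scan_target_sites
from .hrma import Amplicon, PrimerParams, design_amplicon
from .melt import AllelePool
from .mosaic import WT_LABEL, IndelAllele
from .sequences import DnaSequence, revcomp

#: planted site geometry: 17-repeat half-sites, 15 bp spacer, span 51 bp
PLANT_N_LEFT = 17
PLANT_SPACER = 15
PLANT_N_RIGHT = 17
PLANT_SPAN = PLANT_N_LEFT + PLANT_SPACER + PLANT_N_RIGHT + 2


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the requested expected GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _plant(rng: np.random.Generator, gc: float, strict_cg: bool) -> str:
    """A planted target site: T + left bases + spacer + revcomp(T + right).

    With ``strict_cg`` the recognized bases and spacer are drawn from
    {C, G} only (except the terminal-T guideline bases), which makes the
    planted anchors the only T/A pair at a site-compatible distance.
    """

    def seg(n: int) -> str:
        if strict_cg:
            return "".join(rng.choice(list("CG"), size=n))
        return random_dna(rng, n, gc)

    left = seg(PLANT_N_LEFT - 1) + "T"
    right = seg(PLANT_N_RIGHT - 1) + "T"  # binding-strand bases, last = T
    spacer = seg(PLANT_SPACER)
    return "T" + left + spacer + revcomp("T" + right)


def _planted_site(sites: list[TalenSite], start: int) -> TalenSite:
    span = (start, start + PLANT_SPAN)
    for s in sites:
        if s.span == span:
            return s
    raise AssertionError(f"planted site at {span} not recovered by the scanner")


@dataclass(frozen=True)
class DesignFixture:
    gene: DnaSequence
    sites: tuple[TalenSite, ...]  # the planted sites, 5'-most first


def make_design_gene(
    rng: np.random.Generator | int,
    n_sites: int = 1,
    length: int = 400,
    site_spacing: int = 120,
) -> DesignFixture:
    """A synthetic gene containing exactly ``n_sites`` TALEN target sites.

    Filler sequence is drawn from {C, G} so that the planted anchor pairs
    are provably the only T/A pairs at a site-compatible distance; the
    scanner is run to confirm the guarantee. Raises if the requested
    sites do not fit in ``length``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    need = n_sites * site_spacing + 40
    if length < need:
        raise ValueError(
            f"{n_sites} sites spaced {site_spacing} bp apart need >= {need} bp, "
            f"got {length}"
        )
    filler = list(rng.choice(list("CG"), size=length))
    starts = [20 + i * site_spacing for i in range(n_sites)]
    seq = "".join(filler)
    for st in starts:
        seq = seq[:st] + _plant(rng, 0.5, strict_cg=True) + seq[st + PLANT_SPAN :]
    gene = DnaSequence("synthetic_gene", seq, origin="talenkit.fixtures")
    found = scan_target_sites(gene, DesignParams())
    if len(found) != n_sites:
        raise AssertionError(
            f"fixture guarantee violated: expected {n_sites} sites, found {len(found)}"
        )
    return DesignFixture(
        gene=gene, sites=tuple(_planted_site(found, st) for st in starts)
    )


def make_homolog(
    rng: np.random.Generator | int,
    fixture: DesignFixture,
    left_mismatches: int,
    right_mismatches: int,
    site_index: int = 0,
    name: str | None = None,
) -> DnaSequence:
    """A homolog of a design gene differing at a controlled number of
    positions in each half-site's recognized bases.

    Substitutions swap C<->G so no new anchor T/A is created and the
    exact-site-count guarantee carries over to the homolog.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    site = fixture.sites[site_index]
    seq = list(fixture.gene.seq)
    swap = {"C": "G", "G": "C"}
    for half, n_mm in ((site.left, left_mismatches), (site.right, right_mismatches)):
        # + strand coordinates of the RVD-recognized bases
        if half.strand == "+":
            lo, hi = half.start + 1, half.end
        else:
            lo, hi = half.start, half.end - 1
        candidates = [i for i in range(lo, hi) if seq[i] in swap]
        if n_mm > len(candidates):
            raise ValueError("not enough substitutable positions in the half-site")
        for i in rng.choice(candidates, size=n_mm, replace=False):
            seq[int(i)] = swap[seq[int(i)]]
    label = name or f"homolog_L{left_mismatches}_R{right_mismatches}"
    return DnaSequence(label, "".join(seq), origin="talenkit.fixtures")


def make_target_region(
    rng: np.random.Generator | int,
    length: int = 400,
    core_gc: float = 0.45,
    flank_gc: float = 0.58,
    primer_params: PrimerParams | None = None,
    amplicon_tm_range: tuple[float, float] = (80.0, 91.0),
    max_tries: int = 200,
) -> tuple[DnaSequence, TalenSite, Amplicon]:
    """A realistic target region with one amplicon-feasible site.

    The site core is AT-rich enough to melt inside the instrument window
    while the flanks are GC-rich enough to host primers in the 68-72 C
    band; candidate regions are redrawn until the amplicon design succeeds
    and its homoduplex Tm falls inside ``amplicon_tm_range`` (so the melt
    transition, including the post-melt baseline, sits inside the default
    65-95 C acquisition window). The returned region is therefore feasible
    by construction.
    """
    from .thermo import duplex_thermo

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    primer_params = primer_params or PrimerParams()
    start = (length - PLANT_SPAN) // 2
    last_err: str | None = None
    for _ in range(max_tries):
        flank_l = random_dna(rng, start, flank_gc)
        flank_r = random_dna(rng, length - start - PLANT_SPAN, flank_gc)
        seq = flank_l + _plant(rng, core_gc, strict_cg=False) + flank_r
        region = DnaSequence("target_region", seq, origin="talenkit.fixtures")
        sites = scan_target_sites(region, DesignParams())
        site = _planted_site(sites, start)
        try:
            amp = design_amplicon(region, site, primer_params)
        except ValueError as err:
            last_err = str(err)
            continue
        tm = duplex_thermo(amp.seq, amp.seq).tm
        if not (amplicon_tm_range[0] <= tm <= amplicon_tm_range[1]):
            last_err = f"amplicon homoduplex Tm {tm:.1f} C outside window"
            continue
        return region, site, amp
    raise RuntimeError(
        f"no feasible region found in {max_tries} tries (last error: {last_err})"
    )


def make_deletion_allele(site: TalenSite, del_len: int = 18) -> IndelAllele:
    """A fixed deletion allele centered in the spacer (e.g. an 18 bp
    deletion, the classic heterozygote demonstration allele)."""
    sp_start, sp_end = site.spacer_interval
    return IndelAllele(cut_pos=(sp_start + sp_end) // 2, del_len=del_len, ins_seq="")


def make_dilution_pools(
    wt_amplicon: str,
    mutant: IndelAllele,
    fractions: tuple[float, ...] = (1 / 10, 1 / 20, 1 / 50, 1 / 70),
) -> list[tuple[float, AllelePool]]:
    """Mixed WT/mutant pools at exact mutant haploid fractions."""
    mut_seq = mutant.apply(wt_amplicon)
    pools = []
    for f in fractions:
        if not (0 < f < 1):
            raise ValueError("mutant fraction must lie in (0, 1)")
        pools.append(
            (
                f,
                AllelePool(
                    ((WT_LABEL, wt_amplicon), (mutant.label, mut_seq)),
                    (1 - f, f),
                ),
            )
        )
    return pools
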