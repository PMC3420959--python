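"""Generative model of TALEN-injected mosaic embryos and founder germlines.

Injected TALEN mRNA is translated during cleavage divisions, so each cell
cycle every still-wild-type copy of the target site can be cut and
repaired by non-homologous end joining into an indel allele. The model is
a branching cell-division process: mutations accrue over divisions,
independently in different lineages, producing a genetically mosaic
embryo whose genome pool mixes wild type with many distinct alleles.
Germ lines sample a small number of progenitor genomes from that pool,
and each F1 offspring of a founder x wild-type cross inherits one founder
gamete allele plus one wild-type allele — a 50/50 heterozygous pool feeding
directly into the melt simulator.

Dose dependence enters through a saturating (Hill-type) map from injected
RNA dose to the per-division cut probability; the functional form is a
modelling choice, with parameters set so the 4/20/100 pg dose ladder
orders mean mutation load correctly and 100 pg drives roughly half of all
genomes to mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import TalenSite
from .melt import AllelePool

WT_LABEL = "WT"


@dataclass(frozen=True)
class IndelAllele:
    """One NHEJ repair product at the target site.

    ``cut_pos`` is the cut coordinate within the wild-type amplicon;
    ``del_len`` bases centered on the cut are replaced by ``ins_seq``.
    """

    cut_pos: int
    del_len: int
    ins_seq: str

    @property
    def net_change(self) -> int:
        return len(self.ins_seq) - self.del_len

    @property
    def frameshift(self) -> bool:
        return self.net_change % 3 != 0

    @property
    def label(self) -> str:
        return f"{self.cut_pos}:-{self.del_len}+{self.ins_seq or '.'}"

    def apply(self, wt_amplicon: str) -> str:
        start = max(1, self.cut_pos - self.del_len // 2)
        end = min(len(wt_amplicon) - 1, start + self.del_len)
        return wt_amplicon[:start] + self.ins_seq + wt_amplicon[end:]


@dataclass(frozen=True)
class SimParams:
    """Mutagenesis simulation parameters.

    dose_pg : injected TALEN RNA dose (pg total).
    n_divisions : cleavage divisions simulated (10 -> 1024 cells).
    q_max, k_half_pg, hill : saturating dose -> per-division cut
        probability map q(d) = q_max * d^h / (k^h + d^h).
    p_insertion_event : fraction of repair events that are net insertions.
    del_min/del_p : deletion length ~ del_min + Geometric0(del_p).
    ins_p : residual insertion at a deletion ~ Geometric0(ins_p).
    large_indel_prob : probability a deletion comes from the rare >30 bp
        tail instead (drawn uniformly from large_del_range).
    """

    dose_pg: float = 100.0
    n_divisions: int = 10
    q_max: float = 0.08
    k_half_pg: float = 20.0
    hill: float = 1.0
    p_insertion_event: float = 0.2
    del_min: int = 3
    del_p: float = 0.2
    ins_p: float = 0.7
    ins_event_p: float = 0.25
    large_indel_prob: float = 0.02
    large_del_range: tuple[int, int] = (31, 60)


@dataclass(frozen=True)
class MosaicEmbryo:
    freqs: dict[str, float]
    alleles: dict[str, IndelAllele]
    biallelic_cell_fraction: float

    @property
    def mutant_fraction(self) -> float:
        return 1.0 - self.freqs.get(WT_LABEL, 0.0)


@dataclass(frozen=True)
class FounderGermline:
    freqs: dict[str, float]
    alleles: dict[str, IndelAllele]

    @property
    def transmits(self) -> bool:
        return any(lab != WT_LABEL and f > 0 for lab, f in self.freqs.items())

    @property
    def distinct_alleles(self) -> int:
        return sum(1 for lab, f in self.freqs.items() if lab != WT_LABEL and f > 0)

    @property
    def mutant_fraction(self) -> float:
        return 1.0 - self.freqs.get(WT_LABEL, 0.0)


@dataclass(frozen=True)
class F1Individual:
    founder_id: str
    index: int
    allele_label: str | None  # None = inherited WT from the founder
    pool: AllelePool

    @property
    def carrier(self) -> bool:
        return self.allele_label is not None


@dataclass(frozen=True)
class TransmissionSummary:
    n_founders: int
    n_transmitting: int
    mean_distinct_alleles: float | None  # None when no founder transmits
    per_founder_carrier_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def fraction_transmitting(self) -> float:
        return self.n_transmitting / self.n_founders


def cut_probability(dose_pg: float, params: SimParams) -> float:
    """Per-division, per-copy cut probability from the RNA dose."""
    if dose_pg <= 0:
        return 0.0
    d, k, h = dose_pg, params.k_half_pg, params.hill
    return params.q_max * d**h / (k**h + d**h)


def sample_indel(
    site: TalenSite,
    wt_amplicon: str,
    params: SimParams,
    rng: np.random.Generator,
) -> IndelAllele:
    """Draw one NHEJ repair product centered in the spacer.

    The cut position is uniform within the spacer (FokI cleaves between
    the half-sites); most events change 3-20 bp, with a rare >30 bp tail.
    Site coordinates must be relative to ``wt_amplicon``.
    """
    sp_start, sp_end = site.spacer_interval
    if not (0 <= sp_start < sp_end <= len(wt_amplicon)):
        raise ValueError("site spacer does not lie within the amplicon")
    cut = int(rng.integers(sp_start, sp_end))
    if rng.random() < params.p_insertion_event:
        del_len = 0
        ins_len = 1 + int(rng.geometric(params.ins_event_p)) - 1
    else:
        if rng.random() < params.large_indel_prob:
            del_len = int(rng.integers(*params.large_del_range))
        else:
            del_len = params.del_min + int(rng.geometric(params.del_p)) - 1
        ins_len = int(rng.geometric(params.ins_p)) - 1
    ins_seq = "".join(rng.choice(list("ACGT"), size=ins_len)) if ins_len else ""
    return IndelAllele(cut_pos=cut, del_len=del_len, ins_seq=ins_seq)


def simulate_embryo(
    site: TalenSite,
    wt_amplicon: str,
    params: SimParams,
    rng: np.random.Generator,
) -> MosaicEmbryo:
    """Branching cell-division mutagenesis of one injected embryo.

    Each cell carries two copies of the target locus. At fertilisation and
    after every division, each still-WT copy is cut with probability
    q(dose); a cut copy acquires a fresh indel and is never re-cut (the
    binding site is disrupted). Returns the final genome-frequency pool.
    """
    q = cut_probability(params.dose_pg, params)
    alleles: dict[str, IndelAllele] = {}

    def maybe_cut(copy: str) -> str:
        if copy == WT_LABEL and q > 0 and rng.random() < q:
            ind = sample_indel(site, wt_amplicon, params, rng)
            alleles.setdefault(ind.label, ind)
            return ind.label
        return copy

    cells: list[tuple[str, str]] = [(maybe_cut(WT_LABEL), maybe_cut(WT_LABEL))]
    for _ in range(params.n_divisions):
        cells = [
            (maybe_cut(a), maybe_cut(b)) for a, b in cells for _ in range(2)
        ]
    counts: dict[str, int] = {}
    biallelic = 0
    for a, b in cells:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        if a != WT_LABEL and b != WT_LABEL:
            biallelic += 1
    total = 2 * len(cells)
    freqs = {lab: c / total for lab, c in sorted(counts.items())}
    return MosaicEmbryo(
        freqs=freqs,
        alleles=alleles,
        biallelic_cell_fraction=biallelic / len(cells),
    )


def sample_germline(
    embryo: MosaicEmbryo,
    n_progenitors: int = 20,
    rng: np.random.Generator | None = None,
) -> FounderGermline:
    """Sample germline progenitor genomes from the embryo pool.

    Progenitors are a multinomial draw at the embryo pool frequencies;
    the germline allele frequencies are the progenitor empirical
    frequencies.
    """
    if n_progenitors < 1:
        raise ValueError("n_progenitors must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    labels = list(embryo.freqs)
    probs = np.array([embryo.freqs[lab] for lab in labels])
    draws = rng.multinomial(n_progenitors, probs / probs.sum())
    freqs = {
        lab: int(c) / n_progenitors for lab, c in zip(labels, draws) if c > 0
    }
    kept = {
        lab: a for lab, a in embryo.alleles.items() if lab in freqs
    }
    return FounderGermline(freqs=freqs, alleles=kept)


def simulate_f1(
    germline: FounderGermline,
    wt_amplicon: str,
    n_f1: int,
    rng: np.random.Generator,
    founder_id: str = "G0",
) -> list[F1Individual]:
    """Cross a mosaic founder to wild type and genotype the F1.

    Each F1 draws one gamete allele at the germline frequencies plus one
    WT allele: carriers are 0.5/0.5 heterozygous pools, non-carriers pure
    WT.
    """
    if n_f1 < 1:
        raise ValueError("n_f1 must be >= 1")
    labels = list(germline.freqs)
    probs = np.array([germline.freqs[lab] for lab in labels])
    picks = rng.choice(len(labels), size=n_f1, p=probs / probs.sum())
    out = []
    for i, pick in enumerate(picks):
        lab = labels[int(pick)]
        if lab == WT_LABEL:
            pool = AllelePool(((WT_LABEL, wt_amplicon),), (1.0,))
            allele_label = None
        else:
            mut_seq = germline.alleles[lab].apply(wt_amplicon)
            pool = AllelePool(
                ((WT_LABEL, wt_amplicon), (lab, mut_seq)), (0.5, 0.5)
            )
            allele_label = lab
        out.append(
            F1Individual(founder_id=founder_id, index=i, allele_label=allele_label,
                         pool=pool)
        )
    return out


def summarize_transmission(
    founders: Sequence[tuple[FounderGermline, Sequence[F1Individual]]],
) -> TransmissionSummary:
    """Cohort transmission statistics over (germline, F1 clutch) records."""
    if not founders:
        raise ValueError("need at least one founder record")
    n_transmitting = sum(1 for g, _ in founders if g.transmits)
    distinct = [g.distinct_alleles for g, _ in founders if g.transmits]
    carrier_frac = {}
    for k, (_, f1s) in enumerate(founders):
        fid = f1s[0].founder_id if f1s else f"founder_{k}"
        carrier_frac[fid] = (
            sum(1 for f in f1s if f.carrier) / len(f1s) if f1s else 0.0
        )
    return TransmissionSummary(
        n_founders=len(founders),
        n_transmitting=n_transmitting,
        mean_distinct_alleles=(
            float(np.mean(distinct)) if distinct else None
        ),
        per_founder_carrier_fraction=carrier_frac,
    )
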