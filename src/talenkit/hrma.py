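"""HRMA curve normalization, variant calling, allele grouping and
amplicon design.

The analysis mirrors standard high-resolution-melt practice: each raw
curve is rescaled so its pre-melt plateau averages 1 and its post-melt
baseline averages 0; a difference curve (delta fluorescence) is taken
against the mean of wild-type reference replicates; a sample is called
``variant`` when the maximal absolute deviation exceeds k times the
wild-type replicate envelope (default k = 5). Variant samples are grouped
into putative allele classes by complete-linkage clustering of their
difference curves under correlation distance — samples transmitted the
same allele share a melt-curve shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .design import TalenSite
from .melt import MeltCurve
from .sequences import DnaSequence, revcomp


@dataclass(frozen=True)
class NormalizedCurve:
    temps: np.ndarray = field(compare=False)
    fluor_norm: np.ndarray = field(compare=False)
    sample_id: str = ""


@dataclass(frozen=True)
class DifferenceCurve:
    temps: np.ndarray = field(compare=False)
    delta: np.ndarray = field(compare=False)
    sample_id: str = ""

    @property
    def score(self) -> float:
        return float(np.max(np.abs(self.delta)))


@dataclass(frozen=True)
class CallResult:
    sample_id: str
    label: str  # "wt_like" | "variant"
    score: float
    threshold: float
    wt_envelope_sd: float


@dataclass(frozen=True)
class AlleleGroup:
    label: str
    members: tuple[str, ...]
    consensus: np.ndarray = field(compare=False)


def normalize_curve(
    raw: MeltCurve,
    window: tuple[float, float] | None = None,
    plateau_frac: float = 0.1,
) -> NormalizedCurve:
    """Affine rescale of a melt curve to [0, 1] using plateau means.

    The pre-melt plateau (lowest ``plateau_frac`` of temperatures in the
    window) maps to 1 and the post-melt baseline to 0. Idempotent: the
    plateau means of a normalized curve are exactly 1 and 0.
    """
    temps, fluor = raw.temps, np.asarray(raw.fluor, dtype=float)
    if window is not None:
        lo, hi = window
        mask = (temps >= lo) & (temps <= hi)
        if not mask.any():
            raise ValueError("analysis window does not overlap the curve")
        temps, fluor = temps[mask], fluor[mask]
    k = max(1, int(round(plateau_frac * len(temps))))
    plateau = float(np.mean(fluor[:k]))
    baseline = float(np.mean(fluor[-k:]))
    if abs(plateau - baseline) < 1e-12:
        raise ValueError(
            f"curve {raw.sample_id!r} is constant over the analysis window"
        )
    norm = (fluor - baseline) / (plateau - baseline)
    return NormalizedCurve(temps=temps, fluor_norm=norm, sample_id=raw.sample_id)


def _check_grids(curves: list[NormalizedCurve]) -> None:
    t0 = curves[0].temps
    for c in curves[1:]:
        if len(c.temps) != len(t0) or not np.allclose(c.temps, t0):
            raise ValueError("curves are not on a common temperature grid")


def difference_curve(
    sample: NormalizedCurve, wt_refs: list[NormalizedCurve]
) -> DifferenceCurve:
    """Sample minus the mean wild-type reference (delta fluorescence)."""
    if not wt_refs:
        raise ValueError("at least one WT reference is required")
    _check_grids([sample, *wt_refs])
    ref = np.mean([c.fluor_norm for c in wt_refs], axis=0)
    return DifferenceCurve(
        temps=sample.temps, delta=sample.fluor_norm - ref, sample_id=sample.sample_id
    )


def wt_envelope_sd(wt_refs: list[NormalizedCurve]) -> float:
    """Maximal per-temperature standard deviation across WT replicates."""
    if len(wt_refs) < 2:
        raise ValueError("need >= 2 WT reference replicates")
    _check_grids(wt_refs)
    stack = np.stack([c.fluor_norm for c in wt_refs])
    return float(np.max(np.std(stack, axis=0, ddof=1)))


def call_sample(
    sample: NormalizedCurve,
    wt_refs: list[NormalizedCurve],
    k: float = 5.0,
    min_threshold: float = 0.0,
) -> CallResult:
    """Call a sample variant when its melt profile departs from the WT
    envelope by more than k standard deviations anywhere on the grid."""
    sd = wt_envelope_sd(wt_refs)
    diff = difference_curve(sample, wt_refs)
    threshold = max(k * sd, min_threshold)
    score = diff.score
    return CallResult(
        sample_id=sample.sample_id,
        label="variant" if score > threshold else "wt_like",
        score=score,
        threshold=threshold,
        wt_envelope_sd=sd,
    )


def group_samples(
    diff_curves: list[DifferenceCurve],
    cut_distance: float = 0.15,
) -> list[AlleleGroup]:
    """Partition variant samples into putative allele classes.

    Complete-linkage agglomerative clustering on difference curves under
    correlation distance, cut so that within-group maximal distance stays
    below ``cut_distance``. Deterministic: input order ties are broken by
    sample_id. Alleles whose difference curves coincide within noise are
    inherently indistinguishable and will share a group (a warning is
    emitted when all samples merge into one group).
    """
    if not diff_curves:
        raise ValueError("need at least one variant sample to group")
    diff_curves = sorted(diff_curves, key=lambda d: d.sample_id)
    _check_grids(diff_curves)  # type: ignore[arg-type]
    if len(diff_curves) == 1:
        d = diff_curves[0]
        return [AlleleGroup("group_1", (d.sample_id,), d.delta.copy())]
    mat = np.stack([d.delta for d in diff_curves])
    dist = pdist(mat, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)  # constant-delta degenerate rows
    link = hierarchy.linkage(dist, method="complete")
    assignment = hierarchy.fcluster(link, t=cut_distance, criterion="distance")
    groups: list[AlleleGroup] = []
    for gi in sorted(set(assignment)):
        idx = [i for i, g in enumerate(assignment) if g == gi]
        members = tuple(diff_curves[i].sample_id for i in idx)
        consensus = mat[idx].mean(axis=0)
        groups.append(AlleleGroup(f"group_{len(groups) + 1}", members, consensus))
    if len(groups) == 1 and len(diff_curves) > 1:
        warnings.warn(
            "all variant samples grouped together; alleles with shape-"
            "identical melt profiles cannot be distinguished",
            stacklevel=2,
        )
    return groups


def plot_curves(
    curves: list[NormalizedCurve] | list[DifferenceCurve],
    path: str,
    ylabel: str = "normalized fluorescence",
) -> None:
    """Static overlay plot of normalized or difference curves (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        y = c.fluor_norm if isinstance(c, NormalizedCurve) else c.delta
        ax.plot(c.temps, y, lw=0.8, label=c.sample_id)
    ax.set_xlabel("temperature (\N{DEGREE SIGN}C)")
    ax.set_ylabel(ylabel)
    if len(curves) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# amplicon / primer design


@dataclass(frozen=True)
class PrimerParams:
    """Constraints for the short genotyping amplicon and its primers.

    Tm is estimated by the nearest-neighbor model under HRMA buffer
    conditions (200 nM primer, 50 mM monovalent, 2 mM Mg); the default
    68-72 C band suits a combined 70 C anneal/extend step.
    """

    amplicon_min: int = 90
    amplicon_max: int = 120
    primer_min: int = 18
    primer_max: int = 25
    tm_min: float = 68.0
    tm_max: float = 72.0
    primer_nM: float = 200.0
    na_mM: float = 50.0
    mg_mM: float = 2.0


@dataclass(frozen=True)
class Amplicon:
    seq: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    fwd_tm: float
    rev_tm: float

    @property
    def length(self) -> int:
        return self.end - self.start


def primer_tm(seq: str, params: PrimerParams = PrimerParams()) -> float:
    """Nearest-neighbor primer Tm with Owczarzy Mg2+ correction."""
    return float(
        mt.Tm_NN(
            seq,
            nn_table=mt.DNA_NN3,
            dnac1=params.primer_nM,
            dnac2=0,
            Na=params.na_mM,
            Mg=params.mg_mM,
            saltcorr=7,
        )
    )


def design_amplicon(
    region: DnaSequence,
    site: TalenSite,
    params: PrimerParams = PrimerParams(),
) -> Amplicon:
    """Design a 90-120 bp amplicon containing the full TALEN site span.

    Primers flank the site (they never overlap it, so target-site indels
    cannot destroy a primer binding site). The search is deterministic:
    shortest feasible amplicon first, then leftmost placement, then
    shortest primers within the Tm band.
    """
    s = region.seq
    span_start, span_end = site.span
    span_len = span_end - span_start
    if span_len + 2 * params.primer_min > params.amplicon_max:
        raise ValueError(
            f"site span ({span_len} bp) plus two {params.primer_min} bp primers "
            f"exceeds the {params.amplicon_max} bp amplicon ceiling"
        )
    if span_start < params.primer_min or len(s) - span_end < params.primer_min:
        raise ValueError(
            f"flanks too short: need >= {params.primer_min} bp on each side "
            f"of the site span"
        )
    fwd_cache: dict[int, tuple[str, float] | None] = {}
    rev_cache: dict[int, tuple[str, float] | None] = {}
    lo = max(params.amplicon_min, span_len + 2 * params.primer_min)
    for length in range(lo, params.amplicon_max + 1):
        # amplicon [a0, a0+length) must contain the span with primer room
        a0_min = max(0, span_end + params.primer_min - length)
        a0_max = min(span_start - params.primer_min, len(s) - length)
        for a0 in range(a0_min, a0_max + 1):
            if a0 not in fwd_cache:
                fwd_cache[a0] = _pick_primer(s[a0:span_start], params, reverse=False)
            fwd = fwd_cache[a0]
            if fwd is None:
                continue
            e0 = a0 + length
            if e0 not in rev_cache:
                rev_cache[e0] = _pick_primer(s[span_end:e0], params, reverse=True)
            rev = rev_cache[e0]
            if rev is None:
                continue
            return Amplicon(
                seq=s[a0:e0],
                start=a0,
                end=e0,
                fwd_primer=fwd[0],
                rev_primer=rev[0],
                fwd_tm=fwd[1],
                rev_tm=rev[1],
            )
    raise ValueError(
        "no amplicon satisfies the constraints: no flanking primer pair with "
        f"Tm in [{params.tm_min}, {params.tm_max}] C and length in "
        f"[{params.primer_min}, {params.primer_max}] was found"
    )


def _pick_primer(
    flank: str, params: PrimerParams, reverse: bool
) -> tuple[str, float] | None:
    """Shortest primer at the amplicon end of ``flank`` within the Tm band.

    For the forward primer the flank is the region from the amplicon start
    to the site; the primer is its prefix. For the reverse primer the
    flank runs from the site to the amplicon end; the primer is the
    reverse complement of its suffix.
    """
    for plen in range(params.primer_min, params.primer_max + 1):
        if plen > len(flank):
            return None
        primer = revcomp(flank[-plen:]) if reverse else flank[:plen]
        tm = primer_tm(primer, params)
        if params.tm_min <= tm <= params.tm_max:
            return primer, tm
    return None
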