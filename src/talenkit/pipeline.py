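"""End-to-end orchestration: design -> amplicon -> cohort simulation ->
melt simulation -> HRMA calling -> grouping -> summary.

A run is fully determined by its configuration and seed; every stage
artifact is persisted so each reported statistic can be recomputed from
the files alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .assembly import build_construct_map, construct_map_to_gff3, plan_golden_gate
from .design import DesignParams, TalenSite, design_rvd_arrays
from .fixtures import make_target_region
from .hrma import (
    CallResult,
    NormalizedCurve,
    call_sample,
    difference_curve,
    group_samples,
    normalize_curve,
)
from .melt import AllelePool, MeltCurve, pool_melt_curve
from .mosaic import (
    WT_LABEL,
    F1Individual,
    FounderGermline,
    SimParams,
    sample_germline,
    simulate_embryo,
    simulate_f1,
    summarize_transmission,
)
from .report import CountRow, contingency_table, percent, transmission_table
from .thermo import ThermoParams


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run (serializable to YAML)."""

    seed: int = 7
    outdir: str | None = None
    dose_pg: float = 100.0
    n_founders: int = 12
    n_f1: int = 24
    n_wt_refs: int = 8
    n_progenitors: int = 20
    noise_sd: float = 0.004
    call_k: float = 5.0
    cut_distance: float = 0.15
    region_length: int = 400
    n_divisions: int = 10

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineReport:
    config: RunConfig
    site: TalenSite
    amplicon_seq: str
    founders: list[tuple[FounderGermline, list[F1Individual]]]
    calls: pd.DataFrame
    groups_per_founder: dict[str, int]
    summary: pd.DataFrame
    truth_summary: pd.DataFrame


def simulate_sample_curves(
    pools: list[tuple[str, AllelePool]],
    wt_amplicon: str,
    n_wt_refs: int,
    noise_sd: float,
    rng: np.random.Generator,
    thermo: ThermoParams | None = None,
) -> tuple[list[MeltCurve], list[MeltCurve]]:
    """Noisy WT reference curves plus one curve per (sample_id, pool)."""
    thermo = thermo or ThermoParams()
    wt_pool = AllelePool(((WT_LABEL, wt_amplicon),), (1.0,))
    refs = [
        pool_melt_curve(wt_pool, thermo, noise_sd=noise_sd, rng=rng,
                        sample_id=f"WT_ref_{i + 1}")
        for i in range(n_wt_refs)
    ]
    samples = [
        pool_melt_curve(pool, thermo, noise_sd=noise_sd, rng=rng, sample_id=sid)
        for sid, pool in pools
    ]
    return refs, samples


def call_curves(
    refs: list[MeltCurve],
    samples: list[MeltCurve],
    call_k: float = 5.0,
) -> tuple[list[NormalizedCurve], list[NormalizedCurve], list[CallResult]]:
    norm_refs = [normalize_curve(c) for c in refs]
    norm_samples = [normalize_curve(c) for c in samples]
    calls = [call_sample(s, norm_refs, k=call_k) for s in norm_samples]
    return norm_refs, norm_samples, calls


def run_end_to_end(config: RunConfig) -> PipelineReport:
    """Execute the full pipeline on a synthetic target gene.

    Designs a TALEN pair and genotyping amplicon for a generated target
    region, simulates a founder cohort at the configured dose, renders
    each F1's melt curve, calls and groups variants, and assembles the
    transmission summary. Identical config + seed give identical outputs.
    """
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_region = np.random.default_rng(streams[0])
    rng_cohort = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])

    # --- design
    region, site, amp = make_target_region(rng_region, length=config.region_length)
    left_arr, right_arr = design_rvd_arrays(site, DesignParams())
    plans = (plan_golden_gate(left_arr), plan_golden_gate(right_arr))
    site_in_amp = site.shifted(-amp.start)
    wt_amplicon = amp.seq

    # --- cohort simulation
    sim = SimParams(dose_pg=config.dose_pg, n_divisions=config.n_divisions)
    founders: list[tuple[FounderGermline, list[F1Individual]]] = []
    pools: list[tuple[str, AllelePool]] = []
    for fi in range(config.n_founders):
        fid = f"G0_{fi + 1}"
        embryo = simulate_embryo(site_in_amp, wt_amplicon, sim, rng_cohort)
        germline = sample_germline(embryo, config.n_progenitors, rng_cohort)
        f1s = simulate_f1(germline, wt_amplicon, config.n_f1, rng_cohort, founder_id=fid)
        founders.append((germline, f1s))
        pools.extend((f"{fid}_F1_{f.index + 1}", f.pool) for f in f1s)

    # --- melt + calling
    refs, samples = simulate_sample_curves(
        pools, wt_amplicon, config.n_wt_refs, config.noise_sd, rng_noise
    )
    norm_refs, norm_samples, calls = call_curves(refs, samples, config.call_k)

    call_df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "founder": c.sample_id.rsplit("_F1_", 1)[0],
                "label": c.label,
                "score": c.score,
                "threshold": c.threshold,
            }
            for c in calls
        ]
    )

    # --- grouping per founder
    groups_per_founder: dict[str, int] = {}
    by_id = {s.sample_id: s for s in norm_samples}
    for fi in range(config.n_founders):
        fid = f"G0_{fi + 1}"
        variant_ids = call_df.loc[
            (call_df["founder"] == fid) & (call_df["label"] == "variant"),
            "sample_id",
        ].tolist()
        if not variant_ids:
            groups_per_founder[fid] = 0
            continue
        diffs = [difference_curve(by_id[sid], norm_refs) for sid in variant_ids]
        groups_per_founder[fid] = len(group_samples(diffs, config.cut_distance))

    # --- summaries
    truth = summarize_transmission(founders)
    transmitting = [g for g, _ in founders if g.transmits]
    truth_summary = transmission_table(
        locus="synthetic_target",
        n_founders=truth.n_founders,
        n_transmitting=truth.n_transmitting,
        mean_germline_fraction=(
            float(np.mean([g.mutant_fraction for g in transmitting]))
            if transmitting
            else None
        ),
        mean_distinct_alleles=truth.mean_distinct_alleles,
    )

    called_transmitting = sum(
        1
        for fi in range(config.n_founders)
        if (call_df["founder"] == f"G0_{fi + 1}").any()
        and (
            call_df.loc[call_df["founder"] == f"G0_{fi + 1}", "label"] == "variant"
        ).any()
    )
    n_variant = int((call_df["label"] == "variant").sum())
    summary = contingency_table(
        [
            CountRow("F1 carriers (called)", n_variant, len(call_df)),
            CountRow(
                "founders transmitting (called)",
                called_transmitting,
                config.n_founders,
            ),
        ]
    )

    report = PipelineReport(
        config=config,
        site=site,
        amplicon_seq=wt_amplicon,
        founders=founders,
        calls=call_df,
        groups_per_founder=groups_per_founder,
        summary=summary,
        truth_summary=truth_summary,
    )

    if config.outdir:
        _persist(report, region, site, (left_arr, right_arr), plans, amp,
                 refs + samples)
    return report


def _persist(report, region, site, arrays, plans, amp, curves) -> None:
    out = Path(report.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    from .sequences import write_fasta

    write_fasta([region], out / "region.fa")
    tio.write_sites_json([site], out / "site.json", arrays=[arrays])
    for plan in plans:
        cmap = build_construct_map(plan)
        (out / f"construct_{plan.side.lower()}.gff3").write_text(
            construct_map_to_gff3(cmap)
        )
    (out / "amplicon.json").write_text(
        json.dumps(
            {
                "schema_version": tio.SCHEMA_VERSION,
                "start": amp.start,
                "end": amp.end,
                "fwd_primer": amp.fwd_primer,
                "rev_primer": amp.rev_primer,
                "fwd_tm": amp.fwd_tm,
                "rev_tm": amp.rev_tm,
                "seq": amp.seq,
            },
            indent=2,
        )
        + "\n"
    )
    tio.write_curves_tsv(curves, out / "curves.tsv")
    report.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    truth_records = [
        {
            "founder": f1s[0].founder_id if f1s else "",
            "germline_freqs": g.freqs,
            "distinct_alleles": g.distinct_alleles,
            "f1_carriers": sum(1 for f in f1s if f.carrier),
            "n_f1": len(f1s),
        }
        for g, f1s in report.founders
    ]
    tio.write_jsonl(truth_records, out / "cohort_truth.jsonl")
    report.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    report.truth_summary.to_csv(out / "transmission.tsv", sep="\t", index=False)
    report.config.to_yaml(out / "config.yaml")


def somatic_screen(
    site_in_amp: TalenSite,
    wt_amplicon: str,
    dose_pg: float,
    n_embryos: int,
    rng: np.random.Generator,
    noise_sd: float = 0.004,
    n_wt_refs: int = 8,
    call_k: float = 5.0,
    n_divisions: int = 10,
) -> pd.DataFrame:
    """HRMA screen of injected embryos at one dose.

    Simulates mosaic embryos, melts each embryo's (truncated) somatic
    allele pool and calls it against WT references. Returns per-embryo
    truth and call labels.
    """
    sim = SimParams(dose_pg=dose_pg, n_divisions=n_divisions)
    pools = []
    truths = []
    for i in range(n_embryos):
        embryo = simulate_embryo(site_in_amp, wt_amplicon, sim, rng)
        alleles = {WT_LABEL: wt_amplicon}
        for lab, a in embryo.alleles.items():
            alleles[lab] = a.apply(wt_amplicon)
        freqs = {lab: embryo.freqs.get(lab, 0.0) for lab in alleles}
        pool = AllelePool.from_dict(alleles, freqs).truncated()
        pools.append((f"embryo_{i + 1}", pool))
        truths.append(embryo.mutant_fraction)
    refs, samples = simulate_sample_curves(
        pools, wt_amplicon, n_wt_refs, noise_sd, rng
    )
    _, _, calls = call_curves(refs, samples, call_k)
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "dose_pg": dose_pg,
            "mutant_fraction": truths,
            "label": [c.label for c in calls],
            "score": [c.score for c in calls],
        }
    )
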