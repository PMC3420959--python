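# talenkit

An in-silico workbench for TALEN-based targeted mutagenesis with HRMA
readout. It is aimed at genome engineers and zebrafish (or other model
organism) labs who design TALEN pairs against a locus, plan their Golden
Gate assembly, check homologs for off-target cleavage risk, and genotype
mosaic animals by High Resolution Melt Analysis — and at method
developers who want a fully generative, seedable model of that whole
workflow for testing analysis code.

## What it models

**Design.** A TALEN pair is an obligate FokI-DD/RR heterodimer whose
monomers bind opposing strands: each half-target is a 5' T (contacted by
the TALE N-terminus) plus one base per RVD repeat (cipher NI=A, HD=C,
NN=G, NG=T), with the configuration `≥17 bp – N_14–17 – ≥17 bp`
(16–21 repeats per monomer, 14–17 bp spacer). `scan_target_sites`
enumerates every such site exhaustively; `scan_off_targets` Hamming-scans
arbitrary sequence for loci within a per-half mismatch budget and grades
cleavage risk (≤2 total mismatches: cleavable; ~7: not).

**Assembly.** `plan_golden_gate` partitions an n-repeat array into the
standard two-round recipe — intermediate arrays of repeats 1–10 and
11..n−1, then a second round joining both arrays, the n-th repeat and
the destination backbone (Left→pCS2TAL3DD/Flag, Right→pCS2TAL3RR/HA) —
and emits schematic construct maps as GFF3.

**Melt model.** Reannealed amplicons from an allele pool with
frequencies p_i form duplex species by random pairing (fraction p_i·p_j;
a heterozygote gives 2 homo- + 2 heteroduplexes at 0.25 each). Each
species gets nearest-neighbor thermodynamics (unified stacks, published
mismatch corrections, +0.3 kcal/mol per looped-out base for indel
heteroduplexes), Tm = ΔH/(ΔS + R·ln(C_T/4)), and melts as a two-state
transition θ(T) = 1/(1+exp((ΔH/R)(1/T − 1/Tm))); the fluorescence curve
is the fraction-weighted sum.

**HRMA calling.** Curves are normalized (plateau→1, baseline→0),
differenced against WT reference replicates, called variant when
max|Δfluorescence| > k·(WT envelope sd) (k = 5), and grouped into allele
classes by complete-linkage clustering under correlation distance.
`design_amplicon` finds the 90–120 bp genotyping amplicon with
non-site-overlapping primers (Tm 68–72 °C).

**Mosaic simulator.** A branching cell-division model of an injected
embryo: every still-WT locus copy is cut per division with a
dose-dependent (Hill) probability and repaired by NHEJ into an indel
(mostly 3–20 bp, rarely >30 bp), producing mosaic genome pools;
germ lines subsample 20 progenitor genomes; F1 of founder × WT crosses
are 50/50 heterozygote pools feeding straight back into the melt model.

See `docs/methods.md` for assumptions, calibrations and limitations.

## Worked example

```python
from talenkit.pipeline import RunConfig, run_end_to_end

report = run_end_to_end(RunConfig(seed=7, n_founders=12, n_f1=24))
print(report.truth_summary.to_string(index=False))
print(report.summary.to_string(index=False))
print("allele groups per founder:", report.groups_per_founder)
```

prints

```
           locus  founders  transmitting  pct_transmitting  mean_germline_mutant_pct  mean_alleles_per_germline
synthetic_target        12            12             100.0                      50.8                       6.67
                     condition   n  positive  percent
          F1 carriers (called) 288       160     55.6
founders transmitting (called)  12        12    100.0
allele groups per founder: {'G0_1': 2, 'G0_2': 3, 'G0_3': 4, 'G0_4': 2, ...}
```

Reading: at the default 100 pg dose all 12 simulated founders carry
germline mutations (truth), their germ lines are on average half mutant,
and HRMA calling of 288 F1 melt curves finds 55.6 % carriers. The
germ lines truly carry ~6.7 distinct alleles each, but only 2–4 distinct
melt-curve groups are recoverable per founder — melt-pattern counting
is a lower bound on allele diversity, as at the bench.

The same pipeline is scriptable from the shell:

```bash
talenkit fixtures generate --seed 1 --homolog-mm 3,4 --homolog-mm 2,0 --outdir fx
talenkit design scan --fasta fx/genes.fa --spacer 14:17 --rvd 16:21
talenkit design offtarget --fasta fx/genes.fa --site-json sites.synthetic_gene.json --max-mm 4
talenkit melt simulate --pool fx/pool_1_in_50.json --noise 0.004 --seed 7 --out curves.tsv
talenkit e2e --seed 7 --outdir e2e_out
```

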