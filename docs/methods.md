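# Methods

talenkit models the complete in-silico workflow of TALEN-based targeted
mutagenesis with HRMA genotyping: target-site design, Golden Gate
assembly planning, duplex melt thermodynamics, melt-curve calling and
grouping, and a generative model of mosaic mutagenesis in injected
embryos. This note records the models, their assumptions, the defaults
that matter, and the known limitations.

## Target-site model

A TALEN pair binds a site laid out on the + strand as

    T  L1..L(nL)   N(14-17)   R'(nR)..R'1  A
    ^--Left half-target--^spacer^--Right half-target--^

Each monomer's half-target is a 5' thymine contacted by the TALE
N-terminal domain plus one base per RVD repeat module; the Right monomer
binds the − strand, so on the + strand its half-site reads as a reverse
complement ending in A. Defaults: spacer 14–17 bp, 16–21 repeats per
monomer (configurable up to the 31-repeat limit of the assembly kit),
giving the `≥17 – N_14–17 – ≥17` configuration when the anchor thymine is
counted. The RVD cipher defaults to NI=A, HD=C, NN=G, NG=T and is
configurable (e.g. NK for G).

Scanning is exhaustive over all (left length, spacer, right length)
combinations at every anchor pair. A single pair of anchors usually
admits several decompositions (a spacer base can always be re-labelled a
recognized base); one site per anchor pair is reported under a canonical
decomposition — most balanced half-sites first, then shortest spacer,
then longest left half. Ranking follows the design guidelines: sites
whose half-sites end in a recognized T rank first (a soft kit
convention, toggleable via `restrict_options`), then 5'-most position,
then shorter span. Coordinates are 0-based half-open on the + strand,
BED-compatible.

Off-target assessment is an exhaustive per-half-site Hamming scan of
both orientations of every record, not a seeded alignment heuristic:
adequate and exact at the scale of genes and homolog families this
package addresses. Mismatches are counted over RVD-recognized bases
only; the two anchor bases can be included with `include_anchor=True`
(whether tolerated off-target sites must retain the anchor T is not
established, so the default is permissive). Risk classes are calibrated
to observed homolog cleavage — sites differing at ≤2 of ~36 recognized
positions are cleaved efficiently while ~6–7 differences abolish
cleavage: `high` when total mismatches ≤ 2, `low` when ≤ 4, `none`
otherwise. Thresholds are configurable.

## Golden Gate planning

Arrays of n repeats are partitioned into the standard two-round recipe:
round 1 builds intermediate arrays of repeats 1–10 and 11..n−1; round 2
joins both arrays, the n-th repeat module and the destination backbone.
Left monomers are always routed to pCS2TAL3DD (Flag tag, FokI DD) and
Right monomers to pCS2TAL3RR (HA tag, FokI RR), making the pair an
obligate heterodimer. The planner accepts 12 ≤ n ≤ 31 and warns outside
the routine 16–21 range. Construct maps are schematic: feature order is
fixed (promoter, NLS, tag, TAL-N' 136 aa, repeat block, TAL-C' 63 aa,
FokI variant, SV40 pA, NotI), the repeat block is annotated at a default
102 bp per repeat, and vector sequences are not bundled — features
without derivable extents are marked symbolic in the GFF3 output.

## Duplex thermodynamics and melt curves

Reannealing a denatured amplicon pool with allele frequencies p_i forms
duplex species by random pairing: species (i, j) has abundance p_i·p_j,
counting the two strand orientations of a heteroduplex separately, so a
50/50 heterozygote yields two homoduplexes (0.25 each) and two
heteroduplexes (0.25 each).

Each species' van't Hoff parameters are accumulated over its alignment
(edlib global alignment of the two + strands; a column (x, y) is a
Watson–Crick pair iff x = y):

* matched dinucleotide steps use the unified nearest-neighbor stack
  parameters, internal single mismatches the published mismatch stacks
  (both tables shipped with Biopython's `MeltingTemp`);
* bases looped out by an indel contribute no stacking and incur a
  destabilization of +0.3 kcal/mol free energy per base, applied as a
  ΔS adjustment at 310.15 K. The value is a modeling choice calibrated
  qualitatively: an 18 bp-deletion heteroduplex must melt visibly
  (several °C) before its homoduplex;
* Tm = ΔH / (ΔS + R ln(C_T/4)) with default total strand concentration
  C_T = 0.25 µM. The monovalent-salt entropy correction is off by
  default: relative curve shape, not absolute Tm accuracy, is the goal.

Each species melts as a two-state transition,
θ(T) = 1/(1 + exp((ΔH/R)(1/T − 1/Tm))), and the dye signal is the
abundance-weighted sum of species helicities, on a default 65–95 °C grid
at 0.1 °C steps, plus optional Gaussian noise. Two-state melting ignores
domain-wise (staggered) melting; for 90–120 bp amplicons this is an
acceptable simplification but it will understate the structure of melt
curves for longer products.

Instrument noise is modelled as i.i.d. Gaussian on the fluorescence
signal with sd 0.004 (normalized units). With this calibration the
simulated dilution series detects a mutant haploid fraction of 1/50
reliably and 1/70 marginally, matching the sensitivity window of the
instrument-based assay this simulates; the calibration is a noise-model
choice, and real instruments have correlated, temperature-dependent
noise this model does not attempt to reproduce.

## HRMA analysis

Normalization rescales each curve affinely so the pre-melt plateau mean
maps to 1 and the post-melt baseline mean to 0 (plateau = lowest/highest
10 % of grid temperatures); the operation is idempotent. Difference
curves subtract the mean of wild-type reference replicates. Calling is
deliberately transparent (the instrument vendor's algorithm is
proprietary): a sample is `variant` when max_T |Δfluorescence| exceeds
k × the WT replicate envelope (max per-temperature sd), default k = 5
with ≥ 2 replicates required. Curve overlay/temperature shifting, common
in some HRMA software, is not applied.

Variant samples are grouped into putative allele classes by
complete-linkage agglomerative clustering of difference curves under
correlation distance, cut at 0.15 so within-group maximal distance stays
below the cut; ties are broken by sample id for determinism. Alleles
whose difference curves coincide within noise are inherently
indistinguishable — the grouper warns when everything merges into one
group. Group counts therefore estimate a lower bound on transmitted
allele diversity, exactly as melt-pattern counting does at the bench.

Amplicon design searches deterministically (shortest feasible amplicon,
leftmost placement, shortest primers) for a 90–120 bp product strictly
containing the full site span, with 18–25 nt primers that never overlap
the site (so target-site indels cannot destroy a primer binding site)
and nearest-neighbor Tm in 68–72 °C under HRMA buffer conditions
(200 nM primer, 50 mM monovalent, 2 mM Mg2+, Owczarzy correction). This
is a genotyping-support utility, not a primer-design suite: no dimer,
hairpin or uniqueness checks.

## Mosaic mutagenesis model

Injected embryos are modelled as a branching cell-division process over
n_divisions = 10 cleavage divisions (1024 cells). Each cell carries two
copies of the target locus; at fertilisation and after every division
each still-wild-type copy is cut with per-division probability q and
repaired into an indel allele. Indel-bearing sites are never re-cut
(binding-site disruption; small spacer-only indels could in principle be
re-cleavable — a noted simplification). Dose dependence is a saturating
Hill curve q(d) = q_max·d/(K + d) with q_max = 0.08 and K = 20 pg — the
functional form is a free modeling choice; the parameters were fixed so
the 4/20/100 pg ladder orders mean mutation load correctly and 100 pg
drives roughly half of all genomes mutant.

Repair products are drawn centered uniformly in the spacer: 80 % of
events are deletions of 3 + Geometric(0.2) bp (rarely, with probability
0.02, from a uniform 31–60 bp tail) with a small residual insertion;
20 % are net insertions of Geometric(0.25) bp. Under these defaults
most absolute net changes fall in 3–20 bp with a rare >30 bp tail,
the observed NHEJ spectrum at TALEN cut sites. Sequence-context
dependence of NHEJ (microhomology) is not modelled.

Germ lines sample 20 progenitor genomes multinomially from the embryo
pool (the true number of zebrafish germline progenitors contributing to
the gamete pool is not well determined; 20 reproduces strongly mosaic
germ lines transmitting any given allele through well under half of
gametes). Each F1 of a founder × WT cross draws one gamete allele at
germline frequencies plus one WT allele, yielding a 50/50 heterozygous
pool — fed directly to the melt simulator.

For melt simulation of somatic (embryo) pools, alleles below a 1 %
frequency floor are dropped and the pool renormalized (at most 16
alleles kept): a high-dose embryo carries hundreds of distinct alleles,
almost all individually far below the HRMA detection limit, and duplex
enumeration is quadratic in pool size. The dropped mass slightly
understates total heteroduplex signal; at the default dose the retained
alleles carry the overwhelming majority of the mutant fraction.

## Synthetic data

The generators define the conditions the package is tested under:

* **Design genes** guarantee an exact site count by construction:
  filler is drawn from {C, G} so the planted anchors are provably the
  only T/A pair at a site-compatible distance; the scanner re-verifies
  the guarantee. Homologs substitute C↔G at a controlled number of
  recognized positions per half-site, preserving the guarantee.
* **Target regions** for the melt/HRMA pipeline are realistic-composition
  sequences (AT-richer site core, GC-richer flanks) redrawn until the
  amplicon design succeeds *and* the amplicon homoduplex melts at
  80–91 °C, inside the 65–95 °C acquisition window — feasibility by
  rejection, so downstream code never sees an infeasible region.
* **Dilution pools** mix WT and an 18 bp-deletion allele at exact mutant
  haploid fractions (1/10 … 1/70 by default).

What passing tests on these inputs do not show: performance on real
genomic sequence with repeats and polymorphic backgrounds, real
instrument noise (correlated, drifting), PCR amplification bias between
alleles, or deletions large enough to remove a primer site (which the
bench assay also misses).

## Numerical choices

* Temperature grid 65–95 °C, 0.1 °C; helicity exponent clipped at ±500
  to avoid overflow at extreme ΔH.
* Thermodynamics are cached per strand pair (LRU, 65k entries).
* Normalization rejects constant curves; grids must match exactly across
  curves being compared.
* Degenerate alignments (normalized edit distance > 0.8) are rejected as
  "no alignable core" — the pool abstraction is for variants of one
  amplicon, not arbitrary sequences.
* All randomness flows from numpy `SeedSequence` spawning; a pipeline
  run is byte-reproducible from its config + seed.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen
to exercise every code path with tight statistics: 10 kb scans against
brute-force oracles at 2 kb, 100 amplicon designs, 20-replicate dilution
series, cohorts of up to 57 founders × 24 F1, and a 500-F1 carrier
recovery. All are package defaults, adjustable through the respective
parameter objects.
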