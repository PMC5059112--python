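# Methods

`pathscreen` simulates and deconvolves positive-selection pooled screens in
which barcoded pathway-activating constructs compete under drug treatment.
This note records the model, its assumptions, the parameters that matter,
and the design choices made where the design was genuinely open.

## The library manifest

The packaged library couples 36 activating cDNAs — engineered point mutants,
myristoylation-tagged kinases, truncations, and fusion constructs — to 17
canonical oncogenic signaling pathways (Ras-MAPK, PI3K-AKT-mTOR, NF-κB,
JAK-STAT, Wnt/β-catenin, JNK, ERK5, Notch, p38, Hedgehog, TGF-β, the BCL-2
apoptosis family, estrogen receptor, androgen receptor, Hippo, p53, Ral).
Three mitochondrial/death-receptor/pan-apoptosis groupings are collapsed
into the single pathway "Apoptosis (BCL-2 family)"; the original grouping is
preserved in each record's `variant_note`.  Two inert constructs (HcRed,
luciferase) are carried as negative controls and define the enrichment
baseline; constitutively active MEK1 (MEK1-DD) is carried as a positive
control for MAPK-pathway drug screens and is excluded from the baseline.

Real 4-nt barcode sequences for such libraries are not public, so the
packaged manifest carries synthetic barcodes from `assign_barcodes`
(`min_hamming=2, seed=0`).  For distance 2 the candidate pool is the
64-word quaternary parity-check code (digit sum ≡ 0 mod 4), which is the
largest 4-mer code of minimum distance 2; the assignment is a seeded draw
from that pool.  Distance ≥ 2 guarantees that no single substitution turns
one valid barcode into another, which in turn justifies exact-only barcode
matching during demultiplexing: correcting a distance-1 neighbor would be
ambiguous by construction.

## Screen simulator

The simulator emulates one screen as a chain of explicit stochastic steps,
all driven by per-operation sub-seeds derived from a single scenario seed
(`SeedSequence([seed, crc32(tag)])`), so any arm or sample can be
regenerated independently and output files are byte-identical across runs.

**Library pooling.** Titering individual viruses yields only approximately
equal representation.  Construct weights in the pool are i.i.d. lognormal
with coefficient of variation `library_cv` (default 0.3, a typical spread
for pooled libraries).  Without this heterogeneity, two sequencing
replicates of one pool would share no signal variance and their
concordance r² would collapse toward 0; with it, replicate r² ≈ 0.99 at
depth 10⁵, matching the high concordance such assays report.  Vehicle
normalization cancels the pool spread, so enrichment results do not depend
on `library_cv`.

**Infection.** Each of `n_cells` (default 5×10⁵) cells receives
k ~ Poisson(`moi`) integrations (default MOI 0.3); k = 0 cells are dropped,
standing in for puromycin selection.  Each integration draws a construct
from the pool weights.  At MOI 0.3 the surviving pool is
λe^(−λ)/(1−e^(−λ)) ≈ 85.7% single-construct cells.  Multi-integration cells
are kept as multisets of constructs and contribute one sequencing template
per integration.

**Arms and growth.** The infected pool is split multinomially into seven
equal populations: a t₀ pool plus a drug and a paired vehicle well at each
of three doses.  The default dose ladder is 150 nM / 750 nM / 1.5 μM at
nominal growth inhibition (GI) 0.2 / 0.5 / 0.8.  Growth is discretized
daily: genotype g at dose d multiplies by
2^(`baseline_growth` · (1 − GI(d) · min_c ρ(c, d))), where ρ ∈ [0, 1] is the
planted resistance factor of construct c at dose d (1 = fully sensitive,
0 = fully resistant) and the minimum over carried constructs encodes a
dominant-effect assumption for multiplets.  Vehicle arms have GI = 0.
Expected counts are realized by stochastic rounding; whenever an arm
exceeds `capacity` (default 10⁶ cells, a confluent well) it is passaged by
binomial thinning at `split_fraction` (default 1:10).  Default duration is
21 days.  PCR amplification bias beyond multinomial sampling, clonal
evolution, pharmacokinetics, and cell death below zero net growth are not
modeled.

**Sequencing.** Reads are drawn multinomially over templates at
`read_depth` per sample (default 10⁵).  Each read is the fixed 27-nt
layout — 4-nt construct barcode, 17-nt linker (a Kozak-style context ending
in the ORF's ATG; positions [4, 21)), 6-nt sample index ([21, 27)) — with
i.i.d. substitutions at `error_rate` (default 10⁻³) and constant Phred+33
qualities.  Indels and quality-dependent errors are not modeled; at 27 nt
with exact-position parsing, substitutions are the relevant error mode.
Sample indices are generated at pairwise Hamming distance ≥ 3, so a
single-substitution index error is unambiguously correctable when
mismatch-tolerant index matching is enabled.  Each population is sequenced
as two technical replicates by default, multiplexed into one FASTQ.

## Demultiplexing and counting

Reads shorter than 27 nt are rejected (`bad_length`); longer reads are
truncated to 27 (sequencer padding).  The index must match the sample sheet
exactly by default (`max_index_mm=0`); with a positive budget, the unique
best match within the budget is taken and ties are rejected (`bad_index`).
The linker is accepted within `max_linker_mm=2` substitutions
(`bad_linker`), and the barcode must match the manifest exactly
(`bad_barcode`).  Rejections are tallied per sample (or under
`unknown_index`) and the conservation identity assigned + rejected = total
is maintained per file.  Quality scores are ignored.  Counting streams
records through Biopython's FASTQ iterator, so memory is independent of
file size and read order never affects the result.

## Enrichment statistic

For sample s, construct c: fractional representation
f(s, c) = count(s, c) / Σ_c′ count(s, c′).  Zero-read samples are excluded
with a warning.  Fractions are averaged arithmetically over technical
replicates within each biological replicate, then across biological
replicates; a geometric-mean alternative is available behind a flag
(`--geometric-mean`) for sensitivity analysis but is off by default, since
the assay description implies the plain mean.  The averaged
vehicle wells form a single vehicle reference, and per-dose enrichment is

    e(d, c) = (f_drug(d, c) + α) / (f_vehicle(c) + α),  α = 10⁻⁶.

The fixed small pseudocount keeps ratios finite after construct dropout
without distorting abundant constructs (typical fractions are ≈ 1/39 ≈
0.026 ≫ α).  Enrichment is scale-free: multiplying a sample's counts by a
constant changes nothing.  Replicate concordance is reported as the squared
Pearson correlation of raw (not log) fractions.

## Hit calling

The per-dose control baseline is the mean enrichment of the negative
controls.  A construct passes dose d when both

1. it is enriched in drug versus vehicle: e(d, c) > 1, and
2. its relative enrichment e(d, c) / baseline(d) is strictly greater than
   1.5 (>50% above controls).

A pathway is called when at least one of its activating constructs passes
at ≥ 2 doses (the same construct at both doses; a pooled-across-constructs
reading is available behind `per_construct=False` for sensitivity
analysis).  Controls never support hits; missing values fail their dose.
Condition 1 matters in strongly selective arms: when every sensitive
construct — controls included — is driven extinct in a drug arm, the ratio
in condition 2 degenerates to a ratio of vehicle fractions and can exceed
1.5 by pool-composition noise alone; requiring drug-versus-vehicle
enrichment first confines calls to constructs with actual positive
selection evidence.  The hit set is monotone: raising the threshold or the
dose requirement never adds hits.

## What the synthetic screens do and do not show

The planted-resistance preset plants ρ = 0.1 at all doses for one construct
in each of five pathways; at default scale the pipeline recovers exactly
that pathway set in essentially every seeded run, and the matching null
preset (all ρ = 1) yields no hits.  These are parameter-recovery properties
of the simulator's own generative model: they show the deconvolution is
unbiased and the hit rule is calibrated under Poisson infection,
multinomial sampling, and drift — not that any particular biological screen
result is reproduced.  Real screens add PCR bias, fitness heterogeneity
among cells carrying the same construct, construct-silencing, and
off-target construct activity, none of which the generator emulates.

## Problem sizes and numerical choices

Simulation-based checks use the scenario defaults (5×10⁵ cells, depth 10⁵
per sample, 14 samples, 21 days); repeated end-to-end rates use 12–20
seeded runs.  Stochastic rounding keeps expected growth exact at any
population size; subdivision and passaging use multinomial/binomial draws
so cell counts stay integral.  Degenerate inputs are rejected early
(empty populations, zero depth, unknown dose labels, zero-length
manifests), and zero-variance replicate vectors make concordance undefined
(reported as NaN) rather than raising.
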