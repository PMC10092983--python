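# Methods

`ddmrd` implements the computational side of a tumor-informed liquid-biopsy
workflow for measurable residual disease (MRD) detection in pediatric brain
tumors: patient-specific droplet digital PCR (ddPCR) assays are designed
against somatic variants found by tumor/normal whole-genome sequencing, and
cell-free DNA (cfDNA) from cerebrospinal fluid or plasma is then quantified
with those assays. This note records the models, conventions and numerical
choices the package is built on.

## Droplet partitioning model

A ddPCR well partitions a reaction of volume `V_r` (default 22 µL) into
`n` droplets (default 16,000 accepted droplets) of volume `V_d` (default
0.85 nL, the QX200 nominal). Template molecules at concentration `c`
copies/µL of reaction distribute into droplets approximately independently,
so a droplet contains at least one molecule with probability

```
p = 1 − exp(−c · V_d)
```

and the per-droplet occupancy is `λ = c · V_d`. Different templates (each
multiplexed target, plus the reference locus) occupy droplets
independently. The simulator draws per-template occupancy as Bernoulli(`p`)
per droplet, which makes the positive count for any single template exactly
Binomial(`n`, `p`) — the property the quantification inverts.

## Fluorescence amplitude model

Positive droplets form Gaussian clusters in a two-channel amplitude space:
FAM (targets, amplitude-multiplexed into one band per target) and HEX
(reference). The instrument's amplitude scale is arbitrary and
instrument-dependent, so the synthetic convention is: negative cluster at
~1000 a.u. (SD 90), target bands spaced between 3000 and 7000 a.u. (SD
120), reference HEX band at 4500 a.u. Every band clears the negative
cluster and its neighbours by at least 5 SD; the model constructor rejects
geometries that do not, mirroring the practice of discarding assays with
overlapping fluorescence.

Droplets co-occupied by several targets emit the sum of the band offsets
and therefore land above every single-target band; classification counts
them as `unassigned` rather than attributing them to one target. This is a
conservative convention: it loses a fraction `≈ p_other` of counts per
target, negligible at the MRD-relevant occupancies (`λ ≪ 1`) the decision
rules operate at.

Two imperfections are modelled, both **off by default** (the workflow's
operating characteristics — LoD, FPR — are defined for ideal separation):

- `rain_fraction`: proportion of single-target droplets whose FAM amplitude
  is smeared uniformly between the negative mean and the band mean
  (partial amplification). Gated as `unassigned`, excluded from positives
  but kept in totals.
- `fp_rate`: expected count (Poisson) of template-free droplets per well
  relabelled into a random target band (probe cross-reactivity). This is
  the mechanism that gives assays a non-zero false-positive rate.

## Gate derivation

Manual 2D threshold review is replaced by deterministic rectangular gates
derived from the control wells run on each plate:

- FAM threshold: negative-control (NC gDNA) FAM median + 7 robust SDs
  (median absolute deviation × 1.4826), capped below the lowest
  positive-control band (falling back to the NC/PC midpoint if the cap
  bites). Robust statistics keep a handful of stray positives in the NC
  well from inflating the threshold.
- Target bands: positive-control FAM amplitudes above the threshold are
  split into as many clusters as panel targets at the largest gaps; each
  target's gate is centred on its band median with half-width 5 band SDs,
  trimmed to 45% of the gap to the neighbouring band so gates stay
  disjoint. Panel order maps to bands in ascending FAM amplitude.
- HEX threshold: the NC HEX amplitudes (empty + reference-positive
  droplets) are split at the largest gap; threshold = negative median + 7
  SDs, capped at the cluster midpoint.

Controls whose clusters cannot be resolved (too few positive droplets,
bands closer than 5 SD, NC/PC overlap) raise a `GatingError` instead of
producing unreliable gates. Gate intervals are half-open `[low, high)` and
a droplet exactly at a threshold is negative — a fixed convention replacing
the tie-breaking that manual review leaves implicit.

## Quantification

With `k` positive droplets of `n`, the estimate is `λ = −ln(1 − k/n)` and
`c = λ / V_d` copies/µL of reaction. The 95% "Poisson" interval is the
exact Clopper–Pearson interval on `k/n` pushed through the same transform;
exact small-count behaviour matters because calls ride on `k ∈ {0,…,5}`.
Saturated wells (`k = n`) are flagged, not estimated.

Replicate wells (triplicates in the protocol) are merged by pooling counts.
With ≥ 2 wells the reported "total error" interval is the wider of (a) the
pooled Clopper–Pearson interval and (b) a t interval (mean ± t₀.₉₇₅,ₘ₋₁ ·
SD/√m) over the per-well concentrations, lower bound clamped at zero;
`ci_kind` records which rule won. This follows the droplet-reader
convention of reporting total error alongside Poisson error and makes the
interval honest when between-well scatter dominates.

Biofluid-level units: copies detected = copies/µL × 22 µL × wells; scaled
by 40/33 (11 µL of a 40 µL cfDNA eluate loaded per well, three wells = 33
of 40 µL) and divided by the biofluid volume in mL. Total cfDNA in haploid
genomic equivalents (hGE) comes either from the reference-gene channel
(one locus per haploid genome) or, for SNV assays, from wild-type + mutant
copies of the locus. Mass conversions use **3.3 pg per hGE**; display
rounding (hGE to integer; mass in ng to one decimal above 1 ng, else
integer pg) applies only at the reporting layer — all internal arithmetic
is full precision. One published concentration pair (18 hGE/mL ↔ 50 pg/mL)
is inconsistent with any constant near 3.3 pg/hGE and is not reproduced.

## MRD decision rules

Per assay, relative to the 12 merged negative-control cfDNA wells on the
same plate:

1. fewer than 3 merged FAM droplets → **negative**;
2. sample CI lower bound strictly above the NC CI upper bound (on the
   copies/µL scale) → **positive**;
3. otherwise, if the assay's measured false-positive rate is zero →
   **trace positive**;
4. otherwise **negative**.

CI separation is tested before the zero-FPR rule so unambiguous positives
are never downgraded. The FPR is the exact rational total of target-band
events across the NC wells divided by the well count (displayed to two
decimals); its conversion to events per mL of control plasma uses a
configurable factor (default 1.375) because the published volumes do not
pin the factor down. A sample is positive if any assay is positive, else
trace positive if any assay is, else negative. NTC wells must gate clean
or the plate is flagged.

Limit of detection: a ten-fold dilution series of tumor gDNA in normal
gDNA at constant 10 ng total input (1000/100/10/1 pg tumor ≈ 303/30/3/0.3
hGE), one well per step by default. LoD is the smallest mass called
positive with every larger mass also positive; trace-positive does not
count as detected, and a positive reappearing below a negative step flags
the series non-monotone.

## Variant filter chains and prioritization

SNV/indels are retained iff FILTER is PASS, tumor alternate allele count
≥ 5, population frequency ≤ 0.001 *or unannotated*, CADD (PHRED) ≥ 20 *or
unannotated*, and predicted impact HIGH or MODERATE. SVs are retained iff
PASS, PR ≥ 5 and SR ≥ 5 in the tumor, at most one alt-supporting read
(PR + SR summed) in the matched normal, and SOMATICSCORE ≥ 50. A record
missing an annotation whose absence the rule does not explicitly tolerate
(IMPACT, PR/SR) is rejected as unannotated rather than crashing. All
thresholds are inclusive.

Survivors are ranked by gene-list tier — disease-recurrent genes, then a
cancer gene census, then everything else — and within a tier by read
support (alt count for SNVs, min(PR, SR) for SVs). The tier-then-support
order is one consistent resolution of "driver first, then best-supported".
The selected panel aims for ≥ 2 targets per patient and mixes one SNV with
one SV when both kinds survive; fewer survivors set an under-target flag.
The bundled gene lists are small editable starter files, not full curated
releases. For relapsed cases, only variants present at both timepoints are
eligible: exact (chrom, pos, ref, alt) matching for SNVs, breakpoints
within a ±10 bp window (configurable) for SVs.

## What the simulator does and does not emulate

It reproduces the statistics the analysis consumes: Poisson partitioning,
resolvable Gaussian amplitude clusters, triplicates, 12-well NC plates,
dilution series at fixed input, and annotated VCFs with known truth. It
does **not** model thermal-cycling efficiency, probe chemistry, droplet
volume variation, cfDNA fragment-length effects, cluster drift between
wells, or partially overlapping bands — so passing tests demonstrate the
correctness of the decision arithmetic under the stated model, not
robustness to real-instrument pathologies. Real exports still require the
manual review the gate-derivation errors are designed to trigger.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to give the relevant statistics
adequate power: 200 dilution series for LoD rates, 11 × 200 wells per
occupancy for estimator bias (at λ = 0.001 a single well's relative error
moves in ~6% steps, so the batch median is itself medianed over 11
batches), 200 triplicates for CI coverage, and 500 SNV + 200 SV records
for the filter oracle. All randomness flows from explicit integer seeds;
per-well streams are spawned deterministically from a plate seed, and
identical seeds reproduce byte-identical droplet tables and output files.
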