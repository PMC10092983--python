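# ddmrd

Tumor-informed multiplex droplet digital PCR (ddPCR) analysis for
circulating-tumor-DNA-based measurable residual disease (MRD) detection in
liquid biopsies.

Children treated for embryonal brain tumors such as medulloblastoma are
monitored with imaging and cerebrospinal-fluid (CSF) cytology, both of
which can miss residual disease. An alternative is to read the tumor's own
genome out of body fluids: somatic variants found by tumor/normal
whole-genome sequencing are turned into patient-specific ddPCR assays, and
cell-free DNA (cfDNA) from CSF or plasma is then tested for those exact
sequences. `ddmrd` implements the computational side of that workflow for
analysts building or evaluating such pipelines:

- **Target selection** — somatic SNV/indel and structural-variant (SV)
  filter chains over annotated VCFs (PASS + alt count ≥ 5 +
  population-frequency/CADD/impact rules for SNVs; PR/SR ≥ 5, ≤ 1 normal
  read, SOMATICSCORE ≥ 50 for SVs) and gene-list-tiered prioritization
  into a ≥ 2-target panel per patient, ideally one SNV plus one SV.
- **Droplet classification** — reproducible rectangular amplitude gates
  derived from control wells for amplitude-multiplexed FAM bands plus a
  HEX reference channel.
- **Quantification** — Poisson partition statistics: with `k` positive
  droplets of `n`, `λ = −ln(1 − k/n)` and `c = λ/V_d` copies/µL, with
  exact Clopper–Pearson 95% intervals, triplicate merging with a
  total-error interval, conversion to copies/mL of biofluid, haploid
  genomic equivalents (hGE, 3.3 pg each) and DNA mass.
- **MRD calling** — per-assay false-positive rates from 12
  negative-control cfDNA wells; positive / trace-positive / negative
  decisions (≥ 3 FAM droplets; non-overlapping 95% CIs vs. the negative
  control; zero-FPR rule for borderline calls); limit-of-detection
  assessment from 10-fold dilution series at 10 ng total input.
- **Synthetic data** — a droplet-level plate simulator (Poisson
  partitioning, Gaussian amplitude clusters, rain, injected false
  positives, dilution series, NC plates) and a somatic-VCF generator with
  known truth, so the whole pipeline is testable without instrument data.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Simulate a plate with controls, a 12-well negative-control cfDNA set and
two triplicate samples — a CSF sample carrying both targets and a
target-free plasma sample — then gate, quantify and call it:

```python
from ddmrd import RunConfig, SampleConfig, run_pipeline
from ddmrd.quantify import display_hge, display_mass

cfg = RunConfig(
    targets=["dup_1p21", "CSNK2B_c419"],
    samples=[
        SampleConfig(sample_id="csf_d0", biofluid_volume_ml=2.0,
                     target_concentrations={"dup_1p21": 2.0, "CSNK2B_c419": 1.5},
                     reference_concentration=12.0),
        SampleConfig(sample_id="plasma_d19", biofluid_volume_ml=3.0,
                     target_concentrations={},
                     reference_concentration=45.0),
    ],
    seed=1, output_dir="readme_out",
)
res = run_pipeline(cfg)
for s in res.samples:
    print(s.sample_id, s.status)
    for c in s.target_calls:
        print(" ", c.target_id, c.call, "droplets:", c.fam_droplets)
    print("  total cfDNA:", display_hge(s.total_cfdna_hge_per_ml), "hGE/mL =",
          display_mass(s.total_cfdna_hge_per_ml * 3.3), "/mL")
```

prints

```
csf_d0 positive
  dup_1p21 positive droplets: 95
  CSNK2B_c419 positive droplets: 62
  total cfDNA: 479 hGE/mL = 1.6 ng /mL
plasma_d19 negative
  dup_1p21 negative droplets: 0
  CSNK2B_c419 negative droplets: 0
  total cfDNA: 1171 hGE/mL = 3.9 ng /mL
```

The CSF sample is MRD-positive: both assays detect ≥ 3 mutant droplets
(95 and 62 across the triplicate) and their 95% concentration intervals
sit clear of the negative-control wells, which showed a false-positive
rate of 0.00 events/well for both assays. The plasma sample has abundant
cfDNA (1171 hGE/mL ≈ 3.9 ng/mL — normal background) but zero mutant
droplets, hence negative. Outputs (droplet CSV, gates, classification,
quantification and calls TSVs, run log) land in `readme_out/`; re-running
with the same seed reproduces them byte-identically.

The same stages are available from the shell:

```sh
ddmrd run --config cfg.yaml --seed 1 --out results/
ddmrd lod --assay FOSL2_c383 --seed 3        # dilution-series LoD
ddmrd select-targets --vcf-snv somatic_snv.vcf --vcf-sv somatic_sv.vcf
```

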