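# vafqc

Driver-mutation variant allelic frequency (VAF) as a quality-assurance
metric for *MGMT* promoter methylation testing in adult-type diffuse
gliomas.

## The problem

*MGMT* promoter methylation is abnormal and occurs only in tumor cells, but
clinical testing (pyrosequencing, EPIC methylation array, droplet digital
PCR) is performed on bulk tissue. A paucicellular specimen mixes tumor DNA
with DNA from non-neoplastic cells, diluting the methylation signal:

    observed ≈ f · signal_tumor + (1 − f) · signal_background,

where *f* is the tumor-cell fraction. When *f* is low, a truly methylated
tumor can fall below the positivity cutoff — a **false negative** with
direct consequences for temozolomide treatment decisions. Because glioma
driver mutations (*TERT* promoter in IDH-wildtype GBM, *IDH1/2* in
IDH-mutant tumors) are nearly always heterozygous and copy-number neutral,
*f* ≈ 2 · VAF, so the driver VAF reported by routine NGS is an objective
purity readout: samples with low VAF carry an elevated false-negative risk
and warrant orthogonal re-testing.

`vafqc` is aimed at molecular-pathology analysts and methods researchers. It
provides:

- **cohort I/O** (`vafqc.cohort`) — validated delimited-text cohort tables;
- **assay call rules** (`vafqc.calls`) — pyrosequencing mean-CpG threshold
  (≥ 10%, or 7.28%), the MGMT-STP27 logistic model on array M-values of
  cg12434587/cg12981137, ddPCR (≥ 4%);
- **purity** (`vafqc.purity`) — cellularity = min(2·VAF·100%, 100%), OLS
  fits, microscopy-vs-VAF discrepancy analysis;
- **cumulative curves** (`vafqc.curves`) — running positivity / score
  statistics over samples ranked by increasing VAF;
- **cutpoint scan** (`vafqc.cutpoints`) — exhaustive Fisher-exact
  dichotomization over all VAF midpoints (raw minimal p, no
  multiple-testing correction — clearly labeled);
- **changepoint** (`vafqc.changepoint`) — exhaustive two-segment OLS fit of
  a cumulative curve, maximizing the low-minus-high slope difference;
- **risk flagging** (`vafqc.report`) — flag NEGATIVE calls with VAF below
  subtype-specific cutoffs (regression set 0.18 / 0.325 / 0.30 or scan set
  0.115 / 0.325 / 0.405) and cohort-level false-negative-rate estimates;
- **simulation** (`vafqc.simulate`) — a dilution-model cohort generator so
  every stage is testable without patient data.

## Worked example

```python
from vafqc import (SimConfig, simulate_cohort, cumulative_positivity,
                   two_part_fit, scan_vaf_cutoffs, flag_false_negative_risk)

cohort, truth = simulate_cohort(SimConfig(n=500, seed=1))
curve = cumulative_positivity(cohort)

fit = two_part_fit(curve)
print(f"changepoint split_vaf={fit.split_vaf:.3f} "
      f"low_slope={fit.low_fit.slope:.2f} high_slope={fit.high_fit.slope:.3f}")

scan = scan_vaf_cutoffs(cohort)
print(f"scan optimal_cutoff={scan.optimal_cutoff:.4f} p={scan.optimal_p:.3g}")

flags = flag_false_negative_risk(cohort)
print(f"flagged: {flags.n_flagged} of {len(cohort)}")
```

prints

```
changepoint split_vaf=0.239 low_slope=2.30 high_slope=0.394
scan optimal_cutoff=0.1509 p=0.000253
flagged: 35 of 500
```

The cumulative positivity curve of this synthetic cohort rises steeply up to
a knee (the two-part regression places it at VAF ≈ 0.24; the Fisher scan's
sharpest dichotomy sits at ≈ 0.15) and plateaus above it — the dilution
signature. The 35 flagged samples are NEGATIVE calls whose VAF falls below
their subtype's reliability cutoff; for those the report recommends
orthogonal re-testing by methylation array or ddPCR.

The same pipeline is available from the shell:

```sh
vafqc simulate --seed 1 --n 500 --out cohort.tsv
vafqc report --cohort cohort.tsv --out-dir bundle/
vafqc fisher 79 88 101 200        # {"odds_ratio": 1.78..., "p_value": 0.004...}
```

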