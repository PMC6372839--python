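# oxshift

Analysis toolkit for two-arm **oxygen-shift time-course multi-omics**
experiments in fermentative bacteria such as *Zymomonas mobilis*: an
anaerobically grown culture is abruptly exposed to O₂ at t = 0 and
sampled densely (t = 0, 1, 5, 10, 15, 30, 45, 60, 120 min) for
intracellular metabolomics (LC-MS with a fully ¹³C-labeled spike-in
reference), transcriptomics (TPM) and proteomics (log₂ label-free
quantitation), alongside an anaerobic control arm. The package is aimed
at researchers who need the full computational chain from raw feature
intensities to significance calls, absolute concentrations, ¹³C
incorporation rates and a fermentation carbon balance — plus a synthetic
study generator so every stage is testable without instrument data.

## What it computes

**Isotope-ratio normalization** (`oxshift.normalize`). For each
metabolite feature and sample, the ¹²C parent signal is divided by the
co-injected, fully labeled ¹³C reference signal — the per-injection
instrument factor is common to both channels and cancels exactly — then
divided by the sample's OD₆₀₀ (intracellular only), divided by the same
replicate's t = 0 value, log₂-transformed, and averaged over replicates:

    log2FC_j(t) = log2( [P_j(t)/R_j(t)/OD(t)] / [P_j(0)/R_j(0)/OD(0)] ),
    mean log2FC(t) = (1/n) Σ_j log2FC_j(t)

Signals below a reliability floor (default 10⁴ a.u.) are treated as
missing, per cell rather than per replicate.

**Repeated-measures ANOVA** (`oxshift.stats`). Per feature, the
replicate × time matrix from the O₂ arm is decomposed with time as a
*categorical* factor:

    SS_subject = t Σᵢ (ȳᵢ. − ȳ)²,  SS_time = n Σⱼ (ȳ.ⱼ − ȳ)²,
    F = [SS_time/(t−1)] / [SS_error/((t−1)(n−1))]

One p-value per feature, Benjamini–Hochberg FDR across each omic layer,
then the dual filter |fold change| > 1.5 (metabolites) or > 2 (genes)
AND FDR < 0.01.

**Absolute quantitation** (`oxshift.quant`): linear calibration curves,
¹³C internal-standard ratios for nonlinear analytes, and per-proton NMR
internal-standard arithmetic, with dilution handling.

**¹³C switch labeling** (`oxshift.labeling`): isotopologues with ≥ 2
heavy carbons are pooled into a labeled channel; incorporation rate is
the early-window OLS slope of the labeled fraction; a ≤ 0.1 rate ratio
versus the control is called an order-of-magnitude reduction.

**Carbon balance** (`oxshift.carbon_balance`): product percents against
pathway molar potentials (1 mol glucose → 2 mol ethanol, 1 mol
gluconate, …), biomass carbon from 0.41 g CDW · L⁻¹ · OD₆₀₀⁻¹ at 48 %
carbon, and the unaccounted remainder.

**Integration** (`oxshift.integrate`): per-gene regulation-mode calls
(transcription-led induction, degradation-led loss, transcriptional
shutdown with stable protein) from paired mRNA/protein trajectories,
and the `run_pipeline` orchestrator.

**Synthetic studies** (`oxshift.synthetic`): exponential growth,
product-of-logistics impulse transients, transcript impulses driving a
protein ODE (dP/dt = k_tl·M − k_deg·P, RK4), paired-channel LC-MS noise
with shared injection factors, first-order label incorporation, and
growth-coupled product export.

## Worked example

```python
from oxshift.integrate import run_pipeline, default_demo_config

bundle = run_pipeline(default_demo_config(), seed=1)
print(bundle["metab_stats"][["f_stat", "fdr", "max_abs_fc", "significant"]])
```

```
                 f_stat     fdr  max_abs_fc  significant
feature
MEcDP_like      84.6585  0.0000     48.1660         True
depleted       119.8753  0.0000      8.7946         True
upstream_flat    0.3121  0.9501      1.1588        False
```

The demo simulates a metabolite panel containing a transient that peaks
45-fold over baseline at 15 min (modelled on the bottleneck intermediate
MEcDP of the methylerythritol-phosphate pathway), a depleted
intermediate, and a flat upstream feature. The transient is recovered at
a 48-fold maximum change and flagged significant at |FC| > 1.5 /
FDR < 0.01; the flat feature is not (F ≈ 0.31, FDR ≈ 0.95). The same
bundle carries the gene-level calls (`up_gene → transcriptional_up` with
mRNA peaking at 15 min, 105 min before the protein peak), the labeling
comparison (rate ratio 0.0069 → order-of-magnitude reduction) and a
carbon balance in which 18.52 mM ethanol on 10 mM glucose accounts for
92.6 % of consumed carbon, biomass for 2.7 %, leaving 4.0 % unaccounted.

The same pipeline is scriptable from the shell:

```
oxshift run --seed 1 --out results/demo
oxshift stats --features results/demo/metabolomics_raw.csv \
    --design results/demo/design.csv --out results/stats
```

## Acceptance script

`scripts/acceptance.py` re-runs the bundled end-to-end simulation and
analysis from scratch under a caller-supplied seed and writes its JSON
summary:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
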