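# telqpcr

Amplification-efficiency estimation and T/S-ratio analysis for telomere-length
qPCR.

## The problem

Telomere length (TL) is most often measured by quantitative PCR as the **T/S
ratio**: the signal from reactions targeting telomeric repeats (T) relative to
reactions targeting a single-copy gene (S), computed as

```
T/S = (E_T^Cq_T / E_S^Cq_S)^(-1) = E_S^Cq_S / E_T^Cq_T
```

where `E` is the per-cycle amplification efficiency of each reaction set and
`Cq` is the quantification cycle at which fluorescence reaches a fixed
threshold. Because `E` enters through `E^Cq` with `Cq ≈ 20`, a 1% error in the
efficiency propagates into a ~20% error in the estimate — so *how* `E` is
estimated materially changes both the scale and the precision of TL
measurements.

Two families of estimators are compared:

* **standard curve**: regress Cq on log10 known concentration over a serial
  dilution; the slope `M` gives `E = 10^(-1/M)`;
* **log-linear reconstruction** (LinRegPCR-style): per reaction, regress log10
  fluorescence on cycle number within a common *window-of-linearity* per
  amplicon group; the slope gives `E = 10^slope`.

Crossing these with the level at which efficiencies are aggregated (replicate,
sample, plate, amplicon batch; instrument vs reconstructed Cq) yields seven
named T/S calculation approaches: `RotorGeneCurve`, `RotorGeneBatch`,
`LinRegRep`, `LinRegSamp`, `LinRegPlate`, `LinRegBatch`, `LinRegCurve`.

The package provides, for users analysing telomere qPCR data or evaluating
measurement pipelines:

* readers/writers for plain long-format fluorescence CSVs, Cq tables, sample
  metadata and results (`telqpcr.io`);
* baseline correction, window-of-linearity search, per-reaction efficiency,
  fractional Cq determination and efficiency aggregation
  (`telqpcr.efficiency`);
* replicate QC, the seven T/S variants, summaries (`telqpcr.ts_ratio`);
* precision statistics: CVs of ln replicate estimates, the Feltz–Miller CV
  equality test, paired t-tests with Bonferroni control (`telqpcr.precision`);
* external-validity statistics: partial correlations with Fisher-z intervals,
  the 83.4% CI-overlap comparison, `pwr.r.test`-style required sample sizes
  (`telqpcr.validity`);
* the measurement-error attenuation Monte Carlo (`telqpcr.simulation`);
* a synthetic-study generator with full ground truth: sigmoidal amplification
  curves, 100-well plate layouts (22 triplicate samples, 5 triplicate ten-fold
  standards, 6 triplicate positive controls, 1 blank), and a multi-generation
  two-tissue cohort with configurable cross-tissue, parent–offspring and age
  correlations (`telqpcr.synthetic`).

## Worked example

Generate a miniature study (44 samples on 2 paired T/S plate pairs), analyse
it, and run the attenuation simulation and a power calculation:

```
$ telqpcr simulate-study --n-samples 44 --seed 7 --outdir study
wrote 400 reactions on 4 plates for 44 samples to study/

$ telqpcr analyze --fluorescence study/fluorescence.csv \
                  --metadata study/metadata.csv --outdir reports
analyzed 44 samples (44 passing QC); reports in reports/

$ telqpcr simulate-fx --seed 1
share_positive=0.9410 mean_fx=0.0712 sd_fx=0.0480 (941/1000 positive)

$ telqpcr power --r 0.670 --r 0.709
r=+0.670  required n=14.30
r=+0.709  required n=12.41
percent reduction (first -> last): 13.21%
```

`reports/efficiency_summary.csv` then contains (this exact run):

```
regime,t_mean,t_sd,s_mean,s_sd,n_plates,p_between_amplicons
standard_curve_instrument,1.85672671284,0.00175541572635,1.92326944605,0.00232485322431,2,0.00385216828863
standard_curve_reconstructed,1.85712889251,0.00181429028054,1.92352055249,0.00200915011131,2,0.00132121439039
log_linear_plate_mean,1.84628882791,0.000712910516119,1.9033634137,0.000989798880956,2,0.00218386284674
```

Reading it: T reactions amplify less efficiently than S reactions under every
regime (the generator's truth is E_T = 1.86 vs E_S = 1.92; the paired t-test
p-values in the last column flag the difference), and the log-linear plate
mean sits slightly below the standard-curve estimates because the
reconstruction fits the observed curve inside the window, where mild
saturation attenuates the slope. `reports/ts_summary.csv` holds the seven
T/S distributions (mean, SD, between-sample CV) for all samples and per
tissue; `reports/validity_correlations.csv` holds per-approach cross-tissue,
age and parent–offspring partial correlations with 83.4% confidence
intervals.

In the attenuation simulation, `f(x) = (r(TL,tissue) − r(noisyTL,tissue)) −
(r(TL,age) − r(noisyTL,age))` measures whether removing measurement noise
recovers more correlation for a strong correlate (tissue, r = 0.70) than for a
weak one (age, r = 0.15): positive in 941/1000 replications above, with mean
0.071.

## Input format

The fluorescence CSV is long format, one row per well per cycle, with columns
`plate_id, well, amplicon (T|S), role (sample|standard|positive_control|ntc),
sample_id, replicate_index, known_concentration (standards only), cycle,
fluorescence`, optionally `instrument_cq`. Metadata CSVs carry `sample_id,
person_id, age, sex, tissue (leukocyte|buccal), mother_id`. The pipeline is
instrument-agnostic: export your run files to this layout (raw or
background-subtracted fluorescence both work; instrument Cq values, if
supplied, feed the instrument-Cq approaches).

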