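# ppikit

Task-modulated brain connectivity from block-design fMRI, and how much of it
you can trust.  `ppikit` implements psychophysiological interaction (PPI)
analysis — with and without hemodynamic deconvolution — together with the
reproducibility and reliability machinery needed to evaluate it: Dice
overlap of thresholded maps, intraclass correlation (ICC) between runs, and
log-scale coefficients of variation.  A synthetic two-run cohort generator
with known ground truth stands in for real multi-subject data, so every
stage of the pipeline is testable end to end.

It is written for neuroimaging methods researchers and analysts who work
from Python: the importable API is the interface, `examples/` holds short
narrative scripts (one per capability), and a thin `ppikit` command wraps
the simulation, cohort generation and full-study pipelines for shell use.

## The model

A PPI effect is the regression interaction between a seed region's time
series (the physiological variable *x*) and a task indicator (the
psychological variable *z*).  With `*` denoting convolution with the
canonical double-gamma HRF *h*, the two constructions in common use are

    x_PPI1 = (z_psych * h) . x_physio            (non-deconvolution)
    x_PPI2 = (z_psych . z_physio) * h            (deconvolution)

where in the second form `z_physio` is the neuronal-level series estimated
by deconvolution of the observed BOLD under `x = z * h + ε`.  The target
series is regressed on `[task, seed, PPI, constant]` plus nuisance
covariates (Friston-24 motion expansion, WM/CSF series, DCT drifts) — or
without covariates when they have already been regressed out of ROI series.
Because the HRF is a low-pass filter, the two PPI terms nearly coincide for
slow block designs and diverge for event-related designs; the package
quantifies this directly by simulation.

Deconvolution is a frequency-weighted ridge on a full cosine basis (penalty
∝ f² on the coefficient at frequency f), with the weight chosen by
generalized cross-validation or fixed.  Reliability statistics follow the
standard two-way ANOVA decomposition: ICC(3,1) consistency by default,
Dice = 2|A∩B|/(|A|+|B|) under common-t or matched-percentile thresholds,
and CV = exp(√(mean within-subject variance of log effects)) − 1.

## Worked example

`python examples/term_correlation.py` draws 1000 Gaussian neuronal series
and correlates the two PPI constructions per task design:

```
          mean  median     q1     q3
design
event    0.475   0.480  0.432  0.521
block8   0.465   0.466  0.452  0.479
block24  0.831   0.832  0.815  0.849
block40  0.899   0.901  0.885  0.915
block80  0.950   0.953  0.941  0.961
```

(abridged).  The mean correlation rises with block cycle length: above 0.9
for cycles slower than 40 s, below 0.5 for the 2 s-trial event design — the
quantitative case for skipping deconvolution in block designs but not in
event-related ones.

`python examples/full_study.py` runs the whole replica on a 20-subject
synthetic cohort (two runs: 225 scans at TR 0.645 s, 93 scans at TR 1.4 s;
five ROI pairs with injected negative modulation):

```
group t (negative contrast) on the five modulated ROI pairs:
pair            deconv/run1  deconv/run2  nondeconv/run1  nondeconv/run2
L_FG1--L_OC1          -4.72        -2.28           -4.46           -1.58
R_FG1--R_OC2          -5.89        -4.08           -3.80           -2.69
...
edges in the full 4-scenario conjunction at p < 0.01: 3
median edgewise ICC (deconv): -0.027
```

All modulated pairs come out negative in every scenario; the short-TR run
carries more statistical power; and the edgewise ICC is near zero even
where group effects are strong — the characteristic (and cautionary)
reliability profile of PPI effects.  The other examples demonstrate the
deconvolution's high-frequency suppression and the reliability metrics in
isolation.

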