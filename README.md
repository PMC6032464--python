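# dcekit

Tracer-kinetic analysis of dynamic contrast-enhanced MRI (DCE-MRI) for
**early prediction of hepatocellular carcinoma (HCC) response** to
transcatheter arterial chemoembolization (TACE) followed by sorafenib.

Intermediate-stage HCC treated with TACE + sorafenib is usually judged
responding or not a month or more after treatment, by mRECIST on
follow-up imaging. DCE-MRI measured a few days after TACE can see the
perfusion changes much earlier. `dcekit` implements the full analysis
chain for such a study, for imaging scientists and clinical researchers
who want to run it, test it, or re-examine its operating
characteristics on synthetic cohorts:

1. **Signal → concentration.** Tracer concentration is approximated by
   the relative enhancement C(t) = S(t)/S₀ − 1, with S₀ the mean of the
   pre-contrast frames. Aortic curves are merged semi-automatically into
   an arterial input function (AIF) and converted from blood to plasma
   concentration with a fixed hematocrit, C_p = C_b/(1 − Hct), Hct = 0.45.
2. **One-compartment model.** The tissue curve is fit by

   C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^(−(K^trans/DV)(t−τ)) dτ

   yielding the transfer constant **K^trans** (ml/100 ml/min) and the
   distribution volume **DV** (ml/100 ml). With a hepatocyte-specific
   agent (Gd-EOB-DTPA) DV aggregates plasma, interstitial and
   intracellular space. A truncated-SVD deconvolution provides
   model-free plasma-flow maps for ROI guidance.
3. **Response classification.** mRECIST on viable (arterially
   enhancing) diameters: CR / PR / SD / PD, grouped into responders
   (CR, PR) and non-responders (SD, PD).
4. **Early prediction.** "Responder if DV ≤ cutoff" per visit
   (packaged cutoffs 40 / 30 / 17 ml/100 ml at pre-TACE / day 3 /
   day 10; a mean + 2 SD constructor is provided), scored by
   sensitivity, specificity, PPV, NPV and the clinical utility indexes
   CUI⁺ = sensitivity × PPV and CUI⁻ = specificity × NPV.
5. **Small-cohort statistics.** Friedman tests across the three visits,
   Mann–Whitney U between groups, Spearman correlation against
   angiogenesis markers (Ang2, VEGF, c-KIT), and a mixed
   repeated-measures ANOVA — all with *exact* permutation p-values at
   the study's sample sizes.

A synthetic-cohort generator reproduces the study design — the burst
sampling schedule (five frames per 30-s phase at pre-contrast, the
arterial-dominant window, and 60–600 s post-injection), a population
AIF, and per-group kinetic parameter distributions — so the entire
pipeline is testable end to end without patient data. The packaged
study table (`dcekit.load_study_table()`) ships the 11-patient /
21-lesion cohort with its per-visit outcomes.

## Worked example

Simulate a default cohort (11 patients, 21 lesions, SNR 20), fit every
lesion at every visit, and run the analysis:

```python
import dcekit as dk

spec = dk.CohortSpec(seed=1)
dataset, truth, curves = dk.generate_cohort(spec)
fits = dk.fit_study_curves(curves)          # 63 lesion-visit fits
dataset = dk.attach_kinetics(dataset, fits)
results = dk.analyze_study(dataset)
```

`results["summary"]["dv"]` (means ± SD, ml/100 ml):

```
        group timepoint  n  mean   sd
    responder  pre_tace  8  36.2 15.5
    responder      day3  8  12.5  4.5
    responder     day10  8   8.1  3.0
non_responder  pre_tace 13  31.4 10.4
non_responder      day3 13  23.0 13.1
non_responder     day10 13  20.3  6.8
```

DV collapses in responders (36 → 12 → 8) but stays high in
non-responders, exactly the behaviour the predictor exploits. The
within-group trend is significant for responders:

```
responder DV Friedman: chi2=13.00, p=0.0003 (friedman (exact))
```

and `results["diagnostics"]` scores the packaged cutoffs on this cohort:

```
timepoint  cutoff  sensitivity_pct  specificity_pct  ppv_pct  npv_pct  cui_positive  cui_negative
 pre_tace    40.0             50.0             15.0     27.0     33.0         0.133         0.051
     day3    30.0            100.0             38.0     50.0    100.0         0.500         0.385
    day10    17.0            100.0             77.0     73.0    100.0         0.727         0.769
```

Pre-treatment DV predicts poorly; day-10 DV separates the groups well —
the study's central finding, re-emerging from synthetic data.

The same steps are available from the shell:

```bash
dcekit simulate --seed 1 --out run/
dcekit fit --curves run/curves.csv --out run/fits.csv
dcekit analyze --fits run/fits.csv --study run/study.csv \
               --angio run/angiogenesis.csv --out run/stats/
dcekit report --fits run/fits.csv --study run/study.csv --out run/report/
```

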