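# cmr-remodel

Quantitative cardiac magnetic resonance (CMR) analysis of left-ventricular
reverse remodeling, built for studies that track hypertrophy and myocardial
fibrosis before and after an intervention (the motivating setting is septal
myectomy for hypertrophic obstructive cardiomyopathy). The package
implements the full measurement chain — segmental T1/ECV mapping, 6-SD late
gadolinium enhancement (LGE) quantification, LV volumetrics, and the indexed
cellular/extracellular compartment volumes — together with the paired
pre/post cohort statistics, and ships a synthetic short-axis phantom
generator with analytic ground truth so every stage is testable without any
patient data.

## What it computes

**Extracellular volume fraction** from paired native/post-contrast T1 times
and hematocrit:

    ECV = (1 − Hct) · (ΔR1_myo / ΔR1_blood),    ΔR1 = 1/T1_post − 1/T1_native

measured per AHA segment (16-segment model, apex excluded; 10% offset from
the endo- and epicardial edges), with the study-level T1 and ECV taken as
area-weighted means over segments that contain no LGE.

**Focal fibrosis** by the 6-SD method: myocardial voxels whose LGE signal
exceeds the remote-myocardium reference mean by more than six sample
standard deviations, reported as volume, mass (density 1.05 g/mL) and % of
LV myocardium.

**Compartment volumes** splitting the BSA-indexed non-enhanced myocardium by
ECV:

    iECV = (myoV/BSA − lgeV/BSA) · ECV        [mL/m²]
    iCV  = (myoV/BSA − lgeV/BSA) · (1 − ECV)  [mL/m²]

so iECV + iCV equals the indexed non-enhanced myocardial volume exactly.

**Cohort statistics** on paired pre/post tables: Shapiro–Wilk-gated paired
t / Wilcoxon signed-rank tests with Bonferroni correction (0.05/20 default),
Pearson correlations, univariable screening with p-based stepwise
multivariable linear regression (Durbin–Watson, studentized residuals,
Cook's distance), and restricted-cubic-spline nonlinearity checks.

## Worked example

```python
from cmr_remodel import (PhantomParams, LesionSpec, generate_subject,
                         quantify_subject)

params = PhantomParams(
    noise_sd=0.0, seed=11,
    lesion_spec=[LesionSpec(1, 250.0, 40.0, 0.5)])
bundle = generate_subject(params)
m = quantify_subject(bundle)
t = bundle.truth

print(f"true ECV      {t.true_ecv:.4f}   measured {m.global_ecv:.4f}")
print(f"true mass     {t.true_mass:6.1f} g  measured {m.mass_g:6.1f} g")
print(f"true EDV      {t.true_edv:6.1f} mL measured {m.edv_ml:6.1f} mL")
print(f"true LGE vol  {t.true_lge_volume:6.2f} mL measured {m.lge_volume_ml:6.2f} mL")
print(f"iECV {m.iecv:.1f} mL/m2   iCV {m.icv:.1f} mL/m2   "
      f"iECV/(iECV+iCV) = {m.iecv/(m.iecv+m.icv):.4f}")
```

prints

```
true ECV      0.2833   measured 0.2833
true mass      168.0 g  measured  167.2 g
true EDV       145.0 mL measured  145.2 mL
true LGE vol    1.09 mL measured   1.10 mL
iECV 24.9 mL/m2   iCV 63.1 mL/m2   iECV/(iECV+iCV) = 0.2833
```

i.e. on a noise-free phantom with a septal lesion the pipeline recovers the
generating ECV to machine precision, mass and cavity volume to well under
1%, the lesion volume to about one boundary voxel, and the compartment
split reconstructs ECV exactly.

Paired cohorts with configured within-person effect sizes come from the
cohort generator and run end-to-end:

```python
from cmr_remodel import CohortEffects, generate_paired_cohort, run_cohort

pairs, record = generate_paired_cohort(CohortEffects(n_subjects=43, seed=42))
result = run_cohort(pairs, out_dir="results/cohort")
print(result["table2"][["metric", "change_mean", "test", "p", "significant"]])
```

The same operations are available from a shell:

```sh
cmr-remodel phantom subject --seed 3 --out subj1
cmr-remodel quantify subj1 --out subj1_metrics
cmr-remodel phantom cohort --n 43 --seed 4 --out cohort
cmr-remodel cohort cohort --out results
cmr-remodel report results
```

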