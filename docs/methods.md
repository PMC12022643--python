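# Methods

This note documents the models behind `cmr_remodel`, the defaults and why
they were chosen, what the synthetic phantoms do and do not emulate, and
the numerical conventions a user needs to reproduce results exactly.

## Measurement model

### Geometry

A subject-timepoint is a stack of aligned short-axis slices, base to apex,
each carrying endocardial and epicardial contours (as filled label masks)
and two right-ventricular insertion points. The myocardial band is the set
difference epi − endo. All in-plane measurements use polar coordinates
about the cavity centroid with rays at 1° resolution; a voxel belongs to
the ray nearest the angle of its center.

Because a 1° arc is narrower than a voxel at typical radii (~0.4 mm at
25 mm), a single ray catches only a scattering of the wall's voxels. Ray
edge radii for the offset are therefore estimated over a ±2° support
window; wall thickness additionally uses sub-voxel ray marching (0.25-voxel
steps, nearest-voxel lookup) with a 7° circular smoothing of the per-ray
radii, because maximal wall thickness is a max statistic and any unsmoothed
per-ray voxelization wobble (±½ voxel) would bias it upward.

The **10% offset** is interpreted radially: on each ray, voxels within 10%
of the local wall thickness of either edge are removed. A uniform-mm
erosion was rejected because wall thickness in the hypertrophic setting
varies several-fold around the circumference. Rays with walls thinner than
3 voxels keep their single most central voxel and emit a warning. The
offset region is monotone in the fraction (larger trims are subsets).

The **AHA 16-segment model** partitions each slice by sweep angle measured
from the anterior RV insertion direction, sweeping through the free wall
(anterior → anterolateral → inferolateral → inferior → inferoseptal →
anteroseptal); basal and mid slices get six 60° sectors, apical slices four
90° sectors, and the apex cap is never modeled. A sector boundary belongs
to the sector it starts, so a voxel exactly on the anterior-insertion ray
is segment 1 (7, 13). The sweep direction is inferred from the two
insertion points: the septum occupies the short arc between them, so the
free-wall sweep takes the long arc. With more than three slices, slices are
labeled basal/mid/apical in equal thirds and same-level slices pool into
the same six (or four) segments by area-weighted aggregation.

### Tissue

The **6-SD LGE rule** thresholds at reference mean + 6 × sample standard
deviation (n−1 denominator) with a strict `>`; the reference ROI must hold
at least 2 voxels (20 are expected in practice) and lie inside the band.
No minimum-cluster filter is applied by default (a config knob exists);
manual mask editing is out of scope. LGE mass uses a myocardial density of
1.05 g/mL; this same density makes the package's iCV arithmetic consistent
with the worked single-subject example it reproduces.

**ECV** is computed per segment from the segmental mean T1s (not pixelwise
and then averaged): the segment's native and post-contrast T1 means enter
ECV = (1−Hct)·ΔR1_myo/ΔR1_blood. Blood T1s are measured once per study
from the blood-pool ROI of the mid slice (configurable); whether blood
should be sampled per slice is genuinely open, and the mid-slice choice is
recorded in the run manifest. A hematocrit above 1 is treated as a
percentage. Segments containing any enhanced voxel are excluded from the
global (area-weighted) T1 and ECV; the "any voxel" rule is the strictest
reading of segment-level exclusion and the minimum enhanced fraction is
configurable.

### Volumetrics and compartments

Volumes are Simpson slice summations (mask area × slice thickness, zero
inter-slice gap). SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR/1000. BSA
uses Mosteller √(height·weight/3600) by default (Du Bois selectable);
indexed quantities divide by BSA exactly, so indexing round-trips. Maximal
wall thickness is measured on end-diastolic contours (clinical convention;
the choice of phase is a documented assumption). Papillary muscles are
neither generated nor specially handled.

The indexed compartments are

    iECV = (myoV − lgeV)/BSA · ECV,    iCV = (myoV − lgeV)/BSA · (1 − ECV),

with the LGE volume also divided by BSA — the reading of the compartment
formula confirmed by the reproduced worked example (LVMI 114 g/m², LGE
1.2 g, ECV 27.9%, BSA 1.70 m², density 1.05 g/mL gives iCV 77.8 mL/m²).
LGE volume in these formulas is LGE mass / 1.05. Conservation
(iCV + iECV = indexed non-enhanced volume; iECV/(iCV+iECV) = ECV) holds to
machine precision by construction and is asserted on every subject.

Paired changes are reported as post − pre in summary tables (negative =
regression) and as pre − post for regression outcomes (reduction positive),
with percent change always 100·(pre−post)/pre.

## Statistics

Paired comparisons gate on Shapiro–Wilk normality of the differences at
α = 0.05 (the gate's operand and level are conventions, applied to the
paired differences). The normal branch is the paired t-test; otherwise a
Wilcoxon signed-rank test with zeros dropped (Wilcoxon's original rule),
midranks for ties, an exact sign-flip null for n ≤ 25 (dynamic program on
doubled ranks; the two-sided p is P(min(W+, W−) ≤ observed min)), and a
normal approximation with continuity and tie correction beyond. Family-wise
significance uses Bonferroni α/m with m = 20 by default, matching a
20-test change table; m is configurable and can track the produced table.

The regression stage screens candidates univariably (simple OLS, retain
p < 0.05) and then runs bidirectional p-value stepwise selection (entry
≤ 0.05, removal > 0.10) from the empty model; an AIC mode sits behind a
flag. p-based selection was chosen over information criteria to match the
univariable-entry convention of the reporting style it reproduces. The
final model is refit for coefficients and 95% CIs. Residual independence is
summarized by the Durbin–Watson statistic with a Monte-Carlo p-value
(2000 simulated Gaussian-error fits on the same design matrix, one-sided
against positive autocorrelation, seeded); no installed library exposes a
DW p-value, and the null distribution depends on the design. Influence
diagnostics flag |externally studentized residual| > 3 or Cook's D > 0.5,
with an optional refit excluding flagged observations reported alongside.

Nonlinearity is tested with restricted cubic splines in Harrell's
truncated-power form, knots at conventional quantiles (default 4 knots at
the 5/35/65/95th percentiles; 3 and 5 supported), via a joint F-test that
all nonlinear basis coefficients vanish.

## Synthetic phantoms

`phantom` renders concentric annuli (myocardium) around a disc (blood
pool) per slice: native/post-contrast T1 maps, an LGE magnitude image,
cine ED/ES frames, and exact label masks (1 blood pool, 2 myocardium,
3 reference ROI) with insertion-point sidecars. Defaults: 128² grid at
1 mm, nine 8-mm slices (three per basal/mid/apical level — three levels
match clinical T1 mapping, while nine slices let realistic end-diastolic
volumes coexist with anatomical radii), myocardial native T1 1313 ms,
blood 1900/450 ms, hematocrit 0.40. End-systole scales the cavity to a
65.9% ejection fraction with per-slice myocardial area conserved
(incompressible wall). Lesions are angular sectors extending a transmural
fraction outward from the endocardium with an LGE signal multiplier
(default 3× the myocardial base signal). Noise is additive Gaussian per
modality (defaults: T1 15 ms, LGE 3, cine 5 intensity units — chosen so
segment-mean T1 noise stays ~1 ms and the 6-SD threshold is stressed but
not overwhelmed); a Rician option exists and is off by default. Identical
parameters and seed give bit-identical arrays, and NIfTI serialization
fixes the gzip mtime so written files are byte-reproducible.

Ground truth (ECV, volumes, mass, lesion volume, per-segment T1) is
computed analytically from the generating parameters, never from rasters.

**What the phantoms do not emulate:** MR physics (coil profiles, partial
volume, motion, inversion-recovery fitting), papillary muscles and
trabeculae, non-circular contours, long-axis views, the right ventricle,
slice misregistration between modalities, and contouring error — the masks
are exact. Passing recovery tests therefore validates the measurement
arithmetic and geometry engine, not robustness to segmentation error.

### Paired cohorts

The cohort generator draws per-subject baselines (LVMI 101 ± 20 g/m², ECV
28.2 ± 3.3%, EDVI 86.6 ± 12 mL/m², EF 65.9 ± 3.5%, LGE mass 4.5 ± 2 g, BSA
1.67 ± 0.17 m², HR 66 ± 10 bpm, hematocrit 39.3 ± 3.5%, native T1
1313 ± 34 ms; dispersions follow the cohort the defaults describe, with
IQR-derived spreads where only medians are reported) and within-person
changes with configured means/sds (defaults: ΔLVMI −19.8 ± 8.4 g/m², ΔiECV
−4.4 ± 2.6, ΔiCV −16.6 ± 6.6 mL/m², ΔEF −2.6 ± 3.1 points).

iECV, iCV, LVMI and LGE are algebraically linked (LVMI/1.05 = iECV + iCV +
indexed LGE volume), so not all six change distributions can be free dials.
ΔiECV, ΔiCV and ΔEF are drawn directly; the LGE-volume change is the
bookkeeping slack, drawn from a shifted standardized exponential whose
location and scale are solved so the implied ΔLVMI has *exactly* the
configured mean and sd. The exponential's bounded lower support keeps
post-operative LGE volume positive with negligible resampling, avoiding
the truncation bias a Gaussian slack would give; its cost is a mild ΔLVMI
skewness (≈0.2), irrelevant to the mean/sd contracts and to paired-test
behavior at the default effect sizes. The ECV and LGE-mass changes are
consequently *derived*, landing near +2 ECV points and +3–4 g. EDV is held
fixed pre→post (the EF change is realized through ESV); an EDV effect is
not part of the effects type. The optional correlation between changes and
baseline uses the standardized baseline-LVMI draw as the common anchor
(default 0). Post-contrast myocardial T1 is solved per timepoint to realize
the target ECV given the subject's hematocrit and blood T1s. Realized draws
are recorded per subject for oracle comparison; a subject whose draws admit
no physical geometry (negative lesion volume, EF outside 20–85%, ECV
outside 10–60%) is redrawn up to 20 times.

Residual asymptotic biases from the physicality guards are ≤0.2 units on
the change means — far inside the 3-standard-error convergence contract at
n = 1000 and negligible at the default n = 43.

## Problem sizes and determinism

The test suite and acceptance script use: noise-free single subjects
(128² × 9 voxels), a 43-pair rendered cohort for the round trip, n = 1000
(unrendered) for generator-convergence checks, 1000-case fuzz sets for the
ECV and 6-SD oracles, 200 cases for exact-Wilcoxon enumeration (n ≤ 12),
5000 replicates for paired-test type-I error, and 100 replicates (n = 200,
effects ≥ 5 residual sd) for stepwise recovery. All randomness flows
through explicit integer seeds; `--seed` in the acceptance script derives
every child seed. Cohort table rows for metrics with identically zero
differences (e.g. EDVI under the default effects) are reported as
degenerate with p = 1 rather than dropped.

## Known limitations

- Real-data ingestion expects the package's own NIfTI + JSON layout; DICOM
  and vendor map formats are out of scope.
- The ECV pipeline assumes mask/image alignment; no registration is
  performed.
- The stepwise procedure inherits the usual caveats of p-based selection
  (post-selection inference is not corrected); the CIs of the final model
  are conditional on selection.
- The exact Wilcoxon p is defined through the min-tail; other software may
  report the doubled single tail, which differs only at the point mass.
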