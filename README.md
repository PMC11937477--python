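# bronchowall

Quantifying bronchial-wall inflammation from multimodal chest imaging.

In severe asthma the bronchial wall is thickened by a mixture of remodeling
and inflammation that CT alone cannot separate.  A T2-weighted MRI signal
measured over the bronchial wall — here called **BrWall_T2-MIS** — is an
inflammation-sensitive biomarker: after whole-image intensity
normalization, registration of CT and T2w volumes onto a UTE (ultra-short
echo time) MRI reference, and CT-based wall segmentation, the mean
normalized T2w intensity over the wall of four third-generation bronchial
paths (one per lobe: RUL, RLL, LUL, LLL) gives a single value per patient
that separates severe from non-severe asthma and predicts frequent
exacerbations.

`bronchowall` implements that pipeline end to end as a tested Python
library, driven by a synthetic airway phantom with analytic ground truth so
every stage is verifiable without patient data:

- **phantom** — co-registered CT-like / UTE-like / T2w-like volume triplets
  of a branching airway tree with known lumen radius, wall thickness, wall
  T2 signal, parenchymal texture, Rician/Gaussian noise and a known smooth
  inter-modality deformation; plus synthetic cohort tables with the study's
  group structure (means, SDs, correlations, exacerbation model);
- **preprocess** — T2w normalization `f(x) = (x − μₓ)/σₓ + 3σₓ` over all
  voxels, and multiresolution deformable registration onto the UTE frame
  (diffeomorphic demons after histogram matching, with an edge-overlap QC
  score);
- **airway** — lumen region growing, skeleton-based centerline tree with
  generation labels (trachea = 0), lobar path selection with automated
  mucus-plug exclusion, and oblique cross-section reformatting
  perpendicular to the bronchial axis;
- **wallquant** — Laplacian-of-Gaussian boundary detection along radial
  rays: lumen area LA, wall area WA, WA% = 100·WA/(WA+LA), 3D wall masks,
  and the BrWall_T2-MIS aggregation (site → path → patient means);
- **stats** — the full analysis battery: Shapiro–Wilk-gated log transforms,
  Student's t-tests, Fisher/chi-square, ROC with the Youden index and exact
  Clopper–Pearson intervals, stepwise logistic regression, Pearson
  correlations, ICC (two-way mixed, absolute agreement) with the standard
  agreement labels, Bland–Altman, quartile ANOVA with Tukey HSD;
- **pipeline / CLI** — configured, seeded, manifest-logged orchestration of
  whole cohorts (`bronchowall run-all --config cfg.toml --seed 17`).

## Worked example

```python
from bronchowall import PhantomSpec, generate_phantom, normalize_t2
from bronchowall.pipeline import RunConfig, run_subject

cfg = RunConfig(phantom={"noise_sigma": 0.0, "deformation_amplitude": 0.0})
bio, manifest = run_subject(cfg, "demo", wall_signal=60.0, seed=3)

spec = PhantomSpec(wall_t2_signal=60.0, seed=3, noise_sigma=0.0,
                   deformation_amplitude=0.0)
_, _, t2w, truth = generate_phantom(spec)
print(f"measured BrWall_T2-MIS: {bio.brwall_t2_mis:.3f}")
print(f"normalized true wall signal: {normalize_t2(t2w).transform_scalar(60.0):.3f}")
print(f"WA%: {bio.wa_percent:.1f} (analytic {truth.analytic_areas(3)['WA_percent']:.1f})")
```

prints

```
measured BrWall_T2-MIS: 22.248
normalized true wall signal: 22.389
WA%: 72.8 (analytic 70.2)
```

i.e. on a noise-free phantom the pipeline recovers the analytically
normalized ground-truth wall signal to within ~5% of the normalized
wall–parenchyma contrast (the scale of partial-volume effects at the mask
boundary), and measures the normalized wall area within ~3 percentage
points of the analytic annulus value.  The scripts in `examples/` walk through each capability
(phantom generation, normalization + registration, tree extraction, wall
measurement, cohort statistics, the full pipeline) with printed output and
a line on what each number means.

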