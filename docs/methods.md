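# Methods note

This note documents what `perishell` computes, the model behind the
synthetic phantom, the numerical choices made, and what the generator
is — and is not — intended to emulate.

## 1. VOI geometry

**Structuring elements.** All morphology uses discrete Euclidean balls:
the radius-*n* element contains every integer offset with
x² + y² + z² ≤ n². Ball(1) is the 6-neighborhood cross (7 offsets
including the origin); ball(2) has 33 offsets. Radii are in voxels on
the isotropic analysis grid (default 1 mm).

**Construction.** Lesion components are labeled with 26-connectivity
(configurable: 6/18/26) and relabeled in deterministic raster order.
Each component is eroded once by ball(1); components emptied by erosion
are dropped (or kept as a single-voxel stand-in with
`retain_eroded_empty`). Around each (eroded, by default) lesion:

- perilesional shell PL = dilate(lesion, ball(2)) \ (all lesion voxels) ∩ WM;
- shell *n* (n = 1, 2, 3) = dilate(PL, ball(n)) \ (everything interior:
  lesions, PL, shells 1..n−1) ∩ WM.

Subtracting the full interior rather than only the previous shell makes
shells pairwise disjoint by construction, which `VOISet.validate()`
asserts on every build. Tissue masks threshold GM/WM probability maps
strictly above 0.9 with lesion voxels removed. By default only lesion
voxels are excluded from NAWM — the PL and shells remain part of the
white-matter mask — because the perilesional rim is normal-appearing
tissue; `exclude_perilesion_from_wm` provides the stricter variant.

**Common imaging volume.** Maps are resampled to the anatomical grid
(trilinear for quantitative maps with NaN fill, so coverage never
extrapolates; nearest-neighbor for masks). The common volume is the
intersection of non-missing coverage over the supplied maps; lesions
whose VOI family leaves it are dropped (default) or trimmed
(`drop_partial=False`). An entirely absent modality restricts nothing.

## 2. Extraction and statistics

VOI means skip missing voxels and report the contributing voxel count.
Subject-level `avgLesion`/`avgPL` pool voxels over the union masks
(each voxel, not each lesion, carries equal weight); NAWM/NAGM use the
full tissue masks. Group tables report `median (min; max)` of subject
means; the lesion-level shell table reports `mean (SD)` across lesions.

The test battery runs seven contrast families × nine biomarkers:
Mann–Whitney U for the two HC-vs-MS tissue contrasts and Wilcoxon
signed-rank for the five within-patient contrasts. Exact null
distributions are used for n ≤ 25 without ties (always true at study
scale); zero differences are dropped (`wilcox` convention) and all-zero
difference vectors return p = 1 with a warning flag. Both tests are
verified in the test suite against full enumeration (all rank
assignments / all sign patterns) for n ≤ 8.

Benjamini–Hochberg step-up correction is applied within each
nine-test family at α = 0.05: reject ranks 1..k where k is the largest
i with p₍ᵢ₎ ≤ i/m·α; adjusted p-values are the monotone envelope
min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1. The reported `q_crit` is the critical
value i/m·α at each test's rank; the rank-1 value for m = 9 is
0.05/9 ≈ 0.0056 (0.006 at three decimals). The implementation is
cross-checked against `statsmodels.multipletests(fdr_bh)`.

## 3. Phantom model

The generator emulates the *statistical structure* the analysis
assumes, not anatomy. Geometry: nested ellipsoids define background/CSF,
a GM ribbon, and a WM core on a 96³ isotropic grid by default. Spherical
lesions (radius 2–3 voxels, 3–5 per MS subject by default) are
rejection-sampled so each lesion's full shell family (radius + 5) lies
inside the WM core and is separated from every other family — ring
classes of different lesions are disjoint, keeping ground truth exact.
These counts are a deliberate scale-down from clinical lesion loads:
the disjoint-family requirement caps how many lesions a WM core of this
size can hold, and exact ground truth was prioritized over realistic
lesion counts.

Each biomarker map is painted piecewise constant: per-tissue means (WM,
GM; MS subjects receive additive NAWM/NAGM group effects) and a
lesion-to-shell radial profile, plus three Gaussian noise layers:

- **between-subject** σ (default: a quarter of the healthy-control
  subject range, reading a ~14-subject range as ≈ ±2 SD),
- **between-lesion, per ring class** σ (default: the configured
  lesion-level SDs; largest in the lesion core of qT1/qT2/qT2*/PD/QSM),
- **i.i.d. voxel noise** (default: the shell-3 SD, treating far-shell
  between-lesion spread as mostly measurement noise).

These identifications are heuristics: published lesion-level SDs mix
between-lesion and within-lesion variance, so using them as pure
between-lesion SDs overstates heterogeneity. The
`low_heterogeneity(scale)` preset damps the lesion layer; at scale 0.2
the pooled per-subject lesion-vs-PL difference sits ≥ ~5 between-lesion
SDs from zero for every biomarker (computed analytically from the value
tables and ring voxel counts), so the within-patient sign structure
holds in essentially every simulated patient. This calibration applies
to the default geometry; with very few small lesions the 7-voxel eroded
cores leave voxel noise dominant and the guarantee weakens.

Ground truth stores, per subject, the noise-free expectation of every
VOI mean (subject and lesion level), the drawn random effects, and
lesion centers/radii. Note that the NAWM expectation is a *mixture*
(far WM plus the painted PL/shell voxels, which stay inside the WM
mask); the stored expectations account for this exactly, so a σ = 0
cohort is recovered with zero error end to end.

Shell geometry during painting reuses `perishell.voi` — the identical
code path the analysis pipeline runs — so painted classes and extracted
VOIs coincide by construction. The T1w/T2w ratio is never written as a
map: the generator emits weighted images (T1w = ratio × 100, T2w ≡ 100)
and the pipeline recomputes the ratio, exercising the derived-map path.
One control lacks QSM by default (`missing_qsm_hc`), and
`coarse_modalities` can re-grid selected maps onto a coarser grid to
emulate resolution mismatch (off by default).

**Determinism.** Subject streams come from
`SeedSequence(master_seed, spawn_key=(group_key, index))`; adding
subjects or reordering groups never perturbs an existing subject.
Identical spec + seed give bit-identical volumes and byte-identical
pipeline outputs.

## 4. The subject-level marginal simulator

`simulate_subject_table` draws subject-level VOI means directly from
the phantom's model: the same per-subject and per-lesion effect
distributions, ring-class voxel counts from the shared shell-geometry
code, and voxel noise through its pooled standard error σ/√n. It
reproduces the renderer's subject-mean distribution without building
volumes and is used for Monte-Carlo calibration (type-I error of the
NAWM-vs-HCWM Mann–Whitney test over thousands of null cohorts;
sign-structure replicate fractions). It is *not* pathwise identical to
the renderer for a given seed: lesion radii are drawn without the
placement rejection stream, which shifts NAWM mixture weights slightly.

## 5. Limitations

- Piecewise-constant painting with additive Gaussian noise; no partial
  volume effects, no spatial noise correlation, no bias fields, no
  anatomy. The phantom validates the pipeline's arithmetic and
  statistics, not segmentation or registration quality.
- Lesions are spheres with disjoint shell families; confluent lesions
  and overlapping rims (handled by the analysis code via innermost-class
  priority) are not generated by default.
- Noise-scale identifications (Section 3) are heuristic; absolute
  power/type-II numbers from the phantom should not be read as clinical
  estimates. Type-I calibration is insensitive to these choices.
- The heterogeneity flag (lesion/shell-3 SD ratio > 1.5) is a
  descriptive diagnostic; borderline markers (MTsat, ihMTR under the
  default tables) can fall on either side under sampling noise.
- Exact tests fall back to the tie-corrected normal approximation in
  the presence of ties; with continuous synthetic data ties do not
  occur, but heavily rounded real data would engage the approximation.
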