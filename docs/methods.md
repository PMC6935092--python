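# Methods

`kelmplus` implements a learning-using-privileged-information (LUPI)
pipeline for classifying blood-pressure grades from ROI-based brain
morphometry, and a synthetic-cohort generator that makes every stage
testable without access to clinical imaging data. This note records the
models, the parameters that matter, the numerical choices, and the open
design decisions we resolved.

## Problem setting

Blood pressure is graded on the 2017 ACC/AHA four-category scheme from
systolic/diastolic pressure (SBP/DBP, mmHg): normal (grade 1, SBP < 120 and
DBP < 80), elevated (grade 2, SBP 120–129 and DBP < 80), hypertension stage 1
(grade 3, SBP 130–139 and/or DBP 80–89) and stage 2 (grade 4, SBP ≥ 140
and/or DBP ≥ 90; hypertensive crisis folds into grade 4). The and/or rules
overlap, so the highest applicable grade wins — this makes the assignment
total, single-valued and monotone in both pressures, which the tests verify
by exhaustive grid scan at 0.1 mmHg resolution. Printed grade tables
sometimes show "> 140" where the guideline text says "≥ 140"; we follow the
guideline text (≥ 140, ≥ 90).

Each subject contributes five ROI feature tables over the 90-region AAL
parcellation — gray-matter volume (GMV), white-matter volume (WMV),
cerebrospinal-fluid volume (CSFV), cortical thickness, cortical surface
area — plus per-ROI thickness summary statistics (vertex mean and variance)
used to build a sixth, network-based feature.

## Feature pipeline

**Normalization** is per subject: volumes are divided by the subject's
total brain volume (the summed GMV+WMV+CSFV over all ROIs when not supplied
externally); thickness by the subject's population SD of thickness across
its 90 ROI values; area by the subject's summed ROI area. The thickness
rule is the within-subject reading of "normalized according to the standard
deviation" — the only reading computable per subject in isolation, and the
one that parallels the per-subject area rule. Each normalization refuses to
run twice.

**Thickness networks.** Node set: the 90 ROIs minus a configurable
exclusion list, by default the 12 sub-cortical regions (bilateral
hippocampus, amygdala, caudate, putamen, pallidum, thalamus), leaving 78
cortical nodes. Which 12 regions count as sub-cortical is a modelling
choice, not an anatomical constant, hence the config knob. A per-subject
Pearson correlation "between ROIs" is not computable from one scalar per
ROI, so the default edge weight models each ROI's vertex thicknesses as
N(μ, σ²) and uses

    w(i, j) = exp(−[KL(i‖j) + KL(j‖i)] / 2),

the exponentiated symmetrised Gaussian Kullback–Leibler divergence — a
similarity in (0, 1] with unit diagonal that consumes exactly the stated
inputs (mean and variance). A `pearson_vertex` method is available when
vertex-level thickness vectors exist. The strict upper triangle of the
78×78 matrix in row-major order is the subject's 3003-dimensional network
feature; the ordering is fixed and recorded via systematic "ROIa-ROIb"
column names.

**Feature selection** is a two-stage filter fitted inside each training
fold only: a two-sample t-test keeps features with p strictly below
α = 0.05 (Welch by default; pooled variance by option; features constant in
both groups get p = 1), then the survivors are ranked by estimated mutual
information with the label (nearest-neighbour estimator, k = 3 neighbours;
an equal-frequency 8-bin discretised estimator as alternative) and the top
k kept, ties broken toward the lower original index. The post-MI
dimensionality k defaults to min(#survivors, #training subjects), capping
model capacity at the sample size. No multiple-testing correction is
applied — the filter is a screening step, not an inference.

## Classifiers

**Empirical kernel mapping (EKM).** For a kernel ker(·,·) (linear, or RBF
exp(−γ‖x−z‖²)), eigendecompose the m×m training Gram matrix K = PΛPᵀ, keep
eigenpairs with eigenvalue > tol·λ_max (tol = 1e-10), and map

    Φ(x) = Λ^(−1/2) Pᵀ (ker(x, x₁), …, ker(x, x_m))ᵀ ∈ R^r.

Inner products of mapped points reproduce kernel values up to the discarded
eigenvalue mass (tested at 1e-8 for full-rank maps). Eigenvector signs are
fixed by forcing each vector's largest-magnitude component non-negative, so
the map is reproducible across linear-algebra backends. The RBF γ defaults
to the median heuristic 1/(2·median squared pairwise distance).

**KELM.** With ±1 one-vs-all label matrix T (n×m) and training Gram Ω, the
kernel extreme learning machine solves the ridge system in closed form,
β = (I/C + Ω)⁻¹T, and scores test points as k(x, X_train)β with argmax
class decision. C > 0 trades training error against smoothness.

**KELM+ (LUPI).** Privileged features — available at training time only —
enter through their own Gram matrix Ω̃. The classical closed form is

    β = (Ω̃/ε + I/C)⁻¹ (T − (C/ε) Ω̃ J),        J = ones(n, m).

Carrying the KKT derivation of the underlying constrained problem through
in full (stationarity β = Hᵀλ substituted into the training constraint)
retains the main Gram Ω in the inverted factor:

    β = (Ω + Ω̃/ε + I/C)⁻¹ (T − (C/ε) Ω̃ J).

`train_kelm_plus` implements both; `include_main_gram=False` (the classical
form) is the function default, while the ensemble pipeline defaults to the
KKT-consistent variant because of two structural properties: it reduces
exactly to KELM as Ω̃ → 0 or ε → ∞ (so a member whose privileged feature
carries no usable signal can fall back to plain KELM), whereas the
classical form degenerates to β = C·T in those limits. The J term
contributes an identical offset to every score column and therefore never
changes the argmax decision; it is retained for fidelity to the closed
form. Either way, prediction uses only the main-feature kernel row —
privileged data are never consulted at test time, and the trained model
holds no reference to them.

**ELM+** (explicit random sigmoid hidden layers, weights/biases uniform on
[−1, 1], seeded) is retained as a baseline and as the correspondence oracle:
KELM+ with linear kernels applied to the explicit hidden matrices
reproduces ELM+ scores to numerical precision, which is the central
correctness property of the classifier core.

## Ensemble and evaluation

One feature type is the main feature; each remaining type (default: the
other five of GMV/WMV/CSFV/Thickness/Area/Network) is the privileged input
of one KELM+ member. Per feature type: select features on the training
split, fit an EKM on the selected training features, transform. Members
share the main-feature path. The final label is the majority vote over
members; ties (impossible for five members on a binary task) go to the
tied class with the highest summed member score.

Hyperparameters (C, ε, γ-scale) are tuned per member by inner stratified
CV maximizing member accuracy; the plain-KELM baseline used for comparison
is tuned by the same procedure (C and γ-scale), so the comparison is like
for like. Default grids: C ∈ 2^{−5,−3,−1,1,3,5}, ε ∈ {2⁻³, 1, 2³, ∞} (∞ is
the exact no-PI limit), γ-scale ∈ {0.5, 1, 2} times the median heuristic;
5 inner folds, mirroring the outer protocol's fivefold convention. The
grids are deliberately coarse so the full protocol stays at desk scale;
they are config fields, not constants.

Evaluation is stratified five-fold CV repeated five times (25 fold-level
results), everything refitted inside each training fold. Metrics: ACC,
SEN, SPC, Youden index YI = SEN+SPC−1, PPV, NPV, F1 = 2·PPV·SEN/(PPV+SEN),
reported as mean ± sample SD over folds, in percent. The positive class is
the higher blood-pressure grade (recorded in every report). Zero-denominator
metrics are reported as undefined and excluded from aggregation rather than
coerced to zero. Per-fold selections accumulate into a frequency ledger
whose maximum attainable count is n_folds × n_repeats = 25; the
discriminative-feature report ranks features by that frequency, ties by
name.

## Synthetic cohorts

No public dataset backs this problem, so cohorts are emulated at the
feature level. Defaults are the emulated study conditions: 73 subjects per
grade, four grades, 15 affected cortical ROIs drawn from
frontal/temporal/parietal association regions recurrently implicated in
hypertension morphometry. Per feature type, ROI values are Gaussian with
exchangeable inter-ROI correlation ρ = 0.3 (a common-factor construction),
baseline means/SDs in native units (GMV 6000±600 mm³, WMV 4000±450 mm³,
CSFV 1500±200 mm³, thickness 2.8±0.25 mm, area 2500±250 mm²). Affected
ROIs shift by −d·(grade−1)·SD for GMV/WMV/thickness/area and +d·(grade−1)·SD
for CSFV — a monotone grade-dose effect in the direction reported for
blood-pressure-related morphometric change, with default effect size
d = 1.5 per grade step. Thickness means are clipped to the 1–6.5 mm
segmentation bounds and other features to 1% of their baseline mean to
keep raw tables strictly positive (a mild truncation at extreme grades).
Per-ROI vertex variances are gamma-distributed around 0.2 mm². SBP/DBP are
drawn uniformly from bands strictly inside each grade's guideline region,
so the grade assignment round-trips exactly.

What the generator does **not** emulate: realistic cortical covariance
structure (real thickness/volume covariance is spatially organised, not
exchangeable), site or age effects, heavy-tailed measurement noise,
hemispheric asymmetry, or any image-level artefact. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it
assumes — grade-dependent mean shifts against correlated Gaussian noise —
not that it would achieve comparable accuracy on clinical data.

The separate `generate_separable` helper (two isotropic Gaussians at a
given centre distance) is unit-test fodder for the classifier core.

## Numerical choices and degenerate inputs

- Linear systems are solved with symmetric solvers rather than explicit
  inverses; tests cross-check against explicit-inverse oracles at 1e-8.
- Gram matrices are symmetrised (K ← (K+Kᵀ)/2) before eigendecomposition.
- An all-zero training Gram, a zero within-subject thickness SD, and a zero
  ROI thickness variance under the KL network are degenerate-input errors,
  not silent NaNs.
- An empty t-test survivor set yields an empty selection with a warning and
  the pipeline falls back to all features for that fold.
- Readers parse numerics via exact IEEE round-trip conversion; writers emit
  17 significant digits, so write-then-read is bit-exact.

## Problem sizes used in checks

The end-to-end protocol checks run the full study geometry: 73 subjects per
grade (146 for a binary task), 90 ROIs, 3003 network features, 5×5
stratified CV, with the powered run at d = 1.5 in the 15 default affected
ROIs and the null at d = 0. Structural and algebraic checks use small
random problems (n ≤ 50) where closed forms can be compared against
brute-force oracles exactly.

## Known limitations

- The classical KELM+ closed form (without the main Gram) cannot recover
  plain-KELM behaviour in any hyperparameter limit; on cohorts where the
  main feature is already the strongest signal it can sit slightly below a
  tuned KELM. The KKT-consistent variant is the pipeline default for this
  reason; both are exposed.
- Member errors are strongly correlated (all members share the main-feature
  test input), so the vote mainly stabilises rather than boosts accuracy.
- The MI nearest-neighbour estimator adds seeded jitter; results are
  reproducible given a seed but not across estimator choices.
- Multiclass (all-four-grade) classification is supported by the machinery
  but untested against any reference: the emulated studies are binary
  grade pairs.
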