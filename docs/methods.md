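# Methods

## Model and procedure

A quantitative structure model (QSM) represents one tree as a rooted
hierarchy of cylinders, each with a start point, a unit tip-ward axis, a
length and a radius (all metres), plus topology: parent, the "extension"
child continuing the same branch, branch id, position within the branch,
and branch order. The trunk is order 0 and the six primary scaffold
branches are order 1, so the pruning rules "not the trunk, not a primary"
translate to order > 1.

Given two co-registered scans of the same tree in consecutive winters and
one QSM per scan, the pipeline:

1. removes outliers from each cloud (SOR filter: a point is dropped when
   its mean distance to its k nearest neighbours exceeds the global mean
   of those values by more than `sigma_mult` standard deviations;
   defaults k=6, sigma_mult=1);
2. labels points by per-point nearest-neighbour distance to the other
   year's cloud against a threshold `tau` per cloud (strictly greater
   than `tau` means changed; default 0.030 m, the midpoint of the
   0.020–0.045 m range used in practice depending on alignment quality).
   Year-1 changed points are pruned branches; year-2 changed points are
   new shoots — the two labels can never compete on one cylinder;
3. transfers point labels to cylinders: a cylinder takes the year's
   candidate label when score(start) + score(end) < 0.100 m, where
   score(p) is the mean distance from p to its 10 nearest same-label
   changed points (all of them if fewer than 10 exist; +inf if none).
   Vetoes then revert changed cylinders with radius >= 0.020 m (one-year
   shoots stay thinner on these trees) and pruned cylinders of order <= 1;
   finally surviving labels propagate to all descendants, overriding
   vetoes there, because a removed branch is removed in its entirety;
4. fuses the two models: maximal pruned subtrees are extracted from the
   year-1 QSM and re-hung in the year-2 QSM, each base on the cylinder
   whose endpoint lies nearest its start (NEW_SHOOT cylinders are not
   eligible parents — a branch pruned in year 1 cannot hang on a shoot
   that did not yet exist; exact ties go to the smaller cylinder id;
   attachments beyond 0.2 m are logged as suspect). Cylinder ids are
   reassigned contiguously and every topological attribute is rebuilt
   from the root. At a junction, the child with the largest dot product
   between its axis and the parent's axis continues the parent's branch
   (ties: larger radius, then smaller id); every other child starts a
   branch of order + 1;
5. counts events per cylinder: n_pruned_children / n_new_children are the
   numbers of pruned / new-shoot *branch bases* whose parent is the
   cylinder (a base is a changed cylinder with a differently-labelled
   parent). The prediction target is −1 for pruned cylinders, otherwise
   min(n_new_children, 4) — counts above 4 are too rare to model;
6. benchmarks classifiers: pruned rows are dropped, two whole trees are
   held out for evaluation, the rest splits into train/test with test
   size ceil(0.2 × n) (this convention reproduces a 3,312-row test set
   from 16,558 usable rows). Default predictors are start x/y/z,
   axis x/y/z, branch order, position in branch, length, radius and
   n_pruned_children; identifiers and booleans are excluded, and
   n_new_children is the target source, never a predictor. The suite runs
   at library defaults: LGBMClassifier, GaussianNB, NearestCentroid, an
   MLP with hidden layers (64, 128) behind a standard scaler, logistic
   regression, random forest, decision tree and k-NN. Metrics are
   accuracy, balanced accuracy (unweighted mean per-class recall) and
   weighted F1, computed from confusion-matrix arithmetic in-package;
   precision for a never-predicted class is reported as 0 with a warning.

## Synthetic scenarios

Real two-winter nursery scans are not publicly available, so the
generator builds stylized table-topped plane trees with exact ground
truth: a 3 m vertical trunk (6 segments, 8 cm basal radius, short apical
stub above the scaffold whorl), six horizontal primaries at equal azimuth
(1.5 m, 7 segments, 2.5 cm radius), 3–5 second-order branches per primary
(4 × 0.25 m segments, 9–14 mm radius), 1–3 third-order branches per
secondary (2 × 0.25 m, 5–9 mm), all radii tapering 10 % per segment and
directions jittered up to 8°. Side branches attach at distinct segment
endpoints, never at the branch tip, and leave their parent axis at a
crotch angle of at least 60° — the wide-angle geometry of resprouts on
trained trees; this also keeps a branch from hugging its parent's
surface, where the change signal is physically ambiguous at any
threshold.

Each winter, whole order-2 subtrees and surviving order-3 branches are
pruned independently with probability 0.30. Retained radii grow by 8 %.
New shoots (2 × 0.22 m segments, 5–9 mm radius, elevation 45–85°) attach
at a uniform position in the middle of their parent cylinder — near, not
exactly at, the cut — with counts drawn from the planted rule:

- deterministic: one shoot iff the cylinder lost at least one child
  branch and sits at order >= 2;
- poisson: count ~ Poisson(exp(β₀ + β₁·n_pruned + β₂·order + β₃·radius)),
  truncated at 6; defaults β = (−3, 1.5, 0.3, 0).

Clouds are sampled on cylinder lateral surfaces at 6,000 points/m²
(Poisson per-cylinder counts), displaced by isotropic Gaussian noise of
2 mm, plus 0.2 % uniform bounding-box outliers; each surface point
carries its cylinder id and change label as truth. Clouds are generated
pre-aligned, mirroring manually aligned scan pairs; a rigid-offset
parameter exists for robustness experiments only.

Under these defaults about 94 % of retained cylinders carry no shoot,
matching the heavy imbalance of the real per-cylinder tables (> 92 %
zeros). The generator is deliberately *not* a biological growth model: no
internodes, no bud physiology, no L-systems. Passing tests therefore show
that the pipeline recovers planted structure under scanner-like noise and
realistic architecture — not that real resprouting is predictable; on
real data the signal strength is an empirical question.

## Numerical choices and conventions

- Distance thresholds use strict inequality; a point or score exactly at
  the threshold counts as unchanged.
- SOR keeps points equal to the cutoff; k is clipped to n−1 for tiny
  clouds, and a single-point cloud passes through with a warning.
- Endpoint scores with fewer than k same-label points use all of them;
  with none, the score is +inf, so empty change sets label nothing.
- Rule order in labelling is raw → veto → propagate, with propagation
  overriding vetoes on descendants (physical semantics of removal).
- The evaluation trees are a seeded random choice recorded in the
  report; splits use ceil for the test count; no stratification and no
  class weights (all models at library defaults).
- Balanced accuracy raises on a predicted class absent from the truth in
  strict mode (its recall is undefined); the benchmark uses the lenient
  mode, where extra predicted classes only depress true-class recalls.
- One global seed derives per-stage seeds via SHA-256, so reruns are
  byte-identical; generator scenarios spawn child seeds below 2³¹.
- CSV geometry is written with full float repr and parsed with pandas'
  round-trip parser, making the QSM CSV round-trip exact. Point clouds
  are ASCII PLY with integer truth properties.

## Problem sizes

The end-to-end recovery study uses 20 trees (~250 cylinders and ~45,000
points per tree-year); the learnability study uses 50 trees (~13,000
feature rows) — sizes at which every quantity of interest stabilizes
while the whole suite runs in about a minute. The real study's headline
classifier scores (e.g. binary accuracy 90.8 % / balanced accuracy
80.3 %) were measured on 28 real trees' LiDAR data; they depend on the
unknown real resprouting mechanism and are not reproducible from
synthetic scenarios, so the package's acceptance quantities are recovery
and learnability rates with known ground truth instead.

## Known limitations

- Labelling accuracy degrades when distinct branches pass within the
  cloud-to-cloud threshold of each other; the generator's wide crotch
  angles make this rare but real crowns are messier.
- Only the subtree base is re-parented during fusion; internal subtree
  topology is trusted (pruned branches are thicker and fit robustly).
- Whether a shoot count is taken per cylinder or per multi-cylinder
  branch segment is a modelling choice; the per-cylinder reading matches
  the per-cylinder label table the classifiers consume.
- New-shoot rows are included at training time by default (matching the
  printed dataset totals of the study system), although their existence
  is unknowable before resprouting; exclude them by filtering
  `change_label` if desired.
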