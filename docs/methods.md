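# Methods

## Rigid-body atom selection and angle enumeration

Each residue type maps to an ordered atom selection (topological order:
N, CA, CB, side chain outward, then C, O).  The built-in table
(`src/switchscan/data/selection_table.yaml`) keeps backbone N/CA/C/O, CB,
side-chain branch points, and terminal heteroatoms, and drops intermediate
ring carbons: TYR keeps {N, CA, CB, CG, OH, C, O} (7 atoms, 35 angles,
down from 220 for all 12 heavy atoms), and ARG drops CZ to reach 10 atoms
(120 angles).  The resulting sizes — ALA 5, SER 6, TYR 7, ILE/MET 8, GLN 9,
ARG 10 — pin the combinatorial denominators used throughout the report
metrics.  For the residue types not constrained by those counts the same
rule is applied; GLY (4 heavy atoms → 4 angles) and PRO (ring CG/CD kept)
are extrapolations of the rule and are called out here because reasonable
alternatives exist.  The table is an editable YAML file so users can
substitute their own selection without code changes.

An angle triplet is an unordered combination of three selected atoms,
canonicalized so the *vertex* is the middle atom in topological order (the
ALA triplet {O, C, N} is the angle at C).  One angle is computed per
triplet — arccos of the normalized dot product of the two arm vectors,
clamped to [−1, 1] — giving exactly C(k, 3) angles per residue.  Angles are
invariant under rigid motion and uniform scaling, so no superposition or
unit handling is needed at this stage.  Coordinates are used as supplied;
no periodic-boundary imaging is applied, on the assumption that
residue-internal distances are never wrapped.  This is a documented
limitation for triclinic/wrapped trajectories.

Trajectories (DCD/XTC, any number of files, order preserved) are pooled by
concatenation over a shared PDB topology via mdtraj; per-trajectory frame
ranges are carried through the pipeline as *segments* so that kinetic
quantities never bridge two independent trajectories.

RMSD uses Kabsch superposition solved in float64
(`scipy.spatial.transform.Rotation.align_vectors`), with residuals measured
by applying the optimal rotation explicitly; the rotation-library's reported
residual norm loses ~1e−8 to cancellation, which matters because rigid-copy
RMSD is asserted to 1e−9.

## Density of states and features

Each angle series is binned into 90 equal-width bins on [0, π] (2° per
bin) and normalized to total mass 1.  Binning is linear, not circular:
three-atom angles live on [0, π].  Before feature extraction the DoS is
smoothed with a 5-bin centered moving average (symmetric-reflection ends,
mass-preserving).  Modes are local maxima with prominence ≥ 5% of the
tallest bin and ≥ 5 bins apart (`scipy.signal.find_peaks`), sorted by
height with ties going to the lower bin.  The defaults resolve the ~0.9 rad
mode separations typical of switch angles with a wide margin; all are
overridable per call and through the pipeline config.

The 14 features are: mode count, major/minor mode locations and their
separation, major/minor heights, minor/major height ratio,
valley-to-minor-peak ratio (valley = minimum between the two tallest
modes), minor-side mass fraction (capped at 0.5; 0.5 means an even split),
major/minor FWHM (half-height crossings, linearly interpolated), and the
DoS variance, skewness, and bimodality coefficient (skew² + 1)/kurtosis.
Unimodal densities take sentinels: zero separation, zero minor
height/width/mass, minor location pinned to the major location.  All
features are functions of the empirical distribution only, so they are
invariant to duplicating the underlying series.  The feature list is fixed
by name in `switchscan.dos.FEATURE_NAMES` and versioned through the model
schema so a different feature set cannot silently be fed to a stored model.

A rule-based `heuristic_label` (exactly 2 modes, valley ratio < 0.5,
minor mass > 0.05) provides bootstrap labels and a fallback classifier; on
clear-margin synthetic data it agrees with generator truth ≥ 98%.

## Switch classification

Decision tree, random forest (100 trees), and gradient-boosted ensemble
(xgboost, 100 rounds, depth 3) are trained on the 14 features with
stratified 5-fold cross-validation (fixed-seed shuffling; accuracy reported
as "mean (std)" in percent).  Hyperparameters are deliberately plain and
overridable; no search is performed.  Models persist as a joblib document
with a schema version, the feature-name manifest, and training metadata,
and round-trip to identical predictions.

Classification is per angle; the residue-level switch flag is a rollup
(≥ 1 switch angle).  This two-level scheme is what makes ANSR (angle-level
count over C(k, 3)) and the residue switch class simultaneously available.

## Stability: instability ratio and the SS/US boundary

Frames of a switch angle are assigned to two states by 1-D k-means (k = 2,
scikit-learn) initialized at the 10th/90th percentiles of the series, so
the assignment is deterministic and independent of the seed argument;
states are relabeled so the lower-angle center is state 0.  Transitions
are counted on raw consecutive-frame labels — no dwell-time debouncing —
and never across trajectory seams.  The instability ratio is
100 × transitions / total frames; "length of the trajectories" is taken
as the pooled frame count (a frame-interval unit conversion can be applied
by the caller).

A 1-D logistic regression on the ratio (C = 1000, i.e. near-unregularized,
so the boundary falls near the class gap) separates SS from US; the model
validates slope > 0 (flipped labels raise immediately) and exposes the
P = 0.5 ratio as the decision boundary.  Trained on clear-regime examples
(SS < 1%, US > 6%) the boundary lands strictly inside (1%, 6%) — around
4% — and CV accuracy is 1.0.  Ties at exactly P = 0.5 go to US by
convention.  A residue's grade is SS if *any* of its switch angles is SS,
matching the notion that one stable switching angle suffices to couple the
residue to a global transition; majority voting can be layered on by the
caller from the per-angle stability table.

## Residue metrics and property correlation

ANSR is reported as an explicit fraction (numerator = switch angles,
denominator = C(k, 3)); ATSC counts each atom's membership in switch
triplets (vertex and ends alike), so ΣATSC = 3 × switch-angle count — this
conservation is enforced as a validation invariant.  The ranked report
lists switch residues only: SS before US, ANSR descending, ties by residue
index.

State-conditioned property summaries take any per-frame scalar series
(RMSD, an activation level, a Cα–Cα helix distance) aligned with the state
trace and report per-state means, their difference, and the point-biserial
correlation (Pearson correlation of the binary state with the property;
defined as 0 when either series is constant).  The statistic is chosen
because the state is binary; no external activity predictor is bundled —
any user-supplied property series slots in.

## Synthetic ground truth

`AngleDynamicsSpec` describes one angle's dynamics: mode centers/spreads,
mixture weights, a transition schedule (SS), or a per-frame switch
probability (US, a symmetric first-order Markov chain whose expected
transition count is rate × (n − 1)).  Per-frame values are
truncated-Gaussian around the active center, confined to [0, π]
(`scipy.stats.truncnorm` driven by a seeded Generator; bit-for-bit
reproducible).  Defaults — centers 1.6/2.5 rad (separation 0.9 rad),
spread 0.08 rad — reflect the typical geometry of switch angles, whose
two states sit roughly in the 1.5–1.8 and 2.4–2.7 rad ranges.

The labeled corpus balances three classes (unimodal / clean bimodal, half
SS half US / bimodal-with-intermediate) with per-item randomized geometry
inside clear-margin ranges: base center U(1.3, 1.7) rad, separation
U(0.7, 1.0) rad, spreads U(0.05, 0.09) rad (≥ ~7σ separation),
intermediate-state weight U(0.15, 0.35).  Only clean bimodal items carry
switch label 1.  These margins emulate the unambiguous cases a human
labeler would mark confidently; the corpus does **not** emulate borderline
densities (partially filled valleys, minor masses near the detection
floor, drifting mode centers), so classifier accuracies measured on it
(~100%) characterize pipeline correctness on separable data, not expected
accuracy on real MD data.

Toy 3-D systems place five-atom ALA-like residues 0.6 nm apart; in each
dynamic residue the O atom orbits the CA vertex in-plane at 0.24 nm with N
fixed on the +x axis, so the designated N-CA-O angle equals the generated
schedule exactly and all other atoms are static.  Coordinates are kept
within ~2 nm of the origin because DCD stores float32: the round-trip
reconstruction error of the designated angle stays below ~5e−7 rad
(asserted at 1e−6).  Because the moving O atom participates in several
triplets, a dynamic toy residue legitimately has multiple switch angles
(ANSR 5/10), all sharing the residue's kinetics.

## Pipeline and determinism

`run_scan` executes geometry → DoS → classification → stability → metrics
and writes features, per-angle stability rows, the ranked report (CSV and
JSON), and a provenance record (config hash, seed, version, row counts).
When no trained model is supplied it trains one on an internally generated
synthetic corpus from the run seed; the SS/US logistic model is likewise
trained on synthetic clear-regime ratios (100 per class, SS U(0.05, 0.95)%,
US U(6.5, 30)%).  With a fixed config the whole run is deterministic to
the byte; the provenance record deliberately excludes timestamps.
Residues whose selection atoms are missing from the topology are skipped
with a log line rather than failing the run; genuinely constant switch
angles (no two resolvable states) are demoted to nonswitch.

Problem sizes used by the test suite and the acceptance script — 600-item
corpora of 2000-frame series, 1000-frame toy systems, 5000-frame
assignment checks — were chosen so every statistical check sits far from
its threshold while the whole suite runs in seconds.

## Known limitations

- No periodic-boundary imaging; wrapped trajectories must be made whole
  upstream.
- Selection entries for the 13 residue types not pinned by printed angle
  counts are rule-based reconstructions; swap in your own table if you have
  the authoritative one.
- Two-state stability only: angles with three or more populated states are
  excluded at the switch-classification stage by design.
- The bundled classifier is trained on synthetic data by default; for
  production use on real trajectories, train on a manually labeled feature
  set via `switchscan train` and pass the model path in the config.
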