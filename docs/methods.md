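# Methods

## Model and procedure

The package detects B-cell lymphomas by comparing a test case's lymphocyte
distribution with per-cohort reference distributions ("profiles") in a 3-D
marker space, x = kappa − lambda, y = CD19, z = CD5 − CD10.  Subtracting
paired markers cancels shared background: a clonal (malignant) B-cell
population expresses a single light chain and so polarizes along x, while
CD5 − CD10 separates the CLL (z > 0) and FL (z < 0) immunophenotypes.
CD45/SSC-A and FSC-A/FSC-H never enter the model; they exist for
pre-processing only.

A profile is a k-component Gaussian mixture with full covariances fitted
to the pooled events of the training cases — k = 3 for healthy cohorts
(kappa-B, lambda-B, T) and k = 2 for patient cohorts, where light-chain
restriction leaves a single B cluster.  Each component is rendered as the
ellipsoid of points within Mahalanobis distance m of its mean.  "Within m
standard deviations" is interpreted as Mahalanobis distance ≤ m (boundary
inclusive): it is the only reading that produces a single ellipsoid from a
mean and a covariance, and it gives the closed-form calibration that a
matched Gaussian cluster is captured at rate χ²₃(m²) — 73.85 % at m = 2 —
which the test suite verifies by Monte Carlo.

Fitting a test case proceeds top-down because the clusters of interest can
be close or intersecting: T cells are split from B cells first on the
CD19 axis alone (T cells lack CD19), the remaining B cells are K-means
clustered into k − 1 groups, and the profile is rigidly translated by the
offset between its T-cell center and the case's T-cell center before
counting captures.  This T-cell anchoring makes the cell capture rate
(CCR) exactly invariant to global translations of the case — the batch
effect it is designed to absorb — while preserving inter-cluster
distances, which per-cluster alignment would not.  The CCR numerator
counts each B event at most once even if two B ellipsoids overlap, so
CCR ∈ [0, 1] by construction; the denominator is the case's total B-cell
count, which keeps the healthy-vs-healthy rate high and discriminative.

Diagnosis maps the vector (CCR_Normal, CCR_CLL, CCR_FL) to the nearest
coordinate axis: d_i = sqrt(Σ_{j≠i} CCR_j²), label = argmin d_i.  Exact
ties return "Inconclusive"; a diagnostic tool should not silently prefer
one disease label over another.

## Light-chain orientation

Restricted cohorts come in kappa- and lambda-dominant presentations.  Two
symmetric choices keep a single profile per disease: training cases are
mirrored through x = 0 to a canonical kappa orientation before pooling,
and at test time patient profiles are evaluated both as-is and mirrored,
keeping the larger CCR.  Either side alone would mis-serve the opposite
presentation; together they make the profile orientation-free without
doubling the profile count.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `m` | 2.0 | ellipsoid size in standard deviations; capture of a matched cluster is χ²₃(m²) (m=1: 19.9 %, m=2: 73.85 %, m=3: 97.1 %) |
| `ratio_tolerance` | 0.3 | doublet gate: keep events with FSC-A/FSC-H within ±30 % of the case median |
| `bypass` (gate) | off | skip the CD45/SSC-A mixture gate for pre-gated input |
| `asinh_cofactor` | off | optional asinh variance-stabilizing pre-transform; raw intensities are modelled by default since compensation/scaling conventions vary by instrument |
| `fraction` | 0.15 | share of each cohort used as training data in the selection protocol (round-half-up, minimum 1) |
| `random_state`/`seed` | 0 | K-means++ seeding for profile building and B-cell clustering |

Numerical choices: EM stops at relative log-likelihood change < 1e-6 or
500 iterations; K-means uses k-means++ with 10 restarts; covariances carry
a 1e-6 ridge (scikit-learn's `reg_covar`) against singularity; an EM run
that empties a component is retried once with a shifted seed and then
fails loudly.  The T/B split is an exact 1-D two-means (sorted-sweep
minimization of within-group sum of squares), deterministic and
translation-invariant; ties in the sweep take the first minimizing split.
A K-means B-clustering that collapses a cluster falls back to the pooled
mean for the empty center.  The T-cell component of a profile is the one
with the lowest y (CD19) mean.

## Experiment designs

The cross-validation plan uses 3 disjoint folds of 12 donors for the
normal profile and leave-one-out rounds (training on a single patient) for
CLL and FL.  With cohorts of 36/21/15 this yields exactly 180, 1491 and
1065 profile evaluations, and the triple grid — every (normal fold, CLL
round, FL round) combination diagnosing every case held out from all
three trainings — yields 3·21·15·(24+20+14) = 54,810 diagnoses, split
22,680/18,900/13,230 by true cohort.  These counts are closed-form
functions of the cohort sizes and are asserted against the executed grid;
a leakage check ensures no case is ever evaluated against a profile
trained on it.

The selection protocol replaces cross-validation with a single ~15 %
training split: healthy donors are sampled at random (healthy samples are
homogeneous), while patient training cases are those whose T-to-B
cluster-center distance is nearest the cohort mean — the most "typical"
presentations.  The selected count uses round-half-up with a floor of 1,
so cohorts of 44/21/15 train on 7/3/2 cases and test the remaining 68.

## Synthetic data: what it emulates, what it does not

The generator emulates the structure the method assumes: Gaussian
populations over the nine channels with a granulocyte population (CD45
mid, SSC-A high) for the gate to reject, a T population, and cohort-
appropriate B populations; doublets injected by doubling FSC-A at a 5 %
rate; and a per-case global intensity shift realized on the kappa, CD19
and CD5 channels so the 3-D projection translates rigidly.  Default
geometry places cluster means 8 units apart at per-channel standard
deviation 0.5 — at least 11 pooled standard deviations, an "easy regime"
chosen so that every pipeline stage's correctness is identifiable from
ground truth rather than confounded by overlap; a `difficulty` knob
shrinks the separations to probe failure modes.  Per-case event counts
are uniform in [2000, 4000] (the scale of gated lymphocyte counts in
clinical panels, and comfortably inside the test-time budget) and global
shifts uniform in ±2 units per axis, i.e. up to ~3 cluster standard
deviations — large enough that un-anchored capture would visibly fail.

Real cytometry data is not Gaussian (log-normal-ish tails, autofluorescence,
spillover after compensation, debris, rare populations), shifts are not
perfectly rigid, and patient B clusters vary in shape between stages of
disease.  Passing the synthetic screen therefore demonstrates that the
algorithmic chain is implemented correctly and behaves as designed under
its own assumptions; it is not evidence of clinical accuracy on patient
material, which would require validation against expert-gated FCS files.

## Problem sizes

The test suite and the acceptance script run the full study design at the
published cohort sizes (44/21/15 cases; 36/21/15 with 12-donor folds for
the bookkeeping) with the generator's default 2000–4000 events per case;
single-case unit tests use 500–3000 events.  The Monte-Carlo capture check
uses 100,000 draws; the mean-recovery check 20 generator seeds at 3000
events.

## Known limitations

- Only CLL and FL profiles are modelled; CD5−/CD10− restricted lymphomas
  (e.g. some MCL/DLBCL) would need a third patient profile, which the
  multi-profile design accommodates but this package does not ship.
- Spectral compensation, time-channel QC and non-rigid (scaling/rotation)
  alignment are out of scope.
- FCS support is minimal by design: list-mode float data and channel
  names, enough to round-trip event matrices; keyword-level fidelity and
  integer/log-amplified legacy files are not handled.
- The lymphocyte gate assumes exactly two populations on (CD45, SSC-A);
  marrow or heavily contaminated samples should be pre-gated and passed
  with `bypass=True`.
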