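# Methods notes

## The distance model

A treatment course is an ordered event sequence; its distance to another
course is the minimum-cost edit script (unit insertions/deletions,
attribute-weighted substitutions) divided by the longer sequence length.
Two modelling commitments deserve emphasis:

**Missing/unrelated values carry maximum distance, even from themselves.**
`d(Missing, Missing) = 1` for every attribute, mirroring the MI–MI cell of
the therapy-type matrix.  The intent is epistemic honesty: two
undocumented values are not evidence of similarity.  A consequence is that
an event (and hence a course) containing missing attributes has a
*positive self-distance*; the pairwise `DistanceMatrix` nevertheless
forces a zero diagonal because the embedding stage requires one.  The
semantic self-distance remains available through `course_distance(a, a)`.

One deliberate exception: a *documented-empty* complication set compared
with another documented-empty set has Jaccard distance 0 — explicitly
recording "no complications" is informative agreement, whereas an absent
list (state Missing) keeps distance 1.

**Normalisation by max length.** The raw edit cost of comparing a k-event
course with an empty course is k; dividing by max length maps every course
distance into [0, 1] and makes short and long courses comparable.  Two
empty courses get distance 0 (the limit of identical sequences).  Because
substitution costs are bounded by 1, appending the same fully documented
event to both courses can never increase the normalised distance.

Ordinal ranges are UICC 4, ECOG 4, grading 8 (the full oncology grading
code list from conjunctival-melanoma 0 to undifferentiated 8), residual
status 3 (R0=0, R1is/R1cy+=1, R1=2, R2=3).  UICC substages (IA, IIB, …)
are mapped to their main stage for distance purposes; the substage label
is kept as a survival covariate.  The therapy-type matrix ships as a
versioned CSV (decimal commas normalised at load); all weight vectors are
overridable but validated to sum to 1.

## Clustering pipeline

UMAP (2D, metric "precomputed", n_neighbors 25, min_dist 0.1, seed 42 by
default) precedes clustering both to sharpen separability and to give a
plottable plane.  Embedding determinism holds per platform only; numerical
differences across BLAS/OS builds can shift coordinates slightly, so no
test asserts exact coordinates.

Grid search covers:

- hierarchical complete linkage, `distance_threshold` log-spaced 0.1–30
  (25 values) — a single SciPy linkage is cut at every threshold;
- DBSCAN, `eps` linear 0.05–2.0 (20 values) × `min_samples` {5, 7, 10, 15, 25};
- HDBSCAN, `min_cluster_size` {10, 25, 50, 100, 200} × `min_samples` {5, 10, 25}.

A configuration is admissible if its cluster count falls in the requested
granularity band and at most 5% of points are outliers (label −1).
Outliers are excluded from both the cluster count and the silhouette.  The
silhouette is computed on the 2D embedding with Euclidean distance —
that is the space the clustering algorithms actually operate in; ties are
broken deterministically by (algorithm name, parameter tuple).  When no
configuration is admissible the result is flagged band-unsatisfiable
rather than raising.  Silhouette is undefined for a single cluster; such
candidates carry NaN and rank below any scored candidate.

The 15–30 cluster range used by the survival workflow is just another
`GranularityBand` (`SURVIVAL_BAND`); nothing in the machinery is specific
to the three report bands.

## Survival workflow

- Landmark origin: diagnosis date + 56 days; patients dying earlier are
  excluded by the subcohort filter, avoiding immortal-time bias.
- Right censoring at a fixed registry linkage date (default 2023-06-30).
- 4 years is taken as 1460 days from the landmark origin.
- Kaplan–Meier CIs use the log-log (exponential Greenwood) transform, the
  standard choice that keeps bands inside [0, 1].
- Zero-death clusters are reported as excluded with a reason, never
  silently dropped; the reference cluster is the one with the highest
  observed 4-year survival (ties: larger cluster, then smaller label).
- The Cox model codes cluster membership, UICC substage and grading as
  categoricals (references: the selected cluster, the first substage —
  IA for favourable, IIIA for unfavourable cohorts — and the lowest
  grading), age linearly, lobular histology as a binary flag.  A DBSCAN
  outlier label (−1) participates as its own cluster level.  Constant
  design columns are dropped before fitting.
- G-computation: for every cluster value c, all patients are
  counterfactually assigned to c, their model-predicted survival curves
  are averaged, and the averages are compared across c.  Individual curves
  are built from Breslow baseline-hazard increments through the
  product-integral S_i(t) = Π (1 − ΔH₀(t_k) · exp(lp_i)), clipped at 0.
  The product form (rather than exp(−H)) was chosen so the estimator
  degenerates exactly to the pooled Kaplan–Meier curve when all
  coefficients are zero — which makes the null-model identity testable to
  machine precision and keeps adjusted and unadjusted curves on the same
  footing in small samples.  Curves are truncated at the maximum observed
  time.

## The synthetic registry generator

The generator emulates the *structure* of a registry extract, not its
epidemiology.  Archetypes define the joint behaviour; published marginals
only calibrate the mixture.  The default set (weights in parentheses):
diagnosis-only in three age bands (.180/.062/.138), surgery-only BCS
(.123) and mastectomy (.037), BCS+radiotherapy (.094), BCS+hormone therapy
with a 10% chance of additional RT (.175), multimodal neoadjuvant
chemotherapy courses (.170, 85% mastectomy, chest-wall RT), and a small
implausible archetype with radiotherapy dated before breast-conserving
surgery (.022) for data-quality workflows.

Design choices worth knowing:

- **Marginal calibration.** Weights were solved so that age bands land
  near 47.7/15.5/36.9% and treatment modality totals near BCS 43.9%,
  mastectomy 18.1%, systemic therapy 34.5%, radiotherapy 31.2% at cohort
  scale (all within ±5 points at n ≥ 5000).
- **Age-band dominance.** Each treated archetype draws ~86% of its
  patients from one age band.  Treatment clusters in registry data are
  age-stratified, and a categorical age attribute at weight 0.2 would
  otherwise split mixed-age archetypes into age sub-clusters.
- **Documentation quality follows treatment.** Diagnosis-only records get
  higher missingness (UICC .45, ECOG .75, grading .55) than treated
  records (UICC .30, ECOG .55, grading .10): without surgery there is no
  pathology report to feed the registry.  This is both realistic and what
  keeps data-poor records from fragmenting by sporadically documented
  attributes.
- **Truth vs. documentation.** Every patient has true covariate values
  (used by the survival-generating hazard) and a documented view (after
  masking); the truth table records archetype, planted log hazard ratio
  and the uncensored event time.
- **Survival.** Exponential baseline 6e-5/day (≈ 91.6% four-year survival
  at the reference), archetype log-HRs from −0.4 (BCS+RT) to +0.9
  (diagnosis-only), covariate effects for age (0.06/year around 60),
  grading, stage and lobular histology; censoring at 2023-06-30 with
  diagnosis dates uniform over 2019.  Inter-event gaps are lognormal
  (roughly 20–80 days), with neoadjuvant therapy dated before and adjuvant
  therapy after the surgery by construction.

What passing tests on this generator do *not* show: robustness to joint
distributions the generator does not model (treatment choice conditional
on stage, reporting-source structure, inter-registry coding variation),
to courses much longer than five events, or to real-world missingness
correlation patterns beyond the treated/untreated split.

## Problem sizes used in the validation suite

Archetype-recovery runs use n = 1000 patients (coarse band), marginal
checks n = 10 000, Cox calibration 200 replicates of n = 600, and the
edit-distance oracle pairs of up to 4 events — sizes at which the brute
oracles stay exact and a full run of the suite completes in a few minutes
on one CPU.

## Known limitations

- Event dates influence only the event *order*; gap lengths between
  events carry no weight in the distance.
- The grading ordinal mixes two coding systems (G1–G4 and the low/
  intermediate/high-grade triplet) on one 0–8 scale, as coded in oBDS.
- No Damerau transposition: swapped adjacent events cost an insertion
  plus a deletion.
- Proportionality of hazards across clusters is assumed, not tested
  beyond convergence diagnostics from the fitter.
- The CLI exports static SVG; no interactive selection or tooltips.
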