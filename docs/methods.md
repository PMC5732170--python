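# Methods

This note documents the models, numerical choices and limitations of
`lungquant` — what each stage assumes, which knobs matter, and what the
synthetic data can and cannot establish about real CT cohorts.

## Nodule segmentation

Nodules are extracted by constrained seeded region growing: the mask is the
connected component, under 26-neighbourhood connectivity, of voxels whose HU
lies in a band around the user-placed seed, followed by per-axial-slice hole
filling. The default band **[-750, 200] HU** is our choice for "ground glass
through solid": pure lung parenchyma (~-850 HU) stays out, ground-glass
(~-750 to -300 HU) and solid/soft-tissue components (up to +200 HU) stay in.
The band is configuration, not a claim about any particular clinical tool's
internal thresholds, which are not public. A seed whose own HU falls outside
the band is treated as user error and rejected rather than silently growing
from a shifted position. Growing is invariant to the choice of seed within
the same in-range connected component (it returns the whole component), and
manual edit operations (union of additions, then subtraction of removals,
removals winning on conflict) are logged.

Lung masking, needed only to restrict the peritumoral shell to lung, uses a
-400 HU threshold, discards components touching the volume border (outside
air), keeps components at least 5 % the size of the largest (so both lungs
survive while noise does not) and fills holes in 3-D (recovering dense
structures enclosed in lung, e.g. the nodule itself).

## Texture exemplars and glyphs

**Patch features.** A voxel's texture is its 9×9 in-plane HU neighbourhood.
The feature map clips HU to [-1024, 200] (air to soft tissue; denser values
carry no parenchymal information) and rescales to [0, 1]; similarity between
patches is the negative squared Euclidean distance of these 81-vectors. Raw
clipped intensity is the simplest faithful reading of "nearest exemplar by
patch similarity"; the map is pluggable so histogram or gradient features
can be swapped in without touching the clustering or classification code.
Patches are strictly 2-D (in-plane) because axial spacing is routinely
anisotropic (1-5 mm slices versus sub-millimetre in-plane), which would let
the z-axis dominate any 3-D patch metric.

**Affinity propagation.** Exemplars are found by standard
responsibility/availability message passing with damping 0.9, at most 1000
iterations, and convergence declared when the exemplar set is stable for 50
consecutive iterations. The shared preference (self-similarity) is placed on
the diagonal; the number of exemplars grows with the preference, so we
bisect it (starting from the median off-diagonal similarity, bracketed by
zero above and a large negative value below) until exactly the target
number of exemplars emerges, with a 60-run attempt budget. Exact duplicate
points are a known degenerate fixed point of symmetric message passing; we
break the symmetry deterministically with an infinitesimal penalty
(~1e-9 of the similarity scale) on higher-index exemplar candidates, which
also implements the documented tie rule: the lowest index wins. In the
limit of one requested exemplar the procedure reduces to the exact 1-medoid
(the point with maximal summed similarity), which the tests verify by
exhaustive search.

**Colour assignment.** The nine exemplars are ranked by mean patch HU and
mapped, lowest to highest, onto **B, C, G, Y, P, V, I, R, O** — the
ground-glass-like colours (B-C-G) land on the least dense textures and the
solid-like colours (V-I-R-O) on the densest, matching the radiologic
reading of lepidic versus invasive components. This ordering is a documented
convention, configurable in principle; nothing downstream depends on more
than the induced group partition {V,I,R,O}, {B,C,G}, {Y,P}.

**Classification and composites.** Every mask voxel's reflect-padded 9×9
neighbourhood is compared against all nine exemplars; ties go to the lowest
index in the canonical colour order V, I, B, G, Y, O, R, C, P. The glyph is
the percentage distribution over colours (sums to 100 within 1e-6 by
construction); composites V-I-R-O, B-C-G and Y-P partition it exactly, so
in any cohort with constant B-C-G the correlation of V-I-R-O and Y-P is
exactly -1 — on real cohorts, where B-C-G varies, the correlation is merely
strongly negative. The registered cutoffs (V-I-R-O ≤ 71 %, Y-P ≥ 23.5 % of
tumor volume, boundaries inclusive) are applied as published values, not
re-derived; `threshold_at_sensitivity` exists to derive such cutoffs on new
cohorts.

**Risk groups.** Cohort-wise Good/Intermediate/Poor stratification clusters
the 9-dimensional glyph vectors with PAM-style k-medoids (k = 3, squared
Euclidean distance, seeded initialisation) and orders the clusters by
ascending mean V-I-R-O: more solid texture, worse prognosis. An all-identical
cohort is degenerate; everyone is assigned Intermediate with a warning.

## Peritumoral shell and parenchyma classes

The shell is defined by the Euclidean distance transform of the nodule
complement with **anisotropic physical spacing**: a voxel belongs to the
shell when its distance to the nearest nodule voxel is ≤ 10 mm (default,
configurable), it lies in the lung mask, and it is not itself nodule. By
construction shell ∩ nodule = ∅ and shell ⊆ lung; the tests verify the
distance bound voxel-by-voxel against a brute-force scan.

The shell's bounding box is tiled with non-overlapping 15³-voxel VOIs;
blocks keep at least 30 % in-shell occupancy by default (a compromise for
thin shells; at 100 % almost no block around a small nodule qualifies).
Fractions are **voxel-weighted**: each VOI contributes its in-shell voxel
count to its class. Whether the original tooling weighted by VOI or by voxel
is not public; voxel weighting makes thin-shell results insensitive to how
blocks happen to straddle the boundary. When no block qualifies the summary
falls back to per-voxel HU banding. VOI statistics are computed over
in-shell voxels only, so tumor or chest-wall voxels inside a block cannot
contaminate its class.

Classification is a transparent rule table rather than a re-derivation of
the original clustering classifier (whose training VOIs are unavailable).
Defaults, all configuration:

| rule (checked in order)                  | class |
|------------------------------------------|-------|
| fraction of voxels < -950 HU > 0.5        | LA    |
| cyst-wall score > 0.05                    | HC    |
| mean < -950 HU                            | LA    |
| mean in [-950, -700] HU, SD < 80          | N     |
| mean in (-700, -300] HU, SD < 120         | GG    |
| otherwise (high SD or mean > -300)        | R     |

The cyst-wall score is the fraction of in-shell voxels that are cystic air
(< -910 HU) directly adjacent (6-neighbourhood) to dense wall (> -300 HU) —
a minimal operationalisation of honeycombing. -950 HU is the standard
emphysema threshold; the N/GG boundary at -700 HU and the texture SD limits
are our defaults chosen so that clean synthetic textures (normal -850±40,
ground glass -500±60, emphysema -980±12) classify unambiguously. The
fibrosis score is fraction(GG) + fraction(R) + fraction(HC) identically, and
the five fractions always form a probability vector.

A consequence worth knowing: a VOI mixing normal and fibrotic voxels has a
high HU standard deviation and classifies as R. The shell fibrosis score is
therefore an *upper* bound on the voxel-level fibrotic fraction near the
nodule and saturates quickly as severity rises. It remains monotone in the
generator's severity (verified over a 5-level × 5-seed ladder), which is
the property the analysis relies on.

## Synthetic phantoms

The phantom is two ellipsoidal "lungs" of Normal(-850, 40) HU parenchyma in
a non-negative soft-tissue body — sufficient geometry for texture work; no
airway tree, vessels or scanner physics, which the method does not use.
Emphysema is placed by thresholding a smoothed Gaussian random field at the
quantile giving exactly the requested lung fraction, textured at
Normal(-980, 12) HU. Fibrosis voxels are ranked by a fixed score (0.7 ×
pleural proximity + 0.3 × smooth noise) and the top `0.5 × severity`
fraction of non-emphysema lung is textured at Normal(-480, 70) HU; because
selection is by rank on a seed-fixed score, the fibrotic region at lower
severity is a subset of that at higher severity, which is what makes the
monotonicity property testable rather than merely probable. Nodules are
digital balls in physical mm; the solid core radius is
`r·(1 - lepidic_fraction)^(1/3)` so the volume split is exact for a
continuous ball; the mask is purely geometric (seed-independent) while the
HU texture is seeded. All generators are bit-reproducible for a fixed spec
and seed.

## Synthetic cohorts

Per subject: smoking is categorical (never/former/current = 0.12/0.65/0.23,
matching the demographic table packaged with the fixtures), and exemplar
shares are scaled Beta draws — Y ~ 100·Beta(2,8), G ~ 100·Beta(2,9),
P ~ 50·Beta(2,18), B, C ~ 40·Beta(2,18) — with the whole vector redrawn in
the rare case the ground-glass shares exceed 97 % of the nodule. V-I-R-O is
**derived** as `100 - (Y+P) - (B+C+G)` rather than drawn independently: an
independent draw would violate the partition identity that every downstream
consumer assumes. It is split into V, I, R, O at fixed proportions
(0.35/0.25/0.25/0.15). Fibrosis and low attenuation are Beta(1.5, 8.5)
fractions (mean 0.15), jointly renormalised in the measure-zero case their
sum exceeds 1.

The EGFR label is Bernoulli with

    logit = β₀ + β_Y·Y% + β_G·G% + β_never·1[never smoker] + β_fib·fibrosis

defaults β₀ = -3.8, β_Y = 0.06, β_G = 0.05, β_never = 2.0, β_fib = -4.0
(fibrosis on the fraction scale — the percent-vs-fraction convention is not
standardised anywhere, so we fix fractions and document it). These give
~14 % EGFR prevalence — in line with North American surgical series — with
the reported effect directions. KRAS is drawn only among EGFR-wild-type
subjects (probability 0.44), enforcing the observed mutual exclusivity.
DFS is exponential per risk group (scales 80/48/24 months for G/I/P) with
administrative censoring at 60 months; risk group is assigned from V-I-R-O
(≤ 35 → G, ≥ 70 → P, else I).

What passing tests show: the *pipeline* recovers the generative structure —
coefficient CIs cover the truth, stepwise selection separates signal from
noise, nested models order their AUCs as expected. What they do not show:
that real CT cohorts have this structure. Real nodules are not spheres,
real fibrosis is not a thresholded random field, features are not
independent Betas, and real effect sizes are unknown; cohort-level AUCs,
odds ratios and correlations from any particular patient series are
properties of that series and are deliberately not reproduction targets.

## Statistics: numerical choices

- **Fisher exact, r×c**: full enumeration of tables with the observed
  margins; two-sided p by probability ordering (sum of probabilities of
  tables no more probable than observed, with a 1e-7 relative tie
  tolerance, the convention of the major statistical packages). An
  enumeration budget (~2×10⁶ tables) guards the combinatorics; larger
  tables are directed to the chi-square test.
- **Wilcoxon rank-sum**: midranks for ties; exact by enumeration of all
  C(n+m, n) assignments when n+m ≤ 12, else tie-corrected normal
  approximation with continuity correction.
- **Logistic regression**: statsmodels IRLS; separation is flagged (perfect
  prediction warnings or |β| > 50) rather than raised.
- **Stepwise**: entry by Rao score test (needs only the current fit), stay
  by Wald test, both at α = 0.05 by default — the procedure's classical
  defaults; the alphas are configuration. Collinear candidates have
  score-test variance ~0 and never enter; a visited-set guard prevents
  add/drop cycles; empty selection returns the intercept-only model.
- **ROC**: thresholds at every distinct score; trapezoidal AUC, which
  equals pairwise concordance with half-credit ties (asserted to 1e-12 in
  tests). The sensitivity-targeted cutoff maximises specificity subject to
  sensitivity ≥ target; exact ties go to the least strict threshold.
- **Recursive partitioning**: one exhaustive CART split minimising weighted
  Gini impurity over midpoints of sorted distinct values; ties keep the
  earlier feature and lower cutpoint.
- **Cox**: own Newton-Raphson solver on the **Breslow** partial likelihood
  (simplest tie convention; ties are rare at the scales used), with step
  halving and covariate centring; the likelihood-ratio statistic is tested
  against chi-square. Kaplan-Meier estimation is delegated to lifelines.
- No multiple-testing adjustment anywhere: p < 0.05 is the significance
  convention of the analysis this package implements.

## Problem sizes

The test and acceptance runs use 32³ phantoms for exhaustive per-voxel
oracle comparisons, 64³ phantoms for segmentation/shell/fibrosis checks,
cohorts of n = 5000 × 20 replicates for coefficient coverage, n = 1000 × 20
for stepwise accuracy and AUC ordering, and ~100-patch ROI sets for
exemplar training — sizes at which every exhaustive oracle is tractable and
the statistical checks have adequate power.

## Known limitations

- The patch similarity is raw clipped intensity; the original exemplar
  tooling may use a different metric (unpublished here), so learned
  exemplars are comparable in spirit, not in bytes.
- The parenchyma classifier is a rule table, not the published clustering
  classifier; agreement is by construction on clean textures only.
- The lung segmenter assumes non-contrast chest CT with lungs not touching
  the volume border; it is not a general-purpose lung segmenter.
- Glyph risk-grouping clusters the full 9-vector; whether the original
  stratification used the full vector or summary components is unknown.
- The correlation between fibrosis and low attenuation observed in real
  cohorts (~0.95) is *not* built into the generator's defaults — it is a
  property of a particular cohort, not of the method; the two draws are
  independent unless the caller couples them through the feature
  distributions.
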