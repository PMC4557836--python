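# Methods

## Problem setting

`connrel` analyses the test–retest reliability of weighted structural brain
connectomes. The study design it models is a scan–rescan cohort: `n`
subjects each scanned in three sessions — twice on one MRI scanner (A1, A2)
and once on a second unit of the same model with a different head coil (B1)
— with connectivity matrices built per subject and session from
tractography streamlines under two weighting regimes. Treating each
scanning session as a *rater* and each subject as a *target*, reliability
is quantified per connectome link (and per nodal graph measure) with the
intraclass correlation coefficient.

## Connectivity weighting

Nodes are gray-matter parcels from an 83-region scheme (41 bilateral
regions plus an unpaired brainstem node; 42 distinct region names). Two
edge-weighting schemes are implemented:

* **Deterministic** (whole-brain seeded single-path tracking): the
  surface-normalized length-corrected sum

  `w(e) = (2 / (S_i + S_j)) * Σ_f  c_f / l_f`

  where `S_i`, `S_j` are the gray/white boundary surface areas (mm²) of the
  two ROIs, and each fiber record contributes its streamline count `c_f`
  divided by its path length `l_f` (mm). Records whose endpoints resolve to
  a single ROI never form a link.

* **Probabilistic** (seeded from each ROI of a pair in turn): the mean of
  the two seeded streamline masses divided by `S_i + S_j`. With distance
  correction, each streamline contributes its path length rather than 1 to
  the seeded mass; the builder consumes already-corrected masses, matching
  the tracking tools that apply the correction internally.

Matrices are symmetric, nonnegative, zero-diagonal; these invariants are
enforced at construction and by the readers.

## Graph measures

All measures are computed on non-directed weighted matrices:

* **degree** — count of strictly positive incident weights;
* **strength** — sum of incident weights;
* **clustering** — Onnela weighted form: with weights normalized by the
  global maximum, `C_i = (1/(k_i(k_i−1))) Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}`,
  zero when `k_i < 2`; implemented as the diagonal of `(Ŵ^{1/3})³`
  (vectorized), cross-checked in tests against networkx and a direct
  triple-sum oracle;
* **betweenness** — shortest-path betweenness with edge length `1/w`
  (a zero weight is no edge), Brandes accumulation with fractional
  splitting of tied geodesics (networkx), normalized by `2/((n−1)(n−2))`
  so values lie in [0, 1]; cross-checked against exhaustive simple-path
  enumeration.

The reciprocal weight→length map is the standard convention for
streamline-count connectomes. The parenthetical definition of strength as
"degree multiplied by the weight of each connection" that circulates in
the applied literature is internally inconsistent; the standard sum of
incident weights is used.

## Reliability: ICC(A,1)

For a complete `n × k` table (subjects × sessions) the two-way
random-effects decomposition gives row, column and residual mean squares
MSR, MSC, MSE, and the single-measure absolute-agreement coefficient is

`ICC(A,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))`.

Choices, and why:

* **Absolute agreement** rather than consistency: a scanner gain shifts the
  column means and must count against reliability.
* **Single measures**: each link weight is one measurement per session.
* **Pairwise sessions (k = 2)** is the default comparison (A1–A2 within
  scanner, A1–B1 between scanners); any tuple of sessions can be passed
  for a joint multi-rater ICC.
* **Zero-variance tables are undefined**, reported as NA and excluded from
  all distribution statistics (the exclusion count is logged and appears
  in the summary); this covers links absent in every subject.
* **Negative ICCs are retained**; clipping at 0 would bias the method and
  scanner comparisons.
* Degree ICC is **not assessed** when mean matrix sparsity falls below a
  floor (default 0.10): near-fully-connected networks have no
  between-subject degree variance left (ceiling degree effect), as in the
  dense probabilistic regime.

## Correlate statistics and the comparison plan

Secondary analyses per method and session pair: Pearson (default;
Spearman switchable) correlations of link ICC with inter-ROI centroid
distance, summed ROI volume and volume ratio (defined max/min so it is
orientation-free); correlation of link ICCs across methods; paired t-tests
between ICC distributions (signed mean(a)−mean(b); Welch mode available);
correlation of ICC with mean link weight and with the across-subject
coefficient of variation (sample sd / mean, undefined at zero mean); and a
two-proportion chi-square (1 df, no continuity correction) on
reproducible-link counts (ICC strictly > 0.75 by default).

The default design enumerates 38 planned comparisons
(12 anatomical + 2 cross-method + 2 method t-tests + 8 fiber-count/CV +
14 nodal graph-measure analyses, the probabilistic degree being excluded)
and applies the Bonferroni threshold 0.05/38 ≈ 0.0013 uniformly. The plan
is emitted as JSON so the test count is auditable.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Per link (unordered ROI pair):

* base log-intensity `μ_ij = log S_i + log S_j − λ_d · d_ij + B_ij`, where
  `λ_d` is `distance_decay` (default 0.02 mm⁻¹), `d_ij` the centroid
  distance, and `B_ij ~ N(0, link_sd²)` (default 1.2) an anatomy-fixed
  bundle-size spread — counts scale with the product of the two seed/target
  boundary areas and real connectome weights span orders of magnitude;
  intensities are rescaled so the expected total per subject and session
  matches `mean_total_fibers` (defaults 10⁴ sparse / 10⁶ dense; the real
  studies' 10⁵–10¹¹ totals are desk-scaled, only the regime order matters);
* subject effect `a_{s,ij} ~ N(0, subject_sd²)` (default 0.6), persistent
  across sessions — the biology the study re-measures;
* session effect `e ~ N(0, session_sd²)` (default 0.25); scanner B adds
  `scanner_b_extra_sd` (0.25) in quadrature plus a log-gain
  (`scanner_b_gain`, 1.1);
* streamline counts are Poisson around the exponentiated intensity
  (switchable off via `count_noise=False` for exact noise-free limits);
* in the sparse deterministic regime a link fails to track per session
  with probability `1 − exp(−d_ij/dropout_scale)` (scale 150 mm); on
  scanner B the exponent is multiplied by `scanner_b_dropout_gain` (1.5),
  modelling the altered tracking sensitivity of a different head coil;
* fiber lengths are `d_ij ×` a log-normal tortuosity ≥ 1, fixed per link.

The seed drives three sub-streams — anatomy, subject biology, measurement
— with anatomy and biology shared between regimes at equal seed, so both
tractography methods observe the same brains and cross-method reliability
correlations are meaningful.

On the log scale the closed-form link reliability is
`ICC = subject_sd² / (subject_sd² + session_sd²_effective)`, the oracle for
recovery tests. It ignores counting noise, dropout and the scanner gain;
recovery runs therefore use the dense regime with large totals
(`recovery_params`: 2×10⁶ fibers, 34 ROIs → 561 links, no scanner effect,
total log spread 0.5). Under those conditions the raw-scale ICC the
pipeline estimates differs from the log-scale truth only through the mild
log-normal nonlinearity and estimator bias (≲ 0.05 at n = 20).

### What the generator does and does not emulate

It reproduces the qualitative structure real scan-rescan connectome data
show: sparse deterministic vs dense probabilistic matrices, a reliable
strong-link core, lower cross-scanner agreement, distance- and
size-dependent tracking success. It does not simulate voxel grids, DWI
signal, registration error, spatially correlated noise between neighboring
links, or true biological drift between sessions (all within-subject
variation is measurement noise). Passing tests therefore demonstrate that
the pipeline recovers known variance structure and reproduces the
direction of the study-level effects — not that real data would yield the
same magnitudes. One deliberate asymmetry: with link-uniform log-scale
noise the dense regime's CV-vs-ICC relation is structurally positive
(links with more between-subject spread score higher on both), so the
negative dispersion–reliability relation is expected, and checked, in the
sparse deterministic regime, where inconsistently tracked links have both
high dispersion and low ICC.

## Numerical choices

* ICC tables with total sum of squares ≤ 1e−12 (relative) are undefined.
* The batch ICC engine computes all links of a session pair in one
  vectorized pass; it matches an explicit sum-of-squares oracle to 1e−10
  over randomized tables and pingouin's ICC(A,1) to 1e−6.
* Matrix TSVs are written at full float precision and read back with
  round-trip float parsing, so write→read is bit-exact.
* Read matrices are symmetrized by averaging with a configurable
  asymmetry tolerance (default 1e−8 relative); beyond it the file is
  rejected.
* Paired t-tests with a constant nonzero difference report ±∞ with p = 0;
  identical inputs report t = 0, p = 1.
* Bonferroni thresholds are reported exactly and, for display, rounded to
  two significant figures.

## Problem sizes used in validation

The default simulated study runs 20 subjects × 3 sessions × both regimes
on the 83-node scheme (3403 links); parameter-recovery runs use 20
subjects and 561 links per reliability level. These sizes make the full
suite and the reproduction script complete in a few minutes on a single
core while keeping sampling error well inside the stated tolerances.

## Known limitations

* The theoretical ICC attached to `GroundTruth` is a log-scale
  approximation; it is exact for the recovery conditions but not for the
  sparse regime, where dropout and counting noise dominate.
* The probabilistic same-scanner dispersion–reliability relation seen in
  real data is not reproduced (see above).
* ICC confidence intervals and per-link F-tests are out of scope.
* The packaged 83-node fixture carries synthetic geometry; only its label
  scheme follows the standard parcellation.
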