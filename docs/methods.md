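# Methods

This note documents the models and procedures implemented in `digesta`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Ion-peak processing

An ion peak is a detected LC-MS feature `(m/z, charge, RT, abundance)`;
feature detection itself (centroiding, deisotoping) happens upstream in
vendor software and is out of scope — `digesta` starts from exported
per-replicate CSV tables. Retention time is minutes throughout; a config
flag converts seconds on ingest. When a table carries no ion identifiers,
sequential integers are assigned at read time so that matching results have
a stable audit trail. CSV round-trips are lossless: floats are written with
shortest-round-trip (`repr`) precision and parsed with pandas'
`float_precision="round_trip"`.

Processing order matches standard practice for enzyme-background-corrected
profiling:

1. **Noise filter.** Peaks with raw abundance strictly below the threshold
   (default 1 × 10⁵, configurable) are dropped; the boundary value is
   retained.
2. **Blank subtraction.** Any peak matching a peak of the enzyme-only blank
   digest under the tolerance predicate is removed. Exclusion uses the bare
   predicate, not nearest-match ranking, because the question is membership
   in the background, not assignment; the operation is idempotent.
3. **Benchmark matching.** Each remaining digest peak is assigned to its
   nearest in-tolerance benchmark peak (details below). The benchmark table
   itself is abundance-filtered and, by default, blank-corrected before
   serving as the reference (a config switch disables the latter).

Every digest carries a `FilterAudit` whose conservation identity
`observed = abundance-excluded + blank-excluded + retained` is enforced at
construction — count accounting can never silently leak ions.

### Matching rule

Two peaks match when their charges are equal (an integer criterion; no
tolerance is meaningful) and |Δm/z| ≤ 0.003 Th and |ΔRT| ≤ 0.5 min, both
bounds inclusive. Among multiple candidates the winner minimizes

    d(Δm/z, ΔRT) = sqrt( (Δm/z · w)² + ΔRT² ),   w = rt_tol / mz_tol,

a Euclidean distance in a plane where the m/z axis is rescaled so that the
two tolerances are equivalent (0.003 Th ≡ 0.5 min); `d` is reported in
rt-equivalent minutes. Exact ties are broken by smaller |Δm/z|, then
smaller reference ion id — an arbitrary but deterministic rule, required
for reproducibility. Each query peak joins at most one pair; a reference
peak may receive many query peaks, whose abundances are summed in the
per-reference aggregate. The production implementation uses a sorted-m/z
candidate window; its contract is equality with an exhaustive O(n²) search,
which the test suite enforces on dozens of randomized dense tables.

Replicates are matched individually and characteristics averaged
afterwards (never tables merged before matching), so replicate variation
propagates into the feature matrix. Benchmark and blank replicate tables,
by contrast, are pooled by ion union into single reference tables: a
reference list should be as complete as possible, and per-replicate
reference matching would make "overlap with the benchmark" ambiguous.

## Digest characteristics

Five summary characteristics per digest replicate:

| name | definition |
|---|---|
| `frac_ditri` | abundance fraction of peaks with neutral mass ≤ 425 Da |
| `frac_oligo` | 1 − `frac_ditri` |
| `total_abundance` | summed abundance of retained peaks |
| `n_unique` | retained peaks with no benchmark match |
| `pct_overlap` | matched peaks as % of retained peaks |
| `pct_abundance_overlap` | matched-peak abundance as % of retained abundance |

Neutral mass is `(m/z − 1.007276) × z`. The di/tri-vs-oligopeptide split by
a 425 Da neutral-mass cutoff (inclusive) is a pragmatic mass proxy — the
upper range of common tripeptides — since no sequence information is
available at this stage; the cutoff is configurable, absolute fraction
values depend on it, and comparisons across digests under a fixed cutoff do
not. Fractions are abundance-weighted; overlap percentage (d) counts ions
while (e) weights them by abundance. An empty digest yields all-zero
features with a logged warning rather than NaNs, keeping the feature matrix
total. Tile-plot and benchmark-vs-digest abundance comparison tables are
exported per digest.

## Model-based clustering

Sources × features matrices are built from replicate means and
z-standardized per column (sample SD, n−1 denominator) to mean 0, SD 1.
Gaussian mixtures are fitted by EM under the fourteen covariance
parameterizations Σₖ = λₖ Dₖ Aₖ Dₖᵀ — volume λₖ > 0, shape Aₖ diagonal with
unit determinant, orientation Dₖ orthonormal, each Equal / Variable across
components or Identity — with M-steps following the classical closed forms
(Celeux & Govaert 1995). Three families need inner iterations (VEI, VEE,
VEV alternate volume and shape; EVE and VVE update the shared orientation
by a majorize–minimize step on the orthogonal group, Browne & McNicholas
2014). All inner iterations warm-start from the previous EM iteration's
parameters, making each M-step a coordinate ascent from the current point;
the observed-data log-likelihood is therefore monotone non-decreasing at
every EM iteration, which the tests assert for every family. Realized
covariances are constructed from the shared factors themselves, so family
constraints (e.g. identical λ·A spectra across EEV components) hold to
machine precision by construction.

Model selection sweeps families × k (default k = 1…9, bounded by n−1) with
`n_restarts` seeded k-means++ initializations each (default 10; the initial
responsibilities are softened 0.9/0.1 one-hots so every component sees all
points and small-count fits don't die at the first scatter computation).
BIC = 2·loglik − m·log n is maximized; m counts weights (k−1), means (k·d),
and the family-specific covariance parameters. The original package's
model-based hierarchical-agglomeration initializer is deliberately not
reproduced: it is under-documented, and the BIC sweep — not the
initializer — is the procedure of scientific record; seeded restarts give
bitwise-reproducible selection given (data, seed, restart count).

Degeneracy handling: a collapsed component (vanishing weight), a Cholesky
failure, a covariance condition number beyond 10¹⁴, or a non-finite
log-likelihood marks the fit non-converged with a diagnostic message; such
fits are excluded from selection (the analogue of an NA BIC entry). With
~19 sources and up to 11 features this is the *expected* outcome for the
richer families at large k, and the diagonal/spherical families carry the
selection there. If every fit in a sweep degenerates, selection raises with
the sweep table attached.

Convergence: relative log-likelihood change < 1e-8 or 500 iterations (both
configurable). Argmax-responsibility ties break toward the lower component
index.

### Feature presets

- *Proteomic*: `frac_ditri, total_abundance, n_unique, pct_overlap,
  pct_abundance_overlap`. `frac_oligo` is computed and exported but not
  clustered by default: it is exactly 1 − `frac_ditri`, and a perfectly
  anticorrelated pair is singular under full-covariance families while
  double-counting one dimension of evidence under diagonal ones (observed
  empirically as spurious BIC splits). The feature list is configurable.
- *Biological*: the seven assay variables (inulin-FITC leakage, ZO-1
  intersections, viability, alkaline phosphatase, IL-6, TGF-β, NO).
- *Combined*: the four benchmark-relative proteomic characteristics joined
  with the seven biological variables (11 columns, a 7:4 ≈ 2:1 weighting of
  biology over proteomics), standardized jointly.

The blank digest participates as a sample row in the biological clustering
(it is a treatment there) but never in the proteomic one (it is the
subtraction reference).

## Biological statistics

Grubbs screening is the two-sided single-outlier test: G = max|xᵢ − x̄|/s
against G_crit = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student
quantile at n−2 df; one pass, at most one removal per (source, variable)
group (iterative removal is deliberately not the default). A zero-variance
group defines G = 0. Note a structural limitation: at n = 3 the largest
attainable G is (n−1)/√n ≈ 1.1547 while G_crit(α=0.05) ≈ 1.1543, so on
triplicates the test has essentially no power against even enormous
outliers — it only fires when the two remaining values are nearly
identical. Screening gains real power from n ≥ 4; the synthetic detection
benchmarks therefore use 6 replicates.

Benchmark comparisons: per variable, each source vs the benchmark with a
two-sample t-test — Welch by default, since equal variances across protein
sources is not defensible a priori; a pooled-variance mode is available —
plus a one-way ANOVA across all sources. Significance is an uncorrected
p < α call (α = 0.05 default) to match the screening convention this
pipeline supports; no multiple-testing correction is applied by default.
Control-relative normalization divides by the paired run's control mean
(×100 for percent scales) and is scale-equivariant.

## Synthetic data

The generators stand in for instrument data with exact, planted ground
truth.

*Ion tables.* Benchmark, blank, and unique digest ions are placed uniformly
over the acquisition window (70–1200 Th × 0–40 min, charges 1–3 with
probabilities 0.3/0.5/0.2) by rejection sampling under the constraint that
same-charge landmarks are separated by more than twice the tolerance-box
radius in the weighted metric; a planted overlap ion therefore has exactly
one admissible reference and matching ground truth is unambiguous. Digests
consist of `round(overlap_fraction × n)` jittered benchmark copies
(m/z jitter SD 0.0008 Th, RT jitter SD 0.1 min — chosen so > 99.9% of
planted overlaps stay in tolerance; the config rejects jitter that would
break 99%), unique ions, and optionally jittered blank copies. Abundances
are log-normal (σ = 1) located so 25% of digest mass falls below the 10⁵
threshold, keeping the noise filter exercised; benchmark and blank
abundances are drawn truncated *above* the threshold because those tables
serve as the matching reference and subtraction background — if the filter
thinned them, planted overlap and contamination would no longer be exactly
recoverable. With zero jitter and threshold 0 the pipeline recovers planted
pair sets, contamination counts, and unique counts exactly; under default
jitter and filtering, measured `pct_overlap` is unbiased with SD ≈ 0.5
percentage points at 2000 ions (thinning noise only, since the planted
count is deterministic).

*Read-out tables.* Sources are assigned to planted clusters whose mean
vectors sit on scaled coordinate axes, pairwise separated by `cluster_sep`
(default 4) effective source-level SDs, where the effective SD combines
isotropic source scatter (0.3) and replicate noise (1.0, averaged over
replicates) on a baseline of 100 units. At most one outlier per
(source, variable) group is injected (probability `outlier_rate`,
displacement 6–10 replicate SDs) so single-outlier screening has clean
ground truth. Whole-study simulation adds per-source jitter of the group
parameters (overlap ±0.02, abundance scale ±0.1 log units) so that
within-cluster spread is genuinely Gaussian at the source level rather than
pure ion-sampling noise.

What the synthetic benchmarks do **not** show: real digests have correlated
m/z–RT structure, near-duplicate features within tolerance of each other,
isotope/adduct redundancy, batch-wise RT drift, and heavy-tailed assay
noise. Tie-break behaviour under ambiguous references is exercised by
dedicated adversarial fixtures rather than the separated generators.
Passing the planted-recovery tests demonstrates correctness of the
computations, not robustness to those instrument artifacts.

## Problem sizes used in the validation suite

Chosen as the smallest sizes at which each property is statistically
decidable: matching oracles on 50 pairs of 200-ion tables drawn in a
deliberately crowded 0.06 Th × 1 min window; overlap recovery at 2000
digest ions against 2500 benchmark ions; EM monotonicity on 20 random
60 × 3 data sets per family; BIC cluster-count recovery on 25 replicates of
n = 500 three-component mixtures with 4-SD mean separation; Grubbs null
calibration on 10,000 Gaussian samples per n ∈ {3,…,10}. Planted k = 3
recovery for the read-out generator is demonstrated at 60 sources and
8-SD separation: at the study-like size of ~19 sources in 7 dimensions
with 4-SD separation, BIC provably prefers k = 1 (verified with
oracle-initialized fits), i.e. that regime carries too little information
for consistent cluster-count recovery — a finding worth keeping in mind
when interpreting any clustering of ~19 sources.

## Known limitations

- No retention-time alignment/warping between runs and no isotope-envelope
  or adduct collapsing; the matching assumes well-calibrated runs.
- The di/tri-peptide boundary is a neutral-mass proxy, not a sequence call.
- Grubbs on triplicates is near-powerless (see above); the screening is
  faithful to common practice, not an endorsement of its power at n = 3.
- The EM initializer differs from the original package's hierarchical
  agglomeration; on small-n data local optima can differ between the two,
  although the selected model is restart-stabilized.
- BIC cluster counts on ≤ ~20 sources are fragile regardless of
  implementation; the richer covariance families mostly degenerate there
  and selection rests on the spherical/diagonal families.
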