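# Methods

This note documents the statistical model behind `stepconn`, the design of
the synthetic-cohort generator, the calibration that makes its planted
effects land at their nominal values, and the numerical conventions the
implementation commits to.

## Connectivity model

Subject time series are treated as T i.i.d. draws from a zero-mean
R-dimensional Gaussian. Columns are z-scored before covariance estimation,
so the ridge penalty is scale-free: with standardized covariance S, the
regularised precision is P = (S + ρI)⁻¹ and the partial correlation is
r_ij = −P_ij/√(P_ii P_jj). The default ρ = 0.5 follows common practice for
regularised partial-correlation connectomes; a dialect that scales the ridge
by mean(diag(S)) is available (`ridge_dialect="scaled"`) but coincides with
the default for z-scored data. At ρ = 0 the estimator reduces to the
textbook precision-based partial correlation (verified against an
independent implementation to 1e-10 in the tests).

Degree centrality sums absolute edge weights. Negative partial correlations
are a genuine modelling ambiguity: "total strength of connections" does not
dictate their treatment, so both `absolute` (default) and `positive_only`
modes exist. All calibration and validation in this package uses `absolute`.

## Stepwise connectivity

The binarised graph keeps edges above the 95th percentile of the
upper-triangle weights, ranked on signed values by default (`edge_rank=
"absolute"` would admit strong negative partial correlations as
"connections", which we consider a separate analysis). The threshold is
applied per subject. "Paths at a given step distance" are implemented as
walks — entries of Aᵏ — which is the standard operationalisation; counting
simple paths is NP-hard and not attempted. Multiple seeds are summed before
z-normalisation, giving one map per step.

Walk counts are computed by the recursion v_{k+1} = A v_k in float64 (exact
for counts below 2⁵³, BLAS-fast) with an automatic switch to arbitrary-
precision integers beyond that bound; the engine matches an exhaustive
depth-first enumeration exactly on random graphs up to R = 8, k = 5.

Z-normalisation uses the population (1/N) standard-deviation convention; a
zero-variance step yields an all-zero row plus a degeneracy flag rather than
an error. The hub rule "degree > 1.5 × mean degree" is ill-posed on
zero-mean z-scores (the mean is ~0, so every above-average region would be a
hub); hubs are therefore detected on min-shifted z-degrees by default, with
raw counts as an option. This is an implementation decision, documented
rather than inherited.

## Inference conventions

* Seed selection: two-sided p-values from the exact t-transform of Pearson r
  with n−2 df; Benjamini–Hochberg step-up with ties sharing the
  suffix-minimum q. A constant degree column is reported as r = 0, p = 1 and
  flagged instead of aborting a whole-brain map.
* Group tests: Welch's t by default (the groups differ in size and
  variance); pooled-variance available. FDR families are regions-within-step
  and networks-within-step, recorded in the output metadata.
* Permutation tests: scores are shuffled over subjects; the two-sided
  p-value uses the add-one convention p = (1 + #{|r_null| ≥ |r|})/(m + 1),
  which is valid (never zero) and converges to the analytic t-based p for
  Gaussian data. The plug-in proportion is available for comparison.
* Bootstrap stability resamples ⌈0.9 n⌉ subjects **with replacement**. A
  consequence worth stating: because each resample shares most subjects with
  the full sample, the r-map correlation has a null baseline of roughly
  0.7–0.8 from shared estimation noise alone — stability should be read as
  excess over that baseline, not over zero. The tests assert this baseline
  explicitly.

## The synthetic cohort generator

The generator's job is to produce cohorts in which the quantities the
pipeline estimates have known planted values, so recovery can be measured.

**Covariance architecture.** Regions belong to 7 cortical communities and 7
subcortical structures. Within each label, regions form cliques of at most 5
with within-clique covariance 0.3; a gateway ring plus long-range chords
(constant covariance 0.3, one backbone edge per region at most — a matching,
so its spectral perturbation is exactly 0.3 and positive definiteness is
guaranteed for all clique scalings up to 2.0) connect the cliques into one
small-world-like component. Two properties motivated cliques over
community-wide equicorrelated blocks: an equicorrelated block of size m caps
its partial correlations at 1/(m−1), which would starve the estimator at the
246-region scale, and fixed-size cliques keep per-edge effects comparable
across parcellation sizes so one calibration serves both scales.

**Phenotypes.** A latent adiposity factor drives sex-specific WHR (cutoffs
0.85/0.90 exercised by construction) and, through a configurable coupling
(default 0.7), BMI. Healthy-weight/overweight group counts are realised
exactly by zone-wise sampling; "neither" subjects are explicitly kept out of
both group zones. TFEQ subscales are correlated integer scores (restraint
7.6 ± 4.8, disinhibition 4.5 ± 3.0, hunger 4.3 ± 3.2; inter-correlations
0.3/0.45/0.2), truncated at zero.

**Planting and calibration.** True seed regions are whole cliques (selected
by exact subset-sum over clique sizes, signs balanced by region count);
their internal covariance is scaled per subject by a factor linear in a
latent correlated with WHR. Three measured facts shape the calibration:

1. *Attenuation*: estimation noise at finite T dilutes the induced
   degree–WHR correlation, so the latent–WHR correlation is inflated by a
   measured attenuation factor.
2. *Noise-floor drift*: strengthening a clique raises its members' precision
   diagonal, which shrinks **all** their spurious partial correlations; in
   an absolute-value degree this accumulates over R−1 edges and opposes the
   direct signal. The net coupling is modelled as
   S(R,T) = A − B·(R−1)·√(200/T) against noise √((R−1)·200/T) with A, B
   fitted on a measured grid; beyond the crossover (R ≈ 150 at T = 400) the
   net coupling is negative and the generator flips its internal sign so the
   realised correlation keeps the requested sign. Near the crossover large
   targets are not realisable and the generator raises a configuration
   error rather than silently under-delivering.
3. *Off-target leakage*: a scaled clique would also modulate its backbone
   neighbours' partial correlations through the same conditional-variance
   mechanism, planting spurious effects in regions that are nominally null.
   Backbone edge weights are therefore compensated by the endpoints'
   conditional-variance change, which keeps neighbour partial correlations
   flat and the false-discovery proportion of seed recovery at the nominal
   FDR level (measured 0.05–0.07 at n = 300).

Validated realisations at the operating scales: planted 0.3/0.4 at R = 60
give measured 0.29/0.39; planted 0.3 at R = 246 gives 0.28–0.29.

Group effects multiply the target networks' clique covariances for
overweight subjects; the gain is calibrated so the planted magnitude is the
realised network-level step-5 Cohen's d (planted 0.8 → measured
−0.80 ± 0.29 at R = 60, n = 100/75). Behavior effects mix a per-network
latent into the chosen TFEQ subscale, again through a measured attenuation
(planted −0.25 → measured −0.25 ± 0.08 at R = 60, n = 180). Both
calibrations hold at the 60-region test scale with T = 400; at the
246-region scale the walk-count response to clique strengthening changes
sign (the fixed 5% edge budget lets a strengthened community crowd out the
marginal edges that feed it), so group- and behavior-channel plants should
be interpreted only at the scale they were calibrated for. The degree–WHR
channel, whose scale dependence is modelled explicitly, is calibrated at
both scales. When group or behavior effects are planted, seed cliques are
drawn from the remaining networks so the channels stay identifiable.

**Default study conditions.** 301 subjects (25% overweight, 35%
healthy-weight, mirroring 75/104 of 301), 246 regions, T = 400 timepoints.
T sits between a fast-test regime and the ~900 volumes of a long
resting-state acquisition; below T ≈ 300 the attenuation grows so strong
that planted correlations of 0.4 become unrealisable, which is why 400 is
the default. Tests and recovery ensembles run at R = 60, n = 175–300.

**What the generator does not emulate.** No scanner artifacts, head motion,
hemodynamics, autocorrelated noise, or volumetric images; time series are
i.i.d. Gaussian in time. Connectivity structure is stylised (cliques + ring)
rather than connectome-like; hub architecture emerges only from the planted
blocks. Passing recovery tests therefore demonstrates that the *pipeline*
recovers what it assumes, not that real cortical data satisfy those
assumptions.

## Pipeline and reproducibility

`analyze_cohort` chains the stages in memory; `run_pipeline` is the
file-level driver (TSV/JSON only, region identity checked by name) and
writes a manifest with SHA-256 hashes of every output. One master seed
spawns an independent child seed per randomised stage
(`numpy.random.SeedSequence`); the children are logged in the manifest so
any stage can be reproduced in isolation. Floats are serialised at
round-trip precision (%.17g) and parsed with pandas' round-trip parser, so
write→read is numerically exact and re-runs are byte-identical.

The acceptance script (`scripts/acceptance.py`) runs a full-scale study at
R = 246, n = 301 (seed recovery, bootstrap stability, BMI/WHR map
agreement, hub counts, network flags) and ensembles of 10–15 cohorts at
R = 60 for the calibrated recovery measurements, sizes chosen so the whole
script completes in a few minutes on one CPU while keeping Monte-Carlo error
on reported rates below ~0.1.

## Known limitations

* The attenuation model for the degree–WHR channel is fitted at the
  operating scales (R ≈ 60 and R ≈ 246, T = 300–400) and interpolates only
  roughly in between; configurations near the coupling crossover are
  rejected rather than approximated.
* With n = 180, the sampling standard deviation of a Pearson correlation
  near 0.25 is ≈ 0.075, so any per-cohort requirement that a recovered
  coefficient fall within ±0.1 of its target *and* survive FDR cannot exceed
  ≈ 80% joint probability even under perfect calibration; the behavior
  recovery ensemble reports the mean recovered coefficient and the detection
  rate separately for this reason.
* Balanced sign assignment cancels planted-direction leakage only to first
  order; at n ≫ 300 residual off-target correlations (~0.05) would begin to
  reach significance.
* The WHO risk grouping and covariate-residualisation variants are
  implemented and tested for mechanics, but no calibrated ground truth is
  planted for them.
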