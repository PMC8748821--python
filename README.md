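# stepconn

Stepwise functional connectivity (SFC) analysis of obesity-phenotype-associated
brain networks, as a tested, reusable pipeline.

Resting-state fMRI studies of overweight individuals report altered
connectivity in sensory and cognitive-control systems — the two ends of the
cortical hierarchy. SFC quantifies position along that hierarchy: seeding from
regions whose connectivity tracks an obesity phenotype, it counts not only
direct connections (step 1, conventional seed connectivity) but walks of
length *k* on the binarised connectome, so that increasing step distance
traces how signal converges from sensory anchors toward transmodal cortex.
`stepconn` implements the full analysis chain for parcellated time series,
plus a synthetic-cohort generator with recoverable ground truth so every stage
can be validated by parameter-recovery simulation — the original clinical
cohort is access-restricted.

## The pipeline

For each subject with time-series matrix **X** (T timepoints × R regions,
columns z-scored):

1. **Connectivity** — ridge-regularised partial correlation from the
   standardized covariance S: with P = (S + ρI)⁻¹ and ρ = 0.5,
   r<sub>ij</sub> = −P<sub>ij</sub>/√(P<sub>ii</sub>P<sub>jj</sub>).
   Degree centrality d<sub>i</sub> = Σ<sub>j≠i</sub>|r<sub>ij</sub>|.
2. **Seed selection** — Pearson correlation of each region's degree with
   waist-to-hip ratio (WHR) across subjects; two-sided p from the exact
   t-transform (n−2 df); Benjamini–Hochberg FDR; regions with q < 0.05 form
   the seed set. Robustness: 1000 bootstraps of 90% of subjects with
   replacement, correlating each resampled whole-brain r-map with the
   full-sample map.
3. **Stepwise connectivity** — per subject, keep the top 5% strongest edges,
   binarise, and compute walk counts
   counts<sub>k</sub>[j] = Σ<sub>s∈seeds</sub> (Aᵏ)<sub>sj</sub> for
   k = 1…5, z-normalising each step across regions. Hubs are regions whose
   (min-shifted) step degree exceeds 1.5× the mean.
4. **Group contrast** — subjects are labelled healthy-weight
   (18.5 ≤ BMI < 25 and WHR ≤ 0.85 ♀ / 0.90 ♂) or overweight (BMI ≥ 25 and
   WHR above the cutoff); Welch t-tests compare step degrees per region and
   per network (7 cortical communities + subcortical structures), BH-FDR
   within each step. A WHO waist-to-hip risk grouping with size-balanced
   bootstrap (1000 × 51-subject subsamples) is available as a sensitivity
   variant, as is covariate residualisation (age/sex or eating-behavior
   scores) of the connectivity edges.
5. **Behavior association** — network-level step-5 degrees are correlated
   with Three-Factor Eating Questionnaire scores (dietary restraint,
   disinhibition, hunger, and the 1+2 and 1+2+3 composites); p-values come
   from 5000 subject permutations (two-sided, add-one convention), FDR
   jointly across networks × scores.

## Worked example

```python
import stepconn as sc

config = sc.SimulationConfig(
    n_subjects=180, n_regions=60, n_timepoints=400,
    planted_effect_r=0.3, n_true_seeds=26,
    group_effect_magnitude=0.8,   # overweight: somatomotor down, visual up
    rng_seed=42,
)
cohort = sc.generate_cohort(config)

pipe = sc.PipelineConfig()          # rho=0.5, q<0.05, 95% threshold, steps 1-5
result = sc.analyze_cohort(cohort, pipe)

print(f"seed regions (q < 0.05): {len(result.seed_set)}"
      f"  (true planted: {len(cohort.ground_truth.seed_region_ids)})")
print(f"bootstrap stability of the WHR map: "
      f"{result.bootstrap.mean:.2f} +/- {result.bootstrap.sd:.2f}")
print(f"groups: {result.contrast.group_sizes}")
for net in ("somatomotor", "visual"):
    j = result.contrast.network_names.index(net)
    print(f"{net} step-5 contrast: t = {result.contrast.t_network[4, j]:+.2f}, "
          f"q = {result.contrast.q_network[4, j]:.4f}")
```

prints

```
seed regions (q < 0.05): 28  (true planted: 26)
bootstrap stability of the WHR map: 0.96 +/- 0.01
groups: {'overweight': 45, 'healthy_weight': 62}
somatomotor step-5 contrast: t = -6.67, q = 0.0000
visual step-5 contrast: t = +5.11, q = 0.0000
```

The 26 planted phenotype-associated regions are recovered (28 selected, the
two extras are borderline false positives at the 5% FDR level), the
whole-brain effect map is stable under resampling, and the planted
group-level reorganisation — a somatomotor deficit and a visual surplus in
the overweight group — is detected with the correct signs at step distance 5.

A command-line interface mirrors the stages:

```bash
stepconn simulate --out cohort/ --subjects 180 --regions 60 --seed 42
stepconn all --config pipeline.yaml        # manifest with content hashes
stepconn seeds --config pipeline.yaml      # any single stage
```

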