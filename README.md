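# gxebias

Bias in gene–environment interaction (G×E) estimates when the clinically
diagnosed case set is contaminated by a nuisance pathologic state.

Case–control studies usually fit a logistic model with the *clinical*
diagnosis as the outcome.  When a fraction `S(x)` of clinically diagnosed
cases in environment stratum `x` does not actually carry the pathology of
interest — and that fraction varies with the environment — the fitted
coefficients `Γ = (γ0, γG, γX, γG×X)` are biased for the true-risk
coefficients `B = (β0, βG, βX, βG×X)`.  This package provides:

- **Closed-form approximations** to `Γ` (and hence to the bias `Γ − B`) in
  two generative settings: a binary true-risk model with per-stratum
  contamination rates, and a trinomial model with a separate logistic
  contrast for the nuisance state.  Both the exact log-contrast
  ("theoretical") and the first-order ("linearized") forms are computed,
  and the printed null-preservation remarks are available as predicates.
- A **pseudo-true oracle**: the exact large-sample limit of the misspecified
  clinical logistic fit under retrospective case–control sampling, obtained
  by Newton iteration on the enumerated covariate support (all covariates
  binary, so the computation is exact and deterministic).
- An **exact retrospective simulator** with latent pathologic states and a
  synthetic multi-SNP screen generator.
- **Experiment drivers** reproducing the simulation settings A–D
  (empirical average vs oracle vs approximations; contamination
  misspecification sensitivity).
- A **per-SNP bias screen** that corrects a table of fitted coefficients by
  inverting the linearized approximation map, with Bonferroni flags.

## CLI

All subcommands live under a single `gxebias` entry point.  Model,
covariate and design inputs come from a YAML/JSON config whose keys mirror
the dataclass field names (all rates as decimals):

```yaml
model:
  kind: binary_with_contamination        # or: trinomial (uses B_star)
  B: {beta0: -1.0, betaG: -0.41, betaX: 2.0794, betaGxX: 0.0}
  Z_effects: [0.0, -0.08]
  contamination: {S0: 0.36, S1: 0.06}
covariates:
  genotype: {theta: 0.10, coding: raw_bernoulli}  # or dominant_carrier / recessive
  env_freq: 0.14
  covariate_freqs: [0.50, 0.52]
design: {n_controls: 3000, n_cases: 3000, replicates: 500, seed: 1}
```

```bash
gxebias approx-bias --config config.yaml --out bias.csv
gxebias pseudo-true --config config.yaml --out gamma.json
gxebias simulate --config config.yaml --replicate 0 --out data.csv --meta data.json
gxebias run-setting --preset B --replicates 500 --out settingB.csv --plot settingB.png
gxebias misspec-study --out misspec.csv
gxebias snp-screen --fits fits.csv --s0 0.36 --s1 0.06 --alpha 0.05 --out screen.csv
```

Simulated datasets are CSV with header `dcl,d_true,g,x,z1,z2,...`; the
latent state column uses 0 = healthy, 1 = disease of interest,
2 = nuisance state (documented in the JSON sidecar) and must be ignored by
estimation.

## Notes

- The clinical-label mechanism of the contamination model has perfect
  sensitivity and a per-cell calibrated false-positive mass, so that
  `pr(D=0 | DCL=1, x)` equals `S(x)` exactly in every covariate cell.  The
  closed-form approximations correspond to a related but different implicit
  mechanism (false-positive *rate* `S(x)` among true non-cases); the
  pseudo-true oracle is the normative large-sample target throughout, and
  for the trinomial setting the theoretical log-forms coincide with the
  oracle slopes exactly.
- Non-interacting covariates `Z` are handled by applying the linearization
  pattern coefficient-wise; with shared `Z` effects across disease states
  the clinical fit is correctly specified in `Z` and `γZ = βZ` exactly.
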