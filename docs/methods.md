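# Methods

## Data model

The response side is a table of Freundlich parameters `(name, K, 1/n)`
per compound; the packaged fixture covers 47 organic water contaminants
whose adsorption on a reference coal-based activated carbon was measured
in batch-equilibrium experiments (25 °C, ≥ 48 h contact, natural pH
5.3–8.0). `K` carries units (mg/g)(L/mg)^(1/n) and is strictly positive;
`1/n` is dimensionless and lies in (0, 1) for every packaged compound.
The predictor side is a dense compounds × descriptors matrix of
quantum-chemical parameters (charges in e, orbital energies in eV, bond
indices dimensionless), read from CSV with a `zero_fill` policy for
group-charge sums such as Σq(O+N): a compound with no O or N atoms has
an empty sum, which is 0, not missing.

Compound names are joined after Unicode NFKC normalization, case folding
and whitespace collapse, through a canonical alias map (e.g.
"cis-1,2-dichloroethene" → "cis-1,2-Dichloroethylene"). One alias is
genuinely ambiguous in the source material — "dibromochloroethane",
which the packaged table knows only as Dibromochloromethane — so it is
applied by default but can be disabled (`allow_ambiguous_aliases=False`),
and its use is recorded in report provenance.

The packaged 38/9 train/test splits for the K and 1/n responses are the
study's hold-out lists; the partition preserves table order and is
checked to be exact (every compound in exactly one part).

## Isotherm fitting

`fit_freundlich` estimates `(K, 1/n)` from paired `(Ce, Qe)` data two
ways. The log-linear estimator regresses ln Qe on ln Ce (natural logs;
the base only relabels the intercept) and back-transforms
K = exp(intercept). The nonlinear estimator minimizes squared error on
the original Qe scale, initialized from the log-linear fit (recorded in
the result). The two weight errors differently — relative vs absolute —
and published literature values rarely state which produced them, so
both are exposed and the method is always recorded. On noiseless data
they agree to 1e-6 relative and invert the isotherm exactly (checked to
1e-8). Under 5% multiplicative noise with 10 points, the log-linear K
estimate is nearly median-unbiased (|median relative bias| well under
5% across 1000 replicates; the acceptance script recomputes this).

Degenerate inputs are rejected: fewer than 3 points, all-equal Ce,
non-positive Ce or Qe.

## Model building

The stepwise ladder is forward-only: starting empty, each step adds the
descriptor that maximizes the criterion — training R² (default, which
produces the monotone nested ladders of conventional QSAR reporting) or
leave-one-out Q². Ties break lexicographically by descriptor name, and
candidates that would make the design singular are skipped, so ladders
are fully deterministic. Nested-RSS monotonicity is asserted at runtime
on every ladder. Bidirectional selection (with removals) is deliberately
not implemented.

Per-rung metrics: R² = 1 − RSS/TSS; R²adj = 1 − (1−R²)(n−1)/(n−p−1);
SD = √(RSS/(n−p−1)); F = ((TSS−RSS)/p)/(RSS/(n−p−1)) with upper-tail
p-value; RMSE_tr = √(RSS/n); MAE_tr; and the Friedman lack-of-fit score
LOF = (RSS/n)/(1 − (c + d·p)/n)² with c = p+1 basis functions and
smoothing parameter d (default 0.5, configurable) — the form used by the
GFA lineage of QSAR model builders. A constant response is fit as its
mean with R² := 0 and F := 0 (the 0/0 convention). OLS itself goes
through statsmodels; the test suite cross-checks coefficients against a
normal-equations oracle (1e-9) and t/p-values against statsmodels'
summary directly.

The response may be modelled on identity, log10 or sqrt scale. For the
packaged K response — spanning ~129 to 102000 — the scale materially
changes every statistic and the right choice is not derivable from the
packaged data alone, so the pipeline *requires* an explicit
`response_transform` and records it everywhere; there is no default.
Consequently no fit metrics for the untransformed K model are claimed
or asserted anywhere in the package.

## Validation battery

* **Q²_LOO** = 1 − PRESS/TSS with the exact hat-matrix shortcut
  PRESS = Σ(eᵢ/(1−hᵢᵢ))²; a point with hᵢᵢ = 1 raises. The shortcut is
  verified against explicit n-refit leave-one-out to 1e-10 in every test
  run. Q²_LOO ≤ R² always (and tests assert it).
* **Q²_LMO**: per repeat, ⌈f·n⌉ compounds are held out, the same
  descriptor subset refit on the remainder, and held-out compounds
  predicted. Per-repeat Q² references the full training mean; alongside
  the per-repeat mean, a *pooled* Q² accumulates numerator and
  denominator over repeats — the pooled form reduces exactly to Q²_LOO
  for exhaustive leave-one-out draws, which the tests exploit as an
  oracle identity. Defaults: f = 0.3, 100 repeats, seeded.
* **External validation**: r²_ext (squared Pearson of predicted vs
  observed — sign- and scale-blind, which a constructed anti-correlated
  counter-example in the tests demonstrates) and the residual-based
  family Q²_F1 (training-mean reference, the default "Q²ext"), Q²_F2
  (test-mean) and Q²_F3 (training-variance scaling), all reported.
* **Y-randomization**: the response is permuted (default 300 times,
  seeded; explicit permutations injectable for verification, including
  the identity), the fixed subset refit, and (R²_yrand, Q²_yrand)
  recorded with max/mean summaries. For any real relationship the null
  maximum sits far below the original R²; under a true null the
  scrambled R² distribution matches fresh-noise draws (tested via their
  means).
* **Diagnostics**: VIFⱼ = 1/(1−R²ⱼ) with perfect collinearity reported
  as +inf rather than raised; t = β̂/SE with n−p−1 df. The conventional
  acceptance rule set — R² > 0.6, q² > 0.5, Q²ext > 0.5, VIF ∈ [1, 5],
  all coefficient p < 0.05 — is applied by `acceptance_check`, which
  names every violated rule. The thresholds are configurable; a fixed
  critical |t| (such as the 2.179 sometimes quoted, which corresponds to
  ~12–13 df rather than the 32 df of a 38-compound, 5-descriptor model)
  can be imposed by the caller but is not the default, the p-value rule
  being the self-consistent form.

## Applicability domain

Standardized residuals use the root-mean-square scaling
σᵢ = eᵢ/√(Σe²/(n−1)) so that σ is dimensionless and the conventional
(−3, 3) band applies. Test-set residuals are standardized by the
*training* residual scale, keeping both sets comparable on one Williams
plot. Leverages are hᵢ = xᵢ(XᵀX)⁻¹xᵢᵀ on the intercept-augmented
training design (trace identity Σh = m+1 asserted at runtime); the alert
leverage is h\* = 3(m+1)/n. Boundary conventions are explicit and
configurable: hᵢ = h\* counts as high leverage (≥) and |σᵢ| = 3 counts
as in-range (strict >) by default. Flags are pure functions of
(σ, h, h\*) and can be recomputed from the report table alone.

## Chemical space

Fingerprints are consumed as bitstring tables (0/1 columns or packed
hex); no fingerprint family or length is imposed, and no cheminformatics
toolkit is required. Tanimoto similarity T = c/(|a|+|b|−c) with the
both-empty pair defined as T = 1 (indistinguishable to the fingerprint).
The distance 1 − T is embedded by classical (Torgerson) MDS: double-
center −D²/2, take the top eigenpairs (descending eigenvalue, index
order on ties), scale eigenvectors by √max(λ, 0), and fix each axis sign
by making its first nonzero coordinate positive — embeddings are
deterministic and centered. Negative eigenvalues (1 − T need not be
Euclidean) are retained in the diagnostics spectrum; truncation can only
shrink embedded distances relative to the full positive-eigenvalue
embedding, and three-point inputs embed exactly. scikit-bio's principal
coordinates analysis serves as the independent cross-check in the tests.

## Synthetic data

The generator emulates just two features of real descriptor matrices:
per-column value ranges and a controllable overall inter-descriptor
correlation. Columns arise from an equicorrelated latent Gaussian
(Zᵢⱼ = √ρ·gᵢ + √(1−ρ)·eᵢⱼ) pushed through the Gaussian CDF and an affine
map into each column's [low, high] — so columns are bounded by
construction and share pairwise latent correlation ρ. The 31 default
ranges use the observed extrema of the real quantum-chemical parameters
where those are known (charge sums, Wiberg and C–C bond indices, E_LUMO,
Fukui(−)max, total energy) and physically plausible bounds on each
descriptor's natural scale otherwise. The generator makes no claim about
marginal shapes or the true joint law of DFT descriptors — so passing
tests demonstrate correctness of the statistical machinery, not
predictive validity on real compounds.

Responses are y = β₀ + Σβⱼxⱼ + ε with sparse β and Gaussian noise;
isotherm curves get multiplicative noise Qe·(1+η), η ~ N(0, cv²) redrawn
while 1+η ≤ 0, keeping Qe positive as measurements are. One integer seed
drives everything through fixed `SeedSequence` spawn keys (0 =
descriptors, 1 = response noise, 2 = isotherm noise): same seed, same
bits.

**Greedy-recovery caveat.** Forward selection does not guarantee exact
support recovery even on noiseless data: on random 38 × 31 designs with
a planted 5-descriptor, mixed-sign signal, a spurious column can win an
intermediate step, and forward-only search cannot undo it. The recovery
experiments in the tests and the acceptance script (100 seeds each at
noise σ = 0.02, latent correlation 0.3, comparable per-term
contributions) therefore measure a high-probability property of greedy
selection — around nine recoveries in ten, varying a few percent with
the seed stream — not a certainty; the per-seed results are fully
deterministic.

## Pipeline and reproducibility

`run_full_analysis` chains screen → split → ladder → validation →
verdict → applicability domain (→ chemical space when fingerprints are
given). Every stage error is re-raised with the stage name. The report
serializes to JSON (doubles round-trip exactly) and its provenance block
— package version, full config echo, seed, resolved train/test names,
correlation screen, and notes recording the alias-map and
residual-scaling conventions in effect — suffices to re-run the pipeline
to identical numbers; timestamps are the only non-reproducible field.

Problem sizes used by the default test suite and the acceptance script —
38 × 31 descriptor matrices, 100-seed recovery sweeps, 300-permutation
nulls, 500-seed Q² null means, 1000-replicate isotherm Monte Carlo —
were chosen as the smallest sizes at which the measured quantities are
stable to well within the asserted tolerances.

## Known limitations

* Descriptor values are inputs; nothing here computes them from
  structures (no DFT, no SMILES/SDF parsing).
* Forward-only stepwise search (see the greedy-recovery caveat); no
  all-subsets, genetic, or regularized alternatives.
* Only the Freundlich isotherm; no Langmuir or competitive multi-solute
  models.
* The acceptance rule set is the conventional QSAR one; it is a
  screening heuristic, not a guarantee of mechanistic validity.
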