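# Methods

This note documents the models implemented in `streamcom`, the
parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.

## Community size spectrum

The spectrum allocates a community total (abundance N or biomass B)
across species by mean body weight W (g, wet weight):

* abundance index `W^(−β)` with the weight-dependent thinning exponent
  `β = 0.5 · W^0.06`, clamped to [0.5, 0.75]. The clamp floor binds at
  W ≤ 1 g (where the formula equals 0.5 exactly, so the map is
  continuous there) and the ceiling from W ≈ 861 g upward.
* relative abundance = index / Σ index; count = relative abundance × N;
  biomass = count × W.

Counts are carried as continuous reals; an integer column
(`count_int`, round-half-to-even) exists for display only. All
invariants and checks use the continuous values: rounding per-species
counts and then summing cannot simultaneously preserve the stated
total and the relative abundances, so the continuous representation is
authoritative.

**Residual adjustment.** Species whose observed density departs from
the abundance–size trend carry a residual ε (on the log-density scale
of the calibration analysis) and use `β* = β − Δ`, `Δ = 0.15·ε/(3σ)`.
σ defaults to 0.65, the residual standard deviation of the dataset the
adjustment was calibrated on, and is configurable. β* is deliberately
not re-clamped: [0.5, 0.75] is guidance for community-level thinning
exponents, not a hard constraint, and a ±3σ residual is meant to move
β by the full ±0.15. Manual β overrides are likewise taken verbatim,
with a warning outside the guidance range. The adjustment applies only
to species with a stored `density_residual`; Δ = 0 otherwise.

**Biomass target.** At fixed relative abundances, total biomass is
linear in total abundance, so the solver uses the exact closed form
`N = B / Σ(relA_i · W_i)`. A bisection fallback is kept for any future
extension in which per-species weights depend on N; a test pins the
two routes together.

## Occurrence models

One XGBoost binary classifier per species over the five covariates
(drainage area km², mean catchment elevation m, slope %, IWI, BMMI).
Training data: positives are survey sites where the species was
caught; negatives are sites within HUC8s where the species has a
distribution record but was not caught. Absences outside the recorded
range are excluded — they reflect geography, not habitat, and would
teach the model nothing about environmental suitability. Species
caught in fewer than 25 surveys (configurable) are not modelled and
pass through the assemblage filter unfiltered, with their probability
marked unavailable; silently dropping unmodelled (mostly rare) species
would bias every predicted community.

Hyperparameters are exposed under their published configuration names
and mapped to XGBoost natives where the vocabulary differs:
`min_samples_leaf: 3` (a scikit-learn tree parameter with no XGBoost
equivalent) maps to `min_child_weight = 3`, the minimum summed hessian
per leaf, which approximates a minimum leaf size under logistic loss;
`n_iter_no_change: 10` maps to `early_stopping_rounds = 10`. The
remaining four (`n_estimators = 500`, `learning_rate = 0.05`,
`subsample = 0.75`, `max_depth = 3`) pass through unchanged. The
mapping is logged at training time. Early stopping monitors log-loss
on an internal stratified 15 % fold carved from the training table —
a single fold rather than 10-fold cross-validation, trading a little
stopping-point stability for a 10× cheaper fit; with 500 trees and
these shrinkage settings the difference is immaterial at fixture
scale. Training is fully deterministic given a seed (`n_jobs = 1`).

**Thresholds.** P₁, P₀ and SD(P₁) are computed from predictions on the
full training table (not cross-validated — the simplest reading
consistent with how the reference thresholds were derived). The mean
rule `(P₀+P₁)/2` balances the two error types; the robust rule
`max(P₀, P₁ − SD(P₁))` sits lower whenever SD(P₁) > (P₁−P₀)/2, trading
false positives for fewer false negatives. The decision boundary is
inclusive: probability ≥ threshold → present.

**Validation** pools confusion counts over all modelled species
(micro-averaging, matching how the reference confusion matrices were
tabulated) and reports Cohen's κ `(p_o − p_e)/(1 − p_e)` with
marginal-product expected agreement, accuracy, sensitivity and
specificity; the latter two are reported as unavailable (not zero)
when their denominator is empty. The 75/25 train/validation split is
random by site, unstratified.

## Range metrics

Ubiquity = 100·(surveys where found)/(surveys in range); Extent =
100·(HUC8s occupied)/2200, with 2200 a named, overridable estimate of
the conterminous-US HUC8 count; Tolerance = percent of randomly
generated streams predicted occupied; Robustness = E^0.33·T^0.33·U^0.33
(exponent kept at the two-decimal 0.33, so a perfect 100/100/100
species scores 95.5, not 100). Robustness is absent, not zero, when
any component is missing.

Tolerance's random streams are multivariate-normal draws matching the
empirical covariate mean and covariance via Cholesky factorisation
(10,000 draws by default). Two open choices are surfaced as
parameters: (i) the decision cutoff inside Tolerance defaults to a
fixed 0.5 but can be the species' own mean/robust threshold — this
materially changes values and is reported alongside them; (ii) the
bounded covariates IWI and BMMI are clipped to [0, 1] after Gaussian
sampling by default, with an unclipped mode available, since plain
covariance-matched generation can produce physically impossible
streams and either convention is defensible.

## Range-polygon → HUC8 assignment

Rules, in order: (1) if the polygon intersects at most
`small_polygon_limit` HUCs (default 3 — "a few", quantified once and
configurable), every intersecting HUC is included; (2) otherwise HUCs
with ≥ 50 % of their area inside the polygon (inclusive); (3) plus
HUCs with positive sub-half overlap lying exactly one directed flow
edge (up- or downstream) from a step-2 HUC. Connectivity is never
followed transitively — a chain of partially covered HUCs does not
propagate membership. Geometry is planar; fixtures use projected unit
grids, and no geodesic areas are computed.

## Allometry

`W = aL^b` with per-species coefficients and pooled defaults
a = 0.01135, b = 3.07 (cm, g; no unit auto-detection). Species missing
demographic fields get them from three fixed regressions: mean weight
`0.00654·Lmax^2.1675`, mean length `4.7·W^0.3184`, max age
`1.333·Lmax^0.428`. Their coefficients are constants of the package;
the accompanying R² values (0.74, 0.96, 0.37) are stored as metadata
and nothing is re-fitted. Auto-filled fields are flagged in
`derived_fields`.

## Beneficial-use classification

Sport fish: maximum length strictly over 25 cm (20 cm for
Salmon/Trout; 15 cm for Sunfish and Black Bass) and rarity below 7;
otherwise non-game. "Over" is read as strict, so a species exactly at
a cutoff is non-game. Subsistence and exclusively-exotic status are
tribe-level lookups returned as separate flags, with the Rio Grande
Cichlid carved out of the otherwise-exotic cichlid tribe. Rarity
labels map case-insensitively (whitespace-normalised, compound labels
verbatim) onto the 1–10 ordinal scale; 10 means extinct within the
range.

## Synthetic fixtures

The generator emulates the *structure* of the real inputs, not their
content: a rectangular grid of unit-square HUCs joined in a single
row-major flow chain; species ranges as contiguous blocks of 40–100 %
of the chain; survey covariates multivariate-normal around
field-plausible means (drainage 500 ± 400 km², elevation 400 ± 250 m,
slope 2 ± 1.5 %, IWI 0.6 ± 0.2, BMMI 0.5 ± 0.25, with slope–elevation
r = 0.4, slope–drainage r = −0.3, IWI–BMMI r = 0.5), IWI/BMMI clipped
to [0, 1]; and catches Bernoulli from a per-species logistic in the
standardised covariates with slopes of magnitude 1.0–2.5 — strong,
well-separated occurrence structure. The default fixture is 20
species, a 5×5 grid and 3,000 surveys, sized so the whole pipeline
(including training every model) runs in seconds; the model-recovery
suite uses 2,000 surveys and 20 species.

A single root seed fans out via spawned substreams (species table,
grid, covariates, catches), so adding a generator or changing one
component's parameters never perturbs another's draws.

What the fixtures do **not** emulate — and what passing tests
therefore do not show about real data: real ranges are not contiguous
chain blocks and real drainage networks are trees, not a single chain;
real covariates are skewed (drainage area is closer to log-normal)
with regional structure; real detection is imperfect (a species can be
present and uncaught for gear reasons, which deflates P₁ and κ in ways
the logistic fixture does not reproduce); and real occurrence depends
on biotic interactions absent from any five-covariate model. The
national-scale published figures (≈7,400 omission errors; Ubiquity
0.093–74.4, etc.) require the national databases and are out of reach
at fixture scale; the test suite checks the *behaviour* of each
computation (exactness of the audits, parameter recovery, metric
bounds) instead.

## Numerical choices

* Thresholds and filters use inclusive ≥ comparisons throughout.
* κ is defined as 0 when expected agreement is 1 (the all-one-cell
  degenerate matrix carries no information beyond chance).
* CSV floats are written with 17 significant digits and parsed in
  round-trip mode, making every table serialisation bit-exact.
* The biomass solver's closed form is exact; tolerances in tests
  (1e-6 relative) cover only floating-point accumulation.
* Banker's rounding (round half to even) for the display-only integer
  counts.

## Known limitations

The size spectrum ignores competition, predation and habitat
suitability beyond the five covariates; in communities of similarly
sized species its relative abundances should be read as order-of-
magnitude guidance only. Occurrence models extrapolate poorly for
species with tiny ranges but high detectability (their Tolerance is
overestimated because the model never sees unsuitable conditions
inside the range). The assemblage filter mitigates this in practice by
only ever scoring species already recorded in the target HUC8.
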