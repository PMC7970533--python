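# streamcom

Stream-fish community estimation for the conterminous United States —
an offline, scriptable implementation of the pipeline that turns a
watershed's species pool into a plausible stream community and then
distributes abundance and biomass across it by body size.

Fish community data are expensive to collect and rarely available for
an arbitrary stream reach, yet ecological models need a community as an
initial condition. `streamcom` addresses this for researchers and
modellers who need a credible first-pass community estimate: it starts
from species range records on 8-digit Hydrologic Unit Code (HUC8)
subbasins, filters that species pool with per-species probabilistic
occurrence models driven by five stream covariates, and allocates a
user-chosen total abundance or biomass across the surviving species
with a community size spectrum. Because the national databases behind
the original system are not redistributable, the package ships a
seeded synthetic-fixture generator with known ground truth instead;
every stage is testable without any download.

## The models

**Size spectrum.** Abundance in a community falls with mean body
weight as a power law,

    N_i ∝ W_i^(−β_i),    β_i = 0.5 · W_i^0.06  clamped to [0.5, 0.75]

with W in grams (β = 0.5 at or below 1 g, 0.75 at or above 1000 g).
Species whose observed density departs from the size trend carry a
residual ε and use β* = β − Δ with Δ = 0.15·ε/(3σ), σ = 0.65.
Normalising W^(−β) over the community gives relative abundances;
multiplying by the total abundance gives counts and biomasses. Total
biomass is linear in total abundance, so a biomass target is inverted
in closed form.

**Occurrence models.** For each species caught in ≥ 25 surveys, an
XGBoost binary classifier predicts occurrence probability from
drainage area (km²), mean catchment elevation (m), stream slope (%),
the Index of Watershed Integrity (IWI ∈ [0,1]) and the probability of
a good benthic invertebrate multimetric index (BMMI ∈ [0,1]).
Negatives are sites inside the species' recorded range where it was
not caught. Presence is declared when the predicted probability
reaches a species-specific threshold: the mean rule (P₀ + P₁)/2 or the
robust rule max(P₀, P₁ − SD(P₁)), both computed from training-set
predictions. Validation pools the per-species confusion matrices and
reports Cohen's κ, accuracy, sensitivity and specificity.

**Range metrics.** Ubiquity (% of in-range surveys that caught the
species), Extent (% of ~2200 conterminous-US HUC8s occupied),
Tolerance (% of 10,000 covariance-matched random streams — drawn via
Cholesky factorisation — predicted occupied) and the composite
Robustness = E^0.33 · T^0.33 · U^0.33.

**Range assignment.** A hand-drawn range polygon maps to HUC8s by
majority overlap (≥ 50 % of the HUC's area), with one-hop
upstream/downstream neighbours admitted at any positive overlap, and a
small-polygon rule that keeps every intersecting HUC when only a few
are touched.

## Worked example

Allocate 10,000 fish across a seven-species community ranging from a
0.1 g minnow to a 200 g bass:

```sh
$ cat community.csv
species_id,mean_weight_g
minnow_a,0.1
minnow_b,0.3
darter,5
madtom,8
sunfish,25
sucker,120
bass,200

$ streamcom spectrum --species-csv community.csv --total-abundance 10000 --out spectrum.csv
total abundance 10000.0 fish, total biomass 32.32 kg
```

The output table (rounded):

```
species_id  mean_weight_g  beta_effective  relative_abundance  count_int  biomass_g
  minnow_a            0.1           0.500               0.534       5344    534.397
  minnow_b            0.3           0.500               0.309       3085    925.603
    darter            5.0           0.551               0.070        697   3482.710
    madtom            8.0           0.566               0.052        520   4162.996
   sunfish           25.0           0.607               0.024        240   5996.847
    sucker          120.0           0.666               0.007         70   8346.876
      bass          200.0           0.687               0.004         44   8867.745
```

The smallest species dominate numerically (53 % of individuals) while
the largest carry most of the biomass — the expected shape of a stream
size spectrum. `--total-biomass 32317` instead of `--total-abundance`
solves for the abundance that attains that biomass.

The full pipeline runs off a synthetic fixture:

```sh
streamcom simulate --seed 3 --n-species 10 --grid 4 4 --n-surveys 1000 --out-dir fixture
streamcom train --surveys fixture/surveys.csv --distribution fixture/distribution.csv \
    --species fixture/species.csv --out bundle --seed 3
streamcom assemblage --distribution fixture/distribution.csv --species fixture/species.csv \
    --bundle bundle --huc huc01 --drainage-area 300 --elevation 250 --slope 1.5 \
    --iwi 0.6 --bmmi 0.5 --total-abundance 5000 --out-dir run
```

`run/community.csv` lists the retained species with their predicted
probabilities; `run/spectrum.csv` is the abundance/biomass table above
for that community. `streamcom convert --length 10` applies the
length–weight power law W = aL^b (default a = 0.01135, b = 3.07; 10 cm
→ 13.3351 g). `streamcom metrics` and `streamcom check-db` compute the
range metrics and the errors-of-omission audit.

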