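# Methods

## The reconstruction problem

Neutron rem-meters are too large to place inside an anthropomorphic
phantom, so out-of-field organ doses cannot be measured directly.
`neudose` implements the standard work-around: measure the neutron
ambient dose equivalent H\*(10) at a few points on the patient table,
then transfer those readings to organ positions with two corrections —
one lateral (distance bins), one vertical (depth-dose ratio). The
result is a per-organ neutron equivalent dose H_T, from which effective
dose and stochastic-risk projections follow by NCRP-116 coefficient
products.

The package treats the printed reference tables (measurement campaign,
depth-dose curve, organ geometry, coefficients) as data, bundled as
versioned CSV files, so any of them can be replaced — e.g. ICRP-103
tissue weights — without code changes.

## Pipeline and assumptions

1. **Distance bins.** The out-of-field neutron spectrum at the table
   varies by less than ~10% across tens of centimetres, so one
   measurement represents a whole bin: [5, 40] cm → the 20-cm reading,
   (40, 80] cm → the 60-cm reading. Organs beyond the last bin clamp to
   it by default (the reference geometry has a femoral head at
   83.88 cm); organs closer than 5 cm to the central axis are refused —
   in-field and field-edge dosimetry is outside this model's validity,
   whatever the out-of-range policy says about the far side.
2. **Depth correction.** H\*(10) is defined at 10 mm depth in the ICRU
   sphere, so the depth correction is the ratio of a tabulated neutron
   depth-dose curve (0.5 MeV incident energy, the average neutron
   energy at the table) at organ depth to its value at the 1-cm
   reference depth. The reference depth is configurable for sensitivity
   analysis.
3. **Composite organs.** Skin: mean of the two out-of-field readings,
   no depth correction (the in-field skin area is negligibly small).
   Red marrow: skeletal regions borrow surrogate organ doses
   (head→brain, upper limb-girdle→breast, sternum→heart, ribs→heart,
   vertebrae→cord, sacrum→femoral head, lower girdle→femoral head; the
   source lists surrogates only for merged regions, so this expansion
   is this package's choice and the map is an argument) weighted by the
   active red-marrow fractions 0.131/0.062/0.034/0.141/0.109/0.139/0.261.
   Bone surface: unweighted mean over the six non-head regions.
4. **Aggregation.** E = Σ W_T·H_T over the twelve named organs; organs
   without a W_T form one remainder compartment at W = 0.05. Risk:
   cases = H_T[Sv] × (coefficient × 10⁻²) × population, summed over
   named organs plus the remainder; genetic effects apply the 1.00 ×
   10⁻² Sv⁻¹ coefficient to the gonad dose.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| bin rule | [5,40]→20 cm, (40,80]→60 cm, clamp beyond | cm | spectral stability assumption above |
| reference depth | 1.0 | cm | depth at which H\*(10) is defined |
| interpolation scheme | `linear` | — | see below |
| rounding mode | `precise` (`paper` for table reproduction) | — | see below |
| prescription | 60 Gy, 2 Gy/fraction | Gy | reference brain-tumour course |
| marrow normalization | `as-printed` | — | fractions sum to 0.877; see below |
| effective-dose remainder rule | `mean` | — | see below |
| risk remainder rule | `sum` | — | see below |
| population | 10⁶ | persons | risk projections quoted per million |

## Numerical choices

* **Interpolation.** The depth-dose table is interpolated either
  linearly or log-linearly (linear in log dose — exact for exponential
  attenuation). The reference tables were evidently produced with an
  unstated mixture: the heart row matches linear, spleen/colon/bladder
  match log-linear, and kidney/pancreas/femoral-head match neither.
  Default is linear; both schemes are first-class; the discrepant rows
  are asserted as discrepancies in the tests, not matched.
* **Rounding.** `paper` mode rounds the per-Gy dose to two decimals with
  half-even rounding *before* multiplying by the course dose (0.62 ×
  60 = 37.2, not 0.6220 × 60 = 37.32), which is how the reference
  per-course values were evidently computed; skin is the exception (its
  38.70 = 0.645 × 60 is unrounded). `precise` mode never rounds and is
  the default for scientific use; the two modes differ by at most
  0.005 × prescribed dose per organ. Half-even rounding goes through
  `decimal` on the shortest float repr, so 0.645 → 0.64 regardless of
  binary representation.
* **Out-of-grid depths.** Below the first tabulated depth (build-up
  region) the interpolator refuses — the curve carries no information
  there. Beyond the deepest row it clamps to the last value with a
  warning; no organ in the reference geometry needs it.
* **Depth classes.** surface [0, 5] cm, middle (5, 10] cm, deep
  (10, 15] cm, closed upper bounds; depths beyond 15 cm (the spinal
  cord at 16 cm) are reported separately as unclassified rather than
  stretched into "deep".
* **Uncertainty.** Each organ dose inherits the relative standard
  deviation of its bin measurement. Aggregated sds use first-order
  propagation with doses sharing a measurement point treated as fully
  correlated and different points as independent; coefficients carry no
  uncertainty. The reference tables' per-organ ± values follow no
  single discernible propagation rule and are not reproduced.

## Design choices on genuinely open points

* **Remainder asymmetry.** Only a *mean*-pooled remainder closes the
  reference effective dose (13.36 mSv = 13.209 named + 0.05 × 27.6/9),
  while only a *sum*-pooled remainder yields its remainder risk
  (13.80 = 0.05 × 10⁻² × 27.6 mSv scaled to a million). Both rules are
  implemented explicitly with config overrides; the defaults reproduce
  the reference aggregation.
* **Marrow weights.** The printed fractions sum to 0.877 and the source
  is silent on renormalization; `as-printed` is the default with a
  `renormalized` option. Neither variant reproduces the printed marrow
  (6.00 mSv) or bone-surface (9.00 mSv) rows — the stated procedure
  gives ≈ 3.74 and 8.1 mSv from the printed surrogate doses — so those
  rows are reachable only through the organ-dose override file, which
  is also how the downstream aggregates are validated.
* **Genetic effects.** The stated formula gives 34.8 mSv × 1.00 ×
  10⁻² Sv⁻¹ × 10⁶ = **348** cases per million; the printed 384 is
  inconsistent with its own formula (likely a digit transposition). The
  package computes 348 and asserts the discrepancy rather than matching
  the printed number.

## Synthetic data: what a green test establishes

The generator emulates the *structure* of a table-top survey, not
neutron physics:

* distance profile `truth(d) = floor + (h0 − floor)·exp(−d/L)` with
  defaults h0 = 1.30 mSv/Gy, floor = 0.55 mSv/Gy, L = 11 cm — chosen
  once to lie within 10% of the measured 1.30/0.71/0.58 profile at
  0/20/60 cm while keeping the "rapid then smooth" decay shape;
* per-point noise Normal(truth, cv·truth) truncated at zero, cv = 0.05,
  three replicates — the survey protocol reports mean ± sd of three
  repeats with ~10% overall uncertainty, and Normal is the minimal
  distributional assumption;
* a pure-exponential depth-dose curve, for which the log-linear
  interpolant is exact in closed form;
* uniformly sampled organ tables over the reference geometry's ranges.

The replicate sd uses the population formula (ddof = 0). With three
replicates the ±1 sd interval then covers the truth with probability
P(|t₂| ≤ √2) ≈ 70.7% (vs 77.5% for ddof = 1), which is the closest
three-replicate analogue of the nominal 68% Gaussian band; the recovery
tests check the empirical coverage against [60%, 76%].

Green synthetic tests establish that the estimator chain is unbiased
and self-consistent under the generator's assumptions. They do not
establish anything about real neutron spectra, detector response,
room-scatter geometry, or inter-patient anatomical variation.

An independent oracle (`oracle_pipeline`) recomputes every output with
plain scalar arithmetic, sharing no code with the production modules;
tests assert dual-route equality on the reference tables and on
randomized synthetic configurations. The oracle assumes the default bin
rule and region map.

## Known limitations

* No neutron transport, spectrum or room-scatter modelling; the energy
  dependence is frozen into the supplied depth-dose curve.
* Risk projections are flat NCRP-116 coefficient products — no
  age-, sex- or latency-resolved lifetime attributable risk.
* The skeletal surrogate rule is a coarse stand-in for voxel-phantom
  marrow dosimetry.
* Single-field geometry: measurements are assumed gantry-angle
  independent, valid for symmetric bunkers only.
* The uncertainty model (same-bin full correlation) is a package
  decision, not a reproduced one.
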