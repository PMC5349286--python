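# Methods

## The accounting model

One unit of metabolic hydrogen, [2H], is a reducing-equivalent pair
(2 e− + 2 H+), interconvertible with one H2. For each fermentation end
product the package carries a signed stoichiometric coefficient, mol [2H]
per mol product, derived from the glucose fermentation reactions:

| product     | coefficient | role |
|-------------|------------:|------|
| formate     | −1 | sink (CO2 + [2H] → HCOOH) |
| acetate     | +2 | source |
| propionate  | −1 | sink |
| butyrate    | +2 | source |
| valerate    | −1 | sink |
| caproate    | −4 (SC1) / +2 (SC2) | scenario-dependent |
| heptanoate  | −2 | sink |
| methane     | −4 | sink (CO2 + 4 [2H] → CH4) |
| gaseous H2  | −1 | sink (one pair vented per mol) |

Caproate can be formed by condensation of two propionyl-CoA (net −4
[2H]/mol) or of acetyl-CoA units via butyryl-CoA (net +2 [2H]/mol); since
the split is not observable from end-product concentrations, every ledger
is computed under both all-or-nothing scenarios (SC1, SC2). The exact
consequence, used as a test invariant, is
`balance(SC2) − balance(SC1) = 6 × caproate flux`.

Gaseous H2 has no synthesis reaction row; it is scored −1 because each
vented mole removes exactly one reducing pair. Branched-chain VFA
(isobutyrate and the co-eluting isovalerate/2-methylbutyrate pool) derive
from branched-chain amino acids, not glucose, and are excluded from the
ledger while remaining in flux tables and summaries.

Heptanoate is scored −2 per measured mole even though its formation
co-produces propionate that is also measured and scored — fidelity to the
conventional accounting takes precedence over avoiding the implied double
count. (`FluxTable.excluded` can be extended by users who want the
alternative.)

Fluxes: a solute leaving a vessel at steady state carries
concentration (mM) × daily infusion (0.626 L/d) mmol/d. Gases convert by
the ideal-gas molar volume R·T/P — 25.619 L/mol at 312.15 K and
1.013 × 10⁵ Pa, used at full precision by default; the constants object
accepts `molar_volume="paper"` to force the conventional rounded 25.6
exactly when bit-compatibility with printed tables matters.

VFA molar profiles are stored as mol/100 mol with one subtlety: the
normalized sum runs over the eight C2–C7 acids; formate is expressed on
the same basis but outside the closure (the reference profiles sum to 100
only without formate). The record validator enforces 100 ± 0.5 on the
eight-acid sum.

## Gas composition basis

Per-gas percentages are defined on the four-gas sum (CH4 + H2 + CO2 +
N2O). In the reference experiment, total collection-bag volume ×
percentage does *not* reproduce the gas-derived [2H] entries (back-
calculation puts the four-gas sum near 0.18 L/d for the control against a
0.74 L/d bag volume). The engine therefore treats per-gas daily moles (or
volumes) as first-class inputs; `reference_gas_mmol()` backs them out of
the [2H] table itself (CH4 = its [2H] entry / 4, H2 = its entry / 1).
With that basis the control CO2-equivalent total also reconstructs to
≈ 1.0 L/d, consistent with the printed greenhouse-gas row.

## Treatment-level reporting

Ledgers are computed per vessel-day, averaged over days within vessel,
then over vessels; SEM is across vessels (the experimental unit). For a
treatment that received nitrate, part of the [2H] flows into nitrate
reduction, which end-product concentrations cannot see; its consumption
totals, balance and recovery are therefore withheld (NaN) unless an
explicit nitrate-sink estimate (mmol [2H]/d) is supplied, in which case it
is added to consumption and the balance recomputed. Display rounding
follows the conventional layout: one decimal for totals/balances/major
productions, two for per-product entries; internal arithmetic is full
precision.

Known reconstruction limits, kept deliberately visible rather than
absorbed into tolerances:

* cells computed from per-vessel data in the source reproduce from
  treatment means only to ~±0.1 mmol/d (±0.4 for the ×4 caproate cell);
  the printed NOP/AQ balance rows are internally inconsistent with the
  printed totals they should equal (least-square means under unbalanced
  missingness), so no mean-based computation can match both;
* the nitrate [2H] sink computes to 51.1 mmol/d from dose
  (803 mg/d ÷ 62.004 g/mol) and outflows; the source prints 51.6, a
  residual we cannot attribute;
* the maximal nitrate-reduction extent computes to 98.5 %, not the
  printed 94 %;
* the literature microbial chain (0.41 mol [2H]/g dry cells, 0.545 g
  CP/g cell, 16 % N in protein) exceeds the per-mg-N scale calibrated on
  the reference control by ~170×; the per-mg-N preset (1.62/59.8 ≈ 0.0271
  mmol [2H]/mg N) reproduces the reference quadruple to ±0.012 mmol/d,
  and every output records which basis was used;
* supersaturation factors depend on a Henry constant the package
  deliberately does not default (the analysis driver uses 780 µM/atm with
  its provenance stated).

## Auxiliary sinks

* CO2-equivalents: Σ volume × GWP100 with CO2 1, H2 5.6, CH4 28, N2O 265.
* Nitrate: both DNRA (NO3− → NH4+, 8 e−) and denitrification to N2O draw
  ≈4 [2H]/mol NO3−, so the default rule charges 4 × (intake − nitrate
  outflow); a `partial_credit` variant charges outflowing nitrite only the
  1 [2H] actually invested. The N2O branch is not charged separately (it
  carried ~0.02 % of the dose in the reference data).
* Microbial biomass: linear in microbial N for any configuration, so
  treatment *ratios* are coefficient-free.
* Sf = measured dissolved H2 / (Henry constant × H2 partial pressure);
  1 at equilibrium.

## Synthetic-data generator

The generator emulates the measurement structure, not the fermentation
dynamics: for each analyte,
`value(vessel, day) = treatment mean + vessel effect + day effect + residual`,
all effects independent zero-mean normals, the day effect shared by a
treatment's vessels on a day (emulating a repeated-measures day effect),
and the result truncated at zero. Default means are the reference
treatment profiles; default dispersions are backed out of the printed SEM
columns (vessel-mean SD = SEM × √4) and split 50 % vessel / 25 % day /
25 % residual variance — the source reports no partition, so the split is
an explicit, configurable package choice. Truncated normal was chosen
over lognormal for mean fidelity at the small CVs involved; at the
reference means truncation is effectively inactive except for
zero-mean analytes (nitrate in non-nitrate treatments), which are
generated noiselessly by giving them their printed near-zero SEMs only.

Noised VFA shares are renormalized to the profile's own total (not to
exactly 100) so that zero-dispersion runs reproduce the means bit-for-bit
while noisy runs remain valid compositions; gas percentages are treated
the same and capped at 100. Intra-day dissolved-H2 kinetics (the
reference experiment sampled 13 time points per day) are summarized as a
single daily mean; adaptation/recovery trends across days are not
modeled. Passing tests on this generator therefore demonstrate correct
*accounting* under the stated noise model — they do not validate any
fermentation biology.

## Parameter recovery

`balance_recovery_study` simulates complete experiments (default
4 treatments × 4 vessels × 6 days, the reference design), runs the full
per-record pipeline, averages days then vessels, and compares the
estimated treatment-mean SC1 balance with the generator's truth. "Within
3 SEM" uses the *empirical sampling SD of the estimator across
replicates*: with the per-replicate n = 4 estimate the statistic is
t-distributed with 3 degrees of freedom and a 3-SEM band covers only
~94 % by construction, which would test the t distribution rather than
the pipeline. Against the true sampling scale, a ≈ 99.7 % coverage is the
correct expectation for an unbiased estimator; the suite requires
≥ 99 % per treatment over 1000 seeded replicates (runs in a few seconds).
The pipeline is nonlinear in the noised analytes (total × share,
renormalization), so exact unbiasedness is not guaranteed; the observed
bias is ≲ 0.3 mmol/d against sampling SDs of 2–3 mmol/d.

## Numerical conventions

Validation rejects negative concentrations/volumes/masses and gas
fractions outside [0, 100]; missing measurements are `None`/empty cells,
never zeros (a measured 0.00 mM nitrate is data). Recovery is `None`
(flagged, not infinite) when nothing is produced; SEM is NaN (flagged)
for single-unit groups; disappearance above 100 % of input warns instead
of clipping. Result tables are written as CSV plus a JSON twin with
identical content and round-trip within 1e-9. All randomness flows from a
single integer seed through `numpy.random.default_rng`.
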