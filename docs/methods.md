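# Methods

## Problem and model

`redquant` analyses targeted LC–MS/MS peak-area data from rapid equilibrium
dialysis (RED) experiments that separate free from protein-bound drug in
plasma — the concrete system modelled is ropivacaine in dog plasma with a
deuterated internal standard (D7-ropivacaine), but every constant is
configurable. A RED insert holds `V_p = 200 µL` plasma against
`V_b = 333 µL` buffer across an 8 kDa dialysis membrane. At equilibrium the
free concentration `f` is equal on both sides and total drug amount is
conserved (no volume shift is assumed across the membrane):

```
(f + bound(f)) · V_p + f · V_b = C_total · V_p
```

Two binding models are supported. With **linear** binding the bound/free
ratio is constant, `bound = f (1 − fu)/fu`, giving the closed form
`f = C_total V_p / (V_p/fu + V_b)`. With **saturable** (single-site
Langmuir) binding, `bound = Bmax f/(Kd + f)`, the mass balance is solved
with Brent's method and accepted only when the mass residual is below
1e−9 of the total amount. In the limit `Kd → ∞` at fixed
`Bmax/Kd = (1 − fu)/fu` the saturable model reproduces the linear one; this
limit is used as an oracle in the tests.

Because the free concentration is common to both chambers, the free
*amount* splits by volume: the plasma chamber holds
`V_p/(V_p+V_b) ≈ 37.5 %` of it and the buffer chamber `≈ 62.5 %`. (The
stated 37.5/62.5 split is exact for a 333.33 µL buffer chamber; with the
printed 333 µL the shares are 37.52/62.48 %. The package computes shares
from the configured volumes and does not hard-code the percentages.)

## Quantification

Each fraction is quantified against its own matrix-matched calibration
curve: the undiluted buffer fraction on a "1:1" curve (9 levels,
0.05–1000 ng/mL) and the 4-fold-diluted plasma fraction on a "1:4" curve
(13 levels, 0.075–1000 ng/mL). The response is the analyte/IS quantifier
area ratio `y`, fitted against nominal concentration `x` by weighted least
squares with weights `1/x` — the standard bioanalytical down-weighting that
equalises relative influence across a 4–5 decade range. Replicates enter
the fit as individual points (no pre-averaging), preserving the weighting
semantics. The solver is statsmodels WLS on a centred predictor (centring
is purely numerical conditioning; results are checked against a
hand-written weighted-normal-equations oracle in the tests).

`R²` is reported as the unweighted coefficient of determination of the
fitted line on (x, y); the weighted variant is also computed
(`r_squared_weighted`) since vendor conventions differ. Curve acceptance:
`R² > 0.99`, back-calculated accuracy within ±20 % of nominal at the LLOQ
and ±15 % elsewhere, and at least 75 % of levels in band; band edges are
inclusive. Back-calculation is the exact inverse
`(y − intercept)/slope`; negative results are clamped to 0 and flagged.
Out-of-range (above-ULOQ) samples are back-calculated linearly and are not
refused; range flags are available from curve assessment. A
qualifier/quantifier ion-ratio identity check with a ±30 % default
tolerance (common convention; no tighter value is mandated) is provided.

## Mass balance to the original plasma sample

Writing `B` and `P` for the analyzed buffer- and plasma-fraction
concentrations (chamber-level — because samples and standards go through
the identical prep chain, the prep dilution cancels inside each curve):

```
free  = B · (V_p + V_b) / V_p
bound = P − B
total = P + (V_b/V_p) · B      (≡ free + bound, exactly)
```

`free` is the free amount liberated at dialysis equilibrium re-referenced
to the plasma volume. Under linear binding it equals
`fu (V_p+V_b) / (V_p + fu V_b) · total`, which exceeds `fu · total`
because removing free drug into the buffer pulls bound drug off the
protein. With the default `fu = 0.05` this reconstructed free/total ratio
is ≈ 12 %; a ratio of ≈ 5 % corresponds to `fu ≈ 0.02`, consistent with
the ~98–99 % binding reported for dogs. Both readings of the "5 % free"
observation are therefore representable; `fu` is config-exposed and the
default follows the workflow-level observation. Negative bound values
(buffer reading above plasma reading, possible under noise near the LLOQ)
are clamped to 0 and flagged rather than propagated, so batch processing
survives.

The prep volume chain is 25 µL chamber aliquot + 25 µL complementary
matrix + 5 µL acid + 2.25 µL IS solution + 170 µL acetonitrile
(227.25 µL extract; factor 9.09), and the plasma fraction is additionally
diluted "1:4", read as 1 part + 3 parts (factor 4, total 36.36);
the alternative factor-5 reading is config-overridable
(`plasma_post_dilution_factor`).

## Validation statistics

All statistics follow regulated-bioanalysis conventions: accuracy
`100·mean/nominal`; precision as CV % with the n−1 sample SD; intra-run
statistics per run and inter-run statistics pooling all replicates of all
runs (a 3-day × 6-replicate design yields n = 18 — pooling, not the mean
of run means). Acceptance bands are inclusive: 85–115 % accuracy and
CV ≤ 15 % (80–120 % / ≤ 20 % at the LLOQ); per-lot matrix effect at ±15 %
across ≥ 6 lots; stability mean within ±15 % per storage condition
(T0, benchtop, freeze/thaw, long-term −20/−80 °C, processed); carry-over
blanks after the ULOQ at ≤ 20 % of the LLOQ analyte response and ≤ 5 % of
the IS response; selectivity blanks per lot at the same thresholds;
precipitation recovery `100·mean(A)/mean(B)` and overall recovery
`100·mean(A)/mean(C)` per analyte, with the acceptance quantity computed
on per-replicate analyte/IS ratios and a pass when IS and analyte overall
recoveries agree within 15 percentage points. Reinjection reproducibility
is informational and reports *both* reference bases (accuracy vs nominal
and reinjection mean as % of first-run mean), since published tables of
this kind are ambiguous about the basis. Report tables carry raw values
plus values rounded half-up to two decimals.

## Synthetic-data generator

The generator is first-class, tested code; it emulates the statistical
structure the analysis assumes, not chromatography:

* **Response.** Linear per-channel response `area = S·c·lot·(1+ε) + η`,
  with proportional noise `ε` of SD `sigma_prop = 0.03` whose variance is
  half shared between the analyte and IS channels of one injection (an
  isotope-labelled IS tracks preparation and ionisation variability but
  not all of it), and additive baseline noise `sigma_add = 18` area units
  (≈ 0.5 % of the analyte area at the 0.05 ng/mL LLOQ). These defaults
  put simulated CVs in the few-percent range typical of validated MRM
  assays. Area magnitudes are fixture choices (no instrument scale is
  mandated); the default analyte sensitivity makes the noiseless
  response-ratio slope ≈ 0.7274 per ng/mL for realism.
* **Matrix lots** multiply the analyte channel only (a differential matrix
  effect the IS does not cancel); default factors are 1.0.
* **Carry-over**: a fraction of each channel's area bleeds into the next
  injection (first-order recursion over the injection sequence). The
  default is 0 — with a 20 000-fold ULOQ/LLOQ span, any fraction above
  1e−5 would trip the post-ULOQ blank check, so carry-over is injected
  explicitly by tests that exercise detection.
* **Injection order**: calibration standards ascending, a blank
  immediately after the ULOQ (the carry-over check position), then QCs.
* **Blanks** (carry-over and selectivity) receive no internal standard, so
  IS signal in a blank can only be interference or carry-over.
* **Study design defaults** are the validated campaign: both curves in
  technical triplicates over 3 runs; QCs at LLOQ/LQC/MQC/HQC
  (0.05/0.15/300/750 for 1:1 and 0.30/1.00/300/750 ng/mL for 1:4), six
  replicates; whole-workflow spikes 88 and 1742.50 ng/mL through RED
  (the 1742.50 nominal follows the repeatability table's arithmetic; the
  rounder 1740 appears elsewhere and is configurable); recovery spikes 10
  and 2000 ng/mL, n = 5 per approach; six matrix lots.
* **PK module**: one-compartment absorption/elimination
  `C(t) = dose·scale·(e^{−ke t} − e^{−ka t})`, zero at and before dosing,
  with lognormal inter-animal variability (geometric CV 0.3). Defaults
  `ka = 0.09 /min`, `ke = 0.012 /min`, `scale = 369 (ng/mL)/(mg/kg)` put the
  noiseless 1 mg/kg peak near 233 ng/mL around 26 min — plausible for
  intraperitoneal instillation, and anchored only loosely: real animal
  concentration data exist only as figures and are not reproduced.

What the generator does **not** emulate: peak integration and
chromatographic interferences, drift within a run, heteroscedasticity
beyond the proportional+additive structure, non-specific binding to the
RED device, incomplete equilibration (an approach-to-equilibrium rate is
deliberately out of the default path: equilibrium is assumed complete at
6 h), and volume shift across the membrane. Passing tests therefore
demonstrate correctness of the statistics and the mass-balance algebra
under the assumed noise structure — not method performance on real
extracts.

## Numerical choices and degenerate inputs

* Saturable equilibrium: Brent root-finding on `[0, C_total]` with
  near-machine tolerances, hard failure if the 1e−9 relative mass residual
  is not met.
* Weighted fits require ≥ 2 distinct levels and strictly positive
  nominals (weights undefined at 0); singular designs raise.
* Division-by-zero paths (zero slope, zero qualifier area, zero IS area,
  zero denominator means in recovery, n < 2 for an SD) raise or flag
  explicitly rather than propagating NaNs silently.
* A fixed integer seed drives every random draw through one
  `numpy.random.Generator`; identical config + seed reproduces CSV outputs
  byte-for-byte (provenance records the config hash, not timestamps).

## Problem sizes used by the test-suite and acceptance script

The stochastic checks use the full validated design per seed (3 runs × 2
curves × triplicate standards + 6-replicate QCs) across 200 seeds for the
QC band pass rate, 60 seeds for the whole-workflow accuracy property, 1000
random instances for fit-oracle equivalence, and 18 specimens per spike
level for repeatability — sizes chosen to give stable Monte-Carlo
estimates in seconds on one CPU.

## Known limitations

* With the chamber-level quantification convention and `fu = 0.05`, the
  high workflow spike puts the plasma-chamber concentration (~1609 ng/mL)
  above the 1:4 curve's ULOQ; the simulator's linear response makes the
  extrapolation exact, but a real assay would dilute further.
* A published workflow-level observation that ~0.08 ng/mL analyzed in
  buffer corresponds to ~4.4 ng/mL recalculated (a ≈55× factor) is not
  derivable from any single volume chain above and is intentionally not
  implemented.
* The reconstructed "free" is an operational quantity of the dialysis
  experiment (free at equilibrium re-referenced to plasma volume), not the
  in-vivo free concentration `fu·C_total`; users wanting `fu` itself should
  use `c_buffer/c_plasma_chamber` from the chamber readings.
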