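# Methods

This note documents the dose models, the uncertainty machinery, the
synthetic-data generator and the numerical choices behind `doserecon`,
including the places where the design was genuinely open and what the
package chose.

## Calendar model and exposure windows

All integration runs on whole days from the accident origin, 1986-04-26.
The 01:23 accident time is ignored for windowing (Pripyat timelines carry
sub-day resolution internally as hours from the origin). Two windows are
built per child: `[accident, DOB − 51·7 days)` and `[accident, DOB − 38·7
days)`. Window ends are **exclusive** — exposure on the end date is not
counted — which makes the DOB-51→DOB-38 difference exactly 91 days for
every child. When DOB − 51 weeks precedes the accident (possible only for
the earliest eligible children, born 46–51 weeks after the accident), the
DOB-51 window clips to zero length and all DOB-51 doses are zero; the
condition is detectable via `ExposureWindow.is_empty`.

Children are eligible if born ≥ 46 weeks (322 days) after the accident.
Mission doses truncate at the earliest of the window end, the subject's
last mission day, and 1990-12-31 (legal end of cleanup activities).

## Distribution machinery

Five families cover every uncertain parameter: point, U(min,max),
TR(min,mode,max), TN(AM,SD,min,max) and TLN(GM,GSD,min,max). Sampling is
**inverse-CDF on the truncated quantile range**, not rejection, so each
parameter consumes exactly one uniform variate per realization. This
makes substream bookkeeping deterministic (a prerequisite for bit-level
reproducibility and for the common-random-numbers coupling below) and
lets correlated parameters couple through a Gaussian copula: correlated
deposition ratios draw jointly-normal scores with the stated pairwise
coefficient against their anchor nuclide and map through each marginal's
quantile function. The copula family is not dictated by the correlation
coefficients alone; Gaussian is the minimal choice and is recorded here
as a design decision.

Reproducible streams: `RngStream(seed).stream(*key)` hashes each key
component (SHA-256, first 4 bytes) into a `numpy` `SeedSequence` together
with the master seed. Identical (seed, key) pairs give bit-identical
sequences; distinct keys give independent streams.

The lognormal AM→GM conversion defaults to the standard relation
GM = AM·exp(−(ln GSD)²/2). A variant without the ½ factor — a form that
circulates in some legacy parameter tables — is available behind
`printed_form=True`, and the run manifest records which was used.

## Time-and-motion external dosimetry

Mission and Pripyat doses share one kernel: dose = C_g · Σ AKR·Δt·LF.
Central values: 0.710 (testes) / 0.586 (ovaries) for C_g with TN(AM,
0.1·AM, ±2SD); task durations U((1−CV)AM, (1+CV)AM) with CV = 0.1 when
the record carries none; site location factors TN(AM, 0.25·AM, ±2SD);
Pripyat location factors TLN(GM, 1.3, 0.6·GM, 1.7·GM), with indoor GMs
the 8-h-sleep daily averages of the printed day/night values per floor
(0.072/0.0018 → 0.049 for the 1st floor, 0.038/0.0001 → 0.025 for the
5th; the 3rd-floor table value 0.0322 is not exactly reproduced by the
16h/8h weighting, which gives 0.0317 — the package implements the stated
weighting and keeps the discrepancy visible rather than fudging either
number).

All mission/Pripyat parameter errors are unshared: the shared component
of the air-kerma-rate field error is known from the method's validation
literature to contribute under 1% of mission dose, so plain Monte Carlo
per subject is used (10 000 realizations by default). Two choices matter
for the realization structure:

* **C_g is drawn once per realization**, not per entry — it is a property
  of the subject's anatomy, not of the location.
* **AKR is drawn once per (location, grid-cell date) per realization** and
  reused by every itinerary entry resolving that cell. The uncertainty
  attaches to the interpolated field value, not to the entry; without
  this, summing many entries would average the field error away and
  per-subject dose GSDs would collapse toward 1 instead of sitting in the
  1.2–2.5 band typical of time-and-motion reconstructions.

AKR grids are explicit (location, date) tables; lookups between tabulated
dates are piecewise-constant (the governing cell is the latest one on or
before the query date). A parent who is both a Pripyat resident and a
cleanup worker has the residence dose folded into the mission pathway
(the realizations are summed), mirroring how such histories are treated
operationally.

## Residential external dose

The integrand for each nuclide is areal activity × dose-rate coefficient,
with areal activity σ·R_i·e^(−λ_i t) for chain-free nuclides and the
two-member Bateman solution (initial daughter deposit + in-growth from
the parent deposit) for ⁹⁵Nb, ¹³²I and ¹⁴⁰La. The daughter's dose-rate
coefficient is applied to the **total** daughter areal activity,
whichever member it grew from — the alternative normalization (separate
coefficients per origin) is not physically distinguishable for gamma
ground shine. The soil-migration attenuation p(t) = p1·e^(−λ1 t) +
(1−p1)·e^(−λ2 t) (p1 ~ U(0.35,0.45), λ1 ~ TR(1.17,1.27,1.39)×10⁻³/d,
λ2 ~ TR(3.2,3.8,4.7)×10⁻⁵/d) multiplies the ¹³⁴Cs/¹³⁷Cs terms only.

Because every integrand is a finite sum of exponentials (attenuation just
shifts decay constants), the integral is evaluated **analytically**; an
adaptive-quadrature route (`method="quad"`, relative tolerance 1e-8)
exists as an independent numerical cross-check and agrees to 1e-6 in the
test suite. The IV factor (individual outdoor-time variability,
U(0.7,1.3), unshared) multiplies the whole BF, indoor and outdoor time
alike — the data to split it by micro-environment do not exist in
interview records. Doses accumulate per residence interval clipped to the
window and sum across intervals.

Half-lives are an embedded constants table from standard decay data,
overridable via JSON config. Deposition-ratio central values and the
gonadal dose-rate coefficients DC_i are **documented placeholders of
realistic magnitude** (the field databases behind the originals are not
public): ratios follow condensed-component fallout patterns, and DC
scales with each nuclide's gamma energy per decay, normalized so ¹³⁷Cs
lands at ~6×10⁻⁵ mGy/d per kBq/m² (the classic 1 Ci/km² ≈ 0.1 µGy/h in
air), with a 0.85 ovary depth factor. Every oracle and invariant test is
constructed to be independent of these absolute values (linearity,
closed-form agreement, additivity), so replacing the tables does not
touch the verification.

## Radiocesium ingestion

Intake is normalized to the settlement's ¹³⁷Cs deposition: daily intake
I_k(t) = Σ_f rate_f·CF_f·c_milk,k(t). The pasture period runs through 31
July 1986 (milk, milk products and meat only); from 1 August 1986 root
uptake dominates, potatoes, root vegetables and mushrooms join, and the
milk concentration becomes a relative-concentration curve times the
settlement's soil-to-milk transfer factor (TR(0.6,1,1.4)×AM, shared per
settlement). Conversion factors: shop milk U(0.9,1), milk products
U(0.5,0.9), meat U(0.8,1), potato/root U(0.12,0.24), mushrooms U(5,15) —
all shared globally. Consumption rates are unshared TR(0.75,1,1.25)×AM;
mushrooms reported only as "yes" get U(0.010,0.030) kg/d. Dose factors
DF_k are unshared TLN bounded at (0.4·AM, 1.7·AM); the geometric spread
inside the bounds is not specified anywhere, so GSD 1.3 was chosen (the
same spread used for the Pripyat location factors). ¹³⁴Cs intake derives
from ¹³⁷Cs through the fixed initial activity ratio (0.5) and the decay
constant difference. No IV factor applies to ingestion.

The time shapes of the two concentration curves are configuration, with
synthetic defaults: a 14-day effective half-time exponential for the
pasture period (weathering plus decay on grass, starting at 3.0 Bq/L per
kBq/m²) and a 2-year half-time decline for the relative concentration
afterwards. Integration is a **day-resolution left-rectangle sum** on the
daily curves; the period boundary therefore splits any interval exactly,
and the rectangle rule is itself the oracle for piecewise-constant
curves. Meat and potato concentrations follow the milk curve
synchronously (no lag model). Urban residents, whose ingestion doses come
from direct body-burden measurements rather than this model, can carry a
directly supplied dose value on the residence record.

## Monte Carlo engine

Realization counts default to 10 000 (mission/Pripyat) and 1000 sets
(residential); the test suite and acceptance script run at 500/100, which
the engine's vectorization makes essentially free while preserving every
structural contract.

The 2-D scheme draws, per realization set: one deposition density and one
transfer factor per settlement, one ratio vector per area (oblast-level
by default, with the copula correlations), one behaviour factor per
(house type, zone), one attenuation parameter triple and one conversion-
factor vector globally, and one scale each for the two intake curves.
Within a set, every subject resolving the same scope key reads the same
element — the shared-error contract asserted by the tests. Unshared draws
(IV, consumption rates, dose factors) are keyed per subject.

**Common random numbers across windows.** A subject's DOB-51 and DOB-38
cases use identical substreams, so the nesting inequality DOB-38 ≥ DOB-51
holds *realization by realization*, not just in expectation. A
reconstruction that redraws independently per window shows small spurious
window differences from simulation noise; coupling the streams removes
that artifact and is the stronger invariant, at the cost of not
reproducing the noise signature of uncoupled implementations. GSDs are
computed over strictly positive realizations only; a structurally
unexposed pathway reports no GSD rather than a degenerate one.

## Synthetic cohort generator

The generator emulates the *input* side of the study conditions: 298
trios by default (71/51/59/51/66 across categories A–E), one to three
children per trio with weights 242/52/4, DOBs in [1987-03-14, 2005-07-15]
with ~40% born by end-1990. Category A/C/E fathers get mission
itineraries (E starts within days of the accident at high-rate
locations), category B/C mothers get an itinerary or a Pripyat timeline,
category D parents get neither and reside in low-deposition settlements
(< 37 kBq/m²). All parents get residence histories (non-overlapping,
gap-free, ~23% spanning two settlements) and food diaries.

Dose scales are reached by **calibrating the inputs analytically** —
never by back-solving doses. For the father cleanup pathway:
median dose ≈ C_g·(days)·(h/day)·AKR·LF = 0.71·30·6·2.0·0.8 ≈ 200 mGy·...
with the lognormal spreads of mission length (GSD 2.2) and location rates
(GSD 1.8) this lands the cohort median near 144 mGy (the generator
contract checks a factor-1.5 band at n≈200). Mother missions use fewer
days and lower-rate locations (median ≈ 7 mGy); Pripyat timelines
(30–110 h, ~30% outdoors, outdoor rate 0.9 mGy/h declining with a 3-day
half-time) give medians near 7 mGy. Residential medians depend on the
placeholder DC/intake tables and are order-of-magnitude plausible
(~0.2–2 mGy) rather than calibrated.

What the generator does **not** emulate: demographic realism, recall
error and interview heaping, geographic structure beyond settlement/area
ids, seasonal diet, relocation decisions, or the correlation between a
family's two parents' diets. Passing tests therefore demonstrate the
correctness and contracts of the dose machinery under realistic
magnitudes — not agreement with any confidential cohort's dose tables.

## Numerical and formatting choices

* Analytic exponential integrals with a λ→0 guard; quadrature cross-check
  at 1e-8 relative tolerance.
* Dose bins left-closed ([3,10) is printed "3.0-9.99"), 1000+ unbounded;
  GSD bins likewise partition [1, ∞).
* Percentages round half-up to one decimal; medians use pandas' default
  interpolation except where a table convention requires otherwise.
* Bundle CSVs are written with stable ordering and re-read with
  round-trip float parsing, so write→read→write is byte-identical and a
  run manifest (seed, counts, parameter-library checksum, GM-formula
  variant) suffices to reproduce a run exactly.

## Known limitations

* DC, deposition-ratio and intake-curve tables are placeholders; absolute
  residential doses (unlike their structure and uncertainty) inherit that
  placeholder status until real tables are configured.
* Inhalation during the mission and strontium/plutonium ingestion are out
  of scope (minor gonadal pathways).
* The per-subject mission GSD distribution is narrower than the 1.2–4.7
  range seen in real reconstructions when itineraries visit many
  independent grid cells; the dominant driver (shared-cell field error)
  is modelled, but recall error on durations/locations is not.
* A single photon energy/geometry underlies C_g; no energy dependence is
  modelled.
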