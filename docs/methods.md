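# Methods

This note documents the models implemented in `odorcal`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
campaign generator does and does not emulate.

## Olfactometry

A field olfactometer presents ambient air diluted with carbon-filtered air
at discrete dilution-to-threshold (D/T) ratios. An assessor's detection
threshold is bracketed by the last detectable dilution `D/T_yes` and the
first undetectable one `D/T_no`; the individual estimate is the geometric
mean of the bracketing Z values (`Z = D/T + 1`), and the session odor
concentration is the geometric mean of the panel's individual estimates, in
odor units per cubic metre (1 ou/m³ = odor at the panel threshold).

Design choices:

* **Dial ordering.** Nothing forces `D/T_no ≥ D/T_yes` in the arithmetic,
  and instruments are sometimes read in either direction, so any
  non-negative pair is accepted; a reversed pair triggers a warning rather
  than an error, because rejecting data on an unstated convention loses
  real measurements.
* **Dial domain.** Readings are arbitrary non-negative reals; a canonical
  discrete dial set is enforced only inside the synthetic generator, which
  must commit to an instrument model.
* **Panel size.** Sessions need at least two assessors; a `warn`-only mode
  exists for processing single-reader field notes.
* **Numerics.** Geometric means are computed as `exp(mean(log(·)))`; the
  log-space form is exact for the sizes involved and avoids overflow on
  long panels.

## Feature extraction

Two per-channel summaries of an exposure window are supported: the raw
maximum `S_max`, and the decibel peak-to-baseline ratio
`S_dB = 10·log10(S_max/S0)`. The decibel form is canonical here (not the
bare `log10` ratio): the factor 10 only rescales fitted coefficients but
keeps values on the scale conventional for quotient quantities. `S_dB` is
invariant to a channel's electrical gain — multiplying both `S_max` and
`S0` by a constant leaves it unchanged — which is the property that makes
it attractive for drift-prone chemiresistors.

Baselines come from a flagged clean-air segment (mean over the segment),
the offline synthetic-air procedure; a rolling 5th-percentile fallback
exists for field logs without a flagged reference. A window that never
leaves baseline is legal and yields `S_dB = 0`.

**Interferent rejection.** Metal-oxide channels respond to odorless gases
(methane above all), which a human panel cannot smell. A record is rejected
iff its olfactometric concentration is ≤ `cod_low` *and* at least one MOS
feature exceeds `z_high` robust z-scores (median/MAD over the dataset,
single pass; a zero MAD makes any deviation infinitely extreme). Defaults
`cod_low = 3 ou/m³` (the top of the lowest OAQII class: "the panel smelled
essentially nothing") and `z_high = 3` (the conventional robust-outlier
cut). The statistics are computed once on the full input — the filter is
deliberately single-pass, not iterative, so it cannot chew through a
dataset.

## Calibration families

* **MLR** — OLS of `C_od` on the channel features with intercept, fitted in
  raw concentration space exactly as the linear form is written. Requires
  more training rows than channels; a rank-deficient design raises.
* **PCR** — PCA (mean-centered, unit-variance scaled) on the training
  features, then OLS of `C_od` on the leading scores. The retained component
  count defaults to the minimizer of leave-one-out cross-validated RMSE on
  the training split, with PCA refit inside every fold so no held-out row
  leaks into the projection; ties go to the smaller count. An explicit
  integer overrides. With all components retained, PCR is an invertible
  rotation of MLR and reproduces its predictions to machine precision — a
  property the tests use as an oracle.
* **Stevens families** — `C_od = a·b^s` with exponent `s` being a single
  channel's feature (the channel with the highest training R² is chosen),
  the per-row geometric mean of the SdB features (undefined for raw maxima,
  enforced by error), or the first principal-component score (PCA centered
  and scaled, fitted on training rows only; test rows are projected with the
  *stored* training means and scales). All three are fitted by OLS in
  `log10 C_od` — the log-linear form `log10 C = log10 a + s·log10 b` is exactly
  linear, fitting in log space matches the Weber–Fechner framing of the dB
  features, and it guarantees `a > 0` so predictions are strictly positive.
  A flat exponent column degenerates gracefully to `a = gmean(y)`, `b = 1`.

Numerical conventions: PCA eigenvector signs are fixed by making each
component's largest-magnitude element positive (`b^PC1` is not
sign-invariant, so determinism matters); scaling uses sample standard
deviations (ddof = 1), the chemometric autoscaling convention; a constant
response with zero residual counts as R² = 1 (the 0/0 case). Training rows
whose SdB contains non-positive entries are dropped from the geometric-mean
family with a warning (strict mode raises); at predict time such rows yield
NaN and are excluded from evaluation metrics, with the actually used `N`
reported.

## OAQII, accordance and selection

The index has four classes over concentration — `(0,3]`, `(3,10]`,
`(10,60]`, `(60,∞)` ou/m³, lower-exclusive/upper-inclusive, so 3 ou/m³ is
class 0 and 60 ou/m³ class 2. Test-split quality is measured by RMSE (the
Euclidean distance between observed and predicted vectors over `sqrt(n)`)
and by accordance, the fraction of sessions placed in the same class by
model and reference. Selection takes the highest-accordance model among
those whose RMSE is within `(1 + slack)` of the minimum, with `slack = 0.25`
by default: a quarter more concentration error is judged an acceptable price
for better class agreement, and the rule reduces to plain argmin-RMSE at
zero slack. Predicted concentrations are floored at a tiny positive value
before classification so an occasional negative linear-model output lands in
the lowest class instead of crashing.

The scale can also be *derived*: intensity and hedonic annotations are
regressed on `log10 C_od` (Weber–Fechner linearity), each fit is inverted at
three annotation cut-points, and the two candidate concentrations per
boundary are combined by geometric mean — concentrations combine
multiplicatively everywhere else in this domain, so the geometric mean is
the consistent compromise. The default cut-points sit at the midpoints
between the verbal descriptor bands on an intensity scale of 0–6 and a
hedonic scale of 0 to −4; both scales are conventions of this package (the
descriptors themselves are ordinal, not numeric) and are configurable.

## Synthetic campaigns

The generator produces the study the pipeline targets: 60 sessions split
chronologically 40 train / 20 test (a calibrate-then-validate field
protocol; a random split is available), one exposure window per session.

What it emulates, with defaults and reasoning:

* **Emissions.** Background 1.5 ou/m³ (just above threshold — a working
  yard is never odor-free) plus, on half the sessions, a lognormal event
  with median 20 ou/m³ and σ_log = 1. The mix spans all four index classes,
  matching a source whose screening process runs episodically.
* **Sensors.** MOS channels respond as `S0·(1 + g·C^β + h·I)` with
  sub-linear exponents β ≈ 0.5–0.6 (chemiresistor power-law behavior), EC
  channels linearly; `I` is the odorless interferent, coupled only to MOS
  channels, strongest on the methane-class channel. A `powerlaw` response
  variant makes `S_dB` exactly linear in `log10 C` for oracle tests, and an
  optional saturation cap emulates sensor overload. Additive Gaussian noise
  (σ = 0.003 signal units), slow sinusoidal drift (1 %), and a per-session
  lognormal response scatter (σ = 0.2) complete the model. The scatter
  deserves a note: without it the channels are *functionally collinear*
  (every channel a deterministic function of the same scalar), which lets
  raw-space regressions acquire large sign-flipped weights that no physical
  array exhibits; real sensors' selectivity varies session to session, and
  20 % scatter restores that structure.
* **Panel.** Each assessor perceives `C·exp(ε)`, ε ~ N(0, 0.2), and the
  perceived value is bracketed by adjacent positions of the default dial set
  (2, 4, 7, 15, 30, 60) — the standard field-olfactometer stepping. Below
  the lowest dial the reading degenerates to `(0, lowest)`; above the
  highest it saturates at `(highest, highest)`. A continuous-dial mode
  (`dials=None`) recovers the true concentration exactly at zero noise,
  which the consistency tests exploit.
* **Annotations.** Intensity and hedonic values are linear in `log10 C`
  (slopes 2.3 and −1.5, intercepts 0.4 and −0.8 — chosen so the descriptor
  band edges fall near 3, 10 and 60 ou/m³), with noise, rounding to half
  steps, and clipping to the ordinal ranges.

All randomness flows from one integer seed through named substreams
(emission, interferent, sensor, panel, annotation), so changing one
component's noise never perturbs another's draws, and identical
configurations are bit-reproducible.

What it does **not** emulate: temperature/humidity covariates and their
compensation, sensor aging and long-term drift beyond the within-window
sinusoid, atmospheric dispersion between source and device, panel fatigue
or assessor screening, and correlated multi-gas chemistry. Tests passing on
these campaigns therefore demonstrate the correctness and statistical
behavior of the *pipeline*, not the field accuracy of any particular
hardware.

## Problem sizes

The test suite and the acceptance script run at the campaign's native scale
(60 sessions, windows of 60 one-second samples): 50 replicate datasets for
the PCR/MLR equivalence, 100 seeds for noisy Stevens recovery, 10⁴ grid
points for the index partition property, 10⁴ sessions for the Monte-Carlo
generator checks, and 20 replicate low-noise campaigns for the end-to-end
accordance summary — sizes at which every statistical check is stable from
seed to seed.

## Known limitations

* The five families are fitted independently; no regularization,
  uncertainty intervals, or model averaging.
* The interferent filter needs the olfactometric concentration, so it
  protects calibration, not unattended monitoring; during monitoring an
  interferent passes straight into the prediction (the
  `scripts/interferent_demo.py` script quantifies this).
* Accordance is an unweighted 0/1 agreement; near-boundary concentrations
  make it noisy at small test sizes.
* The derived-scale construction assumes both annotation fits are invertible
  (non-zero slope) and combines them with equal weight.
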