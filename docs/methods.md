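# Methods

## Geometry and data model

All calculations are 1D along the beam axis of a water phantom. Depth is
discretized into uniform scoring slices (default 1 mm); slice `i` covers
`[i*dz, (i+1)*dz)` and is reported at its center. A *mixed-field spectrum*
decomposes the dose in each slice by particle species (`p, He, Li, Be, B,
C, other`) and kinetic energy per nucleon; arbitrary Monte Carlo species
labels fold into this vocabulary through an alias map, with anything
unrecognized going to `other`. This folding is deliberate: the mixing
formula below divides by the *total* slice dose, so every component must be
accounted for even when its radiosensitivity is unknown.

CSV formats are comma-separated UTF-8 with `#`-prefixed `key=value`
metadata lines; floats are written with `%.17g` and parsed with pandas'
round-trip parser, so write/read cycles are bit-exact. Grid reconstruction
from depth columns tolerates 1e-6 mm of center mismatch and snaps sub-nm
float residue.

## Pristine kernels and SOBP design

The pristine Bragg curve is an analytic stand-in for transported depth-dose
data, built from three ingredients:

1. **Range–energy relation** `R = (A/Z^2) * a * E^p` with `a = 0.0022 cm`,
   `p = 1.77` (`E` in MeV/u) — the standard power-law fit for water. For
   helium-4 `A/Z^2 = 1`, so He ranges coincide with proton ranges at equal
   energy per nucleon; carbon scales by 1/3. At the top energies of the
   nine standard ion/depth windows this fit lands within 1 cm of each
   window's distal edge (verified in the test suite).
2. **Stopping term** proportional to `1/(R - z)^(1 - 1/p)`, integrable at
   the range; each fine bin is averaged exactly from the antiderivative
   `-p (R - z)^{1/p}`, so the singularity needs no special casing.
3. **Gaussian depth smearing** combining range straggling
   `sigma_strag = 0.012 R^0.935` (cm) with a delivered-beam contribution
   `sigma_beam = p * (dE/E) * R` from a 1% fractional energy spread, added
   in quadrature. The second term models what beamlines actually deliver
   (momentum spread, ripple filters); a strictly monoenergetic peak is so
   narrow that no non-negative weighting of a practical number of beams
   could produce a flat plateau.

Slice values are *bin averages* of the fine curve over the slice thickness,
as a physical scoring slab integrates dose — point-sampling a peak narrower
than the slice width would alias it. For Z > 1 an exponential fragmentation
tail is added beyond the range, with entrance-relative amplitude 0.05 (He)
and 0.12 (C) by default and a 2 cm decay length: fragment tails grow with
projectile mass, and these amplitudes give tails of a few percent to ~10%
of the plateau, the magnitude seen beyond carbon and helium SOBPs. Protons
get no tail. Kernels are normalized to unit entrance dose.

**Weight design.** Given kernels whose ranges tile the plateau, weights
minimize the squared deviation from a unit plateau over the plateau slices,
subject to `w >= 0` (scipy NNLS — deterministic and reproducible). Two
geometric choices make sub-percent ripple attainable:

- one pristine peak per scoring slice of the plateau (minimum 12). A
  12-beam stack is exactly flat for a 1 cm plateau but cannot reach 2%
  ripple over 3–5 cm plateaus: a linear-programming minimax bound puts the
  best achievable ripple for 12 beams at 5–10% there, independent of the
  weight fit.
- the deepest range overshoots the distal plateau edge by 1.5 peak sigmas.
  Without this margin the last plateau slice sits on the falling edge of
  the deepest peak, and non-negative weights cannot raise it without
  overshooting the slices before it.

When a caller supplies kernels that all stop short of the requested distal
edge, the design clips the effective plateau to the deepest kernel range
(dose cannot be flat beyond the deepest peak) and the returned plan carries
the effective interval. After the fit, the composed profile is scaled so
the plateau mean equals the prescription (2 Gy by default), and the scale
is folded into the plan weights so downstream spectra carry absolute doses.

Opposing-field composition mirrors one spectrum in depth (slice `i` to
`n-1-i`) and concatenates records, so the composite total dose is exactly
the sum of the two fields.

## Mixed-field radiobiology

Per slice, the dose-averaged LQ coefficients of the mixed field are

    alpha = sum_i alpha_i D_i / sum_i D_i
    beta  = ( sum_i sqrt(beta_i) D_i / sum_i D_i )^2

— alpha averages linearly, sqrt(beta) averages linearly. Survival is
computed at the slice's *total* dose with the mixed coefficients (not as a
product of per-component survivals), which is what the dose-averaging
construction implies. The iso-survival photon dose solves
`alpha_x Dx + beta_x Dx^2 = alpha D + beta D^2`:

    Dx = (-alpha_x + sqrt(alpha_x^2 + 4 beta_x (alpha D + beta D^2))) / (2 beta_x)

giving RBE = Dx / D and Gy-Eq = Dx. The round-trip identity — photon
survival at Gy-Eq equals mixed survival at D — holds to 1e-10 and is
enforced by tests.

Radiosensitivity tables index alpha and beta per species on a strictly
increasing energy grid. Lookups interpolate alpha and sqrt(beta) linearly
in log(energy); interpolating sqrt(beta) (not beta) makes interpolation
commute with the mixing rule on flat tables. Queries outside the grid clamp
to the nearest endpoint with a logged warning. Species without a table
entry (including `other`) fall back to the photon coefficients — this keeps
the mixing denominator equal to the full physical dose. Zero-dose slices
are flagged undefined, carry S = 1 and RBE = NaN, and are excluded from
downstream comparisons; this avoids the 0/0 of the mixing formula.

## Run statistics and error propagation

Depth-dependent quantities (dose, mixed alpha, mixed beta) are averaged
over n independent runs (n >= 2) with the standard error of the mean

    sem = sqrt( sum_i (x_i - <x>)^2 / (n (n-1)) ).

Survival uncertainty follows from first-order propagation:

    sigma_S = S sqrt( D^2 s_a^2 + D^4 s_b^2 + (alpha + 2 beta D)^2 s_D^2 ),

treating the alpha and beta estimates as independent (no covariance term).
The delta-method result is validated against Monte Carlo sampling in the
tests (within 5% at 2% relative input uncertainties). Survival is computed
from the run-averaged dose and coefficients rather than averaging per-run
survivals; at the percent-level spreads involved the difference is second
order.

## Comparison statistics

RMSE is `sqrt(mean((y_A - y_B)^2))` over the common support. For physical
dose it is evaluated on profiles divided by the reference plateau mean, so
an ideal profile has plateau value 1 and the RMSE reads as a fractional
discrepancy; survival RMSE uses raw surviving fractions.

The 1D gamma index per reference point r is

    gamma(r) = min_z sqrt( ((z - z_r)/DTA)^2 + ((E(z) - R(z_r))/(DD * Dmax))^2 )

with global normalization to the reference maximum. Defaults: 3%/2 mm and
a 10% dose threshold for dose; a stricter 2%/2 mm with no threshold for
survival (the threshold guards against trivial passes in low-dose regions,
which has no analogue for survival values near 1). The threshold applies to
the reference only. Pass rates >= 95% are "good", >= 90% "acceptable",
otherwise "fail".

Numerics: the evaluation curve is linearly resampled on a candidate grid of
step DTA/100 within a +/-4*DTA window, clipped to the evaluation support.
`gamma_1d_bruteforce` uses the same step with a +/-10*DTA window and serves
as the in-repo oracle; because the two share one candidate grid they
coincide exactly wherever gamma <= 4, and tests confirm the narrower window
never flips a pass/fail decision. A point exactly on the gamma = 1 boundary
passes; a 1e-9 tolerance absorbs float round-off there. If several
positions tie for the minimum, only the value matters (position is not
reported).

The LQ sensitivity factor linking relative dose error to relative survival
error is exposed in two variants: the commonly quoted `alpha D + beta D^2`
(`as_printed`) and the exact logarithmic derivative `alpha D + 2 beta D^2`
(`exact_derivative`). They coincide as beta -> 0; both are kept because the
quoted form is widespread while the derivative form is what the LQ model
actually gives. Either way, a factor below 1 attenuates dose discrepancies
in the survival domain — the mechanism by which survival agreement can beat
dose agreement under strict criteria.

## Synthetic generator

The generator stands in for two transport engines and a radiobiological
database; it emulates their *interface*, not their physics.

**Radiosensitivity tables.** A parametric LET model `LET = c Z^2 / E^0.8`
(keV/um, scaled so protons at 10 MeV/u give 4.5 keV/um) feeds

    alpha(E)      = alpha_x (1 + g L/L0) exp(-L/L0)
    sqrt(beta)(E) = sqrt(beta_x) exp(-L/(2 L0))

with `L0 = 80 keV/um` and `g = 3`: alpha rises with LET, peaks at
`L0 (g-1)/g` and declines (overkill), while both anchor to the photon
coefficients as LET goes to 0. The shape is qualitatively right (rise,
peak, overkill decline; heavier ions shifted to higher LET at equal E/u)
but the scale is not fit to any measured cell line. One visible
consequence: at the distal plateau of a carbon SOBP the local LET
overshoots the alpha peak, so the synthetic RBE flattens or dips there
where a measured carbon response would stay elevated; proton and helium
plateaus sit on the rising branch and show the expected monotone
killing-with-depth.

**Spectrum decomposition.** Each beam contributes, per slice above its
range, a primary record whose energy follows the inverse range–energy
relation `E(z) = ((R - z)/(a A/Z^2))^(1/p)`; straggling dose beyond the
range (residual range under 1 um) and all fragment-tail dose are labelled
`other`. The per-slice record sum reproduces the composed SOBP dose
exactly, by construction.

**Code pair.** Code A is the unperturbed decomposition; code B applies a
depth shift (linear resampling, default 0.5 mm), scales the fragment tail
(default 1.1), and both add independent per-slice relative Gaussian noise
(default 1%, clipped at zero) across n runs (default 5). Noise is Gaussian
at the aggregate level rather than Poisson per primary because that is the
level at which the run statistics operate. All randomness flows through
explicit integer seeds; fixed seeds give bit-identical run sets.

What passing tests show — and what they do not: the pipeline reproduces the
*verdict structure* (dose gamma 3%/2 mm and survival gamma 2%/2 mm passing
at >= 90% for sub-mm shifts, tail changes within +/-20% and 1% noise,
across p/He/C and three depth windows, both cell lines). Because the
kernels, tables and perturbations are synthetic, agreement here does not
certify any real transport code pair; it certifies the interface
arithmetic, the statistics and their implementations.

## Problem sizes

Default scenarios use 1 mm slices over the plateau depth plus a 30 mm
margin (50–180 slices), 12–52 beams, 5 runs per code, and two cell lines;
the full nine-scenario sweep with both cell lines runs in well under a
minute on one CPU. The gamma oracle suite uses 100 random smooth profile
pairs on 120-slice grids.

## Known limitations

- 1D only: no lateral transport, no heterogeneities; the scoring radius is
  metadata.
- The kernel is analytic; no nuclear build-up, no per-fragment energy
  spectra (the tail is a single `other` component with photon-fallback
  radiobiology).
- The synthetic alpha(LET) shape is structural, not fitted; absolute RBE
  values from synthetic tables are illustrative.
- Correlations between alpha and beta estimates across runs are neglected
  in the error propagation, and survival is propagated to first order
  only.
- Range–energy and straggling fits are power laws for water; other media
  would need new constants.
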