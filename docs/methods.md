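# Methods

## Signal space separation

An N-channel MEG measurement `b(t)` is expanded in gradients of solid
spherical harmonics about an expansion origin inside the head,

    b = S_in x_in + S_out x_out,

where the columns of `S_in` are the sensor-space fields of interior source
terms (scalar potential `∝ Y_lm(θ,φ) r^-(l+1)`, `l = 1..L_in`) and those of
`S_out` the exterior terms (`∝ r^l Y_lm`, `l = 1..L_out`).  The truncation
orders default to `L_in = 8` and `L_out = 6`, giving `(L+1)² − 1` = 80 and
48 columns; columns are ordered with `l` outer and `m = −l..l` inner, so
the degree of 1-based column `n` is `⌊√n⌋`.

Conventions and numerics:

- **Harmonics.** Fully normalised (orthonormal) real spherical harmonics,
  assembled from the complex orthonormal set with Condon–Shortley phase.
  Any consistent normalisation rescales the moments but leaves all
  reconstructed fields unchanged; the test suite verifies this invariance
  explicitly.
- **Sensor model.** Point magnetometers: each matrix entry is the field of
  one harmonic term projected on the sensor's orientation vector.
- **Internal scaling.** Interior potentials carry a factor
  `ρ^(l+2) / r^(l+1)` and exterior ones `ρ^(1−l) r^l`, with the scale
  radius ρ defaulting to the median sensor distance from the origin.  This
  makes the design-matrix columns order unity at the sensors (moments are
  then "tesla at the scale radius").  Per-degree diagonal filters commute
  with any per-column rescaling, so this choice affects conditioning only.
- **Moment estimation.** `x̂ = S⁺ b` per sample, with an SVD-truncated
  pseudoinverse of the concatenated basis (`pinv_cond`, default 1e-8,
  relative to the largest singular value); discarded singular values are
  logged.
- **Array geometry.** The inside/outside decomposition needs radial
  diversity: on a single spherical shell sampled radially, interior and
  exterior terms produce proportional fields and cannot be separated.  The
  bundled helmet layout therefore places 275 point magnetometers on an
  ellipsoidal cap (equatorial radius 0.08 m, 25% taller polar axis,
  surface-normal orientations) plus two layers of 29 radial reference
  magnetometers at 1.4× and 1.9× the array radius, emulating the reference
  array of whole-head systems.  With this geometry an interior dipole at
  half the array radius keeps ≈99.97% of its fitted power in the interior
  component and a far-exterior source ≈99.98% in the exterior component.

## Region-of-interest filters

A source at distance `a` from the origin drives the degree-l interior
moments with amplitude `∝ a^l`, i.e. an order-l radial power density
`a^(2l)` per unit volume.  For an ROI inside the inner ball of effective
radius `R`, define its share of the order-l volume energy

    W(l) = ∫_ROI |x|^(2l) dV / ∫_ball(R) |x|^(2l) dV,

which is `(r/R)^(2l+3)` for a concentric sphere of radius `r`.  Deep
volumes hold their energy at low degrees and the complementary shell at
high degrees; the ROI and non-ROI gains are the corresponding energy odds,
normalised to peak at 1:

    G_ROI(l)    = (2l+3)/5      · W(l)(1−W(1)) / (W(1)(1−W(l)))
                = (R⁵−r⁵) r^(2l−2) (2l+3) / ((R^(2l+3)−r^(2l+3)) · 5)
    G_¬ROI(l)   = (2L+3)/(2l+3) · W(L)(1−W(l)) / (W(l)(1−W(L)))

with `L = L_in`.  Both lie in [0, 1] and are entrywise monotone
non-decreasing in the ROI size; `G_ROI(1) ≡ 1` and `G_¬ROI(L) ≡ 1` for
every ROI.  The normalisation matters: it keeps a deep ROI source almost
entirely out of the non-ROI subspace (leakage at the 10⁻⁴–10⁻³ level), so
the temporal stage below does not mistake the signal for shared leakage,
while superficial or broad interference remains strong in both subspaces.
The filters act diagonally on the interior moments,
`b̂_ROI = S_in G_ROI x̂_in` and `b̂_¬ROI = S_in G_¬ROI x̂_in`.
`G_ROI + G_¬ROI` is *not* the identity — the sum is ≈1 at `l ∈ {1, L}` and
dips below 1 in between; the test suite audits this per degree.

- **Off-centre ROIs** are handled through the effective radius
  `R = array radius + ‖ROI centre − origin‖` only; the basis is not
  re-expanded about the ROI centre.  The filter therefore has radial but
  no angular selectivity, and the inflated `R` makes the gains
  conservative for off-centre regions.
- **Cuboids.** `W(l)` is integrated over the cuboid volume by tensor
  Gauss–Legendre quadrature in Cartesian coordinates.  The integrand
  `|x|^(2l)` is a polynomial of degree 2l per axis, so `> l` nodes per axis
  integrate it exactly; the implementation compares two refinement levels
  and warns if they disagree beyond 1e-3 (they agree to machine precision
  in practice).  Because the density is radial about the ROI centre, the
  gains are invariant to the cuboid's rotation about its own centre.  A
  cuboid never recovers more than the sphere that circumscribes it.

## Temporal projection

The row spaces (temporal subspaces) of `b̂_ROI` and a reference matrix are
orthonormalised by SVD; the canonical correlations between them are the
singular values of the cross-product of the two temporal bases.  Time
courses with correlation ≥ `correlation_threshold` (default 0.98) are
projected out of `b̂_ROI`: `B ← B(I − UUᵀ)`.  The projection is idempotent
and non-expansive, and residual correlation with removed time courses is
at the 1e-10 level.

Two regularisations make the intersection well-posed; the textbook
description of temporal-subspace intersection leaves both open, and for
the ROI variant they are essential:

1. **Energy floor** (`rank_rtol`, default 1e-3).  The ROI and non-ROI
   matrices are invertible diagonal reweightings of the *same* interior
   moment time series, so their exact row spaces coincide and a naive
   intersection would return correlation 1 for every component.  Each
   temporal basis therefore keeps only components whose singular value
   exceeds `rank_rtol ×` the largest singular value across both matrices
   (−60 dB).  Strong interference stays above this floor in both
   subspaces; a deep source's non-ROI leakage falls below it.
2. **Leakage-origin gate** (`leakage_ratio_min`, default 0.1).  A
   correlated component is removed only if its amplitude in the reference
   subspace is at least this fraction of its amplitude in `b̂_ROI`.
   Content that genuinely originates outside the ROI is substantially
   present in the reference (measured ratios 0.3–0.9 for phantom
   artifacts), whereas the ROI signal's own leak sits near 0.03; the gate
   keeps the noiseless single-source case an exact pass-through.

In the full ROI-tSSS pipeline the reference stacks `b̂_¬ROI` with the SSS
exterior component `b̂_out`: leakage into an ROI can originate from the
rest of the inner volume *or* from the environment, and using only the
interior complement would make ROI-tSSS blind to exterior interference
that plain tSSS removes.  The tSSS baseline uses the same machinery with
`b̂_in` against `b̂_out`.  By default the whole recording forms a single
window; `window_seconds` enables independent chunked operation for long
recordings.

## Denoising pipelines and evaluation

`roi_tsss` composes moment estimation → ROI split → temporal projection
and returns the cleaned ROI component in sensor space together with the
N×N spatial operator `S_in G_ROI P_in` (the pre-temporal map from raw data
to the ROI component).  Applying this operator to leadfield columns keeps
the sensor↔source mapping consistent for downstream beamforming.  Evoked
responses are formed by zero-phase FIR high-pass filtering at 5 Hz
(Hamming window, ≈2 Hz transition band, odd tap count applied centred),
epoching around the upward zero crossings of the 27 Hz drive, baseline
correction over [−0.05, −0.03] s, and trial averaging; topography MSE is
the mean over channels and evoked samples of squared differences, and is
compared between identically processed stimulation and no-stimulation
runs, so the per-method spatial shaping cancels.

Head-tracking correction exploits the rigidity of the three HPI coils:
samples where any pairwise coil distance deviates from its run median by
more than the tolerance (default 2 mm) are flagged and linearly
interpolated from neighbouring good samples; the time average of the
corrected trajectories is the robust head-position estimate.  More than
50% flagged samples triggers an unreliability warning.

## Synthetic phantom

The generator emulates a dry-bench validation recording: a 6.7 μA,
27 Hz current dipole (Sarvas conducting-sphere forward model, sphere
radius 0.065 m) sampled at 2400 Hz, plus

- **DBS pulse train** at 0/5/20/130 Hz: charge-balanced biphasic pulses of
  60 μs (far narrower than one sample, represented as area-preserving
  two-sample impulses) convolved with an exponentially decaying 450 Hz
  ringing kernel (τ = 2 ms).  At 130 Hz the onsets are 7.7 ms apart.  The
  artifact couples through three topographies: a deep source at the
  electrode tip, a line of elementary current dipoles along a great-circle
  wire arc just inside the phantom surface, and a rigid exterior magnetic
  dipole standing for the stimulator feed line.
- **Pulsation movement** at 60 cycles/min: a 1 mm vertical sinusoidal
  displacement.  Movement artifacts are built physically as
  `(dB/dz) · dz(t)` with finite-difference gradient topographies of the
  same forward model, so the modulation depth per millimetre follows from
  the geometry (≈3/r: a few %/mm for deep sources, 15–20 %/mm for the
  surface wires) and the movement streams have spatial patterns distinct
  from the static ones — the property that makes them non-trivial to
  remove and that plain tSSS largely misses.
- **Amplitude scales.** Total DBS artifact 200× the clean dipole RMS and
  wire-movement stream 60× (interference in such recordings exceeds the
  physiological signal by orders of magnitude); exterior share 40×; white
  sensor noise at 5 fT/√Hz, typical of a whole-head axial system.

The simulator returns the clean dipole data, the summed artifacts, the
noise stream and the phase-locked event times, and satisfies
`clean + artifacts + noise == recording` exactly, so every denoising claim
in the tests is checked against ground truth.  What it does not emulate:
real gradiometer coil geometries and balancing, electrode–saline
electrochemistry, non-rigid movement, correlated environmental noise, and
calibration errors — passing tests therefore demonstrate the algorithmic
contracts under the stated physics, not performance on any particular
acquisition system.

## Power functions

The per-degree signal power of a source set is realised numerically:
forward fields are sampled on a dense Fibonacci shell (2000 radial point
magnetometers at radius R), projected onto the interior basis, and the
field power of each degree block accumulated (sources add incoherently).
Field power per degree falls off with the shell radius exactly as
`R^−(2l+4)`, which the tests verify to 2%.  The ROI-modified power
function scales each degree's amplitude by the ROI gain before squaring.
The ROI-size sweep uses 100 randomly oriented dipoles on a 0.04 m shell
with R = 0.08 m, for spheres and for cubes whose body diagonal equals the
sphere diameter.  Because `G_ROI(1) ≡ 1`, the degree-1 share of the power
is recovered at any ROI size; the size- and order-dependence of recovery
lives in the `l ≥ 2` share, which is what the sweep summaries report
alongside the total.

## Problem sizes

Default analyses run with the 333-channel synthetic helmet, 8 s phantom
recordings at 2400 Hz (≈215 epochs per run), 8–10 fixture seeds for the
method comparison, 3×10⁶ Monte-Carlo points for the gain oracle, and
2000-sensor shells for the power sweep.  These sizes were chosen so the
full validation suite completes comfortably on a single CPU while leaving
all reported contrasts far from their decision thresholds.
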