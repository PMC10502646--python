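# Methods

This note documents the model implemented by `refill`, the parameter
choices that matter, what the bundled simulator does and does not
emulate, and the numerical decisions taken where the design was open.

## Signal model

All phase is wrapped to `[−π, π)` (lower limit inclusive); `wrap(x)`
denotes that operation. Arrays are ordered `[x (readout), y (PE),
z (slice)]`. The canonical field unit is the angular frequency offset
ω in rad/s; ω/2π is Hz and ω/γ Tesla (γ = 2.675·10⁸ rad/s/T for 1H).

The phase of echo `j` of a bipolar multi-echo gradient-echo train,
received by coil `c`, is modelled as

    θjc = wrap( TEj·ω + θ0c + sj·φG_FLASH·x )

where `θ0c` is the coil's time-zero phase offset, `φG_FLASH` the linear
readout phase ramp (rad/voxel, `x` counted from the array centre) and
`sj = (−1)^j` the alternating lobe sign (configurable via
`first_lobe_negative`). A single-echo EPI volume with readout polarity
`p` obeys the same model with one echo and ramp term `p·φG_EPI·x`, and is
additionally displaced along PE by `ω/(2π·bw_PE)` voxels.

### Calibration algebra (no spatial unwrapping)

With `TEj = j·ΔTE`:

* `2θ2 − θ1 − θ3` cancels both the field and the offsets, leaving
  `4·φG_FLASH·x`. The slope is read off the phase of the magnitude-
  weighted lag-1 autocorrelation of `exp(i(2θ2−θ1−θ3))` along the readout
  axis, divided by 4 — one scalar per slice, exact for a linear ramp and
  immune to voxelwise wrapping as long as `|φG| < π/4` rad/voxel (real
  ramps are of order 10⁻³–10⁻² rad/voxel, two orders below that bound).
* `2θ1 − θ2` cancels the field term (because `2·TE1 = TE2`), leaving
  `θ0c − 3·s1·φG_FLASH·x`; adding back the estimated ramp isolates the
  wrapped offset. **Operand order matters**: the reversed combination
  `2θ2 − θ1` leaves a residual `3·ΔTE·ω` and would make the offsets
  shim-dependent, destroying the method's central property. The
  implementation uses the field-cancelling form and verifies shim
  invariance by simulation (offsets change < 1e−6 under arbitrary
  uniform+linear field perturbations).
* The EPI ramp is half the phase difference between the first regular
  volume and the readout-reversed calibration volume, extracted with the
  same lag-1 slope fit (robust to a uniform field drift between the two
  volumes, which cancels in the autocorrelation product). The returned
  ramp is *the ramp of the regular-polarity volumes* and is subtracted
  from every combined phase volume; this sign convention is pinned by a
  simulator round trip, not by convention on paper.

Coil combination weights each channel by its squared magnitude:
`θ′ = ∠ Σc Mc²·exp(i(θc − θ0c))`. Applying the ramp correction inside
the per-coil sum or after combination are angles of the same complex
number; the equivalence is asserted to machine precision in the tests.

### Field maps

`ω = unwrap(wrap(θ′ − φG·x)) / TE`. Spatial unwrapping fixes the phase
only up to one global 2π per connected component, so a single-echo map
determines a *uniform* field component only modulo `2π/TE` (≈ 286 rad/s
≈ 45 Hz at TE = 22 ms). Maps are anchored by shifting the masked median
as close as possible to zero (volume 1) or to volume 1's median (later
volumes, which tracks drift). Consequence: the mean field must lie
within ±π/TE of the anchor for the absolute level to be right; spatially
varying components of any size are handled by the spatial unwrapper. A
shim change "up to ±80 Hz at the FOV edge" (uniform + linear) is
recoverable; a *uniform* 80 Hz jump at TE = 22 ms is not — that is an
information limit of single-echo phase, not of the implementation.

The FLASH reference map uses the Hermitian product of echoes 1 and 3
(same lobe polarity, so the ramp cancels) divided by `2ΔTE`; its
aliasing band `2π/(2ΔTE)` is ≈ 1257 rad/s at ΔTE = 2.5 ms.

## Spatial unwrapping and masking

Quality-guided region growing: edge weight
`w = max(0, 1 − |wrap(Δθ)|/π) · min(M)/max(M)` between axis neighbours;
voxel quality is the **geometric mean** of a voxel's edge weights (raw
product would make the scale depend on the number of neighbours and
push ordinary good voxels below the fixed 0.5 mask threshold). Growing
starts at the highest-quality masked voxel and proceeds best-first on a
priority queue (ties by insertion order); each new voxel gets
`neighbour + wrap(θnew − θneighbour)`, so the output is congruent with
the input mod 2π everywhere — a hard invariant. Components are anchored
at their lowest-linear-index voxel, which makes the global 2π choice
independent of floating-point ties and reproduces the classical 1-D Itoh
integration on lines. The mask is `quality ≥ 0.5` restricted to the
largest connected component (signal voids create islands; the threshold
is the conventional value for this kind of quality image). One mask per
run, from volume 1, by default; `mask_per_volume=True` is available.

## Filtering, smoothing, unwarping

* Range filter: field values outside (−600, 2000) rad/s → NaN. The
  asymmetric band reflects air/tissue interface physics at high field
  (large positive offsets near sinuses, moderate negative elsewhere).
* Smoothing: normalized convolution `G*(f·v)/G*(v)` with `v` the finite
  mask, iterated until every voxel is filled; NaNs are excluded from the
  kernel and replaced by smoothed estimates, so the mask edge is
  extrapolated rather than shrunk. Default σ = 2 voxels — small enough
  to preserve quadratic field structure (bias ≈ σ²∇²ω/2), large enough
  to fill typical holes in one or two passes; exposed in the config.
* Unwarp: per-PE-column 1-D linear interpolation at `y + shift(y)`
  (`warp`, the forward model, samples `y − shift(y)`). No intensity
  Jacobian by default (geometric correction only; flag available).
  Out-of-FOV samples become NaN so statistics can exclude them. The
  warp/unwarp pair are inverse to first order in the shift gradient;
  round-trip error grows as `shift·d(shift)/dy`.
* A field map measured in distorted space is brought to undistorted
  space by a single-pass self-unwarp (shift evaluated at the distorted
  location) — adequate for shifts up to a few voxels.

## The simulator: what it states, what it omits

Defaults are the desk-scale stated world: 64×64×8 grid, 8 coils,
bipolar FLASH TEs 2.5/5/7.5 ms, EPI TE 22 ms, PE bandwidth 25 Hz/px,
ramps 0.02 (FLASH) and 0.03 (EPI) rad/voxel. Field dynamics are anchored
to the regimes reported at 7 T: respiration ≈ 1 Hz amplitude, motion-like
regional effects of a few Hz, shim steps up to ±80 Hz at the FOV edge,
slow drift. Coil sensitivities are Gaussian-magnitude loops around the
object with random low-order polynomial phases (`smoothness` in rad per
half-FOV ≈ 1 by default — phase offsets are spatially smooth, which is
what makes low-resolution reference scans sufficient). Noise is i.i.d.
complex Gaussian per coil added before the magnitude/phase split, so the
magnitude is Rician; "SNR 20" means mean per-coil in-object magnitude
over the complex noise σ.

The EPI forward model displaces the object along PE by the
self-consistent shift map (fixed point of `s(y) = ω(y−s(y))/(2π·bw)`)
and lets the phase sample the field at the displaced location — phase
and geometry agree exactly, as in a real acquisition. Two documented
simplifications: coil sensitivities are applied at the rendered
(distorted) location rather than the source location, and the warp has
no intensity Jacobian. Not modelled at all: k-space effects (ghosting,
partial Fourier, ramp sampling), T2* decay across the echo train,
through-plane dephasing, object motion itself (only its field effect).
A green end-to-end test therefore establishes the correctness of the
calibration algebra, unwrapping, and geometric correction — not
robustness to reconstruction artefacts of real scanners.

## Numerical choices and degenerate inputs

* Phase at zero-magnitude voxels is meaningless; identities are asserted
  on the signal support. Zero magnitude gives edge weight 0, so such
  voxels are masked, and `angle(0) = 0` by numpy convention.
* The k-space echo-centring diagnostic interpolates the readout axis to
  `2·RO+1` samples (explicit half-sample DFT), finds the summed-profile
  maximum, and applies the corresponding integer fine-grid shift as a
  pure image-space phase ramp (magnitude untouched); residual ramps are
  below `π/RO` rad/voxel by construction.
* tSNR uses the temporal mean over std (ddof 1), NaN where the std is 0
  or fewer than 3 finite samples.
* Grid-phantom residuals locate each line by intensity centroid within
  ±2 voxels of its nominal position (spacing 5 ⇒ windows never overlap).
* Determinism: every stochastic operation is a pure function of
  (parameters, seed); per-volume noise streams are spawned from one
  `SeedSequence`.

## Known limitations

* Single-pass self-unwarp and first-order warp/unwarp inversion limit
  accuracy for shifts beyond ~3 voxels or strongly varying shift maps.
* The uniform-field component is determined only modulo 2π/TE (above).
* One mask per run mishandles signal dropout appearing later in a run
  (per-volume masking is available but changes the masked set over time).
* PE-reversed volume pairs are refused for ramp estimation: their
  distortions differ voxelwise, so the phase subtraction is invalid
  without prior unwarping.
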