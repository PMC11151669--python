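# Methods

This note records the model assumptions, numerical choices and known
limitations of `padfkit`.  It is the companion to the README's overview;
nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physical model and assumptions

The pipeline assumes **kinematic (single-scattering) elastic diffraction
with no absorption**: each exposure measures |F(q⃗)|² on the Ewald sphere
for a sample in a random, uniformly distributed 3D orientation (or a
statistically independent region of a bulk disordered material).  Under
these assumptions the intensity has Friedel symmetry, so the spherical
harmonic content of the orientation-averaged correlations is even in l,
and the pipeline uses even orders only; including odd orders would only
degrade the conditioning of the inversion.  Measured data are assumed to
be already corrected for solid-angle and polarization effects; the
*forward simulator* can optionally apply a cos³θ_s solid-angle factor so
that synthetic data resemble uncorrected measurements, but no correction
of measured data is applied anywhere in the analysis chain.

Dynamic (multiple) scattering, absorption, incoherent backgrounds and
preferred-orientation effects are out of scope.  Preferred orientation in
particular silently violates the orientation-averaging assumption behind
both the background estimate `C_BG` and the Legendre form of C.

## Conventions

* q = (2/λ) sin(θ_s/2) in cycles/nm (electron convention); all Bessel
  kernels therefore take arguments 2π q r.  A fringe of spacing d peaks
  at q = 1/d.
* Pixel (0,0) spans [0,1)²: pixel centres at half-integer coordinates,
  beam centre in fractional pixels (default: the image centre).
* Polar angle θ counter-clockwise from +x, grid uniform on [0, 2π)
  exclusive; output PADF angle grid is inclusive, [0°, 180°].
* Ring correlations are normalized by nθ, the dataset average by N, so C
  is independent of the angular sampling rate and pattern count.

## Stage-by-stage numerical choices

**Polar resampling.**  Separable spline interpolation
(`scipy.ndimage.map_coordinates`) at the exact (q, θ) sample positions,
cubic by default.  Cubic matters: the highest-frequency intensity
fringes of a structure of extent D have period 1/D in q (≈ 3 detector
pixels for the 30 nm hexagon diagonal at the benchmark geometry), and
linear interpolation measurably attenuates them, biasing peak heights at
large r.  Samples mapping outside the detector are zero.  Point sampling
at the ring radius is used (not bin averaging).

**Background pairing.**  `C_BG` uses a seeded random derangement j(i) and
is symmetrized per pair, ½[corr(Iᵢ, I_j(i)) + corr(I_j(i), Iᵢ)].  The
symmetrization preserves the exchange symmetry
C(q, q′, Δ) = C(q′, q, −Δ) and makes the identity C_DIFF = 2(C − C_BG)
exact for *any* derangement; without it the identity requires an
involution pairing.  Very small datasets (n < 4) fall back to the cyclic
shift i → i+1.

**Mask correction.**  Corrected = C / C_mask where
C_mask > 10⁻¹⁰ × max(C_mask), else 0.  The mask is polar-resampled with
*linear* interpolation so C_mask stays non-negative.

**sin θ conditioning.**  The |sin θ|^w weight (default w = 1) is the
Jacobian from uniform-θ to uniform-cos θ quadrature.  The applied
exponent is recorded on the volume; the inversion refuses unweighted
volumes unless explicitly overridden.

**Harmonic inversion.**  For each ring pair the design matrix has rows at
every θ sample and one column per even order l ≤ l_max.  Internally the
rows carry the weight √|sin θ| — the square-root split of the
orthogonality Jacobian, so that the least-squares residual is weighted by
|sin θ| — and the columns are normalized to unit norm.  With this
normalization the design matrix is near-orthonormal: its singular values
stay within a factor ≈ 2 of each other across the whole detector, and
the relative cutoff of 0.5 (configurable) removes only directions that
the geometry genuinely cannot distinguish (e.g. approaching the
back-scattering limit qλ/2 → 1, where cos ψ collapses to a constant).
Any exponent recorded by the conditioning stage is divided out before the
internal weighting is applied, so the recovered B_l do not depend on the
conditioning exponent chosen; rows inside a recorded θ≈0 mask are
excluded from the fit.  The pseudo-inverses depend only on geometry, not
data.  Where the cutoff discards every singular value, the B_l row is set
to zero.

**Discrete spherical Bessel transform.**  Order l is sampled at
q_ln/(2πR) for the first nr zeros q_ln of j_l; B₀ lands on the uniform
j₀-zero grid (nπ), and with the defaults nr = nq − 1 and
R = nr/(2 q_max) that grid *coincides* with the measurement grid, so no
interpolation is applied to B₀ at all.  Orders l > 0 are interpolated
onto their own zero grids with a cubic spline (bilinear available); the
cubic default exists for the same fringe-sampling reason as in the polar
resampling.  The synthesis weights are √(2π)/(R³ j_{l+1}²(q_ln)), and the
real-space output grid is r_k = k R/nr.  The default R matches the
real-space extent to the measured q range; pair distances beyond R
cannot be represented, so structures larger than nr/(2 q_max) need a
larger nr or an explicit rmax.

**Reassembly and scaling.**  Θ̃ = Σ_l (2l+1)/(4π) B_l(r, r′) P_l(cos θ),
then multiplied by |sin θ| (density per angle rather than per cos θ) and
by r² r′².  The radial factor compensates the 1/r² carried by a pair
shell through the spherical Bessel transform, so that peak *heights* are
proportional to pair-pair counts and can be compared directly with the
enumeration oracle; both factors (and the optional absolute constants
ρ₀²N_I²) are recorded in the volume's scaling record.  The |sin θ| factor
is inconsistent with a finite angular basis near θ = 0: heights within
±(360°/l_max)/2 of 0° are reported as unreliable rather than repaired.

**Smoothing and peaks.**  Gaussian smoothing is separable, normalized,
truncated at 3 half-widths, with reflective boundaries (which conserve
the volume sum exactly).  "Half-width" is interpreted as σ by default,
with an HWHM option.  Peak quantification reads grid-point maxima inside
user windows; ratios are exactly invariant under global rescaling.

## The synthetic-data generator

`padfkit.simulate` produces serial-diffraction datasets by direct
evaluation of |Σⱼ fⱼ(q) exp(2πi q⃗·R rⱼ)|² on the Ewald sphere, with
uniform SO(3) rotations from the unit-quaternion construction.  Atomic
scattering uses a single-Gaussian form factor f₀ e^(−b q²) (b = 0: ideal
point scatterer, the benchmark default).  It emulates ideal kinematic
data: no detector noise unless Poisson sampling is requested, no
background, no beam profile, no polarization, perfectly known geometry,
rigid identical particles.  Passing tests on these data therefore
validates the *transform chain*, not robustness to the systematic errors
of real experiments (imperfect centring, wavelength spread, dynamic
scattering, partially overlapping probe volumes).

The benchmark conditions are six unit point scatterers on a regular
hexagon of side 15 nm, 1000 exposures, a 256² detector with edge
q = 1.28 nm⁻¹ (λ = 0.1 nm, 100 µm pixels, z ≈ 99.4 mm — the edge-q value
fixes only the product, and these are the package defaults), nq = 128,
nθ = 360, l_max = 32.  At these sizes the whole chain runs in about two
minutes on one CPU; convergence of the correlation is the dominant error
source in the peak-height ratios (at 400 exposures the ratio error is
several times larger than at 1000, consistent with 1/√N averaging).

The **enumeration oracle** (`model_padf_oracle`) histograms every ordered
pair of ordered atom pairs of a model at (|r_ij|, |r_kl|, ∠(r_ij, r_kl))
with weight f₀ᵢf₀ⱼf₀ₖf₀ₗ.  For the hexagon the three principal diagonal
peaks carry counts 48 : 48 : 12, giving the ideal height ratios
B/A = 1 and C/A = 0.25 against which the reconstruction is judged.

## Degenerate inputs and tie-breaks

* q = 0 ring: a constant profile; its design matrix is still full rank
  and contributes only smooth low-l structure.
* All-zero mask, or mask correlation below tolerance: corrected
  correlation is identically zero (no division by small numbers).
* File lists sort by the integer captured from the filename format, ties
  broken lexicographically, independent of filesystem order.
* Peak windows with no grid points are an error, not an empty row.
* θ-zero mask removes the mirror region near 2π as well; the exchange
  symmetry of C makes it equally contaminated.

## Known limitations

* The absolute-units mode divides by ρ₀²N_I² but has not been validated
  against a physical standard; all quantitative tests use peak ratios
  and positions, which are invariant to the overall scale (and to the
  choice of per-order weights in the reassembly).
* Angular structure near θ = 0°/180° is limited by the truncated
  Legendre basis; truncation ripple decreases with l_max but never
  vanishes (the data converge at finite resolution).
* The six-fold symmetry of a planar model concentrates *azimuthal*
  harmonic order m in multiples of 6, but m = 0 power reaches every even
  l; B_l spectra therefore favour, not exclusively occupy, six-fold
  orders.
* Preferred orientation is neither detected nor corrected.
* For electron data, dynamic scattering may bias peak heights in ways
  the kinematic simulator cannot probe.
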