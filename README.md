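# padfkit

**Pair angle distribution functions from fluctuation scattering data.**

`padfkit` converts sets of diffraction exposures of randomly oriented
samples — serial X-ray or electron fluctuation scattering of disordered
materials, colloids, liquid crystals or particles — into the **pair angle
distribution function (PADF)** Θ(r, r′, θ): a real-space three- and
four-atom distribution over two atom-pair distances r, r′ and the relative
angle θ between the two pair vectors.  The PADF carries bond-angle and
local-packing information that is invisible to the ordinary (two-atom)
pair distribution function, and it is obtained from the data purely by
linear transformations of an angular intensity cross-correlation — no
model fitting and no orientation recovery.

It is written for experimentalists and simulators working with serial
diffraction data sets (10²–10⁵ exposures) who want local 3D structural
fingerprints of samples that lack long-range order.

## Method

For each exposure, the detector image is resampled onto polar rings
I(q, θ) using the Ewald-sphere pixel map q = (2/λ) sin(θ_s/2) (cycles per
nm; the crystallographic convention carries an extra 2π).  The chain is:

1. **Angular cross-correlation** over the dataset (FFT per ring pair):

       C(q, q′, Δ) = (1/N) Σᵢ (1/nθ) Σⱼ Iᵢ(q, θⱼ) Iᵢ(q′, θⱼ + Δ)

   with optional background (`C_BG`, randomly paired exposures) and
   difference (`C_DIFF`, with `C_DIFF = 2(C − C_BG)`) modes, and a
   division by the mask self-correlation for masked detectors.
2. **Conditioning**: multiplication by |sin θ| (the Jacobian to uniform
   cos θ sampling, required by Legendre orthogonality), optional q
   band-pass and a mask of the noise-variance ridge at θ ≈ 0.
3. **Harmonic inversion**: on the Ewald sphere,
   C(q, q′, θ) = Σ_{even l} B_l(q, q′) P_l(cos ψ) with
   cos ψ = cos θ_q cos θ_q′ + sin θ_q sin θ_q′ cos θ and cos θ_q = qλ/2.
   Each (q, q′) system is solved by a regularized pseudo-inverse
   (singular values below 0.5 of the maximum are discarded); only even
   orders are used (Friedel symmetry, no absorption).
4. **Radial transform**: two discrete spherical Bessel transforms, one
   per q axis, on the scaled zeros of j_l, give B_l(r, r′).
5. **Reassembly**: Θ(r, r′, θ) = r² r′² |sin θ| Σ_l (2l+1)/(4π) ·
   B_l(r, r′) P_l(cos θ) on θ ∈ [0°, 180°].  The angular resolution is
   360°/l_max; peaks within ±(360°/l_max)/2 of θ = 0 are flagged
   unreliable.

A forward kinematic simulator (elastic scattering, no absorption,
optional solid-angle factor and Poisson noise) and a brute-force
enumeration oracle for ideal model PADFs make the whole chain testable
without any experimental data.

## Worked example

The benchmark in `padfkit.workflows` simulates six unit point scatterers
on a regular hexagon of side 15 nm — pair distances 15, √3·15 ≈ 25.98 and
30 nm — with one uniformly random 3D orientation per exposure and a
detector-edge momentum transfer of 1.28 nm⁻¹ (real-space resolution
1/q_max ≈ 0.78 nm):

```python
from padfkit.workflows import hexagon_study

res = hexagon_study(n_patterns=1000, npix=256, seed=1)
print(res["diagonal_peak_radii"])       # [14.84375  25.78125  30.078125]
print(res["angle_at_nn_radius_deg"])    # 59.0
print(res["ratios"])                    # {'B/A': 0.9745, 'C/A': 0.2428}
print(res["ideal_ratios"])              # {'B/A': 1.0,    'C/A': 0.25}
print(res["max_ratio_deviation_pct"])   # 2.87
```

The three principal peaks of the reconstructed PADF sit on the r = r′
diagonal at the pair distances (each within one 0.39 nm grid step), the
angular peaks at the hexagon's 60° and 120° pair-pair angles (within the
1° angular step), and after smoothing with a small Gaussian kernel
(radial 0.75 nm, angular 1°) the peak-height ratios B/A and C/A agree
with the enumeration oracle's ideal values 1 and 0.25 to within a few
percent.  The run takes about two minutes on one CPU.

The same chain is available from the shell, stage by stage:

```bash
padfkit diffract   --outpath data --npatterns 1000 --npix 256 --seed 1
padfkit difftocorr --config run.ini
padfkit maskcorr   --config run.ini
padfkit corrtopadf --config run.ini --lmax 32
padfkit plotfxs3d  --config run.ini --slice req --smooth_r 0.75 --smooth_th 1 --png padf.png
```

Every stage reads its section of an INI config file first; command-line
flags override the file.  `padfkit <stage> --help` lists all parameters.

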