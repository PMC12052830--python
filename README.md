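# vortexflux

Localization-precision analysis and Monte-Carlo simulation for
MINFLUX/RASTMIN nanoscopy with high-order vortex excitation.

MINFLUX localizes a single fluorophore by probing it with the dark spot of
a doughnut-shaped excitation beam at a few positions (a *targeted
coordinate pattern*, TCP) and estimating the position from the relative
photon counts. The standard doughnut is a first-order Laguerre-Gaussian
vortex; this package models vortices of any order `l`, where the intensity
near the dark spot rises as `r^{2|l|}` — a higher order makes the counts
more sensitive to emitter displacement and improves the attainable
precision roughly `|l|`-fold.

For microscopists and method developers, the package answers, for a given
beam (`l`, `p`, waist `w`, `n`-photon excitation), pattern (four-point
MINFLUX or raster-scan RASTMIN of size `L`), photon budget `N`, and
signal-to-background ratio (SBR):

* **Cramér-Rao bound (CRB)** — the Fisher information of the multinomial
  count vector, `J = N Σ_k (1/p_k) ∇p_k ∇p_kᵀ`, scalarized as
  `σ_r = √(Tr J⁻¹/2)`, pointwise or as 2D precision maps with anisotropy
  descriptors. For the four-point pattern the exact central closed form

      σ₀ = L / (2 n √(2N)) · s / (|l| − L²/(2w²)),
      s = √((1 + 3/(4·SBR))(1 + 1/SBR))

  is provided and the numeric pipeline matches it to 1e-6.
* **Optimal pattern size** — shrinking `L` improves the noiseless bound but
  collapses the SBR as `(L/L₀)^{2|l|} e^{−(L²−L₀²)/2w²}`; the search
  rescales an anchored SBR and locates the minimizing `L`.
* **Effective field of view (EFOV)** — diameter of the origin-centered
  circle inside which `σ_r` stays below a threshold (4 nm by default).
* **Bayesian (Van Trees) bound** — precision under a normal positional
  prior: `J_B = E_prior[J] + I/σ_p²`.
* **Monte-Carlo localization** — multinomial photon sampling plus
  maximum-likelihood estimation over an emitter array, with per-emitter
  RMSE (½-trace convention, directly comparable to `σ_r`), estimate
  covariances and CRB-consistency ratios.

See `docs/methods.md` for the model, conventions (two SBR-anchoring modes,
raster grid dimension) and numerical choices.

## Worked example

Central precision of four-point MINFLUX at `L = 50 nm`, `N = 100` photons,
`w = 300 nm`:

```python
import math
from vortexflux import (PhotonModel, VortexBeam, crb_sigma,
                        make_four_point_tcp, efov_diameter)

for l in (1, 2, 3):
    model = PhotonModel(beam=VortexBeam(l=l, waist=300.0),
                        pattern=make_four_point_tcp(50.0),
                        n_photons=100, sbr=4.0)
    print(l, round(crb_sigma([0.0, 0.0], model).sigma, 3),
          round(efov_diameter(model, 4.0), 2))
```

prints

```
1 2.184 35.85
2 1.084 32.79
3 0.721 29.18
```

i.e. raising the vortex order from 1 to 3 improves the central bound from
2.18 nm to 0.72 nm (slightly more than 3×), while the high-precision
region (CRB ≤ 4 nm) shrinks from 35.9 nm to 29.2 nm diameter — the gain of
high-order MINFLUX is concentrated at the pattern center. Running the same
with a 4×4 raster pattern (`make_raster_tcp(50.0, dim=4)`) shows the
opposite EFOV trend (37.9 → 45.9 nm): raster scanning trades central
precision for field of view.

The `examples/` directory contains one short script per capability
(beam profiles, central CRB, optimal `L`, EFOV, Van Trees bound,
Monte-Carlo grid localization); each prints a small table and a line on
what it means.

A thin CLI wraps the same library for scripted runs:

```sh
vortexflux crb-center                      # defaults: l=1, L=50, N=100, SBR=4
vortexflux simulate --config run.toml --seed 7 --out results/
```

Tasks: `crb-center`, `crb-map`, `opt-L`, `efov`, `bayes`, `simulate`,
`sweep`; outputs are JSON/CSV with the fully resolved configuration
embedded.

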