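# Methods

`vortexflux` computes the information-theoretic precision limits of
minimal-photon-flux (MINFLUX-style) single-emitter localization with
Laguerre-Gaussian vortex excitation, and verifies them by Monte-Carlo
simulation of the full estimation chain. This note records the model, the
conventions, and the numerical choices in enough detail to reproduce every
number the package prints.

## Physical model

**Excitation.** The excitation beam is a Laguerre-Gaussian mode LG_{l,p}
with waist `w` (nm). Its amplitude carries the helical phase `exp(-i l θ)`;
the radial intensity for the pure vortex (`p = 0`) is

    I(r) ∝ (2 r² / w²)^{|l|} · exp(-2 r² / w²),

zero on axis for `|l| ≥ 1` and rising as `r^{2|l|}`, with crest at
`r* = w √(|l|/2)`. For `p > 0` the intensity is the squared modulus of the
full mode (single source of truth); inside the region of interest the
associated Laguerre polynomial is nearly constant, so the radial index has
only a small effect on localization (measured in tests: the
`(l,p=1)/(l,p=0)` profile ratio varies by 8.1 / 5.4 / 4.0 % over
`r ≤ 0.2 w` for `l = 1/2/3`, and much less over a 50-nm pattern).
Intensities are normalized to crest value 1; every statistic downstream is
scale-free, which the tests assert.

**Detection.** One localization exposes the emitter at the K positions of a
targeted coordinate pattern (TCP). With `n`-photon excitation the expected
rate at exposure k is `λ_k ∝ I(|r_e − r_k|)^n`. Conditioned on `N` total
detected photons the count vector is multinomial with cell probabilities

    p_k = (λ_k + ξ) / Σ_j (λ_j + ξ),

where `ξ` is a uniform per-exposure background rate. The background is not
raised to the power `n`: it is a detection-side rate, not an excited signal.

**Patterns.** Two TCPs are built in: the four-point MINFLUX pattern (three
exposures on a circle of diameter `L` at 90°/210°/330° plus one at the
center — a four-on-ring variant exists for sensitivity analysis) and the
RASTMIN raster, a `dim × dim` grid spanning `L × L`. The default raster
dimension is **4**: it is the only grid dimension whose minimum-CRB and
field-of-view values are consistent with the reference values this package
reproduces (4×4 gives 1.956/1.339/0.941 nm minima for `l = 1/2/3` where 5×5
gives 1.86/1.29/0.91 nm). An even grid has no dark central exposure, which
also makes the two background conventions below coincide for the raster.

## Background anchoring (SBR conventions)

The signal-to-background ratio is defined as total signal over total
background across the TCP, evaluated for a **centered emitter** at a stated
anchor size `L₀`, after which `ξ` is frozen and does not track the emitter.
Because the four-point pattern has one exposure that sees no signal from a
centered emitter, two anchoring conventions are meaningful and both are
first-class (`sbr_mode`):

* `all_exposures` (default): `ξ = (mean λ over all K exposures) / SBR` —
  the literal total-rate ratio. For the four-point pattern at SBR = 4 this
  gives `ξ = 3λ₀/16`.
* `signal_exposures`: the mean is taken over the signal-carrying exposures
  only (`ξ = λ₀/4` at SBR = 4).

Calibration against the reference values shows the conventions are used
inconsistently across analyses: the fixed-size central CRBs
(2.31/1.15/0.76 nm at L = 50, SBR = 4) require `signal_exposures`, while
the optimal-size minima, the EFOV diameters, the Van Trees bounds **and the
Monte-Carlo experiments** all reproduce under `all_exposures`. Every output
record carries the mode used.

When the pattern size changes with the background held fixed, the SBR
scales as

    SBR(L) = SBR(L₀) · (L/L₀)^{2|l|} · exp(−(L² − L₀²)/(2w²)),

the closed form of the centered-emitter signal ratio; tests verify it
against first-principles recomputation. Note the collapse at small `L` is
steeper for higher orders — the mechanism that creates an optimal `L`.

## Fisher information and bounds

The Fisher information about the emitter position is

    J(r_e) = N Σ_k (1/p_k) ∇p_k ∇p_kᵀ,

with `∇p_k` computed analytically by the chain rule through the radial
intensity slope `dI/dr = (2I/r)(|l| − 2r²/w²)` (general `p` uses the
Laguerre-derivative identity). A finite-difference cross-check at random
positions holds to 1e-6 relative. The scalar bound is
`σ_r = √(Tr J⁻¹ / 2)`; the covariance bound's eigen-decomposition provides
the anisotropy descriptors (worst/best axis, orientation). Singular Fisher
matrices are reported as non-identifiable (NaN in maps), not raised.

**Dark exposures.** Cells with exactly `p_k = 0` (the central exposure with
a centered emitter, noiseless) are dropped from the sum. For `|l| ≥ 2` the
weight `|∇p_k|²/p_k` vanishes in the limit, so the exclusion is exact. For
`l = 1` the limit is a finite constant — the relative slope `2/r` of a
perfect intensity zero diverges — so the noiseless `l = 1` information is
discontinuous at the exact center. At `r = 0` exactly, no photon can ever
land in the dark exposure and the ring-only information is the operative
bound; that is what the closed form expresses and what this package
computes. Any finite background removes the discontinuity, so it never
affects noisy analyses.

**Closed form.** For the four-point pattern with centered emitter,

    σ₀ = L / (2 n √(2N)) · s / (|l| − L²/(2w²)),
    s  = √((1 + 3/(4·SBR_eff)) (1 + 1/SBR_eff)),

where `SBR_eff` is the effective total-signal/total-background ratio
implied by the anchoring convention (`SBR_eff = SBR` for `all_exposures`,
`3·SBR/4` for `signal_exposures`). The numeric pipeline matches this to
1e-6 relative across orders and sizes — an exact identity, derivable by
symmetry at the center.

**EFOV.** The bound is anisotropic, so "the circular area where the CRB is
below threshold" needs a convention: the primary definition takes the
worst case over 64 azimuths at each radius and bisects the boundary radius
to 0.01 nm; an azimuthal-mean variant is available. Worst-case-over-azimuth
is what reproduces the reference diameters.

**Optimal L.** Coarse 1-nm scan of the central bound with `SBR(L)`
rescaling, then bounded scalar minimization to 0.01 nm between the
bracketing grid points; ties break toward smaller L; a boundary minimum
(noiseless case: the bound decreases monotonically as L → 0) is flagged
rather than reported as an optimum.

**Van Trees (Bayesian) bound.** With an isotropic normal positional prior
of standard deviation `σ_p`,

    J_B = E_prior[J(r_e)] + I/σ_p²,    σ_B = √(Tr J_B⁻¹ / 2).

The prior expectation uses tensor Gauss-Hermite quadrature, default 61×61
nodes, checked against order+20 at 1e-6 relative and escalated once (to
2×order) if not converged. With `N = 0` the bound equals `σ_p` exactly.

## Monte-Carlo simulator

Counts are drawn multinomially at the true emitter position; the MLE
maximizes `Σ n_k log p_k(r)` over a coarse 1-nm grid covering the pattern
bounding box inflated 1.5×, then refines by Nelder-Mead (xatol 1e-3 nm)
from the best node. The grid guards against secondary likelihood modes at
sparse counts; ties break at the first maximum in row-major order. No
probability floor is applied: a count in a zero-probability cell yields
−∞ likelihood, which cannot occur with background present.

Per-trial random streams derive from the master seed by counter-based
`SeedSequence` spawn keys `(emitter, trial)`, so runs are bit-reproducible
and order-independent. Per-emitter RMSE uses the ½-trace convention
`RMSE = √(E|r̂ − r|²/2)` to be directly comparable with `σ_r`; the summary
reports per-emitter RMSE with delta-method MC standard errors, the
per-emitter estimate covariances (anisotropy), the array-averaged error,
and pooled RMSE vs pooled CRB.

The reference experiment is a centered 3×3 emitter grid at 5-nm spacing
(a DNA-origami-like arrangement) with `N = 300`, `L = 50 nm`, `SBR = 4`,
the TCP fixed at the array center. The reference run in
`scripts/acceptance.py` uses 2000 trials per emitter; the test suite uses
a 500-trial version, whose remaining MC noise on the RMSE/CRB comparison
is about ±1–2 % (the heavy-tailed MLE errors of corner emitters at `l = 3`
dominate that noise).

## What the generator does and does not emulate

The simulator captures photon-counting statistics (multinomial
conditioning on N), uniform background, and estimator behavior including
anisotropy and heavy tails. It does not model photobleaching or blinking,
detector dead time or afterpulsing, position-dependent background,
aberrated or vectorially-focused beams, drift, or emitter-assignment
ambiguity (each trial localizes a known emitter). Agreement of RMSE with
the CRB here therefore validates the estimation chain under the stated
noise model, not instrument-level performance.

## Known limitations

* The closed-form central bound applies to the four-point pattern with
  `|l| ≥ 1` and `L² < 2|l|w²`; outside that range only the numeric pipeline
  is meaningful, and the config layer rejects such runs.
* The Van Trees values for `l = 2, 3` four-point differ from the reference
  values by ~1–2 % (quadrature/tail handling of the prior expectation);
  `l = 1` agrees to 0.2 %.
* The SBR rescaling law is the single-photon (`n = 1`) signal ratio; for
  `n > 1` excitation the signal ratio would enter at power `n`, which is
  outside the analyses reproduced here.
* 2D only; no axial dimension.
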