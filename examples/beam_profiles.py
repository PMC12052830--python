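"""Vortex-beam intensity profiles and the sensitivity gain of high orders.

Evaluates the doughnut profile I(r) for vortex orders 1-3 and the rate
slope near the dark spot.  The slope at small r grows with |l| — that is
the mechanism by which a higher-order vortex makes photon counts more
sensitive to emitter position.
"""

import numpy as np

from vortexflux import VortexBeam, lg_intensity, rate_radial_derivative

w = 300.0  # beam waist, nm

print(f"beam waist w = {w:.0f} nm, FWHM = {VortexBeam(l=1, waist=w).fwhm:.1f} nm")
print()
print("order  crest radius r* = w sqrt(l/2)   I(25 nm)    slope at r=10 nm")
for l in (1, 2, 3):
    beam = VortexBeam(l=l, waist=w)
    r_star = w * np.sqrt(l / 2)
    I25 = lg_intensity(25.0, beam)
    lam = lg_intensity(10.0, beam)
    slope = rate_radial_derivative(10.0, beam, lam)
    print(f"l={l}      {r_star:7.1f} nm                  {I25:.5f}     "
          f"{slope / lam:.4f} per nm (relative)")

print()
print("The relative slope (d rate/dr)/rate at r = 10 nm is about 2|l|/r:")
print("doubling the vortex order doubles how strongly a small emitter")
print("displacement changes the detected photon rate near the dark spot.")
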