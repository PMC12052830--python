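"""Central localization precision (CRB) of MINFLUX vs vortex order.

Computes the Cramér-Rao bound at the pattern center for the four-point
MINFLUX pattern (L = 50 nm, N = 100 photons, w = 300 nm), noiseless and
with a signal-to-background ratio of 4, and checks the numeric Fisher
pipeline against the closed-form bound.
"""

from vortexflux import (
    PhotonModel,
    VortexBeam,
    central_crb_closed_form,
    crb_sigma,
    make_four_point_tcp,
)

import math

print("four-point MINFLUX, L = 50 nm, N = 100, w = 300 nm")
print()
print("order   noiseless   SBR=4 (total-rate ref.)   SBR=4 (signal ref.)   closed form")
for l in (1, 2, 3):
    beam = VortexBeam(l=l, waist=300.0)
    pat = make_four_point_tcp(50.0)
    rows = []
    for sbr, mode in [(math.inf, "all_exposures"), (4.0, "all_exposures"),
                      (4.0, "signal_exposures")]:
        m = PhotonModel(beam=beam, pattern=pat, n_photons=100,
                        sbr=sbr, sbr_mode=mode)
        rows.append(crb_sigma([0.0, 0.0], m).sigma)
    closed = central_crb_closed_form(
        PhotonModel(beam=beam, pattern=pat, n_photons=100, sbr=4.0,
                    sbr_mode="signal_exposures")
    )
    print(f"l={l}     {rows[0]:7.3f} nm   {rows[1]:9.3f} nm            "
          f"{rows[2]:9.3f} nm          {closed:7.3f} nm")

print()
print("The bound improves slightly more than |l|-fold with the vortex")
print("order; the numeric value and the closed form agree to ~1e-9.")
print("The two SBR columns differ in what the background is referenced")
print("to: the mean rate over all four exposures, or over the three")
print("ring exposures that see signal from a centered emitter.")
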