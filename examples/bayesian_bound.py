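"""Prior-informed (Van Trees) localization bound.

When the emitter position is known beforehand to ~50 nm (wide-field
image, confocal pre-scan), the relevant precision limit averages the
Fisher information over that prior and adds the prior's own information.
This script evaluates the bound vs vortex order and photon budget.
"""

from vortexflux import (
    PhotonModel,
    PriorModel,
    VortexBeam,
    bayesian_crb,
    make_four_point_tcp,
)

prior = PriorModel(std=50.0)
print("four-point MINFLUX, L = 50 nm, SBR = 4, w = 300 nm, 50-nm normal prior")
print()
for l in (1, 2, 3):
    model = PhotonModel(beam=VortexBeam(l=l, waist=300.0),
                        pattern=make_four_point_tcp(50.0),
                        n_photons=100, sbr=4.0)
    print(f"l={l}: Van Trees bound = {bayesian_crb(model, prior):.3f} nm")
print()
print("photon budget sweep (l = 1):")
for N in (0, 25, 100, 400):
    model = PhotonModel(beam=VortexBeam(l=1, waist=300.0),
                        pattern=make_four_point_tcp(50.0),
                        n_photons=N, sbr=4.0)
    print(f"  N={N:4d}: {bayesian_crb(model, prior):7.3f} nm")
print()
print("With no photons the bound equals the 50-nm prior width; photons")
print("tighten it, but far less than the central CRB suggests, because")
print("most of the prior mass lies outside the high-precision region.")
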