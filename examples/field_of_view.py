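"""Effective field of view: where the precision stays below 4 nm.

Maps the CRB over 2D emitter positions and reports the diameter of the
largest origin-centered circle on which the bound stays at or below a
4 nm threshold (worst case over azimuth).  MINFLUX concentrates its
precision gain at the center; the raster pattern trades a slightly worse
center for a wider usable region, and for the raster the region grows
with the vortex order.
"""

from vortexflux import (
    PhotonModel,
    VortexBeam,
    crb_sigma,
    efov_diameter,
    make_four_point_tcp,
    make_raster_tcp,
)

print("L = 50 nm, SBR = 4, N = 100, w = 300 nm, threshold 4 nm")
print()
print("pattern             order   central CRB   EFOV diameter")
for kind in ("four_point", "raster"):
    for l in (1, 2, 3):
        pat = make_four_point_tcp(50.0) if kind == "four_point" else \
            make_raster_tcp(50.0, dim=4)
        model = PhotonModel(beam=VortexBeam(l=l, waist=300.0), pattern=pat,
                            n_photons=100, sbr=4.0)
        center = crb_sigma([0.0, 0.0], model).sigma
        d = efov_diameter(model, 4.0)
        name = "MINFLUX 4-point " if kind == "four_point" else "RASTMIN 4x4    "
        print(f"{name}     l={l}    {center:7.3f} nm    {d:7.2f} nm")
print()
print("For MINFLUX the EFOV shrinks with the order (the gain is local);")
print("for RASTMIN it widens — higher-order vortices buy field of view.")
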