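"""Optimal pattern size under a size-dependent signal-to-background ratio.

Shrinking the pattern improves the noiseless bound without limit, but the
signal collected near the dark spot falls as L^{2|l|}, so with a fixed
background the SBR collapses at small L and an optimal L appears.  This
script rescales SBR = 4 @ L = 50 nm to each candidate size and finds the
minimizing L for both pattern types.
"""

from vortexflux import (
    PhotonModel,
    VortexBeam,
    make_four_point_tcp,
    make_raster_tcp,
    optimal_pattern_size,
)

print("SBR anchored at 4 @ L = 50 nm, N = 100, w = 300 nm")
print()
for kind in ("four_point", "raster"):
    label = "MINFLUX (four-point)" if kind == "four_point" else "RASTMIN (4x4 raster)"
    print(label)
    for l in (1, 2, 3):
        pat = make_four_point_tcp(50.0) if kind == "four_point" else \
            make_raster_tcp(50.0, dim=4)
        model = PhotonModel(beam=VortexBeam(l=l, waist=300.0), pattern=pat,
                            n_photons=100, sbr=4.0)
        res = optimal_pattern_size(model, (10.0, 100.0), sbr_anchor=(4.0, 50.0))
        print(f"  l={l}: optimal L = {res.L_star:6.2f} nm, "
              f"minimum CRB = {res.sigma_star:.3f} nm")
    print()

print("Higher orders reach better optima but at larger optimal L: their")
print("SBR decays faster with shrinking patterns (the size ratio enters")
print("the SBR scaling at power 2|l|), so they cannot be shrunk as far.")
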