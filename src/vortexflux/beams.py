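"""Laguerre-Gaussian vortex beams: amplitude, intensity and radial derivatives.

A vortex beam of topological charge ``l`` carries a helical phase
``exp(-i l theta)`` and, for ``|l| >= 1``, a dark spot (phase singularity)
on axis.  MINFLUX-style localization probes an emitter with this dark spot,
so the quantities that matter downstream are the radial intensity profile
``I(r)`` and its slope ``dI/dr`` near the minimum.

All lengths are in nanometres.  Intensities are normalized so the doughnut
crest has value 1; every downstream statistic (detection probabilities,
Fisher information) is invariant to this scale, which is covered by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import eval_genlaguerre, gammaln

__all__ = [
    "VortexBeam",
    "lg_amplitude",
    "lg_intensity",
    "intensity_radial_derivative",
    "rate_radial_derivative",
]


@dataclass(frozen=True)
class VortexBeam:
    """Excitation beam: Laguerre-Gaussian mode plus excitation order.

    Parameters
    ----------
    l : int
        Azimuthal index (topological charge).  May be negative; the
        intensity depends only on ``|l|``, the sign enters the helical
        phase of the complex amplitude.
    p : int
        Radial index, >= 0.  Adds radial rings to the profile; near the
        axis it only rescales the intensity, which is why it barely
        affects localization precision.
    waist : float
        Beam waist radius w in nm.  FWHM of the fundamental Gaussian is
        ``sqrt(2 ln 2) * w``.
    photon_order : int
        n for n-photon excitation: the detected emission rate is
        proportional to ``I(r)**n``.
    """

    l: int = 1
    p: int = 0
    waist: float = 300.0
    photon_order: int = 1

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"radial index p must be >= 0, got {self.p}")
        if self.waist <= 0:
            raise ValueError(f"beam waist must be positive, got {self.waist}")
        if self.photon_order < 1:
            raise ValueError(
                f"photon order n must be >= 1, got {self.photon_order}"
            )

    @property
    def abs_l(self) -> int:
        return abs(self.l)

    @property
    def fwhm(self) -> float:
        """Full width at half maximum of the underlying Gaussian, nm."""
        return math.sqrt(2.0 * math.log(2.0)) * self.waist


def lg_amplitude(r, theta, beam: VortexBeam):
    """Complex LG_{l,p} field amplitude at polar position (r, theta).

    Includes the mode normalization prefactor, the associated Laguerre
    polynomial ``L_p^{|l|}(2 r^2 / w^2)`` and the helical phase
    ``exp(-i l theta)``.  Arbitrary units (1/nm from the 1/w prefactor).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius r must be non-negative")
    w = beam.waist
    al = beam.abs_l
    u = 2.0 * r**2 / w**2
    # sqrt(2 p! / (pi (p+|l|)!)) via log-gammas to stay finite for large p
    norm = math.sqrt(2.0 / math.pi) * math.exp(
        0.5 * (gammaln(beam.p + 1) - gammaln(beam.p + al + 1))
    )
    radial = (
        (np.sqrt(2.0) * r / w) ** al
        * eval_genlaguerre(beam.p, al, u)
        * np.exp(-(r**2) / w**2)
    )
    return (norm / w) * radial * np.exp(-1j * beam.l * np.asarray(theta))


def _intensity_raw(r, beam: VortexBeam):
    """Unnormalized radial intensity |amplitude|^2, constants dropped."""
    w = beam.waist
    al = beam.abs_l
    u = 2.0 * np.asarray(r, dtype=float) ** 2 / w**2
    if beam.p == 0:
        return u**al * np.exp(-u)
    return u**al * eval_genlaguerre(beam.p, al, u) ** 2 * np.exp(-u)


@lru_cache(maxsize=None)
def _peak_intensity(l: int, p: int, waist: float) -> float:
    """Global maximum of the raw radial intensity, for peak normalization."""
    beam = VortexBeam(l=l, p=p, waist=waist)
    al = abs(l)
    if p == 0:
        # u^l e^-u peaks at u = l with value l^l e^-l  (1 at r=0 for l=0)
        return float(al**al * math.exp(-al)) if al > 0 else 1.0
    rr = np.linspace(0.0, 4.0 * waist, 4001)
    vals = _intensity_raw(rr, beam)
    i = int(np.argmax(vals))
    lo, hi = rr[max(i - 1, 0)], rr[min(i + 1, rr.size - 1)]
    res = minimize_scalar(
        lambda r: -_intensity_raw(r, beam), bounds=(lo, hi), method="bounded"
    )
    return float(-res.fun)


def lg_intensity(r, beam: VortexBeam):
    """Radial intensity profile, normalized to peak value 1.

    For ``p = 0`` this is ``(2 r^2/w^2)^{|l|} exp(-2 r^2/w^2)`` divided by
    its crest value; near the axis it rises as ``r^{2|l|}``, so higher
    orders have a wider, flatter dark region.  For ``p > 0`` the profile is
    ``|amplitude|^2`` of the full LG mode (single source of truth), with a
    numerically located peak.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius r must be non-negative")
    return _intensity_raw(r, beam) / _peak_intensity(beam.l, beam.p, beam.waist)


def intensity_radial_derivative(r, beam: VortexBeam):
    """dI/dr of the peak-normalized intensity profile (per nm).

    Valid at r = 0 by the limiting form (zero for ``|l| >= 1`` and for the
    on-axis Gaussian maximum at ``l = 0``); handles any radial index p via
    the derivative of the associated Laguerre polynomial,
    ``d/du L_p^a(u) = -L_{p-1}^{a+1}(u)``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius r must be non-negative")
    w = beam.waist
    al = beam.abs_l
    u = 2.0 * r**2 / w**2
    L = eval_genlaguerre(beam.p, al, u)
    dL = -eval_genlaguerre(beam.p - 1, al + 1, u) if beam.p > 0 else 0.0
    # d/dr [u^l L^2 e^-u] = (2/r) u^l e^-u [ (l - u) L^2 + 2 u L dL ];
    # the r=0 limit is 0 for every (l, p): the profile is even in r.
    with np.errstate(divide="ignore", invalid="ignore"):
        core = u**al * np.exp(-u) * ((al - u) * L**2 + 2.0 * u * L * dL)
        out = np.where(r > 0, 2.0 * core / np.where(r > 0, r, 1.0), 0.0)
    return out / _peak_intensity(beam.l, beam.p, beam.waist)


def rate_radial_derivative(r, beam: VortexBeam, rate_at_r):
    """Slope of the detection rate: ``(2 rate / r) (|l| - 2 r^2 / w^2)``.

    Relates the local rate to its radial derivative for a pure (p = 0)
    vortex profile; zero at the doughnut crest ``r = w sqrt(|l|/2)`` and
    ``~ 2 rate |l| / r`` well inside the waist, which is the |l|-fold
    sensitivity gain of higher-order vortices.  Units: rate per nm.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError(
            "rate_radial_derivative requires r > 0; use the r^{2|l|} "
            "limiting form at the origin"
        )
    return (2.0 * np.asarray(rate_at_r) / r) * (
        beam.abs_l - 2.0 * r**2 / beam.waist**2
    )
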