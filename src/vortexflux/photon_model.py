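"""Photon statistics of a localization: rates, background and likelihood.

For an emitter at ``r_e`` probed at beam positions ``{r_k}``, the expected
detection rate at exposure k is proportional to ``I(|r_e - r_k|)**n``
(n-photon excitation).  With N total detected photons, the count vector is
multinomial with probabilities

    p_k = (lambda_k + xi) / sum_j (lambda_j + xi)

where ``xi`` is a uniform per-exposure background rate.  The background is
anchored through the signal-to-background ratio

    SBR = sum_k lambda_k / (K xi)

evaluated for a *centered* emitter at a stated anchor pattern size, and xi
is then held fixed as the emitter moves.  Two anchoring conventions are
supported, because patterns with a dark central exposure make the choice
ambiguous:

* ``all_exposures`` — the literal ratio above: xi = mean signal rate over
  all K exposures divided by SBR (default).
* ``signal_exposures`` — xi referenced to the mean over only the exposures
  that see signal from a centered emitter (e.g. the three ring exposures
  of the four-point pattern).

Every overall scale (the brightness coefficient, the intensity
normalization) cancels in p_k, so rates are reported with that
coefficient set to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, xlogy

from .beams import VortexBeam, intensity_radial_derivative, lg_intensity
from .patterns import ExposurePattern, make_four_point_tcp, make_raster_tcp

__all__ = [
    "PhotonModel",
    "DetectionDistribution",
    "expected_rates",
    "background_level",
    "scale_sbr",
    "detection_probabilities",
    "probability_field",
    "probability_gradient_field",
    "multinomial_loglik",
]

_SIGNAL_EPS = 1e-300  # exposures with rate above this count as signal-carrying


@dataclass(frozen=True)
class PhotonModel:
    """Beam + pattern + photon budget + background convention.

    ``sbr`` may be ``math.inf`` for the noiseless case.  ``sbr_anchor_L``
    is the pattern size at which ``sbr`` is defined (defaults to the
    pattern's own size); the derived background level is frozen at that
    anchor and does not track the emitter.
    """

    beam: VortexBeam
    pattern: ExposurePattern
    n_photons: int = 100
    sbr: float = math.inf
    sbr_anchor_L: float | None = None
    sbr_mode: str = "all_exposures"

    def __post_init__(self) -> None:
        if self.n_photons < 0:
            raise ValueError(f"photon budget N must be >= 0, got {self.n_photons}")
        if not (self.sbr > 0):
            raise ValueError(f"SBR must be positive (or inf), got {self.sbr}")
        if self.sbr_mode not in ("all_exposures", "signal_exposures"):
            raise ValueError(f"unknown sbr_mode {self.sbr_mode!r}")
        if self.sbr_anchor_L is None:
            object.__setattr__(self, "sbr_anchor_L", self.pattern.size)

    def with_pattern_size(self, L: float, sbr: float | None = None) -> "PhotonModel":
        """Rebuild the same model with the pattern rescaled to size L."""
        pat = self.pattern
        if pat.kind == "four_point":
            variant = "center" if pat.n_exposures == 4 and np.allclose(
                pat.positions[0], 0.0) else "ring"
            new_pat = make_four_point_tcp(L, variant=variant)
        elif pat.kind == "raster":
            new_pat = make_raster_tcp(L, dim=pat.raster_dim or 5)
        else:
            new_pat = ExposurePattern(
                kind=pat.kind, size=L,
                positions=pat.positions * (L / pat.size),
                raster_dim=pat.raster_dim,
            )
        kwargs = {"pattern": new_pat, "sbr_anchor_L": L}
        if sbr is not None:
            kwargs["sbr"] = sbr
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DetectionDistribution:
    """Multinomial cell probabilities over the K exposures."""

    probabilities: np.ndarray = field(repr=False)
    emitter: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(
            self, "emitter", np.asarray(self.emitter, dtype=float)
        )


def _signal_rates(positions: np.ndarray, model: PhotonModel) -> np.ndarray:
    """Expected signal rates for emitters at ``positions`` (M, 2) -> (M, K)."""
    d = np.linalg.norm(
        positions[:, None, :] - model.pattern.positions[None, :, :], axis=-1
    )
    I = lg_intensity(d, model.beam)
    return I ** model.beam.photon_order


def expected_rates(emitter, model: PhotonModel) -> np.ndarray:
    """Expected photon rates lambda_k for one emitter position (nm).

    The common brightness coefficient is set to 1; only ratios matter for
    the detection statistics.
    """
    emitter = np.asarray(emitter, dtype=float).reshape(1, 2)
    return _signal_rates(emitter, model)[0]


def background_level(model: PhotonModel) -> float:
    """Uniform per-exposure background rate xi implied by the SBR anchor.

    Computed from a centered emitter at pattern size ``sbr_anchor_L``:
    ``xi = (reference mean signal rate) / sbr`` where the reference mean is
    over all K exposures (``all_exposures``) or over the signal-carrying
    ones only (``signal_exposures``).  Returns 0 for infinite SBR.
    """
    if math.isinf(model.sbr):
        return 0.0
    anchor = model if model.sbr_anchor_L == model.pattern.size else \
        model.with_pattern_size(model.sbr_anchor_L, sbr=model.sbr)
    rates = expected_rates([0.0, 0.0], anchor)
    if model.sbr_mode == "all_exposures":
        ref = rates.mean()
    else:
        carrying = rates > _SIGNAL_EPS
        if not carrying.any():
            raise ValueError("centered emitter produces no signal at anchor")
        ref = rates[carrying].mean()
    return float(ref / model.sbr)


def scale_sbr(L: float, L0: float, sbr_at_L0: float, beam: VortexBeam) -> float:
    """Rescale an anchored SBR to a different pattern size.

    With the background held fixed, the signal collected from a centered
    emitter scales with the intensity at the probing radius, giving

        SBR(L) = SBR(L0) * (L/L0)^{2|l|} * exp(-(L^2 - L0^2) / (2 w^2))

    which shrinks sharply as L -> 0, the more so for higher vortex orders.
    """
    if L <= 0 or L0 <= 0:
        raise ValueError("pattern sizes must be positive")
    al = beam.abs_l
    return float(
        sbr_at_L0
        * (L / L0) ** (2 * al)
        * math.exp(-(L**2 - L0**2) / (2.0 * beam.waist**2))
    )


def probability_field(model: PhotonModel, positions) -> np.ndarray:
    """Detection probabilities for emitters at ``positions`` (M, 2) -> (M, K)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    lam = _signal_rates(positions, model)
    xi = background_level(model)
    tot = lam.sum(axis=1) + model.pattern.n_exposures * xi
    if np.any(tot <= 0):
        raise ValueError(
            "degenerate model: zero total rate (no signal and no background)"
        )
    return (lam + xi) / tot[:, None]


def detection_probabilities(emitter, model: PhotonModel) -> DetectionDistribution:
    """Multinomial detection distribution for one emitter position."""
    emitter = np.asarray(emitter, dtype=float).reshape(2)
    p = probability_field(model, emitter[None, :])[0]
    return DetectionDistribution(probabilities=p, emitter=emitter)


def probability_gradient_field(
    model: PhotonModel, positions
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and their analytic emitter-position gradients.

    Returns ``(p, grad)`` with shapes (M, K) and (M, K, 2); ``grad[m, k]``
    is d p_k / d r_e at emitter position m, obtained by the chain rule
    through the radial intensity slope.  This is the kernel of the Fisher
    information computation.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    beam = model.beam
    pat = model.pattern.positions
    diff = positions[:, None, :] - pat[None, :, :]          # (M, K, 2)
    d = np.linalg.norm(diff, axis=-1)                       # (M, K)
    I = lg_intensity(d, beam)
    dI = intensity_radial_derivative(d, beam)
    n = beam.photon_order
    lam = I**n
    # d lambda / d d ; at d = 0 both I and dI vanish for |l| >= 1 -> 0
    dlam = n * np.where(I > 0, I ** (n - 1), 0.0) * dI
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(d[..., None] > 0, diff / np.where(
            d[..., None] > 0, d[..., None], 1.0), 0.0)
    grad_lam = dlam[..., None] * unit                        # (M, K, 2)
    xi = background_level(model)
    tot = lam.sum(axis=1) + model.pattern.n_exposures * xi   # (M,)
    if np.any(tot <= 0):
        raise ValueError(
            "degenerate model: zero total rate (no signal and no background)"
        )
    p = (lam + xi) / tot[:, None]
    grad_tot = grad_lam.sum(axis=1)                          # (M, 2)
    grad_p = (
        grad_lam * tot[:, None, None]
        - (lam + xi)[..., None] * grad_tot[:, None, :]
    ) / tot[:, None, None] ** 2
    return p, grad_p


def multinomial_loglik(counts, dist: DetectionDistribution) -> float:
    """Log-probability of a count vector under the detection distribution.

    Cells with p_k = 0 contribute 0 when n_k = 0 and -inf when n_k > 0.
    """
    counts = np.asarray(counts)
    p = dist.probabilities
    if counts.shape != p.shape:
        raise ValueError(
            f"counts have length {counts.shape}, expected {p.shape}"
        )
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.astype(float)
    N = n.sum()
    with np.errstate(divide="ignore"):
        ll = gammaln(N + 1) - gammaln(n + 1).sum() + xlogy(n, p).sum()
    return float(ll)
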