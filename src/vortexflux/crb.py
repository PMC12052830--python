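"""Fisher information and Cramér-Rao bounds for vortex-beam localization.

The count vector over the K exposures is multinomial, so the Fisher
information about the emitter position is

    J(r_e) = N * sum_k (1/p_k) grad(p_k) grad(p_k)^T

a 2x2 matrix in nm^-2.  Its inverse bounds the covariance of any unbiased
position estimator; the scalar precision figure used throughout is

    sigma_r = sqrt(Tr(J^-1) / 2)

the root of the arithmetic-mean eigenvalue of the bound.

For the four-point pattern with a centered emitter the bound has a closed
form,

    sigma_0 = L / (2 n sqrt(2 N)) * s / (|l| - L^2 / (2 w^2))

with the background factor ``s = sqrt((1 + 3/(4 SBR)) (1 + 1/SBR))`` in
terms of the effective total-signal-over-total-background ratio.  This
module provides the pointwise numeric bound, the closed form, 2D precision
maps, the effective field of view (EFOV), the optimal-pattern-size search
with SBR rescaling, anisotropy descriptors and the Van Trees (Bayesian)
bound under a normal positional prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .photon_model import (
    PhotonModel,
    background_level,
    expected_rates,
    probability_gradient_field,
    scale_sbr,
)

__all__ = [
    "CrbResult",
    "PrecisionMap",
    "PriorModel",
    "OptimalPatternSize",
    "fisher_matrix",
    "fisher_field",
    "crb_sigma",
    "sigma_field",
    "central_crb_closed_form",
    "crb_map",
    "efov_diameter",
    "optimal_pattern_size",
    "bayesian_crb",
]

# Exposures whose probability is exactly zero (a dark exposure coinciding
# with the emitter, noiseless case) are dropped from the Fisher sum: for
# |l| >= 1 both p_k and |grad p_k|^2 / p_k vanish in the limit, which the
# tests verify numerically.
_P_FLOOR = 0.0


@dataclass(frozen=True)
class CrbResult:
    """Fisher matrix, covariance bound and anisotropy at one position."""

    fisher: np.ndarray = field(repr=False)
    covariance: np.ndarray | None = field(repr=False, default=None)
    sigma: float = math.nan
    eigenvalues: np.ndarray | None = field(repr=False, default=None)
    axis_angle: float = math.nan
    identifiable: bool = True

    @property
    def sigma_max(self) -> float:
        """Precision along the worst principal axis, nm."""
        return math.sqrt(float(self.eigenvalues[-1]))

    @property
    def sigma_min(self) -> float:
        """Precision along the best principal axis, nm."""
        return math.sqrt(float(self.eigenvalues[0]))


@dataclass(frozen=True)
class PriorModel:
    """Isotropic normal prior on the emitter position (std in nm)."""

    std: float

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError(f"prior std must be positive, got {self.std}")


@dataclass(frozen=True)
class PrecisionMap:
    """sigma_r evaluated on a square grid of emitter positions."""

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    sigma_max: np.ndarray = field(repr=False)
    sigma_min: np.ndarray = field(repr=False)
    axis_angle: np.ndarray = field(repr=False)
    model: PhotonModel = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y, indexing="xy")
        return pd.DataFrame(
            {
                "x_nm": xx.ravel(),
                "y_nm": yy.ravel(),
                "sigma_nm": self.sigma.ravel(),
                "sigma_max_nm": self.sigma_max.ravel(),
                "sigma_min_nm": self.sigma_min.ravel(),
                "axis_angle_rad": self.axis_angle.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def cut(self, angle_rad: float = 0.0, n_points: int = 201) -> pd.DataFrame:
        """1D profile of sigma_r along a ray direction through the origin."""
        rmax = float(min(self.x.max(), self.y.max()))
        r = np.linspace(-rmax, rmax, n_points)
        pos = np.c_[r * math.cos(angle_rad), r * math.sin(angle_rad)]
        sig = sigma_field(self.model, pos)
        return pd.DataFrame({"r_nm": r, "sigma_nm": sig})


def fisher_field(model: PhotonModel, positions) -> np.ndarray:
    """Fisher information matrices at emitter positions (M, 2) -> (M, 2, 2)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    p, grad = probability_gradient_field(model, positions)
    mask = p > _P_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_p = np.where(mask, 1.0 / np.where(mask, p, 1.0), 0.0)
    outer = grad[..., :, None] * grad[..., None, :]          # (M, K, 2, 2)
    return model.n_photons * np.einsum("mk,mkij->mij", inv_p, outer)


def fisher_matrix(emitter, model: PhotonModel) -> CrbResult:
    """Fisher information matrix for one emitter position (nm^-2)."""
    J = fisher_field(model, np.asarray(emitter, dtype=float).reshape(1, 2))[0]
    return CrbResult(fisher=J)


def _crb_from_fisher(J: np.ndarray) -> CrbResult:
    # symmetrize against round-off before inverting
    J = 0.5 * (J + J.T)
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    trace = J[0, 0] + J[1, 1]
    if det <= 0 or trace <= 0 or not np.isfinite(det):
        return CrbResult(fisher=J, identifiable=False)
    cov = np.array([[J[1, 1], -J[0, 1]], [-J[1, 0], J[0, 0]]]) / det
    evals, evecs = np.linalg.eigh(cov)
    angle = math.atan2(evecs[1, -1], evecs[0, -1])  # worst axis
    return CrbResult(
        fisher=J,
        covariance=cov,
        sigma=math.sqrt(0.5 * (cov[0, 0] + cov[1, 1])),
        eigenvalues=evals,
        axis_angle=angle,
    )


def crb_sigma(emitter, model: PhotonModel) -> CrbResult:
    """Full CRB at one emitter position: covariance bound and anisotropy.

    A singular Fisher matrix (non-identifiable position) is reported via
    ``identifiable=False`` with NaN sigma rather than raised.
    """
    return _crb_from_fisher(fisher_matrix(emitter, model).fisher)


def sigma_field(model: PhotonModel, positions) -> np.ndarray:
    """Scalar sigma_r at many emitter positions; NaN where non-identifiable."""
    J = fisher_field(model, positions)
    det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    trace = J[:, 0, 0] + J[:, 1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.sqrt(0.5 * trace / det)
    sig[(det <= 0) | ~np.isfinite(det)] = np.nan
    return sig


def _effective_sbr(model: PhotonModel) -> float:
    """Total signal over total background for a centered emitter (anchor)."""
    if math.isinf(model.sbr):
        return math.inf
    anchor = (
        model
        if model.sbr_anchor_L == model.pattern.size
        else model.with_pattern_size(model.sbr_anchor_L, sbr=model.sbr)
    )
    rates = expected_rates([0.0, 0.0], anchor)
    xi = background_level(model)
    return float(rates.sum() / (anchor.pattern.n_exposures * xi))


def central_crb_closed_form(model: PhotonModel) -> float:
    """Closed-form sigma_r at the center of the four-point pattern (nm).

    Evaluates ``L / (2 n sqrt(2N)) * s / (|l| - L^2/(2 w^2))`` with the
    background factor s computed from the effective
    total-signal/total-background ratio implied by the model's anchoring
    convention.  Requires ``|l| >= 1`` and ``L^2 < 2 |l| w^2``.
    """
    if model.pattern.kind != "four_point":
        raise ValueError("closed form applies to the four-point pattern only")
    beam = model.beam
    if beam.abs_l < 1:
        raise ValueError("closed form requires a vortex beam (|l| >= 1)")
    L = model.pattern.size
    denom = beam.abs_l - L**2 / (2.0 * beam.waist**2)
    if denom <= 0:
        raise ValueError(
            f"pattern size L={L} too large for vortex order {beam.abs_l} "
            f"(requires L^2 < 2|l|w^2)"
        )
    sbr_eff = _effective_sbr(model)
    if math.isinf(sbr_eff):
        s = 1.0
    else:
        s = math.sqrt((1.0 + 3.0 / (4.0 * sbr_eff)) * (1.0 + 1.0 / sbr_eff))
    return (
        L
        / (2.0 * beam.photon_order * math.sqrt(2.0 * model.n_photons))
        * s
        / denom
    )


def crb_map(
    model: PhotonModel, roi_half_width: float, grid_step: float
) -> PrecisionMap:
    """sigma_r and anisotropy descriptors on a square grid around the origin."""
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    axis = np.arange(-roi_half_width, roi_half_width + grid_step / 2, grid_step)
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    pos = np.c_[xx.ravel(), yy.ravel()]
    J = fisher_field(model, pos)
    det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    trace = J[:, 0, 0] + J[:, 1, 1]
    ok = (det > 0) & np.isfinite(det)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.where(ok, np.sqrt(0.5 * trace / det), np.nan)
        # eigenvalues of the 2x2 covariance bound, in closed form
        mean_ev = 0.5 * trace / det
        half_span = np.sqrt(np.maximum(mean_ev**2 - 1.0 / det, 0.0))
        ev_max = mean_ev + half_span
        ev_min = mean_ev - half_span
        # worst (largest-variance) axis: smallest-eigenvalue axis of J
        angle = 0.5 * np.arctan2(-2.0 * J[:, 0, 1], J[:, 1, 1] - J[:, 0, 0])
    shape = xx.shape
    return PrecisionMap(
        x=axis,
        y=axis,
        sigma=sig.reshape(shape),
        sigma_max=np.where(ok, np.sqrt(np.where(ok, ev_max, np.nan)), np.nan).reshape(shape),
        sigma_min=np.where(ok, np.sqrt(np.where(ok, np.maximum(ev_min, 0.0), np.nan)), np.nan).reshape(shape),
        axis_angle=np.where(ok, angle, np.nan).reshape(shape),
        model=model,
    )


def _azimuthal_sigma(model: PhotonModel, radius: float, n_azimuth: int,
                     reduce) -> float:
    theta = np.linspace(0.0, 2.0 * math.pi, n_azimuth, endpoint=False)
    pos = radius * np.c_[np.cos(theta), np.sin(theta)]
    sig = sigma_field(model, pos)
    if np.any(~np.isfinite(sig)):
        return math.inf
    return float(reduce(sig))


def efov_diameter(
    model: PhotonModel,
    threshold: float,
    definition: str = "worst_case",
    n_azimuth: int = 64,
    tol: float = 0.01,
) -> float:
    """Diameter of the effective field of view at a precision threshold (nm).

    The EFOV is the largest origin-centered circle inside which sigma_r
    stays at or below ``threshold``.  Because the bound is not radially
    symmetric, ``definition="worst_case"`` (default) requires the
    condition at every sampled azimuth; ``definition="azimuthal_mean"``
    applies it to the azimuthal mean instead.  The boundary radius is
    located by bisection to ``tol`` nm.  Returns 0 if even the center
    fails the threshold.
    """
    if definition == "worst_case":
        reduce = np.max
    elif definition == "azimuthal_mean":
        reduce = np.mean
    else:
        raise ValueError(f"unknown EFOV definition {definition!r}")
    center = crb_sigma([0.0, 0.0], model)
    if not center.identifiable or center.sigma > threshold:
        return 0.0

    def g(radius: float) -> float:
        return _azimuthal_sigma(model, radius, n_azimuth, reduce)

    # expand outward until the threshold is crossed
    lo, hi = 0.0, model.pattern.size / 2.0
    step = max(model.pattern.size / 2.0, 1.0)
    while g(hi) <= threshold:
        lo = hi
        hi += step
        if hi > 100.0 * model.pattern.size:
            return 2.0 * hi  # threshold never exceeded within a huge range
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) <= threshold:
            lo = mid
        else:
            hi = mid
    return 2.0 * 0.5 * (lo + hi)


@dataclass(frozen=True)
class OptimalPatternSize:
    """Result of the optimal-L search."""

    L_star: float
    sigma_star: float
    boundary: bool
    curve: pd.DataFrame = field(repr=False, default=None)


def optimal_pattern_size(
    model: PhotonModel,
    L_range: tuple[float, float],
    sbr_anchor: tuple[float, float] | None = None,
    coarse_step: float = 1.0,
    tol: float = 0.01,
) -> OptimalPatternSize:
    """Find the pattern size minimizing the central CRB, with SBR rescaling.

    The anchored SBR (``sbr_anchor = (SBR0, L0)``, defaulting to the
    model's own ``(sbr, sbr_anchor_L)``) is rescaled to each candidate L,
    the central sigma_r recomputed, and the minimum refined by bounded
    scalar minimization after a coarse scan.  A minimum at the range
    boundary (as in the noiseless case, where smaller L is always better)
    is flagged.  Ties break toward smaller L.
    """
    if sbr_anchor is None:
        sbr_anchor = (model.sbr, model.sbr_anchor_L)
    sbr0, L0 = sbr_anchor
    lo, hi = L_range
    if not (0 < lo < hi):
        raise ValueError("L range must satisfy 0 < lo < hi")

    def sigma_at(L: float) -> float:
        sbr_L = scale_sbr(L, L0, sbr0, model.beam) if math.isfinite(sbr0) \
            else math.inf
        m = model.with_pattern_size(L, sbr=sbr_L)
        res = crb_sigma([0.0, 0.0], m)
        return res.sigma if res.identifiable else math.inf

    Ls = np.arange(lo, hi + coarse_step / 2, coarse_step)
    sigmas = np.array([sigma_at(L) for L in Ls])
    i = int(np.argmin(sigmas))  # first minimum -> smaller L on ties
    curve = pd.DataFrame({"L_nm": Ls, "sigma_nm": sigmas})
    if i == 0 or i == Ls.size - 1:
        return OptimalPatternSize(
            L_star=float(Ls[i]), sigma_star=float(sigmas[i]),
            boundary=True, curve=curve,
        )
    res = minimize_scalar(
        sigma_at, bounds=(Ls[i - 1], Ls[i + 1]), method="bounded",
        options={"xatol": tol},
    )
    return OptimalPatternSize(
        L_star=float(res.x), sigma_star=float(res.fun),
        boundary=False, curve=curve,
    )


def bayesian_crb(
    model: PhotonModel, prior: PriorModel, quad_order: int = 61
) -> float:
    """Van Trees bound under an isotropic normal positional prior (nm).

    The Bayesian information matrix is the prior-expected Fisher matrix
    plus the prior's own information,

        J_B = E_prior[ J(r_e) ] + (1 / std^2) I

    integrated over the 2D normal prior by tensor Gauss-Hermite
    quadrature.  Returns ``sqrt(Tr(J_B^-1) / 2)``; with no photons this is
    exactly the prior std.  If the two-dimensional quadrature has not
    converged at ``quad_order`` (checked against order+20), the order is
    escalated once.
    """
    if model.n_photons == 0:
        return prior.std

    def jbar(order: int) -> np.ndarray:
        t, wts = np.polynomial.hermite.hermgauss(order)
        x = math.sqrt(2.0) * prior.std * t
        wts = wts / math.sqrt(math.pi)
        xx, yy = np.meshgrid(x, x, indexing="xy")
        pos = np.c_[xx.ravel(), yy.ravel()]
        J = fisher_field(model, pos)
        wgrid = np.outer(wts, wts).ravel()
        return np.einsum("m,mij->ij", wgrid, J)

    J1 = jbar(quad_order)
    J2 = jbar(quad_order + 20)
    JB = J2 if np.allclose(J1, J2, rtol=1e-6) else jbar(2 * quad_order)
    JB = JB + np.eye(2) / prior.std**2
    cov = np.linalg.inv(JB)
    return float(math.sqrt(0.5 * np.trace(cov)))
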