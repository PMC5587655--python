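"""Unary and pairwise potentials of the edge-guided random-field energy.

The optimization variable F is carried in the log-envelope domain (the
domain in which multiplicative speckle is additive).  The unary term is the
Fisher-Tippett negative log-likelihood of the residual between the observed
log envelope and the (blurred) estimate, gated by the uncertainty layer: a
voxel with no reading contributes exactly zero.  The pairwise term penalizes
the smoothed absolute difference across realized clique pairs, weighted by
spatial proximity and first-order-variation penalties; the first-order term
damps smoothing across observed edges.

Note on conventions: the pairwise clique potential is the exponent of the
Gibbs factor (beta * |f_i - f_j| * w), i.e. the quantity whose sum the MAP
problem minimizes — exponentiating it instead would reward roughness.  The
absolute value is smoothed (Charbonnier) so gradient descent sees a
differentiable energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import LOG_FLOOR, ObservedEnvelope, PSFBank, apply_psf
from .graph import NeighborSampler, offset_slices

__all__ = [
    "UnaryParams",
    "PairwiseParams",
    "EnergyBreakdown",
    "fisher_tippett_nll",
    "fisher_tippett_nll_prime",
    "unary_energy",
    "unary_gradient",
    "w_spatial",
    "w_fov",
    "pair_weights",
    "pairwise_energy",
    "pairwise_gradient",
    "total_energy",
    "energy_gradient",
]

_EXP_CLIP = 700.0


@dataclass(frozen=True)
class UnaryParams:
    """Data-term configuration.

    ``mode='log'`` applies the PSF bank directly to the log-domain estimate
    (fast, approximate); ``mode='exact'`` exponentiates first, blurs in the
    linear envelope domain, and takes the log of the result.  A ``psf_bank``
    of None means identity H.
    """

    sigma: float = 0.5
    alpha: float = 1.0
    psf_bank: PSFBank | None = None
    log_floor: float = LOG_FLOOR
    mode: str = "log"  # 'log' | 'exact'

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.mode not in ("log", "exact"):
            raise ValueError("mode must be 'log' or 'exact'")


@dataclass(frozen=True)
class PairwiseParams:
    beta: float = 0.5
    sigma_sp: float = 3.0
    sigma_fov: float | None = None  # None -> 0.1 * guide range at use time
    epsilon_abs: float = 1e-3
    include_spatial: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma_sp <= 0 or (self.sigma_fov is not None and self.sigma_fov <= 0):
            raise ValueError("penalty bandwidths must be positive")
        if self.epsilon_abs <= 0:
            raise ValueError("epsilon_abs must be positive")

    def resolve_sigma_fov(self, guide: np.ndarray) -> float:
        if self.sigma_fov is not None:
            return self.sigma_fov
        rng_ = float(np.ptp(guide))
        return 0.1 * rng_ if rng_ > 0 else 1.0


@dataclass(frozen=True)
class EnergyBreakdown:
    unary_total: float
    pairwise_total: float

    @property
    def total(self) -> float:
        return self.unary_total + self.pairwise_total


def fisher_tippett_nll(residual, sigma: float):
    """Negative log of the Fisher-Tippett density at the given residual.

    With t = 2 r - ln(2 sigma^2):  -[ln 2 + t - exp(t)].  Strictly convex in
    r with its minimum at r* = ln(2 sigma^2) / 2.  The exponent is clipped
    at 700 to avoid overflow.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = 2.0 * np.asarray(residual, dtype=float) - np.log(2.0 * sigma ** 2)
    t = np.clip(t, -np.inf, _EXP_CLIP)
    return -(np.log(2.0) + t - np.exp(t))


def fisher_tippett_nll_prime(residual, sigma: float):
    """d/dr of :func:`fisher_tippett_nll`: -2 + 2 exp(2r - ln 2 sigma^2)."""
    t = 2.0 * np.asarray(residual, dtype=float) - np.log(2.0 * sigma ** 2)
    t = np.clip(t, -np.inf, _EXP_CLIP)
    return -2.0 + 2.0 * np.exp(t)


def _model_log(F_log: np.ndarray, obs: ObservedEnvelope, params: UnaryParams):
    """log(H F) under the configured mode; returns (model_log, aux)."""
    if params.psf_bank is None:
        return F_log, None
    if params.mode == "log":
        return apply_psf(F_log, params.psf_bank, pitch_z=obs.pitch[0],
                         origin_z=obs.origin[0]), None
    lin = np.exp(F_log)
    blurred = apply_psf(lin, params.psf_bank, pitch_z=obs.pitch[0],
                        origin_z=obs.origin[0])
    low = blurred <= params.log_floor
    if np.any(low & (obs.mask == 1)):
        warnings.warn("blurred estimate clipped at log floor inside the mask",
                      RuntimeWarning, stacklevel=3)
    clipped = np.maximum(blurred, params.log_floor)
    return np.log(clipped), (lin, clipped)


def unary_energy(F_log: np.ndarray, obs: ObservedEnvelope,
                 params: UnaryParams) -> float:
    """alpha * sum over sampled voxels of the Fisher-Tippett nll of the
    residual log g - log(H F); voxels with Cr = 1 contribute exactly 0."""
    model_log, _ = _model_log(np.asarray(F_log, dtype=float), obs, params)
    r = obs.values - model_log
    nll = fisher_tippett_nll(r, params.sigma)
    return float(params.alpha * np.sum(nll[obs.mask == 1]))


def unary_gradient(F_log: np.ndarray, obs: ObservedEnvelope,
                   params: UnaryParams) -> np.ndarray:
    """Analytic gradient of :func:`unary_energy` w.r.t. the log-domain F."""
    F_log = np.asarray(F_log, dtype=float)
    model_log, aux = _model_log(F_log, obs, params)
    r = obs.values - model_log
    dn = fisher_tippett_nll_prime(r, params.sigma) * (obs.mask == 1)
    if params.psf_bank is None:
        return -params.alpha * dn
    if params.mode == "log":
        return -params.alpha * apply_psf(dn, params.psf_bank, pitch_z=obs.pitch[0],
                                         origin_z=obs.origin[0], adjoint=True)
    lin, clipped = aux
    inner = dn / clipped
    back = apply_psf(inner, params.psf_bank, pitch_z=obs.pitch[0],
                     origin_z=obs.origin[0], adjoint=True)
    return -params.alpha * lin * back


def w_spatial(distance, sigma_sp: float):
    """Spatial-proximity penalty exp(-d_E / (2 sigma_sp^2)), first power."""
    if sigma_sp <= 0:
        raise ValueError("sigma_sp must be positive")
    return np.exp(-np.asarray(distance, dtype=float) / (2.0 * sigma_sp ** 2))


def w_fov(g_i, g_j, sigma_fov: float):
    """First-order-variation penalty exp(-|g_i - g_j| / (2 sigma_fov^2)).

    First-power difference: across a strong observed edge the weight is
    small, damping the smoothing penalty there.
    """
    if sigma_fov <= 0:
        raise ValueError("sigma_fov must be positive")
    d = np.abs(np.asarray(g_i, dtype=float) - np.asarray(g_j, dtype=float))
    return np.exp(-d / (2.0 * sigma_fov ** 2))


def _charbonnier(x, eps: float):
    return np.sqrt(x * x + eps * eps) - eps


def _charbonnier_prime(x, eps: float):
    return x / np.sqrt(x * x + eps * eps)


def pair_weights(sampler: NeighborSampler, guide: np.ndarray,
                 params: PairwiseParams) -> list[np.ndarray]:
    """Per-offset pair weights w_sp * w_fov on realized pairs (else 0).

    ``guide`` supplies the observed intensities g entering the
    first-order-variation term; the interpolated initial estimate is the
    natural choice since raw observations are undefined off the beams.
    """
    guide = np.asarray(guide, dtype=float)
    sfov = params.resolve_sigma_fov(guide)
    out = []
    for off, r in zip(sampler.offsets, sampler.realized):
        sa, sb = offset_slices(sampler.shape, off)
        d = float(np.hypot(*off))
        wsp = w_spatial(d, params.sigma_sp) if params.include_spatial else 1.0
        w = np.zeros(sampler.shape)
        w[sa] = wsp * w_fov(guide[sa], guide[sb], sfov) * r[sa]
        out.append(w)
    return out


def pairwise_energy(F_log: np.ndarray, guide: np.ndarray,
                    sampler: NeighborSampler, params: PairwiseParams,
                    weights: list[np.ndarray] | None = None) -> float:
    """beta * sum over realized pairs of s(f_i - f_j) * w_sp * w_fov, where
    s is the Charbonnier-smoothed absolute value.  Zero for constant F."""
    F_log = np.asarray(F_log, dtype=float)
    if weights is None:
        weights = pair_weights(sampler, guide, params)
    total = 0.0
    for off, w in zip(sampler.offsets, weights):
        sa, sb = offset_slices(sampler.shape, off)
        d = F_log[sa] - F_log[sb]
        total += float(np.sum(_charbonnier(d, params.epsilon_abs) * w[sa]))
    return params.beta * total


def pairwise_gradient(F_log: np.ndarray, guide: np.ndarray,
                      sampler: NeighborSampler, params: PairwiseParams,
                      weights: list[np.ndarray] | None = None) -> np.ndarray:
    F_log = np.asarray(F_log, dtype=float)
    if weights is None:
        weights = pair_weights(sampler, guide, params)
    grad = np.zeros_like(F_log)
    for off, w in zip(sampler.offsets, weights):
        sa, sb = offset_slices(sampler.shape, off)
        g = _charbonnier_prime(F_log[sa] - F_log[sb], params.epsilon_abs) * w[sa]
        grad[sa] += g
        grad[sb] -= g
    return params.beta * grad


def total_energy(F_log: np.ndarray, obs: ObservedEnvelope,
                 sampler: NeighborSampler, unary_params: UnaryParams,
                 pairwise_params: PairwiseParams,
                 guide: np.ndarray | None = None,
                 weights: list[np.ndarray] | None = None) -> EnergyBreakdown:
    """Both energy components and their sum; a pure function of its inputs."""
    if guide is None and weights is None:
        raise ValueError("provide guide intensities or precomputed weights")
    u = unary_energy(F_log, obs, unary_params)
    p = pairwise_energy(F_log, guide, sampler, pairwise_params, weights=weights)
    return EnergyBreakdown(unary_total=u, pairwise_total=p)


def energy_gradient(F_log: np.ndarray, obs: ObservedEnvelope,
                    sampler: NeighborSampler, unary_params: UnaryParams,
                    pairwise_params: PairwiseParams,
                    guide: np.ndarray | None = None,
                    weights: list[np.ndarray] | None = None) -> np.ndarray:
    """Analytic gradient of the total energy w.r.t. the log-domain F."""
    if guide is None and weights is None:
        raise ValueError("provide guide intensities or precomputed weights")
    g = unary_gradient(F_log, obs, unary_params)
    g = g + pairwise_gradient(F_log, guide, sampler, pairwise_params,
                              weights=weights)
    return g
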