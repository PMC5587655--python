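"""MAP reconstruction by gradient descent with backtracking.

Each slice is reconstructed independently: the sparse log-envelope readings
are mapped to a full lattice by linear interpolation, the edge map and
clique structure are built once from that initial estimate, and the total
energy is minimized by monotone gradient descent (step halving whenever a
trial step would increase the energy).

"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import ObservedEnvelope, PSFBank, interpolate_to_lattice
from .crf_energy import (EnergyBreakdown, PairwiseParams, UnaryParams,
                         energy_gradient, pair_weights, total_energy)
from .graph import IndicatorParams, build_sampler, edge_map

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "reconstruct_slice",
    "reconstruct_volume",
    "baseline_interpolation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconstructionConfig:
    """All hyperparameters of one reconstruction run.

    The defaults are implementation choices; every field is overridable.
    """

    unary: UnaryParams = field(default_factory=UnaryParams)
    pairwise: PairwiseParams = field(default_factory=PairwiseParams)
    indicator: IndicatorParams = field(default_factory=IndicatorParams)
    step_size: float = 0.1
    max_iters: int = 500
    rel_tol: float = 1e-6
    backtrack_factor: float = 0.5
    max_backtracks: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if not (0 < self.backtrack_factor < 1):
            raise ValueError("backtrack_factor must be in (0, 1)")


@dataclass(frozen=True)
class ReconstructionResult:
    """Estimate (linear envelope domain) plus the full optimization trace."""

    estimate: np.ndarray
    log_estimate: np.ndarray
    energy_trace: tuple[EnergyBreakdown, ...]
    iterations_run: int
    converged: bool


def reconstruct_slice(obs: ObservedEnvelope, bank: PSFBank | None,
                      config: ReconstructionConfig) -> ReconstructionResult:
    """MAP-reconstruct one 2-D slice.

    Initializes from scattered linear interpolation, freezes the edge map
    and clique structure, then runs monotone gradient descent until the
    relative energy change drops below ``rel_tol`` or ``max_iters`` passes.
    """
    init = interpolate_to_lattice(obs)
    indicator = config.indicator
    if indicator.seed is None and config.seed is not None:
        indicator = replace(indicator, seed=config.seed)
    edges = edge_map(init, presmooth_sigma=indicator.edge_presmooth)
    sampler = build_sampler(init, edges, indicator)
    unary = replace(config.unary, psf_bank=bank)
    weights = pair_weights(sampler, init, config.pairwise)

    F = init.copy()
    energy = total_energy(F, obs, sampler, unary, config.pairwise, weights=weights)
    trace = [energy]
    eta = config.step_size
    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        grad = energy_gradient(F, obs, sampler, unary, config.pairwise,
                               weights=weights)
        if not np.all(np.isfinite(grad)):
            raise RuntimeError(f"non-finite gradient at iteration {it}")
        eta = min(eta * 2.0, config.step_size)
        accepted = False
        for _ in range(config.max_backtracks + 1):
            trial = F - eta * grad
            e_trial = total_energy(trial, obs, sampler, unary, config.pairwise,
                                   weights=weights)
            if not np.isfinite(e_trial.total):
                eta *= config.backtrack_factor
                continue
            if e_trial.total <= energy.total:
                accepted = True
                break
            eta *= config.backtrack_factor
        if not accepted:
            log.info("no descent step found at iteration %d; stopping", it)
            converged = True
            break
        F = trial
        prev = energy
        energy = e_trial
        trace.append(energy)
        log.info("iter %d unary=%.6g pairwise=%.6g total=%.6g",
                 it, energy.unary_total, energy.pairwise_total, energy.total)
        denom = max(abs(prev.total), 1e-30)
        if abs(prev.total - energy.total) / denom < config.rel_tol:
            converged = True
            break
    if not np.all(np.isfinite(F)):
        raise RuntimeError(f"non-finite estimate at iteration {it}")
    return ReconstructionResult(estimate=np.exp(F), log_estimate=F,
                                energy_trace=tuple(trace),
                                iterations_run=it, converged=converged)


def _slice_obs(obs: ObservedEnvelope, k: int) -> ObservedEnvelope:
    return ObservedEnvelope(values=obs.values[k], mask=obs.mask[k], cr=obs.cr[k],
                            noise_sigma=obs.noise_sigma, pitch=obs.pitch,
                            origin=obs.origin)


def reconstruct_volume(obs: ObservedEnvelope, bank: PSFBank | None,
                       config: ReconstructionConfig) -> list[ReconstructionResult]:
    """Reconstruct every slice of a 3-D observation independently.

    ``obs.values`` may be 2-D (treated as a single slice) or 3-D with slices
    along axis 0.  Per-slice failures are collected and reported together
    with their slice indices.
    """
    if obs.values.ndim == 2:
        return [reconstruct_slice(obs, bank, config)]
    results: list[ReconstructionResult | None] = []
    failures: list[tuple[int, Exception]] = []
    for k in range(obs.values.shape[0]):
        try:
            results.append(reconstruct_slice(_slice_obs(obs, k), bank, config))
        except Exception as exc:  # noqa: BLE001 - collected and re-raised
            failures.append((k, exc))
            results.append(None)
    if failures:
        detail = "; ".join(f"slice {k}: {exc}" for k, exc in failures)
        raise RuntimeError(f"reconstruction failed for {len(failures)} slice(s): {detail}")
    return results  # type: ignore[return-value]


def baseline_interpolation(obs: ObservedEnvelope) -> np.ndarray:
    """Interpolation-only comparator (no noise model, no PSF, no smoothing).

    Returns the log-domain lattice fill; independent of every random-field
    hyperparameter.
    """
    if obs.values.ndim == 2:
        return interpolate_to_lattice(obs)
    return np.stack([interpolate_to_lattice(_slice_obs(obs, k))
                     for k in range(obs.values.shape[0])])
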