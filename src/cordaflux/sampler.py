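"""Artificially-centered hit-and-run sampling of the flux polytope.

Warmup points are vertices of {v : S v = 0, lb <= v <= ub} found by
optimising random +/-1 objectives.  Each ACHR move picks a point, draws a
direction as (random other point - centre of the cloud), computes how far
the point may travel in that direction without leaving the bounds and
jumps to a uniform position on that segment.  Because every point and the
centre satisfy S v = 0, every direction lies in the null space of S and
mass balance is preserved without projection.

Convergence uses the mixed fraction: per-reaction medians of the
phase-start points define a partition, and the statistic is the fraction
of (point, reaction) pairs still on their starting side, averaged over
non-degenerate reactions.  It starts at 1 and tends to 0.5 under perfect
mixing.  Sampling runs three phases: the first mixes the warmup points to
the threshold, the next two restart the bookkeeping from the previous
phase's final points and mix to the same threshold again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lp import LPSettings, solve_fba
from .model import MetabolicModel

__all__ = [
    "SamplerConfig",
    "SampleSet",
    "generate_warmup",
    "achr_step",
    "mixed_fraction",
    "sample",
]


@dataclass(frozen=True)
class SamplerConfig:
    n_warmup: int | None = None  # default min(2 * n_reactions, 5000)
    threshold: float = 0.52  # mixed-fraction termination threshold
    steps_per_check: int | None = None  # default: one sweep over all points
    max_sweeps: int = 2000  # per phase, before declaring non-convergence
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0.5, 1]")
        if self.n_warmup is not None and self.n_warmup < 2:
            raise ValueError("need at least 2 warmup points")


@dataclass
class SampleSet:
    points: np.ndarray  # (n_points, n_reactions)
    reaction_ids: list[str]
    phase: int
    trace: list[list[float]]  # mixed-fraction trace per phase

    def column(self, rxn_id: str) -> np.ndarray:
        return self.points[:, self.reaction_ids.index(rxn_id)]


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace):
        super().__init__(msg)
        self.trace = trace


def generate_warmup(
    model: MetabolicModel,
    k: int,
    rng: np.random.Generator,
    settings: LPSettings | None = None,
) -> np.ndarray:
    """k polytope vertices from random +/-1 objective vectors."""
    if k < 2:
        raise ValueError("need at least 2 warmup points")
    n = len(model.reactions)
    points = np.empty((k, n))
    for i in range(k):
        c = rng.choice([-1.0, 1.0], size=n)
        sol = solve_fba(model, c, "maximize", settings)
        if sol.status != "optimal":
            raise RuntimeError(f"model is {sol.status}; cannot generate warmup points")
        points[i] = [sol.values[rid] for rid in model.reaction_ids]
    return points


def achr_step(
    points: np.ndarray,
    center: np.ndarray,
    index: int,
    rng: np.random.Generator,
    lb: np.ndarray,
    ub: np.ndarray,
    dir_tol: float = 1e-10,
    max_retries: int = 10,
) -> np.ndarray:
    """Move one point along a centred random direction; returns the point.

    Degenerate directions are resampled a bounded number of times; if the
    step range collapses to a single value the point is returned unmoved.
    """
    x = points[index]
    n_pts = points.shape[0]
    for _ in range(max_retries):
        other = rng.integers(n_pts)
        d = points[other] - center
        norm = float(np.max(np.abs(d)))
        if norm > dir_tol:
            break
    else:
        return x.copy()
    a_min, a_max = -np.inf, np.inf
    active = np.abs(d) > dir_tol
    lo = (lb[active] - x[active]) / d[active]
    hi = (ub[active] - x[active]) / d[active]
    lows = np.minimum(lo, hi)
    highs = np.maximum(lo, hi)
    if lows.size:
        a_min = float(np.max(lows))
        a_max = float(np.min(highs))
    if not np.isfinite(a_min) or not np.isfinite(a_max) or a_max <= a_min:
        return x.copy()
    alpha = rng.uniform(a_min, a_max)
    new = x + alpha * d
    return np.clip(new, lb, ub)


def mixed_fraction(
    initial_sides: np.ndarray,
    points: np.ndarray,
    medians: np.ndarray,
    active: np.ndarray,
) -> float:
    """Fraction of (point, dimension) pairs still on their starting side.

    ``initial_sides`` holds the phase-start comparison against the same
    medians; dimensions flagged inactive (zero width) are excluded.
    """
    if not active.any():
        return 1.0
    current = points[:, active] > medians[active]
    return float(np.mean(current == initial_sides[:, active]))


def sample(
    model: MetabolicModel,
    config: SamplerConfig | None = None,
    settings: LPSettings | None = None,
) -> SampleSet:
    """Three-phase ACHR sampling to the configured mixed-fraction threshold."""
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    n = len(model.reactions)
    lb, ub = model.lb, model.ub
    width_tol = 1e-9
    active = (ub - lb) > width_tol

    k = config.n_warmup or min(2 * n, 5000)
    k = max(k, 2)
    points = generate_warmup(model, k, rng, settings)

    if not active.any():  # fixed-point polytope: nothing to mix
        return SampleSet(points, list(model.reaction_ids), phase=3, trace=[[1.0]] * 3)

    steps_per_check = config.steps_per_check or k
    traces: list[list[float]] = []
    for _phase in range(3):
        medians = np.median(points, axis=0)
        initial_sides = points[:, :] > medians
        trace = [1.0]
        if trace[-1] <= config.threshold:  # vacuous threshold = 1.0
            traces.append(trace)
            continue
        converged = False
        for _sweep in range(config.max_sweeps):
            center = points.mean(axis=0)
            for _ in range(steps_per_check):
                idx = int(rng.integers(k))
                points[idx] = achr_step(points, center, idx, rng, lb, ub)
                center = points.mean(axis=0)
            mf = mixed_fraction(initial_sides, points, medians, active)
            trace.append(mf)
            if mf <= config.threshold:
                converged = True
                break
        traces.append(trace)
        if not converged:
            raise ConvergenceError(
                f"mixed fraction did not reach {config.threshold} within "
                f"{config.max_sweeps} sweeps",
                traces,
            )
    return SampleSet(points, list(model.reaction_ids), phase=3, trace=traces)
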