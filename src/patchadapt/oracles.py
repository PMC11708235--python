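"""Brute-force Monte-Carlo oracles for the analytic machinery.

These simulators share no code with the solver or rate modules — geometry
and dynamics are written out directly from the model parameters — so they
can serve as independent checks in the test suite:

* :func:`branching_establishment_mc` — the spatial branching process that
  the establishment BVP approximates: individuals reproduce independently
  with Poisson(e^(s(x))) offspring displaced by the Gaussian kernel.
* :func:`killed_bm_reach_mc` — killed Brownian walkers estimating the
  reach probability q_d(r).
* :func:`conditioned_no_return_mc` — the same walkers scored for the
  no-return probability P, with sub-generation time steps (the layer
  thickness dx is far below the per-generation step length, so resolving
  it needs a finer clock) and the Broadie-Glasserman-Kou continuity
  correction for discretely monitored barriers.

All estimates carry binomial standard errors and replicate counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import SpatialModel

__all__ = [
    "MCEstimate",
    "InsufficientSamplesError",
    "branching_establishment_mc",
    "killed_bm_reach_mc",
    "conditioned_no_return_mc",
]

# mean overshoot of a Gaussian random walk at a barrier, in step-sd units;
# shifting a discretely monitored barrier by this restores the continuous
# first-passage probability to O(dt) (Broadie, Glasserman & Kou 1997)
_BGK = 0.5826


class InsufficientSamplesError(RuntimeError):
    """Too few conditioning events to form a meaningful estimate."""


@dataclass(frozen=True)
class MCEstimate:
    """Binomial Monte-Carlo estimate with its standard error."""

    estimate: float
    se: float
    n_events: int
    replicates: int
    n_flagged: int = 0
    n_timed_out: int = 0


def _binomial(k: int, n: int, n_flagged: int = 0, n_timed_out: int = 0) -> MCEstimate:
    p = k / n
    se = math.sqrt(max(p * (1.0 - p), 1e-300) / n)
    return MCEstimate(estimate=p, se=se, n_events=k, replicates=n,
                      n_flagged=n_flagged, n_timed_out=n_timed_out)


def branching_establishment_mc(
    model: SpatialModel,
    origin_r: float,
    replicates: int,
    seed: int,
    threshold: int = 500,
    hard_cap: int = 100_000,
    max_gen: int = 20_000,
) -> MCEstimate:
    """Establishment probability of a single mutant by direct branching.

    A replicate starts with one individual at distance ``origin_r`` from
    the patch centre.  Each generation every individual leaves
    Poisson(e^(s(x))) offspring, each displaced by an independent
    N(0, sigma2) step along every axis.  A replicate is established once
    its descendant count reaches ``threshold`` with the majority of
    individuals inside the patch — by then extinction is essentially
    impossible under s1 > 0.  Replicates hitting ``hard_cap`` without the
    inside-majority condition are flagged and excluded, never silently
    counted either way.
    """
    d, sig = model.d, math.sqrt(model.sigma2)
    R2 = model.R**2
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pos = np.zeros((replicates, d))
    pos[:, 0] = origin_r
    rep = np.arange(replicates)
    alive = np.ones(replicates, dtype=bool)
    established = np.zeros(replicates, dtype=bool)
    flagged = np.zeros(replicates, dtype=bool)

    for _ in range(max_gen):
        if rep.size == 0:
            break
        inside = (pos**2).sum(axis=1) <= R2
        s = np.where(inside, model.s1, -model.s2)
        n_off = rng.poisson(np.exp(s))
        pos = np.repeat(pos, n_off, axis=0) + rng.normal(0.0, sig, (int(n_off.sum()), d))
        rep = np.repeat(rep, n_off)

        counts = np.bincount(rep, minlength=replicates)
        inside_counts = np.bincount(
            rep, weights=((pos**2).sum(axis=1) <= R2).astype(float),
            minlength=replicates)
        majority_in = inside_counts > 0.5 * counts

        newly_est = alive & (counts >= threshold) & majority_in
        newly_flag = alive & (counts >= hard_cap) & ~majority_in
        extinct = alive & (counts == 0)
        established |= newly_est
        flagged |= newly_flag
        alive &= ~(newly_est | newly_flag | extinct)
        keep = alive[rep]
        pos, rep = pos[keep], rep[keep]

    n_timed = int(alive.sum())
    n_flag = int(flagged.sum())
    valid = replicates - n_flag - n_timed
    return _binomial(int(established.sum()), valid,
                     n_flagged=n_flag, n_timed_out=n_timed)


def killed_bm_reach_mc(
    model: SpatialModel,
    r_start: float,
    R_prime: float,
    replicates: int,
    seed: int,
    max_gen: int = 100_000,
    boundary_correction: bool = True,
) -> MCEstimate:
    """Probability a killed Brownian lineage reaches radius R_prime.

    Per-generation dynamics: survive with probability e^(-s2), then take a
    Gaussian step of variance sigma2 per axis.  Reaching is monitored at
    generation ends; with ``boundary_correction`` the absorbing radius is
    pulled inward by 0.5826*sigma to compensate the unobserved
    between-generation excursions.
    """
    if r_start > R_prime:
        raise ValueError("need r_start <= R_prime")
    if r_start == R_prime:
        return _binomial(replicates, replicates)
    d, sig = model.d, math.sqrt(model.sigma2)
    barrier = R_prime - (_BGK * sig if boundary_correction else 0.0)
    barrier2 = barrier**2
    p_survive = math.exp(-model.s2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pos = np.zeros((replicates, d))
    pos[:, 0] = r_start
    n_reached = 0
    n_timed = 0
    for _ in range(max_gen):
        if pos.shape[0] == 0:
            break
        survive = rng.random(pos.shape[0]) < p_survive
        pos = pos[survive]
        pos = pos + rng.normal(0.0, sig, pos.shape)
        reached = (pos**2).sum(axis=1) >= barrier2
        n_reached += int(reached.sum())
        pos = pos[~reached]
    else:
        n_timed = pos.shape[0]
    # walkers still alive at the horizon are counted as not (yet) reached
    return _binomial(n_reached, replicates, n_timed_out=n_timed)


def conditioned_no_return_mc(
    model: SpatialModel,
    Rs: float,
    dx: float,
    R_prime: float,
    replicates: int,
    seed: int,
    substeps: int | None = None,
    max_gen: int = 100_000,
    min_events: int = 100,
    boundary_correction: bool = True,
) -> MCEstimate:
    """No-return probability P among walkers conditioned to reach R_prime.

    Walkers start at radius Rs + dx/2, diffuse with killing rate s2, and
    are scored on reaching radius R_prime; the estimate is the fraction of
    reaching walkers that never dipped below Rs - dx/2 on the way.
    Conditioning is by rejection: killed walkers are discarded from the
    denominator.

    The inner layer boundary sits a distance dx/2 << sigma from the start,
    so the walk is advanced in ``substeps`` Euler sub-generations chosen
    to make the sub-step length at most dx/4 (killing rate is applied per
    sub-step as s2/substeps); both barriers carry the continuity
    correction.  Raises :class:`InsufficientSamplesError` when fewer than
    ``min_events`` walkers reach R_prime.
    """
    d = model.d
    sig_gen = math.sqrt(model.sigma2)
    if substeps is None:
        substeps = max(1, math.ceil((4.0 * sig_gen / dx) ** 2))
    dt = 1.0 / substeps
    sig = sig_gen * math.sqrt(dt)
    shift = _BGK * sig if boundary_correction else 0.0
    inner = Rs - dx / 2.0 + shift     # return barrier, pulled toward walker
    outer2 = (R_prime - shift) ** 2   # absorbing barrier, pulled toward walker
    inner2 = inner**2
    p_survive = math.exp(-model.s2 * dt)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pos = np.zeros((replicates, d))
    pos[:, 0] = Rs + dx / 2.0
    returned = np.zeros(replicates, dtype=bool)
    n_reach = 0
    n_reach_clean = 0
    total_steps = max_gen * substeps
    for _ in range(total_steps):
        if pos.shape[0] == 0:
            break
        survive = rng.random(pos.shape[0]) < p_survive
        pos, returned = pos[survive], returned[survive]
        pos = pos + rng.normal(0.0, sig, pos.shape)
        r2 = (pos**2).sum(axis=1)
        returned |= r2 <= inner2
        reached = r2 >= outer2
        n_reach += int(reached.sum())
        n_reach_clean += int((reached & ~returned).sum())
        keep = ~reached
        pos, returned = pos[keep], returned[keep]

    if n_reach < min_events:
        raise InsufficientSamplesError(
            f"only {n_reach} walkers reached R_prime={R_prime} "
            f"(need {min_events}); increase replicates or reduce R_prime")
    return _binomial(n_reach_clean, n_reach)
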