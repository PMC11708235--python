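"""Stepping-stone Wright-Fisher simulator on a d-dimensional lattice.

Validation engine for the continuous-space theory: geographic space is
discretized into demes of ``round(rho * dx^d)`` individuals spaced ``dx``
apart, with nearest-neighbour migration at per-neighbour rate
``m = sigma2 / (2 dx^2)`` so that the per-axis dispersal variance per
generation equals sigma2, matching the Gaussian kernel's diffusion limit.
The lattice must resolve the characteristic scale (dx <= (1/beta2)/5) and
the domain extends far enough beyond every patch that the reflecting
boundary sees a vanishing allele frequency.

Life cycle per generation: migration -> selection -> binomial
Wright-Fisher resampling within each deme.  Establishment is scored when
the frequency of allele A over the demes of the target patch exceeds 0.5.

Two experiments mirror the two establishment routes:

* :func:`run_establishment_replicates` — a single A copy placed at
  distance ``origin_r`` from the target centre; the fraction of replicates
  establishing estimates u_d(origin_r).
* :func:`run_waiting_time` — the source patch initialized fixed for A with
  no mutation; the generation at which the target patch adapts estimates
  T_wait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .migration import SourceGeometry
from .model import SpatialModel

__all__ = [
    "SimGrid",
    "EstablishmentEstimate",
    "WaitingTimeResult",
    "build_grid",
    "step",
    "run_establishment_replicates",
    "run_waiting_time",
    "sample_lineage_displacements",
]

_BATCH = 512  # fixed batching of replicates; part of the reproducibility contract


@dataclass(frozen=True)
class SimGrid:
    """Lattice discretization of the continuous model.

    ``axes`` holds the deme-centre coordinates along each axis (the target
    patch is centred at the origin, the source patch displaced along axis
    0); ``selection_map`` the per-deme log-fitness of allele A; boundaries
    are reflecting.
    """

    model: SpatialModel
    geometry: SourceGeometry | None
    dx_lattice: float
    deme_size: int
    m_neighbor: float
    axes: tuple[np.ndarray, ...]
    selection_map: np.ndarray
    target_mask: np.ndarray
    source_mask: np.ndarray | None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.selection_map.shape

    @property
    def n_target_demes(self) -> int:
        return int(self.target_mask.sum())


def build_grid(
    model: SpatialModel,
    geometry: SourceGeometry | None = None,
    dx_lattice: float | None = None,
    extent_mult: float = 10.0,
) -> SimGrid:
    """Construct a lattice consistent with the continuous model.

    Binding constraints (each raises with its name if violated):
    resolution dx <= (1/beta2)/5; migration probability 2 d m <= 0.5 with
    m = sigma2/(2 dx^2); deme size round(rho_eff dx^d) >= 2; extent at
    least ``extent_mult``/beta2 beyond every patch edge along each axis.

    A deme belongs to a patch iff its centre lies within the patch radius,
    with the boundary counting as inside (half-open convention).
    """
    b2 = model.beta2
    dx = (1.0 / b2) / 5.0 if dx_lattice is None else float(dx_lattice)
    if dx > (1.0 / b2) / 5.0 * (1 + 1e-12):
        raise ValueError(
            f"resolution constraint violated: dx_lattice={dx} > (1/beta2)/5 = {(1 / b2) / 5:.4g}")
    m = model.sigma2 / (2.0 * dx**2)
    if 2 * model.d * m > 0.5:
        raise ValueError(
            f"migration-probability constraint violated: 2*d*m = {2 * model.d * m:.3f} > 0.5 "
            "(raise dx_lattice)")
    K = int(round(model.effective_density * dx**model.d))
    if K < 2:
        raise ValueError(
            f"deme-size constraint violated: round(rho*dx^d) = {K} < 2 "
            "(raise dx_lattice or rho)")
    # branching-process regime: a surviving deleterious lineage carries
    # ~1/s2 members spread over ~1/beta2, so the density per characteristic
    # volume must exceed that for allele A to stay locally rare
    if model.effective_density * model.length_scale**model.d < 1.0 / model.s2:
        warnings.warn(
            f"low-density regime: rho*(1/beta2)^d = "
            f"{model.effective_density * model.length_scale**model.d:.3g} < 1/s2 = "
            f"{1.0 / model.s2:.3g}; local fixation of the deleterious allele can "
            "inflate establishment rates above the branching-process theory",
            stacklevel=2,
        )

    buffer = extent_mult / b2
    if geometry is not None:
        geometry.validate(model)
    lo = model.R + buffer
    hi_first = (geometry.D + geometry.Rs + buffer) if geometry is not None else lo

    def axis_coords(lo_extent: float, hi_extent: float) -> np.ndarray:
        n_lo = int(math.ceil(lo_extent / dx))
        n_hi = int(math.ceil(hi_extent / dx))
        return (np.arange(n_lo + n_hi + 1) - n_lo) * dx

    axes = tuple(axis_coords(lo, hi_first if ax == 0 else lo)
                 for ax in range(model.d))
    mesh = np.meshgrid(*axes, indexing="ij")
    r_target = np.sqrt(sum(c**2 for c in mesh))
    target_mask = r_target <= model.R + 1e-12

    sel = np.where(target_mask, model.s1, -model.s2)
    source_mask = None
    if geometry is not None:
        centred = [mesh[0] - geometry.D] + [mesh[i] for i in range(1, model.d)]
        r_source = np.sqrt(sum(c**2 for c in centred))
        source_mask = r_source <= geometry.Rs + 1e-12
        sel = np.where(source_mask, model.s1, sel)

    return SimGrid(model=model, geometry=geometry, dx_lattice=dx, deme_size=K,
                   m_neighbor=m, axes=axes, selection_map=sel,
                   target_mask=target_mask, source_mask=source_mask)


def step(state: np.ndarray, grid: SimGrid, rng: np.random.Generator) -> np.ndarray:
    """One generation: migration -> selection -> Wright-Fisher sampling.

    ``state`` holds A counts per deme, either ``grid.shape`` or batched as
    ``(B, *grid.shape)``.  Reflecting boundaries are realised by edge
    padding (the missing neighbour is the deme itself), which conserves
    expected allele number under neutrality.
    """
    K = grid.deme_size
    m = grid.m_neighbor
    d = grid.model.d
    batched = state.ndim == d + 1
    p = state / K

    neigh = np.zeros_like(p)
    for ax in range(d):
        sp_ax = ax + 1 if batched else ax
        pad = [(0, 0)] * p.ndim
        pad[sp_ax] = (1, 1)
        padded = np.pad(p, pad, mode="edge")
        n_ax = p.shape[sp_ax]
        left = np.take(padded, np.arange(0, n_ax), axis=sp_ax)
        right = np.take(padded, np.arange(2, n_ax + 2), axis=sp_ax)
        neigh += left + right
    p_m = (1.0 - 2.0 * d * m) * p + m * neigh

    w = p_m * np.exp(grid.selection_map)
    p_sel = w / (w + (1.0 - p_m))
    return rng.binomial(K, p_sel)


def _target_established(state: np.ndarray, grid: SimGrid) -> np.ndarray:
    """A-frequency within the target patch > 0.5, per batched replicate."""
    counts = state[..., grid.target_mask] if state.ndim > grid.model.d \
        else state[grid.target_mask]
    total = grid.deme_size * grid.n_target_demes
    return counts.sum(axis=-1) / total > 0.5


@dataclass(frozen=True)
class EstablishmentEstimate:
    """Binomial establishment estimate from single-mutant replicates.

    ``outcomes`` and ``generations`` record each replicate's fate
    ("established" / "extinct" / "timed_out") and finishing generation
    (-1 when timed out).
    """

    estimate: float
    se: float
    n_established: int
    n_extinct: int
    n_timed_out: int
    replicates: int
    origin_r: float
    outcomes: np.ndarray
    generations: np.ndarray


def run_establishment_replicates(
    grid: SimGrid,
    origin_r: float,
    replicates: int,
    seed: int,
    max_gen: int = 2000,
) -> EstablishmentEstimate:
    """Estimate u_d(origin_r) by releasing one A copy per replicate.

    The copy is placed in the deme whose centre is nearest to distance
    ``origin_r`` from the target centre along axis 0.  Replicates end on
    establishment (target-patch frequency > 0.5) or global loss of A;
    those still segregating at ``max_gen`` are reported as timed out,
    never silently dropped.  Replicates are processed in fixed-size
    batches with seeds spawned per batch, so a given (seed, replicates)
    pair is bit-reproducible.
    """
    if grid.geometry is not None:
        raise ValueError("establishment replicates use a grid without a source patch")
    idx = [int(np.argmin(np.abs(grid.axes[0] - origin_r)))]
    for ax in range(1, grid.model.d):
        idx.append(int(np.argmin(np.abs(grid.axes[ax]))))
    origin_idx = tuple(idx)

    outcomes = np.full(replicates, "timed_out", dtype="<U11")
    generations = np.full(replicates, -1, dtype=np.int64)
    seeds = np.random.SeedSequence(seed).spawn(math.ceil(replicates / _BATCH))
    for b, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        B = min(_BATCH, replicates - b * _BATCH)
        ids = b * _BATCH + np.arange(B)
        state = np.zeros((B,) + grid.shape, dtype=np.int64)
        state[(slice(None),) + origin_idx] = 1
        for g in range(1, max_gen + 1):
            state = step(state, grid, rng)
            est = _target_established(state, grid)
            ext = state.sum(axis=tuple(range(1, state.ndim))) == 0
            outcomes[ids[est]] = "established"
            outcomes[ids[ext]] = "extinct"
            generations[ids[est | ext]] = g
            done = est | ext
            if done.all():
                break
            state, ids = state[~done], ids[~done]
    n_est = int((outcomes == "established").sum())
    n_ext = int((outcomes == "extinct").sum())
    n_timed = replicates - n_est - n_ext
    p_hat = n_est / replicates
    se = math.sqrt(max(p_hat * (1.0 - p_hat), 1e-300) / replicates)
    return EstablishmentEstimate(estimate=p_hat, se=se, n_established=n_est,
                                 n_extinct=n_ext, n_timed_out=n_timed,
                                 replicates=replicates, origin_r=origin_r,
                                 outcomes=outcomes, generations=generations)


@dataclass(frozen=True)
class WaitingTimeResult:
    """Waiting times until migration-driven establishment."""

    mean: float | None
    se: float | None
    generations: np.ndarray          # establishment generations only
    all_generations: np.ndarray      # per replicate, -1 when timed out
    outcomes: np.ndarray             # "established" | "timed_out" per replicate
    n_established: int
    n_timed_out: int
    n_source_lost: int
    replicates: int
    censored: bool = field(default=False)


def run_waiting_time(
    grid: SimGrid,
    replicates: int,
    seed: int,
    max_gen: int = 200_000,
    check_every: int = 1,
) -> WaitingTimeResult:
    """Generations until the target patch adapts, source initially fixed.

    No new mutation arises during a run; allele A enters the target only
    through immigrant lineages.  Replicates exceeding ``max_gen`` are
    timed out; the mean is reported only when at least 90% of replicates
    established (``censored=True`` otherwise).  Replicates in which the
    source patch itself loses the allele (frequency < 0.5) are counted as
    a diagnostic of swamping, which the theory assumes away.
    """
    if grid.geometry is None or grid.source_mask is None:
        raise ValueError("waiting-time runs need a grid with a source patch")
    src = grid.source_mask
    n_src_total = grid.deme_size * int(src.sum())

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    state = np.zeros((replicates,) + grid.shape, dtype=np.int64)
    state[..., src] = grid.deme_size

    gens = np.full(replicates, -1, dtype=np.int64)
    source_lost = np.zeros(replicates, dtype=bool)
    active = np.arange(replicates)
    for g in range(1, max_gen + 1):
        state = step(state, grid, rng)
        if g % check_every:
            continue
        est = _target_established(state, grid)
        source_lost[active] |= state[..., src].sum(axis=-1) / n_src_total < 0.5
        if est.any():
            gens[active[est]] = g
            state = state[~est]
            active = active[~est]
            if active.size == 0:
                break
    n_est = int((gens > 0).sum())
    n_timed = replicates - n_est
    established = gens[gens > 0].astype(float)
    outcomes = np.where(gens > 0, "established", "timed_out").astype("<U11")
    censored = n_est < 0.9 * replicates
    mean = se = None
    if not censored and n_est > 0:
        mean = float(established.mean())
        se = float(established.std(ddof=1) / math.sqrt(n_est)) if n_est > 1 else None
    return WaitingTimeResult(mean=mean, se=se, generations=established,
                             all_generations=gens, outcomes=outcomes,
                             n_established=n_est, n_timed_out=n_timed,
                             n_source_lost=int(source_lost.sum()),
                             replicates=replicates, censored=censored)


def sample_lineage_displacements(
    grid: SimGrid, n_lineages: int, generations: int, seed: int
) -> np.ndarray:
    """Displacements of neutral lineages after ``generations`` steps.

    Each lineage independently follows the lattice migration rule (step
    +-dx along each axis with probability m per direction).  Used to
    calibrate the simulator's dispersal against sigma2: the per-axis
    displacement variance should be sigma2 * generations.
    """
    rng = np.random.default_rng(seed)
    m = grid.m_neighbor
    steps = rng.choice(
        np.array([-1, 0, 1]),
        size=(generations, n_lineages, grid.model.d),
        p=[m, 1.0 - 2.0 * m, m],
    )
    return steps.sum(axis=0) * grid.dx_lattice
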