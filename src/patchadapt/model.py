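"""Physical parameters of the two-environment patch model.

A single biallelic locus A/a in a species spread at uniform density ``rho``
over d-dimensional continuous space (d = 1, 2, 3).  Allele A has log-fitness
advantage ``s1`` inside circular/spherical "environment 1" patches and
log-fitness cost ``-s2`` everywhere else.  Dispersal is Gaussian with
per-axis variance ``sigma2`` per generation.  Distances are measured in
units of the target-patch radius scale (the canonical choice is R = 1) and
time in generations; every rate in this package is per generation.

The decay of a deleterious allele's establishment probability with distance
is governed by ``beta2 = sqrt(2 s2 / sigma2)``; its inverse is the
characteristic spatial scale of the model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "SpatialModel",
    "make_model",
    "characteristic_scale",
    "haldane_baseline",
]


@dataclass(frozen=True)
class SpatialModel:
    """Validated parameter set shared by every other module.

    Attributes
    ----------
    d : int
        Spatial dimension, one of {1, 2, 3}.
    sigma2 : float
        Per-axis dispersal variance per generation (distance^2).
    s1 : float
        Log-fitness advantage of allele A in environment 1 (> 0).
    s2 : float
        Log-fitness cost of allele A in environment 2 (> 0).
    rho : float
        Population density (haploid individuals per unit d-volume).
    R : float
        Target-patch radius.
    ploidy : str
        "haploid" or "diploid".  Under additive fitness a diploid
        population behaves like a haploid one at twice the density, so
        ``effective_density`` is 2*rho for diploids.
    beta2 : float
        Derived decay constant sqrt(2 s2 / sigma2); cached here as the
        single source of truth for all modules.
    """

    d: int
    sigma2: float
    s1: float
    s2: float
    rho: float
    R: float
    ploidy: str = "haploid"
    beta2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.d not in (1, 2, 3):
            raise ValueError(f"d must be 1, 2 or 3, got {self.d!r}")
        for name in ("sigma2", "s1", "s2", "rho", "R"):
            val = getattr(self, name)
            if not (isinstance(val, (int, float)) and math.isfinite(val)):
                raise ValueError(f"{name} must be a finite number, got {val!r}")
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val!r}")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"ploidy must be 'haploid' or 'diploid', got {self.ploidy!r}")
        object.__setattr__(self, "beta2", math.sqrt(2.0 * self.s2 / self.sigma2))

    @property
    def effective_density(self) -> float:
        """Density entering every rate formula: rho, or 2*rho for diploids."""
        return 2.0 * self.rho if self.ploidy == "diploid" else float(self.rho)

    @property
    def length_scale(self) -> float:
        """Characteristic spatial scale 1/beta2."""
        return 1.0 / self.beta2

    def selection(self, r: float) -> float:
        """Piecewise selection coefficient s(r) around the target patch.

        s1 for r <= R (boundary counts as inside), -s2 for r > R.
        """
        return self.s1 if r <= self.R else -self.s2

    def dispersal_kernel(self, displacement) -> float:
        """Gaussian dispersal density for a d-vector parent-offspring offset.

        This is the kernel the stepping-stone simulator approximates:
        independent N(0, sigma2) displacement along each axis.
        """
        import numpy as np

        x = np.asarray(displacement, dtype=float)
        if x.shape[-1] != self.d:
            raise ValueError(f"displacement must have {self.d} components")
        norm = (2.0 * math.pi * self.sigma2) ** (self.d / 2.0)
        return np.exp(-np.sum(x * x, axis=-1) / (2.0 * self.sigma2)) / norm


def make_model(
    d: int,
    sigma2: float,
    s1: float,
    s2: float,
    rho: float,
    R: float,
    ploidy: str = "haploid",
) -> SpatialModel:
    """Validate raw parameters and return a :class:`SpatialModel`.

    Idempotent: passing the fields of a validated model back through
    reproduces an equal model.
    """
    if isinstance(d, float):
        if not d.is_integer():
            raise ValueError(f"d must be an integer, got {d!r}")
        d = int(d)
    return SpatialModel(d=d, sigma2=float(sigma2), s1=float(s1), s2=float(s2),
                        rho=float(rho), R=float(R), ploidy=ploidy)


def characteristic_scale(model: SpatialModel) -> tuple[float, float]:
    """Return (beta2, 1/beta2) with beta2 = sqrt(2 s2 / sigma2)."""
    return model.beta2, model.length_scale


def haldane_baseline(s1: float) -> float:
    """Establishment probability 2*s1 of a uniformly advantageous mutation.

    The classic branching-process result for weak selection; it is the
    interior plateau of the spatial establishment profile when the patch
    is much wider than 1/beta2.
    """
    if s1 < 0:
        raise ValueError(f"s1 must be >= 0, got {s1!r}")
    if s1 > 0.1:
        warnings.warn(
            f"s1={s1} is large; the weak-selection 2*s1 approximation degrades",
            stacklevel=2,
        )
    return 2.0 * s1
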