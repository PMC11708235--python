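"""Shared fixtures: the four benchmark parameter sets and cached solves.

The four (sigma2, s2) combinations span strong/weak selection against
strong/weak dispersal; s1 = 0.05, R = 1 and rho = 216 throughout, the
conditions under which every downstream quantity is validated.
"""

from __future__ import annotations

import functools

import pytest

from patchadapt.model import make_model
from patchadapt.profile import GridControl, solve_establishment

PARAM_SETS = {
    "a": (0.001, 0.005),
    "b": (0.005, 0.005),
    "c": (0.001, 0.001),
    "d": (0.005, 0.001),
}

S1 = 0.05
RHO = 216.0
R = 1.0


@functools.lru_cache(maxsize=None)
def model_for(set_name: str, d: int, rho: float = RHO):
    sigma2, s2 = PARAM_SETS[set_name]
    return make_model(d=d, sigma2=sigma2, s1=S1, s2=s2, rho=rho, R=R)


@functools.lru_cache(maxsize=None)
def profile_for(set_name: str, d: int, rho: float = RHO,
                refine: int = 400, trunc_mult: float = 20.0):
    return solve_establishment(
        model_for(set_name, d, rho),
        GridControl(refine=refine, trunc_mult=trunc_mult))


@pytest.fixture(scope="session")
def fig_sets():
    return PARAM_SETS
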