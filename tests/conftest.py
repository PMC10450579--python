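"""Shared fixtures: random model generators and reference protocols."""

import math

import numpy as np
import pytest

from doubledrug import (DoubleDrugModel, ITCProtocol, SiteAffinities,
                        StateEnsemble)


def random_model(rng: np.random.Generator, allow_inf: bool = True,
                 allow_coupling: bool = True) -> DoubleDrugModel:
    """A random two-state linkage model with log-uniform parameters.

    Each ligand binds at least one state; with ``allow_inf`` a state may be
    a non-binder (Kd = inf).
    """

    def affinities() -> SiteAffinities:
        kds = 10.0 ** rng.uniform(-1, 5, size=2)
        if allow_inf and rng.random() < 0.3:
            kds[rng.integers(2)] = math.inf
        return SiteAffinities(kd_active=kds[0], kd_inactive=kds[1])

    couplings = (10.0 ** rng.uniform(-1, 1, size=2) if allow_coupling
                 else np.ones(2))
    return DoubleDrugModel(
        ensemble=StateEnsemble(10.0 ** rng.uniform(-3, 3)),
        orthosteric=affinities(),
        allosteric=affinities(),
        coupling_active=float(couplings[0]),
        coupling_inactive=float(couplings[1]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def itc_protocol() -> ITCProtocol:
    """The reference direct-titration schedule: 200 uL cell at 5 uM,
    50 uM syringe, 25 x 2 uL injections."""
    return ITCProtocol.uniform(200.0, 5.0, 50.0, 25, 2.0)


@pytest.fixture
def mb1_like_model() -> DoubleDrugModel:
    """Inactive-exclusive orthosteric + inactive-exclusive allosteric ligand
    on a 40 %-active ensemble: the minimal positively cooperative pair."""
    return DoubleDrugModel(
        ensemble=StateEnsemble(0.67),
        orthosteric=SiteAffinities(kd_active=math.inf, kd_inactive=10.0),
        allosteric=SiteAffinities(kd_active=math.inf, kd_inactive=100.0),
    )
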