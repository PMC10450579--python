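"""Two-state conformational-selection linkage thermodynamics.

A kinase is modelled as an equilibrium between one *active* (open) and one
*inactive* (closed) conformation, with two independent ligand sites: an
orthosteric (ATP-site) ligand and an allosteric modulator.  Each ligand has a
state-specific dissociation constant, so binding shifts the conformational
ensemble and the two ligands become thermodynamically coupled even though
they never touch.  This module computes species populations, apparent
(ensemble-averaged) dissociation constants and the cooperativity factor
``alpha`` between the two sites.

Conventions
-----------
* ``k_eq`` is the unliganded active/inactive population ratio
  (``k_eq = 0.67`` means 40 % active).
* Concentrations are in nM and are *free* concentrations unless noted;
  mass-balance conversion to totals lives in :func:`free_concentrations`.
* ``math.inf`` for a dissociation constant means "does not bind that state";
  ``math.inf`` for a partner concentration means the exact saturation limit,
  evaluated analytically rather than as a large number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "NonBinderError",
    "StateEnsemble",
    "SiteAffinities",
    "DoubleDrugModel",
    "SpeciesDistribution",
    "CooperativityResult",
    "statistical_weights",
    "fraction_active",
    "site_occupancy",
    "apparent_kd",
    "cooperativity_factor",
    "free_concentrations",
]

Site = Literal["orthosteric", "allosteric"]

#: relative tolerance used to call a cooperativity factor "none" (alpha == 1)
ALPHA_NONE_RTOL = 1e-6


class DomainError(ValueError):
    """An input is outside the physical domain (e.g. negative concentration)."""


class NonBinderError(ValueError):
    """The ligand binds neither conformational state, so no finite
    half-saturation concentration exists."""


def _inv(kd: float) -> float:
    """1/kd with the convention 1/inf == 0 (non-binder contributes nothing)."""
    return 0.0 if math.isinf(kd) else 1.0 / kd


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateEnsemble:
    """Unliganded two-state ensemble.

    Parameters
    ----------
    k_eq : float
        Active/inactive population ratio of the apo protein.  Must be a
        finite positive number.
    """

    k_eq: float

    def __post_init__(self) -> None:
        if not (self.k_eq > 0 and math.isfinite(self.k_eq)):
            raise DomainError(f"k_eq must be positive and finite, got {self.k_eq}")

    @property
    def fraction_active_apo(self) -> float:
        return self.k_eq / (1.0 + self.k_eq)


@dataclass(frozen=True)
class SiteAffinities:
    """State-specific dissociation constants (nM) of one ligand.

    ``math.inf`` encodes "does not bind that state".
    """

    kd_active: float
    kd_inactive: float

    def __post_init__(self) -> None:
        for name in ("kd_active", "kd_inactive"):
            v = getattr(self, name)
            if not (v > 0):  # inf is allowed
                raise DomainError(f"{name} must be > 0, got {v}")

    @property
    def binds_nothing(self) -> bool:
        return math.isinf(self.kd_active) and math.isinf(self.kd_inactive)


@dataclass(frozen=True)
class DoubleDrugModel:
    """Two-state ensemble plus the state-specific affinities of an
    orthosteric and an allosteric ligand.

    ``coupling_active`` / ``coupling_inactive`` are dimensionless factors
    multiplying the statistical weight of the doubly-bound species within
    each state.  With both couplings equal to 1 (the default used when
    constructing from bare affinities) all cooperativity arises purely from
    the conformational-selection ensemble shift; a coupling different from 1
    encodes direct intrastate interaction between the two bound ligands.
    """

    ensemble: StateEnsemble
    orthosteric: SiteAffinities
    allosteric: SiteAffinities
    coupling_active: float = 1.0
    coupling_inactive: float = 1.0

    def __post_init__(self) -> None:
        for name in ("coupling_active", "coupling_inactive"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise DomainError(f"{name} must be finite and >= 0, got {v}")

    def site(self, which: Site) -> SiteAffinities:
        if which == "orthosteric":
            return self.orthosteric
        if which == "allosteric":
            return self.allosteric
        raise ValueError(f"unknown site {which!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "DoubleDrugModel":
        """Build from the flat key-value parameter document.

        Recognised keys: ``k_eq``, ``kd_o_active``, ``kd_o_inactive``,
        ``kd_a_active``, ``kd_a_inactive``, ``coupling_active``,
        ``coupling_inactive`` (concentrations in nM; the string ``"inf"`` or
        a missing kd key encodes a non-binding state).
        """
        known = {"k_eq", "kd_o_active", "kd_o_inactive", "kd_a_active",
                 "kd_a_inactive", "coupling_active", "coupling_inactive"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")

        def kd(key: str) -> float:
            v = d.get(key, math.inf)
            if isinstance(v, str):
                v = float(v)
            return float(v)

        return cls(
            ensemble=StateEnsemble(float(d["k_eq"])),
            orthosteric=SiteAffinities(kd("kd_o_active"), kd("kd_o_inactive")),
            allosteric=SiteAffinities(kd("kd_a_active"), kd("kd_a_inactive")),
            coupling_active=float(d.get("coupling_active", 1.0)),
            coupling_inactive=float(d.get("coupling_inactive", 1.0)),
        )

    def to_dict(self) -> dict:
        def enc(v: float):
            return "inf" if math.isinf(v) else v

        return {
            "k_eq": self.ensemble.k_eq,
            "kd_o_active": enc(self.orthosteric.kd_active),
            "kd_o_inactive": enc(self.orthosteric.kd_inactive),
            "kd_a_active": enc(self.allosteric.kd_active),
            "kd_a_inactive": enc(self.allosteric.kd_inactive),
            "coupling_active": self.coupling_active,
            "coupling_inactive": self.coupling_inactive,
        }


@dataclass(frozen=True)
class SpeciesDistribution:
    """Populations of the 8 species: 2 states x O bound/free x A bound/free.

    ``populations[state, o, a]`` with state index 0 = inactive, 1 = active and
    o/a index 0 = site empty, 1 = site occupied.  Populations are fractions
    summing to 1.
    """

    populations: np.ndarray = field(repr=False)

    INACTIVE = 0
    ACTIVE = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.populations, dtype=float)
        if p.shape != (2, 2, 2):
            raise ValueError("populations must have shape (2, 2, 2)")
        object.__setattr__(self, "populations", p)

    @property
    def fraction_active(self) -> float:
        return float(self.populations[self.ACTIVE].sum())

    @property
    def occupancy_orthosteric(self) -> float:
        return float(self.populations[:, 1, :].sum())

    @property
    def occupancy_allosteric(self) -> float:
        return float(self.populations[:, :, 1].sum())

    def __getitem__(self, idx) -> float:
        return float(self.populations[idx])


@dataclass(frozen=True)
class CooperativityResult:
    """Fold-change ``alpha`` of a site's apparent Kd on partner saturation.

    ``alpha = Kd_app(partner absent) / Kd_app(partner saturating)``; values
    above 1 mean the partner tightens binding (positive cooperativity), below
    1 that it weakens binding (negative cooperativity).  The fold quoted for
    a negative pair is ``1/alpha``.
    """

    alpha: float
    direction: Literal["positive", "negative", "none"]

    @property
    def fold(self) -> float:
        """The cooperativity magnitude as a fold >= 1."""
        return self.alpha if self.alpha >= 1 else 1.0 / self.alpha


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def _raw_weights(model: DoubleDrugModel, free_o: float, free_a: float) -> np.ndarray:
    """Unnormalised statistical weights of the 8 species.

    Relative to inactive-apo == 1: the active state carries ``k_eq``; each
    bound ligand multiplies its state's weight by ``free/kd_state``; the
    doubly-bound species additionally carries the state's coupling factor.
    """
    if free_o < 0 or free_a < 0:
        raise DomainError("free ligand concentrations must be >= 0")
    w = np.empty((2, 2, 2))
    state_w = {SpeciesDistribution.INACTIVE: 1.0,
               SpeciesDistribution.ACTIVE: model.ensemble.k_eq}
    kd_o = {SpeciesDistribution.INACTIVE: model.orthosteric.kd_inactive,
            SpeciesDistribution.ACTIVE: model.orthosteric.kd_active}
    kd_a = {SpeciesDistribution.INACTIVE: model.allosteric.kd_inactive,
            SpeciesDistribution.ACTIVE: model.allosteric.kd_active}
    coupling = {SpeciesDistribution.INACTIVE: model.coupling_inactive,
                SpeciesDistribution.ACTIVE: model.coupling_active}
    for s in (0, 1):
        ro = free_o * _inv(kd_o[s])
        ra = free_a * _inv(kd_a[s])
        w[s, 0, 0] = state_w[s]
        w[s, 1, 0] = state_w[s] * ro
        w[s, 0, 1] = state_w[s] * ra
        w[s, 1, 1] = state_w[s] * ro * ra * coupling[s]
    return w


def statistical_weights(model: DoubleDrugModel, free_o: float,
                        free_a: float) -> SpeciesDistribution:
    """Equilibrium populations of the 8 species at given *free* ligand
    concentrations (nM)."""
    w = _raw_weights(model, free_o, free_a)
    return SpeciesDistribution(w / w.sum())


def fraction_active(model: DoubleDrugModel, free_o: float, free_a: float) -> float:
    """Total population of the active conformation."""
    return statistical_weights(model, free_o, free_a).fraction_active


def site_occupancy(model: DoubleDrugModel, site: Site, free_self: float,
                   free_partner: float) -> float:
    """Fractional occupancy of ``site`` at free ligand concentrations."""
    if site == "orthosteric":
        return statistical_weights(model, free_self, free_partner).occupancy_orthosteric
    return statistical_weights(model, free_partner, free_self).occupancy_allosteric


# ---------------------------------------------------------------------------
# Apparent Kd and cooperativity
# ---------------------------------------------------------------------------

def _branch_sums(model: DoubleDrugModel, site: Site,
                 partner_free: float) -> tuple[float, float]:
    """Return (N, D) such that apparent Kd of ``site`` = N/D.

    N is the partition-function branch with the site empty, D the
    site-occupied branch divided by the site ligand's free concentration;
    half-occupancy occurs at free = N/D.  ``partner_free = inf`` is taken as
    the analytic saturation limit (only partner-bound species survive).
    """
    k_eq = model.ensemble.k_eq
    state_w = (1.0, k_eq)  # (inactive, active)
    own = model.site(site)
    partner = model.site("allosteric" if site == "orthosteric" else "orthosteric")
    own_kd = (own.kd_inactive, own.kd_active)
    partner_kd = (partner.kd_inactive, partner.kd_active)
    coupling = (model.coupling_inactive, model.coupling_active)

    if math.isinf(partner_free):
        if partner.binds_nothing:
            # partner never binds: saturation is the same as absence
            return _branch_sums(model, site, 0.0)
        n = sum(w * _inv(pk) for w, pk in zip(state_w, partner_kd))
        d = sum(w * c * _inv(pk) * _inv(ok)
                for w, c, pk, ok in zip(state_w, coupling, partner_kd, own_kd))
        return n, d

    n = sum(w * (1.0 + partner_free * _inv(pk))
            for w, pk in zip(state_w, partner_kd))
    d = sum(w * _inv(ok) * (1.0 + c * partner_free * _inv(pk))
            for w, ok, c, pk in zip(state_w, own_kd, coupling, partner_kd))
    return n, d


def apparent_kd(model: DoubleDrugModel, site: Site, partner_free: float) -> float:
    """Apparent dissociation constant (nM) of one site's ligand.

    The free concentration of the site's ligand at which its fractional
    occupancy is 1/2, with the partner site's *free* ligand concentration
    held fixed.  ``partner_free=math.inf`` evaluates the exact saturation
    limit.  Returns ``math.inf`` when partner saturation makes binding
    impossible (mutually exclusive limit).
    """
    if model.site(site).binds_nothing:
        raise NonBinderError(f"{site} ligand binds neither state")
    if not math.isinf(partner_free) and partner_free < 0:
        raise DomainError("partner_free must be >= 0")
    n, d = _branch_sums(model, site, partner_free)
    if d == 0.0:
        return math.inf
    return n / d


def apparent_kd_numeric(model: DoubleDrugModel, site: Site,
                        partner_free: float) -> float:
    """Apparent Kd found as the numeric root of occupancy(free) = 1/2.

    Root-finding cross-check for :func:`apparent_kd`; bisection bracket is
    ``[kd_min * 1e-6, kd_max * 1e6]`` over the site ligand's finite
    state Kds.
    """
    own = model.site(site)
    if own.binds_nothing:
        raise NonBinderError(f"{site} ligand binds neither state")
    finite = [kd for kd in (own.kd_active, own.kd_inactive) if math.isfinite(kd)]
    lo, hi = min(finite) * 1e-6, max(finite) * 1e6

    if math.isinf(partner_free):
        # saturated-partner ensemble: restrict weights to partner-bound branch
        n, d = _branch_sums(model, site, partner_free)
        if d == 0.0:
            return math.inf

        def occ(free: float) -> float:
            return free * d / (n + free * d)
    else:
        def occ(free: float) -> float:
            return site_occupancy(model, site, free, partner_free)

    f = lambda x: occ(x) - 0.5
    if f(hi) < 0:
        return math.inf
    return brentq(f, lo, hi, xtol=1e-300, rtol=1e-14)


def cooperativity_factor(model: DoubleDrugModel, site: Site) -> CooperativityResult:
    """Cooperativity factor between the two sites, measured at ``site``.

    ``alpha = Kd_app(partner absent) / Kd_app(partner saturating)``.  By
    thermodynamic-cycle closure the result is identical whichever site it is
    measured at.
    """
    for which in ("orthosteric", "allosteric"):
        if model.site(which).binds_nothing:
            raise NonBinderError(
                f"cooperativity undefined: {which} ligand binds neither state")
    kd0 = apparent_kd(model, site, 0.0)
    kd_sat = apparent_kd(model, site, math.inf)
    alpha = 0.0 if math.isinf(kd_sat) else kd0 / kd_sat
    if abs(alpha - 1.0) <= ALPHA_NONE_RTOL:
        direction = "none"
    elif alpha > 1.0:
        direction = "positive"
    else:
        direction = "negative"
    return CooperativityResult(alpha=alpha, direction=direction)


# ---------------------------------------------------------------------------
# Mass balance: totals -> free concentrations
# ---------------------------------------------------------------------------

def free_concentrations(model: DoubleDrugModel, o_total: float, a_total: float,
                        e_total: float, rtol: float = 1e-12) -> tuple[float, float]:
    """Free (o, a) ligand concentrations from totals at enzyme ``e_total``.

    Solves the two-ligand mass balance ``free + e_total * occupancy = total``
    exactly (nested Brent bracketing), handling ligand depletion at assay
    enzyme concentrations.  All concentrations in nM.
    """
    if min(o_total, a_total, e_total) < 0 or e_total == 0:
        raise DomainError("totals must be >= 0 and e_total > 0")

    def free_o_given(fa: float) -> float:
        if o_total == 0:
            return 0.0

        def g(fo: float) -> float:
            occ = statistical_weights(model, fo, fa).occupancy_orthosteric
            return fo + e_total * occ - o_total

        if g(o_total) <= 0:  # no measurable binding
            return o_total
        return brentq(g, 0.0, o_total, xtol=1e-300, rtol=1e-15)

    if a_total == 0:
        return free_o_given(0.0), 0.0

    def h(fa: float) -> float:
        fo = free_o_given(fa)
        occ = statistical_weights(model, fo, fa).occupancy_allosteric
        return fa + e_total * occ - a_total

    if h(a_total) <= 0:
        fa = a_total
    else:
        fa = brentq(h, 0.0, a_total, xtol=1e-300, rtol=1e-15)
    return free_o_given(fa), fa
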