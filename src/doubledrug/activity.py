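"""Catalytic activity, dose-response and synergy analysis.

Maps the two-state linkage ensemble onto observed catalytic rates measured
under kcat/Km conditions (substrate far below Km, so the rate is proportional
to the concentration of catalytically competent enzyme).  Each of the 8
linkage species carries a catalytic weight in [0, 1]; by default only
active-state species with an empty orthosteric site turn over — the inactive
(closing-competent) conformation is catalytically silent and an orthosteric
ligand occludes the active site, while an allosteric ligand bound to the
active state leaves activity untouched.

On top of the rate model: inhibition curves over dose grids, four-parameter
logistic (4PL) fits, IC50 and dose-for-residual-activity inversion, and
orthosteric x allosteric synergy grids with per-level dose-reduction factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .binding import TitrationCurve
from .fitting import FitError, FitResult, least_squares
from .linkage import (DomainError, DoubleDrugModel, Site, free_concentrations,
                      statistical_weights)

__all__ = [
    "UnreachableResidualError",
    "ActivityModel",
    "DoseResponse4PL",
    "SynergyGrid",
    "default_species_weights",
    "k_obs",
    "inhibition_curve",
    "fit_4pl",
    "conc_at_residual",
    "synergy_grid",
]

#: enzyme concentration (nM) of the coupled and ADP-detection kinase assays
ASSAY_ENZYME_NM = 20.0


class UnreachableResidualError(ValueError):
    """The requested residual activity lies outside the curve's plateaus
    (e.g. a partial inhibitor whose floor is above the 10 % target)."""


def default_species_weights() -> np.ndarray:
    """Catalytic weights for the 8 species, indexed [state, o, a] like
    :class:`~doubledrug.linkage.SpeciesDistribution`: active-state species
    with an empty orthosteric site are fully competent, everything else is
    silent."""
    w = np.zeros((2, 2, 2))
    w[1, 0, :] = 1.0
    return w


@dataclass(frozen=True)
class ActivityModel:
    """Linkage model plus catalytic parameters.

    ``k_max`` (min^-1) is the rate of a fully active, uninhibited ensemble;
    ``species_weights[state, o, a]`` scales each species' contribution.
    """

    linkage: DoubleDrugModel
    k_max: float = 1.0
    species_weights: np.ndarray = field(default_factory=default_species_weights,
                                        repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.species_weights, dtype=float)
        if w.shape != (2, 2, 2):
            raise ValueError("species_weights must have shape (2, 2, 2)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("species_weights must lie in [0, 1]")
        if self.k_max < 0:
            raise DomainError("k_max must be >= 0")
        object.__setattr__(self, "species_weights", w)


@dataclass(frozen=True)
class DoseResponse4PL:
    """Four-parameter logistic dose response
    ``y = bottom + (top - bottom) / (1 + (x/ic50)^hill)``.

    The (top, bottom, hill) <-> (bottom, top, -hill) symmetry describes the
    same curve; :meth:`canonical` resolves it to ``hill > 0``, under which a
    descending inhibition curve always has ``top >= bottom`` (``top`` is the
    zero-dose value).
    """

    top: float
    bottom: float
    ic50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise DomainError("ic50 must be > 0")
        if self.hill == 0:
            raise DomainError("hill must be nonzero")

    def canonical(self) -> "DoseResponse4PL":
        if self.hill < 0:
            return DoseResponse4PL(top=self.bottom, bottom=self.top,
                                   ic50=self.ic50, hill=-self.hill)
        return self

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, (x / self.ic50) ** self.hill,
                             0.0 if self.hill > 0 else np.inf)
        y = self.bottom + (self.top - self.bottom) / (1.0 + ratio)
        return float(y) if y.ndim == 0 else y

    @property
    def max_inhibition_percent(self) -> float:
        """Maximal inhibition at saturating dose, % of the top plateau."""
        return 100.0 * (1.0 - self.bottom / self.top)


@dataclass(frozen=True)
class SynergyGrid:
    """k_obs over an orthosteric x allosteric dose grid.

    ``k_obs_matrix[i, j]`` is the rate at ``a_grid[i]``, ``o_grid[j]``.
    ``dose_for_residual[i]`` is the orthosteric dose reaching the residual
    target (relative to that row's own zero-orthosteric rate; NaN when the
    row cannot reach it), and ``fold_reduction[i]`` its ratio to the
    zero-allosteric row's dose.
    """

    o_grid: np.ndarray
    a_grid: np.ndarray
    k_obs_matrix: np.ndarray
    residual_fraction: float = 0.1
    dose_for_residual: np.ndarray | None = None
    fold_reduction: np.ndarray | None = None

    def to_long_frame(self):
        """Long-format table (o_nM, a_nM, k_obs) for CSV export."""
        import pandas as pd

        a, o = np.meshgrid(self.a_grid, self.o_grid, indexing="ij")
        return pd.DataFrame({"o_nM": o.ravel(), "a_nM": a.ravel(),
                             "k_obs": self.k_obs_matrix.ravel()})

    def summary(self) -> dict:
        return {
            "residual_fraction": self.residual_fraction,
            "a_nM": list(map(float, self.a_grid)),
            "dose_for_residual_nM": [None if not math.isfinite(v) else float(v)
                                     for v in self.dose_for_residual],
            "fold_reduction": [None if not math.isfinite(v) else float(v)
                               for v in self.fold_reduction],
        }


# ---------------------------------------------------------------------------
# Observed rate
# ---------------------------------------------------------------------------

def k_obs(model: ActivityModel, o_total: float, a_total: float,
          e_total: float = ASSAY_ENZYME_NM) -> float:
    """Observed rate at total inhibitor concentrations (nM).

    Free ligand concentrations come from the exact mass balance at the assay
    enzyme concentration, then
    ``k_obs = k_max * sum(species_weight * population)``.
    """
    free_o, free_a = free_concentrations(model.linkage, o_total, a_total, e_total)
    pops = statistical_weights(model.linkage, free_o, free_a).populations
    return model.k_max * float(np.sum(model.species_weights * pops))


def inhibition_curve(model: ActivityModel, site: Site,
                     conc_grid: Sequence[float], partner_conc: float = 0.0,
                     e_total: float = ASSAY_ENZYME_NM) -> TitrationCurve:
    """k_obs along a dose grid of one inhibitor, the partner held fixed."""
    grid = np.asarray(conc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    if site == "orthosteric":
        rates = [k_obs(model, c, partner_conc, e_total) for c in grid]
    else:
        rates = [k_obs(model, partner_conc, c, e_total) for c in grid]
    return TitrationCurve(grid, np.array(rates))


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

def fit_4pl(doses: Sequence[float], responses: Sequence[float],
            init: DoseResponse4PL | None = None) -> tuple[DoseResponse4PL, FitResult]:
    """Least-squares four-parameter logistic fit.

    Needs >= 5 points.  The returned parameters are canonicalised to
    ``hill > 0, top >= bottom``.  If the dose range leaves either plateau
    unresolved (no datum within 20 % of it) the fit result carries a flag
    message rather than failing.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 5:
        raise FitError("need at least 5 matched dose/response points")
    if np.any(x < 0):
        raise DomainError("doses must be >= 0")

    if init is None:
        top0, bot0 = float(np.max(y)), float(np.min(y))
        if top0 == bot0:
            raise FitError("flat response: nothing to fit")
        mid = 0.5 * (top0 + bot0)
        pos = x[x > 0]
        idx = int(np.argmin(np.abs(y - mid)))
        ic0 = float(x[idx]) if x[idx] > 0 else float(np.sqrt(pos[0] * pos[-1]))
        init = DoseResponse4PL(top=top0, bottom=bot0, ic50=ic0, hill=1.0)

    yscale = float(np.max(np.abs(y))) + 1e-12

    def objective(p: dict) -> np.ndarray:
        model = DoseResponse4PL(top=p["top"], bottom=p["bottom"],
                                ic50=max(p["ic50"], 1e-12), hill=p["hill"])
        return model(x) - y

    result = least_squares(
        objective,
        {"top": init.top, "bottom": init.bottom, "ic50": init.ic50,
         "hill": init.hill},
        {"top": (-10 * yscale, 10 * yscale),
         "bottom": (-10 * yscale, 10 * yscale),
         "ic50": (1e-9, 1e12), "hill": (-10.0, 10.0)})
    params = DoseResponse4PL(top=result.params["top"],
                             bottom=result.params["bottom"],
                             ic50=result.params["ic50"],
                             hill=result.params["hill"]).canonical()
    result.params.update(top=params.top, bottom=params.bottom,
                         ic50=params.ic50, hill=params.hill)
    span = params.top - params.bottom
    if span > 0:
        if np.min(y) > params.bottom + 0.2 * span:
            result.messages.append("bottom plateau unresolved by the dose range")
        if np.max(y) < params.top - 0.2 * span:
            result.messages.append("top plateau unresolved by the dose range")
    pos = x[x > 0]
    if pos.size and not (pos.min() <= params.ic50 <= pos.max()):
        result.messages.append(
            "fitted ic50 outside the dose range: plateaus unresolved")
    magnitude = max(abs(params.top), abs(params.bottom))
    if magnitude > 0 and span < 0.05 * magnitude:
        result.messages.append(
            "fitted transition is <5 % of the response magnitude: curve is "
            "flat over this dose range, plateaus unresolved")
    return params, result


def conc_at_residual(params: DoseResponse4PL, r: float,
                     reference: float) -> float:
    """Dose at which activity falls to ``r * reference`` (e.g. r = 0.10 for
    the (drug)_10%-activity metric), by closed-form inversion of the 4PL.

    Raises :class:`UnreachableResidualError` when the target lies outside
    the open interval (bottom, top) — a partial inhibitor whose saturating
    plateau sits above the target can never reach it.
    """
    if not (0.0 < r < 1.0):
        raise DomainError("residual fraction must lie in (0, 1)")
    p = params.canonical()
    y = r * reference
    if not (p.bottom < y < p.top):
        raise UnreachableResidualError(
            f"target activity {y:.4g} outside the fitted plateaus "
            f"({p.bottom:.4g}, {p.top:.4g})")
    return p.ic50 * ((p.top - p.bottom) / (y - p.bottom) - 1.0) ** (1.0 / p.hill)


# ---------------------------------------------------------------------------
# Synergy grid
# ---------------------------------------------------------------------------

def synergy_grid(model: ActivityModel, o_grid: Sequence[float],
                 a_grid: Sequence[float], residual: float = 0.1,
                 e_total: float = ASSAY_ENZYME_NM) -> SynergyGrid:
    """k_obs matrix over orthosteric x allosteric doses with dose-reduction.

    For each allosteric level, the orthosteric dose reaching ``residual``
    of that row's own uninhibited rate is read from a 4PL fit of the row;
    its ratio to the zero-allosteric requirement is the fold dose-reduction
    delivered by the allosteric partner.  Rows that cannot reach the target
    (plateau above it) report NaN rather than erroring.
    """
    o = np.asarray(o_grid, dtype=float)
    a = np.asarray(a_grid, dtype=float)
    if o.size == 0 or a.size == 0:
        raise ValueError("grids must be non-empty")
    matrix = np.array([[k_obs(model, oc, ac, e_total) for oc in o] for ac in a])

    doses = np.full(a.size, np.nan)
    if o.size >= 5:
        for i, ac in enumerate(a):
            reference = k_obs(model, 0.0, ac, e_total)
            try:
                params, _ = fit_4pl(o, matrix[i])
                doses[i] = conc_at_residual(params, residual, reference)
            except (UnreachableResidualError, FitError):
                continue
    baseline = doses[np.argmin(a)] if a.min() == 0 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = baseline / doses
    return SynergyGrid(o_grid=o, a_grid=a, k_obs_matrix=matrix,
                       residual_fraction=residual, dose_for_residual=doses,
                       fold_reduction=fold)
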