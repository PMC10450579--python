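"""Forward models and fitters for equilibrium binding readouts.

Covers the two binding experiments used to characterise orthosteric /
allosteric ligand pairs on kinases:

* isothermal titration calorimetry (ITC), both direct one-site titrations
  and competitive-replacement titrations in which a too-tight ligand is
  titrated into protein pre-loaded with a weak same-site competitor
  (e.g. an ADP analogue for the ATP site, or a myristoylated peptide for
  the myristoyl pocket);
* tryptophan-FRET saturation titrations at low (10 nM) enzyme, fitted with
  the tight-binding (Morrison) quadratic because ligand depletion is not
  negligible at that enzyme concentration.

Units: instrument heats in uJ, enthalpies in kJ/mol, cell/syringe
concentrations in uM, ligand Kds in nM, volumes in uL.  Conversions are
centralised here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .fitting import FitError, FitResult, least_squares
from .linkage import DomainError

__all__ = [
    "IdentifiabilityWarning",
    "ITCProtocol",
    "ITCOnesiteParams",
    "CompetitionScheme",
    "ITCThermogram",
    "FretParams",
    "TitrationCurve",
    "bound_complex",
    "free_concentrations_competitive",
    "apparent_kd_competitive",
    "simulate_itc",
    "fit_itc_onesite",
    "fret_signal",
    "fit_fret",
]

#: heat unit factor: kJ/mol * uL * uM  ->  uJ
_HEAT_UJ = 1e-3
#: uM per nM
_NM_TO_UM = 1e-3


class IdentifiabilityWarning(UserWarning):
    """The fitted regime barely constrains a parameter (e.g. a titration in
    the stoichiometric, step-function regime)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCProtocol:
    """Injection schedule of a titration.

    cell_volume uL, cell_conc (titrand) uM, syringe_conc (titrant) uM,
    injection_volumes uL, temperature K.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if min(self.cell_volume, self.cell_conc, self.syringe_conc,
               self.temperature) <= 0 or any(v <= 0 for v in vols):
            raise DomainError("ITC protocol values must all be positive")
        if len(vols) < 5:
            raise DomainError("need at least 5 injections")

    @classmethod
    def uniform(cls, cell_volume: float, cell_conc: float, syringe_conc: float,
                n_injections: int, injection_volume: float = 2.0,
                temperature: float = 298.15) -> "ITCProtocol":
        return cls(cell_volume, cell_conc, syringe_conc,
                   tuple([injection_volume] * n_injections), temperature)


@dataclass(frozen=True)
class ITCOnesiteParams:
    """One-site binding parameters: kd nM, dh kJ/mol, stoichiometry n,
    per-injection background heat q_offset uJ."""

    kd: float
    dh: float
    n: float = 1.0
    q_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.kd > 0 and self.n > 0):
            raise DomainError("kd and n must be positive")


@dataclass(frozen=True)
class CompetitionScheme:
    """Weak same-site competitor pre-loaded in the cell for competitive
    replacement: kd_weak uM, dh_weak kJ/mol, competitor_total uM."""

    kd_weak: float
    dh_weak: float
    competitor_total: float

    def __post_init__(self) -> None:
        if self.kd_weak < 0 or self.competitor_total < 0:
            raise DomainError("competition scheme concentrations must be >= 0")


@dataclass(frozen=True)
class ITCThermogram:
    """Integrated per-injection heats (uJ).  ``discard_first`` marks the
    customary exclusion of the first (diffusion-compromised) injection from
    fitting."""

    heats: np.ndarray = field(repr=False)
    discard_first: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", np.asarray(self.heats, dtype=float))

    def usable(self) -> np.ndarray:
        return self.heats[1:] if self.discard_first else self.heats

    def __len__(self) -> int:
        return len(self.heats)


@dataclass(frozen=True)
class FretParams:
    """Quadratic-binding fluorescence parameters: baseline f0 (a.u.),
    amplitude amp (a.u., sign free), enzyme e_total nM, kd nM."""

    f0: float
    amp: float
    e_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.e_total <= 0:
            raise DomainError("e_total must be > 0")
        if self.kd <= 0:
            raise DomainError("kd must be > 0")


@dataclass(frozen=True)
class TitrationCurve:
    """A dose axis (total ligand, nM) with a measured signal."""

    ligand_total: np.ndarray = field(repr=False)
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.ligand_total, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("ligand_total and signal must be equal-length 1-D")
        if x.size == 0:
            raise ValueError("empty titration curve")
        if np.any(x < 0) or np.any(np.diff(x) <= 0):
            raise ValueError("concentrations must be non-negative and "
                             "strictly increasing")
        object.__setattr__(self, "ligand_total", x)
        object.__setattr__(self, "signal", y)

    def __len__(self) -> int:
        return self.ligand_total.size


# ---------------------------------------------------------------------------
# Mass-balance solvers
# ---------------------------------------------------------------------------

def bound_complex(p_total: float, l_total: float, kd: float) -> float:
    """Equilibrium [PL] for one protein + one ligand (tight-binding quadratic).

    Uses the numerically stable form 2PL/(b + sqrt(b^2 - 4PL)) of
    ``((P+L+K) - sqrt((P+L+K)^2 - 4PL))/2``; exact at any depletion level and
    never exceeds min(P, L).  Any consistent concentration unit.
    """
    if p_total < 0 or l_total < 0 or kd < 0:
        raise DomainError("concentrations and kd must be >= 0")
    if p_total == 0 or l_total == 0:
        return 0.0
    b = p_total + l_total + kd
    disc = b * b - 4.0 * p_total * l_total
    return 2.0 * p_total * l_total / (b + math.sqrt(max(disc, 0.0)))


def free_concentrations_competitive(p_total: float, l_total: float,
                                    c_total: float, kd_l: float,
                                    kd_c: float) -> tuple[float, float, float]:
    """Free (P, L, C) for two ligands competing for one protein site.

    Solves the coupled mass balance (a cubic in free protein) on the unique
    physical branch; with ``c_total == 0`` it reduces exactly to the one-ligand
    quadratic.  Complexes are ``p*l/kd_l`` and ``p*c/kd_c``.
    """
    if min(p_total, l_total, c_total, kd_l, kd_c) < 0:
        raise DomainError("all inputs must be >= 0")
    if c_total == 0.0:
        pl = bound_complex(p_total, l_total, kd_l)
        return p_total - pl, l_total - pl, 0.0
    if p_total == 0.0:
        return 0.0, l_total, c_total
    if l_total == 0.0:
        pc = bound_complex(p_total, c_total, kd_c)
        return p_total - pc, 0.0, c_total - pc

    def l_of(p: float) -> float:
        return l_total / (1.0 + p / kd_l)

    def c_of(p: float) -> float:
        return c_total / (1.0 + p / kd_c)

    def f(p: float) -> float:
        return p * (1.0 + l_of(p) / kd_l + c_of(p) / kd_c) - p_total

    p = brentq(f, 0.0, p_total, xtol=1e-300, rtol=1e-15)
    # one Newton polish step towards machine precision
    eps = p * 1e-7 + 1e-30
    deriv = (f(p + eps) - f(p - eps)) / (2 * eps)
    if deriv > 0:
        p = min(max(p - f(p) / deriv, 0.0), p_total)
    l, c = l_of(p), c_of(p)
    if not (0 <= l <= l_total and 0 <= c <= c_total):
        raise FitError("competitive mass balance found no physical root")
    return p, l, c


def apparent_kd_competitive(kd_strong: float, kd_weak: float,
                            competitor_free: float) -> float:
    """Apparent Kd of a tight ligand in the presence of a same-site
    competitor: ``kd_strong * (1 + competitor_free / kd_weak)``.

    The analytic (excess-competitor) limit of the full cubic mass balance;
    agreement is within ~1 % once the competitor exceeds the protein ~50-fold.
    """
    if min(kd_strong, kd_weak, competitor_free) < 0:
        raise DomainError("all inputs must be >= 0")
    if competitor_free == 0.0:
        return kd_strong
    return kd_strong * (1.0 + competitor_free / kd_weak)


# ---------------------------------------------------------------------------
# ITC forward model
# ---------------------------------------------------------------------------

def simulate_itc(protocol: ITCProtocol, params: ITCOnesiteParams,
                 scheme: CompetitionScheme | None = None) -> ITCThermogram:
    """Noise-free thermogram for a (possibly competitive) one-site titration.

    Overfilled-cell convention: all injected material stays thermally
    reported, so each injection grows the working volume by v and dilutes
    every concentration accordingly, and the heat of injection i is the
    enthalpy times the change in *moles* of complex,
    ``q_i = dh * ([PL]_i V_i - [PL]_{i-1} V_{i-1})`` (plus the analogous
    weak-competitor displacement term under a competition scheme) plus
    ``q_offset``.  Because complex moles telescope, the cumulative heat at
    titrant excess converges exactly to ``n * dh * V0 * cell_conc``.
    """
    kd_um = params.kd * _NM_TO_UM
    vol = protocol.cell_volume       # working volume, uL
    p = protocol.cell_conc           # total protein, uM
    x = 0.0                          # total titrant, uM
    c = scheme.competitor_total if scheme else 0.0
    pl_prev = 0.0                    # complex amounts as conc * volume (pmol)
    pc_prev = 0.0
    if scheme:
        pc_prev = bound_complex(params.n * p, c, scheme.kd_weak) * vol
    heats = []
    for v in protocol.injection_volumes:
        new_vol = vol + v
        p *= vol / new_vol
        c *= vol / new_vol
        x = (x * vol + protocol.syringe_conc * v) / new_vol
        vol = new_vol
        sites = params.n * p
        if scheme:
            _, free_l, free_c = free_concentrations_competitive(
                sites, x, c, kd_um, scheme.kd_weak)
            pl = (x - free_l) * vol
            pc = (c - free_c) * vol
        else:
            pl = bound_complex(sites, x, kd_um) * vol
            pc = 0.0
        q = params.dh * (pl - pl_prev) * _HEAT_UJ + params.q_offset
        if scheme:
            q += scheme.dh_weak * (pc - pc_prev) * _HEAT_UJ
        heats.append(q)
        pl_prev, pc_prev = pl, pc
    return ITCThermogram(np.array(heats))


# ---------------------------------------------------------------------------
# ITC fitting
# ---------------------------------------------------------------------------

def _itc_init_heuristic(thermogram: ITCThermogram,
                        protocol: ITCProtocol) -> ITCOnesiteParams:
    """Crude starting values: dh from the early plateau heats, n from the
    molar ratio at the half-heat inflection, kd at c ~ 20."""
    q = thermogram.usable()
    v = np.array(protocol.injection_volumes[1:] if thermogram.discard_first
                 else protocol.injection_volumes)
    dq_mol = q / (protocol.syringe_conc * v * _HEAT_UJ * 1.0)
    dh0 = float(np.sign(np.sum(q)) * np.max(np.abs(dq_mol)))
    if dh0 == 0:
        dh0 = -10.0
    # molar ratio grid (ignoring dilution, adequate for a start)
    titrant = protocol.syringe_conc * np.cumsum(v) / protocol.cell_volume
    ratio = titrant / protocol.cell_conc
    cum = np.cumsum(q)
    half = 0.5 * cum[-1]
    idx = int(np.argmin(np.abs(cum - half)))
    n0 = float(np.clip(ratio[idx] * 2.0 if ratio[idx] > 0 else 1.0, 0.2, 5.0))
    kd0 = protocol.cell_conc / 20.0 / _NM_TO_UM  # nM
    return ITCOnesiteParams(kd=kd0, dh=dh0, n=n0, q_offset=0.0)


def fit_itc_onesite(thermogram: ITCThermogram, protocol: ITCProtocol,
                    init: ITCOnesiteParams | None = None,
                    fix: Sequence[str] = ()) -> FitResult:
    """Least-squares fit of the one-site model (independent-sites fit).

    The first injection is excluded when the thermogram is flagged
    ``discard_first``.  Parameter names in ``fix`` (subset of
    ``kd, dh, n, q_offset``) are held at their init values.  The fit is
    flagged (not failed) when the Wiseman c-value ``n*cell_conc/kd`` falls
    outside [1, 1e4], where the isotherm shape barely constrains kd.
    """
    q_obs = thermogram.usable()
    if q_obs.size < 5:
        raise FitError("need at least 5 usable injections")
    if float(np.std(q_obs)) < 1e-12 and abs(float(np.mean(q_obs))) < 1e-12:
        raise FitError("all-zero heats: no binding signal to fit")
    if init is None:
        init = _itc_init_heuristic(thermogram, protocol)

    skip = 1 if thermogram.discard_first else 0
    all_names = ("kd", "dh", "n", "q_offset")
    init_vals = {"kd": init.kd, "dh": init.dh, "n": init.n,
                 "q_offset": init.q_offset}
    varying = {k: v for k, v in init_vals.items() if k not in fix}
    fixed = {k: v for k, v in init_vals.items() if k in fix}

    def objective(p: dict) -> np.ndarray:
        try:
            model = simulate_itc(protocol, ITCOnesiteParams(
                kd=p["kd"], dh=p["dh"], n=p["n"], q_offset=p["q_offset"]))
        except DomainError:
            return np.full(q_obs.size, 1e6)
        return model.heats[skip:] - q_obs

    bounds = {"kd": (1e-4, 1e10), "dh": (-1e4, 1e4), "n": (0.05, 20.0),
              "q_offset": (-1e6, 1e6)}
    result = least_squares(objective, varying,
                           {k: bounds[k] for k in varying}, fixed)
    for k, v in fixed.items():
        result.params[k] = v
        result.stderr[k] = 0.0
        result.ci68[k] = (v, v)
    c_value = result.params["n"] * protocol.cell_conc / (
        result.params["kd"] * _NM_TO_UM)
    if not (1.0 <= c_value <= 1e4):
        result.messages.append(
            f"c-value {c_value:.3g} outside [1, 1e4]: kd poorly identified")
    return result


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

def fret_signal(i_conc, params: FretParams):
    """Tight-binding quadratic fluorescence model.

    ``F = F0 + A * ((I+Et+Kd) - sqrt((I+Et+Kd)^2 - 4*Et*I)) / (2*Et)``,
    i.e. baseline plus amplitude times the bound fraction of enzyme, with
    ligand depletion at the working enzyme concentration handled exactly.
    Accepts a scalar or array of total ligand concentrations I (nM).
    """
    i_arr = np.asarray(i_conc, dtype=float)
    if np.any(i_arr < 0):
        raise DomainError("ligand concentration must be >= 0")
    et, kd = params.e_total, params.kd
    b = i_arr + et + kd
    disc = np.maximum(b * b - 4.0 * et * i_arr, 0.0)
    bound = (b - np.sqrt(disc)) / 2.0
    out = params.f0 + params.amp * bound / et
    return float(out) if np.isscalar(i_conc) else out


def fit_fret(curve: TitrationCurve, e_total: float,
             init: FretParams | None = None) -> FitResult:
    """Fit F0, amplitude and Kd of the quadratic binding model (Et fixed).

    Requires >= 6 points.  A fitted Kd far below Et is flagged as
    near-stoichiometric: in that regime the curve approaches a step function
    and the data barely distinguish Kd values (a tighter-Kd simulation looks
    the same), so the estimate is an upper bound rather than a measurement.
    """
    if len(curve) < 6:
        raise FitError("need at least 6 titration points")
    if e_total <= 0:
        raise DomainError("e_total must be > 0")
    y = curve.signal
    if init is None:
        amp0 = float(y[-1] - y[0]) or 1.0
        half = y[0] + 0.5 * amp0
        idx = int(np.argmin(np.abs(y - half)))
        kd0 = float(max(curve.ligand_total[idx], e_total / 2))
        init = FretParams(f0=float(y[0]), amp=amp0, e_total=e_total, kd=kd0)

    def objective(p: dict) -> np.ndarray:
        fp = FretParams(f0=p["f0"], amp=p["amp"], e_total=e_total,
                        kd=max(p["kd"], 1e-12))
        return fret_signal(curve.ligand_total, fp) - y

    span = float(np.max(np.abs(y))) + 1.0
    result = least_squares(
        objective,
        {"f0": init.f0, "amp": init.amp, "kd": init.kd},
        {"f0": (-10 * span, 10 * span), "amp": (-10 * span, 10 * span),
         "kd": (1e-6, 1e9)})
    if result.params["kd"] < e_total / 2:
        msg = (f"fitted Kd {result.params['kd']:.3g} nM << Et {e_total:g} nM: "
               "near-stoichiometric (step-function) regime, Kd weakly identified")
        result.messages.append(msg)
        warnings.warn(msg, IdentifiabilityWarning)
    return result
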