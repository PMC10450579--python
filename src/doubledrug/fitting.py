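"""Shared estimation machinery.

Nonlinear least squares (via lmfit/Levenberg-Marquardt) with standard errors
and 68.3 % confidence intervals from the linearised covariance, leave-one-out
jackknife errors, and global multi-condition fits of the two-state linkage
model to apparent-Kd observations.

Error conventions: binding-fit uncertainties are reported as the 68.3 % CI
(+-1 SE) from the fit covariance; quantities derived from inhibition curves
use the jackknife.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import lmfit
import numpy as np

from .linkage import DoubleDrugModel, SiteAffinities, StateEnsemble, apparent_kd

__all__ = [
    "FitError",
    "IdentifiabilityError",
    "FitResult",
    "JackknifeResult",
    "least_squares",
    "jackknife",
    "global_linkage_fit",
]

#: multistart restarts drawn log-uniformly over the bounds when the first
#: attempt fails to converge; fixed seed keeps fits deterministic
MULTISTART_COUNT = 5
MULTISTART_SEED = 20230814


class FitError(RuntimeError):
    """A fit failed to converge or the input is degenerate."""


class IdentifiabilityError(ValueError):
    """The requested parameter map is not identifiable from the data."""


@dataclass
class FitResult:
    """Point estimates with linearised-covariance uncertainties.

    ``ci68`` maps each parameter to ``(lo, hi)`` with half-width equal to one
    standard error (the 68.3 % level of a normal approximation).
    """

    params: dict[str, float]
    stderr: dict[str, float]
    ci68: dict[str, tuple[float, float]]
    residual: np.ndarray
    converged: bool
    objective: float
    n_used: int
    messages: list[str] = dataclasses.field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def report(self) -> dict:
        """JSON-serialisable fit report."""
        return {
            "params": self.params,
            "se": self.stderr,
            "ci68": {k: list(v) for k, v in self.ci68.items()},
            "converged": self.converged,
            "objective": self.objective,
            "n_used": self.n_used,
            "messages": self.messages,
        }


@dataclass
class JackknifeResult:
    """Leave-one-out resampling errors for a fitted quantity."""

    estimate: np.ndarray
    loo_estimates: np.ndarray
    stderr: np.ndarray
    bias: np.ndarray
    n_points: int
    failed: list[int] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Generic least squares
# ---------------------------------------------------------------------------

def _to_lmfit_params(init: Mapping[str, float],
                     bounds: Mapping[str, tuple[float, float]] | None,
                     fixed: Mapping[str, float] | None = None) -> lmfit.Parameters:
    p = lmfit.Parameters()
    bounds = bounds or {}
    for name, value in init.items():
        lo, hi = bounds.get(name, (-math.inf, math.inf))
        p.add(name, value=float(value), min=lo, max=hi)
    for name, value in (fixed or {}).items():
        p.add(name, value=float(value), vary=False)
    return p


def _result_from_minimizer(out: lmfit.minimizer.MinimizerResult,
                           names: Sequence[str]) -> FitResult:
    params = {n: float(out.params[n].value) for n in names}
    resid = np.atleast_1d(np.asarray(out.residual, dtype=float))
    ssr = float(np.sum(resid ** 2))
    stderr = {}
    for n in names:
        se = out.params[n].stderr
        if se is None:
            # perfect fits leave no residual to scale the covariance
            se = 0.0 if ssr <= 1e-24 * max(1.0, len(resid)) else math.nan
        stderr[n] = float(se)
    ci68 = {n: (params[n] - stderr[n], params[n] + stderr[n])
            if math.isfinite(stderr[n]) else (math.nan, math.nan)
            for n in names}
    return FitResult(
        params=params,
        stderr=stderr,
        ci68=ci68,
        residual=resid,
        converged=bool(out.success),
        objective=ssr,
        n_used=int(resid.size),
    )


def least_squares(objective: Callable[[dict[str, float]], np.ndarray],
                  init: Mapping[str, float],
                  bounds: Mapping[str, tuple[float, float]] | None = None,
                  fixed: Mapping[str, float] | None = None) -> FitResult:
    """Minimise ``sum(objective(params)**2)`` over the named parameters.

    ``objective`` receives a dict of parameter values (varying and fixed) and
    returns a residual vector.  On non-convergence the fit is restarted from
    ``MULTISTART_COUNT`` points drawn log-uniformly over the bounds (fixed
    seed, so results are deterministic); if every start fails a
    :class:`FitError` carrying diagnostics is raised.
    """
    names = list(init)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        vals = {k: float(v.value) for k, v in p.items()}
        return np.asarray(objective(vals), dtype=float).ravel()

    def attempt(start: Mapping[str, float]) -> lmfit.minimizer.MinimizerResult:
        p = _to_lmfit_params(start, bounds, fixed)
        return lmfit.minimize(residual, p, method="leastsq")

    try:
        out = attempt(init)
        if out.success and np.all(np.isfinite(out.residual)):
            return _result_from_minimizer(out, names)
    except Exception:
        out = None

    rng = np.random.default_rng(MULTISTART_SEED)
    failures: list[str] = [] if out is None else [str(out.message)]
    best = None
    for _ in range(MULTISTART_COUNT):
        start = {}
        for n in names:
            lo, hi = (bounds or {}).get(n, (math.nan, math.nan))
            if math.isfinite(lo) and math.isfinite(hi) and lo > 0:
                start[n] = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            elif math.isfinite(lo) and math.isfinite(hi):
                start[n] = rng.uniform(lo, hi)
            else:
                start[n] = init[n] * (1 + rng.standard_normal() * 0.3)
        try:
            out = attempt(start)
        except Exception as exc:  # singular Jacobians etc.
            failures.append(str(exc))
            continue
        if out.success and np.all(np.isfinite(out.residual)):
            ssr = float(np.sum(np.asarray(out.residual) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, out)
        else:
            failures.append(str(out.message))
    if best is not None:
        return _result_from_minimizer(best[1], names)
    raise FitError("least_squares failed to converge after multistart; "
                   f"diagnostics: {failures}")


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

def _delete_one(dataset, i: int):
    if isinstance(dataset, tuple):
        return tuple(np.delete(np.asarray(a), i, axis=0) for a in dataset)
    return np.delete(np.asarray(dataset), i, axis=0)


def jackknife(fit_fn: Callable, dataset) -> JackknifeResult:
    """Leave-one-out standard error of ``fit_fn(dataset)``.

    ``dataset`` is an array of points (first axis) or a tuple of parallel
    arrays such as ``(x, y)``; ``fit_fn`` returns a scalar or 1-D parameter
    vector.  The jackknife SE is
    ``sqrt((n-1)/n * sum((theta_i - theta_bar)**2))`` over the leave-one-out
    estimates; failed refits are tolerated only if at least ``n-1`` succeed.
    """
    n = len(dataset[0]) if isinstance(dataset, tuple) else len(dataset)
    if n < 3:
        raise ValueError("jackknife needs at least 3 points")

    full = np.atleast_1d(np.asarray(fit_fn(dataset), dtype=float))
    loo, failed = [], []
    for i in range(n):
        try:
            est = np.atleast_1d(np.asarray(fit_fn(_delete_one(dataset, i)),
                                           dtype=float))
            if not np.all(np.isfinite(est)):
                raise FitError("non-finite leave-one-out estimate")
            loo.append(est)
        except Exception:
            failed.append(i)
    if len(loo) < n - 1:
        raise FitError(f"jackknife: {len(failed)} leave-one-out refits failed "
                       f"(indices {failed})")
    loo_arr = np.vstack(loo)
    m = loo_arr.shape[0]
    mean = loo_arr.mean(axis=0)
    se = np.sqrt((m - 1) / m * np.sum((loo_arr - mean) ** 2, axis=0))
    bias = (m - 1) * (mean - full)
    return JackknifeResult(estimate=full, loo_estimates=loo_arr, stderr=se,
                           bias=bias, n_points=n, failed=failed)


# ---------------------------------------------------------------------------
# Global linkage fit
# ---------------------------------------------------------------------------

#: model fields that may float in a global fit (all strictly positive)
_LINKAGE_FIELDS = ("k_eq", "kd_o_active", "kd_o_inactive", "kd_a_active",
                   "kd_a_inactive", "coupling_active", "coupling_inactive")


def _model_with(template: DoubleDrugModel, overrides: Mapping[str, float]) -> DoubleDrugModel:
    d = template.to_dict()
    d.update(overrides)
    k_eq = float(d["k_eq"])

    def kd(key):
        v = d[key]
        return math.inf if v == "inf" else float(v)

    return DoubleDrugModel(
        ensemble=StateEnsemble(k_eq),
        orthosteric=SiteAffinities(kd("kd_o_active"), kd("kd_o_inactive")),
        allosteric=SiteAffinities(kd("kd_a_active"), kd("kd_a_inactive")),
        coupling_active=float(d["coupling_active"]),
        coupling_inactive=float(d["coupling_inactive"]),
    )


def global_linkage_fit(observations: Sequence[Mapping],
                       template: DoubleDrugModel,
                       free: Sequence[str],
                       init: Mapping[str, float] | None = None) -> FitResult:
    """Jointly fit linkage parameters to apparent-Kd observations.

    Each observation is a mapping with keys ``site`` ("orthosteric" or
    "allosteric"), ``partner_free`` (nM, ``math.inf`` for a
    partner-saturated condition) and ``kd_app`` (nM).  ``free`` names the
    template fields allowed to float (e.g. ``["kd_a_inactive",
    "coupling_inactive"]``); everything else is held at its template value —
    the usual analysis pattern being a shared inactive-state affinity across
    apo and partner-saturated conditions with ``k_eq`` fixed.

    Residuals are relative (log-space), so conditions with very different
    absolute Kds weigh equally.  Raises :class:`IdentifiabilityError` when
    the map cannot be determined: fewer observations than free parameters,
    or a single condition asked to constrain state-resolved quantities.
    """
    free = list(free)
    unknown = set(free) - set(_LINKAGE_FIELDS)
    if unknown:
        raise ValueError(f"unknown linkage fields: {sorted(unknown)}")
    if len(observations) < len(free):
        raise IdentifiabilityError(
            f"{len(free)} free parameters but only {len(observations)} observations")
    conditions = {(o["site"], float(o["partner_free"])) for o in observations}
    if len(conditions) < 2 and len(free) >= 2:
        raise IdentifiabilityError(
            "a single titration condition cannot constrain more than one "
            "linkage parameter; provide apo and partner-saturated conditions")

    obs_kd = np.array([float(o["kd_app"]) for o in observations])
    if np.any(~np.isfinite(obs_kd)) or np.any(obs_kd <= 0):
        raise ValueError("observed apparent Kds must be finite and positive")

    template_vals = template.to_dict()
    start = {}
    for name in free:
        if init and name in init:
            start[name] = float(init[name])
        else:
            v = template_vals[name]
            start[name] = 1.0 if v == "inf" else float(v)

    def objective(p: dict[str, float]) -> np.ndarray:
        model = _model_with(template, {k: p[k] for k in free})
        pred = np.array([apparent_kd(model, o["site"], float(o["partner_free"]))
                         for o in observations])
        if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
            return np.full(len(observations), 1e6)
        return np.log(pred) - np.log(obs_kd)

    bounds = {name: (1e-9, 1e9) for name in free}
    return least_squares(objective, start, bounds)
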