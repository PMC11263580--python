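"""Weighted nonlinear estimation of the model parameters from data tables.

All fitters minimise a chi-square weighted by per-point standard errors
(1/sem^2), work in log-parameter space so positivity is structural, and use
a seeded multi-start over log-uniform boxes so results are deterministic
given the seed.  Ties between equally good minima are broken toward the
smallest dissociation constant, and the tie-break is recorded in the result.

Fitters
-------
- :func:`fit_low_pressure`    — pre-plateau window, f = 1/tau2 → (k, P_c, k_on)
- :func:`fit_pressure_sweep`  — global fit of f(C, P) over several
  concentrations → (k_on_pore, k_off_clog, Kd_clog) shared across curves
- :func:`fit_concentration_sweep` — fixed pressure, varying concentration →
  (k_off_clog, Kd_clog), with k_on supplied or co-fitted
- :func:`fit_clog_dynamics`   — exponential contrast transient → t_clog
- :func:`fit_suction`         — DNA probe curve → (f_suc, P_suc)
- :func:`collapse_metric`     — RMS distance of master-curve points from y = x
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import lmfit
import numpy as np

from .clog import ClogTrace, SuctionParams, dna_frequency
from .curves import FrequencyCurve
from .errors import (
    FitConvergenceError,
    InsufficientDataError,
    InvalidParameterError,
    UnidentifiableError,
)
from .jamming import (
    JammingParams,
    MasterCurvePoint,
    critical_pressure,
    frequency_grid,
    kon_from_critical_pressure,
)
from .physics import FluidEnv, PoreGeometry

_LN10 = math.log(10.0)


@dataclass
class FitResult:
    """Outcome of one weighted fit.

    ``estimates``/``stderrs`` are on the physical (linear) scale.  ``derived``
    carries composite quantities (critical pressure, prefactor, on-rate) that
    are functions of the estimates, never independently fitted.
    """

    estimates: dict[str, float]
    stderrs: dict[str, float | None]
    chi2: float
    ndata: int
    nvarys: int
    success: bool
    message: str
    fixed: dict[str, float] = field(default_factory=dict)
    derived: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    covariance: np.ndarray | None = None
    tie_break: str | None = None

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.ndata - self.nvarys, 1)
        return self.chi2 / dof


def _multistart(
    residual: Callable[[dict[str, float]], np.ndarray],
    log_bounds: dict[str, tuple[float, float]],
    init: dict[str, float],
    n_starts: int,
    seed: int,
) -> tuple[lmfit.minimizer.MinimizerResult, str | None]:
    """Seeded multi-start least squares over log10-parameter boxes.

    The first start uses the data-driven initial guess; the rest are drawn
    log-uniform inside the boxes.  Among minima whose chi-square agree to one
    part in 1e6, the smallest dissociation constant (``log_Kd``) wins.
    """
    rng = np.random.default_rng(seed)
    names = list(log_bounds)

    def _residual_lm(params: lmfit.Parameters) -> np.ndarray:
        values = {n: 10.0 ** params[n].value for n in names}
        return residual(values)

    best: lmfit.minimizer.MinimizerResult | None = None
    tie_break = None
    for i in range(n_starts):
        params = lmfit.Parameters()
        for n in names:
            lo, hi = log_bounds[n]
            if i == 0:
                v = math.log10(init[n])
                v = min(max(v, lo), hi)
            else:
                v = rng.uniform(lo, hi)
            params.add(n, value=v, min=lo, max=hi)
        try:
            res = lmfit.minimize(_residual_lm, params, method="least_squares")
        except Exception:
            continue
        if not np.isfinite(res.chisqr):
            continue
        if best is None or res.chisqr < best.chisqr * (1.0 - 1e-6):
            best = res
            tie_break = None
        elif res.chisqr <= best.chisqr * (1.0 + 1e-6):
            # chi-square tie: prefer the smaller dissociation constant
            if "log_Kd" in names and res.params["log_Kd"].value < best.params["log_Kd"].value:
                best = res
                tie_break = "smallest Kd_clog among tied minima"
    if best is None:
        raise FitConvergenceError("no multi-start attempt converged")
    return best, tie_break


def _linear_scale(res: lmfit.minimizer.MinimizerResult, names: Sequence[str]) -> tuple[dict, dict]:
    estimates, stderrs = {}, {}
    for n in names:
        p = res.params[n]
        value = 10.0 ** p.value
        estimates[n.removeprefix("log_")] = value
        stderrs[n.removeprefix("log_")] = (
            value * _LN10 * p.stderr if p.stderr is not None else None
        )
    return estimates, stderrs


def low_pressure_window(curve: FrequencyCurve) -> np.ndarray:
    """Boolean mask of the pre-plateau window.

    The plateau is estimated per concentration as the mean frequency of the
    three highest pressures; points below half that estimate are kept.
    """
    mask = np.zeros(len(curve), dtype=bool)
    d = curve.data
    for _, idx in d.groupby("concentration").groups.items():
        sub = d.loc[idx].sort_values("pressure")
        plateau = sub["frequency"].tail(3).mean()
        mask[np.asarray(idx)] = d.loc[idx, "frequency"] < 0.5 * plateau
    return mask


def fit_low_pressure(
    curve: FrequencyCurve,
    geom: PoreGeometry,
    fluid: FluidEnv,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit the pre-plateau branch with f = 1/tau2 = k (P/P_c) exp(-P_c/P).

    Extracts the critical pressure and, through the geometry, the wall
    on-rate.  The prefactor is parametrised per unit concentration so curves
    at several concentrations share both parameters.
    """
    mask = low_pressure_window(curve)
    sub = curve.subset(mask)
    if len(sub) < 4:
        raise InsufficientDataError(
            f"low-pressure window holds {len(sub)} points; need >= 4"
        )
    P, C, f, sem = sub.pressures, sub.concentrations, sub.frequencies, sub.sems
    C_ref = float(np.max(C))

    def residual(v: dict[str, float]) -> np.ndarray:
        model = v["kappa"] * C * (P / v["Pc"]) * np.exp(-v["Pc"] / P)
        return (model - f) / sem

    # data-driven init: Pc near the lowest usable pressure, kappa from the
    # highest-pressure point assuming the linear regime
    i_hi = int(np.argmax(P))
    Pc0 = max(float(np.min(P)), 1e-3)
    kappa0 = max(f[i_hi] / (C[i_hi] * P[i_hi] / Pc0), 1e-300)
    bounds = {
        "log_Pc": (math.log10(Pc0) - 3.0, math.log10(float(np.max(P)) * 10.0)),
        "log_kappa": (math.log10(kappa0) - 4.0, math.log10(kappa0) + 4.0),
    }
    res, tie = _multistart(
        lambda v: residual({"Pc": v["log_Pc"], "kappa": v["log_kappa"]}),
        bounds,
        {"log_Pc": Pc0, "log_kappa": kappa0},
        n_starts,
        seed,
    )
    estimates, stderrs = _linear_scale(res, ["log_Pc", "log_kappa"])
    Pc = estimates["Pc"]
    k = estimates["kappa"] * C_ref
    kon = kon_from_critical_pressure(Pc, geom, fluid)
    return FitResult(
        estimates={"Pc": Pc, "k": k},
        stderrs={"Pc": stderrs["Pc"], "k": None},
        chi2=float(res.chisqr),
        ndata=len(sub),
        nvarys=2,
        success=bool(res.success),
        message=str(res.message),
        derived={"kon_pore": kon, "C_ref": C_ref},
        seed=seed,
        covariance=getattr(res, "covar", None),
        tie_break=tie,
    )


def fit_pressure_sweep(
    curve: FrequencyCurve,
    geom: PoreGeometry,
    fluid: FluidEnv,
    n_starts: int = 8,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
) -> FitResult:
    """Global fit of f(C, P) with (k_on, k_off, Kd) shared across all curves.

    ``fixed`` may pin any of ``kon_pore``/``koff_clog``/``Kd_clog`` (used by
    the entry/transit separability analysis).
    """
    fixed = dict(fixed or {})
    d = curve.data
    n_conc = d["concentration"].nunique()
    if n_conc < 2 and not fixed:
        raise InsufficientDataError(
            f"global fit needs >= 2 concentrations, got {n_conc}"
        )
    if (d.groupby("concentration")["pressure"].count() < 4).any():
        raise InsufficientDataError("each concentration needs >= 4 pressures")
    P, C, f, sem = curve.pressures, curve.concentrations, curve.frequencies, curve.sems

    free = [p for p in ("kon_pore", "koff_clog", "Kd_clog") if p not in fixed]
    if not free:
        raise InvalidParameterError("at least one parameter must be free")

    def model(values: dict[str, float]) -> np.ndarray:
        params = JammingParams(**{**fixed, **values})
        return frequency_grid(params, P, C, geom, fluid)

    def residual(values: dict[str, float]) -> np.ndarray:
        return (model(values) - f) / sem

    # data-driven inits: plateau of highest concentration ~ 1/tau1 ~ koff;
    # Pc from the low-pressure shape is bracketed broadly instead.
    f_plateau = float(d[d["concentration"] == d["concentration"].max()]
                      .nlargest(3, "pressure")["frequency"].mean())
    init_all = {
        "kon_pore": kon_from_critical_pressure(
            max(0.1 * float(np.median(P)), 1e-6), geom, fluid
        ),
        "koff_clog": max(f_plateau, 1e-12),
        "Kd_clog": float(np.median(C)),
    }
    bounds_all = {
        "kon_pore": (init_all["kon_pore"] / 1e4, init_all["kon_pore"] * 1e4),
        "koff_clog": (init_all["koff_clog"] / 1e4, init_all["koff_clog"] * 1e4),
        "Kd_clog": (float(np.min(C)) / 1e4, float(np.max(C)) * 1e4),
    }
    name_map = {"kon_pore": "log_kon", "koff_clog": "log_koff", "Kd_clog": "log_Kd"}
    log_bounds = {
        name_map[p]: (math.log10(bounds_all[p][0]), math.log10(bounds_all[p][1]))
        for p in free
    }
    init = {name_map[p]: init_all[p] for p in free}
    inv_map = {v: k for k, v in name_map.items()}
    res, tie = _multistart(
        lambda v: residual({inv_map[n]: x for n, x in v.items()}),
        log_bounds,
        init,
        n_starts,
        seed,
    )
    est_log, se_log = _linear_scale(res, list(log_bounds))
    estimates = {inv_map[f"log_{k}"]: v for k, v in est_log.items()}
    stderrs = {inv_map[f"log_{k}"]: v for k, v in se_log.items()}
    full = {**fixed, **estimates}
    params = JammingParams(**full)
    at_bound = []
    for n, (lo, hi) in log_bounds.items():
        v = res.params[n].value
        if v - lo < 1e-3 or hi - v < 1e-3:
            at_bound.append(inv_map[n])
    message = str(res.message)
    if at_bound:
        message += f" [parameters at bound: {at_bound}]"
    return FitResult(
        estimates=estimates,
        stderrs=stderrs,
        chi2=float(res.chisqr),
        ndata=len(curve),
        nvarys=len(free),
        success=bool(res.success) and not at_bound,
        message=message,
        fixed=fixed,
        derived={"Pc": critical_pressure(params, geom, fluid)},
        seed=seed,
        covariance=getattr(res, "covar", None),
        tie_break=tie,
    )


def fit_concentration_sweep(
    curve: FrequencyCurve,
    geom: PoreGeometry,
    fluid: FluidEnv,
    kon_fixed: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit a fixed-pressure concentration sweep for (k_off_clog, Kd_clog).

    The wall on-rate is supplied (typically from :func:`fit_low_pressure`)
    or co-fitted when ``kon_fixed`` is None.  A concentration grid that never
    approaches the fitted dissociation constant leaves it unidentifiable,
    which is raised explicitly.
    """
    d = curve.data
    if d["concentration"].nunique() < 5:
        raise InsufficientDataError("need >= 5 distinct concentrations")
    if d["pressure"].nunique() != 1:
        raise InvalidParameterError("concentration sweep must be at a single pressure")
    fixed = {} if kon_fixed is None else {"kon_pore": kon_fixed}
    result = _sweep_for_concentration(curve, geom, fluid, n_starts, seed, fixed)
    Kd_hat = result.estimates.get("Kd_clog", result.fixed.get("Kd_clog"))
    if float(d["concentration"].max()) < Kd_hat / 10.0:
        raise UnidentifiableError(
            "all concentrations lie below Kd_clog/10; the dissociation "
            "constant is not identifiable from this design"
        )
    return result


def _sweep_for_concentration(curve, geom, fluid, n_starts, seed, fixed):
    # same objective as fit_pressure_sweep but without the >= 2 concentration
    # requirement (a concentration sweep has one curve, many concentrations)
    d = curve.data
    P, C, f, sem = curve.pressures, curve.concentrations, curve.frequencies, curve.sems
    free = [p for p in ("kon_pore", "koff_clog", "Kd_clog") if p not in fixed]

    def residual(values: dict[str, float]) -> np.ndarray:
        params = JammingParams(**{**fixed, **values})
        return (frequency_grid(params, P, C, geom, fluid) - f) / sem

    f_hi = float(d.nlargest(3, "concentration")["frequency"].mean())
    init_all = {
        "kon_pore": fixed.get("kon_pore", 0.5),
        "koff_clog": max(f_hi, 1e-12),
        "Kd_clog": float(np.median(C)),
    }
    bounds_all = {
        "kon_pore": (init_all["kon_pore"] / 1e4, init_all["kon_pore"] * 1e4),
        "koff_clog": (init_all["koff_clog"] / 1e4, init_all["koff_clog"] * 1e4),
        "Kd_clog": (float(np.min(C)) / 1e4, float(np.max(C)) * 1e4),
    }
    name_map = {"kon_pore": "log_kon", "koff_clog": "log_koff", "Kd_clog": "log_Kd"}
    inv_map = {v: k for k, v in name_map.items()}
    log_bounds = {
        name_map[p]: (math.log10(bounds_all[p][0]), math.log10(bounds_all[p][1]))
        for p in free
    }
    init = {name_map[p]: init_all[p] for p in free}
    res, tie = _multistart(
        lambda v: residual({inv_map[n]: x for n, x in v.items()}),
        log_bounds,
        init,
        n_starts,
        seed,
    )
    est_log, se_log = _linear_scale(res, list(log_bounds))
    estimates = {inv_map[f"log_{k}"]: v for k, v in est_log.items()}
    stderrs = {inv_map[f"log_{k}"]: v for k, v in se_log.items()}
    params = JammingParams(**{**fixed, **estimates})
    return FitResult(
        estimates=estimates,
        stderrs=stderrs,
        chi2=float(res.chisqr),
        ndata=len(curve),
        nvarys=len(free),
        success=bool(res.success),
        message=str(res.message),
        fixed=dict(fixed),
        derived={"Pc": critical_pressure(params, geom, fluid)},
        seed=seed,
        covariance=getattr(res, "covar", None),
        tie_break=tie,
    )


def fit_clog_dynamics(trace: ClogTrace, n_starts: int = 4, seed: int = 0) -> FitResult:
    """Least-squares fit of the contrast transient by exp(-t/t_clog)."""
    t = trace.times
    c = trace.contrast
    if len(t) < 6:
        raise InsufficientDataError(f"need >= 6 time points, got {len(t)}")
    if np.any(c < -0.2) or np.any(c > 1.2):
        raise InvalidParameterError("contrast outside the tolerated [-0.2, 1.2] band")
    # a trace that does not decay overall cannot be an exponential relaxation
    slope = np.polyfit(t, c, 1)[0]
    if slope >= 0:
        raise InvalidParameterError("non-decreasing trace: exponential fit rejected")

    def residual(v: dict[str, float]) -> np.ndarray:
        return np.exp(-t / v["t_clog"]) - c

    span = float(t[-1] - t[0])
    res, _ = _multistart(
        lambda v: residual({"t_clog": v["log_t"]}),
        {"log_t": (math.log10(span / 1e3), math.log10(span * 1e2))},
        {"log_t": span / 3.0},
        n_starts,
        seed,
    )
    est, se = _linear_scale(res, ["log_t"])
    return FitResult(
        estimates={"t_clog": est["t"]},
        stderrs={"t_clog": se["t"]},
        chi2=float(res.chisqr),
        ndata=len(t),
        nvarys=1,
        success=bool(res.success),
        message=str(res.message),
        seed=seed,
        covariance=getattr(res, "covar", None),
    )


def fit_suction(
    dna_curve: FrequencyCurve, n_starts: int = 8, seed: int = 0
) -> FitResult:
    """Fit a DNA-probe curve with the suction model → (f_suc, P_suc)."""
    if len(dna_curve) < 5:
        raise InsufficientDataError("need >= 5 pressures for the suction fit")
    P, f, sem = dna_curve.pressures, dna_curve.frequencies, dna_curve.sems

    def residual(v: dict[str, float]) -> np.ndarray:
        p = SuctionParams(f_suc=v["f_suc"], P_suc=v["P_suc"])
        model = np.array([dna_frequency(p, x) for x in P])
        return (model - f) / sem

    P_suc0 = float(np.median(P))
    f_pos = f[f > 0]
    f_suc0 = float(np.max(f_pos)) if f_pos.size else 1.0
    res, _ = _multistart(
        lambda v: residual({"f_suc": v["log_fsuc"], "P_suc": v["log_Psuc"]}),
        {
            "log_fsuc": (math.log10(f_suc0) - 4.0, math.log10(f_suc0) + 4.0),
            "log_Psuc": (
                math.log10(float(np.min(P))) - 2.0,
                math.log10(float(np.max(P))) + 2.0,
            ),
        },
        {"log_fsuc": f_suc0, "log_Psuc": P_suc0},
        n_starts,
        seed,
    )
    est, se = _linear_scale(res, ["log_fsuc", "log_Psuc"])
    return FitResult(
        estimates={"f_suc": est["fsuc"], "P_suc": est["Psuc"]},
        stderrs={"f_suc": se["fsuc"], "P_suc": se["Psuc"]},
        chi2=float(res.chisqr),
        ndata=len(dna_curve),
        nvarys=2,
        success=bool(res.success),
        message=str(res.message),
        seed=seed,
        covariance=getattr(res, "covar", None),
    )


def collapse_metric(points: Sequence[MasterCurvePoint]) -> float:
    """RMS distance of master-curve points from the identity line y = x."""
    if len(points) < 1:
        raise InsufficientDataError("need at least one master-curve point")
    d = np.array([p.y - p.x for p in points])
    return float(np.sqrt(np.mean(d**2)))
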