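"""Per-mixing-time fitting of multi-exponential echo-attenuation curves.

Four model classes are supported, mirroring the usual taxonomy for
diffusion-weighted signal decays in cellular samples:

========  ==========================  ====================================
model id  form                        notes
========  ==========================  ====================================
model0    2 pools, y0 = 0             fitted on the full b-range
model0B   2 pools, y0 = 0             fitted on a restricted b-window
model1    2 pools + intercept y0      the offset absorbs a non-attenuating
                                      slow pool at low b
model2    3 pools, y0 = 0             full three-compartment decay
========  ==========================  ====================================

Each curve (one mixing time) is fitted by bounded nonlinear least squares with
a deterministic log-linear "peeling" initialisation.  Models are compared via
AIC/BIC in their Gaussian least-squares form, and a per-mixing-time plan
assembles the fits into per-compartment D(t_m), p(t_m) traces (a
:class:`TDDCSeries`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .physics import CompartmentSet, SSEProtocol, b_value, relaxation_factor, stejskal_tanner

__all__ = [
    "MODELS",
    "FitConfig",
    "FitResult",
    "BWindow",
    "InfoCriteria",
    "TDDCSeries",
    "FitTask",
    "fit_attenuation",
    "select_b_window",
    "information_criteria",
    "akaike_weights",
    "fit_series",
    "interval_strategy_series",
]

#: model id -> (number of pools, intercept fitted)
MODELS: dict[str, tuple[int, bool]] = {
    "model0": (2, False),
    "model0B": (2, False),
    "model1": (2, True),
    "model2": (3, False),
}

_LOGD_BOUNDS = (-13.0, -8.0)  # log10 of D bounds, m^2/s
_Y0_MAX = 0.5


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a single-curve fit.

    ``b_window`` is an inclusive (start, stop) index range into the tau grid
    (None = full range).  ``fixed_params`` freezes named parameters, e.g.
    ``{"D1": 1.64e-9}`` (pools numbered from the fastest).  ``unit_sum``
    constrains the amplitudes to the simplex (sum to 1); the free-amplitude
    default lets fitted fractions decay with mixing time, as they physically
    do.  With ``reference_normalized`` and ``unit_sum`` the model is divided
    by its own value at the protocol reference point, matching data normalized
    to the echo at (tau_min, tm_min).
    """

    model_id: str = "model2"
    b_window: tuple[int, int] | None = None
    fixed_params: Mapping[str, float] | None = None
    unit_sum: bool = False
    reference_normalized: bool = True
    init: tuple[Sequence[float], Sequence[float], float] | None = None
    max_iter: int = 2000
    tol: float = 1e-14
    aicc: bool = False
    D_max: float | None = None  # physical upper bound on fitted D, m^2/s

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model id {self.model_id!r}")


class InfoCriteria(NamedTuple):
    AIC: float
    BIC: float
    degenerate: bool = False


@dataclass(frozen=True)
class FitResult:
    """Estimates and diagnostics of one attenuation-curve fit."""

    model_id: str
    estimates: CompartmentSet
    std_errors: dict[str, float]
    RSS: float
    N: int
    k: int
    AIC: float
    BIC: float
    converged: bool
    tm: float
    window: tuple[int, int]
    #: per (descending-D) pool: fitted D pinned at an optimizer bound, which
    #: marks the estimate as a boundary artefact rather than a measurement
    at_bound: tuple[bool, ...] = ()


@dataclass(frozen=True)
class BWindow:
    """Inclusive index window into the tau grid; ``warning`` marks the
    full-range fallback (fast pool never attenuated below epsilon)."""

    start: int
    stop: int
    warning: bool = False

    def slice(self) -> slice:
        return slice(self.start, self.stop + 1)


def select_b_window(pool_attenuations: Sequence[float], epsilon: float = 0.02) -> BWindow:
    """Window starting where the fastest pool's simulated attenuation <= epsilon.

    ``pool_attenuations`` are E/E0 of the (simulated) fastest pool per tau
    index, monotone non-increasing.  Points before the threshold crossing are
    excluded; if the pool never drops below epsilon the full range is returned
    with a warning flag.
    """
    att = np.asarray(pool_attenuations, dtype=float)
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    if np.any(np.diff(att) > 1e-12):
        raise ValueError("pool attenuations must be monotone non-increasing")
    below = np.nonzero(att <= epsilon)[0]
    if below.size == 0:
        return BWindow(0, att.size - 1, warning=True)
    return BWindow(int(below[0]), att.size - 1)


def information_criteria(RSS: float, N: int, k: int, aicc: bool = False) -> InfoCriteria:
    """Gaussian least-squares AIC/BIC: N*ln(RSS/N) + {2k, k*ln N}.

    RSS = 0 (an exact fit) yields -inf sentinels with the degenerate flag.
    ``aicc`` applies the small-sample correction to the AIC.
    """
    if N <= k or k < 1:
        raise ValueError("need N > k >= 1")
    if RSS < 0:
        raise ValueError("RSS must be non-negative")
    if RSS == 0:
        return InfoCriteria(-math.inf, -math.inf, True)
    aic = N * math.log(RSS / N) + 2 * k
    if aicc:
        if N - k - 1 <= 0:
            raise ValueError("AICc undefined for N <= k + 1")
        aic += 2.0 * k * (k + 1) / (N - k - 1)
    bic = N * math.log(RSS / N) + k * math.log(N)
    return InfoCriteria(aic, bic, False)


def akaike_weights(aic_list: Sequence[float]) -> np.ndarray:
    """Akaike weights w_m = exp(-Delta_m/2) / sum(exp(-Delta/2))."""
    aic = np.asarray(aic_list, dtype=float)
    if aic.size < 2:
        raise ValueError("need at least two AIC values")
    if not np.all(np.isfinite(aic)):
        raise ValueError("AIC values must be finite")
    delta = aic - aic.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


# -- single-curve fitting ----------------------------------------------------


def _peel_init(b: np.ndarray, z: np.ndarray, n: int) -> tuple[list[float], list[float]]:
    """Deterministic multi-exponential initialisation.

    Repeatedly fits a log-linear decay to the large-b tail of the (positive)
    residual, peeling one component per pass from slowest to fastest.
    """
    order = np.argsort(b)
    b, z = b[order], z[order]
    resid = z.copy()
    D_init, p_init = [], []
    for i in range(n):
        pos = np.nonzero(resid > 1e-6)[0]
        if pos.size < 2:
            D_init.append(10 ** (-9.0 - i))
            p_init.append(max(1e-3, float(resid.max()) if resid.size else 1e-3))
            continue
        ntail = max(2, pos.size // (n - i))
        idx = pos[-ntail:]
        slope, icpt = np.polyfit(b[idx], np.log(resid[idx]), 1)
        D = min(max(-slope, 10 ** _LOGD_BOUNDS[0]), 10 ** _LOGD_BOUNDS[1])
        p = min(max(math.exp(icpt), 1e-4), 1.0)
        D_init.append(float(D))
        p_init.append(float(p))
        resid = resid - p * np.exp(-D * b)
    order = np.argsort(D_init)[::-1]
    return [D_init[i] for i in order], [p_init[i] for i in order]


def fit_attenuation(
    curve: tuple[Sequence[float], Sequence[float]],
    protocol: SSEProtocol,
    config: FitConfig,
    tm: float | None = None,
) -> FitResult:
    """Fit one E/E0(tau) curve at a single mixing time.

    ``curve`` is (tau values, E/E0 values); ``tm`` defaults to the protocol's
    first mixing time.  Returns descending-D estimates, with fixed parameters
    honoured exactly and non-convergence flagged rather than raised.
    """
    tau = np.asarray(curve[0], dtype=float)
    E = np.asarray(curve[1], dtype=float)
    if tau.shape != E.shape or tau.ndim != 1:
        raise ValueError("curve must be two equal-length 1-D sequences")
    tm = float(protocol.tm_grid[0]) if tm is None else float(tm)
    n_pools, has_y0 = MODELS[config.model_id]

    win = config.b_window or (0, tau.size - 1)
    if not (0 <= win[0] <= win[1] < tau.size):
        raise ValueError("b_window out of range")
    sl = slice(win[0], win[1] + 1)
    tau_w, E_w = tau[sl], E[sl]

    fixed = dict(config.fixed_params or {})
    n_amp = (n_pools - 1) if config.unit_sum else n_pools
    free_D = [i for i in range(n_pools) if f"D{i+1}" not in fixed]
    k_free = len(free_D) + n_amp + (1 if has_y0 else 0)
    if tau_w.size < k_free + 1:
        raise ValueError("window shorter than free parameter count + 1")

    b_w = b_value(tau_w, tm, protocol.G, protocol.gamma)
    rf_w = relaxation_factor(tau_w, tm, protocol.T1, protocol.T2)
    tau0, tm0 = protocol.reference_point
    b0 = b_value(tau0, tm0, protocol.G, protocol.gamma)
    rf0 = relaxation_factor(tau0, tm0, protocol.T1, protocol.T2)
    self_norm = config.unit_sum and config.reference_normalized

    # -- initial guess
    if config.init is not None:
        D0s, p0s, y0_0 = config.init
        D0s, p0s = list(D0s), list(p0s)
    else:
        z = np.clip(E_w / rf_w, 1e-9, None)
        y0_0 = 0.5 * float(z.min()) if has_y0 else 0.0
        D0s, p0s = _peel_init(b_w, np.clip(z - y0_0, 1e-9, None), n_pools)
        for name, val in fixed.items():
            D0s[int(name[1:]) - 1] = val

    def unpack(x):
        Ds = np.empty(n_pools)
        j = 0
        for i in range(n_pools):
            if f"D{i+1}" in fixed:
                Ds[i] = fixed[f"D{i+1}"]
            else:
                Ds[i] = 10.0 ** x[j]
                j += 1
        if config.unit_sum:
            amps = np.empty(n_pools)
            amps[:-1] = x[j:j + n_pools - 1]
            amps[-1] = 1.0 - amps[:-1].sum()
            j += n_pools - 1
        else:
            amps = np.asarray(x[j:j + n_pools])
            j += n_pools
        y0 = x[j] if has_y0 else 0.0
        return Ds, amps, y0

    def model(x):
        Ds, amps, y0 = unpack(x)
        val = rf_w * (amps[None, :] * np.exp(-np.outer(b_w, Ds))).sum(axis=1) + y0
        if self_norm:
            ref = rf0 * (amps * np.exp(-b0 * Ds)).sum() + y0
            val = val / ref
        return val

    def resid(x):
        return model(x) - E_w

    logD_hi = _LOGD_BOUNDS[1] if config.D_max is None \
        else math.log10(config.D_max)
    x0, lb, ub = [], [], []
    for i in free_D:
        x0.append(math.log10(min(max(D0s[i], 10 ** _LOGD_BOUNDS[0]),
                                 10 ** logD_hi)))
        lb.append(_LOGD_BOUNDS[0])
        ub.append(logD_hi)
    for i in range(n_amp):
        x0.append(min(max(p0s[i], 0.0), 1.0))
        lb.append(0.0)
        ub.append(1.0)
    if has_y0:
        x0.append(min(max(y0_0, 0.0), _Y0_MAX))
        lb.append(0.0)
        ub.append(_Y0_MAX)

    sol = optimize.least_squares(
        resid, np.asarray(x0), bounds=(np.asarray(lb), np.asarray(ub)),
        xtol=config.tol, ftol=config.tol, gtol=config.tol,
        max_nfev=config.max_iter * len(x0),
    )
    Ds, amps, y0 = unpack(sol.x)
    amps = np.clip(amps, 0.0, None)
    pinned = np.zeros(n_pools, dtype=bool)
    j = 0
    for i in range(n_pools):
        if f"D{i+1}" not in fixed:
            u = sol.x[j]
            pinned[i] = (u - _LOGD_BOUNDS[0] < 0.01) or (logD_hi - u < 0.01)
            j += 1

    # order pools by descending D (identity convention: fast -> slow)
    order = np.argsort(Ds)[::-1]
    Ds, amps, pinned = Ds[order], amps[order], pinned[order]
    est = CompartmentSet(tuple(Ds), tuple(np.minimum(amps, 1.0)), float(y0))

    RSS = float(sol.fun @ sol.fun)
    N = tau_w.size
    dof = N - k_free
    se_x = _se_from_jac(sol.jac, sol.fun, dof)
    std_errors = _named_errors(se_x, free_D, n_pools, n_amp, has_y0,
                               config.unit_sum, Ds, order, fixed)
    try:
        ic = information_criteria(RSS, N, k_free, aicc=config.aicc)
    except ValueError:
        ic = InfoCriteria(math.nan, math.nan, True)
    return FitResult(
        config.model_id, est, std_errors, RSS, N, k_free,
        ic.AIC, ic.BIC, bool(sol.success), tm, tuple(win),
        at_bound=tuple(bool(x) for x in pinned),
    )


def _se_from_jac(jac, fun, dof):
    if dof <= 0:
        return np.full(jac.shape[1], np.nan)
    try:
        cov = np.linalg.inv(jac.T @ jac) * float(fun @ fun) / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def _named_errors(se_x, free_D, n_pools, n_amp, has_y0, unit_sum, Ds_sorted,
                  order, fixed):
    """Map optimizer-space standard errors onto named, descending-D parameters."""
    se_D = np.full(n_pools, 0.0)  # fixed params carry zero error
    j = 0
    for i in range(n_pools):
        if f"D{i+1}" not in fixed:
            # d(10^u)/du = D * ln 10
            se_D[i] = se_x[j] * math.log(10)
            j += 1
    se_p = np.full(n_pools, np.nan)
    if unit_sum:
        se_p[:-1] = se_x[j:j + n_amp]
        se_p[-1] = math.sqrt(np.nansum(se_x[j:j + n_amp] ** 2))
    else:
        se_p[:] = se_x[j:j + n_amp]
    j += n_amp
    out = {}
    for rank, i in enumerate(order):
        out[f"D{rank+1}"] = float(se_D[i] * Ds_sorted[rank]) if se_D[i] else 0.0
        out[f"p{rank+1}"] = float(se_p[i])
    if has_y0:
        out["y0"] = float(se_x[j])
    return out


# -- series over mixing times ------------------------------------------------


@dataclass(frozen=True)
class FitTask:
    """One planned fit: which mixing time, how to fit it, and which global
    compartment label each pool rank (0 = fastest) maps to."""

    tm_index: int
    config: FitConfig
    comp_map: Mapping[int, int]


@dataclass
class TDDCSeries:
    """Per-compartment D(t_m) and p(t_m) traces with fit diagnostics.

    ``table`` columns: tm (s), comp, D (m^2/s), D_se, p, p_se, y0, model_id,
    RSS, N, k, AIC, BIC, converged.
    """

    table: pd.DataFrame

    COLUMNS = ["tm", "comp", "D", "D_se", "p", "p_se", "y0", "model_id",
               "RSS", "N", "k", "AIC", "BIC", "converged", "at_bound"]

    def comps(self) -> list[int]:
        return sorted(self.table["comp"].unique())

    def trace(self, comp: int, converged_only: bool = True) -> pd.DataFrame:
        """The compartment's D(t_m)/p(t_m) trace; by default only converged,
        non-boundary-artefact rows (failures leave gaps, not values)."""
        sub = self.table[self.table["comp"] == comp]
        if converged_only:
            sub = sub[sub["converged"] & ~sub["at_bound"]]
        return sub.sort_values("tm").reset_index(drop=True)

    def n_mixing_times(self) -> int:
        return self.table["tm"].nunique()

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "TDDCSeries":
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def fit_series(dataset, tasks: Sequence[FitTask]) -> TDDCSeries:
    """Apply a per-mixing-time fit plan to an attenuation dataset.

    ``dataset`` must expose ``protocol`` and ``curve(tm_index) -> (tau, E)``.
    Failures at single mixing times are recorded (converged=False rows built
    from the flagged result) and the series is still returned.
    """
    rows = []
    for task in tasks:
        tm = float(dataset.protocol.tm_grid[task.tm_index])
        tau, E = dataset.curve(task.tm_index)
        try:
            res = fit_attenuation((tau, E), dataset.protocol, task.config, tm=tm)
        except ValueError:
            continue
        for rank, comp in task.comp_map.items():
            if rank >= res.estimates.n:
                continue
            rows.append({
                "tm": tm, "comp": comp,
                "D": res.estimates.D[rank],
                "D_se": res.std_errors.get(f"D{rank+1}", math.nan),
                "p": res.estimates.p[rank],
                "p_se": res.std_errors.get(f"p{rank+1}", math.nan),
                "y0": res.estimates.y0,
                "model_id": res.model_id, "RSS": res.RSS, "N": res.N,
                "k": res.k, "AIC": res.AIC, "BIC": res.BIC,
                "converged": res.converged,
                "at_bound": bool(res.at_bound[rank]) if res.at_bound else False,
            })
    return TDDCSeries.from_rows(rows)


def interval_strategy_series(
    dataset,
    tm_break: float = 2e-3,
    epsilon: float = 0.02,
    fix_D1: float | None = None,
) -> TDDCSeries:
    """The interval fitting strategy for a three-compartment sample.

    Short mixing times (t_m <= ``tm_break``): all three pools still attenuate
    measurably, so the three-compartment model 2 is fitted on the full
    b-range.  Longer mixing times: the fast (extracellular) pool is simulated
    with the short-time D1 estimate, the leading tau points where it still
    contributes more than ``epsilon`` are excluded, and the two-compartment
    model 0B on the window yields compartments 2 and 3.
    """
    protocol = dataset.protocol
    short_idx = [i for i, tm in enumerate(protocol.tm_grid) if tm <= tm_break]
    long_idx = [i for i, tm in enumerate(protocol.tm_grid) if tm > tm_break]

    if fix_D1 is None:
        # first pass: free model-2 fits pin down the fast-pool coefficient,
        # which is then frozen (the usual constraint when the window leaves
        # few points per parameter)
        pre = fit_series(dataset, [
            FitTask(i, FitConfig(model_id="model2"), {0: 1}) for i in short_idx
        ])
        tr1 = pre.trace(1)
        fix_D1 = float(np.median(tr1["D"])) if len(tr1) else 1.6e-9

    tasks = [
        FitTask(i, FitConfig(model_id="model2", fixed_params={"D1": fix_D1}),
                {0: 1, 1: 2, 2: 3})
        for i in short_idx
    ]
    series_short = fit_series(dataset, tasks)

    long_tasks = []
    for i in long_idx:
        tm = float(protocol.tm_grid[i])
        b_tau = b_value(protocol.tau_grid, tm, protocol.G, protocol.gamma)
        win = select_b_window(stejskal_tanner(fix_D1, b_tau), epsilon)
        # pools on the window are slower than the excluded extracellular one
        cfg = FitConfig(model_id="model0B", b_window=(win.start, win.stop),
                        D_max=fix_D1)
        long_tasks.append(FitTask(i, cfg, {0: 2, 1: 3}))
    series_long = fit_series(dataset, long_tasks)
    # a pool pinned at a bound means the two-pool split failed at that t_m:
    # discard both pools there rather than mislabel the surviving one
    lt = series_long.table
    bad_tm = lt.loc[lt["at_bound"], "tm"].unique()
    lt.loc[lt["tm"].isin(bad_tm), "at_bound"] = True
    table = pd.concat([series_short.table, lt], ignore_index=True)
    return TDDCSeries(table.sort_values(["comp", "tm"]).reset_index(drop=True))
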