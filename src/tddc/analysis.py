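"""Biophysics from time-dependent diffusion coefficients.

A restricted water pool shows a characteristic S-shaped D(t) on log-log axes:

* **Region I (short times)** — the Mitra expansion: the apparent coefficient
  falls below the bulk value ``D0`` linearly in sqrt(t) with a slope set by the
  surface-to-volume ratio S/V of the confinement,

      D(t) = D0 * [1 - 4/(3*W*sqrt(pi)) * (S/V) * sqrt(D0*t)].

* **Region II (localization regime)** — displacement saturates at the
  compartment size and the apparent coefficient follows a 1/t law derived from
  the Einstein-Smoluchowski relation <Z^2> = 2*d*D*t with the saturated
  mean-square displacement <Z^2> = 2/(2+d) * R^2:

      D(t) = 2/(2+d) * R^2 / (2*d*t).

Fitting region I yields (D0, S/V); fitting an allometric A*t^k to region II
yields the compartment half-width R (at the k = -1 convention).  Molar
fractions decay exponentially with the mixing time, p(t) = p0*exp(-t/tau),
giving the water lifetime tau and, through P_d = R/(3*tau), the diffusive
membrane permeability of a spherical compartment.

Times are seconds, lengths metres, D in m^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MitraFitResult",
    "RegionIIFitResult",
    "CrossoverResult",
    "MolarDecayFit",
    "CompartmentPlan",
    "CompartmentSummary",
    "mitra_model",
    "fit_mitra",
    "sv_to_radius",
    "es_model",
    "fit_region2",
    "crossover_time",
    "piecewise_D",
    "fit_molar_decay",
    "permeability",
    "characterize",
    "default_yeast_plan",
]


def _mitra_prefactor(W: int) -> float:
    return 4.0 / (3.0 * W * math.sqrt(math.pi))


def mitra_model(t, D0: float, SV: float, W: int = 3):
    """Short-time expansion D(t) = D0*[1 - 4/(3W*sqrt(pi))*(S/V)*sqrt(D0*t)].

    Clipped at zero from below (the expansion is only meaningful while
    positive).  ``W`` is the number of space dimensions in the prefactor.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    val = D0 * (1.0 - _mitra_prefactor(W) * SV * np.sqrt(D0 * t))
    out = np.clip(val, 0.0, None)
    return out if out.ndim else float(out)


def sv_to_radius(SV: float) -> float:
    """Sphere radius from a surface-to-volume ratio: R = 3/(S/V)."""
    if SV <= 0:
        raise ValueError("S/V must be positive")
    return 3.0 / SV


def es_model(t, R: float, d: int = 1):
    """Localization-regime coefficient D(t) = [2/(2+d)] * R^2 / (2*d*t).

    For d = 1 (measurement along the gradient axis) this is R^2/(3t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive (1/t law diverges at 0)")
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    out = (2.0 / (2.0 + d)) * R**2 / (2.0 * d * t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MitraFitResult:
    """Region-I fit: bulk coefficient D0 (m^2/s) and S/V (1/m) at fixed W."""

    D0: float
    SV: float
    W: int
    t_range: tuple[float, float]
    D0_se: float = float("nan")
    SV_se: float = float("nan")

    def __call__(self, t):
        return mitra_model(t, self.D0, self.SV, self.W)


@dataclass(frozen=True)
class RegionIIFitResult:
    """Region-II allometric fit D = A*t^k and the implied size R.

    ``A`` has units m^2 s^-1 s^(-k); ``R`` (m) uses the k = -1 convention
    R = sqrt(A*d*(2+d)).  ``k`` is reported so a permeable-boundary deviation
    from -1 stays visible.
    """

    A: float
    k: float
    R: float
    d: int
    t_range: tuple[float, float]
    A_se: float = float("nan")
    k_se: float = float("nan")
    R_se: float = float("nan")
    exponent_fixed: bool = False

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.A * t**self.k
        return out if out.ndim else float(out)


def _lin_se(x: np.ndarray, resid: np.ndarray, dof: int) -> tuple[float, float]:
    """Standard errors of (intercept, slope) of an OLS line."""
    n = x.size
    if dof <= 0:
        return float("nan"), float("nan")
    s2 = float(resid @ resid) / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        return float("nan"), float("nan")
    se_slope = math.sqrt(s2 / sxx)
    se_icpt = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return se_icpt, se_slope


def fit_mitra(
    t: Sequence[float],
    D: Sequence[float],
    t_range: tuple[float, float] | None = None,
    W: int = 3,
) -> MitraFitResult:
    """Least-squares Mitra fit of D(t) points (optionally restricted to t_range).

    The model is linear in sqrt(t) after the substitution
    D = a + m*sqrt(t) with a = D0, m = -c*SV*D0^(3/2); the fit is solved in
    that linear form (exact on model-class data, no iteration needed) and
    mapped back to (D0, S/V).
    """
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    if t_range is not None:
        keep = (t >= t_range[0]) & (t <= t_range[1])
        t, D = t[keep], D[keep]
    else:
        t_range = (float(t.min()), float(t.max())) if t.size else (0.0, 0.0)
    if t.size < 3:
        raise ValueError("need at least 3 points in the Mitra fit range")
    x = np.sqrt(t)
    slope, icpt = np.polyfit(x, D, 1)
    D0 = float(icpt)
    if D0 <= 0:
        raise ValueError("Mitra fit yielded non-positive D0")
    c = _mitra_prefactor(W)
    SV = max(0.0, float(-slope) / (c * D0**1.5))
    resid = D - (icpt + slope * x)
    se_icpt, se_slope = _lin_se(x, resid, t.size - 2)
    # first-order propagation of (icpt, slope) errors into (D0, SV)
    D0_se = se_icpt
    if SV > 0 and np.isfinite(se_slope):
        rel = math.sqrt((se_slope / slope) ** 2 + (1.5 * se_icpt / D0) ** 2)
        SV_se = SV * rel
    else:
        SV_se = float("nan")
    return MitraFitResult(D0, SV, W, (float(t.min()), float(t.max())), D0_se, SV_se)


def fit_region2(
    t: Sequence[float],
    D: Sequence[float],
    t_range: tuple[float, float] | None = None,
    d: int = 1,
    fix_exponent: bool = False,
) -> RegionIIFitResult:
    """Allometric fit D = A*t^k to localization-regime points (log-log OLS).

    With ``fix_exponent`` the exponent is pinned to -1 (the impermeable-wall
    law); otherwise k is free and its deviation from -1 indicates permeable
    boundaries.  The size conversion R = sqrt(A*d*(2+d)) uses the k = -1
    convention in either case.
    """
    t = np.asarray(t, dtype=float)
    D = np.asarray(D, dtype=float)
    if t_range is not None:
        keep = (t >= t_range[0]) & (t <= t_range[1])
        t, D = t[keep], D[keep]
    keep = D > 0
    t, D = t[keep], D[keep]
    if t.size < 3:
        raise ValueError("need at least 3 positive points in the region-II range")
    lt, lD = np.log(t), np.log(D)
    if fix_exponent:
        k = -1.0
        lnA = float((lD + lt).mean())
        resid = lD - (lnA + k * lt)
        dof = t.size - 1
        s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
        lnA_se = math.sqrt(s2 / t.size) if dof > 0 else float("nan")
        k_se = 0.0
    else:
        k, lnA = np.polyfit(lt, lD, 1)
        resid = lD - (lnA + k * lt)
        lnA_se, k_se = _lin_se(lt, resid, t.size - 2)
        k, lnA = float(k), float(lnA)
    A = math.exp(lnA)
    R = math.sqrt(A * d * (2 + d))
    A_se = A * lnA_se if np.isfinite(lnA_se) else float("nan")
    R_se = 0.5 * R * lnA_se if np.isfinite(lnA_se) else float("nan")
    return RegionIIFitResult(
        A, k, R, d, (float(t.min()), float(t.max())),
        A_se, k_se, R_se, exponent_fixed=fix_exponent,
    )


@dataclass(frozen=True)
class CrossoverResult:
    """Where the short-time and localization branches meet.

    ``exact`` is True when a sign-changing root of D_mitra - D_es was
    bracketed; otherwise ``t_star`` is the grid point of closest approach.
    ``degenerate`` flags (near-)identical curves.
    """

    t_star: float
    exact: bool
    degenerate: bool = False


def crossover_time(
    mitra: MitraFitResult,
    region2: RegionIIFitResult,
    t_grid: Sequence[float],
    prefer: str = "first",
) -> CrossoverResult:
    """Meeting time of the Mitra and Einstein-Smoluchowski branches.

    Returns the first bracketed root of D_mitra - D_es on the grid (bisection
    to 1e-6 relative).  Because the 1/t branch diverges at t -> 0 the curves
    can cross twice; ``prefer="descending"`` selects the crossing where the
    Mitra branch descends through the 1/t law instead (the switch that keeps
    a short-time-then-localization composite monotone).  When no root exists
    the grid point minimizing |D_mitra - D_es| is returned with
    ``exact=False``.
    """
    if prefer not in ("first", "descending"):
        raise ValueError("prefer must be 'first' or 'descending'")
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise ValueError("t_grid must be positive")
    t_grid = np.sort(t_grid)
    dm = mitra(t_grid)
    de = region2(t_grid)
    if not np.any((dm > 0) | (de > 0)):
        raise ValueError("curves are never positive on the grid: no crossover")
    diff = dm - de
    scale = np.maximum(np.abs(dm), np.abs(de))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(scale > 0, np.abs(diff) / scale, 0.0)
    if np.all(rel < 1e-9):
        return CrossoverResult(float(t_grid[0]), exact=True, degenerate=True)

    sign = np.sign(diff)
    down = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    any_change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if prefer == "descending" and down.size:
        i = int(down[0])
    elif any_change.size:
        i = int(any_change[0])
    else:
        j = int(np.argmin(np.abs(diff)))
        return CrossoverResult(float(t_grid[j]), exact=False)
    f = lambda t: mitra(t) - region2(t)
    root = optimize.brentq(f, t_grid[i], t_grid[i + 1], rtol=1e-6)
    return CrossoverResult(float(root), exact=True)


def piecewise_D(t, mitra: MitraFitResult, region2: RegionIIFitResult, t_star: float):
    """Composite D(t): Mitra branch for t <= t*, localization branch beyond.

    Continuous at t* when t* is an exact crossover root.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    out = np.where(t <= t_star, mitra(t), region2(t))
    return out if out.ndim else float(out)


# -- molar-fraction decays and permeability ----------------------------------


@dataclass(frozen=True)
class MolarDecayFit:
    """Exponential decay(s) of a molar fraction p(t) = sum_j p0_j exp(-t/tau_j).

    Components are ordered by ascending lifetime; ``tau = inf`` flags a decay
    below detection (constant fraction).
    """

    p0: tuple[float, ...]
    tau: tuple[float, ...]
    p0_se: tuple[float, ...] = ()
    tau_se: tuple[float, ...] = ()

    @property
    def n_exp(self) -> int:
        return len(self.p0)


def _decay_model(t, amps, rates):
    return sum(a * np.exp(-r * t) for a, r in zip(amps, rates))


def fit_molar_decay(
    t: Sequence[float],
    p: Sequence[float],
    t_range: tuple[float, float] | None = None,
    n_exp: int = 1,
) -> MolarDecayFit:
    """Fit p(t) with one or two exponential decays (amplitudes p0, lifetimes tau).

    A fitted decay smaller than 0.1% over the observed span is reported as
    tau = inf with p0 equal to the mean fraction.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t_range is not None:
        keep = (t >= t_range[0]) & (t <= t_range[1])
        t, p = t[keep], p[keep]
    if n_exp not in (1, 2):
        raise ValueError("n_exp must be 1 or 2")
    if t.size < (3 if n_exp == 1 else 5):
        raise ValueError("too few points for the requested number of components")
    span = float(t.max() - t.min())
    if span <= 0:
        raise ValueError("degenerate time range")

    # deterministic initialisation by log-linear peeling
    def loglin(tt, pp):
        m, a = np.polyfit(tt, np.log(np.clip(pp, 1e-12, None)), 1)
        return math.exp(a), max(0.0, -m)

    if n_exp == 1:
        a0, r0 = loglin(t, p)
        x0 = [a0, r0]
    else:
        half = t >= np.median(t)
        a_s, r_s = loglin(t[half], p[half])
        res = p - a_s * np.exp(-r_s * t)
        pos = res > 1e-9
        if pos.sum() >= 2:
            a_f, r_f = loglin(t[pos], res[pos])
            r_f = max(r_f, 2.0 * r_s + 1.0 / span)
        else:
            a_f, r_f = 0.5 * a_s, 10.0 / span
        x0 = [a_f, r_f, a_s, r_s]

    def resid(x):
        amps, rates = x[0::2], x[1::2]
        return _decay_model(t, amps, rates) - p

    lb = [0.0, 0.0] * n_exp
    ub = [1.5, np.inf] * n_exp
    sol = optimize.least_squares(
        resid, np.clip(x0, lb, [1.5, 1e12] * n_exp), bounds=(lb, ub),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    amps, rates = sol.x[0::2], sol.x[1::2]

    dof = t.size - sol.x.size
    se = _cov_se(sol.jac, sol.fun, dof)
    comp = []
    for j, (a, r) in enumerate(zip(amps, rates)):
        a_se, r_se = se[2 * j], se[2 * j + 1]
        if r * span < 1e-3:  # decay below detection
            comp.append((float(np.mean(p)), math.inf, a_se, math.nan))
        else:
            tau = 1.0 / r
            tau_se = r_se / r**2 if np.isfinite(r_se) else math.nan
            comp.append((float(a), float(tau), a_se, tau_se))
    comp.sort(key=lambda c: c[1])
    return MolarDecayFit(
        p0=tuple(c[0] for c in comp),
        tau=tuple(c[1] for c in comp),
        p0_se=tuple(c[2] for c in comp),
        tau_se=tuple(c[3] for c in comp),
    )


def _cov_se(jac: np.ndarray, resid: np.ndarray, dof: int) -> np.ndarray:
    """Parameter standard errors from a least-squares Jacobian."""
    if dof <= 0:
        return np.full(jac.shape[1], np.nan)
    try:
        cov = np.linalg.inv(jac.T @ jac) * float(resid @ resid) / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def permeability(R: float, tau_life: float) -> float:
    """Diffusive membrane permeability of a spherical compartment, P_d = R/(3*tau).

    ``R`` in m and ``tau_life`` in s give P_d in m/s.  tau -> inf yields 0
    (impermeable limit).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not tau_life > 0:
        raise ValueError("lifetime must be positive")
    return R / (3.0 * tau_life)


# -- whole-compartment characterisation --------------------------------------


@dataclass(frozen=True)
class CompartmentPlan:
    """Analysis regions and conventions for one compartment.

    ``region1``/``region2`` are (t_lo, t_hi) windows in seconds for the Mitra
    and localization fits (None skips the fit).  ``free`` marks an unrestricted
    pool whose D0 is the plain mean over region1.  ``tau_for_pd`` selects the
    lifetime entering P_d when the decay is bi-exponential ("slow" | "fast").
    """

    region1: tuple[float, float] | None = None
    region2: tuple[float, float] | None = None
    free: bool = False
    d: int = 1
    W: int = 3
    n_exp: int = 1
    decay_range: tuple[float, float] | None = None
    tau_for_pd: str = "slow"
    fix_exponent: bool = True


@dataclass
class CompartmentSummary:
    """Per-compartment characterisation report (one row per compartment:
    D0, S/V, p0, tau, R, P_d with uncertainties)."""

    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "comp", "D0_1e-9_m2s", "D0_se_1e-9_m2s", "SV_per_um", "SV_se_per_um",
            "p0", "p0_se", "tau_s", "tau_se_s", "R_um", "R_se_um",
            "Pd_um_s", "Pd_se_um_s", "k_region2",
        ]
        return pd.DataFrame(self.rows, columns=cols)

    def row(self, comp: int) -> dict:
        for r in self.rows:
            if r["comp"] == comp:
                return r
        raise KeyError(comp)


def default_yeast_plan() -> dict[int, CompartmentPlan]:
    """Analysis regions for the three-compartment yeast study.

    Compartment 1 (extracellular) is unrestricted on the observed scale: D0 is
    averaged over 0.2-1 ms.  Compartment 2 (cytoplasm): Mitra region 0.2-5 ms,
    localization region 8-40 ms.  Compartment 3 (organelles): Mitra region
    0.2-2 ms, localization region 2.8-40 ms; its fraction decays
    bi-exponentially and the slower lifetime enters the permeability.
    """
    return {
        1: CompartmentPlan(region1=(0.15e-3, 1.05e-3), free=True),
        2: CompartmentPlan(region1=(0.15e-3, 5.0e-3), region2=(8.0e-3, 41e-3)),
        3: CompartmentPlan(
            region1=(0.15e-3, 2.0e-3), region2=(2.8e-3, 41e-3), n_exp=1
        ),
    }


def characterize(series, plans: Mapping[int, CompartmentPlan]) -> CompartmentSummary:
    """Assemble D0, S/V, p0, tau, R and P_d for every planned compartment.

    ``series`` must expose ``trace(comp)`` returning a DataFrame with columns
    ``tm`` (s), ``D`` (m^2/s) and ``p`` (fractions); missing regions produce
    partial rows with NaN gaps rather than failures.
    """
    if len(plans) < 1:
        raise ValueError("no compartments planned")
    rows = []
    for comp, plan in sorted(plans.items()):
        tr = series.trace(comp)
        t = tr["tm"].to_numpy(dtype=float)
        D = tr["D"].to_numpy(dtype=float)
        p = tr["p"].to_numpy(dtype=float) if "p" in tr else np.full_like(t, np.nan)
        row = dict.fromkeys(
            ["D0_1e-9_m2s", "D0_se_1e-9_m2s", "SV_per_um", "SV_se_per_um",
             "p0", "p0_se", "tau_s", "tau_se_s", "R_um", "R_se_um",
             "Pd_um_s", "Pd_se_um_s", "k_region2"], np.nan)
        row["comp"] = comp

        if plan.free and plan.region1 is not None:
            keep = (t >= plan.region1[0]) & (t <= plan.region1[1])
            if keep.any():
                row["D0_1e-9_m2s"] = float(np.mean(D[keep])) / 1e-9
                row["D0_se_1e-9_m2s"] = (
                    float(np.std(D[keep], ddof=1)) / math.sqrt(keep.sum()) / 1e-9
                    if keep.sum() > 1 else np.nan
                )
        elif plan.region1 is not None:
            try:
                mit = fit_mitra(t, D, plan.region1, W=plan.W)
                row["D0_1e-9_m2s"] = mit.D0 / 1e-9
                row["D0_se_1e-9_m2s"] = mit.D0_se / 1e-9
                if mit.SV > 0:
                    row["SV_per_um"] = mit.SV / 1e6
                    row["SV_se_per_um"] = mit.SV_se / 1e6
            except ValueError:
                pass

        reg2 = None
        if plan.region2 is not None:
            try:
                reg2 = fit_region2(t, D, plan.region2, d=plan.d,
                                   fix_exponent=plan.fix_exponent)
                row["R_um"] = reg2.R / 1e-6
                row["R_se_um"] = reg2.R_se / 1e-6
                row["k_region2"] = reg2.k
            except ValueError:
                reg2 = None

        decay = None
        if np.isfinite(p).sum() >= (3 if plan.n_exp == 1 else 5):
            keep = np.isfinite(p)
            try:
                decay = fit_molar_decay(t[keep], p[keep], plan.decay_range,
                                        n_exp=plan.n_exp)
                row["p0"] = sum(decay.p0)
                row["p0_se"] = (
                    math.sqrt(sum(s**2 for s in decay.p0_se))
                    if all(np.isfinite(decay.p0_se)) else np.nan
                )
                j = -1 if plan.tau_for_pd == "slow" else 0
                row["tau_s"] = decay.tau[j]
                row["tau_se_s"] = decay.tau_se[j]
            except ValueError:
                decay = None

        if reg2 is not None and decay is not None and np.isfinite(row["tau_s"]):
            pd_ms = permeability(reg2.R, row["tau_s"])
            row["Pd_um_s"] = pd_ms / 1e-6
            rel = 0.0
            if np.isfinite(reg2.R_se):
                rel += (reg2.R_se / reg2.R) ** 2
            if np.isfinite(row["tau_se_s"]):
                rel += (row["tau_se_s"] / row["tau_s"]) ** 2
            row["Pd_se_um_s"] = pd_ms / 1e-6 * math.sqrt(rel)
        rows.append(row)
    return CompartmentSummary(rows)
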