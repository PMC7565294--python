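"""Forward model of stimulated-spin-echo (SSE) attenuation under a constant gradient.

A three-pulse stimulated echo acquired in a constant stray-field gradient G is
attenuated both by relaxation and by diffusion during the mixing time ``t_m``.
For a single water pool with apparent diffusion coefficient ``D`` the
normalized echo amplitude is

    E/E0 = exp(-2*tau/T2) * exp(-t_m/T1) * exp(-b*D),
    b    = (gamma*G*tau)**2 * (t_m + 2*tau/3),

where ``tau`` is the gradient-encoding duration.  A multi-compartment sample is
modelled as a sum of such pools with molar fractions ``p_i`` plus an optional
signal offset ``y0``.

All quantities are strictly SI (s, m, T); I/O layers convert ms/um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: CODATA gyromagnetic ratio of the proton, rad s^-1 T^-1.
GAMMA_1H = 2.6752218744e8

__all__ = [
    "GAMMA_1H",
    "SSEProtocol",
    "CompartmentSet",
    "b_value",
    "relaxation_factor",
    "stejskal_tanner",
    "b_for_target_attenuation",
    "forward_attenuation",
]


def _check_strictly_increasing(values: np.ndarray, name: str) -> None:
    if np.any(np.diff(values) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class SSEProtocol:
    """Acquisition protocol of a constant-gradient SSE diffusion experiment.

    Parameters
    ----------
    G : float
        Gradient strength, T/m.
    tau_grid : array-like
        Gradient-encoding durations tau, s, strictly ascending.
    tm_grid : array-like
        Mixing times t_m, s, strictly ascending.
    T1, T2 : float
        Longitudinal / transverse relaxation times, s (T1 >= T2 > 0).
        ``numpy.inf`` disables the corresponding weighting.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1 (defaults to the 1H value).
    """

    G: float
    tau_grid: np.ndarray
    tm_grid: np.ndarray
    T1: float
    T2: float
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_grid", np.asarray(self.tau_grid, dtype=float))
        object.__setattr__(self, "tm_grid", np.asarray(self.tm_grid, dtype=float))
        if self.G <= 0 or self.gamma <= 0:
            raise ValueError("G and gamma must be positive")
        if np.any(self.tau_grid <= 0) or np.any(self.tm_grid <= 0):
            raise ValueError("tau and t_m grids must be positive")
        _check_strictly_increasing(self.tau_grid, "tau_grid")
        _check_strictly_increasing(self.tm_grid, "tm_grid")
        if not (self.T2 > 0 and self.T1 >= self.T2):
            raise ValueError("need T1 >= T2 > 0")

    @property
    def reference_point(self) -> tuple[float, float]:
        """(tau_min, tm_min) — the point the echo amplitude is normalized to."""
        return float(self.tau_grid[0]), float(self.tm_grid[0])

    def b_grid(self) -> np.ndarray:
        """b-values on the full (tm, tau) grid, shape (n_tm, n_tau), s m^-2."""
        return b_value(
            self.tau_grid[None, :], self.tm_grid[:, None], self.G, self.gamma
        )

    def max_b(self) -> float:
        """Largest diffusion weighting reached by the protocol, s m^-2."""
        return float(self.b_grid().max())


@dataclass(frozen=True)
class CompartmentSet:
    """A set of 1-3 water pools: apparent D_i (descending), molar fractions p_i,
    and a signal offset y0.

    Molar fractions may sum to less than one: in a time-resolved analysis the
    apparent fraction of each pool decays with the mixing time, so only the
    equilibrium (t_m -> 0) fractions of a fully detected sample sum to unity.
    """

    D: tuple[float, ...]
    p: tuple[float, ...]
    y0: float = 0.0

    def __post_init__(self) -> None:
        D = tuple(float(x) for x in self.D)
        p = tuple(float(x) for x in self.p)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "p", p)
        if not 1 <= len(D) <= 3:
            raise ValueError("1 to 3 compartments supported")
        if len(D) != len(p):
            raise ValueError("D and p must have equal length")
        if any(d <= 0 for d in D):
            raise ValueError("all D_i must be positive")
        if any(x < 0 for x in p):
            raise ValueError("molar fractions must be non-negative")
        # No unit-sum constraint here: apparent fractions decay with mixing
        # time, and fitted amplitudes on restricted b-windows may exceed the
        # generative budget.  TruthModel enforces sum(p0) <= 1 where it is a
        # physical requirement.
        if any(x > 1.0 + 1e-9 for x in p):
            raise ValueError("individual molar fractions cannot exceed 1")
        if self.y0 < 0:
            raise ValueError("y0 must be non-negative")
        if any(D[i] < D[i + 1] for i in range(len(D) - 1)):
            raise ValueError("D must be stored in descending order")

    @property
    def n(self) -> int:
        return len(self.D)


def b_value(tau, tm, G: float, gamma: float = GAMMA_1H):
    """Diffusion weighting b = (gamma*G*tau)^2 * (t_m + 2*tau/3), s m^-2.

    Monotone increasing in each of tau and t_m.  Accepts scalars or arrays
    (broadcast).
    """
    tau = np.asarray(tau, dtype=float)
    tm = np.asarray(tm, dtype=float)
    if np.any(tau < 0) or np.any(tm < 0):
        raise ValueError("tau and t_m must be non-negative")
    if G <= 0 or gamma <= 0:
        raise ValueError("G and gamma must be positive")
    out = (gamma * G * tau) ** 2 * (tm + 2.0 * tau / 3.0)
    return out if out.ndim else float(out)


def relaxation_factor(tau, tm, T1: float, T2: float):
    """Relaxation weighting exp(-2*tau/T2) * exp(-t_m/T1), in (0, 1]."""
    tau = np.asarray(tau, dtype=float)
    tm = np.asarray(tm, dtype=float)
    if np.any(tau < 0) or np.any(tm < 0):
        raise ValueError("tau and t_m must be non-negative")
    if T1 <= 0 or T2 <= 0:
        raise ValueError("relaxation times must be positive")
    out = np.exp(-2.0 * tau / T2) * np.exp(-tm / T1)
    return out if out.ndim else float(out)


def stejskal_tanner(D, b):
    """Single-pool echo attenuation E/E0 = exp(-b*D)."""
    D = np.asarray(D, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(D < 0) or np.any(b < 0):
        raise ValueError("D and b must be non-negative")
    out = np.exp(-b * D)
    return out if out.ndim else float(out)


def b_for_target_attenuation(D, target):
    """Invert the Stejskal-Tanner relation: b = -ln(target)/D.

    ``target`` is the desired attenuation E/E0 in (0, 1].
    """
    D = np.asarray(D, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.any(D <= 0):
        raise ValueError("D must be positive")
    if np.any(target <= 0) or np.any(target > 1):
        raise ValueError("target attenuation must lie in (0, 1]")
    out = -np.log(target) / D
    return out if out.ndim else float(out)


def forward_attenuation(
    protocol: SSEProtocol,
    comps: CompartmentSet,
    tau,
    tm,
    reference_normalized: bool = False,
):
    """Multi-compartment SSE attenuation E/E0 at (tau, t_m).

    Returns ``relaxation_factor * sum_i p_i exp(-b*D_i) + y0``.  With
    ``reference_normalized`` the result is divided by the same expression at
    the protocol's (tau_min, tm_min), so the value at the reference point is
    exactly 1 — matching data normalized to the echo amplitude at the smallest
    encoding and mixing times.
    """
    val = _raw_attenuation(protocol, comps, tau, tm)
    if reference_normalized:
        tau0, tm0 = protocol.reference_point
        val = val / _raw_attenuation(protocol, comps, tau0, tm0)
    return val if np.ndim(val) else float(val)


def _raw_attenuation(protocol: SSEProtocol, comps: CompartmentSet, tau, tm):
    tau = np.asarray(tau, dtype=float)
    tm = np.asarray(tm, dtype=float)
    b = b_value(tau, tm, protocol.G, protocol.gamma)
    rf = relaxation_factor(tau, tm, protocol.T1, protocol.T2)
    pools = sum(
        p * np.exp(-np.asarray(b) * d) for d, p in zip(comps.D, comps.p)
    )
    return rf * pools + comps.y0
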