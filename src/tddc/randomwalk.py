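"""Monte Carlo random walk of water in a 2D yeast-like geometry.

Walkers take fixed-length steps sigma = sqrt(4*D0*t_s) in uniformly random
directions inside their compartment; steps crossing a boundary are specularly
reflected (completely reflecting, non-exchanging membranes).  Per-region
mean-square displacements at the requested mixing times yield apparent
diffusion coefficients D(t_m) = <r^2>/(4*t_m), the short-time/localization
branches of the time-dependent diffusion coefficient, and — through the
Stejskal-Tanner relation — simulated attenuation-vs-b curves per compartment.

Geometry is circles: a cell with a thin wall annulus and disjoint circular
organelles (nucleus, vacuole, mitochondrion) inside it; the exterior is
modelled as unbounded.  Internally SI units (m, s); geometry constructors
accept um for convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .physics import b_for_target_attenuation

__all__ = [
    "Circle",
    "CellGeometry2D",
    "RWConfig",
    "DisplacementSummary",
    "step_length",
    "n_steps",
    "simulate",
    "msd_to_D",
    "simulated_tddc",
    "simulated_attenuation",
    "default_yeast_geometry",
]

ORGANELLE_LABELS = ("nucleus", "vacuole", "mitochondrion")
REGION_LABELS = ("exterior", "cytoplasm", "wall") + ORGANELLE_LABELS


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("radius must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])


@dataclass(frozen=True)
class CellGeometry2D:
    """Nested circular regions with per-region bulk diffusion coefficients.

    ``organelles`` maps labels to circles strictly inside the wall's inner
    circle and pairwise disjoint; ``region_D0`` maps every region label to its
    bulk self-diffusion coefficient (m^2/s).  All lengths in metres.
    """

    domain_side: float
    cell: Circle
    wall_thickness: float
    organelles: Mapping[str, Circle]
    region_D0: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness < self.cell.r:
            raise ValueError("wall thickness must lie in (0, cell radius)")
        inner_r = self.cell.r - self.wall_thickness
        for label, c in self.organelles.items():
            if label not in ORGANELLE_LABELS:
                raise ValueError(f"unknown organelle label {label!r}")
            gap = inner_r - (np.hypot(c.cx - self.cell.cx, c.cy - self.cell.cy) + c.r)
            if gap <= 0:
                raise ValueError(f"{label} not strictly inside the wall inner circle")
        items = list(self.organelles.items())
        for i, (la, ca) in enumerate(items):
            for lb, cb in items[i + 1:]:
                if np.hypot(ca.cx - cb.cx, ca.cy - cb.cy) <= ca.r + cb.r:
                    raise ValueError(f"organelles {la} and {lb} overlap")
        for label in list(self.organelles) + ["exterior", "cytoplasm", "wall"]:
            if self.region_D0.get(label, 0) <= 0:
                raise ValueError(f"missing or non-positive D0 for region {label!r}")

    @property
    def inner_circle(self) -> Circle:
        return Circle(self.cell.cx, self.cell.cy, self.cell.r - self.wall_thickness)

    def region(self, label: str) -> tuple[Circle | None, list[Circle], np.ndarray]:
        """(outer circle, excluded circles, representative interior point)."""
        if label == "exterior":
            return None, [], np.array([0.0, 0.0])
        if label == "cytoplasm":
            inner = self.inner_circle
            return inner, list(self.organelles.values()), inner.center
        if label == "wall":
            mid = self.cell.r - 0.5 * self.wall_thickness
            rep = self.cell.center + np.array([mid, 0.0])
            return self.cell, [self.inner_circle], rep
        if label in self.organelles:
            c = self.organelles[label]
            return c, [], c.center
        raise ValueError(f"region {label!r} not present in geometry")


def default_yeast_geometry() -> CellGeometry2D:
    """A single yeast cell in a 10 um box.

    Cell radius 2.35 um with a 0.13 um wall; nucleus (r = 1 um), vacuole
    (r = 0.5 um) and mitochondrion (r = 0.25 um) on a fixed non-overlapping
    layout.  Bulk coefficients: exterior 1.64, cytoplasm 0.692, wall 0.03,
    nucleus 0.1, vacuole 0.34, mitochondrion 0.58 (x1e-9 m^2/s).
    """
    um = 1e-6
    return CellGeometry2D(
        domain_side=10 * um,
        cell=Circle(0.0, 0.0, 2.35 * um),
        wall_thickness=0.13 * um,
        organelles={
            "nucleus": Circle(-1.1 * um, 0.0, 1.0 * um),
            "vacuole": Circle(0.95 * um, 0.75 * um, 0.5 * um),
            "mitochondrion": Circle(0.55 * um, -1.15 * um, 0.25 * um),
        },
        region_D0={
            "exterior": 1.64e-9,
            "cytoplasm": 0.692e-9,
            "wall": 0.03e-9,
            "nucleus": 0.1e-9,
            "vacuole": 0.34e-9,
            "mitochondrion": 0.58e-9,
        },
    )


@dataclass(frozen=True)
class RWConfig:
    """Random-walk run parameters.

    ``tm_list`` readout times must be integer multiples of the step duration
    ``t_s``.  ``seed_mode`` places walkers uniformly in the region or at its
    representative center point; the center mode makes the long-time
    mean-square displacement converge to the stationary second moment
    (radial <r^2> -> R^2/2 in a disk), the convention under which the
    localization-regime size inversion holds.
    """

    tm_list: tuple[float, ...]
    t_s: float = 5e-6
    n_particles: int = 5000
    seed: int = 0
    seed_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.t_s <= 0:
            raise ValueError("t_s must be positive")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.seed_mode not in ("uniform", "center"):
            raise ValueError("seed_mode must be 'uniform' or 'center'")
        for tm in self.tm_list:
            n_steps(tm, self.t_s)  # validates multiples


def step_length(D0: float, t_s: float) -> float:
    """Fixed 2D step length sigma = sqrt(4*D0*t_s)."""
    if D0 < 0:
        raise ValueError("D0 must be non-negative")
    if t_s <= 0:
        raise ValueError("t_s must be positive")
    return math.sqrt(4.0 * D0 * t_s)


def n_steps(tm: float, t_s: float) -> int:
    """Number of walk steps N = t_m / t_s (must divide exactly)."""
    if tm <= 0 or t_s <= 0:
        raise ValueError("times must be positive")
    n = tm / t_s
    if abs(n - round(n)) > 1e-6 * max(1.0, n):
        raise ValueError(f"t_m = {tm} is not an integer multiple of t_s = {t_s}")
    return int(round(n))


def msd_to_D(msd, tm, d: int):
    """Apparent diffusion coefficient D = MSD / (2*d*t_m).

    ``msd`` is the d-dimensional mean-square displacement.
    """
    tm = np.asarray(tm, dtype=float)
    if np.any(tm <= 0):
        raise ValueError("t_m must be positive")
    out = np.asarray(msd, dtype=float) / (2.0 * d * tm)
    return out if out.ndim else float(out)


@dataclass
class DisplacementSummary:
    """Per-region displacement statistics at each readout time.

    ``table`` columns: region, tm (s), msd_r2 (m^2, radial), msd_axis (m^2,
    per-axis mean), r_mean (m), n_particles.
    """

    table: pd.DataFrame
    region: str
    seed: int

    def D(self, d: int = 2) -> np.ndarray:
        msd = self.table["msd_r2"] if d == 2 else 2.0 * self.table["msd_axis"]
        return msd_to_D(msd.to_numpy(), self.table["tm"].to_numpy(), d)


# -- core walk ---------------------------------------------------------------


def _seed_positions(rng, n, outer, excluded, rep, mode):
    if mode == "center" or outer is None:
        return np.tile(rep, (n, 1)).astype(float)
    pos = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        # uniform in the outer disk via radial inversion
        r = outer.r * np.sqrt(rng.random(m))
        th = rng.uniform(0.0, 2.0 * np.pi, m)
        cand = np.column_stack([outer.cx + r * np.cos(th),
                                outer.cy + r * np.sin(th)])
        ok = np.ones(m, dtype=bool)
        for c in excluded:
            ok &= np.hypot(cand[:, 0] - c.cx, cand[:, 1] - c.cy) >= c.r
        cand = cand[ok]
        pos[filled:filled + len(cand)] = cand
        filled += len(cand)
    return pos


def _reflect_circle(p, q, center, r, outward: bool):
    """Specularly reflect segments p->q off a circle.

    ``outward=True``: walkers must stay inside the circle (q escaped);
    ``outward=False``: walkers must stay outside (q entered).  Returns the
    reflected endpoints.
    """
    u = q - p
    pc = p - center
    a = (u * u).sum(axis=1)
    bq = 2.0 * (u * pc).sum(axis=1)
    cq = (pc * pc).sum(axis=1) - r * r
    disc = np.clip(bq * bq - 4.0 * a * cq, 0.0, None)
    sq = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (-bq + sq) / (2.0 * a) if outward else (-bq - sq) / (2.0 * a)
    s = np.clip(np.nan_to_num(s, nan=0.0), 0.0, 1.0)[:, None]
    h = p + s * u
    nvec = h - center
    norm = np.linalg.norm(nvec, axis=1, keepdims=True)
    nvec = nvec / np.where(norm > 0, norm, 1.0)
    v = q - h
    v_ref = v - 2.0 * (v * nvec).sum(axis=1, keepdims=True) * nvec
    return h + v_ref


def _confine(pos_old, pos_new, outer, excluded, max_iter: int = 25):
    """Reflect proposed steps until every endpoint lies inside the region."""
    q = pos_new
    for _ in range(max_iter):
        moved = False
        if outer is not None:
            d = np.hypot(q[:, 0] - outer.cx, q[:, 1] - outer.cy)
            out = d > outer.r
            if out.any():
                q[out] = _reflect_circle(
                    pos_old[out], q[out], outer.center, outer.r, outward=True
                )
                moved = True
        for c in excluded:
            d = np.hypot(q[:, 0] - c.cx, q[:, 1] - c.cy)
            inside = d < c.r
            if inside.any():
                q[inside] = _reflect_circle(
                    pos_old[inside], q[inside], c.center, c.r, outward=False
                )
                moved = True
        if not moved:
            return q
    # pathological leftovers (grazing corners): clamp radially
    if outer is not None:
        d = np.hypot(q[:, 0] - outer.cx, q[:, 1] - outer.cy)
        bad = d > outer.r
        if bad.any():
            q[bad] = outer.center + (q[bad] - outer.center) * (
                0.999 * outer.r / d[bad, None]
            )
    for c in excluded:
        d = np.hypot(q[:, 0] - c.cx, q[:, 1] - c.cy)
        bad = d < c.r
        if bad.any():
            q[bad] = c.center + (q[bad] - c.center) * (1.001 * c.r / d[bad, None])
    return q


def _assert_confined(pos, outer, excluded, tol=1e-12):
    if outer is not None:
        d = np.hypot(pos[:, 0] - outer.cx, pos[:, 1] - outer.cy)
        if np.any(d > outer.r * (1 + tol)):
            raise AssertionError("walker escaped its region")
    for c in excluded:
        d = np.hypot(pos[:, 0] - c.cx, pos[:, 1] - c.cy)
        if np.any(d < c.r * (1 - tol)):
            raise AssertionError("walker entered an excluded region")


def simulate(
    geometry: CellGeometry2D, region: str, config: RWConfig,
    check_confinement: bool = False,
) -> DisplacementSummary:
    """Random walk of ``n_particles`` walkers confined to one region.

    Fixed-length steps with uniform random directions; specular reflection at
    every boundary; per-axis and radial mean-square displacements (relative to
    each walker's start) recorded at every time in ``tm_list``.  Bit-identical
    for identical inputs and seed.
    """
    outer, excluded, rep = geometry.region(region)
    D0 = geometry.region_D0[region]
    sigma = step_length(D0, config.t_s)
    if outer is not None and sigma > 2.0 * outer.r:
        raise ValueError("step length exceeds the region size")
    rng = np.random.default_rng(config.seed)
    pos0 = _seed_positions(rng, config.n_particles, outer, excluded, rep,
                           config.seed_mode)
    pos = pos0.copy()

    record_at = {n_steps(tm, config.t_s): tm for tm in config.tm_list}
    total = max(record_at) if record_at else 0
    rows = []
    for step in range(1, total + 1):
        th = rng.uniform(0.0, 2.0 * np.pi, config.n_particles)
        prop = pos + sigma * np.column_stack([np.cos(th), np.sin(th)])
        pos = _confine(pos, prop, outer, excluded) if outer is not None else prop
        if check_confinement:
            _assert_confined(pos, outer, excluded, tol=1e-9)
        if step in record_at:
            disp = pos - pos0
            r2 = (disp * disp).sum(axis=1)
            rows.append({
                "region": region,
                "tm": record_at[step],
                "msd_r2": float(r2.mean()),
                "msd_axis": float((disp * disp).mean()),
                "r_mean": float(np.sqrt(r2).mean()),
                "n_particles": config.n_particles,
            })
    table = pd.DataFrame(rows).sort_values("tm").reset_index(drop=True)
    return DisplacementSummary(table, region, config.seed)


# -- TDDC and attenuation products -------------------------------------------


def simulated_tddc(
    geometry: CellGeometry2D,
    config: RWConfig,
    regions: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Piecewise time-dependent diffusion coefficients per region.

    For each confined region the direct estimate D(t_m) = <r^2>/(4*t_m) is
    fitted with the Mitra expansion at early times and the localization 1/t
    law at late times; the branches are joined at their crossover (closest
    approach when they do not intersect).  The unbounded exterior returns its
    flat direct estimate.  Columns: tm, msd_r2, D, D_piecewise.
    """
    from . import analysis

    if regions is None:
        regions = ["cytoplasm", "wall", *geometry.organelles.keys()]
    out: dict[str, pd.DataFrame] = {}
    for region in regions:
        summ = simulate(geometry, region, config)
        t = summ.table["tm"].to_numpy()
        D_direct = summ.D(d=2)
        df = summ.table[["tm", "msd_r2"]].copy()
        df["D"] = D_direct
        if region == "exterior":
            df["D_piecewise"] = D_direct
            out[region] = df
            continue
        outer, _, _ = geometry.region(region)
        D0 = geometry.region_D0[region]
        # early times: within ~15% of the start of the Mitra fall-off
        t_short = 0.25 * outer.r**2 / D0
        short = t <= max(t_short, t[min(2, len(t) - 1)])
        ns = max(3, int(short.sum()))
        late = t >= t[max(0, len(t) - max(3, len(t) // 3))]
        try:
            mit = analysis.fit_mitra(t[:ns], D_direct[:ns], W=3)
            reg2 = analysis.fit_region2(t[late], D_direct[late], d=2,
                                        fix_exponent=True)
            cross = analysis.crossover_time(mit, reg2, t)
            df["D_piecewise"] = analysis.piecewise_D(t, mit, reg2, cross.t_star)
        except ValueError:
            df["D_piecewise"] = D_direct
        out[region] = df
    return out


def simulated_attenuation(
    D_of_tm: Mapping[str, Sequence[float]],
    tm_list: Sequence[float],
    targets: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Attenuation-vs-b curves per region from its D(t_m) values.

    For a priori attenuation targets E/E0 (descending from 1 towards 0.01)
    the required weighting is b = -ln(E/E0)/D; a zero coefficient yields an
    infinite-b sentinel.  Columns: region, tm, E, b.
    """
    if targets is None:
        targets = np.geomspace(1.0, 0.01, 20)
    targets = np.asarray(targets, dtype=float)
    if np.any(targets <= 0) or np.any(targets > 1):
        raise ValueError("targets must lie in (0, 1]")
    if np.any(np.diff(targets) > 0):
        raise ValueError("targets must be descending")
    rows = []
    for region, Ds in D_of_tm.items():
        Ds = np.asarray(Ds, dtype=float)
        if len(Ds) != len(tm_list):
            raise ValueError("D values and tm_list lengths differ")
        for tm, D in zip(tm_list, Ds):
            if D > 0:
                b = b_for_target_attenuation(D, targets)
            else:
                b = np.where(targets < 1.0, np.inf, 0.0)
            for t_k, b_k in zip(targets, np.atleast_1d(b)):
                rows.append({"region": region, "tm": float(tm),
                             "E": float(t_k), "b": float(b_k)})
    return pd.DataFrame(rows)
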