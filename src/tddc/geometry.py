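"""Geometric bookkeeping for cellular structures.

Sphere/shell volumes, total volumes per structure class, volume fractions of
the intracellular space, molar-fraction weights and weighted mean sizes — the
arithmetic used to relate fitted diffusion compartments to yeast anatomy
(whole cell, cell wall + membrane, nucleus, vacuoles, mitochondria).

Sizes are radii in um and volumes in um^3 throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureSpec",
    "StructureDerived",
    "sphere_volume",
    "shell_volume",
    "derive_structure",
    "weighted_mean_size",
    "expected_molar_fractions",
    "yeast_structures",
    "structure_table",
]


def sphere_volume(R: float) -> float:
    """Volume of a sphere of radius R (um -> um^3)."""
    if R < 0:
        raise ValueError("radius must be non-negative")
    return 4.0 / 3.0 * np.pi * R**3


def shell_volume(R_outer: float, thickness: float) -> float:
    """Volume of a spherical shell: outer sphere minus inner sphere."""
    if not 0 < thickness < R_outer:
        raise ValueError("need 0 < thickness < R_outer")
    return sphere_volume(R_outer) - sphere_volume(R_outer - thickness)


@dataclass(frozen=True)
class StructureSpec:
    """One class of cellular structure.

    ``radius`` is a radius in um; for shells give the outer radius plus
    ``thickness``.  ``count`` is the number of such structures per cell
    (fractional mean counts allowed).  ``d0_literature`` optionally carries a
    literature bulk self-diffusion coefficient (m^2/s) as an annotation.
    """

    name: str
    radius: float
    count: float = 1.0
    shape: str = "sphere"  # "sphere" | "shell"
    thickness: float | None = None
    d0_literature: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.count <= 0:
            raise ValueError("count must be positive")
        if self.shape not in ("sphere", "shell"):
            raise ValueError("shape must be 'sphere' or 'shell'")
        if self.shape == "shell" and (
            self.thickness is None or not 0 < self.thickness < self.radius
        ):
            raise ValueError("shell needs 0 < thickness < radius")

    def unit_volume(self) -> float:
        if self.shape == "shell":
            return shell_volume(self.radius, self.thickness)
        return sphere_volume(self.radius)


@dataclass(frozen=True)
class StructureDerived:
    """Derived volumetrics of a structure class."""

    name: str
    V_unit: float  # um^3 per structure
    V_total: float  # um^3 per cell
    f: float  # V_total / V_intracellular
    f_p02: float  # f weighted by the intracellular molar fraction


def derive_structure(
    spec: StructureSpec, V_intracellular: float, p02: float
) -> StructureDerived:
    """Total volume, intracellular volume fraction f and f*p02 for a structure."""
    if V_intracellular <= 0:
        raise ValueError("V_intracellular must be positive")
    if not 0 <= p02 <= 1:
        raise ValueError("p02 must lie in [0, 1]")
    v_unit = spec.unit_volume()
    v_tot = spec.count * v_unit
    f = v_tot / V_intracellular
    return StructureDerived(spec.name, v_unit, v_tot, f, f * p02)


def weighted_mean_size(structures: Iterable[tuple[float, float]]) -> float:
    """Weighted mean of (size, weight) pairs: sum(size*w)/sum(w)."""
    sizes, weights = zip(*structures)
    w = np.asarray(weights, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    return float((s * w).sum() / w.sum())


def expected_molar_fractions(
    assignment: Mapping[str, Sequence[StructureDerived]], p01: float
) -> dict[str, float]:
    """Split the intracellular molar fraction across compartments.

    ``assignment`` maps a compartment name to the structures contributing to it
    (e.g. the short-time map: nucleus + wall + mitochondrion -> compartment 3,
    the remaining intracellular volume -> compartment 2).  The intracellular
    fraction 1 - p01 is split proportionally to the summed volume fractions f.
    """
    if not 0 < p01 < 1:
        raise ValueError("p01 must lie in (0, 1)")
    if not assignment:
        raise ValueError("empty compartment assignment")
    f_sums = {
        comp: float(sum(d.f for d in derived))
        for comp, derived in assignment.items()
    }
    total = sum(f_sums.values())
    if total == 0:
        raise ValueError("all assigned volume fractions are zero")
    p_intra = 1.0 - p01
    return {comp: p_intra * f / total for comp, f in f_sums.items()}


# -- default yeast anatomy ---------------------------------------------------

#: Intracellular molar fraction used to weight f in the structure table.
DEFAULT_P02 = 0.65

#: Cell-wall(+membrane) thickness range reported for S. cerevisiae, um.
WALL_THICKNESS_RANGE = (0.0792, 0.180)


def yeast_structures(wall_thickness: float | None = None) -> dict[str, StructureSpec]:
    """Literature geometry of a budding-yeast cell.

    Radii/counts: whole cell ~3 um; nucleus 1 um; vacuoles 1 um x 2.7;
    mitochondria 0.25 um x 2.3; combined cell wall + membrane thickness
    0.0792-0.180 um (``wall_thickness`` picks a value; default lower bound).
    """
    w = WALL_THICKNESS_RANGE[0] if wall_thickness is None else wall_thickness
    return {
        "whole_cell": StructureSpec("whole_cell", 3.0),
        "intracellular": StructureSpec("intracellular", 3.0 - w),
        "wall": StructureSpec(
            "wall", 3.0, shape="shell", thickness=w, d0_literature=0.03e-9
        ),
        "nucleus": StructureSpec("nucleus", 1.0, d0_literature=(0.01e-9, 0.1e-9)),
        "vacuole": StructureSpec("vacuole", 1.0, count=2.7, d0_literature=0.34e-9),
        "mitochondrion": StructureSpec(
            "mitochondrion", 0.25, count=2.3, d0_literature=0.58e-9
        ),
    }


def structure_table(
    wall_thickness: float | None = None, p02: float = DEFAULT_P02
) -> pd.DataFrame:
    """Volumetric summary of the default yeast anatomy.

    Columns: radius_um, count, V_unit_um3, V_total_um3, f, f_p02.  The volume
    fraction f is taken against the intracellular sphere (cell radius minus
    wall thickness); the whole-cell row carries no f.
    """
    specs = yeast_structures(wall_thickness)
    v_intra = specs["intracellular"].unit_volume()
    rows = []
    for name, spec in specs.items():
        if name == "whole_cell":
            rows.append((name, spec.radius, spec.count, spec.unit_volume(),
                         spec.unit_volume(), np.nan, np.nan))
            continue
        d = derive_structure(spec, v_intra, p02)
        rows.append((name, spec.radius, spec.count, d.V_unit, d.V_total, d.f, d.f_p02))
    return pd.DataFrame(
        rows,
        columns=["structure", "radius_um", "count", "V_unit_um3",
                 "V_total_um3", "f", "f_p02"],
    ).set_index("structure")
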