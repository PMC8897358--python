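"""Resistance-surface transformations.

A raw covariate rescaled to [0, 1] is turned into a resistance surface by
one of eight two-parameter exponential transformation families, each
defined by a shape parameter ``s`` and a maximum resistance ``m``:

* Monomolecular base curve f(r) = 1 - exp(-r / s) (saturating increase)
* Ricker base curve f(r) = r * exp(-r / s) (unimodal)
* "Reverse" evaluates the base curve at (1 - r) (argument reflection)
* "Inverse" reflects the transformed values (value reflection)

After transformation, values are affinely rescaled so valid cells span
exactly [1, m]; the minimum resistance of 1 makes a uniform (isolation-by-
distance) surface the m -> 1 limit of every family. Composite surfaces sum
cell resistances and report each part's percent contribution to the total
cost of traveling through a cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RasterGrid
from .raster_prep import assert_grid_consistent

__all__ = [
    "FAMILIES",
    "TransformSpec",
    "ResistanceSurface",
    "CompositeSummary",
    "rescale01",
    "apply_transform",
    "compose_surfaces",
    "average_surfaces",
]

FAMILIES = (
    "Monomolecular",
    "Reverse Monomolecular",
    "Inverse Monomolecular",
    "Inverse-Reverse Monomolecular",
    "Ricker",
    "Reverse Ricker",
    "Inverse Ricker",
    "Inverse-Reverse Ricker",
)


@dataclass(frozen=True)
class TransformSpec:
    """One transformation family with shape ``s`` > 0 and max resistance ``m`` > 1."""

    family: str
    shape: float
    max_resistance: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown transformation family {self.family!r}")
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError("shape must be finite and > 0")
        if not (np.isfinite(self.max_resistance) and self.max_resistance > 1):
            raise ValueError("max_resistance must be finite and > 1")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "shape": self.shape,
            "max": self.max_resistance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        return cls(d["family"], d["shape"], d["max"])


@dataclass
class ResistanceSurface:
    """A resistance raster plus where it came from.

    Valid cells are always >= 1 and finite; low resistance means ease of
    movement.
    """

    grid: RasterGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.grid.valid_values()
        if v.size and (not np.all(np.isfinite(v)) or v.min() < 1.0 - 1e-9):
            raise ValueError("resistance values must be finite and >= 1")


@dataclass
class CompositeSummary:
    """Percent contribution of each part to the total per-cell travel cost."""

    contributions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError("contributions must sum to 100%")


def rescale01(grid: RasterGrid) -> RasterGrid:
    """Affine rescale of valid cells onto [0, 1] (min -> 0, max -> 1)."""
    v = grid.valid_values()
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError(
            f"covariate {grid.name!r} is constant over valid cells; it "
            "carries no resistance information"
        )
    lo, hi = v.min(), v.max()
    out = (grid.values - lo) / (hi - lo)
    return grid.with_values(out)


def _base_curve(r: np.ndarray, family: str, s: float) -> np.ndarray:
    base = family.split()[-1]  # Monomolecular | Ricker
    if "Reverse" in family:
        r = 1.0 - r
    if base == "Monomolecular":
        return 1.0 - np.exp(-r / s)
    return r * np.exp(-r / s)


def apply_transform(g01: RasterGrid, t: TransformSpec) -> ResistanceSurface:
    """Apply one transformation family to a [0, 1]-scaled covariate.

    The result spans exactly [1, m] over valid cells. Monotone families
    preserve (or exactly reverse) the input ordering; "Inverse" families
    reflect the transformed values before the final rescale.
    """
    vals = g01.valid_values()
    if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
        raise ValueError("input must be rescaled to [0, 1] first (see rescale01)")
    f = _base_curve(np.clip(g01.values, 0.0, 1.0), t.family, t.shape)
    if "Inverse" in t.family:
        fmax = f[g01.valid].max()
        f = fmax - f
    fv = f[g01.valid]
    lo, hi = fv.min(), fv.max()
    if hi - lo < 1e-15:
        out = np.ones_like(f)
    else:
        out = 1.0 + (f - lo) / (hi - lo) * (t.max_resistance - 1.0)
    grid = RasterGrid(out, g01.spec, mask=g01.mask.copy(), name=f"{g01.name}_resistance")
    return ResistanceSurface(grid, provenance={"covariate": g01.name, **t.to_dict()})


def compose_surfaces(
    parts: list[ResistanceSurface],
) -> tuple[ResistanceSurface, CompositeSummary]:
    """Cellwise sum of part resistances, with percent cost contributions.

    Contribution of part p = mean over valid cells of part_p / sum(parts),
    times 100.
    """
    if not parts:
        raise ValueError("need at least one surface to compose")
    assert_grid_consistent([p.grid for p in parts])
    stack = np.stack([p.grid.values for p in parts])
    mask = np.logical_or.reduce([p.grid.mask for p in parts])
    total = stack.sum(axis=0)
    valid = ~mask
    shares = stack[:, valid] / total[valid]
    contribs = shares.mean(axis=1) * 100.0
    contribs = contribs / contribs.sum() * 100.0
    names: list[str] = []
    for i, p in enumerate(parts):
        n = p.provenance.get("covariate") or p.grid.name or f"part{i}"
        while n in names:
            n = f"{n}_{i}"
        names.append(n)
    grid = RasterGrid(total, parts[0].grid.spec, mask=mask, name="composite_resistance")
    surface = ResistanceSurface(
        grid, provenance={"composite": [p.provenance for p in parts]}
    )
    return surface, CompositeSummary(dict(zip(names, contribs)))


def average_surfaces(runs: list[ResistanceSurface]) -> ResistanceSurface:
    """Cellwise arithmetic mean of resistance surfaces across replicate runs."""
    if not runs:
        raise ValueError("need at least one surface to average")
    assert_grid_consistent([r.grid for r in runs])
    mask = np.logical_or.reduce([r.grid.mask for r in runs])
    mean = np.mean([r.grid.values for r in runs], axis=0)
    grid = RasterGrid(mean, runs[0].grid.spec, mask=mask, name="averaged_resistance")
    return ResistanceSurface(
        grid, provenance={"averaged": [r.provenance for r in runs]}
    )
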