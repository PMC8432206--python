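"""Rectangular (gestational age, birth-weight Z) grids and orthant integration.

The joint outcome space of the competing-risks model is two dimensional:
gestational age at delivery (weeks) on one axis and birth-weight Z score on
the other.  All densities in this package are carried on a regular grid over
that space and integrated with trapezoidal weights; risks are masses of the
lower-left orthant ``{Z < z_cut, GA < ga_cut}`` with linear interpolation at
the cut planes so that cut-offs falling between nodes do not produce step
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid2D", "trapezoid_weights", "orthant_mass"]


def trapezoid_weights(axis: np.ndarray) -> np.ndarray:
    """Composite trapezoid quadrature weights for an increasing 1-D axis."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be 1-D with at least two nodes")
    d = np.diff(axis)
    if np.any(d <= 0):
        raise ValueError("axis must be strictly increasing")
    w = np.zeros_like(axis)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


@dataclass(frozen=True)
class Grid2D:
    """Regular grid over (GA at delivery, birth-weight Z score).

    Density arrays associated with a grid have shape ``(len(ga), len(z))``.
    """

    ga: np.ndarray
    z: np.ndarray
    w_ga: np.ndarray = field(init=False, repr=False)
    w_z: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ga = np.asarray(self.ga, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "ga", ga)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "w_ga", trapezoid_weights(ga))
        object.__setattr__(self, "w_z", trapezoid_weights(z))

    @classmethod
    def default(
        cls,
        ga_range: tuple[float, float] = (24.0, 43.0),
        z_range: tuple[float, float] = (-6.0, 5.0),
        step: float = 0.05,
    ) -> "Grid2D":
        """The default carrier grid: [24, 43] x [-6, 5] weeks x Z at `step`."""
        n_ga = int(round((ga_range[1] - ga_range[0]) / step)) + 1
        n_z = int(round((z_range[1] - z_range[0]) / step)) + 1
        return cls(
            ga=np.linspace(ga_range[0], ga_range[1], n_ga),
            z=np.linspace(z_range[0], z_range[1], n_z),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ga.size, self.z.size)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(GA, Z) meshgrid arrays of shape ``self.shape`` (ij indexing)."""
        return np.meshgrid(self.ga, self.z, indexing="ij")

    def mass(self, density: np.ndarray) -> float:
        """Trapezoidal integral of a density array over the whole grid."""
        density = np.asarray(density, dtype=float)
        if density.shape != self.shape:
            raise ValueError(f"density shape {density.shape} != grid {self.shape}")
        return float(self.w_ga @ density @ self.w_z)


def _cum_to_cut(axis: np.ndarray, values: np.ndarray, cut: float) -> np.ndarray:
    """Integrate ``values`` along the last axis up to ``cut`` (trapezoid).

    The last, partial cell is handled by linearly interpolating the integrand
    at the cut and integrating the resulting trapezoid exactly.
    """
    if cut < axis[0] or cut > axis[-1]:
        raise ValueError(f"cut {cut} outside grid range [{axis[0]}, {axis[-1]}]")
    j = int(np.searchsorted(axis, cut, side="right")) - 1
    # full cells up to node j
    if j > 0:
        d = np.diff(axis[: j + 1])
        full = 0.5 * ((values[..., : j] + values[..., 1 : j + 1]) * d).sum(axis=-1)
    else:
        full = np.zeros(values.shape[:-1])
    if j >= axis.size - 1:
        return full
    frac = (cut - axis[j]) / (axis[j + 1] - axis[j])
    v_cut = values[..., j] * (1.0 - frac) + values[..., j + 1] * frac
    partial = 0.5 * (values[..., j] + v_cut) * (cut - axis[j])
    return full + partial


def orthant_mass(grid: Grid2D, density: np.ndarray, z_cut: float, ga_cut: float) -> float:
    """Mass of ``{Z < z_cut, GA < ga_cut}`` under a gridded density.

    Uses half-open lower orthants with linear interpolation of the density at
    each cut plane.  For a normalized density the result lies in [0, 1] up to
    quadrature error.
    """
    density = np.asarray(density, dtype=float)
    if density.shape != grid.shape:
        raise ValueError(f"density shape {density.shape} != grid {grid.shape}")
    f_of_ga = _cum_to_cut(grid.z, density, z_cut)  # shape (n_ga,)
    return float(_cum_to_cut(grid.ga, f_of_ga, ga_cut))
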