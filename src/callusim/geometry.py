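"""Healing-region geometry: callus, cortex and recruitment boundaries.

The simulated domain is the mid-axis plane of a long-bone fracture: the bone
is idealized as a hollow cylinder (two cortical walls flanking the medullary
canal in section) and the callus as a spheroid, so its section is an ellipse
centred on the fracture gap.  The healing region is the part of the callus
ellipse that is neither cortical bone nor marrow canal; immune cells are
recruited into it across the marrow interface (the canal openings at the gap)
and across the curved periosteal surface of the callus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised for degenerate or inconsistent domain geometry."""


@dataclass(frozen=True)
class DomainSpec:
    """Geometric description of the fracture domain.

    Lengths in µm.  Defaults reproduce a murine tibial osteotomy with a
    1 mm gap (the calibration geometry); the validation femur geometry is
    obtained by setting ``gap_width=700``.

    Parameters
    ----------
    gap_width
        Fracture-gap size along the bone axis (1000 calibration, 700
        validation).
    cortex_thickness
        Radial thickness of the cortical wall.
    bone_outer_radius
        Outer radius of the bone cylinder.
    callus_semi_axes
        Ellipse semi-axes of the callus section ``(axial, transverse)``:
        along the bone axis (y) and across it (x).
    mol_resolution
        Molecular-grid voxel size (µm).
    cell_resolution
        Cell-lattice spacing (µm); cell positions snap to this lattice.
    extent
        Side of the square simulation domain (µm).
    quarter
        If True, only the first quadrant (x ≥ 0, y ≥ 0) is built; the cut
        axes behave as no-flux mirror planes, valid for symmetric specs.
    """

    gap_width: float = 1000.0
    cortex_thickness: float = 200.0
    bone_outer_radius: float = 500.0
    callus_semi_axes: tuple[float, float] = (1000.0, 800.0)
    mol_resolution: float = 10.0
    cell_resolution: float = 1.0
    extent: float = 2000.0
    quarter: bool = False

    def __post_init__(self) -> None:
        lengths = (
            self.gap_width,
            self.cortex_thickness,
            self.bone_outer_radius,
            *self.callus_semi_axes,
            self.mol_resolution,
            self.cell_resolution,
            self.extent,
        )
        if any(not np.isfinite(v) or v <= 0 for v in lengths):
            raise ConfigurationError("all domain lengths must be positive and finite")
        n = self.extent / self.mol_resolution
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("mol_resolution must divide extent")
        if self.gap_width >= self.extent:
            raise ConfigurationError("gap_width must be smaller than extent (no cortex remains)")
        if self.cortex_thickness >= self.bone_outer_radius:
            raise ConfigurationError("cortex_thickness must be below bone_outer_radius")
        if self.callus_semi_axes[1] <= self.bone_outer_radius:
            raise ConfigurationError("callus smaller than the bone cortex (transverse semi-axis)")

    @property
    def inner_radius(self) -> float:
        return self.bone_outer_radius - self.cortex_thickness


@dataclass
class DomainMasks:
    """Boolean rasters (molecular resolution) classifying the domain.

    All arrays have shape ``(ny, nx)``; ``coords`` gives voxel-centre
    coordinates in µm with the origin at the fracture centre (full plane)
    or at the corner of the symmetry quadrant.
    """

    healing_region: np.ndarray
    cortex: np.ndarray
    marrow_interface: np.ndarray
    periosteal_boundary: np.ndarray
    cortex_boundary: np.ndarray
    resolution: float
    origin: tuple[float, float]  # µm coordinate of the (0, 0) voxel corner
    spec: DomainSpec = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.healing_region.shape

    @property
    def recruitment_boundary(self) -> np.ndarray:
        return self.marrow_interface | self.periosteal_boundary

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) µm coordinates of voxel centres as 1D arrays (cols, rows)."""
        h = self.resolution
        ny, nx = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * h
        y = self.origin[1] + (np.arange(ny) + 0.5) * h
        return x, y

    def voxel_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the voxels containing µm positions."""
        h = self.resolution
        col = np.clip(((np.asarray(x) - self.origin[0]) / h).astype(np.int64), 0, self.shape[1] - 1)
        row = np.clip(((np.asarray(y) - self.origin[1]) / h).astype(np.int64), 0, self.shape[0] - 1)
        return row, col


def _adjacent_to(mask: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Sites of `mask` with a 4-neighbour in `other`."""
    nb = np.zeros_like(other, dtype=bool)
    nb[1:, :] |= other[:-1, :]
    nb[:-1, :] |= other[1:, :]
    nb[:, 1:] |= other[:, :-1]
    nb[:, :-1] |= other[:, 1:]
    return mask & nb


def build_domain(spec: DomainSpec) -> DomainMasks:
    """Rasterize the callus/cortex geometry into classification masks.

    The healing region is ``callus ellipse − cortex − marrow canal``; the
    gap segment of the canal (between the cut cortex ends) belongs to the
    healing region, which is how the marrow side connects to the callus.
    """
    h = spec.mol_resolution
    n = int(round(spec.extent / h))
    # voxel-centre coordinates, origin at the fracture centre
    c = (np.arange(n) + 0.5) * h - spec.extent / 2.0
    x, y = np.meshgrid(c, c)  # x: columns, y: rows (bone axis along y)

    ax_axial, ax_trans = spec.callus_semi_axes
    callus = (x / ax_trans) ** 2 + (y / ax_axial) ** 2 <= 1.0
    half_gap = spec.gap_width / 2.0
    wall = (np.abs(x) >= spec.inner_radius) & (np.abs(x) <= spec.bone_outer_radius)
    cortex = wall & (np.abs(y) >= half_gap)
    marrow = (np.abs(x) < spec.inner_radius) & (np.abs(y) >= half_gap)

    healing = callus & ~cortex & ~marrow
    exterior = ~callus & ~cortex & ~marrow

    if cortex.sum() == 0:
        raise ConfigurationError("degenerate geometry: no cortex inside the domain")
    if healing.sum() == 0:
        raise ConfigurationError("degenerate geometry: empty healing region")

    marrow_interface = _adjacent_to(healing, marrow)
    cortex_boundary = _adjacent_to(healing, cortex)
    periosteal = _adjacent_to(healing, exterior) & ~cortex_boundary & ~marrow_interface

    origin = (-spec.extent / 2.0, -spec.extent / 2.0)
    masks = DomainMasks(
        healing_region=healing,
        cortex=cortex,
        marrow_interface=marrow_interface,
        periosteal_boundary=periosteal,
        cortex_boundary=cortex_boundary,
        resolution=h,
        origin=origin,
        spec=spec,
    )
    if spec.quarter:
        n2 = n // 2
        sl = (slice(n2, None), slice(n2, None))
        masks = DomainMasks(
            healing_region=healing[sl],
            cortex=cortex[sl],
            marrow_interface=marrow_interface[sl],
            periosteal_boundary=periosteal[sl],
            cortex_boundary=cortex_boundary[sl],
            resolution=h,
            origin=(0.0, 0.0),
            spec=spec,
        )
        if masks.healing_region.sum() == 0:
            raise ConfigurationError("degenerate geometry: empty healing region (quarter)")
    return masks


def area_of(mask: np.ndarray, resolution: float) -> float:
    """Area of a boolean raster in mm² (pixel count × resolution²)."""
    return float(np.count_nonzero(mask)) * resolution**2 * 1e-6
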