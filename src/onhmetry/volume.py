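"""In-memory containers for segmented OCT acquisitions.

Axis convention (fixed throughout the package):

* ``labels[bscan_index, ascan_index, axial_index]`` with 0-based indices;
* the axial index increases with depth (vitreous -> choroid);
* en-face physical coordinates are ``x = ascan_index * spacing_ascan_um``
  and ``y = bscan_index * spacing_bscan_um`` with the origin at voxel
  (0, 0). All geometry is done in micrometres because voxel spacings are
  anisotropic.

Two acquisition families are supported: raster "cube" volumes (a full 3D
label array) and radial+circular sets (2D label slices with angle or
diameter metadata), mirroring the scan patterns of the commercial devices
the extraction pipeline was designed to harmonise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import FormatError
from .scheme import LabelScheme, DEFAULT_SCHEME


@dataclass
class LabelVolume:
    """A 3D multi-class segmentation label volume with physical metadata."""

    labels: np.ndarray  # (n_bscans, n_ascans, n_axial) integer array
    spacing_bscan_um: float
    spacing_ascan_um: float
    spacing_axial_um: float
    laterality: str = "OD"  # OD (right) | OS (left)
    acquisition: str = "cube"  # cube | radial_circular
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    fovea_enface_um: Optional[tuple] = None  # (x, y) in en-face um

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label array must be 3D (bscan, ascan, axial)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label array must have an integer dtype")
        for name in ("spacing_bscan_um", "spacing_ascan_um", "spacing_axial_um"):
            if not getattr(self, name) > 0:
                raise FormatError(f"{name} must be > 0")
        if self.laterality not in ("OD", "OS"):
            raise FormatError("laterality must be 'OD' or 'OS'")
        if self.acquisition not in ("cube", "radial_circular"):
            raise FormatError("acquisition must be 'cube' or 'radial_circular'")
        present = np.unique(self.labels)
        allowed = set(self.scheme.all_codes)
        unknown = [int(c) for c in present if int(c) not in allowed]
        if unknown:
            raise FormatError(
                f"voxel codes {unknown} are not declared in the label scheme"
            )

    @property
    def shape(self):
        return self.labels.shape

    @property
    def n_bscans(self) -> int:
        return self.labels.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.labels.shape[1]

    @property
    def n_axial(self) -> int:
        return self.labels.shape[2]

    @property
    def enface_extent_um(self) -> tuple:
        """(x_max, y_max) of the en-face voxel-centre grid in um."""
        return (
            (self.n_ascans - 1) * self.spacing_ascan_um,
            (self.n_bscans - 1) * self.spacing_bscan_um,
        )

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            labels=self.labels.copy(),
            spacing_bscan_um=self.spacing_bscan_um,
            spacing_ascan_um=self.spacing_ascan_um,
            spacing_axial_um=self.spacing_axial_um,
            laterality=self.laterality,
            acquisition=self.acquisition,
            scheme=self.scheme,
            fovea_enface_um=self.fovea_enface_um,
        )


@dataclass
class RadialSlice:
    """One radial B-scan through the measurement centre.

    ``labels`` is indexed (radial_position, axial). ``center_offset`` is
    the index of the column at the measurement centre; lateral physical
    position of column ``j`` is ``(j - center_offset) * lateral_step_um``.
    ``angle_deg`` is the slice direction in the TSNIT degree convention
    (the positive lateral half points along that angle).
    """

    angle_deg: float
    labels: np.ndarray
    lateral_step_um: float
    axial_step_um: float
    center_offset: int
    provenance: str = "acquired"  # acquired | synthesized

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("radial slice must be 2D (lateral, axial)")
        if not (0 <= self.center_offset < self.labels.shape[0]):
            raise FormatError("center column outside radial slice")
        if not self.lateral_step_um > 0 or not self.axial_step_um > 0:
            raise FormatError("radial slice steps must be > 0")

    @property
    def lateral_positions_um(self) -> np.ndarray:
        j = np.arange(self.labels.shape[0])
        return (j - self.center_offset) * self.lateral_step_um


@dataclass
class CircularSlice:
    """One circular B-scan at a fixed diameter around the centre.

    Column ``i`` sits at TSNIT angle ``start_angle_deg + direction * i * step``
    where ``step = 360 / n_columns`` and ``direction`` is +1 for columns
    proceeding in increasing TSNIT angle, -1 otherwise.
    """

    diameter_mm: float
    labels: np.ndarray  # (circumferential_position, axial)
    axial_step_um: float
    start_angle_deg: float = 0.0
    direction: int = 1

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("circular slice must be 2D (position, axial)")
        if not self.diameter_mm > 0:
            raise FormatError("circular slice diameter must be > 0")
        if self.direction not in (1, -1):
            raise FormatError("direction must be +1 or -1")

    @property
    def n_columns(self) -> int:
        return self.labels.shape[0]

    @property
    def angles_deg(self) -> np.ndarray:
        i = np.arange(self.n_columns)
        step = 360.0 / self.n_columns
        return np.mod(self.start_angle_deg + self.direction * i * step, 360.0)

    @property
    def lateral_step_um(self) -> float:
        """Arc length between neighbouring columns."""
        return np.pi * self.diameter_mm * 1e3 / self.n_columns


@dataclass
class RadialCircularSet:
    """A radial + circular acquisition (SPECTRALIS-style scan pattern)."""

    radial_slices: Sequence[RadialSlice]
    circular_slices: Sequence[CircularSlice]
    laterality: str = "OD"
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    fovea_enface_um: Optional[tuple] = None

    def __post_init__(self):
        angles = [float(s.angle_deg) % 180.0 for s in self.radial_slices]
        if len(set(np.round(angles, 6))) != len(angles):
            raise FormatError("radial slice angles must be distinct in [0, 180)")
        for c in self.circular_slices:
            if not c.diameter_mm > 0:
                raise FormatError("circular diameters must be > 0")

    def circular_at(self, diameter_mm: float, tol: float = 1e-6) -> CircularSlice:
        for c in self.circular_slices:
            if abs(c.diameter_mm - diameter_mm) <= tol:
                return c
        raise KeyError(f"no circular slice at {diameter_mm} mm")
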