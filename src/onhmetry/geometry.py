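"""Shared coordinate conventions, en-face projection and resampling.

TSNIT degree convention
-----------------------
Circumpapillary profiles are indexed by an angle in degrees with
0° = temporal, 90° = superior, 180° = nasal, 270° = inferior, for both
eyes. Geometrically the sweep runs counterclockwise in the en-face view
for right eyes (OD) and clockwise for left eyes (OS); this mirroring makes
profiles from fellow eyes directly comparable.

The en-face plane uses x = ascan * spacing_ascan_um (increasing to the
"right" of the B-scan) and y = bscan * spacing_bscan_um. Superior is taken
toward smaller bscan indices. When a fovea position is available the
temporal axis (0°) is rotated onto the disc-centre -> fovea direction,
correcting for the tilt of the optic disc with respect to the fovea;
without a fovea the horizontal temporal direction implied by laterality is
used and a warning flag is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, OutOfBoundsError
from .volume import LabelVolume, RadialSlice


# TSNIT sectors: name -> (start_deg, end_deg), half-open [start, end),
# centred on the anatomical axes. Widths: TS 40, NS 40, N 110, NI 40,
# TI 40, T 90 (T wraps around 0°).
TSNIT_SECTORS = {
    "T": (315.0, 45.0),
    "TS": (45.0, 85.0),
    "NS": (85.0, 125.0),
    "N": (125.0, 235.0),
    "NI": (235.0, 275.0),
    "TI": (275.0, 315.0),
}

TSNIT_SECTOR_WIDTHS = {"T": 90.0, "TS": 40.0, "NS": 40.0, "N": 110.0,
                       "NI": 40.0, "TI": 40.0}


def sector_width_deg(name: str) -> float:
    start, end = TSNIT_SECTORS[name]
    return (end - start) % 360.0


def sector_of(angles_deg: np.ndarray) -> np.ndarray:
    """Map TSNIT angles to sector names (object array)."""
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    out = np.empty(a.shape, dtype=object)
    for name, (start, end) in TSNIT_SECTORS.items():
        if start < end:
            sel = (a >= start) & (a < end)
        else:  # wrapped sector (temporal)
            sel = (a >= start) | (a < end)
        out[sel] = name
    return out


def clock_hour_of(angles_deg: np.ndarray) -> np.ndarray:
    """Map TSNIT angles to clock hours 1..12.

    Hour 12 is centred at superior (90°); numbering proceeds nasally,
    which in TSNIT degrees is the direction of increasing angle for both
    eyes (the TSNIT convention already mirrors OS). Each hour spans 30°.
    """
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    # hour h is centred at (90 + 30*h) mod 360 for h = 0 (=12), 1, ..., 11
    h = np.floor(np.mod(a - 90.0 + 15.0, 360.0) / 30.0).astype(int)
    h = np.where(h == 0, 12, h)
    return h


@dataclass
class EnFaceMap:
    """A scalar or binary 2D grid in the en-face (fundus) plane.

    ``values[bscan_index, ascan_index]``; ``undefined`` flags pixels with
    no meaningful value (True = undefined).
    """

    values: np.ndarray
    spacing_x_um: float  # along ascan index (columns)
    spacing_y_um: float  # along bscan index (rows)
    undefined: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("en-face map must be 2D")
        if not (self.spacing_x_um > 0 and self.spacing_y_um > 0):
            raise ValueError("en-face spacings must be > 0")
        if self.undefined is None:
            self.undefined = np.zeros(self.values.shape, dtype=bool)
        else:
            self.undefined = np.asarray(self.undefined, dtype=bool)
            if self.undefined.shape != self.values.shape:
                raise ValueError("undefined mask shape mismatch")

    @property
    def shape(self):
        return self.values.shape

    @property
    def extent_um(self) -> tuple:
        """(x_max, y_max) of the pixel-centre grid."""
        ny, nx = self.values.shape
        return ((nx - 1) * self.spacing_x_um, (ny - 1) * self.spacing_y_um)


@dataclass
class AngularProfile:
    """Values indexed by angle on the circular TSNIT domain.

    Angles are strictly increasing in [0, 360) and the domain wraps
    (360 == 0). ``undefined`` flags angles without a valid value.
    """

    angles_deg: np.ndarray
    values: np.ndarray
    undefined: Optional[np.ndarray] = None
    convention: str = "tsnit"

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.angles_deg.shape != self.values.shape:
            raise ValueError("angles and values must have equal length")
        if self.angles_deg.size and (
            np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 360)
        ):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.undefined is None:
            self.undefined = np.zeros(self.values.shape, dtype=bool)
        else:
            self.undefined = np.asarray(self.undefined, dtype=bool)

    def __len__(self):
        return self.angles_deg.size

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[~self.undefined]

    def mean(self) -> float:
        """Mean over defined samples."""
        v = self.defined_values
        return float(np.mean(v)) if v.size else float("nan")

    def is_uniform(self, tol: float = 1e-6) -> bool:
        """True when the samples are equally spaced over the full circle."""
        if len(self) < 2:
            return True
        steps = np.diff(self.angles_deg)
        return bool(np.allclose(steps, 360.0 / len(self), atol=tol))


@dataclass
class TsnitTransform:
    """Mapping between en-face directions and TSNIT angles for one eye.

    Internally works in (x, u) coordinates with u = -y so that u points
    superior; ``t_hat``/``s_hat`` are the unit vectors of the temporal and
    superior axes in that frame.
    """

    laterality: str
    center_um: tuple
    fovea_um: Optional[tuple] = None
    tilt_applied: bool = field(init=False, default=False)
    warning: Optional[str] = field(init=False, default=None)
    t_hat: np.ndarray = field(init=False, repr=False)
    s_hat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.laterality not in ("OD", "OS"):
            raise ConfigurationError("laterality must be 'OD' or 'OS'")
        sign = 1.0 if self.laterality == "OD" else -1.0
        if self.fovea_um is not None:
            dx = float(self.fovea_um[0]) - float(self.center_um[0])
            du = -(float(self.fovea_um[1]) - float(self.center_um[1]))
            norm = float(np.hypot(dx, du))
            if norm == 0.0:
                raise ConfigurationError(
                    "fovea coincides with the BMO centre; tilt axis undefined"
                )
            self.t_hat = np.array([dx, du]) / norm
            self.tilt_applied = True
        else:
            self.t_hat = np.array([sign, 0.0])
            self.warning = (
                "no fovea position available; temporal axis fixed to the "
                "laterality-implied horizontal (no tilt correction)"
            )
        # superior axis: +90 deg from temporal in the TSNIT sweep direction
        # (counterclockwise in (x, u) for OD, clockwise for OS)
        if self.laterality == "OD":
            self.s_hat = np.array([-self.t_hat[1], self.t_hat[0]])
        else:
            self.s_hat = np.array([self.t_hat[1], -self.t_hat[0]])

    @property
    def tilt_deg(self) -> float:
        """Rotation of the temporal axis away from the laterality default."""
        sign = 1.0 if self.laterality == "OD" else -1.0
        default = np.array([sign, 0.0])
        ang = np.degrees(
            np.arctan2(
                default[0] * self.t_hat[1] - default[1] * self.t_hat[0],
                default @ self.t_hat,
            )
        )
        return float(ang)

    def direction(self, angle_deg) -> np.ndarray:
        """En-face unit vector(s) (dx, dy) for TSNIT angle(s) in degrees."""
        th = np.radians(np.asarray(angle_deg, dtype=float))
        vx = np.cos(th) * self.t_hat[0] + np.sin(th) * self.s_hat[0]
        vu = np.cos(th) * self.t_hat[1] + np.sin(th) * self.s_hat[1]
        return np.stack([vx, -vu], axis=-1)

    def angle_of(self, offset_um) -> np.ndarray:
        """TSNIT angle(s) in [0, 360) of en-face offset vector(s) (dx, dy)."""
        v = np.asarray(offset_um, dtype=float)
        vx = v[..., 0]
        vu = -v[..., 1]
        cos_c = vx * self.t_hat[0] + vu * self.t_hat[1]
        sin_c = vx * self.s_hat[0] + vu * self.s_hat[1]
        return np.mod(np.degrees(np.arctan2(sin_c, cos_c)), 360.0)


def tsnit_angle_transform(laterality, center_um, fovea_um=None) -> TsnitTransform:
    """Build the en-face direction <-> TSNIT angle mapping for one eye."""
    return TsnitTransform(laterality=laterality, center_um=tuple(center_um),
                          fovea_um=None if fovea_um is None else tuple(fovea_um))


def enface_presence(volume: LabelVolume, label_names) -> EnFaceMap:
    """Binary en-face map: True where the A-scan contains any listed label."""
    unknown = [n for n in label_names if n not in volume.scheme]
    if unknown:
        raise KeyError(f"labels {unknown} not in scheme")
    codes = [volume.scheme[n] for n in label_names]
    present = np.isin(volume.labels, codes).any(axis=2)
    return EnFaceMap(
        values=present,
        spacing_x_um=volume.spacing_ascan_um,
        spacing_y_um=volume.spacing_bscan_um,
    )


def sample_circle(
    emap: EnFaceMap,
    center_um,
    diameter_mm: float,
    n_samples: int = 720,
    transform: Optional[TsnitTransform] = None,
) -> AngularProfile:
    """Bilinearly sample an en-face map on a circle, indexed by TSNIT angle.

    Samples ``n_samples`` equally spaced TSNIT angles starting at 0°
    (temporal). Samples whose bilinear stencil touches an undefined pixel
    are flagged undefined. The circle must lie within the map extent.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    if transform is None:
        transform = tsnit_angle_transform("OD", center_um)
    angles = np.arange(n_samples) * (360.0 / n_samples)
    dirs = transform.direction(angles)  # (n, 2) -> (dx, dy)
    r_um = diameter_mm * 1e3 / 2.0
    x = center_um[0] + r_um * dirs[:, 0]
    y = center_um[1] + r_um * dirs[:, 1]
    col = x / emap.spacing_x_um
    row = y / emap.spacing_y_um
    ny, nx = emap.shape
    eps = 1e-9
    if (col.min() < -eps or col.max() > nx - 1 + eps
            or row.min() < -eps or row.max() > ny - 1 + eps):
        raise OutOfBoundsError(
            f"{diameter_mm} mm circle leaves the en-face extent"
        )
    col = np.clip(col, 0.0, nx - 1)
    row = np.clip(row, 0.0, ny - 1)
    vals = ndimage.map_coordinates(
        np.asarray(emap.values, dtype=float), [row, col], order=1, mode="nearest"
    )
    und = ndimage.map_coordinates(
        emap.undefined.astype(float), [row, col], order=1, mode="nearest"
    ) > 1e-12
    return AngularProfile(angles_deg=angles, values=vals, undefined=und)


def _ray_extent_um(center_um, direction, extent_um) -> float:
    """Largest s >= 0 with center + s*direction inside [0,xmax]x[0,ymax]."""
    cx, cy = float(center_um[0]), float(center_um[1])
    dx, dy = float(direction[0]), float(direction[1])
    xmax, ymax = extent_um
    s = np.inf
    for c, d, hi in ((cx, dx, xmax), (cy, dy, ymax)):
        if d > 1e-15:
            s = min(s, (hi - c) / d)
        elif d < -1e-15:
            s = min(s, (0.0 - c) / d)
    return max(0.0, float(s))


def synthesize_radials(
    volume: LabelVolume,
    center_um,
    n_radials: int = 24,
    transform: Optional[TsnitTransform] = None,
) -> list:
    """Resample a cube volume into SPECTRALIS-like radial slices.

    ``n_radials`` slices at TSNIT angles k*(180/n_radials), each spanning
    the full diameter through the centre (clipped to the scanned area).
    Labels are sampled by nearest neighbour in the en-face plane (labels
    are categorical); the lateral step is min(spacing_ascan, spacing_bscan).
    """
    xmax, ymax = volume.enface_extent_um
    cx, cy = float(center_um[0]), float(center_um[1])
    if not (0 <= cx <= xmax and 0 <= cy <= ymax):
        raise OutOfBoundsError("centre lies outside the en-face extent")
    if transform is None:
        transform = tsnit_angle_transform(volume.laterality, center_um,
                                          volume.fovea_enface_um)
    step = min(volume.spacing_ascan_um, volume.spacing_bscan_um)
    slices = []
    for k in range(n_radials):
        angle = k * (180.0 / n_radials)
        d = transform.direction(angle)
        s_pos = _ray_extent_um(center_um, d, (xmax, ymax))
        s_neg = _ray_extent_um(center_um, -d, (xmax, ymax))
        n_pos = int(np.floor(s_pos / step + 1e-9))
        n_neg = int(np.floor(s_neg / step + 1e-9))
        s = (np.arange(-n_neg, n_pos + 1)) * step
        px = cx + s * d[0]
        py = cy + s * d[1]
        a_idx = np.clip(np.rint(px / volume.spacing_ascan_um).astype(int),
                        0, volume.n_ascans - 1)
        b_idx = np.clip(np.rint(py / volume.spacing_bscan_um).astype(int),
                        0, volume.n_bscans - 1)
        labels = volume.labels[b_idx, a_idx, :]
        slices.append(
            RadialSlice(
                angle_deg=angle,
                labels=labels,
                lateral_step_um=step,
                axial_step_um=volume.spacing_axial_um,
                center_offset=n_neg,
                provenance="synthesized",
            )
        )
    return slices
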