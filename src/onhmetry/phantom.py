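"""Synthetic ONH segmentation phantoms with analytic ground truth.

The phantom is defined *continuously* in physical micrometres and only
then rasterised, so every biomarker has a raster-independent ground
truth: refining the grid moves the extracted value toward the truth and
algorithm error can be separated from raster error.

Geometry (z increases with depth):

* a flat peripheral retina whose ILM sits at ``ilm_depth_um``, with an
  RNFL slab of thickness ``t(theta) = t0 + amp * sin(2 theta)`` (theta in
  TSNIT degrees around the BMO centre) directly below it;
* the RPE-BM complex as a slab ``[bm_depth, bm_depth + bm_thickness)``
  wherever the en-face position lies outside the BMO ellipse;
* inside the opening, prelaminar tissue whose top surface
  ``z_top(rho) = z_chord + cup_depth - (cup_depth + rim_height) * rho^2``
  forms a neuroretinal rim rising ``rim_height`` above the BM-endpoint
  chord at the margin (rho = 1) and a cup reaching ``cup_depth`` below
  the chord at the centre, giving closed forms for both the cup volume
  and the per-meridian minimum rim width;
* straight vessel tubes strictly inside the RNFL slab, to exercise the
  nearest-neighbour vessel-resolution rule without changing the
  thickness ground truth.

The default mimics a CIRRUS-style cube: 200 x 200 A-scans over 6 x 6 mm
and 640 axial pixels of 3.125 um over 2 mm depth (axial pixel sizes of
commercial devices range from about 2.6 to 3.9 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .exceptions import ConfigurationError
from .geometry import (
    TSNIT_SECTORS,
    TSNIT_SECTOR_WIDTHS,
    TsnitTransform,
    _ray_extent_um,
    tsnit_angle_transform,
)
from .scheme import DEFAULT_SCHEME, LabelScheme
from .volume import CircularSlice, LabelVolume, RadialCircularSet, RadialSlice


@dataclass
class PhantomSpec:
    """Parameters of a synthetic ONH phantom (all lengths in um)."""

    n_bscans: int = 200
    n_ascans: int = 200
    n_axial: int = 640
    spacing_bscan_um: float = 30.0
    spacing_ascan_um: float = 30.0
    spacing_axial_um: float = 3.125
    laterality: str = "OD"
    fovea_enface_um: Optional[tuple] = None

    bmo_center_um: tuple = (3000.0, 3000.0)
    bmo_semi_major_um: float = 900.0
    bmo_semi_minor_um: float = 700.0
    bmo_rotation_deg: float = 25.0

    ilm_depth_um: float = 501.6
    rnfl_t0_um: float = 100.0
    rnfl_amp_um: float = 30.0

    bm_depth_um: float = 1000.0
    bm_thickness_um: float = 31.3

    cup_depth_um: float = 500.0   # depth of the cup below the chord
    rim_height_um: float = 250.0  # rim rise above the chord at the margin
    prelaminar_base_um: float = 1700.0

    n_vessels: int = 4
    vessel_width_um: float = 90.0

    # optional PPA rings inside the opening: label -> (rho_lo, rho_hi)
    ppa_rings: dict = field(default_factory=dict)

    noise_label_flip_rate: float = 0.0
    noise_bm_enface_flip_rate: float = 0.0
    noise_boundary_jitter_px: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_bscans, self.n_ascans, self.n_axial) < 4:
            raise ConfigurationError("phantom grid too small")
        for name in ("spacing_bscan_um", "spacing_ascan_um", "spacing_axial_um"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        xmax = (self.n_ascans - 1) * self.spacing_ascan_um
        ymax = (self.n_bscans - 1) * self.spacing_bscan_um
        cx, cy = self.bmo_center_um
        a = self.bmo_semi_major_um
        if not (a <= cx <= xmax - a and a <= cy <= ymax - a):
            raise ConfigurationError("BMO ellipse must lie inside the grid")
        if not self.bmo_semi_major_um >= self.bmo_semi_minor_um > 0:
            raise ConfigurationError("BMO semi-axes must satisfy a >= b > 0")
        zmax = (self.n_axial - 1) * self.spacing_axial_um
        deepest = max(self.prelaminar_base_um,
                      self.bm_depth_um + self.bm_thickness_um,
                      self.chord_depth_um + self.cup_depth_um)
        if deepest >= zmax:
            raise ConfigurationError("surfaces exceed the axial extent")
        for name in ("noise_label_flip_rate", "noise_bm_enface_flip_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")

    @property
    def chord_depth_um(self) -> float:
        """Axial position of the BM-endpoint chord (centre of the complex)."""
        return self.bm_depth_um + self.bm_thickness_um / 2.0

    @property
    def scheme(self) -> LabelScheme:
        return DEFAULT_SCHEME

    def transform(self) -> TsnitTransform:
        return tsnit_angle_transform(self.laterality, self.bmo_center_um,
                                     self.fovea_enface_um)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("bmo_center_um") is not None:
            d["bmo_center_um"] = tuple(d["bmo_center_um"])
        if d.get("fovea_enface_um") is not None:
            d["fovea_enface_um"] = tuple(d["fovea_enface_um"])
        return cls(**d)


def _elliptical_rho2(spec: PhantomSpec, x, y):
    cx, cy = spec.bmo_center_um
    phi = np.radians(spec.bmo_rotation_deg)
    dx, dy = x - cx, y - cy
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    return (xr / spec.bmo_semi_major_um) ** 2 + (yr / spec.bmo_semi_minor_um) ** 2


def _rnfl_thickness(spec: PhantomSpec, x, y, transform=None):
    """Continuous RNFL thickness field t(theta) at en-face positions."""
    if transform is None:
        transform = spec.transform()
    cx, cy = spec.bmo_center_um
    offsets = np.stack([np.asarray(x) - cx, np.asarray(y) - cy], axis=-1)
    theta = np.radians(transform.angle_of(offsets))
    return spec.rnfl_t0_um + spec.rnfl_amp_um * np.sin(2.0 * theta)


def _vessel_mask(spec: PhantomSpec, x, y, rho2):
    """Straight vessel tubes in the en-face plane, kept off the disc."""
    if spec.n_vessels <= 0:
        return np.zeros(np.broadcast(x, y).shape, dtype=bool)
    cx, cy = spec.bmo_center_um
    dx, dy = x - cx, y - cy
    mask = np.zeros(np.broadcast(dx, dy).shape, dtype=bool)
    for k in range(spec.n_vessels):
        gamma = np.radians(30.0 + k * 360.0 / spec.n_vessels)
        ux, uy = np.cos(gamma), np.sin(gamma)
        # line through a point offset 200 um perpendicular to its direction
        px, py = -uy * 200.0, ux * 200.0
        dist = np.abs((dx - px) * uy - (dy - py) * ux)
        mask |= dist < spec.vessel_width_um / 2.0
    mask &= rho2 >= 1.15**2
    return mask


def _label_block(spec: PhantomSpec, x, y, z, transform=None) -> np.ndarray:
    """Labels at en-face positions (x, y) [shape (N,)] x depths z [(M,)].

    This is the continuous phantom definition; every rasteriser (cube,
    radial, circular) samples it. A voxel takes the label of the region
    containing its centre.
    """
    scheme = spec.scheme
    x = np.asarray(x, dtype=float).ravel()
    y = np.broadcast_to(np.asarray(y, dtype=float), x.shape).ravel()
    z = np.asarray(z, dtype=float).ravel()[None, :]
    rho2 = _elliptical_rho2(spec, x, y)[:, None]
    t = _rnfl_thickness(spec, x, y, transform)[:, None]
    out = np.full((x.size, z.size), scheme["background"], dtype=np.uint8)

    outside = rho2 >= 1.0
    z_i = spec.ilm_depth_um
    rnfl_band = outside & (z >= z_i) & (z < z_i + t)
    out[rnfl_band] = scheme["rnfl"]
    bm_band = outside & (z >= spec.bm_depth_um) & (
        z < spec.bm_depth_um + spec.bm_thickness_um)
    out[bm_band] = scheme["rpe_bm"]

    inside = ~outside
    h, m0 = spec.cup_depth_um, spec.rim_height_um
    z_top = spec.chord_depth_um + h - (h + m0) * rho2
    pre = inside & (z >= z_top) & (z < spec.prelaminar_base_um)
    out[pre] = scheme["prelaminar"]

    for label, (lo, hi) in spec.ppa_rings.items():
        ring = (rho2 >= lo**2) & (rho2 < hi**2)
        band = ring & (z >= spec.bm_depth_um) & (
            z < spec.bm_depth_um + spec.bm_thickness_um)
        out[band] = scheme[label]

    vessels = _vessel_mask(spec, x, y, rho2[:, 0])[:, None]
    vband = vessels & outside & (z >= z_i + 0.25 * t) & (z < z_i + 0.75 * t)
    out[vband] = scheme["vessel"]
    return out


@dataclass
class GroundTruth:
    """Analytic biomarker values of a phantom (raster-independent)."""

    spec: PhantomSpec
    bmo_area_mm2: float
    bmo_center_um: tuple
    cprnfl_global_um: float
    cprnfl_sector_means_um: dict
    cup_volume_mm3: float

    def cprnfl_value_um(self, angle_deg) -> np.ndarray:
        """Continuous cpRNFL thickness at TSNIT angle(s), any diameter."""
        th = np.radians(np.asarray(angle_deg, dtype=float))
        return self.spec.rnfl_t0_um + self.spec.rnfl_amp_um * np.sin(2 * th)

    def mrw_meridian_um(self, angle_deg: float) -> float:
        """Minimum rim width of one meridian from the continuous surfaces.

        The minimum is taken over the inner (rim/cup) surface, certified
        by dense sampling plus bounded refinement, and the peripheral
        ILM plane.
        """
        spec = self.spec
        transform = spec.transform()
        d = transform.direction(float(angle_deg))
        phi = np.radians(spec.bmo_rotation_deg)
        c = d[0] * np.cos(phi) + d[1] * np.sin(phi)
        s = -d[0] * np.sin(phi) + d[1] * np.cos(phi)
        a, b = spec.bmo_semi_major_um, spec.bmo_semi_minor_um
        L = a * b / np.hypot(b * c, a * s)
        z_e = spec.chord_depth_um
        h, m0 = spec.cup_depth_um, spec.rim_height_um

        def dist2(srel):
            z_top = z_e + h - (h + m0) * (srel / L) ** 2
            return (L - srel) ** 2 + (z_e - z_top) ** 2

        grid = np.linspace(0.0, L, 4001)
        i = int(np.argmin(dist2(grid)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(dist2, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        inner = float(np.sqrt(min(res.fun, dist2(grid[i]))))
        outer = z_e - spec.ilm_depth_um
        return float(min(inner, outer))

    def mrw_mean_um(self, angles_deg) -> float:
        return float(np.mean([self.mrw_meridian_um(a) for a in angles_deg]))


def _sector_mean_closed_form(spec: PhantomSpec, start_deg, width_deg) -> float:
    """Exact angular average of t0 + amp*sin(2 theta) over one sector."""
    th1 = np.radians(start_deg)
    th2 = np.radians(start_deg + width_deg)
    return spec.rnfl_t0_um + spec.rnfl_amp_um * (
        np.cos(2 * th1) - np.cos(2 * th2)) / (2.0 * (th2 - th1))


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    a, b = spec.bmo_semi_major_um, spec.bmo_semi_minor_um
    rho_eff = 1.0
    for label, (lo, hi) in spec.ppa_rings.items():
        if label in ("ppa_alpha", "ppa_beta") and hi >= 1.0 - 1e-9:
            rho_eff = min(rho_eff, lo)
    sector_means = {}
    for name, (start, _end) in TSNIT_SECTORS.items():
        sector_means[name] = _sector_mean_closed_form(
            spec, start, TSNIT_SECTOR_WIDTHS[name])
    h, m0 = spec.cup_depth_um, spec.rim_height_um
    cup = np.pi * a * b * h**2 / (2.0 * (h + m0)) * 1e-9
    return GroundTruth(
        spec=spec,
        bmo_area_mm2=float(np.pi * a * b * rho_eff**2 * 1e-6),
        bmo_center_um=tuple(spec.bmo_center_um),
        cprnfl_global_um=float(spec.rnfl_t0_um),
        cprnfl_sector_means_um=sector_means,
        cup_volume_mm3=float(cup),
    )


def make_phantom(spec: PhantomSpec):
    """Rasterise the phantom. Returns ``(LabelVolume, GroundTruth)``.

    Deterministic for a given spec (including its seed, which drives any
    requested noise). The ground truth is computed from the continuous
    parameters, never from the raster.
    """
    z = np.arange(spec.n_axial) * spec.spacing_axial_um
    x = np.arange(spec.n_ascans) * spec.spacing_ascan_um
    transform = spec.transform()
    labels = np.empty((spec.n_bscans, spec.n_ascans, spec.n_axial),
                      dtype=np.uint8)
    for bi in range(spec.n_bscans):
        yv = bi * spec.spacing_bscan_um
        labels[bi] = _label_block(spec, x, yv, z, transform)
    volume = LabelVolume(
        labels=labels,
        spacing_bscan_um=spec.spacing_bscan_um,
        spacing_ascan_um=spec.spacing_ascan_um,
        spacing_axial_um=spec.spacing_axial_um,
        laterality=spec.laterality,
        acquisition="cube",
        scheme=spec.scheme,
        fovea_enface_um=spec.fovea_enface_um,
    )
    if (spec.noise_label_flip_rate > 0 or spec.noise_bm_enface_flip_rate > 0
            or spec.noise_boundary_jitter_px > 0):
        volume = perturb(
            volume,
            label_flip_rate=spec.noise_label_flip_rate,
            bm_enface_flip_rate=spec.noise_bm_enface_flip_rate,
            boundary_jitter_px=spec.noise_boundary_jitter_px,
            seed=spec.seed,
        )
    return volume, ground_truth(spec)


def derive_radial_set(
    spec: PhantomSpec,
    n_radials: int = 24,
    diameters_mm=(3.5, 4.1, 4.7),
    n_circle_columns: int = 720,
) -> RadialCircularSet:
    """Radial + circular slices sampled from the continuous phantom.

    Emulates a radial-protocol device imaging the same eye: the slices
    are evaluated from the phantom's parametric surfaces (not from the
    cube raster), centred on the true BMO centre. Radial slices use the
    same lateral step as cube-derived synthesized radials so the two
    routes are directly comparable.
    """
    transform = spec.transform()
    z = np.arange(spec.n_axial) * spec.spacing_axial_um
    cx, cy = spec.bmo_center_um
    extent = ((spec.n_ascans - 1) * spec.spacing_ascan_um,
              (spec.n_bscans - 1) * spec.spacing_bscan_um)
    step = min(spec.spacing_ascan_um, spec.spacing_bscan_um)
    radials = []
    for k in range(n_radials):
        angle = k * (180.0 / n_radials)
        d = transform.direction(angle)
        n_pos = int(np.floor(_ray_extent_um(spec.bmo_center_um, d, extent)
                             / step + 1e-9))
        n_neg = int(np.floor(_ray_extent_um(spec.bmo_center_um, -d, extent)
                             / step + 1e-9))
        s = np.arange(-n_neg, n_pos + 1) * step
        labels = _label_block(spec, cx + s * d[0], cy + s * d[1], z, transform)
        radials.append(RadialSlice(
            angle_deg=angle, labels=labels, lateral_step_um=step,
            axial_step_um=spec.spacing_axial_um, center_offset=n_neg,
            provenance="synthesized",
        ))
    circles = []
    for dia in diameters_mm:
        r = dia * 1e3 / 2.0
        angles = np.arange(n_circle_columns) * (360.0 / n_circle_columns)
        dirs = transform.direction(angles)
        px = cx + r * dirs[:, 0]
        py = cy + r * dirs[:, 1]
        if (px.min() < 0 or px.max() > extent[0]
                or py.min() < 0 or py.max() > extent[1]):
            raise ConfigurationError(f"{dia} mm circle outside the grid")
        labels = _label_block(spec, px, py, z, transform)
        circles.append(CircularSlice(
            diameter_mm=float(dia), labels=labels,
            axial_step_um=spec.spacing_axial_um,
            start_angle_deg=0.0, direction=1,
        ))
    return RadialCircularSet(
        radial_slices=radials, circular_slices=circles,
        laterality=spec.laterality, scheme=spec.scheme,
        fovea_enface_um=spec.fovea_enface_um,
    )


def _bm_axial_band(labels, bm_code):
    """Representative axial index band of the BM complex in a volume."""
    bm = labels == bm_code
    cols = bm.any(axis=2)
    if not cols.any():
        return None
    lo = int(np.median(np.argmax(bm[cols], axis=1)))
    per_col = bm[cols]
    last = per_col.shape[1] - 1 - np.argmax(per_col[:, ::-1], axis=1)
    hi = int(np.median(last))
    return lo, hi


def perturb(
    volume: LabelVolume,
    label_flip_rate: float = 0.0,
    bm_enface_flip_rate: float = 0.0,
    boundary_jitter_px: float = 0.0,
    seed: int = 0,
) -> LabelVolume:
    """Seeded segmentation noise; deterministic given the seed.

    ``label_flip_rate``: that fraction of voxels is re-labelled with a
    uniformly random *different* scheme code. ``bm_enface_flip_rate``:
    that fraction of en-face pixels has its BM column toggled (present
    membrane removed, or a membrane slab painted where absent) — salt
    and pepper in the membrane projection. ``boundary_jitter_px``:
    Gaussian radial jitter (in en-face pixels) applied to the membrane
    presence boundary.
    """
    rng = np.random.default_rng(seed)
    out = volume.copy()
    codes = np.array(sorted(out.scheme.all_codes))
    bm_code = out.scheme["rpe_bm"]
    band = _bm_axial_band(out.labels, bm_code)

    def toggle_columns(mask2d):
        if band is None:
            return
        lo, hi = band
        cols_b, cols_a = np.where(mask2d)
        for b, a_ in zip(cols_b, cols_a):
            col = out.labels[b, a_]
            if (col == bm_code).any():
                col[col == bm_code] = out.scheme["background"]
            else:
                col[lo:hi + 1] = bm_code

    if boundary_jitter_px > 0:
        presence = (out.labels == bm_code).any(axis=2)
        inside = ndimage.distance_transform_edt(presence)
        outside = ndimage.distance_transform_edt(~presence)
        sd = np.where(presence, inside - 0.5, -(outside - 0.5))
        # spatially correlated displacement field: boundary placement
        # errors are smooth along the margin, not per-pixel speckle
        field = ndimage.gaussian_filter(rng.normal(size=sd.shape), sigma=3.0)
        field *= boundary_jitter_px / max(field.std(), 1e-12)
        near = np.abs(sd) <= 4.0 * boundary_jitter_px + 2.0
        new_presence = (sd + field) > 0
        toggle_columns(near & (new_presence != presence))

    if bm_enface_flip_rate > 0:
        flips = rng.random(out.labels.shape[:2]) < bm_enface_flip_rate
        toggle_columns(flips)

    if label_flip_rate > 0:
        flat = out.labels.reshape(-1)
        flips = np.flatnonzero(rng.random(flat.size) < label_flip_rate)
        if flips.size:
            old = flat[flips]
            # uniformly random different code
            offset = rng.integers(1, codes.size, size=flips.size)
            old_pos = np.searchsorted(codes, old)
            flat[flips] = codes[(old_pos + offset) % codes.size]
    return out
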