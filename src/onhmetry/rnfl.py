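"""RNFL thickness: vessel resolution, per-A-scan maps, cpRNFL profiles.

Thickness is measured by counting RNFL voxels per A-scan and multiplying
by the axial spacing. Retinal vessels interrupt the RNFL segmentation, so
before counting, every vessel voxel is re-labelled as RNFL or background
depending on which is the nearest neighbouring annotation (Euclidean
distance in physical micrometres within its B-scan plane; ties go to
RNFL so that continuous tissue is not punched full of holes).

Circumpapillary profiles are sampled on a circle centred on the BMO
(cube acquisitions) or taken directly from circular B-scans (radial +
circular acquisitions), then summarised globally, in the six TSNIT
sectors (TS 40°, NS 40°, N 110°, NI 40°, TI 40°, T 90°) and in twelve
30° clock hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError
from .geometry import (
    AngularProfile,
    EnFaceMap,
    TsnitTransform,
    TSNIT_SECTORS,
    clock_hour_of,
    sample_circle,
    sector_of,
    sector_width_deg,
    tsnit_angle_transform,
)
from .volume import CircularSlice, LabelVolume


@dataclass
class SectorSummary:
    """Global / TSNIT-sector / clock-hour means of a circumpapillary profile."""

    global_mean_um: float
    tsnit: dict  # sector name -> mean um (nan when missing)
    clock_hours: dict  # hour 1..12 -> mean um (nan when missing)
    diameter_mm: Optional[float] = None
    tilt_applied: bool = False
    missing_sectors: list = field(default_factory=list)


def _resolve_plane(plane, scheme, lateral_um, axial_um):
    """Re-label vessel pixels in one 2D plane by nearest rnfl/background."""
    rnfl, bg, vessel = scheme["rnfl"], scheme["background"], scheme["vessel"]
    vmask = plane == vessel
    if not vmask.any():
        return plane
    out = plane.copy()
    has_rnfl = bool((plane == rnfl).any())
    has_bg = bool((plane == bg).any())
    if not has_rnfl and not has_bg:
        out[vmask] = rnfl  # tie by convention
        return out
    if not has_rnfl:
        out[vmask] = bg
        return out
    if not has_bg:
        out[vmask] = rnfl
        return out
    sampling = (lateral_um, axial_um)
    d_rnfl = ndimage.distance_transform_edt(plane != rnfl, sampling=sampling)
    d_bg = ndimage.distance_transform_edt(plane != bg, sampling=sampling)
    out[vmask & (d_rnfl <= d_bg)] = rnfl
    out[vmask & (d_rnfl > d_bg)] = bg
    return out


def resolve_vessels(volume: LabelVolume) -> LabelVolume:
    """Assign every vessel voxel to RNFL or background (nearest-neighbour).

    Distances are computed per B-scan plane in physical micrometres
    (anisotropic); exact ties are assigned to RNFL. All other labels are
    unchanged and the total voxel count is conserved.
    """
    out = volume.copy()
    vessel = volume.scheme["vessel"]
    planes = np.flatnonzero((volume.labels == vessel).any(axis=(1, 2)))
    for b in planes:
        out.labels[b] = _resolve_plane(
            volume.labels[b], volume.scheme,
            volume.spacing_ascan_um, volume.spacing_axial_um,
        )
    return out


def resolve_vessels_slice(labels, scheme, lateral_um, axial_um):
    """Vessel resolution for a single 2D slice (radial or circular scan)."""
    return _resolve_plane(np.asarray(labels), scheme, lateral_um, axial_um)


def thickness_map(volume: LabelVolume) -> EnFaceMap:
    """Per-A-scan RNFL thickness in um (vessels must be resolved already)."""
    rnfl = volume.scheme["rnfl"]
    counts = (volume.labels == rnfl).sum(axis=2)
    return EnFaceMap(
        values=counts.astype(float) * volume.spacing_axial_um,
        spacing_x_um=volume.spacing_ascan_um,
        spacing_y_um=volume.spacing_bscan_um,
    )


def summarize_profile(
    profile: AngularProfile,
    diameter_mm: Optional[float] = None,
    tilt_applied: bool = False,
) -> SectorSummary:
    """Aggregate an angular profile into global/TSNIT/clock-hour means.

    Means are unweighted over the profile samples falling in each angular
    bin; undefined samples are excluded, and a bin with no defined sample
    is reported as NaN and flagged missing.
    """
    angles = profile.angles_deg
    values = profile.values
    defined = ~profile.undefined
    missing = []

    def bin_mean(sel):
        sel = sel & defined
        return float(np.mean(values[sel])) if sel.any() else float("nan")

    global_mean = bin_mean(np.ones(len(profile), dtype=bool))
    sectors = sector_of(angles)
    tsnit = {}
    for name in TSNIT_SECTORS:
        m = bin_mean(sectors == name)
        tsnit[name] = m
        if np.isnan(m):
            missing.append(name)
    hours = clock_hour_of(angles)
    clock = {}
    for h in range(1, 13):
        m = bin_mean(hours == h)
        clock[h] = m
        if np.isnan(m):
            missing.append(f"hour_{h}")
    return SectorSummary(
        global_mean_um=global_mean,
        tsnit=tsnit,
        clock_hours=clock,
        diameter_mm=diameter_mm,
        tilt_applied=tilt_applied,
        missing_sectors=missing,
    )


def cprnfl(
    thickness: EnFaceMap,
    ellipse,
    diameter_mm: float,
    transform: Optional[TsnitTransform] = None,
    n_samples: int = 720,
):
    """cpRNFL profile + sector summary at one diameter on a cube volume.

    ``thickness`` is the per-A-scan map from :func:`thickness_map`;
    ``ellipse`` provides the BMO centre. Returns ``(AngularProfile,
    SectorSummary)``.
    """
    center = ellipse.center_um if hasattr(ellipse, "center_um") else ellipse
    if transform is None:
        transform = tsnit_angle_transform("OD", center)
    profile = sample_circle(thickness, center, diameter_mm,
                            n_samples=n_samples, transform=transform)
    summary = summarize_profile(profile, diameter_mm=diameter_mm,
                                tilt_applied=transform.tilt_applied)
    return profile, summary


def cprnfl_from_circular(scan: CircularSlice, scheme, resolve: bool = True):
    """cpRNFL profile + summary from an acquired circular B-scan.

    Per-column thickness (RNFL voxel count x axial step) is mapped to
    TSNIT angles through the scan's start-angle/direction metadata, then
    aggregated exactly as the cube route.
    """
    if scan.start_angle_deg is None or scan.direction is None:
        raise ConfigurationError("circular scan needs start angle/direction")
    labels = scan.labels
    if resolve:
        labels = resolve_vessels_slice(labels, scheme, scan.lateral_step_um,
                                       scan.axial_step_um)
    counts = (labels == scheme["rnfl"]).sum(axis=1)
    thick = counts.astype(float) * scan.axial_step_um
    angles = scan.angles_deg
    order = np.argsort(angles)
    profile = AngularProfile(angles_deg=angles[order], values=thick[order])
    summary = summarize_profile(profile, diameter_mm=scan.diameter_mm)
    return profile, summary


def heatmap(volume: LabelVolume) -> EnFaceMap:
    """RNFL thickness heatmap (identical values to :func:`thickness_map`)."""
    return thickness_map(volume)


def save_heatmap(emap: EnFaceMap, path, vmin: float = 0.0, vmax: float = 250.0,
                 cmap: str = "turbo") -> None:
    """Write the heatmap as a PNG with a fixed colour scale."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import pyplot as plt

    plt.imsave(path, np.asarray(emap.values, dtype=float), vmin=vmin,
               vmax=vmax, cmap=cmap)


# re-exported for callers summarising MRW meridians with the same bins
__all__ = [
    "SectorSummary",
    "resolve_vessels",
    "resolve_vessels_slice",
    "thickness_map",
    "summarize_profile",
    "cprnfl",
    "cprnfl_from_circular",
    "heatmap",
    "save_heatmap",
    "sector_width_deg",
]
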