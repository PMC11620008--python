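"""BMO minimum rim width (MRW) from radial slices.

The MRW at one meridian is the minimum Euclidean distance, in the 2D
plane of a radial scan and in physical micrometres, between the edge of
the Bruch's membrane (the innermost column bearing the RPE-BM complex on
that side of the centre, at the mean axial position of the complex in
that column) and the inner limiting membrane (the shallowest voxel
labelled RNFL, vessel or prelaminar tissue per column). A 24-slice radial
set yields 48 half-meridians; meridians whose membrane edge is obscured
are excluded from the means and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .exceptions import QualityError
from .geometry import AngularProfile, synthesize_radials, tsnit_angle_transform
from .rnfl import SectorSummary, resolve_vessels_slice, summarize_profile
from .volume import LabelVolume, RadialCircularSet, RadialSlice

ILM_LABELS = ("rnfl", "vessel", "prelaminar")


@dataclass
class MRWResult:
    """Per-meridian minimum rim widths and their summaries."""

    per_meridian: AngularProfile  # widths um; undefined = missing meridian
    global_mean_um: float
    sectors: SectorSummary
    n_meridians: int = 0
    n_missing: int = 0
    warnings: list = field(default_factory=list)


def ilm_curve(slice_labels, scheme, axial_step_um: float) -> np.ndarray:
    """Per-column ILM axial position in um (NaN where undefined).

    The ILM is the smallest axial coordinate whose label is RNFL, vessel
    or prelaminar tissue — over the disc centre it follows the top of the
    prelaminar tissue.
    """
    labels = np.asarray(slice_labels)
    codes = [scheme[n] for n in ILM_LABELS if n in scheme]
    tissue = np.isin(labels, codes)
    has = tissue.any(axis=1)
    first = np.argmax(tissue, axis=1).astype(float)
    first[~has] = np.nan
    return first * axial_step_um


def bm_edge_point(slice: RadialSlice, side: str, scheme=None):
    """BM edge on one side of the centre column, or None when missing.

    Returns ``(lateral_um, axial_um)`` of the innermost (closest to
    centre) column containing the RPE-BM complex on that side; the axial
    coordinate is the mean axial position of the complex voxels in that
    column (the complex is several voxels thick and the measurement is
    taken from the complex as a whole).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if scheme is None:
        from .scheme import DEFAULT_SCHEME

        scheme = DEFAULT_SCHEME
    labels = slice.labels
    bm = labels == scheme["rpe_bm"]
    cols = np.flatnonzero(bm.any(axis=1))
    if side == "left":
        cols = cols[cols < slice.center_offset]
        if cols.size == 0:
            return None
        col = int(cols.max())
    else:
        cols = cols[cols > slice.center_offset]
        if cols.size == 0:
            return None
        col = int(cols.min())
    ax = np.flatnonzero(bm[col])
    axial_um = float(np.mean(ax)) * slice.axial_step_um
    lateral_um = (col - slice.center_offset) * slice.lateral_step_um
    return (float(lateral_um), axial_um)


def mrw_meridian(edge, ilm_um, lateral_positions_um, side: str):
    """Minimum distance (um) from a BM edge point to the ILM on one side.

    ``ilm_um`` and ``lateral_positions_um`` are per-column arrays for the
    whole slice; only columns on the edge's side of the centre (including
    those above the edge) participate. Returns NaN when the ILM is
    undefined everywhere on that side.
    """
    ilm_um = np.asarray(ilm_um, dtype=float)
    lat = np.asarray(lateral_positions_um, dtype=float)
    if side == "left":
        sel = lat < 0
    else:
        sel = lat > 0
    sel &= np.isfinite(ilm_um)
    if not sel.any():
        return float("nan")
    d = np.hypot(lat[sel] - edge[0], ilm_um[sel] - edge[1])
    return float(d.min())


def _slice_meridians(slice: RadialSlice, scheme, resolve: bool = True):
    """Both half-meridian widths of one radial slice.

    Returns ``[(angle_deg, width_or_nan), ...]`` for the positive
    (slice angle) and negative (slice angle + 180°) half-meridians.
    """
    labels = slice.labels
    if resolve:
        labels = resolve_vessels_slice(labels, scheme, slice.lateral_step_um,
                                       slice.axial_step_um)
    work = RadialSlice(
        angle_deg=slice.angle_deg, labels=labels,
        lateral_step_um=slice.lateral_step_um,
        axial_step_um=slice.axial_step_um,
        center_offset=slice.center_offset, provenance=slice.provenance,
    )
    ilm = ilm_curve(labels, scheme, slice.axial_step_um)
    lat = work.lateral_positions_um
    out = []
    for side, angle in (("right", slice.angle_deg % 360.0),
                        ("left", (slice.angle_deg + 180.0) % 360.0)):
        edge = bm_edge_point(work, side, scheme)
        if edge is None:
            out.append((angle, float("nan")))
        else:
            out.append((angle, mrw_meridian(edge, ilm, lat, side)))
    return out


def compute_mrw(
    source: Union[LabelVolume, RadialCircularSet],
    ellipse=None,
    n_radials: int = 24,
    transform=None,
    max_missing_fraction: float = 0.5,
) -> MRWResult:
    """MRW per half-meridian plus global and TSNIT-sector means.

    Cube volumes require the fitted BMO ``ellipse`` (its centre seeds the
    synthesized radial slices); radial/circular sets are measured on their
    acquired radial slices directly. Raises :class:`QualityError` when
    more than ``max_missing_fraction`` of the meridians are missing.
    """
    warnings = []
    if isinstance(source, LabelVolume):
        if ellipse is None:
            raise ValueError("cube input requires the fitted BMO ellipse")
        if transform is None:
            transform = tsnit_angle_transform(
                source.laterality, ellipse.center_um, source.fovea_enface_um)
        slices = synthesize_radials(source, ellipse.center_um,
                                    n_radials=n_radials, transform=transform)
        scheme = source.scheme
    else:
        slices = list(source.radial_slices)
        scheme = source.scheme

    meridians = []
    for sl in slices:
        meridians.extend(_slice_meridians(sl, scheme))
    meridians.sort(key=lambda t: t[0])
    angles = np.array([m[0] for m in meridians])
    widths = np.array([m[1] for m in meridians])
    missing = ~np.isfinite(widths)
    n_missing = int(missing.sum())
    if n_missing:
        warnings.append(f"{n_missing} of {len(widths)} meridians missing "
                        "(obscured membrane edge)")
    if len(widths) and n_missing > max_missing_fraction * len(widths):
        raise QualityError(
            f"{n_missing}/{len(widths)} meridians missing; measurement "
            "quality insufficient"
        )
    profile = AngularProfile(
        angles_deg=angles, values=np.where(missing, 0.0, widths),
        undefined=missing,
    )
    sectors = summarize_profile(profile)
    return MRWResult(
        per_meridian=profile,
        global_mean_um=profile.mean(),
        sectors=sectors,
        n_meridians=len(widths),
        n_missing=n_missing,
        warnings=warnings,
    )
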