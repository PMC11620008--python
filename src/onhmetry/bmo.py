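"""Bruch's membrane opening (BMO) detection and ellipse fitting.

The BMO — the anatomic disc margin — is located as the interior hole in
the en-face projection of the RPE-BM complex. Alpha- and beta-zone
peripapillary atrophy count as membrane presence (Bruch's membrane is
intact there); gamma-zone PPA, where the membrane is absent, counts as
opening. Minor segmentation errors are corrected by a morphological
closing before the hole boundary is extracted, and an ellipse is fitted
to the boundary points by direct algebraic least squares with the ellipse
constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .exceptions import EllipseFitError, NoBMOError
from .geometry import EnFaceMap, enface_presence
from .volume import LabelVolume

# Labels whose presence marks an intact Bruch's membrane.
BM_PRESENCE_LABELS = ("rpe_bm", "ppa_alpha", "ppa_beta")


@dataclass(frozen=True)
class BMOEllipse:
    """Fitted BMO ellipse: disc margin and measurement centre."""

    center_um: tuple  # (x, y) en-face um
    semi_major_um: float
    semi_minor_um: float
    rotation_deg: float  # major-axis angle from +x, in [0, 180)
    area_mm2: float

    def __post_init__(self):
        if not (self.semi_major_um >= self.semi_minor_um > 0):
            raise EllipseFitError("ellipse axes must satisfy a >= b > 0")

    def radius_along_um(self, direction) -> float:
        """Distance from centre to the ellipse along an en-face direction."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        phi = np.radians(self.rotation_deg)
        # direction angle relative to the major axis
        c = d[0] * np.cos(phi) + d[1] * np.sin(phi)
        s = -d[0] * np.sin(phi) + d[1] * np.cos(phi)
        a, b = self.semi_major_um, self.semi_minor_um
        return a * b / np.hypot(b * c, a * s)


def bm_presence_map(volume: LabelVolume) -> EnFaceMap:
    """Binary en-face membrane-presence map.

    Presence over {rpe_bm, ppa_alpha, ppa_beta} (PPA labels only when the
    scheme declares them); gamma-zone PPA counts as absence.
    """
    names = [n for n in BM_PRESENCE_LABELS if n in volume.scheme]
    return enface_presence(volume, names)


def close_and_boundary(emap: EnFaceMap, closing_radius_px: int = 3,
                       min_object_px: int = 64):
    """Correct minor errors, then trace the ordered contour of the BMO hole.

    Spurious membrane specks smaller than ``min_object_px`` are removed,
    a morphological closing with a disk structuring element repairs small
    gaps in the membrane, and the boundary of the largest interior hole
    is returned as ``(points_um, warnings)`` with ``points_um`` an (N, 2)
    array of (x, y) positions. Raises :class:`NoBMOError` when no
    interior hole exists; multiple holes keep the largest and record a
    warning.
    """
    mask = np.asarray(emap.values, dtype=bool)
    warnings = []
    if min_object_px > 1:
        mask = morphology.remove_small_objects(mask,
                                               max_size=min_object_px - 1)
    r = int(closing_radius_px)
    if r > 0:
        padded = np.pad(mask, r, mode="edge")
        closed = morphology.closing(padded, morphology.disk(r)).astype(bool)
        closed = closed[r:-r, r:-r]
    else:
        closed = mask
    holes = ~closed
    lab, n = ndimage.label(holes)  # 4-connectivity
    border = np.zeros(holes.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(lab[border & holes])
    interior_ids = [i for i in range(1, n + 1) if i not in border_ids]
    if not interior_ids:
        raise NoBMOError("no interior hole in the membrane projection")
    sizes = {i: int(np.sum(lab == i)) for i in interior_ids}
    chosen = max(sizes, key=sizes.get)
    if len(interior_ids) > 1:
        warnings.append(
            f"{len(interior_ids)} interior holes found; kept the largest "
            f"({sizes[chosen]} px)"
        )
    hole = lab == chosen
    contours = measure.find_contours(hole.astype(float), 0.5)
    # the outer boundary is the longest contour; shorter ones surround
    # interior islands of spurious membrane and are ignored
    contour = max(contours, key=len)
    points_um = np.column_stack(
        [contour[:, 1] * emap.spacing_x_um, contour[:, 0] * emap.spacing_y_um]
    )
    return points_um, warnings


def fit_ellipse(points_um) -> BMOEllipse:
    """Direct least-squares conic fit constrained to an ellipse.

    Requires at least 6 non-collinear points (an under-determined conic
    cannot be guaranteed to be an ellipse). Points are normalised
    (centred and scaled) before fitting, which also makes the fit exactly
    equivariant under uniform scaling of the input coordinates.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise EllipseFitError("ellipse fit needs >= 6 (x, y) points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    scale = float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))
    if scale == 0:
        raise EllipseFitError("degenerate point configuration")
    model = measure.EllipseModel.from_estimate(centred / scale)
    if not model:
        raise EllipseFitError("degenerate point configuration")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("degenerate point configuration")
    xc, yc, a, b = xc * scale, yc * scale, a * scale, b * scale
    if not (a > 0 and b > 0):
        raise EllipseFitError("fit did not produce a proper ellipse")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    rotation = float(np.degrees(theta) % 180.0)
    return BMOEllipse(
        center_um=(float(xc + centroid[0]), float(yc + centroid[1])),
        semi_major_um=float(a),
        semi_minor_um=float(b),
        rotation_deg=rotation,
        area_mm2=float(np.pi * a * b * 1e-6),
    )


def detect_bmo(volume: LabelVolume, closing_radius_px: int = 3,
               min_object_px: int = 64):
    """Full BMO detection: presence map -> closing + boundary -> ellipse.

    Returns ``(BMOEllipse, warnings)``. The ellipse centre anchors all
    downstream circumpapillary and radial measurements.
    """
    emap = bm_presence_map(volume)
    points, warnings = close_and_boundary(emap, closing_radius_px,
                                          min_object_px)
    ellipse = fit_ellipse(points)
    return ellipse, warnings
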