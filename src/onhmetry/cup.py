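"""Cup volume via the per-B-scan BM-endpoint chord construction.

In every B-scan that crosses the BMO, a straight chord is drawn between
the two Bruch's membrane endpoints of that B-scan, and the cup area is
the space enclosed between the chord and the RNFL/prelaminar tissue
surface below it (contributions where tissue lies above the chord clamp
to zero — the cup is a volume, not a signed integral). Areas are summed
across B-scans, weighted by the B-scan spacing, to give a 3D volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mrw import ilm_curve
from .volume import LabelVolume


@dataclass
class CupResult:
    per_bscan: list  # (bscan_index, area_mm2)
    volume_mm3: float
    n_bscans_contributing: int
    skipped_bscans: list = field(default_factory=list)


def bm_endpoints(bscan_labels, scheme, spacing_ascan_um, spacing_axial_um):
    """The two BM endpoints flanking the BMO gap in one B-scan, or None.

    Returns ``((lat_um, ax_um), (lat_um, ax_um))`` for the innermost
    BM-bearing columns on either side of the widest internal gap; the
    axial coordinate is the mean axial position of the complex in that
    column. Returns None for a continuous membrane or membrane on one
    side only.
    """
    labels = np.asarray(bscan_labels)
    bm = labels == scheme["rpe_bm"]
    cols = np.flatnonzero(bm.any(axis=1))
    if cols.size < 2:
        return None
    gaps = np.diff(cols)
    widest = int(np.argmax(gaps))
    if gaps[widest] <= 1:
        return None  # continuous membrane
    c_left = int(cols[widest])
    c_right = int(cols[widest + 1])

    def point(col):
        ax = np.flatnonzero(bm[col])
        return (col * spacing_ascan_um, float(np.mean(ax)) * spacing_axial_um)

    return (point(c_left), point(c_right))


def cup_area(bscan_labels, endpoints, scheme, spacing_ascan_um,
             spacing_axial_um) -> float:
    """Cup cross-sectional area (mm^2) of one B-scan given its endpoints.

    For each column strictly between the endpoints the contribution is
    ``max(0, tissue_top - chord) * spacing_ascan``, where the tissue top
    is the ILM over {rnfl, vessel, prelaminar} and the chord is linearly
    interpolated between the endpoint axial positions.
    """
    (x0, z0), (x1, z1) = endpoints
    labels = np.asarray(bscan_labels)
    c0 = int(round(x0 / spacing_ascan_um))
    c1 = int(round(x1 / spacing_ascan_um))
    if c1 - c0 < 2:
        return 0.0
    cols = np.arange(c0 + 1, c1)
    ilm = ilm_curve(labels, scheme, spacing_axial_um)[cols]
    x = cols * spacing_ascan_um
    chord = z0 + (z1 - z0) * (x - x0) / (x1 - x0)
    depth = ilm - chord
    depth = np.where(np.isfinite(depth), np.maximum(depth, 0.0), 0.0)
    return float(depth.sum() * spacing_ascan_um * 1e-6)  # um^2 -> mm^2


def cup_volume(volume: LabelVolume, ellipse) -> CupResult:
    """Cup volume (mm^3) summed across the B-scans intersecting the BMO.

    B-scans whose endpoints cannot be determined contribute zero and are
    flagged. The chord is defined per B-scan between that B-scan's own
    endpoints (not against a global reference plane).
    """
    phi = np.radians(ellipse.rotation_deg)
    a, b = ellipse.semi_major_um, ellipse.semi_minor_um
    y_extent = float(np.hypot(a * np.sin(phi), b * np.cos(phi)))
    cy = ellipse.center_um[1]
    db = volume.spacing_bscan_um
    b_lo = max(0, int(np.ceil((cy - y_extent) / db)))
    b_hi = min(volume.n_bscans - 1, int(np.floor((cy + y_extent) / db)))
    per_bscan = []
    skipped = []
    total = 0.0
    for bi in range(b_lo, b_hi + 1):
        ep = bm_endpoints(volume.labels[bi], volume.scheme,
                          volume.spacing_ascan_um, volume.spacing_axial_um)
        if ep is None:
            skipped.append(bi)
            per_bscan.append((bi, 0.0))
            continue
        area = cup_area(volume.labels[bi], ep, volume.scheme,
                        volume.spacing_ascan_um, volume.spacing_axial_um)
        per_bscan.append((bi, area))
        total += area * (db * 1e-3)  # mm^2 * mm
    return CupResult(
        per_bscan=per_bscan,
        volume_mm3=float(total),
        n_bscans_contributing=sum(1 for _, a_ in per_bscan if a_ > 0),
        skipped_bscans=skipped,
    )
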