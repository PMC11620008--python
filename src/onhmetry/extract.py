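"""End-to-end biomarker extraction for one eye.

Composes the module pipeline: vessel resolution -> BMO detection ->
cpRNFL at the requested diameters -> minimum rim width -> cup volume,
assembling a :class:`~onhmetry.report.BiomarkerReport` with provenance.
Cube volumes support every biomarker; radial+circular sets measure
cpRNFL from the acquired circular scans and MRW from the acquired radial
scans, with the cube-only outputs (thickness heatmap, cup volume)
flagged unavailable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from . import __version__
from .bmo import BMOEllipse, detect_bmo, fit_ellipse
from .cup import cup_volume
from .exceptions import OutOfBoundsError
from .geometry import tsnit_angle_transform
from .mrw import bm_edge_point, compute_mrw
from .report import BiomarkerReport
from .rnfl import (
    cprnfl,
    cprnfl_from_circular,
    resolve_vessels,
    thickness_map,
)
from .volume import LabelVolume, RadialCircularSet


@dataclass
class RunConfig:
    """Extraction parameters (defaults follow the measurement protocol)."""

    diameters_mm: tuple = (3.4, 3.5)
    n_radials: int = 24
    closing_radius_px: int = 3
    tilt: bool = True
    n_circle_samples: int = 720
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.diameters_mm):
            raise ValueError("diameters must be > 0")
        if self.n_radials < 4:
            raise ValueError("n_radials must be >= 4")


def _dia_key(d: float) -> str:
    return f"{d:g}"


def bmo_from_radials(rset: RadialCircularSet) -> BMOEllipse:
    """Fit the BMO ellipse to the membrane edge points of radial slices.

    Each radial slice contributes up to two edge points, placed in a
    local en-face frame whose origin is the acquisition centre.
    """
    transform = tsnit_angle_transform(rset.laterality, (0.0, 0.0),
                                      rset.fovea_enface_um)
    pts = []
    for sl in rset.radial_slices:
        d = transform.direction(sl.angle_deg)
        for side in ("right", "left"):
            edge = bm_edge_point(sl, side, rset.scheme)
            if edge is not None:
                pts.append((edge[0] * d[0], edge[0] * d[1]))
    return fit_ellipse(np.asarray(pts))


def extract_biomarkers(
    source: Union[LabelVolume, RadialCircularSet],
    config: RunConfig = None,
    input_id: str = "",
) -> BiomarkerReport:
    if config is None:
        config = RunConfig()
    if isinstance(source, LabelVolume):
        return _extract_cube(source, config, input_id)
    return _extract_radial(source, config, input_id)


def _provenance(config: RunConfig, input_id, content) -> dict:
    digest = hashlib.sha256(content).hexdigest()[:16]
    return {
        "input_id": input_id,
        "input_sha256_16": digest,
        "tool": "onhmetry",
        "version": __version__,
        "parameters": {
            "diameters_mm": list(config.diameters_mm),
            "n_radials": config.n_radials,
            "closing_radius_px": config.closing_radius_px,
            "tilt": config.tilt,
            "n_circle_samples": config.n_circle_samples,
        },
    }


def _summary_dicts(summary):
    return {
        "global_mean_um": summary.global_mean_um,
        "tsnit": dict(summary.tsnit),
        "clock_hours": {str(h): v for h, v in summary.clock_hours.items()},
        "tilt_applied": summary.tilt_applied,
        "missing": list(summary.missing_sectors),
    }


def _extract_cube(volume: LabelVolume, config: RunConfig, input_id):
    report = BiomarkerReport()
    report.provenance = _provenance(config, input_id,
                                    np.ascontiguousarray(volume.labels).data)
    resolved = resolve_vessels(volume)
    ellipse, warnings = detect_bmo(resolved, config.closing_radius_px)
    report.warnings.extend(warnings)
    report.bmo_area_mm2 = ellipse.area_mm2
    report.bmo_center_um = ellipse.center_um
    fovea = volume.fovea_enface_um if config.tilt else None
    transform = tsnit_angle_transform(volume.laterality, ellipse.center_um,
                                      fovea)
    if transform.warning:
        report.warnings.append(transform.warning)
    thickness = thickness_map(resolved)
    for dia in config.diameters_mm:
        try:
            _profile, summary = cprnfl(thickness, ellipse, dia,
                                       transform=transform,
                                       n_samples=config.n_circle_samples)
        except OutOfBoundsError:
            report.unavailable.append(f"cprnfl.{_dia_key(dia)}")
            continue
        report.cprnfl[_dia_key(dia)] = _summary_dicts(summary)
    mrw_result = compute_mrw(resolved, ellipse=ellipse,
                             n_radials=config.n_radials, transform=transform)
    report.warnings.extend(mrw_result.warnings)
    report.mrw = {
        "global_mean_um": mrw_result.global_mean_um,
        "tsnit": dict(mrw_result.sectors.tsnit),
        "n_meridians": mrw_result.n_meridians,
        "n_missing": mrw_result.n_missing,
        "per_meridian": {
            "angles_deg": mrw_result.per_meridian.angles_deg.tolist(),
            "widths_um": mrw_result.per_meridian.values.tolist(),
            "defined": (~mrw_result.per_meridian.undefined).tolist(),
        },
    }
    cup = cup_volume(resolved, ellipse)
    report.cup_volume_mm3 = cup.volume_mm3
    if cup.skipped_bscans:
        report.warnings.append(
            f"{len(cup.skipped_bscans)} B-scans without endpoints skipped")
    return report


def _extract_radial(rset: RadialCircularSet, config: RunConfig, input_id):
    report = BiomarkerReport()
    content = b"".join(np.ascontiguousarray(s.labels).tobytes()
                       for s in rset.radial_slices)
    report.provenance = _provenance(config, input_id, content)
    ellipse = bmo_from_radials(rset)
    report.bmo_area_mm2 = ellipse.area_mm2
    report.bmo_center_um = ellipse.center_um
    for sl in rset.circular_slices:
        _profile, summary = cprnfl_from_circular(sl, rset.scheme)
        report.cprnfl[_dia_key(sl.diameter_mm)] = _summary_dicts(summary)
    mrw_result = compute_mrw(rset)
    report.warnings.extend(mrw_result.warnings)
    report.mrw = {
        "global_mean_um": mrw_result.global_mean_um,
        "tsnit": dict(mrw_result.sectors.tsnit),
        "n_meridians": mrw_result.n_meridians,
        "n_missing": mrw_result.n_missing,
        "per_meridian": {
            "angles_deg": mrw_result.per_meridian.angles_deg.tolist(),
            "widths_um": mrw_result.per_meridian.values.tolist(),
            "defined": (~mrw_result.per_meridian.undefined).tolist(),
        },
    }
    report.unavailable.extend(["cup_volume_mm3", "heatmap"])
    return report


def profile_to_csv(profile, path, value_name: str = "thickness_um") -> None:
    """Write an angular profile as CSV (angle_deg, value, defined_flag)."""
    with open(path, "w") as fh:
        fh.write(f"angle_deg,{value_name},defined\n")
        for a, v, u in zip(profile.angles_deg, profile.values,
                           profile.undefined):
            fh.write(f"{a!r},{v!r},{int(not u)}\n")
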