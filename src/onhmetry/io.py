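"""Reading and writing label volumes, radial sets and metadata sidecars.

Label volumes travel as NIfTI (.nii/.nii.gz) or multipage TIFF (one page
per B-scan, each page indexed (ascan, axial)), with a JSON sidecar that
is authoritative for spacings, laterality, acquisition type and the
label scheme. Radial+circular sets travel as two multipage TIFFs (radial
and circular slices) plus one sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .exceptions import ConfigurationError, FormatError
from .scheme import LabelScheme
from .volume import CircularSlice, LabelVolume, RadialCircularSet, RadialSlice

SIDECAR_REQUIRED = ("spacing_bscan_um", "spacing_ascan_um", "spacing_axial_um",
                    "laterality", "acquisition", "labels")


def read_sidecar(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"sidecar {path} does not exist")
    with open(path) as fh:
        meta = json.load(fh)
    missing = [k for k in SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ConfigurationError(
            f"sidecar {path} missing required field(s): {', '.join(missing)}")
    return meta


def write_sidecar(meta: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def _load_array(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input {path} does not exist")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    elif suffixes.endswith((".tif", ".tiff")):
        arr = tifffile.imread(str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int32)
        else:
            raise FormatError("voxel data is not integer-valued")
    return arr


def read_label_volume(path, sidecar_path=None) -> LabelVolume:
    """Read and validate a cube label volume with its JSON sidecar.

    The sidecar defaults to ``<path>.json``. Voxel codes not declared in
    the sidecar's label scheme are rejected.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = read_sidecar(sidecar_path)
    arr = _load_array(path)
    scheme = LabelScheme.from_dict(meta["labels"])
    fovea = meta.get("fovea_enface_um")
    return LabelVolume(
        labels=arr,
        spacing_bscan_um=float(meta["spacing_bscan_um"]),
        spacing_ascan_um=float(meta["spacing_ascan_um"]),
        spacing_axial_um=float(meta["spacing_axial_um"]),
        laterality=meta["laterality"],
        acquisition=meta["acquisition"],
        scheme=scheme,
        fovea_enface_um=None if fovea is None else tuple(fovea),
    )


def write_label_volume(volume: LabelVolume, path, sidecar_path=None) -> None:
    """Write a label volume (NIfTI or TIFF by extension) plus sidecar."""
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([volume.spacing_bscan_um * 1e-3,
                          volume.spacing_ascan_um * 1e-3,
                          volume.spacing_axial_um * 1e-3, 1.0])
        nib.save(nib.Nifti1Image(volume.labels.astype(np.uint8), affine),
                 str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), volume.labels.astype(np.uint8))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    meta = {
        "spacing_bscan_um": volume.spacing_bscan_um,
        "spacing_ascan_um": volume.spacing_ascan_um,
        "spacing_axial_um": volume.spacing_axial_um,
        "laterality": volume.laterality,
        "acquisition": volume.acquisition,
        "labels": volume.scheme.to_dict(),
    }
    if volume.fovea_enface_um is not None:
        meta["fovea_enface_um"] = list(volume.fovea_enface_um)
    write_sidecar(meta, sidecar_path)


def write_radial_set(rset: RadialCircularSet, basepath) -> None:
    """Write a radial+circular set as two TIFFs plus one sidecar.

    ``<base>_radials.tif`` holds one page per radial slice;
    ``<base>_circles.tif`` one page per circular slice;
    ``<base>.json`` the metadata.
    """
    base = Path(basepath)
    with tifffile.TiffWriter(str(base.parent / (base.name + "_radials.tif"))) as tw:
        for sl in rset.radial_slices:
            tw.write(sl.labels.astype(np.uint8))
    with tifffile.TiffWriter(str(base.parent / (base.name + "_circles.tif"))) as tw:
        for sl in rset.circular_slices:
            tw.write(sl.labels.astype(np.uint8))
    first = rset.radial_slices[0]
    meta = {
        "spacing_bscan_um": first.lateral_step_um,
        "spacing_ascan_um": first.lateral_step_um,
        "spacing_axial_um": first.axial_step_um,
        "laterality": rset.laterality,
        "acquisition": "radial_circular",
        "labels": rset.scheme.to_dict(),
        "radial_angles_deg": [s.angle_deg for s in rset.radial_slices],
        "radial_center_offsets": [s.center_offset for s in rset.radial_slices],
        "radial_lateral_step_um": [s.lateral_step_um for s in rset.radial_slices],
        "circle_diameters_mm": [s.diameter_mm for s in rset.circular_slices],
        "circle_start_angle_deg": [s.start_angle_deg for s in rset.circular_slices],
        "circle_direction": [s.direction for s in rset.circular_slices],
    }
    if rset.fovea_enface_um is not None:
        meta["fovea_enface_um"] = list(rset.fovea_enface_um)
    write_sidecar(meta, base.parent / (base.name + ".json"))


def read_radial_set(basepath) -> RadialCircularSet:
    base = Path(basepath)
    meta = read_sidecar(base.parent / (base.name + ".json"))
    for key in ("radial_angles_deg", "circle_diameters_mm",
                "circle_start_angle_deg", "circle_direction"):
        if key not in meta:
            raise ConfigurationError(f"radial-set sidecar missing {key!r}")
    scheme = LabelScheme.from_dict(meta["labels"])
    axial = float(meta["spacing_axial_um"])
    with tifffile.TiffFile(str(base.parent / (base.name + "_radials.tif"))) as tf:
        radial_pages = [p.asarray() for p in tf.pages]
    with tifffile.TiffFile(str(base.parent / (base.name + "_circles.tif"))) as tf:
        circle_pages = [p.asarray() for p in tf.pages]
    steps = meta.get("radial_lateral_step_um")
    offsets = meta.get("radial_center_offsets")
    radials = []
    for i, (angle, page) in enumerate(zip(meta["radial_angles_deg"],
                                          radial_pages)):
        step = float(steps[i]) if steps else float(meta["spacing_ascan_um"])
        off = int(offsets[i]) if offsets else page.shape[0] // 2
        radials.append(RadialSlice(angle_deg=float(angle), labels=page,
                                   lateral_step_um=step, axial_step_um=axial,
                                   center_offset=off))
    circles = []
    for dia, start, direction, page in zip(
            meta["circle_diameters_mm"], meta["circle_start_angle_deg"],
            meta["circle_direction"], circle_pages):
        circles.append(CircularSlice(
            diameter_mm=float(dia), labels=page, axial_step_um=axial,
            start_angle_deg=float(start), direction=int(direction)))
    fovea = meta.get("fovea_enface_um")
    return RadialCircularSet(
        radial_slices=radials, circular_slices=circles,
        laterality=meta["laterality"], scheme=scheme,
        fovea_enface_um=None if fovea is None else tuple(fovea),
    )
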