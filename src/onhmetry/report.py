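"""The per-eye biomarker report and its JSON/CSV serialisation."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import ConfigurationError

NA_TOKEN = "NA"


@dataclass
class BiomarkerReport:
    """All extracted scalars and sector tables for one eye/volume.

    ``cprnfl`` maps a diameter key (e.g. "3.5") to a dict with
    ``global_mean_um``, ``tsnit`` (sector name -> um) and ``clock_hours``
    (hour -> um). Missing values are stored as None and rendered as an
    explicit NA token in CSV. ``provenance`` records the input identity,
    tool version and the parameters used.
    """

    bmo_area_mm2: Optional[float] = None
    bmo_center_um: Optional[tuple] = None
    cprnfl: dict = field(default_factory=dict)
    mrw: Optional[dict] = None
    cup_volume_mm3: Optional[float] = None
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    unavailable: list = field(default_factory=list)

    def get_value(self, key: str):
        """Dotted-path access, e.g. ``cprnfl.3.5.global_mean_um`` or
        ``mrw.global_mean_um`` or ``bmo_area_mm2``."""
        if key in ("bmo_area_mm2", "cup_volume_mm3"):
            return getattr(self, key)
        parts = key.split(".")
        if parts[0] == "cprnfl":
            # diameter keys themselves contain a dot ("3.5")
            if len(parts) < 3:
                raise KeyError(key)
            *dia, leaf = parts[1:]
            node = self.cprnfl.get(".".join(dia))
            if node is None:
                raise KeyError(key)
            return _walk(node, [leaf])
        if parts[0] == "mrw":
            if self.mrw is None:
                raise KeyError(key)
            return _walk(self.mrw, parts[1:])
        raise KeyError(key)

    def to_dict(self) -> dict:
        return {
            "bmo_area_mm2": self.bmo_area_mm2,
            "bmo_center_um": (None if self.bmo_center_um is None
                              else list(self.bmo_center_um)),
            "cprnfl": self.cprnfl,
            "mrw": self.mrw,
            "cup_volume_mm3": self.cup_volume_mm3,
            "provenance": self.provenance,
            "warnings": self.warnings,
            "unavailable": self.unavailable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiomarkerReport":
        r = cls(
            bmo_area_mm2=d.get("bmo_area_mm2"),
            bmo_center_um=(None if d.get("bmo_center_um") is None
                           else tuple(d["bmo_center_um"])),
            cprnfl=d.get("cprnfl", {}),
            mrw=d.get("mrw"),
            cup_volume_mm3=d.get("cup_volume_mm3"),
            provenance=d.get("provenance", {}),
            warnings=d.get("warnings", []),
            unavailable=d.get("unavailable", []),
        )
        r._validate()
        return r

    def _validate(self):
        def check_nonneg(v, what):
            if v is not None and not (isinstance(v, (int, float))
                                      and (math.isnan(v) or v >= 0)):
                raise ConfigurationError(f"{what} must be >= 0 or missing")
        check_nonneg(self.bmo_area_mm2, "bmo_area_mm2")
        check_nonneg(self.cup_volume_mm3, "cup_volume_mm3")
        for dia, node in self.cprnfl.items():
            check_nonneg(node.get("global_mean_um"), f"cprnfl {dia} global")


def _walk(node, parts):
    for p in parts:
        if isinstance(node, dict):
            if p in node:
                node = node[p]
            elif p.isdigit() and int(p) in node:
                node = node[int(p)]
            else:
                raise KeyError(p)
        else:
            raise KeyError(p)
    return node


def _flatten(prefix, node, rows):
    if isinstance(node, dict):
        for k, v in node.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(node, (list, tuple)):
        for i, v in enumerate(node):
            _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, node))


def write_report(report: BiomarkerReport, path, format: str = "json") -> None:
    """Write a report as JSON (lossless full precision) or flat CSV.

    Missing values become ``null`` in JSON and the explicit ``NA`` token
    in CSV. Unsupported formats raise ValueError.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_sanitize(report.to_dict()), fh, indent=2,
                      allow_nan=False)
            fh.write("\n")
    elif format == "csv":
        rows = []
        _flatten("", _sanitize(report.to_dict()), rows)
        with open(path, "w") as fh:
            fh.write("key,value\n")
            for key, value in rows:
                if value is None:
                    rendered = NA_TOKEN
                elif isinstance(value, float):
                    rendered = repr(value)
                else:
                    rendered = str(value).replace(",", ";")
                fh.write(f"{key},{rendered}\n")
    else:
        raise ValueError(f"unsupported report format {format!r}")


def _sanitize(node):
    """NaN -> None so missing values are explicit in both formats."""
    if isinstance(node, dict):
        return {str(k): _sanitize(v) for k, v in node.items()}
    if isinstance(node, (list, tuple)):
        return [_sanitize(v) for v in node]
    if isinstance(node, float) and math.isnan(node):
        return None
    return node


def read_report(path) -> BiomarkerReport:
    with open(path) as fh:
        return BiomarkerReport.from_dict(json.load(fh))
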