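"""Label schemes for multi-class ONH segmentation volumes.

A scheme maps anatomical structure names to integer voxel codes. The
required structures are background, the retinal nerve fiber layer (RNFL),
retinal vessels, the RPE-Bruch's membrane complex (annotated jointly
because Bruch's membrane alone is thinner than the axial pixel size of
commercial OCT devices) and prelaminar tissue. Peripapillary atrophy
zones (alpha/beta/gamma) and the lamina cribrosa are optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field


REQUIRED_LABELS = ("background", "rnfl", "vessel", "rpe_bm", "prelaminar")
OPTIONAL_LABELS = ("lamina_cribrosa", "ppa_alpha", "ppa_beta", "ppa_gamma")


@dataclass(frozen=True)
class LabelScheme:
    """Name -> integer code map for a segmentation label volume."""

    codes: dict = field(
        default_factory=lambda: dict(DEFAULT_CODES)
    )

    def __post_init__(self):
        violations = validate_scheme(self)
        if violations:
            raise ValueError("invalid label scheme: " + "; ".join(violations))

    def __getitem__(self, name: str) -> int:
        return self.codes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.codes

    def get(self, name: str, default=None):
        return self.codes.get(name, default)

    @property
    def names(self):
        return tuple(self.codes)

    @property
    def all_codes(self):
        return tuple(self.codes.values())

    def codes_for(self, names) -> tuple:
        """Codes for the given structure names, skipping absent optionals."""
        out = []
        for name in names:
            if name in self.codes:
                out.append(self.codes[name])
            elif name in REQUIRED_LABELS:
                raise KeyError(f"required label {name!r} missing from scheme")
        return tuple(out)

    def to_dict(self) -> dict:
        return dict(self.codes)

    @classmethod
    def from_dict(cls, mapping: dict) -> "LabelScheme":
        return cls(codes={str(k): int(v) for k, v in mapping.items()})


DEFAULT_CODES = {
    "background": 0,
    "rnfl": 1,
    "vessel": 2,
    "rpe_bm": 3,
    "prelaminar": 4,
    "lamina_cribrosa": 5,
    "ppa_alpha": 6,
    "ppa_beta": 7,
    "ppa_gamma": 8,
}


def validate_scheme(scheme) -> list:
    """Return a list of human-readable invariant violations (empty if valid).

    Checks: all required structures present, codes are distinct
    non-negative integers, and no unknown structure names.
    """
    codes = scheme.codes if isinstance(scheme, LabelScheme) else dict(scheme)
    violations = []
    for name in REQUIRED_LABELS:
        if name not in codes:
            violations.append(f"missing required label {name!r}")
    known = set(REQUIRED_LABELS) | set(OPTIONAL_LABELS)
    for name in codes:
        if name not in known:
            violations.append(f"unknown label name {name!r}")
    for name, code in codes.items():
        if not isinstance(code, (int,)) or isinstance(code, bool):
            violations.append(f"code for {name!r} is not an integer")
        elif code < 0:
            violations.append(f"code for {name!r} is negative")
    seen = {}
    for name, code in codes.items():
        if isinstance(code, int) and not isinstance(code, bool):
            if code in seen:
                violations.append(
                    f"duplicate code {code} for {seen[code]!r} and {name!r}"
                )
            else:
                seen[code] = name
    return violations


DEFAULT_SCHEME = LabelScheme()
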