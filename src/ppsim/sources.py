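"""Light-source models for the Monte Carlo transport.

Four emitter geometries cover the device configurations of interest:

- ``pencil``: collimated zero-width beam,
- ``isotropic_point``: point emitter, uniform over 4π,
- ``led_disk``: Lambertian disk (butt-coupled SMD-LED approximation),
- ``waveguide_face``: disk emitting uniformly within a cone of configurable
  half-angle (waveguide output facet with numerical-aperture cone).

Positions are in micrometres in phantom coordinates; power is specified per
wavelength in watts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KINDS = ("pencil", "isotropic_point", "led_disk", "waveguide_face")
_KIND_CODE = {k: i for i, k in enumerate(KINDS)}


@dataclass
class SourceSpec:
    kind: str
    position_um: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius_um: float = 0.0
    half_angle_deg: float = 20.0
    power_w: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"source kind must be one of {KINDS}, got '{self.kind}'")
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if norm == 0:
            raise ValueError("direction must be a nonzero vector")
        if abs(norm - 1.0) > 1e-12:
            d = d / norm
        self.direction = tuple(d)
        if self.radius_um < 0:
            raise ValueError("radius must be >= 0")
        if not (0 < self.half_angle_deg <= 90):
            raise ValueError("half angle must lie in (0, 90] degrees")
        self.power_w = {float(k): float(v) for k, v in self.power_w.items()}
        if any(p < 0 for p in self.power_w.values()):
            raise ValueError("power must be >= 0")

    @property
    def kind_code(self) -> int:
        return _KIND_CODE[self.kind]

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal frame (e1, e2, dir) for sampling around the beam axis."""
        w = np.asarray(self.direction)
        a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(w, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(w, e1)
        return e1, e2, w

    def power_at(self, wavelength: float) -> float:
        key = float(wavelength)
        if key not in self.power_w:
            raise KeyError(f"source has no power entry at {wavelength} nm")
        return self.power_w[key]
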