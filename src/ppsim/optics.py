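"""Per-tissue optical properties for voxel light transport.

A tissue class pairs a small integer label with a table of wavelength-resolved
optical properties: absorption coefficient mu_a [cm^-1], scattering
coefficient mu_s [cm^-1], Henyey-Greenstein anisotropy g, and refractive
index n.  Default values for the brain tissue classes ship as an editable
JSON table (``data/tissue_optics.json``) compiled from the tissue-optics
literature; they are configuration, not hard-coded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

TISSUE_NAMES = (
    "ambient",
    "grey_matter",
    "white_matter",
    "csf",
    "bone",
    "blood_vessel",
    "nerve_tissue",
    "probe_core",
    "probe_cladding",
)


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one material at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient [cm^-1], >= 0.
    mu_s : float
        Scattering coefficient [cm^-1], >= 0.
    g : float
        Henyey-Greenstein anisotropy factor, -1 < g < 1.
    n : float
        Refractive index, >= 1.
    wavelength : float
        Wavelength [nm] at which these values hold.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"anisotropy g must satisfy -1 < g < 1, got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")


@dataclass
class TissueClass:
    """A labelled material with wavelength-resolved optical properties."""

    label: int
    name: str
    properties: dict[float, OpticalProperties] = field(default_factory=dict)

    def at(self, wavelength: float, interpolate: bool = False) -> OpticalProperties:
        """Return properties at ``wavelength`` [nm].

        Exact table entries are required unless ``interpolate`` is set, in
        which case linear interpolation between the two bracketing table
        wavelengths is performed (never extrapolation).
        """
        key = float(wavelength)
        if key in self.properties:
            return self.properties[key]
        if not interpolate:
            raise KeyError(
                f"tissue class '{self.name}' has no optical properties at "
                f"{wavelength} nm (available: {sorted(self.properties)}); "
                "pass interpolate=True to interpolate"
            )
        wls = np.array(sorted(self.properties))
        if not (wls[0] <= key <= wls[-1]):
            raise KeyError(
                f"wavelength {wavelength} nm outside table range "
                f"[{wls[0]}, {wls[-1]}] for tissue class '{self.name}'"
            )

        def _interp(attr: str) -> float:
            vals = np.array([getattr(self.properties[w], attr) for w in wls])
            return float(np.interp(key, wls, vals))

        return OpticalProperties(
            mu_a=_interp("mu_a"),
            mu_s=_interp("mu_s"),
            g=_interp("g"),
            n=_interp("n"),
            wavelength=key,
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "name": self.name,
            "properties": [
                {
                    "wavelength": p.wavelength,
                    "mu_a": p.mu_a,
                    "mu_s": p.mu_s,
                    "g": p.g,
                    "n": p.n,
                }
                for _, p in sorted(self.properties.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueClass":
        props = {
            float(p["wavelength"]): OpticalProperties(
                mu_a=float(p["mu_a"]),
                mu_s=float(p["mu_s"]),
                g=float(p["g"]),
                n=float(p["n"]),
                wavelength=float(p["wavelength"]),
            )
            for p in d["properties"]
        }
        return cls(label=int(d["label"]), name=str(d["name"]), properties=props)


def load_tissue_table(path: str | Path | None = None) -> list[TissueClass]:
    """Load a tissue-class table from JSON.

    With no argument, loads the packaged default table for the brain /
    probe / ambient classes.
    """
    if path is None:
        text = (
            resources.files("ppsim").joinpath("data/tissue_optics.json").read_text()
        )
    else:
        text = Path(path).read_text()
    data = json.loads(text)
    classes = [TissueClass.from_dict(d) for d in data["classes"]]
    labels = [c.label for c in classes]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels in tissue table")
    return classes


def save_tissue_table(classes: list[TissueClass], path: str | Path) -> None:
    data = {"classes": [c.to_dict() for c in classes]}
    Path(path).write_text(json.dumps(data, indent=2))
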