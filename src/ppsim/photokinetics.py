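"""Two-state E ⇌ Z photoswitch kinetics driven by local photon flux.

The azobenzene photodrug interconverts photochemically in both directions
and thermally in one.  Per voxel the system is linear:

    dC_Z/dt =  k_EZ·C_E − k_ZE·C_Z
    dC_E/dt = −dC_Z/dt

where each direction's total rate combines the photochemical rate constant

    k^λ_ij = ln(10)·10³·ε_i(λ)·φ_ij(λ)·E_PF(λ)      [s⁻¹]

(summed over illumination wavelengths; the 10³ converts litres to cm³ so
that ε [L mol⁻¹ cm⁻¹] times photon flux [einstein cm⁻² s⁻¹] yields s⁻¹)
with the thermal rate k_Δ = ln2/t½ on the configured side.  This is the
optically-thin per-voxel limit: attenuation across voxels is carried by the
Monte Carlo fluence, not by this local formula.  The closed-form solution
is mono-exponential with κ = k_EZ + k_ZE (+ k_Δ) and conserves
C_E + C_Z exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import LN10
from .transport import FluenceMap, irradiance_to_photon_flux

THERMAL_DIRECTIONS = ("Z->E", "E->Z")


@dataclass
class PhotoswitchSpec:
    """Wavelength-resolved photoswitch photochemistry.

    Spectra are tabulated on a wavelength grid [nm] and linearly
    interpolated; querying outside the grid clamps to the end values and
    emits a warning.  ``t_half_s`` may be ``inf`` for a P-type switch (no
    thermal back-reaction); ``thermal_direction`` names the side the
    thermal relaxation feeds.
    """

    name: str
    wavelengths_nm: np.ndarray
    eps_e: np.ndarray  # [L mol^-1 cm^-1]
    eps_z: np.ndarray
    phi_ez: np.ndarray  # quantum yields, dimensionless
    phi_ze: np.ndarray
    t_half_s: float
    thermal_direction: str = "Z->E"

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        for attr in ("eps_e", "eps_z", "phi_ez", "phi_ze"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != self.wavelengths_nm.shape:
                raise ValueError(f"{attr} shape does not match wavelength grid")
            setattr(self, attr, arr)
        if (self.eps_e < 0).any() or (self.eps_z < 0).any():
            raise ValueError("extinction coefficients must be >= 0")
        for attr in ("phi_ez", "phi_ze"):
            arr = getattr(self, attr)
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("quantum yields must lie in [0, 1]")
        if not (self.t_half_s > 0):
            raise ValueError("thermal half-life must be > 0 (use inf for P-type)")
        if self.thermal_direction not in THERMAL_DIRECTIONS:
            raise ValueError(f"thermal_direction must be one of {THERMAL_DIRECTIONS}")

    def at(self, wavelength: float) -> tuple[float, float, float, float]:
        """(ε_E, ε_Z, φ_EZ, φ_ZE) at one wavelength, linearly interpolated."""
        wl = float(wavelength)
        grid = self.wavelengths_nm
        if wl < grid[0] or wl > grid[-1]:
            warnings.warn(
                f"wavelength {wl} nm outside the tabulated range "
                f"[{grid[0]}, {grid[-1]}]; clamping to the nearest end",
                stacklevel=2,
            )
        return (
            float(np.interp(wl, grid, self.eps_e)),
            float(np.interp(wl, grid, self.eps_z)),
            float(np.interp(wl, grid, self.phi_ez)),
            float(np.interp(wl, grid, self.phi_ze)),
        )

    @property
    def stable_isomer(self) -> str:
        return self.thermal_direction[-1]

    # ----------------------------------------------------------------- io
    def to_files(self, csv_path: str | Path, json_path: str | Path) -> None:
        pd.DataFrame(
            {
                "wavelength": self.wavelengths_nm,
                "eps_E": self.eps_e,
                "eps_Z": self.eps_z,
                "phi_EZ": self.phi_ez,
                "phi_ZE": self.phi_ze,
            }
        ).to_csv(csv_path, index=False)
        Path(json_path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "t_half_s": self.t_half_s if np.isfinite(self.t_half_s) else "inf",
                    "thermal_direction": self.thermal_direction,
                    "spectra_csv": str(Path(csv_path).name),
                },
                indent=2,
            )
        )

    @classmethod
    def from_files(cls, json_path: str | Path) -> "PhotoswitchSpec":
        meta = json.loads(Path(json_path).read_text())
        csv_path = Path(json_path).parent / meta["spectra_csv"]
        df = pd.read_csv(csv_path)
        t_half = meta["t_half_s"]
        return cls(
            name=meta.get("name", Path(json_path).stem),
            wavelengths_nm=df["wavelength"].to_numpy(),
            eps_e=df["eps_E"].to_numpy(),
            eps_z=df["eps_Z"].to_numpy(),
            phi_ez=df["phi_EZ"].to_numpy(),
            phi_ze=df["phi_ZE"].to_numpy(),
            t_half_s=np.inf if t_half == "inf" else float(t_half),
            thermal_direction=meta.get("thermal_direction", "Z->E"),
        )

    @classmethod
    def synthetic_azobenzene_inhibitor(cls, t_half_s: float = 600.0) -> "PhotoswitchSpec":
        """Synthetic two-band stand-in for a Z-stable azobenzene photodrug.

        Built to mimic the functional behaviour of a red-shifted azobenzene
        AMPA antagonist that is active (Z) in the dark or under 620 nm light
        and deactivated (→E) at 460 nm: the Z isomer absorbs in the blue,
        the E isomer in the red, and the thermal back-reaction feeds Z.
        Spectral shapes are Gaussians; no measured spectrum is reproduced.
        """
        wl = np.arange(400.0, 701.0, 10.0)
        eps_z = 8000.0 * np.exp(-(((wl - 460.0) / 45.0) ** 2))
        eps_e = 15000.0 * np.exp(-(((wl - 620.0) / 50.0) ** 2)) + 400.0 * np.exp(
            -(((wl - 440.0) / 40.0) ** 2)
        )
        return cls(
            name="synthetic-azo-inhibitor",
            wavelengths_nm=wl,
            eps_e=eps_e,
            eps_z=eps_z,
            phi_ez=np.full_like(wl, 0.30),
            phi_ze=np.full_like(wl, 0.40),
            t_half_s=t_half_s,
            thermal_direction="E->Z",
        )


# ------------------------------------------------------------------ rates
def rate_constant(eps, phi, e_pf):
    """Photochemical first-order rate constant k = ln(10)·10³·ε·φ·E_PF [s⁻¹].

    Linear in each argument; zero flux gives the dark limit k = 0.
    """
    eps = np.asarray(eps, dtype=float)
    phi = np.asarray(phi, dtype=float)
    e_pf = np.asarray(e_pf, dtype=float)
    if (eps < 0).any() or (phi < 0).any() or (e_pf < 0).any():
        raise ValueError("rate-constant inputs must be >= 0")
    return LN10 * 1e3 * eps * phi * e_pf


def thermal_rate(t_half_s: float) -> float:
    """First-order thermal rate k = ln2/t½; infinite t½ (P-type) gives 0."""
    if not (t_half_s > 0):
        raise ValueError("half-life must be > 0")
    if np.isinf(t_half_s):
        return 0.0
    return float(np.log(2.0) / t_half_s)


@dataclass
class RateConstants:
    """First-order rates [s⁻¹] of the two-state system at one point."""

    k_ez_hv: float | np.ndarray
    k_ze_hv: float | np.ndarray
    k_thermal: float = 0.0
    thermal_direction: str = "Z->E"

    def __post_init__(self) -> None:
        if self.thermal_direction not in THERMAL_DIRECTIONS:
            raise ValueError(f"thermal_direction must be one of {THERMAL_DIRECTIONS}")
        for attr in ("k_ez_hv", "k_ze_hv", "k_thermal"):
            if np.any(np.asarray(getattr(self, attr)) < 0):
                raise ValueError("rate constants must be >= 0")

    @property
    def k_ez_total(self):
        extra = self.k_thermal if self.thermal_direction == "E->Z" else 0.0
        return self.k_ez_hv + extra

    @property
    def k_ze_total(self):
        extra = self.k_thermal if self.thermal_direction == "Z->E" else 0.0
        return self.k_ze_hv + extra

    @property
    def kappa(self):
        return self.k_ez_hv + self.k_ze_hv + self.k_thermal


def pss_fraction(rates: RateConstants):
    """Z fraction at the photostationary state.

    f_Z = k_EZ,total / (k_EZ,total + k_ZE,total); with thermal relaxation
    Z→E this is k_EZ_hv/(k_EZ_hv + k_ZE_hv + k_Δ).  Ideal addressability
    (k_ZE = k_Δ = 0) gives complete conversion, f_Z = 1.
    """
    total = np.asarray(rates.kappa, dtype=float)
    if np.all(total == 0):
        raise ValueError("all rates are zero: no stationary state defined")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.asarray(rates.k_ez_total, dtype=float) / total
    return f if f.ndim else float(f)


def integrate_two_state(c_e0, c_z0, rates: RateConstants, t: float):
    """Closed-form concentrations at time t of the two-state system.

    C_Z(t) = C_Z^∞ + (C_Z(0) − C_Z^∞)·exp(−κt) with κ the sum of all rates
    and C_Z^∞ = f_Z·C_tot; C_E follows by exact mass conservation.  Voxels
    (or calls) with κ = 0 are stationary.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    c_e0 = np.asarray(c_e0, dtype=float)
    c_z0 = np.asarray(c_z0, dtype=float)
    if (c_e0 < 0).any() or (c_z0 < 0).any():
        raise ValueError("concentrations must be >= 0")
    c_tot = c_e0 + c_z0
    kappa = np.asarray(rates.kappa, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_inf = np.where(kappa > 0, np.asarray(rates.k_ez_total) / np.where(kappa > 0, kappa, 1.0), 0.0)
    cz_inf = f_inf * c_tot
    ce_inf = (1.0 - f_inf) * c_tot
    decay = np.exp(-kappa * t)
    # convex-combination form is exact at t = 0 and as t -> inf
    c_z = np.where(kappa > 0, c_z0 * decay + cz_inf * (1.0 - decay), c_z0)
    c_e = np.where(kappa > 0, c_e0 * decay + ce_inf * (1.0 - decay), c_e0)
    if c_e.ndim == 0:
        return float(c_e), float(c_z)
    return c_e, c_z


# ------------------------------------------------------------------ field
@dataclass
class ConcentrationField:
    """Per-voxel E/Z isomer concentrations [mol L⁻¹]."""

    c_e: np.ndarray
    c_z: np.ndarray

    def __post_init__(self) -> None:
        self.c_e = np.asarray(self.c_e, dtype=float)
        self.c_z = np.asarray(self.c_z, dtype=float)
        if self.c_e.shape != self.c_z.shape:
            raise ValueError("c_e and c_z grids differ")
        if (self.c_e < 0).any() or (self.c_z < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def c_tot(self) -> np.ndarray:
        return self.c_e + self.c_z

    @property
    def f_z(self) -> np.ndarray:
        tot = self.c_tot
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.c_z / np.where(tot > 0, tot, 1.0), 0.0)

    @classmethod
    def uniform(cls, shape, c_tot: float, f_z: float = 1.0) -> "ConcentrationField":
        if not (0.0 <= f_z <= 1.0):
            raise ValueError("f_z must lie in [0, 1]")
        return cls(
            c_e=np.full(shape, c_tot * (1.0 - f_z)),
            c_z=np.full(shape, c_tot * f_z),
        )


def field_rates(fluence: FluenceMap, spec: PhotoswitchSpec) -> RateConstants:
    """Per-voxel rate constants from a (multi-wavelength) fluence map.

    Photochemical rates are summed across wavelengths; the thermal rate is
    a scalar on the spec's thermal side.
    """
    shape = None
    k_ez = None
    k_ze = None
    for wl in fluence.wavelengths:
        e_pf = irradiance_to_photon_flux(fluence.fluence[wl], wl)
        eps_e, eps_z, phi_ez, phi_ze = spec.at(wl)
        if k_ez is None:
            shape = e_pf.shape
            k_ez = np.zeros(shape)
            k_ze = np.zeros(shape)
        k_ez += rate_constant(eps_e, phi_ez, e_pf)
        k_ze += rate_constant(eps_z, phi_ze, e_pf)
    if k_ez is None:
        raise ValueError("fluence map holds no wavelengths")
    return RateConstants(
        k_ez_hv=k_ez,
        k_ze_hv=k_ze,
        k_thermal=thermal_rate(spec.t_half_s),
        thermal_direction=spec.thermal_direction,
    )


def field_kinetics(
    field: ConcentrationField,
    fluence: FluenceMap,
    spec: PhotoswitchSpec,
    t: float | None = None,
    pss: bool = False,
) -> ConcentrationField:
    """Advance the concentration field under a fluence map.

    Either integrate for a time ``t`` (closed form, voxelwise) or jump to
    the photostationary state (``pss=True``).  Voxels with zero flux evolve
    thermally only.  Grids must match.
    """
    if (t is None) == (not pss):
        raise ValueError("specify exactly one of t or pss=True")
    for wl in fluence.wavelengths:
        if fluence.fluence[wl].shape != field.c_e.shape:
            raise ValueError("fluence and concentration grids differ")
    rates = field_rates(fluence, spec)
    if pss:
        kappa = np.asarray(rates.kappa)
        f_inf = np.where(
            kappa > 0, np.asarray(rates.k_ez_total) / np.where(kappa > 0, kappa, 1.0), field.f_z
        )
        c_tot = field.c_tot
        return ConcentrationField(c_e=(1.0 - f_inf) * c_tot, c_z=f_inf * c_tot)
    c_e, c_z = integrate_two_state(field.c_e, field.c_z, rates, t)
    return ConcentrationField(c_e=c_e, c_z=c_z)


# ------------------------------------------------------------ diagnostics
def addressability_report(
    spec: PhotoswitchSpec,
    wavelengths: tuple[float, ...],
    ratio_threshold: float = 100.0,
    photon_flux: float = 1e-9,
) -> pd.DataFrame:
    """Light-responsiveness diagnostics per wavelength.

    For each wavelength, reports ρ_E = ε_E·φ_EZ and ρ_Z = ε_Z·φ_ZE, whether
    the strict one-sided condition (ρ_Z = 0, ρ_E ≠ 0 — complete conversion
    to Z, or the mirrored case) or the dominance condition
    (ρ_E/ρ_Z ≥ ratio_threshold or its inverse) holds, and the implied PSS
    Z-fraction at the stated photon flux [einstein cm⁻² s⁻¹].
    """
    rows = []
    k_d = thermal_rate(spec.t_half_s)
    for wl in wavelengths:
        eps_e, eps_z, phi_ez, phi_ze = spec.at(wl)
        rho_e = eps_e * phi_ez
        rho_z = eps_z * phi_ze
        cond1 = (rho_z == 0.0 and rho_e > 0.0) or (rho_e == 0.0 and rho_z > 0.0)
        big, small = max(rho_e, rho_z), min(rho_e, rho_z)
        cond2 = small > 0 and big / small >= ratio_threshold or cond1
        rates = RateConstants(
            k_ez_hv=rate_constant(eps_e, phi_ez, photon_flux),
            k_ze_hv=rate_constant(eps_z, phi_ze, photon_flux),
            k_thermal=k_d,
            thermal_direction=spec.thermal_direction,
        )
        f_z = pss_fraction(rates) if rates.kappa > 0 else np.nan
        rows.append(
            {
                "wavelength_nm": wl,
                "rho_E": rho_e,
                "rho_Z": rho_z,
                "condition_one_sided": cond1,
                "condition_dominant": bool(cond2),
                "pss_f_z": f_z,
            }
        )
    return pd.DataFrame(rows)
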