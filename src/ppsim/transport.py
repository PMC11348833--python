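"""Photon-packet Monte Carlo transport through a voxel phantom.

`run_mc` produces per-wavelength fluence-rate maps Φ [W cm⁻²] normalized to
source power, together with a weight ledger for the energy audit.  The
photon flux E_PF [einstein cm⁻² s⁻¹] follows from Φ by E_PF = Φ·λ/(N_A·h·c)
and is what drives the photoswitch kinetics.

The module also exposes the transport primitives (exponential step
sampling, Henyey-Greenstein scattering, Fresnel boundaries, voxel
traversal) as plain NumPy functions for diagnostics and testing; the
production path is the compiled kernel in ``ppsim._kernel``, which inlines
the same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .constants import MOLAR_PHOTON_ENERGY_FACTOR
from .phantom import TissuePhantom
from .sources import SourceSpec


# ------------------------------------------------------------- primitives
def sample_step(rng: np.random.Generator, mu_t: float, size=None):
    """Free-path length s = -ln(ξ)/μ_t [cm], ξ ~ U(0, 1].

    μ_t must be > 0; a μ_t = 0 medium is transparent and is handled by the
    transport loop (propagation to the next boundary), not by sampling.
    """
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0 for step sampling")
    xi = 1.0 - rng.random(size)  # in (0, 1]
    return -np.log(xi) / mu_t


def scatter_hg(rng: np.random.Generator, g: float, size=None):
    """Sample (cosθ, φ) from the Henyey-Greenstein phase function.

    cosθ has mean g; φ is uniform on [0, 2π).
    """
    if abs(g) >= 1.0:
        raise ValueError("anisotropy g must satisfy |g| < 1")
    u = rng.random(size)
    if abs(g) < 1e-12:
        cos_theta = 1.0 - 2.0 * u
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_theta = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    phi = 2.0 * np.pi * rng.random(size)
    return cos_theta, phi


def fresnel_boundary(n1: float, n2: float, cos_incidence: float):
    """Unpolarized Fresnel reflectance at a planar index step.

    Returns ``(R, cos_theta_t, tir)``: the reflectance, the cosine of the
    refraction angle (0 when total internal reflection occurs) and the TIR
    flag.  Matched media give R = 0 and an unchanged direction.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if not (0.0 <= cos_incidence <= 1.0):
        raise ValueError("incidence cosine must lie in [0, 1]")
    return _kernel._fresnel(float(n1), float(n2), float(cos_incidence))


def traverse_voxels(
    position_um,
    direction,
    step_um: float,
    dims: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
):
    """Ray-march a straight step through the voxel grid.

    Returns ``(segments, exited)`` where segments is an ordered list of
    ``((ix, iy, iz), sub_path_um)`` whose lengths sum to the step (or to the
    in-grid portion when the ray exits, with ``exited=True``).
    """
    if step_um < 0:
        raise ValueError("step must be >= 0")
    pos = np.asarray(position_um, dtype=float).copy()
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    d = np.asarray(voxel_size_um, dtype=float)
    n = np.asarray(dims)
    idx = np.floor(pos / d).astype(int)
    if np.any(idx < 0) or np.any(idx >= n):
        raise ValueError("start position outside the grid")
    segments = []
    remaining = float(step_um)
    if remaining == 0.0:
        return [(tuple(int(i) for i in idx), 0.0)], False
    while remaining > 1e-12:
        t = np.full(3, np.inf)
        for a in range(3):
            if u[a] > 0:
                t[a] = ((idx[a] + 1) * d[a] - pos[a]) / u[a]
            elif u[a] < 0:
                t[a] = (idx[a] * d[a] - pos[a]) / u[a]
        tb = max(float(t.min()), 0.0)
        if tb >= remaining:
            segments.append((tuple(int(i) for i in idx), remaining))
            return segments, False
        segments.append((tuple(int(i) for i in idx), tb))
        pos = pos + tb * u
        remaining -= tb
        a = int(np.argmin(t))
        idx[a] += 1 if u[a] > 0 else -1
        if idx[a] < 0 or idx[a] >= n[a]:
            return segments, True
    return segments, False


def irradiance_to_photon_flux(phi, wavelength_nm: float):
    """Convert fluence rate Φ [W cm⁻²] to photon flux [einstein cm⁻² s⁻¹].

    E_PF = Φ·λ / (N_A·h·c); strictly linear in both Φ and λ.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return np.asarray(phi) * (wavelength_nm * 1e-9) / MOLAR_PHOTON_ENERGY_FACTOR


# ------------------------------------------------------------ run config
@dataclass
class RunConfig:
    n_photons: int = 100_000
    rng_seed: int = 1
    wavelengths: tuple[float, ...] = (460.0,)
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_path_cm: float = 100.0

    def __post_init__(self) -> None:
        self.n_photons = int(self.n_photons)
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not (0.0 < self.roulette_survival < 1.0):
            raise ValueError("roulette survival must lie in (0, 1)")
        if self.roulette_threshold <= 0:
            raise ValueError("roulette threshold must be > 0")
        if self.max_path_cm <= 0:
            raise ValueError("max path must be > 0")
        self.wavelengths = tuple(float(w) for w in self.wavelengths)


@dataclass
class FluenceMap:
    """Per-wavelength fluence-rate volumes plus the weight ledger.

    ``fluence[λ]`` is Φ in W cm⁻² (scaled by the source power at λ);
    ``absorbed_w[λ]`` is deposited power per voxel [W].  The ledger keeps
    launched/absorbed/escaped/roulette weights in per-launched-photon units
    so that the audit identity

        launched + roulette_gain == absorbed + escaped + roulette_loss

    can be checked exactly (up to float summation) on every run.
    """

    fluence: dict[float, np.ndarray]
    absorbed_w: dict[float, np.ndarray]
    ledger: dict[float, dict]
    voxel_size_um: tuple[float, float, float]

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.fluence))

    def photon_flux(self, wavelength: float) -> np.ndarray:
        return irradiance_to_photon_flux(self.fluence[float(wavelength)], wavelength)

    def audit_residual(self, wavelength: float) -> float:
        """Relative weight-conservation residual for one wavelength run."""
        led = self.ledger[float(wavelength)]
        launched = led["launched"]
        if launched == 0.0:
            return 0.0
        res = (
            launched
            + led["roulette_gain"]
            - led["absorbed"]
            - led["escaped"]
            - led["roulette_loss"]
        )
        return abs(res) / launched

    def max_audit_residual(self) -> float:
        return max(self.audit_residual(w) for w in self.fluence)


# ------------------------------------------------------------------ runs
def _wavelength_seed(seed: int, wavelength: float, salt: int = 0) -> int:
    return (int(seed) * 1_000_003 + int(round(wavelength * 8)) + 7919 * salt) % (2**62)


def run_mc(
    phantom: TissuePhantom,
    source: SourceSpec,
    config: RunConfig,
    extra_mua: dict[float, np.ndarray] | np.ndarray | None = None,
    seed_salt: int = 0,
) -> FluenceMap:
    """Run the transport kernel for every configured wavelength.

    ``extra_mua`` adds a per-voxel absorption perturbation [cm⁻¹] on top of
    the tissue baseline (one array for all wavelengths, or a dict per
    wavelength) — this is how dissolved photodrug feeds back on the light
    field.  Results are deterministic given (seed, n_photons, phantom,
    source).
    """
    dims = phantom.dims
    dx, dy, dz = (v * 1e-4 for v in phantom.voxel_size)  # um -> cm
    e1, e2, w = source.frame()
    pos_cm = np.asarray(source.position_um, dtype=float) * 1e-4
    radius_cm = source.radius_um * 1e-4
    cos_half = float(np.cos(np.deg2rad(source.half_angle_deg)))
    vol_cm3 = phantom.voxel_volume_cm3

    fluence: dict[float, np.ndarray] = {}
    absorbed_w: dict[float, np.ndarray] = {}
    ledger: dict[float, dict] = {}
    for wl in config.wavelengths:
        mua_l, mus_l, g_l, n_l = phantom.property_arrays(wl)
        if isinstance(extra_mua, dict):
            extra = extra_mua.get(wl)
        else:
            extra = extra_mua
        if extra is None:
            extra = np.zeros(dims)
        else:
            extra = np.ascontiguousarray(extra, dtype=np.float64)
            if extra.shape != dims:
                raise ValueError("extra_mua grid does not match the phantom")
            if extra.min() < 0:
                raise ValueError("extra_mua must be >= 0")
        # an empty power table means "unit power at every wavelength";
        # a populated one gives 0 W (dark) at wavelengths it omits
        power = source.power_w.get(wl, 0.0) if source.power_w else 1.0
        tl = np.zeros(dims)
        ab = np.zeros(dims)
        cl = np.zeros(mua_l.size)
        if power == 0.0:
            fluence[wl] = tl
            absorbed_w[wl] = ab
            ledger[wl] = {
                "launched": 0.0,
                "escaped": 0.0,
                "absorbed": 0.0,
                "roulette_gain": 0.0,
                "roulette_loss": 0.0,
                "absorbed_by_class": {},
                "n_photons": 0,
                "seed": config.rng_seed,
                "power_w": 0.0,
            }
            continue
        launched, escaped, r_gain, r_loss = _kernel.mc_transport(
            phantom.labels,
            mua_l,
            mus_l,
            g_l,
            n_l,
            extra,
            dx,
            dy,
            dz,
            source.kind_code,
            pos_cm[0],
            pos_cm[1],
            pos_cm[2],
            w[0],
            w[1],
            w[2],
            e1[0],
            e1[1],
            e1[2],
            e2[0],
            e2[1],
            e2[2],
            radius_cm,
            cos_half,
            config.n_photons,
            _wavelength_seed(config.rng_seed, wl, seed_salt),
            config.roulette_threshold,
            config.roulette_survival,
            config.max_path_cm,
            tl,
            ab,
            cl,
        )
        fluence[wl] = tl * (power / (vol_cm3 * launched))
        absorbed_w[wl] = ab * (power / launched)
        cmap = phantom.class_map
        ledger[wl] = {
            "launched": launched,
            "escaped": escaped,
            "absorbed": float(cl.sum()),
            "roulette_gain": r_gain,
            "roulette_loss": r_loss,
            "absorbed_by_class": {
                cmap[i].name: float(cl[i]) for i in cmap if i < cl.size and cl[i] > 0
            },
            "n_photons": config.n_photons,
            "seed": config.rng_seed,
            "power_w": power,
        }
    return FluenceMap(
        fluence=fluence,
        absorbed_w=absorbed_w,
        ledger=ledger,
        voxel_size_um=phantom.voxel_size,
    )


def combine_fluence_maps(maps: list[FluenceMap]) -> FluenceMap:
    """Sum fluence maps from independent sources (fluence is additive).

    Ledgers are summed per wavelength so the energy audit stays exact for
    the combined run.
    """
    if not maps:
        raise ValueError("no fluence maps to combine")
    wavelengths = sorted({wl for m in maps for wl in m.fluence})
    shape = next(iter(maps[0].fluence.values())).shape
    fluence = {wl: np.zeros(shape) for wl in wavelengths}
    absorbed = {wl: np.zeros(shape) for wl in wavelengths}
    ledger = {
        wl: {
            "launched": 0.0,
            "escaped": 0.0,
            "absorbed": 0.0,
            "roulette_gain": 0.0,
            "roulette_loss": 0.0,
            "absorbed_by_class": {},
            "n_photons": 0,
            "seed": None,
            "power_w": 0.0,
        }
        for wl in wavelengths
    }
    for m in maps:
        for wl in m.fluence:
            fluence[wl] += m.fluence[wl]
            absorbed[wl] += m.absorbed_w[wl]
            led = ledger[wl]
            src = m.ledger[wl]
            for k in ("launched", "escaped", "absorbed", "roulette_gain",
                      "roulette_loss", "n_photons", "power_w"):
                led[k] += src[k]
            for name, v in src["absorbed_by_class"].items():
                led["absorbed_by_class"][name] = led["absorbed_by_class"].get(name, 0.0) + v
    return FluenceMap(
        fluence=fluence,
        absorbed_w=absorbed,
        ledger=ledger,
        voxel_size_um=maps[0].voxel_size_um,
    )
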