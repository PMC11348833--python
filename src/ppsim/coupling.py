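"""Self-consistent coupling of light transport and photoswitch kinetics.

The dissolved photodrug absorbs light, so the isomer composition perturbs
every voxel's absorption coefficient, which in turn changes the fluence
that drives the photochemistry.  ``coupled_solve`` iterates Monte Carlo
transport and photostationary-state chemistry to a fixed point of the
per-voxel Z fraction; ``time_marched_solve`` is the operator-splitting
variant for dynamics on the thermal-half-life scale.  The drug perturbs
absorption only — scattering by the dilute solute is neglected.

Each iteration runs the Monte Carlo as two half-batches with derived
seeds; the half-difference of the resulting Z-fraction fields estimates
the MC standard error, and a convergence tolerance below that noise floor
is refused (a fixed point cannot be certified tighter than the noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import LN10
from .phantom import TissuePhantom
from .photokinetics import ConcentrationField, PhotoswitchSpec, field_kinetics
from .sources import SourceSpec
from .transport import FluenceMap, RunConfig, combine_fluence_maps, run_mc


def drug_absorption(
    field: ConcentrationField, spec: PhotoswitchSpec, wavelength: float
) -> np.ndarray:
    """Per-voxel absorption added by the drug, Δμa = ln10·(ε_E·C_E + ε_Z·C_Z).

    ε in L mol⁻¹ cm⁻¹ and C in mol L⁻¹ give a decadic absorbance per cm;
    ln10 converts to the natural-log μa convention of the transport.
    """
    eps_e, eps_z, _, _ = spec.at(wavelength)
    return LN10 * (eps_e * field.c_e + eps_z * field.c_z)


@dataclass
class CoupledState:
    fluence: FluenceMap
    concentrations: ConcentrationField
    iteration: int
    metric: float
    converged: bool
    se_estimate: float = np.nan
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metric < 0:
            raise ValueError("convergence metric must be >= 0")


def _initial_field(
    c0: float | ConcentrationField, shape, spec: PhotoswitchSpec
) -> ConcentrationField:
    """Constant-concentration first approximation, in dark equilibrium."""
    if isinstance(c0, ConcentrationField):
        if c0.c_e.shape != tuple(shape):
            raise ValueError("initial field grid does not match the phantom")
        return ConcentrationField(c_e=c0.c_e.copy(), c_z=c0.c_z.copy())
    f_z_dark = 1.0 if spec.stable_isomer == "Z" else 0.0
    if np.isinf(spec.t_half_s):
        f_z_dark = 0.5  # P-type: no thermal preference; split evenly
    return ConcentrationField.uniform(shape, float(c0), f_z=f_z_dark)


def _mc_two_halves(phantom, source, config, extra, iteration):
    """Two half-batch runs with derived seeds; returns (combined, half_a, half_b)."""
    n_half = max(config.n_photons // 2, 1)
    half_cfg = RunConfig(
        n_photons=n_half,
        rng_seed=config.rng_seed,
        wavelengths=config.wavelengths,
        roulette_threshold=config.roulette_threshold,
        roulette_survival=config.roulette_survival,
        max_path_cm=config.max_path_cm,
    )
    salt_a = 2 * iteration + 1
    salt_b = 2 * iteration + 2
    sources = [source] if isinstance(source, SourceSpec) else list(source)
    fa = combine_fluence_maps(
        [
            run_mc(phantom, s, half_cfg, extra_mua=extra, seed_salt=salt_a + 1000 * k)
            for k, s in enumerate(sources)
        ]
    )
    fb = combine_fluence_maps(
        [
            run_mc(phantom, s, half_cfg, extra_mua=extra, seed_salt=salt_b + 1000 * k)
            for k, s in enumerate(sources)
        ]
    )
    combined_fluence = {}
    combined_absorbed = {}
    ledger = {}
    for wl in fa.wavelengths:
        combined_fluence[wl] = 0.5 * (fa.fluence[wl] + fb.fluence[wl])
        combined_absorbed[wl] = 0.5 * (fa.absorbed_w[wl] + fb.absorbed_w[wl])
        la, lb = fa.ledger[wl], fb.ledger[wl]
        ledger[wl] = {
            k: la[k] + lb[k]
            for k in ("launched", "escaped", "absorbed", "roulette_gain", "roulette_loss")
        }
        ledger[wl]["n_photons"] = la["n_photons"] + lb["n_photons"]
        ledger[wl]["seed"] = config.rng_seed
        ledger[wl]["power_w"] = la["power_w"]
        ledger[wl]["absorbed_by_class"] = {
            k: la["absorbed_by_class"].get(k, 0.0) + lb["absorbed_by_class"].get(k, 0.0)
            for k in set(la["absorbed_by_class"]) | set(lb["absorbed_by_class"])
        }
    combined = FluenceMap(
        fluence=combined_fluence,
        absorbed_w=combined_absorbed,
        ledger=ledger,
        voxel_size_um=fa.voxel_size_um,
    )
    return combined, fa, fb


def _fz_se_estimate(field_a, field_b, illuminated) -> float:
    """Median over illuminated voxels of the half-batch f_Z half-difference."""
    if not illuminated.any():
        return 0.0
    d = np.abs(field_a.f_z - field_b.f_z)[illuminated]
    return float(np.median(d) / 2.0)


def coupled_solve(
    phantom: TissuePhantom,
    source: SourceSpec,
    config: RunConfig,
    spec: PhotoswitchSpec,
    c0: float | ConcentrationField,
    tolerance: float = 1e-3,
    max_iter: int = 10,
) -> CoupledState:
    """Fixed point of stationary light + photostationary chemistry.

    Alternates Monte Carlo transport (tissue μa plus the drug's Δμa from
    the current composition) with the voxelwise photostationary state,
    until the maximum change in the Z fraction across voxels drops below
    ``tolerance`` or ``max_iter`` is reached.  The returned state carries
    an honest ``converged`` flag and the per-iteration metric history.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    conc = _initial_field(c0, phantom.dims, spec)
    fluence = None
    history: list[float] = []
    metric = np.inf
    converged = False
    se = np.nan
    iteration = 0
    for iteration in range(1, max_iter + 1):
        extra = {
            wl: drug_absorption(conc, spec, wl) for wl in config.wavelengths
        }
        fluence, fa, fb = _mc_two_halves(phantom, source, config, extra, iteration)
        new_conc = field_kinetics(conc, fluence, spec, pss=True)
        if iteration == 1:
            conc_a = field_kinetics(conc, fa, spec, pss=True)
            conc_b = field_kinetics(conc, fb, spec, pss=True)
            illuminated = sum(fluence.fluence[wl] for wl in fluence.wavelengths) > 0
            se = _fz_se_estimate(conc_a, conc_b, illuminated)
            if tolerance < se:
                raise ValueError(
                    f"tolerance {tolerance:g} is below the estimated MC noise "
                    f"floor of the Z fraction ({se:.3g}); increase n_photons "
                    "or relax the tolerance"
                )
        metric = float(np.max(np.abs(new_conc.f_z - conc.f_z)))
        history.append(metric)
        conc = new_conc
        if metric < tolerance:
            converged = True
            break
    return CoupledState(
        fluence=fluence,
        concentrations=conc,
        iteration=iteration,
        metric=metric,
        converged=converged,
        se_estimate=se,
        history=history,
    )


def time_marched_solve(
    phantom: TissuePhantom,
    source: SourceSpec,
    config: RunConfig,
    spec: PhotoswitchSpec,
    c0: float | ConcentrationField,
    dt: float,
    horizon: float,
    store_every: int = 1,
    step_doubling_check: bool = False,
    step_doubling_tol: float = 1e-2,
) -> list[CoupledState]:
    """Operator-splitting time integration of the coupled system.

    The fluence is frozen over each Δt (recomputed from the current
    composition at the start of the step), then the kinetics advance in
    closed form.  ``horizon=0`` returns the initial state only.  With
    ``step_doubling_check`` the run is repeated at Δt/2 and the final
    Z-fraction fields are compared; a deviation above
    ``step_doubling_tol`` raises, flagging a too-coarse Δt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    conc = _initial_field(c0, phantom.dims, spec)
    states: list[CoupledState] = [
        CoupledState(
            fluence=None, concentrations=conc, iteration=0, metric=0.0, converged=True
        )
    ]
    n_steps = int(round(horizon / dt))
    for step in range(1, n_steps + 1):
        extra = {wl: drug_absorption(conc, spec, wl) for wl in config.wavelengths}
        fluence, _, _ = _mc_two_halves(phantom, source, config, extra, step)
        conc = field_kinetics(conc, fluence, spec, t=dt)
        if step % store_every == 0 or step == n_steps:
            states.append(
                CoupledState(
                    fluence=fluence,
                    concentrations=conc,
                    iteration=step,
                    metric=0.0,
                    converged=True,
                )
            )
    if step_doubling_check and n_steps >= 1:
        fine = time_marched_solve(
            phantom, source, config, spec, c0, dt / 2.0, horizon,
            store_every=max(2 * n_steps, 1), step_doubling_check=False,
        )
        dev = float(
            np.max(np.abs(states[-1].concentrations.f_z - fine[-1].concentrations.f_z))
        )
        if dev > step_doubling_tol:
            raise RuntimeError(
                f"step-doubling check failed: halving dt moves the final Z "
                f"fraction by {dev:.3g} > {step_doubling_tol:g}"
            )
    return states
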